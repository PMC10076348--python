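"""TSV and FASTA input/output with validation and provenance headers.

All tables are UTF-8 tab-separated with '#'-prefixed comment lines; sequences
travel as 80-column-wrapped FASTA keyed by gene_id. Reserved assay tokens in
sample sheets: ``labeled``, ``steady_state``, ``nuclear``, ``chromatin``,
``whole_cell``.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

ASSAY_TOKENS = ("labeled", "steady_state", "nuclear", "chromatin", "whole_cell")


def read_counts(path) -> pd.DataFrame:
    """Read a gene x sample count matrix (first column gene_id, integer cells)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={0: str})
    df = df.set_index(df.columns[0])
    df.index.name = "gene_id"
    dup = df.index[df.index.duplicated()].unique()
    if len(dup):
        raise ValueError(f"duplicate gene ids: {list(dup)}")
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals != vals.round())
        if bad.any():
            row = df.index[bad][0]
            raise ValueError(f"non-integer count at gene {row!r}, sample {col!r}")
        if (vals < 0).any():
            row = df.index[vals < 0][0]
            raise ValueError(f"negative count at gene {row!r}, sample {col!r}")
    return df.astype("int64")


def write_counts(df: pd.DataFrame, path, provenance: list[str] | None = None) -> None:
    write_table(df.reset_index(), path, provenance)


def write_table(df: pd.DataFrame, path, provenance: list[str] | None = None) -> None:
    """Write a TSV with '#' provenance header lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in provenance or []:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def read_sample_sheet(path) -> pd.DataFrame:
    sheet = read_table(path)
    if "sample_id" not in sheet.columns:
        raise ValueError("sample sheet must have a sample_id column")
    sheet = sheet.set_index("sample_id")
    if "assay" in sheet.columns:
        bad = set(sheet["assay"]) - set(ASSAY_TOKENS)
        if bad:
            raise ValueError(f"unknown assay tokens: {sorted(bad)} "
                             f"(expected {ASSAY_TOKENS})")
    return sheet


def write_fasta(sequences: pd.Series, path) -> None:
    """Write gene_id-keyed sequences as 80-column-wrapped FASTA."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    records = [SeqRecord(Seq(s), id=str(g), description="")
               for g, s in sequences.items()]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def read_fasta_regions(paths: dict) -> pd.DataFrame:
    """Read region FASTAs ({'gene_body': path, 'cds': ..., 'utr3': ...}) into a table.

    Sequences are uppercased with U -> T; ids missing one region get NaN there
    and are flagged in the log (a gene without a CDS is excluded from codon
    features only, downstream).
    """
    series = {}
    for region, path in paths.items():
        recs = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            if rec.id in recs:
                raise ValueError(f"duplicate id {rec.id!r} in {path}")
            recs[rec.id] = str(rec.seq).upper().replace("U", "T")
        series[region] = pd.Series(recs, dtype=object)
    out = pd.DataFrame(series)
    out.index.name = "gene_id"
    missing = out.isna().any(axis=1)
    if missing.any():
        logger.warning("%d gene(s) missing at least one region; flagged",
                       int(missing.sum()))
    out["complete"] = ~missing
    return out


def config_hash(obj) -> str:
    """Stable short hash of a config mapping for provenance headers."""
    return hashlib.sha256(repr(obj).encode()).hexdigest()[:12]
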