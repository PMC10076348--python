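"""Spike-in, quantile and depth normalization, pseudoreplicates, small-RNA scaling.

Conventions for a labeling experiment:

* labeled pull-down samples are scaled by the sum of fly spike-in counts of
  the same sample (both the endogenous signal and the fly spike-ins are
  labeled, so the ratio reconstructs the labeled fraction up to one constant);
* steady-state samples are never spike-in normalized — they are depth
  normalized with median-of-ratios size factors;
* yeast spike-ins are a contamination QC readout only and are never used for
  scaling;
* quantile normalization across replicates of one genotype is applied before
  cross-genotype transcription-rate contrasts.

Every transformation appends to a ``provenance`` list on the result so the
chain of operations is auditable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class NormalizedCounts:
    """Gene x sample normalized values plus the ordered list of operations applied."""

    values: pd.DataFrame
    provenance: list[str] = field(default_factory=list)

    def record(self, step: str) -> "NormalizedCounts":
        self.provenance.append(step)
        return self


def fly_sums(spikeins: pd.DataFrame) -> pd.Series:
    """Total fly spike-in count per sample from a spike-in table with a 'kind' column."""
    fly = spikeins[spikeins["kind"] == "fly"]
    return fly.drop(columns="kind").sum(axis=0)


def yeast_contamination_qc(spikeins: pd.DataFrame, counts: pd.DataFrame) -> pd.Series:
    """Yeast read fraction per sample: reported as QC, never applied as scaling."""
    yeast = spikeins.loc[spikeins["kind"] == "yeast"].drop(columns="kind").sum(axis=0)
    total = counts.sum(axis=0) + spikeins.drop(columns="kind").sum(axis=0)
    return (yeast / total).rename("yeast_fraction")


def spikein_normalize(
    counts: pd.DataFrame,
    spikeins: pd.DataFrame,
    sample_sheet: pd.DataFrame,
) -> NormalizedCounts:
    """Divide labeled-sample counts by the fly spike-in sum of each sample.

    Steady-state (and any subcellular-fraction) samples are passed through
    unchanged; they are normalized by depth elsewhere. A labeled sample with
    zero fly spike-in counts is a hard error naming the sample.
    """
    fsum = fly_sums(spikeins)
    labeled = sample_sheet.index[sample_sheet["assay"] == "labeled"]
    missing = [s for s in labeled if s in counts.columns
               and (s not in fsum.index or fsum[s] <= 0)]
    if missing:
        raise ValueError(f"zero fly spike-in sum in labeled sample(s): {missing}")
    out = counts.astype(float).copy()
    cols = [s for s in labeled if s in out.columns]
    out[cols] = out[cols] / fsum[cols]
    return NormalizedCounts(out, [f"spikein_normalize(fly, samples={len(cols)})"])


def make_pseudoreplicate(
    counts: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    genotype: str | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Halve 1 h labeled samples into additional approximate 0.5 h replicates.

    The 1 h sample integrates twice as long a transcription window, so its
    counts divided by 2 approximate an extra 0.5 h replicate. The returned
    sample sheet marks these columns with ``pseudoreplicate=True`` — they
    share a plate with the true replicates and understate between-plate
    variance, so reports must carry the flag. A genotype without a 1 h sample
    simply contributes none (0.5 h-only mode).
    """
    sheet = sample_sheet.copy()
    if "pseudoreplicate" not in sheet.columns:
        sheet["pseudoreplicate"] = False
    tp = pd.to_numeric(sheet["timepoint_h"], errors="coerce")
    sel = (sheet["assay"] == "labeled") & (tp == 1.0)
    if genotype is not None:
        sel &= sheet["genotype"] == genotype
    new_counts = counts.copy()
    for sid in sheet.index[sel]:
        if sid not in counts.columns:
            continue
        pid = f"{sid}_pseudo05"
        new_counts[pid] = counts[sid] / 2.0
        row = sheet.loc[sid].copy()
        row["timepoint_h"] = 0.5
        row["pseudoreplicate"] = True
        sheet.loc[pid] = row
    return new_counts, sheet


def quantile_normalize(values: pd.DataFrame) -> NormalizedCounts:
    """Quantile-normalize columns to the across-column mean of sorted values.

    Each column's sorted values are replaced by the row means of the sorted
    matrix; ranks within a column are preserved and ties receive the average
    of the sorted reference values at their tied ranks. With a single column
    this is the identity (with a warning).
    """
    if values.shape[1] < 2:
        warnings.warn("quantile normalization needs >= 2 columns; returning input")
        return NormalizedCounts(values.astype(float).copy(), ["quantile_normalize(identity)"])
    arr = values.to_numpy(float)
    ref = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        ranks = stats.rankdata(arr[:, j], method="average") - 1.0
        out[:, j] = np.interp(ranks, np.arange(len(ref)), ref)
    return NormalizedCounts(
        pd.DataFrame(out, index=values.index, columns=values.columns),
        [f"quantile_normalize(cols={values.shape[1]})"],
    )


def quantile_normalize_within_genotype(
    values: pd.DataFrame, sample_sheet: pd.DataFrame
) -> NormalizedCounts:
    """Quantile-normalize the replicate columns of each genotype separately."""
    out = values.astype(float).copy()
    prov = []
    for genotype, sub in sample_sheet.groupby("genotype", sort=True):
        cols = [c for c in sub.index if c in out.columns]
        if len(cols) >= 2:
            out[cols] = quantile_normalize(out[cols]).values
        prov.append(f"quantile_normalize(genotype={genotype}, cols={len(cols)})")
    return NormalizedCounts(out, prov)


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors with geometric mean 1.

    For genes with nonzero counts in every sample, each sample's factor is
    the median ratio of its counts to the per-gene geometric mean. Falls back
    to total-count ratios (with a warning) when no gene is everywhere nonzero.
    """
    arr = counts.to_numpy(float)
    ok = np.all(arr > 0, axis=1)
    if not np.any(ok):
        warnings.warn("no gene with nonzero counts in all samples; "
                      "falling back to total-count size factors")
        tot = arr.sum(axis=0)
        f = tot / np.exp(np.mean(np.log(np.maximum(tot, 1e-300))))
    else:
        sub = arr[ok]
        geo = np.exp(np.mean(np.log(sub), axis=1, keepdims=True))
        f = np.median(sub / geo, axis=0)
        f = f / np.exp(np.mean(np.log(f)))
    return pd.Series(f, index=counts.columns, name="size_factor")


def small_rna_absolute_fc(
    counts: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    genotypes: tuple[str, str] | None = None,
) -> pd.DataFrame:
    """Scaled (ladder) and unscaled (depth) per-miRNA log2 fold-changes.

    ``counts`` must carry a ``kind`` column separating ``mirna`` rows from
    ``ladder`` spike-in rows. Unscaled fold-changes use median-of-ratios size
    factors over the miRNA rows (pure depth normalization); scaled
    fold-changes divide each sample by its ladder sum, anchoring abundance to
    the per-cell spike-in mass so global shifts survive. The precision of
    each fold-change is ``|log2FC| / SE(log2FC)``.
    """
    from .buffering import nb_log2fc  # local import to avoid a cycle

    if genotypes is None:
        gs = list(pd.unique(sample_sheet["genotype"]))  # sheet order: A then B
        if len(gs) != 2:
            raise ValueError("need exactly two genotypes")
        genotypes = (gs[0], gs[1])
    mat = counts.drop(columns="kind")
    mirna = mat[counts["kind"] == "mirna"]
    ladder = mat[counts["kind"] == "ladder"]
    lsum = ladder.sum(axis=0)
    if (lsum <= 0).any():
        raise ValueError(f"zero ladder sum in sample(s): {list(lsum.index[lsum <= 0])}")

    cols_a = [s for s in sample_sheet.index[sample_sheet["genotype"] == genotypes[0]]]
    cols_b = [s for s in sample_sheet.index[sample_sheet["genotype"] == genotypes[1]]]

    unscaled = nb_log2fc(mirna[cols_a], mirna[cols_b], size_factors=size_factors(mirna),
                         contrast="SS", min_counts=0)
    geo = np.exp(np.mean(np.log(lsum)))
    scaled = nb_log2fc(mirna[cols_a], mirna[cols_b], size_factors=lsum / geo,
                       contrast="SS", min_counts=0)
    out = pd.DataFrame({
        "log2fc_unscaled": unscaled.set_index("gene_id")["log2fc"],
        "log2fc_scaled": scaled.set_index("gene_id")["log2fc"],
        "lfcse_unscaled": unscaled.set_index("gene_id")["lfcse"],
        "lfcse_scaled": scaled.set_index("gene_id")["lfcse"],
    })
    out["precision_unscaled"] = out["log2fc_unscaled"].abs() / out["lfcse_unscaled"]
    out["precision_scaled"] = out["log2fc_scaled"].abs() / out["lfcse_scaled"]
    out.index.name = "gene_id"
    return out
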