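"""3'UTR motif enrichment for miRNA seeds and RBP k-mers.

Genes are grouped by the direction of their transcription-rate and half-life
changes, and each motif (a literal 6- or 7-mer, RNA alphabet transliterated
U -> T on ingestion) is tested for enrichment of gene-level hits (>= 1 exact
site in the 3'UTR) in a foreground set against the rest of its background set
with a two-sided Fisher exact test, BH-adjusted within each comparison. The
standard comparisons pair buffered foregrounds with their transcription
stratum: TR_down & HL_up vs TR_down, TR_up & HL_down vs TR_up, and the
half-life-only foregrounds TR_not & HL_down / TR_not & HL_up vs TR_not.
Motifs with few detected sites in both sets are removed by a site-count
filter whose threshold is chosen so the p-value histogram is enriched at 0
rather than bimodal.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


def load_motif_table(motifs: pd.DataFrame) -> pd.DataFrame:
    """Validate a motif table (motif_id, kmer, source[, conservation]); U -> T."""
    out = motifs.copy()
    out["kmer"] = out["kmer"].str.upper().str.replace("U", "T")
    bad = out["kmer"].str.contains("[^ACGT]", regex=True)
    if bad.any():
        raise ValueError(f"non-ACGT motifs: {list(out.loc[bad, 'motif_id'])}")
    return out


def count_sites(sequence: str, motif: str) -> int:
    """Number of (possibly overlapping) exact occurrences of motif in sequence."""
    n = 0
    start = sequence.find(motif)
    while start != -1:
        n += 1
        start = sequence.find(motif, start + 1)
    return n


def scan_motif_hits(
    utr3: pd.Series, motif_table: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Exact-match site counts of every motif in every 3'UTR.

    Returns (hits, counts): gene x motif boolean (>= 1 site) and integer
    site-count matrices. Sequences are uppercased; motifs are transliterated
    from RNA to DNA alphabet.
    """
    if len(motif_table) == 0:
        raise ValueError("empty motif set")
    table = load_motif_table(motif_table)
    seqs = utr3.str.upper().str.replace("U", "T")
    counts = {}
    for motif_id, kmer in zip(table["motif_id"], table["kmer"]):
        counts[motif_id] = np.fromiter((count_sites(s, kmer) for s in seqs),
                                       dtype=np.int64, count=len(seqs))
    counts_df = pd.DataFrame(counts, index=seqs.index)
    counts_df.index.name = "gene_id"
    return counts_df > 0, counts_df


@dataclass(frozen=True)
class Comparison:
    """One foreground/background gene-set comparison (foreground ⊆ background)."""

    comparison_id: str
    foreground: frozenset
    background: frozenset


def define_comparisons(direction_labels: pd.DataFrame) -> list[Comparison]:
    """Foreground/background gene sets from TR/HL direction labels.

    Expects the label table from ``assign_direction_labels`` (transite mode,
    TR threshold 0.5). Emits, where non-empty: buffered-down genes
    (TR_down & HL_up) against all TR_down genes, buffered-up genes
    (TR_up & HL_down) against TR_up, and the half-life-only foregrounds
    (TR_not & HL_down, TR_not & HL_up) against TR_not.
    """
    lab = direction_labels.set_index("gene_id")
    specs = [
        ("TRdown_HLup_vs_TRdown", ("down", "up"), "down"),
        ("TRup_HLdown_vs_TRup", ("up", "down"), "up"),
        ("TRnot_HLdown_vs_TRnot", ("not", "down"), "not"),
        ("TRnot_HLup_vs_TRnot", ("not", "up"), "not"),
    ]
    out = []
    for cid, (tr_lab, hl_lab), bg_tr in specs:
        fg = lab.index[(lab["tr_label"] == tr_lab) & (lab["hl_label"] == hl_lab)]
        bg = lab.index[lab["tr_label"] == bg_tr]
        if len(fg) == 0:
            warnings.warn(f"comparison {cid}: empty foreground, skipped")
            continue
        out.append(Comparison(cid, frozenset(fg), frozenset(bg)))
    return out


def enrichment_test(fg_hits: int, fg_n: int, bg_hits: int, bg_n: int) -> dict:
    """Two-sided Fisher exact test of gene-level hit membership, fg vs bg \\ fg.

    ``bg_*`` count the full background including the foreground; the 2x2
    table contrasts the foreground with the background excluding it. The
    enrichment is the sample odds ratio (infinite when the off-foreground
    hit rate is zero and the foreground rate is not).
    """
    rest_hits = bg_hits - fg_hits
    rest_n = bg_n - fg_n
    if rest_n <= 0:
        raise ValueError("background must strictly contain the foreground")
    table = [[fg_hits, fg_n - fg_hits], [rest_hits, rest_n - rest_hits]]
    _, pvalue = stats.fisher_exact(table, alternative="two-sided")
    a, b_, c, d = fg_hits, fg_n - fg_hits, rest_hits, rest_n - rest_hits
    if b_ == 0 or c == 0:
        odds = np.inf if a > 0 and d >= 0 else np.nan
    else:
        odds = (a / b_) / (c / d) if d > 0 else 0.0
    return {"fg_hits": fg_hits, "fg_n": fg_n, "bg_hits": bg_hits, "bg_n": bg_n,
            "enrichment": odds, "pvalue": float(pvalue)}


def run_enrichment(
    hits: pd.DataFrame,
    site_counts: pd.DataFrame,
    comparison: Comparison,
) -> pd.DataFrame:
    """Fisher tests for every motif in one comparison, BH-adjusted across motifs."""
    fg = hits.index.intersection(pd.Index(sorted(comparison.foreground)))
    bg = hits.index.intersection(pd.Index(sorted(comparison.background)))
    rows = []
    for motif in hits.columns:
        rec = enrichment_test(int(hits.loc[fg, motif].sum()), len(fg),
                              int(hits.loc[bg, motif].sum()), len(bg))
        rec["motif_id"] = motif
        rec["comparison_id"] = comparison.comparison_id
        rec["fg_sites"] = int(site_counts.loc[fg, motif].sum())
        rec["bg_sites"] = int(site_counts.loc[bg, motif].sum())
        rows.append(rec)
    out = pd.DataFrame(rows)
    out["padj"] = np.maximum(multipletests(out["pvalue"], method="fdr_bh")[1],
                             out["pvalue"])
    out["direction"] = np.where(out["enrichment"] >= 1.0, "enriched", "depleted")
    cols = ["motif_id", "comparison_id", "fg_hits", "fg_n", "bg_hits", "bg_n",
            "fg_sites", "bg_sites", "enrichment", "pvalue", "padj", "direction"]
    return out[cols]


def site_count_filter(
    records: pd.DataFrame, min_sites: int | None = None
) -> tuple[pd.DataFrame, dict]:
    """Drop motifs with too few detected sites; optionally pick the threshold.

    A motif is removed when both its foreground and background site totals
    are below ``min_sites``. When ``min_sites`` is None, the smallest
    threshold is chosen (per comparison set) such that the p-value histogram
    of the surviving motifs has no more mass in (0.9, 1] than in [0, 0.1] —
    an operational unimodality-at-zero requirement; if no threshold up to the
    90th percentile of site totals satisfies it, all records are kept with a
    flag. Returns (filtered records, diagnostic).
    """
    def mass_ok(sub: pd.DataFrame) -> bool:
        hi = ((sub["pvalue"] > 0.9) & (sub["pvalue"] <= 1.0)).mean()
        lo = (sub["pvalue"] <= 0.1).mean()
        return hi <= lo

    def apply(th: int) -> pd.DataFrame:
        drop = (records["fg_sites"] < th) & (records["bg_sites"] < th)
        return records[~drop]

    if min_sites is not None:
        filtered = apply(min_sites)
        return filtered, {"min_sites": min_sites, "chosen": False,
                          "n_removed": len(records) - len(filtered)}

    cap = int(records[["fg_sites", "bg_sites"]].max(axis=1).quantile(0.9)) + 1
    for th in range(0, cap + 1):
        sub = apply(th)
        if len(sub) and mass_ok(sub):
            return sub, {"min_sites": th, "chosen": True,
                         "n_removed": len(records) - len(sub)}
    warnings.warn("no site-count threshold achieves a p-value histogram "
                  "enriched at 0; keeping all motifs")
    return records, {"min_sites": 0, "chosen": False, "n_removed": 0, "failed": True}


def mirna_seed_fixture(n: int = 439, seed: int = 0) -> pd.DataFrame:
    """Synthetic stand-in for a miRNA-seed motif table (literal 7-mers).

    Emulates the shape of a TargetScan-style seed list — n rows of distinct
    7-mers with family conservation scores in {0, 1, 2} — without any real
    miRNA content; for use where only the table structure matters.
    """
    rng = np.random.default_rng(seed)
    kmers = set()
    while len(kmers) < n:
        kmers.add("".join(rng.choice(list("ACGT"), size=7)))
    kmers = sorted(kmers)
    return pd.DataFrame({
        "motif_id": [f"seed_{i:03d}" for i in range(n)],
        "kmer": kmers[:n],
        "source": "mirna_seed",
        "conservation": rng.integers(0, 3, size=n),
    })
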