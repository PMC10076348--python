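"""Fold-change contrasts and transcription-buffering categorization.

The ratio method decomposes a steady-state change into production and decay:
because Y_ss = alpha/beta and HL = ln2/beta,

    log2FC_SS = log2FC_TR + log2FC_HL,

so the half-life fold-change between genotypes is estimated as
``log2FC_SS - log2FC_TR`` with standard errors propagated under independence
(steady-state and labeled pull-down are disjoint samples). Genes are then
partitioned into

* ``TR_only``        — steady-state tracks the transcription change within 25%;
* ``full_buffered``  — significant TR change, no steady-state change, opposite
                       half-life change;
* ``partial_buffered`` — TR and SS change the same way but SS is attenuated by
                       an opposite half-life change;
* ``HL_only``        — half-life change with no transcription change;
* ``concordant``     — TR and HL move the same way (SS exceeds TR);
* ``unchanged``      — none of the above.

Fold-changes come from an in-repo negative-binomial Wald contrast
(method-of-moments dispersion); the pipeline only relies on the
(log2fc, lfcSE, padj) contract.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

FC_COLUMNS = ["gene_id", "contrast", "log2fc", "lfcse", "pvalue", "padj"]

DISPERSION_FLOOR = 1e-8


def nb_log2fc(
    counts_a: pd.DataFrame,
    counts_b: pd.DataFrame,
    size_factors: pd.Series | None = None,
    contrast: str = "SS",
    min_counts: int = 20,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Per-gene log2 fold-change (B vs A) with Wald SE from an NB model.

    Counts are divided by their sample size factors; the group means on the
    common scale give the fold-change (a pseudocount stabilizes the log of
    near-zero means). The per-gene NB dispersion is a method-of-moments
    estimate pooled over both groups and floored at 1e-8; the delta method
    converts the variance of each group mean into a log2-scale SE, and a
    normal Wald p-value is BH-adjusted across all tested genes. Genes whose
    total raw counts over both groups fall below ``min_counts`` are removed
    before testing.
    """
    if counts_a.shape[1] < 2 or counts_b.shape[1] < 2:
        raise ValueError("need >= 2 columns (replicates) per group")
    genes = counts_a.index
    if not genes.equals(counts_b.index):
        counts_b = counts_b.loc[genes]
    if size_factors is None:
        size_factors = pd.Series(1.0, index=list(counts_a.columns) + list(counts_b.columns))
    size_factors = size_factors[~size_factors.index.duplicated()]

    a = counts_a.to_numpy(float)
    b = counts_b.to_numpy(float)
    sa = size_factors.reindex(counts_a.columns).to_numpy(float)
    sb = size_factors.reindex(counts_b.columns).to_numpy(float)
    na, nb = a.shape[1], b.shape[1]

    keep = (a.sum(axis=1) + b.sum(axis=1)) >= min_counts
    a, b = a[keep], b[keep]
    an, bn = a / sa, b / sb
    qa, qb = an.mean(axis=1), bn.mean(axis=1)

    # method-of-moments NB dispersion pooled over both groups:
    # Var(c_j/s_j) = q/s_j + alpha * q^2
    var_a = an.var(axis=1, ddof=1)
    var_b = bn.var(axis=1, ddof=1)
    pois_a = qa * np.mean(1.0 / sa)
    pois_b = qb * np.mean(1.0 / sb)
    num = (na - 1) * (var_a - pois_a) + (nb - 1) * (var_b - pois_b)
    den = (na - 1) * qa**2 + (nb - 1) * qb**2
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(den > 0, num / den, 0.0)
    disp = np.maximum(disp, DISPERSION_FLOOR)

    var_qa = (qa * np.sum(1.0 / sa) + disp * qa**2 * na) / na**2
    var_qb = (qb * np.sum(1.0 / sb) + disp * qb**2 * nb) / nb**2

    eps_a = pseudocount / na
    eps_b = pseudocount / nb
    log2fc = np.log2(qb + eps_b) - np.log2(qa + eps_a)
    ln2sq = math.log(2.0) ** 2
    lfcse = np.sqrt(var_qa / ((qa + eps_a) ** 2 * ln2sq)
                    + var_qb / ((qb + eps_b) ** 2 * ln2sq))
    lfcse = np.maximum(lfcse, 1e-12)
    z = log2fc / lfcse
    pvalue = 2.0 * stats.norm.sf(np.abs(z))
    padj = multipletests(pvalue, method="fdr_bh")[1] if len(pvalue) else pvalue
    return pd.DataFrame({
        "gene_id": genes[keep],
        "contrast": contrast,
        "log2fc": log2fc,
        "lfcse": lfcse,
        "pvalue": pvalue,
        "padj": np.maximum(padj, pvalue),
    })


def ratio_half_life_fc(ss_records: pd.DataFrame, tr_records: pd.DataFrame) -> pd.DataFrame:
    """Half-life fold-change by the ratio method: ``log2FC_SS - log2FC_TR``.

    SEs add in quadrature (SS and TR come from disjoint samples); the Wald
    p-value uses the normal approximation and is BH-adjusted over the genes
    present in both inputs. Genes missing either contrast are skipped.
    """
    ss = ss_records.set_index("gene_id")
    tr = tr_records.set_index("gene_id")
    genes = ss.index.intersection(tr.index)
    log2fc = ss.loc[genes, "log2fc"] - tr.loc[genes, "log2fc"]
    lfcse = np.sqrt(ss.loc[genes, "lfcse"] ** 2 + tr.loc[genes, "lfcse"] ** 2)
    z = log2fc / lfcse
    pvalue = 2.0 * stats.norm.sf(np.abs(z))
    padj = multipletests(pvalue, method="fdr_bh")[1] if len(genes) else pvalue
    return pd.DataFrame({
        "gene_id": genes,
        "contrast": "HL",
        "log2fc": log2fc.to_numpy(),
        "lfcse": lfcse.to_numpy(),
        "pvalue": pvalue,
        "padj": np.maximum(padj, pvalue),
    })


def z_fc(log2fc_hl, lfcse_a, lfcse_b):
    """Fold-change z score: |log2FC_HL| / sqrt(lfcSE_A^2 + lfcSE_B^2).

    The pooled SE of the two genotype half-life estimates measures the
    accuracy of the half-life fold-change.
    """
    lfcse_a = np.asarray(lfcse_a, float)
    lfcse_b = np.asarray(lfcse_b, float)
    if np.any(lfcse_a <= 0) or np.any(lfcse_b <= 0):
        raise ValueError("standard errors must be positive")
    out = np.abs(np.asarray(log2fc_hl, float)) / np.sqrt(lfcse_a**2 + lfcse_b**2)
    return float(out) if out.ndim == 0 else out


_MODE_TR_THRESHOLDS = {"human": 1.0, "mouse": 0.1, "transite": 0.5}


def assign_direction_labels(
    tr_records: pd.DataFrame,
    hl_records: pd.DataFrame,
    mode: str = "human",
    sig: float = 0.1,
    hl_threshold: float = 1.0,
) -> pd.DataFrame:
    """Per-gene up/down/not labels for transcription rate and half-life.

    Human mode: TR up/down at |log2FC_TR| > 1 with padj < 0.1; HL up/down at
    |log2FC_HL| > 1 with Z_FC strictly above the median Z_FC of the genes
    entering the HL test. Mouse mode uses TR threshold ±0.1 (FDR < 0.1) and
    HL p-value below its 20th percentile. Transite mode (motif-enrichment
    group definitions) uses TR threshold ±0.5. All inequalities are strict.
    """
    if mode not in _MODE_TR_THRESHOLDS:
        raise ValueError(f"unknown mode {mode!r}; expected one of {sorted(_MODE_TR_THRESHOLDS)}")
    tr_thresh = _MODE_TR_THRESHOLDS[mode]
    tr = tr_records.set_index("gene_id")
    hl = hl_records.set_index("gene_id")
    genes = tr.index.union(hl.index)

    out = pd.DataFrame(index=genes)
    out.index.name = "gene_id"
    out["tr_label"] = "not"
    out["hl_label"] = "not"
    out["z_fc"] = np.nan

    tr_fc = tr["log2fc"].reindex(genes)
    tr_padj = tr["padj"].reindex(genes)
    out.loc[(tr_fc > tr_thresh) & (tr_padj < sig), "tr_label"] = "up"
    out.loc[(tr_fc < -tr_thresh) & (tr_padj < sig), "tr_label"] = "down"

    hl_fc = hl["log2fc"].reindex(genes)
    zfc = (hl["log2fc"].abs() / hl["lfcse"]).reindex(genes)
    out["z_fc"] = zfc
    if mode == "mouse":
        pv = hl["pvalue"].reindex(genes)
        cut = hl["pvalue"].quantile(0.2)
        conf = pv < cut
    else:
        conf = zfc > zfc.loc[hl.index].median()
    out.loc[(hl_fc > hl_threshold) & conf, "hl_label"] = "up"
    out.loc[(hl_fc < -hl_threshold) & conf, "hl_label"] = "down"
    return out.reset_index()


def categorize_buffering(
    tr_records: pd.DataFrame,
    ss_records: pd.DataFrame,
    hl_records: pd.DataFrame,
    labels: pd.DataFrame | None = None,
    sig: float = 0.1,
    tr_only_tolerance: float = 0.25,
    mode: str = "human",
) -> tuple[pd.DataFrame, pd.Series]:
    """Assign each gene to one buffering category (fixed rule precedence).

    Rules, applied in order ("significant" = padj < ``sig``):

    1. ``TR_only``: TR significant and |log2FC_SS - log2FC_TR| <
       ``tr_only_tolerance`` * |log2FC_TR| (steady state tracks transcription);
    2. ``full_buffered``: TR significant, SS not significant, HL estimate
       opposite-signed to TR;
    3. ``partial_buffered``: TR and SS significant, |SS| < |TR|, HL
       opposite-signed;
    4. ``HL_only``: TR not significant and the gene carries an HL direction
       label;
    5. ``concordant``: TR significant and HL direction label with the same
       sign as TR;
    6. ``unchanged`` otherwise.

    Returns (per-gene category table, category counts).
    """
    if labels is None:
        labels = assign_direction_labels(tr_records, hl_records, mode=mode, sig=sig)
    tr = tr_records.set_index("gene_id")
    ss = ss_records.set_index("gene_id")
    hl = hl_records.set_index("gene_id")
    lab = labels.set_index("gene_id")
    genes = tr.index.intersection(ss.index).intersection(hl.index)

    tr_fc = tr.loc[genes, "log2fc"].to_numpy()
    tr_sig = (tr.loc[genes, "padj"] < sig).to_numpy()
    ss_fc = ss.loc[genes, "log2fc"].to_numpy()
    ss_sig = (ss.loc[genes, "padj"] < sig).to_numpy()
    hl_fc = hl.loc[genes, "log2fc"].to_numpy()
    hl_lab = lab["hl_label"].reindex(genes).fillna("not").to_numpy()
    hl_lab_sign = np.where(hl_lab == "up", 1.0, np.where(hl_lab == "down", -1.0, 0.0))

    opposite = tr_fc * hl_fc < 0
    cat = np.full(len(genes), "unchanged", dtype=object)
    rule_tr_only = tr_sig & (np.abs(ss_fc - tr_fc) < tr_only_tolerance * np.abs(tr_fc))
    rule_full = tr_sig & ~ss_sig & opposite
    rule_partial = tr_sig & ss_sig & (np.abs(ss_fc) < np.abs(tr_fc)) & opposite
    rule_hl_only = ~tr_sig & (hl_lab != "not")
    rule_concordant = tr_sig & (hl_lab_sign * np.sign(tr_fc) > 0)
    for name, rule in (("TR_only", rule_tr_only), ("full_buffered", rule_full),
                       ("partial_buffered", rule_partial), ("HL_only", rule_hl_only),
                       ("concordant", rule_concordant)):
        cat[(cat == "unchanged") & rule] = name

    table = pd.DataFrame({"gene_id": genes, "category": cat})
    counts = table["category"].value_counts().sort_index()
    return table, counts


def mouse_proxy_half_life(
    wholecell_a: pd.DataFrame,
    wholecell_b: pd.DataFrame,
    fraction_a: pd.DataFrame,
    fraction_b: pd.DataFrame,
    fraction: str = "nuclear",
    min_counts: int = 20,
) -> pd.DataFrame:
    """Half-life proxy fold-change from whole-cell vs subcellular-fraction counts.

    Nuclear or chromatin-associated abundance proxies transcription rate, so
    the genotype x assay interaction — the whole-cell (steady-state) log2FC
    between genotypes minus the fraction (transcription-proxy) log2FC — is a
    relative half-life change. Implemented as the composite of two NB
    contrasts with SEs added in quadrature. Genes with summed counts below
    ``min_counts`` in either compared pair are removed first.
    """
    if fraction not in ("nuclear", "chromatin"):
        raise ValueError("fraction must be 'nuclear' or 'chromatin'")
    ss = nb_log2fc(wholecell_a, wholecell_b,
                   size_factors=size_factors_concat(wholecell_a, wholecell_b),
                   contrast="SS", min_counts=min_counts)
    trp = nb_log2fc(fraction_a, fraction_b,
                    size_factors=size_factors_concat(fraction_a, fraction_b),
                    contrast="TR_proxy", min_counts=min_counts)
    out = ratio_half_life_fc(ss, trp)
    out["contrast"] = f"HL_{fraction}_proxy"
    return out


def size_factors_concat(a: pd.DataFrame, b: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors computed jointly over two groups."""
    from .normalization import size_factors

    return size_factors(pd.concat([a, b], axis=1))


def batch_combined_proxy(
    wholecell: pd.DataFrame,
    fraction_counts: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    genotypes: tuple[str, str],
    fraction: str = "nuclear",
    min_counts: int = 20,
) -> pd.DataFrame:
    """Proxy half-life fold-change with batches combined by inverse variance.

    ``sample_sheet`` must carry genotype / assay / batch columns; the
    interaction contrast is computed within each batch (within-batch
    centering) and the batch estimates are inverse-variance averaged.
    """
    results = []
    for batch, sub in sample_sheet.groupby("batch"):
        def cols(assay, genotype):
            sel = sub.index[(sub["assay"] == assay) & (sub["genotype"] == genotype)]
            return [s for s in sel]

        wc_a, wc_b = cols("whole_cell", genotypes[0]), cols("whole_cell", genotypes[1])
        fr_a, fr_b = cols(fraction, genotypes[0]), cols(fraction, genotypes[1])
        if min(len(wc_a), len(wc_b), len(fr_a), len(fr_b)) < 2:
            raise ValueError(f"batch {batch!r}: unbalanced design with a missing cell")
        results.append(mouse_proxy_half_life(
            wholecell[wc_a], wholecell[wc_b],
            fraction_counts[fr_a], fraction_counts[fr_b],
            fraction=fraction, min_counts=min_counts,
        ).set_index("gene_id"))
    if len(results) == 1:
        combined = results[0]
    else:
        genes = results[0].index
        for r in results[1:]:
            genes = genes.intersection(r.index)
        w = np.column_stack([1.0 / r.loc[genes, "lfcse"] ** 2 for r in results])
        fc = np.column_stack([r.loc[genes, "log2fc"] for r in results])
        est = (w * fc).sum(axis=1) / w.sum(axis=1)
        se = np.sqrt(1.0 / w.sum(axis=1))
        pvalue = 2.0 * stats.norm.sf(np.abs(est / se))
        padj = multipletests(pvalue, method="fdr_bh")[1]
        combined = pd.DataFrame({
            "contrast": f"HL_{fraction}_proxy", "log2fc": est, "lfcse": se,
            "pvalue": pvalue, "padj": np.maximum(padj, pvalue),
        }, index=genes)
        combined.index.name = "gene_id"
    return combined.reset_index()
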