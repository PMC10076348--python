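"""End-to-end orchestration: normalize -> kinetics -> contrasts -> categorize
-> classify -> motifs, with a reproducible run manifest.

The human labeling workflow is:

1. divide labeled-sample counts by their fly spike-in sums (steady-state
   samples stay on the raw count scale and get median-of-ratios size factors);
2. halve each 1 h sample into a pseudo 0.5 h replicate;
3. quantile-normalize the 0.5 h replicate columns within each genotype;
4. transcription-rate (TR) contrast between genotypes on the 0.5 h values,
   steady-state (SS) contrast on the steady-state samples, and the ratio-method
   half-life fold-change log2FC_HL = log2FC_SS - log2FC_TR;
5. direction labels and buffering categories;
6. optional absolute half-lives by saturation-curve fitting with reliability
   filtering, sequence classifiers, and 3'UTR motif enrichment.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import buffering, classify, kinetics, motifs, normalization
from .io import config_hash, read_counts, read_fasta_regions, read_sample_sheet, read_table, write_table
from .simdata import LabelingExperiment

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths, thresholds and seed binding the stages into one run."""

    counts: str | None = None
    sample_sheet: str | None = None
    spikeins: str | None = None
    fasta_gene_body: str | None = None
    fasta_cds: str | None = None
    fasta_utr3: str | None = None
    motif_table: str | None = None
    mode: str = "human_rateseq"
    sig: float = 0.1
    tr_threshold: float = 1.0
    hl_threshold: float = 1.0
    min_counts: int = 20
    min_sites: int | None = None
    fraction: str = "nuclear"
    fit_saturation: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def validate_inputs(self) -> None:
        if self.mode not in ("human_rateseq", "mouse_proxy"):
            raise ValueError(f"unknown mode {self.mode!r}")
        for name in ("counts", "sample_sheet"):
            p = getattr(self, name)
            if p is None or not Path(p).exists():
                raise FileNotFoundError(f"required input {name!r} missing: {p}")
        if self.mode == "human_rateseq":
            if self.spikeins is None or not Path(self.spikeins).exists():
                raise FileNotFoundError("human_rateseq mode requires a spike-in table")


def transcription_rate_contrast(
    exp: LabelingExperiment,
    genotypes: tuple[str, str],
    use_pseudoreplicate: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame, normalization.NormalizedCounts]:
    """Spike-in + pseudoreplicate + quantile normalization, then the TR contrast.

    Returns (tr_records, sheet_with_pseudoreplicates, normalized values used).
    Normalized values are rescaled by the geometric-mean fly sum so they stay
    on a count-like scale for the NB contrast (a constant shared by all
    samples; fold-changes are unaffected).
    """
    norm = normalization.spikein_normalize(exp.counts, exp.spikeins, exp.sample_sheet)
    fsum = normalization.fly_sums(exp.spikeins)
    labeled = exp.sample_sheet.index[exp.sample_sheet["assay"] == "labeled"]
    scale = float(np.exp(np.mean(np.log(fsum[labeled]))))
    norm.values[labeled] = norm.values[labeled] * scale
    norm.record(f"rescale(geomean fly sum = {scale:.4g})")

    if use_pseudoreplicate:
        values, sheet = normalization.make_pseudoreplicate(norm.values, exp.sample_sheet)
        norm.record("pseudoreplicate(1h / 2 -> 0.5h)")
    else:
        values, sheet = norm.values, exp.sample_sheet.copy()
        norm.record("pseudoreplicate(disabled: 0.5h-only mode)")
    tp = pd.to_numeric(sheet["timepoint_h"], errors="coerce")
    early = sheet.index[(sheet["assay"] == "labeled") & (tp == 0.5)]
    qn = normalization.quantile_normalize_within_genotype(values[early], sheet.loc[early])
    values = values.copy()
    values[early] = qn.values
    norm.provenance += qn.provenance

    cols_a = [s for s in early if sheet.loc[s, "genotype"] == genotypes[0]]
    cols_b = [s for s in early if sheet.loc[s, "genotype"] == genotypes[1]]
    tr = buffering.nb_log2fc(values[cols_a], values[cols_b], contrast="TR", min_counts=0)
    return tr, sheet, normalization.NormalizedCounts(values, norm.provenance)


def steady_state_contrast(
    exp: LabelingExperiment, genotypes: tuple[str, str], min_counts: int = 20
) -> pd.DataFrame:
    """Depth-normalized NB contrast between genotypes on steady-state samples."""
    sheet = exp.sample_sheet
    ss_cols = sheet.index[sheet["assay"] == "steady_state"]
    sf = normalization.size_factors(exp.counts[ss_cols])
    cols_a = [s for s in ss_cols if sheet.loc[s, "genotype"] == genotypes[0]]
    cols_b = [s for s in ss_cols if sheet.loc[s, "genotype"] == genotypes[1]]
    return buffering.nb_log2fc(exp.counts[cols_a], exp.counts[cols_b],
                               size_factors=sf, contrast="SS", min_counts=min_counts)


def absolute_half_lives(
    exp: LabelingExperiment,
    normalized: pd.DataFrame,
    sheet: pd.DataFrame,
    seed: int = 0,
) -> dict:
    """Saturation fits per genotype + reliability filtering + global summaries."""
    fits = kinetics.fit_saturation_table(normalized, sheet, seed=seed)
    tp = pd.to_numeric(sheet["timepoint_h"], errors="coerce")
    early = sheet.index[(sheet["assay"] == "labeled") & (tp == 0.5)]
    tr_level = normalized[early].mean(axis=1) / 0.5
    ss_cols = sheet.index[sheet["assay"] == "steady_state"]
    sf = normalization.size_factors(exp.counts[ss_cols])
    ss_level = (exp.counts[ss_cols] / sf).mean(axis=1)
    reliable = kinetics.filter_reliable(fits, tr_level, ss_level)
    shift = kinetics.global_half_life_shift(fits, reliable, seed=seed)
    return {"saturation_fits": fits, "reliable_genes": reliable, "half_life_shift": shift}


def run_human_analysis(
    exp: LabelingExperiment,
    sequences: pd.DataFrame | None = None,
    motif_table: pd.DataFrame | None = None,
    config: PipelineConfig | None = None,
) -> dict:
    """The human labeling workflow on in-memory inputs; returns a result bundle."""
    cfg = config or PipelineConfig()
    genotypes = tuple(pd.unique(exp.sample_sheet["genotype"]))
    if len(genotypes) != 2:
        raise ValueError("expected exactly two genotypes")
    t_start = time.time()
    results: dict = {"genotypes": genotypes}
    stage_rows: dict[str, int] = {}

    tr, sheet, norm = transcription_rate_contrast(exp, genotypes)
    ss = steady_state_contrast(exp, genotypes, min_counts=cfg.min_counts)
    hl = buffering.ratio_half_life_fc(ss, tr)
    stage_rows["tr"] = len(tr)
    stage_rows["ss"] = len(ss)
    stage_rows["hl"] = len(hl)

    labels = buffering.assign_direction_labels(tr, hl, mode="human", sig=cfg.sig,
                                               hl_threshold=cfg.hl_threshold)
    categories, counts = buffering.categorize_buffering(tr, ss, hl, labels=labels,
                                                        sig=cfg.sig)
    results.update({
        "fold_changes": pd.concat([tr, ss, hl], ignore_index=True),
        "tr": tr, "ss": ss, "hl": hl,
        "direction_labels": labels,
        "categories": categories,
        "category_counts": counts,
        "normalized": norm,
        "qc_yeast_fraction": (normalization.yeast_contamination_qc(exp.spikeins, exp.counts)
                              if len(exp.spikeins) else None),
    })
    stage_rows["categories"] = len(categories)

    if cfg.fit_saturation:
        results.update(absolute_half_lives(exp, norm.values, sheet, seed=cfg.seed))
        stage_rows["saturation_fits"] = len(results["saturation_fits"])

    if sequences is not None:
        tr_dir = labels.set_index("gene_id")["tr_label"]
        tr_dir = tr_dir[tr_dir.isin(["up", "down"])]
        common = sequences.index.intersection(tr_dir.index)
        if tr_dir.loc[common].nunique() == 2 and len(common) >= 40:
            feats = classify.kmer_feature_matrix(sequences.loc[common, "gene_body"], 2)
            results["classifier_report"] = classify.train_direction_classifier(
                feats, tr_dir.loc[common], seed=cfg.seed, feature_set="2mers")
            stage_rows["classifier_genes"] = len(common)

    if sequences is not None and motif_table is not None:
        transite_labels = buffering.assign_direction_labels(tr, hl, mode="transite",
                                                            sig=cfg.sig)
        hits, site_counts = motifs.scan_motif_hits(sequences["utr3"], motif_table)
        comparisons = motifs.define_comparisons(transite_labels)
        enr = [motifs.run_enrichment(hits, site_counts, comp) for comp in comparisons]
        if enr:
            records = pd.concat(enr, ignore_index=True)
            filtered, diag = motifs.site_count_filter(records, cfg.min_sites)
            results["enrichment"] = filtered
            results["enrichment_diagnostic"] = diag
            stage_rows["enrichment_records"] = len(filtered)

    results["manifest"] = {
        "mode": "human_rateseq",
        "config_hash": config_hash(dataclasses.asdict(cfg)),
        "seed": cfg.seed,
        "genotypes": list(genotypes),
        "stage_rows": stage_rows,
        "elapsed_s": round(time.time() - t_start, 3),
    }
    return results


def run_mouse_proxy_analysis(
    exp: LabelingExperiment,
    config: PipelineConfig | None = None,
) -> dict:
    """Whole-cell vs nuclear/chromatin proxy workflow on in-memory inputs."""
    cfg = config or PipelineConfig(mode="mouse_proxy")
    sheet = exp.sample_sheet
    genotypes = tuple(pd.unique(sheet["genotype"]))
    assays = set(sheet["assay"])
    if cfg.fraction not in assays or "whole_cell" not in assays:
        raise ValueError(
            f"mouse_proxy mode requires whole_cell and {cfg.fraction!r} samples; "
            f"found assays {sorted(assays)}")

    if "batch" in sheet.columns and sheet["batch"].nunique() > 1:
        hl = buffering.batch_combined_proxy(exp.counts, exp.counts, sheet, genotypes,
                                            fraction=cfg.fraction,
                                            min_counts=cfg.min_counts)
    else:
        def cols(assay, genotype):
            return list(sheet.index[(sheet["assay"] == assay)
                                    & (sheet["genotype"] == genotype)])
        hl = buffering.mouse_proxy_half_life(
            exp.counts[cols("whole_cell", genotypes[0])],
            exp.counts[cols("whole_cell", genotypes[1])],
            exp.counts[cols(cfg.fraction, genotypes[0])],
            exp.counts[cols(cfg.fraction, genotypes[1])],
            fraction=cfg.fraction, min_counts=cfg.min_counts)

    def fc(assay):
        a = list(sheet.index[(sheet["assay"] == assay) & (sheet["genotype"] == genotypes[0])])
        b = list(sheet.index[(sheet["assay"] == assay) & (sheet["genotype"] == genotypes[1])])
        sf = normalization.size_factors(exp.counts[a + b])
        name = "SS" if assay == "whole_cell" else "TR"
        return buffering.nb_log2fc(exp.counts[a], exp.counts[b], size_factors=sf,
                                   contrast=name, min_counts=cfg.min_counts)

    tr_proxy = fc(cfg.fraction)
    ss = fc("whole_cell")
    labels = buffering.assign_direction_labels(tr_proxy, hl, mode="mouse", sig=cfg.sig,
                                               hl_threshold=cfg.hl_threshold)
    categories, counts = buffering.categorize_buffering(tr_proxy, ss, hl, labels=labels,
                                                        sig=cfg.sig, mode="mouse")
    return {
        "genotypes": genotypes, "hl": hl, "tr": tr_proxy, "ss": ss,
        "direction_labels": labels, "categories": categories,
        "category_counts": counts,
        "manifest": {"mode": "mouse_proxy", "fraction": cfg.fraction,
                     "config_hash": config_hash(dataclasses.asdict(cfg)),
                     "seed": cfg.seed},
    }


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """File-based entry point: load inputs, run the workflow, persist outputs."""
    config.validate_inputs()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts = read_counts(config.counts)
    sheet = read_sample_sheet(config.sample_sheet)
    spikeins = (pd.read_csv(config.spikeins, sep="\t", comment="#", index_col=0)
                if config.spikeins else pd.DataFrame({"kind": pd.Series(dtype=str)}))
    exp = LabelingExperiment(counts=counts, sample_sheet=sheet, spikeins=spikeins)

    sequences = None
    if config.fasta_gene_body and config.fasta_utr3:
        paths = {"gene_body": config.fasta_gene_body, "utr3": config.fasta_utr3}
        if config.fasta_cds:
            paths["cds"] = config.fasta_cds
        sequences = read_fasta_regions(paths)
    motif_table = read_table(config.motif_table) if config.motif_table else None

    if config.mode == "mouse_proxy":
        results = run_mouse_proxy_analysis(exp, config)
    else:
        results = run_human_analysis(exp, sequences, motif_table, config)

    prov = [f"config_hash={results['manifest']['config_hash']}"]
    write_table(results["fold_changes"] if "fold_changes" in results else results["hl"],
                out / "fold_changes.tsv", prov)
    write_table(results["categories"], out / "categories.tsv", prov)
    write_table(results["category_counts"].rename("n").reset_index(), out / "category_counts.tsv", prov)
    write_table(results["direction_labels"], out / "direction_labels.tsv", prov)
    if "saturation_fits" in results:
        write_table(results["saturation_fits"], out / "half_lives.tsv", prov)
        write_table(results["half_life_shift"], out / "half_life_shift.tsv", prov)
    if "enrichment" in results:
        write_table(results["enrichment"], out / "enrichment.tsv", prov)
    with open(out / "manifest.json", "w") as fh:
        json.dump(results["manifest"], fh, indent=2, default=str)
    return results
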