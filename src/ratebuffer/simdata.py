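"""Synthetic 4sU labeling experiments with known kinetic, sequence and motif truth.

Generates everything the downstream analysis consumes — count matrices with
spike-in ladders, gene regions (gene body / CDS / 3'UTR), and motif
annotations — from explicit ground truth, so every estimator in the pipeline
can be scored against the quantity it claims to recover.

The kinetic model is first-order turnover (dY/dt = alpha - beta*Y): labeled
RNA approaches steady state as Y_ss*(1 - exp(-beta*t)). Counts are negative
binomial around sampling-model expectations in which each library contains
labeled endogenous RNA, a fixed amount of labeled fly spike-in RNA (the
pull-down scaling control), unlabeled yeast RNA only through pull-down
contamination, and an ERCC-like concentration ladder. Sequences come from
first-order Markov chains whose transition matrices are tilted on a chosen
set of dinucleotides, so the direction signal a classifier should find has a
known, analytically calibrated Bayes accuracy.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

LN2 = math.log(2.0)

CATEGORIES = ("TR_only", "HL_only", "full_buffered", "partial_buffered",
              "concordant", "unchanged")

DEFAULT_PROPORTIONS = {
    "full_buffered": 0.15,
    "partial_buffered": 0.06,
    "HL_only": 0.10,
    "TR_only": 0.09,
    "concordant": 0.0,
    "unchanged": 0.60,
}

BASES = np.frombuffer(b"ACGT", dtype="S1").astype("U1")
DINUCLEOTIDES = tuple(a + b for a in "ACGT" for b in "ACGT")


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class SimConfig:
    """Design of a synthetic two-genotype 4sU labeling time course.

    ``depth`` is the expected total reads per sample; ``dispersion`` the NB
    inverse-size parameter shared by all genes (0 gives Poisson counts);
    ``tr_effect_log2`` / ``hl_effect_log2`` the planted |Δlog2| of
    transcription rate and degradation rate; ``partial_offset_fraction`` the
    share of a planted transcription shift that half-life offsets in
    partially buffered genes; ``median_half_life_h`` the genotype-A median
    half-life and ``global_hl_shift_log2`` an additional Δlog2 half-life
    applied to every genotype-B gene (global stabilization).
    """

    n_genes: int = 1000
    genotypes: tuple[str, str] = ("WT", "MUT")
    n_replicates: int = 2
    timepoints_h: tuple[float, ...] = (0.5, 1.0, 4.0, 8.0, 24.0)
    depth: float = 5e6
    dispersion: float = 0.02
    category_proportions: dict = field(default_factory=lambda: dict(DEFAULT_PROPORTIONS))
    tr_effect_log2: float = 2.0
    hl_effect_log2: float = 2.0
    partial_offset_fraction: float = 0.5
    median_half_life_h: float = 2.5
    global_hl_shift_log2: float = 0.0
    hl_sigma_ln: float = 0.5
    expr_sigma_ln: float = 1.0
    fly_fraction: float = 0.2
    contamination_fraction: float = 0.01
    depth_noise_sigma: float = 0.15
    beta_growth: float = 0.0
    linear_labeling: bool = False
    omit_1h_for: tuple[str, ...] = ()
    seed: int = 0

    def __post_init__(self):
        if self.n_genes <= 0 or self.n_replicates <= 0:
            raise ConfigurationError("n_genes and n_replicates must be positive")
        tp = tuple(self.timepoints_h)
        if any(t <= 0 for t in tp) or any(b <= a for a, b in zip(tp, tp[1:])):
            raise ConfigurationError("timepoints_h must be strictly increasing and positive")
        props = self.category_proportions
        unknown = set(props) - set(CATEGORIES)
        if unknown:
            raise ConfigurationError(f"unknown category labels: {sorted(unknown)}")
        if any(not 0.0 <= p <= 1.0 for p in props.values()):
            raise ConfigurationError("category proportions must be in [0, 1]")
        if abs(sum(props.values()) - 1.0) > 1e-9:
            raise ConfigurationError("category proportions must sum to 1")
        if self.dispersion < 0:
            raise ConfigurationError("dispersion must be >= 0")


def sample_gene_kinetics(cfg: SimConfig) -> pd.DataFrame:
    """Draw per-gene, per-genotype true kinetics with planted categories.

    Genotype-A degradation rates are lognormal with the configured median
    half-life; transcription rates are lognormal, drawn independently of
    beta; Y_ss = alpha / beta. Genotype B modifies (alpha, beta) per planted
    category with a random sign per gene:

    * ``TR_only`` — alpha shifted by ±tr_effect_log2, beta unchanged;
    * ``HL_only`` — beta shifted by ±hl_effect_log2, alpha unchanged;
    * ``full_buffered`` — alpha and beta shifted equally, so Y_ss is unchanged;
    * ``partial_buffered`` — beta offsets ``partial_offset_fraction`` of the
      alpha shift, leaving a same-signed but attenuated steady-state change;
    * ``concordant`` — alpha shifted and beta shifted the opposite way, so the
      steady-state change exceeds the transcription change;
    * ``unchanged`` — identical kinetics.

    Returns a tidy table with one row per gene per genotype:
    gene_id, genotype, alpha, beta, y_ss, half_life_h, category.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_genes
    gene_ids = np.array([f"g{i:05d}" for i in range(n)])

    # production and decay are mechanistically separate processes: alpha and
    # beta are drawn independently and the steady state is their ratio. (An
    # independent y_ss draw would make alpha proportional to beta, coupling
    # expression filters to half-life.)
    beta_a = LN2 / (cfg.median_half_life_h * np.exp(rng.normal(0.0, cfg.hl_sigma_ln, n)))
    alpha_a = 30.0 * np.exp(rng.normal(0.0, cfg.expr_sigma_ln, n))

    # exact planted counts, then a seeded shuffle
    labels = []
    for cat in CATEGORIES:
        labels.extend([cat] * int(round(cfg.category_proportions.get(cat, 0.0) * n)))
    while len(labels) < n:
        labels.append("unchanged")
    category = np.array(labels[:n])
    rng.shuffle(category)
    sign = rng.choice([-1.0, 1.0], size=n)

    d_alpha = np.zeros(n)  # Δlog2 alpha, B vs A
    d_beta = np.zeros(n)   # Δlog2 beta
    tr, hl = cfg.tr_effect_log2, cfg.hl_effect_log2
    f = cfg.partial_offset_fraction
    d_alpha[category == "TR_only"] = (sign * tr)[category == "TR_only"]
    d_beta[category == "HL_only"] = (sign * hl)[category == "HL_only"]
    m = category == "full_buffered"
    d_alpha[m], d_beta[m] = (sign * tr)[m], (sign * tr)[m]
    m = category == "partial_buffered"
    d_alpha[m], d_beta[m] = (sign * tr)[m], (sign * f * tr)[m]
    m = category == "concordant"
    d_alpha[m], d_beta[m] = (sign * tr)[m], (-sign * hl)[m]

    # a global half-life shift lowers every genotype-B beta
    d_beta = d_beta - cfg.global_hl_shift_log2

    alpha_b = alpha_a * 2.0 ** d_alpha
    beta_b = beta_a * 2.0 ** d_beta

    frames = []
    for genotype, alpha, beta in ((cfg.genotypes[0], alpha_a, beta_a),
                                  (cfg.genotypes[1], alpha_b, beta_b)):
        frames.append(pd.DataFrame({
            "gene_id": gene_ids,
            "genotype": genotype,
            "alpha": alpha,
            "beta": beta,
            "y_ss": alpha / beta,
            "half_life_h": LN2 / beta,
            "category": category,
        }))
    return pd.concat(frames, ignore_index=True)


@dataclass
class LabelingExperiment:
    """A simulated (or loaded) labeling experiment.

    ``counts`` is gene x sample (integers); ``sample_sheet`` is indexed by
    sample id with columns genotype / timepoint_h / assay / replicate;
    ``spikeins`` carries fly/yeast/ERCC species counts per sample with a
    ``kind`` column; ``truth`` is the kinetics truth table when simulated.
    """

    counts: pd.DataFrame
    sample_sheet: pd.DataFrame
    spikeins: pd.DataFrame
    truth: pd.DataFrame | None = None


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    mean = np.maximum(np.asarray(mean, dtype=float), 0.0)
    if np.any(~np.isfinite(mean)):
        raise RuntimeError("non-finite count expectation")
    if dispersion <= 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def simulate_labeling_counts(truth: pd.DataFrame, cfg: SimConfig) -> LabelingExperiment:
    """Draw NB counts for a pull-down time course plus steady-state samples.

    Each labeled library contains the labeled endogenous signal
    ``y_ss*(1 - exp(-beta*t))`` per gene, a fixed amount of labeled fly
    spike-in RNA, yeast RNA at ``contamination_fraction`` of the pull-down,
    and a small ERCC ladder spanning >= 4 orders of magnitude; reads are
    multinomial-like shares of ``depth`` (with lognormal per-sample depth
    noise), so dividing endogenous counts by the fly spike-in sum recovers
    the saturation curve up to one global constant. Steady-state samples are
    whole-cell: expectation proportional to y_ss, no fly or yeast species.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    geno_a = cfg.genotypes[0]

    # fly spike-in RNA is a transcriptome-scale pool; ERCC has 92 species
    n_fly, n_yeast, n_ercc = 300, 48, 92
    total_yss_a = float(truth.loc[truth["genotype"] == geno_a, "y_ss"].sum())
    fly_profile = np.sort(rng.dirichlet(np.full(n_fly, 2.0)))[::-1]
    fly_amount = cfg.fly_fraction * total_yss_a * fly_profile
    yeast_profile = rng.dirichlet(np.full(n_yeast, 2.0))
    ercc_amount = 1e-3 * total_yss_a * np.logspace(-2.2, 2.2, n_ercc)  # 4.4 decades

    gene_order = truth.loc[truth["genotype"] == geno_a, "gene_id"].to_numpy()
    counts: dict[str, np.ndarray] = {}
    spike: dict[str, np.ndarray] = {}
    sheet_rows = []

    for genotype in cfg.genotypes:
        sub = truth[truth["genotype"] == genotype].set_index("gene_id").loc[gene_order]
        y_ss = sub["y_ss"].to_numpy(float)
        beta = sub["beta"].to_numpy(float) + cfg.beta_growth
        for rep in range(1, cfg.n_replicates + 1):
            for t in cfg.timepoints_h:
                if t == 1.0 and genotype in cfg.omit_1h_for:
                    continue
                sid = f"{genotype}_t{t:g}_r{rep}"
                if cfg.linear_labeling:
                    signal = y_ss * beta * t
                else:
                    signal = y_ss * -np.expm1(-beta * t)
                pulldown = float(signal.sum()) + float(fly_amount.sum())
                yeast_amt = cfg.contamination_fraction * pulldown * yeast_profile
                lib = pulldown + float(yeast_amt.sum()) + float(ercc_amount.sum())
                d = cfg.depth * np.exp(rng.normal(0.0, cfg.depth_noise_sigma))
                counts[sid] = _nb_draw(rng, d * signal / lib, cfg.dispersion)
                spike[sid] = _nb_draw(
                    rng,
                    d * np.concatenate([fly_amount, yeast_amt, ercc_amount]) / lib,
                    cfg.dispersion,
                )
                sheet_rows.append({"sample_id": sid, "genotype": genotype,
                                   "timepoint_h": t, "assay": "labeled", "replicate": rep})
            sid = f"{genotype}_ss_r{rep}"
            lib = float(y_ss.sum()) + float(ercc_amount.sum())
            d = cfg.depth * np.exp(rng.normal(0.0, cfg.depth_noise_sigma))
            counts[sid] = _nb_draw(rng, d * y_ss / lib, cfg.dispersion)
            spike[sid] = _nb_draw(
                rng,
                d * np.concatenate([np.zeros(n_fly), np.zeros(n_yeast), ercc_amount]) / lib,
                cfg.dispersion,
            )
            sheet_rows.append({"sample_id": sid, "genotype": genotype,
                               "timepoint_h": np.nan, "assay": "steady_state",
                               "replicate": rep})

    counts_df = pd.DataFrame(counts, index=pd.Index(gene_order, name="gene_id"))
    spike_ids = ([f"fly_{i:02d}" for i in range(n_fly)]
                 + [f"yeast_{i:02d}" for i in range(n_yeast)]
                 + [f"ercc_{i:02d}" for i in range(n_ercc)])
    spike_df = pd.DataFrame(spike, index=pd.Index(spike_ids, name="spikein_id"))
    spike_df.insert(0, "kind", ["fly"] * n_fly + ["yeast"] * n_yeast + ["ercc"] * n_ercc)
    sheet = pd.DataFrame(sheet_rows).set_index("sample_id")
    return LabelingExperiment(counts=counts_df, sample_sheet=sheet,
                              spikeins=spike_df, truth=truth)


def simulate_experiment(cfg: SimConfig) -> LabelingExperiment:
    """Convenience: kinetics truth + counts in one call."""
    return simulate_labeling_counts(sample_gene_kinetics(cfg), cfg)


def simulate_fraction_experiment(
    truth: pd.DataFrame,
    cfg: SimConfig,
    fraction: str = "nuclear",
    n_replicates: int = 10,
    n_batches: int = 1,
) -> LabelingExperiment:
    """Whole-cell vs subcellular-fraction counts as a transcription-rate proxy.

    Whole-cell expectations are proportional to y_ss and fraction (nuclear or
    chromatin) expectations to alpha, so the genotype x assay interaction
    recovers the half-life fold-change without labeling. Replicates are
    assigned round-robin to batches; each batch gets its own lognormal
    depth tilt so batch structure is real. No spike-ins in this design.
    """
    if fraction not in ("nuclear", "chromatin"):
        raise ConfigurationError("fraction must be 'nuclear' or 'chromatin'")
    rng = np.random.default_rng(cfg.seed + 2)
    geno_a = cfg.genotypes[0]
    gene_order = truth.loc[truth["genotype"] == geno_a, "gene_id"].to_numpy()
    batch_tilt = np.exp(rng.normal(0.0, 0.1, size=n_batches))

    counts, sheet_rows = {}, []
    for genotype in cfg.genotypes:
        sub = truth[truth["genotype"] == genotype].set_index("gene_id").loc[gene_order]
        profiles = {"whole_cell": sub["y_ss"].to_numpy(float),
                    fraction: sub["alpha"].to_numpy(float)}
        for assay, prof in profiles.items():
            for rep in range(1, n_replicates + 1):
                batch = (rep - 1) % n_batches
                sid = f"{genotype}_{assay}_r{rep}"
                d = (cfg.depth * batch_tilt[batch]
                     * np.exp(rng.normal(0.0, cfg.depth_noise_sigma)))
                counts[sid] = _nb_draw(rng, d * prof / prof.sum(), cfg.dispersion)
                sheet_rows.append({"sample_id": sid, "genotype": genotype,
                                   "timepoint_h": np.nan, "assay": assay,
                                   "replicate": rep, "batch": f"b{batch}"})
    counts_df = pd.DataFrame(counts, index=pd.Index(gene_order, name="gene_id"))
    sheet = pd.DataFrame(sheet_rows).set_index("sample_id")
    spike = pd.DataFrame({"kind": pd.Series(dtype=str)})
    return LabelingExperiment(counts=counts_df, sample_sheet=sheet,
                              spikeins=spike, truth=truth)


# ---------------------------------------------------------------------------
# sequence generation: tilted first-order Markov chains
# ---------------------------------------------------------------------------

def _tilted_transition(planted: tuple[str, ...], tau: float) -> np.ndarray:
    """4x4 transition matrix with planted dinucleotides upweighted by exp(tau)."""
    idx = {b: i for i, b in enumerate("ACGT")}
    P = np.full((4, 4), 0.25)
    for d in planted:
        P[idx[d[0]], idx[d[1]]] *= math.exp(tau)
    return P / P.sum(axis=1, keepdims=True)


def _stationary(P: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eig(P.T)
    pi = np.real(v[:, np.argmin(np.abs(w - 1.0))])
    pi = np.abs(pi)
    return pi / pi.sum()


def _llr_matrix(planted, tau):
    up = _tilted_transition(planted, tau)
    down = _tilted_transition(planted, -tau)
    return np.log(up) - np.log(down), up, down


def _gaussian_accuracy(planted, tau: float, lengths, n_lags: int = 25) -> float:
    """Bayes accuracy of the per-sequence log-odds under a normal approximation.

    The log-odds is a sum of per-transition log-likelihood ratios along a
    Markov chain; its per-step mean and variance (including lag
    autocovariances) are computed exactly from the chain, and the accuracy is
    the two-class average of one-sided normal tail probabilities, averaged
    over the transition-count distribution ``lengths``.
    """
    lengths = np.atleast_1d(np.asarray(lengths, dtype=float))
    G, up, down = _llr_matrix(planted, tau)
    acc = 0.0
    for P, sgn in ((up, 1.0), (down, -1.0)):
        pi = _stationary(P)
        joint = pi[:, None] * P
        m = float((joint * G).sum())
        v = float((joint * G * G).sum()) - m * m
        # lag-k autocovariance: E[g_0 g_k] = sum_b w(b) [P^{k-1} h](b)
        # with w(b) the g-weighted arrival mass in b and h(a) = E[g-step | a]
        gout = (P * G).sum(axis=1)
        start = (pi[:, None] * P * G).sum(axis=0)
        cov_sum = 0.0
        Pk = np.eye(4)
        for _ in range(1, n_lags + 1):
            e_g0gk = float(start @ Pk @ gout)
            cov_sum += e_g0gk - m * m
            Pk = Pk @ P
        var_per_step = max(v + 2.0 * cov_sum, 1e-12)
        z = sgn * np.sqrt(lengths) * m / math.sqrt(var_per_step)
        acc += 0.5 * float(np.mean(stats.norm.cdf(z)))
    return float(acc)


def calibrate_tilt(planted: tuple[str, ...], bayes_accuracy: float, lengths) -> float:
    """Solve for the tilt giving a target Bayes accuracy over a length grid."""
    if not 0.5 < bayes_accuracy < 1.0:
        raise ConfigurationError("Bayes accuracy must be in (0.5, 1)")
    lo, hi = 1e-6, 3.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if _gaussian_accuracy(planted, mid, lengths) < bayes_accuracy:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _generate_markov(rng, P: np.ndarray, lengths: np.ndarray) -> list[str]:
    """Vectorized generation of sequences of varying length from one chain."""
    n = len(lengths)
    if n == 0:
        return []
    maxlen = int(lengths.max())
    cum = np.cumsum(P, axis=1)
    pi = _stationary(P)
    out = np.empty((n, maxlen), dtype=np.int8)
    state = rng.choice(4, size=n, p=pi)
    out[:, 0] = state
    for pos in range(1, maxlen):
        u = rng.random(n)
        state = (u[:, None] > cum[state]).sum(axis=1)
        out[:, pos] = state
    joined = ["".join(BASES[row[:L]]) for row, L in zip(out, lengths)]
    return joined


def sequence_log_odds(seq: str, planted: tuple[str, ...], tau: float) -> float:
    """Exact generating log-odds (up vs down) of one sequence — the oracle statistic."""
    G, _, _ = _llr_matrix(planted, tau)
    idx = {b: i for i, b in enumerate("ACGT")}
    a = np.fromiter((idx[c] for c in seq), dtype=np.int8)
    return float(G[a[:-1], a[1:]].sum())


@dataclass(frozen=True)
class SequenceConfig:
    """Parameters of the sequence generator (lengths in nucleotides).

    The default planted dinucleotides occupy three distinct preceding-base
    rows of the transition matrix. This matters for identifiability: rows of
    a stochastic matrix sum to one, so tilting a cell hands its row-mates an
    equal and opposite aggregate signal. With two planted dinucleotides in
    one row (say CA and CG), the complementary pair CC/CT carries the same
    combined information and complement triples genuinely tie or beat the
    planted triple in a combination search. With one planted dinucleotide
    per row, each row-mate carries only a third of the per-feature signal
    and the planted triple is uniquely the strongest subset.
    """

    planted_dinucleotides: tuple[str, str, str] = ("CA", "GC", "AT")
    bayes_accuracy: float = 0.85
    gene_body_length: tuple[int, int] = (1000, 3000)
    cds_length: tuple[int, int] = (300, 1500)
    utr3_length: tuple[int, int] = (200, 800)
    seed: int = 0

    def __post_init__(self):
        pl = self.planted_dinucleotides
        if len(set(pl)) != 3 or any(len(d) != 2 or set(d) - set("ACGT") for d in pl):
            raise ConfigurationError("planted_dinucleotides must be 3 distinct ACGT 2-mers")
        if len({d[0] for d in pl}) < 3:
            warnings.warn(
                "planted dinucleotides share a preceding-base row; the planted "
                "triple will not be uniquely identifiable in a combination "
                "search (row-mates carry an equal aggregate signal)")
        if not 0.5 < self.bayes_accuracy < 1.0:
            raise ConfigurationError("Bayes accuracy must be in (0.5, 1)")


def generate_sequences(directions: pd.Series, seq_cfg: SequenceConfig) -> pd.DataFrame:
    """Emit gene-body / CDS / 3'UTR sequences with a planted direction signal.

    ``directions`` maps gene_id -> 'up' / 'down' / 'none'. Gene bodies of
    up/down genes come from Markov chains tilted by ±tau on the planted
    dinucleotides, with tau calibrated so an oracle thresholding the true
    log-odds attains the configured Bayes accuracy at the mean gene-body
    length; 'none' genes use the untilted chain. Gene-body length is drawn
    independently of direction. CDS (length a multiple of 3) and 3'UTR are
    untilted. Returns gene_id-indexed columns gene_body / cds / utr3 /
    planted_direction plus the calibrated ``tau`` as ``.attrs['tau']``.
    """
    rng = np.random.default_rng(seq_cfg.seed)
    genes = directions.index.to_numpy()
    n = len(genes)
    lo, hi = seq_cfg.gene_body_length
    gb_len = rng.integers(lo, hi + 1, size=n)
    cds_len = (rng.integers(seq_cfg.cds_length[0] // 3, seq_cfg.cds_length[1] // 3 + 1,
                            size=n) * 3)
    utr_len = rng.integers(seq_cfg.utr3_length[0], seq_cfg.utr3_length[1] + 1, size=n)

    length_grid = np.arange(lo, hi + 1, dtype=float) - 1.0  # transition counts
    tau = calibrate_tilt(seq_cfg.planted_dinucleotides, seq_cfg.bayes_accuracy, length_grid)

    gb = np.empty(n, dtype=object)
    for label, t in (("up", tau), ("down", -tau), ("none", 0.0)):
        mask = directions.to_numpy() == label
        P = _tilted_transition(seq_cfg.planted_dinucleotides, t)
        gb[mask] = _generate_markov(rng, P, gb_len[mask])
    P0 = _tilted_transition(seq_cfg.planted_dinucleotides, 0.0)
    cds = _generate_markov(rng, P0, cds_len)
    utr = _generate_markov(rng, P0, utr_len)

    out = pd.DataFrame({
        "gene_body": gb,
        "cds": cds,
        "utr3": utr,
        "planted_direction": directions.to_numpy(),
    }, index=pd.Index(genes, name="gene_id"))
    out.attrs["tau"] = tau
    out.attrs["planted_dinucleotides"] = seq_cfg.planted_dinucleotides
    return out


def tr_directions_from_truth(truth: pd.DataFrame, genotypes: tuple[str, str]) -> pd.Series:
    """Per-gene planted transcription-rate direction ('up'/'down'/'none') from truth."""
    a = truth[truth["genotype"] == genotypes[0]].set_index("gene_id")["alpha"]
    b = truth[truth["genotype"] == genotypes[1]].set_index("gene_id")["alpha"]
    d = np.log2(b / a.loc[b.index])
    lab = pd.Series("none", index=b.index, name="planted_direction")
    lab[d > 1e-9] = "up"
    lab[d < -1e-9] = "down"
    return lab


def plant_motifs(
    sequences: pd.DataFrame,
    motif: str,
    fg_genes,
    fg_rate: float,
    bg_rate: float,
    seed: int = 0,
) -> pd.DataFrame:
    """Insert literal copies of a motif into 3'UTRs of foreground/background genes.

    Each foreground gene receives one in-place copy (overwriting ``len(motif)``
    bases at a uniform position) with probability ``fg_rate``; background genes
    with probability ``bg_rate``. Returns a copy of ``sequences`` with the
    edited ``utr3`` and a boolean ``planted_<motif>`` column.
    """
    if not 0.0 <= bg_rate <= fg_rate <= 1.0:
        raise ConfigurationError("need 0 <= bg_rate <= fg_rate <= 1")
    motif = motif.upper().replace("U", "T")
    min_len = sequences["utr3"].str.len().min()
    if len(motif) > min_len:
        raise ConfigurationError(
            f"motif length {len(motif)} exceeds shortest 3'UTR ({min_len} nt)")
    rng = np.random.default_rng(seed)
    fg = set(fg_genes)
    out = sequences.copy()
    planted = np.zeros(len(out), dtype=bool)
    utrs = out["utr3"].to_list()
    for i, (gene, utr) in enumerate(zip(out.index, utrs)):
        rate = fg_rate if gene in fg else bg_rate
        if rng.random() < rate:
            pos = int(rng.integers(0, len(utr) - len(motif) + 1))
            utrs[i] = utr[:pos] + motif + utr[pos + len(motif):]
            planted[i] = True
    out["utr3"] = utrs
    out[f"planted_{motif}"] = planted
    return out


# ---------------------------------------------------------------------------
# small-RNA simulation with an absolute spike-in ladder
# ---------------------------------------------------------------------------

def default_spikein_ladder(n: int = 52, lo: float = 0.5, hi: float = 5e4) -> pd.Series:
    """Expected counts of a small-RNA spike-in ladder spanning ~5 decades."""
    vals = np.logspace(math.log10(lo), math.log10(hi), n)
    return pd.Series(vals, index=[f"spike_{i:02d}" for i in range(n)], name="expected")


def simulate_small_rna(
    n_mirna: int,
    spikein_ladder: pd.Series | None = None,
    global_scale_B: float = 1.0,
    seed: int = 0,
    n_replicates: int = 2,
    dispersion: float = 0.05,
    relative_fc: np.ndarray | None = None,
    genotypes: tuple[str, str] = ("WT", "MUT"),
    depth_noise_sigma: float = 0.2,
):
    """Simulate a two-genotype small-RNA experiment with per-cell spike-ins.

    Genotype-B miRNA expectations are the genotype-A expectations times a
    per-miRNA relative fold-change times ``global_scale_B`` (a global,
    per-cell abundance change that depth normalization cannot see). Spike-in
    expectations are identical across genotypes because the ladder is added
    per cell. Every species in a sample shares that sample's lognormal
    library-size factor. Returns (counts, sample_sheet, truth) where counts
    stacks miRNA rows and ladder rows with a ``kind`` column.
    """
    if global_scale_B <= 0:
        raise ConfigurationError("global_scale_B must be positive")
    rng = np.random.default_rng(seed)
    ladder = default_spikein_ladder() if spikein_ladder is None else spikein_ladder
    base = 200.0 * np.exp(rng.normal(0.0, 1.5, n_mirna))
    rel = np.ones(n_mirna) if relative_fc is None else np.asarray(relative_fc, float)
    expect = {genotypes[0]: base, genotypes[1]: base * rel * global_scale_B}

    cols, rows_sheet = {}, []
    for genotype in genotypes:
        for rep in range(1, n_replicates + 1):
            sid = f"{genotype}_r{rep}"
            d = float(np.exp(rng.normal(0.0, depth_noise_sigma)))
            mu = np.concatenate([expect[genotype] * d, ladder.to_numpy() * d])
            cols[sid] = _nb_draw(rng, mu, dispersion)
            rows_sheet.append({"sample_id": sid, "genotype": genotype, "replicate": rep})
    ids = [f"mir_{i:04d}" for i in range(n_mirna)] + list(ladder.index)
    counts = pd.DataFrame(cols, index=pd.Index(ids, name="rna_id"))
    counts.insert(0, "kind", ["mirna"] * n_mirna + ["ladder"] * len(ladder))
    sheet = pd.DataFrame(rows_sheet).set_index("sample_id")
    truth = {"relative_fc": pd.Series(rel, index=ids[:n_mirna]),
             "global_scale_B": global_scale_B,
             "ladder_expected": ladder}
    return counts, sheet, truth
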