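"""First-order RNA labeling kinetics: saturation-curve fitting and half-life summaries.

The model is the approach-to-equilibrium solution of dY/dt = alpha - beta*Y with
Y(0) = 0:

    Y(t) = Y_ss * (1 - exp(-beta * t)),        Y_ss = alpha / beta,

where ``alpha`` is the transcription rate (normalized counts per hour), ``beta``
the first-order degradation rate (per hour) and ``Y_ss`` the steady-state
abundance. The half-life is ln(2)/beta: the time for labeled RNA to reach half
of its steady-state level.

This module provides

* :func:`saturation_fraction` — the labeled fraction 1 - exp(-beta*t);
* :func:`fit_saturation_curve` — two-pass weighted nonlinear least squares for
  (Y_ss, beta) with asymptotic (and optional profile) confidence intervals;
* :func:`transcription_rate` — the early-time-point slope estimate of alpha;
* :func:`fit_actd_decay` — log-linear decay fit for transcription-inhibition
  (actinomycin D) time courses;
* :func:`filter_reliable` / :func:`global_half_life_shift` — reliability
  filtering and genotype-level half-life summaries.

Time is in hours throughout; rates are per hour.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)

LN2 = math.log(2.0)

# optimizer box constraints for the degradation rate (per hour)
BETA_MIN = 1e-4
BETA_MAX = 50.0



def half_life_from_beta(beta: float | np.ndarray) -> float | np.ndarray:
    """Half-life in hours from a first-order degradation rate (per hour)."""
    return LN2 / beta


def beta_from_half_life(half_life_h: float | np.ndarray) -> float | np.ndarray:
    """Degradation rate (per hour) from a half-life in hours."""
    return LN2 / half_life_h


def saturation_fraction(t, beta):
    """Fraction of steady-state reached by time ``t`` under first-order turnover.

    Parameters
    ----------
    t : float or array
        Labeling time in hours, ``t >= 0``.
    beta : float or array
        Degradation rate per hour, ``beta > 0``.

    Returns
    -------
    float or ndarray
        ``1 - exp(-beta * t)``, in ``[0, 1)``.
    """
    t = np.asarray(t, dtype=float)
    beta_arr = np.asarray(beta, dtype=float)
    if np.any(t < 0):
        raise ValueError("labeling time t must be non-negative")
    if np.any(beta_arr <= 0):
        raise ValueError("degradation rate beta must be positive")
    out = -np.expm1(-beta_arr * t)
    if out.ndim == 0:
        return float(out)
    return out


@dataclass
class SaturationFit:
    """Result of a two-pass saturation-curve fit for one gene in one genotype."""

    gene_id: str
    genotype: str
    y_ss_hat: float
    beta_hat: float
    half_life_h: float
    se_beta: float
    se_y_ss: float
    ci50: tuple[float, float]
    ci95: tuple[float, float]
    ci50_width_h: float
    converged: bool
    n_points: int
    message: str = ""

    def as_row(self) -> dict:
        return {
            "gene_id": self.gene_id,
            "genotype": self.genotype,
            "y_ss_hat": self.y_ss_hat,
            "beta_hat": self.beta_hat,
            "half_life_h": self.half_life_h,
            "se_beta": self.se_beta,
            "se_y_ss": self.se_y_ss,
            "ci50_lo": self.ci50[0],
            "ci50_hi": self.ci50[1],
            "ci95_lo": self.ci95[0],
            "ci95_hi": self.ci95[1],
            "ci50_width_h": self.ci50_width_h,
            "converged": self.converged,
            "n_points": self.n_points,
        }


def _model(t: np.ndarray, y_ss: float, beta: float) -> np.ndarray:
    return y_ss * -np.expm1(-beta * t)


def _fit_once(t, y, weights, y_ss0, beta0):
    """One bounded least-squares pass; returns (params, cov, cost) or raises."""
    sw = np.sqrt(weights)

    def resid(p):
        return sw * (_model(t, p[0], p[1]) - y)

    def jac(p):
        sat = -np.expm1(-p[1] * t)
        d_yss = sat
        d_beta = p[0] * t * np.exp(-p[1] * t)
        return sw[:, None] * np.column_stack([d_yss, d_beta])

    res = optimize.least_squares(
        resid,
        x0=[y_ss0, beta0],
        jac=jac,
        bounds=([1e-12, BETA_MIN], [np.inf, BETA_MAX]),
        method="trf",
        x_scale=[max(y_ss0, 1e-6), max(beta0, 1e-3)],
    )
    if not res.success:
        raise RuntimeError(res.message)
    # heteroscedasticity-robust (HC3 sandwich) asymptotic covariance: the 1/Y
    # working weights understate the variance growth of overdispersed counts,
    # so (J'J)^-1 scaled by residual variance would undercover
    J, r = res.jac, res.fun
    try:
        bread = np.linalg.inv(J.T @ J)
        lev = np.clip(np.einsum("ij,jk,ik->i", J, bread, J), 0.0, 0.99)
        meat = J.T @ ((r**2 / (1.0 - lev) ** 2)[:, None] * J)
        cov = bread @ meat @ bread
    except np.linalg.LinAlgError:
        cov = np.full((2, 2), np.inf)
    return res.x, cov, res.cost


def fit_saturation_curve(
    timepoints_h,
    values,
    gene_id: str = "",
    genotype: str = "",
    max_restarts: int = 5,
    seed: int = 0,
    profile_ci: bool = False,
) -> SaturationFit:
    """Fit ``Y(t) = Y_ss (1 - exp(-beta t))`` by two-pass weighted least squares.

    Pass 1 is unweighted; pass 2 reweights each observation by ``1 / Y_hat(t)``
    from the pass-1 curve, correcting for the count-like increase of variance
    with the mean. Asymptotic 50% and 95% confidence intervals for ``beta`` are
    transformed monotonically to half-life intervals. With ``profile_ci=True``
    the 95% interval is replaced by a likelihood-profile interval.

    Parameters
    ----------
    timepoints_h : array
        Hours of each observation (replicates repeat time values).
    values : array
        Normalized labeled counts, same length.
    """
    t = np.asarray(timepoints_h, dtype=float)
    y = np.asarray(values, dtype=float)
    mask = np.isfinite(t) & np.isfinite(y)
    t, y = t[mask], y[mask]
    n = len(t)
    nan_fit = SaturationFit(
        gene_id, genotype, math.nan, math.nan, math.nan, math.nan, math.nan,
        (math.nan, math.nan), (math.nan, math.nan), math.nan, False, n,
    )
    if len(np.unique(t)) < 3 or not np.any(y > 0):
        nan_fit.message = "needs >= 3 distinct time points with a positive value"
        return nan_fit

    y_ss0 = max(float(np.max(y)), 1e-9)
    # invert the saturation fraction at the earliest time point for beta0
    t0 = float(np.min(t[t > 0])) if np.any(t > 0) else 0.5
    frac0 = float(np.clip(np.mean(y[t == np.min(t[t > 0])]) / y_ss0, 1e-4, 0.95))
    beta0 = float(np.clip(-math.log1p(-frac0) / t0, BETA_MIN * 2, BETA_MAX / 2))

    rng = np.random.default_rng(seed)
    params = None
    message = ""
    for attempt in range(max_restarts + 1):
        if attempt == 0:
            y0, b0 = y_ss0, beta0
        else:
            y0 = y_ss0 * float(rng.lognormal(0.0, 0.5))
            b0 = float(np.clip(beta0 * rng.lognormal(0.0, 0.7), BETA_MIN * 2, BETA_MAX / 2))
        try:
            p1, _, _ = _fit_once(t, y, np.ones(n), y0, b0)
            yhat = _model(t, *p1)
            w = 1.0 / np.maximum(yhat, 1e-6 * max(float(np.max(yhat)), 1e-300))
            p2, cov, _ = _fit_once(t, y, w, p1[0], p1[1])
            params = (p2, cov)
            break
        except (RuntimeError, ValueError) as exc:  # jittered restart
            message = str(exc)
            continue
    if params is None:
        nan_fit.message = f"no convergence after {max_restarts} restarts: {message}"
        return nan_fit

    (y_ss_hat, beta_hat), cov = params
    se_y_ss = float(np.sqrt(max(cov[0, 0], 0.0)))
    se_beta = float(np.sqrt(max(cov[1, 1], 0.0)))

    dof = max(n - 2, 1)
    t50, t95 = stats.t.ppf(0.75, dof), stats.t.ppf(0.975, dof)
    if profile_ci:
        b_lo95, b_hi95 = _profile_beta_ci(t, y, y_ss_hat, beta_hat, level=0.95)
    else:
        b_lo95 = beta_hat - t95 * se_beta
        b_hi95 = beta_hat + t95 * se_beta
    b_lo50 = beta_hat - t50 * se_beta
    b_hi50 = beta_hat + t50 * se_beta

    def hl_interval(b_lo, b_hi):
        hi = LN2 / max(b_lo, BETA_MIN) if b_lo > 0 else math.inf
        lo = LN2 / max(b_hi, BETA_MIN)
        return (lo, hi)

    ci50 = hl_interval(b_lo50, b_hi50)
    ci95 = hl_interval(b_lo95, b_hi95)
    width50 = ci50[1] - ci50[0] if math.isfinite(ci50[1]) else math.inf
    # a fit pinned at the beta upper bound means the curve was saturated
    # before the first time point: not a convergent rate estimate
    converged = bool(beta_hat < BETA_MAX * 0.999 and se_beta > 0 and math.isfinite(se_beta))
    return SaturationFit(
        gene_id, genotype, float(y_ss_hat), float(beta_hat),
        LN2 / beta_hat, se_beta, se_y_ss, ci50, ci95, width50, converged, n,
    )


def _profile_beta_ci(t, y, y_ss_hat, beta_hat, level=0.95):
    """Likelihood-profile CI for beta: refit y_ss at fixed beta on a grid."""
    w = 1.0 / np.maximum(_model(t, y_ss_hat, beta_hat), 1e-12)

    def sse_at(beta):
        sat = -np.expm1(-beta * t)
        denom = float(np.sum(w * sat * sat))
        yss = float(np.sum(w * sat * y)) / denom if denom > 0 else 0.0
        r = y - yss * sat
        return float(np.sum(w * r * r))

    sse0 = sse_at(beta_hat)
    dof = max(len(t) - 2, 1)
    crit = sse0 * (1.0 + stats.f.ppf(level, 1, dof) / dof)

    def bracket(direction):
        b = beta_hat
        step = beta_hat * 0.05
        for _ in range(200):
            b_next = b + direction * step
            if b_next <= BETA_MIN or b_next >= BETA_MAX:
                return BETA_MIN if direction < 0 else BETA_MAX
            if sse_at(b_next) > crit:
                return optimize.brentq(lambda x: sse_at(x) - crit, min(b, b_next), max(b, b_next))
            b = b_next
            step *= 1.5
        return BETA_MIN if direction < 0 else BETA_MAX

    return bracket(-1.0), bracket(+1.0)


def fit_saturation_table(
    normalized: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    seed: int = 0,
    profile_ci: bool = False,
) -> pd.DataFrame:
    """Fit every gene in every genotype of a labeling time course.

    ``normalized`` is gene x sample; ``sample_sheet`` (indexed by sample id)
    must carry ``genotype`` and numeric ``timepoint_h`` for labeled samples
    (steady-state / fraction samples are ignored here).
    """
    sheet = sample_sheet.copy()
    tp = pd.to_numeric(sheet["timepoint_h"], errors="coerce")
    labeled = sheet.index[tp.notna()]
    rows = []
    for genotype, sub in sheet.loc[labeled].groupby("genotype", sort=True):
        cols = [c for c in sub.index if c in normalized.columns]
        t = pd.to_numeric(sheet.loc[cols, "timepoint_h"]).to_numpy(float)
        vals = normalized[cols].to_numpy(float)
        for i, gene in enumerate(normalized.index):
            fit = fit_saturation_curve(
                t, vals[i], gene_id=str(gene), genotype=str(genotype),
                seed=seed, profile_ci=profile_ci,
            )
            rows.append(fit.as_row())
    return pd.DataFrame(rows)


@dataclass
class TranscriptionRate:
    """Early-time-point (slope) transcription-rate estimate for one gene."""

    gene_id: str
    genotype: str
    alpha_hat: float
    replicates_used: list[str] = field(default_factory=list)
    has_pseudoreplicate: bool = False


def transcription_rate(
    values_05h,
    gene_id: str = "",
    genotype: str = "",
    sample_ids=None,
    pseudoreplicate_flags=None,
    t_h: float = 0.5,
) -> TranscriptionRate:
    """Transcription rate from labeled abundance at the earliest time point.

    The slope of the saturation curve at t -> 0 equals alpha, so with
    degradation neglected over the first half hour,
    ``alpha_hat = mean(Y(0.5 h)) / 0.5`` per hour. Any pseudoreplicate
    (halved 1 h sample) is included in the mean and flagged in the result.
    The estimate is biased low by the factor ``(1 - exp(-beta t)) / (beta t)``
    for genes whose decay is not negligible by ``t``.
    """
    vals = np.asarray(values_05h, dtype=float)
    if vals.size == 0:
        raise ValueError("at least one replicate at the early time point is required")
    ids = list(sample_ids) if sample_ids is not None else [f"rep{i}" for i in range(vals.size)]
    flags = list(pseudoreplicate_flags) if pseudoreplicate_flags is not None else [False] * vals.size
    return TranscriptionRate(
        gene_id=gene_id,
        genotype=genotype,
        alpha_hat=float(np.mean(vals)) / t_h,
        replicates_used=ids,
        has_pseudoreplicate=any(flags),
    )


def slope_alpha_bias(beta: float | np.ndarray, t: float) -> float | np.ndarray:
    """Multiplicative bias of the slope transcription-rate estimate.

    In the noiseless limit the slope method returns
    ``alpha * (1 - exp(-beta t)) / (beta t)``; this returns that factor.
    """
    bt = np.asarray(beta, dtype=float) * t
    out = -np.expm1(-bt) / bt
    return float(out) if out.ndim == 0 else out


@dataclass
class ActdDecayFit:
    """Transcription-inhibition decay fit: log2 fold-change vs time through the origin."""

    slope: float
    se_slope: float
    half_life_h: float
    ci95: tuple[float, float]
    beta: float
    ok: bool
    message: str = ""


def fit_actd_decay(timepoints_h, log2_fold_changes) -> ActdDecayFit:
    """Half-life from a transcription-inhibition (actinomycin D) time course.

    Fits the no-intercept line ``log2FC = m * t`` by least squares. On the
    log2 scale the decay slope is ``m = -1 / HL``, so ``HL = -1/m`` hours and
    ``beta = -m * ln 2`` per hour. The half-life CI comes from the slope CI.
    """
    t = np.asarray(timepoints_h, dtype=float)
    y = np.asarray(log2_fold_changes, dtype=float)
    if len(t) < 2 or np.all(t <= 0):
        raise ValueError("need at least 2 positive time points")
    st2 = float(np.sum(t * t))
    m = float(np.sum(t * y)) / st2
    resid = y - m * t
    dof = max(len(t) - 1, 1)
    se = math.sqrt(float(np.sum(resid**2)) / dof / st2)
    tcrit = stats.t.ppf(0.975, dof)
    m_lo, m_hi = m - tcrit * se, m + tcrit * se
    if m >= 0:
        return ActdDecayFit(m, se, math.nan, (math.nan, math.nan), math.nan,
                            ok=False, message="non-negative slope: no decay detected")
    hl = -1.0 / m
    # monotone transform of the slope interval; an interval crossing 0 is open above
    hl_hi = -1.0 / m_hi
    hl_lo = -1.0 / m_lo if m_lo < 0 else math.inf
    return ActdDecayFit(m, se, hl, (min(hl_hi, hl_lo), max(hl_hi, hl_lo)), -m * LN2, ok=True)


def filter_reliable(
    fits: pd.DataFrame,
    tr: pd.Series,
    ss: pd.Series,
    tr_quantile: float = 0.10,
    ss_quantile: float = 0.10,
    max_ci_ratio: float = 0.75,
) -> pd.Index:
    """Reliable gene set for absolute half-life summaries.

    Keeps genes whose transcription rate and steady-state abundance both lie
    above their bottom-10% quantiles and whose 50% CI width is less than
    ``max_ci_ratio`` of the half-life estimate. ``fits`` must carry
    ``gene_id``, ``half_life_h``, ``ci50_width_h`` and ``converged``;
    quantiles are taken over the genes present in ``tr`` / ``ss``.
    """
    tr_cut = tr.quantile(tr_quantile)
    ss_cut = ss.quantile(ss_quantile)
    ok_expr = (tr > tr_cut) & (ss > ss_cut)
    by_gene = fits.set_index("gene_id")
    genes = by_gene.index.intersection(ok_expr.index[ok_expr])
    sub = by_gene.loc[genes]
    ratio = sub["ci50_width_h"] / sub["half_life_h"]
    keep = sub.index[(ratio < max_ci_ratio) & sub["converged"].astype(bool)]
    keep = pd.Index(pd.unique(keep))
    if len(keep) == 0:
        warnings.warn("no gene passed the reliability filters; summaries will be suppressed")
    return keep


def global_half_life_shift(
    fits: pd.DataFrame,
    reliable_genes: pd.Index | None = None,
    min_genes: int = 100,
    n_boot: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean and median half-life per genotype over the reliable gene set.

    Returns one row per genotype with bootstrap 95% CIs for both statistics
    and a ``low_n`` flag when fewer than ``min_genes`` genes contribute.
    """
    sub = fits[fits["converged"].astype(bool)]
    if reliable_genes is not None:
        sub = sub[sub["gene_id"].isin(reliable_genes)]
    rng = np.random.default_rng(seed)
    rows = []
    for genotype, grp in sub.groupby("genotype", sort=True):
        hl = grp["half_life_h"].to_numpy(float)
        n = len(hl)
        if n == 0:
            continue
        if n < min_genes:
            warnings.warn(
                f"only {n} reliable genes for genotype {genotype!r} "
                f"(minimum {min_genes}); summaries flagged"
            )
        boots = rng.choice(hl, size=(n_boot, n), replace=True)
        med_b = np.median(boots, axis=1)
        mean_b = np.mean(boots, axis=1)
        rows.append({
            "genotype": genotype,
            "n_genes": n,
            "median_h": float(np.median(hl)),
            "median_ci_lo": float(np.quantile(med_b, 0.025)),
            "median_ci_hi": float(np.quantile(med_b, 0.975)),
            "mean_h": float(np.mean(hl)),
            "mean_ci_lo": float(np.quantile(mean_b, 0.025)),
            "mean_ci_hi": float(np.quantile(mean_b, 0.975)),
            "low_n": n < min_genes,
        })
    return pd.DataFrame(rows)
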