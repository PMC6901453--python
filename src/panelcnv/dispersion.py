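"""Beta-binomial dispersion model for capture-panel counts.

Control counts at target i in sample j are modelled as
``k_ij ~ BetaBinomial(N_j, p_i, rho_i)`` where ``N_j`` is sample j's library
size, ``p_i`` the target's capture fraction and ``rho_i`` the overdispersion
(rho = 0 recovers the binomial). The fit yields per-target central 95% count
intervals; the fraction of a sample's targets falling inside those intervals
is the sample-typicality diagnostic behind the >=95% candidate rule.

Parameterization: the beta mixing density has shape a = p(1-rho)/rho,
b = (1-p)(1-rho)/rho, so rho = 1/(a+b+1) is the intraclass correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import betaln, gammaln
from scipy.stats import binom, norm, t as student_t

from .core import PanelError
from .reference import ReferenceSet

__all__ = [
    "DispersionFit",
    "betabinom_logpmf",
    "fit_beta_binomial",
    "fitted_interval",
    "within_interval_fraction",
    "region_dispersion",
]

RHO_FLOOR = 1e-6
RHO_CEIL = 0.5
SHRINK_PRIOR_WEIGHT = 10.0


def betabinom_logpmf(k: np.ndarray, n: np.ndarray, p: float, rho: float) -> np.ndarray:
    """Log PMF of BetaBinomial(n, p, rho), computed in log space.

    For rho below the floor the exact binomial log PMF is used (the
    beta-binomial converges to it and the shape parameters overflow).
    """
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    if rho < RHO_FLOOR:
        return binom.logpmf(k, n, p)
    a = p * (1.0 - rho) / rho
    b = (1.0 - p) * (1.0 - rho) / rho
    return (
        gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
        + betaln(k + a, n - k + b) - betaln(a, b)
    )


@dataclass
class DispersionFit:
    """Per-target beta-binomial parameters fitted from control counts."""

    p: np.ndarray              # capture fraction per target
    rho: np.ndarray            # shrunk overdispersion per target
    rho_raw: np.ndarray        # per-target MLE before shrinkage
    rho_global: float          # shrinkage anchor (pooled shared-rho MLE)
    low_coverage: np.ndarray   # targets with all-zero control counts
    n_controls: int

    def __post_init__(self) -> None:
        if np.any((self.rho < 0) | (self.rho >= 1)):
            raise PanelError("rho out of [0, 1)")
        if self.p.sum() > 1 + 1e-9:
            raise PanelError("capture fractions sum above 1")


def _rho_mle(k: np.ndarray, n: np.ndarray, p: float) -> float:
    """Maximum-likelihood rho for one target, p held fixed.

    Optimized on log10(rho) over [RHO_FLOOR, RHO_CEIL]; the binomial
    boundary is compared explicitly so zero-variance targets hit the floor.
    """
    def nll(log10_rho: float) -> float:
        return -float(np.sum(betabinom_logpmf(k, n, p, 10.0 ** log10_rho)))

    res = minimize_scalar(
        nll,
        bounds=(np.log10(RHO_FLOOR), np.log10(RHO_CEIL)),
        method="bounded",
        options={"xatol": 1e-3},
    )
    ll_floor = -nll(np.log10(RHO_FLOOR))
    if -res.fun <= ll_floor + 1e-9:
        return RHO_FLOOR
    return float(10.0 ** res.x)


def _global_rho_mle(counts: np.ndarray, totals: np.ndarray, p: np.ndarray,
                    keep: np.ndarray) -> float:
    """Shared-rho MLE pooled over all targets — the shrinkage anchor.

    Pooling gives an essentially unbiased anchor where the median of the
    noisy per-target MLEs lands systematically low (the MLE's sampling
    distribution is right-skewed at ten controls).
    """
    idx = np.flatnonzero(keep)

    def nll(log10_rho: float) -> float:
        rho = 10.0 ** log10_rho
        return -float(sum(
            np.sum(betabinom_logpmf(counts[i], totals, float(p[i]), rho))
            for i in idx
        ))

    res = minimize_scalar(
        nll, bounds=(np.log10(RHO_FLOOR), np.log10(RHO_CEIL)),
        method="bounded", options={"xatol": 1e-3},
    )
    if -res.fun <= -nll(np.log10(RHO_FLOOR)) + 1e-9:
        return RHO_FLOOR
    return float(10.0 ** res.x)


def fit_beta_binomial(reference: ReferenceSet) -> DispersionFit:
    """Fit per-target capture fractions and overdispersion from controls.

    p_i is the pooled estimate sum_j k_ij / sum_j N_j. rho_i is the
    per-target MLE shrunk toward a global anchor (the pooled shared-rho
    MLE) with weight n_eff / (n_eff + 10), n_eff = n_controls * mean
    depth / 1000 — with ten controls the raw MLEs are noisy and unshrunk
    values destabilize the dispersion filter. Targets with no control
    reads get a floor p and a low-coverage flag (the min-reads filter
    removes them downstream).
    """
    counts = reference.raw_matrix()          # targets x controls
    totals = reference.totals()              # controls
    if len(reference.controls) < 3:
        raise PanelError("need >= 3 controls to fit dispersion")
    if (totals <= 0).any():
        raise PanelError("control with zero total count")
    n_targets, n_controls = counts.shape
    pooled_total = float(totals.sum())
    p = counts.sum(axis=1) / pooled_total
    low = p <= 0
    p_floor = 0.5 / pooled_total
    total_mass = min(p.sum(), 1.0)
    p = np.where(low, p_floor, p)
    if p.sum() > total_mass > 0:
        p *= total_mass / p.sum()   # keep the capture fractions summing <= 1

    rho_raw = np.empty(n_targets)
    for i in range(n_targets):
        if low[i]:
            rho_raw[i] = RHO_FLOOR
            continue
        rho_raw[i] = _rho_mle(counts[i], totals, float(p[i]))
    # the per-target MLE loses one degree of freedom to p_i (same n/(n-1)
    # bias as a variance MLE); correct before shrinkage so the dispersion
    # filter and the fitted intervals see calibrated values
    above = rho_raw > RHO_FLOOR
    rho_raw[above] = np.clip(
        rho_raw[above] * n_controls / (n_controls - 1), RHO_FLOOR, RHO_CEIL
    )
    rho_global = min(
        _global_rho_mle(counts, totals, p, ~low) * n_controls / (n_controls - 1),
        RHO_CEIL,
    )

    mean_depth = counts.mean(axis=1)
    n_eff = n_controls * mean_depth / 1000.0
    w = n_eff / (n_eff + SHRINK_PRIOR_WEIGHT)
    rho = np.clip(w * rho_raw + (1.0 - w) * rho_global, RHO_FLOOR, RHO_CEIL)
    return DispersionFit(
        p=p, rho=rho, rho_raw=rho_raw, rho_global=rho_global,
        low_coverage=low, n_controls=n_controls,
    )


def _interval_one(n: int, p: float, rho: float, level: float) -> tuple[int, int]:
    """Equal-tailed central interval by CDF inversion (quantile convention):
    lo = smallest k with CDF(k) >= alpha/2, hi = smallest k with
    CDF(k) >= 1 - alpha/2, so P(lo <= K <= hi) >= level. PMF is accumulated
    over a window around the mean wide enough that the missed tail mass is
    numerically zero."""
    if level >= 1.0:
        return 0, n
    alpha = 1.0 - level
    mean = n * p
    var = n * p * (1 - p) * (1 + (n - 1) * rho)
    sd = max(np.sqrt(max(var, 0.0)), 1.0)
    k_lo = max(0, int(np.floor(mean - 15 * sd)) - 5)
    k_hi = min(n, int(np.ceil(mean + 15 * sd)) + 5)
    ks = np.arange(k_lo, k_hi + 1)
    cdf = np.cumsum(np.exp(betabinom_logpmf(ks, n, p, rho)))
    # mass below the window is negligible by construction of the window
    at_least = ks[cdf >= alpha / 2]
    lo = int(at_least[0]) if len(at_least) else 0
    above = ks[cdf >= 1 - alpha / 2]
    hi = int(above[0]) if len(above) else n
    return lo, hi


def fitted_interval(
    fit: DispersionFit, n_test: int, level: float = 0.95, predictive: bool = False
) -> np.ndarray:
    """Per-target central ``level`` count intervals of the fitted model at
    library size ``n_test``; returns an array of shape (targets, 2).

    With ``predictive=True`` the interval additionally carries the
    new-observation correction for parameters estimated from finitely many
    controls (used by the sample-typicality QC); the default is the plain
    interval of the fitted model, which converges to the exact binomial
    interval as rho -> 0.
    """
    if n_test <= 0:
        raise PanelError("test total must be positive")
    if predictive:
        # standard new-observation prediction correction for a sample
        # judged against parameters estimated from n controls,
        # xbar +- t_{n-1} s sqrt(1+1/n): variance inflated by
        # (1+1/n)(t_{n-1}/z)^2 (~1.47 at n=10), solved into an effective
        # rho so the inflation covers the binomial part too
        n = fit.n_controls
        alpha = 1.0 - level
        t_corr = (student_t.ppf(1 - alpha / 2, n - 1) / norm.ppf(1 - alpha / 2)) ** 2
        infl = (1.0 + 1.0 / n) * t_corr
    else:
        infl = 1.0
    nm1 = max(int(n_test) - 1, 1)
    out = np.empty((len(fit.p), 2), dtype=np.int64)
    for i, (p_i, rho_i) in enumerate(zip(fit.p, fit.rho)):
        rho_pred = min(infl * float(rho_i) + (infl - 1.0) / nm1, RHO_CEIL)
        out[i] = _interval_one(int(n_test), float(p_i), rho_pred, level)
    return out


def within_interval_fraction(
    counts: np.ndarray,
    total: int,
    fit: DispersionFit,
    level: float = 0.95,
    weight: str = "reads",
) -> float:
    """Sample-typicality diagnostic: how much of the sample lies inside
    the fitted intervals.

    With ``weight="reads"`` (the reported "% of reads within fitted
    interval") each target counts proportionally to its expected read
    share, so a deep panel's verdict is not swung by a handful of deleted,
    nearly read-free targets. ``weight="targets"`` gives the plain
    fraction of targets inside their intervals.
    """
    intervals = fitted_interval(fit, total, level, predictive=True)
    inside = (counts >= intervals[:, 0]) & (counts <= intervals[:, 1])
    if weight == "targets":
        return float(inside.mean())
    if weight != "reads":
        raise PanelError(f"unknown weight {weight!r}")
    counts = np.asarray(counts, dtype=float)
    if counts.sum() == 0:
        return 0.0
    return float(counts[inside].sum() / counts.sum())


def region_dispersion(fit: DispersionFit, indices: np.ndarray | list[int]) -> tuple[float, float]:
    """(min, max) fitted rho over a span of targets, reported per call and
    consumed by the dispersion <= 0.01 filter."""
    idx = np.asarray(indices, dtype=int)
    if idx.size == 0:
        raise PanelError("empty region")
    vals = fit.rho[idx]
    return float(vals.min()), float(vals.max())
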