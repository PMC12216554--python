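"""Two-sample Mendelian randomization estimators.

All estimators consume per-variant exposure effects ``bx`` and outcome
effects ``by`` (with outcome standard errors ``se_by``) that have already
been harmonized onto a common effect allele.  The causal effect of the
exposure on the outcome is estimated as:

* Wald ratio  by/bx (single instrument);
* IVW         the 1/se_by^2-weighted regression of by on bx through the
              origin, i.e. the precision-weighted average of per-variant
              Wald ratios; the random-effects variant inflates the standard
              error by sqrt(max(1, Q/(k-1))) with Q Cochran's heterogeneity
              statistic (multiplicative over-dispersion);
* MR-Egger    the same weighted regression with a free intercept after
              orienting every variant so bx > 0; the intercept estimates
              directional pleiotropy and the slope remains consistent under
              the InSIDE assumption;
* weighted median  the weight-0.5 quantile of the per-variant ratios,
              consistent when valid instruments carry a majority of weight;
* simple / weighted mode  the kernel-density mode of the ratios, consistent
              when the largest cluster of instruments is valid.

Confidence intervals are estimate +/- 1.96 * SE and p-values are two-sided
normal throughout.  Bootstrap standard errors (median and modes) are
parametric: effects are redrawn from normal(observed, se) with a caller
supplied seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import DomainError, InsufficientInstruments
from .gwas_io import HarmonizedSet

logger = logging.getLogger(__name__)

Z95 = 1.96  # reporting convention for 95% intervals

METHOD_MIN_SNPS = {
    "wald_ratio": 1,
    "ivw_fixed": 2,
    "ivw_random": 2,
    "egger": 3,
    "weighted_median": 2,
    "simple_mode": 3,
    "weighted_mode": 3,
}


@dataclass
class MREstimate:
    """One method's causal estimate with normal-theory interval and p-value."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_snp: int
    odds_ratio: float | None = None
    or_ci_low: float | None = None
    or_ci_high: float | None = None
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "method": self.method,
            "n_snp": self.n_snp,
            "beta": self.beta,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "pvalue": self.pvalue,
            "or": self.odds_ratio,
            "or_ci_low": self.or_ci_low,
            "or_ci_high": self.or_ci_high,
        }
        return d


def _two_sided_p(beta: float, se: float) -> float:
    if se == 0:
        return 1.0 if beta == 0 else 0.0
    return float(2.0 * sps.norm.sf(abs(beta / se)))


def _finish(method, beta, se, k, binary_outcome=False, extras=None) -> MREstimate:
    beta = float(beta)
    se = float(se)
    est = MREstimate(
        method=method,
        beta=beta,
        se=se,
        ci_low=beta - Z95 * se,
        ci_high=beta + Z95 * se,
        pvalue=_two_sided_p(beta, se),
        n_snp=int(k),
        extras=extras or {},
    )
    if binary_outcome:
        est.odds_ratio = float(np.exp(est.beta))
        est.or_ci_low = float(np.exp(est.ci_low))
        est.or_ci_high = float(np.exp(est.ci_high))
    return est


def _as_arrays(*arrays):
    out = [np.asarray(a, float).ravel() for a in arrays]
    k = len(out[0])
    if any(len(a) != k for a in out):
        raise DomainError("effect arrays must have equal length")
    return out


def wald_ratio(
    bx: float,
    by: float,
    se_by: float,
    se_bx: float | None = None,
    second_order: bool = False,
    binary_outcome: bool = False,
) -> MREstimate:
    """Single-instrument ratio estimate by/bx with delta-method SE.

    The first-order SE is se_by/|bx|; with ``second_order`` and ``se_bx``
    supplied, the exposure-uncertainty term by^2 se_bx^2 / bx^4 is added.
    """
    if bx == 0:
        raise DomainError("wald ratio undefined for bx = 0")
    beta = by / bx
    var = (se_by / bx) ** 2
    if second_order:
        if se_bx is None:
            raise DomainError("second-order Wald SE requires se_bx")
        var += by**2 * se_bx**2 / bx**4
    return _finish("wald_ratio", beta, np.sqrt(var), 1, binary_outcome)


def ivw(
    bx,
    by,
    se_by,
    effects_model: str = "random_multiplicative",
    binary_outcome: bool = False,
) -> MREstimate:
    """Inverse-variance-weighted estimate (weighted regression through origin)."""
    bx, by, se_by = _as_arrays(bx, by, se_by)
    k = len(bx)
    if k < 2:
        raise InsufficientInstruments(f"IVW requires >= 2 instruments, got {k}")
    if effects_model not in ("fixed", "random_multiplicative"):
        raise DomainError(f"unknown effects model {effects_model!r}")
    w = 1.0 / se_by**2
    sxx = float(np.sum(w * bx * bx))
    beta = float(np.sum(w * bx * by)) / sxx
    se_fixed = np.sqrt(1.0 / sxx)
    resid = by - beta * bx
    q = float(np.sum(w * resid**2))
    scale = max(1.0, q / (k - 1))
    se = se_fixed if effects_model == "fixed" else se_fixed * np.sqrt(scale)
    extras = {
        "q_stat": q,
        "q_df": k - 1,
        "q_pvalue": float(sps.chi2.sf(q, k - 1)),
        "se_fixed": float(se_fixed),
        "overdispersion_scale": scale,
        "effects_model": effects_model,
    }
    method = "ivw_fixed" if effects_model == "fixed" else "ivw_random"
    return _finish(method, beta, se, k, binary_outcome, extras)


def mr_egger(bx, by, se_by, binary_outcome: bool = False) -> MREstimate:
    """MR-Egger weighted regression with intercept (pleiotropy) test.

    Variants are oriented so every exposure effect is positive before the
    fit (the intercept's sign is otherwise arbitrary); variants with bx = 0
    are excluded with a warning.  Standard errors carry the multiplicative
    over-dispersion factor sqrt(max(1, RSS/(k-2))).
    """
    bx, by, se_by = _as_arrays(bx, by, se_by)
    nonzero = bx != 0
    if not nonzero.all():
        logger.warning("MR-Egger: excluding %d variants with bx = 0", int((~nonzero).sum()))
        bx, by, se_by = bx[nonzero], by[nonzero], se_by[nonzero]
    k = len(bx)
    if k < 3:
        raise InsufficientInstruments(f"MR-Egger requires >= 3 instruments, got {k}")
    sign = np.where(bx < 0, -1.0, 1.0)
    bx, by = bx * sign, by * sign
    w = 1.0 / se_by**2
    s0 = float(np.sum(w))
    s1 = float(np.sum(w * bx))
    s2 = float(np.sum(w * bx * bx))
    sy = float(np.sum(w * by))
    sxy = float(np.sum(w * bx * by))
    det = s0 * s2 - s1 * s1
    if det <= 0:
        raise DomainError("degenerate design in MR-Egger (no spread in bx)")
    slope = (s0 * sxy - s1 * sy) / det
    intercept = (s2 * sy - s1 * sxy) / det
    resid = by - intercept - slope * bx
    rss = float(np.sum(w * resid**2))
    scale = max(1.0, rss / (k - 2))
    se_slope = np.sqrt(s0 / det * scale)
    se_int = np.sqrt(s2 / det * scale)
    extras = {
        "intercept": float(intercept),
        "intercept_se": float(se_int),
        "intercept_p": _two_sided_p(intercept, se_int),
        "rss": rss,
        "overdispersion_scale": scale,
    }
    return _finish("egger", slope, se_slope, k, binary_outcome, extras)


def _ratio_inputs(bx, by, se_by):
    """Per-variant Wald ratios and their first-order inverse-variance weights."""
    nonzero = bx != 0
    if not nonzero.all():
        logger.warning("excluding %d variants with bx = 0 from ratio set", int((~nonzero).sum()))
        bx, by, se_by = bx[nonzero], by[nonzero], se_by[nonzero]
    ratios = by / bx
    se_ratio = np.abs(se_by / bx)
    weights = 1.0 / se_ratio**2
    return bx, by, se_by, ratios, weights


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Weight-0.5 quantile with linear interpolation (percentile convention)."""
    order = np.argsort(values, kind="mergesort")
    v = values[order]
    w = weights[order] / weights.sum()
    cum = np.cumsum(w) - 0.5 * w
    return float(np.interp(0.5, cum, v))


def _weighted_median_rows(values: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Row-wise weighted medians for (n, k) arrays (bootstrap helper)."""
    order = np.argsort(values, axis=1, kind="mergesort")
    v = np.take_along_axis(values, order, axis=1)
    w = np.take_along_axis(weights, order, axis=1)
    w = w / w.sum(axis=1, keepdims=True)
    cum = np.cumsum(w, axis=1) - 0.5 * w
    out = np.empty(len(v))
    for i in range(len(v)):  # np.interp is 1-D only; rows are short
        out[i] = np.interp(0.5, cum[i], v[i])
    return out


def weighted_median(
    bx,
    by,
    se_by,
    se_bx=None,
    n_boot: int = 1000,
    seed: int | np.random.SeedSequence | None = None,
    binary_outcome: bool = False,
) -> MREstimate:
    """Weighted-median estimator with parametric-bootstrap standard error."""
    bx, by, se_by = _as_arrays(bx, by, se_by)
    if se_bx is not None:
        (se_bx,) = _as_arrays(se_bx)
    if len(bx) < 2:
        raise InsufficientInstruments("weighted median requires >= 2 instruments")
    if n_boot < 100:
        raise DomainError("n_boot must be >= 100 for a usable bootstrap SE")
    if seed is None:
        raise DomainError("a bootstrap seed is required")
    bx, by, se_by, ratios, weights = _ratio_inputs(bx, by, se_by)
    k = len(bx)
    if k < 2:
        raise InsufficientInstruments("weighted median requires >= 2 usable instruments")
    beta = _weighted_median(ratios, weights)

    rng = np.random.default_rng(seed)
    by_b = by + se_by * rng.standard_normal((n_boot, k))
    if se_bx is not None:
        bx_b = bx + se_bx * rng.standard_normal((n_boot, k))
        bx_b = np.where(bx_b == 0, np.finfo(float).tiny, bx_b)
    else:
        bx_b = np.broadcast_to(bx, (n_boot, k))
    ratios_b = by_b / bx_b
    weights_b = (bx_b / se_by) ** 2
    boot = _weighted_median_rows(ratios_b, weights_b)
    se = float(np.std(boot, ddof=1))
    return _finish(
        "weighted_median", beta, se, k, binary_outcome, {"n_boot": n_boot}
    )


def _mode_bandwidth(ratios: np.ndarray, phi: float) -> float:
    """Modified Silverman bandwidth 0.9 * min(sd, 1.4826*MAD) * k^(-1/5) * phi."""
    sd = float(np.std(ratios, ddof=1))
    mad = float(np.median(np.abs(ratios - np.median(ratios)))) * 1.4826
    s = min(x for x in (sd, mad) if x > 0) if max(sd, mad) > 0 else 0.0
    return 0.9 * s * len(ratios) ** (-0.2) * phi


def _kde_mode(ratios: np.ndarray, weights: np.ndarray, phi: float) -> float:
    """Mode of a weighted normal-kernel density over the ratios.

    Evaluated on an odd-length grid with quadratic refinement at the peak so
    a symmetric sample yields its exact centre.
    """
    h = _mode_bandwidth(ratios, phi)
    if h == 0:  # all ratios identical
        return float(ratios[0])
    w = weights / weights.sum()
    grid = np.linspace(ratios.min() - 3 * h, ratios.max() + 3 * h, 513)
    dens = np.exp(-0.5 * ((grid[:, None] - ratios[None, :]) / h) ** 2) @ w
    i = int(np.argmax(dens))
    if 0 < i < len(grid) - 1:
        y0, y1, y2 = dens[i - 1], dens[i], dens[i + 1]
        denom = y0 - 2 * y1 + y2
        if denom < 0:
            return float(grid[i] + 0.5 * (y0 - y2) / denom * (grid[1] - grid[0]))
    return float(grid[i])


def mode_estimator(
    bx,
    by,
    se_by,
    se_bx=None,
    weighted: bool = True,
    bandwidth_phi: float = 1.0,
    n_boot: int = 1000,
    seed: int | np.random.SeedSequence | None = None,
    binary_outcome: bool = False,
) -> MREstimate:
    """Simple or weighted mode-based estimate with bootstrap standard error.

    The point estimate is the kernel-density mode of the per-variant ratios;
    the weighted variant weights each ratio by its inverse variance.  The SE
    is the normalized median absolute deviation of parametric-bootstrap
    replicates (robust to the occasional mode jump between clusters).
    """
    bx, by, se_by = _as_arrays(bx, by, se_by)
    if se_bx is not None:
        (se_bx,) = _as_arrays(se_bx)
    if len(bx) < 3:
        raise InsufficientInstruments("mode estimator requires >= 3 instruments")
    if seed is None:
        raise DomainError("a bootstrap seed is required")
    if bandwidth_phi <= 0:
        raise DomainError("bandwidth_phi must be positive")
    bx, by, se_by, ratios, ivw_weights = _ratio_inputs(bx, by, se_by)
    k = len(bx)
    if k < 3:
        raise InsufficientInstruments("mode estimator requires >= 3 usable instruments")
    weights = ivw_weights if weighted else np.ones(k)
    beta = _kde_mode(ratios, weights, bandwidth_phi)

    rng = np.random.default_rng(seed)
    by_b = by + se_by * rng.standard_normal((n_boot, k))
    if se_bx is not None:
        bx_b = bx + se_bx * rng.standard_normal((n_boot, k))
        bx_b = np.where(bx_b == 0, np.finfo(float).tiny, bx_b)
    else:
        bx_b = np.broadcast_to(bx, (n_boot, k))
    boot = np.empty(n_boot)
    for b in range(n_boot):
        r = by_b[b] / bx_b[b]
        wgt = (bx_b[b] / se_by) ** 2 if weighted else np.ones(k)
        boot[b] = _kde_mode(r, wgt, bandwidth_phi)
    se = float(np.median(np.abs(boot - np.median(boot))) * 1.4826)
    method = "weighted_mode" if weighted else "simple_mode"
    return _finish(method, beta, se, k, binary_outcome, {"n_boot": n_boot})


def fit_all(
    hset: HarmonizedSet,
    binary_outcome: bool | None = None,
    seed: int | np.random.SeedSequence | None = None,
    n_boot: int = 1000,
    methods: tuple[str, ...] | None = None,
) -> dict[str, MREstimate]:
    """Fit every applicable estimator on a harmonized set.

    With a single instrument only the Wald ratio applies; two instruments
    allow IVW and the weighted median; three or more enable MR-Egger and the
    mode estimators.  ``methods`` restricts the set (``"ivw"`` covers both
    effects models).
    """
    if binary_outcome is None:
        binary_outcome = hset.binary_outcome
    bx, se_bx, by, se_by = hset.bx, hset.se_bx, hset.by, hset.se_by
    k = len(bx)
    if k == 0:
        raise InsufficientInstruments("harmonized set has no retained variants")
    wanted = methods or ("ivw", "egger", "weighted_median", "simple_mode", "weighted_mode")
    out: dict[str, MREstimate] = {}
    if k == 1:
        out["wald_ratio"] = wald_ratio(
            float(bx[0]), float(by[0]), float(se_by[0]), binary_outcome=binary_outcome
        )
        return out
    if seed is None:
        seeds = [None] * 3
    else:
        ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
        seeds = ss.spawn(3)
    if "ivw" in wanted:
        out["ivw_fixed"] = ivw(bx, by, se_by, "fixed", binary_outcome)
        out["ivw_random"] = ivw(bx, by, se_by, "random_multiplicative", binary_outcome)
    if "egger" in wanted and k >= 3:
        out["egger"] = mr_egger(bx, by, se_by, binary_outcome)
    if "weighted_median" in wanted:
        out["weighted_median"] = weighted_median(
            bx, by, se_by, se_bx, n_boot=n_boot, seed=seeds[0], binary_outcome=binary_outcome
        )
    if "simple_mode" in wanted and k >= 3:
        out["simple_mode"] = mode_estimator(
            bx, by, se_by, se_bx, weighted=False, n_boot=n_boot, seed=seeds[1],
            binary_outcome=binary_outcome,
        )
    if "weighted_mode" in wanted and k >= 3:
        out["weighted_mode"] = mode_estimator(
            bx, by, se_by, se_bx, weighted=True, n_boot=n_boot, seed=seeds[2],
            binary_outcome=binary_outcome,
        )
    return out


def run_all_methods(
    hset: HarmonizedSet,
    binary_outcome: bool | None = None,
    seed: int | np.random.SeedSequence | None = None,
    n_boot: int = 1000,
    methods: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Estimates from every applicable method as one table.

    Columns: exposure, outcome, method, n_snp, beta, se, ci_low, ci_high,
    pvalue, or, or_ci_low, or_ci_high (OR columns populated for binary
    outcomes only).
    """
    fits = fit_all(hset, binary_outcome, seed=seed, n_boot=n_boot, methods=methods)
    rows = []
    for est in fits.values():
        d = est.to_dict()
        d["exposure"] = hset.exposure_name
        d["outcome"] = hset.outcome_name
        rows.append(d)
    cols = [
        "exposure", "outcome", "method", "n_snp", "beta", "se",
        "ci_low", "ci_high", "pvalue", "or", "or_ci_low", "or_ci_high",
    ]
    return pd.DataFrame(rows)[cols]
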