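"""Heterogeneity and horizontal-pleiotropy diagnostics.

Three complementary checks guard an MR estimate:

* Cochran's Q — the inverse-variance-weighted residual sum of squares about
  the fixed-effects IVW slope, referred to a chi-square with k-1 degrees of
  freedom; large Q signals heterogeneous per-variant effects.
* The MR-Egger intercept test — directional pleiotropy (taken verbatim from
  the Egger fit so there is a single source of truth).
* MR-PRESSO — a parametric-simulation test with three parts: a global
  residual-sum-of-squares test of pleiotropy, a per-variant outlier test
  (Bonferroni-adjusted empirical p-values), and a distortion test comparing
  the outlier-corrected estimate against removal of random variant subsets.

Leave-one-out re-estimation completes the toolbox: a single variant driving
the pooled estimate shows up as an outlying leave-one-out value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .estimators import MREstimate, _as_arrays, ivw, mr_egger
from .exceptions import DomainError, InsufficientInstruments
from .gwas_io import HarmonizedSet

logger = logging.getLogger(__name__)


def cochran_q(bx, by, se_by) -> tuple[float, int, float]:
    """Cochran's Q about the fixed-effects IVW slope: (Q, df, p-value)."""
    bx, by, se_by = _as_arrays(bx, by, se_by)
    k = len(bx)
    if k < 2:
        raise InsufficientInstruments("Cochran's Q requires >= 2 instruments")
    w = 1.0 / se_by**2
    beta = float(np.sum(w * bx * by) / np.sum(w * bx * bx))
    q = float(np.sum(w * (by - beta * bx) ** 2))
    df = k - 1
    return q, df, float(sps.chi2.sf(q, df))


@dataclass
class PressoResult:
    """MR-PRESSO global, outlier and distortion test results."""

    rss_obs: float
    global_p: float
    outlier_p: pd.Series  # Bonferroni-adjusted empirical p per variant
    outliers: list[str]
    corrected: MREstimate | None
    distortion_p: float | None
    n_sim: int
    n_snp: int


def _loo_slopes(bx, by, w):
    """Leave-one-out weighted through-origin slopes for every variant."""
    sxy = np.sum(w * bx * by)
    sxx = np.sum(w * bx * bx)
    return (sxy - w * bx * by) / (sxx - w * bx * bx)


def mr_presso(
    bx,
    by,
    se_by,
    se_bx=None,
    rsids=None,
    n_sim: int = 1000,
    seed: int | np.random.SeedSequence | None = None,
    outlier_alpha: float = 0.05,
    effects_model: str = "random_multiplicative",
) -> PressoResult:
    """MR-PRESSO global test, outlier detection and distortion test.

    The observed statistic is the weighted residual sum of squares about
    the leave-one-out IVW slope of each variant.  Its null distribution is
    simulated parametrically: outcome effects are redrawn around the
    leave-one-out predictions and exposure effects around their observed
    values (held fixed when se_bx is unavailable).  Empirical p-values use
    the (r + 1)/(n_sim + 1) convention.
    """
    bx, by, se_by = _as_arrays(bx, by, se_by)
    k = len(bx)
    if k < 4:
        raise InsufficientInstruments(f"MR-PRESSO requires >= 4 instruments, got {k}")
    if n_sim < 1000:
        raise DomainError("n_sim must be >= 1000 for stable empirical p-values")
    if seed is None:
        raise DomainError("a simulation seed is required")
    if se_bx is not None:
        (se_bx,) = _as_arrays(se_bx)
    else:
        logger.info("MR-PRESSO: se_bx unavailable; exposure effects held fixed in simulation")
    rsid_list = list(rsids) if rsids is not None else [f"snp{i + 1}" for i in range(k)]

    w = 1.0 / se_by**2
    beta_loo = _loo_slopes(bx, by, w)
    resid = by - beta_loo * bx
    obs_sq = w * resid**2
    rss_obs = float(np.sum(obs_sq))

    rng = np.random.default_rng(seed)
    by_sim = beta_loo * bx + se_by * rng.standard_normal((n_sim, k))
    if se_bx is not None:
        bx_sim = bx + se_bx * rng.standard_normal((n_sim, k))
    else:
        bx_sim = np.broadcast_to(bx, (n_sim, k)).copy()
    sxy = np.sum(w * bx_sim * by_sim, axis=1, keepdims=True)
    sxx = np.sum(w * bx_sim * bx_sim, axis=1, keepdims=True)
    beta_loo_sim = (sxy - w * bx_sim * by_sim) / (sxx - w * bx_sim * bx_sim)
    sim_sq = w * (by_sim - beta_loo_sim * bx_sim) ** 2
    rss_sim = sim_sq.sum(axis=1)

    global_p = float((1 + np.sum(rss_sim >= rss_obs)) / (n_sim + 1))
    p_raw = (1 + np.sum(sim_sq >= obs_sq, axis=0)) / (n_sim + 1)
    p_adj = np.minimum(1.0, p_raw * k)
    outlier_p = pd.Series(p_adj, index=rsid_list, name="presso_outlier_p")
    out_mask = p_adj < outlier_alpha
    outliers = [r for r, m in zip(rsid_list, out_mask) if m]

    beta_all = ivw(bx, by, se_by, effects_model)
    corrected: MREstimate | None = beta_all
    distortion_p: float | None = None
    if outliers:
        keep = ~out_mask
        if keep.sum() >= 2:
            corrected = ivw(bx[keep], by[keep], se_by[keep], effects_model)
            d_obs = corrected.beta - beta_all.beta
            n_out = int(out_mask.sum())
            d_rand = np.empty(n_sim)
            idx = np.arange(k)
            for b in range(n_sim):
                drop = rng.choice(idx, size=n_out, replace=False)
                m = np.ones(k, bool)
                m[drop] = False
                w_m, bx_m, by_m = w[m], bx[m], by[m]
                d_rand[b] = np.sum(w_m * bx_m * by_m) / np.sum(w_m * bx_m * bx_m) - beta_all.beta
            distortion_p = float((1 + np.sum(np.abs(d_rand) >= abs(d_obs))) / (n_sim + 1))
        else:
            logger.warning("MR-PRESSO: too few variants left after outlier removal")
            corrected = None
    return PressoResult(
        rss_obs=rss_obs,
        global_p=global_p,
        outlier_p=outlier_p,
        outliers=outliers,
        corrected=corrected,
        distortion_p=distortion_p,
        n_sim=n_sim,
        n_snp=k,
    )


def leave_one_out(
    bx, by, se_by, rsids=None, effects_model: str = "random_multiplicative"
) -> pd.DataFrame:
    """IVW estimate with each variant removed in turn."""
    bx, by, se_by = _as_arrays(bx, by, se_by)
    k = len(bx)
    if k < 3:
        raise InsufficientInstruments("leave-one-out requires >= 3 instruments")
    rsid_list = list(rsids) if rsids is not None else [f"snp{i + 1}" for i in range(k)]
    rows = []
    mask = np.ones(k, bool)
    for i in range(k):
        mask[i] = False
        est = ivw(bx[mask], by[mask], se_by[mask], effects_model)
        rows.append(
            {"rsid": rsid_list[i], "beta": est.beta, "se": est.se, "pvalue": est.pvalue}
        )
        mask[i] = True
    return pd.DataFrame(rows)


@dataclass
class SensitivityReport:
    """Combined heterogeneity and pleiotropy diagnostics for one pair."""

    q_stat: float = np.nan
    q_df: int = 0
    q_pvalue: float = np.nan
    egger_intercept: float = np.nan
    egger_intercept_se: float = np.nan
    egger_intercept_p: float = np.nan
    presso: PressoResult | None = None
    loo: pd.DataFrame | None = None

    @property
    def presso_global_p(self) -> float:
        return self.presso.global_p if self.presso is not None else np.nan

    @property
    def presso_distortion_p(self) -> float:
        if self.presso is None or self.presso.distortion_p is None:
            return np.nan
        return self.presso.distortion_p

    @property
    def n_outliers(self) -> int:
        return len(self.presso.outliers) if self.presso is not None else 0

    def passes(self, alpha: float = 0.05) -> bool:
        """True when no diagnostic rejects at ``alpha`` (NaN = not applicable)."""
        for p in (self.q_pvalue, self.egger_intercept_p, self.presso_global_p):
            if np.isfinite(p) and p <= alpha:
                return False
        return True

    def to_dict(self) -> dict:
        return {
            "q_stat": self.q_stat,
            "q_df": self.q_df,
            "q_pvalue": self.q_pvalue,
            "egger_intercept": self.egger_intercept,
            "egger_intercept_se": self.egger_intercept_se,
            "egger_intercept_p": self.egger_intercept_p,
            "presso_global_p": self.presso_global_p,
            "n_outliers": self.n_outliers,
            "presso_distortion_p": self.presso_distortion_p,
        }


def sensitivity_report(
    hset: HarmonizedSet,
    seed: int | np.random.SeedSequence | None = None,
    n_sim: int = 1000,
    run_presso: bool = True,
    run_loo: bool = False,
    egger: MREstimate | None = None,
) -> SensitivityReport:
    """Assemble the full diagnostic battery appropriate to the set size.

    An already-fitted Egger estimate may be passed in so its intercept block
    is reused byte-for-byte rather than refitted.
    """
    bx, se_bx, by, se_by = hset.bx, hset.se_bx, hset.by, hset.se_by
    k = len(bx)
    rep = SensitivityReport()
    if k >= 2:
        rep.q_stat, rep.q_df, rep.q_pvalue = cochran_q(bx, by, se_by)
    if k >= 3:
        if egger is None:
            egger = mr_egger(bx, by, se_by)
        rep.egger_intercept = egger.extras["intercept"]
        rep.egger_intercept_se = egger.extras["intercept_se"]
        rep.egger_intercept_p = egger.extras["intercept_p"]
    if run_presso and k >= 4:
        rep.presso = mr_presso(
            bx, by, se_by, se_bx=se_bx, rsids=hset.rsids, n_sim=n_sim, seed=seed
        )
    if run_loo and k >= 3:
        rep.loo = leave_one_out(bx, by, se_by, rsids=hset.rsids)
    return rep
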