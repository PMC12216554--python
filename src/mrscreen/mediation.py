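"""Two-step mediation through the product method.

Step 1 (UVMR) estimates beta1, the causal effect of the exposure (a gut
microbiome feature) on the mediator (an immune-cell or cytokine phenotype).
Step 2 estimates beta2, the effect of the mediator on the outcome (e.g.
chronic kidney disease) with the exposure adjusted for via multivariable MR
so that beta2 is a direct effect.  The mediated (indirect) effect is
beta1 * beta2 with a first-order delta-method standard error
sqrt(beta1^2 se2^2 + beta2^2 se1^2); the mediation proportion is the signed
percentage 100 * indirect / beta_total where beta_total is the UVMR
exposure-to-outcome effect.  A proportion whose sign disagrees with the
total effect indicates inconsistent mediation (suppression) and is flagged
rather than hidden.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .estimators import Z95, MREstimate, _as_arrays, _two_sided_p, ivw, wald_ratio
from .exceptions import (
    CollinearityError,
    DomainError,
    InsufficientInstruments,
)
from .gwas_io import SummaryStats, harmonize, harmonize_multi
from .instruments import LDMatrix, SelectionParams, select_instruments

logger = logging.getLogger(__name__)


@dataclass
class MVMRResult:
    """Direct effects of several exposures estimated jointly on one outcome."""

    exposures: list[str]
    beta: np.ndarray
    se: np.ndarray
    pvalue: np.ndarray
    conditional_f: np.ndarray | None
    n_snp: int
    extras: dict = field(default_factory=dict)

    def effect(self, exposure: str) -> tuple[float, float, float]:
        i = self.exposures.index(exposure)
        return float(self.beta[i]), float(self.se[i]), float(self.pvalue[i])


def mvmr_ivw(
    bx_mat,
    by,
    se_by,
    exposure_names: Sequence[str] | None = None,
    se_bx_mat=None,
) -> MVMRResult:
    """Multivariable IVW: weighted multiple regression without intercept.

    Outcome effects are regressed on the (n_snp, n_exposure) matrix of
    exposure effects with weights 1/se_by^2.  Per-exposure slopes are direct
    effects conditional on the other exposures.  Standard errors carry the
    multiplicative over-dispersion factor sqrt(max(1, RSS/(k - p))).
    Conditional instrument-strength F statistics (an approximation based on
    the weighted residual variation of each exposure about the others) are
    reported when exposure standard errors are supplied.
    """
    X = np.atleast_2d(np.asarray(bx_mat, float))
    if X.shape[0] == 1 and X.shape[1] > 1 and np.ndim(bx_mat) == 1:
        X = X.T
    by, se_by = _as_arrays(by, se_by)
    k, p = X.shape
    if p < 2:
        raise DomainError("multivariable MR requires at least two exposures")
    if k != len(by):
        raise DomainError("exposure matrix and outcome vector length mismatch")
    if k <= p:
        raise InsufficientInstruments(
            f"MVMR requires more instruments ({k}) than exposures ({p})"
        )
    names = list(exposure_names) if exposure_names is not None else [
        f"exposure{i + 1}" for i in range(p)
    ]
    w = 1.0 / se_by**2
    # an all-zero exposure column is unidentifiable, not collinear: its
    # direct effect is reported as 0 with infinite SE and the regression
    # reduces to the remaining exposures
    nonzero = np.abs(X).max(axis=0) > 0
    if not nonzero.any():
        raise DomainError("all exposure columns are identically zero")
    Xr = X[:, nonzero]
    pr = int(nonzero.sum())
    Xw = Xr * w[:, None]
    A = Xr.T @ Xw
    if np.linalg.cond(A) > 1e10:
        # identify the offending near-duplicate columns
        C = np.corrcoef(Xr, rowvar=False)
        idx = np.nonzero(nonzero)[0]
        bad = set()
        for i in range(pr):
            for j in range(i + 1, pr):
                if abs(C[i, j]) > 0.999:
                    bad.update((names[idx[i]], names[idx[j]]))
        raise CollinearityError(sorted(bad) or [names[i] for i in idx])
    beta_r = np.linalg.solve(A, Xw.T @ by)
    resid = by - Xr @ beta_r
    rss = float(np.sum(w * resid**2))
    scale = max(1.0, rss / (k - pr))
    cov = np.linalg.inv(A) * scale
    se_r = np.sqrt(np.diag(cov))
    beta = np.zeros(p)
    se = np.full(p, np.inf)
    beta[nonzero] = beta_r
    se[nonzero] = se_r
    if not nonzero.all():
        logger.warning(
            "MVMR: exposure columns %s are identically zero; effects reported as 0",
            [names[i] for i in np.nonzero(~nonzero)[0]],
        )
    pvals = np.array(
        [_two_sided_p(b, s) if np.isfinite(s) else 1.0 for b, s in zip(beta, se)]
    )

    cond_f = None
    if se_bx_mat is not None:
        se_X = np.atleast_2d(np.asarray(se_bx_mat, float))
        if se_X.shape != X.shape:
            se_X = se_X.T
        cond_f = np.empty(p)
        for j in range(p):
            others = np.delete(X, j, axis=1)
            coef = np.linalg.lstsq(others * np.sqrt(w)[:, None],
                                   X[:, j] * np.sqrt(w), rcond=None)[0]
            r = X[:, j] - others @ coef
            cond_f[j] = float(np.sum(r**2 / se_X[:, j] ** 2) / (k - p + 1))
    return MVMRResult(
        exposures=names,
        beta=beta,
        se=se,
        pvalue=pvals,
        conditional_f=cond_f,
        n_snp=k,
        extras={"rss": rss, "overdispersion_scale": scale},
    )


class IndirectEffect(NamedTuple):
    indirect: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float


def indirect_effect(beta1: float, se1: float, beta2: float, se2: float) -> IndirectEffect:
    """Product-method mediated effect beta1*beta2 with delta-method interval."""
    if se1 <= 0 or se2 <= 0:
        raise DomainError("standard errors must be positive")
    ind = beta1 * beta2
    se = float(np.sqrt(beta1**2 * se2**2 + beta2**2 * se1**2))
    return IndirectEffect(
        indirect=float(ind),
        se=se,
        ci_low=float(ind - Z95 * se),
        ci_high=float(ind + Z95 * se),
        pvalue=_two_sided_p(ind, se),
    )


def mediation_proportion(indirect: float, beta_total: float) -> float:
    """Signed mediation proportion 100 * indirect / beta_total (percent).

    A sign disagreement between the indirect and total effects (inconsistent
    mediation, i.e. suppression) yields a negative proportion and a warning.
    """
    if beta_total == 0:
        raise DomainError("mediation proportion undefined for beta_total = 0")
    prop = 100.0 * indirect / beta_total
    if indirect != 0 and np.sign(indirect) != np.sign(beta_total):
        logger.warning(
            "inconsistent mediation: indirect (%.4g) and total (%.4g) effects disagree in sign",
            indirect,
            beta_total,
        )
    return float(prop)


@dataclass
class MediationResult:
    """One exposure-mediator-outcome pathway's mediation decomposition."""

    exposure: str
    mediator: str
    outcome: str
    status: str = "ok"  # "ok" or "failed"
    failed_step: str | None = None
    beta1: float = np.nan
    se1: float = np.nan
    p1: float = np.nan
    beta2: float = np.nan
    se2: float = np.nan
    p2: float = np.nan
    beta_total: float = np.nan
    se_total: float = np.nan
    p_total: float = np.nan
    indirect: float = np.nan
    indirect_se: float = np.nan
    indirect_ci_low: float = np.nan
    indirect_ci_high: float = np.nan
    indirect_p: float = np.nan
    proportion_pct: float = np.nan
    inconsistent: bool = False
    n_snp_step1: int = 0
    n_snp_step2: int = 0
    n_snp_total: int = 0

    def to_dict(self) -> dict:
        return {
            "exposure": self.exposure,
            "mediator": self.mediator,
            "outcome": self.outcome,
            "status": self.status,
            "failed_step": self.failed_step,
            "beta1": self.beta1,
            "se1": self.se1,
            "beta2": self.beta2,
            "se2": self.se2,
            "beta_total": self.beta_total,
            "se_total": self.se_total,
            "indirect": self.indirect,
            "indirect_se": self.indirect_se,
            "ci_low": self.indirect_ci_low,
            "ci_high": self.indirect_ci_high,
            "pvalue": self.indirect_p,
            "proportion_pct": self.proportion_pct,
            "inconsistent": self.inconsistent,
        }


@dataclass(frozen=True)
class MediationConfig:
    """Settings for the two-step mediation computation."""

    exposure_params: SelectionParams = SelectionParams()
    mediator_params: SelectionParams = SelectionParams()
    beta2_mode: str = "mvmr"  # "mvmr" (exposure-adjusted) or "uvmr"
    effects_model: str = "random_multiplicative"

    def __post_init__(self):
        if self.beta2_mode not in ("mvmr", "uvmr"):
            raise DomainError("beta2_mode must be 'mvmr' or 'uvmr'")


def _uvmr_effect(
    exposure: SummaryStats,
    other: SummaryStats,
    rsids: Sequence[str],
    effects_model: str,
) -> tuple[float, float, float, int] | None:
    """IVW (or single-instrument Wald) effect of exposure on `other`."""
    hset = harmonize(exposure, other, rsids)
    k = hset.n_snp
    if k == 0:
        return None
    if k == 1:
        est = wald_ratio(float(hset.bx[0]), float(hset.by[0]), float(hset.se_by[0]))
    else:
        est = ivw(hset.bx, hset.by, hset.se_by, effects_model)
    return est.beta, est.se, est.pvalue, k


def two_step_mediation(
    exposure_stats: SummaryStats,
    mediator_stats: SummaryStats,
    outcome_stats: SummaryStats,
    config: MediationConfig | None = None,
    ld: LDMatrix | None = None,
) -> MediationResult:
    """Full two-step mediation for one exposure-mediator-outcome pathway.

    beta1 and beta_total come from UVMR IVW on the exposure's instruments;
    beta2 comes, by default, from MVMR of the outcome on mediator and
    exposure jointly over the union of both instrument sets.  Any step
    without usable instruments produces a structured failed result naming
    the step instead of raising.
    """
    config = config or MediationConfig()
    res = MediationResult(
        exposure=exposure_stats.trait_name,
        mediator=mediator_stats.trait_name,
        outcome=outcome_stats.trait_name,
    )

    iv_exp = select_instruments(exposure_stats, config.exposure_params, ld=ld)
    if len(iv_exp) == 0:
        res.status, res.failed_step = "failed", "exposure_instruments"
        return res

    step1 = _uvmr_effect(exposure_stats, mediator_stats, iv_exp.rsids, config.effects_model)
    if step1 is None:
        res.status, res.failed_step = "failed", "exposure_to_mediator"
        return res
    res.beta1, res.se1, res.p1, res.n_snp_step1 = step1

    total = _uvmr_effect(exposure_stats, outcome_stats, iv_exp.rsids, config.effects_model)
    if total is None:
        res.status, res.failed_step = "failed", "exposure_to_outcome"
        return res
    res.beta_total, res.se_total, res.p_total, res.n_snp_total = total

    if config.beta2_mode == "uvmr":
        iv_med = select_instruments(mediator_stats, config.mediator_params, ld=ld)
        if len(iv_med) == 0:
            res.status, res.failed_step = "failed", "mediator_instruments"
            return res
        step2 = _uvmr_effect(
            mediator_stats, outcome_stats, iv_med.rsids, config.effects_model
        )
        if step2 is None:
            res.status, res.failed_step = "failed", "mediator_to_outcome"
            return res
        res.beta2, res.se2, res.p2, res.n_snp_step2 = step2
    else:
        iv_med = select_instruments(mediator_stats, config.mediator_params, ld=ld)
        if len(iv_med) == 0:
            res.status, res.failed_step = "failed", "mediator_instruments"
            return res
        union = list(dict.fromkeys(iv_exp.rsids + iv_med.rsids))
        mset = harmonize_multi(outcome_stats, [mediator_stats, exposure_stats], union)
        if mset.n_snp <= 2:
            res.status, res.failed_step = "failed", "mvmr_instruments"
            return res
        try:
            mv = mvmr_ivw(
                mset.X(),
                mset.y,
                mset.se_y,
                exposure_names=mset.trait_names,
                se_bx_mat=mset.se_X(),
            )
        except (CollinearityError, InsufficientInstruments) as exc:
            logger.warning("MVMR step failed: %s", exc)
            res.status, res.failed_step = "failed", "mvmr"
            return res
        res.beta2, res.se2, res.p2 = mv.effect(mediator_stats.trait_name)
        res.n_snp_step2 = mv.n_snp

    ind = indirect_effect(res.beta1, res.se1, res.beta2, res.se2)
    res.indirect = ind.indirect
    res.indirect_se = ind.se
    res.indirect_ci_low = ind.ci_low
    res.indirect_ci_high = ind.ci_high
    res.indirect_p = ind.pvalue
    if res.beta_total != 0:
        res.proportion_pct = mediation_proportion(ind.indirect, res.beta_total)
        res.inconsistent = bool(
            ind.indirect != 0 and np.sign(ind.indirect) != np.sign(res.beta_total)
        )
    return res


def mediation_table(results: Sequence[MediationResult]) -> pd.DataFrame:
    """Combine pathway results into one report table (4 dp effects, 2 dp percents)."""
    df = pd.DataFrame([r.to_dict() for r in results])
    for col in ("beta1", "beta2", "beta_total", "indirect", "ci_low", "ci_high"):
        df[col] = df[col].round(4)
    df["proportion_pct"] = df["proportion_pct"].round(2)
    return df
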