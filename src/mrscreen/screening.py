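"""Batch screening of exposure panels against an outcome.

For every exposure the pipeline selects instruments, harmonizes them with
the outcome, runs the MR estimator battery and the sensitivity diagnostics,
then classifies the pair:

* ``significant`` — IVW p < alpha, IVW and MR-Egger effect directions agree,
  and the Benjamini-Hochberg FDR q-value is below alpha;
* ``suggestive``  — IVW p < alpha without the corrected-threshold pass;
* ``null``        — IVW p >= alpha;
* ``failed``      — no usable instruments (the row is kept, never dropped).

A Bonferroni threshold alpha/m over the declared test family is reported
alongside, and records whose heterogeneity or pleiotropy diagnostics reject
are demoted to a ``failed_sensitivity`` status in a separate column (the
classification itself stays a pure function of the four screening inputs).
Reverse-direction MR reuses the same machinery with outcome and exposure
roles swapped and a genome-wide significance threshold of 5e-8.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .estimators import MREstimate, fit_all
from .exceptions import ConfigurationError, DomainError, MissingMethodError
from .gwas_io import HarmonizedSet, SummaryStats, harmonize
from .instruments import (
    DEFAULT_P_THRESHOLDS,
    LDMatrix,
    SelectionParams,
    select_instruments,
)
from .sensitivity import SensitivityReport, sensitivity_report

logger = logging.getLogger(__name__)

CLASSIFICATIONS = ("significant", "suggestive", "null", "failed")


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise corrected significance threshold alpha/m."""
    if m < 1:
        raise DomainError("number of tests must be >= 1")
    if not (0 < alpha <= 1):
        raise DomainError("alpha must lie in (0, 1]")
    return alpha / m


def fdr_bh(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    Monotone-enforced and returned in the input order; an empty input yields
    an empty array.
    """
    p = np.asarray(pvalues, float)
    if p.size == 0:
        return np.array([])
    # p = 0 is tolerated: extreme z-scores underflow the normal tail
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise DomainError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def direction_consistent(estimates: Mapping[str, MREstimate]) -> bool:
    """True iff the IVW and MR-Egger betas share a strict sign.

    A zero beta in either method counts as inconsistent.  The IVW row is the
    primary (random-effects) estimate when present, else the fixed one.
    """
    ivw_est = estimates.get("ivw_random") or estimates.get("ivw_fixed")
    egger_est = estimates.get("egger")
    if ivw_est is None:
        raise MissingMethodError("ivw")
    if egger_est is None:
        raise MissingMethodError("egger")
    if ivw_est.beta == 0 or egger_est.beta == 0:
        return False
    return bool(np.sign(ivw_est.beta) == np.sign(egger_est.beta))


def classify(
    ivw_p: float,
    fdr_q: float,
    direction_ok: bool | None,
    alpha: float = 0.05,
) -> str:
    """Pure classification from the screening inputs (idempotent by design)."""
    if not np.isfinite(ivw_p):
        return "failed"
    if ivw_p < alpha:
        if direction_ok and np.isfinite(fdr_q) and fdr_q < alpha:
            return "significant"
        return "suggestive"
    return "null"


@dataclass(frozen=True)
class ScreenConfig:
    """Thresholds, seeds and switches for a screening batch.

    ``seed`` is mandatory: every stochastic component (bootstrap SEs,
    MR-PRESSO simulations) derives its own stream from it deterministically.
    """

    seed: int
    p_thresholds: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_P_THRESHOLDS)
    )
    clump_r2: float = 0.001
    clump_window_kb: float = 10_000.0
    f_min: float = 10.0
    alpha: float = 0.05
    n_boot: int = 1000
    presso_n_sim: int = 1000
    run_presso: bool = True
    run_loo: bool = False
    methods: tuple[str, ...] = (
        "ivw",
        "egger",
        "weighted_median",
        "simple_mode",
        "weighted_mode",
    )
    sensitivity_gate: bool = True
    bonferroni_m: int | None = None  # default: family size

    def selection_params(self, trait_class: str) -> SelectionParams:
        p = self.p_thresholds.get(trait_class)
        if p is None:
            raise ConfigurationError(f"no p-threshold configured for class {trait_class!r}")
        return SelectionParams(
            p_threshold=p,
            clump_r2=self.clump_r2,
            clump_window_kb=self.clump_window_kb,
            f_min=self.f_min,
        )

    @classmethod
    def from_yaml(cls, path) -> "ScreenConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "seed" not in raw:
            raise ConfigurationError("screening config must declare a top-level seed")
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        opts = {k: v for k, v in raw.items() if k in known}
        if "methods" in opts:
            opts["methods"] = tuple(opts["methods"])
        return cls(**opts)


@dataclass
class ScreenRecord:
    """Everything the pipeline learned about one exposure-outcome pair."""

    exposure: str
    outcome: str
    direction: str = "forward"
    n_instruments: int = 0
    n_snp: int = 0
    estimates: dict[str, MREstimate] = field(default_factory=dict)
    sensitivity: SensitivityReport | None = None
    ivw_p: float = np.nan
    fdr_q: float = np.nan
    bonferroni_pass: bool = False
    direction_consistent: bool | None = None
    classification: str = "failed"
    status: str = "failed"
    fail_reason: str | None = None

    def to_row(self) -> dict:
        ivw_est = self.estimates.get("ivw_random") or self.estimates.get(
            "ivw_fixed"
        ) or self.estimates.get("wald_ratio")
        row = {
            "exposure": self.exposure,
            "outcome": self.outcome,
            "direction": self.direction,
            "n_instruments": self.n_instruments,
            "n_snp": self.n_snp,
            "beta_ivw": ivw_est.beta if ivw_est else np.nan,
            "se_ivw": ivw_est.se if ivw_est else np.nan,
            "ivw_p": self.ivw_p,
            "beta_egger": self.estimates["egger"].beta if "egger" in self.estimates else np.nan,
            "fdr_q": self.fdr_q,
            "bonferroni_pass": self.bonferroni_pass,
            "direction_consistent": self.direction_consistent,
            "classification": self.classification,
            "status": self.status,
            "fail_reason": self.fail_reason,
        }
        if self.sensitivity is not None:
            row.update(self.sensitivity.to_dict())
        return row


@dataclass
class ScreenResult:
    """A screening batch: one record per exposure, in input order."""

    records: list[ScreenRecord]
    table: pd.DataFrame
    bonferroni_threshold: float


def _screen_one(
    exposure: SummaryStats,
    outcome: SummaryStats,
    config: ScreenConfig,
    seed: np.random.SeedSequence,
    ld: LDMatrix | None,
    direction: str,
) -> ScreenRecord:
    rec = ScreenRecord(
        exposure=exposure.trait_name, outcome=outcome.trait_name, direction=direction
    )
    params = config.selection_params(exposure.trait_class)
    iv = select_instruments(exposure, params, ld=ld)
    rec.n_instruments = len(iv)
    if len(iv) == 0:
        rec.fail_reason = "no_instruments"
        return rec
    hset = harmonize(exposure, outcome, iv.rsids)
    rec.n_snp = hset.n_snp
    if hset.n_snp == 0:
        rec.fail_reason = "harmonization_empty"
        return rec
    est_seed, sens_seed = seed.spawn(2)
    rec.estimates = fit_all(
        hset,
        binary_outcome=outcome.binary_outcome,
        seed=est_seed,
        n_boot=config.n_boot,
        methods=config.methods,
    )
    primary = (
        rec.estimates.get("ivw_random")
        or rec.estimates.get("ivw_fixed")
        or rec.estimates.get("wald_ratio")
    )
    rec.ivw_p = primary.pvalue
    try:
        rec.direction_consistent = direction_consistent(rec.estimates)
    except MissingMethodError:
        rec.direction_consistent = None
    rec.sensitivity = sensitivity_report(
        hset,
        seed=sens_seed,
        n_sim=config.presso_n_sim,
        run_presso=config.run_presso,
        run_loo=config.run_loo,
        egger=rec.estimates.get("egger"),
    )
    return rec


def screen_panel(
    exposures: Sequence[SummaryStats],
    outcome: SummaryStats,
    config: ScreenConfig,
    ld: LDMatrix | None = None,
) -> ScreenResult:
    """Screen a panel of exposures against one outcome.

    Emits exactly one record per exposure; exposures whose selection or
    harmonization comes up empty are recorded as ``failed``, never dropped.
    The FDR family is the set of non-failed exposures in this call (the
    caller is responsible for passing one declared family, e.g. one exposure
    class against one outcome).
    """
    seeds = np.random.SeedSequence(config.seed).spawn(len(exposures))
    records = [
        _screen_one(exp, outcome, config, s, ld, "forward")
        for exp, s in zip(exposures, seeds)
    ]
    _finalize(records, config)
    m = config.bonferroni_m or max(
        1, sum(1 for r in records if np.isfinite(r.ivw_p))
    )
    thr = bonferroni_threshold(config.alpha, m)
    for rec in records:
        rec.bonferroni_pass = bool(np.isfinite(rec.ivw_p) and rec.ivw_p < thr)
    table = pd.DataFrame([r.to_row() for r in records])
    logger.info(
        "screened %d exposures against %s: %s",
        len(records),
        outcome.trait_name,
        table["classification"].value_counts().to_dict(),
    )
    return ScreenResult(records=records, table=table, bonferroni_threshold=thr)


def _finalize(records: list[ScreenRecord], config: ScreenConfig) -> None:
    """Attach FDR q-values, classification and sensitivity-gated status."""
    tested = [r for r in records if np.isfinite(r.ivw_p)]
    if tested:
        qvals = fdr_bh([r.ivw_p for r in tested])
        for r, q in zip(tested, qvals):
            r.fdr_q = float(q)
    for r in records:
        r.classification = classify(r.ivw_p, r.fdr_q, r.direction_consistent, config.alpha)
        r.status = r.classification
        if (
            config.sensitivity_gate
            and r.classification in ("significant", "suggestive")
            and r.sensitivity is not None
            and not r.sensitivity.passes(0.05)
        ):
            r.status = "failed_sensitivity"


def reverse_mr(
    outcome_stats: SummaryStats,
    target_stats: SummaryStats,
    config: ScreenConfig,
    ld: LDMatrix | None = None,
) -> ScreenRecord:
    """Reverse-direction MR: the outcome acts as exposure at p < 5e-8.

    Returns a single record labelled ``direction="reverse"``; FDR is not
    applied (the q-value equals the IVW p for a single test).
    """
    if outcome_stats.trait_class != "outcome":
        outcome_stats = replace(outcome_stats)  # no-op; classes are advisory
    seed = np.random.SeedSequence(config.seed).spawn(1)[0]
    rec = _screen_one(outcome_stats, target_stats, config, seed, ld, "reverse")
    _finalize([rec], config)
    thr = bonferroni_threshold(config.alpha, config.bonferroni_m or 1)
    rec.bonferroni_pass = bool(np.isfinite(rec.ivw_p) and rec.ivw_p < thr)
    return rec
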