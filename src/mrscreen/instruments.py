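"""Instrumental-variable selection from GWAS summary statistics.

Selection proceeds in four steps: (1) keep variants below a per-trait-class
significance threshold, (2) greedy LD clumping so no two retained variants
within a genomic window are in linkage disequilibrium above a cut-off,
(3) compute per-variant explained variance R-squared and instrument-strength
F statistics, and (4) exclude weak instruments (F below a floor,
conventionally 10).

Two F formulas are supported.  The per-variant form F = (beta/se)^2 drives
the weak-instrument exclusion; the aggregate form
F = (R2/K) * (N - K - 1) / (1 - R2) is reported alongside for instrument
sets with known sample size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, DomainError
from .gwas_io import SummaryStats

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SelectionParams:
    """Thresholds governing instrument selection.

    Defaults follow common practice for microbiome exposures: significance
    1e-5, clumping r2 < 0.001 within 10,000 kb, weak-instrument floor F >= 10.
    """

    p_threshold: float = 1e-5
    clump_r2: float = 0.001
    clump_window_kb: float = 10_000.0
    f_min: float = 10.0

    def __post_init__(self):
        if not (0 < self.p_threshold <= 1):
            raise ConfigurationError("p_threshold must lie in (0, 1]")
        if self.clump_r2 < 0 or self.clump_window_kb < 0 or self.f_min < 0:
            raise ConfigurationError("clump_r2, clump_window_kb, f_min must be >= 0")


#: Per-trait-class significance thresholds used by the screening pipeline.
DEFAULT_P_THRESHOLDS = {
    "microbiome_taxon": 1e-5,
    "microbiome_pathway": 1e-5,
    "immune_cell": 1e-5,
    "cytokine": 5e-6,
    "outcome": 5e-8,  # outcomes acting as exposures in reverse MR
}


class LDMatrix:
    """Pluggable source of pairwise LD r-squared values.

    Three forms are supported: a dense symmetric matrix (rsid-labelled rows
    and columns), a long three-column table (rsid_a, rsid_b, r2), or the
    distance-only mode (``LDMatrix(None)``) where every pair is treated as
    independent.  Missing pairs default to r2 = 0 with a warning; ``strict``
    mode raises instead.
    """

    def __init__(self, pairs: dict | None = None, strict: bool = False):
        self._pairs = pairs
        self.strict = strict
        self._warned = False

    @classmethod
    def from_dense(cls, matrix: pd.DataFrame, strict: bool = False) -> "LDMatrix":
        pairs = {}
        rsids = list(matrix.index)
        vals = matrix.to_numpy(float)
        for i, a in enumerate(rsids):
            for j, b in enumerate(rsids):
                if i < j:
                    pairs[frozenset((a, b))] = float(vals[i, j])
        return cls(pairs, strict=strict)

    @classmethod
    def from_dense_tsv(cls, path, strict: bool = False) -> "LDMatrix":
        return cls.from_dense(pd.read_csv(path, sep="\t", index_col=0), strict=strict)

    @classmethod
    def from_long(cls, table: pd.DataFrame, strict: bool = False) -> "LDMatrix":
        pairs = {
            frozenset((a, b)): float(r)
            for a, b, r in zip(table.iloc[:, 0], table.iloc[:, 1], table.iloc[:, 2])
        }
        return cls(pairs, strict=strict)

    @classmethod
    def from_long_tsv(cls, path, strict: bool = False) -> "LDMatrix":
        return cls.from_long(pd.read_csv(path, sep="\t"), strict=strict)

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        if self._pairs is None:  # distance-only mode
            return 0.0
        key = frozenset((a, b))
        if key in self._pairs:
            return self._pairs[key]
        if self.strict:
            raise ConfigurationError(f"no LD entry for pair ({a}, {b})")
        if not self._warned:
            logger.warning(
                "missing LD entries treated as r2=0 (first pair: %s, %s)", a, b
            )
            self._warned = True
        return 0.0


@dataclass
class InstrumentSet:
    """Selected instruments for one trait plus the parameters that chose them."""

    trait_name: str
    table: pd.DataFrame  # canonical columns + r2_explained, f_stat
    params: SelectionParams = field(default_factory=SelectionParams)

    @property
    def rsids(self) -> list[str]:
        return self.table["rsid"].tolist()

    def __len__(self) -> int:
        return len(self.table)


def select_by_pvalue(stats: SummaryStats, p_threshold: float) -> pd.DataFrame:
    """All records with p-value strictly below the threshold, most significant first.

    Ties in p-value break by (chrom, pos, rsid) for determinism.
    """
    if not (0 < p_threshold <= 1):
        raise DomainError("p_threshold must lie in (0, 1]")
    df = stats.table
    hits = df[df["pvalue"] < p_threshold].copy()
    return hits.sort_values(
        ["pvalue", "chrom", "pos", "rsid"], kind="mergesort"
    ).reset_index(drop=True)


def ld_clump(
    candidates: pd.DataFrame,
    ld: LDMatrix | None = None,
    clump_r2: float = 0.001,
    clump_window_kb: float = 10_000.0,
) -> pd.DataFrame:
    """Greedy LD clumping of significance-sorted candidates.

    Repeatedly keep the most significant remaining candidate and discard
    every other candidate on the same chromosome within the window whose
    r-squared with it is at or above ``clump_r2``.  Candidates further apart
    than the window survive regardless of LD.
    """
    if ld is None:
        ld = LDMatrix(None)
    df = candidates.sort_values(
        ["pvalue", "chrom", "pos", "rsid"], kind="mergesort"
    ).reset_index(drop=True)
    window_bp = clump_window_kb * 1_000.0
    alive = np.ones(len(df), dtype=bool)
    rsid = df["rsid"].to_numpy()
    chrom = df["chrom"].astype(str).to_numpy()
    pos = df["pos"].to_numpy(float)
    keep = []
    for i in range(len(df)):
        if not alive[i]:
            continue
        keep.append(i)
        near = (
            alive
            & (chrom == chrom[i])
            & (np.abs(pos - pos[i]) <= window_bp)
        )
        near[i] = False
        for j in np.nonzero(near)[0]:
            if ld.r2(rsid[i], rsid[j]) >= clump_r2:
                alive[j] = False
    return df.iloc[keep].reset_index(drop=True)


def f_statistic(beta, se):
    """Per-variant instrument strength F = (beta / se)^2."""
    beta = np.asarray(beta, float)
    se = np.asarray(se, float)
    if np.any(se <= 0):
        raise DomainError("standard errors must be positive")
    out = (beta / se) ** 2
    return float(out) if out.ndim == 0 else out


def r2_explained(beta, eaf, trait_sd: float = 1.0):
    """Fraction of trait variance explained: 2 * eaf * (1 - eaf) * beta^2 / sd^2."""
    beta = np.asarray(beta, float)
    eaf = np.asarray(eaf, float)
    if np.any((eaf <= 0) | (eaf >= 1)):
        raise DomainError("eaf must lie strictly in (0, 1)")
    if trait_sd <= 0:
        raise DomainError("trait_sd must be positive")
    out = np.clip(2.0 * eaf * (1.0 - eaf) * beta**2 / trait_sd**2, 0.0, np.nextafter(1.0, 0.0))
    return float(out) if out.ndim == 0 else out


def f_from_r2(r2: float, n: float, k: int) -> float:
    """Aggregate instrument F = (R2 / K) * (N - K - 1) / (1 - R2)."""
    if not (0 <= r2 < 1):
        raise DomainError("r2 must lie in [0, 1)")
    if k < 1:
        raise DomainError("k must be >= 1")
    if n <= k + 1:
        raise DomainError("n must exceed k + 1")
    return (r2 / k) * (n - k - 1) / (1.0 - r2)


def filter_weak(rows: pd.DataFrame, f_min: float = 10.0) -> pd.DataFrame:
    """Retain rows with f_stat >= f_min; log the removal count."""
    strong = rows[rows["f_stat"] >= f_min]
    removed = len(rows) - len(strong)
    if removed:
        logger.info("excluded %d weak instruments (F < %g)", removed, f_min)
    return strong.reset_index(drop=True)


def select_instruments(
    stats: SummaryStats,
    params: SelectionParams | None = None,
    ld: LDMatrix | None = None,
    trait_sd: float = 1.0,
) -> InstrumentSet:
    """Full selection pipeline: p-threshold, LD clump, strength metrics, weak filter."""
    params = params or SelectionParams()
    candidates = select_by_pvalue(stats, params.p_threshold)
    survivors = ld_clump(
        candidates, ld=ld, clump_r2=params.clump_r2, clump_window_kb=params.clump_window_kb
    )
    survivors = survivors.copy()
    if len(survivors):
        eaf = survivors["eaf"].to_numpy(float)
        ok = np.isfinite(eaf) & (eaf > 0) & (eaf < 1)
        r2 = np.full(len(survivors), np.nan)
        if ok.any():
            r2[ok] = r2_explained(
                survivors["beta"].to_numpy(float)[ok], eaf[ok], trait_sd
            )
        survivors["r2_explained"] = r2
        survivors["f_stat"] = f_statistic(
            survivors["beta"].to_numpy(float), survivors["se"].to_numpy(float)
        )
        survivors = filter_weak(survivors, params.f_min)
    else:
        survivors["r2_explained"] = pd.Series(dtype=float)
        survivors["f_stat"] = pd.Series(dtype=float)
    return InstrumentSet(trait_name=stats.trait_name, table=survivors, params=params)


def aggregate_f(instruments: InstrumentSet, n: float) -> float:
    """Aggregate-formula F over a selected instrument set at sample size n."""
    r2_total = float(np.nansum(instruments.table["r2_explained"].to_numpy(float)))
    k = len(instruments)
    if k == 0:
        raise DomainError("empty instrument set")
    return f_from_r2(min(r2_total, np.nextafter(1.0, 0.0)), n, k)
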