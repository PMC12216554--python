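"""Reading, validation and allele harmonization of GWAS summary statistics.

A summary-statistics table carries one row per variant: identifier,
chromosome, position, effect allele (EA), other allele (OA), effect-allele
frequency (EAF), per-allele effect size (beta; log-odds for binary traits),
its standard error, p-value and sample size.  Harmonization aligns the
outcome (or mediator) effects onto the exposure's effect allele so that
per-variant ratios are meaningful: swapped alleles flip the sign of the
outcome beta, strand-flipped alleles are matched through their complement,
palindromic variants (A/T or C/G) are removed because their strand cannot
be resolved from alleles alone, and anything else incompatible is dropped.
Every decision is recorded in an action ledger so nothing disappears
silently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import ConfigurationError, InputError

logger = logging.getLogger(__name__)

#: Canonical column order used by :func:`write_summary_stats`.
CANONICAL_COLUMNS = (
    "rsid",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pvalue",
    "n",
)

REQUIRED_COLUMNS = (
    "rsid",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "beta",
    "se",
    "pvalue",
)

TRAIT_CLASSES = (
    "microbiome_taxon",
    "microbiome_pathway",
    "cytokine",
    "immune_cell",
    "outcome",
)

#: Possible outcomes of harmonizing one variant.
ACTIONS = (
    "kept",
    "flipped",
    "dropped_palindromic",
    "dropped_unmatched",
    "dropped_incompatible",
)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_PALINDROMIC_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


@dataclass
class VariantAssociation:
    """One variant's association record for one trait."""

    rsid: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float | None
    beta: float
    se: float
    pvalue: float
    n: float | None = None


@dataclass
class SummaryStats:
    """A validated set of per-variant associations for one trait.

    The table uses the canonical column names; ``rsid`` values are unique
    (duplicates are resolved by keeping the smallest p-value).
    """

    trait_name: str
    table: pd.DataFrame
    trait_class: str = "outcome"
    binary_outcome: bool = False
    _indexed: pd.DataFrame | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if self.trait_class not in TRAIT_CLASSES:
            raise ConfigurationError(
                f"unknown trait_class {self.trait_class!r}; expected one of {TRAIT_CLASSES}"
            )
        missing = [c for c in REQUIRED_COLUMNS if c not in self.table.columns]
        if missing:
            raise ConfigurationError(f"summary table missing columns: {missing}")
        for col in ("eaf", "n"):
            if col not in self.table.columns:
                self.table[col] = np.nan
        dup = self.table["rsid"].duplicated(keep=False)
        if dup.any():
            n_dup = int(dup.sum())
            self.table = (
                self.table.sort_values(["pvalue", "rsid"], kind="mergesort")
                .drop_duplicates("rsid", keep="first")
                .sort_index()
            )
            logger.warning(
                "%s: %d duplicated rsid rows; kept the smallest p-value per rsid",
                self.trait_name,
                n_dup,
            )
        self.table = self.table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def rsids(self) -> list[str]:
        return self.table["rsid"].tolist()

    def indexed(self) -> pd.DataFrame:
        """Table indexed by rsid, built lazily and cached."""
        if self._indexed is None:
            self._indexed = self.table.set_index("rsid")
        return self._indexed

    def record(self, rsid: str) -> VariantAssociation:
        row = self.indexed().loc[rsid]
        return VariantAssociation(
            rsid=rsid,
            chrom=str(row["chrom"]),
            pos=int(row["pos"]),
            effect_allele=str(row["effect_allele"]),
            other_allele=str(row["other_allele"]),
            eaf=None if pd.isna(row["eaf"]) else float(row["eaf"]),
            beta=float(row["beta"]),
            se=float(row["se"]),
            pvalue=float(row["pvalue"]),
            n=None if pd.isna(row["n"]) else float(row["n"]),
        )


def validate_table(df: pd.DataFrame, trait_name: str = "?") -> pd.DataFrame:
    """Drop rows violating basic invariants; warn about p/z inconsistency.

    Hard invariants (row dropped): se > 0, p-value in (0, 1], EAF in [0, 1]
    when present, effect allele differing from the other allele.  A p-value
    more than two orders of magnitude away from the normal-approximation
    p implied by |beta/se| only triggers a warning.
    """
    df = df.copy()
    se = pd.to_numeric(df["se"], errors="coerce")
    p = pd.to_numeric(df["pvalue"], errors="coerce")
    eaf = pd.to_numeric(df["eaf"], errors="coerce") if "eaf" in df else pd.Series(
        np.nan, index=df.index
    )
    bad = (
        ~(se > 0)
        | ~((p > 0) & (p <= 1))
        | (df["effect_allele"].astype(str) == df["other_allele"].astype(str))
        | (eaf.notna() & ~((eaf >= 0) & (eaf <= 1)))
    )
    if bad.any():
        logger.warning("%s: dropped %d invalid rows", trait_name, int(bad.sum()))
        df = df[~bad]
    # soft check: reported p versus normal-approximation p from |beta/se|
    with np.errstate(divide="ignore"):
        z = np.abs(pd.to_numeric(df["beta"], errors="coerce") / df["se"])
        expected = 2.0 * sps.norm.sf(z)
        lo = np.log10(np.maximum(df["pvalue"].astype(float), 1e-300))
        le = np.log10(np.maximum(expected, 1e-300))
        off = np.abs(lo - le) > 2.0
    if off.any():
        logger.warning(
            "%s: %d rows have p-values inconsistent with |beta/se| by >2 orders "
            "of magnitude (kept)",
            trait_name,
            int(off.sum()),
        )
    return df.reset_index(drop=True)


def read_summary_stats(
    path,
    column_map: Mapping[str, str] | None = None,
    trait_name: str | None = None,
    trait_class: str = "outcome",
    binary_outcome: bool = False,
    sep: str | None = None,
) -> SummaryStats:
    """Read a delimited (optionally gzipped) summary-statistics file.

    ``column_map`` maps canonical field names to the file's column names,
    e.g. ``{"rsid": "SNP", "beta": "Effect"}``; unmapped canonical names are
    assumed to appear verbatim.
    """
    if sep is None:
        # sniff the delimiter from the header so the precise C parser can be used
        import gzip

        opener = gzip.open if str(path).endswith(".gz") else open
        with opener(path, "rt") as fh:
            header = fh.readline()
        if not header.strip():
            raise InputError(f"empty summary-statistics file: {path}")
        sep = "\t" if header.count("\t") >= header.count(",") else ","
    try:
        df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise InputError(f"empty summary-statistics file: {path}") from exc
    if df.empty:
        raise InputError(f"summary-statistics file has no data rows: {path}")
    column_map = dict(column_map or {})
    rename = {}
    for canonical in CANONICAL_COLUMNS:
        source = column_map.get(canonical, canonical)
        if source in df.columns:
            rename[source] = canonical
        elif canonical in REQUIRED_COLUMNS:
            raise ConfigurationError(
                f"required column {canonical!r} (mapped from {source!r}) "
                f"not found in {path}"
            )
    df = df.rename(columns=rename)
    df = df[[c for c in CANONICAL_COLUMNS if c in df.columns]]
    for col in ("eaf", "n"):
        if col not in df.columns:
            df[col] = np.nan
    name = trait_name or str(path)
    df = validate_table(df, name)
    if df.empty:
        raise InputError(f"no valid rows remain in {path}")
    return SummaryStats(
        trait_name=name,
        table=df,
        trait_class=trait_class,
        binary_outcome=binary_outcome,
    )


def write_summary_stats(stats: SummaryStats, path) -> None:
    """Write a SummaryStats table as TSV in the canonical column order."""
    if len(stats) == 0:
        raise InputError("refusing to write an empty summary-statistics set")
    stats.table.loc[:, list(CANONICAL_COLUMNS)].to_csv(
        path, sep="\t", index=False, na_rep="NA", float_format="%.17g"
    )


def is_palindromic(a1: str, a2: str) -> bool:
    """True for complementary single-base allele pairs (A/T, T/A, C/G, G/C)."""
    return (str(a1).upper(), str(a2).upper()) in _PALINDROMIC_PAIRS


def _strand_flip(allele: str) -> str | None:
    """Complement a single-base allele; None when not a simple base."""
    return _COMPLEMENT.get(str(allele).upper())


@dataclass
class HarmonizedSet:
    """Exposure and outcome effects aligned to a common effect allele.

    ``table`` holds one row per requested rsid with an ``action`` column; the
    estimator-facing arrays expose only the retained (kept or flipped) rows.
    """

    exposure_name: str
    outcome_name: str
    table: pd.DataFrame
    binary_outcome: bool = False

    @property
    def kept(self) -> pd.DataFrame:
        return self.table[self.table["action"].isin(("kept", "flipped"))]

    @property
    def n_snp(self) -> int:
        return len(self.kept)

    @property
    def rsids(self) -> list[str]:
        return self.kept["rsid"].tolist()

    @property
    def bx(self) -> np.ndarray:
        return self.kept["beta_exposure"].to_numpy(float)

    @property
    def se_bx(self) -> np.ndarray:
        return self.kept["se_exposure"].to_numpy(float)

    @property
    def by(self) -> np.ndarray:
        return self.kept["beta_outcome"].to_numpy(float)

    @property
    def se_by(self) -> np.ndarray:
        return self.kept["se_outcome"].to_numpy(float)

    @property
    def eaf(self) -> np.ndarray:
        return self.kept["eaf"].to_numpy(float)

    def action_counts(self) -> dict[str, int]:
        counts = {a: 0 for a in ACTIONS}
        counts.update(self.table["action"].value_counts().to_dict())
        return counts


def _classify_alleles(ea_x, oa_x, ea_y, oa_y):
    """Decide the harmonization action for one variant.

    Returns (action, flip) where flip means the outcome beta changes sign.
    """
    ea_x, oa_x = str(ea_x).upper(), str(oa_x).upper()
    ea_y, oa_y = str(ea_y).upper(), str(oa_y).upper()
    if is_palindromic(ea_x, oa_x) or is_palindromic(ea_y, oa_y):
        return "dropped_palindromic", False
    if (ea_x, oa_x) == (ea_y, oa_y):
        return "kept", False
    if (ea_x, oa_x) == (oa_y, ea_y):
        return "flipped", True
    # attempt a strand flip of the outcome alleles (single bases only)
    fe, fo = _strand_flip(ea_y), _strand_flip(oa_y)
    if fe is not None and fo is not None:
        if (ea_x, oa_x) == (fe, fo):
            return "kept", False
        if (ea_x, oa_x) == (fo, fe):
            return "flipped", True
    return "dropped_incompatible", False


def harmonize(
    exposure: SummaryStats,
    outcome: SummaryStats,
    rsids: Sequence[str] | None = None,
) -> HarmonizedSet:
    """Align outcome effects onto the exposure's effect alleles.

    ``rsids`` (default: every exposure variant) must all be present in the
    exposure set.  Variants absent from the outcome become
    ``dropped_unmatched``; palindromic pairs are always dropped (no EAF
    rescue); incompatible allele pairs after strand-flip comparison are
    dropped.  The returned ledger partitions the input list across actions.
    """
    if rsids is None:
        rsids = exposure.rsids
    rsids = list(rsids)
    exp_idx = exposure.indexed()
    missing = [r for r in rsids if r not in exp_idx.index]
    if missing:
        raise InputError(
            f"{len(missing)} requested rsids absent from exposure "
            f"{exposure.trait_name!r} (e.g. {missing[:3]})"
        )
    out_idx = outcome.indexed()

    rows = []
    for rsid in rsids:
        ex = exp_idx.loc[rsid]
        base = {
            "rsid": rsid,
            "chrom": str(ex["chrom"]),
            "pos": int(ex["pos"]),
            "effect_allele": str(ex["effect_allele"]).upper(),
            "other_allele": str(ex["other_allele"]).upper(),
            "beta_exposure": float(ex["beta"]),
            "se_exposure": float(ex["se"]),
            "pvalue_exposure": float(ex["pvalue"]),
            "eaf": float(ex["eaf"]) if pd.notna(ex["eaf"]) else np.nan,
            "beta_outcome": np.nan,
            "se_outcome": np.nan,
            "eaf_outcome": np.nan,
        }
        if rsid not in out_idx.index:
            base["action"] = "dropped_unmatched"
            rows.append(base)
            continue
        oy = out_idx.loc[rsid]
        action, flip = _classify_alleles(
            ex["effect_allele"], ex["other_allele"], oy["effect_allele"], oy["other_allele"]
        )
        base["action"] = action
        if action in ("kept", "flipped"):
            sign = -1.0 if flip else 1.0
            base["beta_outcome"] = sign * float(oy["beta"])
            base["se_outcome"] = float(oy["se"])
            if pd.notna(oy["eaf"]):
                base["eaf_outcome"] = 1.0 - float(oy["eaf"]) if flip else float(oy["eaf"])
        rows.append(base)

    table = pd.DataFrame(
        rows,
        columns=[
            "rsid",
            "chrom",
            "pos",
            "effect_allele",
            "other_allele",
            "beta_exposure",
            "se_exposure",
            "pvalue_exposure",
            "eaf",
            "beta_outcome",
            "se_outcome",
            "eaf_outcome",
            "action",
        ],
    )
    hset = HarmonizedSet(
        exposure_name=exposure.trait_name,
        outcome_name=outcome.trait_name,
        table=table,
        binary_outcome=outcome.binary_outcome,
    )
    n_dropped = len(rsids) - hset.n_snp
    if n_dropped:
        logger.info(
            "harmonize %s vs %s: kept %d / %d variants (%s)",
            exposure.trait_name,
            outcome.trait_name,
            hset.n_snp,
            len(rsids),
            {k: v for k, v in hset.action_counts().items() if v},
        )
    return hset


@dataclass
class MultiHarmonizedSet:
    """Several traits aligned onto one reference trait's effect alleles.

    Used for multivariable MR: the reference is the outcome, the aligned
    traits are the exposures whose joint direct effects are estimated.
    """

    reference_name: str
    trait_names: list[str]
    table: pd.DataFrame

    @property
    def n_snp(self) -> int:
        return len(self.table)

    @property
    def rsids(self) -> list[str]:
        return self.table["rsid"].tolist()

    @property
    def y(self) -> np.ndarray:
        """Reference-trait betas (the regression response)."""
        return self.table["beta_reference"].to_numpy(float)

    @property
    def se_y(self) -> np.ndarray:
        return self.table["se_reference"].to_numpy(float)

    def X(self) -> np.ndarray:
        """Aligned trait betas as a (n_snp, n_trait) matrix."""
        return np.column_stack(
            [self.table[f"beta_{t}"].to_numpy(float) for t in self.trait_names]
        )

    def se_X(self) -> np.ndarray:
        return np.column_stack(
            [self.table[f"se_{t}"].to_numpy(float) for t in self.trait_names]
        )


def harmonize_multi(
    reference: SummaryStats,
    traits: Sequence[SummaryStats],
    rsids: Sequence[str],
) -> MultiHarmonizedSet:
    """Jointly align several traits onto the reference's effect alleles.

    Only variants present and allele-compatible in the reference and in
    every trait are retained.  Requested rsids absent from the reference are
    silently skipped (they carry no response value).
    """
    rsids = [r for r in rsids if r in reference.indexed().index]
    per_trait = {t.trait_name: harmonize(reference, t, rsids) for t in traits}
    common = None
    for hset in per_trait.values():
        kept = set(hset.rsids)
        common = kept if common is None else (common & kept)
    common = common or set()
    order = [r for r in rsids if r in common]

    ref_idx = reference.indexed()
    data = {
        "rsid": order,
        "beta_reference": [float(ref_idx.loc[r, "beta"]) for r in order],
        "se_reference": [float(ref_idx.loc[r, "se"]) for r in order],
    }
    for name, hset in per_trait.items():
        k = hset.kept.set_index("rsid")
        data[f"beta_{name}"] = [float(k.loc[r, "beta_outcome"]) for r in order]
        data[f"se_{name}"] = [float(k.loc[r, "se_outcome"]) for r in order]
    return MultiHarmonizedSet(
        reference_name=reference.trait_name,
        trait_names=[t.trait_name for t in traits],
        table=pd.DataFrame(data),
    )


def harmonized_from_arrays(
    bx, se_bx, by, se_by, rsids=None, eaf=None, binary_outcome=False,
    exposure_name="exposure", outcome_name="outcome",
) -> HarmonizedSet:
    """Build a HarmonizedSet directly from aligned effect arrays.

    Convenience constructor for simulation studies and tests where the
    alleles are already aligned by construction.
    """
    bx = np.asarray(bx, float)
    k = len(bx)
    table = pd.DataFrame(
        {
            "rsid": list(rsids) if rsids is not None else [f"rs{i + 1}" for i in range(k)],
            "chrom": "1",
            "pos": np.arange(1, k + 1),
            "effect_allele": "A",
            "other_allele": "G",
            "beta_exposure": bx,
            "se_exposure": np.asarray(se_bx, float),
            "pvalue_exposure": np.nan,
            "eaf": np.asarray(eaf, float) if eaf is not None else np.nan,
            "beta_outcome": np.asarray(by, float),
            "se_outcome": np.asarray(se_by, float),
            "eaf_outcome": np.nan,
            "action": "kept",
        }
    )
    return HarmonizedSet(exposure_name, outcome_name, table, binary_outcome)
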