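"""Synthetic GWAS summary statistics for exposure-mediator-outcome trios.

The generator works directly at the summary level: for each variant a true
per-allele effect is drawn, and the observed effect is that truth plus
normal noise with standard error 1/sqrt(2*eaf*(1-eaf)*n) — the standard
error of a per-allele regression coefficient for a standardized trait at
sample size n.  The causal diagram is

    exposure --beta1--> mediator --beta2--> outcome
        \\________________theta_direct________________/

so a variant with instrument effect gamma on the exposure carries
beta1*gamma onto the mediator and (theta_direct + beta1*beta2)*gamma onto
the outcome; theta_total = theta_direct + beta1*beta2 by construction.
Mediator-specific instruments (effect delta on the mediator, none on the
exposure) make the mediator identifiable in multivariable MR.  Horizontal
pleiotropy adds a per-variant alpha directly on the outcome: balanced
(zero-mean), directional (non-zero mean), or correlated with gamma
(violating the InSIDE assumption); a configurable fraction of the
exposure's instruments is affected.

Instrument-strength presets: "strong" targets mean F around 30-60 at the
default exposure sample size (typical of microbiome GWAS hits), "weak"
mean F around 8 (to exercise the weak-instrument filter), "very_strong"
mean F in the thousands (so finite-sample regression dilution is
negligible in parameter-recovery studies).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

from .exceptions import ConfigurationError
from .gwas_io import SummaryStats

PLEIOTROPY_MODES = ("none", "balanced", "directional", "correlated")

#: Instrument-effect presets: (distribution, low, high) magnitudes with random sign.
GAMMA_PRESETS = {
    "strong": ("uniform_magnitude", 0.06, 0.14),
    "weak": ("uniform_magnitude", 0.030, 0.055),
    "spread": ("uniform_magnitude", 0.02, 0.20),
    "very_strong": ("uniform_magnitude", 0.30, 0.50),
}


@dataclass
class SimulationConfig:
    """Generative parameters for one exposure-mediator-outcome trio.

    ``theta_total`` is derived as ``theta_direct + beta1_true*beta2_true``
    when omitted; supplying an inconsistent value is a configuration error.
    """

    n_snps_causal: int = 30
    n_snps_mediator: int = 0
    n_snps_outcome: int = 0
    n_snps_null: int = 0
    n_exposure: int = 10_000
    n_mediator: int = 50_000
    n_outcome: int = 200_000
    beta1_true: float = 0.0
    beta2_true: float = 0.0
    theta_direct: float = 0.0
    theta_total: float | None = None
    pleiotropy_mode: str = "none"
    pleiotropy_mean: float = 0.015
    pleiotropy_sd: float = 0.004
    pleiotropy_frac: float = 1.0
    pleiotropy_rho: float = 0.5
    gamma_dist: tuple = GAMMA_PRESETS["strong"]
    delta_dist: tuple = GAMMA_PRESETS["strong"]
    #: outcome-specific (disease-locus) effects; sized for a large outcome GWAS
    kappa_dist: tuple = ("uniform_magnitude", 0.025, 0.06)
    eaf_range: tuple = (0.1, 0.9)
    ld_blocks: list | None = None
    binary_outcome: bool = True
    seed: int | None = None

    def __post_init__(self):
        if self.pleiotropy_mode not in PLEIOTROPY_MODES:
            raise ConfigurationError(
                f"pleiotropy_mode must be one of {PLEIOTROPY_MODES}"
            )
        if isinstance(self.gamma_dist, str):
            self.gamma_dist = GAMMA_PRESETS[self.gamma_dist]
        if isinstance(self.delta_dist, str):
            self.delta_dist = GAMMA_PRESETS[self.delta_dist]
        for dist in (self.gamma_dist, self.delta_dist, self.kappa_dist):
            if dist[0] not in ("uniform_magnitude", "normal") or len(dist) != 3:
                raise ConfigurationError(f"unsupported effect distribution {dist!r}")
        if not (0 <= self.pleiotropy_frac <= 1):
            raise ConfigurationError("pleiotropy_frac must lie in [0, 1]")
        lo, hi = self.eaf_range
        if not (0 < lo < hi < 1):
            raise ConfigurationError("eaf_range must satisfy 0 < low < high < 1")
        implied = self.theta_direct + self.beta1_true * self.beta2_true
        if self.theta_total is None:
            self.theta_total = implied
        elif abs(self.theta_total - implied) > 1e-9:
            raise ConfigurationError(
                f"theta_total={self.theta_total} inconsistent with "
                f"theta_direct + beta1*beta2 = {implied}"
            )


@dataclass
class TruthRecord:
    """Latent parameters behind one simulated trio (YAML-serializable)."""

    config: dict
    rsids: list
    gamma: list  # instrument effects on the exposure
    delta: list  # mediator-specific instrument effects
    kappa: list  # outcome-specific (disease-locus) effects
    alpha: list  # direct (pleiotropic) effects on the outcome
    theta_total: float

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_yaml())

    @classmethod
    def from_yaml(cls, text: str) -> "TruthRecord":
        return cls(**yaml.safe_load(text))

    @classmethod
    def load(cls, path) -> "TruthRecord":
        with open(path) as fh:
            return cls.from_yaml(fh.read())


def _draw_effects(dist: tuple, size: int, rng: np.random.Generator) -> np.ndarray:
    kind, a, b = dist
    if kind == "uniform_magnitude":
        mag = rng.uniform(a, b, size)
        return mag * rng.choice([-1.0, 1.0], size)
    return rng.normal(a, b, size)


def gwas_se(eaf: np.ndarray, n: float) -> np.ndarray:
    """Analytic SE of a per-allele effect for a standardized trait."""
    return 1.0 / np.sqrt(2.0 * eaf * (1.0 - eaf) * n)


def simulate_effect_arrays(config: SimulationConfig, rng: np.random.Generator) -> dict:
    """Draw one trio's per-variant truth and observed effects as arrays.

    The array layout is causal exposure instruments first, then
    mediator-specific instruments, then null variants.  This is the
    computational core behind :func:`simulate_trio`; replicate studies use
    it directly to avoid table-construction overhead.
    """
    nc, nm = config.n_snps_causal, config.n_snps_mediator
    no, nn = config.n_snps_outcome, config.n_snps_null
    m = nc + nm + no + nn
    eaf = rng.uniform(*config.eaf_range, m)
    gamma = np.zeros(m)
    gamma[:nc] = _draw_effects(config.gamma_dist, nc, rng)
    delta = np.zeros(m)
    delta[nc : nc + nm] = np.abs(_draw_effects(config.delta_dist, nm, rng))
    kappa = np.zeros(m)
    kappa[nc + nm : nc + nm + no] = _draw_effects(config.kappa_dist, no, rng)

    alpha = np.zeros(m)
    if config.pleiotropy_mode != "none" and nc:
        n_aff = int(round(config.pleiotropy_frac * nc))
        affected = rng.choice(nc, size=n_aff, replace=False)
        if config.pleiotropy_mode == "balanced":
            alpha[affected] = rng.normal(0.0, config.pleiotropy_sd, n_aff)
        elif config.pleiotropy_mode == "directional":
            # aligned with the exposure-raising allele, so the mean survives
            # the bx > 0 orientation applied by MR-Egger
            alpha[affected] = np.sign(gamma[affected]) * rng.normal(
                config.pleiotropy_mean, config.pleiotropy_sd, n_aff
            )
        else:  # correlated with the instrument effect: violates InSIDE
            alpha[affected] = config.pleiotropy_rho * gamma[affected] + rng.normal(
                0.0, config.pleiotropy_sd, n_aff
            )

    true_bx = gamma
    true_bm = config.beta1_true * gamma + delta
    true_by = config.theta_direct * gamma + config.beta2_true * true_bm + alpha + kappa

    se_x = gwas_se(eaf, config.n_exposure)
    se_m = gwas_se(eaf, config.n_mediator)
    se_y = gwas_se(eaf, config.n_outcome)
    bx = true_bx + se_x * rng.standard_normal(m)
    bm = true_bm + se_m * rng.standard_normal(m)
    by = true_by + se_y * rng.standard_normal(m)
    return {
        "eaf": eaf,
        "gamma": gamma,
        "delta": delta,
        "kappa": kappa,
        "alpha": alpha,
        "bx": bx,
        "se_x": se_x,
        "bm": bm,
        "se_m": se_m,
        "by": by,
        "se_y": se_y,
        "n_causal": nc,
        "n_mediator_snps": nm,
        "n_outcome_snps": no,
        "n_null": nn,
    }


def _positions(m: int) -> tuple[np.ndarray, np.ndarray]:
    """Chromosome labels and positions spaced beyond any clumping window."""
    chroms = np.array([str(1 + i % 22) for i in range(m)])
    pos = 1 + 20_000_000 * (np.arange(m) // 22)
    return chroms, pos.astype(int)


def _pvalues(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2.0 * sps.norm.sf(np.abs(beta / se))
    return np.maximum(p, np.finfo(float).tiny)  # summary files never print p = 0


def _stats_frame(rsids, chroms, pos, eaf, beta, se, n) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "rsid": rsids,
            "chrom": chroms,
            "pos": pos,
            "effect_allele": "A",
            "other_allele": "G",
            "eaf": eaf,
            "beta": beta,
            "se": se,
            "pvalue": _pvalues(beta, se),
            "n": float(n),
        }
    )


def simulate_trio(
    config: SimulationConfig, seed: int | np.random.SeedSequence | None = None
) -> tuple[SummaryStats, SummaryStats, SummaryStats, TruthRecord]:
    """Generate exposure, mediator and outcome summary statistics plus truth.

    The same seed reproduces the trio bit-for-bit.  Variants are placed
    farther apart than the default clumping window so LD pruning is a no-op
    unless an LD panel is simulated explicitly.
    """
    if seed is None:
        seed = config.seed
    if seed is None:
        raise ConfigurationError("simulate_trio requires a seed")
    rng = np.random.default_rng(seed)
    arr = simulate_effect_arrays(config, rng)
    m = len(arr["bx"])
    rsids = [f"rs{i + 1:06d}" for i in range(m)]
    chroms, pos = _positions(m)

    exposure = SummaryStats(
        "sim_exposure",
        _stats_frame(rsids, chroms, pos, arr["eaf"], arr["bx"], arr["se_x"], config.n_exposure),
        trait_class="microbiome_taxon",
    )
    mediator = SummaryStats(
        "sim_mediator",
        _stats_frame(rsids, chroms, pos, arr["eaf"], arr["bm"], arr["se_m"], config.n_mediator),
        trait_class="immune_cell",
    )
    outcome = SummaryStats(
        "sim_outcome",
        _stats_frame(rsids, chroms, pos, arr["eaf"], arr["by"], arr["se_y"], config.n_outcome),
        trait_class="outcome",
        binary_outcome=config.binary_outcome,
    )
    truth = TruthRecord(
        config={
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        rsids=rsids,
        gamma=[float(g) for g in arr["gamma"]],
        delta=[float(d) for d in arr["delta"]],
        kappa=[float(x) for x in arr["kappa"]],
        alpha=[float(a) for a in arr["alpha"]],
        theta_total=float(config.theta_total),
    )
    return exposure, mediator, outcome, truth


def simulate_ld_panel(
    config: SimulationConfig, seed: int | np.random.SeedSequence | None = None
) -> tuple[SummaryStats, pd.DataFrame]:
    """Candidate summary statistics with block-structured LD.

    ``config.ld_blocks`` is a list of (block_size, within_block_r2) pairs.
    Variants within a block sit 10 kb apart (well inside the clumping
    window); successive blocks are separated by more than the default
    window so clumping treats them independently.  Between-block r2 is 0.
    Effect sizes decrease along the panel so the significance ranking is
    deterministic.
    """
    if not config.ld_blocks:
        raise ConfigurationError("simulate_ld_panel requires non-empty ld_blocks")
    if seed is None:
        seed = config.seed
    if seed is None:
        raise ConfigurationError("simulate_ld_panel requires a seed")
    rng = np.random.default_rng(seed)
    sizes = [int(b[0]) for b in config.ld_blocks]
    r2s = [float(b[1]) for b in config.ld_blocks]
    m = sum(sizes)
    rsids = [f"ld{i + 1:04d}" for i in range(m)]
    pos = np.empty(m, int)
    r2 = np.eye(m)
    i = 0
    for b, (size, rho) in enumerate(zip(sizes, r2s)):
        base = 1 + b * 20_000_000
        for j in range(size):
            pos[i + j] = base + j * 10_000
        r2[i : i + size, i : i + size] = rho
        np.fill_diagonal(r2[i : i + size, i : i + size], 1.0)
        i += size

    eaf = rng.uniform(*config.eaf_range, m)
    se = gwas_se(eaf, config.n_exposure)
    bx = 0.20 - 0.002 * np.arange(m)  # deterministic ladder: ranking is the point
    stats = SummaryStats(
        "sim_ld_panel",
        _stats_frame(rsids, ["1"] * m, pos, eaf, bx, se, config.n_exposure),
        trait_class="microbiome_taxon",
    )
    ld = pd.DataFrame(r2, index=rsids, columns=rsids)
    return stats, ld


# ---------------------------------------------------------------------------
# Published mediation-table fixture
# ---------------------------------------------------------------------------

#: columns: exposure_db, exposure, mediator, outcome, beta1, beta2,
#: beta_total, printed mediated effect, its printed decimal places, printed
#: CI bounds, printed p-value, printed mediation proportion (percent).
_TABLE1_ROWS = [
    ("MiBioGen", "genus Coprococcus3", "CD3 on CD28+ CD4-CD8- T cell", "CKD",
     -0.3545, -0.0282, -0.1364, 0.0100, 4, -0.030, 0.023, 0.1290, -7.33),
    ("MiBioGen", "genus Coprococcus3", "Naive-mature B cell Absolute Count", "CKD",
     0.3063, -0.0295, -0.1364, -0.0090, 4, -0.021, 0.003, 0.1331, 6.62),
    ("MiBioGen", "genus LachnospiraceaeUCG010", "Naive-mature B cell Absolute Count", "CKD",
     0.2721, -0.0295, -0.1183, -0.0080, 4, -0.018, 0.001, 0.0982, 6.78),
    ("MiBioGen", "order Desulfovibrionales", "CD45RA+ CD8+ T cell %T cell", "CKD",
     0.2192, 0.0044, 0.1420, 0.0009, 4, 0.000, 0.002, 0.1423, 0.67),
    ("DMP", "species Alistipes indistinctus", "CD28+ CD45RA+ CD8+ T cell %", "CKD",
     -0.2395, 0.0048, 0.0729, -0.0012, 4, -0.002, 0.000, 0.0033, -1.59),
    ("DMP", "species Alistipes indistinctus", "CD28+ CD45RA+ CD8dim T cell %", "CKD",
     -0.2028, 0.0110, 0.0729, -0.0022, 4, -0.005, 0.000, 0.0560, -3.06),
    ("DMP", "species Alistipes indistinctus", "CD45RA+ CD8+ T cell %", "CKD",
     -0.2498, 0.0044, 0.0729, -0.0011, 4, -0.002, 0.000, 0.0832, -1.50),
    ("DMP", "species Alistipes indistinctus", "CD86 on myeloid Dendritic Cell", "CKD",
     -0.1896, -0.0450, 0.0729, 0.0085, 4, -0.002, 0.019, 0.1032, 11.72),
    # printed with five decimals in the source table; compared at the
    # table-wide four-decimal precision (see docs/methods.md)
    ("DMP", "species Alistipes putredinis", "CD28+ CD45RA+ CD8+ T cell %", "CKD",
     -0.3274, 0.0048, 0.1310, -0.00159, 4, -0.003, 0.000, 0.0094, -1.21),
    ("DMP", "species Alistipes putredinis", "CD45RA+ CD8+ T cell %", "CKD",
     -0.4103, 0.0044, 0.1310, -0.0018, 4, -0.004, 0.000, 0.0685, -1.37),
    ("DMP", "species Lachnospiraceae bacterium", "CD86 on myeloid Dendritic Cell", "CKD",
     -0.1289, -0.0450, 0.0404, 0.0058, 4, 0.000, 0.012, 0.0613, 14.36),
    ("DMP", "genus Coprobacter", "CD33 on Granulocytic Myeloid-Derived Suppressor Cells", "CKD",
     -0.5003, 0.0243, 0.0820, -0.012, 3, -0.024, -0.001, 0.0401, -14.81),
    ("DMP", "species Coprobacter fastidiosus", "CD33 on Granulocytic Myeloid-Derived Suppressor Cells", "CKD",
     -0.4992, 0.0243, 0.0818, -0.0121, 4, -0.024, -0.001, 0.0401, -14.83),
    ("DMP", "genus Streptococcus", "CD33 on Granulocytic Myeloid-Derived Suppressor Cells", "CKD",
     0.2985, 0.0243, -0.0678, 0.0072, 4, -0.001, 0.016, 0.0897, -10.70),
    ("DMP", "1,4-dihydroxy-2-naphthoate biosynthesis II", "CD33 on Granulocytic Myeloid-Derived Suppressor Cells", "CKD",
     0.2602, 0.0243, 0.0634, 0.0063, 4, -0.001, 0.013, 0.0839, 9.97),
    ("DMP", "1,4-dihydroxy-2-naphthoate biosynthesis II", "Naive-mature B cell Absolute Count", "CKD",
     0.1390, -0.0295, 0.0634, -0.0041, 4, -0.009, 0.001, 0.1166, -6.47),
    ("DMP", "starch degradation III", "CD45RA+ CD8+ T cell %", "CKD",
     0.0771, 0.0044, -0.0408, 0.0003, 4, 0.000, 0.001, 0.1436, -0.83),
    ("DMP", "sucrose degradation IV (sucrose phosphorylase)", "HVEM on CD4+ T cell", "CKD",
     0.4229, -0.0215, 0.1167, -0.009, 3, -0.020, 0.002, 0.1072, -7.78),
    ("DMP", "sucrose degradation IV (sucrose phosphorylase)", "CD45RA on Terminally Differentiated CD8+ T cell", "CKD",
     0.2939, -0.0605, 0.1167, -0.0178, 4, -0.037, 0.001, 0.0687, -15.24),
    ("DMP", "purine nucleotides de novo biosynthesis", "IgD on IgD+ CD24- B cell", "CKD",
     0.1977, -0.0349, -0.0947, -0.0070, 4, -0.016, 0.002, 0.1280, 7.29),
    ("DMP", "superpathway of polyamine biosynthesis I", "CD45RA+ CD8+ T cell %", "CKD",
     0.3595, 0.0044, -0.1265, 0.0016, 4, 0.000, 0.003, 0.0747, -1.25),
    ("DMP", "superpathway of polyamine biosynthesis I", "CD28+ CD45RA+ CD8+ T cell %", "CKD",
     0.2548, 0.0048, -0.1265, 0.0012, 4, 0.000, 0.002, 0.0221, -0.98),
]


def fixture_table1() -> pd.DataFrame:
    """Published two-step mediation results (gut microbiome -> immune cell -> CKD).

    The printed (beta1, beta2, beta_total) triples together with the printed
    mediated effects, intervals, p-values and signed mediation proportions,
    packaged for regression tests of the product-method arithmetic.
    """
    return pd.DataFrame(
        _TABLE1_ROWS,
        columns=[
            "exposure_db",
            "exposure",
            "mediator",
            "outcome",
            "beta1",
            "beta2",
            "beta_total",
            "mediated_printed",
            "mediated_decimals",
            "ci_low_printed",
            "ci_high_printed",
            "pvalue_printed",
            "proportion_pct_printed",
        ],
    )
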