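import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from mrscreen.gwas_io import SummaryStats

settings.register_profile(
    "ci",
    deadline=None,
    max_examples=50,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_stats(
    rows,
    trait_name="trait",
    trait_class="microbiome_taxon",
    binary_outcome=False,
):
    """Build a SummaryStats from (rsid, chrom, pos, ea, oa, eaf, beta, se, p, n) tuples."""
    df = pd.DataFrame(
        rows,
        columns=[
            "rsid", "chrom", "pos", "effect_allele", "other_allele",
            "eaf", "beta", "se", "pvalue", "n",
        ],
    )
    return SummaryStats(trait_name, df, trait_class, binary_outcome)


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def simple_pair():
    """A 5-variant exposure/outcome pair covering every harmonization action."""
    exposure = make_stats(
        [
            ("rs1", "1", 1000, "A", "G", 0.30, 0.10, 0.01, 1e-8, 10000),
            ("rs2", "1", 2000, "C", "T", 0.40, -0.08, 0.01, 1e-7, 10000),
            ("rs3", "2", 1000, "A", "T", 0.50, 0.12, 0.01, 1e-9, 10000),  # palindromic
            ("rs4", "2", 2000, "G", "C", 0.20, 0.09, 0.01, 1e-6, 10000),  # palindromic
            ("rs5", "3", 1000, "T", "C", 0.10, 0.11, 0.01, 1e-8, 10000),
        ]
    )
    outcome = make_stats(
        [
            ("rs1", "1", 1000, "A", "G", 0.30, 0.20, 0.02, 1e-4, 50000),   # same
            ("rs2", "1", 2000, "T", "C", 0.60, 0.05, 0.02, 1e-3, 50000),   # swapped
            ("rs3", "2", 1000, "A", "T", 0.50, 0.01, 0.02, 0.5, 50000),
            ("rs4", "2", 2000, "G", "C", 0.20, 0.02, 0.02, 0.4, 50000),
        ],
        trait_name="outcome",
        trait_class="outcome",
        binary_outcome=True,
    )
    return exposure, outcome
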