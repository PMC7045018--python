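import math
from fractions import Fraction

import hypothesis
import pytest

from varcount import simulate
from varcount.model import Genotype

hypothesis.settings.register_profile(
    "repro", derandomize=True, database=None, deadline=None
)
hypothesis.settings.load_profile("repro")


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def fisher_p_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by direct enumeration of all fixed-margin tables.

    Probability-mass rule with exact rational hypergeometric probabilities in
    factorial form (independent of the implementation's binomial-numerator
    route).
    """
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    f = math.factorial

    def pmf(k):
        return Fraction(
            f(r1) * f(r2) * f(c1) * f(n - c1),
            f(n) * f(k) * f(r1 - k) * f(c1 - k) * f(r2 - c1 + k),
        )

    lo, hi = max(0, c1 - r2), min(r1, c1)
    obs = pmf(a)
    return float(sum(pmf(k) for k in range(lo, hi + 1) if pmf(k) <= obs))


def compound_het_oracle(genotypes) -> bool:
    """Exhaustive pair enumeration: alt of one variant on each haplotype.

    ``genotypes`` is a list of phased diploid Genotypes (one per variant).
    """
    n = len(genotypes)
    for i in range(n):
        for j in range(i + 1, n):
            gi, gj = genotypes[i], genotypes[j]
            a0 = gi.alleles[0] == 1 and gj.alleles[1] == 1
            a1 = gi.alleles[1] == 1 and gj.alleles[0] == 1
            if a0 or a1:
                return True
    return False


# hand-enumerated transmission truth table over the four non-missing parental
# carrier configurations per variant: (mother carries, father carries)
PARENT_CONFIG_ORIGIN = {
    (True, True): "both_parents",
    (True, False): "maternal_only",
    (False, True): "paternal_only",
    (False, False): "neither_parent",
}

PAIR_TRUTH_TABLE = {
    ("maternal_only", "paternal_only"): "in_trans",
    ("paternal_only", "maternal_only"): "in_trans",
    ("maternal_only", "maternal_only"): "in_cis",
    ("paternal_only", "paternal_only"): "in_cis",
    ("maternal_only", "both_parents"): "ambiguous",
    ("paternal_only", "both_parents"): "ambiguous",
    ("both_parents", "maternal_only"): "ambiguous",
    ("both_parents", "paternal_only"): "ambiguous",
    ("both_parents", "both_parents"): "ambiguous",
    ("neither_parent", "maternal_only"): "excluded_de_novo",
    ("neither_parent", "paternal_only"): "excluded_de_novo",
    ("neither_parent", "both_parents"): "excluded_de_novo",
    ("neither_parent", "neither_parent"): "excluded_de_novo",
    ("maternal_only", "neither_parent"): "excluded_de_novo",
    ("paternal_only", "neither_parent"): "excluded_de_novo",
    ("both_parents", "neither_parent"): "excluded_de_novo",
}


# ---------------------------------------------------------------------------
# shared fixtures
# ---------------------------------------------------------------------------

def small_config(seed: int = 5, **overrides) -> simulate.SimulationConfig:
    defaults = dict(
        n_controls=40,
        n_trios=20,
        n_controls_eu=20,
        n_trios_eu=15,
        maf_threshold=0.2,
        common_af_range=(0.3, 0.7),
        transcripts=(
            simulate.TranscriptPlan(
                "T1", "G1", trans_pairs_cases=3, trans_pairs_controls=1
            ),
            simulate.TranscriptPlan(
                "T2",
                "G2",
                cis_pairs_cases=2,
                de_novo_pairs_cases=1,
                hom_carriers_cases=1,
                hom_carriers_controls=2,
            ),
        ),
        seed=seed,
    )
    defaults.update(overrides)
    return simulate.SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def small_controls():
    return simulate.simulate_controls(small_config())


@pytest.fixture(scope="session")
def small_trios():
    return simulate.simulate_trios(small_config())


def gt(a0, a1, phased=False) -> Genotype:
    return Genotype((a0, a1), phased)
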