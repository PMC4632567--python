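"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

from fractions import Fraction

import numpy as np
import pytest

from sexgames import GenotypeDistribution, ModelParams

#: Printed pair-fitness expressions by (male M genotype, female M genotype),
#: used as an oracle independent of the R*(1 + b_m*b_f) implementation.
FITNESS_EXPRESSIONS = {
    ("nn", "nn"): lambda R, b, k: 2 * R,
    ("nn", "nc"): lambda R, b, k: R * (2 - k * (1 - b)),
    ("nn", "cc"): lambda R, b, k: R * (1 + b),
    ("nc", "nn"): lambda R, b, k: R * (2 - k),
    ("nc", "nc"): lambda R, b, k: R * (2 - k - k * (1 - k) * (1 - b)),
    ("nc", "cc"): lambda R, b, k: R * (1 + b * (1 - k)),
    ("cc", "nn"): lambda R, b, k: R,
    ("cc", "nc"): lambda R, b, k: R,
    ("cc", "cc"): lambda R, b, k: R,
}


def gametes(q: int) -> list[tuple[str, str]]:
    """The four (S allele, M allele) gametes of sexual genotype q in G4..G9."""
    s_alleles = ["a", "s"] if q < 3 else ["s", "s"]
    m = q % 3
    m_alleles = ["n", "n"] if m == 0 else (["n", "c"] if m == 1 else ["c", "c"])
    return [(sa, ma) for sa in s_alleles for ma in m_alleles]


def enumerate_offspring(q_male: int, q_female: int) -> list[Fraction]:
    """Brute-force 4x4 gamete enumeration of a sexual crossing (exact)."""
    out = [Fraction(0)] * 9
    for gm in gametes(q_male):
        for gf in gametes(q_female):
            s_count = (gm[0] == "s") + (gf[0] == "s")
            c_count = (gm[1] == "c") + (gf[1] == "c")
            out[3 * s_count + c_count] += Fraction(1, 16)
    return out


def random_distribution(rng: np.random.Generator) -> GenotypeDistribution:
    return GenotypeDistribution(rng.dirichlet(np.ones(9)))


def random_params(rng: np.random.Generator, **fixed) -> ModelParams:
    values = dict(
        R=rng.uniform(0.0, 3.0),
        m=rng.uniform(1.0, 8.0),
        b=rng.uniform(0.0, 1.0),
        k=rng.uniform(0.0, 1.0),
        alpha=rng.uniform(0.0, 1.0),
    )
    values.update(fixed)
    return ModelParams(**values)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)
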