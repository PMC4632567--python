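"""Exact one-generation recursion of a two-locus diploid reproduction game.

The population is infinite and diploid, with discrete non-overlapping
generations.  Two unlinked autosomal loci control reproduction:

* Locus **S** sets the reproductive mode.  ``aa`` individuals reproduce
  clonally (parthenogenesis, strategy S1), ``ss`` individuals reproduce
  sexually, and ``as`` heterozygotes reproduce sexually with probability
  ``alpha`` and clonally otherwise.
* Locus **M** sets the mating system of sexuals, and is silent in
  asexuals.  ``nn`` males are monogamous and provide full parental care
  ("non-costly" sex, strategy S2); ``cc`` males are polygynous, invest
  everything in mate competition and provide no care ("costly" sex,
  strategy S3, which carries the twofold cost); ``nc`` males are
  intermediate according to the dominance ``k`` of the polygyny allele c.

Because the population is infinite, the state is just the 9-vector of
genotype frequencies (aa/as/ss crossed with nn/nc/cc) and one generation
is a deterministic map on the probability simplex: clonal parents copy
their genotype with fitness 1, sexual pairs form at random (weighted by
male mating success), each pair produces Mendelian offspring with a
fitness proportional to ``R * (1 + b_m * b_f)``, and the pooled
contributions are renormalized.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache
from typing import Iterable, NamedTuple, Sequence

import numpy as np

__all__ = [
    "ModelParams",
    "GenotypeDistribution",
    "CareLevels",
    "MatingRates",
    "AlleleFrequencies",
    "FitnessConstants",
    "FITNESS_CONSTANTS",
    "DegenerateStateError",
    "GENOTYPE_LABELS",
    "M_GENOTYPES",
    "S_GENOTYPES",
    "sexual_fraction",
    "care_levels",
    "pair_fitness",
    "mating_rates",
    "segregation_tensor",
    "asexual_contributions",
    "sexual_contributions",
    "step",
    "allele_frequencies",
]

S_GENOTYPES = ("aa", "as", "ss")
M_GENOTYPES = ("nn", "nc", "cc")

#: Genotype order used throughout: index i encodes (S genotype i // 3,
#: M genotype i % 3), i.e. G1=(aa,nn) ... G9=(ss,cc).
GENOTYPE_LABELS = tuple(
    f"{s} {m}" for s in S_GENOTYPES for m in M_GENOTYPES
)

_M_INDEX = {"nn": 0, "nc": 1, "cc": 2}


class DegenerateStateError(RuntimeError):
    """Raised when the total reproductive contribution of a state is zero.

    This cannot happen for a valid genotype distribution (asexuals always
    contribute with fitness 1, and a purely sexual population contributes
    at least one pair type with positive fitness); it guards against
    numerically corrupted states fed through private entry points.
    """


@dataclass(frozen=True)
class FitnessConstants:
    """Fixed constants of the individual fitness ``W = r * N * R * (1 + b_m b_f)``.

    ``r`` is parent-to-offspring relatedness (1 for clones, 1/2 through
    either sexual parent) and ``N`` the number of descendants per
    strategist before fitness weighting.  They are structural constants of
    the model, not tunable parameters.
    """

    r_sexual: float = 0.5
    r_asexual: float = 1.0
    n_descendants: float = 1.0


FITNESS_CONSTANTS = FitnessConstants()


@dataclass(frozen=True)
class ModelParams:
    """The five scalar parameters of the model.

    Parameters
    ----------
    R : float
        Benefit of recombination: multiplicative fitness advantage of a
        sexually produced offspring relative to a clonal one.  Must be
        >= 0; the biologically interesting range is 1--2 (below the
        twofold benefit that would trivially pay for costly sex).
    m : float
        Polygyny potential: maximum mean number of mates of a polygynous
        (cc) male, attained when polygynous males are rare.  Must be >= 1.
    b : float
        Proportion of the potential male care that a polygynous-genotype
        (cc) female accepts, in [0, 1].
    k : float
        Dominance of the polygyny allele c over n at locus M (k=1: c
        dominant, k=0: c recessive), in [0, 1].
    alpha : float
        Probability that an ``as`` heterozygote reproduces sexually,
        in [0, 1].
    """

    R: float
    m: float
    b: float
    k: float
    alpha: float

    def __post_init__(self) -> None:
        if not self.R >= 0:
            raise ValueError(f"R must satisfy R >= 0 (got {self.R})")
        if not self.m >= 1:
            raise ValueError(f"m must satisfy m >= 1 (got {self.m})")
        for name in ("b", "k", "alpha"):
            value = getattr(self, name)
            if not 0 <= value <= 1:
                raise ValueError(
                    f"{name} must lie in [0, 1] (got {value})"
                )


class GenotypeDistribution:
    """Frequencies of the nine two-locus genotypes.

    Entries follow :data:`GENOTYPE_LABELS`.  Construction validates
    nonnegativity, checks the total against 1 within ``atol`` and
    renormalizes; inputs that already sum to 1 at machine precision are
    kept bit-identical so that serialization round-trips exactly.
    """

    __slots__ = ("p",)

    def __init__(self, p: Iterable[float], atol: float = 1e-12) -> None:
        arr = np.array(p, dtype=float).reshape(-1).copy()
        if arr.shape != (9,):
            raise ValueError(
                f"expected 9 genotype frequencies, got {arr.shape[0]}"
            )
        if np.any(arr < 0):
            if arr.min() < -atol:
                raise ValueError(
                    f"genotype frequencies must be >= 0 (min {arr.min()})"
                )
            arr = np.clip(arr, 0.0, None)
        total = arr.sum()
        if abs(total - 1.0) > atol:
            raise ValueError(
                f"genotype frequencies must sum to 1 within {atol} "
                f"(sum {total!r})"
            )
        # Renormalize only when measurably off; a sum already within a few
        # ulps of 1 is left untouched so repeated construction is stable.
        if abs(total - 1.0) > 4e-16:
            arr = arr / total
        arr.setflags(write=False)
        self.p = arr

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        entries = ", ".join(
            f"{lab}={v:.6g}" for lab, v in zip(GENOTYPE_LABELS, self.p)
        )
        return f"GenotypeDistribution({entries})"

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeDistribution):
            return NotImplemented
        return bool(np.array_equal(self.p, other.p))


class CareLevels(NamedTuple):
    """Male potential care ``b_m`` and female acceptance ``b_f`` by M genotype.

    Each field is a triple ordered (nn, nc, cc).  Males: nn give full care
    (1), cc give none (0), nc give ``1 - k``.  Females: nn accept all care
    (1), cc accept a proportion ``b``, nc accept ``1 - k (1 - b)``.
    """

    male: tuple[float, float, float]
    female: tuple[float, float, float]


class MatingRates(NamedTuple):
    """Mean number of mates per male, by his M-locus genotype.

    ``polygynous`` is the cc rate (1 + eta, between 1 and m),
    ``monogamous`` the nn rate (1 - pi, between 0 and 1), and
    ``heterozygote`` the nc rate theta = 1 - pi (1 - k) + eta k, which
    always lies between the other two.
    """

    polygynous: float
    heterozygote: float
    monogamous: float


class AlleleFrequencies(NamedTuple):
    """Frequencies of the four alleles; a + s = 1 and n + c = 1."""

    a: float
    s: float
    n: float
    c: float


def sexual_fraction(dist: GenotypeDistribution, alpha: float) -> float:
    """Proportion tau of sexually reproducing individuals.

    All ``ss`` carriers plus a fraction ``alpha`` of ``as`` heterozygotes
    reproduce sexually; half of the sexuals are female.
    """
    p = dist.p
    return float(alpha * p[3:6].sum() + p[6:9].sum())


def care_levels(params: ModelParams) -> CareLevels:
    """Male care and female care-acceptance levels for the three M genotypes."""
    k, b = params.k, params.b
    return CareLevels(
        male=(1.0, 1.0 - k, 0.0),
        female=(1.0, 1.0 - k * (1.0 - b), b),
    )


def pair_fitness(
    male_m_genotype: str | int,
    female_m_genotype: str | int,
    params: ModelParams,
) -> float:
    """Fitness multiplier ``R * (1 + b_m * b_f)`` of a sexual pair.

    The pair's combined contribution through both parents: a fully caring
    monogamous pair (nn x nn) returns ``2R``, a careless polygynous male
    returns ``R`` with any female, intermediate genotypes interpolate via
    ``k`` and ``b``.
    """
    care = care_levels(params)
    im = _M_INDEX[male_m_genotype] if isinstance(male_m_genotype, str) else male_m_genotype
    jf = _M_INDEX[female_m_genotype] if isinstance(female_m_genotype, str) else female_m_genotype
    return params.R * (1.0 + care.male[im] * care.female[jf])


def _effective_sexual(p: np.ndarray, alpha: float) -> np.ndarray:
    """Sexually reproducing frequency of the six sexual-capable genotypes G4..G9."""
    eff = np.empty(6)
    eff[:3] = alpha * p[3:6]
    eff[3:] = p[6:9]
    return eff


def mating_rates(dist: GenotypeDistribution, params: ModelParams) -> MatingRates:
    """Mean mates per male for polygynous, heterozygote and monogamous males.

    With ``X = alpha P6 + P9 + k (alpha P5 + P8)`` (polygyny-weighted male
    share), ``tau`` the sexual fraction and ``D = 1 + (m - 1) X``::

        polygynous   1 + eta   = (1 + (m - 1) tau)   / D
        heterozygote theta     = (1 + k (m - 1) tau) / D
        monogamous   1 - pi    = 1                   / D

    These are the unique rates for which the male mating successes,
    weighted by male frequencies, balance the total proportion of females
    (tau / 2), and they recover the limits m (polygynous males rare) and
    1/m (monogamous males rare).  When ``tau`` is 0 the rates are still
    returned; they multiply zero frequencies downstream, so pure-asexual
    states remain valid fixed points.
    """
    p = dist.p
    alpha, m, k = params.alpha, params.m, params.k
    eff = _effective_sexual(p, alpha)
    tau = eff.sum()
    X = eff[2] + eff[5] + k * (eff[1] + eff[4])
    D = 1.0 + (m - 1.0) * X
    return MatingRates(
        polygynous=(1.0 + (m - 1.0) * tau) / D,
        heterozygote=(1.0 + k * (m - 1.0) * tau) / D,
        monogamous=1.0 / D,
    )


def _locus_offspring(g_male: int, g_female: int) -> tuple[Fraction, Fraction, Fraction]:
    """Single-locus Mendelian offspring distribution for unordered genotypes.

    Genotypes are encoded by the count (0, 1, 2) of the second allele;
    gametes are fair draws of one allele.
    """
    fm = Fraction(g_male, 2)
    ff = Fraction(g_female, 2)
    return (
        (1 - fm) * (1 - ff),
        (1 - fm) * ff + fm * (1 - ff),
        fm * ff,
    )


@lru_cache(maxsize=1)
def _segregation_cached() -> np.ndarray:
    """Exact 6 x 6 x 9 tensor of filial segregation fractions (read-only)."""
    seg = np.zeros((6, 6, 9))
    for qm in range(6):  # male sexual genotype G4..G9
        s_m = 1 + qm // 3  # count of s alleles: as -> 1, ss -> 2
        m_m = qm % 3       # count of c alleles
        for qf in range(6):
            s_f = 1 + qf // 3
            m_f = qf % 3
            s_dist = _locus_offspring(s_m, s_f)
            m_dist = _locus_offspring(m_m, m_f)
            for si in range(3):
                for mi in range(3):
                    seg[qm, qf, 3 * si + mi] = float(s_dist[si] * m_dist[mi])
    seg.setflags(write=False)
    return seg


def segregation_tensor() -> np.ndarray:
    """Mendelian segregation fractions for the 36 ordered sexual crossings.

    Returns a (6, 6, 9) array indexed [male G4..G9, female G4..G9,
    offspring G1..G9].  The two loci segregate independently with fair
    meiosis, so each entry is the product of the two single-locus
    Mendelian distributions; every parental pair's nine fractions sum
    to 1.  All entries are exact dyadic rationals.
    """
    return _segregation_cached().copy()


# Flattened (36, 9) view used by the inner step loop.
_SEG_FLAT = _segregation_cached().reshape(36, 9)


def asexual_contributions(dist: GenotypeDistribution, alpha: float) -> np.ndarray:
    """Clonal contribution of asexual parents to the next generation.

    ``aa`` genotypes copy themselves with fitness 1; ``as`` heterozygotes
    do so with probability ``1 - alpha``; ``ss`` genotypes contribute
    nothing clonally.
    """
    p = dist.p
    out = np.zeros(9)
    out[:3] = p[:3]
    out[3:6] = (1.0 - alpha) * p[3:6]
    return out


def _fitness_matrix(params: ModelParams) -> np.ndarray:
    """6 x 6 pair-fitness matrix over (male G4..G9, female G4..G9)."""
    care = care_levels(params)
    bm = np.array(care.male * 2)   # male M genotype cycles nn, nc, cc
    bf = np.array(care.female * 2)
    return params.R * (1.0 + np.outer(bm, bf))


def sexual_contributions(
    dist: GenotypeDistribution, params: ModelParams
) -> np.ndarray:
    """Contribution of sexual pairs to the next generation's genotypes.

    Each ordered male x female pair among G4..G9 is weighted by the
    product of the parents' sexually-reproducing frequencies over
    ``2 tau`` (``as`` genotypes carry the factor ``alpha``), multiplied by
    the male's mean mating rate, the pair fitness ``R (1 + b_m b_f)`` and
    the Mendelian segregation fractions of its offspring.  Returns the
    zero vector when no sexual individuals exist.
    """
    p = dist.p
    eff = _effective_sexual(p, params.alpha)
    tau = eff.sum()
    if tau == 0.0:
        return np.zeros(9)
    rates = mating_rates(dist, params)
    rate_by_m = (rates.monogamous, rates.heterozygote, rates.polygynous)
    male_rate = np.array(rate_by_m * 2)
    weights = np.outer(eff * male_rate, eff) * _fitness_matrix(params)
    return (weights.reshape(36) @ _SEG_FLAT) / (2.0 * tau)


def _step_raw(
    p: np.ndarray,
    alpha: float,
    m: float,
    k: float,
    fitness: np.ndarray,
) -> np.ndarray:
    """One generation on a raw frequency vector, with fitness matrix prebuilt."""
    L = np.zeros(9)
    L[:3] = p[:3]
    L[3:6] = (1.0 - alpha) * p[3:6]
    eff = np.empty(6)
    eff[:3] = alpha * p[3:6]
    eff[3:] = p[6:9]
    tau = eff.sum()
    if tau > 0.0:
        X = eff[2] + eff[5] + k * (eff[1] + eff[4])
        D = 1.0 + (m - 1.0) * X
        r_mono = 1.0 / D
        r_het = (1.0 + k * (m - 1.0) * tau) / D
        r_poly = (1.0 + (m - 1.0) * tau) / D
        male_rate = np.array((r_mono, r_het, r_poly, r_mono, r_het, r_poly))
        weights = np.outer(eff * male_rate, eff) * fitness
        L += (weights.reshape(36) @ _SEG_FLAT) / (2.0 * tau)
    total = L.sum()
    if not total > 0.0:
        raise DegenerateStateError(
            "total reproductive contribution is zero; state is corrupted"
        )
    return L / total


def step(dist: GenotypeDistribution, params: ModelParams) -> GenotypeDistribution:
    """Advance the genotype distribution by exactly one generation.

    Pools the clonal and sexual contributions and renormalizes
    (frequencies change shape under selection, so the raw contributions do
    not sum to 1).  The output is a valid distribution: nonnegative and
    summing to 1 at machine precision.
    """
    new_p = _step_raw(
        dist.p, params.alpha, params.m, params.k, _fitness_matrix(params)
    )
    return GenotypeDistribution(new_p)


def allele_frequencies(dist: GenotypeDistribution) -> AlleleFrequencies:
    """Allele frequencies by direct allele counting over genotype labels.

    ``a`` counts both alleles of the aa genotypes and half of the as
    heterozygotes; ``n`` counts the nn genotypes and half of the nc
    heterozygotes, regardless of the S locus.
    """
    p = dist.p
    a = p[0] + p[1] + p[2] + 0.5 * (p[3] + p[4] + p[5])
    n = p[0] + p[3] + p[6] + 0.5 * (p[1] + p[4] + p[7])
    return AlleleFrequencies(a=a, s=1.0 - a, n=n, c=1.0 - n)
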