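"""Closed-form recursions and ESS classification for the pairwise games.

When only two of the three strategies are present the nine-dimensional
recursion collapses to a one-dimensional allele-frequency map with a
closed form, which this module provides as an independent reference for
the full engine:

* **asexuality vs monogamous (non-costly) sex** (allele c absent): every
  sexual pair has fitness 2R, so sex pays whenever R > 1;
* **asexuality vs polygynous (costly) sex** (allele n absent): every
  sexual pair has fitness R but relatedness halves it, so costly sex
  needs the full twofold benefit R > 2;
* **monogamous vs polygynous sex** (allele a absent): the outcome is
  governed by the polygyny potential m against the thresholds 1 + b and
  3 - b, with bistability in between; closed-form thresholds are known
  at the dominance extremes k = 0 and k = 1 only.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

from .core import ModelParams

__all__ = [
    "PairwiseGame",
    "EssOutcome",
    "UnsupportedRegimeError",
    "step_asex_monog",
    "step_asex_polyg",
    "classify_pairwise_ess",
]


class PairwiseGame(enum.Enum):
    """The three two-strategy restrictions of the full game."""

    S1_VS_S2 = "S1_vs_S2"  # asexual vs monogamous sex (c absent)
    S1_VS_S3 = "S1_vs_S3"  # asexual vs polygynous sex (n absent)
    S2_VS_S3 = "S2_vs_S3"  # monogamous vs polygynous sex (a absent)


class UnsupportedRegimeError(ValueError):
    """Raised where no closed-form classification exists.

    The monogamy-polygyny game with intermediate dominance (0 < k < 1)
    admits an extra mixed-equilibrium region whose boundaries are only
    known numerically; classify it by simulation instead.
    """


@dataclass(frozen=True)
class EssOutcome:
    """Result of a pairwise ESS classification.

    ``label`` is one of ``S1``, ``S2``, ``S3`` (that strategy is the only
    ESS), ``neutral_line`` (a line of neutrally stable equilibria at every
    allele frequency), ``bistable`` (either pure strategy can win,
    depending on initial frequencies) or ``mixed_equilibrium`` (stable
    interior coexistence).  ``thresholds`` records the quantities the
    decision compared.
    """

    label: str
    thresholds: dict[str, float] = field(default_factory=dict)


def step_asex_monog(
    a: float, P4: float, tau: float, params: ModelParams
) -> float:
    """One-generation allele-a map when the polygyny allele c is absent.

    With only aa/as/ss genotypes at nn, every sexual pair has fitness 2R
    and every male exactly one mate, giving

        a(t+1) = [a(t) + (1/2) alpha (R - 1) P4(t)] / [1 + (R - 1) tau(t)]

    where ``tau = alpha P4 + P7`` is the sexual fraction.  Asexuality
    fixes for R < 1, monogamous sex for R > 1; R = 1 leaves every allele
    frequency at rest.
    """
    R, alpha = params.R, params.alpha
    return (a + 0.5 * alpha * (R - 1.0) * P4) / (1.0 + (R - 1.0) * tau)


def step_asex_polyg(
    a: float, P6: float, tau: float, params: ModelParams
) -> float:
    """One-generation allele-a map when the monogamy allele n is absent.

    With only aa/as/ss genotypes at cc, all sexual males are equally
    competitive (mean mates 1), pair fitness is R, and

        a(t+1) = [a(t) + (1/4) alpha (R - 2) P6(t)] / [1 + (1/2)(R - 2) tau(t)]

    where ``tau = alpha P6 + P9``.  Costly sex spreads only with a
    twofold recombination benefit (R > 2); R = 2 is the neutral line.
    ``m`` and ``b`` play no role in this restriction.
    """
    R, alpha = params.R, params.alpha
    return (a + 0.25 * alpha * (R - 2.0) * P6) / (1.0 + 0.5 * (R - 2.0) * tau)


def classify_pairwise_ess(
    game: PairwiseGame, params: ModelParams
) -> EssOutcome:
    """Classify the evolutionary outcome of a two-strategy restriction.

    * ``S1_VS_S2``: S1 for R < 1, S2 for R > 1, neutral line at R = 1.
    * ``S1_VS_S3``: S1 for R < 2, S3 for R > 2, neutral line at R = 2.
    * ``S2_VS_S3`` (only at the dominance extremes k = 0 or k = 1):
      S2 is the only ESS for m < 1 + b, S3 for m >= 3 - b, and the game
      is bistable for 1 + b <= m < 3 - b (the boundary m = 1 + b belongs
      to the bistable bracket).

    Raises
    ------
    UnsupportedRegimeError
        For ``S2_VS_S3`` with 0 < k < 1, where an additional interior
        mixed-equilibrium region exists and no closed-form thresholds are
        available; use simulation there.
    """
    R, m, b, k = params.R, params.m, params.b, params.k
    if game is PairwiseGame.S1_VS_S2:
        thresholds = {"R": R, "neutral_R": 1.0}
        if R < 1.0:
            return EssOutcome("S1", thresholds)
        if R > 1.0:
            return EssOutcome("S2", thresholds)
        return EssOutcome("neutral_line", thresholds)
    if game is PairwiseGame.S1_VS_S3:
        thresholds = {"R": R, "neutral_R": 2.0}
        if R < 2.0:
            return EssOutcome("S1", thresholds)
        if R > 2.0:
            return EssOutcome("S3", thresholds)
        return EssOutcome("neutral_line", thresholds)
    if game is PairwiseGame.S2_VS_S3:
        if 0.0 < k < 1.0:
            raise UnsupportedRegimeError(
                "monogamy-polygyny thresholds are only closed-form at "
                f"k = 0 or k = 1 (got k = {k}); classify by simulation"
            )
        thresholds = {"m": m, "lower": 1.0 + b, "upper": 3.0 - b}
        if m < 1.0 + b:
            return EssOutcome("S2", thresholds)
        if m >= 3.0 - b:
            return EssOutcome("S3", thresholds)
        return EssOutcome("bistable", thresholds)
    raise TypeError(f"unknown game {game!r}")
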