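"""Multi-generation simulation, attractor classification and parameter sweeps.

The one-generation map is deterministic, so a trajectory is fully fixed
by the initial genotype distribution and the parameters.  Initial states
are conventionally built from allele frequencies at Hardy-Weinberg
proportions within each locus and linkage equilibrium across loci, the
simplest composition consistent with reporting initial conditions as
allele frequencies alone.

Long-run behaviour is classified from the final window of a trajectory
into fixation, stable interior equilibrium, sustained oscillation, or
oscillation that grazes the boundary of the simplex ("near-fixation"
cycles, which in any finite population would end in fixation but here
persist because trace frequencies are never truncated).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from . import core
from .core import (
    AlleleFrequencies,
    GenotypeDistribution,
    ModelParams,
)

__all__ = [
    "Trajectory",
    "RegimeLabel",
    "WindowTooLongError",
    "init_from_alleles",
    "run",
    "classify_regime",
    "parameter_sweep",
    "SWEEP_COLUMNS",
]

REGIME_CATEGORIES = (
    "fixation",
    "stable_equilibrium",
    "oscillation",
    "near_fixation_oscillation",
)

SWEEP_COLUMNS = (
    "R",
    "m",
    "allele_s",
    "allele_c",
    "allele_a",
    "category",
    "amplitude_s",
    "amplitude_c",
)


class WindowTooLongError(ValueError):
    """Raised when a classification window exceeds the trajectory length."""


def init_from_alleles(a0: float, c0: float) -> GenotypeDistribution:
    """Genotype distribution from allele frequencies.

    Hardy-Weinberg proportions within each locus, linkage equilibrium
    across loci: ``P(S genotype, M genotype) = HW(a0) * HW(c0)``.
    """
    if not 0.0 <= a0 <= 1.0:
        raise ValueError(f"a0 must lie in [0, 1] (got {a0})")
    if not 0.0 <= c0 <= 1.0:
        raise ValueError(f"c0 must lie in [0, 1] (got {c0})")
    hw_s = np.array([a0 * a0, 2.0 * a0 * (1.0 - a0), (1.0 - a0) ** 2])
    hw_m = np.array([(1.0 - c0) ** 2, 2.0 * c0 * (1.0 - c0), c0 * c0])
    return GenotypeDistribution(np.outer(hw_s, hw_m).reshape(9))


@dataclass(frozen=True)
class Trajectory:
    """Recorded states of a deterministic run.

    ``generations[i]`` is the 0-based generation index of row ``i`` of
    ``states`` (generation 0 is the initial state); indices are strictly
    increasing and the final generation is always recorded.
    """

    params: ModelParams
    generations: np.ndarray  # (n_rec,) int64
    states: np.ndarray       # (n_rec, 9) float

    def __len__(self) -> int:
        return self.generations.shape[0]

    @property
    def allele_a(self) -> np.ndarray:
        return self.states[:, :3].sum(axis=1) + 0.5 * self.states[:, 3:6].sum(axis=1)

    @property
    def allele_s(self) -> np.ndarray:
        return 1.0 - self.allele_a

    @property
    def allele_n(self) -> np.ndarray:
        return (
            self.states[:, [0, 3, 6]].sum(axis=1)
            + 0.5 * self.states[:, [1, 4, 7]].sum(axis=1)
        )

    @property
    def allele_c(self) -> np.ndarray:
        return 1.0 - self.allele_n

    @property
    def tau(self) -> np.ndarray:
        """Sexual fraction at every recorded generation."""
        return (
            self.params.alpha * self.states[:, 3:6].sum(axis=1)
            + self.states[:, 6:9].sum(axis=1)
        )

    @property
    def final_state(self) -> GenotypeDistribution:
        return GenotypeDistribution(self.states[-1])

    @property
    def final_alleles(self) -> AlleleFrequencies:
        return core.allele_frequencies(self.final_state)

    def to_frame(self) -> pd.DataFrame:
        """Tabular view: generation, P1..P9, allele frequencies and tau."""
        data = {"generation": self.generations}
        for i in range(9):
            data[f"P{i + 1}"] = self.states[:, i]
        data["a"] = self.allele_a
        data["s"] = self.allele_s
        data["n"] = self.allele_n
        data["c"] = self.allele_c
        data["tau"] = self.tau
        return pd.DataFrame(data)


def run(
    dist0: GenotypeDistribution,
    params: ModelParams,
    generations: int,
    record_every: int = 1,
) -> Trajectory:
    """Iterate the one-generation map and record the trajectory.

    Applies :func:`sexgames.core.step` exactly ``generations`` times,
    recording generation 0, every ``record_every``-th generation and the
    final one.  The map is deterministic: identical inputs give
    bit-identical trajectories.  ``generations`` may be 0, in which case
    only the initial state is recorded.
    """
    if generations < 0:
        raise ValueError(f"generations must be >= 0 (got {generations})")
    if record_every < 1:
        raise ValueError(f"record_every must be >= 1 (got {record_every})")
    fitness = core._fitness_matrix(params)
    alpha, m, k = params.alpha, params.m, params.k
    p = dist0.p.copy()
    rec_gens = [0]
    rec_states = [p.copy()]
    for t in range(1, generations + 1):
        p = core._step_raw(p, alpha, m, k, fitness)
        if t % record_every == 0 or t == generations:
            rec_gens.append(t)
            rec_states.append(p)
    return Trajectory(
        params=params,
        generations=np.asarray(rec_gens, dtype=np.int64),
        states=np.asarray(rec_states),
    )


@dataclass(frozen=True)
class RegimeLabel:
    """Long-run classification of a trajectory's final window.

    ``mean`` holds window-averaged allele frequencies; ``amplitude`` maps
    each allele to max - min over the window (complementary alleles share
    an amplitude).  ``generations`` is the total length of the run.
    """

    category: str
    mean: AlleleFrequencies
    amplitude: dict[str, float]
    window: int
    generations: int


def classify_regime(
    traj: Trajectory,
    window: int = 1000,
    osc_tol: float = 1e-6,
    fix_tol: float = 1e-3,
) -> RegimeLabel:
    """Classify the attractor from the final ``window`` generations.

    Amplitude is max - min of each allele frequency over the window.
    A quiescent window (amplitude < ``osc_tol``) is ``fixation`` if
    allele a or c sits within ``fix_tol`` of 0 or 1, else
    ``stable_equilibrium``.  A moving window is
    ``near_fixation_oscillation`` if any allele approaches within
    ``fix_tol`` of the boundary inside the window, else ``oscillation``.

    Raises :class:`WindowTooLongError` if ``window`` exceeds the number
    of generations in the trajectory.
    """
    if window < 1:
        raise ValueError(f"window must be >= 1 (got {window})")
    total = int(traj.generations[-1])
    if window > total:
        raise WindowTooLongError(
            f"window of {window} generations exceeds trajectory length {total}"
        )
    mask = traj.generations > total - window
    a = traj.allele_a[mask]
    c = traj.allele_c[mask]
    amp_a = float(a.max() - a.min())
    amp_c = float(c.max() - c.min())
    mean_a = float(a.mean())
    mean_c = float(c.mean())
    boundary_dist = min(
        float(a.min()), float(1.0 - a.max()),
        float(c.min()), float(1.0 - c.max()),
    )
    if max(amp_a, amp_c) < osc_tol:
        near_fixed = min(mean_a, 1.0 - mean_a, mean_c, 1.0 - mean_c) < fix_tol
        category = "fixation" if near_fixed else "stable_equilibrium"
    else:
        category = (
            "near_fixation_oscillation"
            if boundary_dist < fix_tol
            else "oscillation"
        )
    return RegimeLabel(
        category=category,
        mean=AlleleFrequencies(
            a=mean_a, s=1.0 - mean_a, n=1.0 - mean_c, c=mean_c
        ),
        amplitude={"a": amp_a, "s": amp_a, "n": amp_c, "c": amp_c},
        window=window,
        generations=total,
    )


def parameter_sweep(
    R_grid: Sequence[float],
    m_grid: Sequence[float],
    a0: float,
    c0: float,
    base_params: ModelParams,
    generations: int = 10_000,
    window: int = 1000,
    osc_tol: float = 1e-6,
    fix_tol: float = 1e-3,
) -> pd.DataFrame:
    """Run and classify one trajectory per (R, m) grid cell.

    Every cell starts from the same Hardy-Weinberg initial state built
    from ``a0`` and ``c0``; ``base_params`` supplies b, k and alpha (its
    R and m are overwritten cell by cell).  Allele frequencies are
    reported at the stated generation, i.e. the state after
    ``generations`` applications of the map; amplitudes come from the
    classification window (clamped to the run length).  Rows are emitted
    in row-major order: outer loop over ``m_grid``, inner over
    ``R_grid``, both in the order given.  A cell whose run raises is
    marked ``failed`` (frequencies NaN) without aborting the sweep.
    """
    if len(R_grid) == 0 or len(m_grid) == 0:
        raise ValueError("R_grid and m_grid must be non-empty")
    dist0 = init_from_alleles(a0, c0)
    eff_window = min(window, generations) if generations >= 1 else window
    rows = []
    for m in m_grid:
        for R in R_grid:
            try:
                params = replace(base_params, R=float(R), m=float(m))
                traj = run(dist0, params, generations)
                label = classify_regime(
                    traj, window=eff_window, osc_tol=osc_tol, fix_tol=fix_tol
                )
                final = traj.final_alleles
                rows.append(
                    (
                        float(R), float(m),
                        final.s, final.c, final.a,
                        label.category,
                        label.amplitude["s"], label.amplitude["c"],
                    )
                )
            except Exception:
                rows.append(
                    (
                        float(R), float(m),
                        float("nan"), float("nan"), float("nan"),
                        "failed", float("nan"), float("nan"),
                    )
                )
    return pd.DataFrame(rows, columns=list(SWEEP_COLUMNS))
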