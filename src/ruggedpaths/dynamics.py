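"""Adaptive-walk dynamics in the weak-mutation regime.

Evolution is modelled as an origin-fixation process: mutations arise one at
a time and are fixed or lost before the next arises, so the population
performs a walk on the landscape.  Fixation follows Kimura's diffusion
approximation for a diploid population of effective size N_e.  Walks stop
on arrival at a fitness peak (a node with no strictly fitter neighbour).

For folding landscapes, fitness is the misfolding cost -A(1-P)/P, so the
strength of selection is governed by the product N_e * A of population size
and required protein abundance; sweeping this product traces the crossover
from neutral random walks to strictly uphill trajectories.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .landscape import Landscape
from .paths import DivergenceProfile, Path, PathBundle, divergence_profile
from .roughness import find_peaks

__all__ = [
    "SelectionParams",
    "TrajectoryEnsemble",
    "misfolding_fitness",
    "fixation_probability",
    "sample_trajectory",
    "build_bundles",
    "selection_sweep",
]


def misfolding_fitness(P: float, A: float) -> float:
    """Fitness of a sequence folding correctly with probability ``P``.

    The expected number of misfolded copies produced before reaching an
    abundance ``A`` of correctly folded ones is A(1-P)/P; fitness is its
    negative.  Zero iff P = 1; strictly increasing in P; sequences with
    P <= 0 are inviable (-inf).
    """
    if A <= 0:
        raise ValueError("abundance must be positive")
    if P <= 0:
        return -math.inf
    if P > 1:
        raise ValueError("folding probability cannot exceed 1")
    return -A * (1.0 - P) / P


def fixation_probability(s: float, N_e: float) -> float:
    """Kimura fixation probability of a new mutant, diploid, size N_e.

    u = (1 - exp(-2s)) / (1 - exp(-4 N_e s)) with the continuous neutral
    limit 1/(2 N_e) at s = 0.  Evaluated stably for large |s| and large
    N_e |s|.
    """
    if N_e <= 0:
        raise ValueError("effective population size must be positive")
    if s == -math.inf:
        return 0.0
    if abs(4.0 * N_e * s) < 1e-12:
        return 1.0 / (2.0 * N_e)
    a, b = -2.0 * s, -4.0 * N_e * s
    # large positive exponents (deleterious mutant): work on the log scale
    if a > 700.0 or b > 700.0:
        # u ~ exp(a) / exp(b) = exp(a - b); N_e >= 1/2 makes a - b <= 0
        return math.exp(min(a - b, 0.0)) if a - b < 700.0 else 1.0
    return math.expm1(a) / math.expm1(b)


@dataclass
class SelectionParams:
    """Knobs of the origin-fixation walk.

    ``selection_mode`` is 'kimura' (acceptance by fixation probability),
    'strong_limit' (only fitness-increasing steps, all equally likely) or
    'neutral_limit' (uniform random walk over present neighbours).  For
    folding landscapes, fitness values already include the abundance factor
    via ``misfolding_fitness``; ``abundance`` here rescales any landscape's
    fitness so that the selection pressure is N_e * abundance.
    """

    N_e: float = 1000.0
    abundance: float = 1.0
    selection_mode: str = "kimura"
    max_steps: int = 10_000
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        if self.N_e <= 0 or self.abundance <= 0 or self.max_steps <= 0:
            raise ValueError("N_e, abundance and max_steps must be positive")
        if self.selection_mode not in ("kimura", "strong_limit", "neutral_limit"):
            raise ValueError(f"unknown selection mode {self.selection_mode!r}")


def _step_weights(
    ls: Landscape, g: str, params: SelectionParams
) -> tuple[list[str], np.ndarray]:
    """Fixation weights over present neighbours (embedded jump chain).

    Proposals are uniform over single-site mutations; those leaving the
    landscape are never fixed.  Conditioning the propose/accept loop on the
    eventual acceptance yields the next fixed mutant with probability
    proportional to its fixation probability — the path law is identical to
    explicit rejection sampling but costs one draw per fixed step.
    """
    nbrs = ls.neighbors(g)
    if params.selection_mode == "neutral_limit":
        w = np.ones(len(nbrs))
    elif params.selection_mode == "strong_limit":
        f = ls.fitness(g)
        w = np.array([1.0 if ls.fitness(nb) > f else 0.0 for nb in nbrs])
    else:
        f = ls.fitness(g)
        w = np.array(
            [
                fixation_probability(
                    params.abundance * (ls.fitness(nb) - f), params.N_e
                )
                for nb in nbrs
            ]
        )
    return nbrs, w


def sample_trajectory(
    ls: Landscape,
    start: str,
    params: SelectionParams,
    rng: np.random.Generator,
) -> tuple[Path, bool]:
    """One origin-fixation walk from ``start`` to a fitness peak.

    Returns the path of fixed genotypes and a flag that is False when the
    walk was truncated at ``max_steps`` before reaching a peak.
    """
    if start not in ls:
        raise KeyError(f"genotype {start!r} not in landscape")
    path = [start]
    g = start
    if not any(ls.fitness(nb) > ls.fitness(g) for nb in ls.neighbors(g)):
        raise ValueError(f"start {start!r} is already a fitness peak")
    for _ in range(params.max_steps):
        nbrs, w = _step_weights(ls, g, params)
        total = w.sum()
        if not nbrs or total == 0.0:
            return tuple(path), True  # isolated or strict peak
        g = nbrs[rng.choice(len(nbrs), p=w / total)]
        path.append(g)
        if not any(ls.fitness(nb) > ls.fitness(g) for nb in ls.neighbors(g)):
            return tuple(path), True
    return tuple(path), False


@dataclass
class TrajectoryEnsemble:
    """Bundles of sampled walks keyed by (start, terminal peak)."""

    bundles: list[PathBundle]
    n_walks: int
    n_truncated: int

    def profile(self) -> DivergenceProfile:
        return divergence_profile(self.bundles)


def build_bundles(
    ls: Landscape,
    walks_per_start: int,
    params: SelectionParams,
    rng: np.random.Generator,
    starts: list[str] | None = None,
) -> TrajectoryEnsemble:
    """Sample walks from every non-peak start and bundle them by endpoints.

    Truncated walks (max_steps reached away from a peak) are excluded from
    the bundles and counted separately.
    """
    if walks_per_start < 1:
        raise ValueError("walks_per_start must be >= 1")
    peaks = find_peaks(ls)
    if starts is None:
        starts = [g for g in sorted(ls.entries) if g not in peaks]
    counts: dict[tuple[str, str], dict[Path, int]] = {}
    n_walks = 0
    n_trunc = 0
    for start in starts:
        for _ in range(walks_per_start):
            path, ok = sample_trajectory(ls, start, params, rng)
            n_walks += 1
            if not ok:
                n_trunc += 1
                continue
            counts.setdefault((start, path[-1]), {}).setdefault(path, 0)
            counts[(start, path[-1])][path] += 1
    bundles = []
    for (start, end), path_counts in sorted(counts.items()):
        paths = list(path_counts)
        total = sum(path_counts.values())
        probs = [path_counts[p] / total for p in paths]
        bundles.append(
            PathBundle(start=start, end=end, paths=paths, probs=probs, n_walks=total)
        )
    return TrajectoryEnsemble(bundles=bundles, n_walks=n_walks, n_truncated=n_trunc)


def selection_sweep(
    ls: Landscape,
    pressures: list[float],
    walks: int,
    rng: np.random.Generator,
    N_e: float = 1000.0,
    max_steps: int = 10_000,
) -> dict[float, DivergenceProfile]:
    """Mean path divergence as a function of selection pressure N_e * A.

    Each pressure p is realised as abundance A = p / N_e at fixed N_e; the
    sweep traces the crossover from the neutral random walk (small p) to
    the strictly uphill plateau (large p).
    """
    if sorted(pressures) != list(pressures):
        raise ValueError("pressures must be sorted ascending")
    out: dict[float, DivergenceProfile] = {}
    for p in pressures:
        params = SelectionParams(
            N_e=N_e, abundance=p / N_e, selection_mode="kimura", max_steps=max_steps
        )
        ens = build_bundles(ls, walks, params, rng)
        out[p] = ens.profile()
    return out
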