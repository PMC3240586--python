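"""Folding-fitness landscape assembly and robust-folder search.

A landscape is grown from a robustly folding seed sequence by breadth-first
mutational expansion: every single-substitution mutant (chain endpoints are
immutable) is scored by its probability of folding to the *seed's* native
structure; mutants at or above the inclusion threshold join the landscape
and are themselves expanded, until the frontier empties.  The folding
oracle is pluggable: the physical simulator for real runs, deterministic
mocks for algorithmic tests.

A simulated-annealing search over sequence space finds compact robust
folders by maximising folding probability divided by the cube of the
native radius of gyration.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .folding import (
    MONOMER_TYPES,
    NativeEnsemble,
    PhysicsConfig,
    folding_probability,
    validate_sequence,
)
from .landscape import Landscape

__all__ = [
    "BuildConfig",
    "AnnealConfig",
    "radius_of_gyration",
    "make_folding_oracle",
    "expand_landscape",
    "anneal_search",
]

#: A folding oracle maps a monomer sequence to a folding probability in [0, 1].
FoldingOracle = Callable[[str], float]


def radius_of_gyration(coords: np.ndarray) -> float:
    """Root-mean-square distance of the monomers from their centroid."""
    coords = np.asarray(coords, float)
    if coords.ndim != 2 or len(coords) < 1:
        raise ValueError("need at least one monomer")
    centred = coords - coords.mean(axis=0)
    return float(np.sqrt((centred**2).sum(axis=1).mean()))


@dataclass
class BuildConfig:
    """Expansion parameters: inclusion threshold and sampling effort."""

    p_min: float = 0.1
    n_samples: int = 50
    max_sequences: int = 100_000
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.p_min <= 1:
            raise ValueError("p_min must be in (0, 1]")
        if self.n_samples < 1 or self.max_sequences < 1:
            raise ValueError("n_samples and max_sequences must be positive")


def make_folding_oracle(
    ref: NativeEnsemble,
    cfg: PhysicsConfig,
    n_samples: int,
    rng: np.random.Generator,
) -> FoldingOracle:
    """Oracle backed by the physical simulator against a fixed reference."""

    def oracle(seq: str) -> float:
        return folding_probability(seq, ref, n_samples, cfg, rng)

    return oracle


def _mutants(seq: str) -> list[str]:
    """All single-substitution mutants with endpoints held fixed."""
    out = []
    for i in range(1, len(seq) - 1):
        for sym in MONOMER_TYPES:
            if sym != seq[i]:
                out.append(seq[:i] + sym + seq[i + 1 :])
    return out


def expand_landscape(
    seed: str,
    oracle: FoldingOracle,
    bc: BuildConfig,
) -> tuple[Landscape, dict]:
    """Breadth-first mutational expansion around a folding seed.

    Every candidate's folding probability (to the seed's fixed reference
    structure, embodied in the oracle) is evaluated once; candidates with
    P >= p_min enter the landscape, recorded with fitness P, and are
    expanded in turn.  Returns the landscape and a provenance dict with
    examined/included counters.
    """
    validate_sequence(seed)
    p_seed = oracle(seed)
    if p_seed < bc.p_min:
        raise ValueError(
            f"seed folding probability {p_seed:.3g} is below p_min={bc.p_min}"
        )
    entries = {seed: p_seed}
    examined = {seed: p_seed}
    frontier = deque([seed])
    while frontier and len(entries) < bc.max_sequences:
        current = frontier.popleft()
        for mut in _mutants(current):
            if mut in examined:
                continue
            p = oracle(mut)
            examined[mut] = p
            if p >= bc.p_min:
                entries[mut] = p
                frontier.append(mut)
    provenance = {
        "seed": seed,
        "p_min": bc.p_min,
        "n_examined": len(examined),
        "n_included": len(entries),
        "examined_per_included": len(examined) / len(entries),
        "truncated": bool(frontier),
    }
    return Landscape(entries, alphabet=MONOMER_TYPES), provenance


@dataclass
class AnnealConfig:
    """Cooling schedule for the robust-folder search.

    A geometric schedule from ``t_initial`` down to ``t_final`` over
    ``n_steps`` proposals; ``t_initial`` = 0 degenerates to a greedy hill
    climb that accepts only improvements.
    """

    t_initial: float = 0.1
    t_final: float = 1e-3
    n_steps: int = 1000
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        if self.t_initial < 0 or self.t_final < 0 or self.n_steps < 1:
            raise ValueError("temperatures must be >= 0 and n_steps >= 1")

    def schedule(self) -> np.ndarray:
        if self.t_initial == 0:
            return np.zeros(self.n_steps)
        lo = max(self.t_final, 1e-12)
        return self.t_initial * (lo / self.t_initial) ** (
            np.arange(self.n_steps) / max(self.n_steps - 1, 1)
        )


def anneal_search(
    start: str,
    objective: Callable[[str], float],
    ac: AnnealConfig,
    rng: np.random.Generator,
) -> tuple[str, float]:
    """Simulated-annealing maximisation over sequences with fixed endpoints.

    ``objective`` is typically folding probability over the cubed radius of
    gyration (compactness-weighted robustness).  Metropolis acceptance:
    improvements always, deteriorations with probability exp(delta / T).
    Returns the best sequence seen and its objective value.
    """
    validate_sequence(start)
    if len(start) < 3:
        raise ValueError("sequence too short to mutate")
    current = start
    f_current = objective(current)
    best, f_best = current, f_current
    interior = range(1, len(start) - 1)
    for T in ac.schedule():
        i = int(rng.choice(list(interior)))
        choices = [s for s in MONOMER_TYPES if s != current[i]]
        cand = current[:i] + choices[int(rng.integers(len(choices)))] + current[i + 1 :]
        f_cand = objective(cand)
        delta = f_cand - f_current
        if delta > 0 or (T > 0 and rng.uniform() < math.exp(delta / T)):
            current, f_current = cand, f_cand
            if f_current > f_best:
                best, f_best = current, f_current
    return best, f_best
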