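"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from ruggedpaths.folding import PhysicsConfig
from ruggedpaths.landscape import Landscape, full_space


def brute_force_monotonic_paths(ls: Landscape, start: str, peak: str) -> int:
    """Independent oracle: enumerate every ordering of the differing sites
    and count those whose intermediates are present with strictly
    increasing fitness."""
    sites = [i for i in range(ls.length) if start[i] != peak[i]]
    count = 0
    for order in itertools.permutations(sites):
        g = start
        ok = True
        f = ls.fitness(g)
        for site in order:
            g = g[: site] + peak[site] + g[site + 1 :]
            if g not in ls or ls.fitness(g) <= f:
                ok = False
                break
            f = ls.fitness(g)
        count += ok
    return count


def random_binary_landscape(
    length: int, rng: np.random.Generator, keep: float = 1.0
) -> Landscape:
    """Random fitness over a (possibly thinned) binary hypercube."""
    entries = {}
    for g in full_space(length, ("0", "1")):
        if rng.uniform() <= keep:
            entries[g] = float(rng.uniform())
    if not entries:
        entries["0" * length] = 0.5
    return Landscape(entries, alphabet=("0", "1"))


def additive_landscape(length: int, effects: list[float]) -> Landscape:
    """Strictly additive binary landscape: peak all-ones with fitness 1,
    site i carrying a negative differential effects[i] when set to 0."""
    assert len(effects) == length and all(e < 0 for e in effects)
    entries = {}
    for g in full_space(length, ("0", "1")):
        entries[g] = 1.0 + sum(e for bit, e in zip(g, effects) if bit == "0")
    return Landscape(entries, alphabet=("0", "1"))


@pytest.fixture
def cube2() -> Landscape:
    """2-site binary landscape with one reciprocal-sign-epistasis valley."""
    return Landscape(
        {"00": 0.1, "01": 0.3, "10": 0.4, "11": 0.2}, alphabet=("0", "1")
    )


@pytest.fixture
def additive3() -> Landscape:
    return additive_landscape(3, [-0.1, -0.2, -0.3])


@pytest.fixture
def fast_cfg() -> PhysicsConfig:
    """Reduced-effort physics for tests that only need qualitative folding."""
    return PhysicsConfig(
        equil_steps=600,
        max_quench_steps=3000,
        stationarity_window=200,
        zero_t_steps=300,
    )
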