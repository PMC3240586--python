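"""Monotonic-path statistics and path divergence.

Two predictability measures complement the roughness statistics:

* the monotonic path fraction — among the d! simple mutational trajectories
  (each differing site changed exactly once, directly to the peak state)
  from a genotype to the main peak, the fraction along which fitness
  strictly increases at every step, averaged over the landscape;
* the mean path divergence of a bundle of trajectories sharing start and
  end points — the expected Hamming separation between two paths drawn
  independently from the bundle.  Low divergence means the realised
  evolutionary path is nearly determined by its endpoints.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

from .landscape import Landscape, hamming_distance

__all__ = [
    "Path",
    "PathBundle",
    "DivergenceProfile",
    "total_simple_paths",
    "count_monotonic_paths",
    "monotonic_path_fraction",
    "path_divergence",
    "bundle_mean_divergence",
    "divergence_profile",
    "enumerate_uphill_bundles",
]

#: A path is an ordered tuple of genotype strings with consecutive entries
#: at Hamming distance 1.  Adaptive walks below weak selection may revisit
#: genotypes; strictly uphill paths never can.
Path = tuple[str, ...]


def total_simple_paths(d: int) -> int:
    """Number of simple trajectories between genotypes differing at d sites.

    Each differing site is changed exactly once, directly to its target
    state, in some order: d! trajectories for any alphabet size.
    """
    if d < 0:
        raise ValueError("Hamming distance must be non-negative")
    return math.factorial(d)


def count_monotonic_paths(ls: Landscape, start: str, peak: str | None = None) -> int:
    """Count simple monotonic trajectories from ``start`` to ``peak``.

    A trajectory changes each site at which ``start`` differs from ``peak``
    exactly once, directly to the peak state; it is monotonic when every
    step strictly increases fitness and every intermediate genotype is
    present in the landscape.  Computed by dynamic programming over subsets
    of the differing sites.
    """
    peak = peak if peak is not None else ls.main_peak()
    if start not in ls or peak not in ls:
        raise KeyError("start and peak must both be present in the landscape")
    sites = [i for i in range(ls.length) if start[i] != peak[i]]

    def genotype_of(mask: int) -> str:
        g = list(start)
        for b, i in enumerate(sites):
            if mask >> b & 1:
                g[i] = peak[i]
        return "".join(g)

    full = (1 << len(sites)) - 1

    @lru_cache(maxsize=None)
    def walk(mask: int) -> int:
        if mask == full:
            return 1
        g = genotype_of(mask)
        f = ls.fitness(g)
        total = 0
        for b in range(len(sites)):
            if mask >> b & 1:
                continue
            nxt = genotype_of(mask | 1 << b)
            if nxt in ls and ls.fitness(nxt) > f:
                total += walk(mask | 1 << b)
        return total

    result = walk(0)
    walk.cache_clear()
    return result


def monotonic_path_fraction(ls: Landscape) -> float:
    """Landscape-average fraction of monotonic simple paths to the main peak.

    (1/(L-1)) * sum over non-peak genotypes x of S_x / d_x!, where S_x is
    the monotonic count and d_x the Hamming distance from x to the peak.
    """
    if len(ls) < 2:
        raise ValueError("need at least 2 entries")
    peak = ls.main_peak()
    acc = 0.0
    for g in ls:
        if g == peak:
            continue
        d = hamming_distance(g, peak)
        acc += count_monotonic_paths(ls, g, peak) / total_simple_paths(d)
    return acc / (len(ls) - 1)


def path_divergence(p: Path, q: Path, *, symmetric: bool = True) -> float:
    """Divergence between two trajectories.

    The directed divergence from p to q is the mean over points of p of the
    shortest Hamming distance to any point of q.  By default the two
    directed means are averaged, making the measure symmetric.
    """
    if not p or not q:
        raise ValueError("paths must be non-empty")

    def directed(a: Path, b: Path) -> float:
        return sum(min(hamming_distance(x, y) for y in b) for x in a) / len(a)

    if symmetric:
        return 0.5 * (directed(p, q) + directed(q, p))
    return directed(p, q)


@dataclass
class PathBundle:
    """All observed trajectories sharing a (start, end) pair.

    ``probs`` are occurrence probabilities (non-negative, summing to 1);
    ``n_walks`` records how many sampled walks the bundle aggregates (equal
    to ``len(paths)`` for exhaustively enumerated bundles).
    """

    start: str
    end: str
    paths: list[Path]
    probs: list[float]
    n_walks: int = 0

    def __post_init__(self) -> None:
        if len(self.paths) != len(self.probs):
            raise ValueError("paths and probs must have equal length")
        if not self.paths:
            raise ValueError("bundle must contain at least one path")
        for p in self.paths:
            if p[0] != self.start or p[-1] != self.end:
                raise ValueError("every path must share the bundle's endpoints")
        if any(w < 0 for w in self.probs):
            raise ValueError("probabilities must be non-negative")
        s = sum(self.probs)
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"probabilities must sum to 1 (got {s})")
        if not self.n_walks:
            self.n_walks = len(self.paths)

    @property
    def distance(self) -> int:
        return hamming_distance(self.start, self.end)


def bundle_mean_divergence(
    b: PathBundle, *, symmetric: bool = True, unbiased: bool = False
) -> float:
    """Expected divergence of two paths drawn independently from the bundle.

    sum_{i,j} P_i P_j D(p_i, p_j), including the zero-contribution i == j
    terms (normalisation is unaffected since the probabilities sum to 1).

    When the probabilities are empirical frequencies from ``n_walks``
    sampled walks, the plug-in estimator underestimates the two-draw
    expectation by a factor (n-1)/n (a V- vs U-statistic effect);
    ``unbiased`` applies the n/(n-1) correction.
    """
    n = len(b.paths)
    acc = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            d = path_divergence(b.paths[i], b.paths[j], symmetric=symmetric)
            acc += 2.0 * b.probs[i] * b.probs[j] * d
    if unbiased and b.n_walks > 1:
        acc *= b.n_walks / (b.n_walks - 1)
    return acc


@dataclass
class DivergenceProfile:
    """Mean path divergence binned by start-to-end Hamming distance."""

    per_distance: dict[int, float]
    overall: float

    def to_dict(self) -> dict:
        return {
            "per_distance": {str(k): v for k, v in sorted(self.per_distance.items())},
            "overall": self.overall,
        }


def divergence_profile(bundles: list[PathBundle]) -> DivergenceProfile:
    """Average bundle divergences at each start-to-end Hamming distance.

    The per-distance value is the arithmetic mean over bundles at that
    distance; the overall value weights each bundle by its walk count.
    """
    if not bundles:
        raise ValueError("need at least one bundle")
    by_dist: dict[int, list[float]] = {}
    wsum = 0.0
    wtot = 0.0
    for b in bundles:
        d = bundle_mean_divergence(b)
        by_dist.setdefault(b.distance, []).append(d)
        wsum += b.n_walks * d
        wtot += b.n_walks
    per = {k: sum(v) / len(v) for k, v in by_dist.items()}
    return DivergenceProfile(per_distance=per, overall=wsum / wtot)


def enumerate_uphill_bundles(
    ls: Landscape, start: str, *, uniform: bool = False
) -> list[PathBundle]:
    """Exhaustively enumerate strictly uphill trajectories from ``start``.

    Walks every strictly fitness-increasing sequence of Hamming-1 steps
    until a node with no fitter neighbour, grouping trajectories into
    bundles by terminal peak.  Path probabilities are those of the
    strong-selection adaptive walk (each uphill step equally likely), or
    uniform within each bundle when ``uniform`` is set.  Exact counterpart
    of Monte-Carlo bundle construction; intended for small landscapes.
    """
    if start not in ls:
        raise KeyError(f"genotype {start!r} not in landscape")
    collected: dict[str, list[tuple[Path, float]]] = {}

    def recurse(path: list[str], prob: float) -> None:
        g = path[-1]
        uphill = [nb for nb in ls.neighbors(g) if ls.fitness(nb) > ls.fitness(g)]
        if not uphill:
            collected.setdefault(g, []).append((tuple(path), prob))
            return
        for nb in uphill:
            path.append(nb)
            recurse(path, prob / len(uphill))
            path.pop()

    recurse([start], 1.0)
    bundles = []
    for end, items in sorted(collected.items()):
        paths = [p for p, _ in items]
        if uniform:
            probs = [1.0 / len(items)] * len(items)
        else:
            total = sum(w for _, w in items)
            probs = [w / total for _, w in items]
        bundles.append(PathBundle(start=start, end=end, paths=paths, probs=probs))
    return bundles
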