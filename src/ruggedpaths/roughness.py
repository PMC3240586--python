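"""Landscape roughness statistics.

Four complementary measures of how rugged a genotype-fitness landscape is:

* deviation from additivity — residual sum of squares of the best-fit
  peak-anchored additive model, scaled by the sum of squared fitnesses;
* local roughness — per-node RMS fitness difference to Hamming-1
  neighbours, averaged over the landscape;
* peak fraction — nodes with no strictly fitter neighbour (plateau members
  qualify) divided by landscape size;
* mean distance to the tree component — the tree component is the set of
  nodes with at most one strictly fitter neighbour; uphill walks on it are
  unbranched, so distance to it measures how far evolution must travel
  before its path becomes deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .landscape import Landscape

__all__ = [
    "AdditiveFit",
    "RoughnessReport",
    "fit_additive",
    "deviation_from_additivity",
    "variability_explained",
    "local_roughness",
    "find_peaks",
    "tree_component",
    "mean_tree_distance",
    "roughness_report",
]


@dataclass
class AdditiveFit:
    """Least-squares additive model anchored at the main peak.

    Predicted fitness of a genotype is the peak fitness plus one fitted
    contribution per (site, state) at which it differs from the peak.  The
    minimum-norm solution is used when the design is rank deficient.
    """

    peak: str
    contributions: dict[tuple[int, str], float]
    fitted: dict[str, float]
    ss_residual: float
    ss_fitness: float

    @property
    def rms_residual(self) -> float:
        """Unscaled root-mean-square residual of the additive fit."""
        return float(np.sqrt(self.ss_residual / len(self.fitted)))


def fit_additive(ls: Landscape) -> AdditiveFit:
    """Fit the peak-anchored additive model by least squares.

    The model has one coefficient per (site, non-peak state) pair observed
    among the entries; the peak's own prediction is exact by construction.
    Contributions are not sign-constrained.
    """
    if len(ls) < 2:
        raise ValueError("additive fit requires at least 2 entries")
    peak = ls.main_peak()
    f_peak = ls.fitness(peak)
    genotypes = sorted(ls.entries)
    # columns: every (site, state != peak state) present in the data
    cols: list[tuple[int, str]] = sorted(
        {(i, g[i]) for g in genotypes for i in range(ls.length) if g[i] != peak[i]}
    )
    col_index = {c: j for j, c in enumerate(cols)}
    X = np.zeros((len(genotypes), len(cols)))
    y = np.empty(len(genotypes))
    for r, g in enumerate(genotypes):
        y[r] = ls.fitness(g) - f_peak
        for i in range(ls.length):
            if g[i] != peak[i]:
                X[r, col_index[(i, g[i])]] = 1.0
    if cols:
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        pred = X @ coef
    else:  # single-genotype column set cannot occur (>=2 entries, same length)
        coef = np.zeros(0)
        pred = np.zeros(len(genotypes))
    resid = y - pred
    fitted = {g: float(pred[r] + f_peak) for r, g in enumerate(genotypes)}
    f = np.array([ls.fitness(g) for g in genotypes])
    return AdditiveFit(
        peak=peak,
        contributions={c: float(coef[j]) for c, j in col_index.items()},
        fitted=fitted,
        ss_residual=float(resid @ resid),
        ss_fitness=float(f @ f),
    )


def deviation_from_additivity(fit: AdditiveFit) -> float:
    """Residual sum of squares over the sum of squared fitnesses.

    Dimensionless; 0 for a perfectly additive landscape.  Undefined (raises)
    when every fitness is zero.
    """
    if fit.ss_fitness == 0.0:
        raise ValueError("deviation from additivity undefined: all fitnesses are zero")
    return fit.ss_residual / fit.ss_fitness


def variability_explained(fit: AdditiveFit) -> float:
    """Fraction of the squared fitness accounted for by the additive model."""
    return 1.0 - deviation_from_additivity(fit)


def local_roughness(ls: Landscape) -> float:
    """Mean over nodes of the RMS fitness difference to their neighbours."""
    total = 0.0
    for g in ls:
        nbrs = ls.neighbors(g)
        if not nbrs:
            raise ValueError(f"genotype {g!r} has no neighbours in the landscape")
        diffs = np.array([ls.fitness(g) - ls.fitness(nb) for nb in nbrs])
        total += float(np.sqrt(np.mean(diffs**2)))
    return total / len(ls)


def find_peaks(ls: Landscape) -> set[str]:
    """All nodes with no strictly fitter neighbour (plateaus are peaks)."""
    return {
        g
        for g in ls
        if not any(ls.fitness(nb) > ls.fitness(g) for nb in ls.neighbors(g))
    }


def tree_component(ls: Landscape) -> set[str]:
    """All nodes with at most one strictly fitter neighbour.

    A superset of ``find_peaks``; monotonic uphill paths restricted to this
    set are unbranched.
    """
    out = set()
    for g in ls:
        fitter = sum(1 for nb in ls.neighbors(g) if ls.fitness(nb) > ls.fitness(g))
        if fitter <= 1:
            out.add(g)
    return out


def _diameter(ls: Landscape) -> int:
    """Maximum pairwise Hamming distance among present genotypes."""
    genotypes = list(ls)
    arr = np.array([[ord(c) for c in g] for g in genotypes])
    best = 0
    for row in arr:
        best = max(best, int((arr != row).sum(axis=1).max()))
    return best


def mean_tree_distance(ls: Landscape) -> float:
    """Mean graph distance from each node to the nearest tree-component node.

    Distances are shortest paths in the landscape's own Hamming-1 graph
    (absent genotypes are inviable and cannot be traversed).  Nodes with no
    path to the tree component are assigned the landscape diameter + 1 and
    a warning is emitted.
    """
    tree = tree_component(ls)
    graph = ls.graph()
    dist = nx.multi_source_dijkstra_path_length(graph, tree) if tree else {}
    unreachable = [g for g in ls if g not in dist]
    if unreachable:
        penalty = _diameter(ls) + 1
        warnings.warn(
            f"{len(unreachable)} node(s) cannot reach the tree component; "
            f"counting their distance as diameter+1 = {penalty}",
            stacklevel=2,
        )
        for g in unreachable:
            dist[g] = penalty
    return float(np.mean([dist[g] for g in ls]))


@dataclass
class RoughnessReport:
    """The roughness block of the landscape characteristics table."""

    deviation_from_additivity: float
    variability_explained: float
    local_roughness: float
    n_peaks: int
    peak_fraction: float
    mean_tree_distance: float
    n_genotypes: int

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def roughness_report(ls: Landscape) -> RoughnessReport:
    """Compute all four roughness characteristics of a landscape."""
    fit = fit_additive(ls)
    peaks = find_peaks(ls)
    return RoughnessReport(
        deviation_from_additivity=deviation_from_additivity(fit),
        variability_explained=variability_explained(fit),
        local_roughness=local_roughness(ls),
        n_peaks=len(peaks),
        peak_fraction=len(peaks) / len(ls),
        mean_tree_distance=mean_tree_distance(ls),
        n_genotypes=len(ls),
    )
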