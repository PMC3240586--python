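"""Permutation null models and the noisy-additive landscape generator.

A scrambled landscape keeps the genotype set (hence the topology) and the
fitness multiset but assigns fitnesses by a uniform random permutation — an
uncorrelated null against which any landscape characteristic is scored as
Z = (original - permutation mean) / permutation SD.

The generator builds additive landscapes perturbed by noise: a designated
peak sequence gets fitness 1; each possible substitution away from the peak
carries a negative fitness differential drawn from an exponential
distribution; the summed additive fitness of a mutant is perturbed by
additive Gaussian noise or by multiplication with a power of a uniform
variate.  Mutants whose perturbed fitness is positive are kept, and the
landscape is restricted to the peak's connected component.  Sweeping the
noise amplitude yields a family of landscapes of continuously varying
roughness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import paths as pathstats
from . import roughness as rough
from .landscape import Landscape, connected_component, full_space

__all__ = [
    "NoiseSpec",
    "ZScoreReport",
    "METRICS",
    "scramble",
    "zscore",
    "generate_noisy_additive",
    "noise_family",
    "mean_path_divergence_strong_limit",
]


def scramble(ls: Landscape, rng: np.random.Generator) -> Landscape:
    """Randomly permute fitness values over the same genotype set."""
    if len(ls) < 2:
        return Landscape(dict(ls.entries), alphabet=ls.alphabet)
    genotypes = sorted(ls.entries)
    values = np.array([ls.entries[g] for g in genotypes])
    perm = rng.permutation(len(values))
    return Landscape(
        {g: float(values[p]) for g, p in zip(genotypes, perm)}, alphabet=ls.alphabet
    )


def mean_path_divergence_strong_limit(ls: Landscape) -> float:
    """Landscape-wide mean path divergence in the strong-selection limit.

    Exhaustively enumerates strictly uphill trajectory bundles from every
    non-peak start (path probabilities of the strong-selection adaptive
    walk) and averages bundle divergences weighted by bundle path counts.
    Intended for landscapes small enough to enumerate.
    """
    peaks = rough.find_peaks(ls)
    bundles = []
    for start in sorted(ls.entries):
        if start in peaks:
            continue
        bundles.extend(pathstats.enumerate_uphill_bundles(ls, start))
    if not bundles:
        return 0.0
    return pathstats.divergence_profile(bundles).overall


#: The six landscape characteristics, as named metric callables.
METRICS = {
    "deviation_from_additivity": lambda ls: rough.deviation_from_additivity(
        rough.fit_additive(ls)
    ),
    "local_roughness": rough.local_roughness,
    "peak_fraction": lambda ls: len(rough.find_peaks(ls)) / len(ls),
    "mean_tree_distance": rough.mean_tree_distance,
    "monotonic_path_fraction": pathstats.monotonic_path_fraction,
    "mean_path_divergence": mean_path_divergence_strong_limit,
}


@dataclass
class ZScoreReport:
    """A landscape characteristic scored against its permutation null."""

    metric: str
    original: float
    perm_mean: float
    perm_sd: float
    z: float  # NaN when the permutation SD is zero
    n_permutations: int

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def zscore(
    ls: Landscape,
    metric: str,
    n_perm: int = 100,
    rng: np.random.Generator | None = None,
) -> ZScoreReport:
    """Score a named characteristic against ``n_perm`` scrambled landscapes.

    With zero permutation SD (e.g. constant fitness) the Z-score is
    reported as NaN.
    """
    if metric not in METRICS:
        raise KeyError(f"unknown metric {metric!r}; choose from {sorted(METRICS)}")
    if n_perm < 2:
        raise ValueError("need at least 2 permutations")
    rng = rng if rng is not None else np.random.default_rng()
    fn = METRICS[metric]
    original = float(fn(ls))
    vals = np.array([fn(scramble(ls, rng)) for _ in range(n_perm)])
    mean, sd = float(vals.mean()), float(vals.std(ddof=1))
    if sd == 0.0:
        import warnings

        warnings.warn(f"zero permutation SD for metric {metric!r}; z undefined",
                      stacklevel=2)
        z = math.nan
    else:
        z = (original - mean) / sd
    return ZScoreReport(
        metric=metric, original=original, perm_mean=mean, perm_sd=sd, z=z,
        n_permutations=n_perm,
    )


@dataclass
class NoiseSpec:
    """Noise model for the additive-landscape generator.

    ``kind`` is 'none', 'additive' (zero-mean Gaussian of SD ``sigma``
    added to the summed fitness) or 'multiplicative' (fitness multiplied by
    U(0,1)**nu; nu = 0 leaves the landscape exactly additive, larger nu
    roughens it).  ``lambda_rate`` is the rate of the exponential
    distribution of the per-substitution fitness differentials; ``None``
    selects 1.25 * length so that the expected additive fitness at maximal
    distance from the peak is 0.2.
    """

    kind: str = "multiplicative"
    sigma: float = 0.0
    nu: float = 1.0
    lambda_rate: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("none", "additive", "multiplicative"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.sigma < 0 or self.nu < 0:
            raise ValueError("sigma and nu must be non-negative")
        if self.lambda_rate is not None and self.lambda_rate <= 0:
            raise ValueError("lambda_rate must be positive")


def generate_noisy_additive(
    length: int,
    alphabet: tuple[str, ...],
    noise: NoiseSpec,
    rng: np.random.Generator,
) -> Landscape:
    """Generate an additive landscape perturbed by noise.

    The designated peak is the all-``alphabet[0]`` sequence with fitness 1.
    Every (site, non-peak state) carries an independent differential
    -Exp(lambda_rate); a mutant's additive fitness is 1 plus the sum of the
    differentials of its substitutions, perturbed by the chosen noise (the
    peak itself is left unperturbed at 1).  Mutants with positive perturbed
    fitness are retained and the result is restricted to the peak's
    connected component.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    alphabet = tuple(alphabet)
    lam = noise.lambda_rate if noise.lambda_rate is not None else 1.25 * length
    peak = alphabet[0] * length
    non_peak = alphabet[1:]
    # per-(site, state) negative differentials
    diffs = -rng.exponential(scale=1.0 / lam, size=(length, len(non_peak)))
    state_idx = {sym: j for j, sym in enumerate(non_peak)}
    entries: dict[str, float] = {peak: 1.0}
    for g in full_space(length, alphabet):
        if g == peak:
            continue
        f = 1.0 + sum(
            diffs[i, state_idx[g[i]]] for i in range(length) if g[i] != alphabet[0]
        )
        if noise.kind == "additive":
            f += rng.normal(0.0, noise.sigma)
        elif noise.kind == "multiplicative":
            f *= rng.uniform() ** noise.nu
        if f > 0.0:
            entries[g] = f
    ls = Landscape(entries, alphabet=alphabet)
    return connected_component(ls, peak)


def noise_family(
    length: int,
    alphabet: tuple[str, ...],
    noise_grid: list[NoiseSpec],
    seeds: list[int],
) -> dict[tuple[int, int], Landscape]:
    """Landscapes for every (noise level, seed) pair, keyed by grid indices.

    Reproducible: the same seed and spec always give the same landscape.
    """
    if not noise_grid:
        raise ValueError("noise grid must be non-empty")
    out = {}
    for i, spec in enumerate(noise_grid):
        for j, seed in enumerate(seeds):
            rng = np.random.default_rng(seed)
            out[(i, j)] = generate_noisy_additive(length, alphabet, spec, rng)
    return out
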