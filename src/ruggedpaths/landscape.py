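"""Genotype-fitness landscapes with Hamming-1 adjacency.

A landscape maps fixed-length genotype strings over a finite alphabet
(binary mutant libraries, 4-letter monomer sequences, 20-letter protein
alphabets) to real fitness values.  Adjacency between genotypes is implicit:
two genotypes are neighbours iff they differ at exactly one site.  Genotypes
absent from the landscape are treated as inviable everywhere downstream.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import networkx as nx
import pandas as pd
import yaml

__all__ = [
    "Landscape",
    "LoadSpec",
    "hamming_distance",
    "load_landscape",
    "write_landscape",
    "connected_component",
]

#: Convenient alphabets by size.
ALPHABETS = {
    2: ("0", "1"),
    4: ("H", "P", "+", "-"),
}


def hamming_distance(a: str, b: str) -> int:
    """Number of sites at which two equal-length genotypes differ.

    Raises ``ValueError`` on a length mismatch.
    """
    if len(a) != len(b):
        raise ValueError(f"genotype length mismatch: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))


@dataclass
class Landscape:
    """A finite genotype-to-fitness mapping with Hamming-1 adjacency.

    Parameters
    ----------
    entries
        Mapping from genotype string to finite fitness.
    alphabet
        The symbol set; inferred from the entries when omitted.
    """

    entries: dict[str, float]
    alphabet: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("landscape must contain at least one genotype")
        lengths = {len(g) for g in self.entries}
        if len(lengths) != 1:
            raise ValueError(f"genotypes have inconsistent lengths: {sorted(lengths)}")
        (self.length,) = lengths
        if self.length == 0:
            raise ValueError("genotypes must have length > 0")
        seen = sorted({c for g in self.entries for c in g})
        if not self.alphabet:
            self.alphabet = tuple(seen)
        else:
            extra = set(seen) - set(self.alphabet)
            if extra:
                raise ValueError(f"symbols outside the alphabet: {sorted(extra)}")
        for g, f in self.entries.items():
            if not math.isfinite(f):
                raise ValueError(f"non-finite fitness for genotype {g!r}")

    # -- basic protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, g: str) -> bool:
        return g in self.entries

    def __iter__(self) -> Iterator[str]:
        return iter(self.entries)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Landscape):
            return NotImplemented
        return self.entries == other.entries and self.alphabet == other.alphabet

    def fitness(self, g: str) -> float:
        return self.entries[g]

    # -- adjacency ------------------------------------------------------
    def neighbors(self, g: str) -> list[str]:
        """All present genotypes at Hamming distance 1, lexicographic order."""
        if g not in self.entries:
            raise KeyError(f"genotype {g!r} not in landscape")
        out = []
        for i in range(self.length):
            for sym in self.alphabet:
                if sym == g[i]:
                    continue
                cand = g[:i] + sym + g[i + 1 :]
                if cand in self.entries:
                    out.append(cand)
        out.sort()
        return out

    def main_peak(self) -> str:
        """Genotype with maximal fitness; ties broken lexicographically."""
        return min(self.entries, key=lambda g: (-self.entries[g], g))

    def graph(self) -> nx.Graph:
        """The Hamming-1 adjacency graph over present genotypes."""
        g = nx.Graph()
        g.add_nodes_from(self.entries)
        for node in self.entries:
            for nb in self.neighbors(node):
                if node < nb:
                    g.add_edge(node, nb)
        return g


@dataclass
class LoadSpec:
    """How to interpret a genotype-fitness table.

    ``genotype_column`` names a column of explicit genotype strings; when it
    is ``None``, ``substitution_columns`` name 0/1 presence/absence columns
    (one per mutated site) that are concatenated into a binary genotype.
    ``transform`` maps the raw fitness proxy ('identity' or 'log', base 10)
    and ``normalize`` min-max rescales the transformed values onto [0, 1].
    """

    genotype_column: str | None = "genotype"
    fitness_column: str = "fitness"
    substitution_columns: tuple[str, ...] = ()
    transform: str = "identity"
    normalize: bool = False

    @classmethod
    def from_yaml(cls, path) -> "LoadSpec":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "substitution_columns" in raw:
            raw["substitution_columns"] = tuple(raw["substitution_columns"])
        return cls(**raw)


def _apply_transform(values: pd.Series, spec: LoadSpec) -> pd.Series:
    if spec.transform == "identity":
        out = values.astype(float)
    elif spec.transform == "log":
        bad = values[values <= 0]
        if not bad.empty:
            row = bad.index[0]
            raise ValueError(
                f"log transform requires positive values; row {row} has {bad.iloc[0]!r}"
            )
        import numpy as np

        out = pd.Series(np.log10(values.astype(float)), index=values.index)
    else:
        raise ValueError(f"unknown transform {spec.transform!r}")
    return out


def load_landscape(path, spec: LoadSpec | None = None) -> Landscape:
    """Read a TSV genotype-fitness table.

    Two dialects are supported: explicit genotype strings, or one 0/1 column
    per named substitution (combinatorial mutant libraries).  The fitness
    proxy transform is applied first, then optional min-max normalization
    onto [0, 1]; with a single distinct value everything maps to 0.
    """
    spec = spec or LoadSpec()
    df = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip",
                     dtype={spec.genotype_column: str}
                     if spec.genotype_column else None)
    if spec.substitution_columns:
        missing = set(spec.substitution_columns) - set(df.columns)
        if missing:
            raise ValueError(f"missing substitution columns: {sorted(missing)}")
        genotypes = (
            df[list(spec.substitution_columns)]
            .astype(int)
            .astype(str)
            .agg("".join, axis=1)
        )
    else:
        genotypes = df[spec.genotype_column].astype(str)
    dup = genotypes[genotypes.duplicated()]
    if not dup.empty:
        raise ValueError(f"duplicate genotype {dup.iloc[0]!r}")
    fitness = _apply_transform(df[spec.fitness_column], spec)
    if spec.normalize:
        lo, hi = float(fitness.min()), float(fitness.max())
        if hi > lo:
            fitness = (fitness - lo) / (hi - lo)
        else:
            fitness = fitness * 0.0
    return Landscape(dict(zip(genotypes, fitness.astype(float))))


def write_landscape(ls: Landscape, path) -> None:
    """Write a landscape as a two-column TSV that round-trips exactly."""
    with open(path, "w") as fh:
        fh.write("genotype\tfitness\n")
        for g in sorted(ls.entries):
            fh.write(f"{g}\t{ls.entries[g]:.17g}\n")


def connected_component(ls: Landscape, g: str) -> Landscape:
    """Sub-landscape reachable from ``g`` via Hamming-1 steps within ``ls``."""
    if g not in ls:
        raise KeyError(f"genotype {g!r} not in landscape")
    seen = {g}
    queue = deque([g])
    while queue:
        node = queue.popleft()
        for nb in ls.neighbors(node):
            if nb not in seen:
                seen.add(nb)
                queue.append(nb)
    return Landscape({x: ls.entries[x] for x in seen}, alphabet=ls.alphabet)


def full_space(length: int, alphabet: Iterable[str]) -> Iterator[str]:
    """Enumerate every genotype of the full Hamming space (lexicographic)."""
    import itertools

    for tup in itertools.product(sorted(alphabet), repeat=length):
        yield "".join(tup)
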