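"""Coarse-grained off-lattice heteropolymer folding.

The polymer is a chain of point monomers of four types — hydrophobic H,
hydrophilic P, and charged + and - — connected by stiff harmonic springs of
rest length ``a`` with unrestricted bond angles.  Monomers two or more
links apart interact through a Lennard-Jones term plus a Debye-Hueckel
screened Coulomb term:

    V_ij(r) = A_ij / r^12 - B_ij / r^6 + q_i q_j exp(-r / lambda_D) / r

The pair coefficients mimic amino-acid interactions in solvent: the HH
attraction is the strongest, like-type pairs attract weakly, H repels P
and repels charged monomers even more strongly.  Dynamics are overdamped
Brownian: each coordinate moves down the energy gradient with added
thermal noise of variance 2 T dt.  A quench equilibrates the chain at the
simulation temperature and then relaxes it at a much lower quench
temperature until the energy is stationary.

A sequence's "native structure" is the largest single-linkage cluster (at
RMSD radius delta) of many independently quenched conformations, and its
folding probability is the fraction of fresh quenches that land within the
cluster's membership threshold (median nearest-neighbour RMSD plus a
multiple of its median absolute deviation).

All physical constants here are model units, not fitted to any protein;
they are configuration fields chosen to satisfy the qualitative orderings
above, and every analysis that consumes folding probabilities treats them
as opaque.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "MONOMER_TYPES",
    "PhysicsConfig",
    "QuenchResult",
    "NativeEnsemble",
    "validate_sequence",
    "pair_potential",
    "chain_energy",
    "chain_gradient",
    "brownian_step",
    "random_chain",
    "quench",
    "rmsd",
    "build_native_ensemble",
    "folding_probability",
    "write_xyz",
    "read_xyz",
]

MONOMER_TYPES = ("H", "P", "+", "-")


def validate_sequence(s: str) -> str:
    """Check a monomer sequence: length >= 3, charged endpoints."""
    if len(s) < 3:
        raise ValueError("sequence must have length >= 3")
    bad = set(s) - set(MONOMER_TYPES)
    if bad:
        raise ValueError(f"unknown monomer types: {sorted(bad)}")
    if s[0] not in "+-" or s[-1] not in "+-":
        raise ValueError("endpoint monomers must be charged (+ or -)")
    return s


def _sym(table: dict[tuple[str, str], float]) -> dict[tuple[str, str], float]:
    out = dict(table)
    for (a, b), v in table.items():
        out[(b, a)] = v
    return out


# Lennard-Jones B coefficients (r^-6 term): positive = attraction.
# HH strongest; like pairs weakly attractive; H-P repulsive; H-charged
# more strongly repulsive; P-charged mildly attractive; +- attract through
# the Coulomb term on top of a weak LJ well.
_DEFAULT_B = _sym(
    {
        ("H", "H"): 2.0,
        ("P", "P"): 0.5,
        ("+", "+"): 0.5,
        ("-", "-"): 0.5,
        ("+", "-"): 0.5,
        ("H", "P"): -0.5,
        ("H", "+"): -1.0,
        ("H", "-"): -1.0,
        ("P", "+"): 0.3,
        ("P", "-"): 0.3,
    }
)
_DEFAULT_A = {pair: 1.0 for pair in _DEFAULT_B}
_DEFAULT_Q = {"H": 0.0, "P": 0.0, "+": 1.0, "-": -1.0}


@dataclass
class PhysicsConfig:
    """Model parameters, all in reduced units (length a, energy k_B T = 1).

    The spring constant multiplies temperature, so bond stiffness tracks
    the thermal scale.  ``noise_coeff`` isolates the Brownian noise
    variance convention (variance = noise_coeff * T * dt).
    """

    rest_length: float = 1.0
    spring_k: float = 200.0
    temperature: float = 0.3
    quench_temperature: float = 0.02
    debye_length: float = 1.0
    lj_A: dict = field(default_factory=lambda: dict(_DEFAULT_A))
    lj_B: dict = field(default_factory=lambda: dict(_DEFAULT_B))
    charges: dict = field(default_factory=lambda: dict(_DEFAULT_Q))
    dt: float = 3e-4
    noise_coeff: float = 2.0
    max_step: float = 0.1  # cap on per-monomer displacement per step
    equil_steps: int = 4000
    max_quench_steps: int = 12_000
    stationarity_tol: float = 2e-3
    stationarity_window: int = 400
    zero_t_steps: int = 800
    cluster_delta: float = 0.5
    mad_multiplier: float = 3.0

    def __post_init__(self) -> None:
        self._table_cache: dict[str, tuple] = {}
        for name in ("rest_length", "spring_k", "temperature", "quench_temperature",
                     "debye_length", "dt", "noise_coeff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for (a, b), v in self.lj_A.items():
            if self.lj_A.get((b, a)) != v or (a, b) not in self.lj_B:
                raise ValueError("pair coefficient tables must be symmetric and aligned")

    def pair_tables(self, seq: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-pair A, B and charge-product matrices for a sequence (cached)."""
        cached = self._table_cache.get(seq)
        if cached is not None:
            return cached
        n = len(seq)
        A = np.empty((n, n))
        B = np.empty((n, n))
        for i in range(n):
            for j in range(n):
                A[i, j] = self.lj_A[(seq[i], seq[j])]
                B[i, j] = self.lj_B[(seq[i], seq[j])]
        q = np.array([self.charges[c] for c in seq])
        tables = (A, B, np.outer(q, q))
        self._table_cache[seq] = tables
        return tables


def pair_potential(r: float, type_i: str, type_j: str, cfg: PhysicsConfig) -> float:
    """Non-bonded pair energy at separation ``r``."""
    if r <= 0:
        raise ValueError("separation must be positive")
    A = cfg.lj_A[(type_i, type_j)]
    B = cfg.lj_B[(type_i, type_j)]
    qq = cfg.charges[type_i] * cfg.charges[type_j]
    v = A / r**12 - B / r**6
    if qq != 0.0:
        v += qq * math.exp(-r / cfg.debye_length) / r
    return v


def _check_shapes(coords: np.ndarray, seq: str) -> np.ndarray:
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3 or coords.shape[0] != len(seq):
        raise ValueError(
            f"coordinates must be ({len(seq)}, 3); got {coords.shape}"
        )
    return coords


def _pair_geometry(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    disp = coords[:, None, :] - coords[None, :, :]
    r = np.sqrt((disp**2).sum(axis=2))
    return disp, r


def chain_energy(coords: np.ndarray, seq: str, cfg: PhysicsConfig) -> float:
    """Total chain energy: non-bonded pairs (|i-j| >= 2) plus bond springs."""
    coords = _check_shapes(coords, seq)
    n = len(seq)
    _, r = _pair_geometry(coords)
    A, B, QQ = cfg.pair_tables(seq)
    iu, ju = np.triu_indices(n, k=2)
    rr = r[iu, ju]
    if np.any(rr == 0.0):
        raise ValueError("coincident non-bonded monomers (zero separation)")
    e = float(
        np.sum(
            A[iu, ju] / rr**12
            - B[iu, ju] / rr**6
            + QQ[iu, ju] * np.exp(-rr / cfg.debye_length) / rr
        )
    )
    bonds = r[np.arange(n - 1), np.arange(1, n)]
    e += float(0.5 * cfg.spring_k * cfg.temperature
               * np.sum((bonds - cfg.rest_length) ** 2))
    return e


def chain_gradient(coords: np.ndarray, seq: str, cfg: PhysicsConfig) -> np.ndarray:
    """Analytic gradient dE/dx, shape (n, 3)."""
    coords = _check_shapes(coords, seq)
    n = len(seq)
    disp, r = _pair_geometry(coords)
    A, B, QQ = cfg.pair_tables(seq)
    mask = np.abs(np.subtract.outer(np.arange(n), np.arange(n))) >= 2
    rs = np.where(r > 0, r, 1.0)
    # dV/dr for the non-bonded terms
    dvdr = -12.0 * A / rs**13 + 6.0 * B / rs**7
    dvdr += QQ * np.exp(-rs / cfg.debye_length) * (-1.0 / (cfg.debye_length * rs) - 1.0 / rs**2)
    dvdr = np.where(mask & (r > 0), dvdr, 0.0)
    # bond springs: dV/dr = k T (r - a)
    bond = np.zeros_like(r)
    idx = np.arange(n - 1)
    bond[idx, idx + 1] = bond[idx + 1, idx] = 1.0
    dvdr += np.where(bond > 0, cfg.spring_k * cfg.temperature * (rs - cfg.rest_length), 0.0)
    grad = (dvdr / rs)[:, :, None] * disp
    out = grad.sum(axis=1)
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("non-finite gradient: configuration diverged")
    return out


def brownian_step(
    coords: np.ndarray,
    seq: str,
    cfg: PhysicsConfig,
    rng: np.random.Generator,
    temperature: float | None = None,
) -> np.ndarray:
    """One overdamped Brownian update of every monomer coordinate.

    x <- x - dE/dx * dt + eta, with eta zero-mean Gaussian of variance
    noise_coeff * T * dt, independent across monomers, coordinates and
    steps.  The deterministic drift is capped at ``max_step`` per monomer
    to keep steep core overlaps from destabilising the integration.
    """
    T = cfg.temperature if temperature is None else temperature
    grad = chain_gradient(coords, seq, cfg)
    drift = -grad * cfg.dt
    norms = np.linalg.norm(drift, axis=1, keepdims=True)
    safe = np.maximum(norms, 1e-300)
    drift *= np.where(norms > cfg.max_step, cfg.max_step / safe, 1.0)
    noise = 0.0
    if T > 0:
        noise = rng.normal(0.0, math.sqrt(cfg.noise_coeff * T * cfg.dt), coords.shape)
    return coords + drift + noise


def random_chain(seq: str, cfg: PhysicsConfig, rng: np.random.Generator) -> np.ndarray:
    """Initial conformation: a random walk at bond length with core spacing."""
    n = len(seq)
    coords = np.zeros((n, 3))
    for i in range(1, n):
        for _ in range(200):
            step = rng.normal(size=3)
            step *= cfg.rest_length / np.linalg.norm(step)
            cand = coords[i - 1] + step
            if i < 2 or np.min(np.linalg.norm(coords[: i - 1] - cand, axis=1)) > 0.7 * cfg.rest_length:
                coords[i] = cand
                break
        else:
            coords[i] = cand
    return coords


@dataclass
class QuenchResult:
    """Outcome of a quench: final conformation plus convergence diagnostics."""

    coords: np.ndarray
    converged: bool
    energy: float
    steps: int


def quench(
    seq: str,
    cfg: PhysicsConfig,
    rng: np.random.Generator,
    start: np.ndarray | None = None,
) -> QuenchResult:
    """Equilibrate at T, drop to the quench temperature, relax to stationarity.

    Stationarity is judged on window-averaged energies (thermal noise keeps
    the instantaneous energy fluctuating): relative change between
    consecutive ``stationarity_window`` averages below ``stationarity_tol``.
    A hard budget of ``max_quench_steps`` flags non-converged results.  A
    final noise-free gradient descent of ``zero_t_steps`` settles the chain
    into its basin minimum so that repeated quenches of the same basin give
    nearly identical conformations.
    """
    validate_sequence(seq)
    coords = random_chain(seq, cfg, rng) if start is None else np.array(start, float)
    for _ in range(cfg.equil_steps):
        coords = brownian_step(coords, seq, cfg, rng)
    prev_mean = math.inf
    steps = 0
    converged = False
    while steps < cfg.max_quench_steps:
        acc = 0.0
        n_meas = 0
        for k in range(cfg.stationarity_window):
            coords = brownian_step(coords, seq, cfg, rng,
                                   temperature=cfg.quench_temperature)
            if k % 10 == 9:  # subsample the energy; successive steps correlate
                acc += chain_energy(coords, seq, cfg)
                n_meas += 1
        steps += cfg.stationarity_window
        mean_e = acc / max(n_meas, 1)
        if abs(mean_e - prev_mean) <= cfg.stationarity_tol * max(abs(prev_mean), 1.0):
            converged = True
            break
        prev_mean = mean_e
    for _ in range(cfg.zero_t_steps):
        coords = brownian_step(coords, seq, cfg, rng, temperature=0.0)
    return QuenchResult(coords=coords, converged=converged,
                        energy=chain_energy(coords, seq, cfg), steps=steps)


def rmsd(c1: np.ndarray, c2: np.ndarray) -> float:
    """RMSD after optimal rigid superposition (Kabsch, proper rotations)."""
    a = np.asarray(c1, float)
    b = np.asarray(c2, float)
    if a.shape != b.shape:
        raise ValueError(f"conformation shapes differ: {a.shape} vs {b.shape}")
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    cov = a.T @ b
    u, _, vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(u @ vt))
    rot = u @ np.diag([1.0, 1.0, d]) @ vt
    diff = a @ rot - b
    return float(np.sqrt((diff**2).sum() / len(a)))


@dataclass
class NativeEnsemble:
    """Largest cluster of quenched conformations: a sequence's native fold.

    Membership of a new conformation requires its shortest RMSD to any
    member to be at most ``threshold`` = median(m) + c * MAD, where m are
    the members' nearest-neighbour RMSDs.
    """

    members: list[np.ndarray]
    delta: float
    median_nn: float
    mad_nn: float
    threshold: float

    def min_rmsd(self, coords: np.ndarray) -> float:
        return min(rmsd(coords, m) for m in self.members)

    def contains(self, coords: np.ndarray) -> bool:
        return self.min_rmsd(coords) <= self.threshold


def cluster_conformations(
    conformations: list[np.ndarray], delta: float
) -> list[list[int]]:
    """Single-linkage clusters at RMSD radius ``delta`` (indices, sorted
    by decreasing size then by smallest member index)."""
    n = len(conformations)
    rows, cols = [], []
    for i in range(n):
        for j in range(i + 1, n):
            if rmsd(conformations[i], conformations[j]) <= delta:
                rows.append(i)
                cols.append(j)
    adj = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    n_comp, labels = connected_components(adj, directed=False)
    clusters: dict[int, list[int]] = {}
    for idx, lab in enumerate(labels):
        clusters.setdefault(lab, []).append(idx)
    return sorted(clusters.values(), key=lambda c: (-len(c), c[0]))


def ensemble_from_conformations(
    conformations: list[np.ndarray], delta: float, mad_multiplier: float = 3.0
) -> NativeEnsemble:
    """Build the native ensemble from an existing conformation collection."""
    if len(conformations) < 2:
        raise ValueError("need at least 2 conformations")
    clusters = cluster_conformations(conformations, delta)
    largest = clusters[0]
    if len(largest) < 2:
        raise ValueError("all clusters are singletons: no reproducible fold")
    members = [conformations[i] for i in largest]
    nn = []
    for i, m in enumerate(members):
        nn.append(min(rmsd(m, o) for j, o in enumerate(members) if j != i))
    nn_arr = np.array(nn)
    m_med = float(np.median(nn_arr))
    mad = float(np.median(np.abs(nn_arr - m_med)))
    return NativeEnsemble(
        members=members,
        delta=delta,
        median_nn=m_med,
        mad_nn=mad,
        threshold=m_med + mad_multiplier * mad,
    )


def build_native_ensemble(
    seq: str, n_quench: int, cfg: PhysicsConfig, rng: np.random.Generator
) -> NativeEnsemble:
    """Quench ``n_quench`` times and keep the largest conformation cluster."""
    if n_quench < 2:
        raise ValueError("need at least 2 quenches")
    confs = [quench(seq, cfg, rng).coords for _ in range(n_quench)]
    return ensemble_from_conformations(confs, cfg.cluster_delta, cfg.mad_multiplier)


def folding_probability(
    seq: str,
    ref: NativeEnsemble,
    n_samples: int,
    cfg: PhysicsConfig,
    rng: np.random.Generator,
) -> float:
    """Fraction of fresh quenches of ``seq`` that fall in the reference
    ensemble; resolution 1 / n_samples."""
    if n_samples < 1:
        raise ValueError("need at least 1 sample")
    hits = sum(
        ref.contains(quench(seq, cfg, rng).coords) for _ in range(n_samples)
    )
    return hits / n_samples


def write_xyz(coords: np.ndarray, seq: str, path, comment: str = "") -> None:
    """Serialize a conformation in XYZ format (type as element column)."""
    coords = _check_shapes(coords, seq)
    with open(path, "w") as fh:
        fh.write(f"{len(seq)}\n{comment}\n")
        for t, (x, y, z) in zip(seq, coords):
            fh.write(f"{t} {x:.17g} {y:.17g} {z:.17g}\n")


def read_xyz(path) -> tuple[np.ndarray, str]:
    """Read an XYZ conformation; returns (coords, sequence)."""
    with open(path) as fh:
        n = int(fh.readline())
        fh.readline()
        types, rows = [], []
        for _ in range(n):
            parts = fh.readline().split()
            types.append(parts[0])
            rows.append([float(v) for v in parts[1:4]])
    return np.array(rows), "".join(types)
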