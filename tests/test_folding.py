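"""Off-lattice folding model: energetics, dynamics, clustering, RMSD."""

import math

import numpy as np
import pytest

from ruggedpaths.builder import radius_of_gyration
from ruggedpaths.folding import (
    PhysicsConfig,
    brownian_step,
    build_native_ensemble,
    chain_energy,
    chain_gradient,
    cluster_conformations,
    ensemble_from_conformations,
    folding_probability,
    pair_potential,
    quench,
    random_chain,
    read_xyz,
    rmsd,
    validate_sequence,
    write_xyz,
)


def _random_rigid_motion(coords, rng):
    from scipy.spatial.transform import Rotation

    rot = Rotation.random(random_state=rng).as_matrix()
    return coords @ rot.T + rng.normal(size=3) * 5.0


class TestPairPotential:
    def test_hh_attractive_at_long_range(self):
        cfg = PhysicsConfig()
        assert pair_potential(3.0, "H", "H", cfg) < 0.0

    def test_like_charges_repulsive_at_long_range(self):
        cfg = PhysicsConfig()
        assert pair_potential(3.0, "+", "+", cfg) > 0.0

    def test_lj_minimum_depth_closed_form(self):
        """At r = (2A/B)^(1/6) the LJ part reaches -B^2 / 4A."""
        cfg = PhysicsConfig()
        A = cfg.lj_A[("H", "H")]
        B = cfg.lj_B[("H", "H")]
        r_min = (2 * A / B) ** (1 / 6)
        assert pair_potential(r_min, "H", "H", cfg) == pytest.approx(
            -(B**2) / (4 * A)
        )

    def test_hh_attraction_strongest(self):
        cfg = PhysicsConfig()
        assert cfg.lj_B[("H", "H")] > max(
            cfg.lj_B[(a, a)] for a in ("P", "+", "-")
        )
        assert cfg.lj_B[("H", "P")] < 0
        assert cfg.lj_B[("H", "+")] < cfg.lj_B[("H", "P")]

    def test_zero_separation_rejected(self):
        with pytest.raises(ValueError):
            pair_potential(0.0, "H", "H", PhysicsConfig())


class TestChainEnergy:
    def test_rest_length_far_apart_springs_zero(self):
        cfg = PhysicsConfig(rest_length=10.0)  # monomers beyond LJ range
        coords = np.array([[0, 0, 0], [10.0, 0, 0], [20.0, 0, 0]])
        e = chain_energy(coords, "PPP", cfg)
        # only the 1-3 pair contributes, at r=20 essentially nothing
        assert abs(e) < 1e-6

    def test_rigid_motion_invariance(self):
        cfg = PhysicsConfig()
        rng = np.random.default_rng(0)
        seq = "+HPH-"
        coords = random_chain(seq, cfg, rng)
        e0 = chain_energy(coords, seq, cfg)
        for k in range(5):
            moved = _random_rigid_motion(coords, np.random.default_rng(k))
            assert chain_energy(moved, seq, cfg) == pytest.approx(e0, abs=1e-10)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            chain_energy(np.zeros((3, 3)), "+HPH-", PhysicsConfig())

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_gradient_matches_finite_differences(self, seed):
        cfg = PhysicsConfig()
        rng = np.random.default_rng(seed)
        seq = "+HHPPH-"
        coords = random_chain(seq, cfg, rng)
        grad = chain_gradient(coords, seq, cfg)
        eps = 1e-6
        for i in range(len(seq)):
            for k in range(3):
                plus = coords.copy()
                plus[i, k] += eps
                minus = coords.copy()
                minus[i, k] -= eps
                num = (
                    chain_energy(plus, seq, cfg) - chain_energy(minus, seq, cfg)
                ) / (2 * eps)
                assert grad[i, k] == pytest.approx(
                    num, rel=1e-5, abs=1e-6
                )


class TestBrownianStep:
    def test_zero_temperature_update_is_pure_drift(self):
        """At T=0 the update is exactly -grad * dt (no noise), and a
        zero-gradient configuration is a fixed point."""
        cfg = PhysicsConfig(rest_length=10.0)  # 1-3 pair beyond LJ/Coulomb range
        coords = np.array(
            [[0.0, 0, 0], [10.0, 0, 0], [20.0, 0, 0]]
        )
        g = chain_gradient(coords, "PPP", cfg)
        moved = brownian_step(coords, "PPP", cfg, np.random.default_rng(0),
                              temperature=0.0)
        assert np.allclose(moved - coords, -g * cfg.dt)
        assert np.allclose(moved, coords, atol=1e-6)  # gradient ~ 0 here

    def test_zero_temperature_descends_energy(self):
        cfg = PhysicsConfig()
        rng = np.random.default_rng(2)
        seq = "+HPH-"
        coords = random_chain(seq, cfg, rng)
        e = chain_energy(coords, seq, cfg)
        for _ in range(50):
            coords = brownian_step(coords, seq, cfg, rng, temperature=0.0)
            e_new = chain_energy(coords, seq, cfg)
            assert e_new <= e + 1e-9
            e = e_new

    def test_free_particle_diffusion_law(self):
        """With interactions switched off, displacement variance over n
        steps is noise_coeff * T * dt * n per coordinate."""
        cfg = PhysicsConfig(
            spring_k=1e-12,
            lj_A={k: 1e-30 for k in PhysicsConfig().lj_A},
            lj_B={k: 0.0 for k in PhysicsConfig().lj_B},
            charges={"H": 0.0, "P": 0.0, "+": 0.0, "-": 0.0},
        )
        rng = np.random.default_rng(7)
        n_steps, n_rep = 40, 300
        seq = "+P-"
        disp = []
        for _ in range(n_rep):
            coords = np.zeros((3, 3))
            start = coords.copy()
            for _ in range(n_steps):
                coords = brownian_step(coords, seq, cfg, rng)
            disp.append(coords - start)
        var = float(np.var(np.array(disp)))
        expected = cfg.noise_coeff * cfg.temperature * cfg.dt * n_steps
        n_samples = n_rep * 9
        se = expected * math.sqrt(2 / n_samples)
        assert var == pytest.approx(expected, abs=5 * se)


class TestQuench:
    def test_fixed_seed_bit_identical(self, fast_cfg):
        res1 = quench("+HHH-", fast_cfg, np.random.default_rng(3))
        res2 = quench("+HHH-", fast_cfg, np.random.default_rng(3))
        assert np.array_equal(res1.coords, res2.coords)

    def test_hydrophobic_chain_more_compact_than_hydrophilic(self, fast_cfg):
        cfg = PhysicsConfig()  # full-effort quench for a physical comparison
        rng = np.random.default_rng(1)
        rg_h = np.mean(
            [radius_of_gyration(quench("+HHHHHHHH-", cfg, rng).coords)
             for _ in range(4)]
        )
        rg_p = np.mean(
            [radius_of_gyration(quench("+PPPPPPPP-", cfg, rng).coords)
             for _ in range(4)]
        )
        assert rg_h < rg_p


class TestRMSD:
    def test_self_is_zero(self):
        c = np.random.default_rng(0).normal(size=(6, 3))
        assert rmsd(c, c) == pytest.approx(0.0, abs=1e-12)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(1)
        c = rng.normal(size=(8, 3))
        for k in range(5):
            assert rmsd(c, _random_rigid_motion(c, np.random.default_rng(k))) == (
                pytest.approx(0.0, abs=1e-10)
            )

    def test_matches_kabsch_oracle_on_toy_conformations(self):
        """Independent quaternion-based superposition oracle on two
        4-point conformations."""
        c1 = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 1]], float)
        c2 = np.array([[0, 0, 0], [1, 0, 0], [1, 1.2, 0], [0.2, 1, 0.8]], float)

        def quaternion_rmsd(a, b):
            a = a - a.mean(axis=0)
            b = b - b.mean(axis=0)
            # Horn's quaternion method
            M = a.T @ b
            Sxx, Sxy, Sxz = M[0]
            Syx, Syy, Syz = M[1]
            Szx, Szy, Szz = M[2]
            K = np.array([
                [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
                [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
                [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
                [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
            ])
            lam = np.linalg.eigvalsh(K)[-1]
            ssd = (a**2).sum() + (b**2).sum() - 2 * lam
            return math.sqrt(max(ssd, 0.0) / len(a))

        assert rmsd(c1, c2) == pytest.approx(quaternion_rmsd(c1, c2), abs=1e-10)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rmsd(np.zeros((3, 3)), np.zeros((4, 3)))


class TestClusteringAndEnsemble:
    def _planted_conformations(self, rng, sizes=(7, 3), spread=0.02, sep=50.0):
        """Well-separated tight clusters of jittered conformations."""
        base = rng.normal(size=(5, 3))
        out = []
        for ci, size in enumerate(sizes):
            centre = base + ci * sep  # rigid translation: RMSD 0 to base
            template = centre + rng.normal(scale=2.0, size=(5, 3)) * (ci + 1)
            for _ in range(size):
                out.append(template + rng.normal(scale=spread, size=(5, 3)))
        return out

    def test_planted_two_cluster_recovery(self):
        rng = np.random.default_rng(0)
        confs = self._planted_conformations(rng)
        ens = ensemble_from_conformations(confs, delta=0.5)
        assert len(ens.members) == 7

    def test_order_invariance(self):
        rng = np.random.default_rng(1)
        confs = self._planted_conformations(rng)
        ens1 = ensemble_from_conformations(confs, delta=0.5)
        perm = list(np.random.default_rng(2).permutation(len(confs)))
        ens2 = ensemble_from_conformations([confs[i] for i in perm], delta=0.5)
        assert len(ens1.members) == len(ens2.members)
        assert ens1.threshold == pytest.approx(ens2.threshold)

    def test_identical_conformations_degenerate_threshold(self):
        c = np.random.default_rng(3).normal(size=(4, 3))
        ens = ensemble_from_conformations([c.copy() for _ in range(5)], delta=0.5)
        assert len(ens.members) == 5
        assert ens.mad_nn == 0.0
        assert ens.threshold == ens.median_nn

    def test_all_singletons_rejected(self):
        rng = np.random.default_rng(4)
        confs = [rng.normal(size=(5, 3)) * 10 for _ in range(4)]
        with pytest.raises(ValueError, match="singleton"):
            ensemble_from_conformations(confs, delta=1e-6)

    def test_single_linkage_chains(self):
        """Single linkage merges chained conformations even when the chain
        ends are farther apart than delta."""
        rng = np.random.default_rng(5)
        confs = self._planted_conformations(rng, sizes=(4, 2))
        clusters = cluster_conformations(confs, delta=0.5)
        assert [len(c) for c in clusters[:2]] == [4, 2]


class TestFoldingProbability:
    def test_granularity(self):
        """Membership counting at resolution 1/n_samples via a stub quench."""
        rng = np.random.default_rng(0)
        member = rng.normal(size=(4, 3))
        far = member + 100.0 * np.eye(4, 3)  # not a rigid motion of member
        ens = ensemble_from_conformations(
            [member + rng.normal(scale=0.01, size=(4, 3)) for _ in range(4)],
            delta=0.5,
        )
        hits = sum(ens.contains(member) for _ in range(3))
        misses = sum(ens.contains(far) for _ in range(7))
        assert hits == 3 and misses == 0

    def test_planted_basin_occupancy(self, fast_cfg, monkeypatch):
        """With quench stubbed to draw from two planted basins, the
        estimate matches the planted occupancy within a binomial CI."""
        from ruggedpaths import folding as fd

        rng = np.random.default_rng(1)
        basin_a = rng.normal(size=(5, 3))
        basin_b = basin_a + 30.0 * rng.normal(size=(5, 3))
        p_true = 0.7

        members = [basin_a + rng.normal(scale=0.01, size=(5, 3)) for _ in range(6)]
        ens = ensemble_from_conformations(members, delta=0.5)

        draw_rng = np.random.default_rng(2)

        class StubResult:
            def __init__(self, coords):
                self.coords = coords

        def stub_quench(seq, cfg, rng_, start=None):
            basin = basin_a if draw_rng.uniform() < p_true else basin_b
            return StubResult(basin + draw_rng.normal(scale=0.001, size=(5, 3)))

        monkeypatch.setattr(fd, "quench", stub_quench)
        n = 400
        est = fd.folding_probability("+HPH-", ens, n, fast_cfg,
                                     np.random.default_rng(3))
        se = math.sqrt(p_true * (1 - p_true) / n)
        assert est == pytest.approx(p_true, abs=4 * se)


class TestSequenceAndIO:
    def test_validate_sequence(self):
        assert validate_sequence("+HPH-") == "+HPH-"
        with pytest.raises(ValueError):
            validate_sequence("HH")
        with pytest.raises(ValueError):
            validate_sequence("HPHPH")  # uncharged endpoints
        with pytest.raises(ValueError):
            validate_sequence("+HXH-")

    def test_xyz_round_trip(self, tmp_path):
        coords = np.random.default_rng(0).normal(size=(5, 3))
        path = tmp_path / "c.xyz"
        write_xyz(coords, "+HPH-", path)
        back, seq = read_xyz(path)
        assert seq == "+HPH-"
        assert np.array_equal(back, coords)
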