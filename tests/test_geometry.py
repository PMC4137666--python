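"""Superposition descriptors, supercoil radius and decoy clustering."""

import numpy as np
import pytest

from coilstab import CrickParameters, Ensemble, build_ideal_coiled_coil
from coilstab.geometry import (
    cluster_by_neighbors,
    estimate_supercoil_radius,
    pairwise_ca_rmsd,
    rmsd_series,
    rmsf_per_residue,
    superpose,
)
from coilstab.vecmath import kabsch

from .oracles import brute_cluster, brute_superpose_rmsd


def _random_rigid(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    R = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
    return R, rng.normal(scale=10.0, size=3)


class TestSuperpose:
    def test_identity(self, lic35):
        R, t, rmsd = superpose(lic35, lic35)
        assert rmsd < 1e-12
        assert np.allclose(R, np.eye(3))
        assert np.linalg.det(R) == pytest.approx(1.0)

    def test_rigid_invariance(self, lic35):
        rng = np.random.default_rng(1)
        R0, t0 = _random_rigid(rng)
        moved = lic35.with_coords(lic35.coords @ R0.T + t0)
        _, _, rmsd = superpose(moved, lic35)
        assert rmsd < 1e-6

    def test_against_quaternion_search_oracle(self):
        rng = np.random.default_rng(7)
        P = rng.normal(size=(5, 3))
        Q = rng.normal(size=(5, 3))
        _, _, rmsd = kabsch(P, Q)
        assert abs(rmsd - brute_superpose_rmsd(P, Q)) < 1e-4

    def test_count_mismatch_and_too_few(self, lic35, lic80):
        with pytest.raises(ValueError):
            superpose(lic35, lic80)
        with pytest.raises(ValueError):
            kabsch(np.zeros((2, 3)), np.zeros((2, 3)))


class TestRmsdSeries:
    def test_constant_ensemble_all_zero(self, lic35):
        ens = Ensemble(lic35, np.repeat(lic35.coords[None], 4, axis=0))
        assert np.allclose(rmsd_series(ens), 0.0)

    def test_single_atom_displacement_closed_form(self, lic35):
        """Displacing one atom by d gives pre-superposition RMSD d/sqrt(N);
        the superposed value can only be smaller and stays close for a
        large structure."""
        ca_mask = lic35.atom_mask("CA")
        n_ca = ca_mask.sum()
        d = 2.0
        coords2 = lic35.coords.copy()
        idx = np.flatnonzero(ca_mask)[n_ca // 2]
        coords2[idx] += [0, 0, d]
        ens = Ensemble(lic35, np.stack([lic35.coords, coords2]))
        series = rmsd_series(ens)
        closed_form = d / np.sqrt(n_ca)
        assert series[0] == 0.0
        assert series[1] <= closed_form + 1e-9
        assert series[1] == pytest.approx(closed_form, rel=0.05)

    def test_series_nonnegative_first_zero(self, lic35):
        rng = np.random.default_rng(0)
        coords = lic35.coords[None] + rng.normal(0, 0.3, size=(5, lic35.n_atoms, 3))
        ens = Ensemble(lic35, coords)
        s = rmsd_series(ens)
        assert s[0] == 0.0 and np.all(s >= 0)

    def test_global_rigid_transform_invariance(self, lic35):
        rng = np.random.default_rng(3)
        coords = lic35.coords[None] + rng.normal(0, 0.5, size=(4, lic35.n_atoms, 3))
        ens = Ensemble(lic35, coords)
        base = rmsd_series(ens)
        R0, t0 = _random_rigid(rng)
        moved = Ensemble(lic35, coords @ R0.T + t0)
        assert np.allclose(rmsd_series(moved), base, atol=1e-6)


class TestRmsf:
    def test_static_ensemble_zero(self, lic35):
        ens = Ensemble(lic35, np.repeat(lic35.coords[None], 3, axis=0))
        _, vals = rmsf_per_residue(ens)
        assert np.allclose(vals, 0.0)

    def test_isotropic_jitter_closed_form(self, lic80):
        """Isotropic Gaussian jitter sigma per coordinate gives RMSF ~
        sigma * sqrt(3)."""
        rng = np.random.default_rng(5)
        sigma = 0.4
        n_frames = 10_000
        ca = lic80.select(lic80.atom_mask("CA"))
        sub = ca.select(ca.chain_ids == "A")
        n = sub.n_atoms
        coords = sub.coords[None] + rng.normal(0, sigma, size=(n_frames, n, 3))
        ens = Ensemble(sub, coords)
        _, vals = rmsf_per_residue(ens, monomer_average=False)
        # superposition absorbs 6 rigid degrees of freedom out of 3n
        expected = sigma * np.sqrt(3) * np.sqrt(1 - 6 / (3 * n))
        assert np.allclose(vals, expected, rtol=0.05)
        assert np.mean(vals) == pytest.approx(sigma * np.sqrt(3), rel=0.05)

    def test_monomer_average_matches_single_monomer(self, lic35):
        """With chain-symmetric jitter the monomer average equals any
        single monomer within sampling error."""
        rng = np.random.default_rng(8)
        jit_a = rng.normal(0, 0.3, size=(300, lic35.chain("A").n_atoms, 3))
        coords = np.repeat(lic35.coords[None], 300, axis=0)
        for k, cid in enumerate("ABC"):
            ang = 2 * np.pi * k / 3
            R = np.array(
                [[np.cos(ang), -np.sin(ang), 0],
                 [np.sin(ang), np.cos(ang), 0],
                 [0, 0, 1]]
            )
            mask = lic35.chain_ids == cid
            coords[:, mask] += jit_a @ R.T  # symmetry-equivalent noise
        ens = Ensemble(lic35, coords)
        resids_avg, avg = rmsf_per_residue(ens, monomer_average=True)
        _, raw = rmsf_per_residue(ens, monomer_average=False)
        chain_a = raw[: len(resids_avg)]
        assert np.allclose(avg, chain_a, rtol=1e-9)

    def test_single_frame_rejected(self, lic35):
        with pytest.raises(ValueError):
            rmsf_per_residue(Ensemble(lic35, lic35.coords[None]))


class TestSupercoilRadius:
    @pytest.mark.parametrize("r0", [5.1, 6.1])
    def test_printed_radii_roundtrip(self, r0):
        s = build_ideal_coiled_coil("A" * 56, CrickParameters(supercoil_radius_r0=r0))
        assert estimate_supercoil_radius(s) == pytest.approx(r0, abs=0.1)

    @pytest.mark.parametrize("d", [5.0, 7.5])
    def test_straight_parallel_helices(self, d):
        params = CrickParameters(supercoil_radius_r0=d, supercoil_frequency_w0=0.0)
        s = build_ideal_coiled_coil("A" * 30, params)
        assert estimate_supercoil_radius(s) == pytest.approx(d, abs=0.1)

    def test_too_few_chains(self, lic35):
        with pytest.raises(ValueError):
            estimate_supercoil_radius(lic35.chain("A"))


def _decoy_ensemble(lic35, rng, sizes=(5, 3), spread=0.3, separation=12.0):
    """Rigid groups of decoys: within-group RMSD < cutoff, between-group
    far beyond it."""
    frames = []
    for g, size in enumerate(sizes):
        base = lic35.coords + g * np.array([separation, 0, 0])
        if g:
            # also rotate the second group so superposed RMSD stays large
            rng2 = np.random.default_rng(99)
            theta = np.pi / 2
            R = np.array(
                [[1, 0, 0],
                 [0, np.cos(theta), -np.sin(theta)],
                 [0, np.sin(theta), np.cos(theta)]]
            )
            com = base.mean(axis=0)
            base = (base - com) @ R.T + com
            # internal distortion so rotation cannot be undone
            base = base + rng2.normal(0, 2.5, size=base.shape)
        for _ in range(size):
            frames.append(base + rng.normal(0, spread, size=base.shape))
    return Ensemble(lic35, np.stack(frames))


class TestClustering:
    def test_identical_models_single_cluster(self, lic35):
        ens = Ensemble(lic35, np.repeat(lic35.coords[None], 6, axis=0))
        energies = [3.0, 1.0, 2.0, 5.0, 4.0, 0.5]
        result = cluster_by_neighbors(ens, energies, top_n=6, rms_cutoff=3.0)
        assert len(result.clusters) == 1
        center, members = result.clusters[0]
        assert sorted(members) == list(range(6))
        assert center == 5  # lowest energy breaks the tie
        assert result.final_model == 5

    def test_two_groups_against_enumeration(self, lic35):
        rng = np.random.default_rng(17)
        ens = _decoy_ensemble(lic35, rng)
        energies = rng.normal(size=ens.n_frames)
        result = cluster_by_neighbors(ens, energies, top_n=8, rms_cutoff=3.0)
        assert len(result.clusters) == 2
        assert set(result.clusters[0][1]) == {0, 1, 2, 3, 4}
        # exhaustive oracle on the same distance matrix
        order = np.argsort(energies, kind="stable")[:8]
        D = pairwise_ca_rmsd(ens, order)
        rank = {int(m): r for r, m in enumerate(order)}
        local = {int(m): i for i, m in enumerate(order)}
        expected = brute_cluster(
            D, {local[m]: rank[m] for m in local}, 3.0
        )
        got = [
            (local[c], sorted(local[m] for m in ms)) for c, ms in result.clusters
        ]
        assert got == expected

    def test_zero_cutoff_gives_singletons(self, lic35):
        rng = np.random.default_rng(2)
        coords = lic35.coords[None] + rng.normal(0, 1.0, size=(5, lic35.n_atoms, 3))
        ens = Ensemble(lic35, coords)
        result = cluster_by_neighbors(ens, rng.normal(size=5), top_n=5, rms_cutoff=0.0)
        assert len(result.clusters) == 5
        assert all(len(m) == 1 for _, m in result.clusters)

    def test_top_n_exceeds_models_warns(self, lic35, caplog):
        ens = Ensemble(lic35, np.repeat(lic35.coords[None], 3, axis=0))
        with caplog.at_level("WARNING", logger="coilstab.geometry"):
            result = cluster_by_neighbors(ens, [1.0, 2.0, 3.0], top_n=10)
        assert result.top_n == 3
        assert any("top_n" in r.message for r in caplog.records)
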