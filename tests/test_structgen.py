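"""Builder geometry, replica generator and toy Boltzmann samplers."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coilstab import (
    CrickParameters,
    Harmonic1D,
    MeltingModel,
    TwoState,
    build_ideal_coiled_coil,
    generate_replica_ensembles,
    generate_toy_thermo_samples,
    place_amide_hydrogens,
)
from coilstab.constants import KB
from coilstab.geometry import estimate_supercoil_radius
from coilstab.interactions import assign_helix
from coilstab.vecmath import angle_deg


def _rotate_z(coords, deg):
    a = np.radians(deg)
    rot = np.array(
        [[np.cos(a), -np.sin(a), 0], [np.sin(a), np.cos(a), 0], [0, 0, 1]]
    )
    return coords @ rot.T


class TestBuilder:
    def test_chain_layout(self, lic80):
        assert lic80.chains == ["A", "B", "C"]
        for cid in "ABC":
            assert len(lic80.chain(cid).residue_table()) == 80

    def test_c3_symmetry_exact(self, lic80):
        a = lic80.chain("A").coords
        for cid, ang in (("B", 120.0), ("C", 240.0)):
            other = lic80.chain(cid).coords
            rmsd = np.sqrt(np.mean(np.sum((_rotate_z(a, ang) - other) ** 2, axis=1)))
            assert rmsd < 1e-6

    @pytest.mark.parametrize("r0", [4.0, 5.1, 6.1, 7.0, 8.0])
    def test_supercoil_radius_roundtrip(self, r0):
        s = build_ideal_coiled_coil("A" * 40, CrickParameters(supercoil_radius_r0=r0))
        assert abs(estimate_supercoil_radius(s) - r0) < 0.1

    def test_ideal_build_is_fully_helical(self, lic35):
        assert assign_helix(lic35).content_pct == 100.0

    @pytest.mark.parametrize("bad", ["", "AAA", "AAAAAAB", "AAAX AA"])
    def test_rejects_bad_sequences(self, bad):
        with pytest.raises(ValueError):
            build_ideal_coiled_coil(bad, CrickParameters())

    def test_symmetry_order_and_registry_validation(self):
        with pytest.raises(ValueError):
            CrickParameters(symmetry_order=1)
        with pytest.raises(ValueError):
            CrickParameters(registry_offset=7)
        with pytest.raises(ValueError):
            CrickParameters(supercoil_radius_r0=-1.0)


class TestAmideHydrogens:
    def test_placement_geometry(self):
        s = build_ideal_coiled_coil("APAAAAAA", CrickParameters())
        rebuilt = place_amide_hydrogens(s)
        for cid in rebuilt.chains:
            ch = rebuilt.chain(cid)
            res = ch.residue_table()
            for row in res.itertuples():
                names = list(ch.atom_names[row.start: row.stop])
                has_h = "H" in names
                if row.resid == 1 or row.resname == "PRO":
                    assert not has_h
                    continue
                assert has_h
                n = ch.residue_atom(cid, row.resid, "N")
                h = ch.residue_atom(cid, row.resid, "H")
                ca = ch.residue_atom(cid, row.resid, "CA")
                c_prev = ch.residue_atom(cid, row.resid - 1, "C")
                assert abs(np.linalg.norm(h - n) - 1.0) < 1e-3
                # H bisects away from both neighbors: near-equal angles
                a1 = angle_deg(h, n, c_prev)
                a2 = angle_deg(h, n, ca)
                assert abs(a1 - a2) < 1e-6

    def test_missing_backbone_raises(self, lic35):
        broken = lic35.select(~lic35.atom_mask("CA"))
        with pytest.raises(ValueError):
            place_amide_hydrogens(broken)


@pytest.fixture(scope="module")
def small_series(lic35):
    model = MeltingModel(frames_per_temperature=20, seed=11)
    ladder = np.linspace(350.0, 750.0, 9)
    return generate_replica_ensembles(lic35, ladder, model), model


class TestReplicaGenerator:
    def test_logistic_limits(self, lic35):
        model = MeltingModel(frames_per_temperature=30, seed=3)
        lo = model.tm_helix - 10 * model.width_helix
        hi = model.tm_helix + 10 * model.width_helix
        series = generate_replica_ensembles(lic35, [lo, hi], model)
        means = series.table.groupby("temperature_K")["helix_content_pct"].mean()
        assert means[lo] >= 99.0
        assert means[hi] <= 1.0

    def test_seed_determinism(self, lic35):
        model = MeltingModel(frames_per_temperature=5, seed=42)
        ladder = [400.0, 600.0]
        s1 = generate_replica_ensembles(lic35, ladder, model)
        s2 = generate_replica_ensembles(lic35, ladder, model)
        assert s1.table.equals(s2.table)
        for t in ladder:
            assert np.array_equal(s1.ensembles[t].coords, s2.ensembles[t].coords)

    def test_bookkeeping_matches_measured_helicity(self, small_series):
        series, _ = small_series
        t = series.temperatures[4]
        ens = series.ensembles[float(t)]
        for f in range(0, 20, 7):
            measured = assign_helix(ens.frame(f))
            row = series.table[
                (series.table["temperature_K"] == t) & (series.table["frame"] == f)
            ].iloc[0]
            n_total = len(measured.flags)
            assert int(measured.flags["helical"].sum()) == int(row["n_helical"])
            assert measured.content_pct == pytest.approx(
                100.0 * row["n_helical"] / n_total
            )

    def test_melting_monotonic_within_noise(self, small_series):
        series, _ = small_series
        g = series.table.groupby("temperature_K")
        for col in ("helix_content_pct", "hydrophobic_contacts"):
            means = g[col].mean().to_numpy()
            ses = (g[col].std(ddof=1) / np.sqrt(g[col].size())).to_numpy()
            for i in range(len(means) - 1):
                slack = 3.0 * np.hypot(ses[i], ses[i + 1])
                assert means[i + 1] <= means[i] + slack

    def test_invalid_ladder_and_model(self, lic35):
        with pytest.raises(ValueError):
            generate_replica_ensembles(
                lic35, [500.0, 400.0], MeltingModel(frames_per_temperature=2)
            )
        with pytest.raises(ValueError):
            MeltingModel(tm_association=600.0, tm_helix=500.0)
        with pytest.raises(ValueError):
            MeltingModel(width_helix=0.0)
        with pytest.raises(ValueError):
            MeltingModel(frames_per_temperature=0)


class TestToySamplers:
    def test_harmonic_moments(self):
        k = 1.0
        series = generate_toy_thermo_samples(Harmonic1D(k), [300.0], 100_000, seed=5)
        x = series.table["x"].to_numpy()
        se = x.std() / np.sqrt(len(x))
        assert abs(x.mean()) < 4 * se
        assert abs(x.var() / (KB * 300.0 / k) - 1) < 0.05
        # energies are exactly U(x)
        assert np.allclose(series.table["energy_kJmol"], 0.5 * k * x**2)

    def test_two_state_occupancy(self):
        de = KB * 300.0 * np.log(2.0)
        series = generate_toy_thermo_samples(TwoState(de), [300.0], 100_000, seed=6)
        frac = series.table["x"].mean()
        assert frac == pytest.approx(1.0 / 3.0, abs=0.01)

    def test_invalid_systems(self):
        with pytest.raises(ValueError):
            generate_toy_thermo_samples(Harmonic1D(1.0), [300.0], 0, seed=0)
        with pytest.raises(ValueError):
            Harmonic1D(-1.0)
        with pytest.raises(ValueError):
            TwoState(float("inf"))
        with pytest.raises(ValueError):
            generate_toy_thermo_samples(object(), [300.0], 10, seed=0)


@settings(max_examples=10, deadline=None, derandomize=True)
@given(r0=st.floats(min_value=4.0, max_value=8.0))
def test_radius_roundtrip_property(r0):
    """build(R0) then estimate recovers R0 within 0.1 A across [4, 8]."""
    s = build_ideal_coiled_coil("A" * 30, CrickParameters(supercoil_radius_r0=r0))
    assert abs(estimate_supercoil_radius(s) - r0) < 0.1
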