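"""Interaction census: cutoffs, catalogs, classification, helix content."""

import numpy as np
import pytest

from coilstab import CrickParameters, Structure, build_ideal_coiled_coil
from coilstab.interactions import (
    assign_helix,
    classify_and_count,
    detect_hbonds,
    detect_hydrophobic_contacts,
    detect_salt_bridges,
)
from coilstab.seqfeatures import assign_protonation

from .conftest import make_random_frame
from .oracles import (
    brute_hbond_count,
    brute_hydrophobic_count,
    brute_salt_bridge_count,
)


def _hbond_pair(distance, angle_dev_deg):
    """Two-residue toy: Ala donor (N-H) on chain A, Ala acceptor O on
    chain B, with controlled N..O distance and deviation from
    linearity."""
    n = np.zeros(3)
    h = np.array([1.0, 0.0, 0.0])
    dev = np.radians(angle_dev_deg)
    # place O at the requested N..O distance with H..O deviating from
    # the N->H line by angle_dev (law of cosines for the N-H-O triangle)
    # solve |HO| from |NO| and the angle at H (180 - dev)
    ang_h = np.pi - dev
    # |NO|^2 = 1 + r^2 - 2 r cos(ang_h)
    r = np.cos(ang_h) + np.sqrt(np.cos(ang_h) ** 2 + distance**2 - 1.0)
    o = h + r * np.array([np.cos(dev), np.sin(dev), 0.0])
    names = ["N", "H", "CA", "C", "O"]
    return Structure(
        ["N", "H", "CA", "O"],
        ["A", "A", "A", "B"],
        [1, 1, 1, 1],
        ["ALA", "ALA", "ALA", "ALA"],
        np.array([n, h, [5.0, 5.0, 5.0], o]),
    ), names


class TestHbonds:
    @pytest.mark.parametrize(
        "dist,dev,expected",
        [
            (3.40, 25.0, 1),
            (3.60, 5.0, 0),   # distance fails
            (3.40, 35.0, 0),  # angle fails
            (3.50, 30.0, 1),  # both cutoffs inclusive
        ],
    )
    def test_cutoff_examples(self, dist, dev, expected):
        frame, _ = _hbond_pair(dist, dev)
        found = detect_hbonds(frame)
        assert len(found) == expected
        if expected:
            rec = found.records.iloc[0]
            assert rec["distance_A"] == pytest.approx(dist, abs=1e-6)
            assert rec["angle_deg"] == pytest.approx(dev, abs=1e-6)
            assert rec["iclass"] == "intermonomer"

    def test_cutoff_flip_epsilon(self):
        for eps in (1e-4,):
            assert len(detect_hbonds(_hbond_pair(3.5 - eps, 10.0)[0])) == 1
            assert len(detect_hbonds(_hbond_pair(3.5 + eps, 10.0)[0])) == 0

    def test_ideal_helix_l_minus_4_per_chain(self, lic35):
        hb = detect_hbonds(lic35)
        bb = hb.records[hb.records["iclass"] == "mainchain"]
        for cid in "ABC":
            per = bb[bb["chain_i"] == cid]
            i_to_im4 = per[per["resid_i"] - per["resid_j"] == 4]
            assert len(i_to_im4) == 35 - 4

    def test_donor_without_h_skipped(self, caplog):
        frame, _ = _hbond_pair(3.4, 10.0)
        no_h = frame.select(~frame.atom_mask("H"))
        with caplog.at_level("WARNING", logger="coilstab.interactions"):
            found = detect_hbonds(no_h)
        assert len(found) == 0
        assert any("skipped" in r.message for r in caplog.records)


def _salt_pair(distance, same_chain=False):
    """Lys charged pseudo-atom vs Glu charged pseudo-atom."""
    chain_j = "A" if same_chain else "B"
    return Structure(
        ["N", "CA", "C", "O", "SC", "SQ", "N", "CA", "C", "O", "SC", "SQ"],
        ["A"] * 6 + [chain_j] * 6,
        [1] * 6 + [2 if same_chain else 1] * 6,
        ["LYS"] * 6 + ["GLU"] * 6,
        np.array(
            [
                [0, 0, 0], [1.5, 0, 0], [2, 1, 0], [2, 2, 0], [0, 2, 0], [0, 4, 0],
                [20, 0, 0], [21, 0, 0], [22, 0, 0], [23, 0, 0],
                [20, 2, 0], [0, 4 + distance, 0],
            ],
            float,
        ),
    )


class TestSaltBridges:
    def test_within_cutoff_across_chains(self):
        ps = assign_protonation(_salt_pair(3.9), 7.4)
        assert len(detect_salt_bridges(_salt_pair(3.9), ps)) == 1
        assert len(detect_salt_bridges(_salt_pair(4.1), ps)) == 0

    def test_same_chain_excluded(self):
        frame = _salt_pair(3.9, same_chain=True)
        ps = assign_protonation(frame, 7.4)
        assert len(detect_salt_bridges(frame, ps)) == 0

    def test_protonated_carboxyl_excluded(self):
        frame = _salt_pair(3.9)
        ps_acid = assign_protonation(frame, 1.6)  # Glu protonated
        assert len(detect_salt_bridges(frame, ps_acid)) == 0

    def test_histidine_only_when_protonated(self):
        frame = _salt_pair(3.9)
        frame = Structure(
            frame.atom_names,
            frame.chain_ids,
            frame.resids,
            np.where(frame.resnames == "LYS", "HIS", frame.resnames),
            frame.coords,
        )
        # pH 5: imidazole protonated (pKa 6), carboxylate unprotonated (4.25)
        assert len(detect_salt_bridges(frame, assign_protonation(frame, 5.0))) == 1
        assert len(detect_salt_bridges(frame, assign_protonation(frame, 7.4))) == 0


def _ala_pair(distance):
    return Structure(
        ["CA", "SC", "CA", "SC"],
        ["A", "A", "B", "B"],
        [1, 1, 1, 1],
        ["ALA"] * 4,
        np.array([[0, 0, 0], [1.5, 0, 0], [30, 0, 0], [1.5 + distance, 0, 0]], float),
    )


class TestHydrophobicContacts:
    def test_cutoff(self):
        assert len(detect_hydrophobic_contacts(_ala_pair(6.9))) == 1
        assert len(detect_hydrophobic_contacts(_ala_pair(7.0))) == 1  # inclusive
        assert len(detect_hydrophobic_contacts(_ala_pair(7.1))) == 0

    def test_glycine_never_participates(self):
        frame = _ala_pair(5.0)
        gly = Structure(
            frame.atom_names,
            frame.chain_ids,
            frame.resids,
            np.array(["GLY", "GLY", "ALA", "ALA"], dtype=object),
            frame.coords,
        )
        gly = gly.select(gly.atom_mask(("CA",)) | (gly.resnames != "GLY"))
        assert len(detect_hydrophobic_contacts(gly)) == 0

    def test_builtin_trimer_matches_brute_force(self, lic80):
        assert len(detect_hydrophobic_contacts(lic80)) == brute_hydrophobic_count(lic80)

    def test_c3_symmetric_pair_counts_equal(self, lic80):
        recs = detect_hydrophobic_contacts(lic80).records
        pair_counts = recs.groupby(
            recs[["chain_i", "chain_j"]].apply(frozenset, axis=1)
        ).size()
        assert pair_counts.nunique() == 1


class TestClassification:
    def test_partition_and_totals(self, lic35):
        hb = detect_hbonds(lic35)
        counts = classify_and_count(hb)
        total = sum(v for (kind, _), v in counts.items() if kind == "hbond")
        assert total == len(hb)
        assert counts[("hbond", "mainchain")] >= 3 * (35 - 4)

    def test_class_labels(self):
        frame, _ = _hbond_pair(3.4, 10.0)
        rec = detect_hbonds(frame).records.iloc[0]
        assert rec["iclass"] == "intermonomer"


class TestBruteForceEquivalence:
    def test_random_frames_match_oracle(self):
        rng = np.random.default_rng(2024)
        for _ in range(6):
            frame = make_random_frame(rng, int(rng.integers(12, 25)))
            ps = assign_protonation(frame, float(rng.choice([1.6, 7.4])))
            assert len(detect_hbonds(frame, protonation=ps, warn_missing_h=False)) == \
                brute_hbond_count(frame, protonation=ps)
            assert len(detect_salt_bridges(frame, ps)) == \
                brute_salt_bridge_count(frame, ps)
            assert len(detect_hydrophobic_contacts(frame)) == \
                brute_hydrophobic_count(frame)


class TestHelixContent:
    def test_ideal_helix_is_100(self, lic35):
        assert assign_helix(lic35).content_pct == 100.0

    def test_extended_chain_is_zero(self):
        # fully extended backbone: phi = psi = 180
        from coilstab.structgen import _rebuild_chains, _ChainInternal

        s = build_ideal_coiled_coil("A" * 12, CrickParameters(symmetry_order=2))
        ic = _ChainInternal(s, "A")
        phi = np.full((1, 12), 180.0)
        psi = np.full((1, 12), 180.0)
        bb = _rebuild_chains(ic, phi, psi)
        coords = s.chain("A").coords.copy()
        for nm in ("N", "CA", "C", "O"):
            idx_local = np.flatnonzero(s.chain("A").atom_names == nm)
            coords[idx_local] = bb[nm][0]
        ext = s.chain("A").with_coords(coords)
        assert assign_helix(ext).content_pct == 0.0

    def test_short_chain_rejected(self):
        s = Structure(
            ["N", "CA", "C"] * 2,
            ["A"] * 3 + ["A"] * 3,
            [1, 1, 1, 2, 2, 2],
            ["ALA"] * 6,
            np.random.default_rng(0).normal(size=(6, 3)),
        )
        with pytest.raises(ValueError):
            assign_helix(s)

    def test_content_bounds(self, lic35):
        content = assign_helix(lic35).content_pct
        assert 0.0 <= content <= 100.0
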