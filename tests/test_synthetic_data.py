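import numpy as np
import pytest

from betacorner._geom import dihedral, rmsd_after_superposition
from betacorner.geometry_metrics import torsions
from betacorner.secondary_structure import assign_torsion_based
from betacorner.synthetic_data import (
    BackboneSpec,
    EnsembleSpec,
    build_ideal_segment,
    build_ideal_strand,
    build_negative_control,
    build_synthetic_corner,
    default_sequence,
    generate_ensemble,
)


class TestIdealSegment:
    def test_torsion_round_trip_exact(self):
        spec = BackboneSpec(
            sequence=["ALA"] * 10,
            torsions=[(-139.0, 135.0, 180.0)] * 10,
        )
        s = build_ideal_segment(spec)
        for t in torsions(s)[1:-1]:
            assert t.phi == pytest.approx(-139.0, abs=1e-6)
            assert t.psi == pytest.approx(135.0, abs=1e-6)

    def test_ca_spacing_of_trans_backbone(self):
        s = build_ideal_strand(12)
        ca = np.array([r.atom("CA").coords for r in s.residues()])
        d = np.linalg.norm(np.diff(ca, axis=0), axis=1)
        assert np.all(np.abs(d - 3.80) < 0.05)

    def test_helix_rise_per_residue(self):
        s = build_ideal_strand(15, phi=-57, psi=-47)
        ca = np.array([r.atom("CA").coords for r in s.residues()])
        centred = ca - ca.mean(axis=0)
        _u, _s, vt = np.linalg.svd(centred)
        rise = np.abs(np.diff(centred @ vt[0]))
        assert np.mean(rise) == pytest.approx(1.5, abs=0.2)

    def test_cb_present_except_glycine(self):
        spec = BackboneSpec(sequence=["ALA", "GLY", "VAL"], torsions=[(-120, 120, 180)] * 3)
        s = build_ideal_segment(spec)
        res = s.residues()
        assert res[0].atom("CB") is not None
        assert res[1].atom("CB") is None
        assert res[2].atom("CB") is not None

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            BackboneSpec(sequence=["ALA"], torsions=[])


class TestSyntheticCorner:
    def test_bounds_validation(self):
        with pytest.raises(ValueError):
            build_synthetic_corner((3, 8, 6), (4, 4))
        with pytest.raises(ValueError):
            build_synthetic_corner((6, 8, 6), (2, 4))
        with pytest.raises(ValueError):
            build_synthetic_corner((10, 10, 10), (12, 14))
        with pytest.raises(ValueError):
            build_synthetic_corner((6, 8, 6), (4, 4), handedness="up")

    def test_determinism(self):
        a, _ = build_synthetic_corner((6, 8, 6), (4, 4), seed=3)
        b, _ = build_synthetic_corner((6, 8, 6), (4, 4), seed=3)
        ca = a.coords()
        cb = b.coords()
        np.testing.assert_array_equal(ca, cb)

    def test_different_seeds_differ(self):
        a, _ = build_synthetic_corner((6, 8, 6), (4, 4), seed=3)
        b, _ = build_synthetic_corner((6, 8, 6), (4, 4), seed=4)
        assert not np.array_equal(a.coords(), b.coords())

    def test_ground_truth_ranges_consistent(self, corner):
        s, gt = corner
        total = gt["total_length"]
        assert len(s.residues()) == total
        assert gt["strand_a"][0] == 1
        assert gt["strand_c"][1] == total
        # label pattern matches construction
        labels = "".join(assign_torsion_based(s))
        for lo, hi in (gt["strand_a"], gt["strand_b"], gt["strand_c"]):
            assert set(labels[lo - 1 : hi]) == {"E"}
        for lo, hi in (gt["loop_ab"], gt["loop_bc"]):
            assert "E" not in labels[lo - 1 : hi]

    def test_default_sequence_hydrophobic_fraction(self):
        seq = default_sequence(30)
        hydro = {"ALA", "VAL", "LEU", "ILE", "MET", "PHE", "TRP", "CYS"}
        assert sum(1 for x in seq if x in hydro) / 30 == pytest.approx(0.4)


class TestNegativeControls:
    def test_coil_has_no_strand_labels(self):
        coil = build_negative_control("coil", 25, seed=2)
        labels = assign_torsion_based(coil)
        assert "E" not in labels

    def test_helix_mostly_helical(self):
        helix = build_negative_control("helix", 30, seed=2)
        labels = assign_torsion_based(helix)
        interior = labels[1:-1]
        assert interior.count("H") / len(interior) >= 0.8

    def test_seed_determinism(self):
        a = build_negative_control("coil", 25, seed=9)
        b = build_negative_control("coil", 25, seed=9)
        np.testing.assert_array_equal(a.coords(), b.coords())

    def test_minimum_size_and_unknown_kind(self):
        with pytest.raises(ValueError):
            build_negative_control("coil", 3)
        with pytest.raises(ValueError):
            build_negative_control("blob", 25)


class TestGenerateEnsemble:
    def test_degenerate_single_state_no_noise(self, corner):
        base, _ = corner
        spec = EnsembleSpec(base=base, n_frames=5, noise_sigma=0.0, seed=1)
        st, labels = generate_ensemble(spec)
        assert st.n_models == 5
        assert set(labels) == {0}
        c0 = st.coords(model=0)
        for m in range(1, 5):
            np.testing.assert_array_equal(st.coords(model=m), c0)
            np.testing.assert_array_equal(c0, base.coords())

    def test_deterministic_allocation(self, corner):
        base, _ = corner
        spec = EnsembleSpec(
            base=base, n_frames=200, noise_sigma=0.1,
            state_fractions=(0.85, 0.15), state_hinge_deg=(0.0, 40.0), seed=2,
        )
        _st, labels = generate_ensemble(spec)
        assert np.bincount(labels).tolist() == [170, 30]

    def test_noise_level_matches_recomputed_rmsd(self, corner):
        """Mean per-frame RMSD to the base must equal the value recomputed
        independently from the same seeded frames."""
        base, _ = corner
        spec = EnsembleSpec(base=base, n_frames=30, noise_sigma=0.5, seed=6)
        st, _ = generate_ensemble(spec)
        ref = base.coords()
        series = [rmsd_after_superposition(ref, st.coords(model=m)) for m in range(30)]
        # isotropic sigma in 3D gives sqrt(6)*sigma between two noisy copies,
        # sqrt(3)*sigma against the noiseless base (minus superposition gain)
        assert np.mean(series) == pytest.approx(np.sqrt(3) * 0.5, rel=0.1)

    def test_spec_validation(self, corner):
        base, _ = corner
        with pytest.raises(ValueError):
            EnsembleSpec(base=base, n_frames=1)
        with pytest.raises(ValueError):
            EnsembleSpec(base=base, state_fractions=(0.6, 0.5), state_hinge_deg=(0, 1))

    def test_seed_determinism(self, corner):
        base, _ = corner
        spec = EnsembleSpec(base=base, n_frames=4, noise_sigma=0.3, seed=12)
        a, la = generate_ensemble(spec)
        b, lb = generate_ensemble(spec)
        np.testing.assert_array_equal(la, lb)
        for m in range(4):
            np.testing.assert_array_equal(a.coords(model=m), b.coords(model=m))
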