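import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from betacorner.config import HBondCriterion
from betacorner.geometry_metrics import (
    StabilityMetrics,
    TorsionPair,
    count_hbonds,
    delta_metrics,
    kabsch_rmsd,
    load_rama_polygons,
    radius_of_gyration,
    rama_classify,
    residue_category,
    sasa,
    torsions,
)
from betacorner.structure_io import Atom, Residue, Structure
from betacorner.synthetic_data import build_ideal_strand

rng = np.random.default_rng(42)


# ---------------------------------------------------------------------------
# Kabsch RMSD
# ---------------------------------------------------------------------------


class TestKabschRmsd:
    def test_identity_is_zero(self):
        p = rng.normal(size=(8, 3))
        assert kabsch_rmsd(p, p, selection="all") == pytest.approx(0.0, abs=1e-12)

    def test_proper_rigid_motion_is_zero(self):
        p = rng.normal(size=(10, 3))
        r = Rotation.random(rng=1).as_matrix()
        q = p @ r.T + np.array([3.0, -7.0, 11.0])
        assert kabsch_rmsd(p, q, selection="all") <= 1e-9

    def test_symmetry(self):
        p = rng.normal(size=(6, 3))
        q = p + rng.normal(scale=0.3, size=p.shape)
        assert kabsch_rmsd(p, q, selection="all") == pytest.approx(
            kabsch_rmsd(q, p, selection="all"), abs=1e-10
        )

    def test_matches_rotation_grid_oracle(self):
        """Brute-force minimisation over a fine rotation grid on a 4-point
        toy set must agree with the closed-form superposition."""
        from conftest import grid_min_rmsd

        p = np.array([[0.0, 0, 0], [1.5, 0, 0], [1.5, 1.5, 0], [0, 1.5, 1.0]])
        q = p + rng.normal(scale=0.2, size=p.shape)
        assert kabsch_rmsd(p, q, selection="all") == pytest.approx(grid_min_rmsd(p, q), abs=1e-4)

    def test_structure_pairing_and_errors(self, corner):
        base, _ = corner
        assert kabsch_rmsd(base, base) == pytest.approx(0.0, abs=1e-12)
        with pytest.raises(ValueError):
            kabsch_rmsd(np.zeros((4, 3)), np.zeros((5, 3)), selection="all")
        with pytest.raises(ValueError):
            kabsch_rmsd(np.zeros((2, 3)), np.zeros((2, 3)), selection="all")


# ---------------------------------------------------------------------------
# radius of gyration
# ---------------------------------------------------------------------------


class TestRadiusOfGyration:
    def test_closed_forms(self):
        assert radius_of_gyration(np.zeros((1, 3))) == 0.0
        two = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        assert radius_of_gyration(two, weighting="uniform") == pytest.approx(1.0)
        cube = np.array([[x, y, z] for x in (0, 2.0) for y in (0, 2.0) for z in (0, 2.0)])
        assert radius_of_gyration(cube, weighting="uniform") == pytest.approx(math.sqrt(3))

    @settings(deadline=None, max_examples=25)
    @given(
        scale=st.floats(0.1, 10.0),
        seed=st.integers(0, 2**16),
    )
    def test_scaling_and_rigid_invariance(self, scale, seed):
        r = np.random.default_rng(seed)
        pts = r.normal(size=(12, 3))
        rg = radius_of_gyration(pts, weighting="uniform")
        assert radius_of_gyration(pts * scale, weighting="uniform") == pytest.approx(scale * rg, rel=1e-9)
        rot = Rotation.random(rng=seed).as_matrix()
        assert radius_of_gyration(pts @ rot.T + 5.0, weighting="uniform") == pytest.approx(rg, rel=1e-9)

    def test_mass_weighting_differs_from_uniform(self, corner):
        base, _ = corner
        assert radius_of_gyration(base, "mass") != pytest.approx(
            radius_of_gyration(base, "uniform"), abs=1e-6
        )


# ---------------------------------------------------------------------------
# SASA
# ---------------------------------------------------------------------------


class TestSasa:
    def test_isolated_atom_analytic_sphere(self):
        _per, total = sasa(np.zeros((1, 3)), probe_radius=1.4, n_sphere_points=960, radii=[1.9])
        assert total == pytest.approx(4 * np.pi * 3.3**2, rel=0.01)

    def test_disjoint_spheres_are_additive(self):
        coords = np.array([[0.0, 0, 0], [100.0, 0, 0]])
        _per, total = sasa(coords, probe_radius=1.4, n_sphere_points=960)
        _s, single = sasa(np.zeros((1, 3)), probe_radius=1.4, n_sphere_points=960)
        assert total == pytest.approx(2 * single, rel=1e-9)

    def test_two_overlapping_spheres_match_cap_formula(self):
        """Two equal spheres of inflated radius R at separation d each lose a
        spherical cap of height h = R - d/2; remaining area per sphere is
        4*pi*R^2 - 2*pi*R*h."""
        r_vdw, probe, d = 1.7, 1.4, 3.0
        r = r_vdw + probe
        coords = np.array([[0.0, 0, 0], [d, 0, 0]])
        per, total = sasa(coords, probe_radius=probe, n_sphere_points=2000, radii=[r_vdw, r_vdw])
        h = r - d / 2.0
        expected_each = 4 * np.pi * r**2 - 2 * np.pi * r * h
        assert per[0] == pytest.approx(expected_each, rel=0.015)
        assert total == pytest.approx(2 * expected_each, rel=0.015)

    def test_monotone_under_occlusion(self, corner):
        base, _ = corner
        per_s, _total = sasa(base, n_sphere_points=240)
        assert (per_s >= 0).all()
        # adding an occluding atom can only reduce every per-atom area
        # (uniform radii so the comparison is atom-for-atom)
        coords = base.coords()
        per, _t = sasa(coords, probe_radius=1.4, n_sphere_points=240)
        extra = np.vstack([coords, coords.mean(axis=0, keepdims=True)])
        per2, _t2 = sasa(extra, probe_radius=1.4, n_sphere_points=240)
        assert (per2[: len(per)] <= per + 1e-9).all()

    def test_unknown_element_raises(self):
        s = Structure(
            id="x",
            models=[{"A": [Residue("UNK", 1, atoms=[Atom(1, "XX", "XX", np.zeros(3))])]}],
        )
        with pytest.raises(ValueError, match="XX"):
            sasa(s)

    def test_against_independent_implementation(self, corner):
        """Cross-check the whole-structure total against biotite's
        Shrake-Rupley with the same element radii."""
        biotite_struc = pytest.importorskip("biotite.structure")
        base, _ = corner
        residues = base.residues()
        n_atoms = base.n_atoms()
        arr = biotite_struc.AtomArray(n_atoms)
        k = 0
        import betacorner.config as cfg

        radii = np.zeros(n_atoms)
        for i, res in enumerate(residues):
            for a in res.atoms:
                arr.coord[k] = a.coords
                arr.chain_id[k] = "A"
                arr.res_id[k] = res.seq_num
                arr.res_name[k] = res.res_name
                arr.atom_name[k] = a.name
                arr.element[k] = a.element
                radii[k] = cfg.VDW_RADII[a.element]
                k += 1
        ref = float(np.nansum(biotite_struc.sasa(arr, probe_radius=1.4, point_number=500, vdw_radii=radii)))
        _per, total = sasa(base, n_sphere_points=500)
        assert total == pytest.approx(ref, rel=0.02)


# ---------------------------------------------------------------------------
# hydrogen bonds
# ---------------------------------------------------------------------------


def _gly(seq_num, n, ca, c, o):
    return Residue(
        "GLY",
        seq_num,
        atoms=[
            Atom(1, "N", "N", np.array(n)),
            Atom(2, "CA", "C", np.array(ca)),
            Atom(3, "C", "C", np.array(c)),
            Atom(4, "O", "O", np.array(o)),
        ],
    )


class TestCountHbonds:
    def test_constructed_pair_within_cutoff(self):
        # donor N of residue 10 placed 2.9 A from acceptor O of residue 1,
        # with the antecedent C behind the donor (angle ~180)
        acceptor = _gly(1, [10, 0, 0], [11.5, 0, 0], [13, 0, 0], [0, 0, 0])
        donor = _gly(10, [2.9, 0, 0], [3.6, 1.2, 0], [5.0, 1.2, 0], [5.6, 2.2, 0])
        s = Structure(id="x", models=[{"A": [acceptor, donor]}])
        n, pairs = count_hbonds(s)
        assert n == 1
        assert pairs[0] == ((1, "N"), (0, "O"))

    def test_distance_cutoff(self):
        acceptor = _gly(1, [10, 0, 0], [11.5, 0, 0], [13, 0, 0], [0, 0, 0])
        donor = _gly(10, [5.0, 0, 0], [5.7, 1.2, 0], [7.1, 1.2, 0], [6.0, -3.0, 0])
        s = Structure(id="x", models=[{"A": [acceptor, donor]}])
        assert count_hbonds(s)[0] == 0

    def test_hairpin_matches_brute_force(self, hairpin):
        """Count on the hairpin fixture equals an independent double loop
        over every backbone N/O pair applying the criterion directly."""
        crit = HBondCriterion()
        residues = hairpin.residues()
        expected = 0
        for i, don in enumerate(residues):
            for j, acc in enumerate(residues):
                if i == j or (j == i - 1):
                    continue
                npos, opos = don.atom("N").coords, acc.atom("O").coords
                if np.linalg.norm(npos - opos) > crit.da_cutoff:
                    continue
                ante = residues[i - 1].atom("C").coords if i > 0 else don.atom("CA").coords
                v1 = opos - npos
                v2 = ante - npos
                cosang = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
                if math.degrees(math.acos(np.clip(cosang, -1, 1))) >= crit.antecedent_min:
                    expected += 1
        got, pairs = count_hbonds(hairpin)
        assert got == expected > 0
        # ladder bonds are reciprocal in an antiparallel sheet
        pair_set = {(d[0], a[0]) for d, a in pairs}
        assert all((a, d) in pair_set for d, a in pair_set)

    def test_permutation_invariance(self, hairpin):
        import copy

        shuffled = copy.deepcopy(hairpin)
        for res in shuffled.residues():
            res.atoms = list(reversed(res.atoms))
        assert count_hbonds(shuffled)[0] == count_hbonds(hairpin)[0]


# ---------------------------------------------------------------------------
# torsions and Ramachandran classes
# ---------------------------------------------------------------------------


class TestTorsions:
    def test_round_trip_of_generated_strand(self):
        s = build_ideal_strand(10, phi=-139.0, psi=135.0, sequence=["ALA"] * 10)
        tors = torsions(s)
        for t in tors[1:-1]:
            assert t.phi == pytest.approx(-139.0, abs=1e-6)
            assert t.psi == pytest.approx(135.0, abs=1e-6)

    def test_termini_undefined(self):
        tors = torsions(build_ideal_strand(5))
        assert tors[0].phi is None and tors[0].psi is not None
        assert tors[-1].psi is None and tors[-1].phi is not None

    def test_omega_round_trip(self):
        from betacorner._geom import dihedral

        s = build_ideal_strand(6, phi=-120, psi=120, omega=180.0)
        res = s.residues()
        for i in range(1, 5):
            om = dihedral(
                res[i - 1].atom("CA").coords,
                res[i - 1].atom("C").coords,
                res[i].atom("N").coords,
                res[i].atom("CA").coords,
            )
            assert abs(om) == pytest.approx(180.0, abs=1e-6)


class TestRamaClassify:
    def test_beta_point_allowed_for_general(self):
        assert rama_classify(TorsionPair(-120.0, 130.0), "general").region == "allowed"

    def test_left_handed_region_glycine_only(self):
        pt = TorsionPair(75.0, -60.0)
        assert rama_classify(pt, "general").region == "disallowed"
        assert rama_classify(pt, "glycine").region == "allowed"

    def test_wrap_invariance(self):
        a = rama_classify(TorsionPair(-120.0, 130.0), "general")
        b = rama_classify(TorsionPair(-120.0 - 360.0, 130.0 + 360.0), "general")
        assert a == b

    def test_undefined_unclassified(self):
        assert rama_classify(TorsionPair(None, 100.0)).region == "unclassified"

    def test_partition_property(self):
        """Every defined pair maps to exactly one of allowed/disallowed in
        every category."""
        cats = list(load_rama_polygons())
        r = np.random.default_rng(3)
        for _ in range(200):
            t = TorsionPair(float(r.uniform(-180, 180)), float(r.uniform(-180, 180)))
            for cat in cats:
                assert rama_classify(t, cat).region in ("allowed", "disallowed")

    def test_residue_category_rules(self):
        assert residue_category("GLY") == "glycine"
        assert residue_category("PRO") == "proline"
        assert residue_category("ALA", "PRO") == "pre-proline"
        assert residue_category("ALA", "SER") == "general"


# ---------------------------------------------------------------------------
# delta metrics
# ---------------------------------------------------------------------------


class TestDeltaMetrics:
    def test_identity_gives_zero(self):
        m = StabilityMetrics(sasa=3000.0, rg=12.0, n_hbonds=15)
        d = delta_metrics(m, m)
        assert d.d_sasa == 0 and d.d_rg == 0 and d.d_hb == 0 and d.d_rg_fraction == 0

    def test_published_value_arithmetic(self):
        """Differences reproduce the reference-vs-simulation arithmetic of
        the comparison table: 3202.64 - 3061.3 = 141.34 and 22 - 14 = 8."""
        exp = StabilityMetrics(sasa=3202.64, rg=13.0, n_hbonds=18)
        md = StabilityMetrics(sasa=3061.3, rg=12.3, n_hbonds=14)
        d = delta_metrics(exp, md)
        assert d.d_sasa == pytest.approx(141.34)
        assert d.d_rg_fraction == pytest.approx(0.7 / 13.0)

        exp2 = StabilityMetrics(sasa=3335.75, rg=12.0, n_hbonds=22)
        md2 = StabilityMetrics(sasa=3085.9, rg=11.9, n_hbonds=14)
        assert delta_metrics(exp2, md2).d_hb == 8
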