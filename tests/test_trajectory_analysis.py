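import copy

import numpy as np
import pytest

from betacorner.config import ClusterParams, StabilityThresholds
from betacorner.geometry_metrics import StabilityMetrics
from betacorner.structure_io import Structure
from betacorner.synthetic_data import EnsembleSpec, generate_ensemble
from betacorner.trajectory_analysis import (
    Ensemble,
    adaptive_cluster,
    aggregate_replicates,
    gromos_cluster,
    major_cluster,
    mean_structure,
    metrics_on_major,
    rmsd_series,
    stability_verdict,
)


def _replicated(base: Structure, n: int) -> Structure:
    return Structure(id="rep", models=[copy.deepcopy(base.models[0]) for _ in range(n)])


@pytest.fixture(scope="module")
def grid_ensemble(corner):
    """10 well-separated hinge states, heavy noise: >12 clusters at 0.3 nm."""
    base, _ = corner
    states = [(a, b) for a in (0.0, 70.0, 140.0, -70.0, -140.0) for b in (0.0, 120.0)]
    spec = EnsembleSpec(
        base=base,
        n_frames=200,
        noise_sigma=1.3,
        state_fractions=tuple([0.1] * 10),
        state_hinge_deg=tuple(states),
        seed=5,
    )
    st, labels = generate_ensemble(spec)
    return Ensemble(st), labels


class TestGromosCluster:
    def test_identical_frames_single_cluster(self, corner):
        base, _ = corner
        e = Ensemble(_replicated(base, 6))
        res = gromos_cluster(e, 0.3)
        assert res.n_clusters == 1
        assert len(res.clusters[0]) == 6

    def test_two_planted_groups_recovered(self, two_state_ensemble):
        st, labels = two_state_ensemble
        e = Ensemble(st)
        res = gromos_cluster(e, 0.3)
        assert res.n_clusters == 2
        recovered = set(res.clusters[0])
        planted = set(np.where(labels == 0)[0])
        assert recovered == planted

    def test_huge_cutoff_single_cluster(self, two_state_ensemble):
        st, _ = two_state_ensemble
        res = gromos_cluster(Ensemble(st), 5.0)
        assert res.n_clusters == 1

    def test_partition_property(self, grid_ensemble):
        e, _ = grid_ensemble
        res = gromos_cluster(e, 0.35)
        members = sorted(f for c in res.clusters for f in c)
        assert members == list(range(e.n_frames))
        sizes = [len(c) for c in res.clusters]
        assert sizes == sorted(sizes, reverse=True)

    def test_cluster_count_non_increasing_in_cutoff(self, grid_ensemble):
        e, _ = grid_ensemble
        counts = [gromos_cluster(e, c).n_clusters for c in (0.25, 0.32, 0.40, 0.55, 1.0)]
        assert counts == sorted(counts, reverse=True)


class TestAdaptiveCluster:
    def test_immediate_acceptance(self, grid_ensemble, corner):
        base, _ = corner
        # 10 clean states, tiny noise: exactly 10 clusters at the initial cutoff
        states = [(a, b) for a in (0.0, 70.0, 140.0, -70.0, -140.0) for b in (0.0, 120.0)]
        spec = EnsembleSpec(
            base=base, n_frames=60, noise_sigma=0.3,
            state_fractions=tuple([0.1] * 10), state_hinge_deg=tuple(states), seed=2,
        )
        st, _ = generate_ensemble(spec)
        res = adaptive_cluster(Ensemble(st))
        assert res.attempts == 1
        assert res.final_cutoff == pytest.approx(0.3)
        assert res.converged

    def test_raises_cutoff_until_in_band(self, grid_ensemble):
        e, _ = grid_ensemble
        assert gromos_cluster(e, 0.3).n_clusters > 12
        res = adaptive_cluster(e)
        assert res.converged
        assert res.final_cutoff > 0.3
        assert 8 <= res.n_clusters <= 12

    def test_two_state_ensemble_exhausts_attempts(self, corner):
        base, _ = corner
        spec = EnsembleSpec(
            base=base, n_frames=30, noise_sigma=0.0,
            state_fractions=(0.5, 0.5), state_hinge_deg=(0.0, 60.0), seed=1,
        )
        st, _ = generate_ensemble(spec)
        res = adaptive_cluster(Ensemble(st))
        assert not res.converged
        assert res.attempts <= 30
        assert res.n_clusters == 2  # closest attainable to the band

    def test_attempt_budget_always_respected(self, two_state_ensemble):
        st, _ = two_state_ensemble
        res = adaptive_cluster(Ensemble(st), ClusterParams(max_attempts=5))
        assert res.attempts <= 5

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            ClusterParams(step=0.0)
        with pytest.raises(ValueError):
            ClusterParams(min_clusters=10, max_clusters=5)


class TestMajorCluster:
    def test_counting_and_threshold(self):
        def fake(sizes):
            clusters = []
            start = 0
            for s in sizes:
                clusters.append(tuple(range(start, start + s)))
                start += s
            from betacorner.trajectory_analysis import ClusterResult

            return ClusterResult(
                clusters=tuple(clusters), centers=tuple(c[0] for c in clusters),
                final_cutoff=0.3, attempts=1,
            )

        m = major_cluster(fake([170, 30]))
        assert m.occupancy == pytest.approx(0.85) and m.is_major
        m = major_cluster(fake([150, 50]))
        assert m.occupancy == pytest.approx(0.75) and not m.is_major
        # the flag flips exactly at the 80% threshold
        assert major_cluster(fake([160, 40])).is_major
        assert not major_cluster(fake([159, 41])).is_major

    def test_planted_occupancy_recovery(self, two_state_ensemble):
        st, _ = two_state_ensemble
        m = major_cluster(gromos_cluster(Ensemble(st), 0.3))
        assert abs(m.occupancy - 0.85) <= 0.03


class TestRmsdSeries:
    def test_copies_of_reference_are_zero(self, corner):
        base, _ = corner
        e = Ensemble(_replicated(base, 4))
        series, mean, sd = rmsd_series(e, base)
        np.testing.assert_allclose(series, 0.0, atol=1e-9)
        assert mean == pytest.approx(0.0, abs=1e-9) and sd == pytest.approx(0.0, abs=1e-9)

    def test_noisy_frames_match_direct_recomputation(self, corner):
        """The series must equal an independent per-frame superposition
        recomputed from the same coordinates."""
        from betacorner._geom import rmsd_after_superposition

        base, _ = corner
        spec = EnsembleSpec(base=base, n_frames=20, noise_sigma=0.5, seed=3)
        st, _ = generate_ensemble(spec)
        e = Ensemble(st)
        series, mean, _sd = rmsd_series(e, base)
        ref = base.coords(atom_names=e.selection)
        expected = [rmsd_after_superposition(ref, f) for f in e.frame_coords]
        np.testing.assert_allclose(series, expected, atol=1e-12)
        assert mean == pytest.approx(np.mean(expected))

    def test_selection_mismatch(self, corner, hairpin):
        base, _ = corner
        e = Ensemble(_replicated(base, 3))
        with pytest.raises(ValueError):
            rmsd_series(e, hairpin)

    def test_replicate_aggregation_arithmetic(self):
        mean, sd = aggregate_replicates([2.0, 3.0, 4.0])
        assert mean == pytest.approx(3.0)
        assert sd == pytest.approx(1.0)
        mean, sd = aggregate_replicates([2.5])
        assert (mean, sd) == (2.5, 0.0)


class TestMetricsOnMajor:
    def test_single_cluster_equals_full_average(self, corner):
        base, _ = corner
        spec = EnsembleSpec(base=base, n_frames=6, noise_sigma=0.2, seed=8)
        st, _ = generate_ensemble(spec)
        e = Ensemble(st)
        cres = gromos_cluster(e, 1.0)
        m = major_cluster(cres)
        from betacorner.config import SasaParams
        from betacorner.geometry_metrics import radius_of_gyration

        got = metrics_on_major(e, m, cres, sasa_params=SasaParams(n_sphere_points=120))
        expected_rg = np.mean([radius_of_gyration(e.frame_structure(f)) for f in range(6)])
        assert got.rg == pytest.approx(expected_rg)

    def test_two_state_average_uses_dominant_frames_only(self, two_state_ensemble):
        st, labels = two_state_ensemble
        e = Ensemble(st)
        cres = gromos_cluster(e, 0.3)
        m = major_cluster(cres)
        from betacorner.config import SasaParams
        from betacorner.geometry_metrics import radius_of_gyration

        got = metrics_on_major(e, m, cres, sasa_params=SasaParams(n_sphere_points=60))
        expected_rg = np.mean(
            [radius_of_gyration(e.frame_structure(f)) for f in np.where(labels == 0)[0]]
        )
        assert got.rg == pytest.approx(expected_rg, rel=1e-6)

    def test_duplicated_frames_are_idempotent(self, corner):
        base, _ = corner
        e = Ensemble(_replicated(base, 5))
        cres = gromos_cluster(e, 0.3)
        m = major_cluster(cres)
        from betacorner.config import SasaParams
        from betacorner.geometry_metrics import compute_metrics

        got = metrics_on_major(e, m, cres, sasa_params=SasaParams(n_sphere_points=120))
        single = compute_metrics(base, sasa_params=SasaParams(n_sphere_points=120))
        assert got.rg == pytest.approx(single.rg)
        assert got.sasa == pytest.approx(single.sasa)
        assert got.n_hbonds == pytest.approx(single.n_hbonds)

    def test_mean_structure_suppresses_noise(self, corner):
        base, _ = corner
        spec = EnsembleSpec(base=base, n_frames=50, noise_sigma=0.5, seed=4)
        st, _ = generate_ensemble(spec)
        e = Ensemble(st)
        avg = mean_structure(e, range(50))
        from betacorner.geometry_metrics import kabsch_rmsd

        assert kabsch_rmsd(base, avg) < 0.2


class TestStabilityVerdict:
    def test_rg_criterion_fails_despite_low_rmsd(self):
        """A 1.3 -> 1.23 nm gyration change is 5.4%: outside the 5% band
        even though RMSD 2.77 A passes easily (criteria are independent)."""
        exp = StabilityMetrics(sasa=3202.64, rg=13.0, n_hbonds=18)
        md = StabilityMetrics(sasa=3061.3, rg=12.3, n_hbonds=14)
        v = stability_verdict(exp, 2.77, md)
        assert v.mean_rmsd < 5.0
        assert abs(v.rg_change_fraction) > 0.05
        assert not v.stable

    def test_stable_case(self):
        exp = StabilityMetrics(sasa=3335.75, rg=12.0, n_hbonds=22)
        md = StabilityMetrics(sasa=3085.9, rg=11.9, n_hbonds=14)
        v = stability_verdict(exp, 2.1, md)
        assert v.stable

    def test_high_rmsd_unstable_regardless(self):
        exp = StabilityMetrics(sasa=3335.75, rg=12.3, n_hbonds=22)
        md = StabilityMetrics(sasa=3846.33, rg=12.3, n_hbonds=19)
        v = stability_verdict(exp, 6.86, md)
        assert not v.stable

    def test_monotonicity(self):
        """Worsening any single criterion never flips unstable -> stable."""
        exp = StabilityMetrics(sasa=3000.0, rg=12.0, n_hbonds=20)
        base_md = StabilityMetrics(sasa=2900.0, rg=11.9, n_hbonds=18)
        r = np.random.default_rng(0)
        for _ in range(50):
            rmsd = float(r.uniform(0, 8))
            rg_md = float(r.uniform(10, 14))
            md = StabilityMetrics(sasa=2900.0, rg=rg_md, n_hbonds=18)
            v = stability_verdict(exp, rmsd, md)
            worse_rmsd = stability_verdict(exp, rmsd + 1.0, md)
            assert not (worse_rmsd.stable and not v.stable)
            worse_rg = StabilityMetrics(sasa=2900.0, rg=rg_md - 0.3 * np.sign(12.0 - rg_md + 1e-9) - 0.3, n_hbonds=18)
            # moving rg further from the reference can only keep or lose stability
            if abs((exp.rg - worse_rg.rg) / exp.rg) >= abs((exp.rg - md.rg) / exp.rg):
                v2 = stability_verdict(exp, rmsd, worse_rg)
                assert not (v2.stable and not v.stable)

    def test_thresholds_configurable(self):
        exp = StabilityMetrics(sasa=3000.0, rg=12.0, n_hbonds=20)
        md = StabilityMetrics(sasa=2900.0, rg=11.9, n_hbonds=18)
        v = stability_verdict(exp, 4.9, md, thresholds=StabilityThresholds(rmsd_max=4.0))
        assert not v.stable
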