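import numpy as np
import pytest
from scipy import stats

from nanoplan import (
    CylinderSV,
    QualityParams,
    ScoringRegion,
    SVSet,
    Track,
    TrackEnsemble,
    count_ensemble,
    count_ensemble_bruteforce,
    ensemble_from_quality,
    point_in_sv,
    sample_sv,
    sample_svs,
)


def tables_equal(a, b):
    a, b = a.sorted(), b.sorted()
    return (
        np.array_equal(a.sv_index, b.sv_index)
        and np.array_equal(a.primary_id, b.primary_id)
        and np.array_equal(a.nu, b.nu)
    )


class TestPointInSV:
    @pytest.mark.parametrize(
        "offset,expected",
        [
            ((0.0, 0.0, 0.0), True),  # center
            ((0.0, 0.0, 8.01), False),  # just past the axial bound
            ((0.9, 0.0, 7.9), True),  # inside both bounds
            ((1.01, 0.0, 0.0), False),  # just past the radial bound
            ((0.0, 0.0, 8.0), True),  # closed boundary
        ],
    )
    def test_axis_aligned_containment(self, offset, expected):
        sv = CylinderSV(center=(0, 0, 0), axis=(0, 0, 1))
        assert point_in_sv(offset, sv) is expected

    def test_non_unit_axis_rejected(self):
        with pytest.raises(ValueError):
            CylinderSV(center=(0, 0, 0), axis=(0, 0, 2))

    def test_non_finite_point_rejected(self):
        sv = CylinderSV(center=(0, 0, 0), axis=(0, 0, 1))
        with pytest.raises(ValueError):
            point_in_sv((np.nan, 0, 0), sv)


class TestSVPlacement:
    def test_fixed_seed_reproduces_sv(self, region):
        a = sample_sv(region, 99)
        b = sample_sv(region, 99)
        assert a == b

    def test_axis_z_components_uniform(self, region):
        svs = sample_svs(region, 10_000, 5)
        # uniform orientation on the sphere -> axis z-component ~ U(-1, 1)
        stat = stats.kstest(svs.axes[:, 2], stats.uniform(loc=-1, scale=2).cdf)
        assert stat.pvalue > 0.01

    def test_whole_sv_inside_region(self, region):
        svs = sample_svs(region, 2000, 6)
        az = np.abs(svs.axes[:, 2])
        ez = 8.0 * az + 1.0 * np.sqrt(1 - az**2)
        assert np.all(np.abs(svs.centers[:, 2]) + ez <= region.height / 2 + 1e-9)
        er = 8.0 * np.hypot(svs.axes[:, 0], svs.axes[:, 1]) + 1.0
        assert np.all(
            np.hypot(svs.centers[:, 0], svs.centers[:, 1]) + er <= region.radius + 1e-9
        )

    def test_degenerate_height_forces_midplane(self):
        region = ScoringRegion(diameter=500.0, height=16.0)
        svs = sample_svs(region, 50, 7, axis=(0, 0, 1))
        assert np.all(svs.centers[:, 2] == 0.0)

    def test_oversized_sv_rejected(self):
        region = ScoringRegion(diameter=10.0, height=10.0)
        with pytest.raises(ValueError, match="larger than"):
            sample_svs(region, 1, 0)


class TestCounting:
    def test_empty_ensemble_counts_nothing(self, region, small_svs):
        ens = TrackEnsemble(
            n_primaries=10,
            points=np.empty((0, 3)),
            primary_index=np.empty(0, dtype=np.int64),
            region=region,
        )
        table = count_ensemble(ens, small_svs)
        assert len(table) == 0
        assert table.n_total_pairs == 10 * len(small_svs)

    def test_collinear_points_in_one_sv(self, region):
        track = Track(0, np.array([[0, 0, -5.0], [0, 0, 0.0], [0, 0, 5.0]]))
        ens = TrackEnsemble.from_tracks([track], region=region)
        svs = SVSet.from_svs(
            [CylinderSV(center=(0, 0, 0), axis=(0, 0, 1))], region
        )
        table = count_ensemble(ens, svs)
        assert len(table) == 1
        assert table.nu[0] == 3

    def test_point_outside_all_svs(self, region):
        ens = TrackEnsemble.from_tracks(
            [Track(0, np.array([[100.0, 100.0, 100.0]]))], region=region
        )
        svs = SVSet.from_svs([CylinderSV(center=(0, 0, 0), axis=(0, 0, 1))], region)
        assert len(count_ensemble(ens, svs)) == 0
        assert len(count_ensemble_bruteforce(ens, svs)) == 0

    @pytest.mark.parametrize("seed", range(10))
    def test_indexed_counting_matches_bruteforce(self, region, seed):
        rng = np.random.SeedSequence(seed).spawn(2)
        ens = ensemble_from_quality(
            QualityParams(0.05, 1.5, 8.0, 1.0), 100, region, rng[0]
        )
        svs = sample_svs(region, 500, rng[1])
        assert tables_equal(count_ensemble(ens, svs), count_ensemble_bruteforce(ens, svs))

    def test_rigid_transform_covariance(self, region, small_ensemble, small_svs):
        # rotating+translating points and SVs together leaves counts unchanged
        rng = np.random.default_rng(44)
        rot = stats.special_ortho_group.rvs(3, random_state=rng)
        shift = rng.normal(size=3) * 50
        before = count_ensemble(small_ensemble, small_svs)
        moved = TrackEnsemble(
            n_primaries=small_ensemble.n_primaries,
            points=small_ensemble.points @ rot.T + shift,
            primary_index=small_ensemble.primary_index,
            region=small_ensemble.region,
        )
        moved_svs = SVSet(
            small_svs.centers @ rot.T + shift,
            small_svs.axes @ rot.T,
            small_svs.diameter,
            small_svs.length,
            small_svs.region,
        )
        assert tables_equal(before, count_ensemble(moved, moved_svs))

    def test_enlarging_sv_never_decreases_counts(self, region, small_ensemble):
        svs = sample_svs(region, 300, 17)
        big = SVSet(svs.centers, svs.axes, svs.diameter * 1.5, svs.length + 4, region)
        t1 = count_ensemble(small_ensemble, svs)
        small_counts = {(s, p): n for s, p, n in zip(t1.sv_index, t1.primary_id, t1.nu)}
        t2 = count_ensemble(small_ensemble, big)
        big_counts = {(s, p): n for s, p, n in zip(t2.sv_index, t2.primary_id, t2.nu)}
        for key, nu in small_counts.items():
            assert big_counts.get(key, 0) >= nu

    def test_per_primary_counts_independent_of_other_primaries(self, region):
        q = QualityParams(0.05, 1.0, 5.0, 1.0)
        ens = ensemble_from_quality(q, 20, region, 5)
        svs = sample_svs(region, 400, 6)
        full = count_ensemble(ens, svs)
        # re-count primary 0 alone
        mask = ens.primary_index == 0
        solo = TrackEnsemble(
            n_primaries=1,
            points=ens.points[mask],
            primary_index=np.zeros(int(mask.sum()), dtype=np.int64),
            region=region,
        )
        solo_t = count_ensemble(solo, svs)
        full_0 = {(s, n) for s, p, n in zip(full.sv_index, full.primary_id, full.nu) if p == 0}
        assert {(s, n) for s, n in zip(solo_t.sv_index, solo_t.nu)} == full_0

    def test_merging_primaries_never_decreases_max_count(self, region):
        ens = ensemble_from_quality(QualityParams(0.05, 1.0, 5.0, 1.0), 10, region, 9)
        svs = sample_svs(region, 400, 10)
        split = count_ensemble(ens, svs)
        merged = TrackEnsemble(
            n_primaries=1,
            points=ens.points,
            primary_index=np.zeros(ens.n_points, dtype=np.int64),
            region=region,
        )
        merged_t = count_ensemble(merged, svs)
        if len(split):
            assert merged_t.nu.max() >= split.nu.max()
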