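"""Number/volume weighting, small-granule percentages, counting metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from granulekit import (
    ParticleSizeData,
    ValidationError,
    bin_particles,
    granules_per_mg,
    percent_small_granules,
    qc_particle_count,
    to_distribution,
)


def binned(lowers, uppers, counts):
    return ParticleSizeData(
        bin_lower=np.array(lowers, float),
        bin_upper=np.array(uppers, float),
        count=np.array(counts),
    )


class TestToDistribution:
    def test_volume_weighting_scales_counts_by_d_cubed(self):
        # 8 particles at 10 um carry the same volume as 1 particle at 20 um
        data = binned([9.9998, 19.9996], [10.0002, 20.0004], [8, 1])
        dist = to_distribution(data, "volume")
        np.testing.assert_allclose(dist.relative_share, [50.0, 50.0], atol=1e-2)

    def test_number_weighting_uses_raw_counts(self):
        data = binned([9.9998, 19.9996], [10.0002, 20.0004], [8, 1])
        dist = to_distribution(data, "number")
        np.testing.assert_allclose(
            dist.relative_share, [800.0 / 9.0, 100.0 / 9.0]
        )

    def test_grid_is_geometric_mean_of_edges(self):
        data = binned([4.0], [9.0], [5])
        dist = to_distribution(data, "number")
        assert dist.grid[0] == pytest.approx(6.0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**20), factor=st.integers(2, 50))
    def test_scale_invariance_under_count_multiplication(self, seed, factor):
        rng = np.random.default_rng(seed)
        edges = np.geomspace(1.5, 40, 30)
        counts = rng.integers(0, 500, size=29)
        counts[3] += 1
        a = binned(edges[:-1], edges[1:], counts)
        b = binned(edges[:-1], edges[1:], counts * factor)
        for weighting in ("number", "volume"):
            np.testing.assert_allclose(
                to_distribution(a, weighting).relative_share,
                to_distribution(b, weighting).relative_share,
                rtol=1e-12,
            )

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**20))
    def test_shares_sum_to_100(self, seed):
        rng = np.random.default_rng(seed)
        edges = np.geomspace(1.4, 42, 64)
        counts = rng.integers(0, 10_000, size=63)
        counts[0] += 1
        data = binned(edges[:-1], edges[1:], counts)
        for weighting in ("number", "volume"):
            dist = to_distribution(data, weighting)
            assert abs(dist.relative_share.sum() - 100.0) < 1e-9
            assert np.all(dist.relative_share >= 0)

    def test_volume_share_order_preserving_in_diameter(self):
        # equal counts: larger-diameter bins never have smaller volume share
        edges = np.geomspace(2, 30, 20)
        data = binned(edges[:-1], edges[1:], np.full(19, 100))
        share = to_distribution(data, "volume").relative_share
        assert np.all(np.diff(share) > 0)


class TestBinParticles:
    def test_count_conservation(self):
        rng = np.random.default_rng(0)
        raw = ParticleSizeData(raw_diameters=rng.uniform(2, 40, size=5000))
        out = bin_particles(raw, np.geomspace(1.4, 42, 100))
        assert out.total_count == 5000

    def test_half_open_upper_edge_goes_to_next_bin(self):
        raw = ParticleSizeData(raw_diameters=np.array([2.0, 2.0, 4.0]))
        out = bin_particles(raw, np.array([1.0, 2.0, 4.0, 8.0]))
        assert out.count.tolist() == [0, 2, 1]

    def test_out_of_range_raises_or_drops(self):
        raw = ParticleSizeData(raw_diameters=np.array([0.5, 5.0]))
        edges = np.array([1.0, 10.0])
        with pytest.raises(ValidationError, match="outside"):
            bin_particles(raw, edges)
        assert bin_particles(raw, edges, out_of_range="drop").total_count == 1


class TestPercentSmallGranules:
    def test_raw_strict_inequality(self):
        data = ParticleSizeData(raw_diameters=np.array([5.0, 5.0, 5.0, 20.0]))
        assert percent_small_granules(data, 10.0) == pytest.approx(75.0)

    def test_binned_same_data(self):
        data = binned([4.0, 18.0], [6.0, 22.0], [3, 1])
        assert percent_small_granules(data, 10.0) == pytest.approx(75.0)

    def test_threshold_at_exact_bin_edge(self):
        data = binned([5.0, 10.0], [10.0, 20.0], [30, 70])
        assert percent_small_granules(data, 10.0) == pytest.approx(30.0)

    def test_straddling_bin_split_pro_rata_by_log_width(self):
        # single bin [5, 20); threshold 10 splits at ln(10/5)/ln(20/5)=0.5
        data = binned([5.0], [20.0], [100])
        assert percent_small_granules(data, 10.0) == pytest.approx(50.0)

    def test_finely_binned_matches_raw_oracle(self):
        rng = np.random.default_rng(42)
        d = np.exp(rng.normal(np.log(8.0), 0.6, size=50_000))
        d = d[(d > 1.0) & (d < 60.0)]
        raw = ParticleSizeData(raw_diameters=d)
        edges = np.arange(1.0, 60.1, 0.1)  # 0.1 um resolution
        fine = bin_particles(raw, edges)
        expected = percent_small_granules(raw, 10.0)
        got = percent_small_granules(fine, 10.0)
        one_bin_share = 100.0 * fine.count.max() / fine.total_count
        assert abs(got - expected) <= one_bin_share

    def test_convergence_as_bins_refine(self):
        rng = np.random.default_rng(7)
        d = np.exp(rng.normal(np.log(9.0), 0.5, size=20_000))
        d = d[(d > 1.4) & (d < 42.0)]
        raw = ParticleSizeData(raw_diameters=d)
        truth = percent_small_granules(raw, 10.0)
        errs = []
        for n_edges in (16, 64, 256):
            data = bin_particles(raw, np.geomspace(1.4, 42, n_edges))
            errs.append(abs(percent_small_granules(data, 10.0) - truth))
        assert errs[2] <= errs[0] + 1e-12
        assert errs[2] < 0.2


class TestGranulesPerMg:
    @pytest.mark.parametrize(
        "count,av,tv,fw,expected",
        [
            (1000, 2.0, 10.0, 50.0, 100.0),
            (0, 2.0, 10.0, 50.0, 0.0),
            (123456, 2.0, 7.5, 33.2, 123456 * 3.75 / 33.2),
        ],
    )
    def test_arithmetic(self, count, av, tv, fw, expected):
        assert granules_per_mg(count, av, tv, fw) == pytest.approx(expected)

    def test_analyzed_volume_cannot_exceed_total(self):
        with pytest.raises(ValidationError):
            granules_per_mg(10, 11.0, 10.0, 1.0)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValidationError):
            granules_per_mg(10, 2.0, 10.0, 0.0)


class TestQcParticleCount:
    def make(self, n):
        return ParticleSizeData(
            bin_lower=np.array([1.0]), bin_upper=np.array([50.0]),
            count=np.array([n]),
        )

    def test_above_minimum_passes(self):
        assert qc_particle_count(self.make(150_000)) == "pass"

    def test_at_minimum_passes_inclusive(self):
        assert qc_particle_count(self.make(100_000)) == "pass"

    def test_below_minimum_warns_not_fails(self):
        with pytest.warns(UserWarning, match="99999 particles"):
            assert qc_particle_count(self.make(99_999)) == "warn"
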