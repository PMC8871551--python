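"""Voxelwise fitting: stretched-exponential, ADC and tensor fits, ROI stats."""

import numpy as np
import pytest

from porodiff import map_engine as me
from porodiff import synthetic_data as sd
from porodiff.containers import ParameterMap, ROIDistribution
from porodiff.signal_models import (
    PGSTEProtocol, SubdiffusionParams, q_value, stretched_attenuation,
)

PROTO = sd.default_alpha_protocol()
Q = q_value(PROTO)
DELTAS = np.array(PROTO.Delta_grid)


class TestVoxelAlphaFit:
    @pytest.mark.parametrize("alpha", [0.70, 0.85, 1.00, 1.20])
    def test_noiseless_recovery(self, alpha):
        true = SubdiffusionParams(alpha=alpha, K_alpha=sd.K_WATER)
        ratios = stretched_attenuation(true, Q, DELTAS)
        params, diag = me.fit_voxel_alpha(ratios, DELTAS, Q)
        assert params is not None
        assert params.alpha == pytest.approx(alpha, rel=1e-6)
        assert params.K_alpha == pytest.approx(sd.K_WATER, rel=1e-6)

    def test_brownian_voxel_recovers_unity(self):
        true = SubdiffusionParams(alpha=1.0, K_alpha=sd.K_WATER)
        ratios = stretched_attenuation(true, Q, DELTAS)
        params, _ = me.fit_voxel_alpha(ratios, DELTAS, Q)
        assert params.alpha == pytest.approx(1.0, abs=1e-6)

    def test_no_decay_masked(self):
        params, diag = me.fit_voxel_alpha(np.ones(8), DELTAS, Q)
        assert params is None
        assert diag["reason"] == "insufficient attenuation"

    def test_fit_idempotence(self):
        true = SubdiffusionParams(alpha=0.78, K_alpha=5e-8)
        ratios = stretched_attenuation(true, Q, DELTAS)
        p1, _ = me.fit_voxel_alpha(ratios, DELTAS, Q)
        refit_input = stretched_attenuation(p1, Q, DELTAS)
        p2, _ = me.fit_voxel_alpha(refit_input, DELTAS, Q)
        assert p2.alpha == pytest.approx(p1.alpha, rel=1e-9)
        assert p2.K_alpha == pytest.approx(p1.K_alpha, rel=1e-9)

    def test_nesting_alpha_one_equals_adc(self):
        # with alpha fixed at 1 the stretched model is exp(-K q^2 Δ); the
        # ADC fit on signals exp(-b D) with b := q^2 Δ must give D = K
        D = 2.3e-9
        K = D
        b = Q**2 * DELTAS
        signals = np.exp(-b * D)
        D_hat, ok = me.fit_voxel_adc(signals, b)
        assert ok
        p, _ = me.fit_voxel_alpha(np.exp(-K * Q**2 * DELTAS), DELTAS, Q)
        assert p.alpha == pytest.approx(1.0, abs=1e-6)
        assert D_hat == pytest.approx(p.K_alpha, rel=1e-6)

    def test_bad_q_rejected(self):
        with pytest.raises(ValueError):
            me.fit_voxel_alpha(np.linspace(1, 0.5, 8), DELTAS, 0.0)


class TestADCAndTensor:
    def test_adc_exact_recovery(self):
        D = 2e-9
        b = np.array([0.0, 5e7, 1e8, 1.5e8])
        D_hat, ok = me.fit_voxel_adc(np.exp(-b * D), b)
        assert ok
        assert D_hat == pytest.approx(D, rel=1e-12)

    def test_adc_two_point_closed_form(self):
        b1, S0, S1 = 1.2e8, 1.0, 0.7
        D_hat, ok = me.fit_voxel_adc([S0, S1], [0.0, b1])
        assert D_hat == pytest.approx(np.log(S0 / S1) / b1, rel=1e-12)

    def test_adc_flat_signal_flagged(self):
        D_hat, ok = me.fit_voxel_adc([1.0, 1.0, 1.0], [0.0, 1e8, 2e8])
        assert not ok

    def test_tensor_isotropic_recovery(self, md_protocol):
        D = 2.2e-9
        b0_dirs = [(1.0, 0.0, 0.0)] + list(md_protocol.directions)
        bvals = [0.0] + [1.5e8] * 6
        signals = np.exp(-np.asarray(bvals) * D)
        md, tensor, ok = me.fit_tensor_md(signals, bvals, b0_dirs)
        assert ok
        assert md == pytest.approx(D, rel=1e-9)
        np.testing.assert_allclose(tensor[3:], 0.0, atol=1e-15)

    def test_tensor_rank_deficient_rejected(self):
        dirs = [(1.0, 0.0, 0.0)] * 7
        with pytest.raises(ValueError, match="rank"):
            me.fit_tensor_md(np.ones(7), [0.0] + [1e8] * 6, dirs)


class TestMaps:
    def test_directional_maps_agree_on_isotropic_phantom(self):
        spec = sd.PhantomSpec(matrix_size=48, alpha_mean=0.9, snr=50.0, seed=3)
        series = sd.make_dwi_series(spec, PROTO)
        maps = me.alpha_maps_by_direction(series, PROTO)
        assert set(maps) == {"x", "y", "z"}
        m = maps["x"].mask & maps["y"].mask & maps["z"].mask
        diff = maps["x"].values[m] - maps["y"].values[m]
        # paired differences centered on zero (isotropy)
        assert abs(diff.mean()) < 3 * diff.std() / np.sqrt(diff.size) + 1e-3

    def test_alpha_map_determinism(self):
        spec = sd.PhantomSpec(matrix_size=32, snr=40.0, seed=11)
        a = me.alpha_maps_by_direction(sd.make_dwi_series(spec, PROTO), PROTO)
        b = me.alpha_maps_by_direction(sd.make_dwi_series(spec, PROTO), PROTO)
        np.testing.assert_array_equal(a["x"].values, b["x"].values)

    def test_mean_alpha_arithmetic_and_mask(self):
        ny = nx = 4
        vals = [np.full((ny, nx), v) for v in (0.8, 0.9, 1.0)]
        masks = [np.ones((ny, nx), bool) for _ in range(3)]
        masks[1][0, 0] = False
        maps = {k: ParameterMap(values=v, mask=m)
                for k, v, m in zip("xyz", vals, masks)}
        mal = me.mean_alpha_map(maps)
        assert mal.values[1, 1] == pytest.approx(0.9, rel=1e-14)
        assert not mal.mask[0, 0]
        assert np.isnan(mal.values[0, 0])

    def test_mean_alpha_identity(self):
        v = np.random.default_rng(0).uniform(0.5, 1.0, (5, 5))
        m = np.ones((5, 5), bool)
        maps = {k: ParameterMap(values=v.copy(), mask=m.copy()) for k in "xyz"}
        np.testing.assert_allclose(me.mean_alpha_map(maps).values, v, rtol=1e-14)

    def test_grid_mismatch_rejected(self):
        maps = {
            "x": ParameterMap(values=np.ones((4, 4)), mask=np.ones((4, 4), bool)),
            "y": ParameterMap(values=np.ones((5, 5)), mask=np.ones((5, 5), bool)),
            "z": ParameterMap(values=np.ones((4, 4)), mask=np.ones((4, 4), bool)),
        }
        with pytest.raises(ValueError, match="mismatch"):
            me.mean_alpha_map(maps)

    def test_missing_direction_named(self):
        spec = sd.PhantomSpec(matrix_size=16, snr=np.inf, seed=0)
        series = sd.make_dwi_series(spec, PROTO)
        keep = [k for k, a in enumerate(series.acquisitions)
                if a.g == 0 or abs(a.direction[2]) < 0.5]
        series.data = series.data[keep]
        series.acquisitions = [series.acquisitions[k] for k in keep]
        with pytest.raises(ValueError, match="missing direction"):
            me.alpha_maps_by_direction(series, PROTO)


class TestROIAndDiscrimination:
    def test_roi_summary_of_known_values(self):
        vals = np.array([[0.8, 0.9], [1.0, 5.0]])
        mask = np.array([[True, True], [True, False]])
        pmap = ParameterMap(values=vals, mask=mask)
        dist = me.roi_distribution(pmap, center=(1.0, 1.0), radius=2.0)
        assert dist.median == pytest.approx(0.9)
        assert dist.count == 3

    def test_uniform_map_iqr_zero(self):
        pmap = ParameterMap(values=np.full((6, 6), 0.5),
                            mask=np.ones((6, 6), bool))
        dist = me.roi_distribution(pmap, center=(3.0, 3.0), radius=2.0)
        assert dist.iqr == 0.0

    def test_empty_roi_rejected(self):
        pmap = ParameterMap(values=np.ones((6, 6)), mask=np.zeros((6, 6), bool))
        with pytest.raises(ValueError):
            me.roi_distribution(pmap, center=(3.0, 3.0), radius=2.0)

    def test_cliffs_delta_identical_and_separated(self):
        rng = np.random.default_rng(0)
        x = ROIDistribution(rng.normal(0, 1, 500))
        assert me.discrimination_stat(x, ROIDistribution(x.values.copy())) == 0.0
        lo = ROIDistribution(rng.normal(0, 0.1, 300))
        hi = ROIDistribution(rng.normal(10, 0.1, 300))
        assert me.discrimination_stat(hi, lo) == 1.0
        assert me.discrimination_stat(lo, hi) == -1.0
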