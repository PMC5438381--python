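import numpy as np
import pytest
from scipy.optimize import least_squares

import asymei as a
from asymei.forward_sim import Material, ScanFrames, Wedge
from asymei.retrieval import GridError, RetrievalError

from conftest import forward_four_point


def vacuum_frames(scheme, geom, flux, n_columns=8, nx=10, ny=2, seed=0, noise=True):
    ph = a.generate_phantom([], (ny, nx), 75.0)
    return a.simulate_scan(ph, geom, scheme, flux, n_columns=n_columns, seed=seed,
                           noise=noise)


def full_inversion(scheme, intensities):
    """Independent oracle: nonlinear least squares on the 4-point system."""
    def residual(p):
        return forward_four_point(scheme, p[0], p[1], p[2]) - intensities

    sol = least_squares(residual, x0=[1.0, 0.0, 0.0], method="lm")
    return sol.x


class TestFlatField:
    def test_counts_equal_flats_give_R(self, geom, scheme):
        fr = vacuum_frames(scheme, geom, 1e4, noise=False)
        norm = a.flat_field(fr, scheme)
        expected = np.broadcast_to(scheme.R[fr.column_subgroup - 1], norm.shape)
        np.testing.assert_allclose(norm, expected, rtol=1e-12)

    def test_zero_counts_give_zero(self, geom, scheme):
        fr = vacuum_frames(scheme, geom, 1e4, noise=False)
        fr.counts = np.zeros_like(fr.counts)
        norm = a.flat_field(fr, scheme)
        assert np.all(norm == 0.0)

    def test_masked_column_propagates_nan(self, geom, scheme):
        fr = vacuum_frames(scheme, geom, 1e4, noise=False)
        fr.flats_before[:, :, 3] = 0.0
        fr.flats_after[:, :, 3] = 0.0
        norm = a.flat_field(fr, scheme)
        assert np.all(np.isnan(norm[:, :, 3]))
        assert np.all(np.isfinite(norm[:, :, :3]))

    def test_averaged_reference_beats_single_flat_under_drift(self, geom, scheme):
        # linear gain drift: flats before at gain (1-d), after at (1+d),
        # the scan itself at the midpoint gain 1.0
        fr = vacuum_frames(scheme, geom, 1e4, noise=False)
        d = 0.05
        fr.flats_before = fr.flats_before * (1.0 - d)
        fr.flats_after = fr.flats_after * (1.0 + d)
        truth = scheme.R[fr.column_subgroup - 1][None, None, :]

        norm_avg = a.flat_field(fr, scheme)
        bias_avg = np.abs(norm_avg - truth).max()

        ref_single = fr.flats_before.mean(axis=0)
        norm_single = fr.counts / ref_single[None] * scheme.R[fr.column_subgroup - 1]
        bias_single = np.abs(norm_single - truth).max()
        assert bias_avg <= 0.5 * bias_single

    def test_self_normalization_with_noise_is_near_R(self, geom, scheme):
        fr = vacuum_frames(scheme, geom, 1e5, nx=40, ny=4, seed=2)
        norm = a.flat_field(fr, scheme)
        rel = norm / scheme.R[fr.column_subgroup - 1][None, None, :]
        assert rel.mean() == pytest.approx(1.0, abs=3 * rel.std() / np.sqrt(rel.size))


class TestAssembleSubgroups:
    def test_128_columns_give_32_per_subgroup(self, geom, scheme):
        fr = vacuum_frames(scheme, geom, 1e3, n_columns=128, nx=6, ny=1)
        sub = a.assemble_subgroups(
            a.flat_field(fr, scheme), fr.column_subgroup, fr.col_frame_offsets,
            fr.n_object_cols, scheme,
        )
        np.testing.assert_array_equal(sub.n_summed, [32, 32, 32, 32])

    def test_single_column_per_subgroup_is_passthrough(self, geom, scheme):
        fr = vacuum_frames(scheme, geom, 1e3, n_columns=4, nx=10, ny=2, seed=8)
        norm = a.flat_field(fr, scheme)
        sub = a.assemble_subgroups(norm, fr.column_subgroup, fr.col_frame_offsets,
                                   fr.n_object_cols, scheme)
        for c in range(4):
            off = int(fr.col_frame_offsets[c])
            np.testing.assert_array_equal(sub.images[c], norm[off:off + 10, :, c].T)

    def test_averaging_reduces_noise_by_sqrt_k(self, geom, scheme):
        k = 32
        fr = vacuum_frames(scheme, geom, 1e3, n_columns=4 * k, nx=60, ny=4, seed=21)
        norm = a.flat_field(fr, scheme)
        sub = a.assemble_subgroups(norm, fr.column_subgroup, fr.col_frame_offsets,
                                   fr.n_object_cols, scheme)
        # single column noise vs assembled noise, same subgroup point
        single = norm[: fr.n_object_cols, :, 0]
        ratio = single.std() / sub.images[0].std()
        assert ratio == pytest.approx(np.sqrt(k), rel=0.15)

    def test_fractional_offsets_interpolate(self, scheme, rng):
        n_frames, ny, nx = 12, 2, 8
        normalized = rng.normal(1.0, 0.1, size=(n_frames, ny, 4))
        offsets = np.array([0.0, 0.5, 1.0, 2.5])
        sub = a.assemble_subgroups(normalized, np.array([1, 2, 3, 4]), offsets, nx,
                                   scheme, interpolate=True)
        expected = 0.5 * normalized[0:8, :, 1] + 0.5 * normalized[1:9, :, 1]
        np.testing.assert_allclose(sub.images[1], expected.T, rtol=1e-12)

    def test_fractional_offsets_rejected_without_interpolation(self, scheme, rng):
        normalized = rng.normal(1.0, 0.1, size=(12, 2, 4))
        offsets = np.array([0.0, 0.5, 1.0, 2.0])
        with pytest.raises(GridError):
            a.assemble_subgroups(normalized, np.array([1, 2, 3, 4]), offsets, 8,
                                 scheme, interpolate=False)

    def test_scan_too_short_rejected(self, scheme, rng):
        normalized = rng.normal(1.0, 0.1, size=(6, 1, 4))
        offsets = np.array([0.0, 1.0, 2.0, 3.0])
        with pytest.raises(GridError):
            a.assemble_subgroups(normalized, np.array([1, 2, 3, 4]), offsets, 8, scheme)


class TestRetrieveMultimodal:
    def _sub(self, scheme, intensities):
        imgs = np.asarray(intensities, dtype=float).reshape(4, 1, 1)
        return a.SubgroupImages(images=imgs, scheme=scheme, n_summed=np.ones(4, int))

    def test_vacuum_gives_unit_transmission_and_zero_signals(self, scheme):
        out = a.retrieve_multimodal(self._sub(scheme, scheme.R))
        assert out.absorption[0, 0] == pytest.approx(1.0, rel=1e-12)
        assert out.dpc[0, 0] == pytest.approx(0.0, abs=1e-12)
        assert out.darkfield[0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_pure_absorption(self, scheme):
        out = a.retrieve_multimodal(self._sub(scheme, 0.5 * scheme.R))
        assert out.absorption[0, 0] == pytest.approx(0.5, rel=1e-12)
        assert out.dpc[0, 0] == pytest.approx(0.0, abs=1e-12)
        assert out.darkfield[0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_small_signal_oracle_equivalence(self, ic, scheme, rng):
        # at |dphi| <= 0.01 w the closed form and the brute-force nonlinear
        # inversion of the full 4-point system coincide to ~1e-4 relative
        w = ic.width
        for _ in range(50):
            ir = rng.uniform(0.3, 1.0)
            dphi = rng.uniform(-0.01, 0.01) * w
            s2 = rng.uniform(0.0, (0.01 * w) ** 2)
            intensities = forward_four_point(scheme, ir, dphi, s2)
            oracle = full_inversion(scheme, intensities)
            np.testing.assert_allclose(oracle, [ir, dphi, s2], rtol=1e-6, atol=1e-12)
            out = a.retrieve_multimodal(self._sub(scheme, intensities))
            assert out.absorption[0, 0] == pytest.approx(ir, rel=5e-4)
            assert out.dpc[0, 0] == pytest.approx(dphi, rel=5e-4, abs=1e-9 * w)

    def test_darkfield_bias_factor_is_the_analytic_constant(self, scheme, rng):
        # the printed closed form drops the Rddot_1 term from the dark-field
        # denominator; for this scheme that is a known multiplicative bias
        # (sigma2 + dphi^2) * (1 - R2*Rddot1/(R1*Rddot2)) on the broadening.
        factor = 1.0 - scheme.R[1] * scheme.Rddot[0] / (scheme.R[0] * scheme.Rddot[1])
        w = scheme.ic.width
        for _ in range(20):
            ir = rng.uniform(0.3, 1.0)
            dphi = rng.uniform(-0.02, 0.02) * w
            s2 = rng.uniform(0.0, (0.02 * w) ** 2)
            out = a.retrieve_multimodal(
                self._sub(scheme, forward_four_point(scheme, ir, dphi, s2))
            )
            predicted_excess = (factor - 1.0) * (dphi**2 + s2)
            got_excess = out.darkfield[0, 0] - s2
            assert got_excess == pytest.approx(predicted_excess, rel=0.05,
                                               abs=1e-8 * w**2)

    def test_convergence_order_of_signal_recovery(self, scheme):
        # noise-free round trip: errors must shrink at order >= 2 in the
        # input magnitude (measured: ~3 for DPC, ~2 for dark field)
        w = scheme.ic.width
        eps = np.array([1.0, 0.5, 0.25, 0.125, 0.0625])
        e_dpc, e_df = [], []
        for e in eps:
            dphi, s2 = 0.05 * w * e, (0.03 * w) ** 2 * e**2
            out = a.retrieve_multimodal(
                self._sub(scheme, forward_four_point(scheme, 0.7, dphi, s2))
            )
            e_dpc.append(abs(out.dpc[0, 0] - dphi))
            e_df.append(abs(out.darkfield[0, 0] - s2))
        slope_dpc = np.polyfit(np.log(eps), np.log(e_dpc), 1)[0]
        slope_df = np.polyfit(np.log(eps), np.log(e_df), 1)[0]
        assert slope_dpc >= 2.0
        assert slope_df >= 1.9

    def test_zero_denominators_flagged_not_zeroed(self, scheme):
        imgs = np.zeros((4, 1, 2))
        imgs[:, 0, 1] = scheme.R  # second pixel is fine
        imgs[1, 0, 0] = 0.5  # I1 + I4 = 0 at the first pixel
        sub = a.SubgroupImages(images=imgs, scheme=scheme, n_summed=np.ones(4, int))
        out = a.retrieve_multimodal(sub)
        assert out.invalid[0, 0]
        assert not out.invalid[0, 1]
        assert np.isnan(out.darkfield[0, 0])

    def test_negative_darkfield_reported_unclipped(self, scheme):
        # perturb toward narrower IC: sigma2 comes out negative and flagged
        intensities = forward_four_point(scheme, 1.0, 0.0, 0.0)
        intensities[1] *= 1.02
        intensities[2] *= 1.02
        sub = a.SubgroupImages(images=np.asarray(intensities).reshape(4, 1, 1),
                               scheme=scheme, n_summed=np.ones(4, int))
        out = a.retrieve_multimodal(sub)
        assert out.darkfield[0, 0] < 0
        assert out.negative_df[0, 0]

    def test_degenerate_scheme_rejected(self, ic):
        flat = a.make_ic(1.0, 1e6, 0.0, 0.0)  # essentially flat IC
        scheme = a.SamplingScheme(offsets=(-2.0, -1.0, 1.0, 2.0), ic=flat)
        sub = a.SubgroupImages(images=np.ones((4, 1, 1)), scheme=scheme,
                               n_summed=np.ones(4, int))
        # Rdot1 + Rdot2 is ~0 but not exactly; force exact zero via symmetry
        # by using a scheme on a constant region is impractical, so check the
        # guard directly with a mocked scheme
        class _Fake:
            R = np.array([0.5, 0.9, 0.9, 0.5])
            Rdot = np.array([0.1, -0.1, 0.1, -0.1])
            Rddot = np.array([0.0, -0.1, -0.1, 0.0])
        sub.scheme = _Fake()
        with pytest.raises(RetrievalError):
            a.retrieve_multimodal(sub)


class TestFullPipeline:
    def test_vacuum_scan_retrieves_unity_and_zeros(self, geom, scheme):
        fr = vacuum_frames(scheme, geom, 1e4, n_columns=32, nx=50, ny=20, seed=4)
        sub = a.assemble_subgroups(a.flat_field(fr, scheme), fr.column_subgroup,
                                   fr.col_frame_offsets, fr.n_object_cols, scheme)
        out = a.retrieve_multimodal(sub)
        n = out.absorption.size
        for img, truth in ((out.absorption, 1.0), (out.dpc, 0.0), (out.darkfield, 0.0)):
            se = img.std() / np.sqrt(n)
            assert abs(img.mean() - truth) < 3 * se

    def test_absorption_noise_halves_when_flux_quadruples(self, geom, scheme):
        stds = []
        for flux, seed in ((1e3, 7), (4e3, 8)):
            fr = vacuum_frames(scheme, geom, flux, n_columns=16, nx=60, ny=25,
                               seed=seed)
            sub = a.assemble_subgroups(a.flat_field(fr, scheme), fr.column_subgroup,
                                       fr.col_frame_offsets, fr.n_object_cols, scheme)
            stds.append(a.retrieve_multimodal(sub).absorption.std())
        assert stds[0] / stds[1] == pytest.approx(2.0, rel=0.1)


class TestSingleShot:
    WEDGE_MAT = Material(delta=3.3e-8, beta=1.5e-10)

    def _wedge_pipeline(self, geom, ic, scheme, t1=3000.0):
        ph = a.generate_phantom(
            [Wedge(x0=750.0, x1=5250.0, t0=0.0, t1=t1, material=self.WEDGE_MAT)],
            (2, 80), 75.0,
        )
        fr = a.simulate_scan(ph, geom, scheme, 1e4, n_columns=8, seed=0, noise=False)
        sub = a.assemble_subgroups(a.flat_field(fr, scheme), fr.column_subgroup,
                                   fr.col_frame_offsets, fr.n_object_cols, scheme)
        phase = a.retrieve_single_shot(
            sub.images[0], ic, float(scheme.positions[0]),
            self.WEDGE_MAT.delta / self.WEDGE_MAT.beta, geom, 80.0, 75.0,
        )
        return ph, phase

    def test_vacuum_maps_to_zero_phase(self, geom, ic, scheme):
        i1 = np.full((3, 40), float(scheme.R[0]))
        phase = a.retrieve_single_shot(i1, ic, float(scheme.positions[0]), 200.0,
                                       geom, 80.0, 75.0)
        np.testing.assert_allclose(phase, 0.0, atol=1e-10)

    def test_wedge_phase_is_linear_in_x(self, geom, ic, scheme):
        ph, phase = self._wedge_pipeline(geom, ic, scheme)
        x = np.arange(80)
        interior = slice(20, 60)
        coeffs = np.polyfit(x[interior], phase[0, interior], 1)
        resid = phase[0, interior] - np.polyval(coeffs, x[interior])
        # residual from linearity is small compared to the phase ramp
        assert np.abs(resid).max() < 0.02 * np.ptp(phase[0, interior])
        assert coeffs[0] < 0  # thicker material -> more negative phase

    def test_phase_monotone_in_thickness(self, geom, ic, scheme):
        ph, phase = self._wedge_pipeline(geom, ic, scheme)
        interior = phase[0, 15:65]
        assert np.all(np.diff(interior) < 0)

    def test_rejects_bad_inputs(self, geom, ic, scheme):
        i1 = np.ones((2, 10))
        with pytest.raises(RetrievalError):
            a.retrieve_single_shot(i1, ic, float(scheme.positions[0]), -1.0, geom,
                                   80.0, 75.0)
        with pytest.raises(RetrievalError):
            # IC maximum: zero slope, not invertible
            a.retrieve_single_shot(i1, ic, ic.center, 200.0, geom, 80.0, 75.0)
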