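import numpy as np
import pytest

import slicestream as ss
from slicestream.preprocess import _next_pow_two, ramp_kernel


def make_frame(data, geom, state):
    return ss.ProjectionFrame(data=data, state=state, geometry=geom)


@pytest.fixture()
def flat_dark(small_geom):
    shape = (small_geom.det_rows, small_geom.det_cols)
    return np.full(shape, 1000.0), np.full(shape, 20.0)


class TestFlatDarkCorrect:
    def test_raw_equal_flat_gives_ones(self, small_geom, flat_dark):
        flat, dark = flat_dark
        raw = make_frame(
            np.broadcast_to(flat, (32, 32, 32)).copy(), small_geom, ss.FrameState.RAW
        )
        out = ss.flat_dark_correct(raw, flat, dark)
        assert np.all(out.data == 1.0)
        assert out.state is ss.FrameState.TRANSMISSION

    def test_raw_equal_dark_clamps_to_floor(self, small_geom, flat_dark):
        flat, dark = flat_dark
        raw = make_frame(
            np.broadcast_to(dark, (32, 32, 32)).copy(), small_geom, ss.FrameState.RAW
        )
        out = ss.flat_dark_correct(raw, flat, dark, floor=1e-6)
        assert np.all(out.data == 1e-6)

    def test_known_transmission_recovered_exactly(self, small_geom, flat_dark):
        flat, dark = flat_dark
        rng = np.random.default_rng(2)
        t_field = 1e-3 + (1 - 1e-3) * rng.random((32, 32, 32))
        raw = make_frame(dark + t_field * (flat - dark), small_geom, ss.FrameState.RAW)
        out = ss.flat_dark_correct(raw, flat, dark)
        assert np.allclose(out.data, t_field, rtol=0, atol=1e-13)

    def test_raster_mismatch_rejected(self, small_geom):
        raw = make_frame(np.ones((32, 32, 32)), small_geom, ss.FrameState.RAW)
        with pytest.raises(ValueError):
            ss.flat_dark_correct(raw, np.ones((8, 8)), np.zeros((8, 8)))

    def test_flat_below_dark_floored_with_warning(self, small_geom, caplog):
        flat = np.full((32, 32), 100.0)
        dark = np.full((32, 32), 5.0)
        flat[3, 4] = 1.0  # dead pixel: flat < dark
        raw = make_frame(np.full((32, 32, 32), 50.0), small_geom, ss.FrameState.RAW)
        with caplog.at_level("WARNING"):
            out = ss.flat_dark_correct(raw, flat, dark)
        assert "floored" in caplog.text
        assert np.all(np.isfinite(out.data))

    def test_state_enforced(self, small_geom, flat_dark):
        flat, dark = flat_dark
        frame = make_frame(np.ones((32, 32, 32)), small_geom, ss.FrameState.FILTERED)
        with pytest.raises(ValueError):
            ss.flat_dark_correct(frame, flat, dark)


class TestNegativeLog:
    def test_known_values(self, small_geom):
        data = np.full((32, 32, 32), np.exp(-5.0))
        frame = make_frame(data, small_geom, ss.FrameState.TRANSMISSION)
        out = ss.negative_log(frame)
        assert np.allclose(out.data, 5.0, atol=1e-14)
        assert out.state is ss.FrameState.LINE_INTEGRAL
        ones = make_frame(np.ones((32, 32, 32)), small_geom, ss.FrameState.TRANSMISSION)
        assert not ss.negative_log(ones).data.any()


class TestPaganin:
    def make_transmission(self, n=16, pixel=2.0, seed=1):
        geom = ss.make_parallel_geometry(1, n, n, pixel)
        rng = np.random.default_rng(seed)
        data = 0.5 + 0.4 * rng.random((1, n, n))
        return geom, make_frame(data, geom, ss.FrameState.TRANSMISSION)

    def spec(self, delta=1e-7):
        return ss.PaganinSpec(
            delta=delta, beta=1e-9, distance=3e5, wavelength=6e-5, pixel_size=2.0
        )

    def test_delta_zero_collapses_to_scaled_log(self):
        geom, frame = self.make_transmission()
        spec = self.spec(delta=0.0)
        mu = 4 * np.pi * spec.beta / spec.wavelength
        out = ss.paganin_filter(frame, spec)
        assert np.allclose(out.data, -(1 / mu) * np.log(frame.data), atol=1e-9)
        assert out.state is ss.FrameState.LINE_INTEGRAL

    def test_zero_frequency_gain_is_unity(self):
        geom, frame = self.make_transmission()
        spec = self.spec()
        coeff = spec.wavelength * spec.distance * spec.delta / (4 * np.pi * spec.beta)
        k = 2 * np.pi * np.fft.fftfreq(16, d=2.0)
        den = 1 + coeff * (k[:, None] ** 2 + k[None, :] ** 2)
        filtered = np.real(
            np.fft.ifft2(np.fft.fft2(frame.data[0]) / den)
        )
        assert filtered.mean() == pytest.approx(frame.data[0].mean(), rel=1e-12)

    def test_matches_dense_dft_oracle(self):
        geom, frame = self.make_transmission()
        spec = self.spec()
        out = ss.paganin_filter(frame, spec).data[0]
        n = 16
        F = np.exp(-2j * np.pi * np.outer(np.arange(n), np.arange(n)) / n)
        Fi = np.conj(F) / n
        coeff = spec.wavelength * spec.distance * spec.delta / (4 * np.pi * spec.beta)
        k = 2 * np.pi * np.fft.fftfreq(n, d=spec.pixel_size)
        den = 1 + coeff * (k[:, None] ** 2 + k[None, :] ** 2)
        filt = np.real(Fi @ ((F @ frame.data[0] @ F.T) / den) @ Fi.T)
        mu = 4 * np.pi * spec.beta / spec.wavelength
        oracle = -(1 / mu) * np.log(filt)
        assert np.abs(out - oracle).max() / np.abs(oracle).max() < 1e-10

    def test_beta_zero_rejected(self):
        with pytest.raises(ValueError):
            ss.PaganinSpec(delta=1e-7, beta=0.0, distance=3e5, wavelength=6e-5, pixel_size=2.0)


class TestRampFilter:
    def line_frame(self, rows_data, pixel_size=1.0):
        n_ang, rows, cols = rows_data.shape
        geom = ss.make_parallel_geometry(n_ang, rows, cols, pixel_size)
        return make_frame(rows_data, geom, ss.FrameState.LINE_INTEGRAL)

    def test_ramp_has_exactly_zero_dc_gain(self):
        # a constant (DC) signal is annihilated: kernel taps sum to zero,
        # so filtering a periodically extended constant row gives zero
        pad = _next_pow_two(2 * 64)
        resp = np.real(np.fft.fft(ramp_kernel(pad, 0.7)))
        assert abs(resp[0]) < 1e-12
        out = np.real(np.fft.ifft(np.fft.fft(np.full(pad, 3.7)) * resp))
        assert np.abs(out).max() < 1e-10 * 3.7
        frame = self.line_frame(np.full((1, 1, 64), 3.7))
        assert ss.ramp_filter(frame).state is ss.FrameState.FILTERED

    def test_fourier_path_matches_direct_convolution(self):
        rng = np.random.default_rng(4)
        L, px = 64, 0.7
        data = rng.normal(size=(3, 2, L))
        frame = self.line_frame(data, pixel_size=px)
        out = ss.ramp_filter(frame).data
        pad = _next_pow_two(2 * L)
        k = ramp_kernel(pad, px)
        # unwrap to lags -(pad/2-1) … pad/2 and convolve directly
        kernel = np.concatenate([k[pad // 2 + 1 :], k[: pad // 2 + 1]])
        for a in range(3):
            for r in range(2):
                direct = np.convolve(data[a, r], kernel, mode="full")[
                    pad // 2 - 1 : pad // 2 - 1 + L
                ]
                rel = np.abs(out[a, r] - direct).max() / np.abs(direct).max()
                assert rel < 1e-9

    def test_linearity_exact(self):
        rng = np.random.default_rng(5)
        a = self.line_frame(rng.normal(size=(2, 3, 32)))
        b = self.line_frame(rng.normal(size=(2, 3, 32)))
        ab = self.line_frame(a.data + b.data)
        fa, fb, fab = (ss.ramp_filter(x).data for x in (a, b, ab))
        assert np.allclose(fab, fa + fb, atol=1e-12)

    def test_rows_and_projections_independent(self):
        rng = np.random.default_rng(6)
        data = rng.normal(size=(4, 5, 32))
        frame = self.line_frame(data)
        filtered = ss.ramp_filter(frame).data
        # permuting detector rows commutes with filtering (exact)
        perm = [3, 0, 4, 1, 2]
        permuted = ss.ramp_filter(self.line_frame(data[:, perm, :])).data
        assert np.array_equal(permuted, filtered[:, perm, :])
        # filtering a subset of projections equals the subset of filtering all
        sub = ss.ramp_filter(self.line_frame(data[1:3])).data
        assert np.array_equal(sub, filtered[1:3])

    def test_shepp_logan_damps_high_frequencies(self):
        rng = np.random.default_rng(7)
        data = rng.normal(size=(1, 1, 64))
        frame = self.line_frame(data)
        ram = ss.ramp_filter(frame, ss.FilterSpec("ram-lak")).data
        shepp = ss.ramp_filter(frame, ss.FilterSpec("shepp-logan")).data
        assert (shepp**2).sum() < (ram**2).sum()

    def test_unknown_filter_rejected(self):
        with pytest.raises(ValueError):
            ss.FilterSpec(name="cosine")
        with pytest.raises(ValueError):
            ss.FilterSpec(cutoff=0.0)

    def test_state_enforced(self, small_geom):
        raw = make_frame(np.ones((32, 32, 32)), small_geom, ss.FrameState.RAW)
        with pytest.raises(ValueError):
            ss.ramp_filter(raw)


class TestPreprocessFrame:
    def test_missing_angles_stay_zero_after_filtering(self, small_geom):
        ph = ss.Phantom([ss.Ellipsoid((0, 0, 0), (8, 8, 8), 0.0, 0.05)])
        frames, flat, dark = ss.simulate_acquisition([ph], small_geom)
        raw = ss.ProjectionFrame(
            frames[0].data, ss.FrameState.RAW, small_geom, missing_angles=(3, 7)
        )
        raw.data[[3, 7]] = 0.0
        out = ss.preprocess_frame(raw, flat, dark)
        assert not out.data[[3, 7]].any()
        assert out.data[0].any()
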