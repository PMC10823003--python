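"""Connectivity estimators vs independent brute-force oracles and anchors."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from neurospd.connectivity import (
    PLV_EDGE_FRAC,
    coh,
    connectivity_matrix,
    mi,
    mutual_information_from_joint,
    pcc,
    plv,
)
from neurospd.exceptions import ConfigError, DataError

# ---------------------------------------------------------------- oracles
# Each oracle re-derives the estimator from its definition through a code path
# independent of the implementation (manual FFT analytic signal, hand-rolled
# Welch segments, explicit bin-count loops).


def analytic_phase_oracle(x):
    """Instantaneous phase via a hand-built analytic signal (FFT half-plane)."""
    n = x.size
    X = np.fft.fft(x)
    h = np.zeros(n)
    h[0] = 1.0
    if n % 2 == 0:
        h[n // 2] = 1.0
        h[1 : n // 2] = 2.0
    else:
        h[1 : (n + 1) // 2] = 2.0
    return np.angle(np.fft.ifft(X * h))


def plv_oracle(x, y):
    T = x.size
    k = int(PLV_EDGE_FRAC * T)
    sl = slice(k, T - k)
    dphi = analytic_phase_oracle(x)[sl] - analytic_phase_oracle(y)[sl]
    return abs(np.mean(np.cos(dphi) + 1j * np.sin(dphi)))


def pcc_oracle(x, y):
    return float(np.corrcoef(x, y)[0, 1])


def coh_oracle(x, y, fs, band=(1.0, 47.0)):
    """Hand-rolled Welch: 0.5-s segments, 50% overlap, periodic Hann window."""
    nps = int(round(fs / 2))
    step = nps // 2
    win = 0.5 - 0.5 * np.cos(2 * np.pi * np.arange(nps) / nps)  # periodic Hann
    sxy = sxx = syy = 0.0
    n_seg = 0
    for s in range(0, x.size - nps + 1, step):
        xs, ys = x[s : s + nps], y[s : s + nps]
        X = np.fft.rfft((xs - xs.mean()) * win)
        Y = np.fft.rfft((ys - ys.mean()) * win)
        sxy = sxy + X * np.conj(Y)
        sxx = sxx + np.abs(X) ** 2
        syy = syy + np.abs(Y) ** 2
        n_seg += 1
    f = np.fft.rfftfreq(nps, 1.0 / fs)
    sel = (f >= band[0]) & (f <= band[1])
    msc = np.abs(sxy[sel]) ** 2 / (sxx[sel] * syy[sel])
    return float(np.mean(msc))


def mi_oracle(x, y, n_bins=16):
    """MI in bits by explicit bin-count loops over an equal-width grid."""
    ex = np.linspace(x.min(), x.max(), n_bins + 1)
    ey = np.linspace(y.min(), y.max(), n_bins + 1)
    ix = np.clip(np.searchsorted(ex, x, side="right") - 1, 0, n_bins - 1)
    iy = np.clip(np.searchsorted(ey, y, side="right") - 1, 0, n_bins - 1)
    joint = np.zeros((n_bins, n_bins))
    for a, b in zip(ix, iy):
        joint[a, b] += 1
    joint /= joint.sum()
    px, py = joint.sum(axis=1), joint.sum(axis=0)
    total = 0.0
    for a in range(n_bins):
        for b in range(n_bins):
            if joint[a, b] > 0:
                total += joint[a, b] * np.log2(joint[a, b] / (px[a] * py[b]))
    return total


def signal_pairs(n_pairs=50, T=200, seed=777):
    rng = np.random.default_rng(seed)
    for _ in range(n_pairs):
        mix = rng.uniform(0, 1)
        s = rng.standard_normal(T)
        x = s + 0.5 * rng.standard_normal(T)
        y = mix * s + (1 - mix) * rng.standard_normal(T)
        yield x, y


# ----------------------------------------------------------------- anchors


class TestPLV:
    def test_identical_signals(self, rng):
        x = rng.standard_normal(300)
        assert plv(x, x) == pytest.approx(1.0, abs=1e-12)

    def test_constant_phase_offset(self):
        t = np.arange(400) / 200
        assert plv(np.sin(2 * np.pi * 10 * t), np.cos(2 * np.pi * 10 * t)) == pytest.approx(
            1.0, abs=1e-3
        )

    def test_matches_bruteforce_oracle(self):
        for x, y in signal_pairs():
            assert plv(x, y) == pytest.approx(plv_oracle(x, y), abs=1e-10)

    def test_constant_signal_rejected(self):
        with pytest.raises(DataError):
            plv(np.ones(100), np.arange(100.0))


class TestPCC:
    @pytest.mark.parametrize(
        "x, y, expected",
        [
            ([1, 2, 3], [2, 4, 6], 1.0),
            ([1, 2, 3], [-1, -2, -3], -1.0),
            ([1, 2, 3], [1, 3, 2], 0.5),
        ],
    )
    def test_hand_anchors(self, x, y, expected):
        assert pcc(np.array(x, float), np.array(y, float)) == pytest.approx(expected, abs=1e-12)

    def test_matches_oracle(self):
        for x, y in signal_pairs():
            assert pcc(x, y) == pytest.approx(pcc_oracle(x, y), abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(DataError):
            pcc(np.ones(50), np.arange(50.0))


class TestCOH:
    def test_identical_signals_full_coherence(self, rng):
        x = rng.standard_normal(200)
        assert coh(x, x, fs=200) == pytest.approx(1.0, abs=1e-10)

    def test_scale_invariance(self, rng):
        x = rng.standard_normal(200)
        assert coh(x, 3 * x, fs=200) == pytest.approx(1.0, abs=1e-10)

    def test_matches_independent_welch(self):
        for x, y in signal_pairs():
            assert coh(x, y, fs=200) == pytest.approx(coh_oracle(x, y, 200), abs=1e-8)

    def test_bad_band_rejected(self, rng):
        with pytest.raises(ConfigError):
            coh(rng.standard_normal(200), rng.standard_normal(200), fs=200, band=(1, 120))


class TestMI:
    def test_independent_joint_is_zero(self):
        assert mutual_information_from_joint(np.full((2, 2), 0.25)) == 0.0

    def test_identity_uniform_four_bins(self):
        x = np.repeat([0.0, 1.0, 2.0, 3.0], 25)
        assert mi(x, x, n_bins=4) == pytest.approx(2.0, abs=1e-12)

    def test_joint_table_anchor(self):
        joint = np.array([[0.25, 0.25], [0.0, 0.5]])
        assert mutual_information_from_joint(joint) == pytest.approx(0.311278, abs=1e-4)

    def test_matches_bruteforce_oracle(self):
        for x, y in signal_pairs():
            assert mi(x, y) == pytest.approx(mi_oracle(x, y), abs=1e-10)

    def test_self_information_upper_bounds_cross(self, rng):
        x = rng.standard_normal(400)
        for _ in range(5):
            y = rng.standard_normal(400)
            assert mi(x, x) >= mi(x, y)

    def test_too_few_samples_rejected(self):
        with pytest.raises(DataError):
            mi(np.array([1.0]), np.array([2.0]))


# ----------------------------------------------------------- matrix assembly


class TestConnectivityMatrix:
    @pytest.mark.parametrize("kind", ["plv", "pcc", "coh", "mi"])
    def test_matrix_equals_pairwise_loop(self, kind, rng):
        X = rng.standard_normal((4, 200)) + np.sin(
            2 * np.pi * 11 * np.arange(200) / 200
        )
        M = connectivity_matrix(X, kind, fs=200).values
        fn = {
            "plv": plv,
            "pcc": pcc,
            "coh": lambda a, b: coh(a, b, fs=200),
            "mi": mi,
        }[kind]
        for i in range(4):
            for j in range(i + 1, 4):
                assert M[i, j] == pytest.approx(fn(X[i], X[j]), abs=1e-8)
        np.testing.assert_array_equal(M, M.T)

    def test_identical_channels_plv_all_ones(self, rng):
        x = rng.standard_normal(200)
        M = connectivity_matrix(np.tile(x, (3, 1)), "plv").values
        np.testing.assert_allclose(M, 1.0, atol=1e-10)

    @pytest.mark.parametrize("kind, diag", [("plv", 1.0), ("pcc", 1.0), ("coh", 1.0)])
    def test_unit_diagonal(self, kind, diag, rng):
        X = rng.standard_normal((3, 200))
        M = connectivity_matrix(X, kind, fs=200).values
        np.testing.assert_allclose(M.diagonal(), diag)

    def test_mi_diagonal_is_self_information(self, rng):
        X = rng.standard_normal((3, 200))
        M = connectivity_matrix(X, "mi").values
        for c in range(3):
            assert M[c, c] == pytest.approx(mi(X[c], X[c]), abs=1e-12)

    def test_unknown_kind_rejected(self, rng):
        with pytest.raises(ConfigError):
            connectivity_matrix(rng.standard_normal((2, 100)), "granger")


# ------------------------------------------------------------- properties

def _pair_from_seed(seed):
    """Generic (non-degenerate) signal pair: Gaussian noise + shared tone."""
    r = np.random.default_rng(seed)
    tone = np.sin(2 * np.pi * r.uniform(2, 20) * np.arange(64) / 64)
    x = r.standard_normal(64) + r.uniform(0, 2) * tone
    y = r.standard_normal(64) + r.uniform(0, 2) * tone
    return x, y


@given(seed=st.integers(0, 10**6))
def test_symmetry_of_all_estimators(seed):
    x, y = _pair_from_seed(seed)
    assert plv(x, y) == plv(y, x)
    assert pcc(x, y) == pytest.approx(pcc(y, x), abs=1e-15)
    assert coh(x, y, fs=64, band=(1, 30)) == pytest.approx(
        coh(y, x, fs=64, band=(1, 30)), abs=1e-12
    )
    assert mi(x, y) == pytest.approx(mi(y, x), abs=1e-12)


@given(seed=st.integers(0, 10**6), scale=st.floats(0.1, 50))
def test_ranges_and_scale_invariance(seed, scale):
    x, y = _pair_from_seed(seed)
    assert 0.0 <= plv(x, y) <= 1.0
    assert -1.0 <= pcc(x, y) <= 1.0
    assert 0.0 <= coh(x, y, fs=64, band=(1, 30)) <= 1.0
    assert mi(x, y) >= 0.0
    # amplitude scaling leaves PLV and COH unchanged; positive affine leaves PCC
    assert plv(scale * x, y) == pytest.approx(plv(x, y), abs=1e-9)
    assert coh(scale * x, y, fs=64, band=(1, 30)) == pytest.approx(
        coh(x, y, fs=64, band=(1, 30)), abs=1e-9
    )
    assert pcc(scale * x + 1.0, y) == pytest.approx(pcc(x, y), abs=1e-9)
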