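"""The 131-feature representation of a 6 s triaxial acceleration window.

Eleven feature families over the three axes (x, y, z), in a frozen registry
order (family sizes 9, 9, 12, 12, 1, 1, 3, 6, 6, 12, 60 = 131):

1.  mean, range, interquartile range per axis (9)
2.  moments: standard deviation, skewness, excess kurtosis per axis (9)
3.  histogram: counts of z-scores in four equal bins partitioning [-2, 1) (12)
4.  moments of the first difference: mean, SD, skewness, kurtosis per axis (12)
5.  mean of the squared norm ax^2 + ay^2 + az^2 (1)
6.  sum of the three axial standard deviations (1)
7.  Pearson r for the axis pairs xy, xz, yz (3)
8.  mean cross-products, raw and normalized (z-scored axes), per pair (6)
9.  absolute values of those six mean cross-products (6)
10. periodogram ordinate statistics: mean, SD, skewness, kurtosis per axis (12)
11. mean periodogram power in the twenty 0.5 Hz bands covering [0, 10) Hz
    per axis (60)

Conventions (documented so oracles are reproducible): quantiles use linear
interpolation; skewness/kurtosis are the population (biased) estimators with
kurtosis as excess; the periodogram is the one-sided, mean-removed,
rectangular-window estimate normalized so its ordinates sum to the population
variance of the axis (Parseval); z-scores outside [-2, 1) are excluded from
the histogram, not clipped. A zero-variance axis takes fallback values
(skew/kurtosis 0, histogram counts 0, Pearson r and normalized products 0)
so every output is finite.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .io import ValidationError
from .windowing import Window

REGISTRY_VERSION = "1.0"

FAMILY_SIZES: tuple[int, ...] = (9, 9, 12, 12, 1, 1, 3, 6, 6, 12, 60)
N_FEATURES = sum(FAMILY_SIZES)  # 131

_AXES = ("x", "y", "z")
_PAIRS = ((0, 1, "xy"), (0, 2, "xz"), (1, 2, "yz"))
_HIST_EDGES = np.array([-2.0, -1.25, -0.5, 0.25, 1.0])
_BAND_EDGES = np.arange(0.0, 10.5, 0.5)  # 20 half-open bands [0,0.5) .. [9.5,10)

FAMILY_NAMES: tuple[str, ...] = (
    "basic_stats",
    "moments",
    "zscore_histogram",
    "derivative_moments",
    "squared_norm_mean",
    "sd_sum",
    "pearson_r",
    "cross_products",
    "abs_cross_products",
    "spectral_moments",
    "band_power",
)


def feature_names() -> list[str]:
    """The frozen, ordered list of 131 feature names."""
    names: list[str] = []
    names += [f"mean_{a}" for a in _AXES]
    names += [f"range_{a}" for a in _AXES]
    names += [f"iqr_{a}" for a in _AXES]
    names += [f"sd_{a}" for a in _AXES]
    names += [f"skew_{a}" for a in _AXES]
    names += [f"kurt_{a}" for a in _AXES]
    for a in _AXES:
        names += [f"zhist_{a}_bin{i}" for i in range(4)]
    for stat in ("mean", "sd", "skew", "kurt"):
        names += [f"diff_{stat}_{a}" for a in _AXES]
    names += ["sq_norm_mean", "sd_sum"]
    names += [f"pearson_r_{p}" for _, _, p in _PAIRS]
    names += [f"cp_raw_{p}" for _, _, p in _PAIRS]
    names += [f"cp_norm_{p}" for _, _, p in _PAIRS]
    names += [f"abs_cp_raw_{p}" for _, _, p in _PAIRS]
    names += [f"abs_cp_norm_{p}" for _, _, p in _PAIRS]
    for stat in ("mean", "sd", "skew", "kurt"):
        names += [f"psd_{stat}_{a}" for a in _AXES]
    for a in _AXES:
        names += [
            f"band_{a}_{_BAND_EDGES[i]:.1f}_{_BAND_EDGES[i + 1]:.1f}"
            for i in range(len(_BAND_EDGES) - 1)
        ]
    assert len(names) == N_FEATURES
    return names


FEATURE_NAMES: tuple[str, ...] = tuple(feature_names())


def family_slices() -> dict[str, slice]:
    """Registry slice per family, in order."""
    out = {}
    start = 0
    for name, size in zip(FAMILY_NAMES, FAMILY_SIZES):
        out[name] = slice(start, start + size)
        start += size
    return out


# ---------------------------------------------------------------------------
# family computations (axis arrays are 1-D samples)


def _moments(x: np.ndarray) -> tuple[float, float, float]:
    """Population SD, skewness and excess kurtosis with zero-variance fallback."""
    sd = float(np.std(x))
    if sd == 0.0:
        return 0.0, 0.0, 0.0
    return (
        sd,
        float(stats.skew(x, bias=True)),
        float(stats.kurtosis(x, fisher=True, bias=True)),
    )


def family_basic_stats(a: np.ndarray) -> np.ndarray:
    means = a.mean(axis=1)
    ranges = a.max(axis=1) - a.min(axis=1)
    q75, q25 = np.percentile(a, [75, 25], axis=1)  # linear interpolation
    return np.concatenate([means, ranges, q75 - q25])


def family_moments(a: np.ndarray) -> np.ndarray:
    sds, skews, kurts = zip(*(_moments(a[i]) for i in range(3)))
    return np.concatenate([sds, skews, kurts])


def family_zscore_histogram(a: np.ndarray) -> np.ndarray:
    out = np.zeros(12)
    for i in range(3):
        x = a[i]
        sd = np.std(x)
        if sd == 0.0:
            continue
        z = (x - x.mean()) / sd
        counts, _ = np.histogram(z, bins=_HIST_EDGES)
        # np.histogram closes the last bin; drop z == 1 exactly to keep [0.25, 1) half-open
        counts[-1] -= int(np.count_nonzero(z == _HIST_EDGES[-1]))
        out[4 * i : 4 * i + 4] = counts
    return out


def family_derivative_moments(a: np.ndarray) -> np.ndarray:
    d = np.diff(a, axis=1)
    means = d.mean(axis=1)
    sds, skews, kurts = zip(*(_moments(d[i]) for i in range(3)))
    return np.concatenate([means, sds, skews, kurts])


def family_norm_and_sd_sum(a: np.ndarray) -> np.ndarray:
    sq_norm = float(np.mean(np.sum(a * a, axis=0)))
    sd_sum = float(np.sum(np.std(a, axis=1)))
    return np.array([sq_norm, sd_sum])


def family_correlations_and_crossproducts(a: np.ndarray) -> np.ndarray:
    sds = np.std(a, axis=1)
    means = a.mean(axis=1)
    z = np.zeros_like(a)
    for i in range(3):
        if sds[i] > 0:
            z[i] = (a[i] - means[i]) / sds[i]
    r = np.zeros(3)
    cp_raw = np.zeros(3)
    cp_norm = np.zeros(3)
    for k, (i, j, _) in enumerate(_PAIRS):
        cp_raw[k] = float(np.mean(a[i] * a[j]))
        if sds[i] > 0 and sds[j] > 0:
            cp_norm[k] = float(np.mean(z[i] * z[j]))
            r[k] = cp_norm[k]  # Pearson r under population moments
    return np.concatenate([r, cp_raw, cp_norm, np.abs(cp_raw), np.abs(cp_norm)])


def periodogram(x: np.ndarray) -> np.ndarray:
    """One-sided, mean-removed periodogram whose ordinates sum to var(x).

    Rectangular window; DC ordinate is ~0 after mean removal; non-DC,
    non-Nyquist ordinates carry the factor 2 of the one-sided fold.
    """
    n = x.size
    x0 = x - x.mean()
    X = np.fft.rfft(x0)
    p = np.abs(X) ** 2 / n**2
    p[1:] *= 2.0
    if n % 2 == 0:
        p[-1] /= 2.0
    return p


def family_spectral(a: np.ndarray, sample_rate_hz: float) -> np.ndarray:
    n = a.shape[1]
    freqs = np.fft.rfftfreq(n, d=1.0 / sample_rate_hz)
    psd_stats = np.zeros(12)
    bands = np.zeros((3, len(_BAND_EDGES) - 1))
    for i in range(3):
        p = periodogram(a[i])
        sd = np.std(p)
        psd_stats[i] = p.mean()
        if sd > 0:
            psd_stats[3 + i] = sd
            psd_stats[6 + i] = float(stats.skew(p, bias=True))
            psd_stats[9 + i] = float(stats.kurtosis(p, fisher=True, bias=True))
        for b in range(len(_BAND_EDGES) - 1):
            mask = (freqs >= _BAND_EDGES[b]) & (freqs < _BAND_EDGES[b + 1])
            if mask.any():
                bands[i, b] = p[mask].mean()
    return np.concatenate([psd_stats, bands.ravel()])


# ---------------------------------------------------------------------------


def extract_features(window: Window) -> np.ndarray:
    """The full 131-vector for one window, in registry order."""
    a = np.asarray(window.a, dtype=float)
    if a.shape[0] != 3 or a.shape[1] < 8:
        raise ValidationError(f"window must be 3xL with L >= 8, got {a.shape}")
    if not np.all(np.isfinite(a)):
        raise ValidationError("window contains non-finite samples")
    vec = np.concatenate(
        [
            family_basic_stats(a),
            family_moments(a),
            family_zscore_histogram(a),
            family_derivative_moments(a),
            family_norm_and_sd_sum(a),
            family_correlations_and_crossproducts(a),
            family_spectral(a, window.sample_rate_hz),
        ]
    )
    assert vec.size == N_FEATURES
    return vec


# ---------------------------------------------------------------------------
# batch path: identical arithmetic over an (n, 3, L) stack, vectorized.
# extract_features above is the per-window reference; tests assert equality.


def _batch_moments(x: np.ndarray):
    """Population SD, skew, excess kurtosis over the last axis with fallbacks."""
    mean = x.mean(axis=-1, keepdims=True)
    d = x - mean
    m2 = np.mean(d**2, axis=-1)
    m3 = np.mean(d**3, axis=-1)
    m4 = np.mean(d**4, axis=-1)
    sd = np.sqrt(m2)
    ok = sd > 0
    skew = np.zeros_like(sd)
    kurt = np.zeros_like(sd)
    np.divide(m3, m2**1.5, out=skew, where=ok)
    np.divide(m4, m2**2, out=kurt, where=ok)
    kurt[ok] -= 3.0
    return sd, skew, kurt


def extract_features_batch(A: np.ndarray, sample_rate_hz: float) -> np.ndarray:
    """Featurize a stack of windows at once; A is (n, 3, L), output (n, 131)."""
    A = np.asarray(A, dtype=float)
    n, n_axes, L = A.shape
    if n_axes != 3 or L < 8:
        raise ValidationError(f"window stack must be (n, 3, L>=8), got {A.shape}")
    means = A.mean(axis=-1)
    ranges = A.max(axis=-1) - A.min(axis=-1)
    q75, q25 = np.percentile(A, [75, 25], axis=-1)
    sd, skew, kurt = _batch_moments(A)

    zhist = np.zeros((n, 3, 4))
    safe_sd = np.where(sd > 0, sd, 1.0)
    z = (A - means[..., None]) / safe_sd[..., None]
    for b in range(4):
        zhist[..., b] = np.sum((z >= _HIST_EDGES[b]) & (z < _HIST_EDGES[b + 1]), axis=-1)
    zhist[sd == 0] = 0.0

    D = np.diff(A, axis=-1)
    d_mean = D.mean(axis=-1)
    d_sd, d_skew, d_kurt = _batch_moments(D)

    sq_norm = np.mean(np.sum(A * A, axis=1), axis=-1)
    sd_sum = sd.sum(axis=-1)

    cp_raw = np.empty((n, 3))
    cp_norm = np.zeros((n, 3))
    for k, (i, j, _) in enumerate(_PAIRS):
        cp_raw[:, k] = np.mean(A[:, i] * A[:, j], axis=-1)
        ok = (sd[:, i] > 0) & (sd[:, j] > 0)
        cp_norm[ok, k] = np.mean(z[ok, i] * z[ok, j], axis=-1)
    r = cp_norm  # Pearson r under population moments

    A0 = A - means[..., None]
    X = np.fft.rfft(A0, axis=-1)
    P = np.abs(X) ** 2 / L**2
    P[..., 1:] *= 2.0
    if L % 2 == 0:
        P[..., -1] /= 2.0
    freqs = np.fft.rfftfreq(L, d=1.0 / sample_rate_hz)
    p_sd, p_skew, p_kurt = _batch_moments(P)
    p_mean = P.mean(axis=-1)
    bands = np.zeros((n, 3, len(_BAND_EDGES) - 1))
    for b in range(len(_BAND_EDGES) - 1):
        mask = (freqs >= _BAND_EDGES[b]) & (freqs < _BAND_EDGES[b + 1])
        if mask.any():
            bands[..., b] = P[..., mask].mean(axis=-1)

    out = np.concatenate(
        [
            means,
            ranges,
            q75 - q25,
            sd,
            skew,
            kurt,
            zhist.reshape(n, 12),
            d_mean,
            d_sd,
            d_skew,
            d_kurt,
            sq_norm[:, None],
            sd_sum[:, None],
            r,
            cp_raw,
            cp_norm,
            np.abs(cp_raw),
            np.abs(cp_norm),
            p_mean,
            p_sd,
            p_skew,
            p_kurt,
            bands.reshape(n, 60),
        ],
        axis=1,
    )
    assert out.shape == (n, N_FEATURES)
    return out


def feature_matrix(windows: list[Window]):
    """Featurize a window list into (X, y, meta).

    X is (n, 131); y is the activity label array; meta is a DataFrame of
    provenance columns (subject_id, group, device, session_id, start_s).
    Windows of equal length and sample rate are featurized in vectorized
    batches; the result matches :func:`extract_features` per window.
    """
    import pandas as pd

    if not windows:
        raise ValidationError("no windows to featurize")
    X = np.empty((len(windows), N_FEATURES))
    groups: dict[tuple[int, float], list[int]] = {}
    for i, w in enumerate(windows):
        groups.setdefault((w.L, w.sample_rate_hz), []).append(i)
    for (_, rate), idx in groups.items():
        A = np.stack([windows[i].a for i in idx])
        X[idx] = extract_features_batch(A, rate)
    y = np.array([w.activity for w in windows])
    meta = pd.DataFrame(
        {
            "subject_id": [w.subject_id for w in windows],
            "group": [w.group for w in windows],
            "device": [w.device for w in windows],
            "session_id": [w.session_id for w in windows],
            "start_s": [w.start_s for w in windows],
        }
    )
    return X, y, meta
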