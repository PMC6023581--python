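"""Per-window feature extraction for 5-s accelerometer windows.

Each non-overlapping 5-s window of the raw (unfiltered) triaxial signal is
summarised by a 41-element feature vector over the vector magnitude
``v = sqrt(x^2 + y^2 + z^2)``, the per-sample orientation angles
``roll = atan2(y, z)``, ``pitch = atan2(x, z)``, ``yaw = atan2(y, x)``, the
low-pass-estimated gravity direction, and the power spectrum of the
mean-removed vector magnitude.  The canonical feature order is fixed in
:data:`FEATURE_NAMES`.

Numerical conventions (documented in the methods note):

* correlations and the 1-s-lag autocorrelation are Pearson correlations, set
  to 0 when either series has zero variance;
* ``coefvariation = sd / mean`` with 0 substituted when the mean is 0;
* angle averages/SDs are arithmetic over per-sample radians in (-pi, pi];
  ``atan2(0, 0) = 0``;
* the gravity direction is the mean of each axis after an order-2
  Butterworth filter applied forward and backward (4th-order zero-phase) at
  the 0.5 Hz cutoff;
* the spectrum is a one-sided periodogram of the mean-removed vector
  magnitude, power = |FFT|^2 / n, zero-frequency bin excluded from all
  searches; an all-zero residual yields 0 for every spectral feature;
* band powers ``fft1..fft15`` sum the half-open bands [k-0.5, k+0.5) Hz;
  ``fmaxband/pmaxband`` search the closed band [0.3, 3] Hz;
* spectral entropy is the Shannon entropy (nats) of the spectrum normalised
  to sum 1, with 0*log(0) = 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .core import TriaxialRecording

__all__ = [
    "FEATURE_NAMES",
    "N_FEATURES",
    "Window",
    "FeatureVector",
    "segment_windows",
    "extract_features",
    "spectral_features",
    "gravity_angles",
    "feature_matrix",
    "write_feature_matrix",
    "read_feature_matrix",
]

FEATURE_NAMES: tuple[str, ...] = (
    "mean",
    "sd",
    "coefvariation",
    "min",
    "max",
    "25thp",
    "median",
    "75thp",
    "autocorr",
    "corrxy",
    "corrxz",
    "corryz",
    "avgroll",
    "avgpitch",
    "avgyaw",
    "sdroll",
    "sdpitch",
    "sdyaw",
    "rollg",
    "pitchg",
    "yawg",
    "fmax",
    "pmax",
    "fmaxband",
    "pmaxband",
    "entropy",
    *[f"fft{k}" for k in range(1, 16)],
)
N_FEATURES = len(FEATURE_NAMES)  # 41

_ZERO_POWER = 1e-24  # residual total power below this counts as a zero signal


@dataclass
class Window:
    """One fixed-length analysis window (150 samples at 30 Hz for 5 s)."""

    window_index: int
    start_time: pd.Timestamp
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    sampling_rate_hz: float = 30.0

    def __len__(self) -> int:
        return len(self.x)


@dataclass
class FeatureVector:
    window_index: int
    values: np.ndarray

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(FEATURE_NAMES), name=self.window_index)

    def __getitem__(self, name: str) -> float:
        return float(self.values[FEATURE_NAMES.index(name)])


def segment_windows(rec: TriaxialRecording, window_s: float = 5.0) -> list[Window]:
    """Split a recording into non-overlapping, consecutive windows.

    A trailing partial window is discarded; a recording shorter than one
    window yields an empty list.
    """
    wlen = int(round(rec.sampling_rate_hz * window_s))
    n = len(rec) // wlen
    out = []
    for i in range(n):
        sl = slice(i * wlen, (i + 1) * wlen)
        out.append(
            Window(
                window_index=i,
                start_time=rec.start_time + pd.Timedelta(seconds=i * window_s),
                x=rec.x[sl],
                y=rec.y[sl],
                z=rec.z[sl],
                sampling_rate_hz=rec.sampling_rate_hz,
            )
        )
    return out


def _row_pearson(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson correlation per row of two (n, w) arrays; 0 on zero variance."""
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    sa = np.sqrt((ac * ac).sum(axis=1))
    sb = np.sqrt((bc * bc).sum(axis=1))
    denom = sa * sb
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (ac * bc).sum(axis=1) / denom
    r = np.where(denom > 0, r, 0.0)
    return np.clip(r, -1.0, 1.0)


def _lowpass_sos(cutoff_hz: float, rate_hz: float):
    if not 0 < cutoff_hz < rate_hz / 2:
        raise ValueError("cutoff must lie in (0, Nyquist)")
    return sps.butter(2, cutoff_hz, btype="low", fs=rate_hz, output="sos")


_GRAVITY_SNAP = 0.01  # components below this fraction of |g| are treated as 0


def _batch_gravity(
    X: np.ndarray, Y: np.ndarray, Z: np.ndarray, rate_hz: float, cutoff_hz: float
) -> np.ndarray:
    """Mean low-pass-filtered direction per window; returns (n, 3).

    Components smaller than ``_GRAVITY_SNAP`` of the gravity magnitude are
    snapped to zero so the subsequent two-argument arctangents stay on the
    atan2(0, 0) = 0 degenerate branch instead of flipping to +-pi/2 on
    residual filter leakage.
    """
    sos = _lowpass_sos(cutoff_hz, rate_hz)
    means = [sps.sosfiltfilt(sos, A, axis=1).mean(axis=1) for A in (X, Y, Z)]
    g = np.column_stack(means)
    gnorm = np.linalg.norm(g, axis=1, keepdims=True)
    g[np.abs(g) < _GRAVITY_SNAP * gnorm] = 0.0
    return g


def _batch_spectral(vm: np.ndarray, rate_hz: float) -> np.ndarray:
    """Spectral feature block for (n, w) vector magnitudes; returns (n, 20)."""
    n_win, w = vm.shape
    resid = vm - vm.mean(axis=1, keepdims=True)
    power = np.abs(np.fft.rfft(resid, axis=1)) ** 2 / w
    freqs = np.fft.rfftfreq(w, d=1.0 / rate_hz)
    # drop the zero-frequency bin from every search, band and the entropy
    P = power[:, 1:]
    f = freqs[1:]
    total = P.sum(axis=1)
    live = total > _ZERO_POWER

    out = np.zeros((n_win, 20))
    if not np.any(live):
        return out

    idx = np.argmax(P, axis=1)  # ties -> lowest frequency (first maximum)
    out[live, 0] = f[idx[live]]  # fmax
    out[live, 1] = P[np.arange(n_win), idx][live]  # pmax

    band = (f >= 0.3) & (f <= 3.0)
    if band.any():
        Pb = P[:, band]
        fb = f[band]
        bidx = np.argmax(Pb, axis=1)
        bmax = Pb[np.arange(n_win), bidx]
        live_b = live & (bmax > 0)
        out[live_b, 2] = fb[bidx[live_b]]  # fmaxband
        out[live_b, 3] = bmax[live_b]  # pmaxband

    with np.errstate(invalid="ignore", divide="ignore"):
        p = P / total[:, None]
        ent = -np.nansum(np.where(p > 0, p * np.log(p), 0.0), axis=1)
    out[live, 4] = ent[live]

    for k in range(1, 16):
        sel = (f >= k - 0.5) & (f < k + 0.5)
        if sel.any():
            out[live, 4 + k] = P[:, sel].sum(axis=1)[live]
    return out


def _batch_features(
    X: np.ndarray,
    Y: np.ndarray,
    Z: np.ndarray,
    rate_hz: float,
    lowpass_cutoff_hz: float,
) -> np.ndarray:
    """Compute the 41 features for stacked windows (n, w); returns (n, 41)."""
    for A in (X, Y, Z):
        if not np.all(np.isfinite(A)):
            raise ValueError("non-finite input sample")
    vm = np.sqrt(X * X + Y * Y + Z * Z)
    n_win, w = vm.shape

    mean = vm.mean(axis=1)
    sd = vm.std(axis=1, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = np.where(mean != 0, sd / mean, 0.0)
    q25, med, q75 = np.percentile(vm, [25, 50, 75], axis=1)

    lag = int(round(rate_hz))
    if 0 < lag < w:
        autocorr = _row_pearson(vm[:, :-lag], vm[:, lag:])
    else:
        autocorr = np.zeros(n_win)
    corrxy = _row_pearson(X, Y)
    corrxz = _row_pearson(X, Z)
    corryz = _row_pearson(Y, Z)

    roll = np.arctan2(Y, Z)
    pitch = np.arctan2(X, Z)
    yaw = np.arctan2(Y, X)
    ang_avg = [a.mean(axis=1) for a in (roll, pitch, yaw)]
    ang_sd = [a.std(axis=1, ddof=1) for a in (roll, pitch, yaw)]

    g = _batch_gravity(X, Y, Z, rate_hz, lowpass_cutoff_hz)
    gnorm = np.linalg.norm(g, axis=1)
    rollg = np.where(gnorm > 0, np.arctan2(g[:, 1], g[:, 2]), 0.0)
    pitchg = np.where(gnorm > 0, np.arctan2(g[:, 0], g[:, 2]), 0.0)
    yawg = np.where(gnorm > 0, np.arctan2(g[:, 1], g[:, 0]), 0.0)

    spectral = _batch_spectral(vm, rate_hz)

    return np.column_stack(
        [
            mean,
            sd,
            cv,
            vm.min(axis=1),
            vm.max(axis=1),
            q25,
            med,
            q75,
            autocorr,
            corrxy,
            corrxz,
            corryz,
            *ang_avg,
            *ang_sd,
            rollg,
            pitchg,
            yawg,
            spectral,
        ]
    )


def extract_features(
    window: Window,
    rate_hz: float | None = None,
    lowpass_cutoff_hz: float = 0.5,
) -> FeatureVector:
    """Compute the 41-element feature vector for a single window."""
    rate = rate_hz if rate_hz is not None else window.sampling_rate_hz
    values = _batch_features(
        window.x[None, :],
        window.y[None, :],
        window.z[None, :],
        rate,
        lowpass_cutoff_hz,
    )[0]
    return FeatureVector(window_index=window.window_index, values=values)


def spectral_features(vm, rate_hz: float) -> dict[str, float]:
    """Spectral features of a vector-magnitude series.

    Returns a dict with keys ``fmax, pmax, fmaxband, pmaxband, entropy,
    fft1..fft15``.
    """
    vm = np.asarray(vm, dtype=float)
    if vm.size < 2:
        raise ValueError("need at least 2 samples")
    row = _batch_spectral(vm[None, :], rate_hz)[0]
    names = ["fmax", "pmax", "fmaxband", "pmaxband", "entropy"] + [
        f"fft{k}" for k in range(1, 16)
    ]
    return dict(zip(names, row))


def gravity_angles(window: Window, cutoff_hz: float = 0.5) -> tuple[float, float, float]:
    """Roll/pitch/yaw of the low-pass-estimated gravity direction."""
    g = _batch_gravity(
        window.x[None, :],
        window.y[None, :],
        window.z[None, :],
        window.sampling_rate_hz,
        cutoff_hz,
    )[0]
    if np.linalg.norm(g) == 0:
        return (0.0, 0.0, 0.0)
    return (
        float(np.arctan2(g[1], g[2])),
        float(np.arctan2(g[0], g[2])),
        float(np.arctan2(g[1], g[0])),
    )


def feature_matrix(
    rec: TriaxialRecording,
    window_s: float = 5.0,
    lowpass_cutoff_hz: float = 0.5,
) -> pd.DataFrame:
    """Feature matrix for a whole recording, one row per window.

    Columns are ``window_start`` followed by the 41 canonical feature names;
    the index is the window index.  Equivalent to calling
    :func:`extract_features` on every window of :func:`segment_windows`,
    but vectorised across windows.
    """
    wlen = int(round(rec.sampling_rate_hz * window_s))
    n = len(rec) // wlen
    if n == 0:
        df = pd.DataFrame(columns=["window_start", *FEATURE_NAMES])
        df.attrs["participant_id"] = rec.participant_id
        return df
    shape = (n, wlen)
    X = rec.x[: n * wlen].reshape(shape)
    Y = rec.y[: n * wlen].reshape(shape)
    Z = rec.z[: n * wlen].reshape(shape)
    values = _batch_features(X, Y, Z, rec.sampling_rate_hz, lowpass_cutoff_hz)
    starts = [
        rec.start_time + pd.Timedelta(seconds=i * window_s) for i in range(n)
    ]
    df = pd.DataFrame(values, columns=list(FEATURE_NAMES))
    df.insert(0, "window_start", starts)
    df.attrs["participant_id"] = rec.participant_id
    return df


def write_feature_matrix(df: pd.DataFrame, path, participant_id: str = "") -> None:
    out = df.copy()
    out.insert(0, "participant_id", participant_id or df.attrs.get("participant_id", ""))
    out.to_csv(path, index=False, float_format="%.9g")


def read_feature_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in FEATURE_NAMES if c not in df.columns]
    if missing:
        raise ValueError(f"feature file missing columns: {missing[:3]}...")
    return df
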