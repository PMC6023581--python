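"""Independent reference implementations used as test oracles.

Each oracle takes a deliberately different algorithmic route from the
package code it checks: naive O(n^2) discrete Fourier sums instead of FFT,
a moving-average low-pass instead of the Butterworth filter, block
enumeration instead of the greedy run-chain for wear time, and a separate
straightforward re-implementation of the transition-filter rules.
"""

from __future__ import annotations

import cmath
import math

import numpy as np

# ---------------------------------------------------------------------------
# spectral oracle: brute-force DFT over all bins


def dft_power_spectrum(vm, rate_hz):
    """One-sided power spectrum of the mean-removed series by direct summation."""
    vm = list(map(float, vm))
    n = len(vm)
    mean = sum(vm) / n
    resid = [v - mean for v in vm]
    n_bins = n // 2 + 1
    powers, freqs = [], []
    for k in range(n_bins):
        acc = 0j
        for t, v in enumerate(resid):
            acc += v * cmath.exp(-2j * cmath.pi * k * t / n)
        powers.append(abs(acc) ** 2 / n)
        freqs.append(k * rate_hz / n)
    return np.array(freqs), np.array(powers)


def spectral_oracle(vm, rate_hz):
    """Recompute every spectral feature from the brute-force spectrum."""
    freqs, powers = dft_power_spectrum(vm, rate_hz)
    f, P = freqs[1:], powers[1:]
    out = {k: 0.0 for k in ["fmax", "pmax", "fmaxband", "pmaxband", "entropy"]}
    out.update({f"fft{k}": 0.0 for k in range(1, 16)})
    total = P.sum()
    if total <= 1e-24:
        return out
    i = int(np.argmax(P))
    out["fmax"], out["pmax"] = float(f[i]), float(P[i])
    band = (f >= 0.3) & (f <= 3.0)
    if band.any() and P[band].max() > 0:
        j = int(np.argmax(P[band]))
        out["fmaxband"], out["pmaxband"] = float(f[band][j]), float(P[band][j])
    p = P / total
    out["entropy"] = float(-sum(pi * math.log(pi) for pi in p if pi > 0))
    for k in range(1, 16):
        sel = (f >= k - 0.5) & (f < k + 0.5)
        out[f"fft{k}"] = float(P[sel].sum())
    return out


def entropy_oracle(vm, rate_hz):
    return spectral_oracle(vm, rate_hz)["entropy"]


# ---------------------------------------------------------------------------
# gravity oracle: moving-average low-pass at the cutoff


def moving_average_gravity(x, y, z, rate_hz, cutoff_hz=0.5):
    """Average direction after a boxcar of width 1/cutoff seconds."""
    width = int(round(rate_hz / cutoff_hz))
    kernel = np.ones(width) / width

    def smooth(a):
        return np.convolve(np.asarray(a, float), kernel, mode="valid")

    g = np.array([smooth(a).mean() for a in (x, y, z)])
    if np.linalg.norm(g) == 0:
        return (0.0, 0.0, 0.0)
    return (
        math.atan2(g[1], g[2]),
        math.atan2(g[0], g[2]),
        math.atan2(g[1], g[0]),
    )


# ---------------------------------------------------------------------------
# transition-filter oracle: independent re-implementation of the two rules

_SIT, _STAND, _STEP, _S2S, _ST2S = 0, 1, 2, 3, 4


def filter_oracle(probs):
    """Decode probabilities and apply both filter passes, list-style."""
    probs = [list(map(float, row)) for row in probs]
    labels = [row.index(max(row)) for row in probs]

    def demote(i):
        nt = probs[i][:3]
        labels[i] = nt.index(max(nt))

    # pass one: while any adjacent transition pair exists, fix the leftmost
    def first_pair():
        for i in range(len(labels) - 1):
            if labels[i] >= 3 and labels[i + 1] >= 3:
                return i
        return None

    while (i := first_pair()) is not None:
        p_left = probs[i][labels[i]]
        p_right = probs[i + 1][labels[i + 1]]
        demote(i if p_left < p_right else i + 1)

    # pass two: single sweep, invalid-context transitions demoted
    n = len(labels)
    for i in range(n):
        if labels[i] == _S2S:
            ok = 0 < i < n - 1 and labels[i - 1] == _SIT and labels[i + 1] in (_STAND, _STEP)
        elif labels[i] == _ST2S:
            ok = 0 < i < n - 1 and labels[i - 1] in (_STAND, _STEP) and labels[i + 1] == _SIT
        else:
            continue
        if not ok:
            demote(i)
    return labels


# ---------------------------------------------------------------------------
# wear-time oracle: enumerate candidate zero-run blocks


def choi_oracle(counts, window_min=90, tolerance_min=2, flank_min=30):
    """Mark any minute inside a valid zero-block of sufficient length as non-wear.

    A candidate block starts and ends on (maximal) zero runs; it is valid if
    every internal non-zero interruption is at most ``tolerance_min`` long
    and flanked by zero runs of at least ``flank_min`` on both sides.
    """
    counts = np.asarray(counts)
    n = len(counts)
    runs = []
    i = 0
    while i < n:
        j = i
        while j < n and (counts[j] == 0) == (counts[i] == 0):
            j += 1
        runs.append((counts[i] == 0, i, j - i))
        i = j

    zero_runs = [k for k, r in enumerate(runs) if r[0]]
    nonwear = np.zeros(n, dtype=bool)
    for a_pos, a in enumerate(zero_runs):
        for b in zero_runs[a_pos:]:
            ok = True
            for k in range(a + 1, b):
                is_zero, _, length = runs[k]
                if is_zero:
                    continue
                if length > tolerance_min:
                    ok = False
                    break
                if runs[k - 1][2] < flank_min or runs[k + 1][2] < flank_min:
                    ok = False
                    break
            if not ok:
                continue
            start = runs[a][1]
            end = runs[b][1] + runs[b][2]
            if end - start >= window_min:
                nonwear[start:end] = True
    return ~nonwear  # wear flags


# ---------------------------------------------------------------------------
# bout oracle: run-length encoding of a sitting indicator


def bout_oracle(sitting, valid, epoch_s):
    """Durations (min) of sitting runs and count of bouts followed by wear activity."""
    sitting = list(map(bool, sitting))
    valid = list(map(bool, valid))
    durations, transitions = [], 0
    run = 0
    for i, (s, v) in enumerate(zip(sitting, valid)):
        if s and v:
            run += 1
        else:
            if run:
                durations.append(run * epoch_s / 60.0)
                if v and not s:
                    transitions += 1
            run = 0
    if run:
        durations.append(run * epoch_s / 60.0)
    return durations, transitions
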