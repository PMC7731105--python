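"""Single-channel and channel-pair features per 8-s epoch.

Single-channel family (13 features x 8 channels = 104 columns):
band power and Gaussian differential entropy in the five classical bands
(delta 1-4, theta 4-8, alpha 8-13, beta 13-30, gamma 30-45 Hz), plus
approximate entropy, sample entropy (m = 2, r = 0.2 x SD) and Higuchi's
fractal dimension.

Channel-pair family (2 x 5 bands x 3 homologous pairs = 30 columns):
differential asymmetry  DASM = ln P_right - ln P_left  and rational
asymmetry  RASM = ln P_right / ln P_left  of band powers, for the pairs
(F3,F4), (F7,F8), (C3,C4).  Even-numbered electrodes sit over the right
hemisphere.

Quality-masked channels propagate NaN to every feature that touches
them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .recording import EpochSet

#: classical EEG bands, Hz (contiguous, ordered)
BANDS = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 45.0),
}

#: homologous (left, right) electrode pairs
PAIRS = (("F3", "F4"), ("F7", "F8"), ("C3", "C4"))


@dataclass(frozen=True)
class EntropyParams:
    """Template-matching entropy settings: m = 2, r = 0.2 x SD."""

    m: int = 2
    r_coef: float = 0.2

    def __post_init__(self):
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.r_coef <= 0:
            raise ValueError("r_coef must be > 0")


# ---------------------------------------------------------------------------
# spectral features

def welch_psd(x: np.ndarray, fs: float) -> tuple:
    """Welch PSD with 2-s Hann windows, 50% overlap (density scaling)."""
    nperseg = min(len(x), int(round(2 * fs)))
    return sps.welch(x, fs=fs, window="hann", nperseg=nperseg, noverlap=nperseg // 2)


def band_power(
    x: np.ndarray, fs: float, band: tuple, psd: tuple | None = None
) -> float:
    """Integral of the Welch PSD over ``band = (lo, hi)`` Hz.

    ``psd`` may carry a precomputed ``(freqs, density)`` pair so one
    Welch estimate serves all five bands.
    """
    lo, hi = band
    if hi > fs / 2.0:
        raise ValueError(f"band {band} exceeds Nyquist {fs / 2.0} Hz")
    f, p = welch_psd(x, fs) if psd is None else psd
    df = f[1] - f[0]
    sel = (f >= lo) & (f < hi) if hi < fs / 2.0 else (f >= lo) & (f <= hi)
    return float(p[sel].sum() * df)


def band_filter(x: np.ndarray, fs: float, band: tuple, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band-pass used by the differential entropy."""
    sos = sps.butter(order, band, btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x)


def differential_entropy(
    x: np.ndarray, fs: float, band: tuple, bandpassed: np.ndarray | None = None
) -> float:
    """Gaussian differential entropy of the band-limited epoch (nats).

    DE = 0.5 * ln(2 pi e sigma^2) with sigma^2 the variance of the
    band-filtered signal; zero variance gives the -inf sentinel (the
    feature is then treated as missing).
    """
    y = band_filter(x, fs, band) if bandpassed is None else bandpassed
    var = float(np.var(y))
    if var <= 0.0:
        return -np.inf
    return 0.5 * np.log(2.0 * np.pi * np.e * var)


# ---------------------------------------------------------------------------
# irregularity / complexity

def _abs_dist(x: np.ndarray) -> np.ndarray:
    """Pairwise |x_i - x_j|; shared between SampEn and ApEn."""
    return np.abs(x[:, None] - x[None, :])


def _cheby(d: np.ndarray, m: int, n_t: int) -> np.ndarray:
    """Chebyshev distance between length-m templates from the sample
    distance matrix ``d``, over the first n_t template positions."""
    dm = d[:n_t, :n_t].copy()
    for k in range(1, m):
        np.maximum(dm, d[k : k + n_t, k : k + n_t], out=dm)
    return dm


def sample_entropy(
    x: np.ndarray,
    params: EntropyParams = EntropyParams(),
    dist: np.ndarray | None = None,
) -> float:
    """Sample entropy: -ln(A/B), self-matches excluded.

    B and A count template pairs matching at lengths m and m+1 under
    Chebyshev distance <= r = r_coef * SD(x), both over the same N-m
    template start positions so the counts are comparable.  A = 0 (or
    B = 0) yields the NaN sentinel, treated as missing downstream.  A
    constant signal returns 0 (every template matches at both lengths).
    ``dist`` may carry a precomputed pairwise |x_i - x_j| matrix.
    """
    x = np.asarray(x, dtype=np.float64)
    if len(x) <= params.m + 1:
        raise ValueError(f"need more than m+1={params.m + 1} samples")
    r = params.r_coef * float(np.std(x))
    d = _abs_dist(x) if dist is None else dist
    n_t = len(x) - params.m
    dm = _cheby(d, params.m, n_t)
    match_b = dm <= r
    np.maximum(dm, d[params.m : params.m + n_t, params.m : params.m + n_t], out=dm)
    match_a = dm <= r
    np.fill_diagonal(match_b, False)
    np.fill_diagonal(match_a, False)
    b, a = int(match_b.sum()), int(match_a.sum())
    if a == 0 or b == 0:
        return np.nan
    return float(-np.log(a / b))


def approx_entropy(
    x: np.ndarray,
    params: EntropyParams = EntropyParams(),
    dist: np.ndarray | None = None,
) -> float:
    """Approximate entropy: Phi(m) - Phi(m+1), self-matches included.

    Phi(m) is the mean over the N-m+1 templates of ln(fraction of
    templates within r); self-matches guarantee every count is
    positive, so ApEn is always defined.  A constant signal returns
    exactly 0.
    """
    x = np.asarray(x, dtype=np.float64)
    if len(x) <= params.m + 1:
        raise ValueError(f"need more than m+1={params.m + 1} samples")
    r = params.r_coef * float(np.std(x))
    d = _abs_dist(x) if dist is None else dist

    def phi(m: int) -> float:
        n_t = len(x) - m + 1
        c = (_cheby(d, m, n_t) <= r).sum(axis=1) / n_t
        return float(np.mean(np.log(c)))

    return phi(params.m) - phi(params.m + 1)


def higuchi_fd(x: np.ndarray, kmax: int = 8) -> float:
    """Higuchi's fractal dimension via curve lengths at scales 1..kmax.

    Least-squares slope of ln L(k) against ln(1/k); a smooth curve gives
    values near 1, white noise near 2.  A constant signal has no defined
    dimension and returns NaN.
    """
    x = np.asarray(x, dtype=np.float64)
    n = len(x)
    if n <= kmax * 2:
        raise ValueError("signal too short for kmax")
    if np.ptp(x) == 0.0:
        return np.nan
    lk = np.empty(kmax)
    for k in range(1, kmax + 1):
        lengths = []
        for m0 in range(k):
            idx = np.arange(m0, n, k)
            if len(idx) < 2:
                continue
            dist = np.abs(np.diff(x[idx])).sum()
            norm = (n - 1) / ((len(idx) - 1) * k)
            lengths.append(dist * norm / k)
        lk[k - 1] = np.mean(lengths)
    k_arr = np.arange(1, kmax + 1)
    slope = np.polyfit(np.log(1.0 / k_arr), np.log(lk), 1)[0]
    return float(slope)


# ---------------------------------------------------------------------------
# asymmetry

def asym_differential(p_left: float, p_right: float) -> float:
    """DASM = ln P_right - ln P_left; NaN for nonpositive power."""
    if p_left <= 0.0 or p_right <= 0.0:
        return np.nan
    return float(np.log(p_right) - np.log(p_left))


def asym_rational(p_left: float, p_right: float, eps: float = 1e-12) -> float:
    """RASM = ln P_right / ln P_left; NaN when |ln P_left| < eps."""
    if p_left <= 0.0 or p_right <= 0.0:
        return np.nan
    log_l = np.log(p_left)
    if abs(log_l) < eps:
        return np.nan
    return float(np.log(p_right) / log_l)


# ---------------------------------------------------------------------------
# per-epoch assembly

def single_channel_names(channels: tuple) -> list:
    names = []
    for ch in channels:
        names += [f"{b}_power_{ch}" for b in BANDS]
        names += [f"{b}_de_{ch}" for b in BANDS]
        names += [f"apen_{ch}", f"sampen_{ch}", f"hfd_{ch}"]
    return names


def pair_names() -> list:
    return [
        f"{kind}_{b}_{left}{right}"
        for left, right in PAIRS
        for b in BANDS
        for kind in ("dasm", "rasm")
    ]


def extract_features(
    es: EpochSet,
    entropy_params: EntropyParams = EntropyParams(),
    kmax: int = 8,
) -> tuple:
    """Compute the single-channel and pair feature tables for an epoch set.

    Returns ``(single_df, pair_df)`` indexed by (subject, movie, epoch).
    Masked channel-epochs produce NaN in every feature involving that
    channel; nonfinite sentinel values are likewise stored as NaN.
    """
    n_ch = len(es.channels)
    single_cols = single_channel_names(es.channels)
    pair_cols = pair_names()
    single = np.full((es.n_epochs, len(single_cols)), np.nan)
    pair = np.full((es.n_epochs, len(pair_cols)), np.nan)

    for i in range(es.n_epochs):
        powers = {}
        col = 0
        for ci in range(n_ch):
            ch = es.channels[ci]
            if es.mask[i, ci]:
                col += 13
                continue
            x = es.epochs[i, ci]
            psd = welch_psd(x, es.fs)
            vals = []
            for b, rng in BANDS.items():
                p = band_power(x, es.fs, rng, psd=psd)
                powers[(ch, b)] = p
                vals.append(p)
            for b, rng in BANDS.items():
                vals.append(differential_entropy(x, es.fs, rng))
            dist = _abs_dist(x)
            vals.append(approx_entropy(x, entropy_params, dist=dist))
            vals.append(sample_entropy(x, entropy_params, dist=dist))
            vals.append(higuchi_fd(x, kmax))
            single[i, col : col + 13] = vals
            col += 13
        col = 0
        for left, right in PAIRS:
            for b in BANDS:
                pl = powers.get((left, b), np.nan)
                pr = powers.get((right, b), np.nan)
                if np.isfinite(pl) and np.isfinite(pr):
                    pair[i, col] = asym_differential(pl, pr)
                    pair[i, col + 1] = asym_rational(pl, pr)
                col += 2

    idx = pd.MultiIndex.from_frame(es.index[["subject", "movie", "epoch"]])
    single_df = pd.DataFrame(single, index=idx, columns=single_cols)
    pair_df = pd.DataFrame(pair, index=idx, columns=pair_cols)
    # -inf differential-entropy sentinels become missing values
    single_df = single_df.replace([np.inf, -np.inf], np.nan)
    return single_df, pair_df
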