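"""Synthetic movie-watching EEG sessions with known affective structure.

The study design this module emulates: a subject watches a series of
movie clips (each preceded by a 30-s neutral clip) while 8-channel
frontal/central EEG is recorded, and rates each clip on the 10-item
short PANAS afterwards.  No public recording exists, so the generator
produces sessions whose statistical structure carries the effects the
analysis is meant to detect:

* **valence** modulates frontal alpha asymmetry: per the
  approach/withdrawal model, positive clips shift the F4-F3 (and, at
  half strength, F8-F7) natural-log alpha-power difference by
  ``+asym_effect``, negative clips by ``-asym_effect`` (greater relative
  right-frontal activity, i.e. lower right alpha, for negative valence);
* **arousal** suppresses alpha and boosts beta by a factor
  ``1 + arousal_effect`` on every channel, and shifts the broadband
  noise fraction (signal irregularity) by ``complexity_effect`` so the
  entropy/complexity features carry arousal information;
* eye blinks and motion artifacts are injected with frontal spatial
  weighting (F7/F8 strongest), and channel-epochs can flatline, mimicking
  a dry-electrode headset losing scalp contact.

The signal model is deliberately simple: per channel, pink (1/f)
background noise plus five per-band oscillators with slowly jittering
instantaneous frequency, mixed according to a noise fraction.  It carries
band-power ratios, asymmetry and irregularity, which is all the
downstream feature families measure; it makes no attempt at forward-
modelled cortical sources.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as sps

from .recording import CHANNELS, Recording

# (centre frequency Hz, relative amplitude) of the per-band oscillators
BAND_OSCILLATORS = {
    "delta": (3.0, 1.0),
    "theta": (6.0, 0.8),
    "alpha": (10.0, 1.2),
    "beta": (20.0, 0.6),
    "gamma": (35.0, 0.35),
}

#: spatial weighting of ocular artifacts (blink templates)
BLINK_WEIGHTS = {
    "F7": 1.0, "F8": 1.0,
    "F3": 0.5, "F4": 0.5, "Fz": 0.45,
    "C3": 0.2, "C4": 0.2, "Cz": 0.2,
}

#: overall amplitude scale of the clean signal, microvolt-like units
BASE_SCALE = 10.0
BLINK_AMPLITUDE = 300.0
MOTION_AMPLITUDE = 400.0

#: lowest frequency carried by the pink background (Hz)
PINK_F_MIN = 1.0


@dataclass(frozen=True)
class AffectScenario:
    """One movie clip: its duration, true affect classes and effect sizes."""

    movie_id: str
    duration_s: float
    true_valence: str  # "positive" | "negative"
    true_arousal: str  # "low" | "high"
    asym_effect: float = 0.5
    complexity_effect: float = 0.3
    arousal_effect: float = 0.3

    def __post_init__(self):
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.true_valence not in ("positive", "negative"):
            raise ValueError(f"bad valence {self.true_valence!r}")
        if self.true_arousal not in ("low", "high"):
            raise ValueError(f"bad arousal {self.true_arousal!r}")
        for name in ("asym_effect", "complexity_effect", "arousal_effect"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


@dataclass(frozen=True)
class SynthConfig:
    """Session-level generator settings.

    ``blink_rate`` / ``motion_rate`` are events per minute;
    ``flatline_prob`` is the per-channel-epoch probability of a contact
    loss; ``panas_noise_sd`` is the standard deviation (in item-scale
    units) of the noise added to questionnaire items before rounding.
    """

    n_subjects: int = 20
    fs: float = 256.0
    channels: tuple = CHANNELS
    n_movies: int = 64
    neutral_s: float = 30.0
    blink_rate: float = 8.0
    motion_rate: float = 0.5
    flatline_prob: float = 0.005
    panas_noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.fs <= 90.0:
            raise ValueError(
                f"fs={self.fs} too low: the gamma band extends to 45 Hz, "
                "so fs must exceed 90 Hz"
            )
        if set(self.channels) != set(CHANNELS):
            raise ValueError(f"channels must be exactly {set(CHANNELS)}")
        for name in ("blink_rate", "motion_rate", "flatline_prob", "panas_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class GroundTruth:
    """Per-(subject, movie) true classes plus the artifact event log."""

    subject_id: str
    movies: pd.DataFrame  # movie_id, true_valence, true_arousal
    events: list = field(default_factory=list)


def make_scenarios(
    n_movies: int,
    seed: int = 0,
    duration_range: tuple = (90.0, 120.0),
    asym_effect: float = 0.5,
    complexity_effect: float = 0.3,
    arousal_effect: float = 0.3,
) -> list:
    """Build a balanced set of scenarios (2x2 affect classes cycled)."""
    rng = np.random.default_rng(seed)
    cells = [("positive", "low"), ("positive", "high"),
             ("negative", "low"), ("negative", "high")]
    out = []
    for i in range(n_movies):
        v, a = cells[i % 4]
        out.append(
            AffectScenario(
                movie_id=f"M{i:03d}",
                duration_s=float(rng.uniform(*duration_range)),
                true_valence=v,
                true_arousal=a,
                asym_effect=asym_effect,
                complexity_effect=complexity_effect,
                arousal_effect=arousal_effect,
            )
        )
    return out


# ---------------------------------------------------------------------------
# signal model

def _pink_noise(rng: np.random.Generator, n: int, fs: float) -> np.ndarray:
    """Unit-variance 1/f (power) noise, flat below PINK_F_MIN cut-off."""
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    amp = np.zeros_like(freqs)
    nz = freqs >= PINK_F_MIN
    amp[nz] = freqs[nz] ** -0.5
    spec = amp * (rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs)))
    x = np.fft.irfft(spec, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _oscillator(rng: np.random.Generator, n: int, fs: float, f0: float,
                jitter: float = 0.05) -> np.ndarray:
    """Unit-amplitude sinusoid with slowly wandering instantaneous frequency."""
    # AR(1)-smoothed frequency modulation, ~2% stationary sd at jitter=0.05
    e = rng.standard_normal(n)
    z = sps.lfilter([np.sqrt(1 - 0.99 ** 2)], [1.0, -0.99], e)
    f_inst = f0 * (1.0 + jitter * z)
    phase = 2.0 * np.pi * np.cumsum(f_inst) / fs + rng.uniform(0, 2 * np.pi)
    return np.sin(phase)


def _band_amplitudes(scenario: AffectScenario | None, channel: str) -> dict:
    """Effective per-band oscillator amplitudes for one channel.

    ``scenario=None`` means a neutral segment (no affect modulation).
    """
    amps = {b: a for b, (_, a) in BAND_OSCILLATORS.items()}
    if scenario is None:
        return amps
    v = 1.0 if scenario.true_valence == "positive" else -1.0
    a_high = scenario.true_arousal == "high"
    # frontal alpha asymmetry: ln-power shift of +-asym_effect on (F3,F4),
    # half strength on (F7,F8); power ratio e^shift -> amplitude e^(shift/2)
    if channel == "F4":
        amps["alpha"] *= np.exp(+v * scenario.asym_effect / 4.0)
    elif channel == "F3":
        amps["alpha"] *= np.exp(-v * scenario.asym_effect / 4.0)
    elif channel == "F8":
        amps["alpha"] *= np.exp(+v * scenario.asym_effect / 8.0)
    elif channel == "F7":
        amps["alpha"] *= np.exp(-v * scenario.asym_effect / 8.0)
    if a_high:
        amps["alpha"] /= 1.0 + scenario.arousal_effect
        amps["beta"] *= 1.0 + scenario.arousal_effect
    return amps


def _noise_fraction(scenario: AffectScenario | None) -> float:
    """Fraction of signal power carried by broadband noise."""
    if scenario is None:
        return 0.5
    s = 1.0 if scenario.true_arousal == "high" else -1.0
    return float(np.clip(0.5 + 0.5 * scenario.complexity_effect * s, 0.05, 0.95))


def _segment(rng: np.random.Generator, n: int, fs: float,
             scenario: AffectScenario | None, channel: str) -> np.ndarray:
    amps = _band_amplitudes(scenario, channel)
    nf = _noise_fraction(scenario)
    osc = np.zeros(n)
    for band, (f0, _) in BAND_OSCILLATORS.items():
        osc += amps[band] * _oscillator(rng, n, fs, f0)
    osc_norm = np.sqrt(sum(a ** 2 for a in amps.values()) / 2.0)
    x = np.sqrt(1.0 - nf) * osc / osc_norm + np.sqrt(nf) * _pink_noise(rng, n, fs)
    return BASE_SCALE * x


def expected_band_power(scenario: AffectScenario | None, channel: str,
                        band_hz: tuple, fs: float) -> float:
    """Model-implied power (units^2) in ``band_hz`` for artifact-free data.

    Serves as the generator's own account of its spectrum: oscillator
    share ``(1-nf) * A_b^2/2 / sum(A^2/2)`` plus the pink background's
    logarithmic band share.  Independent Welch estimates on generated
    epochs should agree with this to within ~10%.
    """
    amps = _band_amplitudes(scenario, channel)
    nf = _noise_fraction(scenario)
    total = BASE_SCALE ** 2
    osc_norm = sum(a ** 2 for a in amps.values()) / 2.0
    lo, hi = band_hz
    osc_power = 0.0
    for b, (f0, _) in BAND_OSCILLATORS.items():
        if lo <= f0 < hi:
            osc_power += (amps[b] ** 2 / 2.0) / osc_norm
    # pink spectrum ~ 1/f on [PINK_F_MIN, fs/2], unit total variance
    lo_eff = max(lo, PINK_F_MIN)
    hi_eff = min(hi, fs / 2.0)
    pink_share = (
        np.log(hi_eff / lo_eff) / np.log((fs / 2.0) / PINK_F_MIN)
        if hi_eff > lo_eff
        else 0.0
    )
    return total * ((1.0 - nf) * osc_power + nf * pink_share)


# ---------------------------------------------------------------------------
# session assembly

def generate_session(
    config: SynthConfig,
    scenarios: list,
    subject: int | str = 0,
    with_artifacts: bool = True,
) -> tuple:
    """Generate one subject's session: ``(Recording, GroundTruth)``.

    Each scenario contributes a neutral lead-in of ``config.neutral_s``
    seconds followed by the movie segment; only movie segments get
    timeline markers.  All randomness derives from ``(config.seed,
    subject index)``, so identical inputs give bit-identical output.
    """
    if not scenarios:
        raise ValueError("scenarios must be non-empty")
    ids = [s.movie_id for s in scenarios]
    if len(set(ids)) != len(ids):
        raise ValueError("movie_id must be unique within a session")
    sub_idx = int(subject) if not isinstance(subject, str) else abs(hash(subject)) % (2 ** 31)
    subject_id = subject if isinstance(subject, str) else f"S{sub_idx:02d}"
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, sub_idx, 11]))

    fs = config.fs
    pieces = []
    rows = []
    cursor = 0
    for sc in scenarios:
        n_neutral = int(round(config.neutral_s * fs))
        n_movie = int(round(sc.duration_s * fs))
        neutral = np.stack(
            [_segment(rng, n_neutral, fs, None, ch) for ch in config.channels]
        ) if n_neutral else np.empty((len(config.channels), 0))
        movie = np.stack(
            [_segment(rng, n_movie, fs, sc, ch) for ch in config.channels]
        )
        pieces += [neutral, movie]
        start = cursor + n_neutral
        rows.append({"movie_id": sc.movie_id, "start": start, "stop": start + n_movie})
        cursor = start + n_movie
    data = np.concatenate(pieces, axis=1)
    rec = Recording(
        subject_id=subject_id,
        data=data,
        fs=fs,
        channels=tuple(config.channels),
        markers=pd.DataFrame(rows),
    )
    truth = GroundTruth(
        subject_id=subject_id,
        movies=pd.DataFrame(
            {
                "movie_id": ids,
                "true_valence": [s.true_valence for s in scenarios],
                "true_arousal": [s.true_arousal for s in scenarios],
            }
        ),
    )
    if with_artifacts:
        rec = inject_artifacts(
            rec, config, truth,
            rng=np.random.default_rng(np.random.SeedSequence([config.seed, sub_idx, 13])),
        )
    return rec, truth


def inject_artifacts(
    rec: Recording,
    config: SynthConfig,
    truth: GroundTruth,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> Recording:
    """Add blinks, motion drifts and flatlines; log every event in ``truth``.

    Blinks are short (<=0.5 s) low-frequency Gaussian bumps with frontal
    spatial weighting F7/F8 > F3/F4 > central; motion events add a large
    smooth drift on all channels; flatline events replace one channel's
    samples with a constant for a whole 8-s epoch span.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    data = rec.data.copy()
    fs = rec.fs
    n = data.shape[1]
    minutes = n / fs / 60.0

    # --- blinks: Poisson count over the session, uniform positions
    n_blinks = rng.poisson(config.blink_rate * minutes)
    blink_half = int(round(0.2 * fs))  # full template 0.4 s < 0.5 s
    tt = np.arange(-blink_half, blink_half + 1) / fs
    template = np.exp(-(tt ** 2) / (2 * 0.07 ** 2))
    for _ in range(n_blinks):
        c = rng.integers(blink_half, n - blink_half - 1)
        amp = BLINK_AMPLITUDE * rng.uniform(0.7, 1.3)
        for ci, ch in enumerate(rec.channels):
            data[ci, c - blink_half : c + blink_half + 1] += (
                amp * BLINK_WEIGHTS[ch] * template
            )
        truth.events.append(
            {"type": "blink", "channel": None,
             "start": int(c - blink_half), "duration_s": len(tt) / fs}
        )

    # --- motion: smooth large drift on all channels
    n_motion = rng.poisson(config.motion_rate * minutes)
    for _ in range(n_motion):
        dur = int(round(rng.uniform(1.0, 3.0) * fs))
        c = rng.integers(0, max(1, n - dur))
        t = np.linspace(0, np.pi, dur)
        drift = np.sin(t) ** 2
        amp = MOTION_AMPLITUDE * rng.uniform(0.7, 1.3)
        per_ch = amp * rng.uniform(0.6, 1.0, size=data.shape[0])
        signs = rng.choice([-1.0, 1.0], size=data.shape[0])
        data[:, c : c + dur] += (per_ch * signs)[:, None] * drift[None, :]
        truth.events.append(
            {"type": "motion", "channel": None, "start": int(c),
             "duration_s": dur / fs}
        )

    # --- flatlines: per channel-epoch Bernoulli over movie segments
    epoch_len = int(round(8.0 * fs))
    for _, m in rec.markers.iterrows():
        n_ep = int((m["stop"] - m["start"]) // epoch_len)
        for e in range(n_ep):
            for ci, ch in enumerate(rec.channels):
                if rng.random() < config.flatline_prob:
                    a = int(m["start"] + e * epoch_len)
                    seg = data[ci, a : a + epoch_len]
                    data[ci, a : a + epoch_len] = seg.mean()
                    truth.events.append(
                        {"type": "flatline", "channel": ch, "start": a,
                         "duration_s": 8.0, "movie_id": m["movie_id"], "epoch": e}
                    )
    return replace(rec, data=data, markers=rec.markers)


# ---------------------------------------------------------------------------
# questionnaire responses

POSITIVE_ITEMS = ("alert", "inspired", "determined", "attentive", "active")
NEGATIVE_ITEMS = ("upset", "hostile", "nervous", "ashamed", "afraid")
PANAS_ITEMS = POSITIVE_ITEMS + NEGATIVE_ITEMS


def panas_base_items(valence: str | None, arousal: str | None) -> dict:
    """Noise-free item map from true affect classes.

    Neutral (``None``) classes contribute nothing, leaving every item at
    the scale midpoint 3.  Positive valence raises positive-affect items
    by 1 and lowers negative-affect items by 1 (vice versa for negative);
    high arousal raises *all* items by 0.5, low arousal lowers them by
    0.5.  With zero noise this map is exactly recovered by the published
    scoring rules: valence score +-10, arousal score 40 (high) / 30 (low,
    on the low side of the midline threshold).
    """
    v = 0.0 if valence is None else (1.0 if valence == "positive" else -1.0)
    a = 0.0 if arousal is None else (0.5 if arousal == "high" else -0.5)
    out = {}
    for item in POSITIVE_ITEMS:
        out[item] = 3.0 + v + a
    for item in NEGATIVE_ITEMS:
        out[item] = 3.0 - v + a
    return out


def generate_panas(
    true_valence: str | None,
    true_arousal: str | None,
    noise_sd: float,
    rng: np.random.Generator | int | None = None,
) -> dict:
    """Draw one 10-item s-PANAS response tied to the true affect classes.

    Each item is the base map plus Gaussian noise, rounded half-up to an
    integer and clipped to the 1..5 scale.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    base = panas_base_items(true_valence, true_arousal)
    out = {}
    for item, b in base.items():
        x = b + (noise_sd * rng.standard_normal() if noise_sd > 0 else 0.0)
        out[item] = int(np.clip(np.floor(x + 0.5), 1, 5))
    return out


def generate_session_panas(
    config: SynthConfig, truth: GroundTruth, subject: int = 0
) -> pd.DataFrame:
    """All of one subject's questionnaire responses, one row per movie."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, int(subject), 17]))
    rows = []
    for _, m in truth.movies.iterrows():
        resp = generate_panas(
            m["true_valence"], m["true_arousal"], config.panas_noise_sd, rng
        )
        rows.append({"subject": truth.subject_id, "movie": m["movie_id"], **resp})
    return pd.DataFrame(rows)


def generate_rater_scores(
    scenarios: list, n_raters: int = 13, noise_sd: float = 1.0, seed: int = 0
) -> pd.DataFrame:
    """Per-movie mean questionnaire responses of independent raters.

    Emulates a separate rating panel scoring the *perceived* affect of
    each clip: each rater answers the same item map with independent
    noise and the per-movie item means are returned.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 19]))
    rows = []
    for sc in scenarios:
        acc = {item: 0.0 for item in PANAS_ITEMS}
        for _ in range(n_raters):
            resp = generate_panas(sc.true_valence, sc.true_arousal, noise_sd, rng)
            for item in PANAS_ITEMS:
                acc[item] += resp[item]
        rows.append(
            {"movie": sc.movie_id, **{k: v / n_raters for k, v in acc.items()}}
        )
    return pd.DataFrame(rows)
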