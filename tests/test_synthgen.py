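"""Generator contracts: determinism, encoded affect structure, artifact
injection statistics and questionnaire response behaviour."""

import numpy as np
import pytest
from scipy import signal as sps
from scipy import stats

from affecteeg import synthgen as sg
from affecteeg.quality import QualityThresholds, score_epochset
from conftest import zeros_recording


def welch_alpha_power(x, fs):
    f, p = sps.welch(x, fs=fs, nperseg=int(2 * fs))
    df = f[1] - f[0]
    return p[(f >= 8) & (f < 13)].sum() * df


class TestGenerateSession:
    def test_deterministic(self, small_session):
        cfg, scen, rec, _ = small_session
        rec2, _ = sg.generate_session(cfg, scen, subject=0)
        assert np.array_equal(rec.data, rec2.data)
        assert rec.markers.equals(rec2.markers)

    def test_session_layout(self, small_session):
        cfg, scen, rec, truth = small_session
        assert len(rec.markers) == len(scen)
        for (_, m), s in zip(rec.markers.iterrows(), scen):
            assert m["stop"] - m["start"] == int(round(s.duration_s * cfg.fs))
        assert len(truth.movies) == len(scen)

    def test_fs_too_low_rejected(self):
        with pytest.raises(ValueError, match="gamma"):
            sg.SynthConfig(fs=80.0)

    def test_asymmetry_sign_separates_valence_groups(self):
        """With asym_effect=1, mean F4-F3 ln-alpha difference has opposite
        sign for positive vs negative movies (Welch-PSD oracle)."""
        cfg = sg.SynthConfig(fs=128.0, n_movies=40, neutral_s=0.5, seed=21,
                             blink_rate=0, motion_rate=0, flatline_prob=0)
        scen = []
        for i in range(40):
            scen.append(sg.AffectScenario(
                movie_id=f"M{i:03d}", duration_s=16.0,
                true_valence="positive" if i < 20 else "negative",
                true_arousal="low", asym_effect=1.0))
        rec, _ = sg.generate_session(cfg, scen, subject=0)
        i3, i4 = rec.channel_index("F3"), rec.channel_index("F4")
        diffs = {"positive": [], "negative": []}
        for (_, m), s in zip(rec.markers.iterrows(), scen):
            seg = rec.data[:, int(m["start"]):int(m["stop"])]
            d = np.log(welch_alpha_power(seg[i4], cfg.fs)) - np.log(
                welch_alpha_power(seg[i3], cfg.fs))
            diffs[s.true_valence].append(d)
        assert np.mean(diffs["positive"]) > 0 > np.mean(diffs["negative"])

    def test_effect_monotonicity(self):
        """Larger asym_effect gives larger positive-vs-negative separation."""
        seps = []
        for eff in (0.5, 2.0):
            cfg = sg.SynthConfig(fs=128.0, n_movies=20, neutral_s=0.5, seed=5,
                                 blink_rate=0, motion_rate=0, flatline_prob=0)
            scen = [sg.AffectScenario(
                movie_id=f"M{i:03d}", duration_s=16.0,
                true_valence="positive" if i % 2 == 0 else "negative",
                true_arousal="low", asym_effect=eff) for i in range(20)]
            rec, _ = sg.generate_session(cfg, scen, subject=0)
            i3, i4 = rec.channel_index("F3"), rec.channel_index("F4")
            pos, neg = [], []
            for (_, m), s in zip(rec.markers.iterrows(), scen):
                seg = rec.data[:, int(m["start"]):int(m["stop"])]
                d = np.log(welch_alpha_power(seg[i4], cfg.fs)) - np.log(
                    welch_alpha_power(seg[i3], cfg.fs))
                (pos if s.true_valence == "positive" else neg).append(d)
            seps.append(np.mean(pos) - np.mean(neg))
        assert seps[1] > seps[0]

    def test_spectral_fidelity(self, small_session):
        """Welch band power on generated movie epochs matches the model's
        own expected band power within 10%."""
        cfg, scen, rec, _ = small_session
        s0 = scen[0]
        m = rec.markers.iloc[0]
        seg = rec.data[:, int(m["start"]):int(m["stop"])]
        for band in ((4.0, 8.0), (8.0, 13.0), (13.0, 30.0)):
            for ch in ("Cz", "F4"):
                ci = rec.channel_index(ch)
                f, p = sps.welch(seg[ci], fs=cfg.fs, nperseg=int(4 * cfg.fs))
                df = f[1] - f[0]
                est = p[(f >= band[0]) & (f < band[1])].sum() * df
                exp = sg.expected_band_power(s0, ch, band, cfg.fs)
                assert est == pytest.approx(exp, rel=0.10)

    def test_clean_session_has_no_certain_bad_epochs(self, small_epochs):
        scores = score_epochset(small_epochs, QualityThresholds())
        assert (scores["score"] == 1.0).sum() == 0


class TestInjectArtifacts:
    def test_blink_spatial_ratio(self):
        rec = zeros_recording(seconds=120.0)
        cfg = sg.SynthConfig(fs=rec.fs, blink_rate=4.0, motion_rate=0.0,
                             flatline_prob=0.0, seed=3)
        truth = sg.GroundTruth("S00", rec.markers.assign(
            true_valence="positive", true_arousal="low"))
        out = sg.inject_artifacts(rec, cfg, truth, seed=3)
        blinks = [e for e in truth.events if e["type"] == "blink"]
        assert blinks
        i7, ic3 = rec.channel_index("F7"), rec.channel_index("C3")
        peak7 = np.max(np.abs(out.data[i7]))
        peak3 = np.max(np.abs(out.data[ic3]))
        expected_ratio = sg.BLINK_WEIGHTS["F7"] / sg.BLINK_WEIGHTS["C3"]
        assert peak7 / peak3 == pytest.approx(expected_ratio, rel=1e-9)

    def test_flatline_kills_variance(self):
        cfg = sg.SynthConfig(fs=128.0, n_movies=1, neutral_s=1.0, seed=9,
                             blink_rate=0, motion_rate=0, flatline_prob=0.2)
        scen = sg.make_scenarios(1, seed=0, duration_range=(40.0, 41.0))
        rec, truth = sg.generate_session(cfg, scen, subject=0)
        flats = [e for e in truth.events if e["type"] == "flatline"]
        assert flats
        session_var = rec.data.var(axis=1)
        epoch_len = int(8 * cfg.fs)
        for e in flats:
            ci = rec.channel_index(e["channel"])
            seg = rec.data[ci, e["start"]: e["start"] + epoch_len]
            assert seg.var() < 1e-12 * session_var[ci]

    def test_blink_count_poisson(self):
        """Total blink count over 200 seeds falls in the 99% interval of
        the summed Poisson law."""
        rec = zeros_recording(seconds=60.0)
        lam_one = 8.0 * 1.0  # rate * minutes
        total = 0
        for seed in range(200):
            cfg = sg.SynthConfig(fs=rec.fs, blink_rate=8.0, motion_rate=0.0,
                                 flatline_prob=0.0, seed=seed)
            truth = sg.GroundTruth("S00", rec.markers.assign(
                true_valence="positive", true_arousal="low"))
            sg.inject_artifacts(rec, cfg, truth, seed=seed)
            total += sum(e["type"] == "blink" for e in truth.events)
        lo, hi = stats.poisson.interval(0.99, 200 * lam_one)
        assert lo <= total <= hi


class TestGeneratePanas:
    def test_neutral_base_scores_thirty(self):
        resp = sg.generate_panas(None, None, noise_sd=0.0)
        assert sum(resp.values()) == 30
        assert all(v == 3 for v in resp.values())

    def test_extreme_valence_bounds(self):
        # noise-free extremes reached through the scoring formulas
        from affecteeg.assembly import score_valence
        items = {i: 5 for i in sg.POSITIVE_ITEMS} | {i: 1 for i in sg.NEGATIVE_ITEMS}
        assert score_valence(items) == 20

    def test_items_in_range_and_deterministic(self):
        r1 = sg.generate_panas("positive", "high", 1.0, rng=42)
        r2 = sg.generate_panas("positive", "high", 1.0, rng=42)
        assert r1 == r2
        assert all(1 <= v <= 5 for v in r1.values())

    def test_noise_free_classes_recoverable(self):
        from affecteeg.assembly import binarize, score_arousal, score_valence
        for v in ("positive", "negative"):
            for a in ("low", "high"):
                resp = sg.generate_panas(v, a, noise_sd=0.0)
                vc, ac = binarize(score_valence(resp), score_arousal(resp))
                assert (vc, ac) == (v, a)

    def test_marginal_means_match_clipped_expectation(self):
        """Monte-Carlo check of the rounded/clipped noise model."""
        noise_sd = 0.5
        base = 3.0  # neutral item
        # exact expectation of clip(floor(base + eps + .5), 1, 5)
        exact = 0.0
        var = 0.0
        for k in range(1, 6):
            if k == 1:
                p = stats.norm.cdf(1.5 - base, scale=noise_sd)
            elif k == 5:
                p = 1 - stats.norm.cdf(4.5 - base, scale=noise_sd)
            else:
                p = (stats.norm.cdf(k + 0.5 - base, scale=noise_sd)
                     - stats.norm.cdf(k - 0.5 - base, scale=noise_sd))
            exact += k * p
            var += k * k * p
        var -= exact ** 2
        rng = np.random.default_rng(77)
        draws = [sg.generate_panas(None, None, noise_sd, rng)["alert"]
                 for _ in range(1000)]
        se = np.sqrt(var / 1000)
        assert abs(np.mean(draws) - exact) < 3 * se


def test_rater_scores_shape_and_range():
    scen = sg.make_scenarios(6, seed=1)
    df = sg.generate_rater_scores(scen, n_raters=5, noise_sd=1.0, seed=2)
    assert len(df) == 6
    for item in sg.PANAS_ITEMS:
        assert df[item].between(1, 5).all()
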