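"""End-to-end orchestration: synth -> preprocess -> quality -> features
-> assembly -> reduction -> models, with one config, persisted stage
outputs and a manifest of seeds and row counts.

Every stage writes its outputs under the run directory and can be
re-run individually; ``resume=True`` skips stages whose outputs already
exist.  A single global seed fans out to per-stage seeds by a
documented derivation (CRC32 of the stage name folded into the seed),
so each stage is independently reproducible.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assembly, features, multiscale, preprocess, quality, synthgen
from .model import CVConfig, comparison_matrix, run_combined, run_cv
from .recording import read_recording, write_recording
from .reduce import reduce_features

log = logging.getLogger("affecteeg")

FAMILIES = ("single", "pair", "mse")
TARGETS = ("arousal", "valence")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    return (int(global_seed) * 1000003 + zlib.crc32(stage.encode())) % (2 ** 31)


@dataclass
class PipelineConfig:
    """Everything the pipeline needs, serializable to/from YAML."""

    seed: int = 0
    n_subjects: int = 2
    n_movies: int = 8
    fs: float = 256.0
    neutral_s: float = 30.0
    duration_range: tuple = (90.0, 120.0)
    asym_effect: float = 0.5
    complexity_effect: float = 0.3
    arousal_effect: float = 0.3
    blink_rate: float = 8.0
    motion_rate: float = 0.5
    flatline_prob: float = 0.005
    panas_noise_sd: float = 1.0
    label_source: str = "subjective"  # "subjective" | "rater"
    n_raters: int = 13
    rater_noise_sd: float = 1.0
    # feature stage
    kmax: int = 8
    mse_scales: int = 6
    memd_dirs: int = 64
    # reduction
    var_target: float = 0.95
    loading_r: float = 0.7
    corr_cutoff: float = 0.95
    # models
    cv_k: int = 5
    n_top: int = 10
    n_trees: int = 100

    def synth_config(self) -> synthgen.SynthConfig:
        return synthgen.SynthConfig(
            n_subjects=self.n_subjects,
            fs=self.fs,
            n_movies=self.n_movies,
            neutral_s=self.neutral_s,
            blink_rate=self.blink_rate,
            motion_rate=self.motion_rate,
            flatline_prob=self.flatline_prob,
            panas_noise_sd=self.panas_noise_sd,
            seed=stage_seed(self.seed, "synth"),
        )

    def scenarios(self) -> list:
        return synthgen.make_scenarios(
            self.n_movies,
            seed=stage_seed(self.seed, "scenarios"),
            duration_range=tuple(self.duration_range),
            asym_effect=self.asym_effect,
            complexity_effect=self.complexity_effect,
            arousal_effect=self.arousal_effect,
        )

    def cv_config(self) -> CVConfig:
        return CVConfig(
            k=self.cv_k, n_top=self.n_top, n_trees=self.n_trees,
            seed=stage_seed(self.seed, "cv"),
        )

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        cfg = cls(**raw)
        if isinstance(cfg.duration_range, list):
            cfg.duration_range = tuple(cfg.duration_range)
        return cfg


# ---------------------------------------------------------------------------
# stages

def _subject_ids(cfg: PipelineConfig) -> list:
    return [f"S{i:02d}" for i in range(cfg.n_subjects)]


def stage_synth(cfg: PipelineConfig, run: Path) -> None:
    out = run / "synth"
    out.mkdir(parents=True, exist_ok=True)
    sc = cfg.synth_config()
    scenarios = cfg.scenarios()
    panas_all, truth_all = [], []
    for i in range(cfg.n_subjects):
        rec, truth = synthgen.generate_session(sc, scenarios, subject=i)
        write_recording(out / f"{rec.subject_id}.h5", rec)
        panas_all.append(synthgen.generate_session_panas(sc, truth, subject=i))
        t = truth.movies.copy()
        t.insert(0, "subject", truth.subject_id)
        truth_all.append(t)
        log.info("synth: subject %s, %d movies, %d events",
                 rec.subject_id, len(truth.movies), len(truth.events))
    pd.concat(panas_all).to_csv(out / "panas.csv", index=False)
    pd.concat(truth_all).to_csv(out / "truth.csv", index=False)
    raters = synthgen.generate_rater_scores(
        scenarios, n_raters=cfg.n_raters, noise_sd=cfg.rater_noise_sd,
        seed=stage_seed(cfg.seed, "raters"),
    )
    raters.to_csv(out / "rater_scores.csv", index=False)


def stage_preprocess(cfg: PipelineConfig, run: Path) -> None:
    out = run / "preprocess"
    out.mkdir(parents=True, exist_ok=True)
    for sid in _subject_ids(cfg):
        rec = read_recording(run / "synth" / f"{sid}.h5")
        filt = preprocess.filter_recording(rec)
        es = preprocess.build_epochset(filt)
        from .recording import write_epochset
        write_epochset(out / f"{sid}_epochs.h5", es)
        log.info("preprocess: %s -> %d epochs", sid, es.n_epochs)


def stage_features(cfg: PipelineConfig, run: Path) -> None:
    """Quality scoring + masking + all three feature families."""
    from .recording import read_epochset, write_epochset
    outq = run / "quality"
    outf = run / "features"
    outq.mkdir(parents=True, exist_ok=True)
    outf.mkdir(parents=True, exist_ok=True)
    scores_all, single_all, pair_all, mse_all, badcount_all = [], [], [], [], []
    for sid in _subject_ids(cfg):
        es = read_epochset(run / "preprocess" / f"{sid}_epochs.h5")
        # score quality on the unfiltered epochs: zero-phase filtering
        # smears flatlines/clipping, masking them from the detector
        raw = preprocess.build_epochset(read_recording(run / "synth" / f"{sid}.h5"))
        scores = quality.score_epochset(raw)
        es = quality.apply_quality(es, scores)
        write_epochset(run / "quality" / f"{sid}_epochs.h5", es)
        scores_all.append(scores)
        single, pair = features.extract_features(es, kmax=cfg.kmax)
        mse = multiscale.mse_table(es, n_scales=cfg.mse_scales, n_dirs=cfg.memd_dirs)
        single_all.append(single)
        pair_all.append(pair)
        mse_all.append(mse)
        badcount_all.append(
            pd.Series(es.mask.sum(axis=1), index=single.index, name="bad_channels")
        )
        log.info("features: %s, %d certain-bad channel-epochs",
                 sid, int(es.mask.sum()))
    pd.concat(scores_all).to_csv(outq / "scores.csv", index=False)
    for name, tables in (("single", single_all), ("pair", pair_all), ("mse", mse_all)):
        pd.concat(tables).to_csv(outf / f"{name}.csv")
    pd.concat(badcount_all).to_csv(outf / "bad_channels.csv")


def _read_family(run: Path, name: str) -> pd.DataFrame:
    df = pd.read_csv(run / "features" / f"{name}.csv")
    return df.set_index(["subject", "movie", "epoch"])


def stage_assemble(cfg: PipelineConfig, run: Path) -> None:
    out = run / "assemble"
    out.mkdir(parents=True, exist_ok=True)
    if cfg.label_source == "subjective":
        responses = pd.read_csv(run / "synth" / "panas.csv")
        labels = assembly.labels_from_panas(responses)
    elif cfg.label_source == "rater":
        raters = pd.read_csv(run / "synth" / "rater_scores.csv")
        labels = assembly.labels_from_raters(raters, _subject_ids(cfg))
    else:
        raise ValueError(f"unknown label_source {cfg.label_source!r}")
    labels.to_csv(out / "labels.csv", index=False)
    bad = pd.read_csv(run / "features" / "bad_channels.csv").set_index(
        ["subject", "movie", "epoch"]
    )["bad_channels"]
    stats_all = {}
    for fam in FAMILIES:
        feats = _read_family(run, fam)
        n_chan = 5 if fam == "mse" else 8
        pooled, dropped_movies, stats = assembly.assemble_family(
            feats, bad, labels, n_channels=n_chan
        )
        pooled.to_csv(out / f"pooled_{fam}.csv")
        stats["dropped_movies"] = [list(t) for t in dropped_movies]
        stats_all[fam] = stats
        log.info("assemble[%s]: %d/%d rows survive", fam,
                 stats["surviving_rows"], stats["raw_rows"])
    (out / "stats.json").write_text(json.dumps(stats_all, indent=2))


def stage_reduce(cfg: PipelineConfig, run: Path) -> None:
    out = run / "reduce"
    out.mkdir(parents=True, exist_ok=True)
    retained = {}
    for fam in FAMILIES:
        pooled = pd.read_csv(run / "assemble" / f"pooled_{fam}.csv").set_index(
            ["subject", "movie", "epoch"]
        )
        X, _ = assembly.split_features_labels(pooled)
        rep = reduce_features(
            X, var_target=cfg.var_target, loading_r=cfg.loading_r,
            corr_cutoff=cfg.corr_cutoff,
        )
        retained[fam] = rep.retained
        log.info("reduce[%s]: %d -> %d features (%d components)",
                 fam, X.shape[1], len(rep.retained), rep.n_components)
    (out / "retained.json").write_text(json.dumps(retained, indent=2))


def stage_train(cfg: PipelineConfig, run: Path) -> dict:
    out = run / "train"
    out.mkdir(parents=True, exist_ok=True)
    retained = json.loads((run / "reduce" / "retained.json").read_text())
    cv = cfg.cv_config()
    # align families on common row keys for the combined model
    tables, labels = {}, {}
    for fam in FAMILIES:
        pooled = pd.read_csv(run / "assemble" / f"pooled_{fam}.csv").set_index(
            ["subject", "movie", "epoch"]
        )
        X, lab = assembly.split_features_labels(pooled)
        tables[fam] = X[retained[fam]]
        labels[fam] = lab
    common = tables[FAMILIES[0]].index
    for fam in FAMILIES[1:]:
        common = common.intersection(tables[fam].index)
    common = common.sort_values()
    tables = {f: t.loc[common] for f, t in tables.items()}
    lab = labels[FAMILIES[0]].loc[common]

    reports = []
    for target in TARGETS:
        y = lab[f"{target}_class"].to_numpy()
        fam_reports = []
        for fam in FAMILIES:
            fam_reports.append(run_cv(tables[fam], y, target, fam, cv))
        fam_reports.append(run_combined(tables, y, target, cv))
        comparison_matrix(fam_reports).to_csv(out / f"comparisons_{target}.csv")
        reports += fam_reports
    (out / "reports.json").write_text(
        json.dumps([r.to_dict() for r in reports], indent=2)
    )
    for r in reports:
        log.info("model[%s/%s]: mean F1 %.3f  CI %s",
                 r.target, r.family, r.mean_f1,
                 np.round(r.ci95, 3).tolist())
    return {(r.target, r.family): r for r in reports}


STAGES = (
    ("synth", stage_synth, "synth/truth.csv"),
    ("preprocess", stage_preprocess, "preprocess"),
    ("features", stage_features, "features/single.csv"),
    ("assemble", stage_assemble, "assemble/stats.json"),
    ("reduce", stage_reduce, "reduce/retained.json"),
    ("train", stage_train, "train/reports.json"),
)


def run_pipeline(cfg: PipelineConfig, run_dir, resume: bool = False) -> dict:
    """Run all stages in order; returns {(target, family): ModelReport}.

    With ``resume=True``, stages whose sentinel output exists are
    skipped and only downstream stages are regenerated.  Writes
    ``manifest.json`` with the config, per-stage seeds and the epoch
    accounting (raw = surviving + quality-dropped + imputation-dropped
    per family).
    """
    run = Path(run_dir)
    run.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(run / "config.yaml")
    result = None
    for name, fn, sentinel in STAGES:
        if resume and (run / sentinel).exists() and name != "train":
            log.info("resume: skipping stage %s", name)
            continue
        try:
            out = fn(cfg, run)
        except Exception as e:
            raise RuntimeError(f"pipeline stage {name!r} failed: {e}") from e
        if name == "train":
            result = out
    stats = json.loads((run / "assemble" / "stats.json").read_text())
    manifest = {
        "seed": cfg.seed,
        "stage_seeds": {s[0]: stage_seed(cfg.seed, s[0]) for s in STAGES},
        "family_stats": stats,
        "conservation_ok": all(
            v["raw_rows"]
            == v["removed_channel_rule"] + v["removed_imputation"] + v["surviving_rows"]
            for v in stats.values()
        ),
    }
    (run / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return result
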