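"""End-to-end classification pipeline and ablation benchmark.

Training (per class): average the training events into a reference
frame, store its gradient signature in the odor database, GA-denoise
each event's feature vector, and fit one one-vs-rest sigmoid network
per class on the denoised features (targets 0.9 for the class, 0.1 for
the rest — strictly inside the sigmoid's range).

Classification of a test event (full neural-genetic pipeline):

1. preprocess and extract the gradient profile and feature vector;
2. GA stage: denoise the feature vector (elite of a population seeded
   from the observation);
3. database matching: rank records by the 6-of-8 / 80% rule;
4. ANN stage: the top record's network scores the elite features; a
   score below the output threshold vetoes the match ("unidentified").

Ablations for the benchmark:

* ``ann_only`` — skip the GA: score the raw feature vector with
  networks trained on raw features, verdict = argmax score;
* ``ga_only`` — skip the ANN: verdict = the record whose stored elite
  feature vector is nearest (L2) to the event's denoised features.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import ann as ann_mod
from . import ga as ga_mod
from .classify import (UNIDENTIFIED, OdorDatabase, build_database,
                       match_database, success_rate)
from .features import profile_of_frame, steady_state_features
from .sim import ClassSpec, SensorFrame, Study, generate_study

TARGET_POS = 0.9
TARGET_NEG = 0.1


@dataclass
class PipelineConfig:
    """One config object driving every stage; a single seed derives all
    stage seeds deterministically."""

    window: int = 10
    saturations: float | Sequence[float] = 5.0
    ga: ga_mod.GAConfig = field(default_factory=ga_mod.GAConfig)
    train: ann_mod.TrainConfig = field(default_factory=ann_mod.TrainConfig)
    sim_threshold: float = 0.80
    min_channels: int = 6
    output_threshold: float = 0.5
    strict_inequality: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.ga.window != self.window:
            self.ga = ga_mod.GAConfig(**{**self.ga.__dict__, "window": self.window})

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        d = dict(d)
        if "ga" in d:
            d["ga"] = ga_mod.GAConfig(**d["ga"])
        if "train" in d:
            d["train"] = ann_mod.TrainConfig(**d["train"])
        return cls(**d)


@dataclass
class TrainedModel:
    database: OdorDatabase
    networks: dict                      # label -> NetworkModel (denoised features)
    raw_networks: dict                  # label -> NetworkModel (raw features)
    train_histories: dict = field(default_factory=dict)


def _event_features(frames: Sequence[SensorFrame], cfg: PipelineConfig) -> np.ndarray:
    return np.vstack([steady_state_features(f, cfg.window, cfg.saturations)
                      for f in frames])


def _denoise_each(feats: np.ndarray, cfg: PipelineConfig,
                  seeds: Sequence[np.random.SeedSequence]) -> np.ndarray:
    out = np.empty_like(feats)
    for i, (row, s) in enumerate(zip(feats, seeds)):
        out[i] = ga_mod.denoise(row[None, :], cfg.ga,
                                np.random.default_rng(s)).elite
    return out


def _fit_one_vs_rest(feats: np.ndarray, labels: Sequence[str],
                     cfg: PipelineConfig, seeds) -> tuple[dict, dict]:
    nets, histories = {}, {}
    labels = np.asarray(labels)
    for label, s in zip(sorted(set(labels)), seeds):
        y = np.where(labels == label, TARGET_POS, TARGET_NEG)
        net = ann_mod.init_network(cfg.train.hidden_size, seed=s)
        result = ann_mod.train(net, feats, y, cfg.train)
        nets[label] = result.net
        histories[label] = result.history
    return nets, histories


def train_model(train_frames: Sequence[SensorFrame], cfg: PipelineConfig) -> TrainedModel:
    """Build the database and the per-class networks from labelled frames."""
    by_class: dict[str, list[SensorFrame]] = {}
    for f in train_frames:
        if f.label is None:
            raise ValueError("training frames must be labelled")
        by_class.setdefault(f.label, []).append(f)
    root = np.random.SeedSequence(cfg.seed)
    db_seed, denoise_seed, net_seed, raw_net_seed = root.spawn(4)

    db = build_database(by_class, cfg.window, cfg.saturations, cfg.ga, seed=db_seed)

    feats = _event_features(train_frames, cfg)
    labels = [f.label for f in train_frames]
    denoised = _denoise_each(feats, cfg, denoise_seed.spawn(len(train_frames)))
    n_classes = len(by_class)
    nets, hist = _fit_one_vs_rest(denoised, labels, cfg, net_seed.spawn(n_classes))
    raw_nets, _ = _fit_one_vs_rest(feats, labels, cfg, raw_net_seed.spawn(n_classes))
    return TrainedModel(database=db, networks=nets, raw_networks=raw_nets,
                        train_histories=hist)


@dataclass
class EventVerdict:
    true_label: str | None
    verdict: str
    n_matched: int
    mean_similarity: float
    ann_score: float


def classify_event(frame: SensorFrame, model: TrainedModel, cfg: PipelineConfig,
                   rng: np.random.Generator | None = None) -> EventVerdict:
    """Full neural-genetic classification of one event (see module docs)."""
    rng = rng or np.random.default_rng(cfg.seed)
    profile = profile_of_frame(frame, cfg.window, cfg.saturations)
    feats = steady_state_features(frame, cfg.window, cfg.saturations)
    elite = ga_mod.denoise(feats[None, :], cfg.ga, rng).elite
    ranked, verdict = match_database(profile, model.database,
                                     cfg.sim_threshold, cfg.min_channels,
                                     strict=cfg.strict_inequality)
    top = ranked[0]
    score = float("nan")
    if verdict != UNIDENTIFIED:
        decision = ann_mod.ann_stage(elite, model.networks[verdict],
                                     cfg.output_threshold)
        score = decision.score
        if not decision.proceed:
            verdict = UNIDENTIFIED
    return EventVerdict(true_label=frame.label, verdict=verdict,
                        n_matched=top.n_matched,
                        mean_similarity=top.mean_similarity, ann_score=score)


def evaluate(test_frames: Sequence[SensorFrame], model: TrainedModel,
             cfg: PipelineConfig) -> tuple[pd.DataFrame, float]:
    """Classify every test frame; return the verdict table and success rate."""
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(1)[0])
    rows = []
    for i, frame in enumerate(test_frames):
        v = classify_event(frame, model, cfg, rng)
        rows.append({"event_id": i, "true_label": v.true_label,
                     "verdict": v.verdict, "n_matched": v.n_matched,
                     "mean_similarity": v.mean_similarity,
                     "ann_score": v.ann_score})
    df = pd.DataFrame(rows)
    rate = success_rate(df["verdict"].tolist(), df["true_label"].tolist())
    return df, rate


def _ann_only_verdicts(test_frames, model: TrainedModel, cfg: PipelineConfig):
    verdicts = []
    for frame in test_frames:
        feats = steady_state_features(frame, cfg.window, cfg.saturations)
        scores = {label: ann_mod.forward(net, feats)
                  for label, net in model.raw_networks.items()}
        verdicts.append(max(sorted(scores), key=lambda k: scores[k]))
    return verdicts


def _ga_only_verdicts(test_frames, model: TrainedModel, cfg: PipelineConfig,
                      rng: np.random.Generator):
    verdicts = []
    for frame in test_frames:
        feats = steady_state_features(frame, cfg.window, cfg.saturations)
        elite = ga_mod.denoise(feats[None, :], cfg.ga, rng).elite
        dists = {rec.label: float(np.linalg.norm(elite - rec.elite_features))
                 for rec in model.database.records}
        verdicts.append(min(sorted(dists), key=lambda k: dists[k]))
    return verdicts


def run_study(specs: Sequence[ClassSpec], cfg: PipelineConfig,
              n_events: int = 50, train_fraction: float = 0.6,
              duration: int = 1000, study: Study | None = None):
    """Generate (or accept) a study, train, evaluate; return all artifacts."""
    if study is None:
        study = generate_study(specs, n_events, train_fraction, duration,
                               seed=cfg.seed)
    model = train_model(study.train, cfg)
    verdicts, rate = evaluate(study.test, model, cfg)
    return study, model, verdicts, rate


def benchmark(specs: Sequence[ClassSpec], cfg: PipelineConfig,
              n_seeds: int = 20, n_events: int = 50,
              train_fraction: float = 0.6, duration: int = 1000) -> pd.DataFrame:
    """Success rates of the full pipeline vs its ablations across seeds.

    Returns one row per (seed, method) with the method's success rate on
    that seed's test split.
    """
    rows = []
    for k in range(n_seeds):
        run_cfg = PipelineConfig(**{**cfg.__dict__, "seed": cfg.seed + k})
        study = generate_study(specs, n_events, train_fraction, duration,
                               seed=run_cfg.seed)
        model = train_model(study.train, run_cfg)
        truths = [f.label for f in study.test]

        _, full_rate = evaluate(study.test, model, run_cfg)
        ann_rate = success_rate(_ann_only_verdicts(study.test, model, run_cfg), truths)
        rng = np.random.default_rng(np.random.SeedSequence(run_cfg.seed).spawn(2)[1])
        ga_rate = success_rate(_ga_only_verdicts(study.test, model, run_cfg, rng), truths)
        rows.extend([
            {"seed": run_cfg.seed, "method": "full", "success_rate": full_rate},
            {"seed": run_cfg.seed, "method": "ann_only", "success_rate": ann_rate},
            {"seed": run_cfg.seed, "method": "ga_only", "success_rate": ga_rate},
        ])
    return pd.DataFrame(rows)
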