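"""Odor-database matching and the 6-of-8 / 80% decision rule.

A reference database stores, per substance class, the gradient signature
of the averaged training events (plus the GA-denoised feature vector).
A query event is identified by comparing its gradient profile against
every stored record channel by channel and epoch by epoch:

* two gradients are *similar* when they share a sign and their relative
  difference is small: sim = 1 - |g_q - g_r| / max(|g_q|, |g_r|);
  opposite signs score 0, and magnitudes below a small epsilon are
  treated as sign 0 (matching only another near-zero gradient, with
  similarity 1).
* a channel *matches* a record when the similarity is at or above the
  threshold (default 0.80) at every shared epoch;
* identification succeeds when at least ``min_channels`` (default 6) of
  the 8 channels match.

Records are ranked by matched-channel count, then mean similarity; the
verdict is the top record's label if it passes the rule, otherwise
"unidentified".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import ga as ga_mod
from .features import GradientProfile, profile_of_frame, steady_state_features
from .sim import SensorFrame, average_event

UNIDENTIFIED = "unidentified"

#: Magnitude below which a gradient counts as zero (normalized units/s).
ZERO_EPS = 1e-6


@dataclass
class ReferenceRecord:
    """One stored class signature."""

    label: str
    signature: GradientProfile
    elite_features: np.ndarray | None = None
    provenance: list = field(default_factory=list)

    def __post_init__(self):
        if len(self.signature.channels) != 8:
            raise ValueError("signature must cover 8 channels")
        if self.signature.n_epochs == 0:
            raise ValueError("signature grid must be non-empty")
        if self.elite_features is not None:
            self.elite_features = np.asarray(self.elite_features, dtype=float)

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "signature": self.signature.to_dict(),
            "elite_features": None if self.elite_features is None
            else self.elite_features.tolist(),
            "provenance": list(self.provenance),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ReferenceRecord":
        return cls(label=d["label"],
                   signature=GradientProfile.from_dict(d["signature"]),
                   elite_features=d.get("elite_features"),
                   provenance=list(d.get("provenance", [])))


@dataclass
class OdorDatabase:
    records: list[ReferenceRecord]
    window: int

    def labels(self) -> list[str]:
        return [r.label for r in self.records]

    def to_dict(self) -> dict:
        return {"window": int(self.window),
                "records": [r.to_dict() for r in self.records]}

    @classmethod
    def from_dict(cls, d: dict) -> "OdorDatabase":
        return cls(records=[ReferenceRecord.from_dict(r) for r in d["records"]],
                   window=int(d["window"]))


def channel_similarity(g_query: float, g_ref: float, eps: float = ZERO_EPS) -> float:
    """Similarity in [0, 1] of two gradient values (see module docstring)."""
    gq, gr = float(g_query), float(g_ref)
    sq = 0 if abs(gq) < eps else (1 if gq > 0 else -1)
    sr = 0 if abs(gr) < eps else (1 if gr > 0 else -1)
    if sq != sr:
        return 0.0
    if sq == 0:
        return 1.0
    return 1.0 - abs(gq - gr) / max(abs(gq), abs(gr))


def _similarity_matrix(q: np.ndarray, r: np.ndarray, eps: float) -> np.ndarray:
    """Vectorized channel_similarity over matching-shape gradient arrays."""
    sq = np.where(np.abs(q) < eps, 0, np.sign(q))
    sr = np.where(np.abs(r) < eps, 0, np.sign(r))
    denom = np.maximum(np.abs(q), np.abs(r))
    with np.errstate(divide="ignore", invalid="ignore"):
        sim = 1.0 - np.abs(q - r) / denom
    sim = np.where(sq != sr, 0.0, sim)
    sim = np.where((sq == 0) & (sr == 0), 1.0, sim)
    return sim


@dataclass
class ClassificationResult:
    label: str
    similarities: np.ndarray       # (8, n_shared_epochs)
    channel_match: np.ndarray      # (8,) bool
    success: bool

    @property
    def n_matched(self) -> int:
        return int(self.channel_match.sum())

    @property
    def mean_similarity(self) -> float:
        return float(self.similarities.mean())


def match_record(query: GradientProfile, record: ReferenceRecord,
                 sim_threshold: float = 0.80, min_channels: int = 6,
                 eps: float = ZERO_EPS, strict: bool = False) -> ClassificationResult:
    """Apply the channel/epoch similarity rule to one stored record.

    A channel matches when its similarity reaches the threshold at every
    shared epoch; ``strict=True`` demands strictly more than the
    threshold, the default reads "more than 80%" inclusively as >= 0.80.
    """
    ref = record.signature
    if query.window != ref.window:
        raise ValueError("query and record use different windows")
    n = min(query.n_epochs, ref.n_epochs)
    if n == 0:
        raise ValueError("no shared epochs between query and record")
    sims = _similarity_matrix(query.values[:, :n], ref.values[:, :n], eps)
    if strict:
        channel_match = np.all(sims > sim_threshold, axis=1)
    else:
        channel_match = np.all(sims >= sim_threshold, axis=1)
    return ClassificationResult(label=record.label, similarities=sims,
                                channel_match=channel_match,
                                success=bool(channel_match.sum() >= min_channels))


def match_database(query: GradientProfile, db: OdorDatabase,
                   sim_threshold: float = 0.80, min_channels: int = 6,
                   eps: float = ZERO_EPS, strict: bool = False):
    """Rank all records against the query and produce a verdict.

    Records are sorted by matched-channel count, then mean similarity
    (ties keep database order).  The verdict is the top record's label
    when it passes the decision rule, else "unidentified".
    """
    if not db.records:
        raise ValueError("database is empty")
    results = [match_record(query, rec, sim_threshold, min_channels, eps, strict)
               for rec in db.records]
    order = sorted(range(len(results)),
                   key=lambda i: (-results[i].n_matched, -results[i].mean_similarity, i))
    ranked = [results[i] for i in order]
    verdict = ranked[0].label if ranked[0].success else UNIDENTIFIED
    return ranked, verdict


def success_rate(verdicts: Sequence[str], truths: Sequence[str]) -> float:
    """Percentage of verdicts equal to the true labels."""
    if len(verdicts) == 0 or len(verdicts) != len(truths):
        raise ValueError("verdicts and truths must be equal-length and non-empty")
    correct = sum(v == t for v, t in zip(verdicts, truths))
    return 100.0 * correct / len(verdicts)


def build_database(frames_by_class: Mapping[str, Sequence[SensorFrame]],
                   window: int, saturations,
                   ga_config: ga_mod.GAConfig | None = None,
                   seed=None) -> OdorDatabase:
    """Build the reference database from labelled training frames.

    Per class: average the training events (noise shrinks as 1/sqrt(n)),
    run the preprocessing and gradient pipeline on the average to obtain
    the stored signature, and run the genetic stage seeded with the
    individual events' feature vectors to obtain the class's denoised
    elite feature vector.
    """
    if not frames_by_class:
        raise ValueError("no training classes supplied")
    ga_config = ga_config or ga_mod.GAConfig(window=window)
    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    records = []
    for class_seed, (label, frames) in zip(root.spawn(len(frames_by_class)),
                                           frames_by_class.items()):
        frames = list(frames)
        if not frames:
            raise ValueError(f"class {label!r} has no training frames")
        avg = average_event(frames)
        signature = profile_of_frame(avg, window, saturations, role="reference")
        signature.label = label
        feats = np.vstack([steady_state_features(f, window, saturations)
                           for f in frames])
        elite = ga_mod.denoise(feats, ga_config,
                               np.random.default_rng(class_seed)).elite
        records.append(ReferenceRecord(
            label=label, signature=signature, elite_features=elite,
            provenance=[f"{label}/train/{i}" for i in range(len(frames))]))
    return OdorDatabase(records=records, window=window)
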