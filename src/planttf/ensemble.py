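"""Ensemble inference: per-family base learners, max voting, two-stage stacking.

Every input sequence is encoded, masked, and scored by one binary classifier
per family; the per-family sigmoid outputs are *not* renormalized across
families. Final labels come from either:

* ``max_vote`` — argmax over the raw base-learner probabilities, or
* ``two_stage`` — the stacking meta-classifier maps the base probability
  vector to normalized per-family scores and the argmax is taken there.

In both cases the winning probability must reach the confidence threshold
(comparison is >=) or the sequence is rejected as ``"unknown"`` — the open-set
mechanism that separates non-TF proteins from genuine family members. Exact
probability ties break toward the lower family index in canonical order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .features import FeatureMask, FeatureScaler
from .kmers import FeatureMatrix, apply_mask, build_vocabulary, encode_corpus
from .models import StackerEnsemble, TrainedModel, predict_proba
from .seqio import LabeledCorpus, ProteinRecord

UNKNOWN_LABEL = "unknown"
METHODS = ("max_vote", "two_stage")
DEFAULT_METHOD = "two_stage"
DEFAULT_THRESHOLD = 0.5

_FLOAT_FORMAT = "%.10g"  # fixed text formatting => byte-identical reruns


@dataclass
class EnsembleModel:
    """One trained binary net per family plus an optional stacking meta-net."""

    k: int
    mask: FeatureMask
    families: list[str]
    binaries: list[TrainedModel]
    stacker: TrainedModel | StackerEnsemble | None = None
    scaler: FeatureScaler | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.binaries) != len(self.families):
            raise ValueError("one binary classifier per family is required")
        if self.mask.k != self.k:
            raise ValueError("mask k does not match ensemble k")

    def save(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.mask.to_json(out_dir / "mask.json")
        manifest = {
            "k": self.k,
            "families": self.families,
            "n_features": len(self.mask),
            "has_stacker": self.stacker is not None,
            "n_stacker_members": (
                len(self.stacker.members)
                if isinstance(self.stacker, StackerEnsemble)
                else (1 if self.stacker is not None else 0)
            ),
            "has_scaler": self.scaler is not None,
            "format_version": 1,
            **self.meta,
        }
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        for i, model in enumerate(self.binaries):
            model.save(out_dir / f"binary_{i:03d}")
        if self.stacker is not None:
            self.stacker.save(out_dir / "stacker")
        if self.scaler is not None:
            self.scaler.to_json(out_dir / "scaler.json")

    @classmethod
    def load(cls, bundle_dir: str | Path) -> "EnsembleModel":
        bundle_dir = Path(bundle_dir)
        manifest = json.loads((bundle_dir / "manifest.json").read_text())
        mask = FeatureMask.from_json(bundle_dir / "mask.json")
        families = manifest["families"]
        binaries = [
            TrainedModel.load(bundle_dir / f"binary_{i:03d}")
            for i in range(len(families))
        ]
        stacker = None
        if manifest.get("has_stacker"):
            n_members = manifest.get("n_stacker_members", 1)
            if n_members > 1:
                stacker = StackerEnsemble.load(bundle_dir / "stacker", n_members)
            else:
                stacker = TrainedModel.load(bundle_dir / "stacker")
        scaler = (
            FeatureScaler.from_json(bundle_dir / "scaler.json")
            if manifest.get("has_scaler")
            else None
        )
        meta = {
            key: val
            for key, val in manifest.items()
            if key not in ("k", "families", "n_features", "has_stacker",
                           "n_stacker_members", "has_scaler", "format_version")
        }
        return cls(
            k=manifest["k"],
            mask=mask,
            families=families,
            binaries=binaries,
            stacker=stacker,
            scaler=scaler,
            meta=meta,
        )


def _masked_features(
    ensemble: EnsembleModel, corpus: LabeledCorpus | Sequence[ProteinRecord]
) -> FeatureMatrix:
    vocab = build_vocabulary(ensemble.k)
    return apply_mask(encode_corpus(corpus, vocab), ensemble.mask)


def score_all(
    ensemble: EnsembleModel,
    corpus: LabeledCorpus | Sequence[ProteinRecord] | FeatureMatrix,
) -> np.ndarray:
    """Base-learner probability matrix, rows = sequences, columns = families."""
    if isinstance(corpus, FeatureMatrix):
        X = corpus
    else:
        X = _masked_features(ensemble, corpus)
    if not X.masked or X.k != ensemble.k or X.shape[1] != len(ensemble.mask):
        raise ValueError("feature matrix does not match the ensemble's k/mask")
    values = X.values
    if ensemble.scaler is not None:
        values = ensemble.scaler.transform(values)
    P = np.empty((values.shape[0], len(ensemble.families)))
    for j, model in enumerate(ensemble.binaries):
        P[:, j] = predict_proba(model, values)
    return P


def max_vote(
    row: np.ndarray, threshold: float, families: Sequence[str] | None = None
) -> tuple[str, float]:
    """Thresholded argmax over one row of per-family probabilities.

    Returns ``(label, confidence)``: the winning family (its index rendered as
    a string when no family names are given) if its probability reaches the
    threshold, else ``"unknown"`` with the losing maximum as confidence.
    Exact ties break toward the lower family index (np.argmax takes the first
    maximum).
    """
    row = np.asarray(row, dtype=np.float64)
    if row.size == 0:
        raise ValueError("empty probability row")
    j = int(np.argmax(row))
    m = float(row[j])
    if m < threshold:
        return (UNKNOWN_LABEL, m)
    return (families[j] if families is not None else str(j), m)


def two_stage(
    row: np.ndarray,
    stacker: TrainedModel | StackerEnsemble,
    threshold: float,
    families: Sequence[str] | None = None,
) -> tuple[str, float]:
    """Stacker-refined thresholded argmax for one base-probability row."""
    scores = predict_proba(stacker, np.asarray(row, dtype=np.float64)[None, :])[0]
    return max_vote(scores, threshold, families)


@dataclass
class PredictionReport:
    """Per-sequence probabilities and final (possibly ``"unknown"``) labels."""

    table: pd.DataFrame
    families: list[str]
    method: str
    threshold: float

    @property
    def final_labels(self) -> list[str]:
        return self.table["final_label"].tolist()

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FORMAT)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "method": self.method,
            "threshold": self.threshold,
            "families": self.families,
            "sequences": json.loads(
                self.table.to_json(orient="records", double_precision=10)
            ),
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    def family_summary(self) -> pd.DataFrame:
        """Per-family counts: sequences assigned after voting, and sequences
        whose probability for that family clears the threshold."""
        prob_cols = [f"p_{f}" for f in self.families]
        source = self.table[prob_cols].to_numpy()
        if self.method == "two_stage":
            stack_cols = [f"p2_{f}" for f in self.families]
            source = self.table[stack_cols].to_numpy()
        assigned = self.table["final_label"].value_counts()
        rows = []
        for i, fam in enumerate(self.families):
            rows.append(
                {
                    "family": fam,
                    "assigned": int(assigned.get(fam, 0)),
                    "above_threshold": int((source[:, i] >= self.threshold).sum()),
                }
            )
        return pd.DataFrame(rows)


def predict(
    ensemble: EnsembleModel,
    corpus: LabeledCorpus | Sequence[ProteinRecord],
    method: str = DEFAULT_METHOD,
    threshold: float = DEFAULT_THRESHOLD,
) -> PredictionReport:
    """Score all sequences and produce final labels with open-set rejection."""
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}, got {method!r}")
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be within [0, 1]")
    if method == "two_stage" and ensemble.stacker is None:
        raise ValueError("two_stage prediction requires a trained stacker")
    records = list(corpus)
    ids = [r.id for r in records]
    if not records:
        table = _empty_table(ensemble.families, method)
        return PredictionReport(table, list(ensemble.families), method, threshold)

    P = score_all(ensemble, records)
    if method == "two_stage":
        S = predict_proba(ensemble.stacker, P)
    else:
        S = None
    labels, confidences = finalize(P if S is None else S, ensemble.families, threshold)

    data: dict[str, object] = {"id": ids}
    for j, fam in enumerate(ensemble.families):
        data[f"p_{fam}"] = P[:, j]
    if S is not None:
        for j, fam in enumerate(ensemble.families):
            data[f"p2_{fam}"] = S[:, j]
    data["method"] = method
    data["threshold"] = threshold
    data["final_label"] = labels
    data["confidence"] = confidences
    return PredictionReport(
        pd.DataFrame(data), list(ensemble.families), method, threshold
    )


def finalize(
    scores: np.ndarray, families: Sequence[str], threshold: float
) -> tuple[list[str], np.ndarray]:
    """Vectorized thresholded argmax: labels (or ``"unknown"``) + confidences."""
    winners = np.argmax(scores, axis=1)
    confidences = scores[np.arange(scores.shape[0]), winners]
    labels = [
        families[j] if c >= threshold else UNKNOWN_LABEL
        for j, c in zip(winners, confidences)
    ]
    return labels, confidences


def _empty_table(families: Sequence[str], method: str) -> pd.DataFrame:
    cols = ["id"] + [f"p_{f}" for f in families]
    if method == "two_stage":
        cols += [f"p2_{f}" for f in families]
    cols += ["method", "threshold", "final_label", "confidence"]
    return pd.DataFrame({c: [] for c in cols})
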