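"""ANOVA F-test feature ranking and fixed-size feature masks.

The one-way ANOVA F-statistic of each k-mer feature across the family groups
(between-group mean square over within-group mean square) scores how much that
k-mer separates families; the top-n features per k form a persisted
:class:`FeatureMask` that every classifier of that k shares.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.sparse as sp
from sklearn.feature_selection import f_classif

from .kmers import FeatureMatrix
from .seqio import STANDARD_ALPHABET

#: Number of retained features per k: 200 of the 400 2-mers, 1000 for k>=3.
DEFAULT_N_FEATURES = {2: 200, 3: 1000, 4: 1000, 5: 1000}


def default_n_features(k: int) -> int:
    return DEFAULT_N_FEATURES.get(k, 1000)


@dataclass
class FeatureMask:
    """Ordered subset of vocabulary indices retained for one k, with F-scores.

    ``indices`` are sorted by decreasing score (ties broken by smaller
    vocabulary index), so ``scores`` is non-increasing.
    """

    k: int
    indices: list[int]
    scores: list[float]
    n_selected: int

    def __post_init__(self) -> None:
        if len(self.indices) != len(self.scores):
            raise ValueError("indices and scores length mismatch")
        if len(set(self.indices)) != len(self.indices):
            raise ValueError("mask indices must be unique")

    def __len__(self) -> int:
        return len(self.indices)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "k": self.k,
            "alphabet": STANDARD_ALPHABET,
            "indices": list(map(int, self.indices)),
            "scores": [float(s) for s in self.scores],
            "n_selected": self.n_selected,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "FeatureMask":
        payload = json.loads(Path(path).read_text())
        if payload.get("alphabet") != STANDARD_ALPHABET:
            raise ValueError(f"{path}: mask built on a different alphabet")
        return cls(
            k=payload["k"],
            indices=payload["indices"],
            scores=payload["scores"],
            n_selected=payload["n_selected"],
        )


def anova_f_scores(
    matrix: FeatureMatrix | np.ndarray | sp.spmatrix, labels: Sequence
) -> np.ndarray:
    """Per-feature one-way ANOVA F-statistic across label groups.

    Features with zero between-group and zero within-group variance (constant
    columns) score 0. Requires >= 2 groups and more rows than groups.
    """
    X = matrix.values if isinstance(matrix, FeatureMatrix) else matrix
    y = np.asarray(labels)
    if len(y) != X.shape[0]:
        raise ValueError("labels length does not match matrix rows")
    groups = np.unique(y)
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least 2 distinct groups")
    if X.shape[0] <= len(groups):
        raise ValueError(
            f"need more rows ({X.shape[0]}) than groups ({len(groups)}) "
            "for a nonzero within-group degree of freedom"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        f_stat, _ = f_classif(X, y)
    # 0/0 (constant feature) -> 0; inf (zero within-group variance with
    # between-group signal) capped so scores serialize and sort cleanly.
    return np.nan_to_num(f_stat, nan=0.0, posinf=np.finfo(np.float64).max)


def select_top_features(scores: np.ndarray, n: int, k: int) -> FeatureMask:
    """Mask of the ``n`` highest-scoring features.

    Ties at the cutoff break toward the smaller vocabulary index; if ``n``
    meets or exceeds the number of features, all are retained.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    scores = np.asarray(scores, dtype=np.float64)
    n_keep = min(n, scores.size)
    # lexsort: primary key -scores (descending score), secondary key the
    # feature index itself for deterministic ties.
    order = np.lexsort((np.arange(scores.size), -scores))[:n_keep]
    return FeatureMask(
        k=k,
        indices=[int(i) for i in order],
        scores=[float(scores[i]) for i in order],
        n_selected=n,
    )


@dataclass
class FeatureScaler:
    """Presence indicator followed by per-column z-scoring.

    Masked k-mer frequencies are sparse and length-dependent: a k-mer present
    once in a sequence of length L contributes ~1/L, so the same biological
    signal (a conserved-motif k-mer occurring at all) varies several-fold
    between an 80-residue and a 300-residue protein. What separates families
    is overwhelmingly *which* selected k-mers occur, not how often, so the
    classifier input is the binary presence indicator of each masked k-mer,
    z-scored with training-split statistics to put the inputs on the unit
    scale the network's initialization assumes. The statistics are persisted
    next to the mask so inference applies the identical transform.
    Zero-variance columns pass through unscaled.
    """

    mean: np.ndarray
    std: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "FeatureScaler":
        present = np.asarray(np.asarray(X) > 0, dtype=np.float64)
        mean = present.mean(axis=0)
        std = present.std(axis=0)
        std = np.where(std > 0, std, 1.0)
        return cls(mean=mean, std=std)

    def transform(self, X: np.ndarray) -> np.ndarray:
        present = np.asarray(np.asarray(X) > 0, dtype=np.float64)
        return (present - self.mean) / self.std

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"mean": self.mean.tolist(), "std": self.std.tolist()})
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "FeatureScaler":
        payload = json.loads(Path(path).read_text())
        return cls(mean=np.asarray(payload["mean"]), std=np.asarray(payload["std"]))


def build_mask(
    matrix: FeatureMatrix, labels: Sequence, n: int | None = None
) -> FeatureMask:
    """Convenience: score with ANOVA and keep the top features for ``matrix.k``."""
    if n is None:
        n = default_n_features(matrix.k)
    return select_top_features(anova_f_scores(matrix, labels), n, matrix.k)
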