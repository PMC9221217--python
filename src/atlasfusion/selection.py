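"""Feature ranking and windowed subset search.

Two stages mirror the classification framework's selection procedure:

1. **MRMR** (minimal redundancy, maximal relevance): greedy ranking that at
   each step adds the feature maximizing ``I(f, class) - mean_s I(f, s)``
   over the already-selected set ``S`` -- the standard incremental reading of
   the set-level MRMR objective.  Mutual information is the plug-in estimate
   on quantile-binned features, in bits.
2. **SFC** (sequential feature collection): every contiguous window of the
   ranked list is scored with a caller-supplied evaluator (here: inner-LOOCV
   accuracy of the SVM), and the best window wins.  For a ranking of length
   L this is exactly L(L-1)/2 evaluator calls.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .exceptions import AlignmentError

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureTable",
    "SelectionResult",
    "quantile_bins",
    "mutual_information",
    "mrmr_rank",
    "sfc_search",
]


@dataclass
class FeatureTable:
    """Subject x feature matrix with labels and per-feature provenance.

    ``labels`` are binary with 1 = patient group (positive class) and
    0 = control group.  ``feature_meta`` carries one ``(modality, atlas,
    region)`` triple per column so downstream reports can name what was
    selected; plumbing-only tables may leave it empty.
    """

    values: np.ndarray
    labels: np.ndarray
    feature_names: list = field(default_factory=list)
    feature_meta: list = field(default_factory=list)
    subject_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.labels = np.asarray(self.labels, dtype=int).ravel()
        if self.values.shape[0] != self.labels.size:
            raise ValueError("one label per subject row required")
        if not self.feature_names:
            self.feature_names = [f"f{j}" for j in range(self.n_features)]
        if len(self.feature_names) != self.n_features:
            raise ValueError("one name per feature column required")
        if not self.feature_meta:
            self.feature_meta = [("", "", name) for name in self.feature_names]
        if not self.subject_ids:
            self.subject_ids = [f"sub-{i:03d}" for i in range(self.n_subjects)]
        bad = [
            self.feature_names[j]
            for j in range(self.n_features)
            if not np.all(np.isfinite(self.values[:, j]))
        ]
        if bad:
            logger.warning("dropping %d feature(s) with missing values: %s", len(bad), bad[:8])
            keep = [j for j in range(self.n_features) if self.feature_names[j] not in set(bad)]
            self.values = self.values[:, keep]
            self.feature_names = [self.feature_names[j] for j in keep]
            self.feature_meta = [self.feature_meta[j] for j in keep]
        if len(np.unique(self.labels)) < 2:
            raise ValueError("feature table must contain both classes")
        if set(np.unique(self.labels).tolist()) - {0, 1}:
            raise ValueError("labels must be coded 0 (control) / 1 (patient)")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def subset(self, columns: Sequence[int]) -> "FeatureTable":
        cols = list(columns)
        return FeatureTable(
            values=self.values[:, cols],
            labels=self.labels.copy(),
            feature_names=[self.feature_names[j] for j in cols],
            feature_meta=[self.feature_meta[j] for j in cols],
            subject_ids=list(self.subject_ids),
        )

    def to_csv(self, path: str | Path) -> None:
        frame = pd.DataFrame(self.values, columns=self.feature_names)
        frame.insert(0, "label", self.labels)
        frame.insert(0, "subject_id", self.subject_ids)
        frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureTable":
        frame = pd.read_csv(path)
        if "label" not in frame.columns:
            raise ValueError(f"{path}: feature CSV needs a 'label' column")
        subject_ids = (
            frame.pop("subject_id").astype(str).tolist()
            if "subject_id" in frame.columns
            else []
        )
        labels = frame.pop("label").to_numpy()
        names = list(frame.columns)
        meta = []
        for name in names:
            parts = name.split(":")
            meta.append(tuple(parts) if len(parts) == 3 else ("", "", name))
        return cls(
            values=frame.to_numpy(dtype=float),
            labels=labels,
            feature_names=names,
            feature_meta=meta,
            subject_ids=subject_ids,
        )


def make_feature_name(atlas_name: str, modality: str, region_name: str) -> str:
    """Canonical ``<atlas>:<modality>:<region>`` feature name."""
    return f"{atlas_name}:{modality}:{region_name}"


@dataclass
class SelectionResult:
    """MRMR ranking plus the SFC window chosen on it.

    ``window`` is 1-based and inclusive into ``ranked_ids``: window (2, 5)
    selects the 2nd through 5th ranked features.
    """

    ranked_ids: list
    window: tuple
    window_score: float
    n_evaluations: int = 0

    def __post_init__(self) -> None:
        start, end = self.window
        if not (1 <= start < end <= len(self.ranked_ids)):
            raise ValueError(f"invalid window {self.window} for {len(self.ranked_ids)} ranked features")

    @property
    def selected_ids(self) -> list:
        start, end = self.window
        return list(self.ranked_ids[start - 1 : end])

    @property
    def n_selected(self) -> int:
        return self.window[1] - self.window[0] + 1

    def to_json(self, path: str | Path) -> None:
        payload = {
            "ranked_ids": [int(i) for i in self.ranked_ids],
            "window": [int(self.window[0]), int(self.window[1])],
            "window_score": float(self.window_score),
            "n_evaluations": int(self.n_evaluations),
            "selected_ids": [int(i) for i in self.selected_ids],
        }
        scores = getattr(self, "window_scores", None)
        if scores:  # per-window audit matrix from sfc_search(keep_scores=True)
            payload["window_scores"] = {f"{s},{e}": v for (s, e), v in scores.items()}
        Path(path).write_text(json.dumps(payload, indent=2))


def quantile_bins(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-frequency discretization with rank-then-split tie handling.

    Samples are ordered (stably) and split into ``n_bins`` near-equal groups,
    so tied values at a bin edge are divided between adjacent bins instead of
    collapsing into one. Returns integer bin codes in ``[0, n_bins)``.
    """
    x = np.asarray(x, dtype=float).ravel()
    order = np.argsort(x, kind="stable")
    bins = np.empty(x.size, dtype=int)
    bins[order] = (np.arange(x.size) * n_bins) // x.size
    return bins


def _discrete_mi_bits(a: np.ndarray, b: np.ndarray) -> float:
    """Plug-in mutual information between two discrete vectors, in bits."""
    joint = pd.crosstab(a, b).to_numpy(dtype=float)
    n = joint.sum()
    pxy = joint / n
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    mask = pxy > 0
    return float(np.sum(pxy[mask] * np.log2(pxy[mask] / (px @ py)[mask])))


def mutual_information(x: np.ndarray, y: np.ndarray, n_bins: int = 5) -> float:
    """Mutual information (bits) between a continuous feature and a discrete label.

    The feature is quantile-binned into ``n_bins`` equal-frequency bins first;
    the plug-in estimate is computed on the joint contingency table.  A
    constant feature carries no information and returns 0 with a warning.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y).ravel()
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 4:
        raise ValueError("need at least 4 samples for a binned MI estimate")
    if x.max() == x.min():
        logger.warning("constant feature: mutual information is 0")
        return 0.0
    return _discrete_mi_bits(quantile_bins(x, n_bins), y)


def mrmr_rank(table: FeatureTable, k: int = 50, n_bins: int = 5) -> list:
    """Greedy MRMR ranking of the top ``k`` features (MID criterion).

    The first pick maximizes relevance ``I(f, class)``; every later pick
    maximizes ``I(f, class) - mean over selected s of I(f, s)``.  Ties break
    to the lowest column index, making the ranking permutation-checkable.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    p = table.n_features
    k = min(k, p)
    binned = np.empty((p, table.n_subjects), dtype=int)
    constant = np.zeros(p, dtype=bool)
    for j in range(p):
        col = table.values[:, j]
        constant[j] = col.max() == col.min()
        binned[j] = quantile_bins(col, n_bins)
    y = table.labels
    relevance = np.array(
        [0.0 if constant[j] else _discrete_mi_bits(binned[j], y) for j in range(p)]
    )
    selected: list[int] = [int(np.argmax(relevance))]
    redundancy_sum = np.zeros(p)
    pair_mi_cache: dict[tuple[int, int], float] = {}

    def pair_mi(a: int, b: int) -> float:
        key = (a, b) if a < b else (b, a)
        if key not in pair_mi_cache:
            pair_mi_cache[key] = _discrete_mi_bits(binned[a], binned[b])
        return pair_mi_cache[key]

    remaining = set(range(p)) - set(selected)
    while len(selected) < k:
        last = selected[-1]
        for j in remaining:
            redundancy_sum[j] += pair_mi(j, last)
        scores = {j: relevance[j] - redundancy_sum[j] / len(selected) for j in remaining}
        best = min(scores, key=lambda j: (-scores[j], j))
        selected.append(int(best))
        remaining.discard(best)
    return selected


def sfc_search(
    ranked_ids: Sequence[int],
    evaluator: Callable[[list], float],
    *,
    keep_scores: bool = False,
) -> SelectionResult:
    """Exhaustive search over contiguous windows of an MRMR ranking.

    Every window ``[s, e]`` with ``1 <= s < e <= L`` (1-based, inclusive) is
    scored by ``evaluator(feature_ids)``; L(L-1)/2 evaluations total.  Ties
    break to the highest score, then the fewest features, then the smallest
    start index (parsimony first).
    """
    ranked = list(ranked_ids)
    length = len(ranked)
    if length < 2:
        raise ValueError("need at least two ranked features")
    best_key = None
    best: tuple | None = None
    n_calls = 0
    scores: dict[tuple, float] = {}
    for start in range(1, length):
        for end in range(start + 1, length + 1):
            subset = ranked[start - 1 : end]
            try:
                score = float(evaluator(subset))
            except Exception as exc:
                raise RuntimeError(f"evaluator failed on window ({start}, {end})") from exc
            n_calls += 1
            if keep_scores:
                scores[(start, end)] = score
            key = (-score, end - start, start)
            if best_key is None or key < best_key:
                best_key = key
                best = (start, end, score)
    assert best is not None
    result = SelectionResult(
        ranked_ids=ranked,
        window=(best[0], best[1]),
        window_score=best[2],
        n_evaluations=n_calls,
    )
    if keep_scores:
        result.window_scores = scores  # type: ignore[attr-defined]
    return result


def align_tables(tables: Sequence[FeatureTable]) -> None:
    """Raise AlignmentError unless all tables share subjects and labels."""
    first = tables[0]
    for t in tables[1:]:
        if t.n_subjects != first.n_subjects or not np.array_equal(t.labels, first.labels):
            raise AlignmentError("feature tables disagree on subjects or labels")
        if t.subject_ids != first.subject_ids:
            raise AlignmentError("feature tables disagree on subject order")
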