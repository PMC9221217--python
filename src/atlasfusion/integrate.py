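"""The four integration strategies: modality x atlas, single or combined.

Feature-level fusion concatenates tables (multi-modal and/or multi-atlas)
before the standard selection + nested-LOOCV pipeline; decision-level fusion
("bagging") majority-votes the out-of-fold predictions of independently
trained single-atlas models.  Votes always use out-of-sample predictions;
hard votes carry no decision values, so bagging rows report no AUC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .classify import ClassifierConfig, CVResult, SelectionConfig, compute_metrics, nested_loocv
from .exceptions import ConfigurationError
from .selection import FeatureTable, align_tables

logger = logging.getLogger(__name__)

__all__ = [
    "StrategySpec",
    "concat_features",
    "majority_vote",
    "run_strategy",
    "run_experiment",
]

STRATEGY_KINDS = (
    "single_modal_single_atlas",
    "single_modal_multi_atlas_bagging",
    "multi_modal_single_atlas",
    "multi_modal_multi_atlas",
)


@dataclass
class StrategySpec:
    """One classification strategy and the tables it consumes.

    ``assignments`` maps a modality name (e.g. ``"GMV"``, ``"HE"``) to the
    list of atlas names it uses.  Bagging requires an odd number of member
    atlases so a binary majority vote can never tie.
    """

    kind: str
    assignments: Mapping[str, Sequence[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in STRATEGY_KINDS:
            raise ConfigurationError(f"unknown strategy kind {self.kind!r}")
        if self.kind == "single_modal_multi_atlas_bagging":
            (members,) = self.assignments.values()
            if len(members) % 2 == 0:
                raise ValueError("bagging needs an odd number of member models")


def concat_features(tables: Sequence[FeatureTable]) -> FeatureTable:
    """Horizontally concatenate feature tables over identical subjects."""
    tables = list(tables)
    if len(tables) == 1:
        return tables[0]
    align_tables(tables)
    names: list = []
    meta: list = []
    for t in tables:
        names.extend(t.feature_names)
        meta.extend(t.feature_meta)
    return FeatureTable(
        values=np.hstack([t.values for t in tables]),
        labels=tables[0].labels.copy(),
        feature_names=names,
        feature_meta=meta,
        subject_ids=list(tables[0].subject_ids),
    )


def majority_vote(member_predictions: Sequence[np.ndarray]) -> np.ndarray:
    """Per-subject majority label over an odd number of member predictions."""
    members = [np.asarray(m, dtype=int).ravel() for m in member_predictions]
    if len(members) % 2 == 0:
        raise ValueError("majority vote needs an odd number of members")
    lengths = {m.size for m in members}
    if len(lengths) != 1:
        raise ValueError("member prediction vectors differ in length")
    stacked = np.stack(members)
    return (stacked.sum(axis=0) * 2 > stacked.shape[0]).astype(int)


def _require(tables: Mapping, modality: str, atlas: str) -> FeatureTable:
    try:
        return tables[(modality, atlas)]
    except KeyError:
        raise ConfigurationError(
            f"no feature table for modality {modality!r}, atlas {atlas!r}"
        ) from None


def _row(modality: str, atlas: str, result: CVResult, n_selected=None) -> dict:
    m = result.metrics
    return {
        "modality": modality,
        "atlas": atlas,
        "n_selected": result.n_selected_mode if n_selected is None else n_selected,
        "accuracy": m.accuracy,
        "specificity": m.specificity,
        "sensitivity": m.sensitivity,
        "auc": m.auc,
    }


def run_strategy(
    spec: StrategySpec,
    tables: Mapping,
    config: ClassifierConfig | None = None,
    selection: SelectionConfig | None = None,
) -> tuple[dict, object]:
    """Execute one strategy and emit a metrics row.

    ``tables`` maps ``(modality, atlas)`` to a FeatureTable.  Returns the row
    (modality, atlas, n-selected, accuracy, specificity, sensitivity, AUC)
    plus the underlying CVResult(s) for auditing.
    """
    row, audit = _run_strategy_inner(spec, tables, config, selection)
    row["strategy"] = spec.kind
    return row, audit


def _run_strategy_inner(spec, tables, config, selection):
    kind = spec.kind
    if kind == "single_modal_single_atlas":
        ((modality, atlases),) = spec.assignments.items()
        table = _require(tables, modality, atlases[0])
        result = nested_loocv(table, config, selection)
        return _row(modality, atlases[0], result), result

    if kind == "single_modal_multi_atlas_bagging":
        ((modality, atlases),) = spec.assignments.items()
        members = [
            nested_loocv(_require(tables, modality, a), config, selection) for a in atlases
        ]
        truths = [m.truth for m in members]
        if not all(np.array_equal(t, truths[0]) for t in truths):
            raise ConfigurationError("bagging members disagree on subject labels")
        voted = majority_vote([m.predictions for m in members])
        metrics, _ = compute_metrics(truths[0], voted)
        n_sel = sum(m.n_selected_mode or 0 for m in members) or None
        voted_result = CVResult(
            truth=truths[0],
            predictions=voted,
            decision_values=None,
            fold_details=[],
            metrics=metrics,
        )
        return (
            _row(modality, "+".join(atlases) + " (bagging)", voted_result, n_sel),
            members,
        )

    if kind == "multi_modal_single_atlas":
        atlases = {mods[0] for mods in spec.assignments.values()}
        if len(atlases) != 1:
            raise ConfigurationError("multi_modal_single_atlas needs one shared atlas")
        atlas = atlases.pop()
        table = concat_features(
            [_require(tables, modality, atlas) for modality in sorted(spec.assignments)]
        )
        result = nested_loocv(table, config, selection)
        return _row("+".join(sorted(spec.assignments)), atlas, result), result

    # multi_modal_multi_atlas: one atlas per modality, concatenated
    parts = []
    labels = []
    for modality in sorted(spec.assignments):
        atlas = spec.assignments[modality][0]
        parts.append(_require(tables, modality, atlas))
        labels.append(f"{modality}:{atlas}")
    result = nested_loocv(concat_features(parts), config, selection)
    return _row("+".join(sorted(spec.assignments)), "+".join(labels), result), result


def run_experiment(
    tables: Mapping,
    config: ClassifierConfig | None = None,
    selection: SelectionConfig | None = None,
    strategies: Sequence[str] = STRATEGY_KINDS,
    n_bagging: int = 3,
    n_fusion: int = 2,
    member_atlases: Mapping[str, Sequence[str]] | None = None,
) -> tuple[list, dict]:
    """Run the full strategy progression and collect one row per model.

    Single-modal single-atlas models run first; their accuracy ranking picks
    the "optimal" atlases that the bagging (top ``n_bagging``) and
    multi-modal multi-atlas fusion (top ``n_fusion`` per modality) strategies
    reuse, unless ``member_atlases`` overrides the ranking with explicit a
    priori lists.  Ranking-based member choice reuses the evaluation data and
    is optimistically biased; a warning is logged when it is used.

    Returns (rows, audits): Table-style rows plus a name -> CVResult map.
    """
    modalities = sorted({m for m, _ in tables})
    atlases = sorted({a for _, a in tables})
    rows: list[dict] = []
    audits: dict = {}
    single_acc: dict[str, dict[str, float]] = {m: {} for m in modalities}

    if "single_modal_single_atlas" in strategies or any(
        s in strategies for s in ("single_modal_multi_atlas_bagging", "multi_modal_multi_atlas")
    ):
        for modality in modalities:
            for atlas in atlases:
                if (modality, atlas) not in tables:
                    continue
                spec = StrategySpec("single_modal_single_atlas", {modality: [atlas]})
                row, res = run_strategy(spec, tables, config, selection)
                single_acc[modality][atlas] = row["accuracy"]
                audits[f"{modality}:{atlas}"] = res
                if "single_modal_single_atlas" in strategies:
                    rows.append(row)

    def top(modality: str, k: int) -> list:
        if member_atlases and modality in member_atlases:
            return list(member_atlases[modality])[:k]
        logger.warning(
            "selecting member atlases by single-model accuracy ranking; this "
            "reuses the evaluation data and is optimistically biased"
        )
        ranked = sorted(single_acc[modality], key=lambda a: (-single_acc[modality][a], a))
        return ranked[:k]

    if "single_modal_multi_atlas_bagging" in strategies:
        for modality in modalities:
            members = top(modality, n_bagging)
            if len(members) < n_bagging:
                logger.warning("skipping bagging for %s: fewer than %d atlases", modality, n_bagging)
                continue
            spec = StrategySpec("single_modal_multi_atlas_bagging", {modality: members})
            row, res = run_strategy(spec, tables, config, selection)
            rows.append(row)
            audits[f"{modality}:bagging"] = res

    if "multi_modal_single_atlas" in strategies and len(modalities) > 1:
        for atlas in atlases:
            if not all((m, atlas) in tables for m in modalities):
                continue
            spec = StrategySpec(
                "multi_modal_single_atlas", {m: [atlas] for m in modalities}
            )
            row, res = run_strategy(spec, tables, config, selection)
            rows.append(row)
            audits[f"multimodal:{atlas}"] = res

    if "multi_modal_multi_atlas" in strategies and len(modalities) > 1:
        tops = {m: top(m, n_fusion) for m in modalities}
        import itertools

        for combo in itertools.product(*(tops[m] for m in modalities)):
            assignment = {m: [a] for m, a in zip(modalities, combo)}
            spec = StrategySpec("multi_modal_multi_atlas", assignment)
            row, res = run_strategy(spec, tables, config, selection)
            rows.append(row)
            audits["fusion:" + "+".join(f"{m}:{a}" for m, a in zip(modalities, combo))] = res

    return rows, audits
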