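"""Leave-one-out cross-validation and case-style evaluation.

Every report counts held-out test cases and wrong identifications;
accuracy is always recomputed as (n_test - n_wrong) / n_test, never
stored independently.  A fold is *degenerate* when removing the test
record leaves its class unrepresented (or the task with fewer than two
classes): such folds cannot be answered correctly by construction and
are counted as wrong with a flag rather than raised as errors.

Tasks mirror the triage study design: multiclass identification at a
single hierarchy level (all records at the main level; one category's
records at the subclass level; one subclass's records at the leaf
level), full-path cascade evaluation, one-vs-rest binary evaluation of
a single disease among its siblings, and the weighted-vs-unweighted
loss comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from symdx.cascade import (
    CascadeConfig,
    CascadeModel,
    _node_seed,
    _train_node,
    diagnose,
    train_cascade,
)
from symdx.errors import FitError
from symdx.taxonomy import CaseRecord, DiseaseTaxonomy

Backend = Literal["nn", "svm"]
TaskLevel = Literal["main", "subclass", "disease", "path"]


@dataclass(frozen=True)
class EvalReport:
    """Outcome of one evaluation task."""

    label: str
    backend: Backend
    level: str
    n_test: int
    n_wrong: int
    confusion: dict = field(default_factory=dict)  # (true, predicted) -> count
    degenerate_folds: int = 0
    seeds: tuple[int, ...] = ()

    def __post_init__(self):
        if not 0 <= self.n_wrong <= self.n_test:
            raise ValueError(
                f"n_wrong={self.n_wrong} outside 0..n_test={self.n_test}"
            )

    @property
    def accuracy(self) -> float:
        return (self.n_test - self.n_wrong) / self.n_test


def _task_slice(records: Sequence[CaseRecord],
                taxonomy: DiseaseTaxonomy,
                level: TaskLevel,
                parent_code: int | None):
    """Records, per-record labels and the class universe for one task."""
    paths = [(*taxonomy.decode(r.disease_code)[1], r.disease_code)
             for r in records]
    if level == "main":
        return list(records), [p[0] for p in paths], taxonomy.codes_at("main")
    if level == "subclass":
        if parent_code is None or taxonomy.level_of(parent_code) != "main":
            raise ValueError("subclass task needs a main-category parent_code")
        keep = [i for i, p in enumerate(paths) if p[0] == parent_code]
        return ([records[i] for i in keep], [paths[i][1] for i in keep],
                taxonomy.children_of(parent_code))
    if level == "disease":
        if parent_code is None or taxonomy.level_of(parent_code) != "subclass":
            raise ValueError("disease task needs a subclass parent_code")
        keep = [i for i, p in enumerate(paths) if p[1] == parent_code]
        return ([records[i] for i in keep], [paths[i][2] for i in keep],
                taxonomy.children_of(parent_code))
    raise ValueError(f"unknown task level {level!r}")


def _flat_loocv(X: np.ndarray,
                labels: np.ndarray,
                class_codes: list[int],
                backend: Backend,
                config: CascadeConfig,
                weights: np.ndarray | None = None) -> tuple[int, dict, int]:
    """Generic single-level LOOCV; returns (n_wrong, confusion, n_degenerate)."""
    n = len(labels)
    n_wrong = 0
    n_degenerate = 0
    confusion: dict = {}
    idx = np.arange(n)
    for i in range(n):
        rest = idx != i
        train_labels = labels[rest]
        populated = [c for c in class_codes if (train_labels == c).any()]
        if labels[i] not in populated or len(populated) < 2:
            n_wrong += 1
            n_degenerate += 1
            confusion[(int(labels[i]), None)] = \
                confusion.get((int(labels[i]), None), 0) + 1
            continue
        node = _train_node(X[rest], train_labels, class_codes, backend, config,
                           _node_seed(config.seed, 9, i),
                           weights=None if weights is None else weights[rest],
                           level="main")
        pred, _ = node.predict_code(X[i], config.svm_mode)
        key = (int(labels[i]), None if pred is None else int(pred))
        confusion[key] = confusion.get(key, 0) + 1
        if pred != labels[i]:
            n_wrong += 1
    return n_wrong, confusion, n_degenerate


def loocv(records: Sequence[CaseRecord],
          taxonomy: DiseaseTaxonomy,
          backend: Backend = "nn",
          level: TaskLevel = "main",
          config: CascadeConfig | None = None,
          parent_code: int | None = None,
          label: str | None = None) -> EvalReport:
    """Leave-one-out evaluation at one hierarchy level or over the
    full cascade path.

    For single-level tasks each fold retrains a flat classifier on the
    remaining records of the task slice.  For ``level="path"`` each
    fold retrains only the cascade nodes whose training set actually
    contained the held-out record (the main node plus the record's own
    subclass and disease nodes — all other nodes never saw it), and
    the fold counts as wrong unless the entire predicted path matches.
    ``None`` predictions count as wrong.
    """
    if config is None:
        config = CascadeConfig()
    if len(records) < 2:
        raise ValueError("leave-one-out needs at least two records")
    if level == "path":
        return _path_loocv(records, taxonomy, backend, config, label)
    subset, labels, class_codes = _task_slice(records, taxonomy, level,
                                              parent_code)
    if len(subset) < 2:
        raise ValueError(f"task slice holds {len(subset)} record(s); need >= 2")
    X = np.asarray([r.symptoms for r in subset], dtype=float)
    labels = np.asarray(labels)
    n_wrong, confusion, n_deg = _flat_loocv(X, labels, class_codes, backend,
                                            config)
    return EvalReport(
        label=label or f"{level}{'' if parent_code is None else f'@{parent_code}'}",
        backend=backend, level=level, n_test=len(subset), n_wrong=n_wrong,
        confusion=confusion, degenerate_folds=n_deg, seeds=(config.seed,),
    )


def _path_loocv(records: Sequence[CaseRecord],
                taxonomy: DiseaseTaxonomy,
                backend: Backend,
                config: CascadeConfig,
                label: str | None) -> EvalReport:
    base = train_cascade(records, taxonomy, backend=backend, config=config)
    paths = [(*taxonomy.decode(r.disease_code)[1], r.disease_code)
             for r in records]
    X = np.asarray([r.symptoms for r in records], dtype=float)
    main_labels = np.array([p[0] for p in paths])
    sub_labels = np.array([p[1] for p in paths])
    leaf_labels = np.array([p[2] for p in paths])
    idx = np.arange(len(records))

    n_wrong = 0
    n_degenerate = 0
    confusion: dict = {}
    for i in range(len(records)):
        rest = idx != i
        true_main, true_sub, true_leaf = paths[i]
        try:
            main_node = _train_node(
                X[rest], main_labels[rest], taxonomy.codes_at("main"),
                backend, config, _node_seed(config.seed, 0, 0),
                level="main", allow_passthrough=False)
            cat_mask = rest & (main_labels == true_main)
            sub_node = _train_node(
                X[cat_mask], sub_labels[cat_mask],
                taxonomy.children_of(true_main), backend, config,
                _node_seed(config.seed, 1, true_main), level="subclass")
            sub_mask = rest & (sub_labels == true_sub)
            dis_node = _train_node(
                X[sub_mask], leaf_labels[sub_mask],
                taxonomy.children_of(true_sub), backend, config,
                _node_seed(config.seed, 2, true_sub), level="disease")
        except FitError:
            n_wrong += 1
            n_degenerate += 1
            confusion[(true_leaf, None)] = confusion.get((true_leaf, None), 0) + 1
            continue
        model = CascadeModel(
            backend=backend, taxonomy=taxonomy, config=config,
            main_model=main_node,
            subclass_models={**base.subclass_models, true_main: sub_node},
            disease_models={**base.disease_models, true_sub: dis_node},
            warnings=list(base.warnings),
        )
        diag = diagnose(model, X[i])
        key = (true_leaf, diag.disease_code)
        confusion[key] = confusion.get(key, 0) + 1
        if diag.path != (true_main, true_sub, true_leaf):
            n_wrong += 1
    return EvalReport(
        label=label or "full-path", backend=backend, level="path",
        n_test=len(records), n_wrong=n_wrong, confusion=confusion,
        degenerate_folds=n_degenerate, seeds=(config.seed,),
    )


def binary_case_eval(records: Sequence[CaseRecord],
                     taxonomy: DiseaseTaxonomy,
                     target_code: int,
                     backend: Backend = "nn",
                     config: CascadeConfig | None = None,
                     weights: Sequence[float] | None = None,
                     label: str | None = None) -> EvalReport:
    """One-vs-rest LOOCV for a single disease among its siblings.

    Records of the target's subclass form the task ("gastritis
    identification in stomach diseases"); cases of the target disease
    are one class and every sibling case is "the other".  ``weights``
    aligns with ``records``; the relevant entries follow the subset.
    """
    if config is None:
        config = CascadeConfig()
    if taxonomy.level_of(target_code) != "disease":
        raise ValueError(f"target {target_code} is not a leaf disease code")
    parent = taxonomy.parent_of(target_code)
    keep = [i for i, r in enumerate(records)
            if taxonomy.parent_of(r.disease_code) == parent]
    subset = [records[i] for i in keep]
    labels = np.array([1 if r.disease_code == target_code else 0
                       for r in subset])
    if not labels.any():
        raise ValueError(f"target code {target_code} absent from the records")
    if labels.all():
        raise ValueError(
            f"every record belongs to {target_code}: no 'other' class to "
            "separate it from"
        )
    X = np.asarray([r.symptoms for r in subset], dtype=float)
    w = None
    if weights is not None:
        w_full = np.asarray(weights, dtype=float)
        if w_full.shape != (len(records),):
            raise ValueError("weights must align one-to-one with records")
        w = w_full[keep]
    n_wrong, confusion, n_deg = _flat_loocv(X, labels, [1, 0], backend, config,
                                            weights=w)
    return EvalReport(
        label=label or f"binary@{target_code}", backend=backend,
        level="binary", n_test=len(subset), n_wrong=n_wrong,
        confusion=confusion, degenerate_folds=n_deg, seeds=(config.seed,),
    )


def weighted_comparison(records: Sequence[CaseRecord],
                        taxonomy: DiseaseTaxonomy,
                        target_code: int,
                        weights: Sequence[float],
                        backend: Backend = "svm",
                        config: CascadeConfig | None = None
                        ) -> tuple[EvalReport, EvalReport, float]:
    """Binary evaluation with and without per-sample loss weights.

    The supplied weights are normalised to mean 1 so that a uniform
    weight vector reduces exactly to the unweighted run.  Returns the
    unweighted report, the weighted report, and |accuracy difference|.
    """
    if config is None:
        config = CascadeConfig()
    w = np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise ValueError("sample weights must be positive")
    w = w / w.mean()
    rep_plain = binary_case_eval(records, taxonomy, target_code, backend,
                                 config, weights=None, label="unweighted")
    rep_weighted = binary_case_eval(records, taxonomy, target_code, backend,
                                    config, weights=w, label="weighted")
    return rep_plain, rep_weighted, abs(rep_plain.accuracy - rep_weighted.accuracy)


def report_table(reports: Sequence[EvalReport]) -> pd.DataFrame:
    """Tabulate reports in the study's layout: one row per (case, method)."""
    return pd.DataFrame(
        [
            {
                "case": r.label,
                "n_test": r.n_test,
                "n_wrong": r.n_wrong,
                "accuracy": round(r.accuracy, 4),
                "method": r.backend,
            }
            for r in reports
        ],
        columns=["case", "n_test", "n_wrong", "accuracy", "method"],
    )


def render_text(table: pd.DataFrame) -> str:
    """Aligned plain-text rendering of a report table."""
    return table.to_string(index=False)
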