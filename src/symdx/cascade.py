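"""Three-level diagnostic cascade over the disease taxonomy.

Training splits the expanded relation entries by level: the main model
NT learns category codes from all records, each per-category model
NT-b learns subclass codes from that category's records, and each
per-subclass model NT-(b,j) learns leaf disease codes.  Either
classifier back-end (neural network or one-vs-rest SVM) can stand
behind every node.

Diagnosis walks the tree: the main prediction selects which subclass
model runs, and the subclass prediction selects which disease model
runs ("predicted" conditioning).  For per-case studies where the
parent level is assumed known, "given" conditioning runs each level's
model under a caller-supplied true parent instead.  Nodes whose class
has a single populated child are pass-throughs (no model is fitted;
the only child is returned).

Concurrence diagnosis handles cases with two or three co-occurring
disease types by treating each declared combination as one composite
class and reusing the same flat classifiers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import yaml

from symdx import nn as _nn
from symdx import svm as _svm
from symdx.errors import ConfigError, FitError
from symdx.taxonomy import CaseRecord, DiseaseTaxonomy

Backend = Literal["nn", "svm"]


@dataclass(frozen=True)
class CascadeConfig:
    """Hyperparameters for both back-ends plus cascade behaviour.

    eta / epochs drive the network back-end, C the SVM back-end;
    ``svm_mode`` selects argmax scoring (default) or the sequential
    first-plane-that-fires scan; ``conditioning`` selects whether
    lower levels run under the predicted or a given parent code.
    """

    eta: float = 0.1
    epochs: int = 200
    C: float = 1.0
    seed: int = 0
    svm_mode: Literal["argmax", "sequential"] = "argmax"
    conditioning: Literal["predicted", "given"] = "predicted"
    tol: float = 1e-6
    patience: int = 10
    svm_tol: float = 1e-3

    def __post_init__(self):
        if self.eta <= 0 or self.C <= 0 or self.epochs < 1:
            raise ConfigError("eta and C must be positive and epochs >= 1")
        if self.svm_tol <= 0:
            raise ConfigError("svm_tol must be positive")
        if self.svm_mode not in ("argmax", "sequential"):
            raise ConfigError(f"unknown svm_mode {self.svm_mode!r}")
        if self.conditioning not in ("predicted", "given"):
            raise ConfigError(f"unknown conditioning {self.conditioning!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CascadeConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**payload)

    def to_dict(self) -> dict:
        return {
            "eta": self.eta, "epochs": self.epochs, "C": self.C,
            "seed": self.seed, "svm_mode": self.svm_mode,
            "conditioning": self.conditioning, "tol": self.tol,
            "patience": self.patience, "svm_tol": self.svm_tol,
        }


def _node_seed(base_seed: int, level_depth: int, parent_code: int) -> np.random.SeedSequence:
    """Deterministic per-node seed, independent of training order."""
    return np.random.SeedSequence([base_seed, level_depth, parent_code])


@dataclass
class _Node:
    """One trained decision point: a classifier over child codes, or a
    pass-through when only one child is populated."""

    kind: Literal["nn", "svm", "passthrough"]
    class_codes: list[int]
    model: object | None = None  # NetworkParams or OvrSvmSet

    def predict_code(self, x: Sequence[float], svm_mode: str) -> tuple[int | None, np.ndarray | None]:
        if self.kind == "passthrough":
            return self.class_codes[0], None
        if self.kind == "nn":
            trace = _nn.forward(self.model, x)
            return self.class_codes[int(np.argmax(trace.yo))], trace.yo
        scores = self.model.scores(x)
        if svm_mode == "sequential":
            return _svm.sequential_identify(self.model, x), scores
        return _svm.argmax_identify(self.model, x), scores

    def to_dict(self) -> dict:
        payload = {"kind": self.kind, "class_codes": self.class_codes}
        if self.model is not None:
            payload["model"] = self.model.to_dict()
        return payload

    @classmethod
    def from_dict(cls, payload: dict) -> "_Node":
        model = None
        if payload["kind"] == "nn":
            model = _nn.NetworkParams.from_dict(payload["model"])
        elif payload["kind"] == "svm":
            model = _svm.OvrSvmSet.from_dict(payload["model"])
        return cls(kind=payload["kind"], class_codes=payload["class_codes"],
                   model=model)


@dataclass(frozen=True)
class Diagnosis:
    """Per-level codes (``None`` when a level was unreachable) and the
    raw per-level classifier scores that produced them."""

    main_code: int | None
    subclass_code: int | None
    disease_code: int | None
    scores: dict = field(default_factory=dict)

    @property
    def path(self) -> tuple[int | None, int | None, int | None]:
        return (self.main_code, self.subclass_code, self.disease_code)


@dataclass
class CascadeModel:
    """The trained three-level cascade.

    ``subclass_models`` maps category codes to NT-b nodes and
    ``disease_models`` maps subclass codes to NT-(b,j) nodes; levels
    that could not be trained (fewer than two populated classes and no
    single-child pass-through) are recorded in ``warnings``.
    """

    backend: Backend
    taxonomy: DiseaseTaxonomy
    config: CascadeConfig
    main_model: _Node
    subclass_models: dict[int, _Node] = field(default_factory=dict)
    disease_models: dict[int, _Node] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    # -- persistence --------------------------------------------------

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.taxonomy.to_json(directory / "taxonomy.json")
        payload = {
            "backend": self.backend,
            "config": self.config.to_dict(),
            "main": self.main_model.to_dict(),
            "subclass": {str(k): v.to_dict() for k, v in self.subclass_models.items()},
            "disease": {str(k): v.to_dict() for k, v in self.disease_models.items()},
            "warnings": self.warnings,
        }
        (directory / "cascade.json").write_text(json.dumps(payload))

    @classmethod
    def load(cls, directory: str | Path) -> "CascadeModel":
        directory = Path(directory)
        taxonomy = DiseaseTaxonomy.from_json(directory / "taxonomy.json")
        payload = json.loads((directory / "cascade.json").read_text())
        return cls(
            backend=payload["backend"],
            taxonomy=taxonomy,
            config=CascadeConfig(**payload["config"]),
            main_model=_Node.from_dict(payload["main"]),
            subclass_models={int(k): _Node.from_dict(v)
                             for k, v in payload["subclass"].items()},
            disease_models={int(k): _Node.from_dict(v)
                            for k, v in payload["disease"].items()},
            warnings=payload["warnings"],
        )


def _train_node(X: np.ndarray,
                labels: np.ndarray,
                class_codes: list[int],
                backend: Backend,
                config: CascadeConfig,
                seed: np.random.SeedSequence,
                weights: np.ndarray | None = None,
                level: str = "main",
                parent_code: int | None = None,
                allow_passthrough: bool = True) -> _Node:
    """Fit one decision point over ``class_codes`` from labelled entries."""
    populated = [c for c in class_codes if (labels == c).any()]
    if len(populated) == 1 and allow_passthrough:
        return _Node(kind="passthrough", class_codes=populated)
    if len(populated) < 2:
        raise FitError(
            f"node {parent_code if parent_code is not None else 'main'} has "
            f"{len(populated)} populated class(es); need at least 2"
        )
    if backend == "nn":
        init_seed, shuffle_seed = seed.spawn(2)
        params = _nn.init_network(X.shape[1], len(populated), eta=config.eta,
                                  seed=init_seed)
        code_index = {c: i for i, c in enumerate(populated)}
        D = np.zeros((len(labels), len(populated)))
        D[np.arange(len(labels)), [code_index[c] for c in labels]] = 1.0
        trained, _ = _nn.train(params, X, D, weights=weights,
                               epochs=config.epochs, shuffle_seed=shuffle_seed,
                               tol=config.tol, patience=config.patience)
        return _Node(kind="nn", class_codes=populated, model=trained)
    ovr = _svm.fit_one_vs_rest(X, labels, populated, level=level,
                               parent_code=parent_code, C=config.C,
                               weights=weights, tol=config.svm_tol)
    return _Node(kind="svm", class_codes=populated, model=ovr)


def train_cascade(records: Sequence[CaseRecord],
                  taxonomy: DiseaseTaxonomy,
                  backend: Backend = "nn",
                  config: CascadeConfig | None = None,
                  weights: Sequence[float] | None = None) -> CascadeModel:
    """Train NT, NT-b and NT-(b,j) from leaf-labelled case records.

    Records are expanded into the three-level relation list; each node
    trains on the entries of its level restricted to its branch.
    Nodes whose branch holds fewer than two populated classes are
    skipped with a warning recorded on the model (single-child nodes
    become pass-throughs).  Deterministic given ``config.seed``.
    """
    if config is None:
        config = CascadeConfig()
    if not records:
        raise FitError("no training records")
    X = np.asarray([r.symptoms for r in records], dtype=float)
    w_all = None if weights is None else np.asarray(weights, dtype=float)
    paths = [(*taxonomy.decode(r.disease_code)[1], r.disease_code)
             for r in records]
    main_labels = np.array([p[0] for p in paths])
    sub_labels = np.array([p[1] for p in paths])
    leaf_labels = np.array([p[2] for p in paths])

    warnings: list[str] = []
    main_codes = taxonomy.codes_at("main")
    main_model = _train_node(X, main_labels, main_codes, backend, config,
                             _node_seed(config.seed, 0, 0), weights=w_all,
                             level="main", allow_passthrough=False)

    subclass_models: dict[int, _Node] = {}
    for cat_code in main_codes:
        mask = main_labels == cat_code
        children = taxonomy.children_of(cat_code)
        if not mask.any() or not children:
            continue
        try:
            subclass_models[cat_code] = _train_node(
                X[mask], sub_labels[mask], children, backend, config,
                _node_seed(config.seed, 1, cat_code),
                weights=None if w_all is None else w_all[mask],
                level="subclass", parent_code=cat_code)
        except FitError as exc:
            warnings.append(f"subclass node {cat_code} skipped: {exc}")

    disease_models: dict[int, _Node] = {}
    for sub_code in taxonomy.codes_at("subclass"):
        mask = sub_labels == sub_code
        children = taxonomy.children_of(sub_code)
        if not mask.any() or not children:
            continue
        try:
            disease_models[sub_code] = _train_node(
                X[mask], leaf_labels[mask], children, backend, config,
                _node_seed(config.seed, 2, sub_code),
                weights=None if w_all is None else w_all[mask],
                level="disease", parent_code=sub_code)
        except FitError as exc:
            warnings.append(f"disease node {sub_code} skipped: {exc}")

    return CascadeModel(backend=backend, taxonomy=taxonomy, config=config,
                        main_model=main_model,
                        subclass_models=subclass_models,
                        disease_models=disease_models, warnings=warnings)


def diagnose(model: CascadeModel,
             x: Sequence[float],
             given_path: tuple[int | None, int | None] = (None, None)) -> Diagnosis:
    """Run the cascade on one symptom vector.

    With "predicted" conditioning each level runs under the previous
    level's prediction; with "given" conditioning the caller supplies
    the true (main, subclass) codes in ``given_path`` and each level's
    model runs under those instead.  A missing or non-firing node
    leaves that level and everything below it absent.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (model.taxonomy.n_symptoms,):
        raise ValueError(
            f"symptom vector has shape {x.shape}, taxonomy declares "
            f"({model.taxonomy.n_symptoms},)"
        )
    scores: dict = {}
    svm_mode = model.config.svm_mode
    main_code, s = model.main_model.predict_code(x, svm_mode)
    scores["main"] = s

    cond_main = main_code
    if model.config.conditioning == "given" and given_path[0] is not None:
        cond_main = given_path[0]
    subclass_code = None
    if cond_main is not None and cond_main in model.subclass_models:
        subclass_code, s = model.subclass_models[cond_main].predict_code(x, svm_mode)
        scores["subclass"] = s

    cond_sub = subclass_code
    if model.config.conditioning == "given" and given_path[1] is not None:
        cond_sub = given_path[1]
    disease_code = None
    if cond_sub is not None and cond_sub in model.disease_models:
        disease_code, s = model.disease_models[cond_sub].predict_code(x, svm_mode)
        scores["disease"] = s

    return Diagnosis(main_code=main_code, subclass_code=subclass_code,
                     disease_code=disease_code, scores=scores)


# -- concurrence-of-diseases classification ---------------------------


@dataclass(frozen=True)
class ConcurrenceClass:
    """Two or three co-occurring disease-type codes treated as one
    composite class."""

    member_codes: frozenset[int]

    def __post_init__(self):
        if len(self.member_codes) not in (2, 3):
            raise ConfigError(
                f"a concurrence class needs 2 or 3 member codes, got "
                f"{sorted(self.member_codes)}"
            )

    @property
    def key(self) -> tuple[int, ...]:
        return tuple(sorted(self.member_codes))


@dataclass
class ConcurrenceModel:
    """Flat classifier over declared disease-type combinations."""

    backend: Backend
    taxonomy: DiseaseTaxonomy
    config: CascadeConfig
    combos: list[ConcurrenceClass]
    node: _Node | None = None

    def combo_of_code(self, code: int) -> ConcurrenceClass:
        return self.combos[code]


def train_concurrence(records: Sequence[tuple[Sequence[int], ConcurrenceClass]],
                      taxonomy: DiseaseTaxonomy,
                      combos: Sequence[ConcurrenceClass],
                      backend: Backend = "nn",
                      config: CascadeConfig | None = None) -> ConcurrenceModel:
    """Train a composite-class model from combo-labelled records.

    Each record is (symptom flags, declared combination); every
    combination is one class.  Records labelled with an undeclared
    combination are rejected.
    """
    if config is None:
        config = CascadeConfig()
    combos = list(combos)
    if len(combos) < 2:
        raise FitError("need at least two declared disease combinations")
    keys = {c.key: i for i, c in enumerate(combos)}
    if len(keys) != len(combos):
        raise ConfigError("duplicate combination declared")
    X = np.asarray([flags for flags, _ in records], dtype=float)
    labels = []
    for i, (_, combo) in enumerate(records):
        if combo.key not in keys:
            raise FitError(
                f"record {i} labelled with undeclared combination {combo.key}"
            )
        labels.append(keys[combo.key])
    node = _train_node(X, np.asarray(labels), list(range(len(combos))),
                       backend, config, _node_seed(config.seed, 3, 0),
                       level="concurrence")
    return ConcurrenceModel(backend=backend, taxonomy=taxonomy, config=config,
                            combos=combos, node=node)


def diagnose_concurrence(model: ConcurrenceModel,
                         x: Sequence[float]) -> ConcurrenceClass | None:
    """Composite class for one symptom vector (``None`` when the SVM
    sequential mode finds no firing plane)."""
    idx, _ = model.node.predict_code(np.asarray(x, dtype=float),
                                     model.config.svm_mode)
    return None if idx is None else model.combos[idx]
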