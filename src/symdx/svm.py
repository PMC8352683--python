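"""Linear support vector machine, written from scratch.

The separating hyperplane is f(x) = omega . x + c.  The intercept is
carried as one extra always-on feature, after which the soft-margin
dual is a box-constrained QP without equality constraint,

    min_a  1/2 a' Q a - e' a,   0 <= a_k <= C w_k,
    Q_kl = y_k y_l (x_k . x_l + 1),

solved by cyclic dual coordinate ascent: each single-variable
subproblem has the closed-form update a_k <- clip(a_k - g_k / Q_kk),
and the primal vector (omega, c) = sum_k a_k y_k (x_k, 1) is kept
incrementally so one pass costs O(n d).  Iteration stops when the
largest projected-gradient violation in a pass drops below ``tol``.
Per-sample loss weights w_k enter as individual box bounds C w_k;
hard margins are approximated by a large penalty (C = 1e4 in the
margin tests).  Folding the intercept into the regulariser is the
standard linear-SVM treatment; on the data scales used here it leaves
decisions indistinguishable from the equality-constrained dual.

Multiclass identification is one-against-the-rest: one hyperplane per
class at a taxonomy level, the target class mapped to +1 and all other
classes to -1 before fitting.  Two identification modes are provided:
``sequential_identify`` scans the planes in taxonomy order and returns
the first class whose plane fires (or ``None`` when none does), and
``argmax_identify`` returns the class with the largest raw score.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from symdx.errors import FitError, SolverError

HARD_MARGIN_C = 1e4  # penalty treated as "effectively hard margin"


@dataclass(frozen=True)
class Hyperplane:
    """Separating hyperplane f(x) = omega . x + c."""

    omega: np.ndarray
    c: float

    def score(self, x: Sequence[float]) -> float:
        x = np.asarray(x, dtype=float)
        if x.shape != self.omega.shape:
            raise ValueError(
                f"input has shape {x.shape}, hyperplane expects {self.omega.shape}"
            )
        return float(self.omega @ x + self.c)


def decide(plane: Hyperplane, x: Sequence[float]) -> bool:
    """Membership rule: member iff omega . x + c > 0.

    A score of exactly 0 sits on the boundary and is resolved as
    nonmember.
    """
    return plane.score(x) > 0.0


def fit_binary(X: Sequence[Sequence[float]],
               y: Sequence[int],
               C: float = 10.0,
               weights: Sequence[float] | None = None,
               tol: float = 1e-8,
               max_passes: int = 100_000) -> Hyperplane:
    """Fit one soft-margin hyperplane on +/-1 labels.

    ``tol`` bounds the final KKT violation (largest projected dual
    gradient); ``max_passes`` caps the number of sweeps over the
    samples.  Raises :class:`FitError` on single-class input and
    :class:`SolverError` on non-convergence.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or y.shape != (X.shape[0],):
        raise ValueError("X must be 2-D with one label per row")
    if not set(np.unique(y)) <= {-1.0, 1.0}:
        raise FitError(f"labels must be +1/-1, got {sorted(set(y))}")
    if len(set(y)) < 2:
        raise FitError("both classes must be present to fit a hyperplane")
    if C <= 0:
        raise ValueError("penalty C must be positive")
    n, d = X.shape
    if weights is None:
        box = np.full(n, C)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,):
            raise ValueError("weights must align one-to-one with samples")
        if np.any(w <= 0):
            raise ValueError("sample weights must be positive")
        box = C * w

    Xa = np.hstack([X, np.ones((n, 1))])     # intercept as an extra feature
    q_diag = np.einsum("ij,ij->i", Xa, Xa)
    q_diag = np.maximum(q_diag, 1e-12)
    alpha = np.zeros(n)
    w_aug = np.zeros(d + 1)

    for n_pass in range(max_passes):
        worst = 0.0
        for k in range(n):
            g = y[k] * (w_aug @ Xa[k]) - 1.0   # dual gradient component
            a = alpha[k]
            if a <= 0.0:
                pg = min(g, 0.0)
            elif a >= box[k]:
                pg = max(g, 0.0)
            else:
                pg = g
            if pg != 0.0:
                worst = max(worst, abs(pg))
                a_new = min(max(a - g / q_diag[k], 0.0), box[k])
                if a_new != a:
                    w_aug += (a_new - a) * y[k] * Xa[k]
                    alpha[k] = a_new
        if worst < tol:
            break
    else:
        raise SolverError(
            f"SVM dual solver did not reach tolerance {tol} within "
            f"{max_passes} passes (KKT violation {worst:.3e})",
            n_iter=max_passes,
        )
    return Hyperplane(omega=w_aug[:d].copy(), c=float(w_aug[d]))


Level = Literal["main", "subclass", "disease", "concurrence"]


@dataclass
class OvrSvmSet:
    """One-against-the-rest hyperplanes at one taxonomy level."""

    level: Level
    parent_code: int | None
    planes: list[tuple[int, Hyperplane]] = field(default_factory=list)

    @property
    def class_codes(self) -> list[int]:
        return [code for code, _ in self.planes]

    def scores(self, x: Sequence[float]) -> np.ndarray:
        return np.array([plane.score(x) for _, plane in self.planes])

    # -- persistence --------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "level": self.level,
            "parent_code": self.parent_code,
            "planes": [
                {"code": code, "omega": plane.omega.tolist(), "c": plane.c}
                for code, plane in self.planes
            ],
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "OvrSvmSet":
        return cls(
            level=payload["level"],
            parent_code=payload["parent_code"],
            planes=[
                (p["code"], Hyperplane(np.asarray(p["omega"], dtype=float), p["c"]))
                for p in payload["planes"]
            ],
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def from_json(cls, path: str | Path) -> "OvrSvmSet":
        return cls.from_dict(json.loads(Path(path).read_text()))


def fit_one_vs_rest(X: Sequence[Sequence[float]],
                    labels: Sequence[int],
                    class_codes: Sequence[int],
                    level: Level = "main",
                    parent_code: int | None = None,
                    C: float = 10.0,
                    weights: Sequence[float] | None = None,
                    tol: float = 1e-8,
                    max_passes: int = 100_000) -> OvrSvmSet:
    """Fit one plane per class code (class -> +1, all others -> -1).

    ``class_codes`` fixes the plane order (taxonomy order); every code
    must have at least one sample.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    if len(class_codes) < 2:
        raise FitError("one-vs-rest needs at least two classes")
    planes = []
    for code in class_codes:
        mask = labels == code
        if not mask.any():
            raise FitError(f"class {code} has no training samples")
        y = np.where(mask, 1.0, -1.0)
        planes.append((int(code), fit_binary(X, y, C=C, weights=weights,
                                             tol=tol, max_passes=max_passes)))
    return OvrSvmSet(level=level, parent_code=parent_code, planes=planes)


def sequential_identify(ovr: OvrSvmSet, x: Sequence[float]) -> int | None:
    """Scan planes in order; return the first class whose plane fires.

    Returns ``None`` when no plane accepts the case ("quit out").  The
    result is order-dependent whenever several planes fire.
    """
    for code, plane in ovr.planes:
        if decide(plane, x):
            return code
    return None


def argmax_identify(ovr: OvrSvmSet, x: Sequence[float]) -> int:
    """Class with the largest raw score; ties go to the lowest code."""
    if not ovr.planes:
        raise ValueError("empty one-vs-rest set")
    scores = ovr.scores(x)
    best = np.flatnonzero(scores == scores.max())
    codes = np.asarray(ovr.class_codes)
    return int(codes[best].min())
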