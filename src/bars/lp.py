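"""Linear program for re-weighting energy terms.

Given one or more reverse-sampling paths under current weights W0, find new
nonnegative weights W minimizing the L1 change ||W - W0||_1 subject to

  monotonicity :  W . E_i  <=  W . E_{i+1}   along every path,
  smoothing    :  W . E_n  <=  (1/m) sum_j W . E_n^(j)   per path,
  budget       :  sum_k w_k = sum_k w0_k,   W >= 0.

Monotonicity preserves the shape (energy ordering) of the attraction basin;
smoothing pushes each edge point's energy below the mean of its perturbation
neighborhood so it stops being a local ridge; the budget forbids the trivial
global rescaling.  The L1 objective is linearized with auxiliary variables
u_k >= |w_k - w0_k|; per-row nonnegative slacks (heavily penalized) keep the
program feasible and make constraint conflicts visible instead of fatal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import linprog

from .sampling import ReversePath, subsample_path
from .weights import TermSchema, WeightVector, l1_norm

__all__ = ["LPSpec", "LPResult", "build_lp", "solve_lp", "verify_solution"]

_FEAS_TOL = 1e-8


@dataclass(frozen=True)
class LPSpec:
    """Assembled constraint data for one weight-tuning solve."""

    schema: TermSchema
    w0: WeightVector
    monotonic_rows: tuple[tuple[np.ndarray, np.ndarray], ...]
    smoothing_rows: tuple[tuple[np.ndarray, np.ndarray], ...]
    norm_target: float
    slack_penalty: float = 1e4
    epsilon: float = 0.0  # optional strictness margin on the inequalities

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "monotonic_rows",
            tuple(
                (np.asarray(a, float), np.asarray(b, float))
                for a, b in self.monotonic_rows
            ),
        )
        object.__setattr__(
            self,
            "smoothing_rows",
            tuple(
                (np.asarray(a, float), np.asarray(b, float))
                for a, b in self.smoothing_rows
            ),
        )
        k = len(self.schema)
        self.schema.check_compatible(self.w0.schema)
        for a, b in (*self.monotonic_rows, *self.smoothing_rows):
            if a.shape != (k,) or b.shape != (k,):
                raise ValueError("constraint row has wrong term count")
        if not self.norm_target > 0:
            raise ValueError("norm_target must be positive")

    @property
    def n_rows(self) -> int:
        return len(self.monotonic_rows) + len(self.smoothing_rows)

    def to_json(self, path: str | Path) -> None:
        doc = {
            "schema": list(self.schema.names),
            "w0": [float(v) for v in self.w0.values],
            "monotonic_rows": [
                [a.tolist(), b.tolist()] for a, b in self.monotonic_rows
            ],
            "smoothing_rows": [
                [a.tolist(), b.tolist()] for a, b in self.smoothing_rows
            ],
            "norm_target": self.norm_target,
            "slack_penalty": self.slack_penalty,
            "epsilon": self.epsilon,
        }
        Path(path).write_text(json.dumps(doc, indent=1) + "\n", encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "LPSpec":
        doc = json.loads(Path(path).read_text(encoding="utf-8"))
        schema = TermSchema(tuple(doc["schema"]))
        return cls(
            schema=schema,
            w0=WeightVector(schema, np.array(doc["w0"])),
            monotonic_rows=tuple(
                (np.array(a), np.array(b)) for a, b in doc["monotonic_rows"]
            ),
            smoothing_rows=tuple(
                (np.array(a), np.array(b)) for a, b in doc["smoothing_rows"]
            ),
            norm_target=float(doc["norm_target"]),
            slack_penalty=float(doc["slack_penalty"]),
            epsilon=float(doc["epsilon"]),
        )


@dataclass(frozen=True)
class LPResult:
    """Solved weights, L1 objective, status and per-row slack report."""

    w_star: WeightVector
    objective: float
    status: Literal["optimal", "optimal_with_slack", "infeasible"]
    slack_report: tuple[float, ...]
    message: str = ""

    def to_json(self, path: str | Path) -> None:
        doc = {
            "w_star": self.w_star.as_dict(),
            "objective": self.objective,
            "status": self.status,
            "slack_report": list(self.slack_report),
            "message": self.message,
        }
        Path(path).write_text(json.dumps(doc, indent=1) + "\n", encoding="utf-8")


def build_lp(
    paths: Sequence[ReversePath],
    w0: WeightVector,
    max_points: int = 20,
    slack_penalty: float = 1e4,
    epsilon: float = 0.0,
    smoothing: Literal["mean", "hardest"] = "mean",
) -> LPSpec:
    """Assemble the LP from reverse paths.

    Each path is thinned to at most *max_points* points; every consecutive
    pair contributes one monotonicity row and each path contributes one
    smoothing row.  With smoothing="mean" the row compares the edge point
    against the mean neighbor term vector; "hardest" compares it against
    the single neighbor with the highest energy under w0 (so that at least
    that one neighbor ends up above the edge point).
    """
    if len(paths) == 0:
        raise ValueError("need at least one reverse path")
    schema = w0.schema
    mono: list[tuple[np.ndarray, np.ndarray]] = []
    smooth: list[tuple[np.ndarray, np.ndarray]] = []
    for path in paths:
        if path.m < 1:
            raise ValueError("every path needs at least one neighbor vector")
        thin = subsample_path(path, max_points)
        for p, q in zip(thin.points, thin.points[1:]):
            schema.check_compatible(p.terms.schema)
            mono.append((p.terms.values, q.terms.values))
        nb = np.stack([tv.values for tv in path.neighbor_terms])
        edge = path.edge.terms.values
        if smoothing == "mean":
            target = nb.mean(axis=0)
        elif smoothing == "hardest":
            target = nb[int(np.argmax(nb @ w0.values))]
        else:
            raise ValueError(f"unknown smoothing mode {smoothing!r}")
        smooth.append((edge, target))
    return LPSpec(
        schema=schema,
        w0=w0,
        monotonic_rows=tuple(mono),
        smoothing_rows=tuple(smooth),
        norm_target=l1_norm(w0),
        slack_penalty=slack_penalty,
        epsilon=epsilon,
    )


def _row_matrix(spec: LPSpec) -> np.ndarray:
    """Stack all inequality rows as (lhs - rhs) term-vector differences."""
    rows = [a - b for a, b in spec.monotonic_rows]
    rows += [a - b for a, b in spec.smoothing_rows]
    if rows:
        return np.stack(rows)
    return np.empty((0, len(spec.schema)))


def solve_lp(spec: LPSpec) -> LPResult:
    """Solve the weight-tuning LP with HiGHS.

    Variables are [w (K), u (K), s (R)]: u linearizes |w - w0|, s are
    per-row slacks.  The objective sum(u) + slack_penalty * sum(s) prefers
    any genuinely feasible solution over a slack-violating one.  Status is
    "optimal" iff every slack is below 1e-8, "optimal_with_slack" when the
    solver succeeded but some constraint needed slack, and "infeasible" on
    solver failure (with the solver's diagnostic message attached).
    """
    k = len(spec.schema)
    rows = _row_matrix(spec)
    r = rows.shape[0]
    nvar = 2 * k + r

    c = np.concatenate(
        [np.zeros(k), np.ones(k), np.full(r, spec.slack_penalty)]
    )

    # |w - w0| linearization: w - u <= w0, -w - u <= -w0
    a_ub = np.zeros((2 * k + r, nvar))
    b_ub = np.zeros(2 * k + r)
    eye = np.eye(k)
    a_ub[:k, :k] = eye
    a_ub[:k, k : 2 * k] = -eye
    b_ub[:k] = spec.w0.values
    a_ub[k : 2 * k, :k] = -eye
    a_ub[k : 2 * k, k : 2 * k] = -eye
    b_ub[k : 2 * k] = -spec.w0.values
    # constraint rows: (E_lhs - E_rhs) . w - s_row <= -epsilon
    if r:
        a_ub[2 * k :, :k] = rows
        a_ub[2 * k :, 2 * k :] = -np.eye(r)
        b_ub[2 * k :] = -spec.epsilon

    a_eq = np.zeros((1, nvar))
    a_eq[0, :k] = 1.0
    b_eq = np.array([spec.norm_target])

    res = linprog(
        c,
        A_ub=a_ub,
        b_ub=b_ub,
        A_eq=a_eq,
        b_eq=b_eq,
        bounds=[(0, None)] * nvar,
        method="highs",
    )
    if not res.success:
        return LPResult(
            w_star=spec.w0,
            objective=float("nan"),
            status="infeasible",
            slack_report=tuple([float("nan")] * r),
            message=str(res.message),
        )
    w = np.clip(res.x[:k], 0.0, None)
    slacks = tuple(float(s) for s in res.x[2 * k :])
    w_star = WeightVector(spec.schema, w)
    objective = float(np.abs(w - spec.w0.values).sum())
    status = "optimal" if all(s < _FEAS_TOL for s in slacks) else "optimal_with_slack"
    return LPResult(
        w_star=w_star,
        objective=objective,
        status=status,
        slack_report=slacks,
        message=str(res.message),
    )


def verify_solution(res: LPResult, spec: LPSpec) -> dict:
    """Independently re-check every constraint family at ``res.w_star``.

    Plain numpy re-evaluation, no solver involvement.  Returns per-family
    maximum violations and the indices of violated rows (beyond 1e-8).
    """
    w = res.w_star.values
    mono = np.array(
        [float((a - b) @ w + spec.epsilon) for a, b in spec.monotonic_rows]
    )
    smooth = np.array(
        [float((a - b) @ w + spec.epsilon) for a, b in spec.smoothing_rows]
    )
    norm_violation = abs(float(w.sum()) - spec.norm_target)
    neg_violation = float(max(0.0, -w.min())) if len(w) else 0.0
    report = {
        "max_monotonic_violation": float(mono.max(initial=0.0)),
        "max_smoothing_violation": float(smooth.max(initial=0.0)),
        "norm_violation": norm_violation,
        "negativity_violation": neg_violation,
        "monotonic_violations": [float(max(v, 0.0)) for v in mono],
        "smoothing_violations": [float(max(v, 0.0)) for v in smooth],
        "violated_monotonic_rows": [
            int(i) for i in np.flatnonzero(mono > _FEAS_TOL)
        ],
        "violated_smoothing_rows": [
            int(i) for i in np.flatnonzero(smooth > _FEAS_TOL)
        ],
    }
    report["max_violation"] = max(
        report["max_monotonic_violation"],
        report["max_smoothing_violation"],
        norm_violation,
        neg_violation,
    )
    return report
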