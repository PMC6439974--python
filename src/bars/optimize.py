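"""The BARS driver loop: alternate reverse sampling and LP weight tuning.

Each iteration (i) measures the current basin radius by drawing independent
reverse paths and averaging their edge-point RMSDs, (ii) draws a fresh batch
of reverse paths under the current weights, (iii) solves the weight-tuning
linear program with the current weights as the anchor W0, and (iv) accepts
the tuned weights.  Iteration stops when the Manhattan distance between
successive weight vectors drops below the convergence threshold (0.3 by
default, the published stopping rule) or the iteration budget is exhausted.

By default the LP pools the constraint rows of all paths drawn so far, not
only the current iteration's: monotonicity and smoothing, once demanded of
an edge, remain demanded.  The feasible set then shrinks monotonically,
which damps the weight trajectory (successive changes decrease) and
prevents the loop from re-flattening a direction it already broadened.

Randomness: a master seed fans out into per-(iteration, purpose, path)
child streams via numpy SeedSequence spawn keys, so runs are reproducible
and individual paths are independent and order-invariant.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .lp import LPResult, build_lp, solve_lp
from .sampling import MCConfig, ReversePath, path_radius, reverse_sample
from .toymodel import Conformation, perturb, total_energy
from .weights import WeightVector, l1_distance, write_weights

__all__ = [
    "BarsConfig",
    "BarsState",
    "run_bars",
    "basin_radius",
    "convergence_check",
]

_RADIUS_STREAM = 0
_LP_STREAM = 1
_PRECHECK_STREAM = 2


@dataclass(frozen=True)
class BarsConfig:
    """Outer-loop parameters.

    paths_per_lp    : reverse paths pooled into each LP (one basin has many
                      edges; a single path constrains only one of them).
    radius_paths    : reverse paths per basin-radius measurement (50 is the
                      published protocol; scale down for quick runs).
    m_neighbors     : perturbation neighbors per edge point (published: 1000).
    convergence_tau : Manhattan-distance stopping threshold (published: 0.3).
    max_iterations  : LP-tuning iteration budget.
    max_points      : per-path cap on LP monotonicity points.
    pool_iterations : if True (default), each iteration's LP also keeps the
                      constraint rows of all earlier iterations' paths, so
                      the feasible set only shrinks and the tuned weights
                      cannot oscillate back onto previously smoothened
                      edges.  If False, each LP sees only the current
                      iteration's paths.
    mc              : inner Monte Carlo move parameters.
    seed            : master seed for all randomness.
    measure_after_tuning : if True, the per-iteration radius is measured
                      under that iteration's *tuned* weights instead of the
                      weights it started from.
    """

    paths_per_lp: int = 10
    radius_paths: int = 50
    m_neighbors: int = 1000
    convergence_tau: float = 0.3
    max_iterations: int = 20
    max_points: int = 60
    pool_iterations: bool = True
    mc: MCConfig = field(default_factory=MCConfig)
    seed: int = 0
    measure_after_tuning: bool = False

    def __post_init__(self) -> None:
        if min(self.paths_per_lp, self.radius_paths, self.m_neighbors) < 1:
            raise ValueError("all path/neighbor counts must be >= 1")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if not self.convergence_tau > 0:
            raise ValueError("convergence_tau must be positive")
        if self.max_points < 2:
            raise ValueError("max_points must be >= 2")


@dataclass
class BarsState:
    """Record of one BARS run.

    weight_history[0] is the initial weighting; one entry is appended per
    iteration.  radius_history has one (mean, sd) entry per weighting in
    weight_history: the basin radius measured under that weighting.
    flagged_iterations lists iterations whose LP needed slack.
    """

    weight_history: list[WeightVector]
    delta_history: list[float]
    radius_history: list[tuple[float, float]]
    converged: bool
    iterations_run: int
    flagged_iterations: list[int] = field(default_factory=list)
    aborted: bool = False
    lp_results: list[LPResult] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        doc = {
            "weight_history": [w.as_dict() for w in self.weight_history],
            "delta_history": self.delta_history,
            "radius_history": [
                {"mean": m, "sd": s} for m, s in self.radius_history
            ],
            "converged": self.converged,
            "iterations_run": self.iterations_run,
            "flagged_iterations": self.flagged_iterations,
            "aborted": self.aborted,
            "lp_status": [r.status for r in self.lp_results],
        }
        Path(path).write_text(json.dumps(doc, indent=1) + "\n", encoding="utf-8")


def _child_rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def convergence_check(
    prev: WeightVector, curr: WeightVector, tau: float
) -> bool:
    """True when the Manhattan distance between weightings is below tau."""
    return l1_distance(prev, curr) < tau


def basin_radius(
    native: Conformation,
    w: WeightVector,
    n_paths: int,
    cfg: MCConfig,
    seed: int = 0,
    stream: tuple[int, ...] = (),
    m: int = 1,
) -> tuple[float, float]:
    """Mean and sd of edge-point RMSD over *n_paths* reverse samples.

    Each path runs under its own child seed derived from (seed, stream,
    path index).  A single path reports sd 0 by convention.  Only a token
    neighborhood (m=1) is evaluated per path since neighbors do not enter
    the radius.
    """
    if n_paths < 1:
        raise ValueError("n_paths must be >= 1")
    radii = []
    for p in range(n_paths):
        rng = _child_rng(seed, *stream, p)
        path = reverse_sample(native, w, cfg, m=m, rng=rng)
        radii.append(path_radius(path, native))
    arr = np.asarray(radii)
    sd = float(arr.std()) if n_paths > 1 else 0.0
    return float(arr.mean()), sd


def _draw_lp_paths(
    native: Conformation,
    w: WeightVector,
    cfg: BarsConfig,
    iteration: int,
) -> list[ReversePath]:
    paths = []
    for p in range(cfg.paths_per_lp):
        rng = _child_rng(cfg.seed, _LP_STREAM, iteration, p)
        paths.append(
            reverse_sample(native, w, cfg.mc, m=cfg.m_neighbors, rng=rng)
        )
    return paths


def _warn_if_not_minimum(
    native: Conformation, w0: WeightVector, cfg: BarsConfig, n_probe: int = 50
) -> None:
    rng = _child_rng(cfg.seed, _PRECHECK_STREAM)
    e0 = total_energy(native, w0)
    for _ in range(n_probe):
        cand = perturb(native, rng, cfg.mc.window, cfg.mc.sigma)
        if total_energy(cand, w0) < e0:
            warnings.warn(
                "native structure is not a local minimum of the initial "
                "energy within the move neighborhood; reverse sampling may "
                "not start from the basin bottom",
                stacklevel=3,
            )
            return


def run_bars(
    native: Conformation,
    w0: WeightVector,
    cfg: BarsConfig,
    run_dir: str | Path | None = None,
) -> BarsState:
    """Run the alternating broaden/sample loop until convergence.

    Per iteration: measure the basin radius under the current weights, draw
    ``paths_per_lp`` reverse paths, solve the LP anchored at the current
    weights, and record the tuned weights and their Manhattan delta.  Stops
    early once the delta falls below ``convergence_tau``; aborts (keeping
    the state so far) if the LP reports infeasibility.  After the loop the
    radius under the final weights is measured, so ``radius_history`` always
    has one entry per recorded weighting.

    If *run_dir* is given, per-iteration weights, the radius trajectory and
    the machine-readable state are written there.
    """
    _warn_if_not_minimum(native, w0, cfg)
    state = BarsState(
        weight_history=[w0],
        delta_history=[],
        radius_history=[],
        converged=False,
        iterations_run=0,
    )
    out = Path(run_dir) if run_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        write_weights(w0, out / "weights_iter0.tsv")

    current = w0
    pooled: list[ReversePath] = []
    for t in range(cfg.max_iterations):
        if not cfg.measure_after_tuning:
            state.radius_history.append(
                basin_radius(
                    native,
                    current,
                    cfg.radius_paths,
                    cfg.mc,
                    seed=cfg.seed,
                    stream=(_RADIUS_STREAM, t),
                )
            )
        paths = _draw_lp_paths(native, current, cfg, t)
        if cfg.pool_iterations:
            pooled.extend(paths)
            paths = pooled
        spec = build_lp(paths, current, max_points=cfg.max_points)
        res = solve_lp(spec)
        state.lp_results.append(res)
        if res.status == "infeasible":
            state.aborted = True
            warnings.warn(
                f"LP infeasible at iteration {t}: {res.message}; aborting",
                stacklevel=2,
            )
            if not cfg.measure_after_tuning:
                # keep the one-radius-per-weighting invariant
                state.radius_history = state.radius_history[: len(
                    state.weight_history
                )]
            break
        if res.status == "optimal_with_slack":
            state.flagged_iterations.append(t)
        new_w = res.w_star
        delta = l1_distance(current, new_w)
        state.weight_history.append(new_w)
        state.delta_history.append(delta)
        state.iterations_run = t + 1
        current = new_w
        if cfg.measure_after_tuning:
            state.radius_history.append(
                basin_radius(
                    native,
                    current,
                    cfg.radius_paths,
                    cfg.mc,
                    seed=cfg.seed,
                    stream=(_RADIUS_STREAM, t),
                )
            )
        if out is not None:
            write_weights(current, out / f"weights_iter{t + 1}.tsv")
        if delta < cfg.convergence_tau:
            state.converged = True
            break

    if not cfg.measure_after_tuning and not state.aborted:
        # radius under the final weighting
        state.radius_history.append(
            basin_radius(
                native,
                current,
                cfg.radius_paths,
                cfg.mc,
                seed=cfg.seed,
                stream=(_RADIUS_STREAM, cfg.max_iterations),
            )
        )

    if out is not None:
        lines = ["iteration\tmean_radius\tsd_radius"]
        for i, (mean, sd) in enumerate(state.radius_history):
            lines.append(f"{i}\t{mean:.6g}\t{sd:.6g}")
        (out / "radius.tsv").write_text("\n".join(lines) + "\n", encoding="utf-8")
        state.to_json(out / "state.json")
    return state
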