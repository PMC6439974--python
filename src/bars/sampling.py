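"""Forward Metropolis search and reverse Monte Carlo basin sampling.

Forward search is the usual conformation search: propose a local move,
accept downhill moves always and uphill moves with Metropolis probability
exp(-dE/T).  Reverse sampling inverts this: starting from the native
structure it accepts only strictly energy-increasing moves, walking uphill
until a conformation is reached whose sampled perturbations stop increasing
the energy — an edge point of the native attraction basin.  The RMSD from
the native to the edge point is a rough per-path measure of the basin
radius; the edge point's perturbation neighborhood (m term vectors) is the
raw material for the weight-tuning linear program.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
import numpy as np

from .toymodel import (
    Conformation,
    TermVector,
    kabsch_rmsd,
    perturb,
    term_energies,
    total_energy,
)
from .weights import WeightVector

__all__ = [
    "MCConfig",
    "PathPoint",
    "ReversePath",
    "ForwardResult",
    "forward_search",
    "reverse_sample",
    "edge_neighbors",
    "path_radius",
    "subsample_path",
    "write_path_tsv",
    "write_neighbors_tsv",
]


@dataclass(frozen=True)
class MCConfig:
    """Monte Carlo move/schedule parameters.

    temperature : Metropolis temperature for forward search (energy units).
    max_steps   : accepted-move budget.
    window      : residues per local move.
    sigma       : move size, sd of the Gaussian angle noise (degrees).
    max_fail    : consecutive rejections before reverse sampling declares
                  an edge point.
    seed        : RNG seed used when no generator is supplied.
    """

    temperature: float = 2.0
    max_steps: int = 500
    window: int = 3
    sigma: float = 10.0
    max_fail: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        if self.max_steps < 1:
            raise ValueError("max_steps must be >= 1")
        if self.max_fail < 1:
            raise ValueError("max_fail must be >= 1")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")


@dataclass(frozen=True)
class PathPoint:
    """One accepted conformation on a search path, with its term vector,
    total energy under the generating weights, and RMSD to the native."""

    conformation: Conformation
    terms: TermVector
    energy: float
    rmsd_to_native: float


def _make_point(
    conf: Conformation, w: WeightVector, native: Conformation | None
) -> PathPoint:
    terms = term_energies(conf)
    energy = total_energy(terms, w)
    rmsd = (
        kabsch_rmsd(native.coords, conf.coords)
        if native is not None
        else float("nan")
    )
    return PathPoint(conf, terms, energy, rmsd)


@dataclass(frozen=True)
class ReversePath:
    """A reverse-sampling path S_0 -> S_1 -> ... -> S_n.

    points[0] is the native structure, points[-1] the edge point S_n;
    energies strictly increase along the path.  neighbor_terms are the term
    vectors of the m perturbation neighbors of the edge point.  stopped_by
    records why the walk ended: "max_fail" (the failure budget declared an
    edge point) or "max_steps" (the accepted-step budget ran out first).
    """

    points: tuple[PathPoint, ...]
    neighbor_terms: tuple[TermVector, ...]
    stopped_by: str = "max_fail"

    def __post_init__(self) -> None:
        object.__setattr__(self, "points", tuple(self.points))
        object.__setattr__(self, "neighbor_terms", tuple(self.neighbor_terms))
        if len(self.points) < 1:
            raise ValueError("path must contain at least the native point")
        energies = [p.energy for p in self.points]
        if any(b <= a for a, b in zip(energies, energies[1:])):
            raise ValueError("path energies must strictly increase")

    @property
    def edge_index(self) -> int:
        return len(self.points) - 1

    @property
    def edge(self) -> PathPoint:
        return self.points[-1]

    @property
    def m(self) -> int:
        return len(self.neighbor_terms)


@dataclass(frozen=True)
class ForwardResult:
    """Accepted-state trajectory of a forward search plus its best point."""

    trajectory: tuple[PathPoint, ...]
    best: PathPoint


def _resolve_rng(
    cfg: MCConfig, rng: np.random.Generator | None
) -> np.random.Generator:
    return rng if rng is not None else np.random.default_rng(cfg.seed)


def forward_search(
    init: Conformation,
    w: WeightVector,
    cfg: MCConfig,
    rng: np.random.Generator | None = None,
    native: Conformation | None = None,
) -> ForwardResult:
    """Metropolis search for low energy, starting from *init*.

    Downhill proposals are always accepted; an uphill proposal of height dE
    is accepted with probability exp(-dE / temperature).  Returns the
    trajectory of accepted states (including the start) and the best-energy
    point seen.  Deterministic given the generator state.
    """
    rng = _resolve_rng(cfg, rng)
    current = _make_point(init, w, native)
    trajectory = [current]
    best = current
    for _ in range(cfg.max_steps):
        cand = perturb(current.conformation, rng, cfg.window, cfg.sigma)
        terms = term_energies(cand)
        energy = total_energy(terms, w)
        d_e = energy - current.energy
        if d_e <= 0 or rng.random() < np.exp(-d_e / cfg.temperature):
            rmsd = (
                kabsch_rmsd(native.coords, cand.coords)
                if native is not None
                else float("nan")
            )
            current = PathPoint(cand, terms, energy, rmsd)
            trajectory.append(current)
            if current.energy < best.energy:
                best = current
    return ForwardResult(tuple(trajectory), best)


def edge_neighbors(
    edge: Conformation,
    m: int,
    cfg: MCConfig,
    rng: np.random.Generator | None = None,
) -> list[TermVector]:
    """Term vectors of *m* independent perturbation neighbors of *edge*."""
    if m < 1:
        raise ValueError("m must be >= 1")
    rng = _resolve_rng(cfg, rng)
    out = []
    for _ in range(m):
        cand = perturb(edge, rng, cfg.window, cfg.sigma)
        out.append(term_energies(cand))
    return out


def reverse_sample(
    native: Conformation,
    w: WeightVector,
    cfg: MCConfig,
    m: int = 1000,
    rng: np.random.Generator | None = None,
) -> ReversePath:
    """Greedy uphill walk from the native to an edge of its basin.

    A proposal is appended iff its energy is strictly greater than the
    current point's.  The walk stops after cfg.max_fail consecutive
    rejections (the current point is then the edge point: its sampled
    perturbations no longer increase the energy) or after cfg.max_steps
    accepted points.  Finally the edge point's m perturbation neighbors are
    evaluated and their term vectors attached.
    """
    rng = _resolve_rng(cfg, rng)
    current = _make_point(native, w, native)
    if not np.isfinite(current.energy):
        raise ValueError("native energy must be finite")
    points = [current]
    fails = 0
    accepted = 0
    while fails < cfg.max_fail and accepted < cfg.max_steps:
        cand = perturb(current.conformation, rng, cfg.window, cfg.sigma)
        terms = term_energies(cand)
        energy = total_energy(terms, w)
        if energy > current.energy:
            current = PathPoint(
                cand, terms, energy, kabsch_rmsd(native.coords, cand.coords)
            )
            points.append(current)
            accepted += 1
            fails = 0
        else:
            fails += 1
    stopped_by = "max_fail" if fails >= cfg.max_fail else "max_steps"
    neighbors = edge_neighbors(current.conformation, m, cfg, rng)
    return ReversePath(tuple(points), tuple(neighbors), stopped_by)


def path_radius(path: ReversePath, native: Conformation) -> float:
    """RMSD between the native structure and the path's edge point (A)."""
    return kabsch_rmsd(native.coords, path.edge.conformation.coords)


def subsample_path(path: ReversePath, max_points: int) -> ReversePath:
    """Thin a path to at most *max_points* points at uniform index spacing.

    The endpoints (native and edge point) are always kept; strict energy
    increase is preserved because any subsequence of a strictly increasing
    sequence is strictly increasing.
    """
    if max_points < 2:
        raise ValueError("max_points must be >= 2")
    n = len(path.points)
    if n <= max_points:
        return path
    idx = np.unique(np.round(np.linspace(0, n - 1, max_points)).astype(int))
    return ReversePath(
        tuple(path.points[i] for i in idx),
        path.neighbor_terms,
        path.stopped_by,
    )


def _fmt(x: float) -> str:
    return f"{x:.6g}"


def write_path_tsv(path: ReversePath, out: str | Path) -> None:
    """Archive a path as TSV: point_index, energy, rmsd_to_native, terms."""
    schema = path.points[0].terms.schema
    lines = ["\t".join(["point_index", "energy", "rmsd_to_native", *schema.names])]
    for i, p in enumerate(path.points):
        lines.append(
            "\t".join(
                [str(i), _fmt(p.energy), _fmt(p.rmsd_to_native)]
                + [_fmt(v) for v in p.terms.values]
            )
        )
    Path(out).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_neighbors_tsv(path: ReversePath, out: str | Path) -> None:
    """Archive the edge point's neighbor term vectors as TSV."""
    schema = path.points[0].terms.schema
    lines = ["\t".join(["neighbor_index", *schema.names])]
    for i, tv in enumerate(path.neighbor_terms):
        lines.append("\t".join([str(i)] + [_fmt(v) for v in tv.values]))
    Path(out).write_text("\n".join(lines) + "\n", encoding="utf-8")
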