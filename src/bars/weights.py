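"""Weight vectors over named energy terms.

An energy function here is a weighted sum ``W · E`` of per-term energies.
This module provides the weight-vector data type, the arithmetic used to
compare weighting schemes (Manhattan distance, cosine similarity, L1 norm),
TSV/JSON serialization, and the published BARS weighting schemes for the
benchmark proteins 1ctfA, 1iloA and 1iieA (13-term Rosetta score3 schema),
stored exactly as printed at two decimals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np

__all__ = [
    "TermSchema",
    "WeightVector",
    "SchemaMismatchError",
    "SCORE3_SCHEMA",
    "l1_distance",
    "cosine",
    "l1_norm",
    "read_weights",
    "write_weights",
    "score3_trajectory_1ctfA",
    "published_final_weights",
]


class SchemaMismatchError(ValueError):
    """Raised when two weight/term vectors use incompatible term schemas."""


@dataclass(frozen=True)
class TermSchema:
    """Ordered collection of unique, non-empty energy-term names."""

    names: tuple[str, ...]

    def __post_init__(self) -> None:
        names = tuple(self.names)
        object.__setattr__(self, "names", names)
        if len(names) < 1:
            raise ValueError("schema needs at least one term")
        if any(not isinstance(n, str) or not n for n in names):
            raise ValueError("term names must be non-empty strings")
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate term names: {dupes}")

    def __len__(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)

    def check_compatible(self, other: "TermSchema") -> None:
        if self.names != other.names:
            only_self = [n for n in self.names if n not in other.names]
            only_other = [n for n in other.names if n not in self.names]
            raise SchemaMismatchError(
                "incompatible term schemas: "
                f"only in first: {only_self}; only in second: {only_other}; "
                f"order differs: {sorted(self.names) == sorted(other.names)}"
            )


#: The 13 residue-level term names of Rosetta's score3, in table order.
SCORE3_SCHEMA = TermSchema(
    (
        "Env",
        "Pair",
        "Vdw",
        "Hs",
        "Ss",
        "Sheet",
        "R-sigma",
        "Cb",
        "Rg",
        "Co",
        "Ramachandran",
        "Hb-srbb",
        "Hb-lrbb",
    )
)


@dataclass(frozen=True)
class WeightVector:
    """Nonnegative, finite weights over a term schema.

    Weights are dimensionless multipliers; nonnegativity is a structural
    requirement of the weight-tuning linear program (``W >= 0``).
    """

    schema: TermSchema
    values: np.ndarray = field(compare=False)

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float).copy()
        if vals.shape != (len(self.schema),):
            raise ValueError(
                f"expected {len(self.schema)} weights, got shape {vals.shape}"
            )
        if not np.all(np.isfinite(vals)):
            raise ValueError("weights must be finite")
        if np.any(vals < 0):
            bad = [self.schema.names[i] for i in np.flatnonzero(vals < 0)]
            raise ValueError(f"negative weights for terms: {bad}")
        vals.flags.writeable = False
        object.__setattr__(self, "values", vals)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WeightVector):
            return NotImplemented
        return self.schema == other.schema and np.array_equal(
            self.values, other.values
        )

    def __hash__(self) -> int:  # frozen dataclass with array payload
        return hash((self.schema, self.values.tobytes()))

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.schema.index(name)])

    def as_dict(self) -> dict[str, float]:
        return {n: float(v) for n, v in zip(self.schema.names, self.values)}

    @classmethod
    def from_mapping(
        cls, mapping: Mapping[str, float], schema: TermSchema | None = None
    ) -> "WeightVector":
        if schema is None:
            schema = TermSchema(tuple(mapping.keys()))
        missing = [n for n in schema.names if n not in mapping]
        if missing:
            raise ValueError(f"missing weights for terms: {missing}")
        unknown = [n for n in mapping if n not in schema.names]
        if unknown:
            raise ValueError(f"unknown terms not in schema: {unknown}")
        return cls(schema, np.array([mapping[n] for n in schema.names]))

    @classmethod
    def uniform(cls, schema: TermSchema, value: float = 1.0) -> "WeightVector":
        return cls(schema, np.full(len(schema), float(value)))


def l1_distance(a: WeightVector, b: WeightVector) -> float:
    """Manhattan (L1) distance between two weighting schemes.

    This is the metric used both to compare successive weighting schemes
    during iteration and as the convergence criterion.
    """
    a.schema.check_compatible(b.schema)
    return float(np.abs(a.values - b.values).sum())


def cosine(a: WeightVector, b: WeightVector) -> float:
    """Cosine of the angle between two weight vectors; in [0, 1].

    Nonnegative weights confine both vectors to the positive orthant, so
    the cosine cannot be negative.
    """
    a.schema.check_compatible(b.schema)
    na = float(np.linalg.norm(a.values))
    nb = float(np.linalg.norm(b.values))
    if na == 0.0 or nb == 0.0:
        raise ValueError("cosine undefined for a zero-norm weight vector")
    return float(np.dot(a.values, b.values) / (na * nb))


def l1_norm(w: WeightVector) -> float:
    """Total weight ``|W| = sum_k w_k`` (equals the L1 norm since W >= 0)."""
    return float(w.values.sum())


def _parse_weight(term: str, raw: str) -> float:
    try:
        value = float(raw)
    except ValueError as exc:
        raise ValueError(f"non-numeric weight {raw!r} for term {term!r}") from exc
    return value


def read_weights(
    path: str | Path, schema: TermSchema | None = None
) -> WeightVector:
    """Read a weight vector from a two-column TSV or a flat JSON object.

    TSV layout: header ``term<TAB>weight``, one row per term.  If *schema*
    is given the file must cover exactly its terms; otherwise the file's
    own term order defines the schema.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    mapping: dict[str, float] = {}
    if path.suffix.lower() == ".json":
        obj = json.loads(text)
        if not isinstance(obj, dict):
            raise ValueError("weight JSON must be a flat object {term: weight}")
        for term, raw in obj.items():
            mapping[term] = float(raw)
    else:
        lines = [ln for ln in text.splitlines() if ln.strip()]
        if not lines:
            raise ValueError(f"empty weight file: {path}")
        start = 1 if lines[0].lower().startswith("term") else 0
        for ln in lines[start:]:
            parts = ln.split("\t")
            if len(parts) != 2:
                raise ValueError(f"expected 'term<TAB>weight', got {ln!r}")
            term = parts[0].strip()
            if term in mapping:
                raise ValueError(f"duplicate term {term!r} in {path}")
            mapping[term] = _parse_weight(term, parts[1].strip())
    return WeightVector.from_mapping(mapping, schema)


def write_weights(w: WeightVector, path: str | Path) -> None:
    """Write a weight vector as TSV (or JSON if the path ends in .json)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(
            json.dumps(w.as_dict(), indent=2, sort_keys=False) + "\n",
            encoding="utf-8",
        )
        return
    lines = ["term\tweight"]
    for name, value in zip(w.schema.names, w.values):
        lines.append(f"{name}\t{float(value)!r}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def _load_packaged(name: str) -> WeightVector:
    ref = resources.files("bars.data").joinpath(name)
    with resources.as_file(ref) as fp:
        return read_weights(fp, SCORE3_SCHEMA)


def score3_trajectory_1ctfA() -> list[WeightVector]:
    """The published 1ctfA weighting trajectory: initial score3 weights
    followed by the six BARS iterates, exactly as printed (two decimals)."""
    names = ["weights_1ctfA_initial.tsv"] + [
        f"weights_1ctfA_iter{i}.tsv" for i in range(1, 7)
    ]
    return [_load_packaged(n) for n in names]


def published_final_weights() -> dict[str, WeightVector]:
    """Published final (converged) weights per benchmark protein."""
    return {
        "1ctfA": _load_packaged("weights_1ctfA_iter6.tsv"),
        "1iloA": _load_packaged("weights_1iloA_final.tsv"),
        "1iieA": _load_packaged("weights_1iieA_final.tsv"),
    }
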