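"""Coarse-grained C-alpha protein model with a decomposable toy energy.

The chain is a sequence of pseudo-atoms connected by virtual bonds of fixed
length 3.8 Angstrom and parameterized by internal coordinates: N-2 pseudo
bond angles (degrees, open interval (0, 180)) and N-3 pseudo torsions
(degrees, half-open (-180, 180]).  Cartesian coordinates are a deterministic
function of the internal coordinates under a fixed chain-build convention.

The energy is a weighted sum of K=6 terms that play the roles of the usual
residue-level knowledge-based terms (steric clash, compactness, secondary-
structure local geometry, native contacts, helical hydrogen-bond proxy,
hydrophobic burial).  The weighted-sum interface — not the physical realism
of any individual term — is what the weight-optimization machinery needs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Iterable

import numpy as np
from scipy.spatial.transform import Rotation

from .weights import TermSchema, WeightVector

__all__ = [
    "BOND_LENGTH",
    "TOY_SCHEMA",
    "SS_IDEALS",
    "ToyProtein",
    "Conformation",
    "TermVector",
    "build_coords",
    "term_energies",
    "total_energy",
    "perturb",
    "kabsch_rmsd",
    "radius_of_gyration",
    "write_ca_pdb",
    "read_ca_pdb",
]

#: Virtual C-alpha - C-alpha bond length in Angstrom.
BOND_LENGTH = 3.8

#: Margin keeping pseudo bond angles strictly inside (0, 180) degrees.
_ANGLE_EPS = 1e-6

#: Term schema of the toy energy function.
TOY_SCHEMA = TermSchema(
    ("clash", "rg", "ss_local", "contact", "hbond", "env")
)

#: Ideal (pseudo bond angle, pseudo torsion) per secondary-structure state.
SS_IDEALS = {"H": (89.0, 50.0), "E": (120.0, -170.0)}

_CLASH_CUT = 4.0       # Angstrom, soft steric radius
_CONTACT_CUT = 8.0     # Angstrom, native-contact distance
_ENV_CUT = 10.0        # Angstrom, burial neighborhood
_ENV_MIN_NEIGHBORS = 4
_HBOND_IDEAL = 6.2     # Angstrom, helical i,i+4 distance
_HBOND_CAP = 25.0
_RG_COEF = 2.2         # target Rg = 2.2 * N**0.38 (Flory-like scaling)
_RG_EXP = 0.38
_SS_SCALE = 1000.0


@dataclass(frozen=True)
class ToyProtein:
    """Topology of a toy protein: secondary structure labels, a hydrophobic
    pattern and a set of native attraction (contact) pairs."""

    length: int
    ss_labels: tuple[str, ...]
    hydrophobic: tuple[bool, ...]
    attraction_pairs: frozenset[tuple[int, int]]

    def __post_init__(self) -> None:
        object.__setattr__(self, "ss_labels", tuple(self.ss_labels))
        object.__setattr__(self, "hydrophobic", tuple(self.hydrophobic))
        object.__setattr__(
            self, "attraction_pairs", frozenset(self.attraction_pairs)
        )
        if self.length < 4:
            raise ValueError("need at least 4 residues")
        if len(self.ss_labels) != self.length:
            raise ValueError("ss_labels length mismatch")
        if any(s not in ("H", "E", "C") for s in self.ss_labels):
            raise ValueError("ss labels must be in {H, E, C}")
        if len(self.hydrophobic) != self.length:
            raise ValueError("hydrophobic length mismatch")
        for i, j in self.attraction_pairs:
            if not (0 <= i < j < self.length):
                raise ValueError(f"bad pair indices ({i}, {j})")
            if j - i < 3:
                raise ValueError(f"pair ({i}, {j}) too close in sequence")


def _wrap_torsion(t: np.ndarray | float):
    """Wrap torsions into the half-open interval (-180, 180]."""
    return 180.0 - np.mod(180.0 - np.asarray(t, dtype=float), 360.0)


def build_coords(
    bond_angles: np.ndarray, torsions: np.ndarray
) -> np.ndarray:
    """Build N x 3 Cartesian coordinates from internal coordinates.

    Convention: residue 0 at the origin, residue 1 on the +x axis, residue 2
    in the xy half-plane with positive y; each later residue is placed from
    the three preceding ones by (bond = 3.8 A, bond angle, torsion), the
    standard natural-extension (NeRF) construction.
    """
    theta = np.asarray(bond_angles, dtype=float)
    phi = np.asarray(torsions, dtype=float)
    if theta.ndim != 1 or phi.ndim != 1 or len(theta) != len(phi) + 1:
        raise ValueError("need N-2 bond angles and N-3 torsions")
    if np.any(theta <= 0.0) or np.any(theta >= 180.0):
        raise ValueError("bond angles must lie strictly inside (0, 180)")
    if np.any(phi <= -180.0) or np.any(phi > 180.0):
        raise ValueError("torsions must lie in (-180, 180]")
    n = len(theta) + 2
    coords = np.zeros((n, 3))
    coords[1] = (BOND_LENGTH, 0.0, 0.0)
    th0 = np.radians(theta[0])
    coords[2] = coords[1] + BOND_LENGTH * np.array(
        [-np.cos(th0), np.sin(th0), 0.0]
    )
    th = np.radians(theta[1:])
    ph = np.radians(phi)
    # scalar inner loop: small-vector numpy ops are the bottleneck here
    cos_t, sin_t = np.cos(th), np.sin(th)
    cos_p, sin_p = np.cos(ph), np.sin(ph)
    ax, ay, az = coords[0]
    bx, by, bz = coords[1]
    cx, cy, cz = coords[2]
    from math import sqrt

    for i in range(3, n):
        bcx, bcy, bcz = cx - bx, cy - by, cz - bz
        inv = 1.0 / sqrt(bcx * bcx + bcy * bcy + bcz * bcz)
        bcx, bcy, bcz = bcx * inv, bcy * inv, bcz * inv
        abx, aby, abz = bx - ax, by - ay, bz - az
        nx = aby * bcz - abz * bcy
        ny = abz * bcx - abx * bcz
        nz = abx * bcy - aby * bcx
        inv = 1.0 / sqrt(nx * nx + ny * ny + nz * nz)
        nx, ny, nz = nx * inv, ny * inv, nz * inv
        mx = ny * bcz - nz * bcy
        my = nz * bcx - nx * bcz
        mz = nx * bcy - ny * bcx
        k = i - 3
        c1 = -BOND_LENGTH * cos_t[k]
        c2 = BOND_LENGTH * sin_t[k] * cos_p[k]
        c3 = BOND_LENGTH * sin_t[k] * sin_p[k]
        dx = c1 * bcx + c2 * mx + c3 * nx
        dy = c1 * bcy + c2 * my + c3 * ny
        dz = c1 * bcz + c2 * mz + c3 * nz
        ax, ay, az = bx, by, bz
        bx, by, bz = cx, cy, cz
        cx, cy, cz = cx + dx, cy + dy, cz + dz
        coords[i] = (cx, cy, cz)
    return coords


@dataclass(frozen=True)
class Conformation:
    """A chain conformation in internal coordinates with derived Cartesian
    C-alpha coordinates (built eagerly, immutable thereafter)."""

    protein: ToyProtein
    bond_angles: np.ndarray = field(compare=False)
    torsions: np.ndarray = field(compare=False)
    coords: np.ndarray = field(init=False, compare=False)

    def __post_init__(self) -> None:
        ba = np.asarray(self.bond_angles, dtype=float).copy()
        to = np.asarray(self.torsions, dtype=float).copy()
        n = self.protein.length
        if ba.shape != (n - 2,):
            raise ValueError(f"expected {n - 2} bond angles, got {ba.shape}")
        if to.shape != (n - 3,):
            raise ValueError(f"expected {n - 3} torsions, got {to.shape}")
        xyz = build_coords(ba, to)
        for arr in (ba, to, xyz):
            arr.flags.writeable = False
        object.__setattr__(self, "bond_angles", ba)
        object.__setattr__(self, "torsions", to)
        object.__setattr__(self, "coords", xyz)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Conformation):
            return NotImplemented
        return (
            self.protein == other.protein
            and np.array_equal(self.bond_angles, other.bond_angles)
            and np.array_equal(self.torsions, other.torsions)
        )

    def __hash__(self) -> int:
        return hash(
            (self.protein, self.bond_angles.tobytes(), self.torsions.tobytes())
        )


@dataclass(frozen=True)
class TermVector:
    """Per-term unweighted energies of one conformation."""

    schema: TermSchema
    values: np.ndarray = field(compare=False)

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float).copy()
        if vals.shape != (len(self.schema),):
            raise ValueError(
                f"expected {len(self.schema)} term energies, got {vals.shape}"
            )
        if not np.all(np.isfinite(vals)):
            raise ValueError("term energies must be finite")
        vals.flags.writeable = False
        object.__setattr__(self, "values", vals)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TermVector):
            return NotImplemented
        return self.schema == other.schema and np.array_equal(
            self.values, other.values
        )

    def __hash__(self) -> int:
        return hash((self.schema, self.values.tobytes()))


def radius_of_gyration(coords: np.ndarray) -> float:
    """Root mean square distance of the points from their centroid (A)."""
    xyz = np.asarray(coords, dtype=float)
    if xyz.ndim != 2 or xyz.shape[0] < 1:
        raise ValueError("need an N x 3 coordinate array with N >= 1")
    centered = xyz - xyz.mean(axis=0)
    return float(np.sqrt((centered**2).sum(axis=1).mean()))


@lru_cache(maxsize=64)
def _term_index_cache(prot: ToyProtein):
    """Precomputed index arrays for the counting/SS terms of one protein."""
    n = prot.length
    ang_idx, ang_ideal = [], []
    tor_idx, tor_ideal = [], []
    for i, label in enumerate(prot.ss_labels):
        ideal = SS_IDEALS.get(label)
        if ideal is None:
            continue
        if 1 <= i <= n - 2:
            ang_idx.append(i - 1)
            ang_ideal.append(ideal[0])
        if 1 <= i <= n - 3:
            tor_idx.append(i - 1)
            tor_ideal.append(ideal[1])
    pairs = np.array(sorted(prot.attraction_pairs), dtype=int).reshape(-1, 2)
    hb = np.array(
        [
            i
            for i in range(n - 4)
            if all(prot.ss_labels[i + k] == "H" for k in range(5))
        ],
        dtype=int,
    )
    phob = np.flatnonzero(np.asarray(prot.hydrophobic, dtype=bool))
    return (
        np.array(ang_idx, int),
        np.array(ang_ideal),
        np.array(tor_idx, int),
        np.array(tor_ideal),
        pairs,
        hb,
        phob,
    )


def term_energies(conf: Conformation) -> TermVector:
    """Evaluate the six toy energy terms of a conformation.

    clash    : sum over |i-j| >= 3 of max(0, 4.0 - d_ij)^2
    rg       : (Rg - 2.2 N^0.38)^2
    ss_local : per-residue squared deviation of pseudo angle/torsion from
               the secondary-structure ideal, / 1000 (coil contributes 0)
    contact  : minus the number of attraction pairs within 8 A
    hbond    : for every window i..i+4 of five helical residues,
               min((d_{i,i+4} - 6.2)^2, 25)
    env      : for every hydrophobic residue, max(0, 4 - burial count),
               burial = sequence-distant neighbors (|i-j| >= 3) within 10 A
    """
    prot = conf.protein
    n = prot.length
    xyz = conf.coords
    sep = xyz[:, None, :] - xyz[None, :, :]
    dmat = np.sqrt((sep * sep).sum(axis=2))
    ii, jj = np.triu_indices(n, k=3)
    dlong = dmat[ii, jj]
    ang_idx, ang_ideal, tor_idx, tor_ideal, pairs, hb, phob = (
        _term_index_cache(prot)
    )

    clash = float((np.clip(_CLASH_CUT - dlong, 0.0, None) ** 2).sum())

    centered = xyz - xyz.mean(axis=0)
    rg_val = np.sqrt((centered * centered).sum(axis=1).mean())
    rg = (rg_val - _RG_COEF * n**_RG_EXP) ** 2

    ss_local = float(
        ((conf.bond_angles[ang_idx] - ang_ideal) ** 2).sum()
        + (_wrap_torsion(conf.torsions[tor_idx] - tor_ideal) ** 2).sum()
    ) / _SS_SCALE

    if len(pairs):
        contact = -float((dmat[pairs[:, 0], pairs[:, 1]] < _CONTACT_CUT).sum())
    else:
        contact = 0.0

    if len(hb):
        dev = (dmat[hb, hb + 4] - _HBOND_IDEAL) ** 2
        hbond = float(np.minimum(dev, _HBOND_CAP).sum())
    else:
        hbond = 0.0

    if len(phob):
        sub = dmat[phob]  # rows: hydrophobic residues
        seq = np.arange(n)
        mask = (sub < _ENV_CUT) & (np.abs(phob[:, None] - seq[None, :]) >= 3)
        counts = mask.sum(axis=1)
        env = float(np.clip(_ENV_MIN_NEIGHBORS - counts, 0, None).sum())
    else:
        env = 0.0

    return TermVector(
        TOY_SCHEMA,
        np.array([clash, rg, ss_local, contact, hbond, env]),
    )


def total_energy(
    conf: Conformation | TermVector, w: WeightVector
) -> float:
    """Weighted-sum energy ``W . E``; linear and homogeneous in the weights."""
    terms = conf if isinstance(conf, TermVector) else term_energies(conf)
    w.schema.check_compatible(terms.schema)
    return float(np.dot(w.values, terms.values))


def perturb(
    conf: Conformation,
    rng: np.random.Generator,
    window: int = 3,
    sigma: float = 10.0,
) -> Conformation:
    """Gaussian local move: perturb a random contiguous window of internal
    coordinates (both torsions and bond angles) with sd *sigma* degrees.

    Stand-in for fragment replacement: a compact local change that moves
    everything downstream of the window rigidly.  The input conformation is
    left unmodified; the move is deterministic given the generator state.
    """
    n = conf.protein.length
    if not 1 <= window <= n - 3:
        raise ValueError(f"window must be in [1, {n - 3}], got {window}")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    start = int(rng.integers(0, n - 2 - window))  # torsion window fits
    ba = conf.bond_angles.copy()
    to = conf.torsions.copy()
    ba[start : start + window] += rng.normal(0.0, sigma, window)
    to[start : start + window] += rng.normal(0.0, sigma, window)
    np.clip(ba, _ANGLE_EPS, 180.0 - _ANGLE_EPS, out=ba)
    to = _wrap_torsion(to)
    return Conformation(conf.protein, ba, to)


def kabsch_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Minimum RMSD over proper rotations + translations (Kabsch), in A.

    Reflections are excluded; the result is symmetric in its arguments and
    zero iff the two point sets are congruent.
    """
    pa = np.asarray(a, dtype=float)
    pb = np.asarray(b, dtype=float)
    if pa.shape != pb.shape:
        raise ValueError(f"size mismatch: {pa.shape} vs {pb.shape}")
    if pa.ndim != 2 or pa.shape[0] < 3 or pa.shape[1] != 3:
        raise ValueError("need N x 3 arrays with N >= 3")
    ca = pa - pa.mean(axis=0)
    cb = pb - pb.mean(axis=0)
    rot, _ = Rotation.align_vectors(ca, cb)
    diff = ca - rot.apply(cb)  # explicit residual: rssd loses precision
    return float(np.sqrt((diff**2).sum() / pa.shape[0]))


def write_ca_pdb(
    path: str | Path,
    coords: np.ndarray | Iterable[np.ndarray],
    multi_model: bool = False,
) -> None:
    """Write C-alpha traces as standard PDB ATOM records (chain A, GLY)."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    if multi_model:
        models = [np.asarray(c, dtype=float) for c in coords]
    else:
        models = [np.asarray(coords, dtype=float)]
    n = models[0].shape[0]
    atoms = struc.AtomArrayStack(len(models), n)
    atoms.coord = np.stack(models)
    atoms.chain_id = np.full(n, "A")
    atoms.res_id = np.arange(1, n + 1)
    atoms.res_name = np.full(n, "GLY")
    atoms.atom_name = np.full(n, "CA")
    atoms.element = np.full(n, "C")
    atoms.hetero = np.zeros(n, dtype=bool)
    atoms.set_annotation("occupancy", np.ones(n))
    atoms.set_annotation("b_factor", np.zeros(n))
    f = pdb.PDBFile()
    f.set_structure(atoms)
    f.write(str(path))


def read_ca_pdb(path: str | Path, chain: str | None = None) -> np.ndarray:
    """Read the C-alpha trace of one chain from a PDB file.

    Returns an N x 3 array (first model).  If *chain* is None the first
    chain containing CA atoms is used.
    """
    import biotite.structure.io.pdb as pdb

    f = pdb.PDBFile.read(str(path))
    atoms = f.get_structure(model=1)
    mask = atoms.atom_name == "CA"
    if chain is None:
        chains = atoms.chain_id[mask]
        if len(chains) == 0:
            raise ValueError(f"no CA atoms in {path}")
        chain = chains[0]
    mask &= atoms.chain_id == chain
    if not mask.any():
        raise ValueError(f"no CA atoms for chain {chain!r} in {path}")
    return np.asarray(atoms.coord[mask], dtype=float)
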