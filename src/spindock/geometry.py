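"""Structure I/O, rigid bodies, transforms, superposition and rotation sampling.

All coordinates are in Angstrom. Residue numbering is taken verbatim from the
source file (author numbering); chains are never remapped implicitly.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Atom",
    "RigidBody",
    "Transform",
    "load_structure",
    "write_pdb",
    "transform_body",
    "superpose",
    "sample_rotation",
]

_ORTHO_TOL = 1e-8


@dataclasses.dataclass(frozen=True)
class Atom:
    """A single atom with PDB-style naming and a position in Angstrom."""

    chain_id: str
    residue_number: int
    residue_name: str
    atom_name: str
    element: str
    position: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,):
            raise ValueError(f"position must be a 3-vector, got shape {pos.shape}")
        if not np.all(np.isfinite(pos)):
            raise ValueError("atom position must be finite")
        if not self.atom_name:
            raise ValueError("atom_name must be non-empty")
        object.__setattr__(self, "position", pos)

    def distance_to(self, other: "Atom") -> float:
        return float(np.linalg.norm(self.position - other.position))


class RigidBody:
    """An ordered, immutable collection of atoms moved only by rigid transforms."""

    def __init__(self, name: str, atoms: Sequence[Atom], source: str = ""):
        if len(atoms) == 0:
            raise ValueError("RigidBody needs at least one atom")
        self.name = name
        self.atoms = tuple(atoms)
        self.source = source
        self._coords = np.array([a.position for a in self.atoms], dtype=float)
        self._coords.setflags(write=False)

    @property
    def coords(self) -> np.ndarray:
        """(N, 3) coordinate array, read-only view."""
        return self._coords

    def __len__(self) -> int:
        return len(self.atoms)

    def __repr__(self) -> str:
        return f"RigidBody({self.name!r}, {len(self)} atoms)"

    @property
    def chain_ids(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain_id, None)
        return tuple(seen)

    def select(
        self,
        chain_id: str | None = None,
        residue_number: int | None = None,
        atom_name: str | None = None,
    ) -> list[Atom]:
        """All atoms matching the given (optional) chain / residue / atom name."""
        out = []
        for a in self.atoms:
            if chain_id is not None and a.chain_id != chain_id:
                continue
            if residue_number is not None and a.residue_number != residue_number:
                continue
            if atom_name is not None and a.atom_name != atom_name:
                continue
            out.append(a)
        return out

    def atom(self, chain_id: str, residue_number: int, atom_name: str) -> Atom:
        """The unique atom with the given selector, or KeyError."""
        hits = self.select(chain_id, residue_number, atom_name)
        if not hits:
            raise KeyError(
                f"no atom {chain_id}/{residue_number}/{atom_name} in body {self.name!r}"
            )
        if len(hits) > 1:
            raise KeyError(
                f"selector {chain_id}/{residue_number}/{atom_name} is ambiguous "
                f"({len(hits)} atoms)"
            )
        return hits[0]

    def backbone_indices(self) -> np.ndarray:
        names = {"N", "CA", "C", "O"}
        return np.array(
            [i for i, a in enumerate(self.atoms) if a.atom_name in names], dtype=int
        )

    def with_coords(self, coords: np.ndarray) -> "RigidBody":
        """New body with identical atom metadata but replaced coordinates."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != self._coords.shape:
            raise ValueError("coordinate array shape mismatch")
        atoms = [
            dataclasses.replace(a, position=coords[i]) for i, a in enumerate(self.atoms)
        ]
        return RigidBody(self.name, atoms, self.source)


class Transform:
    """A proper rigid transform p -> R p + t (rotation 3x3, translation Angstrom)."""

    def __init__(self, rotation: np.ndarray, translation: np.ndarray):
        rotation = np.asarray(rotation, dtype=float)
        translation = np.asarray(translation, dtype=float).reshape(3)
        _check_rotation(rotation)
        self.rotation = rotation
        self.translation = translation

    @classmethod
    def identity(cls) -> "Transform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        return points @ self.rotation.T + self.translation

    def compose(self, other: "Transform") -> "Transform":
        """self after other: (self @ other)(p) = self(other(p))."""
        return Transform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "Transform":
        rt = self.rotation.T
        return Transform(rt, -rt @ self.translation)

    def __matmul__(self, other: "Transform") -> "Transform":
        return self.compose(other)

    def __repr__(self) -> str:
        return f"Transform(t={np.round(self.translation, 3)})"


def _check_rotation(rotation: np.ndarray) -> None:
    if rotation.shape != (3, 3):
        raise ValueError("rotation must be 3x3")
    err = np.abs(rotation @ rotation.T - np.eye(3)).max()
    if err > 1e-6:
        raise ValueError(f"rotation is not orthonormal (max deviation {err:.2e})")
    if np.linalg.det(rotation) < 0:
        raise ValueError("rotation has determinant -1 (reflection)")


def transform_body(body: RigidBody, t: Transform) -> RigidBody:
    """Apply a rigid transform to every atom of a body."""
    return body.with_coords(t.apply(body.coords))


# --------------------------------------------------------------------------
# PDB I/O (Biopython-backed reader; minimal writer for ATOM/MODEL records)
# --------------------------------------------------------------------------

def load_structure(
    path: str | Path,
    chain_filter: Iterable[str] | None = None,
    model_index: int = 0,
    name: str | None = None,
    keep_hydrogens: bool = False,
    keep_het: bool = False,
) -> RigidBody:
    """Load a PDB file into a RigidBody.

    Alternate locations are resolved to the highest-occupancy conformer.
    Hydrogens and waters are dropped by default.
    """
    from Bio.PDB import PDBParser

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(path.stem, str(path))
    models = list(structure)
    if model_index >= len(models):
        raise IndexError(f"model {model_index} absent ({len(models)} models in file)")
    model = models[model_index]

    wanted = set(chain_filter) if chain_filter is not None else None
    present = {c.id for c in model}
    if wanted is not None:
        missing = wanted - present
        if missing:
            raise KeyError(f"chains {sorted(missing)} not found in {path.name}")

    atoms: list[Atom] = []
    for chain in model:
        if wanted is not None and chain.id not in wanted:
            continue
        for residue in chain:
            hetflag = residue.id[0]
            if hetflag != " " and not keep_het:
                continue
            for bio_atom in residue:
                # DisorderedAtom resolves to its highest-occupancy child.
                elem = (bio_atom.element or "").strip() or bio_atom.get_name()[0]
                if not keep_hydrogens and elem == "H":
                    continue
                atoms.append(
                    Atom(
                        chain_id=chain.id,
                        residue_number=residue.id[1],
                        residue_name=residue.get_resname().strip(),
                        atom_name=bio_atom.get_name().strip(),
                        element=elem,
                        position=np.asarray(bio_atom.get_coord(), dtype=float),
                    )
                )
    if not atoms:
        raise ValueError(f"no atoms left after filtering in {path.name}")
    src = f"{path.name} model={model_index}"
    if wanted is not None:
        src += f" chains={''.join(sorted(wanted))}"
    return RigidBody(name or path.stem, atoms, source=src)


def _format_atom_line(serial: int, atom: Atom) -> str:
    name = atom.atom_name
    # PDB column convention: 1-letter elements start at column 14
    padded = f" {name:<3s}" if len(name) < 4 else name
    x, y, z = atom.position
    return (
        f"ATOM  {serial:>5d} {padded:<4s} {atom.residue_name:<3s} "
        f"{atom.chain_id:1s}{atom.residue_number:>4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
        f"{atom.element:>2s}"
    )


def write_pdb(path: str | Path, bodies: RigidBody | Sequence[RigidBody]) -> None:
    """Write one body (single model) or several (MODEL/ENDMDL ensemble) as PDB."""
    if isinstance(bodies, RigidBody):
        bodies = [bodies]
    lines: list[str] = []
    multi = len(bodies) > 1
    for i, body in enumerate(bodies, start=1):
        if multi:
            lines.append(f"MODEL     {i:>4d}")
        serial = 1
        prev_chain = None
        for atom in body.atoms:
            if prev_chain is not None and atom.chain_id != prev_chain:
                lines.append("TER")
            lines.append(_format_atom_line(serial, atom))
            serial += 1
            prev_chain = atom.chain_id
        lines.append("TER")
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# --------------------------------------------------------------------------
# Superposition and rotation sampling
# --------------------------------------------------------------------------

def superpose(
    mobile: np.ndarray, reference: np.ndarray
) -> tuple[Transform, float]:
    """Least-squares rigid superposition of mobile onto reference (Kabsch).

    Reflections are excluded by sign-correcting the smallest singular value.
    Returns the transform and the post-fit RMSD in Angstrom.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile and reference must be matching (N, 3) arrays")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError("superposition needs at least 3 points")

    mu_m = mobile.mean(axis=0)
    mu_r = reference.mean(axis=0)
    x = mobile - mu_m
    y = reference - mu_r

    # collinearity check via the covariance of the joined cloud
    for pts in (x, y):
        s = np.linalg.svd(pts, compute_uv=False)
        if s[1] <= 1e-10 * max(s[0], 1.0):
            warnings.warn("degenerate (collinear) point configuration", stacklevel=2)

    h = x.T @ y
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rotation = vt.T @ corr @ u.T
    translation = mu_r - rotation @ mu_m
    t = Transform(rotation, translation)
    diff = t.apply(mobile) - reference
    rmsd = float(np.sqrt((diff**2).sum() / n))
    return t, rmsd


def sample_rotation(rng: np.random.Generator) -> Transform:
    """A rotation drawn uniformly from SO(3) (normalized random quaternion)."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rotation = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )
    return Transform(rotation, np.zeros(3))
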