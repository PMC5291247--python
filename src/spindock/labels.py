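"""Spin-label ensemble simulation by accessible-volume sampling.

Two label chemistries are modeled: a monofunctional nitroxide attached at one
residue (R1) and a bifunctional label bridging two residues (Rx2). The
unpaired electron of each conformer is represented by a single point; no label
atoms are added to the host body.

Sampling happens in a local frame derived from the site's backbone geometry,
so ensembles transform covariantly with the host body.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Literal

import numpy as np

from spindock.geometry import Atom, RigidBody, Transform

__all__ = [
    "LabelSite",
    "SpinEnsemble",
    "AccessibleVolumeParams",
    "attach_r1_ensemble",
    "attach_rx2_label",
    "ensemble_distance",
    "UnlabelableSiteError",
    "UnbridgeableSiteError",
]


class UnlabelableSiteError(ValueError):
    """Every candidate label position clashed with the host body."""


class UnbridgeableSiteError(ValueError):
    """The two anchor residues are too close or too far apart to bridge."""


@dataclasses.dataclass(frozen=True)
class LabelSite:
    """A labeling site: one anchor residue for R1, two for Rx2."""

    kind: Literal["R1", "Rx2"]
    anchors: tuple[tuple[str, int], ...]  # (chain_id, residue_number)
    label: str = ""

    def __post_init__(self) -> None:
        expected = 1 if self.kind == "R1" else 2
        if len(self.anchors) != expected:
            raise ValueError(f"{self.kind} site needs {expected} anchor(s)")


@dataclasses.dataclass(frozen=True)
class AccessibleVolumeParams:
    r_min: float = 4.0  # Angstrom from CB
    r_max: float = 12.0
    clash_cutoff: float = 3.0  # to host heavy atoms
    n_candidates: int = 5000
    # Rx2 specifics
    bridge_min: float = 5.0  # bridgeable CB-CB separation
    bridge_max: float = 14.0
    tether_min: float = 3.0  # electron-to-anchor-CB distance range
    tether_max: float = 8.0
    asymmetry_tol: float = 1.5  # max | d(CB1) - d(CB2) | for Rx2 conformers


@dataclasses.dataclass(frozen=True)
class SpinEnsemble:
    """Weighted point cloud of simulated unpaired-electron positions."""

    site: LabelSite
    positions: np.ndarray  # (N, 3), Angstrom
    weights: np.ndarray  # (N,), sums to 1

    def __post_init__(self) -> None:
        positions = np.asarray(self.positions, dtype=float)
        weights = np.asarray(self.weights, dtype=float)
        if positions.ndim != 2 or positions.shape[1] != 3 or len(positions) == 0:
            raise ValueError("positions must be a non-empty (N, 3) array")
        if weights.shape != (len(positions),):
            raise ValueError("weights length mismatch")
        if np.any(weights < 0):
            raise ValueError("weights must be non-negative")
        total = weights.sum()
        if total <= 0:
            raise ValueError("weights must have positive sum")
        object.__setattr__(self, "positions", positions)
        object.__setattr__(self, "weights", weights / total)

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def centroid(self) -> np.ndarray:
        return self.weights @ self.positions

    def transformed(self, t: Transform) -> "SpinEnsemble":
        return SpinEnsemble(self.site, t.apply(self.positions), self.weights.copy())

    def subsampled(self, n_max: int, seed: int = 0) -> "SpinEnsemble":
        """Deterministic weight-proportional subsample used to bound docking cost."""
        if len(self) <= n_max:
            return self
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(self), size=n_max, replace=False, p=self.weights)
        idx.sort()
        w = np.full(n_max, 1.0 / n_max)
        return SpinEnsemble(self.site, self.positions[idx], w)

    def to_table(self, path: str | Path) -> None:
        rows = ["# x y z weight"]
        for p, w in zip(self.positions, self.weights):
            rows.append(f"{p[0]:.4f} {p[1]:.4f} {p[2]:.4f} {w:.6e}")
        Path(path).write_text("\n".join(rows) + "\n")

    def to_pseudoatom_bodies(self) -> list[RigidBody]:
        """One single-atom body per conformer, for multi-model PDB export."""
        bodies = []
        for i, p in enumerate(self.positions):
            atom = Atom("X", i + 1, "NO", "NO", "N", p)
            bodies.append(RigidBody(f"label_{i}", [atom]))
        return bodies


def _residue_atoms(body: RigidBody, chain_id: str, residue_number: int) -> dict[str, Atom]:
    atoms = {a.atom_name: a for a in body.select(chain_id, residue_number)}
    if not atoms:
        raise KeyError(f"residue {chain_id}:{residue_number} absent from {body.name!r}")
    return atoms


def _cb_position(res: dict[str, Atom]) -> np.ndarray:
    if "CB" in res:
        return res["CB"].position
    # pseudo-CB for Gly from ideal tetrahedral backbone geometry
    try:
        n, ca, c = res["N"].position, res["CA"].position, res["C"].position
    except KeyError as exc:
        raise KeyError("residue lacks CB and complete backbone") from exc
    b1 = n - ca
    b2 = c - ca
    bisector = -(b1 + b2)
    bisector /= np.linalg.norm(bisector)
    perp = np.cross(b2, b1)
    perp /= np.linalg.norm(perp)
    # 1.53 A bond, ~54 deg out of the N-CA-C plane
    direction = bisector * np.cos(0.94) + perp * np.sin(0.94)
    return ca + 1.53 * direction


def _local_frame(origin: np.ndarray, axis_point: np.ndarray, ref_point: np.ndarray) -> np.ndarray:
    """Right-handed orthonormal frame rows (e1, e2, e3); e3 along origin-axis_point."""
    e3 = origin - axis_point
    e3 /= np.linalg.norm(e3)
    r = ref_point - axis_point
    e1 = r - (r @ e3) * e3
    n1 = np.linalg.norm(e1)
    if n1 < 1e-6:
        # fall back to an arbitrary perpendicular
        trial = np.array([1.0, 0.0, 0.0])
        e1 = trial - (trial @ e3) * e3
        n1 = np.linalg.norm(e1)
    e1 /= n1
    e2 = np.cross(e3, e1)
    return np.stack([e1, e2, e3])


def _clash_mask(
    candidates: np.ndarray,
    body: RigidBody,
    exclude: set[int],
    cutoff: float,
) -> np.ndarray:
    """True where a candidate is clash-free against all non-excluded atoms."""
    from scipy.spatial import cKDTree

    keep_idx = [i for i in range(len(body)) if i not in exclude]
    if not keep_idx:
        return np.ones(len(candidates), dtype=bool)
    tree = cKDTree(body.coords[keep_idx])
    dmin, _ = tree.query(candidates, k=1)
    return dmin >= cutoff


def _sidechain_exclusion(body: RigidBody, chain_id: str, residue_number: int) -> set[int]:
    """Indices of the labeled residue's own side-chain atoms (kept out of clash test)."""
    backbone = {"N", "CA", "C", "O"}
    return {
        i
        for i, a in enumerate(body.atoms)
        if a.chain_id == chain_id
        and a.residue_number == residue_number
        and a.atom_name not in backbone
    }


def attach_r1_ensemble(
    body: RigidBody,
    site: LabelSite,
    params: AccessibleVolumeParams | None = None,
    seed: int = 0,
    return_candidates: bool = False,
):
    """Accessible-volume ensemble for a monofunctional label.

    Candidate electron positions are drawn on shells r in [r_min, r_max]
    around the anchor CB, biased away from the backbone (only directions with
    a positive component along CA->CB are kept), then clash-filtered against
    the host heavy atoms excluding the labeled residue's own side chain.
    """
    if site.kind != "R1":
        raise ValueError("attach_r1_ensemble needs an R1 site")
    params = params or AccessibleVolumeParams()
    chain_id, resnum = site.anchors[0]
    res = _residue_atoms(body, chain_id, resnum)
    if "CA" not in res:
        raise KeyError(f"residue {chain_id}:{resnum} lacks CA")
    ca = res["CA"].position
    cb = _cb_position(res)
    n_ref = res.get("N", res["CA"]).position

    frame = _local_frame(cb, ca, n_ref)  # e3 points along CA->CB
    rng = np.random.default_rng(seed)
    # sample in the local frame: uniform directions in the outward hemisphere,
    # radius uniform in volume between the two shells
    n = params.n_candidates
    dirs = rng.normal(size=(n, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    dirs[dirs[:, 2] < 0, 2] *= -1  # outward bias: away from the backbone
    u = rng.uniform(size=n)
    radii = (params.r_min**3 + u * (params.r_max**3 - params.r_min**3)) ** (1.0 / 3.0)
    candidates = cb + (dirs * radii[:, None]) @ frame

    exclude = _sidechain_exclusion(body, chain_id, resnum)
    ok = _clash_mask(candidates, body, exclude, params.clash_cutoff)
    survivors = candidates[ok]
    if len(survivors) == 0:
        raise UnlabelableSiteError(
            f"site {chain_id}:{resnum} is buried: all {n} candidates clash"
        )
    weights = np.full(len(survivors), 1.0 / len(survivors))
    ensemble = SpinEnsemble(site, survivors, weights)
    if return_candidates:
        return ensemble, candidates
    return ensemble


def attach_rx2_label(
    body: RigidBody,
    site: LabelSite,
    params: AccessibleVolumeParams | None = None,
    seed: int = 0,
) -> SpinEnsemble:
    """Ensemble for a bifunctional label bridging two anchor residues.

    Conformers are sampled near the perpendicular bisector plane of the two
    anchor CB atoms, at tether-consistent distances from both, and
    clash-filtered. The resulting ensemble is compact by construction.
    """
    if site.kind != "Rx2":
        raise ValueError("attach_rx2_label needs an Rx2 site")
    params = params or AccessibleVolumeParams()
    (ch1, r1), (ch2, r2) = site.anchors
    res1 = _residue_atoms(body, ch1, r1)
    res2 = _residue_atoms(body, ch2, r2)
    cb1 = _cb_position(res1)
    cb2 = _cb_position(res2)
    sep = float(np.linalg.norm(cb2 - cb1))
    if not (params.bridge_min <= sep <= params.bridge_max):
        raise UnbridgeableSiteError(
            f"anchor CB separation {sep:.2f} A outside "
            f"[{params.bridge_min}, {params.bridge_max}] A"
        )

    mid = 0.5 * (cb1 + cb2)
    frame = _local_frame(cb2, cb1, res1["CA"].position)  # e3 along cb1->cb2
    rng = np.random.default_rng(seed)
    n = params.n_candidates
    # offsets in the bisector plane (e1, e2) plus a small along-axis jitter
    max_lat = np.sqrt(max(params.tether_max**2 - (sep / 2.0) ** 2, 0.0))
    if max_lat <= 0:
        raise UnbridgeableSiteError(
            f"tether_max {params.tether_max} cannot span half-separation {sep / 2:.2f}"
        )
    ang = rng.uniform(0, 2 * np.pi, size=n)
    lat = max_lat * np.sqrt(rng.uniform(size=n))
    axial = rng.uniform(-params.asymmetry_tol / 2, params.asymmetry_tol / 2, size=n)
    local = np.stack([lat * np.cos(ang), lat * np.sin(ang), axial], axis=1)
    candidates = mid + local @ frame

    d1 = np.linalg.norm(candidates - cb1, axis=1)
    d2 = np.linalg.norm(candidates - cb2, axis=1)
    ok = (
        (d1 >= params.tether_min)
        & (d1 <= params.tether_max)
        & (d2 >= params.tether_min)
        & (d2 <= params.tether_max)
        & (np.abs(d1 - d2) <= params.asymmetry_tol)
    )
    exclude = _sidechain_exclusion(body, ch1, r1) | _sidechain_exclusion(body, ch2, r2)
    ok &= _clash_mask(candidates, body, exclude, params.clash_cutoff)
    survivors = candidates[ok]
    if len(survivors) == 0:
        raise UnlabelableSiteError(
            f"Rx2 site {site.label or site.anchors}: all candidates rejected"
        )
    weights = np.full(len(survivors), 1.0 / len(survivors))
    return SpinEnsemble(site, survivors, weights)


def ensemble_distance(
    a: SpinEnsemble, b: SpinEnsemble, n_bins: int = 100
) -> tuple[float, float, tuple[np.ndarray, np.ndarray]]:
    """Weighted pairwise distance statistics between two ensembles.

    Returns (weighted mean, histogram modal distance, (bin_centers, density)).
    """
    diff = a.positions[:, None, :] - b.positions[None, :, :]
    d = np.sqrt((diff**2).sum(axis=2)).ravel()
    w = np.outer(a.weights, b.weights).ravel()
    mean = float(d @ w)
    hist, edges = np.histogram(d, bins=n_bins, weights=w, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    modal = float(centers[int(np.argmax(hist))])
    return mean, modal, (centers, hist)
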