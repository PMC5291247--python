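"""Rigid-body docking of two bodies against sparse distance restraints.

Body A stays fixed; body B is posed by a rigid transform. Each docking run
starts from a uniformly random relative orientation, places B so that one
randomly chosen restraint is initially satisfied, and locally minimizes

    e_total = e_noe + e_clash

over the six rigid degrees of freedom, where e_noe is a sum of weighted
squared flat-bottom violations and e_clash a soft quadratic repulsion between
inter-body heavy atoms closer than a cutoff. Solutions are accepted on a
violation basis (max restraint deviation and clash energy), aligned on body
A, averaged, and validated against the restraints.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
from scipy import optimize
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from spindock.geometry import RigidBody, Transform, sample_rotation, superpose, transform_body
from spindock.labels import SpinEnsemble
from spindock.restraints import AtomSite, DistanceRestraint, EnsembleSite

__all__ = [
    "DockingParams",
    "Pose",
    "Solution",
    "ModelEnsemble",
    "pose_energy",
    "minimize_pose",
    "run_docking",
    "average_models",
    "validate_model",
    "extrapolate_tetramer",
]


@dataclasses.dataclass
class DockingParams:
    clash_distance: float = 3.0  # Angstrom; inter-body pairs closer repel
    k_rep: float = 1.0  # model units per Angstrom^2
    d_acc: float = 3.0  # acceptance: max restraint violation
    clash_max: float = 50.0  # acceptance: max clash energy
    minimizer_tol: float = 1e-8
    max_iterations: int = 500
    funnel_width: float = 0.0  # stage-1 well widening (Angstrom); 0 = single stage
    ensemble_max_points: int = 50  # subsample spin ensembles for speed
    peldor_distance_mode: str = "mean"  # "mean" | "modal"
    clash_atom_stride: int = 1  # evaluate repulsion on every k-th atom (speed knob)


def _rodrigues(rotvec: np.ndarray) -> np.ndarray:
    """Rotation matrix from a rotation vector (angle-axis), plain numpy."""
    theta = np.linalg.norm(rotvec)
    if theta < 1e-12:
        return np.eye(3)
    k = rotvec / theta
    kx = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(theta) * kx + (1 - np.cos(theta)) * (kx @ kx)


@dataclasses.dataclass(frozen=True)
class Pose:
    """Rigid placement of body B in body A's frame."""

    transform: Transform

    @classmethod
    def from_params(cls, params: np.ndarray) -> "Pose":
        rotvec, translation = params[:3], params[3:]
        return cls(Transform(_rodrigues(np.asarray(rotvec, dtype=float)), translation))

    def to_params(self) -> np.ndarray:
        rotvec = Rotation.from_matrix(self.transform.rotation).as_rotvec()
        return np.concatenate([rotvec, self.transform.translation])


@dataclasses.dataclass
class Solution:
    pose: Pose
    e_noe: float
    e_clash: float
    deviations: np.ndarray  # signed, per restraint, Angstrom
    violations: np.ndarray | None = None  # flat-bottom excess, per restraint
    accepted: bool = False
    converged: bool = True

    @property
    def e_total(self) -> float:
        return self.e_noe + self.e_clash

    @property
    def max_violation(self) -> float:
        return float(np.abs(self.deviations).max()) if len(self.deviations) else 0.0


@dataclasses.dataclass
class ModelEnsemble:
    solutions: list[Solution]
    average_coords_a: np.ndarray
    average_coords_b: np.ndarray
    rmsd_backbone_mean: float
    rmsd_heavy_mean: float


class _RestraintEvaluator:
    """Precomputed site geometry for fast energy evaluation.

    Sites on body A are fixed; body-B site points are stored in B's reference
    frame and mapped through the candidate pose at evaluation time.
    """

    def __init__(
        self,
        body_a: RigidBody,
        body_b: RigidBody,
        restraints: Sequence[DistanceRestraint],
        ensembles: dict[str, SpinEnsemble] | None,
        params: DockingParams,
    ):
        self.restraints = list(restraints)
        self.params = params
        ensembles = ensembles or {}
        self._site_points: list[tuple[str, np.ndarray, np.ndarray]] = []
        for r in self.restraints:
            self._site_points.append(
                (
                    "pair",
                    *[
                        self._resolve(site, body_a, body_b, ensembles)
                        for site in (r.site_a, r.site_b)
                    ],
                )
            )
        stride = max(1, params.clash_atom_stride)
        self.coords_a = body_a.coords[::stride]
        self.coords_b = body_b.coords[::stride]
        self.tree_a = cKDTree(self.coords_a)
        # bounding spheres for a cheap no-clash early exit
        self._center_a = self.coords_a.mean(axis=0)
        self._rad_a = float(np.linalg.norm(self.coords_a - self._center_a, axis=1).max())
        self._center_b = self.coords_b.mean(axis=0)
        self._rad_b = float(np.linalg.norm(self.coords_b - self._center_b, axis=1).max())
        # fast path: all restraints between single fixed points (A-atom vs B-atom)
        self._simple = all(
            len(sa[1]) == 1 and len(sb[1]) == 1 and sa[0] != sb[0]
            for _, sa, sb in self._site_points
        )
        if self._simple:
            pa, pb = [], []
            for _, sa, sb in self._site_points:
                a_side = sa if sa[0] == "A" else sb
                b_side = sb if sb[0] == "B" else sa
                pa.append(a_side[1][0])
                pb.append(b_side[1][0])
            self._pa = np.array(pa)
            self._pb = np.array(pb)
            self._lower = np.array([r.lower_bound for r in self.restraints])
            self._upper = np.array([r.upper_bound for r in self.restraints])
            self._weights = np.array([r.weight for r in self.restraints])

    @staticmethod
    def _resolve(site, body_a, body_b, ensembles):
        body = {"A": body_a, "B": body_b}
        if isinstance(site, AtomSite):
            atom = body[site.body].atom(site.chain_id, site.residue_number, site.atom_name)
            return (site.body, atom.position[None, :], np.array([1.0]))
        if isinstance(site, EnsembleSite):
            key = f"{site.body}/{site.label}"
            if key not in ensembles:
                raise KeyError(f"ensemble {key!r} not provided")
            ens = ensembles[key]
            return (site.body, ens.positions, ens.weights)
        raise TypeError(f"unknown site type {type(site)}")

    def restraint_distances(self, pose: Pose) -> np.ndarray:
        t = pose.transform
        if self._simple:
            moved = self._pb @ t.rotation.T + t.translation
            return np.linalg.norm(self._pa - moved, axis=1)
        out = np.empty(len(self.restraints))
        for i, (_, sa, sb) in enumerate(self._site_points):
            pa = self._posed(sa, t)
            pb = self._posed(sb, t)
            out[i] = _cloud_distance(pa, pb, self.params.peldor_distance_mode)
        return out

    @staticmethod
    def _posed(site_data, t: Transform):
        body, points, weights = site_data
        if body == "B":
            return (t.apply(points), weights)
        return (points, weights)

    def energies(self, pose: Pose) -> tuple[float, float, np.ndarray]:
        d = self.restraint_distances(pose)
        if self._simple:
            v = np.maximum(0.0, np.maximum(d - self._upper, self._lower - d))
            e_noe = float(self._weights @ (v * v))
            deviations = np.array(
                [r.deviation(di) for r, di in zip(self.restraints, d)]
            )
        else:
            e_noe = 0.0
            deviations = np.empty(len(d))
            for i, r in enumerate(self.restraints):
                vi = r.violation(d[i])
                e_noe += r.weight * vi * vi
                deviations[i] = r.deviation(d[i])
        e_clash = self.clash_energy(pose)
        return e_noe, e_clash, deviations

    def noe_energy(self, pose: Pose) -> float:
        d = self.restraint_distances(pose)
        if self._simple:
            v = np.maximum(0.0, np.maximum(d - self._upper, self._lower - d))
            return float(self._weights @ (v * v))
        e = 0.0
        for r, di in zip(self.restraints, d):
            vi = r.violation(di)
            e += r.weight * vi * vi
        return e

    def clash_energy(self, pose: Pose) -> float:
        t = pose.transform
        return self._clash_rt(t.rotation, t.translation)

    def _clash_rt(self, rotation: np.ndarray, translation: np.ndarray) -> float:
        center_b = rotation @ self._center_b + translation
        gap = np.linalg.norm(center_b - self._center_a)
        cutoff = self.params.clash_distance
        if gap > self._rad_a + self._rad_b + cutoff:
            return 0.0
        from scipy.spatial.distance import cdist

        moved_b = self.coords_b @ rotation.T + translation
        d = cdist(self.coords_a, moved_b)
        close = d < cutoff
        if not close.any():
            return 0.0
        return float(self.params.k_rep * ((cutoff - d[close]) ** 2).sum())

    def energy_from_params(self, x: np.ndarray) -> float:
        """e_total at pose parameters (rotvec, translation); hot-loop path."""
        rotation = _rodrigues(x[:3])
        translation = x[3:]
        if self._simple:
            moved = self._pb @ rotation.T + translation
            d = np.linalg.norm(self._pa - moved, axis=1)
            v = np.maximum(0.0, np.maximum(d - self._upper, self._lower - d))
            e_noe = float(self._weights @ (v * v))
        else:
            pose = Pose(Transform(rotation, translation))
            e_noe = self.noe_energy(pose)
        return e_noe + self._clash_rt(rotation, translation)

    def residuals_from_params(self, x: np.ndarray, margin: float = 0.0) -> np.ndarray:
        """Residual vector whose squared sum is e_total (for least-squares).

        ``margin`` widens every flat bottom symmetrically; used for the
        coarse funnel stage of the minimizer.
        """
        rotation = _rodrigues(x[:3])
        translation = x[3:]
        if self._simple:
            moved = self._pb @ rotation.T + translation
            d = np.linalg.norm(self._pa - moved, axis=1)
            v = np.maximum(
                0.0, np.maximum(d - self._upper - margin, self._lower - margin - d)
            )
            res = np.sqrt(self._weights) * v
        else:
            pose = Pose(Transform(rotation, translation))
            d = self.restraint_distances(pose)
            res = np.array(
                [
                    np.sqrt(r.weight)
                    * max(0.0, d_i - r.upper_bound - margin, r.lower_bound - margin - d_i)
                    for r, d_i in zip(self.restraints, d)
                ]
            )
        clash = self._clash_rt(rotation, translation)
        res = np.append(res, np.sqrt(clash))
        if len(res) < 6:
            # Levenberg-Marquardt needs at least as many residuals as
            # parameters; zero padding changes nothing about the objective
            res = np.concatenate([res, np.zeros(6 - len(res))])
        return res

    def violations(self, pose: Pose) -> np.ndarray:
        d = self.restraint_distances(pose)
        return np.array([r.violation(di) for r, di in zip(self.restraints, d)])


def _cloud_distance(a, b, mode: str) -> float:
    pa, wa = a
    pb, wb = b
    if len(pa) == 1 and len(pb) == 1:
        return float(np.linalg.norm(pa[0] - pb[0]))
    diff = pa[:, None, :] - pb[None, :, :]
    d = np.sqrt((diff**2).sum(axis=2))
    w = np.outer(wa, wb)
    if mode == "mean":
        return float((d * w).sum() / w.sum())
    if mode == "modal":
        hist, edges = np.histogram(d.ravel(), bins=50, weights=w.ravel())
        centers = 0.5 * (edges[:-1] + edges[1:])
        return float(centers[int(np.argmax(hist))])
    raise ValueError(f"unknown distance mode {mode!r}")


def _prepare(
    body_a: RigidBody,
    body_b: RigidBody,
    restraints: Sequence[DistanceRestraint],
    ensembles: dict[str, SpinEnsemble] | None,
    params: DockingParams,
) -> _RestraintEvaluator:
    if ensembles:
        ensembles = {
            k: e.subsampled(params.ensemble_max_points) for k, e in ensembles.items()
        }
    return _RestraintEvaluator(body_a, body_b, restraints, ensembles, params)


def pose_energy(
    body_a: RigidBody,
    body_b: RigidBody,
    pose: Pose,
    restraints: Sequence[DistanceRestraint],
    ensembles: dict[str, SpinEnsemble] | None = None,
    params: DockingParams | None = None,
) -> tuple[float, float, np.ndarray]:
    """(e_noe, e_clash, per-restraint signed deviations) for one pose."""
    params = params or DockingParams()
    ev = _prepare(body_a, body_b, restraints, ensembles, params)
    return ev.energies(pose)


def _minimize(ev: _RestraintEvaluator, start: Pose, params: DockingParams) -> Solution:
    x0 = start.to_params()
    try:
        if params.funnel_width > 0:
            coarse = optimize.least_squares(
                ev.residuals_from_params,
                x0,
                method="lm",
                kwargs={"margin": params.funnel_width},
                xtol=1e-8,
                ftol=1e-6,
                max_nfev=params.max_iterations * 4,
            )
            x0 = coarse.x
        res = optimize.least_squares(
            ev.residuals_from_params,
            x0,
            method="lm",
            xtol=1e-10,
            ftol=params.minimizer_tol,
            max_nfev=params.max_iterations * 8,
        )
        x_final = res.x
        converged = bool(np.all(np.isfinite(res.fun)))
    except (ValueError, FloatingPointError):
        x_final = x0
        converged = False
    pose = Pose.from_params(np.asarray(x_final, dtype=float))
    e_noe, e_clash, deviations = ev.energies(pose)
    if not np.isfinite(e_noe + e_clash):
        converged = False
    return Solution(
        pose,
        float(e_noe),
        float(e_clash),
        deviations,
        violations=ev.violations(pose),
        converged=converged,
    )


def minimize_pose(
    body_a: RigidBody,
    body_b: RigidBody,
    start: Pose,
    restraints: Sequence[DistanceRestraint],
    ensembles: dict[str, SpinEnsemble] | None = None,
    params: DockingParams | None = None,
) -> Solution:
    """Local minimization of e_total over the 6 rigid degrees of freedom."""
    params = params or DockingParams()
    ev = _prepare(body_a, body_b, restraints, ensembles, params)
    return _minimize(ev, start, params)


def _random_start(
    ev: _RestraintEvaluator,
    rng: np.random.Generator,
) -> Pose:
    """Random orientation; translation chosen so one restraint starts satisfied."""
    rotation = sample_rotation(rng).rotation
    restraint_idx = rng.integers(len(ev.restraints))
    r = ev.restraints[restraint_idx]
    target = r.target if r.target is not None else 0.5 * (r.lower_bound + r.upper_bound)
    _, sa, sb = ev._site_points[restraint_idx]

    def centroid(site_data, rot):
        body, points, weights = site_data
        pts = points @ rot.T if body == "B" else points
        return weights @ pts / weights.sum()

    ca = centroid(sa if sa[0] == "A" else sb, np.eye(3))
    cb_rot = centroid(sb if sb[0] == "B" else sa, rotation)
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    translation = ca + target * direction - cb_rot
    return Pose(Transform(rotation, translation))


def run_docking(
    body_a: RigidBody,
    body_b: RigidBody,
    restraints: Sequence[DistanceRestraint],
    ensembles: dict[str, SpinEnsemble] | None = None,
    n_starts: int = 500,
    seed: int = 0,
    params: DockingParams | None = None,
) -> list[Solution]:
    """Dock body B against body A from randomized starts.

    Each start is minimized; a solution is accepted when its maximum restraint
    violation is at most ``d_acc`` and its clash energy at most ``clash_max``.
    Deterministic for a fixed seed.
    """
    if len(restraints) == 0:
        raise ValueError("unconstrained docking refused: provide at least one restraint")
    params = params or DockingParams()
    ev = _prepare(body_a, body_b, restraints, ensembles, params)
    rng = np.random.default_rng(seed)
    solutions = []
    for _ in range(n_starts):
        start = _random_start(ev, rng)
        sol = _minimize(ev, start, params)
        if sol.converged:
            violation = float(sol.violations.max())
            sol.accepted = (
                violation <= params.d_acc and sol.e_clash <= params.clash_max
            )
        solutions.append(sol)
    return solutions


def average_models(
    accepted: Sequence[Solution],
    body_a: RigidBody,
    body_b: RigidBody,
) -> ModelEnsemble:
    """Superpose accepted solutions on body A's backbone and average coordinates.

    Body A is the common frame, so only body B varies between solutions; the
    per-solution backbone / heavy-atom RMSDs to the coordinate-wise mean are
    computed over the full two-body complex.
    """
    accepted = [s for s in accepted if s.accepted] or list(accepted)
    if not accepted:
        raise ValueError("no solutions to average")
    coords_b = np.stack(
        [s.pose.transform.apply(body_b.coords) for s in accepted]
    )  # (n, Nb, 3)
    mean_b = coords_b.mean(axis=0)
    na = len(body_a)
    bb_a = body_a.backbone_indices()
    bb_b = body_b.backbone_indices()

    rmsd_bb = []
    rmsd_heavy = []
    for i in range(len(accepted)):
        diff = coords_b[i] - mean_b
        sq = (diff**2).sum(axis=1)
        # body A contributes zero deviation in this frame
        rmsd_heavy.append(np.sqrt(sq.sum() / (na + len(body_b))))
        n_bb = len(bb_a) + len(bb_b)
        rmsd_bb.append(np.sqrt(sq[bb_b].sum() / n_bb))
    return ModelEnsemble(
        solutions=list(accepted),
        average_coords_a=body_a.coords.copy(),
        average_coords_b=mean_b,
        rmsd_backbone_mean=float(np.mean(rmsd_bb)),
        rmsd_heavy_mean=float(np.mean(rmsd_heavy)),
    )


def validate_model(
    body_a: RigidBody,
    body_b: RigidBody,
    pose: Pose,
    restraints: Sequence[DistanceRestraint],
    ensembles: dict[str, SpinEnsemble] | None = None,
    params: DockingParams | None = None,
) -> tuple[np.ndarray, float]:
    """Per-restraint signed deviations of a model and the max absolute deviation."""
    params = params or DockingParams()
    ev = _prepare(body_a, body_b, restraints, ensembles, params)
    d = ev.restraint_distances(pose)
    deviations = np.array([r.deviation(di) for r, di in zip(restraints, d)])
    return deviations, float(np.abs(deviations).max())


def extrapolate_tetramer(
    model: RigidBody,
    template: RigidBody,
    model_dimer_chains: tuple[str, ...],
    template_dimer_chains: Sequence[tuple[str, ...]],
    drop_chains: tuple[str, ...],
    clash_cutoff: float = 3.0,
    rmsd_warn: float = 3.0,
) -> tuple[list[RigidBody], int]:
    """Extend a complex by aligning one copy onto each dimer of a template.

    For each chain group in ``template_dimer_chains``, the model is superposed
    via the shared backbone atoms of its ``model_dimer_chains`` onto the
    template group, chains in ``drop_chains`` are removed, and the posed copy
    collected. Returns the copies plus the count of inter-copy heavy-atom
    pairs closer than ``clash_cutoff`` (between retained non-template chains).
    """
    backbone = {"N", "CA", "C", "O"}

    def backbone_map(body: RigidBody, chains: tuple[str, ...]):
        out = {}
        for i, a in enumerate(body.atoms):
            if a.chain_id in chains and a.atom_name in backbone:
                out[(chains.index(a.chain_id), a.residue_number, a.atom_name)] = i
        return out

    model_map = backbone_map(model, model_dimer_chains)
    copies = []
    for group in template_dimer_chains:
        if len(group) != len(model_dimer_chains):
            raise ValueError("chain group size mismatch")
        templ_map = backbone_map(template, tuple(group))
        shared = sorted(set(model_map) & set(templ_map))
        if len(shared) < 3:
            raise ValueError(f"cannot map chains {group}: fewer than 3 shared backbone atoms")
        mobile = model.coords[[model_map[k] for k in shared]]
        reference = template.coords[[templ_map[k] for k in shared]]
        t, rmsd = superpose(mobile, reference)
        if rmsd > rmsd_warn:
            warnings.warn(
                f"superposition onto chains {group} has RMSD {rmsd:.2f} A", stacklevel=2
            )
        posed = transform_body(model, t)
        kept = [a for a in posed.atoms if a.chain_id not in drop_chains]
        copies.append(RigidBody(f"{model.name}_on_{''.join(group)}", kept, model.source))

    # clash report between the non-histone parts of the copies
    n_clashes = 0
    retained_new = [
        np.array(
            [
                a.position
                for a in c.atoms
                if a.chain_id not in set(sum(map(tuple, template_dimer_chains), ()))
            ]
        )
        for c in copies
    ]
    for i in range(len(copies)):
        for j in range(i + 1, len(copies)):
            if len(retained_new[i]) == 0 or len(retained_new[j]) == 0:
                continue
            tree = cKDTree(retained_new[i])
            n_clashes += int(
                sum(len(x) for x in tree.query_ball_point(retained_new[j], clash_cutoff))
            )
    return copies, n_clashes
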