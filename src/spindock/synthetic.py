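"""Ground-truth synthetic data for every pipeline stage.

Everything here is a pure function of (configuration, seed): toy rigid bodies
in a known relative pose, distance restraints with controlled noise, dipolar
traces from stated distributions, and cross-linked MS/MS spectra with
isotope-coded precursor doublets.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from spindock import masses
from spindock.geometry import Atom, RigidBody, Transform, sample_rotation, transform_body
from spindock.peldor import BackgroundModel, DipolarTrace, DistanceDistribution, simulate_trace
from spindock.restraints import AtomSite, DistanceRestraint
from spindock.xlms import (
    BS2G,
    Linker,
    Peptide,
    ProteinSequence,
    Spectrum,
    CrossLinkCandidate,
    digest,
    theoretical_fragments,
)

__all__ = [
    "ScenarioConfig",
    "make_toy_bodies",
    "simulate_restraints",
    "simulate_dipolar_dataset",
    "simulate_xl_spectra",
]


@dataclasses.dataclass
class ScenarioConfig:
    seed: int = 0
    n_restraints: int = 5
    restraint_noise_sd: float = 0.0  # Angstrom
    # trace parameters
    t_max_us: float = 4.0
    n_times: int = 200
    trace_noise_sd: float = 0.0
    background_k: float = 0.05
    modulation_depth: float = 0.4
    # spectrum parameters
    n_true_links: int = 10
    fragment_coverage: float = 0.8
    n_noise_peaks: int = 20
    n_background_spectra: int = 20

    def __post_init__(self) -> None:
        if not (0.0 <= self.fragment_coverage <= 1.0):
            raise ValueError("fragment coverage must be in [0, 1]")


# --------------------------------------------------------------------------
# Toy bodies
# --------------------------------------------------------------------------

_HELIX_RISE = 1.5
_HELIX_RADIUS = 2.3
_HELIX_TWIST = np.deg2rad(100.0)


def _helical_body(
    name: str,
    chain_id: str,
    n_residues: int,
    lysine_every: int = 5,
) -> RigidBody:
    """An idealized helical fragment with pseudo side-chain atoms.

    Each residue carries N, CA, C, O and CB; every ``lysine_every``-th residue
    is a LYS with an additional NZ placed 4 A outward from CB.
    """
    atoms: list[Atom] = []
    for i in range(n_residues):
        ang = _HELIX_TWIST * i
        radial = np.array([np.cos(ang), np.sin(ang), 0.0])
        tangent = np.array([-np.sin(ang), np.cos(ang), 0.0])
        axis = np.array([0.0, 0.0, 1.0])
        ca = _HELIX_RADIUS * radial + axis * _HELIX_RISE * i
        is_lys = (i % lysine_every) == (lysine_every - 1)
        resname = "LYS" if is_lys else "ALA"
        resnum = i + 1
        positions = {
            "N": ca - 1.2 * tangent - 0.5 * axis,
            "CA": ca,
            "C": ca + 1.2 * tangent + 0.5 * axis,
            "O": ca + 1.2 * tangent + 1.7 * axis,
            "CB": ca + 1.5 * radial,
        }
        if is_lys:
            positions["NZ"] = ca + 4.0 * radial + 0.8 * axis
        for atom_name, pos in positions.items():
            atoms.append(
                Atom(chain_id, resnum, resname, atom_name, atom_name[0], pos)
            )
    return RigidBody(name, atoms, source="synthetic helix")


def make_toy_bodies(
    seed: int = 0,
    n_residues: int = 32,
    separation: float = 40.0,
) -> tuple[RigidBody, RigidBody, list[AtomSite], list[AtomSite], Transform]:
    """Two non-overlapping helical bodies in a known relative pose.

    Returns (body A, body B at reference position, label anchor sites,
    lysine NZ sites, truth pose). Body B's stored coordinates are its own
    reference frame; applying the truth pose puts it beside A without clashes.
    """
    rng = np.random.default_rng(seed)
    body_a = _helical_body("toyA", "A", n_residues)
    body_b = _helical_body("toyB", "B", n_residues)

    rotation = sample_rotation(rng).rotation
    for attempt in range(20):
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        translation = (
            body_a.coords.mean(axis=0)
            + (separation + 2.0 * attempt) * direction
            - rotation @ body_b.coords.mean(axis=0)
        )
        truth = Transform(rotation, translation)
        moved = truth.apply(body_b.coords)
        tree = cKDTree(body_a.coords)
        n_close = sum(len(x) for x in tree.query_ball_point(moved, 4.0))
        if n_close == 0:
            break
    else:  # pragma: no cover - separation growth guarantees termination earlier
        raise RuntimeError("could not place toy bodies without clashes")

    label_sites = [
        AtomSite("A", "A", 6, "CB"),
        AtomSite("A", "A", 16, "CB"),
        AtomSite("B", "B", 8, "CB"),
        AtomSite("B", "B", 20, "CB"),
    ]
    lysine_sites = [
        AtomSite(body, chain, a.residue_number, "NZ")
        for body, chain, b in (("A", "A", body_a), ("B", "B", body_b))
        for a in b.atoms
        if a.atom_name == "NZ"
    ]
    return body_a, body_b, label_sites, lysine_sites, truth


def simulate_restraints(
    body_a: RigidBody,
    body_b: RigidBody,
    site_pairs: Sequence[tuple[AtomSite, AtomSite]],
    truth_pose: Transform,
    noise_sd: float = 0.0,
    seed: int = 0,
    half_width: float = 2.0,
    weight: float = 1.0,
) -> list[DistanceRestraint]:
    """Restraints whose targets are the truth-pose distances plus Gaussian noise."""
    rng = np.random.default_rng(seed)
    bodies = {"A": body_a, "B": transform_body(body_b, truth_pose)}
    restraints = []
    for i, (sa, sb) in enumerate(site_pairs):
        pa = bodies[sa.body].atom(sa.chain_id, sa.residue_number, sa.atom_name).position
        pb = bodies[sb.body].atom(sb.chain_id, sb.residue_number, sb.atom_name).position
        true_d = float(np.linalg.norm(pa - pb))
        target = true_d + (rng.normal(scale=noise_sd) if noise_sd > 0 else 0.0)
        target = max(target, half_width + 0.1)
        restraints.append(
            DistanceRestraint(
                label=f"synth{i + 1}",
                source="SYNTH",
                site_a=sa,
                site_b=sb,
                target=target,
                lower_bound=target - half_width,
                upper_bound=target + half_width,
                weight=weight,
            )
        )
    return restraints


def select_restraint_pairs(
    body_a: RigidBody,
    body_b: RigidBody,
    label_sites: Sequence[AtomSite],
    lysine_sites: Sequence[AtomSite],
    truth_pose: Transform,
    n_restraints: int = 5,
    n_short: int = 3,
    max_per_site: int = 2,
) -> list[tuple[AtomSite, AtomSite]]:
    """Choose well-conditioned restraint site pairs for a docking scenario.

    Mimics the structure of real sparse-restraint experiments: a few short
    interface-proximal contacts (cross-link-like) plus long-range distances
    (spin-label-like) that discriminate between remote branches of the
    constraint manifold. Pairs are picked greedily from the cross-body
    distance table at the truth pose, shortest first then longest, with at
    most ``max_per_site`` uses of any one site.
    """
    moved_b = transform_body(body_b, truth_pose)
    bodies = {"A": body_a, "B": moved_b}
    sites = list(label_sites) + list(lysine_sites)
    side_a = [s for s in sites if s.body == "A"]
    side_b = [s for s in sites if s.body == "B"]
    table = []
    for sa in side_a:
        pa = bodies["A"].atom(sa.chain_id, sa.residue_number, sa.atom_name).position
        for sb in side_b:
            pb = bodies["B"].atom(sb.chain_id, sb.residue_number, sb.atom_name).position
            table.append((float(np.linalg.norm(pa - pb)), sa, sb))
    table.sort(key=lambda row: row[0])

    chosen: list[tuple[AtomSite, AtomSite]] = []
    uses: dict[str, int] = {}

    def take(rows, limit):
        for _, sa, sb in rows:
            if uses.get(str(sa), 0) >= max_per_site or uses.get(str(sb), 0) >= max_per_site:
                continue
            chosen.append((sa, sb))
            uses[str(sa)] = uses.get(str(sa), 0) + 1
            uses[str(sb)] = uses.get(str(sb), 0) + 1
            if len(chosen) >= limit:
                return

    take(table, n_short)
    take(reversed(table), n_restraints)
    if len(chosen) < n_restraints:
        raise ValueError("not enough distinct sites for the requested restraint count")
    return chosen


def docking_scenario(
    seed: int,
    n_restraints: int = 5,
    noise_sd: float = 0.0,
    separation: float = 16.0,
    half_width: float = 0.02,
):
    """A complete two-body docking problem with known ground truth.

    Returns (body A, body B, restraints, truth pose). The restraints are
    generated at the truth pose via :func:`select_restraint_pairs` and
    :func:`simulate_restraints`.
    """
    body_a, body_b, label_sites, lysine_sites, truth = make_toy_bodies(
        seed, separation=separation
    )
    pairs = select_restraint_pairs(
        body_a, body_b, label_sites, lysine_sites, truth, n_restraints=n_restraints
    )
    restraints = simulate_restraints(
        body_a, body_b, pairs, truth, noise_sd=noise_sd, seed=seed, half_width=half_width
    )
    return body_a, body_b, restraints, truth


# --------------------------------------------------------------------------
# Dipolar traces
# --------------------------------------------------------------------------

def gaussian_mixture_distribution(
    r_grid: np.ndarray,
    components: Sequence[tuple[float, float, float]],
) -> DistanceDistribution:
    """P(r) from (mean nm, sd nm, weight) Gaussian components on the grid."""
    r = np.asarray(r_grid, dtype=float)
    p = np.zeros_like(r)
    for mu, sigma, w in components:
        p += w * np.exp(-0.5 * ((r - mu) / sigma) ** 2) / (sigma * np.sqrt(2 * np.pi))
    return DistanceDistribution(r, p).normalized()


def simulate_dipolar_dataset(
    components: Sequence[tuple[float, float, float]],
    config: ScenarioConfig,
    r_grid: np.ndarray | None = None,
) -> tuple[DipolarTrace, DistanceDistribution, BackgroundModel]:
    """A dipolar trace simulated from a Gaussian-mixture P(r), plus the truth."""
    from spindock.peldor import default_r_grid

    if r_grid is None:
        r_grid = default_r_grid()
    truth = gaussian_mixture_distribution(r_grid, components)
    times = np.linspace(0.0, config.t_max_us, config.n_times)
    background = BackgroundModel(
        decay_rate=config.background_k, modulation_depth=config.modulation_depth
    )
    rng = np.random.default_rng(config.seed)
    trace = simulate_trace(
        truth, times, background, noise_sd=config.trace_noise_sd, rng=rng,
        label=f"synthetic seed={config.seed}",
    )
    return trace, truth, background


# --------------------------------------------------------------------------
# Cross-linked MS/MS spectra
# --------------------------------------------------------------------------

def _peptide_covering(protein: ProteinSequence, position: int, max_missed: int = 3) -> Peptide:
    """Shortest tryptic peptide in which ``position`` is a linkable (internal) K."""
    best = None
    for pep in digest(protein, max_missed=max_missed, min_length=5):
        if position in pep.lysine_link_sites(allow_nterm=False):
            if best is None or (pep.missed_cleavages, len(pep.sequence)) < (
                best.missed_cleavages,
                len(best.sequence),
            ):
                best = pep
    if best is None:
        raise ValueError(f"{protein.id} position {position} is not a linkable lysine")
    return best


def simulate_xl_spectra(
    proteins: Sequence[ProteinSequence],
    planted_links: Sequence[tuple[tuple[str, int], tuple[str, int]]],
    config: ScenarioConfig,
    linker: Linker = BS2G,
    charges: tuple[int, ...] = (3, 4),
) -> tuple[list[Spectrum], list[tuple[str, int, str, int]]]:
    """Spectra for planted cross-links plus background, with the truth table.

    Each planted link yields a d0 and a d4 spectrum at every requested charge,
    containing the configured fraction of theoretical b/y ions and uniform
    random noise peaks. Background spectra carry plausible precursor masses
    but purely random peaks.
    """
    rng = np.random.default_rng(config.seed)
    by_id = {p.id: p for p in proteins}
    spectra: list[Spectrum] = []
    truth: list[tuple[str, int, str, int]] = []

    for li, ((pid_a, pos_a), (pid_b, pos_b)) in enumerate(planted_links):
        pep_a = _peptide_covering(by_id[pid_a], pos_a)
        pep_b = _peptide_covering(by_id[pid_b], pos_b)
        key = (pid_a, pos_a, pid_b, pos_b)
        if (pid_b, pos_b) < (pid_a, pos_a):
            key = (pid_b, pos_b, pid_a, pos_a)
        truth.append(key)
        for form in ("d0", "d4"):
            cand = CrossLinkCandidate(pep_a, pos_a, pep_b, pos_b, form)
            neutral = (
                pep_a.monoisotopic_mass
                + pep_b.monoisotopic_mass
                + linker.bridge_mass(form)
            )
            for z in charges:
                frags = theoretical_fragments(cand, linker, max_charge=z - 1)
                fmz = np.array([m for _, m in frags])
                n_keep = max(1, int(round(config.fragment_coverage * len(fmz))))
                keep = rng.choice(len(fmz), size=n_keep, replace=False)
                mz = fmz[keep]
                inten = rng.uniform(0.3, 1.0, size=n_keep)
                if config.n_noise_peaks:
                    noise_mz = rng.uniform(100.0, fmz.max() + 200.0, size=config.n_noise_peaks)
                    noise_in = rng.uniform(0.01, 0.2, size=config.n_noise_peaks)
                    mz = np.concatenate([mz, noise_mz])
                    inten = np.concatenate([inten, noise_in])
                order = np.argsort(mz)
                spectra.append(
                    Spectrum(
                        title=f"planted{li}_{form}_z{z}",
                        precursor_mz=(neutral + z * masses.PROTON_MASS) / z,
                        charge=z,
                        mz=mz[order],
                        intensity=inten[order],
                        retention_index=float(li),
                    )
                )

    # background spectra: plausible precursor mass, random peaks only
    for bi in range(config.n_background_spectra):
        z = int(rng.choice(charges))
        neutral = rng.uniform(1500.0, 4500.0)
        n_pk = config.n_noise_peaks + 30
        mz = np.sort(rng.uniform(100.0, 2000.0, size=n_pk))
        inten = rng.uniform(0.01, 1.0, size=n_pk)
        spectra.append(
            Spectrum(
                title=f"background{bi}",
                precursor_mz=(neutral + z * masses.PROTON_MASS) / z,
                charge=z,
                mz=mz,
                intensity=inten,
                retention_index=100.0 + bi,
            )
        )
    return spectra, truth


def random_protein(seed: int, length: int, lysine_fraction: float = 0.12) -> ProteinSequence:
    """A random canonical sequence with a controlled lysine density."""
    rng = np.random.default_rng(seed)
    alphabet = np.array(list("ADEFGHILNPQSTVWY"))
    residues = rng.choice(alphabet, size=length)
    n_lys = max(2, int(length * lysine_fraction))
    lys_pos = rng.choice(length, size=n_lys, replace=False)
    residues[lys_pos] = "K"
    # a few arginines so digestion has both cleavage residues
    arg_pos = rng.choice(np.setdiff1d(np.arange(length), lys_pos), size=2, replace=False)
    residues[arg_pos] = "R"
    return ProteinSequence(f"synth{seed}", "".join(residues))
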