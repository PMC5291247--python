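"""Identification of isotope-coded cross-linked peptide pairs from peak lists.

The workflow is: tryptic digestion of the target (and reversed-decoy)
sequences, enumeration of cross-linked candidates within an MS1 tolerance for
both isotope forms of the linker, b/y-ion scoring of each candidate against
the spectrum, and decoy-based FDR estimation. Accepted inter-protein
lysine-lysine links convert to flat-bottom NZ-NZ distance restraints.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from spindock import masses
from spindock.geometry import RigidBody
from spindock.restraints import AtomSite, DistanceRestraint

logger = logging.getLogger(__name__)

__all__ = [
    "ProteinSequence",
    "Linker",
    "BS2G",
    "Peptide",
    "Spectrum",
    "CrossLinkCandidate",
    "CrossLinkMatch",
    "digest",
    "build_peptide_index",
    "enumerate_candidates",
    "detect_isotope_doublets",
    "theoretical_fragments",
    "score_match",
    "estimate_fdr",
    "search_spectra",
    "aggregate_matches",
    "crosslinks_to_restraints",
    "read_fasta",
    "write_fasta",
    "read_mgf",
    "write_mgf",
]

_CANONICAL = set("ACDEFGHIKLMNPQRSTVWY")
DECOY_PREFIX = "DECOY_"


@dataclasses.dataclass(frozen=True)
class ProteinSequence:
    id: str
    residues: str

    def __post_init__(self) -> None:
        bad = set(self.residues) - _CANONICAL
        if bad:
            raise ValueError(f"non-canonical residues in {self.id}: {sorted(bad)}")

    def reversed_decoy(self) -> "ProteinSequence":
        return ProteinSequence(DECOY_PREFIX + self.id, self.residues[::-1])


@dataclasses.dataclass(frozen=True)
class Linker:
    """Amine-reactive bifunctional cross-linker with light/heavy isotope forms."""

    name: str
    bridge_mass_light: float
    bridge_mass_heavy: float
    spacer_length: float  # Angstrom

    def __post_init__(self) -> None:
        if self.isotope_delta <= 0:
            raise ValueError("heavy bridge must be heavier than light")

    @property
    def isotope_delta(self) -> float:
        return self.bridge_mass_heavy - self.bridge_mass_light

    def bridge_mass(self, form: str) -> float:
        if form == "d0":
            return self.bridge_mass_light
        if form == "d4":
            return self.bridge_mass_heavy
        raise ValueError(f"unknown isotope form {form!r}")


BS2G = Linker(
    name="BS2G-d0/d4",
    bridge_mass_light=masses.BS2G_BRIDGE_LIGHT,
    bridge_mass_heavy=masses.BS2G_BRIDGE_HEAVY,
    spacer_length=masses.BS2G_SPACER_LENGTH,
)


@dataclasses.dataclass(frozen=True)
class Peptide:
    parent_id: str
    start: int  # 1-based inclusive, in parent
    end: int
    sequence: str
    missed_cleavages: int
    monoisotopic_mass: float

    @property
    def is_decoy(self) -> bool:
        return self.parent_id.startswith(DECOY_PREFIX)

    def lysine_link_sites(self, allow_nterm: bool = True) -> list[int]:
        """1-based parent positions of linkable residues.

        Internal lysines qualify; the C-terminal K of the peptide does not
        (trypsin would not have cleaved a modified K). The protein N-terminus
        qualifies through NHS-ester chemistry regardless of identity.
        """
        sites = []
        for i, aa in enumerate(self.sequence):
            pos = self.start + i
            if aa == "K" and i < len(self.sequence) - 1:
                sites.append(pos)
        if allow_nterm and self.start == 1:
            if 1 not in sites:
                sites.insert(0, 1)
        return sites


@dataclasses.dataclass
class Spectrum:
    """A centroided MS/MS spectrum with its precursor description."""

    title: str
    precursor_mz: float
    charge: int
    mz: np.ndarray
    intensity: np.ndarray
    retention_index: float = 0.0

    @property
    def precursor_neutral_mass(self) -> float:
        return self.precursor_mz * self.charge - self.charge * masses.PROTON_MASS


@dataclasses.dataclass(frozen=True)
class CrossLinkCandidate:
    alpha: Peptide
    alpha_site: int  # 1-based parent position of linked residue
    beta: Peptide
    beta_site: int
    isotope_form: str  # "d0" | "d4"

    @property
    def is_decoy(self) -> bool:
        return self.alpha.is_decoy or self.beta.is_decoy

    @property
    def residue_pair(self) -> tuple[str, int, str, int]:
        a = (self.alpha.parent_id, self.alpha_site)
        b = (self.beta.parent_id, self.beta_site)
        if b < a:
            a, b = b, a
        return (*a, *b)


@dataclasses.dataclass
class CrossLinkMatch:
    candidate: CrossLinkCandidate
    spectrum_title: str
    precursor_charge: int
    score: float
    fdr_q: float = np.nan
    times_observed: int = 1

    @property
    def is_decoy(self) -> bool:
        return self.candidate.is_decoy


# --------------------------------------------------------------------------
# Digestion
# --------------------------------------------------------------------------

def digest(
    protein: ProteinSequence,
    max_missed: int = 3,
    min_length: int = 1,
) -> list[Peptide]:
    """Tryptic digestion: cleave after K or R except before P.

    Emits every peptide with up to ``max_missed`` internal cleavage sites.
    """
    seq = protein.residues
    if not seq:
        raise ValueError("empty sequence")
    cut_after = [
        i
        for i in range(len(seq) - 1)
        if seq[i] in "KR" and seq[i + 1] != "P"
    ]
    boundaries = [0] + [i + 1 for i in cut_after] + [len(seq)]
    peptides = []
    n_frag = len(boundaries) - 1
    for i in range(n_frag):
        for j in range(i, min(i + max_missed + 1, n_frag)):
            start, end = boundaries[i], boundaries[j + 1]
            sub = seq[start:end]
            if len(sub) < min_length:
                continue
            peptides.append(
                Peptide(
                    parent_id=protein.id,
                    start=start + 1,
                    end=end,
                    sequence=sub,
                    missed_cleavages=j - i,
                    monoisotopic_mass=masses.peptide_mass(sub),
                )
            )
    return peptides


def build_peptide_index(
    proteins: Iterable[ProteinSequence],
    max_missed: int = 3,
    min_length: int = 5,
    with_decoys: bool = True,
) -> list[Peptide]:
    """Digest all proteins (plus reversed decoys) into a flat peptide list."""
    peptides: list[Peptide] = []
    for protein in proteins:
        peptides.extend(digest(protein, max_missed=max_missed, min_length=min_length))
        if with_decoys:
            peptides.extend(
                digest(protein.reversed_decoy(), max_missed=max_missed, min_length=min_length)
            )
    return peptides


# --------------------------------------------------------------------------
# Candidate enumeration and doublet detection
# --------------------------------------------------------------------------

def enumerate_candidates(
    peptides: Sequence[Peptide],
    linker: Linker,
    precursor_mass: float,
    ms1_tol_ppm: float = 1.0,
    min_length: int = 5,
    forms: tuple[str, ...] = ("d0", "d4"),
) -> list[CrossLinkCandidate]:
    """All cross-linked peptide pairs matching a precursor neutral mass.

    A pair qualifies when mass(alpha) + mass(beta) + bridge is within
    ``ms1_tol_ppm`` of the precursor mass for either isotope form, both
    peptides are long enough, and each carries a linkable residue.
    """
    pool = [p for p in peptides if len(p.sequence) >= min_length]
    pool.sort(key=lambda p: p.monoisotopic_mass)
    pep_masses = np.array([p.monoisotopic_mass for p in pool])
    tol = ms1_tol_ppm * 1e-6 * precursor_mass
    out: list[CrossLinkCandidate] = []
    for form in forms:
        bridge = linker.bridge_mass(form)
        for i, alpha in enumerate(pool):
            need = precursor_mass - bridge - alpha.monoisotopic_mass
            if need < pep_masses[0] - tol:
                break
            lo = np.searchsorted(pep_masses, need - tol, side="left")
            hi = np.searchsorted(pep_masses, need + tol, side="right")
            for j in range(lo, hi):
                if j < i:
                    continue  # unordered pairs once
                beta = pool[j]
                for a_site in alpha.lysine_link_sites():
                    for b_site in beta.lysine_link_sites():
                        if (
                            alpha.parent_id == beta.parent_id
                            and a_site == b_site
                        ):
                            continue
                        out.append(
                            CrossLinkCandidate(alpha, a_site, beta, b_site, form)
                        )
    return out


def detect_isotope_doublets(
    features: Sequence[tuple[float, int, float]],
    isotope_delta: float = masses.BS2G_ISOTOPE_DELTA,
    tol_ppm: float = 10.0,
    charge_range: tuple[int, int] = (3, 6),
    retention_window: float = 1.0,
) -> list[tuple[int, int]]:
    """Pair co-eluting precursor features whose neutral masses differ by the
    isotope delta.

    ``features`` are (monoisotopic m/z, charge, retention index) triples.
    Returns index pairs (light, heavy). The ppm tolerance applies to the
    neutral mass and is inclusive at the boundary.
    """
    neutral = [
        (i, mz * z - z * masses.PROTON_MASS, z, rt)
        for i, (mz, z, rt) in enumerate(features)
        if charge_range[0] <= z <= charge_range[1]
    ]
    pairs = []
    for ai in range(len(neutral)):
        i, mi, zi, ri = neutral[ai]
        for bj in range(len(neutral)):
            j, mj, zj, rj = neutral[bj]
            if i == j or zi != zj:
                continue
            if abs(ri - rj) > retention_window:
                continue
            diff = mj - mi
            if diff <= 0:
                continue
            # inclusive at the stated tolerance boundary (small fp guard)
            tol = tol_ppm * 1e-6 * mi
            if abs(diff - isotope_delta) <= tol * (1 + 1e-9) + 1e-12:
                pairs.append((i, j))
    return pairs


# --------------------------------------------------------------------------
# Fragment generation and scoring
# --------------------------------------------------------------------------

def theoretical_fragments(
    candidate: CrossLinkCandidate,
    linker: Linker,
    max_charge: int,
) -> list[tuple[str, float]]:
    """(label, m/z) of all b/y ions of both peptides at charges 1..max_charge.

    Fragments containing the linked residue carry the partner peptide plus the
    bridge as a fixed mass shift.
    """
    bridge = linker.bridge_mass(candidate.isotope_form)
    frags: list[tuple[str, float]] = []
    pair = (
        (candidate.alpha, candidate.alpha_site, candidate.beta, "a"),
        (candidate.beta, candidate.beta_site, candidate.alpha, "b"),
    )
    for peptide, site, partner, tag in pair:
        seq = peptide.sequence
        link_idx = site - peptide.start  # 0-based within peptide
        shift = partner.monoisotopic_mass + bridge
        n = len(seq)
        prefix = np.cumsum([masses.RESIDUE_MASSES[aa] for aa in seq])
        total = prefix[-1]
        for i in range(1, n):  # fragment after residue i-1 (b_i / y_{n-i})
            b_neutral = prefix[i - 1]
            y_neutral = total - prefix[i - 1] + masses.WATER_MASS
            b_linked = link_idx <= i - 1
            if b_linked:
                b_neutral += shift
            else:
                y_neutral += shift
            for z in range(1, max_charge + 1):
                frags.append(
                    (f"{tag}:b{i}+{z}", (b_neutral + z * masses.PROTON_MASS) / z)
                )
                frags.append(
                    (f"{tag}:y{n - i}+{z}", (y_neutral + z * masses.PROTON_MASS) / z)
                )
    return frags


def score_match(
    candidate: CrossLinkCandidate,
    spectrum: Spectrum,
    linker: Linker = BS2G,
    ms2_tol_ppm: float = 10.0,
) -> float:
    """Log-intensity-weighted count of matched b/y ions.

    score = sum over matched theoretical ions of (1 + log10 I_rel), where
    I_rel is the peak intensity relative to the base peak. Each theoretical
    ion matches at most one peak (the nearest within tolerance).
    """
    if len(spectrum.mz) == 0:
        return 0.0
    max_charge = max(1, spectrum.charge - 1)
    frags = theoretical_fragments(candidate, linker, max_charge)
    order = np.argsort(spectrum.mz)
    mz = np.asarray(spectrum.mz, dtype=float)[order]
    inten = np.asarray(spectrum.intensity, dtype=float)[order]
    rel = inten / inten.max()
    score = 0.0
    for _, fmz in frags:
        tol = ms2_tol_ppm * 1e-6 * fmz
        lo = np.searchsorted(mz, fmz - tol, side="left")
        hi = np.searchsorted(mz, fmz + tol, side="right")
        if hi > lo:
            best = lo + int(np.argmin(np.abs(mz[lo:hi] - fmz)))
            score += 1.0 + np.log10(max(rel[best], 1e-12))
    return float(score)


# --------------------------------------------------------------------------
# FDR estimation
# --------------------------------------------------------------------------

def estimate_fdr(matches: Sequence[CrossLinkMatch]) -> None:
    """Assign decoy-based q-values in place.

    At each score threshold, FDR = decoys / targets among matches scoring at
    least that threshold; the q-value of a match is the minimum FDR over all
    thresholds that admit it (cumulative minimum from the permissive end).
    """
    if not matches:
        return
    order = sorted(range(len(matches)), key=lambda i: -matches[i].score)
    n_decoy = 0
    n_target = 0
    fdrs = np.empty(len(order))
    for rank, i in enumerate(order):
        if matches[i].is_decoy:
            n_decoy += 1
        else:
            n_target += 1
        fdrs[rank] = n_decoy / max(n_target, 1)
    q = np.minimum.accumulate(fdrs[::-1])[::-1]
    for rank, i in enumerate(order):
        matches[i].fdr_q = float(q[rank])


# --------------------------------------------------------------------------
# End-to-end search
# --------------------------------------------------------------------------

@dataclasses.dataclass
class SearchParams:
    ms1_tol_ppm: float = 1.0
    ms2_tol_ppm: float = 10.0
    min_peptide_length: int = 5
    max_missed: int = 3
    fdr_threshold: float = 0.05
    min_times_observed: int = 3  # "observed > 2 times"


def search_spectra(
    spectra: Sequence[Spectrum],
    proteins: Sequence[ProteinSequence],
    linker: Linker = BS2G,
    params: SearchParams | None = None,
) -> tuple[list[CrossLinkMatch], list[CrossLinkMatch]]:
    """Search spectra against target + reversed-decoy cross-link candidates.

    Returns (all spectrum-level matches with q-values, accepted matches after
    the q <= fdr_threshold and times-observed filters).
    """
    params = params or SearchParams()
    peptides = build_peptide_index(
        proteins,
        max_missed=params.max_missed,
        min_length=params.min_peptide_length,
        with_decoys=True,
    )
    matches: list[CrossLinkMatch] = []
    for spectrum in spectra:
        candidates = enumerate_candidates(
            peptides,
            linker,
            spectrum.precursor_neutral_mass,
            ms1_tol_ppm=params.ms1_tol_ppm,
            min_length=params.min_peptide_length,
        )
        if not candidates:
            continue
        scored = [
            (score_match(c, spectrum, linker, params.ms2_tol_ppm), c)
            for c in candidates
        ]
        best_score, best = max(scored, key=lambda t: t[0])
        if best_score <= 0:
            continue
        matches.append(
            CrossLinkMatch(
                candidate=best,
                spectrum_title=spectrum.title,
                precursor_charge=spectrum.charge,
                score=best_score,
            )
        )
    estimate_fdr(matches)
    accepted = aggregate_matches(matches, params)
    return matches, accepted


def aggregate_matches(
    matches: Sequence[CrossLinkMatch], params: SearchParams
) -> list[CrossLinkMatch]:
    """Collapse spectrum-level matches to residue pairs and apply acceptance.

    A residue pair is accepted when its best q-value is within the FDR
    threshold and it is supported by at least ``min_times_observed`` spectra
    (d0 and d4 forms pooled).
    """
    by_pair: dict[tuple, list[CrossLinkMatch]] = {}
    for m in matches:
        by_pair.setdefault(m.candidate.residue_pair, []).append(m)
    accepted = []
    for group in by_pair.values():
        best = min(group, key=lambda m: (m.fdr_q, -m.score))
        best.times_observed = len(group)
        if (
            best.fdr_q <= params.fdr_threshold
            and best.times_observed >= params.min_times_observed
        ):
            accepted.append(best)
    accepted.sort(key=lambda m: -m.score)
    return accepted


def matches_to_table(matches: Sequence[CrossLinkMatch], path: str | Path) -> None:
    """Tab-separated results mirroring the accepted-link report."""
    lines = [
        "alpha_protein\talpha_pos\tbeta_protein\tbeta_pos\tisotope_form\t"
        "charge\tscore\tq_value\ttimes_observed\tdecoy"
    ]
    for m in matches:
        c = m.candidate
        lines.append(
            f"{c.alpha.parent_id}\t{c.alpha_site}\t{c.beta.parent_id}\t"
            f"{c.beta_site}\t{c.isotope_form}\t{m.precursor_charge}\t"
            f"{m.score:.4f}\t{m.fdr_q:.4f}\t{m.times_observed}\t{int(m.is_decoy)}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


# --------------------------------------------------------------------------
# Restraint conversion
# --------------------------------------------------------------------------

def crosslinks_to_restraints(
    accepted: Sequence[CrossLinkMatch],
    bodies: dict[str, RigidBody],
    chain_map: dict[str, tuple[str, str]],
    upper_bound: float = 20.0,
    weight: float = 1.0,
) -> list[DistanceRestraint]:
    """Accepted K-K links become flat-bottom NZ-NZ restraints.

    ``chain_map`` resolves a protein id to (body key, chain id). Links whose
    residues are missing from the coordinates are dropped with a warning.
    """
    restraints = []
    for m in accepted:
        c = m.candidate
        sites = []
        ok = True
        for pid, pos in ((c.alpha.parent_id, c.alpha_site), (c.beta.parent_id, c.beta_site)):
            if pid not in chain_map:
                raise KeyError(f"protein id {pid!r} not in chain map")
            body_key, chain = chain_map[pid]
            body = bodies[body_key]
            if not body.select(chain, pos, "NZ"):
                logger.warning(
                    "dropping link %s:%s-%s:%s: residue %s:%s has no NZ in %s",
                    c.alpha.parent_id, c.alpha_site, c.beta.parent_id, c.beta_site,
                    chain, pos, body_key,
                )
                ok = False
                break
            sites.append(AtomSite(body_key, chain, pos, "NZ"))
        if not ok:
            continue
        restraints.append(
            DistanceRestraint(
                label=f"{c.alpha.parent_id}K{c.alpha_site}-{c.beta.parent_id}K{c.beta_site}",
                source="XLMS",
                site_a=sites[0],
                site_b=sites[1],
                target=None,
                lower_bound=0.0,
                upper_bound=upper_bound,
                weight=weight,
            )
        )
    return restraints


# --------------------------------------------------------------------------
# FASTA / MGF I/O
# --------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[ProteinSequence]:
    from Bio import SeqIO

    return [
        ProteinSequence(rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(path: str | Path, proteins: Sequence[ProteinSequence]) -> None:
    lines = []
    for p in proteins:
        lines.append(f">{p.id}")
        for i in range(0, len(p.residues), 60):
            lines.append(p.residues[i : i + 60])
    Path(path).write_text("\n".join(lines) + "\n")


def read_mgf(path: str | Path) -> list[Spectrum]:
    spectra = []
    title = ""
    pepmass = charge = rtin = None
    mzs: list[float] = []
    intens: list[float] = []
    in_block = False
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line == "BEGIN IONS":
            in_block = True
            title, pepmass, charge, rtin = "", None, None, 0.0
            mzs, intens = [], []
        elif line == "END IONS":
            if pepmass is None or charge is None:
                raise ValueError(f"{path}: spectrum missing PEPMASS or CHARGE")
            spectra.append(
                Spectrum(
                    title=title,
                    precursor_mz=pepmass,
                    charge=charge,
                    mz=np.array(mzs),
                    intensity=np.array(intens),
                    retention_index=rtin or 0.0,
                )
            )
            in_block = False
        elif in_block:
            if line.startswith("TITLE="):
                title = line[6:]
            elif line.startswith("PEPMASS="):
                pepmass = float(line[8:].split()[0])
            elif line.startswith("CHARGE="):
                charge = int(line[7:].rstrip("+-"))
            elif line.startswith("RTINSECONDS="):
                rtin = float(line[12:])
            elif line[0].isdigit() or line[0] in ".-":
                parts = line.split()
                mzs.append(float(parts[0]))
                intens.append(float(parts[1]) if len(parts) > 1 else 1.0)
    return spectra


def write_mgf(path: str | Path, spectra: Sequence[Spectrum]) -> None:
    lines = []
    for s in spectra:
        lines.append("BEGIN IONS")
        lines.append(f"TITLE={s.title}")
        lines.append(f"PEPMASS={s.precursor_mz:.6f}")
        lines.append(f"CHARGE={s.charge}+")
        lines.append(f"RTINSECONDS={s.retention_index:.2f}")
        for mz, inten in zip(s.mz, s.intensity):
            lines.append(f"{mz:.6f} {inten:.4f}")
        lines.append("END IONS")
        lines.append("")
    Path(path).write_text("\n".join(lines))
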