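"""Flat-bottom distance restraints and their tabular text representation.

A restraint site is either an atom selector ``chain:resnum:atomname`` resolved
on one of the two docked bodies, or a named spin-label ensemble. Restraint
tables are tab-separated text with the columns
``label  type  site_a  site_b  target  lower  upper  weight``.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Union

__all__ = ["AtomSite", "EnsembleSite", "DistanceRestraint",
           "read_restraint_table", "write_restraint_table"]


@dataclasses.dataclass(frozen=True)
class AtomSite:
    """Selector for a single atom: which body, chain, residue and atom name."""

    body: str  # "A" or "B"
    chain_id: str
    residue_number: int
    atom_name: str

    def __str__(self) -> str:
        return f"{self.body}/{self.chain_id}:{self.residue_number}:{self.atom_name}"

    @classmethod
    def parse(cls, text: str) -> "AtomSite":
        body, rest = text.split("/", 1)
        chain, resnum, atom = rest.split(":")
        return cls(body, chain, int(resnum), atom)


@dataclasses.dataclass(frozen=True)
class EnsembleSite:
    """Reference to a named spin-label ensemble attached to one body."""

    body: str
    label: str  # e.g. "Y35Rx2"

    def __str__(self) -> str:
        return f"{self.body}/ens:{self.label}"

    @classmethod
    def parse(cls, text: str) -> "EnsembleSite":
        body, rest = text.split("/", 1)
        return cls(body, rest.split(":", 1)[1])


Site = Union[AtomSite, EnsembleSite]


def _parse_site(text: str) -> Site:
    if "/ens:" in text:
        return EnsembleSite.parse(text)
    return AtomSite.parse(text)


@dataclasses.dataclass(frozen=True)
class DistanceRestraint:
    """Flat-bottom well between two sites; zero penalty inside [lower, upper]."""

    label: str
    source: str  # "PELDOR" | "XLMS" | "SYNTH"
    site_a: Site
    site_b: Site
    target: float | None  # Angstrom; None for pure-bound restraints
    lower_bound: float
    upper_bound: float
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.lower_bound > self.upper_bound:
            raise ValueError("lower_bound > upper_bound")
        if self.target is not None and not (
            self.lower_bound <= self.target <= self.upper_bound
        ):
            raise ValueError("target outside [lower, upper]")
        if self.weight <= 0:
            raise ValueError("weight must be positive")

    def violation(self, distance: float) -> float:
        """Positive amount by which a distance falls outside the flat bottom."""
        return max(0.0, distance - self.upper_bound, self.lower_bound - distance)

    def deviation(self, distance: float) -> float:
        """Signed distance-to-target (falls back to nearest bound if no target)."""
        ref = self.target if self.target is not None else None
        if ref is None:
            if distance > self.upper_bound:
                return distance - self.upper_bound
            if distance < self.lower_bound:
                return distance - self.lower_bound
            return 0.0
        return distance - ref


_COLUMNS = ("label", "type", "site_a", "site_b", "target", "lower", "upper", "weight")


def write_restraint_table(path: str | Path, restraints: list[DistanceRestraint]) -> None:
    lines = ["\t".join(_COLUMNS)]
    for r in restraints:
        target = "" if r.target is None else f"{r.target:.4f}"
        lines.append(
            "\t".join(
                [
                    r.label,
                    r.source,
                    str(r.site_a),
                    str(r.site_b),
                    target,
                    f"{r.lower_bound:.4f}",
                    f"{r.upper_bound:.4f}",
                    f"{r.weight:.4f}",
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_restraint_table(path: str | Path) -> list[DistanceRestraint]:
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ValueError("empty restraint table")
    header = lines[0].rstrip("\n").split("\t")
    if tuple(header) != _COLUMNS:
        raise ValueError(f"unexpected restraint table header: {header}")
    out = []
    for line in lines[1:]:
        if not line.strip():
            continue
        label, rtype, sa, sb, target, lower, upper, weight = line.split("\t")
        out.append(
            DistanceRestraint(
                label=label,
                source=rtype,
                site_a=_parse_site(sa),
                site_b=_parse_site(sb),
                target=float(target) if target else None,
                lower_bound=float(lower),
                upper_bound=float(upper),
                weight=float(weight),
            )
        )
    return out
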