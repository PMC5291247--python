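"""End-to-end analysis workflows on real deposited structures.

These functions run the integrative-docking analysis on deposited structures when
required PDB files are available locally (they are not bundled; download e.g.
``https://files.rcsb.org/download/2ZD7.pdb`` into the data directory).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np

from spindock.docking import (
    DockingParams,
    Pose,
    average_models,
    run_docking,
    validate_model,
)
from spindock.geometry import RigidBody, load_structure
from spindock.labels import (
    AccessibleVolumeParams,
    LabelSite,
    attach_r1_ensemble,
    attach_rx2_label,
)
from spindock.restraints import AtomSite, DistanceRestraint, EnsembleSite

__all__ = ["ComplexChains", "chaperone_histone_docking", "octamer_k56_k64_distance"]


@dataclasses.dataclass
class ComplexChains:
    """Chain assignment for the dimer structure and the chaperone-histone complex."""

    vps75: tuple[str, str] = ("A", "B")
    h3: str = "A"
    h4: str = "B"
    asf1: str = "C"


def _peldor_restraint(label, ens_a, ens_b, target, half_width=3.0):
    return DistanceRestraint(
        label=label,
        source="PELDOR",
        site_a=ens_a,
        site_b=ens_b,
        target=target,
        lower_bound=target - half_width,
        upper_bound=target + half_width,
        weight=1.0,
    )


def build_experimental_restraints(chains: ComplexChains) -> list[DistanceRestraint]:
    """The five experimentally derived restraints: three spin-spin distances + two cross-links.

    Modal distances 6.65, 5.49 and 6.13 nm enter as 66.5, 54.9 and 61.3 A
    targets between the bifunctional label on the dimer and the three
    monofunctional histone labels; the two cross-links become 20 A
    upper-bound NZ-NZ restraints.
    """
    rx2 = EnsembleSite("A", "Y35Rx2")
    restraints = [
        _peldor_restraint("E1", rx2, EnsembleSite("B", "H3Q125R1"), 66.5),
        _peldor_restraint("E2", rx2, EnsembleSite("B", "H4N25R1"), 54.9),
        _peldor_restraint("E3", rx2, EnsembleSite("B", "H4R45R1"), 61.3),
    ]
    for label, resnum in (("X1", 177), ("X2", 169)):
        restraints.append(
            DistanceRestraint(
                label=label,
                source="XLMS",
                site_a=AtomSite("A", chains.vps75[0], resnum, "NZ"),
                site_b=AtomSite("B", chains.asf1, 143, "NZ"),
                target=None,
                lower_bound=0.0,
                upper_bound=20.0,
                weight=1.0,
            )
        )
    return restraints


def chaperone_histone_docking(
    dimer_pdb: str | Path,
    complex_pdb: str | Path,
    chains: ComplexChains | None = None,
    n_starts: int = 500,
    seed: int = 0,
    params: DockingParams | None = None,
):
    """Dock the chaperone dimer against the capped histone complex.

    Returns (accepted ensemble, per-restraint deviations of the averaged
    model, max |deviation| in Angstrom).
    """
    chains = chains or ComplexChains()
    body_a = load_structure(dimer_pdb, chain_filter=set(chains.vps75), name="dimer")
    body_b = load_structure(
        complex_pdb, chain_filter={chains.h3, chains.h4, chains.asf1}, name="complex"
    )
    av = AccessibleVolumeParams()
    ensembles = {
        "A/Y35Rx2": attach_rx2_label(
            body_a,
            LabelSite("Rx2", ((chains.vps75[0], 35), (chains.vps75[1], 35)), "Y35Rx2"),
            AccessibleVolumeParams(bridge_max=30.0, tether_max=16.0),
            seed=seed,
        ),
        "B/H3Q125R1": attach_r1_ensemble(
            body_b, LabelSite("R1", ((chains.h3, 125),), "H3Q125R1"), av, seed=seed
        ),
        "B/H4N25R1": attach_r1_ensemble(
            body_b, LabelSite("R1", ((chains.h4, 25),), "H4N25R1"), av, seed=seed
        ),
        "B/H4R45R1": attach_r1_ensemble(
            body_b, LabelSite("R1", ((chains.h4, 45),), "H4R45R1"), av, seed=seed
        ),
    }
    restraints = build_experimental_restraints(chains)
    params = params or DockingParams(
        d_acc=3.0, clash_max=100.0, clash_atom_stride=4, max_iterations=40,
        funnel_width=3.0,
    )
    solutions = run_docking(
        body_a, body_b, restraints, ensembles=ensembles,
        n_starts=n_starts, seed=seed, params=params,
    )
    accepted = [s for s in solutions if s.accepted]
    if not accepted:
        raise RuntimeError("no docking solution satisfied the restraints")
    ensemble = average_models(accepted, body_a, body_b)
    avg_body_b = body_b.with_coords(ensemble.average_coords_b)
    # B-side label ensembles are regenerated on the averaged coordinates so
    # validation measures distances to labels that follow the averaged model
    val_ensembles = {
        "A/Y35Rx2": ensembles["A/Y35Rx2"],
        "B/H3Q125R1": attach_r1_ensemble(
            avg_body_b, LabelSite("R1", ((chains.h3, 125),), "H3Q125R1"), av, seed=seed
        ),
        "B/H4N25R1": attach_r1_ensemble(
            avg_body_b, LabelSite("R1", ((chains.h4, 25),), "H4N25R1"), av, seed=seed
        ),
        "B/H4R45R1": attach_r1_ensemble(
            avg_body_b, LabelSite("R1", ((chains.h4, 45),), "H4R45R1"), av, seed=seed
        ),
    }
    deviations, max_dev = validate_model(
        body_a,
        avg_body_b,
        Pose.from_params(np.zeros(6)),
        restraints,
        ensembles=val_ensembles,
        params=params,
    )
    return ensemble, deviations, max_dev


def octamer_k56_k64_distance(octamer_pdb: str | Path) -> float:
    """NZ-NZ distance between lysines 56 and 64 within one H3 chain (Angstrom)."""
    body = load_structure(octamer_pdb, name="octamer")
    for chain_id in body.chain_ids:
        k56 = body.select(chain_id, 56, "NZ")
        k64 = body.select(chain_id, 64, "NZ")
        if (
            len(k56) == 1
            and len(k64) == 1
            and k56[0].residue_name == "LYS"
            and k64[0].residue_name == "LYS"
        ):
            return k56[0].distance_to(k64[0])
    raise ValueError("no chain with LYS 56 and LYS 64 found")
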