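# spindock

Integrative rigid-body modelling of a two-component protein complex from
sparse spectroscopic distance restraints. The package covers the full
pipeline used to derive a chaperone–histone complex model:

- **`spindock.geometry`** — PDB I/O, rigid bodies, proper rigid transforms,
  Kabsch superposition (reflection-free), uniform SO(3) sampling.
- **`spindock.labels`** — spin-label ensembles by accessible-volume sampling:
  monofunctional nitroxide (R1) at one residue and a bifunctional label (Rx2)
  bridging two residues; ensemble distance statistics.
- **`spindock.peldor`** — dipolar evolution traces: powder-averaged kernel
  (Fresnel closed form, D = 52.041 MHz·nm³), 3-D exponential background
  correction, non-negative Tikhonov inversion with L-curve α selection,
  forward trace simulation.
- **`spindock.xlms`** — isotope-coded (d0/d4) cross-linked peptide
  identification: tryptic digestion, candidate enumeration at MS1 ppm
  tolerance, precursor doublet detection (Δ = 4.0251 Da), b/y-ion scoring,
  reversed-decoy FDR, conversion of accepted lysine–lysine links to
  flat-bottom Nζ–Nζ restraints.
- **`spindock.docking`** — rigid-body docking of two bodies against
  flat-bottom restraints from randomized starts (uniform SO(3) orientations),
  Levenberg–Marquardt minimization with optional coarse-to-fine well
  widening, violation-based acceptance, backbone alignment and coordinate
  averaging, restraint validation, and template-based extrapolation of the
  docked model onto higher-order assemblies.
- **`spindock.massacct`** — adduct counting from observed vs theoretical
  SEC-MALS masses and simple complex-mass sums.
- **`spindock.synthetic`** — ground-truth generators for every stage: toy
  rigid bodies in a known pose, restraints with controlled noise, dipolar
  traces from stated P(r), and cross-linked MS/MS spectra with d0/d4
  precursor doublets and decoy contamination.
- **`spindock.workflows`** — end-to-end runs on deposited structures
  (require local PDB files, see below).

## CLI

A single entry point with subcommands:

```sh
spindock adducts --observed 65.3 --theoretical 62.6 --adduct-da 174
spindock simulate trace --seed 1 --out sim/          # also: bodies|restraints|spectra
spindock invert --trace sim/trace.txt --alpha auto --out pr.txt
spindock xlsearch --fasta prot.fasta --mgf spectra.mgf --ms1-ppm 1 --fdr 0.05
spindock dock --body-a A.pdb --body-b B.pdb --restraints R.tsv --starts 500 --seed 1
spindock validate --model-a A.pdb --model-b B_posed.pdb --restraints R.tsv
```

## File formats

Traces and distance distributions are two-column text; restraint tables are
TSV (`label type site_a site_b target lower upper weight` with sites written
as `BODY/CHAIN:RES:ATOM` or `BODY/ens:NAME`); sequences are FASTA; spectra
are MGF; structures are PDB (multi-model for ensembles). All internal
distances are in Ångström; nanometres appear only at the dipolar-trace
boundary.
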