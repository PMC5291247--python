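import numpy as np
import pytest

from spindock import masses, xlms
from spindock.geometry import Atom, RigidBody
from spindock.xlms import (
    BS2G,
    CrossLinkCandidate,
    CrossLinkMatch,
    ProteinSequence,
    SearchParams,
    Spectrum,
    build_peptide_index,
    crosslinks_to_restraints,
    detect_isotope_doublets,
    digest,
    enumerate_candidates,
    estimate_fdr,
    score_match,
    theoretical_fragments,
)


class TestDigest:
    def test_no_cleavage_before_proline(self):
        peps = digest(ProteinSequence("p", "AKRPG"), max_missed=0)
        assert {p.sequence for p in peps} == {"AK", "RPG"}

    def test_missed_cleavage_adds_full_span(self):
        peps = digest(ProteinSequence("p", "AKRPG"), max_missed=1)
        assert {p.sequence for p in peps} == {"AK", "RPG", "AKRPG"}

    def test_no_cut_sites(self):
        peps = digest(ProteinSequence("p", "AGSTV"), max_missed=2)
        assert [p.sequence for p in peps] == ["AGSTV"]

    def test_invalid_residue(self):
        with pytest.raises(ValueError):
            ProteinSequence("p", "AXK")

    def test_masses_recomputable(self):
        for pep in digest(ProteinSequence("p", "MKTAYRAKGSW"), max_missed=2):
            assert abs(pep.monoisotopic_mass - masses.peptide_mass(pep.sequence)) < 1e-4

    def test_order_invariance_of_set(self):
        peps = digest(ProteinSequence("p", "AKCKDKEK"), max_missed=2)
        keys = [(p.start, p.end) for p in peps]
        assert len(keys) == len(set(keys))


class TestLinker:
    def test_isotope_delta_from_atomic_masses(self):
        assert abs(BS2G.isotope_delta - 4.02510) < 1e-4

    def test_invalid_linker(self):
        with pytest.raises(ValueError):
            xlms.Linker("bad", 100.0, 99.0, 7.7)


def _make_pair():
    prot_a = ProteinSequence("A", "GASTKLVNR")
    prot_b = ProteinSequence("B", "VLDMKFAGK")
    peps_a = [p for p in digest(prot_a, max_missed=2) if "K" in p.sequence[:-1]]
    peps_b = [p for p in digest(prot_b, max_missed=2) if "K" in p.sequence[:-1]]
    return prot_a, prot_b, peps_a[0], peps_b[0]


class TestEnumerate:
    def test_constructed_precursor_d0(self):
        prot_a, prot_b, pa, pb = _make_pair()
        peptides = build_peptide_index([prot_a, prot_b], with_decoys=False)
        mass = pa.monoisotopic_mass + pb.monoisotopic_mass + BS2G.bridge_mass_light
        cands = enumerate_candidates(peptides, BS2G, mass, ms1_tol_ppm=1.0)
        forms = {c.isotope_form for c in cands}
        assert "d0" in forms
        assert any(
            {c.alpha.sequence, c.beta.sequence} == {pa.sequence, pb.sequence}
            for c in cands
        )

    def test_same_pair_matches_d4_at_shifted_precursor(self):
        prot_a, prot_b, pa, pb = _make_pair()
        peptides = build_peptide_index([prot_a, prot_b], with_decoys=False)
        mass = (
            pa.monoisotopic_mass + pb.monoisotopic_mass
            + BS2G.bridge_mass_light + 4.02510
        )
        cands = enumerate_candidates(peptides, BS2G, mass, ms1_tol_ppm=1.0)
        assert cands
        assert all(c.isotope_form == "d4" for c in cands)

    def test_pair_without_linkable_lysine_excluded(self):
        # peptides whose only K is C-terminal carry no link site
        prot = ProteinSequence("C", "GASTRLVDK")
        peptides = [p for p in digest(prot, max_missed=0) if len(p.sequence) >= 5]
        assert peptides
        mass = 2 * peptides[0].monoisotopic_mass + BS2G.bridge_mass_light
        cands = enumerate_candidates(peptides, BS2G, mass, ms1_tol_ppm=5.0)
        assert cands == []


class TestDoublets:
    def _mz(self, neutral, z):
        return (neutral + z * masses.PROTON_MASS) / z

    def test_exact_delta_paired(self):
        m = 2400.0
        feats = [
            (self._mz(m, 4), 4, 10.0),
            (self._mz(m + 4.02510, 4), 4, 10.2),
        ]
        assert detect_isotope_doublets(feats) == [(0, 1)]

    def test_wrong_delta_rejected(self):
        m = 2400.0
        feats = [(self._mz(m, 4), 4, 10.0), (self._mz(m + 4.5, 4), 4, 10.0)]
        assert detect_isotope_doublets(feats) == []

    def test_boundary_inclusive_at_10ppm(self):
        m = 2400.0
        delta = 4.02510 + 10e-6 * m
        feats = [(self._mz(m, 3), 3, 5.0), (self._mz(m + delta, 3), 3, 5.0)]
        assert detect_isotope_doublets(feats) == [(0, 1)]

    def test_charge_mismatch_and_range(self):
        m = 2400.0
        feats = [
            (self._mz(m, 3), 3, 1.0),
            (self._mz(m + 4.02510, 4), 4, 1.0),  # different charge
            (self._mz(m, 2), 2, 1.0),
            (self._mz(m + 4.02510, 2), 2, 1.0),  # charge outside [3, 6]
        ]
        assert detect_isotope_doublets(feats) == []

    def test_coelution_required(self):
        m = 2400.0
        feats = [(self._mz(m, 4), 4, 0.0), (self._mz(m + 4.02510, 4), 4, 50.0)]
        assert detect_isotope_doublets(feats, retention_window=1.0) == []


def bruteforce_score(candidate, spectrum, linker, ms2_tol_ppm):
    """Independent ion-by-ion matcher."""
    frags = theoretical_fragments(candidate, linker, max(1, spectrum.charge - 1))
    rel = spectrum.intensity / spectrum.intensity.max()
    total = 0.0
    for _, fmz in frags:
        best = None
        for mz, ri in zip(spectrum.mz, rel):
            if abs(mz - fmz) <= ms2_tol_ppm * 1e-6 * fmz:
                if best is None or abs(mz - fmz) < best[0]:
                    best = (abs(mz - fmz), ri)
        if best is not None:
            total += 1.0 + np.log10(max(best[1], 1e-12))
    return total


class TestScore:
    def _candidate(self):
        prot_a, prot_b, pa, pb = _make_pair()
        site_a = pa.lysine_link_sites()[0]
        site_b = pb.lysine_link_sites()[0]
        return CrossLinkCandidate(pa, site_a, pb, site_b, "d0")

    def test_full_coverage_score_is_ion_count(self):
        cand = self._candidate()
        frags = theoretical_fragments(cand, BS2G, 2)
        mz = np.array(sorted(m for _, m in frags))
        spec = Spectrum("t", 1000.0, 3, mz, np.ones(len(mz)))
        score = score_match(cand, spec, BS2G, ms2_tol_ppm=1.0)
        assert abs(score - len(frags)) < 1e-9

    def test_empty_spectrum_scores_zero(self):
        cand = self._candidate()
        spec = Spectrum("t", 1000.0, 3, np.array([]), np.array([]))
        assert score_match(cand, spec) == 0.0

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(3)
        cand = self._candidate()
        frags = theoretical_fragments(cand, BS2G, 2)
        fmz = np.array([m for _, m in frags])
        keep = rng.choice(len(fmz), size=len(fmz) // 2, replace=False)
        mz = np.concatenate([fmz[keep], rng.uniform(100, 2000, size=30)])
        inten = rng.uniform(0.01, 1.0, size=len(mz))
        order = np.argsort(mz)
        spec = Spectrum("t", 1000.0, 3, mz[order], inten[order])
        mine = score_match(cand, spec, BS2G, ms2_tol_ppm=10.0)
        brute = bruteforce_score(cand, spec, BS2G, ms2_tol_ppm=10.0)
        assert abs(mine - brute) < 1e-9

    def test_intensity_doubling_preserves_order(self):
        rng = np.random.default_rng(4)
        cand = self._candidate()
        frags = theoretical_fragments(cand, BS2G, 2)
        fmz = np.array([m for _, m in frags])
        mz = np.concatenate([fmz[::2], rng.uniform(100, 2000, size=20)])
        inten = rng.uniform(0.1, 1.0, size=len(mz))
        s1 = Spectrum("t", 1000.0, 3, mz, inten)
        s2 = Spectrum("t", 1000.0, 3, mz, inten * 2.0)
        assert abs(score_match(cand, s1) - score_match(cand, s2)) < 1e-9


def _match(score, decoy, pair_tag):
    prot = ProteinSequence("DECOY_X" if decoy else "X", "GASTKLVNR")
    pep = digest(prot, max_missed=1)[0]
    cand = CrossLinkCandidate(pep, 5, pep, 5, "d0")
    m = CrossLinkMatch(cand, f"spec{pair_tag}", 3, score)
    return m


class TestFDR:
    def test_no_decoys_all_zero(self):
        matches = [_match(s, False, i) for i, s in enumerate([10, 8, 5])]
        estimate_fdr(matches)
        assert all(m.fdr_q == 0.0 for m in matches)

    def test_stated_estimator(self):
        # 18 targets above threshold, then 2 decoys below them
        matches = [_match(20 - i, False, i) for i in range(18)]
        matches += [_match(1.0, True, 100), _match(0.5, True, 101)]
        estimate_fdr(matches)
        # at the threshold admitting everything, FDR = 2/18
        assert abs(max(m.fdr_q for m in matches) - 2 / 18) < 1e-12

    def test_q_monotone_nonincreasing_in_score(self):
        rng = np.random.default_rng(0)
        matches = [
            _match(float(rng.uniform(0, 10)), bool(rng.uniform() < 0.3), i)
            for i in range(50)
        ]
        estimate_fdr(matches)
        ordered = sorted(matches, key=lambda m: -m.score)
        qs = [m.fdr_q for m in ordered]
        assert all(qs[i] <= qs[i + 1] + 1e-12 for i in range(len(qs) - 1))


class TestRestraintConversion:
    def _bodies(self):
        def lys(chain, resnum, x):
            return [
                Atom(chain, resnum, "LYS", "CA", "C", [x, 0.0, 0.0]),
                Atom(chain, resnum, "LYS", "NZ", "N", [x, 4.0, 0.0]),
            ]

        body_a = RigidBody("vps", lys("V", 177, 0.0) + lys("V", 169, 5.0))
        body_b = RigidBody("asf", lys("S", 143, 15.0))
        return {"A": body_a, "B": body_b}

    def _accepted(self, pos_a=143, pos_b=177):
        asf = ProteinSequence("Asf1", "G" * 140 + "AGKGR")
        vps = ProteinSequence("Vps75", "G" * 175 + "AKAGR" + "KGGGR")
        pep_a = [p for p in digest(asf, 2) if p.start <= pos_a <= p.end][0]
        pep_b = [p for p in digest(vps, 2) if p.start <= pos_b <= p.end][0]
        cand = CrossLinkCandidate(pep_a, pos_a, pep_b, pos_b, "d0")
        return CrossLinkMatch(cand, "s1", 4, 12.0, fdr_q=0.0, times_observed=4)

    def test_link_becomes_nz_nz_restraint(self):
        bodies = self._bodies()
        chain_map = {"Asf1": ("B", "S"), "Vps75": ("A", "V")}
        restraints = crosslinks_to_restraints([self._accepted()], bodies, chain_map)
        assert len(restraints) == 1
        r = restraints[0]
        assert {r.site_a.atom_name, r.site_b.atom_name} == {"NZ"}
        assert {r.site_a.residue_number, r.site_b.residue_number} == {143, 177}
        assert r.lower_bound == 0.0
        assert r.upper_bound == 20.0

    def test_unresolved_residue_dropped_with_warning(self, caplog):
        bodies = self._bodies()
        chain_map = {"Asf1": ("B", "S"), "Vps75": ("A", "V")}
        bad = self._accepted(pos_b=181)  # no residue 181 in coordinates
        import logging

        with caplog.at_level(logging.WARNING, logger="spindock.xlms"):
            restraints = crosslinks_to_restraints([bad], bodies, chain_map)
        assert restraints == []
        assert any("dropping link" in rec.message for rec in caplog.records)

    def test_unmappable_protein_id(self):
        with pytest.raises(KeyError):
            crosslinks_to_restraints([self._accepted()], self._bodies(), {})

    def test_flat_bottom_deviation_zero_inside(self):
        bodies = self._bodies()
        chain_map = {"Asf1": ("B", "S"), "Vps75": ("A", "V")}
        (r,) = crosslinks_to_restraints([self._accepted()], bodies, chain_map)
        assert r.violation(12.0) == 0.0
        assert r.violation(19.999) == 0.0
        assert r.violation(21.0) == pytest.approx(1.0)


class TestMgfFasta:
    def test_mgf_roundtrip(self, tmp_path):
        spectra = [
            Spectrum("one", 800.123456, 3, np.array([100.0, 200.5]), np.array([1.0, 0.5]), 12.0),
            Spectrum("two", 901.0, 4, np.array([150.25]), np.array([2.0]), 13.5),
        ]
        path = tmp_path / "t.mgf"
        xlms.write_mgf(path, spectra)
        back = xlms.read_mgf(path)
        assert [s.title for s in back] == ["one", "two"]
        assert back[0].charge == 3
        np.testing.assert_allclose(back[0].mz, spectra[0].mz)
        assert back[1].precursor_mz == pytest.approx(901.0)

    def test_fasta_roundtrip(self, tmp_path):
        prots = [ProteinSequence("alpha", "GASTK" * 30), ProteinSequence("beta", "MKWR")]
        path = tmp_path / "p.fasta"
        xlms.write_fasta(path, prots)
        back = xlms.read_fasta(path)
        assert [(p.id, p.residues) for p in back] == [(p.id, p.residues) for p in prots]
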