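"""Digestion, mass arithmetic, fragment ladders, XCorr and target-decoy FDR."""

import numpy as np
import pytest
from pyteomics import mass as pmass

from lenspg.config import PipelineConfig, TMT
from lenspg.search import (PROTON, WATER, Peptide, PeptideSpectrumMatch,
                           RESIDUE_MASS, SearchDatabase, Spectrum, cleave,
                           digest, fdr_filter, generate_fragments,
                           peptide_mass, search, xcorr)
from lenspg.synth import simulate_spectra


@pytest.fixture()
def plain_cfg():
    """No TMT, no fixed mods: directly comparable to textbook masses."""
    return PipelineConfig(tmt_labeling=False, fixed_mods=())


RNG = np.random.default_rng(42)
AMINO = list(RESIDUE_MASS)


def random_protein(n):
    return "".join(AMINO[i] for i in RNG.integers(0, 20, n))


class TestDigest:
    def test_validated_peptide_is_the_only_long_product(self, cfg):
        cfg0 = PipelineConfig(max_missed_cleavages=0)
        assert [p.sequence for p in digest("MKWLIEISKR", cfg0)] == ["WLIEISK"]

    def test_no_cleavage_before_proline(self):
        assert cleave("AKPAAAAR") == ["AKPAAAAR"]
        assert cleave("AKPRAAAK") == ["AKPR", "AAAK"]

    def test_cleavage_concatenation_identity(self):
        for _ in range(20):
            protein = random_protein(int(RNG.integers(10, 300)))
            assert "".join(cleave(protein)) == protein

    def test_missed_cleavage_superset(self, cfg):
        protein = random_protein(200)
        prev = set()
        for k in range(3):
            cfg_k = PipelineConfig(max_missed_cleavages=k)
            cur = {(p.sequence, p.missed_cleavages) for p in digest(protein, cfg_k)}
            assert prev <= cur
            prev = cur

    def test_length_gate(self, cfg):
        assert all(len(p.sequence) >= cfg.min_peptide_len
                   for p in digest(random_protein(300), cfg))


class TestMass:
    def test_single_glycine(self, plain_cfg):
        m = peptide_mass(Peptide("G"), plain_cfg)
        assert m == pytest.approx(RESIDUE_MASS["G"] + WATER, abs=1e-9)

    def test_modification_additivity(self, plain_cfg):
        from lenspg.config import OXIDATION
        base = peptide_mass(Peptide("SAMPLER"), plain_cfg)
        ox = peptide_mass(Peptide("SAMPLER", mods=((2, OXIDATION),)), plain_cfg)
        assert ox - base == pytest.approx(15.99491, abs=1e-9)

    def test_twenty_random_peptides_match_independent_calculator(self, plain_cfg):
        for _ in range(20):
            pep = random_protein(int(RNG.integers(6, 25)))
            mine = peptide_mass(Peptide(pep), plain_cfg)
            ref = pmass.calculate_mass(sequence=pep)
            assert mine == pytest.approx(ref, abs=1e-4)

    def test_mz_definition(self, plain_cfg):
        m, mz = peptide_mass(Peptide("WLIEISK"), plain_cfg, charge=2)
        assert mz == pytest.approx((m + 2 * PROTON) / 2)

    def test_unknown_residue_rejected(self):
        with pytest.raises(ValueError):
            Peptide("PEPTIDEZ")


class TestFragments:
    def test_ion_count(self, plain_cfg):
        ions = generate_fragments(Peptide("WLIEISK"), plain_cfg, charge=2)
        assert len(ions) == 2 * 6
        ions3 = generate_fragments(Peptide("WLIEISK"), plain_cfg, charge=3)
        assert len(ions3) == 4 * 6

    def test_b_y_complementarity(self, plain_cfg):
        pep = "SMGEDTVPK"
        ions = dict(generate_fragments(Peptide(pep), plain_cfg, charge=2))
        M = peptide_mass(Peptide(pep), plain_cfg)
        for i in range(1, len(pep)):
            assert ions[f"b{i}"] + ions[f"y{len(pep) - i}"] == pytest.approx(
                M + 2 * PROTON, abs=1e-9)

    def test_tmt_shifts_y1_of_lysine_terminated_peptide(self):
        with_tmt = PipelineConfig(tmt_labeling=True, fixed_mods=())
        without = PipelineConfig(tmt_labeling=False, fixed_mods=())
        y1_tmt = dict(generate_fragments(Peptide("SAQALVK"), with_tmt, 2))["y1"]
        y1 = dict(generate_fragments(Peptide("SAQALVK"), without, 2))["y1"]
        assert y1_tmt - y1 == pytest.approx(TMT.delta_mass, abs=1e-9)


class TestXcorr:
    def spectrum_for(self, pep, cfg, seed=3, **kw):
        [s] = simulate_spectra([pep], cfg, seed=seed, **kw)
        return s

    def test_true_peptide_beats_100_shuffles(self, cfg):
        pep = "SMGEDTVPKLR"
        s = self.spectrum_for(pep, cfg)
        spec = s.as_spectrum()
        true_score = xcorr(spec, generate_fragments(Peptide(pep), cfg, s.charge), cfg)
        rng = np.random.default_rng(0)
        for _ in range(100):
            shuffled = "".join(rng.permutation(list(pep)))
            if shuffled == pep:
                continue
            alt = xcorr(spec, generate_fragments(Peptide(shuffled), cfg, s.charge), cfg)
            assert alt < true_score

    def test_scale_invariance(self, cfg):
        pep = "AVGVDCSAPEPR"
        s = self.spectrum_for(pep, cfg)
        spec = s.as_spectrum()
        ions = generate_fragments(Peptide(pep), cfg, s.charge)
        doubled = Spectrum(spec.id, spec.precursor_mz, spec.charge,
                           spec.mz, spec.intensity * 2)
        assert xcorr(doubled, ions, cfg) == pytest.approx(xcorr(spec, ions, cfg))

    def test_disjoint_bins_score_nonpositive(self, cfg):
        pep = "AVGVDCSAPEPR"
        s = self.spectrum_for(pep, cfg)
        ions = generate_fragments(Peptide(pep), cfg, s.charge)
        shifted = [(lbl, m + 7.777) for lbl, m in ions]
        assert xcorr(s.as_spectrum(), shifted, cfg) <= 1e-2


@pytest.fixture(scope="module")
def toy_db():
    cfg = PipelineConfig()
    rng = np.random.default_rng(9)
    proteins = [(f"p{i}", "".join(AMINO[j] for j in rng.integers(0, 20, 120)))
                for i in range(8)]
    return cfg, proteins


class TestSearch:

    def test_zero_noise_spectra_recover_generators(self, toy_db):
        cfg, proteins = toy_db
        db = SearchDatabase.build(proteins, cfg)
        # pick real tryptic peptides from the proteins
        peps = []
        for _, seq in proteins:
            peps.extend(p.sequence for p in digest(seq, cfg)
                        if 8 <= len(p.sequence) <= 16)
        peps = sorted(set(peps))[:20]
        spectra = [s.as_spectrum() for s in
                   simulate_spectra(peps, cfg, seed=5, noise_peaks=0, mass_jitter=0.0)]
        psms = search(spectra, db, cfg)
        best = {}
        for m in psms:
            if not m.is_decoy:
                cur = best.get(m.spectrum_id)
                if cur is None or m.xcorr > cur.xcorr:
                    best[m.spectrum_id] = m
        correct = sum(best[s.id].peptide.sequence == pep
                      for s, pep in zip(spectra, peps) if s.id in best)
        assert correct / len(peps) >= 0.95

    def test_precursor_tolerance_gate(self, toy_db):
        cfg, proteins = toy_db
        db = SearchDatabase.build(proteins, cfg)
        pep = next(p.sequence for _, seq in proteins for p in digest(seq, cfg))
        [s] = simulate_spectra([pep], cfg, seed=6, noise_peaks=0, mass_jitter=0.0)
        off = Spectrum(s.id, s.precursor_mz * (1 + 50e-6), s.charge,
                       np.array([p[0] for p in s.peaks]),
                       np.array([p[1] for p in s.peaks]))
        psms = search([off], db, cfg)
        assert all(m.peptide.sequence != pep or abs(m.precursor_error_ppm) <= 10
                   for m in psms)

    def test_target_and_decoy_counts_balanced(self, toy_db):
        cfg, proteins = toy_db
        db = SearchDatabase.build(proteins, cfg)
        inv = _inverse(db.order)
        n_target = len({c.sequence for i, c in enumerate(db.candidates)
                        if not db.is_decoy[inv[i]]})
        n_decoy = len({c.sequence for i, c in enumerate(db.candidates)
                       if db.is_decoy[inv[i]]})
        # reversal preserves composition; only palindromic collisions differ
        assert abs(n_target - n_decoy) <= 0.02 * n_target


def _inverse(order):
    inv = np.empty_like(order)
    inv[order] = np.arange(len(order))
    return inv


class TestFdrFilter:
    def psm(self, score, decoy):
        return PeptideSpectrumMatch("s", Peptide("PEPTIDEK"), 2, score, 0.0, decoy)

    def test_no_decoys_all_retained_q_zero(self, cfg):
        psms = [self.psm(x, False) for x in (5, 4, 3)]
        out = fdr_filter(psms, cfg)
        assert len(out) == 3 and all(m.q_value == 0 for m in out)

    def test_all_decoys_on_top_nothing_retained(self, cfg):
        psms = [self.psm(9, True), self.psm(8, True), self.psm(1, False)]
        out = fdr_filter(psms, cfg)
        assert out == []
        assert all(m.q_value >= 1 for m in psms if not m.is_decoy)

    def test_hand_computed_ten_psm_tally(self, cfg):
        # scores descending; D marks decoys:  T T T D T T D T T D
        flags = [False, False, False, True, False, False, True, False, False, True]
        scores = list(range(10, 0, -1))
        psms = [self.psm(s, d) for s, d in zip(scores, flags)]
        fdr_filter(psms, cfg)
        by_score = {m.xcorr: m.q_value for m in psms}
        # running decoys/targets: 0/1,0/2,0/3,1/3,1/4,1/5,2/5,2/6,2/7,3/7
        expected = [0, 0, 0, 1 / 3, 1 / 4, 1 / 5, 2 / 5, 2 / 6, 2 / 7, 3 / 7]
        # q = running min from the bottom
        q = expected[:]
        for i in range(len(q) - 2, -1, -1):
            q[i] = min(q[i], q[i + 1])
        for s, expect in zip(scores, q):
            assert by_score[s] == pytest.approx(expect)

    def test_q_monotone_in_rank(self, cfg):
        rng = np.random.default_rng(3)
        psms = [self.psm(float(rng.uniform(0, 10)), bool(rng.random() < 0.4))
                for _ in range(200)]
        fdr_filter(psms, cfg)
        ranked = sorted(psms, key=lambda m: -m.xcorr)
        qs = [m.q_value for m in ranked]
        assert all(b >= a - 1e-12 for a, b in zip(qs, qs[1:]))

    def test_zero_targets_empty(self, cfg):
        assert fdr_filter([self.psm(5, True)], cfg) == []
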