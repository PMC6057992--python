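"""Generator checks: determinism, planted-structure validity, spectrum physics."""

import hashlib

import numpy as np
import pytest
from Bio.Seq import Seq
from pyteomics import mass as pmass
from scipy import stats

from lenspg.config import PipelineConfig
from lenspg.orfdb import extract_transcript_sequence, translate
from lenspg.search import PROTON, Peptide, generate_fragments
from lenspg.synth import (StudySizes, generate_annotation, generate_genome,
                          plant_as_events, plant_transcripts,
                          simulate_count_events, simulate_spectra,
                          synthesize_study, write_study)


def test_generate_genome_deterministic_and_shaped():
    g1 = generate_genome(1, 50_000, seed=7)
    g2 = generate_genome(1, 50_000, seed=7)
    assert g1 == g2
    g = generate_genome(2, 20_000, seed=1)
    assert sorted(g) == ["chr1", "chr2"]
    assert all(len(s) == 20_000 for s in g.values())
    assert all(set(s) <= set("ACGT") for s in g.values())
    with pytest.raises(ValueError):
        generate_genome(1, 0, seed=0)


def test_genome_base_composition_uniform_within_binomial_bounds():
    seq = generate_genome(1, 50_000, seed=3)["chr1"]
    n = len(seq)
    # two-sided binomial(n, 1/4) interval at alpha=1e-6 per base
    lo = stats.binom.ppf(5e-7, n, 0.25)
    hi = stats.binom.ppf(1 - 5e-7, n, 0.25)
    for base in "ACGT":
        assert lo <= seq.count(base) <= hi


def test_annotation_round_trip_reproduces_proteome():
    """Spliced re-extraction + frame-0 translation equals the emitted proteome."""
    genome = generate_genome(1, 120_000, seed=2)
    genome, genes = generate_annotation(genome, 8, seed=4)
    for g in genes:
        tx_seq = extract_transcript_sequence(g.transcript, genome)
        assert translate(tx_seq)[:-1] == g.protein
        # independent oracle for the translation step
        assert str(Seq(tx_seq).translate())[:-1] == g.protein
        s, e = g.transcript.span
        assert 0 <= s < e <= len(genome[g.transcript.chrom])


def test_annotation_introns_have_gt_ag_boundaries():
    genome = generate_genome(1, 120_000, seed=9)
    genome, genes = generate_annotation(genome, 8, seed=5)
    for g in genes:
        t = g.transcript
        chrom = genome[t.chrom]
        for (s1, e1), (s2, e2) in zip(t.exons, t.exons[1:]):
            intron = chrom[e1:s2]
            if t.strand == "+":
                assert intron[:2] == "GT" and intron[-2:] == "AG"
            else:
                # '-' strand introns read GT..AG on the sense strand,
                # i.e. CT..AC on the genomic plus strand
                assert intron[:2] == "CT" and intron[-2:] == "AC"


def test_annotation_space_error():
    genome = generate_genome(1, 10_000, seed=0)
    with pytest.raises(ValueError, match="too small"):
        generate_annotation(genome, 50, seed=0)


@pytest.fixture(scope="module")
def planted():
    cfg = PipelineConfig()
    genome = generate_genome(4, 250_000, seed=21)
    genome, genes = generate_annotation(genome, 20, seed=22)
    assembled, truth = plant_transcripts(genome, genes, 80, 60, cfg, seed=23)
    return genome, genes, assembled, truth


class TestPlantTranscripts:

    def test_labels_partition_transcripts(self, planted):
        _, _, assembled, truth = planted
        assert set(truth.transcript_labels) == {t.id for t in assembled}
        assert set(truth.transcript_labels.values()) <= {
            "annotated", "novel", "semi-novel"}

    def test_novel_zero_overlap_semi_partial(self, planted):
        from lenspg.catalog import AnnotationIndex
        _, genes, assembled, truth = planted
        index = AnnotationIndex([g.transcript for g in genes])
        for t in assembled:
            label = truth.transcript_labels[t.id]
            ov = index.overlap_bases(t)
            if label == "novel":
                assert ov == 0
            elif label == "semi-novel":
                assert 0 < ov < t.exonic_len

    def test_multi_exon_proportions(self, planted):
        _, _, assembled, truth = planted
        novel = [t for t in assembled if truth.transcript_labels[t.id] == "novel"]
        semi = [t for t in assembled if truth.transcript_labels[t.id] == "semi-novel"]
        frac_novel = np.mean([len(t.exons) > 1 for t in novel])
        frac_semi = np.mean([len(t.exons) > 1 for t in semi])
        # ~25% of novel and >85% of semi-novel are multi-exonic
        assert 0.10 <= frac_novel <= 0.45
        assert frac_semi > 0.75

    def test_tpm_gate_exercised(self, planted):
        _, _, assembled, _ = planted
        values = [v for t in assembled for v in t.tpm.values()]
        assert any(v < 1.0 for v in values) and any(v >= 1.0 for v in values)


def test_no_novel_requested_means_no_novel_labels():
    cfg = PipelineConfig()
    genome = generate_genome(1, 100_000, seed=1)
    genome, genes = generate_annotation(genome, 5, seed=1)
    _, truth = plant_transcripts(genome, genes, 0, 2, cfg, seed=1)
    assert not truth.labels_of("novel")


def test_plant_as_events_covers_all_types():
    cfg = PipelineConfig()
    genome = generate_genome(2, 200_000, seed=31)
    genome, genes = generate_annotation(genome, 24, seed=32, min_exons=4)
    isoforms, events, planted = plant_as_events(
        genes, {t: 2 for t in ("ES", "A5SS", "A3SS", "MXE", "IR")}, 200,
        cfg, seed=33)
    assert sorted({e.event_type for e in events}) == ["A3SS", "A5SS", "ES", "IR", "MXE"]
    assert len(events) == 10 and len(isoforms) == 20
    for ev, pl in zip(events, planted):
        assert ev.event_type == pl.event_type and ev.coords == pl.coords
        for st in cfg.stages:
            i, s = ev.counts[st]
            assert i + s == 200


def test_degenerate_binomial_psi_one_gives_zero_skipping(cfg):
    events = simulate_count_events(20, 100, cfg, seed=1, psi_a=1.0)
    assert all(ev.counts["E15"][1] == 0 for ev in events)


def test_empirical_psi_matches_planted_mean(cfg):
    from lenspg.events import compute_psi
    events = simulate_count_events(1000, 100, cfg, seed=8, psi_a=0.37)
    mean_psi = np.mean([compute_psi(ev, "E15") for ev in events])
    assert abs(mean_psi - 0.37) < 0.01


class TestSimulateSpectra:
    def test_zero_jitter_zero_noise_exact_ions(self, cfg):
        pep = "SMGEDTVPKR"
        [s] = simulate_spectra([pep], cfg, seed=3, noise_peaks=0, mass_jitter=0.0)
        theo = sorted(m for _, m in generate_fragments(Peptide(pep), cfg, s.charge))
        obs = sorted(m for m, _ in s.peaks)
        assert np.allclose(obs, theo, atol=1e-9)
        # at charge 2 exactly the 2(n-1) singly charged b/y ions
        if s.charge == 2:
            assert len(obs) == 2 * (len(pep) - 1)
        else:
            assert len(obs) <= 4 * (len(pep) - 1)

    def test_fragment_mz_agree_with_independent_mass_calculator(self):
        cfg = PipelineConfig(tmt_labeling=False, fixed_mods=())
        pep = "WLIEISK"
        ions = dict(generate_fragments(Peptide(pep), cfg, charge=2))
        for i in range(1, len(pep)):
            b = pmass.calculate_mass(sequence=pep[:i], ion_type="b", charge=1)
            y = pmass.calculate_mass(sequence=pep[i:], ion_type="y", charge=1)
            assert ions[f"b{i}"] == pytest.approx(b, abs=1e-4)
            assert ions[f"y{len(pep) - i}"] == pytest.approx(y, abs=1e-4)

    def test_precursor_consistent_within_tolerance(self, cfg):
        specs = simulate_spectra(["AVGVDCSAPEPR", "LNNVNILKGR"], cfg, seed=5)
        from lenspg.search import peptide_mass
        for s in specs:
            m = peptide_mass(Peptide(s.truth), cfg)
            ppm = abs((s.precursor_mz * s.charge - s.charge * PROTON - m) / m) * 1e6
            assert ppm <= cfg.precursor_tol_ppm

    def test_empty_peptide_list_warns_and_returns_empty(self, cfg, caplog):
        import logging
        with caplog.at_level(logging.WARNING, logger="lenspg.synth"):
            assert simulate_spectra([], cfg, seed=1) == []
        assert "empty" in caplog.text


def test_full_study_outputs_byte_deterministic(tmp_path):
    cfg = PipelineConfig()
    sizes = StudySizes(n_chromosomes=1, chrom_length=120_000, n_genes=10,
                       n_novel=4, n_semi=3,
                       as_counts={"ES": 1, "IR": 1}, n_planted_peptides=4,
                       n_known_spectra=10, n_noise_spectra=3)
    digests = []
    for sub in ("a", "b"):
        study = synthesize_study(cfg, seed=41, sizes=sizes)
        paths = write_study(study, tmp_path / sub, cfg)
        digests.append({k: hashlib.sha256(p.read_bytes()).hexdigest()
                        for k, p in paths.items()})
    assert digests[0] == digests[1]


def test_ground_truth_peptides_are_substrings_of_three_frame_translation(small_study):
    from lenspg.orfdb import translate_three_frames
    tx_by_id = {t.id: t for t in small_study.assembled}
    for p in small_study.truth.planted_novel_peptides:
        tx = tx_by_id[p.source_transcript]
        seq = extract_transcript_sequence(tx, small_study.genome)
        frames = translate_three_frames(seq)
        assert p.peptide in frames[p.frame]


def test_ground_truth_novelty_precheck_matches_filter(small_study, cfg):
    from lenspg.novelty import min_mismatch_to_proteome
    for p in small_study.truth.planted_novel_peptides:
        mm, _, _ = min_mismatch_to_proteome(p.peptide, small_study.proteome)
        assert mm >= cfg.novelty_min_mismatch
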