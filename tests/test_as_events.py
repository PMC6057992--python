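"""AS event taxonomy, PSI arithmetic, the Fisher/BH screen and the tallies."""

import numpy as np
import pytest

from lenspg.catalog import AnnotationIndex, TranscriptModel
from lenspg.config import PipelineConfig
from lenspg.events import (ASEvent, benjamini_hochberg, compare_stages,
                           compute_psi, enumerate_events, expressed_stages,
                           tally_events)
from lenspg.synth import simulate_count_events


def tx(id, exons, strand="+", gene="g"):
    return TranscriptModel(id, "chr1", strand, tuple(exons), {}, gene)


FULL = [(100, 200), (300, 400), (500, 600), (700, 800)]


class TestEnumeration:
    def enumerate(self, *isoforms):
        return enumerate_events({"g": list(isoforms)})

    def test_exon_skipping(self):
        a = tx("a", FULL)
        b = tx("b", [FULL[0], FULL[2], FULL[3]])
        events = self.enumerate(a, b)
        assert [e.event_type for e in events] == ["ES"]
        assert events[0].coords == (200, 300, 400, 500)

    def test_alt_donor_is_a5ss_on_plus_a3ss_on_minus(self):
        for strand, expect in (("+", "A5SS"), ("-", "A3SS")):
            a = tx("a", [(100, 200), (300, 400)], strand=strand)
            b = tx("b", [(100, 240), (300, 400)], strand=strand)
            events = self.enumerate(a, b)
            assert [e.event_type for e in events] == [expect]
            assert events[0].coords == (200, 240, 300, 300)

    def test_alt_acceptor_is_a3ss_on_plus(self):
        a = tx("a", [(100, 200), (300, 400)])
        b = tx("b", [(100, 200), (280, 400)])
        events = self.enumerate(a, b)
        assert [e.event_type for e in events] == ["A3SS"]

    def test_intron_retention(self):
        a = tx("a", [(100, 200), (300, 400)])
        b = tx("b", [(100, 400)])
        events = self.enumerate(a, b)
        assert [e.event_type for e in events] == ["IR"]
        assert events[0].coords == (200, 300)

    def test_mutually_exclusive_exons(self):
        a = tx("a", [FULL[0], FULL[1], FULL[3]])
        b = tx("b", [FULL[0], FULL[2], FULL[3]])
        events = self.enumerate(a, b)
        assert [e.event_type for e in events] == ["MXE"]
        assert events[0].coords == (200, 300, 400, 500, 600, 700)

    def test_mxe_suppressed_when_exons_cooccur(self):
        a = tx("a", [FULL[0], FULL[1], FULL[3]])
        b = tx("b", [FULL[0], FULL[2], FULL[3]])
        both = tx("c", FULL)  # an isoform carrying both middle exons
        events = self.enumerate(a, b, both)
        assert "MXE" not in {e.event_type for e in events}

    def test_single_isoform_gene_contributes_nothing(self):
        assert enumerate_events({"g": [tx("a", FULL)]}) == []

    def test_events_deduplicated_across_pairs(self):
        a = tx("a", FULL)
        b = tx("b", [FULL[0], FULL[2], FULL[3]])
        b2 = tx("b2", [FULL[0], FULL[2], FULL[3], (900, 950)])
        events = self.enumerate(a, b, b2)
        assert sum(e.event_type == "ES" for e in events) == 1

    def test_novel_flag_from_annotation_junctions(self):
        a = tx("a", FULL)
        b = tx("b", [FULL[0], FULL[2], FULL[3]])
        index = AnnotationIndex([a])  # knows only the inclusion chain
        [ev] = enumerate_events({"g": [a, b]}, index)
        assert ev.novel_flag  # the skipping junction is unannotated
        index_all = AnnotationIndex([a, b])
        [ev2] = enumerate_events({"g": [a, b]}, index_all)
        assert not ev2.novel_flag

    def test_matches_definition_based_rescan_of_es(self):
        """Independent re-derivation of ES events on random isoform sets."""
        rng = np.random.default_rng(4)
        for trial in range(20):
            n = int(rng.integers(3, 7))
            bounds = np.sort(rng.choice(np.arange(100, 2000), 2 * n, replace=False))
            exons = [(int(bounds[2 * i]), int(bounds[2 * i + 1])) for i in range(n)]
            isoforms = [tx("full", exons)]
            for k in range(int(rng.integers(1, 4))):
                drop = int(rng.integers(1, n - 1))
                isoforms.append(tx(f"v{k}", exons[:drop] + exons[drop + 1:]))
            got = {e.coords for e in enumerate_events({"g": isoforms})
                   if e.event_type == "ES"}
            expected = set()
            for a in isoforms:
                for b in isoforms:
                    for i in range(1, len(a.exons) - 1):
                        up = a.exons[i - 1][1]
                        down = a.exons[i + 1][0]
                        if (up, down) in b.intron_chain():
                            expected.add((up, a.exons[i][0], a.exons[i][1], down))
            assert got == expected


class TestPsi:
    def make(self, counts, li=2, ls=1):
        return ASEvent("ES", "g", "chr1", "+", (0, 10, 20, 30), li, ls,
                       counts={"E15": counts})

    def test_boundary_values(self):
        assert compute_psi(self.make((0, 10)), "E15") == 0.0
        assert compute_psi(self.make((10, 0)), "E15") == 1.0

    def test_length_normalized_formula(self):
        assert compute_psi(self.make((30, 10)), "E15") == pytest.approx(0.6)

    def test_monotone_in_inclusion_reads(self):
        values = [compute_psi(self.make((i, 10)), "E15") for i in range(0, 50, 5)]
        assert all(b > a for a, b in zip(values, values[1:]))
        assert all(0 <= v <= 1 for v in values)

    def test_undefined_when_both_zero(self):
        with pytest.raises(ValueError):
            compute_psi(self.make((0, 0)), "E15")


class TestScreen:
    def test_identical_counts_null(self, cfg):
        ev = ASEvent("ES", "g", "chr1", "+", (0, 10, 20, 30), 2, 1,
                     counts={"E15": (40, 20), "E18": (40, 20)})
        comp = compare_stages([ev], "E15", "E18", cfg)
        assert comp.table["p_value"].iloc[0] == pytest.approx(1.0)
        assert not comp.table["significant"].iloc[0]

    def test_swap_negates_delta_and_keeps_p(self, cfg):
        events = simulate_count_events(50, 150, cfg, seed=2, psi_a=0.3, psi_b=0.7)
        fwd = compare_stages(events, "E15", "E18", cfg)
        rev = compare_stages(events, "E18", "E15", cfg)
        assert np.allclose(fwd.table["delta_psi"], -rev.table["delta_psi"])
        assert np.allclose(fwd.table["p_value"], rev.table["p_value"])

    def test_bh_matches_hand_formula(self):
        p = [0.001, 0.01, 0.02, 0.5]
        # step-up: q_i = min_{j>=i} p_(j) * n / j
        assert benjamini_hochberg(p) == pytest.approx(
            [0.004, 0.02, 0.02 * 4 / 3, 0.5])

    def test_power_large_shift_depth_200(self, cfg):
        hits = 0
        reps = 200
        for r in range(reps):
            ev = simulate_count_events(1, 200, cfg, seed=1000 + r,
                                       psi_a=0.9, psi_b=0.1)
            comp = compare_stages(ev, "E15", "E18", cfg)
            hits += bool(comp.table["significant"].iloc[0])
        assert hits / reps >= 0.99

    def test_null_fdr_controlled(self, cfg):
        events = simulate_count_events(1000, 100, cfg, seed=7)
        comp = compare_stages(events, "E15", "E18", cfg)
        assert comp.table["significant"].mean() <= 0.02

    def test_q_values_in_unit_interval_and_monotone(self, cfg):
        events = simulate_count_events(200, 120, cfg, seed=12, psi_a=0.4, psi_b=0.6)
        comp = compare_stages(events, "E15", "E18", cfg)
        q = comp.table.sort_values("p_value")["q_value"].to_numpy()
        assert ((0 <= q) & (q <= 1)).all()
        assert (np.diff(q) >= -1e-12).all()


class TestTallies:
    def test_single_timepoint_attribution(self, cfg):
        counts = {st: (0, 0) for st in cfg.stages}
        counts["E15"] = (10, 10)
        ev = ASEvent("ES", "g", "chr1", "+", (0, 10, 20, 30), 2, 1, counts=counts)
        assert expressed_stages(ev, cfg) == ["E15"]
        tall = tally_events([ev], [], cfg)
        assert tall["single_timepoint"]["ES"] == 1
        assert tall["multi_timepoint"]["ES"] == 0

    def test_type_totals_partition_grand_total(self, small_study, cfg):
        tall = tally_events(small_study.as_events, [], cfg)
        assert sum(tall["per_type"].values()) == tall["grand_total"]

    def test_per_type_totals_equal_planted(self, small_study, cfg):
        tall = tally_events(small_study.as_events, [], cfg)
        planted = {}
        for ev in small_study.truth.planted_as_events:
            planted[ev.event_type] = planted.get(ev.event_type, 0) + 1
        for etype, n in planted.items():
            assert tall["per_type"][etype] == n
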