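"""Alternative-splicing events: taxonomy, PSI, and the pairwise FDR screen.

Events between isoforms of one gene are typed as exon skipping (ES),
alternative 5'/3' splice site (A5SS/A3SS), mutually exclusive exons (MXE), or
intron retention (IR). PSI is the length-normalized inclusion fraction

    PSI = (I / L_inc) / (I / L_inc + S / L_skip)

where I and S are inclusion- and skipping-form junction read counts and the
L's are effective junction counts of the two forms (2 vs 1 for ES and IR,
2 vs 2 for MXE, 1 vs 1 for the splice-site events). Differential splicing
between two stages is screened with Fisher's exact test on the
length-normalized counts, Benjamini-Hochberg adjusted across events, at the
study's FDR <= 0.01 threshold.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .catalog import AnnotationIndex, TranscriptModel
from .config import PipelineConfig

log = logging.getLogger(__name__)

EVENT_TYPES = ("ES", "A5SS", "A3SS", "MXE", "IR")

#: Effective junction-form lengths (inclusion, skipping) per event type.
FORM_LENGTHS = {"ES": (2, 1), "IR": (2, 1), "MXE": (2, 2), "A5SS": (1, 1), "A3SS": (1, 1)}


@dataclass
class ASEvent:
    event_type: str
    gene: str
    chrom: str
    strand: str
    coords: tuple[int, ...]  # type-specific defining coordinates, half-open 0-based
    inclusion_len: int
    skipping_len: int
    counts: dict[str, tuple[int, int]] = field(default_factory=dict)
    novel_flag: bool = False

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.event_type!r}")
        if self.inclusion_len <= 0 or self.skipping_len <= 0:
            raise ValueError("form lengths must be positive")
        for stage, (i, s) in self.counts.items():
            if i < 0 or s < 0:
                raise ValueError(f"negative counts at stage {stage}")

    @property
    def key(self) -> tuple:
        return (self.event_type, self.chrom, self.strand, self.coords)


# ---------------------------------------------------------------------------
# Event enumeration from isoform structure
# ---------------------------------------------------------------------------

def enumerate_events(transcripts_by_gene: dict[str, list[TranscriptModel]],
                     annotation: AnnotationIndex | None = None) -> list[ASEvent]:
    """Enumerate all typed events between isoform pairs of each gene.

    Every maximal event of each type between any isoform pair is reported
    once, deduplicated by its defining coordinates. ``novel_flag`` is set when
    at least one defining junction is absent from the reference annotation.
    """
    seen: dict[tuple, ASEvent] = {}
    for gene, isoforms in transcripts_by_gene.items():
        if len(isoforms) < 2:
            continue
        for a, b in itertools.combinations(isoforms, 2):
            if a.chrom != b.chrom or a.strand != b.strand:
                continue
            for ev in _pair_events(gene, a, b, isoforms):
                seen.setdefault(ev.key, ev)
    events = list(seen.values())
    if annotation is not None:
        for ev in events:
            ev.novel_flag = any(
                not annotation.has_junction(ev.chrom, ev.strand, d, a)
                for d, a in _defining_junctions(ev)
            )
    return sorted(events, key=lambda e: (e.chrom, e.coords, e.event_type))


def _pair_events(gene, a, b, all_isoforms):
    yield from _es_events(gene, a, b)
    yield from _es_events(gene, b, a)
    yield from _altss_events(gene, a, b)
    yield from _mxe_events(gene, a, b, all_isoforms)
    yield from _ir_events(gene, a, b)
    yield from _ir_events(gene, b, a)


def _es_events(gene, inc, skp):
    """Exon skipping: internal exon of `inc` spliced around by `skp`."""
    inc_j = set(inc.intron_chain())
    skp_j = set(skp.intron_chain())
    for i in range(1, len(inc.exons) - 1):
        es, ee = inc.exons[i]
        up_end = inc.exons[i - 1][1]
        down_start = inc.exons[i + 1][0]
        if (up_end, es) in inc_j and (ee, down_start) in inc_j and (up_end, down_start) in skp_j:
            yield ASEvent(
                "ES", gene, inc.chrom, inc.strand,
                coords=(up_end, es, ee, down_start),
                inclusion_len=FORM_LENGTHS["ES"][0], skipping_len=FORM_LENGTHS["ES"][1],
            )


def _altss_events(gene, a, b):
    """Alternative donor/acceptor: two junctions sharing one boundary.

    On '+', a varying donor (left) side is an alternative 5' splice site and a
    varying acceptor (right) side an alternative 3' one; on '-', the roles
    swap.
    """
    ja, jb = set(a.intron_chain()), set(b.intron_chain())
    for (d1, acc) in ja - jb:
        for (d2, acc2) in jb - ja:
            if acc == acc2 and d1 != d2:
                # the two donor-side exons must be alternative boundaries of
                # the same exon (i.e. overlap), not different exons as in ES
                ea, eb = _exon_ending(a, d1), _exon_ending(b, d2)
                if ea and eb and _overlaps(ea, eb):
                    etype = "A5SS" if a.strand != "-" else "A3SS"
                    lo, hi = sorted((d1, d2))
                    # donor-varying: (d_lo, d_hi, acc, acc)
                    yield ASEvent(etype, gene, a.chrom, a.strand,
                                  coords=(lo, hi, acc, acc),
                                  inclusion_len=FORM_LENGTHS[etype][0],
                                  skipping_len=FORM_LENGTHS[etype][1])
            if d1 == d2 and acc != acc2:
                ea, eb = _exon_starting(a, acc), _exon_starting(b, acc2)
                if ea and eb and _overlaps(ea, eb):
                    etype = "A3SS" if a.strand != "-" else "A5SS"
                    lo, hi = sorted((acc, acc2))
                    # acceptor-varying: (d, d, a_lo, a_hi)
                    yield ASEvent(etype, gene, a.chrom, a.strand,
                                  coords=(d1, d1, lo, hi),
                                  inclusion_len=FORM_LENGTHS[etype][0],
                                  skipping_len=FORM_LENGTHS[etype][1])


def _exon_ending(t, end):
    return next(((s, e) for s, e in t.exons if e == end), None)


def _exon_starting(t, start):
    return next(((s, e) for s, e in t.exons if s == start), None)


def _mxe_events(gene, a, b, all_isoforms):
    """Mutually exclusive exons with shared flanking junction anchors."""
    ja, jb = set(a.intron_chain()), set(b.intron_chain())
    for i in range(1, len(a.exons) - 1):
        ea = a.exons[i]
        for j in range(1, len(b.exons) - 1):
            eb = b.exons[j]
            if ea == eb or _overlaps(ea, eb):
                continue
            up_end = a.exons[i - 1][1]
            down_start = a.exons[i + 1][0]
            if b.exons[j - 1][1] != up_end or b.exons[j + 1][0] != down_start:
                continue
            if not ({(up_end, ea[0]), (ea[1], down_start)} <= ja):
                continue
            if not ({(up_end, eb[0]), (eb[1], down_start)} <= jb):
                continue
            # never co-occurring in any observed isoform of the gene
            if any(ea in t.exons and eb in t.exons for t in all_isoforms):
                continue
            first, second = sorted((ea, eb))
            yield ASEvent("MXE", gene, a.chrom, a.strand,
                          coords=(up_end, *first, *second, down_start),
                          inclusion_len=FORM_LENGTHS["MXE"][0],
                          skipping_len=FORM_LENGTHS["MXE"][1])


def _ir_events(gene, spliced, retained):
    """Intron retention: an intron of `spliced` lies inside an exon of `retained`."""
    for d, a in spliced.intron_chain():
        for s, e in retained.exons:
            if s <= d and a <= e:
                yield ASEvent("IR", gene, spliced.chrom, spliced.strand,
                              coords=(d, a),
                              inclusion_len=FORM_LENGTHS["IR"][0],
                              skipping_len=FORM_LENGTHS["IR"][1])


def _overlaps(x, y):
    return x[0] < y[1] and y[0] < x[1]


def _defining_junctions(ev: ASEvent):
    """The splice junctions whose presence defines the event."""
    c = ev.coords
    if ev.event_type == "ES":
        return [(c[0], c[1]), (c[2], c[3]), (c[0], c[3])]
    if ev.event_type == "MXE":
        return [(c[0], c[1]), (c[2], c[5]), (c[0], c[3]), (c[4], c[5])]
    if ev.event_type == "IR":
        return [(c[0], c[1])]
    if ev.event_type in ("A5SS", "A3SS"):
        if c[2] == c[3]:  # donor-varying: (d_lo, d_hi, acc, acc)
            return [(c[0], c[2]), (c[1], c[2])]
        return [(c[0], c[2]), (c[0], c[3])]  # acceptor-varying: (d, d, a_lo, a_hi)
    raise AssertionError(ev.event_type)


# ---------------------------------------------------------------------------
# PSI and the pairwise screen
# ---------------------------------------------------------------------------

def compute_psi(event: ASEvent, stage: str) -> float:
    """Length-normalized percent-spliced-in at one stage (in [0, 1])."""
    i, s = event.counts[stage]
    if i + s == 0:
        raise ValueError(f"event {event.key}: no counts at stage {stage}")
    inc = i / event.inclusion_len
    skp = s / event.skipping_len
    return inc / (inc + skp)


@dataclass
class ASComparison:
    stage_a: str
    stage_b: str
    table: pd.DataFrame  # per-event: delta_psi, p_value, q_value, significant


def compare_stages(events: list[ASEvent], stage_a: str, stage_b: str,
                   cfg: PipelineConfig) -> ASComparison:
    """Screen every event for differential splicing between two stages.

    Fisher's exact test (two-sided) of the homogeneity of the two
    length-normalized inclusion proportions, BH-adjusted across events within
    the comparison; significant iff q <= ``as_fdr_max``.
    """
    records = []
    for ev in events:
        ca = ev.counts.get(stage_a)
        cb = ev.counts.get(stage_b)
        if not ca or not cb or sum(ca) == 0 or sum(cb) == 0:
            log.debug("event %s skipped in %s vs %s: missing counts",
                      ev.key, stage_a, stage_b)
            continue
        na = [round(ca[0] / ev.inclusion_len), round(ca[1] / ev.skipping_len)]
        nb = [round(cb[0] / ev.inclusion_len), round(cb[1] / ev.skipping_len)]
        _, p = stats.fisher_exact([na, nb], alternative="two-sided")
        records.append({
            "event_type": ev.event_type,
            "gene": ev.gene,
            "chrom": ev.chrom,
            "coords": ":".join(map(str, ev.coords)),
            "psi_a": compute_psi(ev, stage_a),
            "psi_b": compute_psi(ev, stage_b),
            "p_value": min(1.0, p),
        })
    table = pd.DataFrame(records)
    if not table.empty:
        table["delta_psi"] = table["psi_b"] - table["psi_a"]
        _, q, _, _ = multipletests(table["p_value"], method="fdr_bh")
        table["q_value"] = q
        table["significant"] = table["q_value"] <= cfg.as_fdr_max
    else:
        table = pd.DataFrame(columns=["event_type", "gene", "chrom", "coords",
                                      "psi_a", "psi_b", "p_value", "delta_psi",
                                      "q_value", "significant"])
    return ASComparison(stage_a, stage_b, table)


def benjamini_hochberg(pvalues):
    """BH adjusted q-values (step-up), exposed for direct use and checking."""
    _, q, _, _ = multipletests(pvalues, method="fdr_bh")
    return list(q)


# ---------------------------------------------------------------------------
# Tallies (per-type totals; one vs >=2 time points)
# ---------------------------------------------------------------------------

def expressed_stages(event: ASEvent, cfg: PipelineConfig) -> list[str]:
    """Stages where both junction forms of the event are observed."""
    return [st for st in cfg.stages
            if event.counts.get(st) and event.counts[st][0] > 0 and event.counts[st][1] > 0]


def tally_events(events: list[ASEvent], comparisons: list[ASComparison],
                 cfg: PipelineConfig) -> dict:
    """Per-type totals and the one- vs >=2-time-point decomposition.

    Primary attribution of an event to a time point is expression-based (both
    junction forms observed there); a significance-based decomposition
    (number of stage pairs at which the event is significant) is also
    emitted, since either reading of "time points" is defensible.
    """
    per_type = {t: 0 for t in EVENT_TYPES}
    single = {t: 0 for t in EVENT_TYPES}
    multi = {t: 0 for t in EVENT_TYPES}
    for ev in events:
        per_type[ev.event_type] += 1
        n = len(expressed_stages(ev, cfg))
        if n == 1:
            single[ev.event_type] += 1
        elif n >= 2:
            multi[ev.event_type] += 1

    sig_pairs: dict[tuple, int] = {}
    sig_per_comparison = []
    for comp in comparisons:
        tab = comp.table
        n_sig = {t: 0 for t in EVENT_TYPES}
        n_tot = {t: 0 for t in EVENT_TYPES}
        for _, row in tab.iterrows():
            key = (row["event_type"], row["chrom"], row["coords"])
            n_tot[row["event_type"]] += 1
            if row["significant"]:
                n_sig[row["event_type"]] += 1
                sig_pairs[key] = sig_pairs.get(key, 0) + 1
        sig_per_comparison.append({
            "comparison": f"{comp.stage_a} vs. {comp.stage_b}",
            **{f"total_{t}": n_tot[t] for t in EVENT_TYPES},
            **{f"significant_{t}": n_sig[t] for t in EVENT_TYPES},
        })

    sig_single = sum(1 for v in sig_pairs.values() if v == 1)
    sig_multi = sum(1 for v in sig_pairs.values() if v >= 2)
    return {
        "per_type": per_type,
        "grand_total": sum(per_type.values()),
        "single_timepoint": single,
        "multi_timepoint": multi,
        "per_comparison": pd.DataFrame(sig_per_comparison),
        "significance_based": {"single_pair": sig_single, "multi_pair": sig_multi},
    }


def events_frame(events: list[ASEvent], cfg: PipelineConfig) -> pd.DataFrame:
    records = []
    for ev in events:
        rec = {
            "event_type": ev.event_type,
            "gene": ev.gene,
            "chrom": ev.chrom,
            "strand": ev.strand,
            "coords": ":".join(map(str, ev.coords)),
            "novel": ev.novel_flag,
        }
        for st in cfg.stages:
            i, s = ev.counts.get(st, (0, 0))
            rec[f"inc_{st}"] = i
            rec[f"skip_{st}"] = s
            rec[f"psi_{st}"] = (
                compute_psi(ev, st) if (i + s) > 0 else math.nan
            )
        records.append(rec)
    return pd.DataFrame(records)
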