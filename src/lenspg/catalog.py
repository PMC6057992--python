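"""Transcript catalog: GTF I/O and novelty classification against a reference.

An assembled transcript is *annotated* when it matches a reference transcript
(exact intron-chain match for multi-exon transcripts; >=95% containment within
a single annotated exon for mono-exonic ones), *novel* when none of its exonic
bases overlap any annotated exon, and *semi-novel* otherwise (it touches both
annotated and unannotated sequence). Per-stage expressed counts use the
study's >=1.0 TPM gate, with the "Total" row counting transcripts expressed in
at least one stage (a union, not a column sum).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import pandas as pd
from intervaltree import IntervalTree

from .config import PipelineConfig

log = logging.getLogger(__name__)

CATEGORIES = ("annotated", "novel", "semi-novel")

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"\s*;')


@dataclass
class TranscriptModel:
    """A stranded exon chain with optional per-stage abundances.

    Exons are half-open, 0-based genomic intervals, kept sorted and
    non-overlapping. ``tpm`` maps stage label -> TPM.
    """

    id: str
    chrom: str
    strand: str  # '+', '-' or '.'
    exons: tuple[tuple[int, int], ...]
    tpm: dict[str, float] = field(default_factory=dict)
    gene_id: str = ""
    attributes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        exons = tuple(sorted((int(s), int(e)) for s, e in self.exons))
        for s, e in exons:
            if not e > s:
                raise ValueError(f"transcript {self.id}: empty exon [{s},{e})")
        for (_, e1), (s2, _) in zip(exons, exons[1:]):
            if s2 < e1:
                raise ValueError(f"transcript {self.id}: overlapping exons")
        self.exons = exons
        if self.strand not in "+-.":
            raise ValueError(f"transcript {self.id}: bad strand {self.strand!r}")
        if any(v < 0 for v in self.tpm.values()):
            raise ValueError(f"transcript {self.id}: negative TPM")

    @property
    def exonic_len(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    def intron_chain(self) -> tuple[tuple[int, int], ...]:
        """Ordered (donor-side end, acceptor-side start) genomic junction pairs."""
        return tuple((e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:]))


@dataclass
class ClassifiedTranscript:
    transcript: TranscriptModel
    category: str
    overlap_bases: int
    exonic_len: int


class GtfFormatError(ValueError):
    pass


# ---------------------------------------------------------------------------
# GTF I/O (exon features only; 1-based inclusive on disk, half-open in memory)
# ---------------------------------------------------------------------------

def read_gtf(path) -> list[TranscriptModel]:
    """Parse exon features of a GTF file into transcript models.

    Exon lines are grouped by ``transcript_id``; unsorted exons are sorted.
    Per-stage abundances are read from ``TPM_<stage>`` attributes when present.
    """
    exons_by_tx: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                raise GtfFormatError(f"{path}:{lineno}: expected 9 tab-separated fields")
            chrom, _source, feature, start, end, _score, strand, _frame, attrs = parts
            if feature != "exon":
                continue
            attr = dict(_ATTR_RE.findall(attrs))
            tid = attr.get("transcript_id")
            if not tid:
                raise GtfFormatError(f"{path}:{lineno}: exon feature without transcript_id")
            # GTF is 1-based inclusive; store half-open 0-based.
            exons_by_tx.setdefault(tid, []).append((int(start) - 1, int(end)))
            if tid not in meta:
                order.append(tid)
                meta[tid] = {"chrom": chrom, "strand": strand, "attr": attr}
    if not exons_by_tx:
        log.warning("%s: no exon features found", path)
        return []
    transcripts = []
    for tid in order:
        m = meta[tid]
        attr = m["attr"]
        tpm = {}
        extra = {}
        for key, value in attr.items():
            if key.startswith("TPM_"):
                tpm[key[4:]] = float(value)
            elif key not in ("gene_id", "transcript_id"):
                extra[key] = value
        transcripts.append(
            TranscriptModel(
                id=tid,
                chrom=m["chrom"],
                strand=m["strand"],
                exons=tuple(sorted(exons_by_tx[tid])),
                tpm=tpm,
                gene_id=attr.get("gene_id", ""),
                attributes=extra,
            )
        )
    return transcripts


def write_gtf(transcripts, path, source: str = "lenspg") -> None:
    """Write transcripts as GTF exon features (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        for t in transcripts:
            attrs = [f'gene_id "{t.gene_id or t.id}"', f'transcript_id "{t.id}"']
            for stage in sorted(t.tpm):
                attrs.append(f'TPM_{stage} "{t.tpm[stage]:.6f}"')
            for key, value in t.attributes.items():
                attrs.append(f'{key} "{value}"')
            attr_str = "; ".join(attrs) + ";"
            for s, e in t.exons:
                fh.write(
                    f"{t.chrom}\t{source}\texon\t{s + 1}\t{e}\t.\t{t.strand}\t.\t{attr_str}\n"
                )


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

class AnnotationIndex:
    """Interval index over reference exons plus intron-chain lookup tables."""

    def __init__(self, reference: list[TranscriptModel]):
        self.trees: dict[tuple[str, str], IntervalTree] = {}
        self.chains: set[tuple] = set()
        self.junctions: set[tuple[str, str, int, int]] = set()
        for t in reference:
            tree = self.trees.setdefault((t.chrom, t.strand), IntervalTree())
            for s, e in t.exons:
                tree.addi(s, e)
            if len(t.exons) > 1:
                self.chains.add((t.chrom, t.strand, t.intron_chain()))
                for d, a in t.intron_chain():
                    self.junctions.add((t.chrom, t.strand, d, a))

    def _strands_for(self, strand: str):
        return ("+", "-") if strand == "." else (strand, ".")

    def overlap_bases(self, t: TranscriptModel) -> int:
        """Exonic bases of t covered by any reference exon (merged union)."""
        total = 0
        for s, e in t.exons:
            hits = []
            for strand in self._strands_for(t.strand):
                tree = self.trees.get((t.chrom, strand))
                if tree:
                    hits.extend((max(iv.begin, s), min(iv.end, e)) for iv in tree.overlap(s, e))
            # merge to avoid double counting overlapping reference exons
            for a, b in _merge(hits):
                total += b - a
        return total

    def has_chain(self, t: TranscriptModel) -> bool:
        for strand in self._strands_for(t.strand):
            if (t.chrom, strand, t.intron_chain()) in self.chains:
                return True
        return False

    def has_junction(self, chrom: str, strand: str, donor: int, acceptor: int) -> bool:
        strands = ("+", "-") if strand == "." else (strand, ".")
        return any((chrom, s, donor, acceptor) in self.junctions for s in strands)

    def max_single_exon_containment(self, t: TranscriptModel) -> int:
        """Largest overlap of t's single exon with one reference exon."""
        (s, e), = t.exons
        best = 0
        for strand in self._strands_for(t.strand):
            tree = self.trees.get((t.chrom, strand))
            if tree:
                for iv in tree.overlap(s, e):
                    best = max(best, min(iv.end, e) - max(iv.begin, s))
        return best


def _merge(intervals):
    out = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return out


def classify_transcript(t: TranscriptModel, index: AnnotationIndex,
                        cfg: PipelineConfig | None = None) -> ClassifiedTranscript:
    """Assign the annotated / novel / semi-novel label by exonic overlap."""
    cfg = cfg or PipelineConfig()
    if not any((t.chrom, s) in index.trees for s in ("+", "-", ".")):
        log.info("transcript %s: chromosome %s absent from annotation", t.id, t.chrom)
    overlap = index.overlap_bases(t)
    if overlap == 0:
        category = "novel"
    elif len(t.exons) > 1:
        category = "annotated" if index.has_chain(t) else "semi-novel"
    else:
        contained = index.max_single_exon_containment(t)
        category = (
            "annotated"
            if contained >= cfg.annotated_containment * t.exonic_len
            else "semi-novel"
        )
    return ClassifiedTranscript(t, category, overlap, t.exonic_len)


def classify_all(transcripts, reference, cfg: PipelineConfig | None = None):
    index = AnnotationIndex(reference)
    return [classify_transcript(t, index, cfg) for t in transcripts]


def stage_expression_table(classified: list[ClassifiedTranscript],
                           cfg: PipelineConfig) -> pd.DataFrame:
    """Per-stage expressed counts by category, plus a union "Total" row.

    A transcript counts toward a stage when its TPM there meets the expression
    gate; the Total row counts transcripts expressed in >=1 stage.
    """
    rows = {stage: {c: 0 for c in CATEGORIES} for stage in cfg.stages}
    total = {c: 0 for c in CATEGORIES}
    for ct in classified:
        expressed_any = False
        for stage in cfg.stages:
            if ct.transcript.tpm.get(stage, 0.0) >= cfg.tpm_min:
                rows[stage][ct.category] += 1
                expressed_any = True
        if expressed_any:
            total[ct.category] += 1
    table = pd.DataFrame.from_dict(rows, orient="index", columns=list(CATEGORIES))
    table.loc["Total"] = [total[c] for c in CATEGORIES]
    table.index.name = "stage"
    return table


def classification_frame(classified, cfg: PipelineConfig) -> pd.DataFrame:
    records = []
    for ct in classified:
        rec = {
            "transcript_id": ct.transcript.id,
            "category": ct.category,
            "overlap_bases": ct.overlap_bases,
            "exonic_len": ct.exonic_len,
            "n_exons": len(ct.transcript.exons),
        }
        for stage in cfg.stages:
            rec[f"TPM_{stage}"] = ct.transcript.tpm.get(stage, 0.0)
        records.append(rec)
    return pd.DataFrame(records)
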