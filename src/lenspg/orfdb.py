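"""Theoretical protein database from novel transcripts.

Each novel transcript's spliced sequence is translated in the three sense
frames; every stop-free segment of at least ``min_peptide_len`` residues
becomes a database entry carrying full provenance (source transcript, frame,
transcript-coordinate span, genomic span), so any peptide hit can later be
placed back on the genome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .catalog import TranscriptModel
from .config import PipelineConfig

log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# Standard genetic code; '*' marks stops.
_BASES = "TCAG"
_AA = ("FFLLSSSSYY**CC*W"
       "LLLLPPPPHHQQRRRR"
       "IIIMTTTTNNKKSSRR"
       "VVVVAAAADDEEGGGG")
CODON_TABLE = {
    b1 + b2 + b3: _AA[i * 16 + j * 4 + k]
    for i, b1 in enumerate(_BASES)
    for j, b2 in enumerate(_BASES)
    for k, b3 in enumerate(_BASES)
}


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def extract_transcript_sequence(t: TranscriptModel, genome: dict[str, str]) -> str:
    """Spliced transcript sequence, 5'->3' in transcript orientation."""
    if t.chrom not in genome:
        raise KeyError(f"transcript {t.id}: chromosome {t.chrom} not in genome")
    chrom = genome[t.chrom]
    for s, e in t.exons:
        if s < 0 or e > len(chrom):
            raise ValueError(f"transcript {t.id}: exon [{s},{e}) out of bounds")
    seq = "".join(chrom[s:e] for s, e in t.exons)
    if t.strand == "-":
        seq = reverse_complement(seq)
    return seq.upper()


def translate(seq: str) -> str:
    """Translate in frame 0; trailing 1-2 nt dropped; N-codons become 'X'."""
    out = []
    for i in range(0, len(seq) - 2, 3):
        codon = seq[i:i + 3].upper()
        out.append(CODON_TABLE.get(codon, "X"))
    return "".join(out)


def translate_three_frames(seq: str) -> tuple[str, str, str]:
    """Translations at offsets 0, 1, 2 on the sense strand (stops kept)."""
    return translate(seq), translate(seq[1:]), translate(seq[2:])


@dataclass(frozen=True)
class TheoreticalProtein:
    """One stop-free translation segment of a novel transcript."""

    id: str
    sequence: str
    source_transcript: str
    frame: int
    tx_span: tuple[int, int]  # half-open, transcript coordinates (nt)
    genomic_span: tuple[tuple[int, int], ...]  # half-open genomic intervals
    chrom: str
    strand: str


def project_tx_interval(t: TranscriptModel, start: int, end: int
                        ) -> tuple[tuple[int, int], ...]:
    """Map a half-open transcript-coordinate interval to genomic intervals.

    Transcript coordinates run 5'->3'; on the '-' strand that is right-to-left
    on the genome. Returned intervals are half-open, 0-based, sorted by
    genomic position.
    """
    if not (0 <= start < end <= t.exonic_len):
        raise ValueError(f"interval [{start},{end}) outside transcript {t.id}")
    # exon segments in transcript order
    exons = t.exons if t.strand != "-" else tuple(reversed(t.exons))
    out = []
    offset = 0
    for gs, ge in exons:
        length = ge - gs
        lo = max(start, offset)
        hi = min(end, offset + length)
        if lo < hi:
            if t.strand == "-":
                out.append((ge - (hi - offset), ge - (lo - offset)))
            else:
                out.append((gs + (lo - offset), gs + (hi - offset)))
        offset += length
    return tuple(sorted(out))


def build_reference_db(novel: list[TranscriptModel], genome: dict[str, str],
                       cfg: PipelineConfig) -> list[TheoreticalProtein]:
    """Three-frame translate novel transcripts into the search database.

    Frame translations are split at stop codons; segments shorter than
    ``min_peptide_len`` or containing undetermined residues ('X') are
    dropped. Output is deduplicated by (sequence, source, frame, span) and
    deterministically ordered.
    """
    if not novel:
        log.warning("build_reference_db: no novel transcripts supplied")
        return []
    seen = set()
    proteins = []
    for t in novel:
        seq = extract_transcript_sequence(t, genome)
        strands = [False] if t.strand in "+-" else [False, True]
        if t.strand == ".":
            log.info("transcript %s unstranded: translating six frames", t.id)
        for use_revcomp in strands:
            tx_seq = reverse_complement(seq) if use_revcomp else seq
            for frame, aa in enumerate(translate_three_frames(tx_seq)):
                for seg_start, segment in _split_at_stops(aa):
                    if len(segment) < cfg.min_peptide_len or "X" in segment:
                        continue
                    tx_start = frame + 3 * seg_start
                    tx_end = tx_start + 3 * len(segment)
                    key = (segment, t.id, frame, tx_start, use_revcomp)
                    if key in seen:
                        continue
                    seen.add(key)
                    if use_revcomp:
                        # positions on the antisense read-through map back to
                        # sense coordinates mirrored about the transcript end
                        n = t.exonic_len
                        gspan = project_tx_interval(t, n - tx_end, n - tx_start)
                    else:
                        gspan = project_tx_interval(t, tx_start, tx_end)
                    pid = f"{t.id}|F{frame}|{tx_start}-{tx_end}"
                    if use_revcomp:
                        pid += "|rc"
                    proteins.append(TheoreticalProtein(
                        id=pid,
                        sequence=segment,
                        source_transcript=t.id,
                        frame=frame,
                        tx_span=(tx_start, tx_end),
                        genomic_span=gspan,
                        chrom=t.chrom,
                        strand=t.strand,
                    ))
    proteins.sort(key=lambda p: p.id)
    return proteins


def _split_at_stops(aa: str):
    """Yield (offset_in_codons, segment) for '*'-delimited segments."""
    start = 0
    for i, ch in enumerate(aa):
        if ch == "*":
            if i > start:
                yield start, aa[start:i]
            start = i + 1
    if len(aa) > start:
        yield start, aa[start:]


def write_db_fasta(proteins: list[TheoreticalProtein], path) -> None:
    """FASTA with provenance headers: id|frame|tx span|chrom:gspan(strand)."""
    with open(path, "w") as fh:
        for p in proteins:
            g0 = p.genomic_span[0][0]
            g1 = p.genomic_span[-1][1]
            fh.write(f">{p.source_transcript}|{p.frame}|{p.tx_span[0]}-{p.tx_span[1]}|"
                     f"{p.chrom}:{g0}-{g1}({p.strand})\n{p.sequence}\n")


def map_peptide_to_genome(peptide: str, parent: TheoreticalProtein,
                          transcript: TranscriptModel) -> tuple[str, tuple[tuple[int, int], ...]]:
    """Project a peptide within a theoretical protein to genomic coordinates.

    Returns the chromosome and 1-based inclusive genomic intervals covered by
    the peptide's codons (split across introns when needed).
    """
    idx = parent.sequence.find(peptide)
    if idx < 0:
        raise ValueError(f"peptide {peptide} absent from protein {parent.id}")
    nt_start = parent.tx_span[0] + 3 * idx
    nt_end = nt_start + 3 * len(peptide)
    intervals = project_tx_interval(transcript, nt_start, nt_end)
    one_based = tuple((s + 1, e) for s, e in intervals)
    return parent.chrom, one_based
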