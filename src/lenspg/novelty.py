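"""Peptide novelty filter.

A retained peptide is called novel iff its best (minimum-Hamming) match over
every equal-length window of the known proteome has at least
``novelty_min_mismatch`` substitutions (default 2) and its best supporting
XCorr is at least ``novelty_min_xcorr`` (default 2.5). Mismatches are
substitution-only on equal-length windows — no indels — since search
candidates have fixed length. Isoleucine and leucine are distinct residues;
an I/L-collapsed minimum is reported alongside as a diagnostic, because the
two are mass-indistinguishable and could masquerade as mismatches.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .catalog import TranscriptModel
from .config import PipelineConfig
from .orfdb import TheoreticalProtein, map_peptide_to_genome
from .search import PeptideSpectrumMatch

log = logging.getLogger(__name__)


@dataclass
class NovelPeptideCall:
    """One row of the novel-peptide report."""

    peptide: str
    length: int
    n_psms: int
    min_mismatch: int
    best_known_window: tuple[str, int] | None
    min_mismatch_il_collapsed: int
    xcorr_best: float
    source_transcript: str
    chrom: str
    genomic_coordinates: tuple[tuple[int, int], ...]  # 1-based inclusive

    @property
    def coordinate_string(self) -> str:
        s = self.genomic_coordinates[0][0]
        e = self.genomic_coordinates[-1][1]
        return f"{self.chrom}: {s}-{e}"


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def min_mismatch_to_proteome(peptide: str, proteome: list[tuple[str, str]],
                             collapse_il: bool = False
                             ) -> tuple[int, str | None, int | None]:
    """Minimum Hamming distance of `peptide` to any equal-length window.

    Returns (count, protein id, window offset); ties resolved to the first
    protein in input order, then the lowest offset. A peptide longer than
    every protein scores len(peptide) with no window.
    """
    if not proteome:
        raise ValueError("empty proteome")
    pep = peptide
    if collapse_il:
        pep = pep.replace("I", "L")
    p = _encode(pep)
    k = len(p)
    best = (k, None, None)
    for pid, seq in proteome:
        if collapse_il:
            seq = seq.replace("I", "L")
        n = len(seq)
        if n < k:
            continue
        s = _encode(seq)
        windows = np.lib.stride_tricks.sliding_window_view(s, k)
        mismatches = (windows != p).sum(axis=1)
        off = int(mismatches.argmin())
        count = int(mismatches[off])
        if count < best[0]:
            best = (count, pid, off)
        if best[0] == 0:
            break
    if best[1] is None:
        log.warning("peptide %s longer than every protein in the proteome", peptide)
    return best


def call_novel_peptides(retained: list[PeptideSpectrumMatch],
                        proteome: list[tuple[str, str]],
                        proteins_by_id: dict[str, TheoreticalProtein],
                        transcripts_by_id: dict[str, TranscriptModel],
                        cfg: PipelineConfig) -> list[NovelPeptideCall]:
    """Apply the novelty criterion to FDR-retained PSMs, grouped by peptide."""
    groups: dict[str, list[PeptideSpectrumMatch]] = {}
    for m in retained:
        if m.is_decoy:
            continue
        groups.setdefault(m.peptide.sequence, []).append(m)
    calls = []
    for seq in sorted(groups):
        psms = groups[seq]
        xbest = max(m.xcorr for m in psms)
        mm, pid, off = min_mismatch_to_proteome(seq, proteome)
        if mm < cfg.novelty_min_mismatch or xbest < cfg.novelty_min_xcorr:
            continue
        mm_il, _, _ = min_mismatch_to_proteome(seq, proteome, collapse_il=True)
        parent_ids = sorted(set().union(*(m.peptide.parents for m in psms)))
        parent = next((proteins_by_id[p] for p in parent_ids if p in proteins_by_id), None)
        if parent is None:
            raise ValueError(f"peptide {seq}: no ORF provenance among parents {parent_ids}")
        transcript = transcripts_by_id[parent.source_transcript]
        chrom, coords = map_peptide_to_genome(seq, parent, transcript)
        calls.append(NovelPeptideCall(
            peptide=seq,
            length=len(seq),
            n_psms=len(psms),
            min_mismatch=mm,
            best_known_window=(pid, off) if pid is not None else None,
            min_mismatch_il_collapsed=mm_il,
            xcorr_best=xbest,
            source_transcript=parent.source_transcript,
            chrom=chrom,
            genomic_coordinates=coords,
        ))
    return calls
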