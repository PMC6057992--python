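"""Synthetic study generator with machine-readable ground truth.

Produces a complete toy version of the developing-lens study: a random
genome; multi-exon protein-coding genes with GT-AG introns whose translations
form the known proteome; planted novel (fully intergenic) and semi-novel
(partially overlapping) transcripts with log-normal six-stage TPM profiles;
isoform pairs realizing the five alternative-splicing event types with
binomial junction counts; and b/y-ion fragmentation spectra for peptides from
both the known proteome and the planted novel ORFs, with noise peaks. Every
planted object is recorded in a ``GroundTruth`` that downstream stages are
tested against.

All randomness flows from a single seed; identical seeds give byte-identical
FASTA/GTF/MGF outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from pyteomics import mgf as _mgf

from .catalog import TranscriptModel, write_gtf
from .config import PipelineConfig
from .events import ASEvent, FORM_LENGTHS
from .novelty import min_mismatch_to_proteome
from .orfdb import (TheoreticalProtein, build_reference_db, map_peptide_to_genome,
                    reverse_complement, translate)
from .search import Peptide, Spectrum, digest, generate_fragments, peptide_mass

log = logging.getLogger(__name__)

_STOPS = {"TAA", "TAG", "TGA"}
_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]
_SENSE_CODONS = [c for c in _CODONS if c not in _STOPS]


# ---------------------------------------------------------------------------
# Ground truth containers
# ---------------------------------------------------------------------------

@dataclass
class PlantedEvent:
    event_type: str
    gene: str
    chrom: str
    strand: str
    coords: tuple[int, ...]
    psi: dict[str, float]
    shifted: bool
    significant_pairs: list[tuple[str, str]]


@dataclass
class PlantedPeptide:
    peptide: str
    source_transcript: str
    frame: int
    chrom: str
    genomic_span: tuple[tuple[int, int], ...]  # 1-based inclusive


@dataclass
class GroundTruth:
    transcript_labels: dict[str, str] = field(default_factory=dict)
    planted_as_events: list[PlantedEvent] = field(default_factory=list)
    planted_novel_peptides: list[PlantedPeptide] = field(default_factory=list)
    spectrum_provenance: dict[str, str] = field(default_factory=dict)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, default=list))

    def labels_of(self, category: str) -> set[str]:
        return {t for t, c in self.transcript_labels.items() if c == category}


@dataclass
class SimulatedSpectrum:
    id: str
    precursor_mz: float
    charge: int
    peaks: list[tuple[float, float]]
    truth: str  # generating peptide sequence or "noise"

    def as_spectrum(self) -> Spectrum:
        mz = np.array([p[0] for p in self.peaks])
        inten = np.array([p[1] for p in self.peaks])
        return Spectrum(self.id, self.precursor_mz, self.charge, mz, inten)


# ---------------------------------------------------------------------------
# Genome and annotation
# ---------------------------------------------------------------------------

def generate_genome(n_chromosomes: int, length_per_chrom: int, seed: int
                    ) -> dict[str, str]:
    """Uniform-composition random chromosomes, deterministic given the seed."""
    if length_per_chrom < 10_000:
        raise ValueError("chromosome length must be >= 10,000 b")
    if n_chromosomes < 1:
        raise ValueError("need at least one chromosome")
    rng = np.random.default_rng(seed)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    return {
        f"chr{i + 1}": bases[rng.integers(0, 4, size=length_per_chrom)].tobytes().decode()
        for i in range(n_chromosomes)
    }


@dataclass
class GeneModel:
    gene_id: str
    transcript: TranscriptModel
    protein: str


def generate_annotation(genome: dict[str, str], n_genes: int, seed: int,
                        min_exons: int = 2, max_exons: int = 8
                        ) -> tuple[dict[str, str], list[GeneModel]]:
    """Plant multi-exon protein-coding genes into the genome.

    Each gene gets a valid ORF (ATG ... stop, no internal stops) split across
    2-8 exons with GT-AG introns; the spliced CDS translated in frame 0 is the
    gene's protein. Returns the edited genome and the gene models.
    """
    rng = np.random.default_rng(seed)
    genome = dict(genome)
    chroms = sorted(genome)
    edited = {c: bytearray(genome[c], "ascii") for c in chroms}
    genes: list[GeneModel] = []
    ci = 0
    cursor = 1000
    for g in range(n_genes):
        n_exons = int(rng.integers(min_exons, max_exons + 1))
        n_codons = int(rng.integers(60, 200))
        cds = "ATG" + "".join(
            _SENSE_CODONS[i] for i in rng.integers(0, len(_SENSE_CODONS), n_codons)
        ) + ("TAA", "TAG", "TGA")[rng.integers(0, 3)]
        # split the CDS into exon pieces of >= 15 nt
        cuts = sorted(rng.choice(np.arange(15, len(cds) - 15), size=n_exons - 1,
                                 replace=False).tolist()) if n_exons > 1 else []
        bounds = [0, *cuts, len(cds)]
        if any(b - a < 10 for a, b in zip(bounds, bounds[1:])):
            bounds = [0, len(cds)]  # degenerate cut set: fall back to fewer exons
        exon_seqs = [cds[a:b] for a, b in zip(bounds, bounds[1:])]
        intron_lens = rng.integers(60, 300, size=len(exon_seqs) - 1)
        introns = []
        for L in intron_lens:
            body = bases_string(rng, int(L) - 4)
            introns.append("GT" + body + "AG")
        block = exon_seqs[0]
        offsets = [(0, len(exon_seqs[0]))]
        for ex, intr in zip(exon_seqs[1:], introns):
            block += intr
            offsets.append((len(block), len(block) + len(ex)))
            block += ex
        strand = "+" if rng.random() < 0.5 else "-"
        # find room
        while ci < len(chroms) and cursor + len(block) + 1000 > len(genome[chroms[ci]]):
            ci += 1
            cursor = 1000
        if ci >= len(chroms):
            raise ValueError(f"genome too small: placed {g} of {n_genes} genes")
        chrom = chroms[ci]
        pos = cursor
        written = block if strand == "+" else reverse_complement(block)
        edited[chrom][pos:pos + len(block)] = written.encode()
        if strand == "+":
            exon_coords = [(pos + a, pos + b) for a, b in offsets]
        else:
            exon_coords = sorted(
                (pos + len(block) - b, pos + len(block) - a) for a, b in offsets)
        gid = f"gene{g + 1:04d}"
        tx = TranscriptModel(id=f"{gid}.1", chrom=chrom, strand=strand,
                             exons=tuple(exon_coords), gene_id=gid)
        genes.append(GeneModel(gid, tx, translate(cds)[:-1]))
        cursor = pos + len(block) + int(rng.integers(1500, 4000))
    out_genome = {c: edited[c].decode() for c in chroms}
    return out_genome, genes


def bases_string(rng, n: int) -> str:
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    return bases[rng.integers(0, 4, size=n)].tobytes().decode()


# ---------------------------------------------------------------------------
# Assembled transcripts: annotated copies + planted novel / semi-novel
# ---------------------------------------------------------------------------

def _free_intervals(genome, genes, margin=300):
    occupied = {}
    for g in genes:
        s, e = g.transcript.span
        occupied.setdefault(g.transcript.chrom, []).append((s - margin, e + margin))
    free = {}
    for chrom, seq in sorted(genome.items()):
        merged = []
        for s, e in sorted(occupied.get(chrom, [])):
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        gaps = []
        prev = 500
        for s, e in merged:
            if s - prev > 400:
                gaps.append([prev, s])
            prev = e
        if len(seq) - 500 - prev > 400:
            gaps.append([prev, len(seq) - 500])
        free[chrom] = gaps
    return free


def _take_space(free, chrom, need, rng):
    gaps = [g for g in free[chrom] if g[1] - g[0] >= need + 100]
    if not gaps:
        return None
    gap = gaps[rng.integers(0, len(gaps))]
    start = int(gap[0] + 50)
    gap[0] = start + need + 50  # shrink the gap so later picks cannot overlap
    return start


def plant_transcripts(genome: dict[str, str], genes: list[GeneModel],
                      n_novel: int, n_semi: int, cfg: PipelineConfig, seed: int,
                      novel_multi_frac: float = 0.25,
                      semi_multi_frac: float = 0.90,
                      tpm_mu: float = 0.8, tpm_sigma: float = 1.3
                      ) -> tuple[list[TranscriptModel], GroundTruth]:
    """Build the assembled transcript set with per-stage TPMs and labels.

    The assembled set contains an exact copy of every annotated isoform plus
    ``n_novel`` fully intergenic and ``n_semi`` partially overlapping
    transcripts. Roughly a quarter of novel transcripts are multi-exonic and
    >85% of semi-novel ones are, mirroring the exon-structure proportions
    reported for assembled lens transcripts. Per-stage abundances are
    log-normal, so a realistic fraction falls under the 1.0 TPM gate.
    """
    rng = np.random.default_rng(seed)
    truth = GroundTruth()
    free = _free_intervals(genome, genes)
    chrom_names = sorted(genome)
    assembled: list[TranscriptModel] = []

    def tpms():
        return {st: float(rng.lognormal(tpm_mu, tpm_sigma)) for st in cfg.stages}

    for k, g in enumerate(genes):
        t = g.transcript
        tid = f"asm.{k + 1}.1"
        assembled.append(TranscriptModel(tid, t.chrom, t.strand, t.exons,
                                         tpm=tpms(), gene_id=t.gene_id))
        truth.transcript_labels[tid] = "annotated"

    made = 0
    attempts = 0
    while made < n_novel:
        attempts += 1
        if attempts > 50 * n_novel:
            raise ValueError(f"insufficient intergenic space: planted {made} of {n_novel}")
        chrom = chrom_names[rng.integers(0, len(chrom_names))]
        multi = rng.random() < novel_multi_frac
        if multi:
            n_ex = int(rng.integers(2, 4))
            ex_lens = rng.integers(300, 700, size=n_ex)
            in_lens = rng.integers(80, 200, size=n_ex - 1)
            need = int(ex_lens.sum() + in_lens.sum())
        else:
            n_ex, ex_lens, in_lens = 1, np.array([int(rng.integers(600, 1200))]), np.array([], int)
            need = int(ex_lens[0])
        start = _take_space(free, chrom, need, rng)
        if start is None:
            continue
        exons = []
        pos = start
        for i in range(n_ex):
            exons.append((pos, pos + int(ex_lens[i])))
            pos = exons[-1][1] + (int(in_lens[i]) if i < n_ex - 1 else 0)
        tid = f"asm.n{made + 1}.1"
        strand = "+" if rng.random() < 0.5 else "-"
        assembled.append(TranscriptModel(tid, chrom, strand, tuple(exons), tpm=tpms()))
        truth.transcript_labels[tid] = "novel"
        made += 1

    made = 0
    attempts = 0
    while made < n_semi:
        attempts += 1
        if attempts > 50 * n_semi:
            raise ValueError(f"insufficient space: planted {made} of {n_semi} semi-novel")
        g = genes[rng.integers(0, len(genes))]
        t = g.transcript
        ex_i = int(rng.integers(0, len(t.exons)))
        es, ee = t.exons[ex_i]
        multi = rng.random() < semi_multi_frac
        # first exon: overlap the annotated exon partially, extend to the right
        # beyond the gene, into its intron, or past the gene end
        inner = max(es + (ee - es) // 2, es + 5)
        ext = int(rng.integers(max(80, (ee - inner) // 2 + 40), 400))
        exon1 = (inner, ee + ext)
        gene_end = t.span[1]
        if multi:
            gap = int(rng.integers(100, 400))
            len2 = int(rng.integers(200, 500))
            exon2 = (gene_end + gap, gene_end + gap + len2)
            if exon2[0] <= exon1[1]:
                exon2 = (exon1[1] + gap, exon1[1] + gap + len2)
            exons = (exon1, exon2)
        else:
            exons = (exon1,)
        if exons[-1][1] + 200 > len(genome[t.chrom]):
            continue
        # reject geometries that stray into a neighbouring gene's exons
        if _hits_other_gene(exons, genes, t.chrom, g.gene_id):
            continue
        tid = f"asm.s{made + 1}.1"
        assembled.append(TranscriptModel(tid, t.chrom, t.strand, exons, tpm=tpms()))
        truth.transcript_labels[tid] = "semi-novel"
        made += 1

    return assembled, truth


def _hits_other_gene(exons, genes, chrom, own_gene):
    for g in genes:
        if g.transcript.chrom != chrom or g.gene_id == own_gene:
            continue
        for s, e in g.transcript.exons:
            for xs, xe in exons:
                if xs < e and s < xe:
                    return True
    return False


# ---------------------------------------------------------------------------
# Alternative-splicing event planting
# ---------------------------------------------------------------------------

def plant_as_events(genes: list[GeneModel], counts_per_type: dict[str, int],
                    depth: int, cfg: PipelineConfig, seed: int,
                    shifted_fraction: float = 0.5,
                    psi_low: float = 0.15, psi_high: float = 0.85
                    ) -> tuple[list[TranscriptModel], list[ASEvent], list[PlantedEvent]]:
    """Construct isoform pairs realizing each requested event type.

    Each event lives on its own gene. Junction read counts per stage are
    binomial(depth, p) with p chosen so that the length-normalized PSI equals
    the planted value. A ``shifted_fraction`` of events receives a low->high
    PSI switch halfway through the stages, large enough to be detectable; the
    rest keep a constant PSI.
    """
    rng = np.random.default_rng(seed)
    need = {"ES": 3, "A5SS": 2, "A3SS": 2, "MXE": 4, "IR": 2}
    pool = [genes[i] for i in rng.permutation(len(genes))]
    isoforms: list[TranscriptModel] = []
    events: list[ASEvent] = []
    planted: list[PlantedEvent] = []
    used = set()
    for etype in ("ES", "A5SS", "A3SS", "MXE", "IR"):
        wanted = counts_per_type.get(etype, 0)
        got = 0
        for g in pool:
            if got >= wanted:
                break
            if g.gene_id in used or len(g.transcript.exons) < need[etype]:
                continue
            built = _build_event(g, etype, rng)
            if built is None:
                continue
            used.add(g.gene_id)
            iso_a, iso_b, coords = built
            shifted = rng.random() < shifted_fraction
            if shifted:
                lo_first = rng.random() < 0.5
                psi = {st: (psi_low if (i < len(cfg.stages) // 2) == lo_first else psi_high)
                       for i, st in enumerate(cfg.stages)}
            else:
                base = float(rng.uniform(0.35, 0.65))
                psi = {st: base for st in cfg.stages}
            li, ls = FORM_LENGTHS[etype]
            counts = {}
            for st in cfg.stages:
                w = psi[st] * li
                p = w / (w + (1 - psi[st]) * ls)
                i_reads = int(rng.binomial(depth, p))
                counts[st] = (i_reads, depth - i_reads)
            ev = ASEvent(etype, g.gene_id, g.transcript.chrom, g.transcript.strand,
                         coords=coords, inclusion_len=li, skipping_len=ls,
                         counts=counts)
            sig_pairs = [(a, b) for i, a in enumerate(cfg.stages)
                         for b in cfg.stages[i + 1:] if abs(psi[a] - psi[b]) > 1e-9]
            events.append(ev)
            isoforms.extend([iso_a, iso_b])
            planted.append(PlantedEvent(etype, g.gene_id, g.transcript.chrom,
                                        g.transcript.strand, coords, psi, shifted,
                                        sig_pairs))
            got += 1
        if got < wanted:
            raise ValueError(f"cannot realize {wanted} {etype} events "
                             f"(only {got} suitable genes)")
    return isoforms, events, planted


def _build_event(g: GeneModel, etype: str, rng):
    t = g.transcript
    ex = list(t.exons)
    n = len(ex)
    gid = f"asgene_{g.gene_id}_{etype}"

    def iso(suffix, exons):
        return TranscriptModel(id=f"{gid}.{suffix}", chrom=t.chrom, strand=t.strand,
                               exons=tuple(exons), gene_id=gid)

    if etype == "ES":
        i = int(rng.integers(1, n - 1))
        coords = (ex[i - 1][1], ex[i][0], ex[i][1], ex[i + 1][0])
        return iso("inc", ex), iso("skp", ex[:i] + ex[i + 1:]), coords
    if etype in ("A5SS", "A3SS"):
        j = int(rng.integers(0, n - 1))
        intron_len = ex[j + 1][0] - ex[j][1]
        if intron_len < 50:
            return None
        delta = int(rng.integers(20, min(80, intron_len - 20)))
        vary_left = (etype == "A5SS") == (t.strand != "-")
        if vary_left:
            long_ex = list(ex)
            long_ex[j] = (ex[j][0], ex[j][1] + delta)
            coords = (ex[j][1], ex[j][1] + delta, ex[j + 1][0], ex[j + 1][0])
        else:
            long_ex = list(ex)
            long_ex[j + 1] = (ex[j + 1][0] - delta, ex[j + 1][1])
            coords = (ex[j][1], ex[j][1], ex[j + 1][0] - delta, ex[j + 1][0])
        return iso("long", long_ex), iso("short", ex), coords
    if etype == "MXE":
        i = int(rng.integers(1, n - 2))
        first, second = ex[i], ex[i + 1]
        coords = (ex[i - 1][1], *first, *second, ex[i + 2][0])
        a = iso("first", ex[:i + 1] + ex[i + 2:])   # keeps `first`, drops `second`
        b = iso("second", ex[:i] + ex[i + 1:])      # keeps `second`, drops `first`
        return a, b, coords
    if etype == "IR":
        j = int(rng.integers(0, n - 1))
        coords = (ex[j][1], ex[j + 1][0])
        merged = ex[:j] + [(ex[j][0], ex[j + 1][1])] + ex[j + 2:]
        return iso("spl", ex), iso("ret", merged), coords
    raise AssertionError(etype)


def simulate_count_events(n_events: int, depth: int, cfg: PipelineConfig, seed: int,
                          psi_a: float = 0.5, psi_b: float | None = None,
                          stage_a: str | None = None, stage_b: str | None = None
                          ) -> list[ASEvent]:
    """Bare ES-type events with binomial junction counts at two stages.

    Used for calibration studies of the screen itself: under the null
    (``psi_b`` omitted) both stages share ``psi_a``; otherwise the second
    stage uses ``psi_b``. Coordinates are synthetic placeholders.
    """
    rng = np.random.default_rng(seed)
    stage_a = stage_a or cfg.stages[0]
    stage_b = stage_b or cfg.stages[1]
    li, ls = FORM_LENGTHS["ES"]
    psi_b = psi_a if psi_b is None else psi_b
    events = []
    for k in range(n_events):
        counts = {}
        for st, psi in ((stage_a, psi_a), (stage_b, psi_b)):
            w = psi * li
            p = w / (w + (1 - psi) * ls)
            i_reads = int(rng.binomial(depth, p))
            counts[st] = (i_reads, depth - i_reads)
        base = 10_000 * k
        events.append(ASEvent("ES", f"nullgene{k}", "chrS", "+",
                              coords=(base, base + 100, base + 200, base + 300),
                              inclusion_len=li, skipping_len=ls, counts=counts))
    return events


# ---------------------------------------------------------------------------
# Spectra
# ---------------------------------------------------------------------------

def simulate_spectra(peptides: list[str], cfg: PipelineConfig, seed: int,
                     noise_peaks: int = 12, mass_jitter: float = 0.004,
                     n_noise_spectra: int = 0, id_prefix: str = "spec"
                     ) -> list[SimulatedSpectrum]:
    """Simulate b/y fragmentation spectra (charge 2 or 3) for each peptide.

    Signal peaks are the singly (and, at charge 3, doubly) charged b/y ions
    with Gaussian m/z jitter truncated well inside the fragment tolerance;
    intensities are uniform on [0.2, 1.0]. ``noise_peaks`` uniform peaks on
    [0, 0.1] are added, plus optional pure-noise spectra. Precursor m/z is
    jittered within the precursor tolerance.
    """
    if not peptides and n_noise_spectra == 0:
        log.warning("simulate_spectra: empty peptide list")
        return []
    rng = np.random.default_rng(seed)
    out: list[SimulatedSpectrum] = []
    jitter_clip = min(2.5 * mass_jitter, 0.75 * cfg.fragment_tol_da) if mass_jitter else 0.0
    for k, pep in enumerate(peptides):
        charge = int(rng.choice([2, 3]))
        p = Peptide(pep)
        _, mz = peptide_mass(p, cfg, charge)
        ppm = float(np.clip(rng.normal(0, 2.0), -6, 6)) if mass_jitter else 0.0
        prec = mz * (1 + ppm * 1e-6)
        ions = generate_fragments(p, cfg, charge=charge)
        peaks = []
        for _, ion_mz in ions:
            d = float(np.clip(rng.normal(0, mass_jitter), -jitter_clip, jitter_clip)) \
                if mass_jitter else 0.0
            peaks.append((ion_mz + d, float(rng.uniform(0.2, 1.0))))
        top = max(m for m, _ in peaks)
        for _ in range(noise_peaks):
            peaks.append((float(rng.uniform(100, top + 100)), float(rng.uniform(0, 0.1))))
        peaks.sort()
        out.append(SimulatedSpectrum(f"{id_prefix}{k + 1:05d}", prec, charge, peaks, pep))
    for k in range(n_noise_spectra):
        charge = 2
        prec = float(rng.uniform(400, 1200))
        peaks = sorted((float(rng.uniform(100, 1800)), float(rng.uniform(0, 0.1)))
                       for _ in range(max(noise_peaks, 15)))
        out.append(SimulatedSpectrum(f"{id_prefix}_noise{k + 1:04d}", prec, charge,
                                     peaks, "noise"))
    return out


def write_mgf(spectra: list[SimulatedSpectrum], path) -> None:
    entries = []
    for s in spectra:
        entries.append({
            "m/z array": np.array([p[0] for p in s.peaks]),
            "intensity array": np.array([p[1] for p in s.peaks]),
            "params": {"title": s.id, "pepmass": s.precursor_mz,
                       "charge": f"{s.charge}+"},
        })
    _mgf.write(entries, str(path), file_mode="w")


def read_mgf(path) -> list[Spectrum]:
    out = []
    with _mgf.read(str(path)) as reader:
        for entry in reader:
            params = entry["params"]
            charge = int(params["charge"][0])
            out.append(Spectrum(
                id=params["title"],
                precursor_mz=float(params["pepmass"][0]),
                charge=charge,
                mz=entry["m/z array"],
                intensity=entry["intensity array"],
            ))
    return out


# ---------------------------------------------------------------------------
# Whole-study assembly
# ---------------------------------------------------------------------------

@dataclass
class StudySizes:
    """Problem sizes of the default synthetic study."""

    n_chromosomes: int = 2
    chrom_length: int = 300_000
    n_genes: int = 30
    n_novel: int = 24
    n_semi: int = 16
    as_counts: dict[str, int] = field(default_factory=lambda: {
        "ES": 3, "A5SS": 3, "A3SS": 3, "MXE": 3, "IR": 3})
    as_depth: int = 200
    as_shifted_fraction: float = 0.5
    n_planted_peptides: int = 60
    max_psms_per_peptide: int = 4
    n_known_spectra: int = 300
    n_noise_spectra: int = 50
    peptide_len_range: tuple[int, int] = (9, 18)


@dataclass
class SyntheticStudy:
    genome: dict[str, str]
    genes: list[GeneModel]
    proteome: list[tuple[str, str]]
    assembled: list[TranscriptModel]
    as_isoforms: list[TranscriptModel]
    as_events: list[ASEvent]
    spectra: list[SimulatedSpectrum]
    truth: GroundTruth


def pick_planted_peptides(db: list[TheoreticalProtein],
                          proteome: list[tuple[str, str]],
                          transcripts_by_id: dict[str, TranscriptModel],
                          cfg: PipelineConfig, rng, n: int,
                          len_range: tuple[int, int]) -> list[PlantedPeptide]:
    """Sample tryptic peptides of novel ORFs, rejecting any whose minimum
    mismatch to the known proteome falls under the novelty threshold."""
    seen = set()
    candidates = []
    for prot in db:
        for pep in digest(prot.sequence, cfg, parent=prot.id):
            s = pep.sequence
            if len_range[0] <= len(s) <= len_range[1] and s not in seen:
                seen.add(s)
                candidates.append((s, prot))
    candidates = [candidates[i] for i in rng.permutation(len(candidates))]
    planted = []
    for s, prot in candidates:
        if len(planted) >= n:
            break
        mm, _, _ = min_mismatch_to_proteome(s, proteome)
        if mm < cfg.novelty_min_mismatch:
            continue
        chrom, coords = map_peptide_to_genome(s, prot, transcripts_by_id[prot.source_transcript])
        planted.append(PlantedPeptide(s, prot.source_transcript, prot.frame, chrom, coords))
    if len(planted) < n:
        log.warning("only %d of %d requested planted peptides available", len(planted), n)
    return planted


def synthesize_study(cfg: PipelineConfig, seed: int,
                     sizes: StudySizes | None = None) -> SyntheticStudy:
    """Generate the full default study with ground truth."""
    sizes = sizes or StudySizes()
    rng = np.random.default_rng(seed)

    genome = generate_genome(sizes.n_chromosomes, sizes.chrom_length, seed)
    genome, genes = generate_annotation(genome, sizes.n_genes, seed + 1)
    proteome = [(g.gene_id, g.protein) for g in genes]

    assembled, truth = plant_transcripts(genome, genes, sizes.n_novel, sizes.n_semi,
                                         cfg, seed + 2)
    as_isoforms, as_events, planted_events = plant_as_events(
        genes, sizes.as_counts, sizes.as_depth, cfg, seed + 3,
        shifted_fraction=sizes.as_shifted_fraction)
    truth.planted_as_events = planted_events

    novel_tx = [t for t in assembled if truth.transcript_labels[t.id] == "novel"]
    db = build_reference_db(novel_tx, genome, cfg)
    tx_by_id = {t.id: t for t in assembled}
    planted = pick_planted_peptides(db, proteome, tx_by_id, cfg, rng,
                                    sizes.n_planted_peptides, sizes.peptide_len_range)
    truth.planted_novel_peptides = planted

    # spectra: planted novel peptides (1..max PSMs each), known tryptic
    # peptides, pure noise
    pep_list = []
    for p in planted:
        for _ in range(int(rng.integers(1, sizes.max_psms_per_peptide + 1))):
            pep_list.append(p.peptide)
    known_peps = []
    for pid, seq in proteome:
        for pep in digest(seq, cfg, parent=pid):
            if 7 <= len(pep.sequence) <= 25:
                known_peps.append(pep.sequence)
    known_peps = sorted(set(known_peps))
    idx = rng.integers(0, len(known_peps), size=sizes.n_known_spectra)
    pep_list.extend(known_peps[i] for i in idx)

    spectra = simulate_spectra(pep_list, cfg, seed + 4,
                               n_noise_spectra=sizes.n_noise_spectra)
    planted_set = {p.peptide for p in planted}
    for s in spectra:
        if s.truth == "noise":
            truth.spectrum_provenance[s.id] = "noise"
        elif s.truth in planted_set:
            truth.spectrum_provenance[s.id] = s.truth
        else:
            truth.spectrum_provenance[s.id] = f"known:{s.truth}"
    return SyntheticStudy(genome, genes, proteome, assembled, as_isoforms,
                          as_events, spectra, truth)


def write_study(study: SyntheticStudy, outdir, cfg: PipelineConfig) -> dict[str, Path]:
    """Write every study artifact in its standard plain-text format."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": outdir / "genome.fa",
        "annotation": outdir / "annotation.gtf",
        "transcripts": outdir / "transcripts.gtf",
        "as_isoforms": outdir / "as_isoforms.gtf",
        "as_counts": outdir / "as_junction_counts.tsv",
        "proteome": outdir / "proteome.fa",
        "spectra": outdir / "spectra.mgf",
        "truth": outdir / "ground_truth.json",
    }
    with open(paths["genome"], "w") as fh:
        for chrom in sorted(study.genome):
            fh.write(f">{chrom}\n")
            seq = study.genome[chrom]
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")
    write_gtf([g.transcript for g in study.genes], paths["annotation"])
    write_gtf(study.assembled, paths["transcripts"])
    write_gtf(study.as_isoforms, paths["as_isoforms"])
    with open(paths["as_counts"], "w") as fh:
        cols = "\t".join(f"inc_{s}\tskip_{s}" for s in cfg.stages)
        fh.write(f"event_type\tgene\tchrom\tstrand\tcoords\t{cols}\n")
        for ev in study.as_events:
            vals = "\t".join(f"{ev.counts[s][0]}\t{ev.counts[s][1]}" for s in cfg.stages)
            fh.write(f"{ev.event_type}\t{ev.gene}\t{ev.chrom}\t{ev.strand}\t"
                     f"{':'.join(map(str, ev.coords))}\t{vals}\n")
    with open(paths["proteome"], "w") as fh:
        for pid, seq in study.proteome:
            fh.write(f">{pid}\n{seq}\n")
    write_mgf(study.spectra, paths["spectra"])
    study.truth.to_json(paths["truth"])
    return paths
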