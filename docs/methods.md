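# Methods

`lenspg` re-implements, as a tested pipeline over synthetic data with planted
ground truth, the proteogenomic procedure used to find novel transcripts,
alternative-splicing (AS) events and novel peptides in a developing-lens
multi-omic study: transcript classification against a reference annotation,
AS-event typing with a PSI/FDR screen, three-frame ORF database construction,
cross-correlation peptide–spectrum matching with target–decoy FDR, a
mismatch-based peptide novelty filter, and synthetic-peptide spectrum
validation. This note records the models, the parameters that matter, what
the generator does and does not emulate, and the design choices that were
genuinely open.

## Transcript classification

Assembled transcripts are partitioned against the reference annotation by
exonic overlap, computed strand-aware on merged reference exons
(unstranded records match both strands):

* **novel** — zero exonic bases overlap any annotated exon;
* **annotated** — for multi-exon transcripts, an exact intron-chain match to
  some reference transcript (identical ordered internal junctions; terminal
  exon ends may differ). A mono-exonic transcript is annotated when at least
  95% of its length (`annotated_containment`, configurable) lies inside one
  annotated exon — the rule must be explicit because most novel transcripts
  in this setting are single-exon;
* **semi-novel** — everything else with positive overlap (touches both
  annotated and unannotated sequence).

The three-way split used by assembly tools is not formally defined anywhere;
intron-chain equality is the conventional transcript-identity relation and is
what this package commits to. Per-stage expressed counts apply the
`tpm_min = 1.0` TPM gate; the "Total" row counts transcripts expressed in at
least one stage (a union, never a column sum).

## AS events, PSI and the screen

Events between isoforms of a gene are typed as ES, A5SS, A3SS, MXE or IR
from exon-chain geometry: ES needs the skipping junction joining the two
flanking exons; the alternative splice-site events require the two variant
junctions to share one boundary *and* their variant-side exons to overlap
(otherwise an ES pair would masquerade as A3SS); MXE requires shared flanking
junction anchors and that the two middle exons never co-occur in any observed
isoform; IR requires an intron of one isoform to lie inside an exon of the
other. Donor-side variation is A5SS on '+' and A3SS on '−'. Events are
deduplicated by defining coordinates, and a junction lookup against the
reference annotation sets the novel flag.

PSI is length-normalized:
`PSI = (I/L_inc) / (I/L_inc + S/L_skip)` with effective junction-form lengths
(L_inc, L_skip) of (2, 1) for ES, (2, 2) for MXE, (1, 1) for A5SS/A3SS. For
IR the package also uses (2, 1) — the two exon–intron boundary junctions vs
the spliced junction — rather than the intron-length normalization used for
body-read counting, because all counts here are junction counts; normalizing
junction counts by intron length would bias PSI.

The original study screened events with rMATS; its hierarchical likelihood
model belongs to that tool and is deliberately not re-implemented. The
stand-in, as a screen with the same contract, is Fisher's exact test
(two-sided) of homogeneity of the two length-normalized inclusion
proportions per stage pair, Benjamini–Hochberg adjusted across events within
the comparison, significant iff q ≤ 0.01. Under null simulation (1,000
events, equal PSI, depth 100) the empirical significant fraction is ~0 —
Fisher + BH is conservative, which is the right failure direction for a
screen. A planted PSI shift of 0.9 vs 0.1 at depth 200 is detected with
probability ≥ 0.99.

"Time points" tallies are ambiguous in such study designs (stages of
expression vs significant pairwise comparisons). The package's primary
attribution is expression-based — an event belongs to a time point when both
junction forms are observed there — because it is stable across the 15
pairwise screens; the significance-based decomposition is emitted alongside.

## ORF database

Classified-novel transcripts are spliced ('−' strand reverse-complemented),
translated in the three sense frames (assembly provides the strand;
unstranded transcripts fall back to six frames with a logged notice), split
at stop codons, and segments of ≥ 6 residues become database entries. The
split is required, not optional: search candidates cannot span a stop.
Segments need no initiator methionine and may abut transcript ends — the
goal is *all potential* proteins, maximizing sensitivity. Codons containing
N translate to 'X' and any segment containing 'X' is excluded (undefined
mass). Every entry records source transcript, frame, transcript-coordinate
span and the genomic intervals of its codons, so a peptide hit projects back
to 1-based genomic coordinates exactly (split across introns when needed).

## Search and FDR

Tryptic digestion cuts C-terminal to K/R except before P, products with 0–2
missed cleavages and ≥ 6 residues. Masses are monoisotopic sums over a
residue table + water; fixed carbamidomethyl (C, +57.02146), variable
oxidation (M, +15.99491) and N-terminal acetylation (+42.01057), and the TMT
label (+229.162932 on peptide N-terminus and K) on by default — the lens
proteome and the synthetic validation peptides were TMT-labeled, although
published search-parameter lists for such studies often omit the label, so
it is switchable (`tmt_labeling`). Variable-mod placements are capped at 3
per peptide.

Scoring follows the fast cross-correlation construction: square-rooted
intensities, ten-region normalization of the observed spectrum to a maximum
of 50, binning at the fragment tolerance (0.02 Da), background subtraction
of the mean correlation over lags within ±75 bins, matched sum divided by
10⁴. This reproduces the familiar score scale — a confident match of a
~10-residue peptide lands in the 3–5 range — which matters because the
novelty criterion quotes an absolute XCorr ≥ 2.5. The exact SEQUEST variant
inside commercial suites is not public, so scale comparability of that cut
is approximate and the threshold is configurable.

Candidates are selected within ±10 ppm of the precursor neutral mass; the
best target and best decoy per spectrum are kept. Decoys are full-protein
reversals digested identically (preserves length and composition
distributions); decoy peptides whose sequence collides with a target
(palindromes) stay targets. q-values are plain target–decoy:
FDR(t) = decoys/targets above t, q = running minimum from the bottom,
retained iff q ≤ 0.01. Learned rescoring (Percolator) is out of scope by
design; this is recorded in the run manifest.

## Novelty filter

A retained peptide is novel iff (a) its minimum Hamming distance to every
equal-length window of the known proteome is ≥ 2 and (b) its best
supporting XCorr is ≥ 2.5. Mismatch is substitution-only — search
candidates have fixed length, so indel-tolerant alignment would answer a
different question; the original screen against a large protein database may
have allowed gaps, which is why the window-Hamming reading is stated
explicitly and oracle-tested against an exhaustive scan. Isoleucine and
leucine are distinct residues, but since they are mass-indistinguishable an
I/L-collapsed minimum is reported as a diagnostic column. Report rows carry
peptide, length, PSM count, source transcript and 1-based genomic
coordinates.

## Spectrum validation

The manual "similar fragmentation pattern" judgement is replaced by two
explicit statistics computed on the theoretical b/y ladder of the peptide
(TMT applied when enabled): the fraction of ladder ions found in *both*
spectra within the fragment tolerance, and the cosine similarity of the
intensities of those co-matched ions. Verdict thresholds default to 0.5 and
0.7 and are always reported, never silent. The comparison is symmetric in
its two spectra and scale-invariant in intensity. When endogenous and
synthetic spectra have different precursor charges the ladder is computed at
the higher charge, so a charge-2 spectrum can match at most half of a
charge-3 ladder — the 0.5 threshold is chosen to tolerate exactly this.

## The synthetic study

The generator emulates the study's inputs with planted truth; all
randomness flows from one seed and outputs are byte-deterministic.

* Genome: uniform-random chromosomes (default 2 × 300 kb).
* Annotation: 30 multi-exon genes (2–8 exons), each a valid ORF split across
  exons with GT–AG introns; spliced frame-0 translations form the known
  proteome. On '−' strand genes the genomic intron shows CT..AC on the plus
  strand, as in real annotation.
* Assembled transcripts: exact copies of every annotated isoform, 24 novel
  transcripts placed in intergenic space (~25% multi-exonic) and 16
  semi-novel transcripts overlapping an annotated exon partially and
  extending into unannotated sequence (~90% multi-exonic) — the exon-count
  proportions reported for assembled lens transcripts. TPMs are log-normal
  (μ = 0.8, σ = 1.3 on the log scale), putting a realistic ~25–30% of
  stage-values under the 1.0 TPM gate.
* AS events: 3 events per type, each on its own gene, realized as an isoform
  pair. Junction counts are binomial(depth = 200) with the success
  probability chosen so the length-normalized PSI equals the planted value;
  half the events get a 0.15 ↔ 0.85 PSI switch halfway through the stages,
  the rest a constant PSI in [0.35, 0.65].
* Spectra: 60 planted novel peptides (tryptic products of the novel ORFs,
  9–18 residues, each rejected at generation unless ≥ 2 mismatches from the
  proteome — the ground-truth pre-check therefore provably agrees with the
  novelty filter), 1–4 spectra each; 300 spectra of known tryptic peptides;
  50 pure-noise spectra — ~500 in total. Signal peaks are the b/y ions with
  Gaussian jitter (σ = 0.004 Da, truncated inside the 0.02 Da tolerance) and
  uniform [0.2, 1.0] intensities; noise peaks are uniform with intensity
  [0, 0.1]; precursors are jittered within the 10 ppm tolerance.

What the generator does **not** emulate — and therefore what passing tests
cannot show about real data: read-level sequencing noise, alignment and
assembly artifacts (transcript models are taken as given, as the spec's
upstream tools are out of scope), biological co-expression structure, real
fragmentation intensity patterns (intensities are uniform, not
physicochemical), chimeric/fusion transcripts, TMT reporter-ion
quantification, and the scale of a real proteome (30 proteins vs tens of
thousands, which makes the mismatch screen easier than against a
non-redundant database).

## Numerical and degenerate-input choices

PSI is undefined when both counts are zero (the event is excluded from that
comparison and logged). Fisher tables round length-normalized counts to
integers. Mismatch ties resolve to the first protein in input order, lowest
offset; a peptide longer than every protein scores its own length, flagged.
XCorr returns 0 for empty inputs and the observed-spectrum preprocessing is
cached per spectrum. GTF exons arriving unsorted are sorted, not rejected;
an exon without `transcript_id` is a format error naming the line. The ORF
database build is order-independent (set semantics, sorted output).

## Problem sizes

Default sizes (above) were chosen so the full pipeline — synthesis through
validation — completes in well under a minute and the whole test suite in
about half a minute, while keeping every recovery statistic estimated over
hundreds of spectra and a thousand null events. All sizes are fields of
`StudySizes` and can be scaled up freely.

## Known limitations

The XCorr scale is comparable to, not identical with, commercial SEQUEST
implementations. The screen's Fisher/BH stand-in is conservative relative to
rMATS's likelihood model. Protein-level inference, coding-potential scoring,
fusion detection, retention-time and isotope-envelope modeling are all out
of scope. The novelty screen here runs against the synthetic known proteome;
against a real non-redundant database the mismatch distribution would be far
tighter.
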