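# lenspg

Proteogenomic discovery of novel transcripts, alternative-splicing events
and novel peptides, re-implemented as a tested pipeline on synthetic data
with planted ground truth.

Bulk RNA-seq of a developing tissue (here modeled on the ocular lens across
six stages E15, E18, P0, P3, P6, P9) assembles transcripts that a reference
annotation does not know: some map entirely to unannotated genome (*novel*),
some touch both annotated and unannotated sequence (*semi-novel*). Whether
any of those novel transcripts are translated is a proteomics question: the
pipeline translates them into all three reading frames, builds a theoretical
protein database, searches MS/MS spectra against it, and keeps only peptides
that no known protein can explain. `lenspg` implements that whole chain and
— because the original datasets are not desk-scale — ships a synthetic-study
generator whose planted truth every stage is scored against.

## What the pipeline computes

* **Transcript catalog** — classify each assembled transcript by exonic
  overlap with the annotation (novel ⇔ zero overlap; annotated ⇔
  intron-chain match; semi-novel otherwise) and count expressed transcripts
  per stage at the ≥ 1.0 TPM gate, with a union-semantics Total row.
* **AS screen** — type events between isoforms (ES, A5SS, A3SS, MXE, IR),
  compute the length-normalized inclusion fraction
  `PSI = (I/L_inc) / (I/L_inc + S/L_skip)` from junction counts, and screen
  all 15 stage pairs with Fisher's exact test + Benjamini–Hochberg at
  FDR ≤ 0.01.
* **ORF database** — spliced novel-transcript sequences translated in three
  frames, split at stops, segments ≥ 6 aa kept with full provenance
  (frame, transcript span, genomic span).
* **Search** — tryptic digestion (≤ 2 missed cleavages, no cut before P),
  candidate selection at ±10 ppm precursor tolerance, b/y ladders with
  fixed/variable modifications (TMT on by default), SEQUEST-style
  cross-correlation (XCorr) scoring at 0.02 Da fragment tolerance, and
  target–decoy q-values with retention at q ≤ 0.01.
* **Novelty filter** — a peptide is novel iff its minimum Hamming distance
  to every equal-length window of the known proteome is ≥ 2 *and* its best
  XCorr is ≥ 2.5.
* **Validation** — endogenous vs synthetic-peptide spectrum comparison:
  matched b/y-ion fraction and cosine similarity of co-matched intensities,
  with an explicit consistent/inconsistent verdict.

## Worked example

The numbered scripts under `analysis/` run the study end to end, writing
tables under `results/`:

```bash
python analysis/01_synthesize_study.py
python analysis/02_classify_transcripts.py
python analysis/03_splicing_screen.py
python analysis/04_orf_search_novelty.py
python analysis/05_validate_peptides.py
```

With the default seed, `02` prints the per-stage expressed-count table and
its agreement with the planted labels:

```
       annotated  novel  semi-novel
stage
E15           19     17          11
E18           25     19          13
P0            20     17          13
P3            21     15          11
P6            24     20          10
P9            22     17           8
Total         30     24          16

classification matches planted labels: 70/70
```

Each stage row counts transcripts at ≥ 1.0 TPM in that stage; the Total row
is the union over stages, and the classification recovers every planted
label. `03` recovers the 15 planted splicing events (3 per type) and reports
a null-calibration rate of 0.0000 significant at q ≤ 0.01 over 1,000
equal-PSI events. `04` then reports:

```
ORF database: 931 theoretical proteins from 24 novel transcripts
search: 498 spectra, 552 PSMs, 148 retained at q<=0.01
novelty: 60 calls; precision 1.000, recall 1.000 vs planted ground truth
```

i.e. every planted novel peptide that received spectra is called, and
nothing else is. `05` confirms all 60 calls against simulated
synthetic-peptide spectra (`60/60 consistent`).

The same pipeline is available as a CLI
(`lenspg synth|classify|as|orfdb|search|novelty|validate|all`), sharing
`--config/--seed/--workdir`, with every threshold overridable by flag.

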