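"""Build the three-frame ORF database from novel transcripts, search the
spectra, and call novel peptides.

Reads the genome, transcripts, proteome and MGF written by 01 plus the
classification from 02; translates classified-novel transcripts in three
frames (segments >= 6 aa), scores every spectrum with the cross-correlation
search at 10 ppm / 0.02 Da, applies target-decoy FDR < 0.01, then the
novelty criterion (>= 2 mismatches to the known proteome, XCorr >= 2.5), and
writes the novel-peptide report table.
"""

import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from lenspg.catalog import read_gtf
from lenspg.config import load_config
from lenspg.novelty import call_novel_peptides
from lenspg.orfdb import build_reference_db, write_db_fasta
from lenspg.pipeline import _psm_frame
from lenspg.search import SearchDatabase, fdr_filter, search
from lenspg.synth import read_mgf

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cfg = load_config(RESULTS / "study" / "config.yaml")
    genome = {r.id: str(r.seq) for r in
              SeqIO.parse(RESULTS / "study" / "genome.fa", "fasta")}
    assembled = read_gtf(RESULTS / "study" / "transcripts.gtf")
    cls = pd.read_csv(RESULTS / "classified_transcripts.tsv", sep="\t")
    novel_ids = set(cls.loc[cls["category"] == "novel", "transcript_id"])
    novel_tx = [t for t in assembled if t.id in novel_ids]

    db = build_reference_db(novel_tx, genome, cfg)
    write_db_fasta(db, RESULTS / "orf_db.fasta")
    print(f"ORF database: {len(db)} theoretical proteins "
          f"from {len(novel_tx)} novel transcripts")

    spectra = read_mgf(RESULTS / "study" / "spectra.mgf")
    psms = search(spectra, SearchDatabase.build(db, cfg), cfg)
    retained = fdr_filter(psms, cfg)
    _psm_frame(psms).to_csv(RESULTS / "psms.tsv", sep="\t", index=False)
    print(f"search: {len(spectra)} spectra, {len(psms)} PSMs, "
          f"{len(retained)} retained at q<={cfg.search_fdr_max}")

    proteome = [(r.id, str(r.seq)) for r in
                SeqIO.parse(RESULTS / "study" / "proteome.fa", "fasta")]
    calls = call_novel_peptides(retained, proteome, {p.id: p for p in db},
                                {t.id: t for t in assembled}, cfg)
    rows = [{
        "No.": i, "Novel Peptide": c.peptide, "Amino Acid Length": c.length,
        "Number of PSMs": c.n_psms, "Novel Transcript ID": c.source_transcript,
        "Genomic Coordinates": c.coordinate_string,
        "Min Mismatch": c.min_mismatch, "Best XCorr": round(c.xcorr_best, 3),
    } for i, c in enumerate(calls, start=1)]
    pd.DataFrame(rows).to_csv(RESULTS / "table3_novel_peptides.tsv",
                              sep="\t", index=False)

    truth = json.loads((RESULTS / "study" / "ground_truth.json").read_text())
    planted = {p["peptide"] for p in truth["planted_novel_peptides"]}
    with_spectra = {v for v in truth["spectrum_provenance"].values()
                    if v in planted}
    called = {c.peptide for c in calls}
    tp = len(called & with_spectra)
    print(f"novelty: {len(calls)} calls; precision "
          f"{tp / max(len(called), 1):.3f}, recall "
          f"{tp / max(len(with_spectra), 1):.3f} vs planted ground truth")


if __name__ == "__main__":
    main()
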