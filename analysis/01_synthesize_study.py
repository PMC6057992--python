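"""Generate the default synthetic study and write its inputs under results/study.

Emits the toy genome, reference annotation, assembled transcripts with
six-stage TPMs, splicing isoform pairs with junction counts, the known
proteome, the fragmentation spectra, and the machine-readable ground truth
that later steps are scored against.
"""

from pathlib import Path

from lenspg.config import PipelineConfig, save_config
from lenspg.synth import StudySizes, synthesize_study, write_study

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cfg = PipelineConfig()
    study = synthesize_study(cfg, cfg.rng_seed, StudySizes())
    paths = write_study(study, RESULTS / "study", cfg)
    save_config(cfg, RESULTS / "study" / "config.yaml")

    labels = study.truth.transcript_labels
    print(f"genome: {len(study.genome)} chromosomes, "
          f"{sum(map(len, study.genome.values())):,} b")
    print(f"annotation: {len(study.genes)} genes / proteins")
    for cat in ("annotated", "novel", "semi-novel"):
        print(f"assembled {cat}: {sum(v == cat for v in labels.values())}")
    print(f"splicing events planted: {len(study.truth.planted_as_events)}")
    print(f"novel peptides planted: {len(study.truth.planted_novel_peptides)}")
    print(f"spectra: {len(study.spectra)}")
    for name, p in paths.items():
        print(f"  wrote {name}: {p}")


if __name__ == "__main__":
    main()
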