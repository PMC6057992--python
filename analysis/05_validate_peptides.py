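"""Validate called novel peptides against synthetic-peptide spectra.

For every peptide in the report from 04, simulates the spectrum its
commercially synthesized (TMT-labeled) counterpart would produce, compares
it with an endogenous spectrum of the same peptide (matched-ion fraction +
cosine on co-matched intensities), and writes the verdict table plus
plot-ready mirrored-spectrum data for the first few peptides.
"""

from pathlib import Path

import pandas as pd

from lenspg.config import load_config
from lenspg.synth import read_mgf, simulate_spectra
from lenspg.validate import compare_spectra, mirror_plot_data

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cfg = load_config(RESULTS / "study" / "config.yaml")
    table3 = pd.read_csv(RESULTS / "table3_novel_peptides.tsv", sep="\t")
    peptides = list(table3["Novel Peptide"])
    psms = pd.read_csv(RESULTS / "psms.tsv", sep="\t")
    spectra = {s.id: s for s in read_mgf(RESULTS / "study" / "spectra.mgf")}

    best_psm = (psms[~psms["is_decoy"]]
                .sort_values("xcorr", ascending=False)
                .drop_duplicates("peptide")
                .set_index("peptide"))
    synthetic = simulate_spectra(peptides, cfg, cfg.rng_seed + 9999,
                                 id_prefix="synthetic")
    rows = []
    for pep, syn in zip(peptides, synthetic):
        endo = spectra[best_psm.loc[pep, "spectrum_id"]]
        res = compare_spectra(endo, syn.as_spectrum(), pep, cfg)
        rows.append({
            "peptide": pep, "endogenous": res.endogenous_id,
            "synthetic": res.synthetic_id,
            "matched_fragment_fraction": round(res.matched_fragment_fraction, 3),
            "cosine_similarity": round(res.cosine_similarity, 3),
            "verdict": res.verdict,
        })
        if len(rows) <= 3:
            mirror = pd.DataFrame(mirror_plot_data(endo, syn.as_spectrum(), pep, cfg))
            mirror.to_csv(RESULTS / f"mirror_{pep}.csv", index=False)
    out = pd.DataFrame(rows)
    out.to_csv(RESULTS / "validation.tsv", sep="\t", index=False)
    n_ok = (out["verdict"] == "consistent").sum()
    print(out.head(10).to_string(index=False))
    print(f"\n{n_ok}/{len(out)} novel peptides consistent with their "
          f"synthetic-peptide spectra")


if __name__ == "__main__":
    main()
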