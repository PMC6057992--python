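"""Synthetic-peptide spectrum validation.

A novel peptide's endogenous spectrum is compared against the spectrum of a
commercially synthesized copy of the same sequence. The manual "similar
fragmentation pattern" judgement is replaced by two explicit statistics: the
fraction of the theoretical b/y ladder found in *both* spectra within the
fragment tolerance, and the cosine similarity of the intensities of those
co-matched ions. The verdict is ``consistent`` iff both statistics meet
their configured thresholds (defaults 0.5 and 0.7). Synthetic peptides were
TMT-labeled, so ladders are computed with the label applied whenever the
configuration enables it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import PipelineConfig
from .search import Peptide, Spectrum, generate_fragments


@dataclass
class SpectrumComparison:
    peptide: str
    endogenous_id: str
    synthetic_id: str
    matched_fragment_fraction: float
    cosine_similarity: float
    verdict: str  # "consistent" | "inconsistent"
    matched_ions: tuple[str, ...] = ()


def _match_ladder(spectrum: Spectrum, ladder, tol: float):
    """For each theoretical ion, the intensity of the nearest peak within tol
    (or None)."""
    out = {}
    mz = spectrum.mz
    for label, ion_mz in ladder:
        i = np.searchsorted(mz, ion_mz)
        cand = [j for j in (i - 1, i) if 0 <= j < mz.size]
        best = None
        for j in cand:
            if abs(mz[j] - ion_mz) <= tol:
                if best is None or spectrum.intensity[j] > best:
                    best = float(spectrum.intensity[j])
        out[label] = best
    return out


def compare_spectra(endogenous: Spectrum, synthetic: Spectrum, peptide: str,
                    cfg: PipelineConfig) -> SpectrumComparison:
    """Quantitative fragmentation-pattern comparison (symmetric in inputs)."""
    if endogenous.mz.size == 0 or synthetic.mz.size == 0:
        raise ValueError("cannot compare empty spectra")
    charge = max(endogenous.charge, synthetic.charge)
    ladder = generate_fragments(Peptide(peptide), cfg, charge=charge)
    m_end = _match_ladder(endogenous, ladder, cfg.fragment_tol_da)
    m_syn = _match_ladder(synthetic, ladder, cfg.fragment_tol_da)
    co = [label for label, _ in ladder
          if m_end[label] is not None and m_syn[label] is not None]
    fraction = len(co) / len(ladder)
    if co:
        a = np.array([m_end[l] for l in co])
        b = np.array([m_syn[l] for l in co])
        denom = np.linalg.norm(a) * np.linalg.norm(b)
        cosine = float(a @ b / denom) if denom > 0 else 0.0
    else:
        cosine = 0.0
    ok = fraction >= cfg.validate_min_fraction and cosine >= cfg.validate_min_cosine
    return SpectrumComparison(
        peptide=peptide,
        endogenous_id=endogenous.id,
        synthetic_id=synthetic.id,
        matched_fragment_fraction=fraction,
        cosine_similarity=cosine,
        verdict="consistent" if ok else "inconsistent",
        matched_ions=tuple(co),
    )


def mirror_plot_data(endogenous: Spectrum, synthetic: Spectrum, peptide: str,
                     cfg: PipelineConfig):
    """Plot-ready rows (m/z, signed intensity, ion label) for a mirrored
    spectrum figure: endogenous up, synthetic down."""
    charge = max(endogenous.charge, synthetic.charge)
    ladder = generate_fragments(Peptide(peptide), cfg, charge=charge)
    labels = {}
    for label, ion_mz in ladder:
        labels[round(ion_mz / cfg.fragment_tol_da)] = label
    rows = []
    for spec, sign, which in ((endogenous, 1.0, "endogenous"), (synthetic, -1.0, "synthetic")):
        top = spec.intensity.max() or 1.0
        for m, i in zip(spec.mz, spec.intensity):
            rows.append({
                "spectrum": which,
                "mz": float(m),
                "intensity": sign * float(i) / top,
                "ion": labels.get(round(m / cfg.fragment_tol_da), ""),
            })
    return rows
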