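"""In-silico peptide-spectrum matching against the theoretical database.

Tryptic digestion (cleavage C-terminal to K/R, suppressed before proline, up
to a configurable number of missed cleavages), monoisotopic mass arithmetic
with fixed and variable modifications, b/y fragment ladders, a SEQUEST-style
cross-correlation (XCorr) score, and plain target-decoy FDR filtering with
q-values. Decoys are full-protein reversals digested identically.

The XCorr follows the fast cross-correlation construction: square-rooted
intensities, ten-region normalization of the observed spectrum to a maximum
of 50, binning at the fragment tolerance, and subtraction of the mean
correlation over background lags within +/-75 bins; the final score is the
matched sum divided by 1e4, which puts a confident match of a ~10-residue
peptide in the 3-5 range familiar from SEQUEST output.
"""

from __future__ import annotations

import itertools
import logging
import re
from dataclasses import dataclass, field, replace

import numpy as np

from .config import ModificationSpec, PipelineConfig
from .orfdb import TheoreticalProtein

log = logging.getLogger(__name__)

PROTON = 1.00727646688
WATER = 18.0105646863

#: Monoisotopic residue masses (Da).
RESIDUE_MASS = {
    "G": 57.02146372, "A": 71.03711378, "S": 87.03202840, "P": 97.05276385,
    "V": 99.06841391, "T": 101.04767847, "C": 103.00918478, "L": 113.08406398,
    "I": 113.08406398, "N": 114.04292744, "D": 115.02694302, "Q": 128.05857751,
    "K": 128.09496301, "E": 129.04259309, "M": 131.04048491, "H": 137.05891186,
    "F": 147.06841391, "R": 156.10111102, "Y": 163.06332853, "W": 186.07931295,
}


@dataclass(frozen=True)
class Peptide:
    """A (possibly modified) digestion product.

    ``mods`` holds (position, spec) pairs where position is a 0-based residue
    index or the token ``"N-term"`` / ``"C-term"``.
    """

    sequence: str
    mods: tuple[tuple[object, ModificationSpec], ...] = ()
    missed_cleavages: int = 0
    parents: frozenset[str] = frozenset()

    def __post_init__(self):
        bad = set(self.sequence) - set(RESIDUE_MASS)
        if bad:
            raise ValueError(f"peptide {self.sequence}: unknown residue(s) {sorted(bad)}")


@dataclass
class Spectrum:
    """A centroided fragment spectrum."""

    id: str
    precursor_mz: float
    charge: int
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        order = np.argsort(self.mz)
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]

    @property
    def neutral_mass(self) -> float:
        return (self.precursor_mz - PROTON) * self.charge


@dataclass
class PeptideSpectrumMatch:
    spectrum_id: str
    peptide: Peptide
    charge: int
    xcorr: float
    precursor_error_ppm: float
    is_decoy: bool
    q_value: float = float("nan")
    retained: bool = False


# ---------------------------------------------------------------------------
# Digestion
# ---------------------------------------------------------------------------

def cleave(sequence: str) -> list[str]:
    """Fully tryptic base segments: cut after K/R unless followed by P."""
    pieces = re.split(r"(?<=[KR])(?!P)", sequence)
    return [p for p in pieces if p]


def digest(sequence: str, cfg: PipelineConfig, parent: str = "") -> list[Peptide]:
    """All tryptic products with 0..max_missed_cleavages internal sites and
    length >= min_peptide_len."""
    segments = cleave(sequence)
    out = []
    for i in range(len(segments)):
        for mc in range(cfg.max_missed_cleavages + 1):
            if i + mc >= len(segments):
                break
            pep = "".join(segments[i:i + mc + 1])
            if len(pep) >= cfg.min_peptide_len:
                out.append(Peptide(pep, missed_cleavages=mc,
                                   parents=frozenset({parent} if parent else ())))
    return out


# ---------------------------------------------------------------------------
# Mass arithmetic and fragment ladders
# ---------------------------------------------------------------------------

def _mod_deltas(p: Peptide, cfg: PipelineConfig) -> tuple[np.ndarray, float, float]:
    """Per-residue, N-terminal and C-terminal mass deltas.

    Fixed modifications from the config (including the TMT label when
    enabled) are applied implicitly; the peptide's own ``mods`` list adds the
    variable ones.
    """
    n = len(p.sequence)
    deltas = np.zeros(n)
    nterm = cterm = 0.0
    for spec in cfg.active_fixed_mods():
        for tgt in spec.targets:
            if tgt == "N-term":
                nterm += spec.delta_mass
            elif tgt == "C-term":
                cterm += spec.delta_mass
            else:
                for i, aa in enumerate(p.sequence):
                    if aa == tgt:
                        deltas[i] += spec.delta_mass
    for pos, spec in p.mods:
        if pos == "N-term":
            nterm += spec.delta_mass
        elif pos == "C-term":
            cterm += spec.delta_mass
        else:
            deltas[int(pos)] += spec.delta_mass
    return deltas, nterm, cterm


def peptide_mass(p: Peptide, cfg: PipelineConfig, charge: int | None = None):
    """Monoisotopic neutral mass; with ``charge``, also the precursor m/z."""
    deltas, nterm, cterm = _mod_deltas(p, cfg)
    mass = sum(RESIDUE_MASS[aa] for aa in p.sequence) + WATER + deltas.sum() + nterm + cterm
    if charge is None:
        return mass
    return mass, (mass + charge * PROTON) / charge


def generate_fragments(p: Peptide, cfg: PipelineConfig, charge: int = 2
                       ) -> list[tuple[str, float]]:
    """Theoretical b/y ion m/z values (labels like ``b3``, ``y5++``).

    Singly charged b1..b(n-1) and y1..y(n-1); doubly charged ions are added
    when the precursor charge is >= 3.
    """
    n = len(p.sequence)
    if n < 2:
        raise ValueError("need at least 2 residues for fragments")
    deltas, nterm, cterm = _mod_deltas(p, cfg)
    res = np.array([RESIDUE_MASS[aa] for aa in p.sequence]) + deltas
    prefix = np.cumsum(res)
    total = prefix[-1]
    ions = []
    for i in range(1, n):
        b_neutral = prefix[i - 1] + nterm
        y_neutral = (total - prefix[i - 1]) + cterm + WATER
        ions.append((f"b{i}", b_neutral + PROTON))
        ions.append((f"y{n - i}", y_neutral + PROTON))
        if charge >= 3:
            ions.append((f"b{i}++", (b_neutral + 2 * PROTON) / 2))
            ions.append((f"y{n - i}++", (y_neutral + 2 * PROTON) / 2))
    return ions


# ---------------------------------------------------------------------------
# XCorr
# ---------------------------------------------------------------------------

_XCORR_LAG = 75
_XCORR_REGIONS = 10
_XCORR_HEIGHT = 50.0


def _preprocess(observed: Spectrum, bin_width: float, n_bins: int) -> np.ndarray:
    """Background-corrected binned intensity vector y' of the fast XCorr.

    The per-candidate score is then just the sum of y' over theoretical ion
    bins times the theoretical peak height, divided by 1e4.
    """
    mz = observed.mz
    inten = np.sqrt(np.maximum(observed.intensity, 0.0))
    binned = np.zeros(n_bins)
    if mz.size:
        lo, hi = mz.min(), mz.max()
        width = max(hi - lo, 1e-9)
        region = np.minimum(((mz - lo) / width * _XCORR_REGIONS).astype(int),
                            _XCORR_REGIONS - 1)
        for r in range(_XCORR_REGIONS):
            sel = region == r
            if not sel.any():
                continue
            peak = inten[sel].max()
            if peak <= 0:
                continue
            vals = inten[sel] / peak * _XCORR_HEIGHT
            idx = np.floor(mz[sel] / bin_width + 0.5).astype(int)
            keep = (idx >= 0) & (idx < n_bins)
            np.maximum.at(binned, idx[keep], vals[keep])
    # mean over lags -75..75 excluding 0
    window = 2 * _XCORR_LAG + 1
    padded = np.concatenate([np.zeros(_XCORR_LAG), binned, np.zeros(_XCORR_LAG)])
    csum = np.concatenate([[0.0], np.cumsum(padded)])
    background = (csum[window:] - csum[:-window] - binned) / (window - 1)
    return binned - background


def xcorr(observed: Spectrum, theoretical_mz, cfg: PipelineConfig,
          _cache: dict | None = None) -> float:
    """SEQUEST-style cross-correlation of one candidate against a spectrum."""
    mzs = [m for _, m in theoretical_mz] if theoretical_mz and isinstance(
        theoretical_mz[0], tuple) else list(theoretical_mz)
    if observed.mz.size == 0 or not mzs:
        return 0.0
    bin_width = cfg.fragment_tol_da
    n_bins = int(max(float(observed.mz.max()), max(mzs)) / bin_width) + _XCORR_LAG + 2
    if _cache is not None and "yprime" in _cache and len(_cache["yprime"]) >= n_bins:
        yprime = _cache["yprime"]
    else:
        yprime = _preprocess(observed, bin_width, n_bins)
        if _cache is not None:
            _cache["yprime"] = yprime
    idx = np.floor(np.asarray(mzs) / bin_width + 0.5).astype(int)
    idx = idx[(idx >= 0) & (idx < len(yprime))]
    return float(_XCORR_HEIGHT * yprime[idx].sum() / 1e4)


# ---------------------------------------------------------------------------
# Candidate generation and the search proper
# ---------------------------------------------------------------------------

def _variable_forms(p: Peptide, cfg: PipelineConfig):
    """Enumerate variable-modification placements, capped combinatorially."""
    sites: list[tuple[object, ModificationSpec]] = []
    for spec in cfg.variable_mods:
        for tgt in spec.targets:
            if tgt in ("N-term", "C-term"):
                sites.append((tgt, spec))
            else:
                sites.extend((i, spec) for i, aa in enumerate(p.sequence) if aa == tgt)
    yield p
    max_k = min(cfg.max_variable_mods, len(sites))
    for k in range(1, max_k + 1):
        for combo in itertools.combinations(sites, k):
            positions = [c[0] for c in combo]
            if len(set(positions)) != len(positions):
                continue
            yield replace(p, mods=tuple(combo))


@dataclass
class SearchDatabase:
    """Digested, mass-indexed target+decoy candidate collection."""

    candidates: list[Peptide]
    masses: np.ndarray  # sorted neutral masses, parallel to `order`
    order: np.ndarray
    is_decoy: np.ndarray

    @classmethod
    def build(cls, proteins: list[TheoreticalProtein] | list[tuple[str, str]],
              cfg: PipelineConfig) -> "SearchDatabase":
        entries = []
        for p in proteins:
            if isinstance(p, TheoreticalProtein):
                entries.append((p.id, p.sequence))
            else:
                entries.append(p)
        target_peps: dict[tuple, Peptide] = {}
        decoy_peps: dict[tuple, Peptide] = {}
        for pid, seq in entries:
            for pep in digest(seq, cfg, parent=pid):
                key = (pep.sequence,)
                if key in target_peps:
                    target_peps[key] = replace(
                        target_peps[key],
                        parents=target_peps[key].parents | pep.parents)
                else:
                    target_peps[key] = pep
        for pid, seq in entries:
            for pep in digest(seq[::-1], cfg, parent="DECOY_" + pid):
                key = (pep.sequence,)
                if (pep.sequence,) in target_peps:
                    continue  # sequence collision (e.g. palindromic) stays a target
                if key in decoy_peps:
                    decoy_peps[key] = replace(
                        decoy_peps[key],
                        parents=decoy_peps[key].parents | pep.parents)
                else:
                    decoy_peps[key] = pep

        candidates: list[Peptide] = []
        decoy_flags: list[bool] = []
        for pool, flag in ((target_peps, False), (decoy_peps, True)):
            for pep in pool.values():
                for form in _variable_forms(pep, cfg):
                    candidates.append(form)
                    decoy_flags.append(flag)
        masses = np.array([peptide_mass(c, cfg) for c in candidates])
        order = np.argsort(masses, kind="stable")
        return cls(candidates=candidates, masses=masses[order], order=order,
                   is_decoy=np.array(decoy_flags)[order])

    def lookup(self, neutral_mass: float, tol_ppm: float):
        tol = neutral_mass * tol_ppm * 1e-6
        lo = np.searchsorted(self.masses, neutral_mass - tol, side="left")
        hi = np.searchsorted(self.masses, neutral_mass + tol, side="right")
        for j in range(lo, hi):
            yield self.candidates[self.order[j]], self.masses[j], bool(self.is_decoy[j])


def search(spectra: list[Spectrum], proteins, cfg: PipelineConfig
           ) -> list[PeptideSpectrumMatch]:
    """Match every spectrum against the database within the precursor window.

    Per spectrum the best-scoring target and best-scoring decoy are retained
    (separate-competition target-decoy bookkeeping).
    """
    db = proteins if isinstance(proteins, SearchDatabase) else SearchDatabase.build(proteins, cfg)
    if not db.candidates:
        raise ValueError("empty search database")
    psms: list[PeptideSpectrumMatch] = []
    for spec in spectra:
        cache: dict = {}
        best: dict[bool, PeptideSpectrumMatch] = {}
        for pep, mass, decoy in db.lookup(spec.neutral_mass, cfg.precursor_tol_ppm):
            ions = generate_fragments(pep, cfg, charge=spec.charge)
            score = xcorr(spec, ions, cfg, _cache=cache)
            err = (spec.neutral_mass - mass) / mass * 1e6
            cur = best.get(decoy)
            if cur is None or score > cur.xcorr:
                best[decoy] = PeptideSpectrumMatch(
                    spectrum_id=spec.id, peptide=pep, charge=spec.charge,
                    xcorr=score, precursor_error_ppm=err, is_decoy=decoy)
        psms.extend(best.values())
    return psms


def fdr_filter(psms: list[PeptideSpectrumMatch], cfg: PipelineConfig
               ) -> list[PeptideSpectrumMatch]:
    """Assign target-decoy q-values on XCorr and retain q <= search_fdr_max.

    FDR at a score threshold is (#decoys >= t) / (#targets >= t); q-values
    are the running minimum of FDR from the bottom of the ranked list, so
    they are monotone non-increasing in score.
    """
    if not any(not m.is_decoy for m in psms):
        return []
    ranked = sorted(psms, key=lambda m: m.xcorr, reverse=True)
    n_targets = n_decoys = 0
    fdrs = []
    for m in ranked:
        if m.is_decoy:
            n_decoys += 1
        else:
            n_targets += 1
        fdrs.append(n_decoys / max(n_targets, 1))
    q = 0.0
    qvals = [0.0] * len(ranked)
    running = float("inf")
    for i in range(len(ranked) - 1, -1, -1):
        running = min(running, fdrs[i])
        qvals[i] = min(running, 1.0)
    retained = []
    for m, q in zip(ranked, qvals):
        m.q_value = q
        m.retained = (not m.is_decoy) and q <= cfg.search_fdr_max
        if m.retained:
            retained.append(m)
    return retained
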