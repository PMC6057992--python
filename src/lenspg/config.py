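"""Pipeline configuration: every threshold and physical constant in one place.

The defaults reproduce the published search and screening parameters for the
developing-lens study: expression gate 1.0 TPM, splicing and search FDR 0.01,
precursor/fragment mass tolerances 10 ppm / 0.02 Da, trypsin with at most two
missed cleavages, minimum peptide length 6, and the peptide novelty criterion
of >=2 amino-acid mismatches against the known proteome at XCorr >= 2.5.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = [
    "ModificationSpec",
    "PipelineConfig",
    "ConfigError",
    "load_config",
    "save_config",
    "DEFAULT_STAGES",
]

#: Developmental stages of the study, in temporal order: embryonic day 15 and
#: 18, postnatal days 0, 3, 6 and 9.
DEFAULT_STAGES = ("E15", "E18", "P0", "P3", "P6", "P9")


class ConfigError(ValueError):
    """Raised when a configuration file is malformed or violates a constraint."""


@dataclass(frozen=True)
class ModificationSpec:
    """A post-translational or chemical modification.

    Parameters
    ----------
    name : short label, e.g. ``"carbamidomethyl"``.
    delta_mass : monoisotopic mass shift in Da.
    targets : residues the modification attaches to, or the special tokens
        ``"N-term"`` / ``"C-term"``.
    fixed : fixed modifications are applied unconditionally to every target;
        variable ones are enumerated combinatorially during the search.
    """

    name: str
    delta_mass: float
    targets: tuple[str, ...]
    fixed: bool

    def __post_init__(self) -> None:
        import math

        if not math.isfinite(self.delta_mass):
            raise ConfigError(f"modification {self.name!r}: delta_mass not finite")
        if not self.targets:
            raise ConfigError(f"modification {self.name!r}: empty target set")


# Unimod monoisotopic deltas.
CARBAMIDOMETHYL = ModificationSpec("carbamidomethyl", 57.02146, ("C",), fixed=True)
OXIDATION = ModificationSpec("oxidation", 15.99491, ("M",), fixed=False)
ACETYL_NTERM = ModificationSpec("acetyl", 42.01057, ("N-term",), fixed=False)
#: Amine-reactive isobaric label used on the lens proteome and on the
#: synthetic validation peptides; attaches to the peptide N-terminus and to
#: lysine side chains.
TMT = ModificationSpec("TMT6plex", 229.162932, ("N-term", "K"), fixed=True)


@dataclass
class PipelineConfig:
    """All tunable thresholds of the pipeline, with the study's defaults."""

    tpm_min: float = 1.0
    as_fdr_max: float = 0.01
    search_fdr_max: float = 0.01
    precursor_tol_ppm: float = 10.0
    fragment_tol_da: float = 0.02
    max_missed_cleavages: int = 2
    min_peptide_len: int = 6
    novelty_min_mismatch: int = 2
    novelty_min_xcorr: float = 2.5
    stages: tuple[str, ...] = DEFAULT_STAGES
    fixed_mods: tuple[ModificationSpec, ...] = (CARBAMIDOMETHYL,)
    variable_mods: tuple[ModificationSpec, ...] = (OXIDATION, ACETYL_NTERM)
    #: The lens proteome and the synthetic peptides were TMT-labeled; the label
    #: is therefore on by default for spectrum simulation and for the search.
    tmt_labeling: bool = True
    max_variable_mods: int = 3
    #: A single-exon assembled transcript counts as "annotated" only when at
    #: least this fraction of its length lies inside one annotated exon.
    annotated_containment: float = 0.95
    #: Spectrum-validation verdict thresholds (matched-ion fraction, cosine).
    validate_min_fraction: float = 0.5
    validate_min_cosine: float = 0.7
    rng_seed: int = 17

    def __post_init__(self) -> None:
        self.stages = tuple(self.stages)
        self.fixed_mods = tuple(self.fixed_mods)
        self.variable_mods = tuple(self.variable_mods)
        self.validate()

    def validate(self) -> None:
        positive = {
            "tpm_min": self.tpm_min,
            "as_fdr_max": self.as_fdr_max,
            "search_fdr_max": self.search_fdr_max,
            "precursor_tol_ppm": self.precursor_tol_ppm,
            "fragment_tol_da": self.fragment_tol_da,
            "novelty_min_xcorr": self.novelty_min_xcorr,
        }
        for key, value in positive.items():
            if not value > 0:
                raise ConfigError(f"{key} must be strictly positive, got {value}")
        if self.min_peptide_len < 1:
            raise ConfigError(f"min_peptide_len must be >= 1, got {self.min_peptide_len}")
        if self.max_missed_cleavages < 0:
            raise ConfigError("max_missed_cleavages must be >= 0")
        if self.novelty_min_mismatch < 0:
            raise ConfigError("novelty_min_mismatch must be >= 0")
        if len(set(self.stages)) != len(self.stages):
            raise ConfigError("stage labels must be unique")

    # -- modification helpers -------------------------------------------------

    def active_fixed_mods(self) -> tuple[ModificationSpec, ...]:
        """Fixed modifications including the TMT label when enabled."""
        mods = self.fixed_mods
        if self.tmt_labeling:
            mods = mods + (TMT,)
        return mods

    # -- (de)serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        d["fixed_mods"] = [_mod_to_dict(m) for m in self.fixed_mods]
        d["variable_mods"] = [_mod_to_dict(m) for m in self.variable_mods]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown configuration key(s): {sorted(unknown)}")
        for key in ("fixed_mods", "variable_mods"):
            if key in d:
                d[key] = tuple(_mod_from_dict(m, key) for m in d[key])
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        try:
            return cls(**d)
        except TypeError as exc:  # pragma: no cover - defensive
            raise ConfigError(str(exc)) from exc


def _mod_to_dict(m: ModificationSpec) -> dict:
    return {
        "name": m.name,
        "delta_mass": m.delta_mass,
        "targets": list(m.targets),
        "fixed": m.fixed,
    }


def _mod_from_dict(d: dict, context: str) -> ModificationSpec:
    if isinstance(d, ModificationSpec):
        return d
    try:
        return ModificationSpec(
            name=d["name"],
            delta_mass=float(d["delta_mass"]),
            targets=tuple(d["targets"]),
            fixed=bool(d["fixed"]),
        )
    except KeyError as exc:
        raise ConfigError(f"{context}: modification missing key {exc}") from exc


def load_config(path: str | Path) -> PipelineConfig:
    """Read a YAML config file; absent keys take the study defaults."""
    text = Path(path).read_text()
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse config file {path}: {exc}") from exc
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"config file {path} must contain a mapping")
    return PipelineConfig.from_dict(data)


def save_config(cfg: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))
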