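"""Pipeline configuration: flat YAML key/value files with strict validation."""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Optional

import yaml

from .resources import data_path

__all__ = ["PipelineConfig", "ConfigError", "load_config", "default_config"]

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Raised for unknown keys or missing referenced files."""


_PATH_KEYS = (
    "enzyme_lexicon",
    "taxon_lexicon",
    "substrate_lexicon",
    "assay_lexicon",
    "ase_stoplist",
    "organism_blocklist",
    "host_cues",
    "generic_organism_cues",
    "sentence_abbreviations",
    "cue_activity_stability",
    "cue_kinetic",
    "cue_assay_conditions",
    "cue_glycosylation",
    "cue_specificity",
    "cue_product",
)


@dataclass
class PipelineConfig:
    enzyme_lexicon: str = "lexicons/enzymes.tsv"
    taxon_lexicon: str = "lexicons/taxa.tsv"
    substrate_lexicon: str = "lexicons/substrates.tsv"
    assay_lexicon: str = "lexicons/assays.tsv"
    ase_stoplist: str = "lists/ase_stoplist.txt"
    organism_blocklist: str = "lists/organism_blocklist.txt"
    host_cues: str = "lists/host_cues.txt"
    generic_organism_cues: str = "lists/generic_organism_cues.txt"
    sentence_abbreviations: str = "lists/sentence_abbreviations.txt"
    cue_activity_stability: str = "cues/activity_stability.txt"
    cue_kinetic: str = "cues/kinetic.txt"
    cue_assay_conditions: str = "cues/assay_conditions.txt"
    cue_glycosylation: str = "cues/glycosylation.txt"
    cue_specificity: str = "cues/specificity.txt"
    cue_product: str = "cues/product.txt"
    enzyme_url_template: str = "https://www.brenda-enzymes.org/enzyme.php?ecno={ec}"
    taxon_url_template: str = (
        "https://www.ncbi.nlm.nih.gov/Taxonomy/Browser/wwwtax.cgi?id={taxid}"
    )
    generic_organism_mentions: bool = True
    host_detection: bool = True
    rdf_format: str = "turtle"

    def resolve(self, key: str) -> Path:
        """Resolve a path-valued key against the packaged data directory."""
        value = getattr(self, key)
        p = Path(value)
        if p.is_absolute() or p.exists():
            return p
        return data_path(value)

    def validate(self) -> None:
        for key in _PATH_KEYS:
            try:
                path = self.resolve(key)
            except FileNotFoundError as exc:
                raise ConfigError(f"{key}: {exc}") from exc
            if not path.exists():
                raise ConfigError(f"{key}: file not found: {path}")


def default_config() -> PipelineConfig:
    cfg = PipelineConfig()
    cfg.validate()
    return cfg


def load_config(path: Optional[str] = None) -> PipelineConfig:
    """Load configuration from a flat YAML file (defaults when path is None)."""
    if path is None:
        return default_config()
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a flat key/value mapping")
    known = {f.name for f in fields(PipelineConfig)}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ConfigError(f"{path}: unknown config keys: {unknown}")
    base = Path(path).parent
    cfg = PipelineConfig()
    for key, value in raw.items():
        if key in _PATH_KEYS and isinstance(value, str):
            candidate = base / value
            if not Path(value).is_absolute() and candidate.exists():
                value = str(candidate)
        setattr(cfg, key, value)
    cfg.validate()
    return cfg
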