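"""Pipeline configuration.

A flat key-value document (YAML on disk) holding the parse conventions for
MaxQuant-style protein-group tables and the analysis thresholds. Defaults equal
the printed values used throughout the analysis: proteins are *enriched* by an
antibody at z >= 3, *interactors* at z >= 5 with raw LFQ intensity >= 1e7, and
*plasma background contaminants* at a frequency of identification f > 0.20.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import yaml

from .errors import SchemaError

SD_CONVENTIONS = ("population", "sample")
SCALES = ("log10", "raw")


@dataclasses.dataclass(frozen=True)
class PipelineConfig:
    # -- parsing the protein-group table (MaxQuant proteinGroups dialect) --
    lfq_prefix: str = "LFQ intensity "
    protein_id_column: str = "Majority protein IDs"
    gene_column: str = "Gene names"
    species_column: str = "Species"
    contaminant_column: str = "Potential contaminant"
    # gene-symbol prefixes identifying human immunoglobulin variable chains
    ig_variable_prefixes: tuple[str, ...] = ("IGHV", "IGKV", "IGLV")

    # -- analysis thresholds --
    z_enriched: float = 3.0
    z_interactor: float = 5.0
    intensity_interactor: float = 1e7  # raw LFQ scale
    freq_contaminant: float = 0.20     # strict ">" rule

    # -- numerical conventions --
    sd_convention: str = "population"  # "population" (divide by n) or "sample" (n-1)
    scale: str = "log10"               # intensity scale for population stats and z

    def validate(self) -> "PipelineConfig":
        if self.sd_convention not in SD_CONVENTIONS:
            raise SchemaError(
                f"sd_convention must be one of {SD_CONVENTIONS}, got {self.sd_convention!r}"
            )
        if self.scale not in SCALES:
            raise SchemaError(f"scale must be one of {SCALES}, got {self.scale!r}")
        if self.z_interactor < self.z_enriched:
            raise SchemaError("z_interactor must be >= z_enriched")
        if not (0 <= self.freq_contaminant <= 1):
            raise SchemaError("freq_contaminant must lie in [0, 1]")
        if self.intensity_interactor <= 0:
            raise SchemaError("intensity_interactor must be positive")
        return self

    @property
    def ddof(self) -> int:
        return 0 if self.sd_convention == "population" else 1

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["ig_variable_prefixes"] = list(self.ig_variable_prefixes)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        if "ig_variable_prefixes" in d:
            d = {**d, "ig_variable_prefixes": tuple(d["ig_variable_prefixes"])}
        return cls(**d).validate()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh) or {}
        if not isinstance(doc, dict):
            raise SchemaError(f"config file {path} must hold a flat mapping")
        return cls.from_dict(doc)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def content_hash(self) -> str:
        """Stable hash of the configuration, recorded in run manifests."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
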