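"""Reading and writing LFQ protein-group tables and IP metadata.

The on-disk dialect mirrors MaxQuant ``proteinGroups.txt``: one row per protein
group, a ``Majority protein IDs`` column with ';'-separated accessions, a
``Gene names`` column, an optional per-accession ``Species`` column, a
``Potential contaminant`` flag column ('+' when flagged), and one
``LFQ intensity <ip>`` column per immunoprecipitation. Missing intensity cells
are read as 0, the convention for values below the limit of detection.

In memory the matrix is an :class:`LfqMatrix`: a protein annotation frame plus
a dense proteins x IPs intensity frame. IP metadata is a validated pandas
DataFrame with one row per IP (antibody, intended targets, plasma treatment,
batch, replicate role, technical group).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .errors import JoinError, SchemaError

TREATMENTS = ("heat", "untreated")
REPLICATE_ROLES = ("biological", "technical")

METADATA_COLUMNS = (
    "ip_id",
    "antibody_id",
    "target_ids",
    "treatment",
    "batch",
    "replicate_role",
    "tech_group",
)

#: columns of the protein annotation frame
PROTEIN_COLUMNS = (
    "accessions",
    "gene_symbols",
    "species",
    "is_maxquant_contaminant",
    "is_ig_variable",
)


def split_ids(cell: str) -> list[str]:
    """Split a ';'-separated id cell into a list, dropping empty entries."""
    return [tok for tok in str(cell).split(";") if tok]


@dataclasses.dataclass
class LfqMatrix:
    """Protein-group x IP label-free quantification matrix.

    Attributes
    ----------
    proteins:
        Annotation frame indexed by ``group_id`` (the first accession of the
        group), with columns :data:`PROTEIN_COLUMNS`. ``accessions``,
        ``gene_symbols`` and ``species`` are ';'-joined strings.
    intensity:
        Dense float frame, rows aligned with ``proteins``, one column per IP.
        Non-negative on the raw scale.
    scale:
        ``"raw"`` or ``"log10"``; transitions only raw -> log10.
    detected:
        Boolean frame (raw LFQ > 0), recorded by the log transformation so the
        detection status survives the zero -> 1 substitution.
    """

    proteins: pd.DataFrame
    intensity: pd.DataFrame
    scale: str = "raw"
    detected: pd.DataFrame | None = None

    def __post_init__(self):
        if self.scale not in ("raw", "log10"):
            raise SchemaError(f"unknown scale {self.scale!r}")
        if not self.proteins.index.is_unique:
            dups = self.proteins.index[self.proteins.index.duplicated()].unique()
            raise SchemaError(f"duplicate protein group_id(s): {list(dups)[:5]}")
        if not self.proteins.index.equals(self.intensity.index):
            raise SchemaError("protein annotation and intensity rows do not align")
        if self.scale == "raw" and (self.intensity.to_numpy() < 0).any():
            raise SchemaError("raw-scale intensities must be non-negative")
        if self.detected is not None:
            if self.detected.shape != self.intensity.shape:
                raise SchemaError("detection mask shape mismatch")

    # -- conveniences -------------------------------------------------------
    @property
    def n_proteins(self) -> int:
        return self.intensity.shape[0]

    @property
    def n_ips(self) -> int:
        return self.intensity.shape[1]

    @property
    def ip_ids(self) -> list[str]:
        return list(self.intensity.columns)

    @property
    def group_ids(self) -> list[str]:
        return list(self.proteins.index)

    def detection_mask(self) -> pd.DataFrame:
        """Boolean detected frame; on the raw scale detection is LFQ > 0."""
        if self.detected is not None:
            return self.detected
        if self.scale != "raw":
            raise SchemaError("log10 matrix without a recorded detection mask")
        return self.intensity > 0

    def subset_ips(self, ip_ids: list[str]) -> "LfqMatrix":
        return LfqMatrix(
            proteins=self.proteins,
            intensity=self.intensity.loc[:, ip_ids],
            scale=self.scale,
            detected=None if self.detected is None else self.detected.loc[:, ip_ids],
        )

    def subset_proteins(self, group_ids: list[str]) -> "LfqMatrix":
        return LfqMatrix(
            proteins=self.proteins.loc[group_ids],
            intensity=self.intensity.loc[group_ids],
            scale=self.scale,
            detected=None if self.detected is None else self.detected.loc[group_ids],
        )


def _is_ig_variable(gene_cell: str, prefixes: tuple[str, ...]) -> bool:
    return any(
        g.upper().startswith(p) for g in split_ids(gene_cell) for p in prefixes
    )


def read_lfq_table(path: str | Path, config: PipelineConfig | None = None) -> LfqMatrix:
    """Parse a tab-separated protein-group table into a raw-scale LfqMatrix.

    Intensity columns are those whose header starts with ``config.lfq_prefix``;
    the IP id is the remainder of the header. Empty intensity cells become 0.
    Duplicate group ids and non-numeric intensity cells are hard errors.
    """
    config = config or PipelineConfig()
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if config.protein_id_column not in df.columns:
        raise SchemaError(
            f"{path}: missing protein id column {config.protein_id_column!r}"
        )

    lfq_cols = [c for c in df.columns if c.startswith(config.lfq_prefix)]
    if not lfq_cols:
        raise SchemaError(f"{path}: no columns with prefix {config.lfq_prefix!r}")
    ip_ids = [c[len(config.lfq_prefix):] for c in lfq_cols]

    accessions = df[config.protein_id_column].astype(str)
    group_ids = []
    for i, cell in enumerate(accessions):
        accs = split_ids(cell)
        if not accs:
            raise SchemaError(f"{path}: row {i}: empty accession list")
        group_ids.append(accs[0])
    index = pd.Index(group_ids, name="group_id")
    if not index.is_unique:
        dups = index[index.duplicated()].unique()
        raise SchemaError(f"{path}: duplicated group_id(s): {list(dups)}")

    genes = (
        df[config.gene_column].astype(str)
        if config.gene_column in df.columns
        else pd.Series([""] * len(df))
    )
    species = (
        df[config.species_column].astype(str)
        if config.species_column in df.columns
        else pd.Series([""] * len(df))
    )
    flagged = (
        df[config.contaminant_column].astype(str).str.strip() == "+"
        if config.contaminant_column in df.columns
        else pd.Series([False] * len(df))
    )

    proteins = pd.DataFrame(
        {
            "accessions": accessions.values,
            "gene_symbols": genes.values,
            "species": species.values,
            "is_maxquant_contaminant": flagged.values,
            "is_ig_variable": [
                _is_ig_variable(g, config.ig_variable_prefixes) for g in genes
            ],
        },
        index=index,
    )

    values = np.empty((len(df), len(lfq_cols)), dtype=float)
    for j, col in enumerate(lfq_cols):
        raw = df[col].astype(str).str.strip()
        raw = raw.where(raw != "", "0")  # missing-as-zero convention
        arr = raw.to_numpy()
        try:
            # numpy's parser is round-trip exact, unlike pandas' fast path
            values[:, j] = arr.astype(np.float64)
        except ValueError:
            for i, cell in enumerate(arr):
                try:
                    float(cell)
                except ValueError:
                    raise SchemaError(
                        f"{path}: non-numeric intensity {df[col].iloc[i]!r} "
                        f"in row {i} (group {group_ids[i]}), column {col!r}"
                    ) from None
            raise

    intensity = pd.DataFrame(values, index=index, columns=ip_ids)
    return LfqMatrix(proteins=proteins, intensity=intensity, scale="raw")


def write_lfq_table(
    matrix: LfqMatrix, path: str | Path, config: PipelineConfig | None = None
) -> None:
    """Write an LfqMatrix in the same tab-separated dialect read_lfq_table parses.

    Floats are written with shortest-round-trip repr, so write -> read is
    bit-exact on the raw scale.
    """
    config = config or PipelineConfig()
    out = pd.DataFrame(
        {
            config.protein_id_column: matrix.proteins["accessions"].values,
            config.gene_column: matrix.proteins["gene_symbols"].values,
            config.species_column: matrix.proteins["species"].values,
            config.contaminant_column: np.where(
                matrix.proteins["is_maxquant_contaminant"].values, "+", ""
            ),
        }
    )
    for ip in matrix.ip_ids:
        out[config.lfq_prefix + ip] = matrix.intensity[ip].values
    out.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read and validate the IP metadata table (one row per IP).

    Unknown treatment labels and replicate roles are rejected; an empty
    tech_group defaults to the ip_id (each IP its own technical group).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns and c != "tech_group"]
    if missing:
        raise SchemaError(f"{path}: metadata missing columns {missing}")
    if "tech_group" not in df.columns:
        df["tech_group"] = ""
    return validate_metadata(df[list(METADATA_COLUMNS)].copy())


def validate_metadata(df: pd.DataFrame) -> pd.DataFrame:
    if df["ip_id"].duplicated().any():
        dups = df.loc[df["ip_id"].duplicated(), "ip_id"].unique()
        raise SchemaError(f"duplicated ip_id(s) in metadata: {list(dups)}")
    bad_treat = sorted(set(df["treatment"]) - set(TREATMENTS))
    if bad_treat:
        raise SchemaError(
            f"unknown treatment label(s) {bad_treat}; expected one of {TREATMENTS}"
        )
    bad_role = sorted(set(df["replicate_role"]) - set(REPLICATE_ROLES))
    if bad_role:
        raise SchemaError(
            f"unknown replicate_role(s) {bad_role}; expected one of {REPLICATE_ROLES}"
        )
    if (df["antibody_id"].str.len() == 0).any():
        raise SchemaError("antibody_id must be non-empty for every IP")
    df = df.copy()
    empty_tg = df["tech_group"].str.len() == 0
    df.loc[empty_tg, "tech_group"] = df.loc[empty_tg, "ip_id"]
    return df.reset_index(drop=True)


def write_metadata(df: pd.DataFrame, path: str | Path) -> None:
    df[list(METADATA_COLUMNS)].to_csv(path, sep="\t", index=False, lineterminator="\n")


def align_metadata(matrix: LfqMatrix, metadata: pd.DataFrame) -> pd.DataFrame:
    """Check matrix IPs and metadata rows describe the same IP set.

    Returns the metadata reordered to the matrix column order; mismatches are a
    JoinError naming the offending ids.
    """
    mat_ids = set(matrix.ip_ids)
    meta_ids = set(metadata["ip_id"])
    only_meta = sorted(meta_ids - mat_ids)
    only_mat = sorted(mat_ids - meta_ids)
    if only_meta or only_mat:
        raise JoinError(
            f"IP id mismatch: metadata-only={only_meta[:10]}, matrix-only={only_mat[:10]}"
        )
    return (
        metadata.set_index("ip_id").loc[matrix.ip_ids].reset_index()
    )
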