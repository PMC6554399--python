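"""Treatment-stratified frequencies, population statistics and antibody z-scores.

The analysis matrix is split by plasma pre-treatment (heat / untreated) and
each stratum is treated as its own population of IPs. Per protein ``x`` and
stratum:

* frequency of identification  f = (# IPs with raw LFQ > 0) / n_ips
* population mean mu_p and standard deviation s_p of the log10 intensities
  over *all* IPs of the stratum (non-detections enter as 0)
* per antibody, the biological replicates are merged by averaging the log10
  intensities, but only for proteins detected in every replicate of that
  antibody; all others are disregarded
* the antibody-related z-score  z_x = (LFQint_x - mu_p) / s_p  where
  LFQint_x is the merged intensity.

A protein is *enriched* by an antibody when z >= 3 (inclusive). Proteins with
s_p = 0 carry no enrichment information and receive no z-score.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .errors import PlasmaIpError, SchemaError
from .io import TREATMENTS, LfqMatrix

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class TreatmentStratum:
    """All IPs performed with one plasma pre-treatment."""

    treatment: str
    matrix: LfqMatrix
    metadata: pd.DataFrame  # rows restricted to this stratum, matrix column order

    @property
    def n_ips(self) -> int:
        return self.matrix.n_ips


@dataclasses.dataclass
class PopulationStats:
    """Per-protein mean/sd of intensities over all IPs of one stratum."""

    treatment: str
    mu: pd.Series
    sd: pd.Series

    @property
    def constant(self) -> pd.Series:
        """Proteins with zero spread (no z-score can be assigned)."""
        return self.sd == 0


@dataclasses.dataclass
class EnrichmentTable:
    """Long-format (antibody, protein) table for one stratum.

    Columns: antibody_id, protein, merged_intensity (log10; NaN when the
    protein was not detected in all replicates of the antibody), z (NaN when
    merged_intensity is NaN or s_p = 0), f (frequency of identification).
    """

    treatment: str
    data: pd.DataFrame

    def z_wide(self) -> pd.DataFrame:
        return self.data.pivot(index="protein", columns="antibody_id", values="z")

    def for_antibody(self, antibody_id: str) -> pd.DataFrame:
        return self.data[self.data["antibody_id"] == antibody_id]


def split_by_treatment(
    matrix: LfqMatrix, metadata: pd.DataFrame
) -> dict[str, TreatmentStratum]:
    """Partition the IP columns into treatment strata.

    Every IP must carry a treatment label (guaranteed by metadata validation).
    Only treatments that actually occur appear in the result; requesting an
    absent stratum is the caller's KeyError.
    """
    meta = metadata.set_index("ip_id").loc[matrix.ip_ids].reset_index()
    strata: dict[str, TreatmentStratum] = {}
    for treatment in TREATMENTS:
        ips = [
            ip
            for ip, t in zip(meta["ip_id"], meta["treatment"])
            if t == treatment
        ]
        if not ips:
            continue
        strata[treatment] = TreatmentStratum(
            treatment=treatment,
            matrix=matrix.subset_ips(ips),
            metadata=meta[meta["ip_id"].isin(ips)].reset_index(drop=True),
        )
    total = sum(s.n_ips for s in strata.values())
    assert total == matrix.n_ips
    return strata


def compute_frequency(stratum: TreatmentStratum) -> pd.Series:
    """Frequency of identification per protein: detections / n_ips in [0, 1]."""
    detected = stratum.matrix.detection_mask()
    return detected.sum(axis=1) / stratum.n_ips


def compute_population_stats(
    stratum: TreatmentStratum, config: PipelineConfig | None = None
) -> PopulationStats:
    """Per-protein mu_p and s_p over all IPs of the stratum (zeros included).

    Requires n_ips >= 2 (s_p is undefined on a single IP) and the configured
    intensity scale. The sd denominator follows ``config.sd_convention``
    (population, i.e. divide by n, by default).
    """
    config = config or PipelineConfig()
    if stratum.n_ips < 2:
        raise SchemaError(
            f"stratum {stratum.treatment!r} has {stratum.n_ips} IP(s); "
            "population statistics need at least 2"
        )
    if stratum.matrix.scale != config.scale:
        raise SchemaError(
            f"stratum matrix on scale {stratum.matrix.scale!r}, "
            f"config requires {config.scale!r}"
        )
    values = stratum.matrix.intensity
    mu = values.mean(axis=1)
    sd = values.std(axis=1, ddof=config.ddof)
    n_const = int((sd == 0).sum())
    if n_const:
        logger.info(
            "%s stratum: %d protein(s) with zero spread (no z-score)",
            stratum.treatment, n_const,
        )
    return PopulationStats(treatment=stratum.treatment, mu=mu, sd=sd)


def per_ip_zscores(stratum: TreatmentStratum, stats: PopulationStats) -> pd.DataFrame:
    """Z-scores of the raw (un-merged) IP columns against the stratum stats.

    Rows with s_p = 0 are NaN. For s_p > 0 these scores have mean 0 and sd 1
    (population convention) by construction.
    """
    if stats.treatment != stratum.treatment:
        raise PlasmaIpError("population stats from a different stratum")
    sd = stats.sd.replace(0, np.nan)
    return stratum.matrix.intensity.sub(stats.mu, axis=0).div(sd, axis=0)


def merge_biological_replicates(stratum: TreatmentStratum) -> pd.DataFrame:
    """Merge each antibody's biological replicates within the stratum.

    Returns a proteins x antibodies frame of merged intensities: the mean of
    the (log10) intensities over the antibody's replicate IPs, defined only
    where the protein was detected (raw LFQ > 0) in *every* replicate; NaN
    otherwise.
    """
    detected = stratum.matrix.detection_mask()
    antibody_of = stratum.metadata.set_index("ip_id")["antibody_id"]
    groups = antibody_of.loc[stratum.matrix.ip_ids]
    mean = stratum.matrix.intensity.T.groupby(groups).mean().T
    all_detected = detected.T.groupby(groups).all().T
    merged = mean.where(all_detected)
    merged.columns.name = "antibody_id"
    return merged


def compute_zscores(
    merged: pd.DataFrame,
    stats: PopulationStats,
    frequency: pd.Series | None = None,
    treatment: str | None = None,
) -> EnrichmentTable:
    """Antibody-related z-scores: z = (merged - mu_p) / s_p.

    NaN wherever the merged intensity is undefined or s_p = 0. ``merged`` and
    ``stats`` must come from the same stratum (same protein universe; the
    treatment tag is checked when given).
    """
    treatment = treatment or stats.treatment
    if treatment != stats.treatment:
        raise PlasmaIpError(
            f"stratum mismatch: merged profiles {treatment!r} vs stats {stats.treatment!r}"
        )
    if not merged.index.equals(stats.mu.index):
        raise PlasmaIpError("stratum mismatch: protein universes differ")
    sd = stats.sd.replace(0, np.nan)
    z = merged.sub(stats.mu, axis=0).div(sd, axis=0)

    long = merged.stack(future_stack=True).rename("merged_intensity").reset_index()
    long.columns = ["protein", "antibody_id", "merged_intensity"]
    long["z"] = z.stack(future_stack=True).reset_index(drop=True)
    if frequency is not None:
        long["f"] = frequency.reindex(long["protein"]).to_numpy()
    long = long[["antibody_id", "protein", "merged_intensity", "z"]
                + (["f"] if frequency is not None else [])]
    return EnrichmentTable(treatment=treatment, data=long)


def call_enriched(
    table: EnrichmentTable, z_min: float = 3.0
) -> dict[str, pd.DataFrame]:
    """Per-antibody enriched proteins: rows with z >= z_min (inclusive).

    Antibodies with no defined z at all map to an empty frame.
    """
    hits = table.data[table.data["z"] >= z_min]
    out: dict[str, pd.DataFrame] = {
        ab: df.reset_index(drop=True) for ab, df in hits.groupby("antibody_id")
    }
    for ab in table.data["antibody_id"].unique():
        out.setdefault(
            ab, table.data.iloc[0:0].reset_index(drop=True)
        )
    return out
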