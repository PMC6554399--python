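"""Filtering, technical-replicate selection and the log10 transformation.

Three protein-exclusion rules produce the analysis-ready protein set:
(i) MaxQuant-contaminant-flagged groups that are not human, (ii) rabbit Ig
gamma chain C region (rabbit IgG is spiked into the assay buffer, so it is
always present), and (iii) human immunoglobulin variable-chain groups. The
rules are independent, so the retained set does not depend on application
order.

Technical replicates (repeated MS injections of the same IP, sharing a
``tech_group``) are collapsed by keeping the injection with the highest median
LFQ intensity over all proteins; the rest are dropped. Medians are computed on
the raw scale — log10 is monotone, so the selected injection is the same on
either scale.

Zeros (below limit of detection) are substituted with 1 before log10, so a
non-detection maps to a transformed intensity of exactly 0. The original
detection status (raw LFQ > 0) is kept as a boolean mask alongside the matrix.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import SchemaError
from .io import LfqMatrix, split_ids

logger = logging.getLogger(__name__)


def select_technical_replicate(
    matrix: LfqMatrix, metadata: pd.DataFrame
) -> tuple[LfqMatrix, pd.DataFrame]:
    """Keep one IP column per tech_group: the member with the highest median
    intensity over all proteins. Ties keep the lexicographically smallest
    ip_id. Groups of any size are allowed (singletons pass through unchanged).

    Returns the reduced matrix and the metadata restricted to the kept IPs.
    """
    meta = metadata.set_index("ip_id")
    medians = matrix.intensity.median(axis=0)
    keep: list[str] = []
    for _, group in meta.groupby("tech_group", sort=False):
        members = [ip for ip in matrix.ip_ids if ip in set(group.index)]
        if not members:
            continue
        med = medians[members]
        best = min(ip for ip in members if med[ip] == med.max())
        keep.append(best)
        dropped = [ip for ip in members if ip != best]
        if dropped:
            logger.info("tech_group %s: kept %s, dropped %s",
                        group["tech_group"].iloc[0] if "tech_group" in group else best,
                        best, dropped)
    # preserve original column order
    keep_ordered = [ip for ip in matrix.ip_ids if ip in set(keep)]
    reduced = matrix.subset_ips(keep_ordered)
    meta_kept = metadata[metadata["ip_id"].isin(keep_ordered)].reset_index(drop=True)
    return reduced, meta_kept


def _is_human(species_cell: str) -> bool:
    """A group counts as human if any accession is annotated Homo sapiens, or
    if no species annotation is present (assumed human)."""
    species = split_ids(species_cell)
    if not species:
        return True
    return any("homo sapiens" in s.lower() for s in species)


def _is_rabbit_ig_gamma(species_cell: str, gene_cell: str) -> bool:
    rabbit = any("oryctolagus" in s.lower() for s in split_ids(species_cell))
    ig_gamma = any(g.upper().startswith("IGHG") for g in split_ids(gene_cell))
    return rabbit and ig_gamma


def contaminant_protein_mask(matrix: LfqMatrix) -> pd.Series:
    """Boolean mask of protein groups removed by the three exclusion rules."""
    prot = matrix.proteins
    human = prot["species"].map(_is_human)
    rule_nonhuman_contaminant = prot["is_maxquant_contaminant"] & ~human
    rule_rabbit_igg = pd.Series(
        [
            _is_rabbit_ig_gamma(s, g)
            for s, g in zip(prot["species"], prot["gene_symbols"])
        ],
        index=prot.index,
    )
    rule_ig_variable = prot["is_ig_variable"] & human
    return rule_nonhuman_contaminant | rule_rabbit_igg | rule_ig_variable


def filter_contaminant_proteins(matrix: LfqMatrix) -> LfqMatrix:
    """Drop the excluded protein groups, preserving row order. Human proteins
    on the MaxQuant contaminant list are retained (the rule applies only to
    non-human entries)."""
    drop = contaminant_protein_mask(matrix)
    kept = [g for g, d in zip(matrix.group_ids, drop) if not d]
    if not kept:
        logger.warning("all protein groups removed by contaminant filtering")
    return matrix.subset_proteins(kept)


def impute_and_log(matrix: LfqMatrix) -> LfqMatrix:
    """Substitute LFQ = 0 with 1, then log10-transform.

    A non-detection therefore becomes exactly 0.0 on the transformed scale.
    The detection mask (raw LFQ > 0) is recorded on the result. Raw scale and
    non-negative input are preconditions.
    """
    if matrix.scale != "raw":
        raise SchemaError("impute_and_log expects a raw-scale matrix")
    values = matrix.intensity.to_numpy()
    if (values < 0).any():
        raise SchemaError("negative LFQ intensity encountered")
    if ((values > 0) & (values < 1)).any():
        # the 0 -> 1 substitution assumes 1 lies below any detected intensity;
        # a positive value under 1 would break the order of the transform
        raise SchemaError("positive LFQ intensity below 1 encountered")
    detected = values > 0
    transformed = np.log10(np.where(detected, values, 1.0))
    return LfqMatrix(
        proteins=matrix.proteins,
        intensity=pd.DataFrame(
            transformed, index=matrix.intensity.index, columns=matrix.intensity.columns
        ),
        scale="log10",
        detected=pd.DataFrame(
            detected, index=matrix.intensity.index, columns=matrix.intensity.columns
        ),
    )
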