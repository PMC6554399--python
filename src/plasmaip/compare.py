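"""Heat-treated vs untreated comparison and batch QC.

Comparisons mirror the resource-level questions: do the two plasma
preparations identify the same proteins at similar frequencies (rank
correlation of f, per-protein delta-f), and do the common background
contaminants shift in enrichment (delta of mean and max antibody z-scores)?
Batch QC is a per-protein Kruskal-Wallis rank test of intensities across
experimental batches within a stratum, Bonferroni-adjusted.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .enrichment import EnrichmentTable, TreatmentStratum
from .errors import PlasmaIpError, SchemaError

logger = logging.getLogger(__name__)


def compare_frequencies(
    freq_a: pd.Series, freq_b: pd.Series
) -> tuple[pd.DataFrame, float, float]:
    """Per-protein frequency comparison between two strata.

    Proteins absent from one stratum's universe enter with f = 0. Returns the
    per-protein table (f_a, f_b, delta_f = f_a - f_b) over the union of
    protein universes, plus the Spearman rank correlation (average ranks on
    ties) and its p-value. An empty union is an error.
    """
    union = freq_a.index.union(freq_b.index)
    if len(union) == 0:
        raise SchemaError("no proteins shared between strata")
    a = freq_a.reindex(union, fill_value=0.0)
    b = freq_b.reindex(union, fill_value=0.0)
    table = pd.DataFrame({"f_a": a, "f_b": b, "delta_f": a - b})
    table.index.name = "protein"
    if len(union) < 2 or a.nunique() == 1 or b.nunique() == 1:
        rho, pval = np.nan, np.nan
    else:
        rho, pval = sps.spearmanr(a, b)
    return table, float(rho), float(pval)


def z_summaries(table: EnrichmentTable) -> pd.DataFrame:
    """Per-protein mean and max of the *defined* z values across antibodies."""
    grouped = table.data.dropna(subset=["z"]).groupby("protein")["z"]
    out = grouped.agg(mean_z="mean", max_z="max", n_defined="size")
    return out


def compare_z_summaries(
    table_a: EnrichmentTable,
    table_b: EnrichmentTable,
    contaminants: list[str],
) -> pd.DataFrame:
    """Delta of mean/max z between strata for the common contaminants.

    ``contaminants`` should be the proteins flagged frequent in both strata.
    A protein with no defined z in either stratum is dropped with a notice.
    """
    sa = z_summaries(table_a)
    sb = z_summaries(table_b)
    rows = []
    dropped = []
    for p in contaminants:
        if p not in sa.index or p not in sb.index:
            dropped.append(p)
            continue
        rows.append(
            {
                "protein": p,
                "mean_z_a": sa.at[p, "mean_z"],
                "mean_z_b": sb.at[p, "mean_z"],
                "max_z_a": sa.at[p, "max_z"],
                "max_z_b": sb.at[p, "max_z"],
                "delta_mean_z": sa.at[p, "mean_z"] - sb.at[p, "mean_z"],
                "delta_max_z": sa.at[p, "max_z"] - sb.at[p, "max_z"],
            }
        )
    if dropped:
        logger.info(
            "%d contaminant(s) without defined z in a stratum dropped: %s",
            len(dropped), dropped[:5],
        )
    return pd.DataFrame(
        rows,
        columns=[
            "protein", "mean_z_a", "mean_z_b", "max_z_a", "max_z_b",
            "delta_mean_z", "delta_max_z",
        ],
    )


def batch_effect_test(stratum: TreatmentStratum) -> pd.DataFrame:
    """Per-protein Kruskal-Wallis test of intensities across batches.

    Requires >= 2 batches with >= 2 IPs each. Proteins whose values are
    identical everywhere get statistic 0 and p = 1 (ties convention).
    Bonferroni-adjusted p-values are reported alongside the raw ones.
    """
    batches = stratum.metadata.set_index("ip_id")["batch"].loc[stratum.matrix.ip_ids]
    counts = batches.value_counts()
    if len(counts) < 2:
        raise SchemaError(
            f"batch QC needs >= 2 batches, found {len(counts)} in "
            f"{stratum.treatment!r} stratum"
        )
    small = counts[counts < 2]
    if len(small):
        raise SchemaError(f"batches with < 2 IPs: {list(small.index)}")

    values = stratum.matrix.intensity.to_numpy()
    groups_idx = [np.flatnonzero((batches == b).to_numpy()) for b in counts.index]
    stat = np.empty(values.shape[0])
    pval = np.empty(values.shape[0])
    for i, row in enumerate(values):
        samples = [row[idx] for idx in groups_idx]
        if np.ptp(row) == 0:  # all values identical: no rank information
            stat[i], pval[i] = 0.0, 1.0
            continue
        res = sps.kruskal(*samples)
        stat[i], pval[i] = res.statistic, res.pvalue
    adj = multipletests(pval, method="bonferroni")[1]
    out = pd.DataFrame(
        {"statistic": stat, "pvalue": pval, "pvalue_bonferroni": adj},
        index=stratum.matrix.intensity.index,
    )
    out.index.name = "protein"
    return out
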