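"""Antibody classification, interactor calls and contaminant annotation.

Each antibody, per treatment stratum, falls in exactly one category based on
its enriched proteins (z >= 3):

* ``ON``  — only the intended target enriched
* ``CO``  — the target plus other proteins enriched
* ``OFF`` — proteins enriched, but not the target
* ``NO``  — nothing enriched

The verdict is *supportive* iff the target is enriched (ON or CO), otherwise
*uncertain*. Negative-control antibodies (no intended target) can only be OFF
or NO and are excluded from the supportive tally.

Candidate interactors use the stringent cut z >= 5 and raw LFQ intensity
>= 1e7 (i.e. merged log10 intensity >= 7), excluding the bait itself. Plasma
background contaminants are proteins identified in more than 20% of the IPs of
a stratum (strict inequality); the union-over-treatments flag marks proteins
frequent in either preparation.
"""

from __future__ import annotations

import dataclasses
import logging
import math

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .enrichment import EnrichmentTable
from .io import split_ids

logger = logging.getLogger(__name__)

CATEGORIES = ("ON", "CO", "OFF", "NO")


@dataclasses.dataclass
class AntibodyClassification:
    antibody_id: str
    treatment: str
    category: str               # ON / CO / OFF / NO
    verdict: str                # supportive / uncertain
    target_z: float             # max z over target-matching groups (NaN if none)
    target_detected: bool       # any target group with a defined merged intensity
    enriched: dict[str, float]  # protein -> z, z >= z_enriched
    interactors: list[str]      # subset of enriched meeting the stringent cut
    is_control: bool = False
    warning: str | None = None


def build_target_index(proteins: pd.DataFrame) -> dict[str, set[str]]:
    """Uppercased accession/gene-symbol -> protein group ids lookup."""
    index: dict[str, set[str]] = {}
    for gid, acc, genes in zip(
        proteins.index, proteins["accessions"], proteins["gene_symbols"]
    ):
        for name in split_ids(acc) + split_ids(genes):
            index.setdefault(name.upper(), set()).add(gid)
    return index


def target_group_ids(
    proteins: pd.DataFrame,
    target_ids: list[str],
    index: dict[str, set[str]] | None = None,
) -> list[str]:
    """Protein groups matching any target id by accession or gene symbol,
    case-insensitively. Protein groups make exact matching ambiguous, so any
    member id counts."""
    if not target_ids:
        return []
    index = index if index is not None else build_target_index(proteins)
    hits: set[str] = set()
    for t in target_ids:
        hits |= index.get(t.upper(), set())
    return sorted(hits)


def classify_antibody(
    antibody_id: str,
    treatment: str,
    antibody_table: pd.DataFrame,
    target_ids: list[str],
    proteins: pd.DataFrame,
    config: PipelineConfig | None = None,
    target_index: dict[str, set[str]] | None = None,
) -> AntibodyClassification:
    """Classify one antibody from its (protein, merged_intensity, z) rows."""
    config = config or PipelineConfig()
    targets = set(target_group_ids(proteins, target_ids, target_index))
    is_control = not target_ids

    defined = antibody_table.dropna(subset=["z"])
    warning = None
    if defined.empty:
        warning = "no defined z-scores for this antibody"

    enriched_rows = defined[defined["z"] >= config.z_enriched]
    enriched = dict(zip(enriched_rows["protein"], enriched_rows["z"]))
    target_hit = bool(targets & set(enriched))

    tgt = defined[defined["protein"].isin(targets)]
    target_z = float(tgt["z"].max()) if len(tgt) else math.nan
    target_detected = bool(len(tgt))

    if not enriched:
        category = "NO"
    elif is_control:
        category = "OFF"
    elif target_hit:
        category = "ON" if set(enriched) <= targets else "CO"
    else:
        category = "OFF"
    verdict = "supportive" if category in ("ON", "CO") else "uncertain"

    interactors = call_interactors(antibody_table, targets, config)
    return AntibodyClassification(
        antibody_id=antibody_id,
        treatment=treatment,
        category=category,
        verdict=verdict,
        target_z=target_z,
        target_detected=target_detected,
        enriched=enriched,
        interactors=interactors,
        is_control=is_control,
        warning=warning,
    )


def call_interactors(
    antibody_table: pd.DataFrame,
    target_groups: set[str],
    config: PipelineConfig | None = None,
) -> list[str]:
    """Candidate interactors: z >= z_interactor and raw intensity >=
    intensity_interactor, excluding the intended target (the bait)."""
    config = config or PipelineConfig()
    log_cut = math.log10(config.intensity_interactor)
    defined = antibody_table.dropna(subset=["z"])
    hits = defined[
        (defined["z"] >= config.z_interactor)
        & (defined["merged_intensity"] >= log_cut)
        & ~defined["protein"].isin(target_groups)
    ]
    return sorted(hits["protein"])


def classify_all(
    table: EnrichmentTable,
    metadata: pd.DataFrame,
    proteins: pd.DataFrame,
    config: PipelineConfig | None = None,
) -> list[AntibodyClassification]:
    """Classify every antibody present in the stratum's enrichment table."""
    config = config or PipelineConfig()
    targets_of = (
        metadata.drop_duplicates("antibody_id")
        .set_index("antibody_id")["target_ids"]
        .map(split_ids)
    )
    index = build_target_index(proteins)
    out = []
    for antibody_id, sub in table.data.groupby("antibody_id", sort=True):
        out.append(
            classify_antibody(
                antibody_id,
                table.treatment,
                sub,
                targets_of.get(antibody_id, []),
                proteins,
                config,
                target_index=index,
            )
        )
    return out


def classification_report(classifications: list[AntibodyClassification]) -> pd.DataFrame:
    """Tab-separable long report, one row per (antibody, treatment)."""
    rows = []
    for c in classifications:
        rows.append(
            {
                "antibody_id": c.antibody_id,
                "treatment": c.treatment,
                "category": c.category,
                "verdict": c.verdict,
                "target_z": c.target_z,
                "target_detected": c.target_detected,
                "n_enriched": len(c.enriched),
                "enriched": ";".join(
                    f"{p}:{z:.3f}" for p, z in sorted(c.enriched.items())
                ),
                "interactors": ";".join(c.interactors),
                "is_control": c.is_control,
                "warning": c.warning or "",
            }
        )
    return pd.DataFrame(rows)


def merge_verdicts(classifications: list[AntibodyClassification]) -> pd.DataFrame:
    """Best-evidence merge across treatments (an interpretation: an antibody
    counts supportive if it is supportive in either treatment)."""
    per_ab: dict[str, dict] = {}
    for c in classifications:
        d = per_ab.setdefault(
            c.antibody_id,
            {"antibody_id": c.antibody_id, "is_control": c.is_control},
        )
        d[f"category_{c.treatment}"] = c.category
    rows = []
    for ab, d in sorted(per_ab.items()):
        cats = [d.get("category_heat"), d.get("category_untreated")]
        supportive = any(c in ("ON", "CO") for c in cats if c)
        rows.append(
            {
                "antibody_id": ab,
                "category_heat": d.get("category_heat", ""),
                "category_untreated": d.get("category_untreated", ""),
                "merged_verdict": "supportive" if supportive else "uncertain",
                "is_control": d["is_control"],
            }
        )
    return pd.DataFrame(rows)


def annotate_contaminants(
    frequencies: dict[str, pd.Series], config: PipelineConfig | None = None
) -> pd.DataFrame:
    """Plasma background contaminant flags per protein.

    ``is_contaminant_<treatment>`` is f > freq_contaminant (strict); the union
    flag marks proteins frequent in either preparation.
    """
    config = config or PipelineConfig()
    out = pd.DataFrame(index=next(iter(frequencies.values())).index)
    union = pd.Series(False, index=out.index)
    for treatment, f in frequencies.items():
        out[f"f_{treatment}"] = f
        flag = f > config.freq_contaminant
        out[f"is_contaminant_{treatment}"] = flag
        union |= flag.reindex(out.index, fill_value=False)
    out["is_contaminant_union"] = union
    flags = [c for c in out.columns if c.startswith("is_contaminant_") and c != "is_contaminant_union"]
    out["is_contaminant_common"] = out[flags].all(axis=1) if flags else False
    out.index.name = "protein"
    return out


# -- enrichment-profile plot data (Fig-style z vs intensity scatter) ---------

PLOT_COLORS = ("green", "yellow", "red", "none")


def plot_enrichment_profile(
    antibody_table: pd.DataFrame, config: PipelineConfig | None = None
) -> pd.DataFrame:
    """Per-protein (z, intensity, color) records for one antibody.

    Color classes: green = z > 5 and intensity >= 1e7; yellow = 3 < z <= 5 and
    intensity >= 1e7; red = z > 3 and intensity < 1e7; everything else "none".
    The three colored classes are mutually exclusive and jointly cover all
    z > 3 proteins. Rendering is optional (see :func:`render_profile`).
    """
    config = config or PipelineConfig()
    defined = antibody_table.dropna(subset=["z"]).copy()
    intensity = np.power(10.0, defined["merged_intensity"])
    z = defined["z"]
    high_i = intensity >= config.intensity_interactor
    color = np.select(
        [
            (z > config.z_interactor) & high_i,
            (z > config.z_enriched) & high_i,
            (z > config.z_enriched) & ~high_i,
        ],
        ["green", "yellow", "red"],
        default="none",
    )
    return pd.DataFrame(
        {
            "protein": defined["protein"].to_numpy(),
            "z": z.to_numpy(),
            "intensity": intensity.to_numpy(),
            "color": color,
        }
    )


def render_profile(plot_data: pd.DataFrame, title: str = "", path=None):
    """Render the z vs LFQ-intensity scatter with matplotlib (optional extra)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    palette = {"green": "tab:green", "yellow": "gold", "red": "tab:red", "none": "0.7"}
    for color, sub in plot_data.groupby("color"):
        ax.scatter(sub["z"], sub["intensity"], s=12, c=palette[color], label=color)
    ax.set_yscale("log")
    ax.set_xlabel("z-score")
    ax.set_ylabel("LFQ intensity")
    ax.set_title(title)
    ax.legend(frameon=False, fontsize=8)
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig


def concordance_paired_antibodies(
    classifications: list[AntibodyClassification],
    metadata: pd.DataFrame,
) -> pd.DataFrame:
    """Cross-check interactor sets of antibodies raised against a common target.

    For each (target id, treatment) with >= 2 classified antibodies, reports
    the union and intersection of their interactor sets and the proteins
    supported by at least two antibodies (``concordant``). Targets with a
    single antibody are skipped with a log notice.
    """
    targets_of = (
        metadata.drop_duplicates("antibody_id")
        .set_index("antibody_id")["target_ids"]
        .map(split_ids)
    )
    by_key: dict[tuple[str, str], list[AntibodyClassification]] = {}
    for c in classifications:
        for t in targets_of.get(c.antibody_id, []):
            by_key.setdefault((t.upper(), c.treatment), []).append(c)

    rows = []
    for (target, treatment), group in sorted(by_key.items()):
        if len(group) < 2:
            logger.info(
                "target %s (%s): single antibody, concordance skipped", target, treatment
            )
            continue
        sets = {c.antibody_id: set(c.interactors) for c in group}
        union: set[str] = set().union(*sets.values())
        inter = set.intersection(*sets.values()) if sets else set()
        concordant = {
            p for p in union if sum(p in s for s in sets.values()) >= 2
        }
        rows.append(
            {
                "target": target,
                "treatment": treatment,
                "antibodies": ";".join(sorted(sets)),
                "n_antibodies": len(sets),
                "union": ";".join(sorted(union)),
                "intersection": ";".join(sorted(inter)),
                "concordant": ";".join(sorted(concordant)),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "target", "treatment", "antibodies", "n_antibodies",
            "union", "intersection", "concordant",
        ],
    )
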