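"""Synthetic plasma IP-MS datasets with a ground-truth record.

The generator emulates the statistical structure the analysis assumes: a
protein x IP matrix of raw LFQ intensities where

* each protein has a log10 baseline abundance; a configurable fraction are
  frequent plasma background (complement-like carry-over, high baseline) and
  the rest are rare, low-abundance proteins,
* each cell adds per-cell noise ("stickiness", the protein's carry-over
  propensity), a per-batch global shift and a per-protein heat-treatment
  shift,
* the IPs of an antibody that *plants* a protein add an enrichment boost,
  expressed as a planted effect delta in population-sd units,
* detection follows a logistic model in the realized log10 abundance
  (missingness = below limit of detection), and undetected cells are zero.

A designated "fibrinogen-like" subset of frequent proteins receives an extra
abundance shift under heat and is planted with stratum-specific enrichment
(high z in heat-treated, low in untreated plasma), mimicking heat-induced
denaturation driving carry-over. All randomness flows from one explicit seed.

``study_scale_preset`` reproduces the study's shape: 1313 proteins x 414 IPs
(276 heat / 138 untreated), 153 antibodies with 2-4 replicated incubations,
~33% frequent background.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import SchemaError
from .io import LfqMatrix, validate_metadata

HEAT_BATCH_PREFIX = "BH"
UNTREATED_BATCH_PREFIX = "BU"


@dataclasses.dataclass(frozen=True)
class SyntheticConfig:
    """Generator configuration. Defaults are the study-scale study conditions."""

    # shape
    n_proteins: int = 1313
    n_antibodies: int = 153
    n_controls: int = 3           # antibodies with no intended target
    heat_ips: int = 276
    untreated_ips: int = 138
    n_ab_heat: int = 120          # antibodies assayed in heat-treated plasma
    n_ab_untreated: int = 60      # antibodies assayed in untreated plasma (27 overlap)
    replicates_min: int = 2
    replicates_max: int = 4
    n_batches_heat: int = 4
    n_batches_untreated: int = 2
    n_tech_duplicates: int = 0    # extra technical re-injections (lower intensity)

    # abundance model (log10 units)
    frequent_fraction: float = 0.33
    baseline_frequent_mean: float = 6.6
    baseline_frequent_sd: float = 0.7
    baseline_rare_mean: float = 3.5
    baseline_rare_sd: float = 0.25
    stickiness_min: float = 0.3   # per-cell noise sd
    stickiness_max: float = 0.6
    batch_sd: float = 0.15
    heat_shift_sd: float = 0.10

    # detection model: P(detect) = logistic((log10 abundance - mid) / scale)
    detect_mid: float = 6.0
    detect_scale: float = 0.35

    # planted enrichment
    delta_target: float = 6.0     # per-antibody target effect, population-sd units
    effect_sd: float = 0.8        # log10 units corresponding to one delta unit
    n_fibrinogen_like: int = 3
    n_fib_binders: int = 2        # antibodies (assayed in both strata) enriching them
    fib_baseline_mean: float = 8.6
    fib_baseline_sd: float = 0.2
    fib_heat_shift: float = 1.0   # extra abundance under heat
    delta_fib_heat: float = 4.5   # planted max z in heat-treated plasma
    delta_fib_untreated: float = 1.5
    tech_duplicate_drop: float = 0.3  # log10 intensity deficit of re-injections

    def validate(self) -> "SyntheticConfig":
        if self.replicates_min < 1 or self.replicates_max < self.replicates_min:
            raise SchemaError("replicate bounds must satisfy 1 <= min <= max")
        for name, n_ab, n_ips in (
            ("heat", self.n_ab_heat, self.heat_ips),
            ("untreated", self.n_ab_untreated, self.untreated_ips),
        ):
            if n_ab < 1 or n_ips < 2:
                raise SchemaError(f"{name} stratum is empty or has < 2 IPs")
            if not (self.replicates_min * n_ab <= n_ips <= self.replicates_max * n_ab):
                raise SchemaError(
                    f"{name} stratum: {n_ips} IPs cannot be split over {n_ab} "
                    f"antibodies with {self.replicates_min}-{self.replicates_max} replicates"
                )
        overlap = self.n_ab_heat + self.n_ab_untreated - self.n_antibodies
        if overlap < 0:
            raise SchemaError("stratum antibody sets do not cover all antibodies")
        if self.n_fib_binders > overlap and self.n_fib_binders > 0:
            raise SchemaError("fibrinogen binders must be assayed in both strata")
        n_rare = self.n_proteins - round(self.frequent_fraction * self.n_proteins)
        if n_rare < self.n_antibodies - self.n_controls:
            raise SchemaError("not enough rare proteins to assign unique targets")
        return self


def study_scale_preset(scale: float = 1.0) -> SyntheticConfig:
    """Preset emulating the study's shape, optionally scaled down.

    ``scale=1`` gives 1313 proteins x 414 IPs with 276/138 stratum widths;
    ``scale=0.1`` gives a 131 x 41 matrix with the same proportions.
    """
    def r(x, lo=0):
        return max(lo, round(x * scale))

    n_ips = r(414, 4)
    heat = r(276, 2)
    n_ab = r(153, 2)
    n_ab_heat = r(120, 1)
    overlap = r(27, 1)
    return SyntheticConfig(
        n_proteins=r(1313, 10),
        n_antibodies=n_ab,
        n_controls=r(3),
        heat_ips=heat,
        untreated_ips=n_ips - heat,
        n_ab_heat=n_ab_heat,
        n_ab_untreated=n_ab - n_ab_heat + overlap,
        n_fibrinogen_like=max(1, r(3)),
        n_fib_binders=max(1, min(r(2), overlap)),
    ).validate()


def null_config(config: SyntheticConfig) -> SyntheticConfig:
    """The same conditions with all planted enrichment effects set to zero."""
    return dataclasses.replace(
        config, delta_target=0.0, delta_fib_heat=0.0, delta_fib_untreated=0.0
    )


@dataclasses.dataclass
class SyntheticTruth:
    """Planted parameters behind a generated dataset."""

    proteins: pd.DataFrame    # baseline, stickiness, heat_shift, class flags
    antibodies: pd.DataFrame  # target, stratum membership, replicate counts
    planted: pd.DataFrame     # antibody_id, protein, treatment, delta, log_boost
    batches: pd.DataFrame     # batch, treatment, shift
    config: SyntheticConfig
    seed: int

    def detection_probability(self, log_abundance):
        c = self.config
        return expit((np.asarray(log_abundance) - c.detect_mid) / c.detect_scale)

    def analytic_null_supportive(self, n_mc: int = 400) -> float:
        """Upper bound on the per-antibody probability of a supportive call
        under delta = 0: the chance that the intended target is detected in
        all replicates of at least one stratum, integrated over the
        generator's own noise model by Monte Carlo (deterministic given the
        dataset seed)."""
        c = self.config
        rng = np.random.default_rng(self.seed + 987_654)
        probs = []
        for _, ab in self.antibodies.iterrows():
            if not ab["target_protein"]:
                continue
            prot = self.proteins.loc[ab["target_protein"]]
            p_any = 0.0
            for treatment, kcol in (("heat", "k_heat"), ("untreated", "k_untreated")):
                k = int(ab[kcol])
                if k == 0:
                    continue
                base = prot["baseline"] + (
                    prot["heat_shift"] if treatment == "heat" else 0.0
                )
                noise = rng.normal(0.0, prot["stickiness"], size=(n_mc, k))
                batch = rng.normal(0.0, c.batch_sd, size=(n_mc, 1))
                p_cell = expit((base + batch + noise - c.detect_mid) / c.detect_scale)
                p_all = float(np.mean(np.prod(p_cell, axis=1)))
                p_any = 1.0 - (1.0 - p_any) * (1.0 - p_all)
            probs.append(p_any)
        return float(np.mean(probs)) if probs else 0.0


def _allocate_replicates(
    n_ips: int, antibodies: list[str], kmin: int, kmax: int, rng: np.random.Generator
) -> dict[str, int]:
    counts = {ab: kmin for ab in antibodies}
    extra = n_ips - kmin * len(antibodies)
    room = [ab for ab in antibodies for _ in range(kmax - kmin)]
    picks = rng.permutation(len(room))[:extra]
    for i in picks:
        counts[room[i]] += 1
    assert sum(counts.values()) == n_ips
    return counts


def generate_dataset(
    config: SyntheticConfig, seed: int
) -> tuple[LfqMatrix, pd.DataFrame, SyntheticTruth]:
    """Generate (raw LfqMatrix, IP metadata, SyntheticTruth).

    Cell construction: log10 intensity = baseline + stickiness noise + batch
    shift + treatment shift + planted boost, zeroed when the logistic
    detection draw fails. Bit-identical output for identical (config, seed).
    """
    config.validate()
    rng = np.random.default_rng(seed)
    c = config

    # -- proteins ------------------------------------------------------------
    n_freq = round(c.frequent_fraction * c.n_proteins)
    n_fib = min(c.n_fibrinogen_like, n_freq)
    n_rare = c.n_proteins - n_freq
    gids = [f"SYNP{i:05d}" for i in range(c.n_proteins)]
    genes = [f"G{i:05d}" for i in range(c.n_proteins)]
    klass = np.array(["fib"] * n_fib + ["frequent"] * (n_freq - n_fib) + ["rare"] * n_rare)
    baseline = np.concatenate(
        [
            rng.normal(c.fib_baseline_mean, c.fib_baseline_sd, n_fib),
            rng.normal(c.baseline_frequent_mean, c.baseline_frequent_sd, n_freq - n_fib),
            rng.normal(c.baseline_rare_mean, c.baseline_rare_sd, n_rare),
        ]
    )
    stickiness = rng.uniform(c.stickiness_min, c.stickiness_max, c.n_proteins)
    heat_shift = rng.normal(0.0, c.heat_shift_sd, c.n_proteins)
    heat_shift[klass == "fib"] += c.fib_heat_shift
    proteins_truth = pd.DataFrame(
        {
            "gene_symbol": genes,
            "baseline": baseline,
            "stickiness": stickiness,
            "heat_shift": heat_shift,
            "class": klass,
            "is_frequent": klass != "rare",
            "is_fibrinogen_like": klass == "fib",
        },
        index=pd.Index(gids, name="group_id"),
    )

    # -- antibodies and replicate layout --------------------------------------
    ab_ids = [f"AB{i:03d}" for i in range(c.n_antibodies)]
    heat_set = ab_ids[: c.n_ab_heat]
    untreated_set = ab_ids[c.n_antibodies - c.n_ab_untreated:]
    overlap = [ab for ab in heat_set if ab in set(untreated_set)]
    controls = set(overlap[: c.n_controls]) if c.n_controls else set()
    fib_binders = [ab for ab in overlap if ab not in controls][: c.n_fib_binders]

    rare_ids = [g for g, k in zip(gids, klass) if k == "rare"]
    target_pool = list(rng.permutation(rare_ids))
    targets: dict[str, str] = {}
    for ab in ab_ids:
        targets[ab] = "" if ab in controls else target_pool.pop()

    k_heat = _allocate_replicates(
        c.heat_ips, heat_set, c.replicates_min, c.replicates_max, rng
    )
    k_untreated = _allocate_replicates(
        c.untreated_ips, untreated_set, c.replicates_min, c.replicates_max, rng
    )

    # -- IP layout, batches ----------------------------------------------------
    rows = []
    ip_counter = 0
    for treatment, members, counts, n_batches, prefix in (
        ("heat", heat_set, k_heat, c.n_batches_heat, HEAT_BATCH_PREFIX),
        ("untreated", untreated_set, k_untreated, c.n_batches_untreated, UNTREATED_BATCH_PREFIX),
    ):
        stratum_rows = []
        for ab in members:
            for _ in range(counts[ab]):
                ip_id = f"IP{ip_counter:04d}"
                ip_counter += 1
                stratum_rows.append(
                    {
                        "ip_id": ip_id,
                        "antibody_id": ab,
                        "target_ids": proteins_truth.at[targets[ab], "gene_symbol"]
                        if targets[ab]
                        else "",
                        "treatment": treatment,
                        "replicate_role": "biological",
                        "tech_group": ip_id,
                    }
                )
        # contiguous batch blocks: experiments were prepared batch-wise
        n_batches = max(1, min(n_batches, len(stratum_rows) // 2))
        bounds = np.linspace(0, len(stratum_rows), n_batches + 1).astype(int)
        for b in range(n_batches):
            for r in stratum_rows[bounds[b]: bounds[b + 1]]:
                r["batch"] = f"{prefix}{b + 1}"
        rows.extend(stratum_rows)
    metadata = pd.DataFrame(rows)

    batch_names = list(dict.fromkeys(metadata["batch"]))
    batch_shift = {b: rng.normal(0.0, c.batch_sd) for b in batch_names}
    batches_truth = pd.DataFrame(
        {
            "batch": batch_names,
            "treatment": [
                "heat" if b.startswith(HEAT_BATCH_PREFIX) else "untreated"
                for b in batch_names
            ],
            "shift": [batch_shift[b] for b in batch_names],
        }
    )

    # -- planted effects -------------------------------------------------------
    planted_rows = []
    for ab in ab_ids:
        if not targets[ab] or c.delta_target == 0:
            continue
        for treatment, members in (("heat", heat_set), ("untreated", untreated_set)):
            if ab in set(members):
                planted_rows.append(
                    {
                        "antibody_id": ab,
                        "protein": targets[ab],
                        "treatment": treatment,
                        "delta": c.delta_target,
                        "log_boost": c.delta_target * c.effect_sd,
                    }
                )
    fib_ids = [g for g, k in zip(gids, klass) if k == "fib"]
    for ab in fib_binders:
        for fp in fib_ids:
            # fibrinogen-like proteins are detected throughout, so their
            # population sd is the cell noise plus batch spread; a boost of
            # delta * that sd plants a z-score of about delta
            sigma = float(
                np.sqrt(proteins_truth.at[fp, "stickiness"] ** 2 + c.batch_sd**2)
            )
            for treatment, delta in (
                ("heat", c.delta_fib_heat),
                ("untreated", c.delta_fib_untreated),
            ):
                if delta == 0:
                    continue
                planted_rows.append(
                    {
                        "antibody_id": ab,
                        "protein": fp,
                        "treatment": treatment,
                        "delta": delta,
                        "log_boost": delta * sigma,
                    }
                )
    planted = pd.DataFrame(
        planted_rows, columns=["antibody_id", "protein", "treatment", "delta", "log_boost"]
    )

    antibodies_truth = pd.DataFrame(
        {
            "antibody_id": ab_ids,
            "target_protein": [targets[ab] for ab in ab_ids],
            "is_control": [ab in controls for ab in ab_ids],
            "is_fib_binder": [ab in set(fib_binders) for ab in ab_ids],
            "k_heat": [k_heat.get(ab, 0) for ab in ab_ids],
            "k_untreated": [k_untreated.get(ab, 0) for ab in ab_ids],
        }
    ).set_index("antibody_id", drop=False)

    # -- assemble the matrix ----------------------------------------------------
    n_ips = len(metadata)
    gid_pos = {g: i for i, g in enumerate(gids)}
    is_heat = (metadata["treatment"] == "heat").to_numpy()
    col_batch_shift = metadata["batch"].map(batch_shift).to_numpy()

    log_mu = (
        baseline[:, None]
        + heat_shift[:, None] * is_heat[None, :]
        + col_batch_shift[None, :]
    )
    if len(planted):
        cols_of = {
            (ab, tr): np.flatnonzero(
                (metadata["antibody_id"] == ab).to_numpy()
                & (metadata["treatment"] == tr).to_numpy()
            )
            for ab, tr in set(zip(planted["antibody_id"], planted["treatment"]))
        }
        for row in planted.itertuples(index=False):
            log_mu[gid_pos[row.protein], cols_of[(row.antibody_id, row.treatment)]] += (
                row.log_boost
            )

    noise = rng.normal(0.0, 1.0, size=(c.n_proteins, n_ips)) * stickiness[:, None]
    log_abund = log_mu + noise
    p_detect = expit((log_abund - c.detect_mid) / c.detect_scale)
    detected = rng.random(size=log_abund.shape) < p_detect
    raw = np.where(detected, np.power(10.0, log_abund), 0.0)

    # -- optional technical re-injections (exercise replicate selection) -------
    if c.n_tech_duplicates:
        dup_idx = rng.choice(n_ips, size=min(c.n_tech_duplicates, n_ips), replace=False)
        dup_cols = []
        dup_rows = []
        for j in sorted(dup_idx):
            src = metadata.iloc[j]
            dup_cols.append(raw[:, j] * 10.0 ** (-c.tech_duplicate_drop))
            dup_rows.append(
                {
                    **src.to_dict(),
                    "ip_id": src["ip_id"] + "_inj2",
                    "replicate_role": "technical",
                    "tech_group": src["tech_group"],
                }
            )
        raw = np.column_stack([raw] + [col[:, None] for col in dup_cols]).reshape(
            c.n_proteins, -1
        )
        metadata = pd.concat([metadata, pd.DataFrame(dup_rows)], ignore_index=True)

    proteins = pd.DataFrame(
        {
            "accessions": gids,
            "gene_symbols": genes,
            "species": "Homo sapiens",
            "is_maxquant_contaminant": False,
            "is_ig_variable": False,
        },
        index=pd.Index(gids, name="group_id"),
    )
    matrix = LfqMatrix(
        proteins=proteins,
        intensity=pd.DataFrame(
            raw, index=proteins.index, columns=list(metadata["ip_id"])
        ),
        scale="raw",
    )
    metadata = validate_metadata(metadata)
    truth = SyntheticTruth(
        proteins=proteins_truth,
        antibodies=antibodies_truth,
        planted=planted,
        batches=batches_truth,
        config=config,
        seed=seed,
    )
    return matrix, metadata, truth
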