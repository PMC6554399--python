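# Methods

## The analysis model

`plasmaip` scores antibody enrichment against a *population of IPs* rather
than against matched IgG controls. The assumptions, in order of consequence:

1. **Population reference.** Within a treatment stratum, the distribution of a
   protein's intensity over all IPs — most of which used unrelated antibodies —
   estimates its background behaviour. `µp` and `sp` are computed over every IP
   of the stratum, including non-detections (transformed value 0). Excluding
   zeros would make rarely-seen proteins look unremarkable exactly when their
   detection is the signal.
2. **Log scale.** z-scores are computed on log10-transformed intensities. The
   z formula is stated in terms of LFQ intensity, but the whole matrix is
   log10-transformed beforehand; computing on the raw scale would let single
   high values dominate `sp`. A config switch (`scale: raw`) preserves the
   alternative reading.
3. **Missing = below LOD.** `LFQ = 0` is treated as below the limit of
   detection, substituted with 1 so it maps to exactly 0 after log10
   (single-value imputation). Positive intensities below 1 are rejected: the
   substitution is order-preserving only on {0} ∪ [1, ∞), and real LFQ values
   are either 0 or large.
4. **Replicate intersection.** An antibody's merged intensity for a protein is
   the mean of its replicates' log10 intensities, defined only when the
   protein is detected in *every* replicate. A protein seen in k−1 of k
   replicates never receives a z-score.
5. **Fixed thresholds, no multiple-testing control.** Enrichment (`z ≥ 3`),
   interactors (`z ≥ 5` and raw intensity `≥ 1e7`) and contaminants
   (`f > 0.20`, strict) are fixed cuts, not hypothesis tests; no FDR is
   applied and users should not expect one.

A consequence of the population z-score worth knowing: for a protein detected
`m` times in a stratum of `n` IPs at a roughly constant log intensity, the
z-score of an antibody detecting it in all replicates is ≈ `sqrt(n/m − 1)`,
nearly independent of the intensity itself. The score measures *rarity of
consistent detection*, which is the intended semantics — and why intensity has
its own threshold in the interactor call.

## Parameters

All thresholds live in the pipeline config (YAML, flat keys) and default to
the printed analysis values:

| key | default | meaning |
|-----|---------|---------|
| `z_enriched` | 3.0 | enrichment call, inclusive |
| `z_interactor` | 5.0 | interactor call, inclusive |
| `intensity_interactor` | 1e7 | raw-scale intensity floor for interactors |
| `freq_contaminant` | 0.20 | contaminant rule, strict `>` |
| `sd_convention` | population | `sp` denominator (n); `sample` gives n−1 |
| `scale` | log10 | intensity scale for `µp`, `sp`, z |
| `lfq_prefix` | `LFQ intensity ` | intensity-column prefix in the table |
| `ig_variable_prefixes` | IGHV, IGKV, IGLV | gene prefixes of Ig variable chains |

The population sd convention makes the per-IP normalization identity exact
(each non-constant protein's per-IP z-scores have mean 0, sd 1); with n = 276
or 138 IPs the numerical difference from the sample convention is negligible.

## Numerical and procedural choices

* **Technical replicates**: of the re-injections sharing a `tech_group`, the
  one with the highest median intensity over all proteins is kept (groups of
  any size; ties keep the lexicographically smallest IP id). Medians are taken
  on the raw scale; log10 is monotone, so the same column wins on either
  scale. Including zeros in the median penalizes runs with many missing
  values, which is the point of the rule.
* **Protein exclusion**: (i) MaxQuant-contaminant-flagged non-human groups,
  (ii) rabbit Ig gamma chain C (rabbit IgG is deliberately added to the assay
  buffer), (iii) human Ig variable-chain groups, identified by gene-symbol
  prefix. The rules are independent predicates, so application order cannot
  change the retained set. Human proteins on the MaxQuant list are retained.
  Groups without species annotation are assumed human.
* **Group identity**: the first accession of a protein group is its stable id;
  a target matches a group if any accession or gene symbol equals any declared
  target id, case-insensitively.
* **Degenerate cases**: `sp = 0` yields an undefined z (never ±inf) and the
  protein is excluded from calls; antibodies with no defined z are classified
  NO-target with a warning; negative-control antibodies (no declared target)
  can only be OFF or NO and are excluded from supportive tallies.
* **Profile colors**: the z-vs-intensity plot data uses green (`z > 5`,
  intensity ≥ 1e7), yellow (`3 < z ≤ 5`, intensity ≥ 1e7), red (`z > 3`,
  intensity < 1e7). Intensity exactly 1e7 counts as high so the three classes
  partition all `z > 3` points.
* **Cross-treatment verdict merge**: per-treatment categories are the primary
  output; the additional "best-evidence" merge (supportive if supportive in
  either stratum) is an interpretation, labeled as such in the report.
* **Batch QC**: per-protein Kruskal–Wallis across batches within a stratum
  (scipy), Bonferroni-adjusted (statsmodels); a protein with identical values
  everywhere gets statistic 0, p = 1 by the ties convention.

## The synthetic-data generator

The generator emulates the data structure the analysis assumes, not the
physics of LC-MS. Per protein: a log10 baseline abundance; a per-cell noise sd
("stickiness", carry-over propensity, U(0.3, 0.6)); a per-protein heat shift
(N(0, 0.1)); per-batch global shifts (N(0, 0.15)). Cell log-abundance is the
sum of these plus any planted enrichment; detection is a logistic draw in the
realized log-abundance (midpoint 6.0, scale 0.35), and undetected cells are 0.
All randomness flows from one seed.

Three protein classes set the abundance structure:

* **frequent background** (33% of proteins, baseline N(6.6, 0.7)): the
  complement-like carry-over population; detected in 20–100% of IPs.
* **rare** (the rest, baseline N(3.5, 0.25)): below-LOD plasma proteins,
  essentially undetected except when enriched. Intended targets are drawn from
  this class. The low baseline is deliberate: the z-score of a protein
  detected only in one antibody's replicates is ≈ `sqrt(n/m − 1)` regardless
  of intensity, so a heavy rare-class detection tail would create chance
  co-detections that outrank planted targets; the generator models targets as
  confidently enrichable, which is the regime the recovery tests probe.
* **fibrinogen-like** (3 proteins, baseline N(8.6, 0.2) plus a +1.0 heat
  shift): near-universally detected, high abundance, so occasional
  non-detections do not corrupt their population sd.

Planted effects: each non-control antibody enriches its target by
`delta_target × effect_sd` log10 units (defaults 6 × 0.8 = +4.8, enough to
saturate all-replicate detection of the boosted target). Two antibodies
assayed in both strata enrich the fibrinogen-like proteins with planted
z-scores of 4.5 (heat) and 1.5 (untreated), implemented as a boost of
`delta × sqrt(stickiness² + batch_sd²)` — the protein's expected population
sd — mimicking heat-induced denaturation driving bead carry-over.

The study-shape preset produces exactly 1313 proteins × 414 IPs (276
heat-treated, 138 untreated) from 153 antibodies: 120 antibodies in the heat
stratum and 60 in the untreated stratum (27 in both), each with 2 base
replicates per stratum plus randomly distributed extras up to 4. Under these
defaults the generated resource shows ~32% frequent background, ~300
identifications per IP, and a frequency rank correlation of ~0.80 between
strata — the same regime as real plasma IP-MS collections of this design.

**What passing tests do and do not show.** The generator has independent
log-normal cells, logistic missingness and additive batch/treatment effects.
Real data add correlated carry-over between related proteins, protein-group
ambiguity, intensity-dependent normalization artifacts and passenger antigens;
recovery results here demonstrate the pipeline's correctness under its own
model, not the field accuracy of antibody classification.

**Recovery tolerances.** The planted fibrinogen-like Δmax-z of 3.0 is
recovered within ±1.0 (mean over 10 seeds). The band is wide for two known
reasons: the planted IPs themselves inflate the stratum sd (plug-in bias,
shrinking realized z by ~5–10%), and the untreated maximum is governed by the
population maximum over ~120 antibody profiles (~1.5–1.7) rather than the
planted 1.5 alone. The null comparison uses an analytic upper bound on the
supportive probability (chance all-replicate target detection, a Monte-Carlo
integral over the generator's own noise model), so it is conservative.

## Problem sizes

The default test suite and the acceptance script run the full 1313 × 414
preset: 20 seeded planted runs and 5 null runs for classification recovery,
10 seeds for the heat-effect recovery, 50 random ≤ 10 × 10 matrices for the
brute-force equivalence check. One preset generation-plus-analysis cycle takes
about two seconds on a single core.

## Known limitations

* Protein groups are reduced to their first accession; shared-peptide
  structure beyond that is not modeled.
* No sequence homology scoring or interaction-database lookups: CO-target
  sub-categorization (homology- vs abundance- vs interaction-driven) is
  descriptive, via frequencies and an optional user-supplied concentration
  table.
* Frequencies are computed on the analysis matrix (after technical-replicate
  exclusion), i.e. the denominator is the number of retained IPs per stratum.
* The generator does not simulate peptide-level evidence, spectral noise, or
  realistic protein-group inference.
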