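import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plasmaip import PipelineConfig, PlasmaIpError, SchemaError
from plasmaip.enrichment import (
    call_enriched,
    compute_frequency,
    compute_population_stats,
    compute_zscores,
    merge_biological_replicates,
    per_ip_zscores,
    split_by_treatment,
)
from plasmaip.preprocess import impute_and_log

import _oracles as oracle
from conftest import make_matrix, make_metadata, random_small_dataset


def prepared(values, antibodies, treatments, **meta_kwargs):
    m = impute_and_log(make_matrix(np.asarray(values, dtype=float)))
    meta = make_metadata(m.ip_ids, antibodies, treatments, **meta_kwargs)
    return split_by_treatment(m, meta)


class TestSplit:
    def test_widths(self):
        strata = prepared(
            [[1.0] * 6], ["a"] * 6, ["heat"] * 4 + ["untreated"] * 2
        )
        assert strata["heat"].n_ips == 4
        assert strata["untreated"].n_ips == 2

    def test_absent_stratum_not_created(self):
        strata = prepared([[1.0] * 3], ["a"] * 3, ["heat"] * 3)
        assert "untreated" not in strata
        assert strata["heat"].n_ips == 3

    def test_single_ip_stratum_rejected_for_stats(self):
        strata = prepared([[1.0, 1.0, 1.0]], ["a"] * 3, ["heat", "heat", "untreated"])
        with pytest.raises(SchemaError, match="at least 2"):
            compute_population_stats(strata["untreated"])


class TestFrequency:
    @pytest.mark.parametrize(
        "row, expected",
        [
            ([1e6, 1e6, 1e6, 1e6], 1.0),
            ([1e6, 0, 0, 0, 0], 0.2),
            ([0, 0, 0], 0.0),
        ],
    )
    def test_examples(self, row, expected):
        strata = prepared([row], ["a"] * len(row), ["heat"] * len(row))
        f = compute_frequency(strata["heat"])
        assert f["P0"] == pytest.approx(expected)

    @settings(max_examples=40, derandomize=True)
    @given(
        st.lists(
            st.one_of(
                st.just(0.0),
                st.floats(min_value=1, max_value=1e9, allow_nan=False),
            ),
            min_size=2, max_size=10,
        ),
        st.data(),
    )
    def test_monotone_in_detections(self, row, data):
        """Turning any zero cell positive never decreases f."""
        strata = prepared([row], ["a"] * len(row), ["heat"] * len(row))
        f0 = compute_frequency(strata["heat"])["P0"]
        zeros = [j for j, v in enumerate(row) if v == 0]
        if not zeros:
            return
        j = data.draw(st.sampled_from(zeros))
        bumped = list(row)
        bumped[j] = 1e5
        strata2 = prepared([bumped], ["a"] * len(row), ["heat"] * len(row))
        assert compute_frequency(strata2["heat"])["P0"] >= f0


class TestPopulationStats:
    def test_constant_protein_flagged(self):
        strata = prepared([[1e7, 1e7, 1e7]], ["a"] * 3, ["heat"] * 3)
        stats = compute_population_stats(strata["heat"])
        assert stats.mu["P0"] == pytest.approx(7.0)
        assert stats.sd["P0"] == 0.0
        assert bool(stats.constant["P0"])

    def test_zeros_included_with_population_sd(self):
        # log10 values [0, 0, 6, 8]: mu = 3.5, population sd = sqrt(51/4)
        strata = prepared([[0, 0, 1e6, 1e8]], ["a"] * 4, ["heat"] * 4)
        stats = compute_population_stats(strata["heat"])
        assert stats.mu["P0"] == pytest.approx(3.5)
        assert stats.sd["P0"] == pytest.approx(math.sqrt(51 / 4))

    def test_sample_sd_convention_switch(self):
        strata = prepared([[0, 0, 1e6, 1e8]], ["a"] * 4, ["heat"] * 4)
        cfg = PipelineConfig(sd_convention="sample")
        stats = compute_population_stats(strata["heat"], cfg)
        assert stats.sd["P0"] == pytest.approx(math.sqrt(51 / 3))


class TestMerging:
    def test_mean_of_log_replicates(self):
        strata = prepared([[1e7, 1e7]], ["ab1", "ab1"], ["heat"] * 2)
        merged = merge_biological_replicates(strata["heat"])
        assert merged.loc["P0", "ab1"] == pytest.approx(7.0)

    def test_partial_detection_disregarded(self):
        strata = prepared([[1e7, 0]], ["ab1", "ab1"], ["heat"] * 2)
        merged = merge_biological_replicates(strata["heat"])
        assert math.isnan(merged.loc["P0", "ab1"])

    def test_single_replicate_identity(self):
        strata = prepared(
            [[1e5, 3e7], [0, 5e6]], ["ab1", "ab2"], ["heat"] * 2
        )
        merged = merge_biological_replicates(strata["heat"])
        assert merged.loc["P0", "ab1"] == pytest.approx(5.0)
        assert math.isnan(merged.loc["P1", "ab1"])
        # single-replicate antibody equals its column restricted to detections
        col = strata["heat"].matrix.intensity["ip1"]
        det = strata["heat"].matrix.detected["ip1"]
        expect = col.where(det)
        pd.testing.assert_series_equal(
            merged["ab2"], expect, check_names=False
        )


class TestZScores:
    def test_centering_and_arithmetic(self):
        # protein values chosen so mu=3, sd=2 for P1 is irrelevant; use direct
        merged = pd.DataFrame({"ab": [9.0, 3.0]}, index=pd.Index(["P0", "P1"], name="group_id"))
        stats_mu = pd.Series([3.0, 3.0], index=merged.index)
        stats_sd = pd.Series([2.0, 2.0], index=merged.index)
        from plasmaip.enrichment import PopulationStats

        stats = PopulationStats(treatment="heat", mu=stats_mu, sd=stats_sd)
        table = compute_zscores(merged, stats, treatment="heat")
        z = table.data.set_index("protein")["z"]
        assert z["P0"] == pytest.approx(3.0)
        assert z["P1"] == pytest.approx(0.0)

    def test_zero_sd_yields_undefined_not_infinite(self):
        strata = prepared([[1e7, 1e7, 1e7]], ["ab1"] * 3, ["heat"] * 3)
        stats = compute_population_stats(strata["heat"])
        merged = merge_biological_replicates(strata["heat"])
        table = compute_zscores(merged, stats)
        assert table.data["z"].isna().all()
        assert all(len(df) == 0 for df in call_enriched(table).values())

    def test_stratum_mismatch_is_hard_error(self):
        strata = prepared(
            [[1e7, 1e6, 1e5, 1e4]], ["a"] * 4, ["heat", "heat", "untreated", "untreated"]
        )
        stats_unt = compute_population_stats(strata["untreated"])
        merged_heat = merge_biological_replicates(strata["heat"])
        with pytest.raises(PlasmaIpError, match="mismatch"):
            compute_zscores(merged_heat, stats_unt, treatment="heat")

    def test_enrichment_threshold_inclusive(self):
        table_df = pd.DataFrame(
            {
                "antibody_id": ["ab"] * 3,
                "protein": ["P0", "P1", "P2"],
                "merged_intensity": [7.0, 7.0, 7.0],
                "z": [3.0, 2.99, float("nan")],
            }
        )
        from plasmaip.enrichment import EnrichmentTable

        calls = call_enriched(EnrichmentTable("heat", table_df))
        assert list(calls["ab"]["protein"]) == ["P0"]

    def test_per_ip_normalization_identity(self):
        rng = np.random.default_rng(3)
        values = rng.uniform(0, 1e8, size=(6, 9))
        values[rng.random((6, 9)) < 0.3] = 0
        strata = prepared(values, [f"a{j}" for j in range(9)], ["heat"] * 9)
        stats = compute_population_stats(strata["heat"])
        z = per_ip_zscores(strata["heat"], stats)
        ok = stats.sd > 0
        assert np.allclose(z[ok.values].mean(axis=1), 0, atol=1e-9)
        assert np.allclose(z[ok.values].std(axis=1, ddof=0), 1, atol=1e-9)

    def test_column_reordering_invariance(self):
        rng = np.random.default_rng(5)
        values = rng.uniform(0, 1e8, size=(5, 6))
        abs_ = ["a1", "a1", "a2", "a2", "a3", "a3"]

        def z_of(vals, names, ips):
            m = impute_and_log(make_matrix(vals, ip_ids=ips))
            meta = make_metadata(ips, names, ["heat"] * len(ips))
            s = split_by_treatment(m, meta)["heat"]
            table = compute_zscores(
                merge_biological_replicates(s), compute_population_stats(s)
            )
            return table.data.set_index(["antibody_id", "protein"])["z"].sort_index()

        ips = [f"i{j}" for j in range(6)]
        base = z_of(values, abs_, ips)
        perm = [4, 2, 0, 5, 3, 1]
        permuted = z_of(values[:, perm], [abs_[j] for j in perm], [ips[j] for j in perm])
        pd.testing.assert_series_equal(base, permuted)


class TestOracleEquivalence:
    def test_matches_brute_force_on_random_matrices(self):
        """Vectorized f, mu, sd, merged and z equal plain-loop references."""
        rng = np.random.default_rng(2024)
        for _ in range(10):
            matrix, metadata = random_small_dataset(rng)
            logm = impute_and_log(matrix)
            stratum = split_by_treatment(logm, metadata)["heat"]
            raw_rows = matrix.intensity.to_numpy().tolist()
            log_rows = oracle.brute_log10(raw_rows)

            f = compute_frequency(stratum)
            np.testing.assert_allclose(
                f.to_numpy(), oracle.brute_frequency(raw_rows, matrix.n_ips),
                atol=1e-12, rtol=0,
            )
            stats = compute_population_stats(stratum)
            mus, sds = oracle.brute_population_stats(log_rows, ddof=0)
            np.testing.assert_allclose(stats.mu.to_numpy(), mus, atol=1e-12, rtol=0)
            np.testing.assert_allclose(stats.sd.to_numpy(), sds, atol=1e-12, rtol=0)

            merged = merge_biological_replicates(stratum)
            table = compute_zscores(merged, stats)
            for ab in merged.columns:
                cols = [
                    matrix.ip_ids.index(ip)
                    for ip in metadata.loc[metadata["antibody_id"] == ab, "ip_id"]
                ]
                bm = oracle.brute_merged(raw_rows, log_rows, cols)
                bz = oracle.brute_z(bm, mus, sds)
                got = merged[ab].to_numpy()
                np.testing.assert_allclose(got, bm, atol=1e-12, rtol=0, equal_nan=True)
                gz = (
                    table.data[table.data["antibody_id"] == ab]
                    .set_index("protein")["z"]
                    .loc[matrix.group_ids]
                    .to_numpy()
                )
                np.testing.assert_allclose(gz, bz, atol=1e-12, rtol=0, equal_nan=True)
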