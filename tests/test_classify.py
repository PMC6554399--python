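import math

import numpy as np
import pandas as pd
import pytest

from plasmaip import PipelineConfig
from plasmaip.classify import (
    annotate_contaminants,
    call_interactors,
    classify_antibody,
    concordance_paired_antibodies,
    merge_verdicts,
    plot_enrichment_profile,
)

from conftest import make_matrix, make_metadata


def proteins_frame(gids, genes=None):
    return make_matrix(
        np.ones((len(gids), 2)),
        genes=genes,
    ).proteins.set_index(pd.Index(gids, name="group_id")).assign(
        accessions=gids, gene_symbols=genes or gids
    )


def ab_table(rows):
    """rows: (protein, merged_intensity, z)"""
    return pd.DataFrame(
        {
            "antibody_id": "ab",
            "protein": [r[0] for r in rows],
            "merged_intensity": [r[1] for r in rows],
            "z": [r[2] for r in rows],
        }
    )


class TestClassifyAntibody:
    PROTS = proteins_frame(["TGT", "OTHER", "THIRD"])

    def classify(self, rows, targets=("TGT",)):
        return classify_antibody("ab", "heat", ab_table(rows), list(targets), self.PROTS)

    def test_on_target(self):
        c = self.classify([("TGT", 7.5, 6.1), ("OTHER", 6.0, 1.0)])
        assert (c.category, c.verdict) == ("ON", "supportive")
        assert c.target_z == pytest.approx(6.1)

    def test_co_target(self):
        c = self.classify([("TGT", 7.5, 4.0), ("OTHER", 7.2, 5.0)])
        assert (c.category, c.verdict) == ("CO", "supportive")
        assert set(c.enriched) == {"TGT", "OTHER"}

    def test_off_target(self):
        c = self.classify([("TGT", 7.5, 1.0), ("OTHER", 7.2, 5.0)])
        assert (c.category, c.verdict) == ("OFF", "uncertain")

    def test_no_target(self):
        c = self.classify([("TGT", 7.5, 2.0), ("OTHER", 7.2, 1.0)])
        assert (c.category, c.verdict) == ("NO", "uncertain")

    def test_no_z_data_is_no_with_warning(self):
        c = self.classify([("TGT", float("nan"), float("nan"))])
        assert c.category == "NO"
        assert c.warning is not None
        assert not c.target_detected

    def test_negative_control_off_or_no(self):
        off = self.classify([("OTHER", 7.2, 5.0)], targets=())
        assert (off.category, off.is_control) == ("OFF", True)
        no = self.classify([("OTHER", 7.2, 1.0)], targets=())
        assert no.category == "NO"

    def test_target_matching_case_insensitive_gene_symbol(self):
        prots = proteins_frame(["P1", "P2"], genes=["MyGene", "Other"])
        c = classify_antibody(
            "ab", "heat",
            pd.DataFrame(
                {"antibody_id": "ab", "protein": ["P1"], "merged_intensity": [7.5],
                 "z": [4.2]}
            ),
            ["mygene"], prots,
        )
        assert c.category == "ON"

    def test_determinism(self):
        rows = [("TGT", 7.5, 4.0), ("OTHER", 7.2, 5.5), ("THIRD", 6.0, 2.0)]
        a, b = self.classify(rows), self.classify(rows)
        assert a == b


class TestInteractors:
    @pytest.mark.parametrize(
        "z, intensity, expected",
        [
            (5.2, 2e7, True),    # both criteria met
            (8.0, 5e6, False),   # intensity below 1e7
            (4.9, 2e7, False),   # z below 5
            (5.0, 1e7, True),    # boundaries inclusive
        ],
    )
    def test_thresholds(self, z, intensity, expected):
        table = ab_table([("X", math.log10(intensity), z)])
        assert (call_interactors(table, set()) == ["X"]) == expected

    def test_bait_excluded(self):
        table = ab_table([("TGT", 8.0, 9.0), ("X", 7.5, 6.0)])
        assert call_interactors(table, {"TGT"}) == ["X"]

    def test_interactors_subset_of_enriched(self):
        rng = np.random.default_rng(8)
        rows = [
            (f"P{i}", rng.uniform(5, 9), rng.uniform(-2, 8)) for i in range(40)
        ]
        table = ab_table(rows)
        cfg = PipelineConfig()
        inter = set(call_interactors(table, set(), cfg))
        enriched = set(table.loc[table["z"] >= cfg.z_enriched, "protein"])
        assert inter <= enriched


class TestContaminants:
    def test_strict_threshold(self):
        f = {"heat": pd.Series({"A": 0.21, "B": 0.20, "C": 0.05})}
        ann = annotate_contaminants(f)
        assert bool(ann.loc["A", "is_contaminant_heat"])
        assert not ann.loc["B", "is_contaminant_heat"]
        assert not ann.loc["C", "is_contaminant_heat"]

    def test_union_and_common_flags(self):
        f = {
            "heat": pd.Series({"A": 0.25, "B": 0.30}),
            "untreated": pd.Series({"A": 0.05, "B": 0.30}),
        }
        ann = annotate_contaminants(f)
        assert bool(ann.loc["A", "is_contaminant_heat"])
        assert not ann.loc["A", "is_contaminant_untreated"]
        assert bool(ann.loc["A", "is_contaminant_union"])
        assert not ann.loc["A", "is_contaminant_common"]
        assert bool(ann.loc["B", "is_contaminant_common"])


class TestPlotData:
    @pytest.mark.parametrize(
        "z, intensity, color",
        [
            (5.5, 2e7, "green"),
            (3.5, 2e7, "yellow"),
            (3.5, 5e6, "red"),
            (2.0, 2e7, "none"),
        ],
    )
    def test_color_legend(self, z, intensity, color):
        table = ab_table([("X", math.log10(intensity), z)])
        assert plot_enrichment_profile(table)["color"].iloc[0] == color

    def test_classes_partition_enriched_points(self):
        rng = np.random.default_rng(11)
        rows = [
            (f"P{i}", rng.uniform(5, 9), rng.uniform(-2, 9)) for i in range(200)
        ]
        data = plot_enrichment_profile(ab_table(rows))
        colored = data["color"] != "none"
        assert (colored == (data["z"] > 3)).all()
        assert set(data["color"]) <= {"green", "yellow", "red", "none"}


class TestConcordance:
    def _cls(self, ab, interactors, treatment="heat"):
        return classify_antibody(
            ab, treatment,
            pd.DataFrame(
                {
                    "antibody_id": ab,
                    "protein": interactors,
                    "merged_intensity": [8.0] * len(interactors),
                    "z": [6.0] * len(interactors),
                }
            ),
            ["TGT"],
            proteins_frame(["TGT"] + interactors),
        )

    def _meta(self, abs_):
        return make_metadata(
            [f"i{k}" for k in range(len(abs_))], abs_, ["heat"] * len(abs_),
            targets=["TGT"] * len(abs_),
        )

    def test_shared_interactors_flagged_concordant(self):
        cls = [self._cls("ab1", ["IGF1L", "IGF2L"]), self._cls("ab2", ["IGF1L", "IGF2L"])]
        rep = concordance_paired_antibodies(cls, self._meta(["ab1", "ab2"]))
        assert rep.loc[0, "concordant"] == "IGF1L;IGF2L"
        assert rep.loc[0, "intersection"] == "IGF1L;IGF2L"

    def test_disjoint_sets_have_empty_concordance(self):
        cls = [self._cls("ab1", ["A"]), self._cls("ab2", ["B"])]
        rep = concordance_paired_antibodies(cls, self._meta(["ab1", "ab2"]))
        assert rep.loc[0, "concordant"] == ""
        assert rep.loc[0, "union"] == "A;B"

    def test_single_antibody_target_skipped(self):
        cls = [self._cls("ab1", ["A"])]
        rep = concordance_paired_antibodies(cls, self._meta(["ab1"]))
        assert rep.empty


def test_merge_verdicts_supportive_if_either_treatment():
    prots = proteins_frame(["TGT", "OTHER"])
    heat = classify_antibody(
        "ab", "heat", ab_table([("TGT", 7.0, 1.0)]), ["TGT"], prots
    )
    unt = classify_antibody(
        "ab", "untreated", ab_table([("TGT", 7.0, 4.0)]), ["TGT"], prots
    )
    merged = merge_verdicts([heat, unt])
    assert merged.loc[0, "merged_verdict"] == "supportive"
    assert merged.loc[0, "category_heat"] == "NO"
    assert merged.loc[0, "category_untreated"] == "ON"
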