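"""Genomic alterations, weight tables and the additive classifier score."""

import json

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thyrisk.errors import ParseError, ValidationError
from thyrisk.genomics import (
    AlterationClass,
    GenomicAlteration,
    WeightTable,
    annotate_alteration,
    compute_xgc,
    infer_alteration_class,
    load_weight_table,
)

BRAF = GenomicAlteration("BRAF", AlterationClass.SNV, "p.Val600Glu")


def alt(gene="G", cls=AlterationClass.SNV, detail="p.X1Y"):
    return GenomicAlteration(gene, cls, detail)


class TestWeightTableLoading:
    def test_json_round_trip_single_entry(self, tmp_path):
        p = tmp_path / "w.json"
        p.write_text(json.dumps({"BRAF:p.Val600Glu": 0.95}))
        table = load_weight_table(p)
        assert len(table) == 1
        assert table.entries["BRAF:p.Val600Glu"] == 0.95

    def test_json_fallback_key(self, tmp_path):
        p = tmp_path / "w.json"
        p.write_text(json.dumps({"X:1": 0.5, "_fallback": 0.1}))
        assert load_weight_table(p).fallback_weight == 0.1

    def test_weight_out_of_range_rejected(self, tmp_path):
        p = tmp_path / "w.json"
        p.write_text(json.dumps({"X:1": 1.3}))
        with pytest.raises(ValidationError, match="outside"):
            load_weight_table(p)

    def test_duplicate_identifier_in_tsv_rejected(self, tmp_path):
        p = tmp_path / "w.tsv"
        p.write_text("identifier\tweight\nA:1\t0.5\nA:1\t0.6\n")
        with pytest.raises(ParseError, match="duplicate"):
            load_weight_table(p)

    def test_tsv_with_comments_and_provenance(self, tmp_path):
        p = tmp_path / "w.tsv"
        p.write_text(
            "# curated defaults\nidentifier\tweight\tprovenance\n"
            "BRAF:p.Val600Glu\t0.95\tTCGA/COSMIC\n_fallback\t0.05\n"
        )
        table = load_weight_table(p)
        assert table.entries["BRAF:p.Val600Glu"] == 0.95
        assert table.provenance["BRAF:p.Val600Glu"] == "TCGA/COSMIC"
        assert table.fallback_weight == 0.05

    def test_missing_file(self, tmp_path):
        with pytest.raises(ParseError, match="not found"):
            load_weight_table(tmp_path / "absent.tsv")

    @pytest.mark.parametrize("body", ["A:1\t0.5\n", "identifier\tweight\nA:1\n"])
    def test_malformed_tsv(self, tmp_path, body):
        p = tmp_path / "w.tsv"
        p.write_text(body)
        with pytest.raises(ParseError):
            load_weight_table(p)


class TestAnnotation:
    def test_known_identifier_lookup(self):
        table = WeightTable(entries={"BRAF:p.Val600Glu": 0.95})
        assert annotate_alteration(BRAF, table) == 0.95

    @pytest.mark.parametrize("fallback", [0.0, 0.1])
    def test_unknown_uses_fallback_with_warning(self, fallback, caplog):
        table = WeightTable(entries={}, fallback_weight=fallback)
        with caplog.at_level("WARNING", logger="thyrisk.genomics"):
            assert annotate_alteration(BRAF, table) == fallback
        assert "fallback" in caplog.text

    def test_identifier_normalization(self):
        a = GenomicAlteration("braf", AlterationClass.SNV, "  p.Val600Glu ")
        assert a.identifier == "BRAF:p.Val600Glu"


class TestComputeXgc:
    def test_empty_list_scores_zero(self, weights):
        profile = compute_xgc([], weights)
        assert profile.x_gc == 0.0
        assert profile.components == (0.0, 0.0, 0.0)

    def test_single_snv(self):
        table = WeightTable(entries={BRAF.identifier: 0.95})
        assert compute_xgc([BRAF], table).x_gc == pytest.approx(0.95)

    def test_components_sum_without_cap(self):
        table = WeightTable(
            entries={"A:p.X1Y": 0.5, "B:p.X2Y": 0.3, "C:amplification": 0.25}
        )
        profile = compute_xgc(
            [
                alt("A", AlterationClass.SNV, "p.X1Y"),
                alt("B", AlterationClass.SNV, "p.X2Y"),
                alt("C", AlterationClass.CNV, "amplification"),
            ],
            table,
        )
        assert profile.components == pytest.approx((0.8, 0.0, 0.25))
        assert profile.x_gc == pytest.approx(1.05)  # the additive score has no cap

    def test_fusion_component(self):
        fusion = GenomicAlteration("PAX8", AlterationClass.GENE_FUSION, "PAX8-PPARG")
        table = WeightTable(entries={fusion.identifier: 0.9})
        assert compute_xgc([fusion], table).components == pytest.approx((0.0, 0.9, 0.0))


_alterations = st.lists(
    st.builds(
        GenomicAlteration,
        gene=st.sampled_from(["BRAF", "NRAS", "RET", "PAX8", "CCND1"]),
        alteration_class=st.sampled_from(list(AlterationClass)),
        detail=st.sampled_from(["p.A1B", "p.C2D", "amplification", "X-Y"]),
    ),
    max_size=6,
)
_weights_strategy = st.fixed_dictionaries(
    {},
    optional={
        f"{g}:{d}": st.floats(0, 1)
        for g in ["BRAF", "NRAS", "RET", "PAX8", "CCND1"]
        for d in ["p.A1B", "p.C2D", "amplification", "X-Y"]
    },
)


class TestScoreProperties:
    @settings(derandomize=True, max_examples=60)
    @given(a=_alterations, b=_alterations, w=_weights_strategy)
    def test_additive_over_disjoint_lists_and_permutation_invariant(self, a, b, w):
        table = WeightTable(entries=w, fallback_weight=0.25)
        total = compute_xgc(a + b, table).x_gc
        assert total == pytest.approx(compute_xgc(a, table).x_gc + compute_xgc(b, table).x_gc)
        assert compute_xgc(list(reversed(a + b)), table).x_gc == pytest.approx(total)

    @settings(derandomize=True, max_examples=60)
    @given(a=_alterations, w=_weights_strategy)
    def test_positive_weight_strictly_increases_score(self, a, w):
        table = WeightTable(entries={**w, "BRAF:p.A1B": 0.4})
        extra = alt("BRAF", AlterationClass.SNV, "p.A1B")
        assert compute_xgc(a + [extra], table).x_gc > compute_xgc(a, table).x_gc

    @settings(derandomize=True, max_examples=30)
    @given(a=_alterations)
    def test_all_zero_weights_score_zero(self, a):
        table = WeightTable(entries={}, fallback_weight=0.0)
        assert compute_xgc(a, table).x_gc == 0.0


class TestClassInference:
    @pytest.mark.parametrize(
        "detail,expected",
        [
            ("p.Val600Glu", AlterationClass.SNV),
            ("c.1-124C>T", AlterationClass.SNV),
            ("p.Glu23del", AlterationClass.INDEL),
            ("p.Thr20dup", AlterationClass.INDEL),
            ("PAX8-PPARG", AlterationClass.GENE_FUSION),
            ("amplification", AlterationClass.CNV),
            ("deletion", AlterationClass.CNV),
        ],
    )
    def test_inference_rules(self, detail, expected):
        assert infer_alteration_class(detail) is expected

    def test_from_identifier(self):
        a = GenomicAlteration.from_identifier("BRAF:p.Val600Glu")
        assert a == BRAF
        with pytest.raises(ParseError):
            GenomicAlteration.from_identifier("no-colon")
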