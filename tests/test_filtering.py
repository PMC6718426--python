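"""The somatic filter cascade: per-rule behaviour, two-pass cohort
filtering, idempotence, monotonicity and the burden statistic."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mocprog.filtering import (CohortContext, FilterDecision,
                               build_cohort_context, classify_variant,
                               filter_cohort, variants_per_mb)
from mocprog.model import CaseRecord, ThresholdConfig
from mocprog.simulate import CohortSpec, simulate_cohort, true_somatic_keys

from conftest import make_variant

CTX = CohortContext()


def decide(v, mode="exome_paired", ctx=CTX, cfg=None):
    return classify_variant(v, mode, ctx, cfg)


class TestSingleRules:
    def test_clean_paired_variant_kept(self):
        v = make_variant(qual=45.0, depth=60, alt_depth=9, vaf_tumor=0.15,
                         vaf_normal=0.0, pop_af=None,
                         callers=frozenset({"VarDict", "Platypus"}))
        assert decide(v) == FilterDecision(True, ())

    def test_varscan_only_rejected_every_mode(self):
        v = make_variant(callers=frozenset({"VarScan"}), vaf_normal=None)
        for mode in ("exome_unpaired", "panel"):
            d = decide(make_variant(callers=frozenset({"VarScan"}),
                                    vaf_normal=None,
                                    depth=100, alt_depth=30), mode)
            assert d.reasons == ("caller_concordance",)
        d = decide(make_variant(callers=frozenset({"VarScan"})), "exome_paired")
        assert "caller_concordance" in d.reasons

    def test_ug_only_rejected_only_when_unpaired(self):
        kw = dict(callers=frozenset({"UnifiedGenotyper"}), depth=100,
                  alt_depth=30)
        assert decide(make_variant(**kw), "exome_paired").keep
        assert not decide(make_variant(**kw, vaf_normal=None),
                          "exome_unpaired").keep
        assert not decide(make_variant(**kw, vaf_normal=None), "panel").keep

    def test_panel_depth_minimums(self):
        v = make_variant(depth=19, alt_depth=10, vaf_normal=None)
        assert decide(v, "panel").reasons == ("depth",)
        v = make_variant(depth=25, alt_depth=9, vaf_normal=None)
        assert decide(v, "panel").reasons == ("alt_depth",)
        # the same numbers pass in exome mode
        assert decide(make_variant(depth=19, alt_depth=9, vaf_tumor=9 / 19)).keep

    def test_quality_and_vaf_rules(self):
        assert decide(make_variant(qual=29.9)).reasons == ("qual",)
        assert decide(make_variant(qual=None)).reasons == ("qual",)
        assert decide(make_variant(depth=9, alt_depth=2,
                                   vaf_tumor=2 / 9)).reasons == ("depth",)
        assert decide(make_variant(vaf_tumor=0.05)).reasons == ("vaf_tumor",)
        assert decide(make_variant(vaf_tumor=0.051)).keep

    def test_population_af_with_clinvar_rescue(self):
        assert decide(make_variant(pop_af=2e-4)).reasons == ("population_af",)
        assert decide(make_variant(pop_af=1e-4)).keep  # at the cutoff: kept
        assert decide(make_variant(pop_af=2e-4, clinvar_pathogenic=True)).keep

    def test_germline_leak_rejected_in_paired(self):
        v = make_variant(vaf_normal=0.3)
        assert decide(v).reasons == ("normal_vaf",)
        with pytest.raises(ValueError, match="vaf_normal"):
            decide(make_variant(vaf_normal=None), "exome_paired")

    def test_blacklist_and_panel_of_normals(self):
        ctx = CohortContext(blacklist=frozenset({"TP53"}))
        assert decide(make_variant(), ctx=ctx).reasons == ("blacklist",)
        v = make_variant()
        ctx = CohortContext(pon_hits={v.key: 2})
        assert decide(v, ctx=ctx).reasons == ("panel_of_normals",)
        ctx = CohortContext(pon_hits={v.key: 1})  # "more than one" only
        assert decide(v, ctx=ctx).keep

    def test_cohort_recurrence_spares_hotspots(self):
        v = make_variant(is_hotspot=False)
        ctx = CohortContext(cohort_fractions={v.key: 0.35})
        assert decide(v, ctx=ctx).reasons == ("cohort_recurrence",)
        h = make_variant(is_hotspot=True, gene="KRAS", effect="missense")
        ctx = CohortContext(cohort_fractions={h.key: 0.35})
        assert decide(h, ctx=ctx).keep

    def test_batch_normals_panel_only(self):
        v = make_variant(vaf_normal=None)
        ctx = CohortContext(batch_normal_keys=frozenset({v.key}))
        assert decide(v, "panel", ctx=ctx).reasons == ("batch_normals",)
        assert decide(v, "exome_unpaired", ctx=ctx).keep

    def test_all_violations_reported(self):
        v = make_variant(qual=10.0, depth=5, alt_depth=1, vaf_tumor=0.02,
                         callers=frozenset({"VarScan"}),
                         passes_caller_filters=False, vaf_normal=0.5)
        d = decide(v)
        assert set(d.reasons) == {"qual", "depth", "alt_depth", "vaf_tumor",
                                  "normal_vaf", "caller_concordance",
                                  "caller_filters"}


class TestCohortFilter:
    def _cohort(self, n=10, carriers=3):
        shared = make_variant(pos=777, is_hotspot=False)
        cases = []
        for i in range(n):
            vs = [make_variant(pos=1000 + i)]
            if i < carriers:
                vs.append(make_variant(pos=777))
            cases.append(CaseRecord(f"c{i}", "G1", "exome_paired", variants=vs))
        return cases, shared

    def test_recurrent_variant_rejected_in_every_carrier(self):
        cases, shared = self._cohort(n=10, carriers=3)
        kept, ledger = filter_cohort(cases)
        for i in range(3):
            assert shared.key not in {v.key for v in kept[f"c{i}"]}
        assert ledger.rule_counts["cohort_recurrence"] == 3
        # at exactly 20% the variant is kept ("> 20%" rule)
        cases, shared = self._cohort(n=10, carriers=2)
        kept, _ = filter_cohort(cases)
        assert shared.key in {v.key for v in kept["c0"]}

    def test_idempotent(self):
        cases, _ = simulate_cohort(CohortSpec(seed=9, n_per_group={"G1": 30}))
        kept1, _ = filter_cohort(cases)
        refiltered = [CaseRecord(c.case_id, c.classification, c.platform_mode,
                                 variants=kept1[c.case_id])
                      for c in cases]
        kept2, ledger2 = filter_cohort(refiltered)
        assert ledger2.n_rejected == 0
        for c in cases:
            assert [v.key for v in kept2[c.case_id]] == \
                   [v.key for v in kept1[c.case_id]]

    def test_empty_cohort_error(self):
        with pytest.raises(ValueError):
            filter_cohort([])

    def test_synthetic_truth_recovered(self):
        cases, _ = simulate_cohort(CohortSpec(seed=10, n_per_group={
            "G1": 50, "G2": 50, "G3": 50}))
        kept, _ = filter_cohort(cases)
        for c in cases:
            assert {v.key for v in kept[c.case_id]} == true_somatic_keys(c)

    @given(qual_min=st.floats(30, 200))
    @settings(max_examples=25, deadline=None)
    def test_raising_threshold_never_grows_kept_set(self, qual_min):
        cases, _ = simulate_cohort(CohortSpec(seed=12, n_per_group={"G2": 10}))
        base, _ = filter_cohort(cases, ThresholdConfig())
        strict, _ = filter_cohort(cases, ThresholdConfig(qual_min=qual_min))
        for cid in base:
            assert {v.key for v in strict[cid]} <= {v.key for v in base[cid]}


class TestBurden:
    PANEL = frozenset({"TP53", "KRAS"})

    def test_zero_variants(self):
        assert variants_per_mb([], self.PANEL) == 0.0

    def test_divides_by_target_size(self):
        vs = [make_variant(pos=i) for i in range(207)]
        assert variants_per_mb(vs, self.PANEL) == pytest.approx(100.0)

    def test_only_coding_splice_in_panel_counted(self):
        vs = ([make_variant(pos=i, consequence="coding", gene="TP53")
               for i in range(4)]
              + [make_variant(pos=10 + i, consequence="coding", gene="ZZZ9")
                 for i in range(2)]
              + [make_variant(pos=20, consequence="other", gene="TP53")])
        assert variants_per_mb(vs, self.PANEL) == pytest.approx(4 / 2.07)

    def test_bad_target(self):
        with pytest.raises(ValueError):
            variants_per_mb([], self.PANEL, target_mb=0)
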