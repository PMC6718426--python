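"""Copy-number calls, FGA with a per-base brute-force oracle, profile
rules, region comparison and minimal amplicon overlap."""

import numpy as np
import pytest
from scipy.stats import fisher_exact

from mocprog.cnv import (RegionComparison, call_segments, classify_profile,
                         compare_group_frequencies, fraction_genome_altered,
                         minimal_overlap_region)
from mocprog.genome import GenomeBuild
from mocprog.model import CaseRecord, CNSegment


def seg(chrom, start, end, log2=0.0, call=None, loh=False):
    return CNSegment(chrom, start, end, log2, call=call, loh=loh)


class TestCalls:
    @pytest.mark.parametrize("log2,expected", [
        (-1.2, "homdel"), (-1.0, "loss"), (-0.5, "loss"), (-0.2, "loss"),
        (-0.19, "neutral"), (0.0, "neutral"), (0.19, "neutral"),
        (0.2, "gain"), (0.5, "gain"), (0.6, "gain"), (0.61, "amp"),
        (0.7, "amp"),
    ])
    def test_thresholds_and_boundaries(self, log2, expected):
        (called,) = call_segments([seg("chr1", 0, 10, log2)])
        assert called.call == expected


def brute_force_fga(segments, build):
    """Independent per-base count of altered positions."""
    fracs = []
    for chrom in build.chrom_names:
        mask = np.zeros(build.length(chrom), dtype=bool)
        for s in segments:
            if s.chrom == chrom and s.call != "neutral":
                mask[s.start:s.end] = True
        fracs.append(mask.sum() / build.length(chrom))
    return float(np.mean(fracs))


def random_profile(rng, build, max_segs=12):
    segments = []
    for chrom in build.chrom_names:
        points = sorted(rng.choice(build.length(chrom),
                                   size=2 * rng.integers(0, max_segs // 2 + 1),
                                   replace=False))
        for a, b in zip(points[::2], points[1::2]):
            if a < b:
                segments.append(seg(chrom, int(a), int(b),
                                    float(rng.uniform(-2, 2))))
    return call_segments(segments)


class TestFGA:
    def test_no_alterations(self, toy_build):
        assert fraction_genome_altered(
            [seg("chrA", 0, 50, 0.0, call="neutral")], toy_build) == 0.0

    def test_whole_chromosome_loss_definition(self, toy_build):
        # chrA fully lost, chrB untouched: (1.0 + 0.0) / 2
        segs = [seg("chrA", 0, 100, -0.5, call="loss")]
        assert fraction_genome_altered(segs, toy_build) == pytest.approx(0.5)

    def test_matches_per_base_oracle(self, toy_build_large, rng):
        for _ in range(40):
            segs = random_profile(rng, toy_build_large)
            assert fraction_genome_altered(segs, toy_build_large) == \
                pytest.approx(brute_force_fga(segs, toy_build_large), abs=1e-12)

    def test_monotone_in_alterations(self, toy_build):
        neutral = seg("chrB", 0, 80, 0.0, call="neutral")
        base = [seg("chrA", 0, 30, 0.4, call="gain"), neutral]
        more = [base[0], seg("chrB", 0, 80, -0.5, call="loss")]
        assert fraction_genome_altered(more, toy_build) >= \
            fraction_genome_altered(base, toy_build)

    def test_requires_calls_and_bounds(self, toy_build):
        with pytest.raises(ValueError, match="no call"):
            fraction_genome_altered([seg("chrA", 0, 10, 0.3)], toy_build)
        with pytest.raises(ValueError, match="beyond"):
            fraction_genome_altered(
                [seg("chrA", 0, 150, 0.3, call="gain")], toy_build)


class TestProfileClassification:
    BUILD = GenomeBuild(tuple(f"chr{i}" for i in range(1, 9)),
                        {f"chr{i}": 1000 for i in range(1, 9)}, name="toy8")

    def test_no_alterations_is_simple(self):
        segs = [seg("chr1", 0, 500, 0.0, call="neutral")]
        assert classify_profile(segs, self.BUILD) == "simple"

    def test_multi_chromosome_amps_dominate(self):
        segs = call_segments(
            [seg("chr1", 0, 100, -0.5), seg("chr2", 0, 100, 0.3),
             seg("chr3", 0, 50, 0.9), seg("chr4", 0, 50, 0.9),
             seg("chr5", 0, 50, 0.9)])
        assert classify_profile(segs, self.BUILD) == "complex_multi_amp"

    def test_single_amp_with_few_events(self):
        segs = call_segments([seg("chr1", 0, 100, -0.5),
                              seg("chr3", 0, 50, 0.9)])
        assert classify_profile(segs, self.BUILD) == "simple_one_amp"

    def test_whole_chromosome_dominated_complex(self):
        segs = [seg(f"chr{i}", 0, 1000, 0.4, call="gain") for i in (1, 2, 3)]
        segs += [seg("chr4", i * 20, i * 20 + 10, -0.5, call="loss")
                 for i in range(8)]
        assert len([s for s in segs if s.call != "neutral"]) >= 10
        assert classify_profile(segs, self.BUILD) == "complex_whole_chr"

    def test_complex_without_whole_chromosomes(self):
        segs = [seg("chr1", i * 60, i * 60 + 30, -0.5, call="loss")
                for i in range(12)]
        assert classify_profile(segs, self.BUILD) == "complex"

    def test_invariant_to_order_and_splitting(self):
        segs = call_segments(
            [seg("chr1", 0, 100, -0.5), seg("chr2", 0, 100, 0.3),
             seg("chr3", 0, 50, 0.9)])
        label = classify_profile(segs, self.BUILD)
        assert classify_profile(segs[::-1], self.BUILD) == label
        split = call_segments(
            [seg("chr1", 0, 40, -0.5), seg("chr1", 40, 100, -0.5),
             seg("chr2", 0, 100, 0.3), seg("chr3", 0, 50, 0.9)])
        assert classify_profile(split, self.BUILD) == label


def group(n, case_segs, prefix, build):
    return [CaseRecord(f"{prefix}{i}", "G1", "panel",
                       segments=call_segments(case_segs(i)))
            for i in range(n)]


class TestGroupComparison:
    BUILD = GenomeBuild(("chr1",), {"chr1": 1000}, name="one")

    def _groups(self, a_gain, b_gain, n=20):
        g1 = group(n, lambda i: [seg("chr1", 0, 500, 0.4 if i < a_gain else 0.0)],
                   "a", self.BUILD)
        g2 = group(n, lambda i: [seg("chr1", 0, 500, 0.4 if i < b_gain else 0.0)],
                   "b", self.BUILD)
        return g1, g2

    def test_no_aberration_not_significant(self):
        g1, g2 = self._groups(0, 0)
        out = compare_group_frequencies(g1, g2, self.BUILD)
        assert all(r.p_value == 1.0 and not r.significant for r in out)

    def test_strong_difference_detected(self):
        g1, g2 = self._groups(18, 2)
        out = [r for r in compare_group_frequencies(g1, g2, self.BUILD)
               if r.direction == "gain"]
        (r,) = out
        expected_p = fisher_exact([[18, 2], [2, 18]])[1]
        assert r.p_value == pytest.approx(expected_p)
        assert r.freq_diff == pytest.approx(0.8)
        assert r.significant

    def test_swapping_groups_preserves_p(self):
        g1, g2 = self._groups(12, 3)
        a = compare_group_frequencies(g1, g2, self.BUILD)
        b = compare_group_frequencies(g2, g1, self.BUILD)
        assert [r.p_value for r in a] == pytest.approx([r.p_value for r in b])

    def test_cnp_overlap_excludes(self):
        g1, g2 = self._groups(18, 2)
        out = compare_group_frequencies(
            g1, g2, self.BUILD, cnp_track=[("chr1", 0, 480)])
        (r,) = [r for r in out if r.direction == "gain"]
        assert r.cnp_overlap > 0.90 and not r.significant

    def test_platform_artifact_excludes(self):
        g1, g2 = self._groups(18, 2)
        out = compare_group_frequencies(
            g1, g2, self.BUILD,
            platform_artifact_regions=[("chr1", 100, 200)])
        (r,) = [r for r in out if r.direction == "gain"]
        assert r.platform_artifact and not r.significant

    def test_empty_group_rejected(self):
        g1, _ = self._groups(1, 1)
        with pytest.raises(ValueError):
            compare_group_frequencies(g1, [], self.BUILD)


class TestMinimalOverlap:
    def test_two_case_intersection(self):
        cases = {"a": [seg("chr9", 10, 50, 0.9, call="amp")],
                 "b": [seg("chr9", 30, 70, 0.9, call="amp")]}
        assert minimal_overlap_region(cases, "chr9") == [(30, 50)]

    def test_identical_segments(self):
        s = seg("chr9", 5, 25, 0.9, call="amp")
        assert minimal_overlap_region({"a": [s], "b": [s]}, "chr9") == [(5, 25)]

    def test_planted_core_recovered(self, rng):
        # 17 cases, each an amp spanning a common core with random flanks
        core = (33_785_000, 35_159_000)
        cases = {}
        for i in range(17):
            # two tight cases realize the core boundaries; others flank
            start = core[0] - int(rng.integers(0, 3_000_000)) if i != 0 else core[0]
            end = core[1] + int(rng.integers(0, 3_000_000)) if i != 1 else core[1]
            segs = [seg("chr9", start, end, 1.0, call="amp")]
            if rng.random() < 0.5:  # unrelated distal amp
                segs.append(seg("chr9", 90_000_000 + i * 10_000,
                                90_005_000 + i * 10_000, 1.0, call="amp"))
            cases[f"case{i}"] = segs
        assert minimal_overlap_region(cases, "chr9") == [core]

    def test_case_without_amp_named(self):
        cases = {"good": [seg("chr9", 10, 50, 0.9, call="amp")],
                 "bad": [seg("chr9", 10, 50, -0.5, call="loss")]}
        with pytest.raises(ValueError, match="bad"):
            minimal_overlap_region(cases, "chr9")
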