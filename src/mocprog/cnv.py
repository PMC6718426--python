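"""Copy-number analyses: discrete calls, fraction of genome altered,
profile-type classification, group frequency comparison and minimal
amplicon overlap.

Call thresholds on the log2 ratio: gains and losses at |log2| >= 0.2, high
level amplification at log2 > 0.6, homozygous deletion at log2 < -1. The
boundary values +/-0.2 are assigned to gain/loss; amp and homdel use
strict inequalities.

FGA (fraction of genome altered) is the per-chromosome fraction of bases
affected by copy-number change, averaged over ALL chromosomes of the
build; chromosomes with no segments contribute zero. Copy-neutral LOH does
not count as altered (the definition is change in copy number).
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import fisher_exact

from .genome import GenomeBuild
from .model import CaseRecord, CNSegment, ThresholdConfig

PROFILE_TYPES = ("simple", "simple_one_amp", "complex", "complex_whole_chr",
                 "complex_multi_amp")

Interval = tuple[str, int, int]  # chrom, start, end (half-open)


def call_segments(segments: list[CNSegment],
                  cfg: ThresholdConfig | None = None) -> list[CNSegment]:
    """Return segments with discrete calls assigned from log2 ratios."""
    cfg = cfg or ThresholdConfig()
    out = []
    for s in segments:
        if s.log2 < cfg.log2_homdel:
            call = "homdel"
        elif s.log2 <= cfg.log2_loss:
            call = "loss"
        elif s.log2 < cfg.log2_gain:
            call = "neutral"
        elif s.log2 <= cfg.log2_amp:
            call = "gain"
        else:
            call = "amp"
        out.append(CNSegment(s.chrom, s.start, s.end, s.log2, call=call, loh=s.loh))
    return out


def _require_called(segments: list[CNSegment]) -> None:
    for s in segments:
        if s.call is None:
            raise ValueError(
                f"segment {s.chrom}:{s.start}-{s.end} has no call; run "
                "call_segments first")


def fraction_genome_altered(segments: list[CNSegment],
                            build: GenomeBuild) -> float:
    """Mean over build chromosomes of (bases with call != neutral) / length."""
    _require_called(segments)
    altered: dict[str, int] = {c: 0 for c in build.chrom_names}
    for s in segments:
        if s.chrom not in build:
            raise ValueError(f"segment chromosome {s.chrom!r} not in build")
        if s.end > build.length(s.chrom):
            raise ValueError(
                f"segment {s.chrom}:{s.start}-{s.end} beyond chromosome end")
        if s.call != "neutral":
            altered[s.chrom] += s.length
    fracs = [altered[c] / build.length(c) for c in build.chrom_names]
    return sum(fracs) / build.n_chromosomes


def _coalesce(segments: list[CNSegment]) -> list[CNSegment]:
    """Merge adjacent same-call segments into single events, so that
    classification is invariant to splitting a segment into equal-call
    pieces."""
    out: list[CNSegment] = []
    for s in sorted(segments, key=lambda s: (s.chrom, s.start)):
        if (out and out[-1].chrom == s.chrom and out[-1].call == s.call
                and out[-1].end >= s.start):
            prev = out.pop()
            s = CNSegment(s.chrom, prev.start, max(prev.end, s.end), prev.log2,
                          call=s.call, loh=prev.loh or s.loh)
        out.append(s)
    return out


def classify_profile(segments: list[CNSegment], build: GenomeBuild,
                     cfg: ThresholdConfig | None = None,
                     complexity_cutoff: int = 10,
                     whole_chrom_fraction: float = 0.95,
                     whole_chrom_share: float = 0.80) -> str:
    """Assign one of the five global copy-number profile types.

    Rules (in precedence order, all cutoffs configurable):

    1. amplifications on >= 2 chromosomes -> ``complex_multi_amp``;
    2. fewer than ``complexity_cutoff`` altered autosomal events ->
       ``simple_one_amp`` when exactly one chromosome bears an amp,
       else ``simple``;
    3. otherwise complex: ``complex_whole_chr`` when at least
       ``whole_chrom_share`` of altered bases come from whole-chromosome
       events (covering >= ``whole_chrom_fraction`` of their chromosome),
       else ``complex``.
    """
    _require_called(segments)
    events = [s for s in _coalesce(segments) if s.call != "neutral"]
    amp_chroms = {s.chrom for s in events if s.call == "amp"}
    if len(amp_chroms) >= 2:
        return "complex_multi_amp"
    autosomal = [s for s in events
                 if s.chrom not in ("chrX", "X", "chrY", "Y")]
    if len(autosomal) < complexity_cutoff:
        return "simple_one_amp" if len(amp_chroms) == 1 else "simple"
    altered_bases = sum(s.length for s in events)
    whole = sum(s.length for s in events
                if s.length >= whole_chrom_fraction * build.length(s.chrom))
    if altered_bases and whole / altered_bases >= whole_chrom_share:
        return "complex_whole_chr"
    return "complex"


# ------------------------------------------------- group comparison

@dataclass
class RegionComparison:
    """One minimal genomic interval compared between two case groups for
    one aberration direction."""

    chrom: str
    start: int
    end: int
    direction: str  # "gain" (gain or amp) | "loss" (loss or homdel)
    freq_group1: float
    freq_group2: float
    p_value: float
    cnp_overlap: float
    platform_artifact: bool
    significant: bool

    @property
    def freq_diff(self) -> float:
        return self.freq_group1 - self.freq_group2


_DIRECTION_CALLS = {"gain": ("gain", "amp"), "loss": ("loss", "homdel")}


def _overlap_fraction(chrom: str, start: int, end: int,
                      track: list[Interval]) -> float:
    covered = 0
    for (tc, ts, te) in track:
        if tc == chrom:
            covered += max(0, min(end, te) - max(start, ts))
    return covered / (end - start)


def compare_group_frequencies(
        group1: list[CaseRecord], group2: list[CaseRecord],
        build: GenomeBuild, cfg: ThresholdConfig | None = None,
        cnp_track: list[Interval] | None = None,
        platform_artifact_regions: list[Interval] | None = None,
        ) -> list[RegionComparison]:
    """Fisher-exact per-region aberration-frequency comparison.

    The genome is partitioned into minimal consistent intervals (the union
    of all segment breakpoints across both groups); within each interval
    and direction a 2x2 Fisher's exact test compares aberrant case counts.
    A region is significant when p < cfg.cmp_p, the absolute frequency
    difference is >= cfg.cmp_diff, the interval does not touch a platform
    artifact region, and its copy-number-polymorphism overlap is <=
    cfg.cnp_overlap.
    """
    if not group1 or not group2:
        raise ValueError("both groups need at least one case")
    cfg = cfg or ThresholdConfig()
    cnp_track = cnp_track or []
    artifacts = platform_artifact_regions or []
    for case in (*group1, *group2):
        _require_called(case.segments)

    breakpoints: dict[str, set[int]] = {}
    for case in (*group1, *group2):
        for s in case.segments:
            breakpoints.setdefault(s.chrom, set()).update((s.start, s.end))

    out: list[RegionComparison] = []
    for chrom in sorted(breakpoints, key=lambda c: build.chrom_names.index(c)
                        if c in build.chrom_names else len(build.chrom_names)):
        pts = sorted(breakpoints[chrom])
        for start, end in zip(pts, pts[1:]):
            def covers(case: CaseRecord) -> bool:
                return any(s.chrom == chrom and s.start <= start
                           and s.end >= end for s in case.segments)

            if not any(covers(c) for c in (*group1, *group2)):
                continue  # a gap between segments, not a measured region
            for direction, calls in _DIRECTION_CALLS.items():
                def aberrant(case: CaseRecord) -> bool:
                    return any(
                        s.chrom == chrom and s.start <= start and s.end >= end
                        and s.call in calls for s in case.segments)

                a1 = sum(aberrant(c) for c in group1)
                a2 = sum(aberrant(c) for c in group2)
                n1, n2 = len(group1), len(group2)
                _, p = fisher_exact([[a1, n1 - a1], [a2, n2 - a2]])
                f1, f2 = a1 / n1, a2 / n2
                cnp = _overlap_fraction(chrom, start, end, cnp_track)
                art = _overlap_fraction(chrom, start, end, artifacts) > 0
                sig = (p < cfg.cmp_p and abs(f1 - f2) >= cfg.cmp_diff
                       and not art and cnp <= cfg.cnp_overlap)
                out.append(RegionComparison(chrom, start, end, direction,
                                            f1, f2, float(p), cnp, art, sig))
    return out


# ------------------------------------------------- minimal overlap

def _union(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [tuple(x) for x in merged]


def _intersect(a: list[tuple[int, int]],
               b: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            out.append((s, e))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def minimal_overlap_region(
        amp_segments_by_case: dict[str, list[CNSegment]], chrom: str,
        arm: tuple[int, int] | None = None) -> list[tuple[int, int]]:
    """Intersection across cases of each case's union of amplified
    segments on ``chrom`` (optionally restricted to an ``arm`` interval).

    Returns the shared core as a list of half-open intervals (usually one);
    an empty list means no common region. A case contributing no amp on
    the target raises, naming the case.
    """
    core: list[tuple[int, int]] | None = None
    for case_id, segs in amp_segments_by_case.items():
        ivs = [(s.start, s.end) for s in segs
               if s.chrom == chrom and (s.call is None or s.call == "amp")]
        if arm is not None:
            ivs = _intersect(_union(ivs), [arm])
        else:
            ivs = _union(ivs)
        if not ivs:
            raise ValueError(
                f"case {case_id} has no amplified segment on {chrom}"
                + (f" within {arm}" if arm else ""))
        core = ivs if core is None else _intersect(core, ivs)
    return core or []
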