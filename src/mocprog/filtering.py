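"""The high-confidence somatic variant filter cascade.

Twelve conjunctive rules turn raw multi-caller calls into a high-confidence
somatic set, in all four platform modes (paired exome, unpaired exome, WGS,
targeted panel). WGS follows the paired-exome rule set. Each rejected
variant carries the ordered list of every rule it violated, so rule order
never changes the keep/reject outcome, only the reason ordering.

Rules, in application order:

1.  population allele frequency — exclude when the maximum AF across the
    population resources exceeds the cutoff (1e-4), unless the variant is
    ClinVar (potentially) pathogenic;
2.  QUAL >= 30 (absent QUAL fails);
3.  read depth >= 10 (panel: 20);
4.  alt-supporting reads >= 2 (panel: 10);
5.  tumor VAF > 0.05;
6.  paired modes only: normal VAF <= 0.05;
7.  gene not blacklisted;
8.  present in at most one panel-of-normals germline exome;
9.  present in <= 20% of the cohort, unless a known hotspot (e.g. KRAS
    codon 12);
10. caller concordance — exclude VarScan-only calls; in unpaired and panel
    modes also UnifiedGenotyper-only calls;
11. default caller filters passed;
12. panel mode only: absent from the batch normal samples.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .model import CaseRecord, ThresholdConfig, VariantCall

#: canonical somatic hotspots (gene -> codons); editable by the caller.
DEFAULT_HOTSPOTS: dict[str, tuple[int, ...]] = {
    "KRAS": (12, 13, 61),
    "BRAF": (600,),
    "PIK3CA": (542, 545, 1047),
    "TP53": (175, 245, 248, 273, 282),
}

RULES = (
    "population_af", "qual", "depth", "alt_depth", "vaf_tumor", "normal_vaf",
    "blacklist", "panel_of_normals", "cohort_recurrence", "caller_concordance",
    "caller_filters", "batch_normals",
)


@dataclass(frozen=True)
class FilterDecision:
    """Outcome of the cascade for one variant: keep iff no rule failed."""

    keep: bool
    reasons: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.keep != (len(self.reasons) == 0):
            raise ValueError("keep must hold exactly when reasons is empty")


@dataclass
class CohortContext:
    """Cohort-level evidence the per-variant rules need.

    ``cohort_fractions`` maps variant identity (chrom, pos, ref, alt) to
    the fraction of cohort cases carrying it; ``pon_hits`` to the number of
    panel-of-normals germline exomes carrying it; ``batch_normal_keys`` is
    the identity set seen in the panel batch normals.
    """

    cohort_fractions: dict[tuple, float] = field(default_factory=dict)
    pon_hits: dict[tuple, int] = field(default_factory=dict)
    blacklist: frozenset[str] = frozenset()
    batch_normal_keys: frozenset[tuple] = frozenset()

    def cohort_fraction(self, v: VariantCall) -> float:
        return self.cohort_fractions.get(v.key, 0.0)

    def pon_hit_count(self, v: VariantCall) -> int:
        return self.pon_hits.get(v.key, 0)


def classify_variant(v: VariantCall, mode: str, ctx: CohortContext,
                     cfg: ThresholdConfig | None = None) -> FilterDecision:
    """Run the full cascade on one variant; report every violated rule."""
    cfg = cfg or ThresholdConfig()
    reasons: list[str] = []

    if (v.pop_af is not None and v.pop_af > cfg.pop_af_max
            and not v.clinvar_pathogenic):
        reasons.append("population_af")
    if v.qual is None or v.qual < cfg.qual_min:
        reasons.append("qual")
    if v.depth < cfg.depth_min_for(mode):
        reasons.append("depth")
    if v.alt_depth < cfg.alt_depth_min_for(mode):
        reasons.append("alt_depth")
    if not v.vaf_tumor > cfg.vaf_min:
        reasons.append("vaf_tumor")
    if mode in ("exome_paired", "wgs"):
        if v.vaf_normal is None:
            raise ValueError(
                f"paired-mode variant {v.chrom}:{v.pos} lacks vaf_normal")
        if v.vaf_normal > cfg.normal_vaf_max:
            reasons.append("normal_vaf")
    if v.gene is not None and v.gene in ctx.blacklist:
        reasons.append("blacklist")
    if ctx.pon_hit_count(v) > cfg.pon_max_hits:
        reasons.append("panel_of_normals")
    if ctx.cohort_fraction(v) > cfg.cohort_recurrence_max and not v.is_hotspot:
        reasons.append("cohort_recurrence")
    only = v.callers
    if only == frozenset({"VarScan"}):
        reasons.append("caller_concordance")
    elif (mode in ("exome_unpaired", "panel")
          and only == frozenset({"UnifiedGenotyper"})):
        reasons.append("caller_concordance")
    if not v.passes_caller_filters:
        reasons.append("caller_filters")
    if mode == "panel" and v.key in ctx.batch_normal_keys:
        reasons.append("batch_normals")

    return FilterDecision(keep=not reasons, reasons=tuple(reasons))


@dataclass
class RejectionLedger:
    """Per-rule rejection tallies across a cohort filter run."""

    rule_counts: Counter = field(default_factory=Counter)
    n_input: int = 0
    n_kept: int = 0

    @property
    def n_rejected(self) -> int:
        return self.n_input - self.n_kept

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [{"rule": r, "rejections": self.rule_counts.get(r, 0)} for r in RULES]
        )


def build_cohort_context(cases: list[CaseRecord],
                         blacklist: frozenset[str] = frozenset(),
                         pon_hits: dict[tuple, int] | None = None,
                         batch_normal_keys: frozenset[tuple] = frozenset(),
                         ) -> CohortContext:
    """Pass 1: cohort recurrence over rule-independent variant identity."""
    n = len(cases)
    counts: Counter = Counter()
    for c in cases:
        for key in {v.key for v in c.variants}:
            counts[key] += 1
    fractions = {k: cnt / n for k, cnt in counts.items()}
    return CohortContext(fractions, pon_hits or {}, blacklist, batch_normal_keys)


def filter_cohort(cases: list[CaseRecord],
                  cfg: ThresholdConfig | None = None,
                  blacklist: frozenset[str] = frozenset(),
                  pon_hits: dict[tuple, int] | None = None,
                  batch_normal_keys: frozenset[tuple] = frozenset(),
                  ) -> tuple[dict[str, list[VariantCall]], RejectionLedger]:
    """Two-pass cohort filter: recurrence first, then the cascade per case.

    Returns per-case kept variants plus a per-rule rejection ledger.
    Idempotent: re-filtering the kept sets changes nothing (recurrence can
    only drop when computed on already-kept variants).
    """
    if not cases:
        raise ValueError("empty cohort")
    cfg = cfg or ThresholdConfig()
    ctx = build_cohort_context(cases, blacklist, pon_hits, batch_normal_keys)
    ledger = RejectionLedger()
    kept: dict[str, list[VariantCall]] = {}
    for case in cases:
        keep_list = []
        for v in case.variants:
            ledger.n_input += 1
            d = classify_variant(v, case.platform_mode, ctx, cfg)
            if d.keep:
                keep_list.append(v)
                ledger.n_kept += 1
            else:
                ledger.rule_counts.update(d.reasons)
        kept[case.case_id] = keep_list
    return kept, ledger


def variants_per_mb(kept: list[VariantCall],
                    panel_genes: frozenset[str] | None,
                    target_mb: float = 2.07) -> float:
    """Coding + splice-site burden per megabase of capture target.

    Only variants in the validation-panel gene set count (pass ``None`` to
    disable the gene restriction); the divisor is the panel target size in
    Mb, 2.07 by default.
    """
    if target_mb <= 0:
        raise ValueError(f"target_mb must be positive, got {target_mb}")
    n = sum(
        1 for v in kept
        if v.consequence in ("coding", "splice")
        and (panel_genes is None or (v.gene is not None and v.gene in panel_genes))
    )
    return n / target_mb
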