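"""Domain types for the mucinous ovarian tumor progression analyses.

Coordinate conventions: point variants are 1-based (VCF); copy-number
segments are half-open 0-based intervals (BED). All conversions happen at
the I/O boundary, never inside analysis code.
"""

from __future__ import annotations

from dataclasses import dataclass, field

CLASSIFICATIONS = ("BEN", "MBT", "G1", "G2", "G3", "EOM")
PLATFORM_MODES = ("exome_paired", "exome_unpaired", "wgs", "panel")
CALLERS = ("UnifiedGenotyper", "Platypus", "VarScan", "VarDict", "MuTect2")
CONSEQUENCES = ("coding", "splice", "other")
CN_CALLS = ("homdel", "loss", "neutral", "gain", "amp")
SV_TYPES = ("deletion", "duplication", "inversion", "translocation")


@dataclass
class VariantCall:
    """One called variant in one case, with the quality, caller and
    annotation evidence the somatic filter cascade consumes.

    Absent annotations are ``None``, never 0: an absent quality field fails
    the corresponding filter rather than passing silently.
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    qual: float | None
    depth: int
    alt_depth: int
    vaf_tumor: float
    vaf_normal: float | None = None
    callers: frozenset[str] = frozenset()
    passes_caller_filters: bool = True
    consequence: str = "other"
    gene: str | None = None
    pop_af: float | None = None  # max over ExAC-minus-TCGA / ExAC-NFE / EVS
    clinvar_pathogenic: bool = False
    is_hotspot: bool = False
    effect: str | None = None  # finer class (missense/nonsense/...) for event rules

    def __post_init__(self) -> None:
        if self.alt_depth > self.depth:
            raise ValueError(
                f"alt_depth {self.alt_depth} exceeds depth {self.depth} "
                f"at {self.chrom}:{self.pos}"
            )
        for name in ("vaf_tumor", "vaf_normal"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1] at {self.chrom}:{self.pos}")
        if not self.callers:
            raise ValueError(f"empty caller set at {self.chrom}:{self.pos}")
        unknown = set(self.callers) - set(CALLERS)
        if unknown:
            raise ValueError(f"unknown callers {sorted(unknown)}")
        if self.consequence not in CONSEQUENCES:
            raise ValueError(f"unknown consequence {self.consequence!r}")
        self.callers = frozenset(self.callers)

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Rule-independent variant identity used for cohort recurrence."""
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1


@dataclass
class CNSegment:
    """A genomic interval with a log2 copy-number ratio, optional discrete
    call and LOH flag. Half-open 0-based coordinates."""

    chrom: str
    start: int
    end: int
    log2: float
    call: str | None = None
    loh: bool = False

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"empty/inverted segment {self.chrom}:{self.start}-{self.end}"
            )
        if self.call is not None and self.call not in CN_CALLS:
            raise ValueError(f"unknown call {self.call!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class SVBreakpointPair:
    """Two breakends forming one structural-variant call."""

    chrom_a: str
    pos_a: int
    chrom_b: str
    pos_b: int
    sv_type: str

    def __post_init__(self) -> None:
        if self.sv_type not in SV_TYPES:
            raise ValueError(f"unknown sv_type {self.sv_type!r}")
        inter = self.chrom_a != self.chrom_b
        if inter != (self.sv_type == "translocation"):
            raise ValueError(
                "sv_type 'translocation' if and only if breakends are on "
                f"different chromosomes ({self.chrom_a} vs {self.chrom_b})"
            )

    @property
    def size(self) -> int | None:
        """|pos_b - pos_a| for intra-chromosomal events, else None."""
        if self.chrom_a != self.chrom_b:
            return None
        return abs(self.pos_b - self.pos_a)


@dataclass
class CaseRecord:
    """One tumor: classification, platform, variants, segments, SVs and
    survival. ``truth`` carries simulator oracle labels; analysis stages
    never read it."""

    case_id: str
    classification: str
    platform_mode: str
    stage: str | None = None  # FIGO I-IV
    time: float | None = None  # months
    event: str | None = None  # "death-of-disease" | "censored"
    variants: list[VariantCall] = field(default_factory=list)
    segments: list[CNSegment] = field(default_factory=list)
    svs: list[SVBreakpointPair] = field(default_factory=list)
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.classification not in CLASSIFICATIONS:
            raise ValueError(f"unknown classification {self.classification!r}")
        if self.platform_mode not in PLATFORM_MODES:
            raise ValueError(f"unknown platform_mode {self.platform_mode!r}")
        if self.platform_mode == "panel":
            for v in self.variants:
                if v.vaf_normal is not None:
                    raise ValueError(
                        f"panel-mode case {self.case_id} carries vaf_normal"
                    )

    @property
    def is_paired(self) -> bool:
        return self.platform_mode in ("exome_paired", "wgs")


@dataclass
class ThresholdConfig:
    """All analysis cutoffs in one place.

    Defaults are the working values of the pipeline: the somatic cascade
    minimums, the log2 call thresholds, SV size classes and the
    region-comparison gates. Panel mode tightens depth and support because
    FFPE targeted sequencing runs much deeper than exomes.
    """

    pop_af_max: float = 1e-4
    qual_min: float = 30.0
    depth_min: int = 10
    panel_depth_min: int = 20
    alt_depth_min: int = 2
    panel_alt_depth_min: int = 10
    vaf_min: float = 0.05
    normal_vaf_max: float = 0.05
    cohort_recurrence_max: float = 0.20
    pon_max_hits: int = 1
    panel_target_mb: float = 2.07
    log2_gain: float = 0.2
    log2_loss: float = -0.2
    log2_amp: float = 0.6
    log2_homdel: float = -1.0
    sv_small_bp: float = 1e6
    foldback_bp: float = 3e4
    cmp_p: float = 0.002
    cmp_diff: float = 0.15
    cnp_overlap: float = 0.90
    sig_sparsity: float = 0.06
    nmf_k: int = 3

    def __post_init__(self) -> None:
        import math

        for f, v in vars(self).items():
            if isinstance(v, (int, float)) and not math.isfinite(v):
                raise ValueError(f"threshold {f} is not finite")

    def depth_min_for(self, mode: str) -> int:
        return self.panel_depth_min if mode == "panel" else self.depth_min

    def alt_depth_min_for(self, mode: str) -> int:
        return self.panel_alt_depth_min if mode == "panel" else self.alt_depth_min
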