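"""Synthetic cohorts with the statistical structure the downstream
analyses assume.

The generator emulates a benign -> borderline -> grade 1-3 mucinous
ovarian tumor progression cohort: per-group driver-event frequencies,
a grade-increasing fraction-of-genome-altered (FGA) gradient realized
through copy-number profile archetypes, caller-specific artifact variants
that each violate exactly one rule of the somatic filter cascade, and
survival times whose hazard rises exponentially with FGA.

Every simulated variant, segment and survival time carries oracle truth
labels in ``CaseRecord.truth``; analysis stages never read that field.
Read counts follow the standard sampling model: alt reads ~
Binomial(depth, true VAF), with depth Poisson around a platform mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .genome import GenomeBuild, hg19
from .model import (CaseRecord, CNSegment, SVBreakpointPair, ThresholdConfig,
                    VariantCall)
from .signatures import CHANNELS_96, SignatureCatalog, SignatureSet

GROUPS = ("BEN", "MBT", "G1", "G2", "G3", "EOM")
MOC_GROUPS = ("G1", "G2", "G3")

_BASES = "ACGT"


class ToyReference:
    """A small multi-chromosome nucleotide reference for trinucleotide-
    context lookup; pyfaidx-like ``ref[chrom][start:end]`` slicing."""

    def __init__(self, seqs: dict[str, str]):
        self.seqs = seqs

    @classmethod
    def generate(cls, rng: np.random.Generator, n_chroms: int = 3,
                 length: int = 30_000) -> "ToyReference":
        seqs = {
            f"chrS{i + 1}": "".join(
                rng.choice(list(_BASES), size=length))
            for i in range(n_chroms)
        }
        return cls(seqs)

    def __getitem__(self, chrom: str) -> str:
        return self.seqs[chrom]

    @property
    def chroms(self) -> tuple[str, ...]:
        return tuple(self.seqs)

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name, seq in self.seqs.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i:i + 70] + "\n")


# --------------------------------------------------------------- defaults

def _default_n() -> dict[str, int]:
    return {"BEN": 22, "MBT": 39, "G1": 87, "G2": 79, "G3": 24, "EOM": 23}


def _default_event_freqs() -> dict[str, dict[str, float]]:
    moc = {"KRAS": 0.64, "TP53": 0.64, "CDKN2A_mut": 0.16, "CDKN2A_del": 0.60,
           "ERBB2_amp": 0.26, "RNF43": 0.12, "BRAF": 0.10, "PIK3CA": 0.09,
           "ARID1A": 0.08}
    return {
        "BEN": {"KRAS": 0.50, "CDKN2A_del": 0.30, "BRAF": 0.10},
        "MBT": {"KRAS": 0.64, "TP53": 0.18, "CDKN2A_mut": 0.11,
                "CDKN2A_del": 0.45, "ERBB2_amp": 0.03, "BRAF": 0.25,
                "PIK3CA": 0.03},
        "G1": dict(moc), "G2": dict(moc), "G3": dict(moc),
        "EOM": {"KRAS": 0.40, "TP53": 0.50, "CDKN2A_del": 0.25,
                "SMAD4": 0.30},
    }


def _default_fga_means() -> dict[str, float]:
    return {"BEN": 0.01, "MBT": 0.04, "G1": 0.10, "G2": 0.16, "G3": 0.24,
            "EOM": 0.18}


def _default_artifact_rates() -> dict[str, float]:
    return {"population": 1.0, "low_qual": 1.0, "low_depth": 1.0,
            "varscan_only": 1.0, "ug_only": 1.0, "germline_leak": 1.0,
            "recurrent_site_prob": 0.30}


def _default_profile_weights() -> dict[str, dict[str, float]]:
    return {
        "BEN": {"simple": 0.96, "simple_one_amp": 0.01, "complex": 0.02,
                "complex_whole_chr": 0.01, "complex_multi_amp": 0.0},
        "MBT": {"simple": 0.82, "simple_one_amp": 0.03, "complex": 0.12,
                "complex_whole_chr": 0.03, "complex_multi_amp": 0.0},
        "G1": {"simple": 0.45, "simple_one_amp": 0.12, "complex": 0.22,
               "complex_whole_chr": 0.06, "complex_multi_amp": 0.15},
        "G2": {"simple": 0.25, "simple_one_amp": 0.10, "complex": 0.23,
               "complex_whole_chr": 0.05, "complex_multi_amp": 0.37},
        "G3": {"simple": 0.10, "simple_one_amp": 0.06, "complex": 0.24,
               "complex_whole_chr": 0.05, "complex_multi_amp": 0.55},
        "EOM": {"simple": 0.30, "simple_one_amp": 0.10, "complex": 0.30,
                "complex_whole_chr": 0.05, "complex_multi_amp": 0.25},
    }


def _default_platform_weights() -> dict[str, float]:
    return {"exome_paired": 0.20, "exome_unpaired": 0.04, "wgs": 0.04,
            "panel": 0.72}


#: effect distributions for mutation-type driver events
_DRIVER_EFFECTS = {
    "KRAS": (("missense",), (1.0,)),
    "BRAF": (("missense",), (1.0,)),
    "PIK3CA": (("missense",), (1.0,)),
    "TP53": (("missense", "nonsense", "frameshift"), (0.6, 0.25, 0.15)),
    "CDKN2A_mut": (("nonsense", "frameshift", "splice"), (0.4, 0.4, 0.2)),
    "RNF43": (("nonsense", "frameshift"), (0.5, 0.5)),
    "ARID1A": (("nonsense", "frameshift"), (0.5, 0.5)),
    "SMAD4": (("missense", "nonsense"), (0.5, 0.5)),
}
_HOTSPOT_GENES = {"KRAS", "BRAF", "PIK3CA"}
_CN_EVENTS = {"CDKN2A_del", "ERBB2_amp"}

#: symbolic validation-panel gene set for passengers and burden
PANEL_GENES = tuple(sorted(
    {"KRAS", "TP53", "CDKN2A", "ERBB2", "RNF43", "BRAF", "PIK3CA", "ARID1A",
     "SMAD4", "APC", "MYC"}
    | {f"PNL{i:03d}" for i in range(1, 26)}))


@dataclass
class CohortSpec:
    """Generator configuration; defaults encode the study conditions the
    analyses expect (per-group driver frequencies, FGA gradient,
    artifact classes, FGA-linked survival)."""

    n_per_group: dict[str, int] = field(default_factory=_default_n)
    event_freqs: dict[str, dict[str, float]] = field(
        default_factory=_default_event_freqs)
    fga_means: dict[str, float] = field(default_factory=_default_fga_means)
    artifact_rates: dict[str, float] = field(
        default_factory=_default_artifact_rates)
    profile_weights: dict[str, dict[str, float]] = field(
        default_factory=_default_profile_weights)
    platform_weights: dict[str, float] = field(
        default_factory=_default_platform_weights)
    passenger_mean: float = 6.0
    survival_link: float = 7.0  # log-hazard units per unit FGA
    baseline_hazard: float = np.log(2) / 100  # per month at FGA 0.10
    n_recurrent_sites: int = 3
    include_variants: bool = True
    include_svs: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for g, freqs in self.event_freqs.items():
            for ev, p in freqs.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"event_freqs[{g}][{ev}]={p} not in [0,1]")
        for g, m in self.fga_means.items():
            if not 0.0 <= m < 1.0:
                raise ValueError(f"fga_means[{g}]={m} must be in [0, 1)")
        gradient = [self.fga_means[g] for g in ("BEN", "MBT", "G1", "G2", "G3")]
        if not all(a < b for a, b in zip(gradient, gradient[1:])):
            raise ValueError("fga_means must increase strictly BEN<MBT<G1<G2<G3")


# ---------------------------------------------------------------- variants

_PLATFORM_DEPTH = {"exome_paired": 80, "exome_unpaired": 80, "wgs": 60,
                   "panel": 400}
_PLATFORM_CALLERS = {
    "exome_paired": frozenset({"UnifiedGenotyper", "Platypus", "VarScan"}),
    "exome_unpaired": frozenset({"UnifiedGenotyper", "Platypus", "VarScan"}),
    "wgs": frozenset({"VarDict", "MuTect2"}),
    "panel": frozenset({"VarDict", "VarScan"}),
}


class _SitePools:
    """Cohort-shared variant sites: per-gene driver pools, hotspots and
    the designated recurrent-artifact sites."""

    def __init__(self, reference: ToyReference, rng: np.random.Generator,
                 n_recurrent: int):
        self.reference = reference
        self.rng = rng
        self.driver_sites: dict[str, list[tuple]] = {}
        pool_sizes = {"KRAS": 2, "BRAF": 1, "PIK3CA": 3}
        genes = list(_DRIVER_EFFECTS)
        for gene in genes:
            n = pool_sizes.get(gene, 60)
            self.driver_sites[gene] = [self._draw_site() for _ in range(n)]
        # hotspot status is positional: any variant landing on these sites
        # is a hotspot call no matter which simulation path drew it
        self.hotspot_keys = {tuple(site) for gene in _HOTSPOT_GENES
                             for site in self.driver_sites[gene]}
        self.recurrent_sites = []
        while len(self.recurrent_sites) < n_recurrent:
            site = self._draw_site()
            if tuple(site) not in self.hotspot_keys:
                self.recurrent_sites.append(site)

    def _draw_site(self) -> tuple[str, int, str, str]:
        chrom = self.rng.choice(self.reference.chroms)
        length = len(self.reference[chrom])
        pos = int(self.rng.integers(2, length - 1))  # room for context
        ref = self.reference[chrom][pos - 1]
        alt = self.rng.choice([b for b in _BASES if b != ref])
        return (chrom, pos, ref, alt)

    def random_site(self) -> tuple[str, int, str, str]:
        return self._draw_site()


def _read_support(rng: np.random.Generator, mode: str, true_vaf: float,
                  cfg: ThresholdConfig) -> tuple[int, int, float]:
    """Draw (depth, alt_depth, vaf) passing the cascade's quantitative
    minimums for the platform (rejection-resampled; a clonal variant at
    adequate depth essentially always passes)."""
    dmin = cfg.depth_min_for(mode)
    amin = cfg.alt_depth_min_for(mode)
    for _ in range(200):
        depth = max(dmin, int(rng.poisson(_PLATFORM_DEPTH[mode])))
        alt = int(rng.binomial(depth, true_vaf))
        vaf = alt / depth
        if alt >= amin and vaf > cfg.vaf_min:
            return depth, alt, vaf
    raise RuntimeError("could not draw passing read support")  # pragma: no cover


def _somatic_variant(rng, mode, site, gene, effect, consequence, cfg,
                     is_hotspot=False) -> VariantCall:
    chrom, pos, ref, alt = site
    true_vaf = float(rng.beta(14, 21))  # clonal-ish, mean 0.4
    depth, alt_depth, vaf = _read_support(rng, mode, max(true_vaf, 0.12), cfg)
    return VariantCall(
        chrom=chrom, pos=pos, ref=ref, alt=alt,
        qual=float(rng.uniform(60, 200)), depth=depth, alt_depth=alt_depth,
        vaf_tumor=vaf,
        vaf_normal=(float(rng.uniform(0, 0.02))
                    if mode in ("exome_paired", "wgs") else None),
        callers=_PLATFORM_CALLERS[mode], passes_caller_filters=True,
        consequence=consequence, gene=gene, pop_af=None,
        clinvar_pathogenic=False, is_hotspot=is_hotspot, effect=effect)


def simulate_case_variants(case: CaseRecord, spec: CohortSpec,
                           reference: ToyReference, pools: _SitePools,
                           rng: np.random.Generator,
                           cfg: ThresholdConfig | None = None) -> None:
    """Fill ``case.variants`` with true somatic drivers/passengers plus
    artifact classes each violating exactly one cascade rule, and record
    truth labels in ``case.truth['variants']``."""
    cfg = cfg or ThresholdConfig()
    mode = case.platform_mode
    rates = spec.artifact_rates
    truth: dict[tuple, str] = {}
    variants: list[VariantCall] = []
    cn_truth: list[str] = []

    def add(v: VariantCall, label: str) -> None:
        if v.key in truth:
            return  # site collision within a case: keep the first
        if tuple(v.key) in pools.hotspot_keys:
            v.is_hotspot = True
        truth[v.key] = label
        variants.append(v)

    freqs = spec.event_freqs.get(case.classification, {})
    for event, p in freqs.items():
        if rng.random() >= p:
            continue
        if event in _CN_EVENTS:
            cn_truth.append(event)
            continue
        gene = "CDKN2A" if event == "CDKN2A_mut" else event
        effects, wts = _DRIVER_EFFECTS[event]
        effect = str(rng.choice(effects, p=wts))
        sites = pools.driver_sites[event]
        site = sites[int(rng.integers(len(sites)))]
        cq = "splice" if effect == "splice" else "coding"
        add(_somatic_variant(rng, mode, site, gene, effect, cq, cfg,
                             is_hotspot=event in _HOTSPOT_GENES), "somatic")

    for _ in range(rng.poisson(spec.passenger_mean)):
        gene = str(rng.choice(PANEL_GENES))
        effect = str(rng.choice(
            ["missense", "synonymous", "nonsense", "splice", "other"],
            p=[0.55, 0.25, 0.05, 0.05, 0.10]))
        cq = {"splice": "splice", "other": "other"}.get(effect, "coding")
        add(_somatic_variant(rng, mode, pools.random_site(), gene, effect,
                             cq, cfg), "somatic")

    def artifact_base(site=None) -> VariantCall:
        return _somatic_variant(rng, mode, site or pools.random_site(),
                                str(rng.choice(PANEL_GENES)), "missense",
                                "coding", cfg)

    for _ in range(rng.poisson(rates.get("population", 0))):
        v = artifact_base()
        v.pop_af = float(np.exp(rng.uniform(np.log(2e-4), np.log(5e-2))))
        add(v, "population")
    for _ in range(rng.poisson(rates.get("low_qual", 0))):
        v = artifact_base()
        v.qual = float(rng.uniform(5, 29))
        add(v, "low_qual")
    for _ in range(rng.poisson(rates.get("low_depth", 0))):
        v = artifact_base()
        dmin = cfg.depth_min_for(mode)
        amin = cfg.alt_depth_min_for(mode)
        depth = int(rng.integers(max(amin, int(0.06 * dmin) + 1), dmin))
        alt = int(rng.integers(amin, depth + 1)) if depth >= amin else depth
        v.depth, v.alt_depth, v.vaf_tumor = depth, alt, alt / depth
        add(v, "low_depth")
    for _ in range(rng.poisson(rates.get("varscan_only", 0))):
        v = artifact_base()
        v.callers = frozenset({"VarScan"})
        add(v, "varscan_only")
    if mode in ("exome_unpaired", "panel"):
        for _ in range(rng.poisson(rates.get("ug_only", 0))):
            v = artifact_base()
            v.callers = frozenset({"UnifiedGenotyper"})
            add(v, "ug_only")
    if mode in ("exome_paired", "wgs"):
        for _ in range(rng.poisson(rates.get("germline_leak", 0))):
            v = artifact_base()
            v.vaf_normal = float(rng.uniform(0.2, 0.6))
            add(v, "germline_leak")
    for site in pools.recurrent_sites:
        if rng.random() < rates.get("recurrent_site_prob", 0):
            add(artifact_base(site), "recurrent")

    case.variants = variants
    case.truth["variants"] = truth
    case.truth["cn_events"] = cn_truth


def true_somatic_keys(case: CaseRecord) -> set[tuple]:
    return {k for k, lab in case.truth.get("variants", {}).items()
            if lab == "somatic"}


# ------------------------------------------------------------ copy number

_CDKN2A = ("chr9", 21967751, 21995300)
_ERBB2 = ("chr17", 37844393, 37886915)

_ARCHETYPE_EVENTS = {  # (n_events low, high) for sub-chromosomal alterations
    "simple": (1, 7), "simple_one_amp": (1, 6), "complex": (12, 30),
    "complex_whole_chr": (10, 13), "complex_multi_amp": (12, 30),
}


def _place(rng, used: dict[str, list[tuple[int, int]]], build: GenomeBuild,
           chrom: str, size: int) -> tuple[int, int] | None:
    length = build.length(chrom)
    size = min(size, length)
    for _ in range(20):
        start = int(rng.integers(0, max(1, length - size + 1)))
        end = start + size
        if all(end <= s or start >= e for s, e in used.get(chrom, [])):
            used.setdefault(chrom, []).append((start, end))
            return start, end
    return None


def simulate_case_cn_sv(case: CaseRecord, spec: CohortSpec,
                        build: GenomeBuild, rng: np.random.Generator) -> None:
    """Fill ``case.segments``, ``case.svs`` and survival fields.

    A target FGA is drawn around the group mean (Beta, concentration 60),
    a profile archetype is sampled with grade-dependent weights, altered
    segments are placed to realize the target, fold-back-sized inversions
    accompany amplified chromosomes, and survival follows an exponential
    model with hazard proportional to exp(survival_link * FGA).
    """
    group = case.classification
    mean = spec.fga_means[group]
    if mean >= 1:
        raise ValueError(f"FGA target {mean} for {group} not below 1")
    conc = 60.0
    target = float(rng.beta(mean * conc, (1 - mean) * conc))
    target = min(target, 0.9)
    weights = spec.profile_weights[group]
    archetypes = list(weights)
    w = np.array([weights[a] for a in archetypes], float)
    archetype = str(rng.choice(archetypes, p=w / w.sum()))

    used: dict[str, list[tuple[int, int]]] = {}
    segments: list[CNSegment] = []
    amp_chroms: set[str] = set()

    def add_seg(chrom, start, end, log2, loh=False):
        segments.append(CNSegment(chrom, start, end, log2, loh=loh))

    # planted gene-level CN drivers
    for event in case.truth.get("cn_events", []):
        chrom, gs, ge = _CDKN2A if event == "CDKN2A_del" else _ERBB2
        if chrom not in build:  # toy builds without the driver loci
            continue
        pad = int(rng.uniform(1e5, 1.5e6))
        start = max(0, gs - pad)
        end = min(build.length(chrom), ge + pad)
        if all(end <= s or start >= e for s, e in used.get(chrom, [])):
            used.setdefault(chrom, []).append((start, end))
            if event == "CDKN2A_del":
                add_seg(chrom, start, end, float(rng.uniform(-2.0, -1.1)), loh=True)
            else:
                add_seg(chrom, start, end, float(rng.uniform(0.8, 2.0)))
                amp_chroms.add(chrom)

    # focal amplifications demanded by the archetype
    n_amp_chroms = {"simple_one_amp": 1, "complex_multi_amp":
                    int(rng.integers(2, 5))}.get(archetype, 0)
    autosomes = [c for c in build.chrom_names if c not in ("chrX", "chrY")]
    while len(amp_chroms) < n_amp_chroms:
        chrom = str(rng.choice([c for c in autosomes if c not in amp_chroms]))
        size = int(rng.uniform(5e5, 4e6))
        placed = _place(rng, used, build, chrom, size)
        if placed:
            add_seg(chrom, *placed, float(rng.uniform(0.8, 1.8)))
            amp_chroms.add(chrom)

    # whole-chromosome events for the whole-chr archetype
    needed = target * build.n_chromosomes  # sum of per-chromosome fractions
    got = sum(s.length / build.length(s.chrom) for s in segments)
    if archetype == "complex_whole_chr":
        free = [c for c in autosomes if c not in used]
        rng.shuffle(free)
        for chrom in free:
            if got >= needed - 0.5:
                break
            used.setdefault(chrom, []).append((0, build.length(chrom)))
            log2 = float(rng.choice([-0.5, 0.35]))
            add_seg(chrom, 0, build.length(chrom), log2)
            got += 1.0

    # sub-chromosomal altered segments to realize the FGA target
    lo, hi = _ARCHETYPE_EVENTS[archetype]
    n_events = int(rng.integers(lo, hi + 1))
    remaining = max(0.0, needed - got)
    # complex-family archetypes keep their event count even when the
    # whole-chromosome events already met the FGA target
    if n_events and (remaining > 0 or lo >= 10):
        shares = list(rng.dirichlet(np.full(n_events, 2.0)) * remaining)
        # undershoot from per-event caps or placement collisions carries
        # over, then a few top-up events absorb any residue (complex
        # families only, to keep the simple-family event count low)
        extra = 6 if n_events >= 10 else 2
        shares += [0.0] * extra
        carry = 0.0
        for i, share in enumerate(shares):
            want = share + carry
            carry = 0.0
            if lo >= 10 and i < n_events:
                # complex families keep every event; floor keeps it visible
                want = max(want, 1.5e-3)
            elif want < 1e-3:
                continue
            placed = None
            for chrom in rng.choice(autosomes, size=8, replace=False):
                chrom = str(chrom)
                frac = min(0.9, want)
                size = max(int(1e4), int(frac * build.length(chrom)))
                placed = _place(rng, used, build, chrom, size)
                if placed is not None:
                    break
            if placed is None:
                carry = want
                continue
            carry = want - (placed[1] - placed[0]) / build.length(chrom)
            sign = rng.random() < 0.5
            log2 = float(rng.uniform(0.25, 0.55)) if sign else \
                float(rng.uniform(-0.9, -0.25))
            add_seg(chrom, *placed, log2, loh=not sign and rng.random() < 0.5)
    case.segments = segments
    case.truth["fga_target"] = target
    case.truth["archetype"] = archetype

    # structural variants
    svs: list[SVBreakpointPair] = []
    if spec.include_svs:
        realized = sum(s.length / build.length(s.chrom) for s in segments
                       ) / build.n_chromosomes
        n_sv = rng.poisson(4 + 40 * realized)
        for _ in range(n_sv):
            kind = str(rng.choice(["deletion", "duplication", "inversion",
                                   "translocation"], p=[0.3, 0.2, 0.25, 0.25]))
            if kind == "translocation":
                ca, cb = rng.choice(autosomes, size=2, replace=False)
                svs.append(SVBreakpointPair(
                    str(ca), int(rng.integers(1, build.length(str(ca)))),
                    str(cb), int(rng.integers(1, build.length(str(cb)))),
                    "translocation"))
            else:
                chrom = str(rng.choice(autosomes))
                size = int(np.exp(rng.normal(12, 2)))
                pos = int(rng.integers(1, max(2, build.length(chrom) - size)))
                svs.append(SVBreakpointPair(chrom, pos, chrom, pos + size, kind))
        # sorted: set order depends on hash randomization across processes
        for chrom in sorted(amp_chroms):  # fold-back inversions flank amplicons
            for _ in range(rng.poisson(3)):
                size = int(rng.uniform(1e3, 2.9e4))
                pos = int(rng.integers(1, build.length(chrom) - size))
                svs.append(SVBreakpointPair(chrom, pos, chrom, pos + size,
                                            "inversion"))
    case.svs = svs

    # survival: hazard rises exponentially with FGA; deaths from other
    # causes and administrative follow-up end censor
    fga = sum(s.length / build.length(s.chrom) for s in segments
              ) / build.n_chromosomes
    hazard = spec.baseline_hazard * np.exp(spec.survival_link * (fga - 0.10))
    t_disease = float(rng.exponential(1.0 / hazard))
    t_other = float(rng.exponential(600.0))
    t_admin = float(rng.uniform(12, 120))
    t = min(t_disease, t_other, t_admin)
    case.time = round(t, 2)
    case.event = "death-of-disease" if t == t_disease else "censored"


# ----------------------------------------------------------------- cohort

def simulate_cohort(spec: CohortSpec, build: GenomeBuild | None = None,
                    ) -> tuple[list[CaseRecord], ToyReference]:
    """Generate a full cohort; reproducible byte-for-byte given
    ``spec.seed``."""
    build = build or hg19()
    rng = np.random.default_rng(spec.seed)
    reference = ToyReference.generate(rng)
    pools = _SitePools(reference, rng, spec.n_recurrent_sites)
    modes = list(spec.platform_weights)
    mode_w = np.array([spec.platform_weights[m] for m in modes], float)
    mode_w /= mode_w.sum()
    cases: list[CaseRecord] = []
    for group in GROUPS:
        n = spec.n_per_group.get(group, 0)
        for i in range(n):
            mode = str(rng.choice(modes, p=mode_w))
            stage = None
            if group in MOC_GROUPS or group == "EOM":
                stage = str(rng.choice(["I", "II", "III", "IV"],
                                       p=[0.6, 0.15, 0.15, 0.1]))
            case = CaseRecord(case_id=f"{group}-{i + 1:03d}",
                              classification=group, platform_mode=mode,
                              stage=stage)
            if spec.include_variants:
                simulate_case_variants(case, spec, reference, pools, rng)
            else:
                case.truth["cn_events"] = [
                    ev for ev, p in spec.event_freqs.get(group, {}).items()
                    if ev in _CN_EVENTS and rng.random() < p]
            simulate_case_cn_sv(case, spec, build, rng)
            cases.append(case)
    return cases, reference


# --------------------------------------------- catalogs from signatures

def simulate_catalogs(signatures: SignatureSet, n_cases: int,
                      total_mean: float = 500.0,
                      exposures: np.ndarray | None = None,
                      seed: int = 0) -> tuple[list[SignatureCatalog], np.ndarray]:
    """Draw per-case 96-channel catalogs from a mixture of signatures.

    Exposures default to Dirichlet(1) per case; counts are multinomial
    with Poisson totals around ``total_mean``. Returns catalogs and the
    n_cases x K exposure matrix used."""
    rng = np.random.default_rng(seed)
    k = signatures.k
    if exposures is None:
        exposures = rng.dirichlet(np.ones(k), size=n_cases)
    catalogs = []
    for i in range(n_cases):
        p = signatures.matrix @ exposures[i]
        p = p / p.sum()
        total = max(1, int(rng.poisson(total_mean)))
        counts = rng.multinomial(total, p)
        catalogs.append(SignatureCatalog(f"sim-{i + 1:03d}", counts))
    return catalogs, exposures
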