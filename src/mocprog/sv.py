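"""Structural-variant classification and per-sample breakpoint summaries.

Deletions, duplications and inversions are intra-chromosomal and size-
classified: small when < 1 Mb, and inversions additionally called
fold-back inversions when < 30 kb (a hallmark of amplification through
breakage-fusion-bridge cycles). Everything joining two chromosomes is an
inter-chromosomal translocation. Orientation is not required for the
fold-back call; the size-only rule is used.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .model import SVBreakpointPair, ThresholdConfig

SV_CLASSES = (
    "small_deletion", "large_deletion", "small_duplication",
    "large_duplication", "small_inversion", "foldback_inversion",
    "large_inversion", "interchromosomal_translocation",
)

_SMALL_INTRA = frozenset({"small_deletion", "small_duplication",
                          "small_inversion", "foldback_inversion"})
_LARGE_INTRA = frozenset({"large_deletion", "large_duplication",
                          "large_inversion"})


def classify_sv(pair: SVBreakpointPair,
                cfg: ThresholdConfig | None = None) -> str:
    """Assign exactly one SV class to a breakpoint pair."""
    cfg = cfg or ThresholdConfig()
    if pair.sv_type == "translocation":
        return "interchromosomal_translocation"
    size = pair.size
    if size is None or size < 0:
        raise ValueError(f"invalid size for intra-chromosomal pair: {size}")
    if pair.sv_type == "inversion":
        if size < cfg.foldback_bp:
            return "foldback_inversion"
        return "small_inversion" if size < cfg.sv_small_bp else "large_inversion"
    small = size < cfg.sv_small_bp
    if pair.sv_type == "deletion":
        return "small_deletion" if small else "large_deletion"
    return "small_duplication" if small else "large_duplication"


@dataclass
class BreakpointSummary:
    """Class counts and proportions over one case's breakpoint pairs.

    Proportions are of all pairs; ``foldback`` is also a subset of the
    small intra-chromosomal group. All proportion fields are None for an
    empty input.
    """

    counts: dict[str, int]
    n: int
    proportions: dict[str, float] | None
    small_intra: float | None
    large_intra: float | None
    interchromosomal: float | None
    foldback: float | None
    foldback_of_inversions: float | None


def breakpoint_summary(svs: list[SVBreakpointPair],
                       cfg: ThresholdConfig | None = None) -> BreakpointSummary:
    """Tabulate SV classes for one case; classes partition the input."""
    cfg = cfg or ThresholdConfig()
    classes = [classify_sv(s, cfg) for s in svs]
    counts = Counter(classes)
    n = len(svs)
    full = {c: counts.get(c, 0) for c in SV_CLASSES}
    if n == 0:
        return BreakpointSummary(full, 0, None, None, None, None, None, None)
    props = {c: full[c] / n for c in SV_CLASSES}
    n_inv = sum(full[c] for c in
                ("small_inversion", "foldback_inversion", "large_inversion"))
    return BreakpointSummary(
        counts=full, n=n, proportions=props,
        small_intra=sum(full[c] for c in _SMALL_INTRA) / n,
        large_intra=sum(full[c] for c in _LARGE_INTRA) / n,
        interchromosomal=full["interchromosomal_translocation"] / n,
        foldback=full["foldback_inversion"] / n,
        foldback_of_inversions=(full["foldback_inversion"] / n_inv
                                if n_inv else None),
    )
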