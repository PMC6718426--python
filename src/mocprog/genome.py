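"""Genome builds: ordered chromosome names and lengths.

The chromosome count of the active build drives the per-region significance
level used in copy-number group comparisons (a Bonferroni-style division of
0.05 by the number of chromosomes, since segments within a chromosome are
not independent).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

# GRCh37/hg19 chromosome sizes, autosomes + X.  Y is excluded by default:
# the analyses here average per-chromosome statistics and the cohort is
# entirely female, so Y never carries segments.
_HG19_LENGTHS = {
    "chr1": 249250621, "chr2": 243199373, "chr3": 198022430,
    "chr4": 191154276, "chr5": 180915260, "chr6": 171115067,
    "chr7": 159138663, "chr8": 146364022, "chr9": 141213431,
    "chr10": 135534747, "chr11": 135006516, "chr12": 133851895,
    "chr13": 115169878, "chr14": 107349540, "chr15": 102531392,
    "chr16": 90354753, "chr17": 81195210, "chr18": 78077248,
    "chr19": 59128983, "chr20": 63025520, "chr21": 48129895,
    "chr22": 51304566, "chrX": 155270560,
}


@dataclass(frozen=True)
class GenomeBuild:
    """An ordered set of chromosomes with base-pair lengths."""

    chrom_names: tuple[str, ...]
    chrom_lengths: dict[str, int] = field(compare=True)
    name: str = "custom"

    def __post_init__(self) -> None:
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise ValueError("duplicate chromosome names in build")
        for c in self.chrom_names:
            if c not in self.chrom_lengths:
                raise ValueError(f"no length recorded for chromosome {c!r}")
            if self.chrom_lengths[c] <= 0:
                raise ValueError(
                    f"nonpositive length {self.chrom_lengths[c]} for {c!r}"
                )

    @property
    def n_chromosomes(self) -> int:
        return len(self.chrom_names)

    def length(self, chrom: str) -> int:
        try:
            return self.chrom_lengths[chrom]
        except KeyError:
            raise KeyError(f"chromosome {chrom!r} not in build {self.name!r}")

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chrom_lengths

    def region_alpha(self, alpha: float = 0.05) -> float:
        """Per-region significance level: alpha divided by chromosome count,
        quoted to one significant figure (0.05 / 23 -> 0.002)."""
        raw = alpha / self.n_chromosomes
        # round down to one significant figure, matching the quoted bound
        import math

        exp = math.floor(math.log10(raw))
        return math.floor(raw / 10**exp) * 10**exp


def hg19() -> GenomeBuild:
    """The default analysis build: hg19 autosomes + X (23 chromosomes)."""
    return GenomeBuild(tuple(_HG19_LENGTHS), dict(_HG19_LENGTHS), name="hg19")


def load_genome_build(name_or_path: str | Path) -> GenomeBuild:
    """Load a build by name ("hg19") or from a two-column chrom/length table.

    The table is whitespace- or tab-delimited with no header, one chromosome
    per line (the samtools .fai first-two-columns convention also parses).
    """
    if str(name_or_path) == "hg19":
        return hg19()
    path = Path(name_or_path)
    if not path.exists():
        raise ValueError(f"unknown genome build {name_or_path!r}")
    df = pd.read_csv(path, sep=r"\s+", header=None, comment="#",
                     usecols=[0, 1], names=["chrom", "length"],
                     dtype={"chrom": str})
    names = tuple(df["chrom"])
    lengths = dict(zip(df["chrom"], df["length"].astype(int)))
    return GenomeBuild(names, lengths, name=path.stem)
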