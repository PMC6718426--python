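import numpy as np
import pytest

from mocprog.genome import GenomeBuild
from mocprog.model import VariantCall


@pytest.fixture
def toy_build() -> GenomeBuild:
    return GenomeBuild(("chrA", "chrB"), {"chrA": 100, "chrB": 200}, name="toy")


@pytest.fixture
def toy_build_large() -> GenomeBuild:
    """Six 100 kb chromosomes; small enough for per-base brute force."""
    names = tuple(f"chr{i}" for i in range(1, 7))
    return GenomeBuild(names, {c: 100_000 for c in names}, name="toy6")


def make_variant(**kw) -> VariantCall:
    base = dict(chrom="chr1", pos=100, ref="C", alt="T", qual=60.0, depth=80,
                alt_depth=20, vaf_tumor=0.25, vaf_normal=0.0,
                callers=frozenset({"VarDict", "Platypus"}),
                passes_caller_filters=True, consequence="coding", gene="TP53",
                effect="missense")
    base.update(kw)
    return VariantCall(**base)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
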