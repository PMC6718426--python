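"""Cross-tumor-type genetic event frequencies and hierarchical clustering.

A gene "event" in a case is either a qualifying mutation (per-gene rule:
most genes count every non-synonymous mutation, but e.g. KRAS counts
missense only and CDKN2A inactivating mutations only) or a qualifying
copy-number call overlapping the gene — and only high-level amplifications
and homozygous deletions count as copy-number events.

Tumor types are clustered on their gene-frequency columns with Euclidean
distance and complete linkage, with the dendrogram leaves reordered by
column mean (the heatmap-default convention), so another implementation
can reproduce the leaf order exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .model import CaseRecord, CNSegment, VariantCall

#: all mutation effect classes except silent ones
NONSYNONYMOUS = frozenset({"missense", "nonsense", "frameshift", "splice",
                           "inframe_indel", "other"})
INACTIVATING = frozenset({"nonsense", "frameshift", "splice"})


@dataclass(frozen=True)
class EventRule:
    """Which evidence counts as an event for one gene."""

    mutation_effects: frozenset[str] = NONSYNONYMOUS
    cn_events: frozenset[str] = frozenset()  # subset of {"amp", "homdel"}


#: default per-gene rules for the recurrent genes of the analysis
DEFAULT_RULES: dict[str, EventRule] = {
    "KRAS": EventRule(mutation_effects=frozenset({"missense"})),
    "CDKN2A": EventRule(mutation_effects=INACTIVATING,
                        cn_events=frozenset({"homdel"})),
    "ERBB2": EventRule(cn_events=frozenset({"amp"})),
    "TP53": EventRule(),
    "BRAF": EventRule(mutation_effects=frozenset({"missense"})),
    "PIK3CA": EventRule(mutation_effects=frozenset({"missense"})),
    "RNF43": EventRule(),
    "ARID1A": EventRule(),
    "APC": EventRule(),
    "SMAD4": EventRule(cn_events=frozenset({"homdel"})),
    "MYC": EventRule(cn_events=frozenset({"amp"})),
}

#: hg19 loci for copy-number/gene overlap of the CN-eligible genes
DEFAULT_GENE_LOCI: dict[str, tuple[str, int, int]] = {
    "CDKN2A": ("chr9", 21967751, 21995300),
    "ERBB2": ("chr17", 37844393, 37886915),
    "SMAD4": ("chr18", 48556583, 48611415),
    "MYC": ("chr8", 128748315, 128753680),
}


@dataclass
class EventMatrix:
    """Binary gene x case indicator matrix plus the rules that built it."""

    data: pd.DataFrame  # genes x cases, values in {0, 1}
    rules: dict[str, EventRule] = field(default_factory=dict)

    def frequencies(self) -> pd.Series:
        return self.data.mean(axis=1)


def _mutation_event(v: VariantCall, rule: EventRule) -> bool:
    effect = v.effect if v.effect is not None else "other"
    return effect in rule.mutation_effects


def _cn_event(seg: CNSegment, locus: tuple[str, int, int],
              rule: EventRule) -> bool:
    chrom, start, end = locus
    return (seg.call in rule.cn_events and seg.chrom == chrom
            and seg.start < end and seg.end > start)


def build_event_matrix(cases: list[CaseRecord],
                       rules: dict[str, EventRule] | None = None,
                       gene_loci: dict[str, tuple[str, int, int]] | None = None,
                       variants_by_case: dict[str, list[VariantCall]] | None = None,
                       genes: list[str] | None = None) -> EventMatrix:
    """Apply the per-gene event rules to filtered variants and called
    segments.

    ``variants_by_case`` (e.g. the kept sets from the filter cascade)
    overrides each case's own variant list when given. ``genes`` selects
    the genes to score (default: the rule table's keys); a requested gene
    without a rule is an error. Variants in genes outside the scored set
    are ignored.
    """
    rules = dict(DEFAULT_RULES) if rules is None else rules
    gene_loci = dict(DEFAULT_GENE_LOCI) if gene_loci is None else gene_loci
    genes = sorted(rules) if genes is None else list(genes)
    for g in genes:
        if g not in rules:
            raise KeyError(f"gene {g!r} has no event rule")
    scored = set(genes)
    mat = pd.DataFrame(0, index=genes, columns=[c.case_id for c in cases],
                       dtype=int)
    for case in cases:
        variants = (variants_by_case.get(case.case_id, case.variants)
                    if variants_by_case is not None else case.variants)
        for v in variants:
            if v.gene is None or v.gene not in scored:
                continue
            if _mutation_event(v, rules[v.gene]):
                mat.loc[v.gene, case.case_id] = 1
        for gene in genes:
            rule = rules[gene]
            if not rule.cn_events or gene not in gene_loci:
                continue
            if any(_cn_event(s, gene_loci[gene], rule) for s in case.segments):
                mat.loc[gene, case.case_id] = 1
    return EventMatrix(mat, rules)


@dataclass
class FrequencyMatrix:
    """Gene x tumor-type event frequencies with per-type case counts."""

    data: pd.DataFrame  # genes x types, in [0, 1]
    n_cases: dict[str, int]


def build_frequency_matrix(matrices: dict[str, EventMatrix]) -> FrequencyMatrix:
    """Summarize per-type event matrices into a frequency table."""
    cols = {t: m.frequencies() for t, m in matrices.items()}
    df = pd.DataFrame(cols)
    return FrequencyMatrix(df, {t: m.data.shape[1] for t, m in matrices.items()})


# ------------------------------------------------------------- clustering

@dataclass
class ClusterResult:
    labels: tuple[str, ...]
    linkage: np.ndarray
    leaf_order: tuple[str, ...]
    cophenetic: pd.DataFrame
    newick: str


def _reorder(node, weights: dict[int, float]) -> list[int]:
    """Mean-value weighted dendrogram reordering: at each merge, put the
    subtree with the smaller mean leaf weight first."""
    if node.is_leaf():
        return [node.id]
    left = _reorder(node.left, weights)
    right = _reorder(node.right, weights)
    if np.mean([weights[i] for i in left]) > np.mean([weights[i] for i in right]):
        left, right = right, left
    return left + right


def _newick(node, labels, parent_height=None) -> str:
    height = node.dist
    if node.is_leaf():
        body = labels[node.id]
    else:
        body = (f"({_newick(node.left, labels, height)},"
                f"{_newick(node.right, labels, height)})")
    if parent_height is None:
        return body + ";"
    return f"{body}:{parent_height - height:g}"


def cluster_tumor_types(freq: FrequencyMatrix | pd.DataFrame) -> ClusterResult:
    """Hierarchical clustering of tumor types on gene-frequency columns.

    Euclidean distance, complete linkage, deterministic leaf order via
    mean-weighted dendrogram reordering. Returns the merge tree, leaf
    order, cophenetic distances and a Newick string.
    """
    df = freq.data if isinstance(freq, FrequencyMatrix) else freq
    if df.shape[1] < 2:
        raise ValueError("need at least two tumor types to cluster")
    labels = tuple(df.columns)
    X = df.to_numpy(dtype=float).T  # types x genes
    d = pdist(X, metric="euclidean")
    if np.allclose(d, 0):
        warnings.warn("constant frequency matrix: all distances zero, "
                      "tree is degenerate", stacklevel=2)
    Z = hierarchy.linkage(d, method="complete")
    tree = hierarchy.to_tree(Z)
    weights = {i: float(X[i].mean()) for i in range(len(labels))}
    order = _reorder(tree, weights)
    coph = squareform(hierarchy.cophenet(Z))
    coph_df = pd.DataFrame(coph, index=labels, columns=labels)
    return ClusterResult(
        labels=labels, linkage=Z,
        leaf_order=tuple(labels[i] for i in order),
        cophenetic=coph_df,
        newick=_newick(tree, labels),
    )
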