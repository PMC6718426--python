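"""Trinucleotide-context mutation catalogs, signature refitting and de novo
NMF discovery.

Catalogs use the standard 96-channel layout: six pyrimidine-strand
substitution classes (C>A, C>G, C>T, T>A, T>C, T>G) crossed with the 16
flanking-base contexts, ordered substitution-major then 5' base then 3'
base (A, C, G, T). Purine-reference SNVs are folded to the pyrimidine
strand by reverse complement before tabulation.

Refitting follows the forward-selection scheme of signature-refitting
tools: signatures are admitted one at a time, each step choosing the one
whose admission maximally reduces the squared reconstruction error of the
normalized catalog under nonnegative weights, stopping when the relative
improvement falls below 1e-3; weights below the sparsity cutoff (0.06) are
zeroed and the remainder renormalized.

De novo discovery is multiplicative-update NMF (Frobenius objective) with
seeded random restarts; the update rule guarantees a non-increasing
reconstruction error, which the implementation asserts each iteration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls

from .model import VariantCall

SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
BASES = ("A", "C", "G", "T")
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: the 96 channel labels, e.g. "A[C>A]A", in canonical order.
CHANNELS_96 = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTIONS for five in BASES for three in BASES
)
_CHANNEL_INDEX = {c: i for i, c in enumerate(CHANNELS_96)}


def channel_of(ref: str, alt: str, context: str) -> int:
    """Map an SNV with trinucleotide ``context`` (ref base centered) to its
    channel index, folding purine references to the pyrimidine strand."""
    ref, alt, context = ref.upper(), alt.upper(), context.upper()
    if len(context) != 3 or context[1] != ref:
        raise ValueError(f"context {context!r} does not center on ref {ref!r}")
    if ref in ("A", "G"):
        ref = _COMPLEMENT[ref]
        alt = _COMPLEMENT[alt]
        context = "".join(_COMPLEMENT[b] for b in reversed(context))
    return _CHANNEL_INDEX[f"{context[0]}[{ref}>{alt}]{context[2]}"]


@dataclass
class SignatureCatalog:
    """Per-case 96-channel mutation counts."""

    case_id: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (96,):
            raise ValueError(f"catalog must have 96 channels, got {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValueError("negative catalog counts")

    @property
    def total(self) -> float:
        return float(self.counts.sum())


@dataclass
class SignatureSet:
    """A 96 x K matrix of signatures; columns sum to 1."""

    names: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (96, len(self.names)):
            raise ValueError("matrix must be 96 x len(names)")
        sums = self.matrix.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-8):
            raise ValueError("signature columns must sum to 1 within 1e-8")

    @property
    def k(self) -> int:
        return len(self.names)


@dataclass
class ExposureVector:
    """Signature weights for one catalog plus unexplained residual.

    Weights are nonnegative, sum to at most 1, and weights below the
    sparsity cutoff used in refitting are exactly zero.
    """

    names: tuple[str, ...]
    weights: np.ndarray
    residual: float

    @property
    def major(self) -> str:
        return self.names[int(np.argmax(self.weights))]

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, map(float, self.weights)))


def build_catalog(snvs: list[VariantCall], reference,
                  case_id: str = "case") -> SignatureCatalog:
    """Tabulate SNVs into a 96-channel catalog using ``reference`` for the
    trinucleotide context.

    ``reference`` is anything with pyfaidx-style ``ref[chrom][start:end]``
    slicing on 0-based coordinates (a ``pyfaidx.Fasta`` or the simulator's
    ToyReference). The reference base must equal each SNV's ref allele.
    """
    counts = np.zeros(96)
    for v in snvs:
        if not v.is_snv:
            continue
        ctx = str(reference[v.chrom][v.pos - 2: v.pos + 1]).upper()
        if len(ctx) != 3:
            raise ValueError(
                f"cannot fetch context at {v.chrom}:{v.pos} (chromosome edge?)")
        if ctx[1] != v.ref.upper():
            raise ValueError(
                f"reference mismatch at {v.chrom}:{v.pos}: "
                f"reference has {ctx[1]!r}, variant ref is {v.ref!r}")
        counts[channel_of(v.ref, v.alt, ctx)] += 1
    return SignatureCatalog(case_id, counts)


def synthetic_reference_signatures() -> SignatureSet:
    """A small synthetic stand-in reference signature set.

    Five idealized processes echoing well-known mutational signatures —
    an age-like C>T-at-CpG process, the two APOBEC-like TpC processes
    (C>T and C>G), a broad C>A process and a near-flat background — built
    from simple parametric profiles, not fitted to any external catalog.
    Synthetic: shapes are constructed here, not the published reference
    signatures.
    """
    mats = {}
    m = np.full(96, 0.05 / 96)
    for five in BASES:
        for three in BASES:
            w = 10.0 if three == "G" else 0.3
            m[_CHANNEL_INDEX[f"{five}[C>T]{three}"]] += w
    mats["SYN-age"] = m
    m = np.full(96, 0.05 / 96)
    for three in BASES:
        m[_CHANNEL_INDEX[f"T[C>T]{three}"]] += 10.0
    mats["SYN-apobec-ct"] = m
    m = np.full(96, 0.05 / 96)
    for three in BASES:
        m[_CHANNEL_INDEX[f"T[C>G]{three}"]] += 10.0
    mats["SYN-apobec-cg"] = m
    m = np.full(96, 0.05 / 96)
    for five in BASES:
        for three in BASES:
            m[_CHANNEL_INDEX[f"{five}[C>A]{three}"]] += 1.0
    mats["SYN-broad-ca"] = m
    mats["SYN-flat"] = np.ones(96)
    names = tuple(mats)
    matrix = np.column_stack([mats[n] / mats[n].sum() for n in names])
    return SignatureSet(names, matrix)


def refit_signatures(catalog: SignatureCatalog, signatures: SignatureSet,
                     sparsity: float = 0.06,
                     rel_tol: float = 1e-3) -> ExposureVector:
    """Forward-selection nonnegative refit of ``catalog`` onto the columns
    of ``signatures``; deterministic."""
    if catalog.total <= 0:
        raise ValueError(f"catalog {catalog.case_id} has zero counts")
    y = catalog.counts / catalog.total
    M = signatures.matrix
    selected: list[int] = []
    best_err = float(y @ y)  # error of the empty model
    best_w = np.zeros(0)
    while len(selected) < signatures.k:
        cand_best = None
        for j in range(signatures.k):
            if j in selected:
                continue
            cols = selected + [j]
            w, _ = nnls(M[:, cols], y)
            err = float(np.sum((y - M[:, cols] @ w) ** 2))
            if cand_best is None or err < cand_best[0]:
                cand_best = (err, j, w)
        err, j, w = cand_best
        if best_err > 0 and (best_err - err) / best_err < rel_tol:
            break
        selected.append(j)
        best_err, best_w = err, w

    weights = np.zeros(signatures.k)
    if selected:
        weights[selected] = best_w
    total = weights.sum()
    if total > 1.0:
        weights /= total
        total = 1.0
    weights[weights < sparsity] = 0.0
    if weights.sum() > 0:
        weights *= total / weights.sum()
    residual = float(np.sum((y - M @ weights) ** 2))
    return ExposureVector(signatures.names, weights, residual)


def _nmf_once(V: np.ndarray, k: int, rng: np.random.Generator,
              max_iter: int, tol: float) -> tuple[np.ndarray, np.ndarray, float]:
    m, n = V.shape
    W = rng.uniform(0.1, 1.0, size=(m, k))
    H = rng.uniform(0.1, 1.0, size=(k, n))
    eps = 1e-12
    prev = float(np.linalg.norm(V - W @ H) ** 2)
    for _ in range(max_iter):
        H *= (W.T @ V) / (W.T @ W @ H + eps)
        W *= (V @ H.T) / (W @ H @ H.T + eps)
        err = float(np.linalg.norm(V - W @ H) ** 2)
        # Lee–Seung updates never increase the Frobenius objective
        assert err <= prev * (1 + 1e-9), "NMF objective increased"
        if prev - err < tol * max(prev, 1.0):
            prev = err
            break
        prev = err
    return W, H, prev


def discover_signatures_nmf(catalogs: list[SignatureCatalog], k: int = 3,
                            restarts: int = 50, seed: int = 0,
                            max_iter: int = 500, tol: float = 1e-10,
                            ) -> tuple[SignatureSet, np.ndarray]:
    """De novo signature discovery: best-of-``restarts`` multiplicative-
    update NMF on the 96 x n catalog matrix.

    Returns the column-normalized signatures and the n x k exposure matrix
    (counts attributed per case per signature). Reproducible given seed.
    """
    if k > len(catalogs):
        raise ValueError(f"k={k} exceeds the {len(catalogs)} catalogs")
    for c in catalogs:
        if c.total <= 0:
            raise ValueError(f"catalog {c.case_id} has zero counts")
    V = np.column_stack([c.counts for c in catalogs])
    best = None
    root = np.random.default_rng(seed)
    for _ in range(max(1, restarts)):
        W, H, err = _nmf_once(V, k, root, max_iter, tol)
        if best is None or err < best[2]:
            best = (W, H, err)
    W, H, _ = best
    scale = W.sum(axis=0)
    scale[scale == 0] = 1.0
    W = W / scale
    H = H * scale[:, None]
    names = tuple(f"S{i + 1}" for i in range(k))
    return SignatureSet(names, W), H.T


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))


def match_signatures(found: SignatureSet, truth: SignatureSet) -> dict[str, float]:
    """Best one-to-one matching of discovered to true signatures; returns
    cosine similarity per true signature (Hungarian assignment)."""
    from scipy.optimize import linear_sum_assignment

    sim = np.array([[cosine_similarity(found.matrix[:, i], truth.matrix[:, j])
                     for j in range(truth.k)] for i in range(found.k)])
    ri, ci = linear_sum_assignment(-sim)
    return {truth.names[j]: float(sim[i, j]) for i, j in zip(ri, ci)}
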