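"""Multivariate discrimination of accessions from allele presence encodings.

Genotypes are recoded per (locus, allele) column: the *binary* encoding marks
presence (1) / absence (0) of each allele; the *trinary* encoding additionally
scores each allele of a heterozygote 0.5 so that every non-missing locus
contributes a row sum of exactly 1. Pairwise Dice distances
(``d = 1 - 2a/(2a + b + c)``) on the binary encoding feed agglomerative
clustering; the linkage method is chosen by the highest cophenetic correlation
(tie-broken by the smaller Mather delta), and clade stability is assessed by
bootstrap resampling of loci. PCA operates on the column-centered trinary
encoding (covariance, no column scaling).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from ssrmarkers.genotypes import MISSING, GenotypeMatrix

LINKAGE_METHODS = {
    "single": "single",
    "complete": "complete",
    "UPGMA": "average",
    "WPGMA": "weighted",
}


@dataclass
class AlleleEncoding:
    """Accessions x (locus, allele) design matrix with its bookkeeping."""

    values: np.ndarray
    accession_ids: list[str]
    columns: list[tuple[str, str]]  # (locus, allele)
    missing: np.ndarray  # accessions x loci boolean
    loci: list[str]

    @property
    def column_labels(self) -> list[str]:
        return [f"{locus}:{allele}" for locus, allele in self.columns]

    def locus_block(self, locus: str) -> np.ndarray:
        idx = [j for j, (l, _) in enumerate(self.columns) if l == locus]
        return self.values[:, idx]


def _encode(matrix: GenotypeMatrix, het_weight: float) -> AlleleEncoding:
    columns: list[tuple[str, str]] = []
    for locus in matrix.loci:
        alleles = set()
        for aid in matrix.accession_ids:
            call = matrix.call(aid, locus)
            if call is not MISSING:
                alleles.update(call)
        columns.extend((locus, a) for a in sorted(alleles))
    col_index = {col: j for j, col in enumerate(columns)}
    n = len(matrix.accessions)
    values = np.zeros((n, len(columns)), dtype=float)
    missing = np.zeros((n, len(matrix.loci)), dtype=bool)
    for i, aid in enumerate(matrix.accession_ids):
        for li, locus in enumerate(matrix.loci):
            call = matrix.call(aid, locus)
            if call is MISSING:
                missing[i, li] = True
                continue
            a, b = call
            if a == b:
                values[i, col_index[(locus, a)]] = 1.0
            else:
                values[i, col_index[(locus, a)]] = het_weight
                values[i, col_index[(locus, b)]] = het_weight
    return AlleleEncoding(
        values=values,
        accession_ids=list(matrix.accession_ids),
        columns=columns,
        missing=missing,
        loci=list(matrix.loci),
    )


def encode_binary(matrix: GenotypeMatrix) -> AlleleEncoding:
    """Presence/absence (1/0) coding of every observed allele."""
    enc = _encode(matrix, het_weight=1.0)
    enc.values = enc.values.astype(int).astype(float)
    return enc


def encode_trinary(matrix: GenotypeMatrix) -> AlleleEncoding:
    """Allele-dosage coding: homozygote allele 1, each heterozygote allele 0.5."""
    return _encode(matrix, het_weight=0.5)


@dataclass
class DistanceMatrix:
    values: np.ndarray
    ids: list[str]

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-10):
            raise ValueError("distance matrix must have a zero diagonal")
        self.values = v

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)


def dice_distance_matrix(encoding: AlleleEncoding) -> DistanceMatrix:
    """Pairwise Dice distances ``1 - 2a/(2a+b+c)`` on a binary allele matrix."""
    x = (encoding.values > 0).astype(float)
    shared = x @ x.T  # a for each pair
    totals = x.sum(axis=1)
    denom = totals[:, None] + totals[None, :]
    if np.any((denom == 0) & ~np.eye(len(x), dtype=bool)):
        i, j = np.argwhere((denom == 0) & ~np.eye(len(x), dtype=bool))[0]
        raise ValueError(
            "Dice similarity undefined between all-zero profiles "
            f"{encoding.accession_ids[i]} and {encoding.accession_ids[j]}"
        )
    with np.errstate(invalid="ignore"):
        sim = 2.0 * shared / denom
    d = 1.0 - sim
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(values=d, ids=list(encoding.accession_ids))


@dataclass
class Dendrogram:
    """Rooted binary merge tree from agglomerative clustering.

    ``linkage`` is a SciPy linkage matrix; merge heights are the inter-cluster
    distances at merge, so cophenetic distances live on the scale of the input
    distance matrix.
    """

    linkage: np.ndarray
    ids: list[str]
    method: str
    supports: Optional[dict[frozenset, float]] = None

    def cophenetic(self) -> DistanceMatrix:
        coph = hierarchy.cophenet(self.linkage)
        return DistanceMatrix(values=squareform(coph), ids=list(self.ids))

    def bipartitions(self) -> set[frozenset]:
        """Leaf-id sets under each internal node (trivial root/leaf sets excluded)."""
        n = len(self.ids)
        members: dict[int, frozenset] = {i: frozenset([self.ids[i]]) for i in range(n)}
        parts: set[frozenset] = set()
        for step, (a, b, _, _) in enumerate(self.linkage):
            merged = members[int(a)] | members[int(b)]
            members[n + step] = merged
            if 1 < len(merged) < n:
                parts.add(merged)
        return parts

    def to_newick(self, include_supports: bool = True) -> str:
        """Newick string with branch lengths; bootstrap supports, when present,
        appear as internal node labels.

        Uses the half-height convention (each node sits at half its merge
        distance), so the path length between two leaves equals their
        cophenetic distance.
        """
        n = len(self.ids)
        tree = hierarchy.to_tree(self.linkage)
        members: dict[int, frozenset] = {}

        def leafset(node) -> frozenset:
            if node.id in members:
                return members[node.id]
            s = (
                frozenset([self.ids[node.id]])
                if node.is_leaf()
                else leafset(node.left) | leafset(node.right)
            )
            members[node.id] = s
            return s

        def render(node, parent_height: float) -> str:
            length = max(parent_height - node.dist, 0.0) / 2.0
            if node.is_leaf():
                return f"{self.ids[node.id]}:{length:.6g}"
            inner = ",".join(
                render(child, node.dist) for child in (node.left, node.right)
            )
            label = ""
            if include_supports and self.supports is not None:
                key = leafset(node)
                if key in self.supports:
                    label = f"{self.supports[key]:.1f}"
            return f"({inner}){label}:{length:.6g}"

        return f"({render(tree.left, tree.dist)},{render(tree.right, tree.dist)});"


def hcluster(D: DistanceMatrix, method: str = "UPGMA") -> Dendrogram:
    """Agglomerative clustering of a distance matrix.

    Methods: ``single``, ``complete``, ``UPGMA`` (arithmetic average over all
    inter-cluster pairs) and ``WPGMA``. Merge heights equal the inter-cluster
    distance at merge.
    """
    if method not in LINKAGE_METHODS:
        raise ValueError(f"unknown linkage method {method!r}; choose from {sorted(LINKAGE_METHODS)}")
    Z = hierarchy.linkage(D.condensed(), method=LINKAGE_METHODS[method])
    return Dendrogram(linkage=Z, ids=list(D.ids), method=method)


@dataclass
class LinkageEvaluation:
    method: str
    cc: float
    delta_05: float
    delta_1: float


def cc_and_delta(D: DistanceMatrix, dend_or_C, method: str = "") -> LinkageEvaluation:
    """Cophenetic correlation and Mather's delta between data and dendrogram.

    ``CC`` is the Pearson correlation of the upper-triangle entries of the
    input distances ``d`` and the cophenetic distances ``c``;
    ``delta_q = sqrt( sum (d^q - c^q)^2 / sum d^(2q) )`` for ``q`` in
    {0.5, 1}. Lower delta and higher CC mean the tree distorts the distances
    less.
    """
    if isinstance(dend_or_C, Dendrogram):
        C = dend_or_C.cophenetic()
        method = method or dend_or_C.method
    else:
        C = dend_or_C
    d = D.condensed()
    c = C.condensed()
    if np.allclose(d, d[0]):
        raise ValueError("cophenetic correlation undefined for a constant distance matrix")
    cc = float(np.corrcoef(d, c)[0, 1])
    deltas = {}
    for q in (0.5, 1.0):
        deltas[q] = float(np.sqrt(np.sum((d**q - c**q) ** 2) / np.sum(d ** (2 * q))))
    return LinkageEvaluation(method=method, cc=cc, delta_05=deltas[0.5], delta_1=deltas[1.0])


def select_linkage(
    D: DistanceMatrix, methods: Sequence[str] = ("single", "complete", "UPGMA", "WPGMA")
) -> tuple[str, list[LinkageEvaluation]]:
    """Pick the linkage with the highest CC; ties go to the smaller delta_1.

    A residual full tie (e.g. an ultrametric input, where every method
    reproduces the tree exactly) resolves to average linkage: UPGMA, then
    WPGMA, complete, single.
    """
    if not methods:
        raise ValueError("select_linkage needs at least one method")
    preference = {"UPGMA": 0, "WPGMA": 1, "complete": 2, "single": 3}
    evaluations = []
    for method in methods:
        dend = hcluster(D, method)
        evaluations.append(cc_and_delta(D, dend))
    best = min(
        evaluations, key=lambda e: (-e.cc, e.delta_1, preference.get(e.method, 9))
    )
    return best.method, evaluations


def bootstrap_supports(
    matrix: GenotypeMatrix,
    method: str = "UPGMA",
    n_boot: int = 10000,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> Dendrogram:
    """Bootstrap clade supports by resampling loci with replacement.

    Each replicate redraws the locus set, rebuilds the binary encoding, the
    Dice matrix and the dendrogram, and scores which reference bipartitions
    reappear. Supports are percentages over ``n_boot`` replicates, attached to
    the returned reference dendrogram. Loci (not allele columns) are the
    resampling unit so within-locus allele dependence is preserved.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if len(matrix.loci) < 3:
        raise ValueError("bootstrap needs at least 3 loci")
    if rng is None:
        rng = np.random.default_rng(seed)
    encoding = encode_binary(matrix)
    reference = hcluster(dice_distance_matrix(encoding), method)
    ref_parts = reference.bipartitions()
    counts = {part: 0 for part in ref_parts}

    blocks = {locus: encoding.locus_block(locus) for locus in encoding.loci}
    n_loci = len(encoding.loci)
    for _ in range(n_boot):
        chosen = rng.integers(0, n_loci, size=n_loci)
        x = np.hstack([blocks[encoding.loci[j]] for j in chosen])
        boot_enc = AlleleEncoding(
            values=x,
            accession_ids=encoding.accession_ids,
            columns=[("boot", str(j)) for j in range(x.shape[1])],
            missing=encoding.missing,
            loci=[str(j) for j in chosen],
        )
        dend = hcluster(dice_distance_matrix(boot_enc), method)
        for part in dend.bipartitions():
            if part in counts:
                counts[part] += 1
    reference.supports = {part: 100.0 * c / n_boot for part, c in counts.items()}
    return reference


@dataclass
class PCAResult:
    scores: np.ndarray
    explained_pct: np.ndarray  # over all components, sums to 100
    loadings: np.ndarray  # columns x components
    accession_ids: list[str]


def pca(encoding: AlleleEncoding, n_components: int = 2) -> PCAResult:
    """PCA of the column-centered allele matrix (covariance, no scaling).

    Percent variance explained is reported for every principal axis and sums
    to 100. Component signs are fixed so the largest-magnitude loading of
    each returned component is positive.
    """
    x = np.asarray(encoding.values, dtype=float)
    if x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("pca needs at least 2 accessions and 2 allele columns")
    centered = x - x.mean(axis=0)
    if np.allclose(centered, 0.0):
        raise ValueError("pca undefined for a zero-variance matrix")
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    eig = s**2
    explained = 100.0 * eig / eig.sum()
    k = min(n_components, len(s))
    scores = u[:, :k] * s[:k]
    loadings = vt[:k].T
    for j in range(k):
        pivot = np.argmax(np.abs(loadings[:, j]))
        if loadings[pivot, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    return PCAResult(
        scores=scores,
        explained_pct=explained,
        loadings=loadings,
        accession_ids=list(encoding.accession_ids),
    )


def write_phylip_distance(D: DistanceMatrix, path) -> None:
    """Square PHYLIP distance-matrix format."""
    with open(path, "w") as handle:
        handle.write(f"{len(D.ids)}\n")
        for i, name in enumerate(D.ids):
            row = " ".join(f"{v:.6f}" for v in D.values[i])
            handle.write(f"{name:<12s}{row}\n")
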