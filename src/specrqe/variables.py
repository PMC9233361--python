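"""Builders that turn per-sample variables into sample-by-sample dissimilarity matrices.

Specificity analysis scores every feature (OTU/ASV/metabolite/...) against a
square matrix ``D`` of pairwise differences between samples.  ``D`` can come
from many places: a numeric metadata column (elevation, pH), a host phylogeny
(cophenetic distances), a hierarchical sample-type ontology converted to a
unit-branch cladogram, the beta-diversity of a co-occurring feature table, or
a precomputed matrix.  Everything in this module funnels through
:func:`validate_dissim`, which enforces the invariants the downstream
statistic relies on: square, symmetric, zero diagonal, nonnegative, and
aligned to the abundance table's sample order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

logger = logging.getLogger("specrqe")

#: relative tolerance used when checking matrix symmetry
SYMMETRY_RTOL = 1e-8


@dataclass(frozen=True)
class DissimilarityMatrix:
    """A validated square matrix of pairwise differences between samples.

    Attributes
    ----------
    labels : tuple of str
        Sample identifiers, in the order of the matrix rows/columns.
    values : numpy.ndarray
        ``n x n`` symmetric nonnegative matrix with a zero diagonal.
    """

    labels: tuple
    values: np.ndarray = field(repr=False)

    @property
    def n(self) -> int:
        return len(self.labels)

    def reorder(self, order: Sequence[str]) -> "DissimilarityMatrix":
        """Return a copy aligned to ``order`` (a subset is allowed)."""
        pos = {s: i for i, s in enumerate(self.labels)}
        missing = [s for s in order if s not in pos]
        if missing:
            raise KeyError(
                f"samples missing from dissimilarity matrix: {missing[:5]}"
            )
        idx = np.array([pos[s] for s in order], dtype=int)
        return DissimilarityMatrix(tuple(order), self.values[np.ix_(idx, idx)])


@dataclass
class SampleTree:
    """A rooted tree plus a many-to-one map from samples to its tips."""

    tree: dendropy.Tree
    sample_map: Mapping[str, str]

    def __post_init__(self) -> None:
        tips = {leaf.taxon.label for leaf in self.tree.leaf_node_iter()}
        for sample, tip in self.sample_map.items():
            if tip not in tips:
                raise KeyError(
                    f"sample {sample!r} maps to unknown tip {tip!r}"
                )
        for edge in self.tree.preorder_edge_iter():
            if edge.length is not None and (
                not np.isfinite(edge.length) or edge.length < 0
            ):
                raise ValueError(f"negative or non-finite branch length {edge.length}")


def validate_dissim(
    values,
    labels: Sequence[str],
    order: Sequence[str] | None = None,
    rtol: float = SYMMETRY_RTOL,
) -> DissimilarityMatrix:
    """Validate (and optionally re-align) a candidate dissimilarity matrix.

    Checks squareness, label uniqueness, finiteness, nonnegativity, a zero
    diagonal and symmetry within ``rtol`` (matrices within tolerance are
    symmetrized by averaging).  When ``order`` is given the matrix is
    reordered to it; samples present in the matrix but not in ``order`` are
    dropped with a logged warning, samples missing from the matrix raise.
    """
    values = np.asarray(values, dtype=float)
    labels = list(labels)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError(f"matrix is not square: shape {values.shape}")
    if len(labels) != values.shape[0]:
        raise ValueError("label count does not match matrix size")
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate sample labels")
    if not np.all(np.isfinite(values)):
        raise ValueError("matrix contains non-finite entries")
    if np.any(values < 0):
        raise ValueError("matrix contains negative entries")
    scale = np.abs(values).max()
    if not np.allclose(values, values.T, rtol=0, atol=rtol * max(scale, 1.0)):
        raise ValueError("matrix is asymmetric beyond tolerance")
    if np.any(np.diag(values) != 0):
        raise ValueError("matrix diagonal is not exactly zero")
    values = (values + values.T) / 2.0

    D = DissimilarityMatrix(tuple(labels), values)
    if order is not None:
        extra = set(labels) - set(order)
        if extra:
            logger.warning(
                "dropping %d matrix sample(s) absent from the table", len(extra)
            )
        D = D.reorder(list(order))
    return D


def vector_to_dissim(
    x, labels: Sequence[str] | None = None
) -> DissimilarityMatrix:
    """Absolute pairwise differences of a per-sample numeric variable.

    ``D_ij = |x_i - x_j|`` — the 1-D euclidean transform used for elevation,
    rainfall and similar scalar metadata.  The variable is not standardized:
    the Spec statistic is scale-invariant in ``D``.
    """
    x = np.asarray(x, dtype=float)
    if labels is None:
        labels = [f"s{i}" for i in range(len(x))]
    labels = list(labels)
    if len(labels) != len(x):
        raise ValueError("labels length does not match vector length")
    bad = np.flatnonzero(~np.isfinite(x))
    if bad.size:
        raise ValueError(
            f"non-finite value for sample(s) {[labels[i] for i in bad[:5]]}"
        )
    if np.ptp(x) == 0:
        logger.warning(
            "constant variable: all dissimilarities are zero; "
            "Spec will be undefined for this variable"
        )
    D = np.abs(x[:, None] - x[None, :])
    np.fill_diagonal(D, 0.0)
    return validate_dissim(D, labels)


def tree_to_dissim(stree: SampleTree, samples: Sequence[str] | None = None) -> DissimilarityMatrix:
    """Cophenetic (tip-to-tip path length) distances between samples.

    Samples mapped to the same tip are at distance zero, matching the
    host-phylogeny convention: replicate samples from one host species do
    not differ.
    """
    if samples is None:
        samples = list(stree.sample_map)
    missing = [s for s in samples if s not in stree.sample_map]
    if missing:
        raise KeyError(f"sample(s) not in sample_map: {missing[:5]}")
    pdm = stree.tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in stree.tree.taxon_namespace}
    n = len(samples)
    D = np.zeros((n, n))
    for i in range(n):
        ti = taxa[stree.sample_map[samples[i]]]
        for j in range(i + 1, n):
            tj = taxa[stree.sample_map[samples[j]]]
            if ti is tj:
                d = 0.0
            else:
                d = pdm.patristic_distance(ti, tj)
            D[i, j] = D[j, i] = d
    return validate_dissim(D, list(samples))


def onto_to_tree(onto: pd.DataFrame) -> SampleTree:
    """Convert a hierarchical sample-type ontology into a unit-branch cladogram.

    ``onto`` has one row per sample and ordered columns coarse→fine (e.g.
    EMPO1..EMPO3).  The result is a rooted tree — root, level-1 labels, ...,
    finest-level labels as tips — with every branch length 1; each sample
    maps to its finest-level label.  Singleton internal nodes are kept, so a
    tip's depth always equals the number of levels; only the absolute
    cophenetic scale depends on this, and Spec's standardization cancels it.
    """
    if onto.isna().any().any():
        bad = onto.index[onto.isna().any(axis=1)][:5].tolist()
        raise ValueError(f"missing ontology labels for sample(s) {bad}")
    levels = list(onto.columns)
    if not levels:
        raise ValueError("ontology table has no levels")
    # consistency: a label at level k+1 has exactly one parent at level k
    for k in range(len(levels) - 1):
        parents = onto.groupby(levels[k + 1], sort=False)[levels[k]].nunique()
        bad = parents[parents > 1]
        if len(bad):
            raise ValueError(
                f"inconsistent hierarchy: label {bad.index[0]!r} at level "
                f"{levels[k + 1]!r} has {bad.iloc[0]} parents at level {levels[k]!r}"
            )

    taxon_namespace = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxon_namespace)
    nodes: dict[tuple, dendropy.Node] = {(): tree.seed_node}
    paths = onto[levels].drop_duplicates().sort_values(levels)
    for row in paths.itertuples(index=False):
        for depth in range(1, len(levels) + 1):
            key = tuple(row[:depth])
            if key not in nodes:
                child = nodes[key[:-1]].new_child(edge_length=1.0)
                nodes[key] = child
                if depth == len(levels):
                    child.taxon = taxon_namespace.new_taxon(label=str(row[depth - 1]))
    sample_map = {str(s): str(v) for s, v in onto[levels[-1]].items()}
    return SampleTree(tree=tree, sample_map=sample_map)


def table_to_dissim(
    table: pd.DataFrame, metric: str = "braycurtis"
) -> DissimilarityMatrix:
    """Beta-diversity of a co-occurring feature table (samples x features).

    Supports Bray–Curtis (compositional data such as an algal ASV table) and
    Euclidean (e.g. metabolite concentrations within one compound class).
    """
    if metric not in ("braycurtis", "euclidean"):
        raise ValueError(f"unsupported metric {metric!r}")
    X = np.asarray(table.values, dtype=float)
    if np.any(X < 0) or not np.all(np.isfinite(X)):
        raise ValueError("feature table must be nonnegative and finite")
    if metric == "braycurtis":
        zero = np.flatnonzero(X.sum(axis=1) == 0)
        if zero.size:
            raise ValueError(
                "all-zero sample row(s) under braycurtis: "
                f"{[table.index[i] for i in zero[:5]]}"
            )
    D = squareform(pdist(X, metric=metric))
    np.fill_diagonal(D, 0.0)
    return validate_dissim(D, list(table.index))
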