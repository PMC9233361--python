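"""Readers, writers, preprocessing filters and summary statistics.

Canonical tabular dialect is TSV (header row, first column holds sample or
feature ids); CSV is accepted on read.  Results are written one TSV per
variable because the Benjamini–Hochberg adjustment is performed within a
variable across features.
"""

from __future__ import annotations

import logging
from itertools import permutations
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .variables import DissimilarityMatrix, SampleTree, validate_dissim

logger = logging.getLogger("specrqe")

__all__ = [
    "read_table", "read_metadata", "read_square_matrix", "read_newick",
    "read_ontology", "write_results", "read_results", "close_tss", "filter_occupancy",
    "filter_depth", "pairwise_spec_cor", "mantel",
]


def _sep(path) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


def read_table(path) -> pd.DataFrame:
    """Samples x features abundance table (rows = samples)."""
    df = pd.read_csv(path, sep=_sep(path), index_col=0)
    if df.index.has_duplicates or df.columns.has_duplicates:
        raise ValueError(f"{path}: duplicate sample or feature ids")
    values = df.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)) or np.any(values < 0):
        raise ValueError(f"{path}: table must be nonnegative and finite")
    return df.astype(float)


def read_metadata(path) -> pd.DataFrame:
    return pd.read_csv(path, sep=_sep(path), index_col=0)


def read_square_matrix(path, order=None) -> DissimilarityMatrix:
    """Square dissimilarity matrix with sample labels in first row and column."""
    df = pd.read_csv(path, sep=_sep(path), index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError(f"{path}: row and column labels differ")
    return validate_dissim(df.to_numpy(dtype=float), list(df.index), order=order)


def read_newick(path, sample_map) -> SampleTree:
    """Newick tree plus a sample→tip map (dict, Series, or 2-column TSV path)."""
    tree = dendropy.Tree.get(path=str(path), schema="newick",
                             preserve_underscores=True)
    if isinstance(sample_map, (str, Path)):
        m = pd.read_csv(sample_map, sep=_sep(sample_map), index_col=0).iloc[:, 0]
        sample_map = {str(k): str(v) for k, v in m.items()}
    elif isinstance(sample_map, pd.Series):
        sample_map = {str(k): str(v) for k, v in sample_map.items()}
    return SampleTree(tree=tree, sample_map=dict(sample_map))


def read_ontology(path) -> pd.DataFrame:
    """Sample ontology: one row per sample, ordered columns coarse→fine."""
    return pd.read_csv(path, sep=_sep(path), index_col=0, dtype=str)


def write_results(results: pd.DataFrame, outdir) -> list[Path]:
    """Write one result TSV per variable; floats at full round-trip precision."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for var, sub in results.groupby("variable_id", sort=False):
        path = outdir / f"spec_{var}.tsv"
        sub.to_csv(path, sep="\t", index=False, float_format="%.17g")
        paths.append(path)
    return paths


def read_results(path) -> pd.DataFrame:
    """Read a result TSV back with exact (round-trip) float parsing."""
    return pd.read_csv(path, sep="\t", float_precision="round_trip")


def close_tss(table: pd.DataFrame) -> pd.DataFrame:
    """Total sum scaling ("closure"): each sample's weights sum to 1."""
    totals = table.sum(axis=1)
    zero = totals.index[totals <= 0]
    if len(zero):
        raise ValueError(f"zero-total sample(s): {list(zero[:5])}")
    return table.div(totals, axis=0)


def filter_occupancy(table: pd.DataFrame, min_occ: int) -> pd.DataFrame:
    """Keep features with positive weight in at least ``min_occ`` samples."""
    if min_occ < 1:
        raise ValueError("min_occ must be >= 1")
    occ = (table > 0).sum(axis=0)
    kept = table.loc[:, occ >= min_occ]
    logger.info("occupancy filter (>=%d): %d -> %d features",
                min_occ, table.shape[1], kept.shape[1])
    return kept


def filter_depth(table: pd.DataFrame, min_reads: int) -> pd.DataFrame:
    """Drop samples whose total count is below ``min_reads``."""
    totals = table.sum(axis=1)
    kept = table.loc[totals >= min_reads]
    logger.info("depth filter (>=%d reads): %d -> %d samples",
                min_reads, table.shape[0], kept.shape[0])
    if kept.shape[0] == 0:
        raise ValueError(
            f"no samples left after depth filter >= {min_reads}; review the threshold"
        )
    return kept


def pairwise_spec_cor(results: pd.DataFrame, min_shared: int = 3) -> pd.DataFrame:
    """Pearson correlation of Spec vectors between every pair of variables.

    Features flagged or without a Spec value are excluded per pair; pairs
    sharing fewer than ``min_shared`` analyzable features get NaN with a
    warning.  Diagonal is exactly 1.
    """
    ok = results[results["spec"].notna()]
    wide = ok.pivot(index="feature_id", columns="variable_id", values="spec")
    if wide.shape[1] < 2:
        raise ValueError("need at least two variables with Spec values")
    cor = wide.corr(method="pearson", min_periods=min_shared)
    if cor.isna().any().any():
        logger.warning("insufficient shared features for some variable pairs")
    np.fill_diagonal(cor.values, 1.0)
    return cor


def _offdiag(values: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(values.shape[0], k=1)
    return values[iu]


def mantel(
    D1: DissimilarityMatrix,
    D2: DissimilarityMatrix,
    n_perm: int = 999,
    seed=None,
    alternative: str = "greater",
    exhaustive: bool = False,
):
    """Mantel test: correlation between two sample dissimilarity matrices.

    Pearson r over the upper off-diagonal triangles; the p-value comes from
    relabeling the samples of ``D2`` (``n_perm`` random relabelings, or all
    n! when ``exhaustive``), counted with the identity included:
    p = (#{r_perm as or more extreme} + 1) / (N + 1).
    """
    if D1.labels != D2.labels:
        raise ValueError("matrices have different sample labels")
    if alternative not in ("greater", "less", "two-sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    x = _offdiag(D1.values)
    n = D1.n
    r_obs = float(np.corrcoef(x, _offdiag(D2.values))[0, 1])

    def _r(perm) -> float:
        V = D2.values[np.ix_(perm, perm)]
        return float(np.corrcoef(x, _offdiag(V))[0, 1])

    if exhaustive:
        r_perm = np.array([_r(np.array(s)) for s in permutations(range(n))])
    else:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        r_perm = np.array([_r(rng.permutation(n)) for _ in range(n_perm)])
    if alternative == "greater":
        hits = np.count_nonzero(r_perm >= r_obs)
    elif alternative == "less":
        hits = np.count_nonzero(r_perm <= r_obs)
    else:
        hits = np.count_nonzero(np.abs(r_perm) >= abs(r_obs))
    if exhaustive:  # the identity relabeling is already in the enumeration
        p = hits / len(r_perm)
    else:
        p = (hits + 1) / (len(r_perm) + 1)
    return r_obs, float(p)
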