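"""Rao's quadratic entropy, the Spec statistic, and the per-feature driver.

For a feature with per-sample weights ``p`` (relative abundances or any other
importance score) and a sample dissimilarity matrix ``D``,

    RQE = sum over ordered pairs i != j of D_ij * p_i * p_j .

A perfectly specific feature — positive weight only on mutually identical
samples — has RQE = 0.  RQE's scale depends on the scales of ``p`` and ``D``,
so it is standardized against a permutation null into Spec in [-1, 1]:

    Spec = (RQE_emp - c) / c                     if RQE_emp <= c
    Spec = (RQE_emp - c) / (RQE_max - c)         if RQE_emp >  c

where ``c`` is the central tendency (mean by default) of RQE over random
permutations of ``p`` and RQE_max is the permutation maximum found by the
genetic algorithm in :mod:`specrqe.ga`.  Spec = -1 means perfect
specificity, 0 the null, +1 maximal generality.  A left-tail permutation
p-value (the fraction of null values below RQE_emp) with Benjamini–Hochberg
adjustment across the features of one variable completes the test.

Both summation triangles are counted throughout (``rqe``, the null, the GA);
the constant factor of two cancels in every Spec ratio, so only consistency
matters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from joblib import Parallel, delayed
from statsmodels.stats.multitest import multipletests

from .ga import GAConfig, rqe_max_ga
from .variables import DissimilarityMatrix

logger = logging.getLogger("specrqe")

__all__ = [
    "rqe",
    "rqe_null",
    "NullDistribution",
    "spec_stat",
    "spec_pvalue",
    "adjust_bh",
    "SpecResult",
    "run_specificity",
    "DEFAULT_N_SIM",
]

#: default number of weight permutations in the null distribution
DEFAULT_N_SIM = 500

RESULT_COLUMNS = [
    "feature_id", "variable_id", "rqe_emp", "sim_center", "rqe_max",
    "spec", "pval", "pval_adj", "occupancy", "flags",
]


def _as_matrix(D) -> np.ndarray:
    if isinstance(D, DissimilarityMatrix):
        return D.values
    return np.asarray(D, dtype=float)


def rqe(p, D) -> float:
    """Rao's quadratic entropy of weights ``p`` against dissimilarities ``D``.

    Sums ``D_ij p_i p_j`` over all ordered pairs ``i != j`` (both triangles).
    Zero exactly when every pair of samples that both carry positive weight
    is at dissimilarity zero.
    """
    p = np.asarray(p, dtype=float)
    Dv = _as_matrix(D)
    if Dv.shape != (p.shape[0], p.shape[0]):
        raise ValueError(
            f"length mismatch: p has {p.shape[0]} samples, D is {Dv.shape}"
        )
    return float(p @ Dv @ p)  # diag(D) == 0, so the i == j terms vanish


@dataclass
class NullDistribution:
    """RQE under random permutations of the weights vector."""

    values: np.ndarray = field(repr=False)
    seed: object = None

    @property
    def n_sim(self) -> int:
        return self.values.shape[0]

    def center(self, mode: str = "mean") -> float:
        if mode == "mean":
            return float(self.values.mean())
        if mode == "median":
            return float(np.median(self.values))
        raise ValueError(f"unknown center mode {mode!r}")


def rqe_null(p, D, n_sim: int = DEFAULT_N_SIM, seed=None) -> NullDistribution:
    """Score ``n_sim`` independent uniform-random permutations of ``p``.

    ``seed`` may be an int, a ``SeedSequence`` or a ``Generator``;
    the same seed always yields the same null values.
    """
    if n_sim < 2:
        raise ValueError("n_sim must be >= 2")
    p = np.asarray(p, dtype=float)
    Dv = _as_matrix(D)
    if Dv.shape != (p.shape[0], p.shape[0]):
        raise ValueError("length mismatch between p and D")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = p.shape[0]
    idx = rng.permuted(np.broadcast_to(np.arange(n), (n_sim, n)), axis=1)
    V = p[idx]
    values = np.einsum("ij,jk,ik->i", V, Dv, V)
    return NullDistribution(values=values, seed=seed)


def spec_stat(
    rqe_emp: float,
    null: NullDistribution | float,
    rqe_max: float | None = None,
    denom_type: str = "ga",
    center: str = "mean",
) -> float:
    """Standardize an empirical RQE into Spec.

    The lower branch maps [0, c] onto [-1, 0]; the upper branch divides by
    ``RQE_max - c`` (``denom_type='ga'``) or reuses ``c`` as a fast ordinal
    scale (``denom_type='sim_center'``; identical to GA mode for every
    feature with Spec < 0).  A degenerate null (``c == 0``) leaves Spec
    undefined and returns NaN.
    """
    if denom_type not in ("ga", "sim_center"):
        raise ValueError(f"unknown denom_type {denom_type!r}")
    c = null.center(center) if isinstance(null, NullDistribution) else float(null)
    if c == 0.0:
        return float("nan")
    if rqe_emp <= c:
        return (rqe_emp - c) / c
    if denom_type == "sim_center":
        return (rqe_emp - c) / c
    if rqe_max is None:
        raise ValueError("denom_type='ga' requires rqe_max when RQE_emp > center")
    if rqe_max < rqe_emp:
        raise ValueError("rqe_max must be >= rqe_emp")
    if rqe_max == c:
        return float("nan")
    return (rqe_emp - c) / (rqe_max - c)


def spec_pvalue(rqe_emp: float, null: NullDistribution, mode: str = "proportion") -> float:
    """Left-tail permutation p: the fraction of null RQE values below RQE_emp.

    ``mode='proportion'`` is the literal count/n_sim; ``mode='add_one'``
    returns (count+1)/(n_sim+1), which cannot be exactly zero.
    """
    count = int(np.count_nonzero(null.values < rqe_emp))
    if mode == "proportion":
        return count / null.n_sim
    if mode == "add_one":
        return (count + 1) / (null.n_sim + 1)
    raise ValueError(f"unknown p-value mode {mode!r}")


def adjust_bh(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment (NaNs passed through)."""
    p = np.asarray(pvals, dtype=float)
    ok = ~np.isnan(p)
    if np.any((p[ok] < 0) | (p[ok] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full_like(p, np.nan)
    if ok.sum():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


@dataclass
class SpecResult:
    """Per-(feature, variable) specificity outcome."""

    feature_id: str
    variable_id: str
    rqe_emp: float
    sim_center: float
    rqe_max: float  # NaN when the GA was not run
    spec: float
    pval: float
    pval_adj: float
    occupancy: int
    flags: frozenset


def _feature_seed(master_seed: int, var_index: int, feat_index: int) -> np.random.SeedSequence:
    """Reproducible per-(variable, feature) RNG stream.

    Derived from the master seed by index so serial and parallel runs agree
    bit-for-bit, and any single feature can be replayed in isolation.
    """
    return np.random.SeedSequence(entropy=(int(master_seed), var_index, feat_index))


def _one_feature(
    feature_id: str,
    variable_id: str,
    p: np.ndarray,
    Dv: np.ndarray,
    ss: np.random.SeedSequence,
    n_sim: int,
    denom_type: str,
    center: str,
    p_mode: str,
    ga_config: GAConfig | None,
) -> SpecResult:
    rng = np.random.default_rng(ss)
    occupancy = int(np.count_nonzero(p > 0))
    flags = set()
    if occupancy < 2:
        flags.add("low_occupancy")
        return SpecResult(feature_id, variable_id, float("nan"), float("nan"),
                          float("nan"), float("nan"), float("nan"), float("nan"),
                          occupancy, frozenset(flags))
    emp = rqe(p, Dv)
    null = rqe_null(p, Dv, n_sim=n_sim, seed=rng)
    c = null.center(center)
    pval = spec_pvalue(emp, null, mode=p_mode)
    rmax = float("nan")
    if c == 0.0:
        flags.add("degenerate_null")
        spec = float("nan")
    elif emp > c and denom_type == "ga":
        result = rqe_max_ga(p, Dv, config=ga_config, rng=rng)
        rmax = result.rqe_max
        if rmax < emp:  # elitism + p in the population make this unreachable
            rmax = emp
        spec = spec_stat(emp, c, rqe_max=rmax, denom_type="ga")
        if np.isnan(spec):
            flags.add("degenerate_null")
    else:
        if emp > c:
            flags.add("ga_not_run")
        spec = spec_stat(emp, c, denom_type="sim_center")
    if np.isnan(rmax) and denom_type == "ga" and emp <= c:
        flags.add("ga_not_run")
    return SpecResult(feature_id, variable_id, emp, c, rmax, spec, pval,
                      float("nan"), occupancy, frozenset(flags))


def run_specificity(
    table: pd.DataFrame,
    variables: dict,
    n_sim: int = DEFAULT_N_SIM,
    denom_type: str = "ga",
    center: str = "mean",
    p_mode: str = "proportion",
    ga_config: GAConfig | None = None,
    seed: int = 0,
    n_workers: int = 1,
) -> pd.DataFrame:
    """Score every feature of ``table`` against every variable.

    Parameters
    ----------
    table : DataFrame
        Samples x features weights (rows = samples).  Weights are used as
        given; apply :func:`specrqe.io.close_tss` first if you want
        relative abundances.
    variables : dict of str -> DissimilarityMatrix
        Named variables.  A variable covering only a subset of the table's
        samples restricts that variable's analysis to the intersection
        (other variables are unaffected); an empty intersection raises.
    seed : int
        Master seed; per-(variable, feature) RNG streams are derived from it
        by index, so results are reproducible and independent of
        ``n_workers``.

    Returns
    -------
    DataFrame
        One row per (feature, variable) with RQE_emp, the null center,
        RQE_max (when searched), Spec, the raw and BH-adjusted p-values
        (adjusted within each variable), occupancy and flags.
    """
    if denom_type not in ("ga", "sim_center"):
        raise ValueError(f"unknown denom_type {denom_type!r}")
    features = list(table.columns)
    rows: list[SpecResult] = []
    for vi, (var_name, D) in enumerate(variables.items()):
        if not isinstance(D, DissimilarityMatrix):
            raise TypeError(f"variable {var_name!r} is not a DissimilarityMatrix")
        shared = [s for s in table.index if s in set(D.labels)]
        if not shared:
            raise ValueError(f"no samples shared between table and variable {var_name!r}")
        if len(shared) < len(table.index):
            logger.warning(
                "variable %s: dropping %d sample(s) without metadata",
                var_name, len(table.index) - len(shared),
            )
        Dv = D.reorder(shared).values
        sub = table.loc[shared]
        jobs = [
            (str(f), var_name, sub[f].to_numpy(dtype=float), Dv,
             _feature_seed(seed, vi, fi), n_sim, denom_type, center, p_mode,
             ga_config)
            for fi, f in enumerate(features)
        ]
        if n_workers == 1:
            results = [_one_feature(*j) for j in jobs]
        else:
            results = Parallel(n_jobs=n_workers)(delayed(_one_feature)(*j) for j in jobs)
        adj = adjust_bh([r.pval for r in results])
        for r, a in zip(results, adj):
            r.pval_adj = float(a)
        rows.extend(results)

    return pd.DataFrame([vars(r) | {"flags": ";".join(sorted(r.flags))} for r in rows],
                        columns=RESULT_COLUMNS)
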