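"""Synthetic species with controlled specificity along an environmental gradient.

The validation machinery: simulated species respond to a 1-D environmental
gradient (think elevation) as a Gaussian curve centred on a niche optimum —
weight at a sample is proportional to the normal density at that sample's
environmental value.  Niche breadth is the curve's standard deviation;
mixing in a uniform component weakens specificity smoothly (``uniform_mix=1``
is a species indifferent to the gradient); multimodality sums several
curves.  Occupancy is manipulated by zeroing randomly chosen positive
weights, and empirical weight distributions can be re-ordered into
high-specificity species and then degraded by recursive random swaps.

The response curve is deterministic given the gradient; a Poisson sampling
wrapper adds count noise when realism matters more than exactness.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "SimSpec",
    "env_gradient",
    "sim_species",
    "add_poisson_noise",
    "thin_occupancy",
    "reorder_to_specific",
    "swap_series",
    "downsample_samples",
    "make_dataset",
    "write_fixture",
]


@dataclass
class SimSpec:
    """Parameters of one simulated species' response to the gradient.

    optimum : niche centre on the gradient (e.g. an elevation of 300 m).
    sd : niche breadth; larger means a broader, less specific species.
    uniform_mix : proportion of a uniform background component in [0, 1].
    modes : optional list of ``(optimum, sd, mode_weight)`` triples for
        multimodal species; mode weights must sum to 1.
    occupancy_target : optionally thin the species to exactly this many
        occupied samples (uses ``seed``).
    """

    optimum: float = 0.0
    sd: float = 1.0
    uniform_mix: float = 0.0
    modes: list | None = None
    occupancy_target: int | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("sd must be positive")
        if not 0.0 <= self.uniform_mix <= 1.0:
            raise ValueError("uniform_mix must be in [0, 1]")
        if self.modes is not None:
            w = sum(m[2] for m in self.modes)
            if abs(w - 1.0) > 1e-9:
                raise ValueError("mode weights must sum to 1")
            if any(m[1] <= 0 for m in self.modes):
                raise ValueError("mode sds must be positive")


def env_gradient(n: int, lo: float, hi: float, seed=None) -> np.ndarray:
    """``n`` uniform sample locations on [lo, hi]."""
    if n < 3:
        raise ValueError("need at least 3 samples")
    if not lo < hi:
        raise ValueError("lo must be < hi")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.uniform(lo, hi, size=n)


def sim_species(env, spec: SimSpec, lo: float | None = None, hi: float | None = None) -> np.ndarray:
    """Weights of one simulated species at the given environmental values.

    weight_i ∝ (1 - uniform_mix) * φ(env_i; optimum, sd) + uniform_mix / (hi - lo),
    summed over modes for multimodal species, then normalized to sum 1.
    """
    env = np.asarray(env, dtype=float)
    if not np.all(np.isfinite(env)):
        raise ValueError("environmental values must be finite")
    if lo is None:
        lo = float(env.min())
    if hi is None:
        hi = float(env.max())
    width = hi - lo if hi > lo else 1.0
    modes = spec.modes if spec.modes is not None else [(spec.optimum, spec.sd, 1.0)]
    density = np.zeros_like(env)
    for opt, sd, mw in modes:
        density += mw * norm.pdf(env, loc=opt, scale=sd)
    w = (1.0 - spec.uniform_mix) * density + spec.uniform_mix / width
    total = w.sum()
    if total <= 0:
        raise ValueError("species has zero total weight on this gradient")
    w = w / total
    if spec.occupancy_target is not None:
        w = thin_occupancy(w, spec.occupancy_target, seed=spec.seed)
        w = w / w.sum()
    return w


def add_poisson_noise(p, depth: int, seed=None) -> np.ndarray:
    """Resample weights as Poisson counts at the given sequencing depth."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = np.asarray(p, dtype=float)
    counts = rng.poisson(p / p.sum() * depth)
    return counts / max(counts.sum(), 1)


def thin_occupancy(p, target: int, seed=None) -> np.ndarray:
    """Zero uniformly chosen positive weights until exactly ``target`` remain."""
    p = np.asarray(p, dtype=float)
    pos = np.flatnonzero(p > 0)
    if not 2 <= target <= pos.size:
        raise ValueError(
            f"target occupancy {target} outside [2, {pos.size}]"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    drop = rng.choice(pos, size=pos.size - target, replace=False)
    out = p.copy()
    out[drop] = 0.0
    return out


def reorder_to_specific(p, env, optimum: float) -> np.ndarray:
    """Re-order empirical weights into a maximally specific arrangement.

    The multiset of weights is preserved; the largest weights are assigned
    to the samples environmentally nearest the optimum (descending weights
    matched onto ascending ``|env - optimum|``).
    """
    p = np.asarray(p, dtype=float)
    env = np.asarray(env, dtype=float)
    if p.shape != env.shape:
        raise ValueError("p and env lengths disagree")
    order = np.argsort(np.abs(env - optimum), kind="stable")
    out = np.empty_like(p)
    out[order] = np.sort(p)[::-1]
    return out


def swap_series(p, generations: int = 1000, swaps_per_gen: int = 2, seed=None) -> np.ndarray:
    """Recursively degrade a weights vector by random pairwise swaps.

    Generation ``g`` applies ``swaps_per_gen`` random transpositions to
    generation ``g-1``; the returned array has ``generations + 1`` rows,
    row 0 being ``p`` itself.  Applied to a highly specific vector this
    traces the decay of specificity as entropy is introduced.
    """
    if generations < 1:
        raise ValueError("generations must be >= 1")
    p = np.asarray(p, dtype=float)
    n = p.shape[0]
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = np.empty((generations + 1, n))
    out[0] = p
    cur = p.copy()
    for g in range(1, generations + 1):
        for _ in range(swaps_per_gen):
            i = int(rng.integers(n))
            j = int(rng.integers(n - 1))
            if j >= i:
                j += 1
            cur[i], cur[j] = cur[j], cur[i]
        out[g] = cur
    return out


def downsample_samples(table: pd.DataFrame, D, n_keep: int, seed=None):
    """Uniformly subsample samples, applied consistently to table and D."""
    from .variables import DissimilarityMatrix

    n = table.shape[0]
    if not 3 <= n_keep <= n:
        raise ValueError(f"n_keep {n_keep} outside [3, {n}]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    keep = np.sort(rng.choice(n, size=n_keep, replace=False))
    sub = table.iloc[keep]
    if isinstance(D, DissimilarityMatrix):
        D2 = D.reorder(list(sub.index))
    else:
        D2 = np.asarray(D)[np.ix_(keep, keep)]
    return sub, D2


def make_dataset(
    n_samples: int = 40,
    sd_values=(10.0, 30.0, 100.0, 300.0),
    uniform_mixes=(0.0, 0.25, 0.5),
    occupancies=(None,),
    reps: int = 1,
    lo: float = 0.0,
    hi: float = 1000.0,
    noise_depth: int | None = None,
    seed: int = 0,
):
    """A full synthetic study: gradient, metadata and a species table.

    One species per (sd, uniform_mix, occupancy, rep) cell, each a Gaussian
    responder with a random optimum on the middle 80% of the gradient.
    ``noise_depth`` resamples every species as Poisson counts at that
    sequencing depth, adding the count noise real surveys carry (and letting
    weakly specific species land on the generality side of the null).

    Returns ``(table, metadata, truth)``: a samples x features DataFrame of
    weights, a one-column metadata DataFrame holding the gradient, and a
    per-feature DataFrame of the simulation parameters.
    """
    rng = np.random.default_rng(seed)
    env = env_gradient(n_samples, lo, hi, seed=rng)
    samples = [f"s{i:03d}" for i in range(n_samples)]
    cols, truth = {}, []
    k = 0
    for sd in sd_values:
        for mix in uniform_mixes:
            for occ in occupancies:
                for _ in range(reps):
                    opt = rng.uniform(lo + 0.1 * (hi - lo), hi - 0.1 * (hi - lo))
                    sub_seed = int(rng.integers(2**31))
                    sp = SimSpec(optimum=opt, sd=sd, uniform_mix=mix)
                    fid = f"f{k:04d}"
                    w = sim_species(env, sp, lo=lo, hi=hi)
                    if occ is not None:
                        # narrow niches can occupy fewer samples than asked
                        npos = int(np.count_nonzero(w > 0))
                        w = thin_occupancy(w, min(occ, npos), seed=sub_seed)
                        w = w / w.sum()
                    if noise_depth is not None:
                        w = add_poisson_noise(w, noise_depth, seed=rng)
                    cols[fid] = w
                    truth.append({"feature_id": fid, "optimum": opt, "sd": sd,
                                  "uniform_mix": mix, "occupancy_target": occ})
                    k += 1
    table = pd.DataFrame(cols, index=samples)
    metadata = pd.DataFrame({"gradient": env}, index=samples)
    return table, metadata, pd.DataFrame(truth).set_index("feature_id")


def write_fixture(outdir, seed: int = 0, **kwargs) -> dict:
    """Write a synthetic study as TSVs (table, metadata, truth) for CLI tests."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table, metadata, truth = make_dataset(seed=seed, **kwargs)
    paths = {
        "table": outdir / "table.tsv",
        "metadata": outdir / "metadata.tsv",
        "truth": outdir / "truth.tsv",
    }
    table.to_csv(paths["table"], sep="\t", index_label="sample_id")
    metadata.to_csv(paths["metadata"], sep="\t", index_label="sample_id")
    truth.to_csv(paths["truth"], sep="\t")
    return paths
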