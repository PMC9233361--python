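"""Elitist genetic algorithm for the generality denominator RQE_max.

The Spec statistic's positive branch divides by ``RQE_max - mean(RQE_sim)``,
where RQE_max is the largest Rao's-quadratic-entropy value attainable by any
permutation of the weights vector ``p``.  There is no closed form, so it is
found by search: an elitist GA whose population holds permutations of ``p``,
mutated by random pairwise swaps, with optional partially-mapped crossover
(PMX).  Internally the population stores *index* permutations into ``p``,
which keeps tied weight values unambiguous and makes PMX well defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GAConfig", "GAResult", "swap_mutate", "pmx_crossover", "rqe_max_ga"]


@dataclass
class GAConfig:
    """Tunables of the RQE_max search.

    The defaults are the search settings the method was published with:
    an initial population of 150 random permutations of ``p``, 150
    random-swap variants of ``p``, and ``p`` itself (301 vectors); 5 elites
    kept per generation; up to 400 generations with early stop after 10
    generations without improvement; swap counts per mutant drawn from
    {1, 1, 2, 3}; crossover off (it did not improve search efficiency).
    """

    n_perm_init: int = 150
    n_swap_init: int = 150
    keep: int = 5
    population: int | None = None  # defaults to n_perm_init + n_swap_init + 1
    max_generations: int = 400
    patience: int = 10
    swap_counts: tuple = (1, 1, 2, 3)
    use_pmx: bool = False
    pmx_fraction: float = 0.25  # fraction of mutants replaced by PMX children
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.population is None:
            self.population = self.n_perm_init + self.n_swap_init + 1
        if self.keep >= self.population:
            raise ValueError("keep must be smaller than population")
        if min(self.n_perm_init, self.n_swap_init, self.keep,
               self.max_generations, self.patience) < 1:
            raise ValueError("all GA counts must be positive")
        if any(k < 1 for k in self.swap_counts):
            raise ValueError("swap counts must be >= 1")


@dataclass
class GAResult:
    rqe_max: float
    best_vector: np.ndarray
    generations_run: int
    terminated_early: bool
    trajectory: np.ndarray = field(repr=False)


def swap_mutate(v, k: int, rng: np.random.Generator) -> np.ndarray:
    """Apply ``k`` successive random pairwise swaps to a copy of ``v``.

    Each swap exchanges two distinct positions drawn uniformly at random;
    positions may repeat across successive swaps.
    """
    v = np.asarray(v)
    n = v.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if n < 2:
        raise ValueError("vector must have length >= 2")
    out = v.copy()
    for _ in range(k):
        i = int(rng.integers(n))
        j = int(rng.integers(n - 1))
        if j >= i:
            j += 1
        out[i], out[j] = out[j], out[i]
    return out


def pmx_crossover(
    parent1,
    parent2,
    rng: np.random.Generator | None = None,
    cut_points: tuple | None = None,
) -> np.ndarray:
    """Partially-mapped crossover of two permutations of distinct items.

    The child keeps ``parent1``'s segment between the cut points, takes
    ``parent2``'s genes elsewhere, and resolves conflicts through the
    segment's value mapping — preserving both order and position information
    of the parents.  Parents must hold distinct elements (the GA always
    passes index permutations, which sidesteps tied weights).
    """
    p1 = np.asarray(parent1)
    p2 = np.asarray(parent2)
    if p1.shape != p2.shape:
        raise ValueError("parents have different lengths")
    n = p1.shape[0]
    if len(set(p1.tolist())) != n or set(p1.tolist()) != set(p2.tolist()):
        raise ValueError("parents must be permutations of the same distinct items")
    if cut_points is None:
        if rng is None:
            raise ValueError("either rng or cut_points is required")
        c1, c2 = sorted(rng.choice(n + 1, size=2, replace=False))
    else:
        c1, c2 = cut_points
    child = np.empty_like(p1)
    child[c1:c2] = p1[c1:c2]
    segment = set(p1[c1:c2].tolist())
    mapping = {p1[i]: p2[i] for i in range(c1, c2)}
    for i in list(range(0, c1)) + list(range(c2, n)):
        g = p2[i]
        while g in segment:
            g = mapping[g]
        child[i] = g
    return child


def _score(pop_idx: np.ndarray, p: np.ndarray, D: np.ndarray) -> np.ndarray:
    """RQE of every index-permutation row: v D v^T with v = p[row]."""
    V = p[pop_idx]
    return np.einsum("ij,jk,ik->i", V, D, V)


def rqe_max_ga(p, D, config: GAConfig | None = None,
               rng: np.random.Generator | None = None) -> GAResult:
    """Search permutations of ``p`` for the maximum RQE against ``D``.

    Each generation scores the whole population, keeps the ``keep`` highest
    (ties broken by first occurrence), and refills with swap-mutated copies
    of the elites allocated round-robin; when PMX is enabled a fraction of
    the mutants is replaced by crossover children of randomly paired elites.
    The search stops after ``max_generations``, or once ``patience``
    generations pass without a strict improvement of the best-ever score.
    """
    if config is None:
        config = GAConfig()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    p = np.asarray(p, dtype=float)
    D = np.asarray(D, dtype=float)
    n = p.shape[0]
    if D.shape != (n, n):
        raise ValueError("p and D sizes disagree")

    emp = float(p @ D @ p)
    if np.unique(p).size < 2:
        # RQE is invariant under permutation of a constant vector
        return GAResult(emp, p.copy(), 0, True, np.array([emp]))

    identity = np.arange(n)
    pop = np.empty((config.population, n), dtype=np.intp)
    pop[0] = identity
    for r in range(1, 1 + config.n_perm_init):
        pop[r] = rng.permutation(n)
    for r in range(1 + config.n_perm_init, config.population):
        k = int(rng.choice(config.swap_counts))
        pop[r] = swap_mutate(identity, k, rng)

    best_score = -np.inf
    best_vec = identity
    since_improve = 0
    trajectory = []
    gens = 0
    terminated_early = False
    for gen in range(config.max_generations):
        gens = gen + 1
        scores = _score(pop, p, D)
        order = np.argsort(-scores, kind="stable")
        elites = pop[order[: config.keep]].copy()
        gen_best = float(scores[order[0]])
        if gen_best > best_score:
            best_score = gen_best
            best_vec = pop[order[0]].copy()
            since_improve = 0
        else:
            since_improve += 1
        trajectory.append(best_score)
        if since_improve >= config.patience:
            terminated_early = True
            break
        n_fill = config.population - config.keep
        n_pmx = int(round(config.pmx_fraction * n_fill)) if config.use_pmx else 0
        children = np.empty((n_fill, n), dtype=np.intp)
        for m in range(n_fill - n_pmx):
            k = int(rng.choice(config.swap_counts))
            children[m] = swap_mutate(elites[m % config.keep], k, rng)
        for m in range(n_fill - n_pmx, n_fill):
            i, j = rng.choice(config.keep, size=2, replace=True)
            children[m] = pmx_crossover(elites[i], elites[j], rng=rng)
        pop[: config.keep] = elites
        pop[config.keep:] = children

    return GAResult(
        rqe_max=best_score,
        best_vector=p[best_vec],
        generations_run=gens,
        terminated_early=terminated_early,
        trajectory=np.asarray(trajectory),
    )
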