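"""Genetic-algorithm variable selection for PLS-DA.

The GA searches binary inclusion masks over the m/z variables, minimizing the
venetian-blinds cross-validated root-mean-squared error of the PLS-DA
predicted score (RMSECV on the +/-1 coded class variable). Default operator
settings: population 64, window width 1 (one gene per variable), mutation
rate 0.005 per gene, double-point crossover, tournament selection of size 2,
elitism of one, at most 50 generations. Runs are fully reproducible from the
seed. An optional stall-based early stop substitutes for interactive
monitoring of the generation count.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .chemometrics import _nipals_pls1, _pls_reg_coef
from .preprocess import CvFolds, venetian_blinds

logger = logging.getLogger(__name__)


@dataclass
class GaConfig:
    population_size: int = 64
    window_width: int = 1
    mutation_rate: float = 0.005
    max_generations: int = 50
    init_inclusion_prob: float = 0.3
    n_lv: int = 2
    cv_folds: int = 10
    seed: int = 0
    stall_generations: int | None = None  # early stop when best fitness stalls

    def __post_init__(self):
        if self.population_size < 2 or self.population_size % 2 != 0:
            raise ValueError("population_size must be an even integer >= 2")
        if not (0.0 < self.mutation_rate < 1.0):
            raise ValueError("mutation_rate must lie in (0, 1)")
        if self.window_width < 1:
            raise ValueError("window_width must be >= 1")
        if not (1 <= self.max_generations <= 500):
            raise ValueError("max_generations must lie in [1, 500]")
        if not (0.0 < self.init_inclusion_prob <= 1.0):
            raise ValueError("init_inclusion_prob must lie in (0, 1]")

    def to_dict(self) -> dict:
        return {
            "population_size": self.population_size,
            "window_width": self.window_width,
            "mutation_rate": self.mutation_rate,
            "max_generations": self.max_generations,
            "init_inclusion_prob": self.init_inclusion_prob,
            "n_lv": self.n_lv,
            "cv_folds": self.cv_folds,
            "seed": self.seed,
            "stall_generations": self.stall_generations,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GaConfig":
        return cls(**d)


@dataclass
class GaResult:
    best_mask: np.ndarray
    best_fitness: float
    fitness_history: list[tuple[float, float]]  # per generation: (best, mean)
    generations_run: int

    def history_frame(self):
        import pandas as pd

        return pd.DataFrame(self.fitness_history, columns=["best", "mean"]).rename_axis(
            "generation"
        )


def window_expand(genes: np.ndarray, window_width: int,
                  n_variables: int | None = None) -> np.ndarray:
    """Expand a gene vector to a variable mask; each gene controls a
    contiguous block of ``window_width`` variables (last block may be
    truncated). Width 1 is the identity mapping."""
    genes = np.asarray(genes, dtype=bool)
    if window_width < 1:
        raise ValueError("window_width must be >= 1")
    full = np.repeat(genes, window_width)
    if n_variables is not None:
        if n_variables > len(full):
            raise ValueError("n_variables exceeds expanded mask length")
        full = full[:n_variables]
    return full


def ga_fitness(mask: np.ndarray, X: np.ndarray, y: np.ndarray, n_lv: int,
               folds: CvFolds) -> float:
    """RMSECV of the PLS-DA score restricted to the masked columns.

    Scaling and the PLS model are refit inside every fold on the selected
    columns, so the fitness reflects honest held-out prediction error.
    An empty mask is +infinity (never selected).
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() == 0:
        return math.inf
    Xm = X[:, mask]
    y = np.asarray(y, dtype=float)
    sse = 0.0
    n_tot = 0
    for tr, te in folds.iter_folds():
        Xtr = Xm[tr]
        mu = Xtr.mean(axis=0)
        sd = Xtr.std(axis=0, ddof=1)
        keep = sd >= 1e-12
        if not keep.any():
            return math.inf
        Ztr = (Xtr[:, keep] - mu[keep]) / sd[keep]
        Zte = (Xm[te][:, keep] - mu[keep]) / sd[keep]
        ytr = y[tr]
        ym = ytr.mean()
        a = min(n_lv, Ztr.shape[0] - 1, Ztr.shape[1])
        if a < 1:
            return math.inf
        W, P, q, _, _ = _nipals_pls1(Ztr, ytr - ym, a)
        b = _pls_reg_coef(W, P, q)
        pred = Zte @ b + ym
        sse += float(((pred - y[te]) ** 2).sum())
        n_tot += len(te)
    return math.sqrt(sse / n_tot)


def _double_point_crossover(a: np.ndarray, b: np.ndarray, rng) -> tuple[np.ndarray, np.ndarray]:
    g = len(a)
    i, j = sorted(rng.integers(0, g + 1, size=2).tolist())
    c1, c2 = a.copy(), b.copy()
    c1[i:j], c2[i:j] = b[i:j], a[i:j]
    return c1, c2


def run_ga(X: np.ndarray, y: np.ndarray, cfg: GaConfig,
           folds: CvFolds | None = None) -> GaResult:
    """Evolve a variable-inclusion mask minimizing PLS-DA RMSECV.

    X must be autoscaled training data. Deterministic given (X, y, cfg,
    folds): the random stream is consumed in a fixed order regardless of
    fitness values.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if folds is None:
        folds = venetian_blinds(n, min(cfg.cv_folds, n))
    rng = np.random.default_rng(cfg.seed)
    n_genes = math.ceil(p / cfg.window_width)

    pop = rng.random((cfg.population_size, n_genes)) < cfg.init_inclusion_prob
    # an all-false individual would be unselectable; give it one random gene
    for i in range(cfg.population_size):
        if not pop[i].any():
            pop[i, rng.integers(0, n_genes)] = True

    cache: dict[bytes, float] = {}

    def fitness_of(genes: np.ndarray) -> float:
        key = np.packbits(genes).tobytes()
        if key not in cache:
            cache[key] = ga_fitness(
                window_expand(genes, cfg.window_width, p), X, y, cfg.n_lv, folds
            )
        return cache[key]

    history: list[tuple[float, float]] = []
    best_genes = None
    best_fit = math.inf
    stall = 0
    gens_run = 0
    for gen in range(cfg.max_generations):
        fits = np.array([fitness_of(ind) for ind in pop])
        order = np.argsort(fits, kind="stable")
        gen_best = float(fits[order[0]])
        finite = fits[np.isfinite(fits)]
        history.append((gen_best, float(finite.mean()) if finite.size else math.inf))
        if gen_best < best_fit - 1e-12:
            best_fit = gen_best
            best_genes = pop[order[0]].copy()
            stall = 0
        else:
            stall += 1
            if best_genes is None:
                best_genes = pop[order[0]].copy()
                best_fit = gen_best
        gens_run = gen + 1
        if cfg.stall_generations is not None and stall >= cfg.stall_generations:
            logger.info("GA stopped at generation %d (stalled %d)", gens_run, stall)
            break
        if gen == cfg.max_generations - 1:
            break
        # next generation: elite + tournament-selected double-point offspring
        new_pop = [best_genes.copy()]
        while len(new_pop) < cfg.population_size:
            idx = rng.integers(0, cfg.population_size, size=4)
            pa = pop[idx[0]] if fits[idx[0]] <= fits[idx[1]] else pop[idx[1]]
            pb = pop[idx[2]] if fits[idx[2]] <= fits[idx[3]] else pop[idx[3]]
            c1, c2 = _double_point_crossover(pa, pb, rng)
            new_pop.append(c1)
            if len(new_pop) < cfg.population_size:
                new_pop.append(c2)
        pop = np.array(new_pop)
        flips = rng.random(pop.shape) < cfg.mutation_rate
        flips[0] = False  # elite passes unchanged
        pop ^= flips
        for i in range(cfg.population_size):
            if not pop[i].any():
                pop[i, rng.integers(0, n_genes)] = True

    best_mask = window_expand(best_genes, cfg.window_width, p)
    return GaResult(
        best_mask=best_mask,
        best_fitness=best_fit,
        fitness_history=history,
        generations_run=gens_run,
    )
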