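"""Genetic-algorithm descriptor selection around PLS (GA-PLS).

A fixed-length chromosome holds the indices of the selected descriptors
(five, by default); fitness is the training R^2 of a three-latent-variable
PLS fit on those descriptors.  Evolution uses tournament selection,
subset-preserving crossover (the child keeps the genes the parents share
and fills the rest from their symmetric difference), per-gene mutation
(rate 0.1 in a population of 500) with duplicate repair, and
single-individual elitism, stopping after a fixed number of generations
or when the best fitness stalls.  Several independent restarts are run
and the best individual of each is refined by steepest-ascent
single-descriptor exchange before the winner is refit and validated —
the usual memetic guard against premature convergence in descriptor
selection.

The split rule keeps the compounds with the smallest and largest endpoint
value in the training set (18 training / 9 test compounds by default for
a 27-compound series), so the model never extrapolates in y during
external validation.  Two post-hoc robustness checks are provided:
y-randomization (refit on permuted responses; a real model must beat the
permuted ones) and the leverage applicability domain used in Williams
plots (critical leverage h* = 3(p+1)/n_train, residual band +-3 sigma).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pls import (PLSModel, ValidationStats, pls_fit, pls_predict, q2_loo,
                  validation_stats)

__all__ = [
    "GAConfig",
    "split_minmax",
    "GAPLS",
    "GAPLSResults",
    "ga_select",
    "YRandomizationResult",
    "y_randomization",
    "ADResult",
    "leverage_ad",
]


@dataclass
class GAConfig:
    """GA hyperparameters.  Defaults follow the study settings
    (population 500, mutation rate 0.1, 5 descriptors, 3 LVs)."""

    population_size: int = 500
    mutation_rate: float = 0.1
    n_descriptors: int = 5
    n_lv: int = 3
    n_generations: int = 100
    elitism: int = 1
    tournament_size: int = 2
    stall_generations: int = 20
    n_restarts: int = 3
    local_refinement: bool = True
    fitness: str = "r2"          # "r2" (training R^2) or "q2" (LOO Q^2)
    seed: int | None = None

    def __post_init__(self):
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if not 0 <= self.mutation_rate <= 1:
            raise ValueError("mutation_rate must be in [0, 1]")
        if self.n_descriptors < self.n_lv:
            raise ValueError("n_descriptors must be >= n_lv")
        if self.fitness not in ("r2", "q2"):
            raise ValueError("fitness must be 'r2' or 'q2'")


def split_minmax(y, n_train: int, n_test: int, seed=None):
    """Random train/test split that forces the endpoint's extremes into
    the training set.

    The argmin and argmax compounds of ``y`` are swapped into the training
    set (against randomly chosen training members) whenever the random
    partition places them in the test set.  Deterministic for a fixed
    seed.  Returns positional index arrays ``(train_idx, test_idx)``.
    """
    ya = np.asarray(y, dtype=float).ravel()
    n = ya.size
    if n_train + n_test != n:
        raise ValueError("n_train + n_test must equal len(y)")
    if n_train < 2:
        raise ValueError("n_train must be >= 2")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    train = list(perm[:n_train])
    test = list(perm[n_train:])
    for extreme in (int(np.argmin(ya)), int(np.argmax(ya))):
        if extreme in test:
            swap_pos = int(rng.integers(n_train))
            while train[swap_pos] in (int(np.argmin(ya)), int(np.argmax(ya))):
                swap_pos = int(rng.integers(n_train))
            test[test.index(extreme)] = train[swap_pos]
            train[swap_pos] = extreme
    return np.array(sorted(train)), np.array(sorted(test))


class GAPLS:
    """GA-PLS model: descriptor selection plus a validated PLS fit.

    Parameters
    ----------
    X:
        Descriptor DataFrame (compounds x descriptors), already cleaned
        of constant/near-constant columns.
    y:
        Endpoint values aligned with ``X`` rows.
    config:
        :class:`GAConfig`; defaults follow the study settings.
    split:
        Optional ``(train_idx, test_idx)`` positional arrays; by default
        a seeded :func:`split_minmax` with an 18/9-proportioned split.
    """

    def __init__(self, X: pd.DataFrame, y, config: GAConfig | None = None,
                 split=None):
        self.X = X if isinstance(X, pd.DataFrame) else pd.DataFrame(X)
        self.y = np.asarray(y, dtype=float).ravel()
        self.config = config or GAConfig()
        if np.ptp(self.y) == 0:
            raise ValueError("endpoint has zero variance")
        if self.X.shape[1] < self.config.n_descriptors:
            raise ValueError(
                f"need at least {self.config.n_descriptors} usable descriptors"
            )
        if split is None:
            n = len(self.y)
            n_train = int(round(n * 2 / 3))
            split = split_minmax(self.y, n_train, n - n_train, self.config.seed)
        self.train_idx, self.test_idx = (np.asarray(split[0]), np.asarray(split[1]))

    # -- GA internals -------------------------------------------------

    def _fitness_fn(self, Xtr: np.ndarray, ytr: np.ndarray):
        cfg = self.config
        tss = float(((ytr - ytr.mean()) ** 2).sum())
        cache: dict[tuple, float] = {}

        def fitness(genes: tuple) -> float:
            val = cache.get(genes)
            if val is not None:
                return val
            sub = Xtr[:, list(genes)]
            try:
                if cfg.fitness == "r2":
                    m = pls_fit(sub, ytr, cfg.n_lv)
                    resid = ytr - pls_predict(m, sub)
                    val = 1.0 - float((resid**2).sum()) / tss
                else:
                    val, _ = q2_loo(sub, ytr, cfg.n_lv)
            except ValueError:
                val = -np.inf   # degenerate subset (collinear/zero-variance)
            cache[genes] = val
            return val

        return fitness

    @staticmethod
    def _repair(genes: list[int], pool_size: int, rng) -> tuple:
        seen = set()
        out = []
        for g in genes:
            if g not in seen:
                seen.add(g)
                out.append(g)
        while len(out) < len(genes):
            g = int(rng.integers(pool_size))
            if g not in seen:
                seen.add(g)
                out.append(g)
        return tuple(sorted(out))

    def _evolve(self, fitness, rng) -> tuple[tuple, float, list[float]]:
        """One GA run: returns its best chromosome, score and trajectory."""
        cfg = self.config
        pool = self.X.shape[1]
        k = cfg.n_descriptors
        population = [tuple(sorted(rng.choice(pool, size=k, replace=False)))
                      for _ in range(cfg.population_size)]
        scores = np.array([fitness(c) for c in population])
        best_idx = int(scores.argmax())
        best, best_score = population[best_idx], float(scores[best_idx])
        trajectory = [best_score]
        stall = 0
        for _ in range(cfg.n_generations):
            order = np.argsort(scores)[::-1]
            children = [population[i] for i in order[: cfg.elitism]]
            while len(children) < cfg.population_size:
                parents = []
                for _ in range(2):
                    contenders = rng.integers(cfg.population_size,
                                              size=cfg.tournament_size)
                    win = max(contenders, key=lambda i: scores[i])
                    parents.append(population[win])
                shared = set(parents[0]) & set(parents[1])
                rest = list((set(parents[0]) | set(parents[1])) - shared)
                child = list(shared) + list(
                    rng.choice(rest, size=k - len(shared), replace=False))
                mut = rng.random(k) < cfg.mutation_rate
                for j in np.flatnonzero(mut):
                    child[j] = int(rng.integers(pool))
                children.append(self._repair(child, pool, rng))
            population = children
            scores = np.array([fitness(c) for c in population])
            gen_best = int(scores.argmax())
            if scores[gen_best] > best_score:
                best, best_score = population[gen_best], float(scores[gen_best])
                stall = 0
            else:
                stall += 1
            trajectory.append(best_score)
            if stall >= cfg.stall_generations:
                break
        return best, best_score, trajectory

    def _local_refine(self, genes: tuple, score: float,
                      fitness) -> tuple[tuple, float]:
        """Steepest-ascent single-descriptor exchange until no swap helps."""
        pool = self.X.shape[1]
        current = set(genes)
        improved = True
        while improved:
            improved = False
            for out_gene in list(current):
                for cand in range(pool):
                    if cand in current:
                        continue
                    trial = tuple(sorted((current - {out_gene}) | {cand}))
                    trial_score = fitness(trial)
                    if trial_score > score:
                        genes, score = trial, trial_score
                        current = set(genes)
                        improved = True
                        break
                if improved:
                    break
        return genes, score

    def fit(self) -> "GAPLSResults":
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        pool = self.X.shape[1]
        k = cfg.n_descriptors
        Xtr = self.X.iloc[self.train_idx].to_numpy(dtype=float)
        ytr = self.y[self.train_idx]
        fitness = self._fitness_fn(Xtr, ytr)

        if pool == k:
            genes = tuple(range(k))
            return self._finalize(genes, [fitness(genes)])

        best, best_score = None, -np.inf
        trajectory: list[float] = []
        for _ in range(max(1, cfg.n_restarts)):
            genes, score, run_traj = self._evolve(fitness, rng)
            if cfg.local_refinement:
                genes, score = self._local_refine(genes, score, fitness)
            # trajectory records the running best across restarts
            for v in run_traj:
                trajectory.append(max(best_score, v,
                                      trajectory[-1] if trajectory else -np.inf))
            if score > best_score:
                best, best_score = genes, score
            trajectory[-1] = max(trajectory[-1], best_score)
        return self._finalize(best, trajectory)

    def _finalize(self, genes: tuple, trajectory: list[float]) -> "GAPLSResults":
        cfg = self.config
        names = [str(self.X.columns[g]) for g in genes]
        X_sel = self.X.iloc[:, list(genes)]
        Xtr = X_sel.iloc[self.train_idx]
        Xte = X_sel.iloc[self.test_idx]
        ytr = self.y[self.train_idx]
        yte = self.y[self.test_idx]
        model = pls_fit(Xtr, ytr, cfg.n_lv)
        pred_tr = pls_predict(model, Xtr)
        pred_te = pls_predict(model, Xte)
        stats = validation_stats(ytr, pred_tr, yte, pred_te)
        stats.q2_loo, stats.rmse_cv = q2_loo(Xtr, ytr, cfg.n_lv)
        ad = leverage_ad(model, Xtr, Xte, np.concatenate([ytr, yte]),
                         np.concatenate([pred_tr, pred_te]))
        return GAPLSResults(self, tuple(names), genes, model, stats, ad,
                            np.asarray(trajectory),
                            (list(self.train_idx), list(self.test_idx)))


@dataclass
class GAPLSResults:
    """Selected descriptors, the refit PLS model, and its validation."""

    model_spec: GAPLS
    selected: tuple[str, ...]
    selected_idx: tuple[int, ...]
    model: PLSModel
    stats: ValidationStats
    ad: "ADResult"
    fitness_trajectory: np.ndarray
    split: tuple[list, list]

    def y_randomization(self, n_permutations: int = 200, seed=None,
                        compute_q2: bool = True) -> "YRandomizationResult":
        spec = self.model_spec
        Xtr = spec.X.iloc[spec.train_idx, list(self.selected_idx)]
        ytr = spec.y[spec.train_idx]
        return y_randomization(Xtr, ytr, spec.config.n_lv,
                               n_permutations=n_permutations, seed=seed,
                               compute_q2=compute_q2)

    def summary(self) -> str:
        lines = [
            f"GA-PLS: {len(self.selected)} descriptors, "
            f"{self.model.n_components} LVs, "
            f"train/test = {len(self.split[0])}/{len(self.split[1])}",
            f"  selected: {', '.join(self.selected)}",
            "  " + self.stats.summary(),
            f"  generations run: {len(self.fitness_trajectory) - 1}, "
            f"best fitness: {self.fitness_trajectory[-1]:.4f}",
            f"  AD: h* = {self.ad.h_star:.4f}, "
            f"{int(self.ad.outside_h_star.sum())} compound(s) beyond h*, "
            f"{int(self.ad.outside_3sigma.sum())} beyond +-3 sigma",
        ]
        return "\n".join(lines)


def ga_select(X, y, config: GAConfig | None = None, split=None) -> GAPLSResults:
    """Convenience wrapper: ``GAPLS(X, y, config, split).fit()``."""
    return GAPLS(X, y, config=config, split=split).fit()


@dataclass
class YRandomizationResult:
    """Permuted-response refits versus the original model."""

    r2_original: float
    q2_original: float | None
    r2_permuted: np.ndarray
    q2_permuted: np.ndarray | None
    n_permutations: int

    @property
    def r2_exceedance(self) -> float:
        """Fraction of permuted models with R^2 >= the original."""
        return float(np.mean(self.r2_permuted >= self.r2_original))

    @property
    def q2_exceedance(self) -> float | None:
        if self.q2_permuted is None:
            return None
        return float(np.mean(self.q2_permuted >= self.q2_original))


def y_randomization(X_selected, y, n_lv: int, n_permutations: int = 200,
                    seed=None, compute_q2: bool = True) -> YRandomizationResult:
    """Refit on permuted responses to rule out chance correlation.

    The descriptor subset is held fixed; for each permutation the
    endpoint is shuffled, the PLS model refit, and R^2 (and optionally
    leave-one-out Q^2) recorded.  A robust original model should exceed
    essentially the whole permuted distribution.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    Xa = X_selected.to_numpy(dtype=float) if isinstance(X_selected, pd.DataFrame) \
        else np.asarray(X_selected, dtype=float)
    ya = np.asarray(y, dtype=float).ravel()
    if np.ptp(ya) == 0:
        raise ValueError("endpoint has zero variance")
    rng = np.random.default_rng(seed)
    tss = float(((ya - ya.mean()) ** 2).sum())

    def r2_of(yv):
        m = pls_fit(Xa, yv, n_lv)
        resid = yv - pls_predict(m, Xa)
        return 1.0 - float((resid**2).sum()) / float(((yv - yv.mean()) ** 2).sum())

    r2_orig = r2_of(ya)
    q2_orig = q2_loo(Xa, ya, n_lv)[0] if compute_q2 else None
    r2s = np.empty(n_permutations)
    q2s = np.empty(n_permutations) if compute_q2 else None
    for i in range(n_permutations):
        yp = rng.permutation(ya)
        r2s[i] = r2_of(yp)
        if compute_q2:
            q2s[i] = q2_loo(Xa, yp, n_lv)[0]
    return YRandomizationResult(r2_orig, q2_orig, r2s, q2s, n_permutations)


@dataclass
class ADResult:
    """Leverage applicability domain (Williams plot data)."""

    leverage: np.ndarray
    h_star: float
    std_residual: np.ndarray
    outside_h_star: np.ndarray
    outside_3sigma: np.ndarray
    is_train: np.ndarray

    def frame(self, ids=None) -> pd.DataFrame:
        idx = ids if ids is not None else np.arange(self.leverage.size)
        return pd.DataFrame(
            {
                "leverage": self.leverage,
                "std_residual": self.std_residual,
                "train": self.is_train,
                "outside_h_star": self.outside_h_star,
                "outside_3sigma": self.outside_3sigma,
            },
            index=idx,
        )


def leverage_ad(model: PLSModel, X_train, X_test, y_obs, y_pred) -> ADResult:
    """Leverages and standardized residuals for the Williams plot.

    Leverage is the hat-matrix diagonal h_i = z_i (Z'Z)^-1 z_i' on the
    autoscaled selected descriptors augmented with an intercept column
    (training leverages then sum to p+1).  The critical value is the
    conventional h* = 3(p+1)/n_train.  Residuals are standardized by the
    SD of the training residuals; the acceptance band is +-3 units.
    """
    def scale(X):
        arr = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) \
            else np.asarray(X, dtype=float)
        return (arr - model.x_mean) / model.x_std

    Ztr = np.column_stack([np.ones(len(scale(X_train))), scale(X_train)])
    Zte = np.column_stack([np.ones(len(scale(X_test))), scale(X_test)])
    gram = Ztr.T @ Ztr
    if np.linalg.matrix_rank(gram) < gram.shape[0]:
        raise ValueError("collinear selected descriptors: singular X'X")
    gram_inv = np.linalg.inv(gram)
    lev = np.concatenate([
        np.einsum("ij,jk,ik->i", Ztr, gram_inv, Ztr),
        np.einsum("ij,jk,ik->i", Zte, gram_inv, Zte),
    ])
    n_train = Ztr.shape[0]
    p = len(model.feature_names)
    h_star = 3.0 * (p + 1) / n_train

    resid = np.asarray(y_obs, dtype=float) - np.asarray(y_pred, dtype=float)
    train_sd = float(resid[:n_train].std(ddof=1))
    if train_sd == 0:
        std_resid = np.zeros_like(resid)
    else:
        std_resid = resid / train_sd
    is_train = np.zeros(lev.size, dtype=bool)
    is_train[:n_train] = True
    return ADResult(lev, h_star, std_resid, lev > h_star,
                    np.abs(std_resid) > 3.0, is_train)
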