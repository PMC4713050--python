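"""Comparison models: NB, SVM, group-MKL, SVM-RFE and GA/PSO wrappers.

Every model exposes the same minimal estimator surface used by the
evaluation harness — ``fit(X, y)`` / ``decision_function(X)`` plus a
``selected_features`` attribute for the feature-selection approaches — so
all of them share fold assignments within one experiment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.svm import SVC

from .fsmkl import FSMKLClassifier

__all__ = [
    "NaiveBayesModel",
    "SVMModel",
    "SVMRFEModel",
    "WrapperConfig",
    "WrapperModel",
    "GroupMKLModel",
    "FeatureMask",
]


def _check_two_classes(y: np.ndarray) -> None:
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")


@dataclass
class FeatureMask:
    """Binary selection over feature columns with its provenance."""

    bits: np.ndarray
    method: str
    iteration: int = 0

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=bool)
        if self.bits.sum() == 0:
            raise ValueError("feature mask must select at least one feature")


class NaiveBayesModel:
    """Gaussian naive Bayes (per-class Gaussians, conditional independence)."""

    def fit(self, X: pd.DataFrame, y) -> "NaiveBayesModel":
        y = np.asarray(y)
        _check_two_classes(y)
        self.clf_ = GaussianNB().fit(X.to_numpy(dtype=float), y)
        return self

    def decision_function(self, X: pd.DataFrame) -> np.ndarray:
        # signed score: log P(y=1|x) - log P(y=0|x); threshold 0 = posterior 0.5
        lp = self.clf_.predict_log_proba(X.to_numpy(dtype=float))
        return lp[:, 1] - lp[:, 0]

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        return self.clf_.predict_proba(X.to_numpy(dtype=float))


class SVMModel:
    """Soft-margin RBF SVM with an inner-CV grid over (C, gamma) by AUROC."""

    def __init__(
        self,
        C_grid=(0.1, 1.0, 10.0, 100.0),
        gamma_grid=("scale", 0.001, 0.01, 0.1),
        inner_cv: int = 3,
        random_state: int = 0,
    ) -> None:
        self.C_grid = C_grid
        self.gamma_grid = gamma_grid
        self.inner_cv = inner_cv
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y) -> "SVMModel":
        y = np.asarray(y)
        _check_two_classes(y)
        Xa = X.to_numpy(dtype=float)
        best = (-np.inf, self.C_grid[0], self.gamma_grid[0])
        skf = StratifiedKFold(self.inner_cv, shuffle=True, random_state=self.random_state)
        for C in self.C_grid:
            for gamma in self.gamma_grid:
                scores = []
                for tr, te in skf.split(Xa, y):
                    clf = SVC(C=C, gamma=gamma, kernel="rbf").fit(Xa[tr], y[tr])
                    scores.append(roc_auc_score(y[te], clf.decision_function(Xa[te])))
                mean = float(np.mean(scores))
                if mean > best[0]:
                    best = (mean, C, gamma)
        _, self.C_, self.gamma_ = best
        self.clf_ = SVC(C=self.C_, gamma=self.gamma_, kernel="rbf").fit(Xa, y)
        return self

    def decision_function(self, X: pd.DataFrame) -> np.ndarray:
        return self.clf_.decision_function(X.to_numpy(dtype=float))


class SVMRFEModel:
    """Recursive feature elimination on squared linear-SVM weights.

    Each iteration removes ``ceil(step_fraction x remaining)`` features with
    the smallest ``w_i^2`` (one at a time once fewer than ``fine_below``
    remain); the retained depth is the one maximizing inner-CV AUROC.
    """

    def __init__(
        self,
        step_fraction: float = 0.1,
        fine_below: int = 30,
        C: float = 1.0,
        inner_cv: int = 3,
        random_state: int = 0,
    ) -> None:
        self.step_fraction = step_fraction
        self.fine_below = fine_below
        self.C = C
        self.inner_cv = inner_cv
        self.random_state = random_state

    def _elimination_order(self, X: np.ndarray, y: np.ndarray,
                           n_features: int) -> tuple[list[int], list[list[int]]]:
        remaining = list(range(n_features))
        eliminated: list[int] = []
        snapshots = [list(remaining)]
        while len(remaining) > 1:
            clf = SVC(kernel="linear", C=self.C).fit(X[:, remaining], y)
            w2 = (clf.coef_[0] ** 2)
            if len(remaining) < self.fine_below:
                n_drop = 1
            else:
                n_drop = max(1, math.ceil(self.step_fraction * len(remaining)))
            n_drop = min(n_drop, len(remaining) - 1)
            drop_local = np.argsort(w2, kind="stable")[:n_drop]
            for i in sorted(drop_local, reverse=True):
                eliminated.append(remaining.pop(i))
            snapshots.append(list(remaining))
        return eliminated, snapshots

    def fit(self, X: pd.DataFrame, y) -> "SVMRFEModel":
        y = np.asarray(y)
        _check_two_classes(y)
        Xa = X.to_numpy(dtype=float)
        eliminated, snapshots = self._elimination_order(Xa, y, Xa.shape[1])
        # full ranking: survivors first, then eliminated in reverse order
        self.ranking_ = snapshots[-1] + eliminated[::-1]
        skf = StratifiedKFold(self.inner_cv, shuffle=True, random_state=self.random_state)
        best = (-np.inf, snapshots[0])
        for subset in snapshots:
            scores = []
            for tr, te in skf.split(Xa, y):
                clf = SVC(kernel="linear", C=self.C).fit(Xa[tr][:, subset], y[tr])
                scores.append(
                    roc_auc_score(y[te], clf.decision_function(Xa[te][:, subset]))
                )
            mean = float(np.mean(scores))
            if mean > best[0]:
                best = (mean, subset)
        self.subset_ = best[1]
        self.mask_ = FeatureMask(
            np.isin(np.arange(Xa.shape[1]), self.subset_), method="svm-rfe"
        )
        self.selected_features = [X.columns[i] for i in self.subset_]
        self.clf_ = SVC(kernel="linear", C=self.C).fit(Xa[:, self.subset_], y)
        self._columns = list(X.columns)
        return self

    def decision_function(self, X: pd.DataFrame) -> np.ndarray:
        Xa = X[self._columns].to_numpy(dtype=float)
        return self.clf_.decision_function(Xa[:, self.subset_])


@dataclass
class WrapperConfig:
    """Search-budget and operator parameters for the GA / PSO wrappers."""

    population: int = 50
    iterations: int = 100
    crossover_rate: float = 0.8       # GA uniform crossover
    mutation_rate: float | None = None  # default 1/p bit-flip
    elitism: int = 1
    inertia: float = 0.9              # PSO velocity terms
    c1: float = 2.0
    c2: float = 2.0
    v_max: float = 4.0
    inner_cv: int = 3
    svm_C: float = 1.0


class WrapperModel:
    """GA or binary-PSO feature-subset search with an SVM fitness function.

    Fitness of a mask is the inner-CV AUROC of an RBF SVM restricted to the
    selected columns; evaluations are memoized per mask. Seed-reproducible;
    the best-so-far fitness trace is non-decreasing (elitism).
    """

    def __init__(self, engine: str = "GA", config: WrapperConfig | None = None,
                 random_state: int = 0) -> None:
        if engine not in ("GA", "PSO"):
            raise ValueError("engine must be 'GA' or 'PSO'")
        self.engine = engine
        self.config = config or WrapperConfig()
        self.random_state = random_state

    # fitness -----------------------------------------------------------

    def _fitness(self, mask: np.ndarray) -> float:
        key = mask.tobytes()
        if key in self._cache:
            return self._cache[key]
        cols = np.flatnonzero(mask)
        skf = StratifiedKFold(
            self.config.inner_cv, shuffle=True, random_state=self.random_state
        )
        scores = []
        for tr, te in skf.split(self._X, self._y):
            clf = SVC(C=self.config.svm_C, kernel="rbf").fit(
                self._X[tr][:, cols], self._y[tr]
            )
            scores.append(
                roc_auc_score(self._y[te], clf.decision_function(self._X[te][:, cols]))
            )
        value = float(np.mean(scores))
        self._cache[key] = value
        return value

    def _repair(self, mask: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if not mask.any():
            mask = mask.copy()
            mask[rng.integers(len(mask))] = True
        return mask

    # engines -----------------------------------------------------------

    def _run_ga(self, p: int, rng: np.random.Generator):
        cfg = self.config
        mut = cfg.mutation_rate if cfg.mutation_rate is not None else 1.0 / p
        pop = [self._repair(rng.random(p) < 0.5, rng) for _ in range(cfg.population)]
        fits = np.array([self._fitness(m) for m in pop])
        trace = [float(fits.max())]
        best_mask = pop[int(np.argmax(fits))].copy()
        best_fit = float(fits.max())
        for _gen in range(cfg.iterations):
            new_pop = [best_mask.copy() for _ in range(cfg.elitism)]
            while len(new_pop) < cfg.population:
                # binary tournament selection
                a, b = rng.integers(cfg.population, size=2)
                p1 = pop[a] if fits[a] >= fits[b] else pop[b]
                a, b = rng.integers(cfg.population, size=2)
                p2 = pop[a] if fits[a] >= fits[b] else pop[b]
                if rng.random() < cfg.crossover_rate:
                    take = rng.random(p) < 0.5
                    child = np.where(take, p1, p2)
                else:
                    child = p1.copy()
                flip = rng.random(p) < mut
                child = np.logical_xor(child, flip)
                new_pop.append(self._repair(child, rng))
            pop = new_pop
            fits = np.array([self._fitness(m) for m in pop])
            gen_best = int(np.argmax(fits))
            if fits[gen_best] > best_fit:
                best_fit = float(fits[gen_best])
                best_mask = pop[gen_best].copy()
            trace.append(best_fit)
        return best_mask, trace

    def _run_pso(self, p: int, rng: np.random.Generator):
        cfg = self.config
        pos = [self._repair(rng.random(p) < 0.5, rng) for _ in range(cfg.population)]
        vel = rng.uniform(-1, 1, size=(cfg.population, p))
        fits = np.array([self._fitness(m) for m in pos])
        pbest = [m.copy() for m in pos]
        pbest_fit = fits.copy()
        g = int(np.argmax(fits))
        gbest, gbest_fit = pos[g].copy(), float(fits[g])
        trace = [gbest_fit]
        for _it in range(cfg.iterations):
            for i in range(cfg.population):
                r1 = rng.random(p)
                r2 = rng.random(p)
                vel[i] = (
                    cfg.inertia * vel[i]
                    + cfg.c1 * r1 * (pbest[i].astype(float) - pos[i].astype(float))
                    + cfg.c2 * r2 * (gbest.astype(float) - pos[i].astype(float))
                )
                vel[i] = np.clip(vel[i], -cfg.v_max, cfg.v_max)
                prob = 1.0 / (1.0 + np.exp(-vel[i]))  # sigmoid thresholding
                pos[i] = self._repair(rng.random(p) < prob, rng)
                f = self._fitness(pos[i])
                if f > pbest_fit[i]:
                    pbest_fit[i] = f
                    pbest[i] = pos[i].copy()
                if f > gbest_fit:
                    gbest_fit = float(f)
                    gbest = pos[i].copy()
            trace.append(gbest_fit)
        return gbest, trace

    # estimator surface --------------------------------------------------

    def fit(self, X: pd.DataFrame, y) -> "WrapperModel":
        y = np.asarray(y)
        _check_two_classes(y)
        self._X = X.to_numpy(dtype=float)
        self._y = y
        self._cache: dict[bytes, float] = {}
        rng = np.random.default_rng(self.random_state)
        p = self._X.shape[1]
        if self.engine == "GA":
            mask, trace = self._run_ga(p, rng)
        else:
            mask, trace = self._run_pso(p, rng)
        self.mask_ = FeatureMask(mask, method=self.engine.lower())
        self.fitness_trace_ = trace
        self.selected_features = [X.columns[i] for i in np.flatnonzero(mask)]
        cols = np.flatnonzero(mask)
        self.clf_ = SVC(C=self.config.svm_C, kernel="rbf").fit(self._X[:, cols], y)
        self._columns = list(X.columns)
        self._cols = cols
        return self

    def decision_function(self, X: pd.DataFrame) -> np.ndarray:
        Xa = X[self._columns].to_numpy(dtype=float)
        return self.clf_.decision_function(Xa[:, self._cols])


class GroupMKLModel(FSMKLClassifier):
    """MKL over whole texture groups: one kernel per (group, family).

    Reuses the FSMKL trainer with the subset size fixed to the full group;
    the dominant group is the one whose kernels carry the largest total
    weight.
    """

    def __init__(self, groups: dict[str, str], C: float = 10.0, **kwargs) -> None:
        super().__init__(groups=groups, subset_sizes=("all",), C=C, **kwargs)

    @property
    def group_weights(self) -> pd.Series:
        w: dict[str, float] = {}
        for i, spec in enumerate(self.bank_.specs):
            w[spec.group] = w.get(spec.group, 0.0) + float(self.model_.weights[i])
        return pd.Series(w).sort_values(ascending=False)

    @property
    def dominant_group(self) -> str:
        return self.group_weights.index[0]
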