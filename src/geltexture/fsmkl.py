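"""Feature-selection multiple kernel learning (FSMKL).

For each texture family the features are ranked by absolute point-biserial
correlation with the class label; nested prefixes of each ranking are encoded
as kernels (polynomial of degree 1 and 2, and Gaussian kernels with low width
parameters). A sparse convex combination of the resulting kernel bank is then
learned jointly with an SVM in the SimpleMKL fashion: alternate between
solving the SVM dual on the combined Gram matrix ``K(d) = sum_m d_m K_m`` and
a reduced-gradient descent step for the weights ``d`` on the probability
simplex. Kernels with non-zero weight select both texture groups and the
features inside them, and the weights rank the kernels by importance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.svm import SVC

__all__ = [
    "KernelSpec",
    "KernelBank",
    "MKLModel",
    "ImportanceReport",
    "rank_features",
    "build_kernel_bank",
    "train",
    "predict",
    "report_importance",
    "FSMKLClassifier",
    "DEFAULT_SUBSET_SIZES",
    "DEFAULT_GAMMA_SCALES",
]

DEFAULT_SUBSET_SIZES: tuple = (1, 2, 3, 5, 8, 13, "all")
#: gaussian widths are these values divided by the kernel's subset size
DEFAULT_GAMMA_SCALES: tuple[float, ...] = (0.01, 0.1, 1.0)
WEIGHT_CLAMP = 1e-4


@dataclass(frozen=True)
class KernelSpec:
    """One kernel of the bank: a feature prefix of one group plus a family."""

    group: str
    features: tuple[str, ...]
    family: str  # polynomial-1 | polynomial-2 | gaussian
    gamma: float | None = None

    def __post_init__(self) -> None:
        if not self.features:
            raise ValueError("kernel feature subset must be non-empty")
        if self.family not in ("polynomial-1", "polynomial-2", "gaussian"):
            raise ValueError(f"unknown kernel family {self.family!r}")
        if self.family == "gaussian" and (self.gamma is None or self.gamma <= 0):
            raise ValueError("gaussian kernel needs gamma > 0")


def _raw_kernel(spec: KernelSpec, A: np.ndarray, B: np.ndarray) -> np.ndarray:
    if spec.family == "polynomial-1":
        return 1.0 + A @ B.T
    if spec.family == "polynomial-2":
        return (1.0 + A @ B.T) ** 2
    sq = (
        (A ** 2).sum(axis=1)[:, None]
        + (B ** 2).sum(axis=1)[None, :]
        - 2.0 * A @ B.T
    )
    return np.exp(-spec.gamma * np.maximum(sq, 0.0))


@dataclass
class KernelBank:
    """Kernel specs plus precomputed training Gram matrices.

    Every Gram matrix is normalized to unit mean diagonal so that the
    simplex weights of heterogeneous kernel families are commensurable; the
    normalization constants are reused for test-time cross-kernels.
    """

    specs: list[KernelSpec]
    X: pd.DataFrame
    grams: list[np.ndarray] = field(default_factory=list, repr=False)
    norms: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.grams:
            for spec in self.specs:
                A = self.X[list(spec.features)].to_numpy(dtype=np.float64)
                K = _raw_kernel(spec, A, A)
                c = float(np.trace(K) / K.shape[0])
                c = c if c > 0 else 1.0
                self.grams.append(K / c)
                self.norms.append(c)

    def __len__(self) -> int:
        return len(self.specs)

    def cross(self, X_test: pd.DataFrame) -> list[np.ndarray]:
        """Test-versus-train kernel matrices under the training normalization."""
        missing = [
            f for spec in self.specs for f in spec.features
            if f not in X_test.columns
        ]
        if missing:
            raise ValueError(f"test table lacks features {sorted(set(missing))[:5]}")
        out = []
        for spec, c in zip(self.specs, self.norms):
            A = X_test[list(spec.features)].to_numpy(dtype=np.float64)
            B = self.X[list(spec.features)].to_numpy(dtype=np.float64)
            out.append(_raw_kernel(spec, A, B) / c)
        return out


def rank_features(X: pd.DataFrame, y: np.ndarray, features: list[str]) -> pd.DataFrame:
    """Rank features by decreasing |point-biserial correlation| with the label.

    Ties (including constant features, score 0) keep their input order.
    """
    y = np.asarray(y, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("feature ranking needs both classes present")
    yc = y - y.mean()
    ynorm = float(np.sqrt((yc ** 2).sum()))
    scores = []
    for f in features:
        v = X[f].to_numpy(dtype=np.float64)
        vc = v - v.mean()
        denom = float(np.sqrt((vc ** 2).sum())) * ynorm
        scores.append(abs(float(vc @ yc) / denom) if denom > 0 else 0.0)
    order = np.argsort(-np.asarray(scores), kind="stable")
    return pd.DataFrame(
        {"feature": [features[i] for i in order],
         "score": [scores[i] for i in order]}
    )


def build_kernel_bank(
    X: pd.DataFrame,
    rankings: dict[str, list[str]],
    subset_sizes=DEFAULT_SUBSET_SIZES,
    gamma_scales=DEFAULT_GAMMA_SCALES,
    families: tuple[str, ...] = ("polynomial-1", "polynomial-2", "gaussian"),
) -> KernelBank:
    """Build the (group x prefix x family) kernel bank on standardized data.

    ``rankings`` maps group name to its ranked feature list. Subset sizes are
    capped at the group size and deduplicated; ``"all"`` means the whole
    group. Gaussian widths are ``gamma_scales / subset_size``.
    """
    if len(X) == 0:
        raise ValueError("empty table")
    specs: list[KernelSpec] = []
    for group, ranked in rankings.items():
        sizes = sorted(
            {len(ranked) if s == "all" else min(int(s), len(ranked))
             for s in subset_sizes}
        )
        for size in sizes:
            prefix = tuple(ranked[:size])
            for family in families:
                if family == "gaussian":
                    for scale in gamma_scales:
                        specs.append(
                            KernelSpec(group, prefix, family, gamma=scale / size)
                        )
                else:
                    specs.append(KernelSpec(group, prefix, family))
    return KernelBank(specs=specs, X=X.copy())


@dataclass
class MKLModel:
    """A trained sparse MKL model on a kernel bank."""

    weights: np.ndarray
    dual_coef: np.ndarray  # signed alpha_i * y_i over all training points
    intercept: float
    C: float
    objective_trace: list[float]
    converged: bool
    n_support: int

    @property
    def active_kernels(self) -> np.ndarray:
        return np.flatnonzero(self.weights > 0)


def _fit_svm(K: np.ndarray, y: np.ndarray, C: float,
             svm_tol: float = 1e-3) -> tuple[np.ndarray, float, float]:
    """SVM dual on a precomputed kernel; returns (beta, b, objective J).

    ``beta`` is the signed dual vector over all training points and
    ``J = sum alpha - 0.5 beta' K beta`` is the dual objective, the quantity
    SimpleMKL minimizes over the kernel weights.
    """
    clf = SVC(C=C, kernel="precomputed", tol=svm_tol)
    clf.fit(K, y)
    n = len(y)
    beta = np.zeros(n)
    beta[clf.support_] = clf.dual_coef_[0]
    J = float(np.abs(beta).sum() - 0.5 * beta @ K @ beta)
    return beta, float(clf.intercept_[0]), J


def train(
    bank: KernelBank,
    y: np.ndarray,
    C: float = 10.0,
    tol: float = 1e-3,
    max_iter: int = 60,
    svm_tol: float = 1e-3,
) -> MKLModel:
    """SimpleMKL alternating optimization on the probability simplex.

    Each outer iteration solves the SVM dual on ``K(d)`` and performs one
    reduced-gradient descent step with a backtracking line search; stops when
    the largest weight change falls below ``tol``. Weights below 1e-4 are
    clamped to zero and the rest renormalized before the final SVM refit.
    """
    if len(bank) == 0:
        raise ValueError("empty kernel bank")
    if C <= 0:
        raise ValueError("C must be > 0")
    y = np.asarray(y)
    M = len(bank)
    grams = np.stack(bank.grams)
    d = np.full(M, 1.0 / M)
    trace: list[float] = []
    converged = False

    def combined(dv: np.ndarray) -> np.ndarray:
        return np.tensordot(dv, grams, axes=1)

    beta, b, J = _fit_svm(combined(d), y, C, svm_tol)
    trace.append(J)
    for _ in range(max_iter):
        grad = -0.5 * np.einsum("i,mij,j->m", beta, grams, beta)
        mu = int(np.argmax(d))
        red = grad - grad[mu]
        D = np.where((d > 0) | (red < 0), -red, 0.0)
        D[mu] = -(D.sum() - D[mu])
        if np.abs(D).max() < 1e-12:
            converged = True
            break
        # maximal admissible step before a weight hits zero
        neg = D < 0
        gamma_max = np.min(-d[neg] / D[neg]) if neg.any() else 1.0
        gamma_max = min(gamma_max, 1.0)
        accepted = False
        gamma = gamma_max
        for _ls in range(8):
            d_new = np.clip(d + gamma * D, 0.0, None)
            d_new /= d_new.sum()
            beta_new, b_new, J_new = _fit_svm(combined(d_new), y, C, svm_tol)
            if J_new <= J:
                accepted = True
                break
            gamma *= 0.5
        if not accepted:
            converged = True
            break
        delta = np.abs(d_new - d).max()
        d, beta, b, J = d_new, beta_new, b_new, J_new
        trace.append(J)
        if delta < tol:
            converged = True
            break

    d = np.where(d < WEIGHT_CLAMP, 0.0, d)
    if d.sum() == 0:
        d = np.full(M, 1.0 / M)
    d /= d.sum()
    beta, b, J = _fit_svm(combined(d), y, C, svm_tol)
    trace.append(J)
    return MKLModel(
        weights=d, dual_coef=beta, intercept=b, C=C,
        objective_trace=trace, converged=converged,
        n_support=int(np.count_nonzero(beta)),
    )


def predict(model: MKLModel, cross_grams: list[np.ndarray]) -> np.ndarray:
    """Decision values for test rows given test-vs-train kernel matrices."""
    if len(cross_grams) != len(model.weights):
        raise ValueError("kernel bank mismatch between train and test")
    K = np.tensordot(model.weights, np.stack(cross_grams), axes=1)
    return K @ model.dual_coef + model.intercept


@dataclass
class ImportanceReport:
    kernels: pd.DataFrame       # rank, group, subset, family, weight, cumulative
    features_raw: pd.Series     # sum of kernel weights over kernels with feature
    features_normalized: pd.Series
    selected_features: list[str]


def report_importance(model: MKLModel, bank: KernelBank) -> ImportanceReport:
    """Kernel importances (sorted, with cumulative share) and feature rollups.

    Per-feature importance aggregates kernel weights over the kernels that
    contain the feature; both the raw aggregate and the simplex-normalized
    version (divided by the total over features) are reported. Selected
    features are the union over non-zero-weight kernels.
    """
    order = np.argsort(-model.weights, kind="stable")
    weights = model.weights[order]
    rows = []
    for rank, (i, w) in enumerate(zip(order, weights), start=1):
        spec = bank.specs[i]
        rows.append(
            {
                "rank": rank,
                "group": spec.group,
                "subset": ";".join(spec.features),
                "subset_size": len(spec.features),
                "family": spec.family,
                "gamma": spec.gamma,
                "weight": float(w),
                "cumulative": float(weights[:rank].sum()),
            }
        )
    kernels = pd.DataFrame(rows)
    raw: dict[str, float] = {}
    for i in np.flatnonzero(model.weights):
        for f in bank.specs[i].features:
            raw[f] = raw.get(f, 0.0) + float(model.weights[i])
    features_raw = pd.Series(raw, dtype=float).sort_values(ascending=False)
    total = features_raw.sum()
    features_norm = features_raw / total if total > 0 else features_raw
    return ImportanceReport(
        kernels=kernels,
        features_raw=features_raw,
        features_normalized=features_norm,
        selected_features=list(features_raw.index),
    )


class FSMKLClassifier:
    """Estimator-style wrapper: ranking, bank construction, training, scoring.

    Parameters
    ----------
    groups : mapping feature name -> texture group. Features absent from the
        mapping are ignored.
    subset_sizes, gamma_scales, families : bank construction knobs.
    C : SVM regularization; ``"grid"`` selects from {0.1, 1, 10, 100} by
        inner 5-fold AUROC (expensive: one full MKL training per candidate
        per inner fold).
    """

    C_GRID = (0.1, 1.0, 10.0, 100.0)

    def __init__(
        self,
        groups: dict[str, str],
        subset_sizes=DEFAULT_SUBSET_SIZES,
        gamma_scales=DEFAULT_GAMMA_SCALES,
        families: tuple[str, ...] = ("polynomial-1", "polynomial-2", "gaussian"),
        C: float | str = 10.0,
        tol: float = 1e-3,
        max_iter: int = 60,
        inner_cv: int = 5,
        random_state: int = 0,
    ) -> None:
        self.groups = groups
        self.subset_sizes = subset_sizes
        self.gamma_scales = gamma_scales
        self.families = families
        self.C = C
        self.tol = tol
        self.max_iter = max_iter
        self.inner_cv = inner_cv
        self.random_state = random_state

    # -- internals -----------------------------------------------------

    def _rankings(self, X: pd.DataFrame, y: np.ndarray) -> dict[str, list[str]]:
        by_group: dict[str, list[str]] = {}
        for f in X.columns:
            g = self.groups.get(f)
            if g is not None:
                by_group.setdefault(g, []).append(f)
        return {
            g: list(rank_features(X, y, feats)["feature"])
            for g, feats in by_group.items()
        }

    def _bank(self, X: pd.DataFrame, y: np.ndarray) -> KernelBank:
        return build_kernel_bank(
            X, self._rankings(X, y), self.subset_sizes,
            self.gamma_scales, self.families,
        )

    def _select_C(self, X: pd.DataFrame, y: np.ndarray) -> float:
        from sklearn.metrics import roc_auc_score
        from sklearn.model_selection import StratifiedKFold

        skf = StratifiedKFold(
            n_splits=self.inner_cv, shuffle=True, random_state=self.random_state
        )
        best_C, best_score = self.C_GRID[0], -np.inf
        for C in self.C_GRID:
            scores = []
            for tr, te in skf.split(X, y):
                bank = self._bank(X.iloc[tr], y[tr])
                model = train(bank, y[tr], C=C, tol=self.tol, max_iter=self.max_iter)
                s = predict(model, bank.cross(X.iloc[te]))
                scores.append(roc_auc_score(y[te], s))
            mean = float(np.mean(scores))
            if mean > best_score:
                best_C, best_score = C, mean
        return best_C

    # -- estimator surface ---------------------------------------------

    def fit(self, X: pd.DataFrame, y) -> "FSMKLClassifier":
        y = np.asarray(y)
        C = self._select_C(X, y) if self.C == "grid" else float(self.C)
        self.bank_ = self._bank(X, y)
        self.model_ = train(self.bank_, y, C=C, tol=self.tol, max_iter=self.max_iter)
        self.C_ = C
        self.importance_ = report_importance(self.model_, self.bank_)
        self.selected_features = self.importance_.selected_features
        return self

    def decision_function(self, X: pd.DataFrame) -> np.ndarray:
        return predict(self.model_, self.bank_.cross(X))

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return (self.decision_function(X) > 0).astype(int)
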