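"""Nonparametric model-selection statistics.

The comparison workflow over a complete blocks-by-treatments AUROC matrix
(folds x models): Shapiro-Wilk normality and Bartlett homoscedasticity
checks (gatekeeping narrative for preferring a nonparametric route), the
Friedman rank test with the Iman-Davenport F extension as omnibus, the
Finner step-down procedure for the multiple comparisons against the
top-ranked control, and a pairwise Wilcoxon signed-rank tie-break on
per-fold selected-feature counts when two or more models remain
statistically indistinguishable.

Rank direction: rank 1 = best (highest metric). The Finner critical scores
are ``c_i = 1 - (1 - alpha)^(i / (k-1))`` and the matching adjustment is
``p~_(j) = max_{i<=j} [1 - (1 - p_(i))^((k-1)/i)]`` over comparisons ordered
by ascending raw p (ties share the smaller index).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "shapiro_wilk",
    "bartlett",
    "friedman_imandavenport",
    "friedman_exact_p",
    "finner_critical_scores",
    "finner_adjust",
    "finner_posthoc",
    "wilcoxon_signed_rank",
    "decision_workflow",
    "FriedmanResult",
    "PosthocResult",
    "WorkflowReport",
]


# ------------------------------------------------------------ normality etc.


def shapiro_wilk(x) -> tuple[float, float]:
    """Shapiro-Wilk W and p (Royston AS R94), for 3 <= n <= 5000."""
    x = np.asarray(x, dtype=float)
    if not 3 <= len(x) <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise ValueError("Shapiro-Wilk undefined for constant input")
    res = stats.shapiro(x)
    return float(res.statistic), float(res.pvalue)


def bartlett(groups) -> tuple[float, int, float]:
    """Bartlett's K^2 across groups, its df = k-1, and the chi-square p."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("Bartlett requires at least 2 groups")
    for g in groups:
        if len(g) < 2:
            raise ValueError("every group needs >= 2 values")
        if g.var(ddof=1) == 0:
            raise ValueError("zero-variance group: Bartlett statistic undefined")
    stat, p = stats.bartlett(*groups)
    return float(stat), len(groups) - 1, float(p)


# ------------------------------------------------------------------ Friedman


@dataclass
class FriedmanResult:
    avg_ranks: pd.Series
    chi2: float
    f_id: float
    df: tuple[int, int]
    p_value: float
    degenerate: bool = False


def _block_ranks(M: pd.DataFrame) -> pd.DataFrame:
    """Within-block ranks, rank 1 = best (highest value), ties averaged."""
    return M.rank(axis=1, ascending=False, method="average")


def friedman_imandavenport(M: pd.DataFrame) -> FriedmanResult:
    """Friedman chi-square and the Iman-Davenport F for a complete matrix.

    Rows are blocks (folds), columns treatments (models). Uses the classic
    statistic ``chi2_F = 12n/(k(k+1)) [sum R_j^2 - k(k+1)^2/4]`` on average
    ranks, and ``F_ID = (n-1) chi2_F / (n(k-1) - chi2_F)`` with df
    ``(k-1, (k-1)(n-1))``.
    """
    if M.isna().any().any():
        raise ValueError("matrix must be complete")
    n, k = M.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 blocks and 2 treatments")
    ranks = _block_ranks(M)
    R = ranks.mean(axis=0)
    chi2 = 12.0 * n / (k * (k + 1)) * float((R ** 2).sum() - k * (k + 1) ** 2 / 4.0)
    denom = n * (k - 1) - chi2
    df = (k - 1, (k - 1) * (n - 1))
    if denom <= 0:
        return FriedmanResult(R, chi2, float("inf"), df, 0.0, degenerate=True)
    f_id = (n - 1) * chi2 / denom
    p = float(stats.f.sf(f_id, *df))
    return FriedmanResult(R, chi2, f_id, df, p)


def friedman_exact_p(M: pd.DataFrame) -> float:
    """Exact permutation p of the Friedman chi-square for small matrices.

    Enumerates all (k!)^n within-block orderings; p is the share of
    configurations with chi-square >= the observed one. Feasible only for
    tiny n and k (e.g. 3 x 3).
    """
    n, k = M.shape
    if math.factorial(k) ** n > 2_000_000:
        raise ValueError("matrix too large for exact enumeration")

    def chi2_of(rank_rows: np.ndarray) -> float:
        R = rank_rows.mean(axis=0)
        return 12.0 * n / (k * (k + 1)) * float((R ** 2).sum() - k * (k + 1) ** 2 / 4.0)

    observed = chi2_of(_block_ranks(M).to_numpy())
    perms = [np.array(p, dtype=float) + 1 for p in itertools.permutations(range(k))]
    count = 0
    total = 0
    for combo in itertools.product(range(len(perms)), repeat=n):
        rows = np.vstack([perms[i] for i in combo])
        if chi2_of(rows) >= observed - 1e-12:
            count += 1
        total += 1
    return count / total


# -------------------------------------------------------------------- Finner


def finner_critical_scores(k: int, alpha: float = 0.05) -> np.ndarray:
    """Step-down critical scores c_i = 1 - (1-alpha)^(i/(k-1)), i = 1..k-1."""
    i = np.arange(1, k)
    return 1.0 - (1.0 - alpha) ** (i / (k - 1.0))


def finner_adjust(raw_p: np.ndarray, k: int) -> np.ndarray:
    """Finner-adjusted p-values for comparisons ordered by ascending raw p.

    Tied raw p-values share the smaller ordering index in the exponent.
    Input must already be sorted ascending; output is monotone
    non-decreasing and capped at 1.
    """
    raw_p = np.asarray(raw_p, dtype=float)
    m = len(raw_p)
    idx = np.arange(1, m + 1, dtype=float)
    # ties share the smallest index of their tie group
    for j in range(1, m):
        if raw_p[j] == raw_p[j - 1]:
            idx[j] = idx[j - 1]
    adj = 1.0 - (1.0 - raw_p) ** ((k - 1.0) / idx)
    adj = np.maximum.accumulate(adj)
    return np.minimum(adj, 1.0)


@dataclass
class PosthocResult:
    control: str
    table: pd.DataFrame
    avg_ranks: pd.Series
    alpha: float
    k: int
    n: int


def finner_posthoc(
    avg_ranks: pd.Series, n: int, control: str | None = None, alpha: float = 0.05
) -> PosthocResult:
    """Finner step-down comparisons of every treatment against a control.

    ``avg_ranks`` are Friedman average ranks over ``n`` blocks; the control
    defaults to the best (lowest) rank. z_i = (R_i - R_c) / sqrt(k(k+1)/6n)
    with two-sided normal raw p-values; rejection by the step-down pass on
    the critical scores.
    """
    k = len(avg_ranks)
    if control is None:
        control = avg_ranks.idxmin()
    if control not in avg_ranks.index:
        raise ValueError(f"control {control!r} not among treatments")
    se = np.sqrt(k * (k + 1) / (6.0 * n))
    others = [t for t in avg_ranks.index if t != control]
    z = np.array([(avg_ranks[t] - avg_ranks[control]) / se for t in others])
    raw = 2.0 * stats.norm.sf(np.abs(z))
    order = np.argsort(raw, kind="stable")
    sorted_raw = raw[order]
    adjusted = finner_adjust(sorted_raw, k)
    crit = finner_critical_scores(k, alpha)[: len(others)]
    # step-down: walk in ascending raw-p order; first non-rejection stops
    reject = np.zeros(len(others), dtype=bool)
    still = True
    for j in range(len(others)):
        if still and sorted_raw[j] <= crit[j]:
            reject[j] = True
        else:
            still = False
    table = pd.DataFrame(
        {
            "comparison": [others[i] for i in order],
            "z": z[order],
            "p_raw": sorted_raw,
            "p_finner": adjusted,
            "finner_score": crit,
            "reject": reject,
        }
    )
    return PosthocResult(control=control, table=table, avg_ranks=avg_ranks,
                         alpha=alpha, k=k, n=n)


# ------------------------------------------------------------------ Wilcoxon


def wilcoxon_signed_rank(a, b) -> tuple[float, float, bool]:
    """Paired Wilcoxon signed-rank test; returns (W, p, all_zero_flag).

    Zero differences are dropped; the distribution is exact for n <= 25
    without ties, otherwise a tie-corrected normal approximation is used.
    All-zero differences give p = 1 with the flag set.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) != len(b) or len(a) < 3:
        raise ValueError("need paired vectors of equal length >= 3")
    d = a - b
    if np.all(d == 0):
        return 0.0, 1.0, True
    res = stats.wilcoxon(a, b, zero_method="wilcox", method="auto")
    return float(res.statistic), float(res.pvalue), False


# ------------------------------------------------------------------ workflow


@dataclass
class WorkflowReport:
    winner: str
    shapiro: tuple[float, float]
    bartlett: tuple[float, int, float]
    friedman: FriedmanResult
    posthoc: PosthocResult
    tie_break: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = [
            f"Shapiro-Wilk: W={self.shapiro[0]:.4f}, p={self.shapiro[1]:.3g}",
            f"Bartlett: K^2={self.bartlett[0]:.3f}, df={self.bartlett[1]}, "
            f"p={self.bartlett[2]:.3g}",
            f"Friedman chi2={self.friedman.chi2:.3f}, "
            f"Iman-Davenport F={self.friedman.f_id:.3f} "
            f"df={self.friedman.df}, p={self.friedman.p_value:.3g}",
            "Average ranks (1 = best): "
            + ", ".join(f"{m}={r:.2f}" for m, r in
                        self.posthoc.avg_ranks.sort_values().items()),
            f"Control: {self.posthoc.control}",
            self.posthoc.table.to_string(index=False),
        ]
        if self.tie_break:
            lines.append(
                "Tie-break (Wilcoxon on per-fold feature counts): "
                + ", ".join(f"{k}: p={v:.3g}" for k, v in
                            self.tie_break.get("p_values", {}).items())
            )
        lines.append(f"Winner: {self.winner}")
        return "\n".join(lines)


def decision_workflow(
    metrics: pd.DataFrame,
    feature_counts: pd.DataFrame | None = None,
    alpha: float = 0.05,
) -> WorkflowReport:
    """The full model-selection procedure over a tidy per-fold metric table.

    ``metrics`` needs columns (model, fold, auroc); ``feature_counts`` the
    same shape with column n_features for the tie-break. The winner is the
    top-ranked model; if any competitor is not separated by Finner, the
    pairwise Wilcoxon on per-fold selected-feature counts decides (fewer
    features wins when significant).
    """
    M = metrics.pivot(index="fold", columns="model", values="auroc")
    if M.isna().any().any():
        raise ValueError("incomplete fold x model matrix")
    pooled = metrics["auroc"].to_numpy()
    try:
        sw = shapiro_wilk(pooled)
    except ValueError:
        sw = (float("nan"), float("nan"))
    try:
        bt = bartlett([g["auroc"].to_numpy() for _, g in metrics.groupby("model")])
    except ValueError:
        bt = (float("nan"), M.shape[1] - 1, float("nan"))
    fried = friedman_imandavenport(M)
    post = finner_posthoc(fried.avg_ranks, n=M.shape[0], alpha=alpha)
    winner = post.control
    tie_break: dict = {}
    not_separated = list(post.table.loc[~post.table["reject"], "comparison"])
    if not_separated and feature_counts is not None:
        fc = feature_counts.pivot(index="fold", columns="model", values="n_features")
        p_values = {}
        for rival in not_separated:
            _, p, _ = wilcoxon_signed_rank(fc[winner], fc[rival])
            p_values[rival] = p
            if p < alpha and fc[rival].median() < fc[winner].median():
                winner = rival
        tie_break = {"candidates": not_separated, "p_values": p_values}
    return WorkflowReport(
        winner=winner, shapiro=sw, bartlett=bt,
        friedman=fried, posthoc=post, tie_break=tie_break,
    )
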