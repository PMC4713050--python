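"""Independent brute-force oracles used by the test suite.

Everything here is written as naive double loops / exhaustive enumeration,
deliberately sharing no code with the package implementation.
"""

from __future__ import annotations

import itertools

import numpy as np


# ----------------------------------------------------------------- textures


def glcm_oracle(levels: np.ndarray, mask: np.ndarray, ng: int,
                step: tuple[int, int]) -> np.ndarray:
    """Symmetric normalized co-occurrence matrix via an explicit pixel loop."""
    h, w = levels.shape
    dr, dc = step
    counts = np.zeros((ng, ng))
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w and mask[r, c] and mask[r2, c2]:
                i, j = levels[r, c] - 1, levels[r2, c2] - 1
                counts[i, j] += 1
                counts[j, i] += 1
    return counts / counts.sum()


def haralick_oracle(p: np.ndarray) -> dict[str, float]:
    """The 11 co-occurrence statistics evaluated with explicit loops."""
    ng = p.shape[0]
    mu_x = sum((i + 1) * p[i, j] for i in range(ng) for j in range(ng))
    var_x = sum((i + 1 - mu_x) ** 2 * p[i, j] for i in range(ng) for j in range(ng))
    p_sum = {k: 0.0 for k in range(2, 2 * ng + 1)}
    p_diff = {k: 0.0 for k in range(ng)}
    for i in range(ng):
        for j in range(ng):
            p_sum[i + j + 2] += p[i, j]
            p_diff[abs(i - j)] += p[i, j]
    sum_avg = sum(k * v for k, v in p_sum.items())
    diff_avg = sum(k * v for k, v in p_diff.items())

    def ent(vals):
        return -sum(v * np.log(v) for v in vals if v > 0)

    out = {
        "AngScMom": sum(p[i, j] ** 2 for i in range(ng) for j in range(ng)),
        "Contrast": sum((i - j) ** 2 * p[i, j] for i in range(ng) for j in range(ng)),
        "SumOfSqs": var_x,
        "InvDfMom": sum(p[i, j] / (1 + (i - j) ** 2)
                        for i in range(ng) for j in range(ng)),
        "SumAverg": sum_avg,
        "SumVarnc": sum((k - sum_avg) ** 2 * v for k, v in p_sum.items()),
        "SumEntrp": ent(p_sum.values()),
        "Entropy": ent(p.ravel()),
        "DifVarnc": sum((k - diff_avg) ** 2 * v for k, v in p_diff.items()),
        "DifEntrp": ent(p_diff.values()),
    }
    if var_x > 0:
        out["Correlat"] = (
            sum((i + 1) * (j + 1) * p[i, j] for i in range(ng) for j in range(ng))
            - mu_x ** 2
        ) / var_x
    else:
        out["Correlat"] = 0.0
    return out


def rlm_oracle(levels: np.ndarray, mask: np.ndarray, ng: int,
               direction: str) -> np.ndarray:
    """Run-length matrix by walking every line pixel by pixel."""
    h, w = levels.shape
    lines = []
    if direction == "H":
        lines = [[(r, c) for c in range(w)] for r in range(h)]
    elif direction == "V":
        lines = [[(r, c) for r in range(h)] for c in range(w)]
    elif direction == "135":  # step (1, 1)
        for off in range(-h + 1, w):
            line = [(r, r + off) for r in range(h) if 0 <= r + off < w]
            if line:
                lines.append(line)
    elif direction == "45":  # step (-1, 1): walk from bottom to top
        for off in range(-h + 1, w):
            line = [(h - 1 - i, off + i) for i in range(h) if 0 <= off + i < w]
            line = [(r, c) for r, c in line if 0 <= c < w]
            if line:
                lines.append(line)
    mat = np.zeros((ng, max(h, w)))
    for line in lines:
        run_level, run_len = None, 0
        for r, c in line + [(-1, -1)]:
            inside = r >= 0 and mask[r, c]
            lev = levels[r, c] if inside else None
            if inside and lev == run_level:
                run_len += 1
            else:
                if run_level is not None:
                    mat[run_level - 1, run_len - 1] += 1
                run_level, run_len = (lev, 1) if inside else (None, 0)
    return mat


def gradient_oracle(pixels: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Gradient magnitudes at interior pixels via explicit loops."""
    h, w = pixels.shape
    mags = []
    for r in range(1, h - 1):
        for c in range(1, w - 1):
            if (mask[r, c] and mask[r - 1, c] and mask[r + 1, c]
                    and mask[r, c - 1] and mask[r, c + 1]):
                dx = float(pixels[r, c + 1]) - float(pixels[r, c - 1])
                dy = float(pixels[r + 1, c]) - float(pixels[r - 1, c])
                mags.append(np.sqrt(dx * dx + dy * dy))
    return np.array(mags)


def ar_oracle(pixels: np.ndarray, mask: np.ndarray):
    """Four-neighbour AR fit via explicitly assembled normal equations."""
    s = pixels.astype(float) - pixels[mask].mean()
    h, w = pixels.shape
    rows, ys = [], []
    for r in range(1, h):
        for c in range(1, w - 1):
            if (mask[r, c] and mask[r, c - 1] and mask[r - 1, c]
                    and mask[r - 1, c - 1] and mask[r - 1, c + 1]):
                rows.append([s[r, c - 1], s[r - 1, c], s[r - 1, c - 1], s[r - 1, c + 1]])
                ys.append(s[r, c])
    X = np.array(rows)
    y = np.array(ys)
    theta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ theta
    return theta, float(resid.std())


def haar2d_oracle(a: np.ndarray) -> tuple[np.ndarray, ...]:
    """One orthonormal Haar step on an even-sized array, by explicit 2x2 blocks."""
    h, w = a.shape
    ll = np.zeros((h // 2, w // 2))
    lh = np.zeros_like(ll)
    hl = np.zeros_like(ll)
    hh = np.zeros_like(ll)
    for r in range(h // 2):
        for c in range(w // 2):
            blk = a[2 * r:2 * r + 2, 2 * c:2 * c + 2]
            ll[r, c] = blk.sum() / 2.0
            # row filter applied along columns (axis 0), column filter along rows
            lh[r, c] = (blk[0, 0] + blk[1, 0] - blk[0, 1] - blk[1, 1]) / 2.0
            hl[r, c] = (blk[0, 0] - blk[1, 0] + blk[0, 1] - blk[1, 1]) / 2.0
            hh[r, c] = (blk[0, 0] - blk[1, 0] - blk[0, 1] + blk[1, 1]) / 2.0
    return ll, lh, hl, hh


def hist_oracle(vals: np.ndarray) -> dict[str, float]:
    n = len(vals)
    mu = sum(vals) / n
    var = sum((v - mu) ** 2 for v in vals) / n
    if var == 0:
        skew = kurt = 0.0
    else:
        skew = sum((v - mu) ** 3 for v in vals) / n / var ** 1.5
        kurt = sum((v - mu) ** 4 for v in vals) / n / var ** 2 - 3.0
    s = sorted(vals)
    out = {"Mean": mu, "Variance": var, "Skewness": skew, "Kurtosis": kurt}
    for q in (1, 10, 50, 90, 99):
        idx = max(1, int(np.ceil(q / 100 * n))) - 1
        out[f"Perc.{q:02d}%"] = float(s[idx])
    return out


# --------------------------------------------------------------- evaluation


def auroc_pairs_oracle(scores, labels) -> float:
    """(concordant + half-tied) / total over all positive-negative pairs."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = len(pos) * len(neg)
    acc = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                acc += 1.0
            elif sp == sn:
                acc += 0.5
    return acc / total


# --------------------------------------------------------------- statistics


def wilcoxon_exact_oracle(a, b) -> float:
    """Two-sided exact signed-rank p by enumerating all sign assignments."""
    d = np.asarray(a, float) - np.asarray(b, float)
    d = d[d != 0]
    n = len(d)
    absd = np.abs(d)
    # average ranks of |d|
    order = np.argsort(absd)
    ranks = np.empty(n)
    sorted_abs = absd[order]
    i = 0
    while i < n:
        j = i
        while j < n and sorted_abs[j] == sorted_abs[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0
        i = j
    w_plus = ranks[d > 0].sum()
    w_obs = min(w_plus, ranks.sum() - w_plus)
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        wp = sum(r for r, s in zip(ranks, signs) if s)
        if min(wp, ranks.sum() - wp) <= w_obs + 1e-12:
            count += 1
    return count / 2 ** n


def friedman_perm_oracle(M: np.ndarray) -> float:
    """Exact permutation p of the Friedman chi-square, written from scratch."""
    n, k = M.shape

    def rank_row(row):
        order = sorted(range(k), key=lambda i: -row[i])
        ranks = [0.0] * k
        i = 0
        while i < k:
            j = i
            while j < k and row[order[j]] == row[order[i]]:
                j += 1
            for t in range(i, j):
                ranks[order[t]] = (i + j + 1) / 2.0
            i = j
        return ranks

    def chi2(rank_rows):
        R = [sum(r[j] for r in rank_rows) / n for j in range(k)]
        return 12 * n / (k * (k + 1)) * (sum(x * x for x in R) - k * (k + 1) ** 2 / 4)

    observed = chi2([rank_row(M[i]) for i in range(n)])
    perms = [list(np.array(p) + 1.0) for p in itertools.permutations(range(k))]
    hits = total = 0
    for combo in itertools.product(perms, repeat=n):
        if chi2(list(combo)) >= observed - 1e-12:
            hits += 1
        total += 1
    return hits / total


def bartlett_oracle(groups) -> float:
    """Textbook Bartlett K^2 evaluated term by term."""
    k = len(groups)
    ns = [len(g) for g in groups]
    N = sum(ns)
    vars_ = [np.var(g, ddof=1) for g in groups]
    sp2 = sum((n - 1) * v for n, v in zip(ns, vars_)) / (N - k)
    num = (N - k) * np.log(sp2) - sum((n - 1) * np.log(v) for n, v in zip(ns, vars_))
    den = 1 + (sum(1 / (n - 1) for n in ns) - 1 / (N - k)) / (3 * (k - 1))
    return num / den
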