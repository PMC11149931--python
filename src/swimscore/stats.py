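"""Cohort statistics: Fisher tests on pattern tables, rank tests,
Spearman correlation, variance decomposition (PVE), and correspondence
analysis of pattern-composition tables.

Pattern sets are compositional, categorical data, so group comparisons
use Fisher's exact test (exact on 2x2 tables, Monte-Carlo with fixed
margins on larger ones) and correspondence analysis for ordination.
Before/after kinematic contrasts use the Wilcoxon signed-rank test (the
paired rank test); between-group contrasts use Mann-Whitney U with
Bonferroni correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import gammaln

from .patterns import PatternTable


# ---------------------------------------------------------------- Fisher

def _table_log_prob(table: np.ndarray, row_margin_logfact: float,
                    col_margin_logfact: float, n_logfact: float) -> float:
    """Log multivariate-hypergeometric probability of an RxC table."""
    return (row_margin_logfact + col_margin_logfact - n_logfact
            - gammaln(table + 1.0).sum())


@dataclass
class FisherResult:
    p_value: float
    method: str                      # "exact" | "monte_carlo"
    standard_error: float = 0.0
    n_reps: int = 0


def fisher_exact(table, mc_reps: int = 100_000, seed: int | None = None,
                 two_sided_rule: str = "prob_le") -> FisherResult:
    """Two-sided Fisher's exact test on a contingency table.

    2x2 tables are tested exactly (hypergeometric; two-sided p sums the
    probabilities of tables no more likely than the observed one, the
    ``prob_le`` rule; ``doubling`` doubles the smaller one-sided tail and
    caps at 1).  Larger tables use a seeded Monte-Carlo estimate over
    random tables with the observed margins, reported with its binomial
    standard error.
    """
    if isinstance(table, PatternTable):
        table = table.counts
    tab = np.asarray(table, dtype=np.int64)
    tab = tab[tab.sum(axis=1) > 0][:, tab[tab.sum(axis=1) > 0].sum(axis=0) > 0]
    if tab.ndim != 2 or tab.shape[0] < 2 or tab.shape[1] < 2:
        raise ValueError("need >= 2 rows and >= 2 columns with nonzero margins")
    if (tab < 0).any():
        raise ValueError("counts must be non-negative")
    if tab.shape == (2, 2):
        if two_sided_rule == "prob_le":
            _, p = sps.fisher_exact(tab, alternative="two-sided")
        elif two_sided_rule == "doubling":
            _, p_less = sps.fisher_exact(tab, alternative="less")
            _, p_greater = sps.fisher_exact(tab, alternative="greater")
            p = min(1.0, 2.0 * min(p_less, p_greater))
        else:
            raise ValueError(f"unknown two_sided_rule {two_sided_rule!r}")
        return FisherResult(p_value=float(p), method="exact")

    # Monte Carlo over tables with fixed margins (permutation construction)
    rng = np.random.default_rng(seed)
    rows, cols = tab.sum(axis=1), tab.sum(axis=0)
    n = int(tab.sum())
    rml = gammaln(rows + 1.0).sum()
    cml = gammaln(cols + 1.0).sum()
    nl = gammaln(n + 1.0)
    obs_lp = _table_log_prob(tab, rml, cml, nl)
    col_labels = np.repeat(np.arange(cols.size), cols)
    row_edges = np.concatenate([[0], np.cumsum(rows)])
    hits = 0
    reps = int(mc_reps)
    for _ in range(reps):
        rng.shuffle(col_labels)
        sim = np.stack([
            np.bincount(col_labels[row_edges[i]:row_edges[i + 1]],
                        minlength=cols.size)
            for i in range(rows.size)
        ])
        if _table_log_prob(sim, rml, cml, nl) <= obs_lp + 1e-7:
            hits += 1
    p = (hits + 1) / (reps + 1)
    se = float(np.sqrt(p * (1 - p) / reps))
    return FisherResult(p_value=float(p), method="monte_carlo",
                        standard_error=se, n_reps=reps)


# ------------------------------------------------------------ rank tests

def paired_rank_test(before, after) -> float:
    """Wilcoxon signed-rank two-sided p for paired before/after means.

    Zero differences are dropped (count reported via warning when any).
    The exact null distribution is used for n <= 25 without ties in the
    absolute differences; the tie-corrected normal approximation
    otherwise.  All-zero differences give p = 1 with a warning.
    """
    before = np.asarray(before, float)
    after = np.asarray(after, float)
    if before.shape != after.shape or before.size < 3:
        raise ValueError("need equal-length paired samples of size >= 3")
    d = after - before
    n_zero = int(np.sum(d == 0))
    d = d[d != 0]
    if n_zero:
        warnings.warn(f"dropped {n_zero} zero difference(s)", stacklevel=2)
    if d.size == 0:
        warnings.warn("all paired differences are zero; p = 1", stacklevel=2)
        return 1.0
    absd = np.abs(d)
    no_ties = np.unique(absd).size == absd.size
    method = "exact" if (d.size <= 25 and no_ties) else "approx"
    res = sps.wilcoxon(d, alternative="two-sided", method=method,
                       correction=False)
    return float(res.pvalue)


def unpaired_rank_test(a, b, m_comparisons: int = 1) -> float:
    """Mann-Whitney U two-sided p, Bonferroni-multiplied and capped at 1.

    Exact for small tie-free samples, tie-corrected normal otherwise.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 observations")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (max(a.size, b.size) <= 25 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(min(1.0, res.pvalue * m_comparisons))


def spearman_t(x, y) -> tuple[float, float]:
    """Spearman rank correlation with a Student-t p-value.

    rho is the Pearson correlation of average ranks; the p-value comes
    from t = rho * sqrt((n - 2) / (1 - rho^2)) on n - 2 degrees of
    freedom (two-sided), with p = 0 at rho = +/-1.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 4:
        raise ValueError("need paired samples of size >= 4")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValueError("correlation undefined for a constant vector")
    rx, ry = sps.rankdata(x), sps.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if abs(rho) >= 1.0 - 1e-15:
        return float(np.sign(rho)), 0.0
    n = x.size
    t = rho * np.sqrt((n - 2) / (1 - rho ** 2))
    p = 2.0 * sps.t.sf(abs(t), df=n - 2)
    return rho, float(p)


# ----------------------------------------------------------------- PVE

@dataclass
class PveResult:
    """Percentage of olfactory-score variation explained by a predictor."""

    pve: float                 # percent, in [0, 100]
    n: int
    predictor_kind: str        # "categorical" | "continuous"
    p_value: float
    n_permutations: int = 0


def _pve_stat(scores: np.ndarray, predictor, kind: str) -> float:
    if kind == "categorical":
        groups = pd.Series(scores).groupby(pd.Series(predictor))
        grand = scores.mean()
        ss_total = float(np.sum((scores - grand) ** 2))
        if ss_total == 0:
            return 0.0
        ss_between = float(sum(
            len(g) * (g.mean() - grand) ** 2 for _, g in groups))
        return 100.0 * ss_between / ss_total
    r = np.corrcoef(scores, np.asarray(predictor, float))[0, 1]
    return 100.0 * float(r) ** 2


def pve(scores, predictor, kind: str | None = None,
        n_permutations: int = 10_000, seed: int | None = None) -> PveResult:
    """Variance explained by a baseline personality predictor, with a
    seeded permutation p-value.

    Categorical predictors (pattern category) use the between-group share
    of the total sum of squares (eta squared); continuous ones (baseline
    speed) the squared Pearson correlation.  Constant scores give PVE 0
    with a warning.
    """
    scores = np.asarray(scores, float)
    predictor = np.asarray(predictor)
    if kind is None:
        kind = ("continuous" if np.issubdtype(predictor.dtype, np.number)
                else "categorical")
    if kind == "categorical":
        _, counts = np.unique(predictor, return_counts=True)
        if counts.size < 2 or counts.min() < 2:
            raise ValueError("need >= 2 groups with >= 2 fish each")
    elif scores.size < 4:
        raise ValueError("need n >= 4 for a continuous predictor")
    if np.unique(scores).size == 1:
        warnings.warn("scores are constant; PVE = 0", stacklevel=2)
        return PveResult(pve=0.0, n=scores.size, predictor_kind=kind,
                         p_value=1.0)
    obs = _pve_stat(scores, predictor, kind)
    rng = np.random.default_rng(seed)
    perm = predictor.copy()
    hits = 0
    for _ in range(int(n_permutations)):
        rng.shuffle(perm)
        if _pve_stat(scores, perm, kind) >= obs - 1e-12:
            hits += 1
    p = (hits + 1) / (n_permutations + 1)
    return PveResult(pve=float(obs), n=int(scores.size), predictor_kind=kind,
                     p_value=float(p), n_permutations=int(n_permutations))


# -------------------------------------------------- correspondence analysis

@dataclass
class CAResult:
    """Correspondence analysis of a contingency table.

    Principal coordinates are the mass-rescaled singular vectors scaled
    by the singular values; total inertia equals chi2/n and decomposes
    over the min(rows, cols) - 1 dimensions as the squared singular
    values.
    """

    row_coords: pd.DataFrame
    col_coords: pd.DataFrame
    singular_values: np.ndarray
    total_inertia: float
    explained_inertia: np.ndarray       # fraction per dimension


def correspondence_analysis(table) -> CAResult:
    """CA of a pattern-composition table via SVD of standardized residuals.

    With correspondence matrix P = counts/n, row/column masses r and c,
    the SVD of S = D_r^{-1/2} (P - r c^T) D_c^{-1/2} yields principal
    coordinates D_r^{-1/2} U S (rows) and D_c^{-1/2} V S (columns).
    """
    if isinstance(table, PatternTable):
        table = table.counts
    if isinstance(table, pd.DataFrame):
        row_names, col_names = list(table.index), list(table.columns)
        tab = table.to_numpy(float)
    else:
        tab = np.asarray(table, float)
        row_names = [f"r{i}" for i in range(tab.shape[0])]
        col_names = [f"c{j}" for j in range(tab.shape[1])]
    if tab.ndim != 2 or tab.shape[0] < 2 or tab.shape[1] < 2:
        raise ValueError("need >= 2 rows and >= 2 columns")
    if (tab < 0).any():
        raise ValueError("counts must be non-negative")
    r_m, c_m = tab.sum(axis=1), tab.sum(axis=0)
    if (r_m == 0).any() or (c_m == 0).any():
        raise ValueError("zero row or column margin")
    n = tab.sum()
    P = tab / n
    r, c = r_m / n, c_m / n
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, sv, Vt = np.linalg.svd(S, full_matrices=False)
    k = min(tab.shape) - 1
    U, sv, Vt = U[:, :k], sv[:k], Vt[:k]
    row_coords = (U / np.sqrt(r)[:, None]) * sv
    col_coords = (Vt.T / np.sqrt(c)[:, None]) * sv
    total = float(np.sum(sv ** 2))
    explained = (sv ** 2) / total if total > 0 else np.zeros(k)
    dims = [f"dim{i + 1}" for i in range(k)]
    return CAResult(
        row_coords=pd.DataFrame(row_coords, index=row_names, columns=dims),
        col_coords=pd.DataFrame(col_coords, index=col_names, columns=dims),
        singular_values=sv,
        total_inertia=total,
        explained_inertia=explained,
    )


def test_report(name: str, groups, n, statistic, p, adjustment=None,
                seed=None) -> dict:
    """Uniform JSON-serializable record for one statistical comparison."""
    return {
        "test": name,
        "groups": list(groups),
        "n": n,
        "statistic": statistic,
        "p_value": p,
        "adjustment": adjustment,
        "seed": seed,
    }
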