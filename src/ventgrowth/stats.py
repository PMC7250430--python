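"""Rank-based factorial statistics for growth-rate tables.

The analysis chain mirrors common practice for heteroscedastic,
non-normal growth-rate data from a two-factor (pH × temperature)
layout, run separately per salinity stratum:

1. Shapiro-Wilk normality and Brown-Forsythe variance-homogeneity
   checks on the raw rates.
2. Aligned rank transform (ART): for each effect (A, B, A×B) the
   response is aligned — every other effect's cell-means estimate is
   stripped — then ranked, and an ordinary two-way fixed-effects ANOVA
   is run on that effect's ranks, reporting only the focal effect.
3. Where the interaction is significant, one-way Kruskal-Wallis tests
   of each factor at each level of the other, followed by Dunn's
   pairwise comparisons and a compact letter display.

Ties take average ranks throughout; the tie correction enters both the
Kruskal-Wallis H and the Dunn pooled variance.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

ALIGNMENT_TOL = 1e-9

EFFECTS = ("A", "B", "A:B")


class StatsError(ValueError):
    """Raised for invalid inputs to a statistical routine."""


# ---------------------------------------------------------------------------
# distributional checks


def shapiro_wilk(values) -> tuple[float, float]:
    """Shapiro-Wilk W and p for 3 <= n <= 5000 observations."""
    x = np.asarray(values, dtype=float)
    if len(x) < 3:
        raise StatsError(f"Shapiro-Wilk needs n >= 3, got {len(x)}")
    if len(x) > 5000:
        raise StatsError("Shapiro-Wilk is unreliable above n = 5000")
    res = sps.shapiro(x)
    return float(res.statistic), float(res.pvalue)


def brown_forsythe(*groups) -> tuple[float, float]:
    """Brown-Forsythe homogeneity-of-variance test.

    Levene-type F on absolute deviations from group medians.  With all
    observations identical the statistic is degenerate; that case is
    reported as non-rejection (statistic 0, p 1) with a warning.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise StatsError("need >= 2 groups")
    for g in arrays:
        if len(g) < 2:
            raise StatsError("every group needs n >= 2")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        warnings.warn(
            "all observations identical; Brown-Forsythe statistic degenerate, "
            "reporting non-rejection",
            RuntimeWarning,
            stacklevel=2,
        )
        return 0.0, 1.0
    stat, p = sps.levene(*arrays, center="median")
    return float(stat), float(p)


# ---------------------------------------------------------------------------
# aligned rank transform


@dataclass(frozen=True)
class ArtTable:
    """Aligned responses and ranks per effect for a two-factor layout.

    ``frame`` carries the factor columns plus, for each effect E in
    {A, B, A:B}, columns ``aligned_<E>`` and ``rank_<E>``.
    """

    frame: pd.DataFrame
    factor_a: str
    factor_b: str
    balanced: bool


def _cell_decomposition(df: pd.DataFrame, fa: str, fb: str, resp: str):
    """Unweighted cell-means decomposition of a fully crossed layout.

    Marginal effect estimates are means of cell means (not of raw
    observations), so the alignment identity holds even when cell
    sizes differ.
    """
    cell_means = df.groupby([fa, fb], sort=True)[resp].mean().unstack(fb)
    if cell_means.isna().any().any():
        a, b = next(
            (a, b)
            for a in cell_means.index
            for b in cell_means.columns
            if pd.isna(cell_means.loc[a, b])
        )
        raise StatsError(f"empty cell: ({fa}={a}, {fb}={b})")
    mu = float(cell_means.to_numpy().mean())
    alpha = cell_means.mean(axis=1) - mu                   # A main effects
    beta = cell_means.mean(axis=0) - mu                    # B main effects
    gamma = cell_means.sub(alpha, axis=0).sub(beta, axis=1) - mu  # interaction
    return cell_means, mu, alpha, beta, gamma


def aligned_rank_transform(
    table: pd.DataFrame,
    factor_a: str,
    factor_b: str,
    response: str = "response",
) -> ArtTable:
    """Aligned rank transform for a fully crossed two-factor layout.

    For each effect the aligned response is the residual from the full
    cell-means model plus that effect's own estimate (main effects from
    marginal means of cell means; interaction from cell mean − marginal
    effects − grand mean).  Aligned responses are then ranked with
    average ranks for ties.  Each effect's aligned column, re-decomposed,
    carries zero estimated contribution from every other effect (checked
    to 1e-9).
    """
    df = table[[factor_a, factor_b, response]].copy()
    if df[factor_a].nunique() < 2 or df[factor_b].nunique() < 2:
        raise StatsError("both factors need >= 2 levels")
    cell_means, mu, alpha, beta, gamma = _cell_decomposition(
        df, factor_a, factor_b, response
    )
    a_of = df[factor_a].map(alpha).to_numpy(dtype=float)
    b_of = df[factor_b].map(beta).to_numpy(dtype=float)
    g_of = np.array(
        [gamma.loc[a, b] for a, b in zip(df[factor_a], df[factor_b])],
        dtype=float,
    )
    fitted = mu + a_of + b_of + g_of
    resid = df[response].to_numpy(dtype=float) - fitted

    aligned = {
        "A": resid + a_of,
        "B": resid + b_of,
        "A:B": resid + g_of,
    }
    for eff, col in aligned.items():
        _assert_alignment(df, factor_a, factor_b, eff, col)
        df[f"aligned_{eff}"] = col
        df[f"rank_{eff}"] = sps.rankdata(col, method="average")

    sizes = df.groupby([factor_a, factor_b]).size()
    return ArtTable(
        frame=df,
        factor_a=factor_a,
        factor_b=factor_b,
        balanced=bool(sizes.nunique() == 1),
    )


def _assert_alignment(df, fa, fb, effect, aligned_col) -> None:
    """Alignment identity: non-focal estimated effects vanish pre-ranking."""
    tmp = df[[fa, fb]].copy()
    tmp["y"] = aligned_col
    _, mu, alpha, beta, gamma = _cell_decomposition(tmp, fa, fb, "y")
    checks = {"A": alpha.to_numpy(), "B": beta.to_numpy(),
              "A:B": gamma.to_numpy().ravel(), "mu": np.array([mu])}
    for other in ("A", "B", "A:B"):
        if other == effect:
            continue
        worst = float(np.max(np.abs(checks[other])))
        if worst > ALIGNMENT_TOL:
            raise AssertionError(
                f"alignment identity violated for effect {effect}: "
                f"residual {other} contribution {worst:.2e}"
            )


@dataclass(frozen=True)
class EffectTest:
    effect: str
    f_statistic: float
    df1: int
    df2: int
    p_value: float


def _balanced_twoway_anova(y, ai, bi, n_a, n_b):
    """F statistics for a balanced a × b × n fixed-effects layout."""
    y = np.asarray(y, dtype=float)
    n = len(y) // (n_a * n_b)
    grand = y.mean()
    cell = np.zeros((n_a, n_b))
    for i in range(n_a):
        for j in range(n_b):
            cell[i, j] = y[(ai == i) & (bi == j)].mean()
    a_means = cell.mean(axis=1)
    b_means = cell.mean(axis=0)
    ss_a = n_b * n * np.sum((a_means - grand) ** 2)
    ss_b = n_a * n * np.sum((b_means - grand) ** 2)
    ss_cells = n * np.sum((cell - grand) ** 2)
    ss_ab = ss_cells - ss_a - ss_b
    fitted = cell[ai, bi]
    ss_e = np.sum((y - fitted) ** 2)
    df_a, df_b = n_a - 1, n_b - 1
    df_ab = df_a * df_b
    df_e = n_a * n_b * (n - 1)
    if df_e < 1:
        raise StatsError("insufficient residual degrees of freedom")
    ms_e = ss_e / df_e
    out = {}
    for eff, ss, df1 in (("A", ss_a, df_a), ("B", ss_b, df_b), ("A:B", ss_ab, df_ab)):
        if ms_e == 0:
            f = np.inf if ss > 0 else 0.0
            p = 0.0 if ss > 0 else 1.0
        else:
            f = (ss / df1) / ms_e
            p = float(sps.f.sf(f, df1, df_e))
        out[eff] = EffectTest(eff, max(float(f), 0.0), df1, df_e, p)
    return out


def art_anova(art: ArtTable) -> list[EffectTest]:
    """Two-way ANOVA on each effect's aligned-rank column.

    Each rank column gets the full factorial ANOVA but only the focal
    effect's F and p are reported, as in the standard ART procedure.
    Requires a balanced layout (equal cell sizes).
    """
    df = art.frame
    if not art.balanced:
        raise StatsError("art_anova requires a balanced layout")
    a_levels = np.sort(df[art.factor_a].unique())
    b_levels = np.sort(df[art.factor_b].unique())
    ai = np.searchsorted(a_levels, df[art.factor_a].to_numpy())
    bi = np.searchsorted(b_levels, df[art.factor_b].to_numpy())
    results = []
    for eff in EFFECTS:
        tests = _balanced_twoway_anova(
            df[f"rank_{eff}"].to_numpy(), ai, bi, len(a_levels), len(b_levels)
        )
        results.append(tests[eff])
    return results


# ---------------------------------------------------------------------------
# one-way chain: Kruskal-Wallis, Dunn, compact letters


def kruskal_wallis(*groups) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and chi-square p-value."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise StatsError("need >= 2 groups")
    if any(len(g) == 0 for g in arrays):
        raise StatsError("empty group")
    pooled = np.concatenate(arrays)
    if len(pooled) < 3:
        raise StatsError("need total n >= 3")
    if np.ptp(pooled) == 0:
        # all values tied: no separation, H = 0 by convention
        return 0.0, 1.0
    h, p = sps.kruskal(*arrays)
    return float(h), float(p)


@dataclass(frozen=True)
class PairwiseResult:
    level_i: object
    level_j: object
    z: float
    p_value: float
    p_adjusted: float
    significant: bool


def dunn_test(
    groups: dict,
    alpha: float = 0.05,
    adjustment: str = "none",
) -> list[PairwiseResult]:
    """Dunn's rank-based pairwise comparisons after Kruskal-Wallis.

    z_ij = (R̄_i − R̄_j) / sqrt([N(N+1)/12 − ΣT/(12(N−1))] (1/n_i + 1/n_j))

    with ΣT = Σ(t³ − t) over tie groups of the pooled ranks; two-sided
    normal p-values; ``adjustment`` in {"none", "bonferroni", "holm"}.
    """
    if adjustment not in ("none", "bonferroni", "holm"):
        raise StatsError(f"unknown adjustment: {adjustment}")
    names = list(groups)
    arrays = [np.asarray(groups[k], dtype=float) for k in names]
    if len(arrays) < 2:
        raise StatsError("need >= 2 groups")
    if any(len(g) == 0 for g in arrays):
        raise StatsError("empty group")
    pooled = np.concatenate(arrays)
    n_total = len(pooled)
    ranks = sps.rankdata(pooled, method="average")
    mean_ranks, sizes = [], []
    start = 0
    for g in arrays:
        mean_ranks.append(ranks[start:start + len(g)].mean())
        sizes.append(len(g))
        start += len(g)

    _, counts = np.unique(pooled, return_counts=True)
    tie_sum = float(np.sum(counts ** 3 - counts))
    var_core = n_total * (n_total + 1) / 12.0
    if n_total > 1:
        var_core -= tie_sum / (12.0 * (n_total - 1))

    pairs = list(itertools.combinations(range(len(names)), 2))
    zs, ps = [], []
    for i, j in pairs:
        se2 = var_core * (1.0 / sizes[i] + 1.0 / sizes[j])
        if se2 <= 0:
            z = 0.0  # every pooled value tied
        else:
            z = (mean_ranks[i] - mean_ranks[j]) / np.sqrt(se2)
        zs.append(z)
        ps.append(min(1.0, 2.0 * sps.norm.sf(abs(z))))

    if adjustment == "none" or not ps:
        adj = list(ps)
    else:
        adj = multipletests(ps, alpha=alpha, method=adjustment)[1].tolist()

    return [
        PairwiseResult(
            names[i], names[j], float(z), float(p), float(pa), bool(pa < alpha)
        )
        for (i, j), z, p, pa in zip(pairs, zs, ps, adj)
    ]


def letter_display(pairwise: list[PairwiseResult], levels=None) -> dict:
    """Compact letter display from pairwise significance flags.

    Two levels share at least one letter iff they are NOT significantly
    different (insert-and-absorb algorithm).  Deterministic: levels are
    processed in ascending sorted order.  Raises on a missing pair.
    """
    sig = {}
    seen = set()
    for r in pairwise:
        key = frozenset((r.level_i, r.level_j))
        sig[key] = r.significant
        seen.update((r.level_i, r.level_j))
    if levels is None:
        levels = sorted(seen)
    else:
        levels = sorted(levels)
    for a, b in itertools.combinations(levels, 2):
        if frozenset((a, b)) not in sig:
            raise StatsError(f"missing pairwise result for ({a}, {b})")

    if len(levels) == 1:
        return {levels[0]: {"a"}}

    # insert-and-absorb on sets of mutually non-different levels
    groups: list[set] = [set(levels)]
    for a, b in itertools.combinations(levels, 2):
        if not sig[frozenset((a, b))]:
            continue
        new_groups = []
        for g in groups:
            if a in g and b in g:
                new_groups.extend((g - {a}, g - {b}))
            else:
                new_groups.append(g)
        # absorb subsets, keep first occurrence order
        groups = []
        for g in sorted(new_groups, key=len, reverse=True):
            if g and not any(g <= kept for kept in groups):
                groups.append(g)
    # stable letter order: by smallest member then size
    groups.sort(key=lambda g: (sorted(g), -len(g)))
    letters = "abcdefghijklmnopqrstuvwxyz"
    out = {lv: set() for lv in levels}
    for letter, g in zip(letters, groups):
        for lv in g:
            out[lv].add(letter)
    return out
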