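"""Group-level inference over scalars and source maps.

Scalar measures (scores, subject-average spectral parameters) are compared
across diagnostic groups with an ANCOVA (value ~ group + age) and Tukey HSD
on covariate-adjusted values. Source-resolved measures (alpha relative
power, alpha peak frequency per source) are compared pairwise with
cluster-based permutation tests (CBPT): per-source F statistics from the
group+age linear model, supra-threshold sources joined into clusters by grid
adjacency, cluster mass tested against a permutation null of the maximum
cluster mass. With complete data the permutation scheme is Freedman-Lane
(permute residuals of the age-only model); with per-source missing entries
the test permutes group labels while keeping age attached to each subject.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import sparse, stats
from scipy.sparse.csgraph import connected_components
import statsmodels.api as sm
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .cohort import SourceGrid
from .errors import DegenerateModelError, ParameterError, StructuralError

__all__ = [
    "AncovaResult",
    "ClusterTestResult",
    "ancova_group_effect",
    "cluster_permutation_test",
    "run_contrast_battery",
]


@dataclass
class AncovaResult:
    f_stat: float
    p_value: float
    df: tuple[int, int]
    adjusted_means: dict[str, float]
    age_coefficient: float
    pairwise: dict[tuple[str, str], float]


@dataclass
class ClusterTestResult:
    """Clusters as (sorted source-index tuple, mass, p-value) triples."""

    clusters: list[tuple[tuple[int, ...], float, float]]
    sig_mask: np.ndarray
    n_permutations: int
    statistic_map: np.ndarray  # signed t per source (NaN where untested)
    seed: int | None
    tested_sources: np.ndarray  # indices that survived coverage filtering


def ancova_group_effect(values, groups, age) -> AncovaResult:
    """ANCOVA of a scalar on group with age as covariate.

    Fits value ~ group + age by OLS, tests the group factor with a partial F
    test, and (when the factor is significant at 0.05) runs Tukey HSD on
    age-adjusted values, i.e. the raw values minus the fitted age effect
    centred at the sample mean age.
    """
    y = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    a = np.asarray(age, dtype=float)
    if y.shape != g.shape or y.shape != a.shape:
        raise StructuralError("values, groups and age must have equal length")
    labels, counts = np.unique(g, return_counts=True)
    if labels.size < 2:
        raise ParameterError("need >= 2 groups")
    if counts.min() < 3:
        raise ParameterError(f"every group needs n >= 3, got {dict(zip(labels, counts))}")
    if np.ptp(y) == 0:
        raise DegenerateModelError("response is constant; ANCOVA is undefined")

    dummies = (g[:, None] == labels[None, 1:]).astype(float)  # first label is baseline
    x_full = np.column_stack([np.ones_like(y), dummies, a])
    x_red = np.column_stack([np.ones_like(y), a])
    full = sm.OLS(y, x_full).fit()
    red = sm.OLS(y, x_red).fit()
    df_num = labels.size - 1
    df_den = int(full.df_resid)
    f_stat = ((red.ssr - full.ssr) / df_num) / (full.ssr / df_den)
    p_value = float(stats.f.sf(f_stat, df_num, df_den))

    beta = full.params
    age_coef = float(beta[-1])
    mean_age = a.mean()
    adjusted = {str(labels[0]): float(beta[0] + age_coef * mean_age)}
    for j, lab in enumerate(labels[1:]):
        adjusted[str(lab)] = float(beta[0] + beta[1 + j] + age_coef * mean_age)

    pairwise: dict[tuple[str, str], float] = {}
    if p_value < 0.05:
        y_adj = y - age_coef * (a - mean_age)
        tk = pairwise_tukeyhsd(y_adj, g, alpha=0.05)
        i_idx, j_idx = tk._multicomp.pairindices
        for i, j, p in zip(i_idx, j_idx, tk.pvalues):
            pairwise[(str(tk.groupsunique[i]), str(tk.groupsunique[j]))] = float(p)
    return AncovaResult(
        f_stat=float(f_stat), p_value=p_value, df=(df_num, df_den),
        adjusted_means=adjusted, age_coefficient=age_coef, pairwise=pairwise,
    )


# ---------------------------------------------------------------------------
# cluster-based permutation machinery


def _design(group01: np.ndarray, age: np.ndarray | None) -> np.ndarray:
    cols = [np.ones_like(group01, dtype=float), group01.astype(float)]
    if age is not None:
        cols.append(np.asarray(age, dtype=float))
    return np.column_stack(cols)


def _tmap(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """t statistic of the group column (index 1) for every source column of y.

    ``y`` may be (n, S) for one design or (B, n, S) for a batch sharing x.
    """
    n, p = x.shape
    xtx_inv = np.linalg.inv(x.T @ x)
    a = xtx_inv @ x.T                      # (p, n)
    beta = np.einsum("pn,...ns->...ps", a, y)
    resid = y - np.einsum("np,...ps->...ns", x, beta)
    rss = np.einsum("...ns,...ns->...s", resid, resid)
    dof = n - p
    sigma2 = rss / dof
    denom = np.sqrt(np.maximum(xtx_inv[1, 1] * sigma2, 1e-300))
    return beta[..., 1, :] / denom


def _clusters_from_t(t: np.ndarray, t_crit: float,
                     adj: sparse.csr_matrix) -> list[tuple[np.ndarray, float]]:
    """Signed supra-threshold clusters; mass is the summed F (= t**2)."""
    out = []
    for sign in (1.0, -1.0):
        mask = (sign * t) > t_crit
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            continue
        if idx.size == 1:
            out.append((idx, float(t[idx[0]] ** 2)))
            continue
        sub = adj[idx][:, idx]
        n_comp, labels = connected_components(sub, directed=False)
        for c in range(n_comp):
            members = idx[labels == c]
            out.append((members, float((t[members] ** 2).sum())))
    return out


def _null_max_masses(t_batch: np.ndarray, t_crit: float,
                     adj: sparse.csr_matrix) -> np.ndarray:
    masses = np.zeros(t_batch.shape[0])
    for b in range(t_batch.shape[0]):
        cl = _clusters_from_t(t_batch[b], t_crit, adj)
        if cl:
            masses[b] = max(m for _, m in cl)
    return masses


def cluster_permutation_test(
    maps: np.ndarray,
    groups,
    age=None,
    grid: SourceGrid | None = None,
    n_perm: int = 2000,
    cluster_alpha: float = 0.05,
    alpha: float = 0.05,
    seed: int | None = 0,
    exact: bool = False,
    min_coverage: float = 0.8,
) -> ClusterTestResult:
    """Two-group cluster-based permutation test over a source grid.

    Parameters
    ----------
    maps
        (subjects x sources) measure matrix; NaN marks missing entries
        (e.g. sources where no alpha peak was fit for a subject).
    groups
        Per-subject labels with exactly two distinct values.
    age
        Optional per-subject covariate, always kept in the per-source model.
    grid
        Source grid supplying adjacency; its source count must match.
    exact
        Enumerate all distinct group-label assignments instead of Monte-Carlo
        sampling (only without a covariate, and only when the count of
        assignments is modest). Used as a small-sample oracle.
    min_coverage
        Sources observed in fewer than this fraction of subjects are
        excluded from testing.
    """
    maps = np.asarray(maps, dtype=float)
    g = np.asarray(groups)
    labels = np.unique(g)
    if labels.size != 2:
        raise ParameterError(f"need exactly 2 groups, got {labels.tolist()}")
    n, n_src = maps.shape
    counts = [(g == lab).sum() for lab in labels]
    if min(counts) < 5 and not exact:
        raise ParameterError(f"both groups need n >= 5, got {counts}")
    if grid is None or grid.n_sources != n_src:
        raise StructuralError("grid is required and must match the source dimension")

    group01 = (g == labels[1]).astype(float)
    age_arr = None if age is None else np.asarray(age, dtype=float)

    observed = ~np.isnan(maps)
    coverage = observed.mean(axis=0)
    tested = np.flatnonzero(coverage >= min_coverage)
    if tested.size == 0:
        return ClusterTestResult([], np.zeros(n_src, bool), n_perm,
                                 np.full(n_src, np.nan), seed, tested)
    sub_maps = maps[:, tested]
    adj = sparse.csr_matrix(grid.adjacency[np.ix_(tested, tested)])

    p_model = 3 if age_arr is not None else 2
    dof = n - p_model
    t_crit = float(stats.t.isf(cluster_alpha / 2.0, dof))

    complete = not np.isnan(sub_maps).any()
    x_full = _design(group01, age_arr)

    if complete:
        t_obs = _tmap(x_full, sub_maps)
    else:
        t_obs = _tmap_missing(x_full, sub_maps)

    obs_clusters = _clusters_from_t(t_obs, t_crit, adj)

    if exact:
        if age_arr is not None:
            raise ParameterError("exact enumeration is only supported without a covariate")
        n1 = int(group01.sum())
        total = comb(n, n1)
        if total > 200_000:
            raise ParameterError(f"{total} assignments is too many to enumerate")
        null = np.zeros(total)
        for b, chosen in enumerate(combinations(range(n), n1)):
            gperm = np.zeros(n)
            gperm[list(chosen)] = 1.0
            xb = _design(gperm, None)
            tb = (_tmap(xb, sub_maps) if complete else _tmap_missing(xb, sub_maps))
            cl = _clusters_from_t(tb, t_crit, adj)
            null[b] = max((m for _, m in cl), default=0.0)
        n_eff = total
        denom_count = total
        pvals = [(np.count_nonzero(null >= mass - 1e-12)) / denom_count
                 for _, mass in obs_clusters]
    else:
        rng = np.random.default_rng(seed)
        null = np.zeros(n_perm)
        if complete:
            # Freedman-Lane: permute residuals of the reduced (nuisance) model
            x_red = (np.column_stack([np.ones(n), age_arr])
                     if age_arr is not None else np.ones((n, 1)))
            hat = x_red @ np.linalg.inv(x_red.T @ x_red) @ x_red.T
            fitted = hat @ sub_maps
            resid = sub_maps - fitted
            chunk = max(1, int(2e7 // (n * tested.size + 1)))
            done = 0
            while done < n_perm:
                b = min(chunk, n_perm - done)
                perms = np.stack([rng.permutation(n) for _ in range(b)])
                y_star = fitted[None] + resid[perms]
                t_batch = _tmap(x_full, y_star)
                null[done:done + b] = _null_max_masses(t_batch, t_crit, adj)
                done += b
        else:
            for b in range(n_perm):
                perm = rng.permutation(n)
                xb = _design(group01[perm], age_arr)
                tb = _tmap_missing(xb, sub_maps)
                cl = _clusters_from_t(tb, t_crit, adj)
                null[b] = max((m for _, m in cl), default=0.0)
        n_eff = n_perm
        pvals = [(1 + np.count_nonzero(null >= mass - 1e-12)) / (n_perm + 1)
                 for _, mass in obs_clusters]

    clusters = []
    sig_mask = np.zeros(n_src, dtype=bool)
    for (members, mass), p in zip(obs_clusters, pvals):
        global_members = tuple(int(tested[m]) for m in members)
        clusters.append((global_members, mass, float(p)))
        if p <= alpha:
            sig_mask[list(global_members)] = True
    clusters.sort(key=lambda c: c[2])

    stat_map = np.full(n_src, np.nan)
    stat_map[tested] = t_obs
    return ClusterTestResult(
        clusters=clusters, sig_mask=sig_mask, n_permutations=n_eff,
        statistic_map=stat_map, seed=seed, tested_sources=tested,
    )


def _tmap_missing(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per-source t of the group column with per-source subject exclusion.

    Sources sharing a missingness pattern are solved together.
    """
    n, n_src = y.shape
    out = np.full(n_src, np.nan)
    observed = ~np.isnan(y)
    patterns: dict[bytes, list[int]] = {}
    for s in range(n_src):
        patterns.setdefault(observed[:, s].tobytes(), []).append(s)
    for key, cols in patterns.items():
        keep = np.frombuffer(key, dtype=bool)
        if keep.sum() <= x.shape[1] + 1:
            continue
        xs = x[keep]
        if np.ptp(xs[:, 1]) == 0:  # one group fully missing here
            continue
        out[cols] = _tmap(xs, y[np.ix_(keep, cols)])
    return out


def run_contrast_battery(
    maps: np.ndarray,
    groups,
    age,
    grid: SourceGrid,
    contrasts: list[tuple[str, str]],
    n_perm: int = 2000,
    cluster_alpha: float = 0.05,
    alpha: float = 0.05,
    seed: int | None = 0,
    min_coverage: float = 0.8,
) -> dict[tuple[str, str], ClusterTestResult]:
    """Run one cluster permutation test per group pair on a measure matrix."""
    g = np.asarray(groups)
    age = np.asarray(age, dtype=float)
    present = set(np.unique(g).tolist())
    results: dict[tuple[str, str], ClusterTestResult] = {}
    rng = np.random.default_rng(seed)
    for pair in contrasts:
        a_lab, b_lab = pair
        for lab in pair:
            if lab not in present:
                raise ParameterError(f"unknown group label {lab!r}")
        sel = np.isin(g, list(pair))
        results[pair] = cluster_permutation_test(
            maps[sel], g[sel], age[sel], grid,
            n_perm=n_perm, cluster_alpha=cluster_alpha, alpha=alpha,
            seed=int(rng.integers(2**31)), min_coverage=min_coverage,
        )
    return results
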