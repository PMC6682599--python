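"""Stage-group definition and permutation-based differential abundance.

Sample locations are grouped from the data itself: PCA for inspection and
agglomerative clustering of locations on Euclidean distance, cut at *k*
clusters.  Clusters are named after the majority a-priori stage label of
their members (Secretion, Maturation, DEJ, Cuspal, NonEnamel).  Per-protein
differential abundance across the named enamel groups is then assessed by a
non-parametric one-way ANOVA: the observed F statistic is compared with its
permutation null obtained by uniformly shuffling group labels (exhaustive
enumeration whenever the number of distinct label arrangements is no larger
than the requested permutation count), and the Benjamini–Hochberg step-up
procedure controls the false discovery rate across proteins.  Significant
proteins receive a per-group higher/lower direction from cluster means, and
groups can be pre-filtered by dropping their least abundant proteins
(lowest decile by default) before over-representation analysis against a
user-supplied annotation table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import hypergeom
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests
from sympy.utilities.iterables import multiset_permutations

from .errors import ValidationError

GROUP_NAMES = ("DEJ", "Secretion", "Maturation", "Cuspal", "NonEnamel")

STAGE_TO_GROUP = {
    "secretory": "Secretion",
    "early_maturation": "Maturation",
    "late_maturation": "Maturation",
    "erupted": "Cuspal",
    "DEJ": "DEJ",
    "dentin": "NonEnamel",
    "bone": "NonEnamel",
}

# tie-break order for majority voting: earlier developmental stage wins
_STAGE_ORDER = ("secretory", "early_maturation", "late_maturation",
                "erupted", "DEJ", "dentin", "bone")


@dataclass
class GroupAssignment:
    """Location -> cluster mapping with named groups and the merge tree."""

    labels: dict  # location_id -> cluster index (1-based)
    group_names: dict  # cluster index -> name from GROUP_NAMES
    linkage_matrix: np.ndarray
    locations: list

    def group_of(self, location_id):
        return self.group_names[self.labels[location_id]]

    def members(self, name):
        return [loc for loc in self.locations if self.group_of(loc) == name]


@dataclass
class DiffAbundanceResult:
    protein: str
    statistic: float
    p_value: float
    q_value: float
    group_means: dict
    direction: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# missing-value policy


def complete_matrix(matrix, policy="zero"):
    """Make an abundance matrix complete for PCA/clustering/testing.

    ``zero`` (default) imputes missing cells as 0 — on the percent scale a
    missing cell means "not detected", so zero abundance is the natural
    fill; ``drop`` deletes rows with any missing cell instead.  Returns
    ``(DataFrame, audit dict)``.
    """
    df = matrix if isinstance(matrix, pd.DataFrame) else matrix.values
    if policy == "zero":
        n = int(df.isna().sum().sum())
        return df.fillna(0.0), {"imputed_zero_cells": n}
    if policy == "drop":
        keep = df.notna().all(axis=1)
        return df.loc[keep], {"dropped_incomplete_rows": int((~keep).sum())}
    raise ValidationError(f"unknown missing-value policy {policy!r}")


# ---------------------------------------------------------------------------
# PCA and clustering of locations


def pca_locations(df, n_components=None):
    """PCA of locations (observations) over protein abundances (features).

    Column-centered; components ordered by decreasing variance; the sign of
    each component is fixed so its largest-magnitude loading is positive.
    Returns ``(scores DataFrame, explained-variance fractions array)``.
    """
    X = np.asarray(df, dtype=float).T  # locations x proteins
    n_loc = X.shape[0]
    if n_loc < 2:
        raise ValidationError("PCA needs at least 2 locations")
    if n_components is None:
        n_components = min(n_loc - 1, X.shape[1])
    centered = X - X.mean(axis=0)
    if np.allclose(centered, 0.0):
        scores = np.zeros((n_loc, n_components))
        frac = np.zeros(n_components)
    else:
        model = PCA(n_components=n_components, svd_solver="full")
        scores = model.fit_transform(X)
        for i, comp in enumerate(model.components_):
            j = int(np.argmax(np.abs(comp)))
            if comp[j] < 0:
                scores[:, i] *= -1.0
        frac = model.explained_variance_ratio_
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return pd.DataFrame(scores, index=list(df.columns), columns=cols), np.asarray(frac)


def hcluster_locations(df, grid, k, linkage_method="average", metric="euclidean"):
    """Agglomerative clustering of locations, cut at *k* clusters.

    The merge tree is deterministic for fixed input; named groups come from
    the majority a-priori stage label of each cluster's members, ties broken
    toward the earlier developmental stage.
    """
    locations = list(df.columns)
    n = len(locations)
    if not 1 <= k <= n:
        raise ValidationError(f"k={k} outside [1, {n}]")
    if linkage_method not in ("single", "complete", "average", "ward"):
        raise ValidationError(f"unsupported linkage method {linkage_method!r}")
    X = np.asarray(df, dtype=float).T
    Z = linkage(X, method=linkage_method, metric=metric)
    flat = fcluster(Z, t=k, criterion="maxclust")
    labels = dict(zip(locations, (int(c) for c in flat)))

    stage_of = {b.location_id: b.stage for b in grid}
    group_names = {}
    for c in sorted(set(labels.values())):
        members = [loc for loc in locations if labels[loc] == c]
        counts = {}
        for loc in members:
            s = stage_of[loc]
            counts[s] = counts.get(s, 0) + 1
        best = min(counts, key=lambda s: (-counts[s], _STAGE_ORDER.index(s)))
        group_names[c] = STAGE_TO_GROUP[best]
    return GroupAssignment(labels, group_names, Z, locations)


# ---------------------------------------------------------------------------
# permutation ANOVA


def _f_statistic(values, group_index, k, counts):
    """One-way F for rows of *values* (..., n) under fixed group indexing.

    Degenerate conventions: zero within-group variance with nonzero
    between-group variance -> +inf; all values identical -> 0.
    """
    values = np.atleast_2d(values)
    n = values.shape[-1]
    grand = values.mean(axis=-1, keepdims=True)
    ssb = np.zeros(values.shape[0])
    ssw = np.zeros(values.shape[0])
    for g in range(k):
        sub = values[:, group_index == g]
        m = sub.mean(axis=-1, keepdims=True)
        ssb += counts[g] * ((m - grand) ** 2).ravel()
        ssw += ((sub - m) ** 2).sum(axis=-1)
    msb = ssb / (k - 1)
    msw = ssw / (n - k)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = msb / msw
    f = np.where(ssw > 0, f, np.where(ssb > 0, np.inf, 0.0))
    return f


def _n_arrangements(counts):
    n = sum(counts)
    total = math.factorial(n)
    for c in counts:
        total //= math.factorial(c)
    return total


def permutation_anova(values, groups, n_permutations=4999, seed=None):
    """Permutation one-way ANOVA for a single protein.

    *values* and *groups* are parallel sequences over tested locations.  The
    null is built by uniformly permuting group labels; when the number of
    distinct label arrangements is at most ``n_permutations`` the null is
    enumerated exhaustively (p = #{F_perm >= F_obs} / #arrangements,
    including the observed arrangement), otherwise ``n_permutations`` random
    permutations are drawn and p = (1 + #{F_perm >= F_obs}) /
    (1 + n_permutations).  Returns ``(F, p)``.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape:
        raise ValidationError("values and groups must be parallel")
    if np.isnan(values).any():
        raise ValidationError("permutation_anova requires complete values")
    uniq, group_index = np.unique(groups, return_inverse=True)
    k = len(uniq)
    counts = np.bincount(group_index)
    if k < 2:
        raise ValidationError("need at least 2 groups")
    if (counts < 2).any():
        small = [str(uniq[i]) for i in np.flatnonzero(counts < 2)]
        raise ValidationError(f"group(s) with fewer than 2 members: {small}")

    obs = float(_f_statistic(values, group_index, k, counts)[0])
    tol = 1e-9 * (abs(obs) + 1.0) if np.isfinite(obs) else 0.0

    total = _n_arrangements(counts.tolist())
    if total <= n_permutations:
        hits = 0
        for arrangement in multiset_permutations(group_index.tolist()):
            f = float(_f_statistic(values, np.asarray(arrangement), k, counts)[0])
            if f >= obs - tol:
                hits += 1
        return obs, hits / total

    rng = np.random.default_rng(seed)
    n = len(values)
    perm_idx = np.argsort(rng.random((n_permutations, n)), axis=1)
    perm_values = values[perm_idx]  # permuting values == permuting labels
    f_null = _f_statistic(perm_values, group_index, k, counts)
    hits = int(np.sum(f_null >= obs - tol))
    return obs, (1 + hits) / (1 + n_permutations)


def bh_adjust(p_values, alpha=0.05):
    """Benjamini–Hochberg step-up adjustment.

    Returns ``(q_values, rejection flags)``; q-values are monotone-enforced.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size and ((p <= 0) | (p > 1)).any():
        raise ValidationError("p-values must lie in (0, 1]")
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    reject, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return q, reject


def assign_direction(values, groups, rtol=1e-12):
    """Per named group: higher/lower than the pooled mean of the other
    groups' values; ties are neutral."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    out = {}
    for g in np.unique(groups):
        inside = values[groups == g].mean()
        outside = values[groups != g].mean()
        if np.isclose(inside, outside, rtol=rtol, atol=0.0):
            out[str(g)] = "neutral"
        else:
            out[str(g)] = "higher" if inside > outside else "lower"
    return out


def differential_abundance(df, assignment, n_permutations=4999, seed=None,
                           alpha=0.05, exclude_groups=("NonEnamel",)):
    """Per-protein permutation ANOVA across named location groups with BH-FDR.

    *df* is a complete proteins x locations DataFrame (apply
    :func:`complete_matrix` first).  Groups named in ``exclude_groups`` and
    groups with fewer than 2 member locations are left out of the test.
    Returns a DataFrame sorted by q-value, one row per protein, with the
    direction pattern filled in for BH-significant proteins.
    """
    group_of = {loc: assignment.group_of(loc) for loc in assignment.locations}
    tested_locs = [loc for loc in df.columns
                   if group_of.get(loc) not in (None, *exclude_groups)]
    groups = np.asarray([group_of[loc] for loc in tested_locs])
    uniq, counts = np.unique(groups, return_counts=True)
    keep_groups = set(uniq[counts >= 2])
    tested_locs = [loc for loc in tested_locs if group_of[loc] in keep_groups]
    groups = np.asarray([group_of[loc] for loc in tested_locs])
    if len(set(groups)) < 2:
        raise ValidationError("fewer than 2 usable groups for testing")

    sub = df[tested_locs]
    rng = np.random.default_rng(seed)
    rows = []
    for prot in sub.index:
        vals = sub.loc[prot].to_numpy(dtype=float)
        child = int(rng.integers(0, 2**31 - 1))
        stat, p = permutation_anova(vals, groups, n_permutations, seed=child)
        means = {g: float(vals[groups == g].mean()) for g in sorted(set(groups))}
        rows.append({"protein": prot, "statistic": stat, "p_value": p,
                     "group_means": means, "values": vals})

    q, reject = bh_adjust([r["p_value"] for r in rows], alpha=alpha)
    results = []
    for r, qv, rej in zip(rows, q, reject):
        direction = (assign_direction(r["values"], groups) if rej
                     else {g: "neutral" for g in sorted(set(groups))})
        results.append({"protein": r["protein"], "statistic": r["statistic"],
                        "p_value": r["p_value"], "q_value": float(qv),
                        "significant": bool(rej),
                        **{f"mean_{g}": m for g, m in r["group_means"].items()},
                        **{f"direction_{g}": d for g, d in direction.items()}})
    out = pd.DataFrame(results).sort_values("q_value", kind="stable")
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# abundance pre-filter and over-representation


def percentile_filter(group_means, percentile=10):
    """Drop a group's least abundant proteins: the lowest ``percentile``
    of group-mean abundance under the nearest-rank convention.

    With k = ceil(percentile * n / 100), the cutoff is the (k+1)-th smallest
    mean and proteins strictly below it are removed — exactly k proteins
    when all means are distinct, none when all are equal (ties at the cutoff
    are retained).  Accepts and returns a pandas Series (protein -> mean).
    """
    s = pd.Series(group_means, dtype=float)
    n = len(s)
    if n == 0:
        return s
    k = math.ceil(percentile * n / 100.0)
    ordered = np.sort(s.to_numpy())
    if k >= n:
        return s.iloc[0:0]
    cutoff = ordered[k]  # (k+1)-th smallest
    return s[s >= cutoff]


def over_representation(gene_set, annotations, background, alpha=0.05,
                        min_hits=2):
    """One-sided hypergeometric over-representation per annotation term.

    *annotations* is a two-column DataFrame (identifier, term) or a mapping
    term -> iterable of identifiers; *background* the reference identifier
    set.  Genes absent from the background are ignored and counted in the
    audit.  Terms with fewer than ``min_hits`` genes from the set are
    skipped.  Returns ``(DataFrame, audit dict)``.
    """
    if isinstance(annotations, pd.DataFrame):
        id_col, term_col = annotations.columns[:2]
        term_map = {}
        for ident, term in zip(annotations[id_col], annotations[term_col]):
            term_map.setdefault(term, set()).add(ident)
    else:
        term_map = {t: set(g) for t, g in annotations.items()}

    background = set(background)
    gene_set = set(gene_set)
    unknown = sorted(gene_set - background)
    genes = gene_set & background
    M, N = len(background), len(genes)

    rows = []
    for term in sorted(term_map):
        members = term_map[term] & background
        K = len(members)
        k = len(members & genes)
        if k < min_hits or K == 0:
            continue
        p = float(hypergeom.sf(k - 1, M, K, N))
        fold = (k / N) / (K / M) if N else float("nan")
        rows.append({"term": term, "hits": k, "set_size": N,
                     "term_size": K, "background_size": M,
                     "fold_enrichment": fold, "p_value": min(max(p, 1e-300), 1.0)})
    df = pd.DataFrame(rows, columns=["term", "hits", "set_size", "term_size",
                                     "background_size", "fold_enrichment",
                                     "p_value"])
    if len(df):
        q, reject = bh_adjust(df["p_value"].to_numpy(), alpha=alpha)
        df["q_value"], df["significant"] = q, reject
        df = df.sort_values("p_value", kind="stable").reset_index(drop=True)
    else:
        df["q_value"], df["significant"] = pd.Series(dtype=float), pd.Series(dtype=bool)
    return df, {"genes_absent_from_background": unknown}
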