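"""Diversity metrics and permutation inference, implemented from definitions.

This module is the statistical toolbox of the pipeline: rarefaction to a
common depth, Good's coverage, alpha diversity (observed ASVs, Shannon in
bits, Simpson, Faith's phylogenetic diversity), Bray-Curtis dissimilarity,
principal coordinates analysis, PERMANOVA (omnibus, strata-restricted and
pairwise with FDR correction), the Kruskal–Wallis and Wilcoxon rank-sum
tests, and Benjamini–Hochberg adjustment.

Every test statistic and permutation scheme is computed here from its
definition rather than delegated, so the inference is fully transparent;
the test suite cross-checks each against an independent implementation.

Conventions
-----------
* Shannon entropy uses log base 2 (bits), matching the convention of the
  amplicon-analysis platforms this pipeline mirrors.
* Permutation p-values use the (b + 1) / (m + 1) estimator so that p is
  never exactly zero.
* Faith's PD includes the branch path from the observed tips up to the
  root by default; a crown-group variant is available.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import chi2, rankdata
from skbio import DistanceMatrix, TreeNode

from .containers import ASVTable, ValidationError

__all__ = [
    "rarefy",
    "goods_coverage",
    "remove_singletons",
    "alpha_diversity",
    "alpha_table",
    "faith_pd",
    "bray_curtis",
    "pcoa",
    "OrdinationResult",
    "permanova",
    "pairwise_permanova",
    "PermanovaResult",
    "kruskal_wallis",
    "wilcoxon_rank_sum",
    "bh_adjust",
]


# ---------------------------------------------------------------------------
# Rarefaction and coverage
# ---------------------------------------------------------------------------

def rarefy(table: ASVTable, depth: int | str = "min", seed: int = 0) -> ASVTable:
    """Subsample every sample without replacement to a common depth.

    ``depth="min"`` resolves to the smallest library size, the choice that
    keeps every sample in the analysis. Each rarefied sample is a single
    multivariate-hypergeometric draw from its reads (one draw, not an
    average over draws), deterministic given ``seed``.
    """
    counts = table.counts.to_numpy(dtype=np.int64)
    totals = counts.sum(axis=1)
    if depth == "min":
        depth = int(totals.min())
    depth = int(depth)
    if depth < 1:
        raise ValidationError("rarefaction depth must be positive")
    low = [sid for sid, t in zip(table.sample_ids, totals) if t < depth]
    if low:
        raise ValidationError(
            f"samples shallower than depth {depth}: " + ", ".join(low)
        )
    rng = np.random.default_rng(seed)
    out = np.empty_like(counts)
    for i, row in enumerate(counts):
        out[i] = rng.multivariate_hypergeometric(row, depth)
    rarefied = pd.DataFrame(out, index=table.counts.index, columns=table.counts.columns)
    return table.with_counts(rarefied)


def goods_coverage(counts) -> float:
    """Good's coverage 1 - F1/N: estimated fraction of the community seen.

    F1 is the number of ASVs observed exactly once and N the total reads in
    the sample.
    """
    x = np.asarray(counts)
    if x.size == 0 or x.sum() == 0:
        raise ValidationError("cannot compute coverage of an empty sample")
    if np.any(x < 0):
        raise ValidationError("negative counts")
    n_singletons = int(np.count_nonzero(x == 1))
    return 1.0 - n_singletons / float(x.sum())


def remove_singletons(table: ASVTable) -> ASVTable:
    """Drop ASVs whose total count across all samples is exactly 1."""
    totals = table.counts.sum(axis=0)
    keep = totals[totals != 1].index
    return table.with_counts(table.counts[keep].copy())


# ---------------------------------------------------------------------------
# Alpha diversity
# ---------------------------------------------------------------------------

def _proportions(counts: np.ndarray) -> np.ndarray:
    total = counts.sum()
    if total <= 0:
        raise ValidationError("sample has no reads")
    return counts[counts > 0] / total


def faith_pd(
    counts,
    taxa: list[str],
    tree: TreeNode,
    include_root: bool = True,
) -> float:
    """Faith's phylogenetic diversity of the taxa observed in a sample.

    Sum of branch lengths of the minimal subtree spanning the observed tips
    and (by default) the root. With ``include_root=False`` only the crown
    group below the observed tips' last common ancestor is counted.
    """
    x = np.asarray(counts)
    observed = {t for t, c in zip(taxa, x) if c > 0}
    if not observed:
        return 0.0
    tip_names = {tip.name for tip in tree.tips()}
    missing = sorted(observed - tip_names)
    if missing:
        raise ValidationError("tips absent from tree: " + ", ".join(missing))
    if include_root:
        top = tree
    else:
        obs = sorted(observed)
        top = tree.lca(obs) if len(obs) > 1 else tree.find(obs[0])
    total = 0.0
    for node in top.postorder(include_self=False):
        covered = getattr(node, "_phyllo_covered", None)
        if node.is_tip():
            covered = node.name in observed
        else:
            covered = any(
                getattr(c, "_phyllo_covered", False) for c in node.children
            )
        node._phyllo_covered = covered
        if covered and node.length:
            total += node.length
    for node in top.postorder(include_self=True):
        if hasattr(node, "_phyllo_covered"):
            del node._phyllo_covered
    return total


def alpha_diversity(counts, metric: str, taxa=None, tree: TreeNode | None = None):
    """Single-sample alpha diversity.

    Metrics: ``observed`` (#taxa with count > 0), ``shannon``
    (−Σ p log2 p, bits), ``simpson`` (1 − Σ p², the Gini–Simpson index)
    and ``faith_pd`` (requires ``taxa`` and ``tree``).
    """
    x = np.asarray(counts, dtype=float)
    if np.any(x < 0):
        raise ValidationError("negative counts")
    if metric == "observed":
        return int(np.count_nonzero(x > 0))
    if metric == "shannon":
        p = _proportions(x)
        return float(-(p * np.log2(p)).sum())
    if metric == "simpson":
        p = _proportions(x)
        return float(1.0 - (p * p).sum())
    if metric == "faith_pd":
        if taxa is None or tree is None:
            raise ValidationError("faith_pd requires taxa ids and a tree")
        return faith_pd(x, list(taxa), tree)
    raise ValueError(f"unknown alpha metric: {metric!r}")


def alpha_table(table: ASVTable, tree: TreeNode | None = None) -> pd.DataFrame:
    """Per-sample alpha-diversity records (one row per sample)."""
    metrics = ["observed", "shannon", "simpson"] + (
        ["faith_pd"] if tree is not None else []
    )
    records = {}
    taxa = table.asv_ids
    for sid in table.sample_ids:
        row = table.counts.loc[sid].to_numpy()
        records[sid] = {
            m: alpha_diversity(row, m, taxa=taxa, tree=tree) for m in metrics
        }
    out = pd.DataFrame.from_dict(records, orient="index")
    out.index.name = "sample_id"
    return out.join(table.metadata)


# ---------------------------------------------------------------------------
# Beta diversity and ordination
# ---------------------------------------------------------------------------

def bray_curtis(table: ASVTable) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity: Σ|x−y| / Σ(x+y)."""
    X = table.counts.to_numpy(dtype=float)
    if np.any(X.sum(axis=1) == 0):
        zero = [s for s, t in zip(table.sample_ids, X.sum(axis=1)) if t == 0]
        raise ValidationError("all-zero samples: " + ", ".join(zero))
    condensed = pdist(X, metric="braycurtis")
    return DistanceMatrix(squareform(condensed), ids=table.sample_ids)


@dataclass
class OrdinationResult:
    """PCoA output: sample coordinates on the positive-eigenvalue axes."""

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray


def pcoa(dm: DistanceMatrix, correction: str | None = None) -> OrdinationResult:
    """Classical scaling (principal coordinates) of a dissimilarity matrix.

    Double-centres −½ D², eigendecomposes the Gower matrix and scales the
    eigenvectors by √λ, descending. Negative eigenvalues are reported but
    excluded from the coordinates and the proportions explained;
    ``correction="lingoes"`` adds the constant that makes all eigenvalues
    non-negative before decomposition.
    """
    D = np.asarray(dm.data, dtype=float)
    if not np.allclose(D, D.T):
        raise ValidationError("distance matrix must be symmetric")
    n = D.shape[0]
    D2 = D**2
    if correction == "lingoes":
        # Lingoes: add 2c to off-diagonal squared distances, c = -lambda_min
        lam_min = np.linalg.eigvalsh(_gower(D2)).min()
        if lam_min < 0:
            D2 = D2 - 2.0 * lam_min * (1.0 - np.eye(n))
    elif correction is not None:
        raise ValueError(f"unknown correction: {correction!r}")
    B = _gower(D2)
    eigvals, eigvecs = np.linalg.eigh(B)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(abs(eigvals[0]), 1.0) * 1e-10
    pos = eigvals > tol
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    axes = [f"PC{i + 1}" for i in range(int(pos.sum()))]
    return OrdinationResult(
        coordinates=pd.DataFrame(coords, index=list(dm.ids), columns=axes),
        eigenvalues=eigvals,
        proportion_explained=eigvals[pos] / eigvals[pos].sum(),
    )


def _gower(D2: np.ndarray) -> np.ndarray:
    n = D2.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * J @ D2 @ J


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

@dataclass
class PermanovaResult:
    pseudo_F: float
    R2: float
    p_value: float
    n_permutations: int
    seed: int


def _as_labels(grouping, ids) -> np.ndarray:
    if isinstance(grouping, pd.Series):
        return grouping.loc[list(ids)].to_numpy()
    if isinstance(grouping, dict):
        return np.asarray([grouping[i] for i in ids])
    arr = np.asarray(grouping)
    if arr.shape[0] != len(ids):
        raise ValidationError("grouping length does not match distance matrix")
    return arr


def _pseudo_f(D2: np.ndarray, codes: np.ndarray, group_index: list[np.ndarray]):
    """Distance-based one-way pseudo-F from within/between squared distances."""
    N = len(codes)
    a = len(group_index)
    ss_total = D2.sum() / (2.0 * N)
    ss_within = 0.0
    for idx in group_index:
        sub = D2[np.ix_(idx, idx)]
        ss_within += sub.sum() / (2.0 * idx.size)
    ss_between = ss_total - ss_within
    if ss_within <= 0:
        f = np.inf if ss_between > 0 else 0.0
    else:
        f = (ss_between / (a - 1)) / (ss_within / (N - a))
    r2 = ss_between / ss_total if ss_total > 0 else 0.0
    return f, r2


def _distinct_assignments(codes: np.ndarray) -> int:
    """Number of distinct label assignments (multiset permutations)."""
    from math import factorial

    n = len(codes)
    total = factorial(n)
    for c in np.bincount(codes):
        total //= factorial(c)
    return total


def permanova(
    dm: DistanceMatrix,
    grouping,
    n_permutations: int = 999,
    seed: int = 0,
    strata=None,
    method: str = "sampled",
) -> PermanovaResult:
    """Permutational multivariate ANOVA on a distance matrix.

    The pseudo-F compares between- to within-group mean squared distances;
    significance comes from shuffling group labels (within strata when
    given, e.g. restricting permutations to within sampling years).

    ``method="sampled"`` draws ``n_permutations`` random label shuffles and
    reports p = (b + 1) / (m + 1) where b counts permuted F ≥ observed F.
    ``method="exact"`` enumerates every distinct label assignment, removing
    Monte-Carlo noise — essential for tiny groups, where the attainable p
    floor (e.g. 2/70 for two groups of four) sits close to the decision
    threshold. ``method="auto"`` uses the exact test whenever the number of
    distinct assignments is at most ``n_permutations`` (strata permitting).
    """
    ids = list(dm.ids)
    labels = _as_labels(grouping, ids)
    uniq, codes = np.unique(labels, return_inverse=True)
    if len(uniq) < 2:
        raise ValidationError("PERMANOVA needs at least two groups")
    sizes = np.bincount(codes)
    if sizes.min() < 2:
        small = [str(uniq[g]) for g in np.flatnonzero(sizes < 2)]
        raise ValidationError("groups with a single sample: " + ", ".join(small))

    D2 = np.asarray(dm.data, dtype=float) ** 2
    n = len(ids)

    def group_index(c):
        return [np.flatnonzero(c == g) for g in range(len(uniq))]

    f_obs, r2 = _pseudo_f(D2, codes, group_index(codes))

    if method not in ("sampled", "exact", "auto"):
        raise ValueError(f"unknown method: {method!r}")
    use_exact = False
    if method in ("exact", "auto") and strata is None:
        n_distinct = _distinct_assignments(codes)
        use_exact = method == "exact" or n_distinct <= n_permutations
        if method == "exact" and n_distinct > 500_000:
            raise ValidationError(
                f"{n_distinct} distinct assignments: too many to enumerate"
            )
    elif method == "exact":
        raise ValidationError("exact enumeration does not support strata")

    if use_exact:
        from sympy.utilities.iterables import multiset_permutations

        b = 0
        m = 0
        for arrangement in multiset_permutations(list(codes)):
            perm = np.asarray(arrangement)
            f_perm, _ = _pseudo_f(D2, perm, group_index(perm))
            m += 1
            if f_perm >= f_obs:
                b += 1
        # observed assignment is one of the enumerated ones, so p = b / m
        return PermanovaResult(
            pseudo_F=float(f_obs),
            R2=float(r2),
            p_value=b / m,
            n_permutations=m - 1,
            seed=seed,
        )

    if strata is not None:
        strata_labels = _as_labels(strata, ids)
        blocks = [np.flatnonzero(strata_labels == s) for s in np.unique(strata_labels)]
    else:
        blocks = [np.arange(n)]

    rng = np.random.default_rng(seed)
    b = 0
    perm = codes.copy()
    for _ in range(n_permutations):
        for blk in blocks:
            perm[blk] = codes[blk][rng.permutation(blk.size)]
        f_perm, _ = _pseudo_f(D2, perm, group_index(perm))
        if f_perm >= f_obs:
            b += 1
    return PermanovaResult(
        pseudo_F=float(f_obs),
        R2=float(r2),
        p_value=(b + 1) / (n_permutations + 1),
        n_permutations=n_permutations,
        seed=seed,
    )


def pairwise_permanova(
    dm: DistanceMatrix,
    grouping,
    n_permutations: int = 999,
    seed: int = 0,
    method: str = "auto",
) -> pd.DataFrame:
    """One PERMANOVA per group pair, with BH adjustment across the pairs.

    Pairs are tested exactly (full enumeration) whenever the pair is small
    enough — the usual case for replicate-level designs, where the p floor
    of a sampled test would otherwise wobble around the FDR threshold.
    """
    ids = np.asarray(dm.ids)
    labels = _as_labels(grouping, ids)
    uniq = list(pd.unique(labels))
    if len(uniq) < 2:
        raise ValidationError("need at least two groups")
    rows = []
    raw = []
    for i in range(len(uniq)):
        for j in range(i + 1, len(uniq)):
            sel = np.isin(labels, [uniq[i], uniq[j]])
            sub = dm.filter(ids[sel])
            res = permanova(
                sub,
                labels[sel],
                n_permutations=n_permutations,
                seed=seed + i * len(uniq) + j,
                method=method,
            )
            rows.append(
                {
                    "group_a": uniq[i],
                    "group_b": uniq[j],
                    "pseudo_F": res.pseudo_F,
                    "R2": res.R2,
                    "p_value": res.p_value,
                }
            )
            raw.append(res.p_value)
    out = pd.DataFrame(rows)
    out["p_adjusted"] = bh_adjust(raw)
    return out


# ---------------------------------------------------------------------------
# Rank tests
# ---------------------------------------------------------------------------

def kruskal_wallis(groups, n_permutations: int | None = None, seed: int = 0):
    """Kruskal–Wallis H with average-rank tie correction.

    Returns (H, p) with p from the chi-square reference (a − 1 df). When
    ``n_permutations`` is given, p is instead estimated by shuffling the
    pooled observations over the group layout.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size == 0 for g in groups):
        raise ValidationError("need >= 2 non-empty groups")
    pooled = np.concatenate(groups)
    N = pooled.size
    sizes = np.array([g.size for g in groups])

    def h_stat(pooled_vals):
        ranks = rankdata(pooled_vals)
        h = 0.0
        start = 0
        for n_g in sizes:
            rbar = ranks[start : start + n_g].mean()
            h += n_g * (rbar - (N + 1) / 2.0) ** 2
            start += n_g
        h *= 12.0 / (N * (N + 1))
        _, t = np.unique(pooled_vals, return_counts=True)
        denom = 1.0 - (t**3 - t).sum() / (N**3 - N)
        if denom <= 0:  # every observation identical
            return 0.0
        return h / denom

    H = h_stat(pooled)
    if H == 0.0 and np.unique(pooled).size == 1:
        return 0.0, 1.0
    if n_permutations is None:
        return float(H), float(chi2.sf(H, len(groups) - 1))
    rng = np.random.default_rng(seed)
    b = sum(
        h_stat(pooled[rng.permutation(N)]) >= H for _ in range(n_permutations)
    )
    return float(H), (b + 1) / (n_permutations + 1)


def _u_exact_counts(n1: int, n2: int) -> np.ndarray:
    """Counts of sequences by Mann–Whitney U, via a prefix DP.

    Processing pooled ranks left to right, placing a y after k x's adds k
    to U(x beats y); dp[k, u] counts prefixes with k x's and statistic u.
    """
    max_u = n1 * n2
    dp = np.zeros((n1 + 1, max_u + 1), dtype=float)
    dp[0, 0] = 1.0
    for t in range(1, n1 + n2 + 1):
        new = np.zeros_like(dp)
        for k in range(min(t, n1) + 1):
            n_y = t - k
            if n_y > n2:
                continue
            # place an x at position t
            if k >= 1:
                new[k] += dp[k - 1]
            # place a y: every x already placed beats it (+k to U)
            if n_y >= 1 and k <= n1:
                new[k, k:] += dp[k, : max_u + 1 - k]
        dp = new
    return dp[n1]


def wilcoxon_rank_sum(x, y):
    """Two-sided Wilcoxon rank-sum / Mann–Whitney test.

    Returns (U, p) where U counts pairs with x > y (+ half the ties). The
    p-value is exact (full null distribution) when both samples have ≤ 10
    observations and the pooled data are tie-free; otherwise a normal
    approximation with tie correction and continuity correction is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    w_x = ranks[:n1].sum()
    u = w_x - n1 * (n1 + 1) / 2.0

    has_ties = np.unique(pooled).size < pooled.size
    if n1 <= 10 and n2 <= 10 and not has_ties:
        counts = _u_exact_counts(n1, n2)
        total = comb(n1 + n2, n1)
        k = int(round(u))
        p_le = counts[: k + 1].sum() / total
        p_ge = counts[k:].sum() / total
        return float(u), float(min(1.0, 2.0 * min(p_le, p_ge)))

    mu = n1 * n2 / 2.0
    N = n1 + n2
    _, t = np.unique(pooled, return_counts=True)
    tie_term = (t**3 - t).sum() / (N * (N - 1.0))
    sigma2 = n1 * n2 / 12.0 * ((N + 1.0) - tie_term)
    if sigma2 <= 0:
        return float(u), 1.0
    z = (abs(u - mu) - 0.5) / np.sqrt(sigma2)
    z = max(z, 0.0)
    from scipy.stats import norm

    return float(u), float(min(1.0, 2.0 * norm.sf(z)))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, clipped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out
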