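"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the library's own code paths: flood
fill uses an explicit BFS queue, the persistence evaluator loops over
genera × years, and the exact PERMANOVA p enumerates label assignments
with scikit-bio computing the statistic.
"""

from __future__ import annotations

from collections import deque
from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from phyllo import ASVTable, CommunityConfig, gen_asv_table, gen_tree


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def flood_fill_label(mask: np.ndarray, connectivity: int = 8) -> np.ndarray:
    """Brute-force BFS connected-component labelling of a boolean mask."""
    mask = np.asarray(mask, dtype=bool)
    labels = np.zeros(mask.shape, dtype=np.int32)
    if connectivity == 8:
        steps = [(dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
                 if (dy, dx) != (0, 0)]
    else:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    current = 0
    h, w = mask.shape
    for sy in range(h):
        for sx in range(w):
            if not mask[sy, sx] or labels[sy, sx]:
                continue
            current += 1
            queue = deque([(sy, sx)])
            labels[sy, sx] = current
            while queue:
                y, x = queue.popleft()
                for dy, dx in steps:
                    ny, nx = y + dy, x + dx
                    if (0 <= ny < h and 0 <= nx < w
                            and mask[ny, nx] and not labels[ny, nx]):
                        labels[ny, nx] = current
                        queue.append((ny, nx))
    return labels


def labelings_equivalent(a: np.ndarray, b: np.ndarray) -> bool:
    """True iff two label images agree up to a bijective relabelling."""
    a, b = np.asarray(a), np.asarray(b)
    if a.shape != b.shape:
        return False
    if (a > 0).sum() != (b > 0).sum() or ((a > 0) != (b > 0)).any():
        return False
    pairs = {(int(x), int(y)) for x, y in zip(a[a > 0], b[a > 0])}
    return (len({p[0] for p in pairs}) == len(pairs)
            and len({p[1] for p in pairs}) == len(pairs))


def brute_force_persistent(genus_counts: pd.DataFrame, metadata: pd.DataFrame,
                           site: str, min_frac: float = 0.75,
                           presence: int = 1) -> set[str]:
    """Loop-over-everything persistence evaluator (genera × years)."""
    result = set()
    site_samples = metadata.index[metadata["site"] == site]
    years = sorted(metadata.loc[site_samples, "year"].unique())
    for genus in genus_counts.columns:
        ok = True
        for year in years:
            reps = [s for s in site_samples if metadata.loc[s, "year"] == year]
            n_present = sum(genus_counts.loc[s, genus] >= presence for s in reps)
            if n_present / len(reps) < min_frac:
                ok = False
        if ok:
            result.add(genus)
    return result


def exhaustive_permanova_p(dm, grouping: list[str]) -> float:
    """Exact PERMANOVA p by enumerating assignments, F via scikit-bio."""
    from skbio.stats.distance import permanova as sk_permanova

    labels = np.asarray(grouping)
    n = len(labels)
    group_a = [g for g in pd.unique(labels)][0]
    n_a = int((labels == group_a).sum())
    f_obs = float(
        sk_permanova(dm, grouping=list(labels), permutations=0)["test statistic"]
    )
    n_ge = 0
    n_total = 0
    for idx_a in combinations(range(n), n_a):
        assignment = np.array(["B"] * n, dtype=object)
        assignment[list(idx_a)] = "A"
        f = float(
            sk_permanova(dm, grouping=list(assignment), permutations=0)[
                "test statistic"
            ]
        )
        n_total += 1
        if f >= f_obs - 1e-12:
            n_ge += 1
    return n_ge / n_total


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def default_community():
    """One default synthetic community: table, taxonomy, ground truth."""
    return gen_asv_table(CommunityConfig(seed=42))


@pytest.fixture(scope="session")
def small_table() -> ASVTable:
    """Hand-sized 4-sample × 5-ASV table for arithmetic checks."""
    counts = pd.DataFrame(
        [[5, 0, 3, 1, 0],
         [2, 2, 2, 2, 2],
         [0, 7, 1, 0, 1],
         [4, 1, 0, 3, 0]],
        index=["s1", "s2", "s3", "s4"],
        columns=[f"ASV{i}" for i in range(1, 6)],
    )
    metadata = pd.DataFrame(
        {"site": ["Rural", "Rural", "Inner-city", "Inner-city"],
         "year": [2014, 2016, 2014, 2016],
         "replicate": [1, 1, 1, 1]},
        index=counts.index,
    )
    return ASVTable(counts=counts, metadata=metadata)


@pytest.fixture(scope="session")
def star_tree():
    return gen_tree([f"ASV{i}" for i in range(1, 6)], mode="star")
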