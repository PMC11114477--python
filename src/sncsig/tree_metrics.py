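"""Root-to-tip distances and rank-sum comparison of tip groups.

The root-to-tip distance of a tip - the summed branch lengths on the unique
path from the root - is a standard proxy for the evolutionary rate of a
lineage; comparing the distances of two labelled tip groups (e.g. one
Argonaute subfamily against another on a gene-family tree) asks whether one
subfamily evolves under stronger constraint. The comparison is a two-sided
Mann-Whitney U test: exact enumeration over all group labellings when the
pooled sample is small (n_A + n_B <= 12), otherwise the normal approximation
with tie correction.

The U convention used here counts, for group A, the number of (a, b) pairs
with b > a (ties counted half), i.e. U_A = n_A*n_B + n_A(n_A+1)/2 - R_A with
R_A the midrank sum of A; U_A + U_B = n_A * n_B always holds.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb, erfc, sqrt
from typing import Mapping, Sequence

import dendropy
import pandas as pd
from scipy.stats import rankdata

EXACT_LIMIT = 12


@dataclass
class GroupComparison:
    group_a: list[str]
    group_b: list[str]
    distances_a: list[float]
    distances_b: list[float]
    u_a: float
    u_b: float
    p_value: float
    method: str                  # "exact" | "normal"
    direction: str               # "A", "B" or "none" (group with smaller median)


def parse_newick(text: str) -> dendropy.Tree:
    """Parse a rooted newick tree, requiring branch lengths and unique tips."""
    try:
        tree = dendropy.Tree.get(data=text, schema="newick",
                                 suppress_internal_node_taxa=True)
    except Exception as exc:
        raise ValueError(f"malformed newick: {exc}") from exc
    tips = [leaf.taxon.label for leaf in tree.leaf_node_iter() if leaf.taxon]
    if len(tips) != len(set(tips)):
        raise ValueError("duplicate tip names")
    for node in tree.preorder_node_iter():
        if node.parent_node is not None and node.edge.length is None:
            raise ValueError("missing branch length")
        if node.edge.length is not None and node.edge.length < 0:
            raise ValueError("negative branch length")
    return tree


def root_to_tip_distances(tree: dendropy.Tree) -> dict[str, float]:
    """Summed branch lengths from the root to every named tip."""
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    return {leaf.taxon.label: float(leaf.root_distance)
            for leaf in tree.leaf_node_iter() if leaf.taxon}


def _u_from_values(values_a: Sequence[float], values_b: Sequence[float]) -> tuple[float, float]:
    pooled = list(values_a) + list(values_b)
    ranks = rankdata(pooled)            # midranks on ties
    n_a, n_b = len(values_a), len(values_b)
    r_a = float(ranks[:n_a].sum())
    u_a = n_a * n_b + n_a * (n_a + 1) / 2 - r_a
    return u_a, n_a * n_b - u_a


def rank_sum_compare(distances: Mapping[str, float], tips_a: Sequence[str],
                     tips_b: Sequence[str], alternative: str = "two-sided") -> GroupComparison:
    """Mann-Whitney U comparison of root-to-tip distances between two groups.

    Exact: the null distribution of U is enumerated over all C(n_A+n_B, n_A)
    assignments of the pooled distances to group A; p is the fraction of
    assignments whose U is at least as extreme (two-sided: as far from
    n_A*n_B/2) as observed. Large samples use the normal approximation with
    the usual tie-corrected variance.
    """
    set_a, set_b = set(tips_a), set(tips_b)
    if set_a & set_b:
        raise ValueError(f"groups overlap: {sorted(set_a & set_b)}")
    if not set_a or not set_b:
        raise ValueError("both groups must be non-empty")
    missing = (set_a | set_b) - set(distances)
    if missing:
        raise ValueError(f"tips absent from the tree: {sorted(missing)}")
    if alternative not in ("two-sided", "less", "greater"):
        raise ValueError(f"unknown alternative: {alternative!r}")

    values_a = [distances[t] for t in tips_a]
    values_b = [distances[t] for t in tips_b]
    n_a, n_b = len(values_a), len(values_b)
    u_a, u_b = _u_from_values(values_a, values_b)

    pooled = values_a + values_b
    if n_a + n_b <= EXACT_LIMIT:
        method = "exact"
        p = _exact_p(pooled, n_a, n_b, u_a, alternative)
    else:
        method = "normal"
        p = _normal_p(pooled, n_a, n_b, u_a, alternative)

    med_a = _median(values_a)
    med_b = _median(values_b)
    direction = "none" if med_a == med_b else ("A" if med_a < med_b else "B")
    return GroupComparison(group_a=list(tips_a), group_b=list(tips_b),
                           distances_a=values_a, distances_b=values_b,
                           u_a=u_a, u_b=u_b, p_value=p, method=method,
                           direction=direction)


def _median(values: Sequence[float]) -> float:
    s = sorted(values)
    n = len(s)
    return s[n // 2] if n % 2 else (s[n // 2 - 1] + s[n // 2]) / 2


def _exact_p(pooled: Sequence[float], n_a: int, n_b: int, u_obs: float,
             alternative: str) -> float:
    n = n_a + n_b
    center = n_a * n_b / 2
    hits = 0
    total = comb(n, n_a)
    for idx_a in combinations(range(n), n_a):
        mask = set(idx_a)
        va = [pooled[i] for i in idx_a]
        vb = [pooled[i] for i in range(n) if i not in mask]
        u, _ = _u_from_values(va, vb)
        if alternative == "two-sided":
            extreme = abs(u - center) >= abs(u_obs - center) - 1e-12
        elif alternative == "greater":
            extreme = u >= u_obs - 1e-12
        else:
            extreme = u <= u_obs + 1e-12
        hits += extreme
    return hits / total


def _normal_p(pooled: Sequence[float], n_a: int, n_b: int, u_a: float,
              alternative: str) -> float:
    n = n_a + n_b
    mu = n_a * n_b / 2
    # tie-corrected variance
    tie_sizes = pd.Series(pooled).value_counts().to_numpy()
    tie_term = float(((tie_sizes ** 3 - tie_sizes).sum()) / (n * (n - 1)))
    sigma2 = n_a * n_b / 12 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        return 1.0
    z = (u_a - mu) / sqrt(sigma2)
    if alternative == "two-sided":
        return min(1.0, erfc(abs(z) / sqrt(2)))
    if alternative == "greater":
        return 0.5 * erfc(z / sqrt(2))
    return 0.5 * erfc(-z / sqrt(2))


def comparison_table(distances: Mapping[str, float], tips_a: Sequence[str],
                     tips_b: Sequence[str], label_a: str = "A",
                     label_b: str = "B") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-tip distance table plus a one-row test summary."""
    comp = rank_sum_compare(distances, tips_a, tips_b)
    tips = ([(t, label_a, distances[t]) for t in tips_a]
            + [(t, label_b, distances[t]) for t in tips_b])
    per_tip = pd.DataFrame(tips, columns=["tip", "group", "distance"])
    summary = pd.DataFrame([{
        "u_a": comp.u_a, "u_b": comp.u_b, "p_value": comp.p_value,
        "method": comp.method,
        "smaller_median": {"A": label_a, "B": label_b, "none": "none"}[comp.direction],
    }])
    return per_tip, summary
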