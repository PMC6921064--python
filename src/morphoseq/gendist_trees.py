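"""Pairwise genetic distances, UPGMA clustering, and bootstrap support.

Distances are computed on alignment columns surviving complete deletion
(every sequence unambiguously A/C/G/T) under a choice of closed-form
models: raw p-distance, Jukes-Cantor with or without gamma rate variation,
and Tamura-Nei 1993 with or without gamma. UPGMA agglomerates the closest
pair at each step (size-weighted average linkage, merge height = half the
between-cluster distance), yielding an ultrametric tree; clade support is
estimated by resampling alignment columns with replacement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

MODELS = ("p", "jc", "jc+g", "tn93", "tn93+g")

_UNAMBIGUOUS = frozenset("ACGT")


class SaturationError(ValueError):
    """Observed divergence exceeds what the model can map to a finite
    distance."""


def _coerce_alignment(alignment: Iterable) -> tuple[list[str], list[str]]:
    """Accept AlignedSequence-likes or (label, sequence) pairs."""
    labels, seqs = [], []
    for item in alignment:
        if hasattr(item, "columns"):
            labels.append(item.seq_id)
            seqs.append(item.columns.upper())
        else:
            label, seq = item
            labels.append(label)
            seqs.append(seq.upper())
    if len(set(map(len, seqs))) > 1:
        raise ValueError("sequences have unequal lengths")
    return labels, seqs


def complete_deletion(alignment: Iterable) -> tuple[list[str], list[str]]:
    """Retain exactly the columns where every sequence has an unambiguous
    A/C/G/T (gaps and missing data eliminated)."""
    labels, seqs = _coerce_alignment(alignment)
    if not seqs:
        return labels, seqs
    keep = [
        j
        for j in range(len(seqs[0]))
        if all(s[j] in _UNAMBIGUOUS for s in seqs)
    ]
    if not keep:
        raise ValueError("no columns survive complete deletion")
    return labels, ["".join(s[j] for j in keep) for s in seqs]


def p_distance(s1: str, s2: str) -> float:
    """Proportion of differing sites between two gap-filtered sequences."""
    if len(s1) != len(s2):
        raise ValueError("sequences must have equal length")
    if len(s1) == 0:
        raise ValueError("zero comparable sites")
    diffs = sum(1 for a, b in zip(s1, s2) if a != b)
    return diffs / len(s1)


def model_distance(p: float, model: str = "jc", gamma_shape: float = 1.0) -> float:
    """Map a proportion of differing sites to an evolutionary distance.

    JC: d = -(3/4) ln(1 - 4p/3); JC+gamma: d = (3a/4)[(1 - 4p/3)^(-1/a) - 1].
    The TN93 family needs base/transition composition, not a scalar p —
    use :func:`tn93_distance` for those.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p = {p} outside [0, 1]")
    if model == "p":
        return p
    if model in ("jc", "jc+g"):
        w = 1.0 - 4.0 * p / 3.0
        if w <= 0.0:
            raise SaturationError(f"p = {p} at or beyond Jukes-Cantor saturation (3/4)")
        if model == "jc":
            return -0.75 * math.log(w)
        a = gamma_shape
        return 0.75 * a * (w ** (-1.0 / a) - 1.0)
    if model in ("tn93", "tn93+g"):
        raise ValueError("TN93 distances require sequences; use tn93_distance")
    raise ValueError(f"unknown model {model!r}; choose from {MODELS}")


_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}


def tn93_distance(s1: str, s2: str, gamma_shape: float | None = None) -> float:
    """Tamura-Nei 1993 distance (optionally gamma-corrected) between two
    gap-filtered sequences, from their transition/transversion composition."""
    if len(s1) != len(s2) or len(s1) == 0:
        raise ValueError("sequences must be nonempty and equal length")
    n = len(s1)
    counts = {b: 0.0 for b in "ACGT"}
    p1 = p2 = q = 0
    for a, b in zip(s1, s2):
        counts[a] += 0.5
        counts[b] += 0.5
        if a == b:
            continue
        pair = {a, b}
        if pair == _PURINES:
            p1 += 1
        elif pair == _PYRIMIDINES:
            p2 += 1
        else:
            q += 1
    P1, P2, Q = p1 / n, p2 / n, q / n
    gA, gC, gG, gT = (counts[b] / n for b in "ACGT")
    gR, gY = gA + gG, gC + gT
    if min(gR, gY) <= 0:
        raise SaturationError("degenerate base composition for TN93")
    k1 = 2.0 * gA * gG / gR
    k2 = 2.0 * gT * gC / gY
    k3 = 2.0 * (gR * gY - gA * gG * gY / gR - gT * gC * gR / gY)
    w1 = 1.0 - P1 / k1 - Q / (2.0 * gR) if k1 > 0 else 1.0
    w2 = 1.0 - P2 / k2 - Q / (2.0 * gY) if k2 > 0 else 1.0
    w3 = 1.0 - Q / (2.0 * gR * gY)
    if min(w1, w2, w3) <= 0:
        raise SaturationError("sequence pair beyond TN93 saturation")
    if gamma_shape is None:
        return -(k1 * math.log(w1) + k2 * math.log(w2) + k3 * math.log(w3))
    a = gamma_shape
    return a * (
        k1 * w1 ** (-1.0 / a)
        + k2 * w2 ** (-1.0 / a)
        + k3 * w3 ** (-1.0 / a)
        - (k1 + k2 + k3)
    )


def pair_distance(s1: str, s2: str, model: str = "jc+g", gamma_shape: float = 1.0) -> float:
    if model in ("tn93", "tn93+g"):
        return tn93_distance(s1, s2, gamma_shape if model == "tn93+g" else None)
    return model_distance(p_distance(s1, s2), model, gamma_shape)


def distance_matrix(
    alignment: Iterable,
    model: str = "jc+g",
    gamma_shape: float = 1.0,
    filtered: bool = False,
) -> pd.DataFrame:
    """Pairwise model distances after complete deletion (unless the input
    is already gap-filtered)."""
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; choose from {MODELS}")
    if filtered:
        labels, seqs = _coerce_alignment(alignment)
    else:
        labels, seqs = complete_deletion(alignment)
    n = len(labels)
    M = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        d = pair_distance(seqs[i], seqs[j], model, gamma_shape)
        M[i, j] = M[j, i] = d
    return pd.DataFrame(M, index=labels, columns=labels)


def mean_intragroup_distance(matrix: pd.DataFrame, members: Sequence[str]) -> float:
    """Arithmetic mean distance over all unordered pairs of ``members``."""
    missing = [m for m in members if m not in matrix.index]
    if missing:
        raise KeyError(f"taxa not in matrix: {missing}")
    if len(members) < 2:
        raise ValueError("need at least 2 members")
    vals = [matrix.loc[a, b] for a, b in combinations(members, 2)]
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# UPGMA


def upgma(matrix: pd.DataFrame) -> TreeNode:
    """Unweighted pair-group (arithmetic average) agglomeration.

    The closest pair of clusters is merged at height d/2; the new cluster's
    distance to the rest is the size-weighted mean of its parts. Ties are
    broken toward the lexicographically smallest taxon pair so the result
    is deterministic. The returned tree is ultrametric.
    """
    labels = list(matrix.index)
    M = np.asarray(matrix, dtype=float)
    if np.isnan(M).any():
        raise ValueError("NaN in distance matrix")
    if not np.allclose(M, M.T, atol=1e-12):
        raise ValueError("distance matrix is not symmetric")
    n = len(labels)
    if n < 2:
        raise ValueError("need at least 2 taxa")

    clusters: dict[int, dict] = {
        i: {
            "node": TreeNode(name=labels[i]),
            "size": 1,
            "height": 0.0,
            "min_label": labels[i],
        }
        for i in range(n)
    }
    dist: dict[frozenset, float] = {
        frozenset((i, j)): M[i, j] for i, j in combinations(range(n), 2)
    }
    next_id = n
    while len(clusters) > 1:
        best_key = min(
            dist,
            key=lambda key: (
                dist[key],
                tuple(sorted(clusters[c]["min_label"] for c in key)),
            ),
        )
        d = dist[best_key]
        i, j = sorted(best_key, key=lambda c: clusters[c]["min_label"])
        height = d / 2.0
        ci, cj = clusters.pop(i), clusters.pop(j)
        ci["node"].length = max(0.0, height - ci["height"])
        cj["node"].length = max(0.0, height - cj["height"])
        node = TreeNode(children=[ci["node"], cj["node"]])
        new_dists = {
            frozenset((next_id, k)): (
                ci["size"] * dist[frozenset((i, k))] + cj["size"] * dist[frozenset((j, k))]
            )
            / (ci["size"] + cj["size"])
            for k in clusters
        }
        dist = {key: v for key, v in dist.items() if i not in key and j not in key}
        dist.update(new_dists)
        clusters[next_id] = {
            "node": node,
            "size": ci["size"] + cj["size"],
            "height": height,
            "min_label": min(ci["min_label"], cj["min_label"]),
        }
        next_id += 1

    root = next(iter(clusters.values()))["node"]
    root.length = None
    return root


@dataclass
class BootstrapResult:
    replicates: int
    supports: dict[frozenset, float]  # leaf bipartition -> percent


def _nontrivial_splits(tree: TreeNode) -> set[frozenset]:
    """Unrooted bipartitions as frozensets of the side not containing the
    reference (lexicographically first) leaf; trivial splits excluded."""
    tips = sorted(t.name for t in tree.tips())
    ref = tips[0]
    n = len(tips)
    splits = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if ref in side:
            side = frozenset(tips) - side
        if 2 <= len(side) <= n - 2:
            splits.add(side)
    return splits


def bootstrap_upgma(
    alignment: Iterable,
    model: str = "jc+g",
    gamma_shape: float = 1.0,
    replicates: int = 1000,
    seed: int = 0,
) -> tuple[TreeNode, BootstrapResult]:
    """UPGMA tree with clade support from column-resampling bootstrap.

    Columns surviving complete deletion are resampled with replacement
    ``replicates`` times; each resample is re-distanced and re-clustered,
    and each original clade's support is the percentage of replicate trees
    containing the same leaf bipartition. Supports are written onto the
    internal nodes as labels.
    """
    if replicates < 1:
        raise ValueError("need at least 1 bootstrap replicate")
    labels, seqs = complete_deletion(alignment)
    cols = np.array([list(s) for s in seqs])  # (n, m)
    m = cols.shape[1]

    tree = upgma(distance_matrix(zip(labels, seqs), model, gamma_shape, filtered=True))
    target_splits = {
        node: frozenset(t.name for t in node.tips())
        for node in tree.non_tips(include_self=False)
    }
    counts = {node: 0 for node in target_splits}

    rng = np.random.default_rng(seed)
    all_tips = frozenset(labels)
    ref = sorted(labels)[0]
    for _ in range(replicates):
        idx = rng.integers(0, m, size=m)
        rseqs = ["".join(row) for row in cols[:, idx]]
        rep_tree = upgma(distance_matrix(zip(labels, rseqs), model, gamma_shape, filtered=True))
        rep_splits = _nontrivial_splits(rep_tree)
        for node, clade in target_splits.items():
            side = clade if ref not in clade else all_tips - clade
            if 2 <= len(side) <= len(labels) - 2:
                if side in rep_splits:
                    counts[node] += 1
            else:
                counts[node] += 1  # trivial splits are in every tree
    supports: dict[frozenset, float] = {}
    for node, clade in target_splits.items():
        pct = 100.0 * counts[node] / replicates
        node.name = f"{pct:.0f}"
        supports[clade] = pct
    return tree, BootstrapResult(replicates=replicates, supports=supports)
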