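"""Quantitative congruence between a morphometric phenogram and a genetic
dendrogram.

The two trees are pruned to their shared leaves (after optional leaf-name
harmonization, since morphometric sample codes and sequence codes often
differ), then compared by Robinson-Foulds distance over unrooted
bipartitions, Pearson correlation of cophenetic distances, and
per-group-label monophyly in each tree. These metrics are added
instrumentation for what is usually an eyeball comparison of side-by-side
dendrograms.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping

import numpy as np
from scipy import stats
from skbio import TreeNode


@dataclass
class CongruenceReport:
    shared_leaves: list[str]
    rf_raw: int
    rf_normalized: float  # in [0, 1]; 0 for <=3 shared leaves
    cophenetic_correlation: float
    monophyly: dict[str, tuple[bool, bool]]  # group -> (in tree a, in tree b)

    @property
    def topologically_identical(self) -> bool:
        return self.rf_raw == 0


def _rename_tips(tree: TreeNode, mapping: Mapping[str, str]) -> TreeNode:
    tree = tree.copy()
    for tip in tree.tips():
        if tip.name in mapping:
            tip.name = mapping[tip.name]
    return tree


def _splits(tree: TreeNode) -> set[frozenset]:
    tips = sorted(t.name for t in tree.tips())
    ref = tips[0]
    full = frozenset(tips)
    n = len(tips)
    out = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if ref in side:
            side = full - side
        if 2 <= len(side) <= n - 2:
            out.add(side)
    return out


def _is_clade(tree: TreeNode, members: frozenset) -> bool:
    if len(members) <= 1:
        return True
    tips = frozenset(t.name for t in tree.tips())
    if members == tips:
        return True
    for node in tree.non_tips(include_self=False):
        if frozenset(t.name for t in node.tips()) == members:
            return True
    return False


def _cophenetic_vector(tree: TreeNode, leaves: list[str]) -> np.ndarray:
    dm = tree.tip_tip_distances(endpoints=leaves)
    ids = list(dm.ids)
    return np.array(
        [dm[ids.index(a), ids.index(b)] for a, b in combinations(leaves, 2)]
    )


def compare_dendrograms(
    morph: TreeNode,
    gene: TreeNode,
    name_map: Mapping[str, str] | None = None,
    groups: Mapping[str, str] | None = None,
) -> CongruenceReport:
    """Compare two dendrograms over their shared leaves.

    ``name_map`` translates the gene tree's leaf names into the morph
    tree's naming scheme before intersection; ``groups`` maps (harmonized)
    leaf names to group labels for the monophyly flags. Raises when fewer
    than 3 leaves are shared.
    """
    gene_h = _rename_tips(gene, name_map) if name_map else gene.copy()
    morph_h = morph.copy()
    names_m = {t.name for t in morph_h.tips()}
    names_g = {t.name for t in gene_h.tips()}
    shared = sorted(names_m & names_g)
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared leaves; need at least 3")
    morph_h = morph_h.shear(shared)
    gene_h = gene_h.shear(shared)

    sm, sg = _splits(morph_h), _splits(gene_h)
    rf = len(sm ^ sg)
    n = len(shared)
    norm = rf / (2.0 * (n - 3)) if n > 3 else 0.0

    vm = _cophenetic_vector(morph_h, shared)
    vg = _cophenetic_vector(gene_h, shared)
    if np.ptp(vm) == 0 or np.ptp(vg) == 0:
        coph = 1.0 if (np.ptp(vm) == 0 and np.ptp(vg) == 0) else 0.0
    else:
        coph = float(stats.pearsonr(vm, vg)[0])

    mono: dict[str, tuple[bool, bool]] = {}
    if groups:
        by_group: dict[str, set[str]] = {}
        for leaf in shared:
            if leaf in groups:
                by_group.setdefault(groups[leaf], set()).add(leaf)
        for gname, members in sorted(by_group.items()):
            fs = frozenset(members)
            mono[gname] = (_is_clade(morph_h, fs), _is_clade(gene_h, fs))

    return CongruenceReport(
        shared_leaves=shared,
        rf_raw=rf,
        rf_normalized=float(norm),
        cophenetic_correlation=coph,
        monophyly=mono,
    )
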