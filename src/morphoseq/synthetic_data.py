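"""Synthetic data with the statistical structure the analyses assume.

Two generators:

* morphotype-structured landmark datasets — a shared mean wing shape plus
  group-specific deformation fields, optional group size-scale factors
  (emulating smaller-winged morphotypes), per-landmark isotropic Gaussian
  noise, and nuisance rotation / translation / scale exactly as Procrustes
  superimposition assumes it removes;

* ITS1-like sequences — an AT-rich base template laid out on a fixed
  669-column canonical alignment frame, with type-defining diagnostic
  motifs inserted at their rule-table columns, a handful of fixed
  type-private substitutions (emulating the unlisted SNPs that accompany
  every published type description), optional background substitution
  noise outside marker regions, optional homopolymer slippage, and
  optional flanking-gene wrappers for trim testing.

The canonical template is a deterministic constant: its column semantics
(which columns are gaps reserved for which insertions, which residues sit
at diagnostic SNP columns) must match the bundled rule table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from skbio import TreeNode

from .io_formats import SequenceRecord
from .morphometry import LandmarkConfiguration, ShapeDataset, centroid_size
from .rules import Marker, RuleConfig, default_rules
from .seqtyping import AlignedSequence

import pandas as pd

# ---------------------------------------------------------------------------
# Canonical ITS1-like template

TEMPLATE_LENGTH = 669

# columns reserved as gaps in the base template, to be filled by
# type-specific insertions / repeat expansions (1-based, inclusive)
_GAP_BLOCKS: list[tuple[int, int]] = [
    (125, 125), (129, 131), (138, 139), (143, 145), (162, 162), (166, 166),
    (177, 180), (211, 217), (226, 230), (232, 232), (249, 250), (291, 299),
    (301, 310), (354, 361), (368, 376), (380, 388), (391, 391), (419, 420),
    (445, 445), (478, 480), (493, 503), (539, 582), (602, 606), (668, 668),
]

# fixed residues the rule table relies on: ancestral motifs, diagnostic-SNP
# backgrounds (differing from every type's residue), homopolymer context,
# and guard residues that keep short diagnostic motifs from arising by
# chance next to their windows
_FORCED_RESIDUES: dict[int, str] = {
    # ancestral TATAT at the reduction site
    110: "T", 111: "A", 112: "T", 113: "A", 114: "T",
    # T6 homopolymer context for the (T)6 -> (T)7 expansion
    243: "T", 244: "T", 245: "T", 246: "T", 247: "T", 248: "T",
    # homopolymer-run guards
    242: "C", 290: "C", 300: "C", 367: "C", 377: "C", 538: "C", 583: "C",
    # diagnostic-SNP backgrounds (type residue differs)
    353: "A", 403: "T", 417: "A",            # TI: G, C, G
    137: "C", 190: "T", 410: "C", 669: "C",  # TII: T, A, T, G
    119: "A", 151: "A", 343: "T", 421: "T",  # TIV: T, G, C, A
    # guards around one/two-base insertion markers
    124: "C", 126: "C", 132: "C", 140: "C", 161: "C", 163: "C",
    165: "C", 167: "C", 231: "C", 233: "C", 251: "C", 390: "C",
    392: "C", 418: "C", 444: "C", 446: "C", 667: "C",
}

_TEMPLATE_SEED = 4081115  # the canonical frame is a fixed constant


def _gap_columns() -> frozenset[int]:
    cols: set[int] = set()
    for lo, hi in _GAP_BLOCKS:
        cols.update(range(lo, hi + 1))
    return frozenset(cols)

GAP_COLUMNS = _gap_columns()


def _build_template() -> str:
    rng = np.random.default_rng(_TEMPLATE_SEED)
    bases = np.array(list("ATCG"))
    cols = []
    for c in range(1, TEMPLATE_LENGTH + 1):
        if c in GAP_COLUMNS:
            cols.append("-")
        elif c in _FORCED_RESIDUES:
            cols.append(_FORCED_RESIDUES[c])
        elif c <= 109:
            # interrupted poly(A): mostly A with scattered breaks
            cols.append(str(rng.choice(bases, p=[0.70, 0.18, 0.06, 0.06])))
        else:
            # AT-rich background (~75% AT overall)
            cols.append(str(rng.choice(bases, p=[0.375, 0.375, 0.125, 0.125])))
    return "".join(cols)


CANONICAL_TEMPLATE = _build_template()


class MarkerCollisionError(ValueError):
    """A marker cannot be placed in the template's reserved gap columns."""


def _place_string(cols: list[str], s: str, window: tuple[int, int]) -> None:
    """Place ``s`` contiguously (in ungapped space) inside the window:
    template residues matching the next character are consumed in place,
    reserved gap columns take the remaining characters."""
    lo, hi = window
    for start in range(lo - 1, hi):
        pos = start
        placements = []
        ok = True
        for ch in s:
            if pos >= hi:
                ok = False
                break
            if CANONICAL_TEMPLATE[pos] != "-":
                if cols[pos] != ch:
                    ok = False
                    break
            else:
                if cols[pos] != "-":
                    ok = False
                    break
                placements.append((pos, ch))
            pos += 1
        if ok:
            for p, ch in placements:
                cols[p] = ch
            return
    raise MarkerCollisionError(f"cannot place {s!r} in columns {lo}-{hi}")


def _apply_marker(cols: list[str], m: Marker, n_repeat: int | None = None) -> None:
    if m.kind == "substitution":
        for off, ch in enumerate(m.motif):
            cols[m.start - 1 + off] = ch
    elif m.kind == "reduction":
        for off in range(m.start - 1, m.end):
            cols[off] = "-"
        for off, ch in enumerate(m.motif):
            cols[m.start - 1 + off] = ch
    elif m.kind == "insertion":
        _place_string(cols, m.motif, m.window(TEMPLATE_LENGTH))
    elif m.kind == "repeat":
        n = n_repeat if n_repeat is not None else m.n_min
        _place_string(cols, m.motif * n, m.window(TEMPLATE_LENGTH))
    else:  # pragma: no cover
        raise ValueError(m.kind)


def _marker_window_columns(rules: RuleConfig) -> frozenset[int]:
    cols: set[int] = set()
    for t in rules.types.values():
        for m in t.markers:
            lo, hi = m.window(rules.alignment_length)
            cols.update(range(lo, hi + 1))
    return frozenset(cols)


def _private_snps(rules: RuleConfig) -> dict[str, dict[int, str]]:
    """Fixed type-private substitutions at otherwise-neutral columns.

    Published type descriptions invariably mention additional unlisted
    SNPs ("a few other SNPs") on top of the tabulated markers; these give
    each type a stable genetic identity (and distinct, tie-free pairwise
    distances) without entering the diagnostic rule table. Counts grow
    with declaration order so no two type pairs are equidistant.
    """
    protected = set(_FORCED_RESIDUES) | set(_marker_window_columns(rules)) | GAP_COLUMNS
    eligible = [
        c for c in range(110, TEMPLATE_LENGTH + 1)
        if c not in protected
    ]
    rng = np.random.default_rng(_TEMPLATE_SEED + 1)
    rng.shuffle(eligible)
    # complementary substitutions keep the AT fraction unchanged
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    out: dict[str, dict[int, str]] = {}
    cursor = 0
    for i, name in enumerate(rules.types):
        count = _PRIVATE_SNP_COUNTS.get(name, 2 + 2 * (i % 5))
        chosen = eligible[cursor : cursor + count]
        cursor += count
        snps = {c: comp[CANONICAL_TEMPLATE[c - 1]] for c in chosen}
        parent = rules.types[name].parent
        if parent is not None and parent in out:
            # variants carry their parent's substitution background plus a
            # few private ones, as real variants do
            snps = {**out[parent], **snps}
        out[name] = snps
    return out


# Counts of type-own private substitutions. Base-type counts are spaced
# geometrically so between-family distances (hence UPGMA merge heights) are
# well separated rather than tied: with near-equidistant types the
# dendrogram topology would be decided by noise, which no clustering method
# can recover reliably. Variant-own counts set the within-family divergence:
# small for the Andean variant, larger for the divergent Mexican variants.
_PRIVATE_SNP_COUNTS: dict[str, int] = {
    "TI": 2, "TIa": 3, "TIb": 2, "TIc": 4, "TId": 10, "TIe": 6,
    "TII": 24, "TIIa": 8, "TIIb": 10, "TIIc": 12, "TIIIA": 40,
    "TIV": 60, "TIVa": 3,
}


def build_type_columns(
    type_name: str,
    rules: RuleConfig | None = None,
    rng: np.random.Generator | None = None,
) -> str:
    """Noise-free canonical columns for one sequence type: the template
    plus the type's effective markers and its private substitutions.
    Repeat copy numbers with a range are drawn from ``rng`` (minimum copy
    number when no rng is given)."""
    rules = rules or default_rules()
    if type_name not in rules.types:
        raise KeyError(f"unknown type {type_name!r}")
    cols = list(CANONICAL_TEMPLATE)
    for m in rules.effective_markers(type_name):
        if not m.required:
            continue
        n = None
        if m.kind == "repeat" and rng is not None and m.n_max > m.n_min:
            n = int(rng.integers(m.n_min, m.n_max + 1))
        _apply_marker(cols, m, n)
    for c, res in _private_snps(rules)[type_name].items():
        cols[c - 1] = res
    return "".join(cols)


def exemplar_set(rules: RuleConfig | None = None) -> list[AlignedSequence]:
    """One noise-free aligned exemplar per defined type (synthetic stand-in
    for a curated reference alignment)."""
    rules = rules or default_rules()
    return [
        AlignedSequence(seq_id=name, columns=build_type_columns(name, rules))
        for name in rules.types
    ]


# reference fragments of the flanking rRNA genes (the conserved primer
# regions at the 18S 3' end and 5.8S 5' end)
FLANK5 = "TAACTCGCATTGATTAAGTCCC"
FLANK3 = "CATCGACATTTGAACGCATATC"


@dataclass
class SeqSimSpec:
    """Simulation settings for one sample's ITS1-like sequences.

    ``snp_rate`` is a per-site background substitution probability applied
    outside all marker windows (so truth labels stay valid); the
    ``adversarial`` flag lifts that protection to probe classifier
    robustness. ``slippage_rate`` is a per-homopolymer-tract probability of
    a one-base expansion/contraction in the output record.
    """

    type_name: str
    n: int = 5
    snp_rate: float = 0.0
    slippage_rate: float = 0.0
    sample_code: str | None = None
    wrap_flanks: bool = False
    adversarial: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for r in (self.snp_rate, self.slippage_rate):
            if not 0.0 <= r < 1.0:
                raise ValueError("rates must lie in [0, 1)")


@dataclass
class SeqSimResult:
    records: list[SequenceRecord]
    aligned: list[AlignedSequence]
    true_type: str
    mutable_columns: int  # background-substitution target count


def _mutable_columns(rules: RuleConfig) -> list[int]:
    protected = set(_FORCED_RESIDUES) | set(_marker_window_columns(rules)) | GAP_COLUMNS
    for snps in _private_snps(rules).values():
        protected |= set(snps)
    return [c for c in range(110, TEMPLATE_LENGTH + 1) if c not in protected]


def _slip_homopolymers(seq: str, rate: float, rng: np.random.Generator) -> str:
    out = []
    i = 0
    while i < len(seq):
        j = i
        while j < len(seq) and seq[j] == seq[i]:
            j += 1
        run = seq[i:j]
        if len(run) >= 4 and rng.random() < rate:
            run = run + seq[i] if rng.random() < 0.5 else run[:-1]
        out.append(run)
        i = j
    return "".join(out)


def gen_its1(spec: SeqSimSpec, rules: RuleConfig | None = None) -> SeqSimResult:
    """Generate ITS1-like sequences of one type (530-583 nt cores)."""
    rules = rules or default_rules()
    rng = np.random.default_rng(spec.seed)
    mutable = _mutable_columns(rules)
    bases = "ACGT"
    records, aligned = [], []
    for i in range(spec.n):
        cols = list(build_type_columns(spec.type_name, rules, rng))
        targets = (
            [c for c in range(110, TEMPLATE_LENGTH + 1) if cols[c - 1] != "-"]
            if spec.adversarial
            else mutable
        )
        for c in targets:
            if rng.random() < spec.snp_rate:
                cur = cols[c - 1]
                cols[c - 1] = rng.choice([b for b in bases if b != cur])
        col_str = "".join(cols)
        seq_id = f"{spec.sample_code or spec.type_name}_{i + 1}"
        aligned.append(AlignedSequence(seq_id=seq_id, columns=col_str))
        core = col_str.replace("-", "")
        if spec.slippage_rate > 0:
            core = _slip_homopolymers(core, spec.slippage_rate, rng)
        if spec.wrap_flanks:
            pad5 = "".join(rng.choice(list("ACGT"), size=140))
            pad3 = "".join(rng.choice(list("ACGT"), size=140))
            core = pad5 + FLANK5 + core + FLANK3 + pad3
        records.append(
            SequenceRecord(seq_id=seq_id, residues=core, sample_code=spec.sample_code)
        )
    return SeqSimResult(
        records=records,
        aligned=aligned,
        true_type=spec.type_name,
        mutable_columns=len(mutable),
    )


# ---------------------------------------------------------------------------
# Landmark datasets

# idealized right-wing landmark template (vein junctions/terminations),
# image units; order follows the 18-landmark homology scheme
BASE_WING = np.array(
    [
        [2.0, 45.0],   # 1 humeral/costal junction
        [28.0, 56.0],  # 2 subcostal break
        [55.0, 60.0],  # 3 apex R1
        [80.0, 52.0],  # 4 apex R2+3
        [96.0, 38.0],  # 5 apex R4+5
        [92.0, 20.0],  # 6 apex M
        [68.0, 7.0],   # 7 apex CuA1
        [30.0, 10.0],  # 8 apex CuA2
        [34.0, 47.0],  # 9 bifurcation R2+3 / R4+5
        [56.0, 43.0],  # 10 R4+5 x r-m
        [12.0, 38.0],  # 11 basal angle of cell bm
        [28.0, 34.0],  # 12 M x dm-bm
        [56.0, 34.0],  # 13 M x r-m
        [73.0, 27.0],  # 14 M x dm-cu
        [17.0, 26.0],  # 15 CuA1 x Cu2
        [30.0, 27.0],  # 16 CuA1 x bm-cu
        [70.0, 17.0],  # 17 CuA1 x dm-cu
        [11.0, 19.0],  # 18 A x Cu2 (apex of cell bcu)
    ]
)


@dataclass
class LandmarkSimSpec:
    """Simulation settings for a morphotype-structured landmark dataset.

    Deformation magnitude ``deformation_scale`` and landmark noise
    ``noise_sd`` are in units of the unit-centroid-size template; the
    defaults put group separation well above noise, the regime in which
    wing-shape morphotypes are distinguishable at all. ``size_scales``
    emulates morphotypes with smaller wings; ``group_tree`` (leaf names =
    group names) makes deformations hierarchical so that morphological
    distances mirror the tree — the concordant-evolution scenario.
    """

    groups: Sequence[str] = ("g1", "g2", "g3", "g4", "g5", "g6")
    n_per_group: int = 40
    k: int = 18
    base_shape: np.ndarray | None = None
    deformation_scale: float = 0.05
    noise_sd: float = 0.0025
    size_scales: Sequence[float] | None = None
    size_jitter: float = 0.03
    image_scale: float = 100.0
    max_translation: float = 20.0
    rotate: bool = True
    seed: int = 0
    group_tree: TreeNode | None = None

    def __post_init__(self) -> None:
        if len(self.groups) < 2:
            raise ValueError("need at least 2 groups")
        if self.deformation_scale < 0 or self.noise_sd <= 0:
            raise ValueError("deformation_scale must be >= 0 and noise_sd > 0")
        if self.size_scales is not None and len(self.size_scales) != len(self.groups):
            raise ValueError("size_scales must match groups")


@dataclass
class LandmarkSimResult:
    dataset: ShapeDataset
    deformations: dict[str, np.ndarray]
    deformation_distances: "pd.DataFrame"


def _unit_base(spec: LandmarkSimSpec) -> np.ndarray:
    base = BASE_WING if spec.base_shape is None else np.asarray(spec.base_shape, float)
    if base.shape != (spec.k, 2):
        raise ValueError(f"base shape must be ({spec.k}, 2)")
    base = base - base.mean(axis=0)
    cs = centroid_size(base)
    return base / cs


def _nuisance_basis(base: np.ndarray) -> np.ndarray:
    """Orthonormal basis (2k x 4) of the similarity directions at ``base``
    (x/y translation, infinitesimal rotation, scaling). Deformations drawn
    orthogonal to these are pure shape changes, which superimposition
    cannot absorb."""
    k = base.shape[0]
    tx = np.tile([1.0, 0.0], k)
    ty = np.tile([0.0, 1.0], k)
    rot = np.column_stack([-base[:, 1], base[:, 0]]).ravel()
    scl = base.ravel()
    Q, _ = np.linalg.qr(np.column_stack([tx, ty, rot, scl]))
    return Q


def _shape_space_project(v: np.ndarray, nuisance: np.ndarray) -> np.ndarray:
    flat = v.ravel()
    flat = flat - nuisance @ (nuisance.T @ flat)
    return flat.reshape(v.shape)


def _tree_deformations(
    spec: LandmarkSimSpec, rng: np.random.Generator, base: np.ndarray
) -> dict[str, np.ndarray]:
    tree = spec.group_tree
    tips = {t.name for t in tree.tips()}
    if set(spec.groups) - tips:
        raise ValueError("group_tree must contain every group as a tip")
    depth = max(sum(a.length or 0.0 for a in t.ancestors() if a.length) + (t.length or 0.0)
                for t in tree.tips())
    if depth <= 0:
        raise ValueError("group_tree has zero height")
    nodes = list(tree.preorder(include_self=False))
    # branch offsets are drawn mutually orthogonal and inside the shape
    # subspace (orthogonal to the similarity directions), so squared
    # deformation distances are exactly proportional to tree path lengths
    # and superimposition cannot absorb any part of them (possible while
    # the number of branches fits in the 2k - 4 shape dimensions)
    nuisance = _nuisance_basis(base)
    G = rng.normal(size=(2 * spec.k, max(len(nodes), 1)))
    G = G - nuisance @ (nuisance.T @ G)
    if len(nodes) <= 2 * spec.k - 4:
        Q, _ = np.linalg.qr(G)
        directions = Q.T
    else:
        directions = (G / np.linalg.norm(G, axis=0)).T
    offsets: dict[int, np.ndarray] = {}
    for node, direction in zip(nodes, directions):
        b = node.length or 0.0
        v = direction.reshape(spec.k, 2) * spec.deformation_scale * np.sqrt(b / depth)
        offsets[id(node)] = v
    out = {}
    for tip in tree.tips():
        v = offsets[id(tip)].copy()
        for anc in tip.ancestors():
            if id(anc) in offsets:
                v += offsets[id(anc)]
        out[tip.name] = v
    return out


def gen_landmarks(spec: LandmarkSimSpec) -> LandmarkSimResult:
    """Generate a labeled landmark dataset: specimen i of group j is
    sizescale_j * s_i * R(theta_i) (base + deformation_j + noise) + t_i,
    so the raw data carry nuisance rotation, translation and size exactly
    as GPA assumes it removes."""
    rng = np.random.default_rng(spec.seed)
    base = _unit_base(spec)
    if spec.group_tree is not None:
        deformations = _tree_deformations(spec, rng, base)
    else:
        # mutually orthogonal shape-space directions with magnitudes spread
        # around the nominal scale, so pairwise deformation distances are
        # well separated (a meaningful target ordering) instead of all tied
        nuisance = _nuisance_basis(base)
        g = len(spec.groups)
        G = rng.normal(size=(2 * spec.k, g))
        G = G - nuisance @ (nuisance.T @ G)
        if g <= 2 * spec.k - 4:
            Q, _ = np.linalg.qr(G)
            directions = Q.T
        else:
            directions = (G / np.linalg.norm(G, axis=0)).T
        spread = np.linspace(0.6, 1.5, g) if g > 1 else np.ones(1)
        deformations = {
            gname: directions[j].reshape(spec.k, 2) * spec.deformation_scale * spread[j]
            for j, gname in enumerate(spec.groups)
        }
    scales = dict(zip(spec.groups, spec.size_scales or [1.0] * len(spec.groups)))
    configs = []
    for gname in spec.groups:
        for i in range(spec.n_per_group):
            shape = base + deformations[gname] + rng.normal(scale=spec.noise_sd, size=(spec.k, 2))
            if spec.rotate:
                th = rng.uniform(0.0, 2.0 * np.pi)
                R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
                shape = shape @ R.T
            s = scales[gname] * np.exp(rng.normal(0.0, spec.size_jitter))
            coords = shape * s * spec.image_scale + rng.uniform(
                -spec.max_translation, spec.max_translation, size=2
            )
            configs.append(
                LandmarkConfiguration(
                    specimen_id=f"{gname}_{i + 1}", landmarks=coords, group_label=gname
                )
            )
    g = list(spec.groups)
    D = np.zeros((len(g), len(g)))
    for a in range(len(g)):
        for b in range(a + 1, len(g)):
            D[a, b] = D[b, a] = np.linalg.norm(deformations[g[a]] - deformations[g[b]])
    return LandmarkSimResult(
        dataset=ShapeDataset(configurations=configs),
        deformations=deformations,
        deformation_distances=pd.DataFrame(D, index=g, columns=g),
    )
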