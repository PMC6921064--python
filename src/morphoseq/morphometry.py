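"""Landmark geometric morphometrics: Procrustes superimposition, canonical
variate analysis, Mahalanobis distances, group classification and centroid
size comparisons.

The pipeline mirrors standard practice for wing-shape taxonomy: raw 2D
landmark configurations are superimposed by generalized Procrustes analysis
(GPA), removing translation, scale and orientation; the resulting shape
coordinates feed a canonical variate analysis (CVA) that maximizes
between-group relative to within-group variation; squared Mahalanobis
distances between group means summarize morphological divergence and are
clustered into a UPGMA phenogram; a nearest-group-mean rule yields the
classification matrix; and centroid sizes are compared nonparametrically
(Kruskal-Wallis with Dunn/Bonferroni post hoc tests).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, stats


# ---------------------------------------------------------------------------
# Domain containers


@dataclass
class LandmarkConfiguration:
    """One specimen's ordered 2D landmark coordinates.

    Landmark order is the homology order (landmark 1 = junction of the
    humeral and costal veins, ... landmark 18 = apex of cell bcu for the
    fruit-fly wing scheme); coordinates are in image units.
    """

    specimen_id: str
    landmarks: np.ndarray  # (k, 2)
    group_label: str | None = None

    def __post_init__(self) -> None:
        self.landmarks = np.asarray(self.landmarks, dtype=float)
        if self.landmarks.ndim != 2 or self.landmarks.shape[1] != 2:
            raise ValueError("landmarks must be a (k, 2) array")
        if self.landmarks.shape[0] < 3:
            raise ValueError("a configuration needs at least 3 landmarks")
        if not np.all(np.isfinite(self.landmarks)):
            raise ValueError(f"non-finite coordinates in {self.specimen_id!r}")

    @property
    def k(self) -> int:
        return self.landmarks.shape[0]


@dataclass
class ShapeDataset:
    """Labeled collection of landmark configurations feeding GPA/CVA."""

    configurations: list[LandmarkConfiguration]

    def __post_init__(self) -> None:
        ks = {c.k for c in self.configurations}
        if len(ks) > 1:
            raise ValueError(f"inconsistent landmark counts across specimens: {sorted(ks)}")
        ids = [c.specimen_id for c in self.configurations]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate specimen ids")

    def __len__(self) -> int:
        return len(self.configurations)

    @property
    def k(self) -> int:
        return self.configurations[0].k if self.configurations else 0

    @property
    def groups(self) -> list[str]:
        """Ordered unique group labels (first-appearance order)."""
        seen: dict[str, None] = {}
        for c in self.configurations:
            if c.group_label is not None:
                seen.setdefault(c.group_label, None)
        return list(seen)

    def group_assignment(self) -> dict[str, str]:
        out = {}
        for c in self.configurations:
            if c.group_label is None:
                raise ValueError(f"specimen {c.specimen_id!r} has no group label")
            out[c.specimen_id] = c.group_label
        return out

    def assign_groups(self, mapping: Mapping[str, str]) -> None:
        """Attach group labels from a specimen_id -> group mapping."""
        for c in self.configurations:
            if c.specimen_id in mapping:
                c.group_label = mapping[c.specimen_id]

    def coordinate_array(self) -> np.ndarray:
        return np.stack([c.landmarks for c in self.configurations])


@dataclass
class ProcrustesFit:
    """Result of a generalized Procrustes superimposition.

    ``aligned`` holds one flattened (x1, y1, ..., xk, yk) row per specimen;
    every row is centered at the origin with unit centroid size, as is the
    consensus.
    """

    specimen_ids: list[str]
    aligned: np.ndarray  # (n, 2k)
    consensus: np.ndarray  # (k, 2)
    centroid_sizes: np.ndarray  # (n,)
    iterations: int
    converged: bool

    @property
    def k(self) -> int:
        return self.consensus.shape[0]

    def aligned_configuration(self, i: int) -> np.ndarray:
        return self.aligned[i].reshape(self.k, 2)


class GPAConvergenceError(RuntimeError):
    """GPA failed to converge; ``last_fit`` carries the final iterate."""

    def __init__(self, msg: str, last_fit: ProcrustesFit):
        super().__init__(msg)
        self.last_fit = last_fit


@dataclass
class CVAResult:
    """Canonical variate analysis of Procrustes shape coordinates.

    Eigenvalues come from the generalized eigenproblem B v = lambda W v on
    the rank-reduced coordinates (B, W = between/within sums of squares and
    cross products); canonical axes are scaled so the pooled within-group
    covariance of the scores is the identity, making Euclidean distance in
    score space a Mahalanobis distance.
    """

    groups: list[str]
    specimen_ids: list[str]
    group_labels: list[str]
    eigenvalues: np.ndarray  # (c,)
    axes: np.ndarray  # (p, c) loadings in the reduced space
    scores: np.ndarray  # (n, c)
    percent_variance: np.ndarray  # (c,)
    wilks_lambda: float
    f_statistic: float
    df1: float
    df2: float
    group_means_canonical: np.ndarray  # (g, c)
    # internals for Mahalanobis / classification in the reduced space
    reduced_coords: np.ndarray = field(repr=False)  # (n, p)
    group_means_reduced: np.ndarray = field(repr=False)  # (g, p)
    pooled_cov_reduced: np.ndarray = field(repr=False)  # (p, p)
    pc_basis: np.ndarray = field(repr=False)  # (2k, p)
    grand_mean: np.ndarray = field(repr=False)  # (2k,)

    @property
    def n_axes(self) -> int:
        return len(self.eigenvalues)


@dataclass
class ClassificationMatrix:
    """Observed (rows) vs predicted (columns) group counts."""

    counts: pd.DataFrame  # g x g integer table

    def __post_init__(self) -> None:
        if not (self.counts.index == self.counts.columns).all():
            raise ValueError("rows and columns must list the same groups in order")

    @property
    def total(self) -> int:
        return int(self.counts.values.sum())

    def row_percent_correct(self) -> pd.Series:
        return percent_correct(self)[0]

    def overall_percent_correct(self) -> float:
        return percent_correct(self)[1]


@dataclass
class SizeTestResult:
    """Kruskal-Wallis + Dunn/Bonferroni comparison of centroid sizes."""

    h_statistic: float
    df: int
    p_value: float
    dunn: pd.DataFrame  # columns: group1, group2, z, p, p_adjusted
    letters: dict[str, str]  # compact letter display at the chosen alpha
    alpha: float


# ---------------------------------------------------------------------------
# Centroid size


def centroid_size(config: LandmarkConfiguration | np.ndarray) -> float:
    """Square root of the summed squared deviations of landmarks from
    their centroid — the size measure removed by Procrustes scaling."""
    X = config.landmarks if isinstance(config, LandmarkConfiguration) else np.asarray(config, float)
    centered = X - X.mean(axis=0)
    cs = float(np.sqrt((centered**2).sum()))
    if cs <= 0.0:
        raise ValueError("degenerate configuration: all landmarks coincide")
    return cs


# ---------------------------------------------------------------------------
# Generalized Procrustes analysis


def _optimal_rotation(X: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Rotation R (det +1, no reflection) minimizing ||X R - target||_F."""
    U, _, Vt = np.linalg.svd(X.T @ target)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, d])
    return U @ D @ Vt


def _center_and_scale(X: np.ndarray) -> np.ndarray:
    centered = X - X.mean(axis=0)
    return centered / np.sqrt((centered**2).sum())


def gpa(dataset: ShapeDataset, tol: float = 1e-10, max_iter: int = 100) -> ProcrustesFit:
    """Generalized Procrustes superimposition.

    Each configuration is centered, scaled to unit centroid size, and
    iteratively rotated onto the running consensus (mean shape, itself
    normalized to unit size) until the root-mean-square change of the
    consensus drops below ``tol``. Only proper rotations are allowed: the
    wings are all of the same chirality, so reflections are excluded.
    """
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    raw = dataset.coordinate_array()
    n, k, _ = raw.shape
    sizes = np.array([centroid_size(raw[i]) for i in range(n)])
    shapes = np.stack([_center_and_scale(raw[i]) for i in range(n)])

    consensus = _center_and_scale(shapes[0].copy())
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        for i in range(n):
            shapes[i] = shapes[i] @ _optimal_rotation(shapes[i], consensus)
        new_consensus = _center_and_scale(shapes.mean(axis=0))
        # align the new consensus to the old one so the frame is stable
        new_consensus = new_consensus @ _optimal_rotation(new_consensus, consensus)
        rms = np.sqrt(((new_consensus - consensus) ** 2).mean())
        consensus = new_consensus
        if rms < tol:
            converged = True
            break

    fit = ProcrustesFit(
        specimen_ids=[c.specimen_id for c in dataset.configurations],
        aligned=shapes.reshape(n, 2 * k),
        consensus=consensus,
        centroid_sizes=sizes,
        iterations=iterations,
        converged=converged,
    )
    if not converged:
        raise GPAConvergenceError(f"GPA did not converge in {max_iter} iterations", fit)
    return fit


def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Partial Procrustes distance between two (k, 2) configurations."""
    A = _center_and_scale(np.asarray(a, float))
    B = _center_and_scale(np.asarray(b, float))
    A = A @ _optimal_rotation(A, B)
    return float(np.sqrt(((A - B) ** 2).sum()))


def tangent_project(fit: ProcrustesFit) -> np.ndarray:
    """Orthogonal projection of aligned coordinates onto the tangent space
    at the consensus (removes the component along the consensus vector)."""
    c = fit.consensus.ravel()
    c = c / np.linalg.norm(c)
    X = fit.aligned
    return X - np.outer(X @ c, c)


# ---------------------------------------------------------------------------
# Canonical variate analysis


def cva(
    fit: ProcrustesFit,
    groups: Mapping[str, str],
    tangent: bool = True,
    rank_tol: float = 1e-10,
) -> CVAResult:
    """Canonical variate analysis on (tangent-projected) shape coordinates.

    Shape coordinates are rank-deficient (GPA removes 4 degrees of freedom
    in 2D), so the coordinates are first reduced to the principal-component
    subspace with non-negligible variance (eigenvalue > rank_tol x largest,
    at most n - g and at most 2k - 4 axes). In that subspace the
    generalized eigenproblem B v = lambda W v is solved for between/within
    SSCP matrices; c = min(g - 1, p) axes are retained; Wilks' Lambda =
    prod 1/(1 + lambda_i) with Rao's F approximation.
    """
    labels = [groups[sid] for sid in fit.specimen_ids]
    group_names: list[str] = []
    for lb in labels:
        if lb not in group_names:
            group_names.append(lb)
    g = len(group_names)
    if g < 2:
        raise ValueError("CVA needs at least 2 groups")
    counts = {gn: labels.count(gn) for gn in group_names}
    small = [gn for gn, c in counts.items() if c < 2]
    if small:
        raise ValueError(f"groups with fewer than 2 specimens: {small}")

    X = tangent_project(fit) if tangent else fit.aligned
    n, twok = X.shape
    grand = X.mean(axis=0)
    Xc = X - grand

    # rank reduction via PCA
    _, svals, Vt = np.linalg.svd(Xc, full_matrices=False)
    eigvals = svals**2
    keep = eigvals > rank_tol * eigvals[0]
    max_dim = min(n - g, twok - 4)
    p = min(int(keep.sum()), max_dim)
    if p < 1:
        raise ValueError("no usable shape variation after rank reduction")
    basis = Vt[:p].T  # (2k, p)
    Y = Xc @ basis  # (n, p)

    idx = {gn: [i for i, lb in enumerate(labels) if lb == gn] for gn in group_names}
    means = np.stack([Y[idx[gn]].mean(axis=0) for gn in group_names])  # (g, p)
    W = np.zeros((p, p))
    B = np.zeros((p, p))
    for gi, gn in enumerate(group_names):
        d = Y[idx[gn]] - means[gi]
        W += d.T @ d
        mb = means[gi] - Y.mean(axis=0)
        B += counts[gn] * np.outer(mb, mb)

    try:
        evals, evecs = linalg.eigh(B, W)
    except linalg.LinAlgError as exc:  # pragma: no cover - degenerate input
        raise ValueError(
            "singular within-group scatter after reduction; lower the retained rank"
        ) from exc
    order = np.argsort(evals)[::-1]
    c = min(g - 1, p)
    lam = np.clip(evals[order][:c], 0.0, None)
    V = evecs[:, order][:, :c]
    # scale axes so the pooled within-group covariance of scores is identity
    pooled_cov = W / (n - g)
    for j in range(c):
        s = float(V[:, j] @ pooled_cov @ V[:, j])
        if s > 0:
            V[:, j] = V[:, j] / np.sqrt(s)

    scores = Y @ V
    means_canon = means @ V
    total = lam.sum()
    pct = 100.0 * lam / total if total > 0 else np.zeros_like(lam)

    wilks = float(np.prod(1.0 / (1.0 + lam)))
    q = g - 1
    df1 = p * q
    denom = p**2 + q**2 - 5
    s = np.sqrt((p**2 * q**2 - 4) / denom) if denom > 0 else 1.0
    m_ = n - 1 - (p + q + 1) / 2.0
    df2 = m_ * s - df1 / 2.0 + 1.0
    lam_s = wilks ** (1.0 / s)
    f_stat = ((1.0 - lam_s) / lam_s) * (df2 / df1) if lam_s > 0 else np.inf

    return CVAResult(
        groups=group_names,
        specimen_ids=list(fit.specimen_ids),
        group_labels=labels,
        eigenvalues=lam,
        axes=V,
        scores=scores,
        percent_variance=pct,
        wilks_lambda=wilks,
        f_statistic=float(f_stat),
        df1=float(df1),
        df2=float(df2),
        group_means_canonical=means_canon,
        reduced_coords=Y,
        group_means_reduced=means,
        pooled_cov_reduced=pooled_cov,
        pc_basis=basis,
        grand_mean=grand,
    )


def mahalanobis_sq(result: CVAResult, g1: str, g2: str) -> float:
    """Squared Mahalanobis distance between two group means in the metric
    of the pooled within-group covariance (reduced space)."""
    for gn in (g1, g2):
        if gn not in result.groups:
            raise KeyError(f"unknown group {gn!r}")
    if g1 == g2:
        return 0.0
    i, j = result.groups.index(g1), result.groups.index(g2)
    diff = result.group_means_reduced[i] - result.group_means_reduced[j]
    sol = linalg.solve(result.pooled_cov_reduced, diff, assume_a="pos")
    return float(diff @ sol)


def shape_distance_matrix(result: CVAResult) -> pd.DataFrame:
    """Symmetric g x g matrix of squared Mahalanobis distances."""
    g = len(result.groups)
    M = np.zeros((g, g))
    for i, j in combinations(range(g), 2):
        d = mahalanobis_sq(result, result.groups[i], result.groups[j])
        M[i, j] = M[j, i] = d
    return pd.DataFrame(M, index=result.groups, columns=result.groups)


def upgma_phenogram(distances: pd.DataFrame):
    """UPGMA phenogram of group shape distances (see gendist_trees.upgma)."""
    from .gendist_trees import upgma

    return upgma(distances)


# ---------------------------------------------------------------------------
# Classification


def _mahalanobis_assign(y: np.ndarray, means: np.ndarray, cov: np.ndarray) -> int:
    chol = linalg.cho_factor(cov)
    d2 = [float((y - m) @ linalg.cho_solve(chol, y - m)) for m in means]
    return int(np.argmin(d2))


def classify(result: CVAResult, mode: str = "resubstitution") -> ClassificationMatrix:
    """Assign each specimen to the group with the nearest mean in the
    Mahalanobis metric of the pooled within-group covariance.

    ``resubstitution`` scores each specimen against group statistics fitted
    on all data (the optimistic, conventional matrix); ``leave_one_out``
    removes the specimen from its own group mean and from the pooled
    covariance before assignment (the honest error estimate).
    """
    if mode not in ("resubstitution", "leave_one_out"):
        raise ValueError(f"unknown mode {mode!r}")
    Y = result.reduced_coords
    labels = result.group_labels
    groups = result.groups
    n, p = Y.shape
    g = len(groups)
    counts = np.zeros((g, g), dtype=int)

    if mode == "resubstitution":
        for i in range(n):
            pred = _mahalanobis_assign(Y[i], result.group_means_reduced, result.pooled_cov_reduced)
            counts[groups.index(labels[i]), pred] += 1
    else:
        idx = {gn: np.array([i for i, lb in enumerate(labels) if lb == gn]) for gn in groups}
        for i in range(n):
            own = labels[i]
            means = []
            W = np.zeros((p, p))
            for gn in groups:
                members = idx[gn][idx[gn] != i]
                if len(members) == 0:
                    raise ValueError(f"group {own!r} has a single specimen; cannot leave it out")
                mu = Y[members].mean(axis=0)
                means.append(mu)
                d = Y[members] - mu
                W += d.T @ d
            cov = W / (n - 1 - g)
            pred = _mahalanobis_assign(Y[i], np.stack(means), cov)
            counts[groups.index(own), pred] += 1

    return ClassificationMatrix(pd.DataFrame(counts, index=groups, columns=groups))


def _round_half_up(x: float, ndigits: int = 1) -> float:
    return float(
        Decimal(repr(float(x))).quantize(Decimal("0." + "0" * ndigits), rounding=ROUND_HALF_UP)
    )


def percent_correct(matrix: ClassificationMatrix) -> tuple[pd.Series, float]:
    """Per-group and overall percent correctly classified.

    Row percent = 100 * diagonal / row sum; overall = 100 * trace / total.
    Reported to one decimal, rounded half-up, matching conventional
    confusion-matrix presentation.
    """
    counts = matrix.counts.values
    row_sums = counts.sum(axis=1)
    if np.any(row_sums == 0):
        empty = [matrix.counts.index[i] for i in np.where(row_sums == 0)[0]]
        raise ValueError(f"empty observed group(s): {empty}")
    diag = np.diag(counts)
    rows = pd.Series(
        [_round_half_up(100.0 * d / s) for d, s in zip(diag, row_sums)],
        index=matrix.counts.index,
        name="percent_correct",
    )
    overall = _round_half_up(100.0 * diag.sum() / counts.sum())
    return rows, overall


# ---------------------------------------------------------------------------
# Centroid size comparison


def _compact_letter_display(
    groups: Sequence[str], significant_pairs: set[tuple[str, str]]
) -> dict[str, str]:
    """Insert-and-absorb compact letter display: groups sharing a letter do
    not differ significantly."""
    letters: list[set[str]] = [set(groups)]
    for a, b in significant_pairs:
        for L in list(letters):
            if a in L and b in L:
                letters.remove(L)
                la, lb = L - {a}, L - {b}
                for cand in (la, lb):
                    if cand and not any(cand <= other for other in letters):
                        letters.append(cand)
        # absorb redundant subsets
        letters = [L for L in letters if not any(L < other for other in letters)]
    # stable ordering: by earliest member in group order
    order = {gn: i for i, gn in enumerate(groups)}
    letters.sort(key=lambda L: min(order[gn] for gn in L))
    out = {gn: "" for gn in groups}
    for ch, L in zip("abcdefghijklmnopqrstuvwxyz", letters):
        for gn in L:
            out[gn] += ch
    return {gn: "".join(sorted(v)) for gn, v in out.items()}


def centroid_size_test(
    sizes: Sequence[float] | np.ndarray,
    groups: Sequence[str],
    alpha: float = 0.05,
) -> SizeTestResult:
    """Kruskal-Wallis test on centroid sizes followed by Dunn's pairwise
    z tests on mean ranks with Bonferroni correction over all pairs.

    Returns the tie-corrected H statistic, per-pair z and adjusted p, and a
    compact letter display of significance groups at ``alpha``.
    """
    sizes = np.asarray(sizes, float)
    groups = list(groups)
    if len(sizes) != len(groups):
        raise ValueError("sizes and groups differ in length")
    names: list[str] = []
    for gn in groups:
        if gn not in names:
            names.append(gn)
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    samples = {gn: sizes[[i for i, x in enumerate(groups) if x == gn]] for gn in names}
    for gn, s in samples.items():
        if len(s) == 0:
            raise ValueError(f"group {gn!r} has no observations")

    data = [samples[gn] for gn in names]
    if np.ptp(np.concatenate(data)) == 0:
        # all observations identical: H = 0 by convention (scipy refuses)
        h, p = 0.0, 1.0
    else:
        h, p = stats.kruskal(*data)

    # Dunn's test on mean ranks with tie correction
    N = len(sizes)
    ranks = stats.rankdata(sizes)
    mean_ranks = {gn: ranks[[i for i, x in enumerate(groups) if x == gn]].mean() for gn in names}
    _, tie_counts = np.unique(sizes, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (12.0 * (N - 1))) if N > 1 else 0.0
    m = len(names) * (len(names) - 1) // 2
    rows = []
    sig: set[tuple[str, str]] = set()
    for a, b in combinations(names, 2):
        na, nb = len(samples[a]), len(samples[b])
        se2 = (N * (N + 1) / 12.0 - tie_term) * (1.0 / na + 1.0 / nb)
        if se2 <= 0:
            z, praw = 0.0, 1.0
        else:
            z = (mean_ranks[a] - mean_ranks[b]) / np.sqrt(se2)
            praw = 2.0 * stats.norm.sf(abs(z))
        padj = min(1.0, praw * m)
        rows.append({"group1": a, "group2": b, "z": z, "p": praw, "p_adjusted": padj})
        if padj < alpha:
            sig.add((a, b))
    dunn = pd.DataFrame(rows)
    letters = _compact_letter_display(names, sig)
    return SizeTestResult(
        h_statistic=float(h),
        df=len(names) - 1,
        p_value=float(p),
        dunn=dunn,
        letters=letters,
        alpha=alpha,
    )
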