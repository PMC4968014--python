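"""Weighted co-expression network construction and module detection for one tissue.

Implements the classic WGCNA sequence: Pearson gene-gene correlation, soft-threshold
adjacency, topological overlap (TOM), average-linkage clustering of ``1 - TOM`` with a
dynamic branch cut, eigengene-based module merging, and Pearson eigengene-trait
association.  The module eigengene is the first principal component of the per-gene
standardized module submatrix, signed so that it correlates non-negatively with the
module's mean expression profile.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import ClusterNode, linkage, to_tree
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

UNASSIGNED = "unassigned"


@dataclass
class ExpressionDataset:
    """Genes x samples expression matrix with a per-sample trait table.

    ``values`` has one row per gene.  ``traits`` is samples x traits and must share the
    sample axis.  Zero-variance gene rows are dropped at construction (with a warning):
    they carry no co-expression information and would break Pearson correlation.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    traits: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if np.isnan(self.values).any():
            raise ValueError("expression matrix contains missing values")
        if list(self.traits.index) != list(self.sample_ids):
            if set(self.traits.index) == set(self.sample_ids):
                self.traits = self.traits.loc[self.sample_ids]
            else:
                raise ValueError("trait table sample IDs do not match expression columns")
        keep = self.values.std(axis=1) > 0
        if not keep.all():
            dropped = [g for g, k in zip(self.gene_ids, keep) if not k]
            logger.warning("dropping %d zero-variance genes: %s", len(dropped), dropped[:10])
            self.gene_ids = [g for g, k in zip(self.gene_ids, keep) if k]
            self.values = self.values[keep]

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class NetworkParams:
    """Tuning parameters of the network construction and module cut.

    soft_power is the exponent applied to |correlation|; it is a user input (validated,
    not auto-selected).  ``min_module_size`` is the smallest branch accepted as a module.
    ``deep_split`` >= 1 splits heterogeneous branches more aggressively.  ``cut_height``
    is the dissimilarity level at which the dendrogram is cut, and ``me_diss_threshold``
    the eigengene dissimilarity below which modules are merged.
    """

    soft_power: float = 6.0
    min_module_size: int = 15
    deep_split: int = 0
    cut_height: float = 0.995
    me_diss_threshold: float = 0.30
    signed: bool = False

    def __post_init__(self) -> None:
        if self.soft_power <= 0:
            raise ValueError("soft_power must be positive")
        if self.min_module_size < 1:
            raise ValueError("min_module_size must be a positive count")
        if self.deep_split < 0:
            raise ValueError("deep_split must be >= 0")
        if not 0 < self.cut_height <= 1:
            raise ValueError("cut_height must lie in (0, 1]")
        if not 0 <= self.me_diss_threshold <= 1:
            raise ValueError("me_diss_threshold must lie in [0, 1]")


@dataclass
class ModuleSet:
    """A partition of the gene set into disjoint modules plus an unassigned pool."""

    assignment: dict[str, str]

    @property
    def labels(self) -> list[str]:
        return sorted({m for m in self.assignment.values() if m != UNASSIGNED})

    def genes(self, label: str) -> list[str]:
        return [g for g, m in self.assignment.items() if m == label]

    def sizes(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for m in self.assignment.values():
            if m != UNASSIGNED:
                out[m] = out.get(m, 0) + 1
        return dict(sorted(out.items()))

    @property
    def universe(self) -> list[str]:
        """All genes that entered module detection, assigned or not."""
        return list(self.assignment)

    def modules(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {m: [] for m in self.labels}
        for g, m in self.assignment.items():
            if m != UNASSIGNED:
                out[m].append(g)
        return out


@dataclass
class ModuleTraitResult:
    """Eigengenes and their Pearson association with each trait."""

    module_labels: list[str]
    sample_ids: list[str]
    eigengenes: np.ndarray  # modules x samples, unit norm rows
    r: pd.DataFrame  # modules x traits
    p: pd.DataFrame  # modules x traits
    trait_p_threshold: float = 0.05

    def disease_associated(self) -> dict[str, bool]:
        """A module counts as disease-associated when any trait has p < threshold."""
        return {
            m: bool(self.p.loc[m].min() < self.trait_p_threshold) for m in self.module_labels
        }

    def min_trait_p(self) -> dict[str, float]:
        return {m: float(self.p.loc[m].min()) for m in self.module_labels}


def correlation_matrix(data: ExpressionDataset) -> np.ndarray:
    """Pearson correlation across samples for every gene pair."""
    if data.n_samples < 3:
        raise ValueError("need at least 3 samples for gene-gene correlation")
    sd = data.values.std(axis=1)
    if np.any(sd == 0):
        raise ValueError("zero-variance gene reached correlation stage")
    corr = np.corrcoef(data.values)
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return corr


def soft_adjacency(corr: np.ndarray, params: NetworkParams) -> np.ndarray:
    """Soft-threshold adjacency a_ij = |r_ij|^beta (signed mode: ((1+r)/2)^beta).

    The diagonal is zeroed so that row sums are connectivities.
    """
    if params.soft_power <= 0:
        raise ValueError("soft_power must be positive")
    if params.signed:
        adj = ((1.0 + corr) / 2.0) ** params.soft_power
    else:
        adj = np.abs(corr) ** params.soft_power
    np.fill_diagonal(adj, 0.0)
    return adj


def scale_free_fit(adjacency: np.ndarray, n_bins: int = 10) -> float:
    """Signed R^2 of the log-log degree-distribution fit (scale-free topology index).

    Connectivities k_i are binned; log10(frequency) is regressed on log10(mean k) per
    occupied bin.  The R^2 is negated when the slope is positive (a scale-free network
    has a decreasing degree distribution).  Used to report/validate a chosen soft power.
    """
    adjacency = np.asarray(adjacency, dtype=float)
    if adjacency.shape[0] < 10:
        raise ValueError("need at least 10 genes for a degree-distribution fit")
    k = adjacency.sum(axis=1)
    if np.all(k == 0):
        raise ValueError("all-zero adjacency")
    if np.ptp(k) == 0:
        warnings.warn("constant connectivity: scale-free fit undefined, returning 0")
        return 0.0
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    log_k, log_f = [], []
    for b in range(n_bins):
        mask = idx == b
        if mask.sum() == 0:
            continue
        mean_k = k[mask].mean()
        if mean_k <= 0:
            continue
        log_k.append(np.log10(mean_k))
        log_f.append(np.log10(mask.sum() / len(k)))
    if len(log_k) < 3:
        warnings.warn("too few occupied bins for scale-free fit, returning 0")
        return 0.0
    slope, _, r_value, _, _ = stats.linregress(log_k, log_f)
    r2 = float(r_value**2)
    return -r2 if slope > 0 else r2


def tom_similarity(adjacency: np.ndarray) -> np.ndarray:
    """Unsigned topological overlap matrix.

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij) off the diagonal and
    1 on it.  Genes sharing many strong neighbours score high even when their direct
    adjacency is modest.
    """
    a = np.asarray(adjacency, dtype=float)
    if a.min() < 0 or a.max() > 1:
        raise ValueError("adjacency entries must lie in [0, 1]")
    if np.any(np.diag(a) != 0):
        raise ValueError("adjacency diagonal must be zero")
    if not np.allclose(a, a.T, atol=1e-12):
        raise ValueError("adjacency must be symmetric")
    k = a.sum(axis=1)
    shared = a @ a
    denom = np.minimum.outer(k, k) + 1.0 - a
    assert np.all(denom > 0), "TOM denominator must be positive for valid adjacency"
    tom = (shared + a) / denom
    np.fill_diagonal(tom, 1.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    return tom


def _collect_leaves(node: ClusterNode) -> list[int]:
    return node.pre_order(lambda leaf: leaf.id)


def _split_branch(
    node: ClusterNode, deep_split: int, min_module_size: int
) -> list[list[int]]:
    """Recursively split a below-cut branch when the merge-height gap is large.

    A branch at height h with children at heights h1, h2 is split when
    ``h - max(h1, h2) > (0.25 / deep_split) * h`` and both halves reach the minimum
    module size.  deep_split = 0 never splits.
    """
    if deep_split <= 0 or node.is_leaf():
        return [_collect_leaves(node)]
    left, right = node.get_left(), node.get_right()
    gap = node.dist - max(left.dist, right.dist)
    if (
        gap > (0.25 / deep_split) * node.dist
        and left.get_count() >= min_module_size
        and right.get_count() >= min_module_size
    ):
        return _split_branch(left, deep_split, min_module_size) + _split_branch(
            right, deep_split, min_module_size
        )
    return [_collect_leaves(node)]


def cluster_and_cut(
    tom: np.ndarray, params: NetworkParams, gene_ids: list[str] | None = None
) -> ModuleSet:
    """Average-linkage clustering of 1 - TOM with a dynamic branch cut.

    Branches below ``cut_height`` of size >= ``min_module_size`` become modules
    (optionally split further, see ``deep_split``).  Leftover genes are rescued into the
    module with the highest mean TOM to its members when (a) that exceeds their mean TOM
    to non-members and (b) their mean dissimilarity to the module is below ``cut_height``
    (module genes are network hubs, so condition (a) alone would absorb pure-noise
    genes); otherwise they stay unassigned.
    """
    n = tom.shape[0]
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(n)]
    if params.min_module_size > n:
        warnings.warn("min_module_size exceeds gene count: everything unassigned")
        return ModuleSet({g: UNASSIGNED for g in gene_ids})

    diss = 1.0 - tom
    np.fill_diagonal(diss, 0.0)
    link = linkage(squareform(diss, checks=False), method="average")
    root = to_tree(link)

    branches: list[list[int]] = []
    leftovers: list[int] = []

    def descend(node: ClusterNode) -> None:
        if node.dist <= params.cut_height:
            leaves = _collect_leaves(node)
            if len(leaves) >= params.min_module_size:
                branches.extend(_split_branch(node, params.deep_split, params.min_module_size))
            else:
                leftovers.extend(leaves)
            return
        if node.is_leaf():
            leftovers.append(node.id)
            return
        descend(node.get_left())
        descend(node.get_right())

    descend(root)

    # order modules by size (largest first) for stable labels
    branches.sort(key=lambda b: (-len(b), min(b)))
    assignment = np.full(n, -1, dtype=int)
    for m, members in enumerate(branches):
        assignment[members] = m

    # rescue leftovers by mean TOM to module members vs non-members
    for i in leftovers:
        best_m, best_mean = -1, -np.inf
        for m, members in enumerate(branches):
            mean_tom = tom[i, members].mean()
            if mean_tom > best_mean:
                best_mean, best_m = mean_tom, m
        if best_m >= 0 and (1.0 - best_mean) <= params.cut_height:
            member_set = set(branches[best_m])
            non_members = [j for j in range(n) if j != i and j not in member_set]
            outside = tom[i, non_members].mean() if non_members else 0.0
            if best_mean > outside:
                assignment[i] = best_m

    out = {
        gene_ids[i]: (f"M{assignment[i] + 1}" if assignment[i] >= 0 else UNASSIGNED)
        for i in range(n)
    }
    return ModuleSet(out)


def module_eigengene(data: ExpressionDataset, module_genes: list[str]) -> np.ndarray:
    """First principal component of the per-gene standardized module submatrix.

    Returned with unit norm, oriented so that its correlation with the module's mean
    expression profile is non-negative (PCA sign is otherwise arbitrary).
    """
    if len(module_genes) < 2:
        raise ValueError("module eigengene needs at least 2 genes")
    idx = [data.gene_ids.index(g) for g in module_genes]
    sub = data.values[idx]
    sd = sub.std(axis=1, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("module contains a constant gene row")
    z = (sub - sub.mean(axis=1, keepdims=True)) / sd
    # first right singular vector spans the sample axis
    _, _, vt = np.linalg.svd(z, full_matrices=False)
    eig = vt[0]
    eig = eig / np.linalg.norm(eig)
    mean_profile = z.mean(axis=0)
    if np.dot(eig, mean_profile - mean_profile.mean()) < 0:
        eig = -eig
    return eig


def merge_modules(
    data: ExpressionDataset, modules: ModuleSet, me_diss_threshold: float
) -> ModuleSet:
    """Merge modules whose eigengenes are nearly parallel.

    Repeatedly merges the closest module pair with eigengene dissimilarity
    ``1 - cor(E_a, E_b) < me_diss_threshold``, recomputing eigengenes after each merge,
    until no such pair remains.  Idempotent; a threshold of 0 is the identity.
    """
    if me_diss_threshold <= 0:
        return modules
    groups = modules.modules()
    while len(groups) >= 2:
        labels = sorted(groups)
        eigs = np.array([module_eigengene(data, groups[m]) for m in labels])
        corr = np.corrcoef(eigs)
        diss = 1.0 - corr
        np.fill_diagonal(diss, np.inf)
        i, j = np.unravel_index(np.argmin(diss), diss.shape)
        if diss[i, j] >= me_diss_threshold:
            break
        keep, absorb = sorted((labels[i], labels[j]))
        groups[keep] = groups[keep] + groups[absorb]
        del groups[absorb]
    assignment = {g: UNASSIGNED for g in modules.assignment}
    # relabel by size for stable output
    ordered = sorted(groups.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    for m, (_, genes) in enumerate(ordered):
        for g in genes:
            assignment[g] = f"M{m + 1}"
    return ModuleSet(assignment)


def _pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r with the two-sided p-value from the t statistic on n-2 df."""
    n = len(x)
    if np.std(y) == 0 or np.std(x) == 0:
        warnings.warn("constant vector in correlation: r undefined, p set to 1")
        return np.nan, 1.0
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return r, float(p)


def module_trait_correlation(
    data: ExpressionDataset,
    modules: ModuleSet,
    trait_p_threshold: float = 0.05,
) -> ModuleTraitResult:
    """Pearson correlation of each module eigengene with each trait.

    p-values are two-sided from the exact t distribution with n - 2 degrees of freedom;
    no multiplicity adjustment is applied at this stage (each module-trait cell is
    tested on its own).
    """
    if data.n_samples < 3:
        raise ValueError("need at least 3 samples for eigengene-trait correlation")
    labels = modules.labels
    groups = modules.modules()
    eigs = np.array([module_eigengene(data, groups[m]) for m in labels]) if labels else np.empty((0, data.n_samples))
    trait_names = list(data.traits.columns)
    r = np.zeros((len(labels), len(trait_names)))
    p = np.ones((len(labels), len(trait_names)))
    for i in range(len(labels)):
        for j, t in enumerate(trait_names):
            r[i, j], p[i, j] = _pearson_with_p(eigs[i], data.traits[t].to_numpy(dtype=float))
    return ModuleTraitResult(
        module_labels=labels,
        sample_ids=list(data.sample_ids),
        eigengenes=eigs,
        r=pd.DataFrame(r, index=labels, columns=trait_names),
        p=pd.DataFrame(p, index=labels, columns=trait_names),
        trait_p_threshold=trait_p_threshold,
    )


def detect_modules(data: ExpressionDataset, params: NetworkParams) -> ModuleSet:
    """Full single-tissue module detection: correlation -> adjacency -> TOM -> cut -> merge."""
    corr = correlation_matrix(data)
    adj = soft_adjacency(corr, params)
    tom = tom_similarity(adj)
    modules = cluster_and_cut(tom, params, gene_ids=data.gene_ids)
    if modules.labels:
        modules = merge_modules(data, modules, params.me_diss_threshold)
    return modules
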