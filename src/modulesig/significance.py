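"""Cross-tissue module-pair scoring and permutation significance.

For n modules A_1..A_n in blood and m modules B_1..B_m in a brain region, the pair
similarity S_ij is the number of overlapping top-K annotations (or, as a baseline,
overlapping mapped genes).  Significance comes from a random-module null: K_A x K_B
sets of random modules of exactly the original sizes are scored for every pair
((A_ik, B_jl), giving K_A*K_B null scores per pair (10,000 at the defaults), and the
familywise error rate over the n x m comparisons is controlled with Westfall-Young
step-down minP.  Discrete scores make minP conservative, which motivates the 10%
strict and 50% marginal significance levels used downstream.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Protocol

import numpy as np
import pandas as pd

from .annotate import ModuleAnnotation, ModuleAnnotator
from .network import ModuleTraitResult

logger = logging.getLogger(__name__)

STRICT_FWER = 0.10
MARGINAL_FWER = 0.50


def annotation_overlap(a: ModuleAnnotation, b: ModuleAnnotation) -> int:
    """Number of annotation concepts shared by two modules' top-K lists (scores ignored)."""
    if a.category != b.category:
        raise ValueError(f"category mismatch: {a.category!r} vs {b.category!r}")
    return len(a.concepts & b.concepts)


def gene_overlap(
    module_a_genes: list[str], module_b_genes: list[str], id_map: dict[str, str]
) -> int:
    """Number of genes shared by two modules after mapping A's identifiers into B's."""
    if not id_map:
        warnings.warn("empty gene-identifier mapping: all gene overlaps are 0")
        return 0
    mapped = {id_map[g] for g in module_a_genes if g in id_map}
    return len(mapped & set(module_b_genes))


class PairScorer(Protocol):
    """Common interface of the annotation-overlap and gene-overlap scoring routes.

    A module is reduced to a boolean membership mask over a fixed item space (top-K
    annotation concepts, or mapped gene identifiers); the pair score is the mask
    intersection size.  Both routes therefore share all permutation machinery.
    """

    def item_mask_a(self, module_genes: list[str]) -> np.ndarray: ...

    def item_mask_b(self, module_genes: list[str]) -> np.ndarray: ...


@dataclass
class AnnotationOverlapScorer:
    annotator_a: ModuleAnnotator
    annotator_b: ModuleAnnotator
    category: str

    def item_mask_a(self, module_genes: list[str]) -> np.ndarray:
        return self.annotator_a.top_concept_mask(module_genes, self.category)

    def item_mask_b(self, module_genes: list[str]) -> np.ndarray:
        return self.annotator_b.top_concept_mask(module_genes, self.category)


@dataclass
class GeneOverlapScorer:
    """Baseline scorer: modules overlap when their (mapped) gene sets intersect."""

    id_map: dict[str, str]
    universe_b: list[str]
    _idx: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self.id_map:
            warnings.warn("empty gene-identifier mapping: all gene overlaps are 0")
        self._idx = {g: i for i, g in enumerate(self.universe_b)}

    def _mask(self, ids) -> np.ndarray:
        mask = np.zeros(len(self.universe_b), dtype=bool)
        for g in ids:
            i = self._idx.get(g)
            if i is not None:
                mask[i] = True
        return mask

    def item_mask_a(self, module_genes: list[str]) -> np.ndarray:
        return self._mask(self.id_map.get(g) for g in module_genes)

    def item_mask_b(self, module_genes: list[str]) -> np.ndarray:
        return self._mask(module_genes)


@dataclass
class PairScoreMatrix:
    """Observed similarity scores for all blood x brain module pairs in one category."""

    category: str
    labels_a: list[str]
    labels_b: list[str]
    scores: np.ndarray  # n x m integer matrix

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=self.labels_a, columns=self.labels_b)


@dataclass
class PermutationNull:
    """Null similarity scores S_ijkl from the K_A x K_B random-module cross."""

    category: str
    null_scores: np.ndarray  # n x m x (K_A * K_B)
    k_a: int
    k_b: int

    @property
    def n_replicates(self) -> int:
        return self.k_a * self.k_b


@dataclass
class PairSignificance:
    """Raw and minP-adjusted permutation p-values for every module pair."""

    category: str
    labels_a: list[str]
    labels_b: list[str]
    observed: np.ndarray
    raw_p: np.ndarray
    adjusted_p: np.ndarray
    strict_threshold: float = STRICT_FWER
    marginal_threshold: float = MARGINAL_FWER

    def frame(self) -> pd.DataFrame:
        rows = []
        for i, a in enumerate(self.labels_a):
            for j, b in enumerate(self.labels_b):
                adj = self.adjusted_p[i, j]
                rows.append(
                    {
                        "module_a": a,
                        "module_b": b,
                        "category": self.category,
                        "score": int(self.observed[i, j]),
                        "raw_p": self.raw_p[i, j],
                        "adjusted_p": adj,
                        "strict": adj <= self.strict_threshold,
                        "marginal": self.strict_threshold < adj <= self.marginal_threshold,
                    }
                )
        return pd.DataFrame(rows)


@dataclass
class Signature:
    """A blood-brain module pair passing both the FWER and the trait-association test."""

    module_a: str
    module_b: str
    category: str
    score: int
    adjusted_p: float
    strict: bool  # strict (FWER <= 10%) vs marginal (10% < FWER <= 50%)
    shared_concepts: list[str]
    min_trait_p_a: float
    min_trait_p_b: float


def score_pairs(
    scorer: PairScorer,
    modules_a: dict[str, list[str]],
    modules_b: dict[str, list[str]],
    category: str,
) -> PairScoreMatrix:
    """Observed S_ij for every module pair."""
    labels_a, labels_b = sorted(modules_a), sorted(modules_b)
    masks_a = np.array([scorer.item_mask_a(modules_a[a]) for a in labels_a])
    masks_b = np.array([scorer.item_mask_b(modules_b[b]) for b in labels_b])
    scores = masks_a.astype(np.int64) @ masks_b.T.astype(np.int64)
    return PairScoreMatrix(category=category, labels_a=labels_a, labels_b=labels_b, scores=scores)


def random_module_sets(
    universe: list[str],
    sizes: list[int],
    k: int = 100,
    rng: np.random.Generator | int | None = None,
) -> list[list[list[str]]]:
    """K replicates of disjoint random modules matching the original sizes exactly.

    Each replicate permutes the gene universe and slices consecutive blocks, so the
    random modules replicate the partition structure of the real module set.
    """
    if sum(sizes) > len(universe):
        raise ValueError(
            f"total module size {sum(sizes)} exceeds universe of {len(universe)} genes"
        )
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    universe = list(universe)
    replicates = []
    for _ in range(k):
        perm = rng.permutation(len(universe))
        offset, modules = 0, []
        for s in sizes:
            modules.append([universe[i] for i in perm[offset : offset + s]])
            offset += s
        replicates.append(modules)
    return replicates


def build_null(
    scorer: PairScorer,
    random_sets_a: list[list[list[str]]],
    random_sets_b: list[list[list[str]]],
    category: str,
) -> PermutationNull:
    """Score every random pair (A_ik, B_jl): the full K_A x K_B cross per module pair."""
    k_a, k_b = len(random_sets_a), len(random_sets_b)
    n, m = len(random_sets_a[0]), len(random_sets_b[0])
    # masks: (K, n_modules, n_items)
    masks_a = np.array(
        [[scorer.item_mask_a(mod) for mod in rep] for rep in random_sets_a], dtype=np.int64
    )
    masks_b = np.array(
        [[scorer.item_mask_b(mod) for mod in rep] for rep in random_sets_b], dtype=np.int64
    )
    # S[i, j, k, l] = masks_a[k, i] . masks_b[l, j]
    s = np.einsum("kit,ljt->ijkl", masks_a, masks_b)
    return PermutationNull(
        category=category, null_scores=s.reshape(n, m, k_a * k_b), k_a=k_a, k_b=k_b
    )


def minp_adjust(observed: PairScoreMatrix, null: PermutationNull) -> PairSignificance:
    """Westfall-Young step-down minP adjustment of the permutation p-values.

    Raw p_ij = (1 + #{replicates with null score >= S_ij}) / (1 + R): with R = 10,000
    a pair can only reach the 10% level when its observed score is the most extreme
    among all permutations.  Ties count as extreme (>=), which is conservative for
    discrete scores.  Per-replicate p-values use the same >= convention against the
    pair's own null distribution; the step-down adjusted p of the h-th hypothesis (in
    ascending raw-p order) is the +1-corrected fraction of replicates whose minimum
    per-replicate p over hypotheses h..last is <= raw p_h, made monotone by a running
    maximum.
    """
    if null.n_replicates == 0:
        raise ValueError("permutation null has zero replicates")
    s_obs = observed.scores
    s_null = null.null_scores  # n x m x R
    n, m, r = s_null.shape
    if s_obs.shape != (n, m):
        raise ValueError("observed score matrix does not match the null's pair grid")

    exceed = (s_null >= s_obs[:, :, None]).sum(axis=2)
    raw_p = (1.0 + exceed) / (1.0 + r)

    # per-replicate empirical p: rank of each null score within its pair's own null
    flat_null = s_null.reshape(n * m, r)
    null_p = np.empty((n * m, r))
    for q in range(n * m):
        srt = np.sort(flat_null[q])
        ge = r - np.searchsorted(srt, flat_null[q], side="left")
        null_p[q] = (1.0 + ge) / (1.0 + r)

    flat_raw = raw_p.reshape(-1)
    flat_null_p = null_p
    h_order = np.argsort(flat_raw, kind="stable")

    # successive minima of per-replicate p over hypotheses h..last
    adjusted = np.empty(n * m)
    run_min = np.full(r, np.inf)
    for h in reversed(range(n * m)):
        idx = h_order[h]
        run_min = np.minimum(run_min, flat_null_p[idx])
        adjusted[h] = (1.0 + (run_min <= flat_raw[idx]).sum()) / (1.0 + r)
    # monotone enforcement in ascending raw-p order
    adjusted = np.maximum.accumulate(adjusted)
    adj = np.empty(n * m)
    adj[h_order] = adjusted

    return PairSignificance(
        category=observed.category,
        labels_a=observed.labels_a,
        labels_b=observed.labels_b,
        observed=s_obs,
        raw_p=raw_p,
        adjusted_p=adj.reshape(n, m),
    )


def classify_signatures(
    sig: PairSignificance,
    annotations_a: dict[str, ModuleAnnotation],
    annotations_b: dict[str, ModuleAnnotation],
    traits_a: ModuleTraitResult,
    traits_b: ModuleTraitResult,
    trait_p_threshold: float = 0.05,
) -> list[Signature]:
    """Common disease signatures: FWER-significant pairs whose two modules are each
    trait-associated (minimum trait p < threshold).

    Pairs with adjusted p <= 10% are strict signatures; pairs in (10%, 50%] are
    flagged as marginal.  Each signature reports the shared annotation concepts.
    """
    min_p_a = traits_a.min_trait_p()
    min_p_b = traits_b.min_trait_p()
    out: list[Signature] = []
    for i, a in enumerate(sig.labels_a):
        for j, b in enumerate(sig.labels_b):
            adj = float(sig.adjusted_p[i, j])
            if adj > sig.marginal_threshold:
                continue
            if a not in min_p_a or b not in min_p_b:
                raise ValueError(f"missing trait results for significant pair ({a}, {b})")
            if min_p_a[a] >= trait_p_threshold or min_p_b[b] >= trait_p_threshold:
                continue
            shared = sorted(annotations_a[a].concepts & annotations_b[b].concepts)
            out.append(
                Signature(
                    module_a=a,
                    module_b=b,
                    category=sig.category,
                    score=int(sig.observed[i, j]),
                    adjusted_p=adj,
                    strict=adj <= sig.strict_threshold,
                    shared_concepts=shared,
                    min_trait_p_a=min_p_a[a],
                    min_trait_p_b=min_p_b[b],
                )
            )
    out.sort(key=lambda s: (s.adjusted_p, s.module_a, s.module_b))
    return out
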