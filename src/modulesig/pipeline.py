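"""End-to-end workflow: modules -> annotation -> pairing -> significance -> signatures.

One call runs both tissues through module detection, annotates every module per
semantic category, scores all cross-tissue module pairs by annotation overlap, builds
the shared random-module permutation null, adjusts with step-down minP, and classifies
common disease signatures.  The random module sets are drawn once per tissue and
reused across every category (and the gene-overlap baseline), so all scoring routes
share the same permutation draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotate import DEFAULT_TOP_K, ModuleAnnotation, ModuleAnnotator
from .network import (
    ExpressionDataset,
    ModuleSet,
    ModuleTraitResult,
    NetworkParams,
    detect_modules,
    module_trait_correlation,
)
from .profiles import CATEGORIES, Corpus, ProfileStore
from .significance import (
    MARGINAL_FWER,
    STRICT_FWER,
    AnnotationOverlapScorer,
    GeneOverlapScorer,
    PairSignificance,
    Signature,
    build_null,
    classify_signatures,
    minp_adjust,
    random_module_sets,
    score_pairs,
)


@dataclass
class AnalysisParams:
    """All tunables of the cross-tissue analysis (module detection aside)."""

    k_annotations: int = DEFAULT_TOP_K
    min_docs: int = 5
    k_a: int = 100
    k_b: int = 100
    strict_threshold: float = STRICT_FWER
    marginal_threshold: float = MARGINAL_FWER
    trait_p_threshold: float = 0.05
    categories: tuple[str, ...] = CATEGORIES
    seed: int = 0

    def __post_init__(self) -> None:
        for thr in (self.strict_threshold, self.marginal_threshold, self.trait_p_threshold):
            if not 0 < thr <= 1:
                raise ValueError("thresholds must lie in (0, 1]")
        if self.k_a < 1 or self.k_b < 1:
            raise ValueError("permutation replicate counts must be positive")


@dataclass
class SignatureReport:
    """Everything the analysis produced, per tissue and per semantic category."""

    tissue_a: str
    tissue_b: str
    modules: dict[str, ModuleSet]
    trait_results: dict[str, ModuleTraitResult]
    annotations: dict[str, dict[str, dict[str, ModuleAnnotation]]]  # tissue -> cat -> module
    significance: dict[str, PairSignificance]  # category -> pair significance
    signatures: dict[str, list[Signature]]  # category -> signatures
    gene_overlap_significance: PairSignificance | None = None
    params: AnalysisParams = field(default_factory=AnalysisParams)

    def summary_counts(self) -> pd.DataFrame:
        """Strict/marginal significant-pair counts per category (machine Fig.-3 analog)."""
        rows = []
        for cat, sig in self.significance.items():
            frame = sig.frame()
            rows.append(
                {
                    "category": cat,
                    "strict_pairs": int(frame["strict"].sum()),
                    "marginal_pairs": int(frame["marginal"].sum()),
                    "strict_signatures": sum(s.strict for s in self.signatures[cat]),
                    "marginal_signatures": sum(not s.strict for s in self.signatures[cat]),
                }
            )
        return pd.DataFrame(rows)

    def all_signatures(self) -> list[Signature]:
        return [s for cat in sorted(self.signatures) for s in self.signatures[cat]]

    def report_text(self) -> str:
        """Deterministic human-readable report body (no timestamps)."""
        lines = [
            f"Cross-tissue module signature report: {self.tissue_a} vs {self.tissue_b}",
            "",
        ]
        for tissue in (self.tissue_a, self.tissue_b):
            sizes = self.modules[tissue].sizes()
            lines.append(f"[{tissue}] {len(sizes)} modules: " + ", ".join(
                f"{m}={s}" for m, s in sizes.items()
            ))
            assoc = self.trait_results[tissue].disease_associated()
            flagged = sorted(m for m, a in assoc.items() if a)
            lines.append(f"[{tissue}] trait-associated modules: {flagged or 'none'}")
        lines.append("")
        lines.append(self.summary_counts().to_string(index=False))
        lines.append("")
        for cat in sorted(self.signatures):
            for s in self.signatures[cat]:
                kind = "strict" if s.strict else "marginal"
                lines.append(
                    f"signature [{kind}] {s.module_a} ~ {s.module_b} ({cat}): "
                    f"overlap={s.score}, FWER={s.adjusted_p:.4g}, "
                    f"shared={','.join(s.shared_concepts)}"
                )
        if not any(self.signatures.values()):
            lines.append("no common signatures at the configured thresholds")
        return "\n".join(lines) + "\n"


def summarize_similarity(significance: dict[str, PairSignificance]) -> pd.DataFrame:
    """Per-category counts of strict and marginal significant pairs."""
    rows = []
    for cat in sorted(significance):
        frame = significance[cat].frame()
        rows.append(
            {
                "category": cat,
                "strict_pairs": int(frame["strict"].sum()),
                "marginal_pairs": int(frame["marginal"].sum()),
            }
        )
    return pd.DataFrame(rows)


def analyze_study(
    datasets: dict[str, ExpressionDataset],
    corpus: Corpus,
    network_params: dict[str, NetworkParams],
    params: AnalysisParams | None = None,
    concept_sets: dict[str, list[str]] | None = None,
    gene_id_map: dict[str, str] | None = None,
    modules: dict[str, ModuleSet] | None = None,
) -> SignatureReport:
    """Run the full two-tissue analysis on in-memory inputs.

    ``datasets`` maps exactly two tissue labels to their expression data; the first is
    treated as blood (tissue A).  ``concept_sets`` defaults to the corpus's declared
    annotation categories.  Pre-computed ``modules`` can be supplied to skip detection.
    """
    params = params or AnalysisParams()
    tissues = list(datasets)
    if len(tissues) != 2:
        raise ValueError("analysis needs exactly two tissues")
    tissue_a, tissue_b = tissues

    if modules is None:
        modules = {t: detect_modules(datasets[t], network_params[t]) for t in tissues}
    trait_results = {
        t: module_trait_correlation(datasets[t], modules[t], params.trait_p_threshold)
        for t in tissues
    }

    if concept_sets is None:
        concept_sets = {
            cat: corpus.concepts_in_category(cat)
            for cat in params.categories
            if corpus.concepts_in_category(cat)
        }
    profiles = ProfileStore.from_corpus(corpus, min_docs=params.min_docs)
    annotators = {
        t: ModuleAnnotator(
            profiles, concept_sets, universe=modules[t].universe, k=params.k_annotations
        )
        for t in tissues
    }

    annotations: dict[str, dict[str, dict[str, ModuleAnnotation]]] = {t: {} for t in tissues}
    for t in tissues:
        groups = modules[t].modules()
        for cat in concept_sets:
            annotations[t][cat] = {
                m: annotators[t].annotate(m, genes, cat) for m, genes in groups.items()
            }

    # one shared permutation draw per tissue, reused across categories and routes
    seed = params.seed % (2**31)
    sizes = {t: [len(g) for _, g in sorted(modules[t].modules().items())] for t in tissues}
    random_sets = {
        tissue_a: random_module_sets(
            modules[tissue_a].universe, sizes[tissue_a], k=params.k_a,
            rng=np.random.default_rng([seed, 101]),
        ),
        tissue_b: random_module_sets(
            modules[tissue_b].universe, sizes[tissue_b], k=params.k_b,
            rng=np.random.default_rng([seed, 102]),
        ),
    }

    significance: dict[str, PairSignificance] = {}
    signatures: dict[str, list[Signature]] = {}
    for cat in concept_sets:
        scorer = AnnotationOverlapScorer(annotators[tissue_a], annotators[tissue_b], cat)
        observed = score_pairs(
            scorer, modules[tissue_a].modules(), modules[tissue_b].modules(), cat
        )
        null = build_null(scorer, random_sets[tissue_a], random_sets[tissue_b], cat)
        sig = minp_adjust(observed, null)
        sig.strict_threshold = params.strict_threshold
        sig.marginal_threshold = params.marginal_threshold
        significance[cat] = sig
        signatures[cat] = classify_signatures(
            sig,
            annotations[tissue_a][cat],
            annotations[tissue_b][cat],
            trait_results[tissue_a],
            trait_results[tissue_b],
            params.trait_p_threshold,
        )

    gene_sig = None
    if gene_id_map:
        scorer = GeneOverlapScorer(gene_id_map, universe_b=modules[tissue_b].universe)
        observed = score_pairs(
            scorer, modules[tissue_a].modules(), modules[tissue_b].modules(), "gene_overlap"
        )
        null = build_null(scorer, random_sets[tissue_a], random_sets[tissue_b], "gene_overlap")
        gene_sig = minp_adjust(observed, null)
        gene_sig.strict_threshold = params.strict_threshold
        gene_sig.marginal_threshold = params.marginal_threshold

    return SignatureReport(
        tissue_a=tissue_a,
        tissue_b=tissue_b,
        modules=modules,
        trait_results=trait_results,
        annotations=annotations,
        significance=significance,
        signatures=signatures,
        gene_overlap_significance=gene_sig,
        params=params,
    )
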