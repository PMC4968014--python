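"""Synthetic study generator: expression, traits, and a literature-like corpus.

Emulates the statistical structure of a two-tissue disease-transcriptomics study:

* Each planted module is driven by a single latent factor per sample (the eigengene
  analogue); module genes are ``loading * factor + N(0, noise_sd)`` and background
  genes are pure noise.
* Clinical traits (binary carrier status; continuous CAG repeat length, motor score,
  and TFC, with TFC anti-correlated with motor score) are drawn first; module factors
  are built as linear combinations of the standardized traits so the factor-trait
  correlations converge to configured targets.
* The corpus is a bag-of-concepts document collection.  Every gene and annotation
  concept occurs independently at a background rate; on top of that, each annotation
  concept has its own small literature: topic documents in which it co-occurs with its
  linked genes.  A shared-function annotation concept is linked to the genes of the
  modules carrying that function in BOTH tissues; a background annotation concept is
  linked to a few random genes.  Topic-document counts are calibrated so a linked
  gene-annotation pair co-occurs at ``cooccurrence_enrichment`` times the background
  joint rate (enrichment 1 adds no topic documents at all).  The two tissues use
  disjoint gene identifiers but shared-function module pairs point at the SAME
  annotation concepts — function conserved across tissues, gene membership not.

Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import ExpressionDataset
from .profiles import CATEGORIES, Corpus

TRAIT_NAMES = ("carrier", "cag", "motor", "tfc")

#: correlation between motor score and TFC in the trait generator (TFC drops as the
#: motor score worsens)
MOTOR_TFC_CORRELATION = -0.7


@dataclass
class ModuleSpec:
    """One planted co-expression module."""

    module_id: str
    n_genes: int
    trait_effects: dict[str, float] = field(default_factory=dict)
    shared_function_id: str | None = None
    loading: float = 1.0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("module must contain at least one gene")
        for t, r in self.trait_effects.items():
            if t not in TRAIT_NAMES:
                raise ValueError(f"unknown trait {t!r}; traits are {TRAIT_NAMES}")
            if not -1.0 <= r <= 1.0:
                raise ValueError(f"trait correlation target {r} outside [-1, 1]")


@dataclass
class SimulationConfig:
    """Study conditions for one simulated two-tissue experiment."""

    n_samples_per_tissue: int = 40
    module_specs: list[ModuleSpec] = field(default_factory=list)
    n_background_genes: int = 60
    noise_sd: float = 0.5
    corpus_n_docs: int = 1500
    docs_per_concept: int = 5
    cooccurrence_enrichment: float = 5.0
    seed: int = 0
    tissues: tuple[str, str] = ("blood", "brain")
    n_annotations_per_category: int = 40
    concepts_per_function: int = 10
    concept_base_rate: float = 0.02
    background_link_size: int = 12

    def __post_init__(self) -> None:
        if self.n_samples_per_tissue <= 0 or self.n_background_genes < 0:
            raise ValueError("counts must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.docs_per_concept < 5:
            raise ValueError("docs_per_concept must be >= 5 so every concept earns a profile")
        if self.cooccurrence_enrichment < 1:
            raise ValueError("cooccurrence_enrichment must be >= 1")
        if self.corpus_n_docs <= 0:
            raise ValueError("corpus_n_docs must be positive")
        total_genes = sum(s.n_genes for s in self.module_specs) + self.n_background_genes
        if total_genes == 0:
            raise ValueError("configuration generates zero genes")
        if self.noise_sd > 0:
            for s in self.module_specs:
                if any(abs(r) == 1.0 for r in s.trait_effects.values()):
                    raise ValueError(
                        "correlation target of magnitude 1 is incompatible with nonzero noise"
                    )


@dataclass
class GroundTruth:
    """What was planted, for recovery checks downstream."""

    tissue: str
    gene_module: dict[str, str]  # gene -> planted module id ("background" for noise genes)
    shared_functions: dict[str, str]  # module id -> function id (only modules that have one)
    trait_effects: dict[str, dict[str, float]]  # module id -> trait -> target r

    def module_genes(self, module_id: str) -> list[str]:
        return [g for g, m in self.gene_module.items() if m == module_id]


def _tissue_rng(config: SimulationConfig, tissue: str, stream: int) -> np.random.Generator:
    tissue_idx = config.tissues.index(tissue)
    return np.random.default_rng([config.seed % (2**31), tissue_idx, stream])


def _generate_traits(rng: np.random.Generator, n: int) -> pd.DataFrame:
    """Carrier status is balanced binary; CAG/motor continuous; TFC tracks -motor."""
    carrier = np.zeros(n)
    carrier[rng.permutation(n)[: n // 2]] = 1.0
    cag = rng.normal(size=n)
    motor = rng.normal(size=n)
    rho = MOTOR_TFC_CORRELATION
    tfc = rho * motor + np.sqrt(1 - rho**2) * rng.normal(size=n)
    return pd.DataFrame(
        {"carrier": carrier, "cag": cag, "motor": motor, "tfc": tfc},
        index=[f"s{i:03d}" for i in range(n)],
    )


def _standardize(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std()


def _module_factor(
    rng: np.random.Generator, traits: pd.DataFrame, effects: dict[str, float]
) -> np.ndarray:
    """A latent factor whose empirical correlation with each trait targets ``effects``.

    With z the standardized trait vectors and Sigma their empirical correlation matrix,
    the factor ``z @ (Sigma^-1 r) + c * eps`` has expected trait correlations exactly r;
    c absorbs the remaining variance (requires r' Sigma^-1 r <= 1).
    """
    n = len(traits)
    if not effects:
        return rng.normal(size=n)
    names = [t for t in TRAIT_NAMES if t in effects]
    z = np.column_stack([_standardize(traits[t].to_numpy(dtype=float)) for t in names])
    r = np.array([effects[t] for t in names])
    sigma = (z.T @ z) / n
    b = np.linalg.solve(sigma, r)
    explained = float(r @ b)
    if explained > 1.0:
        raise ValueError(
            f"trait correlation targets {effects} jointly demand variance {explained:.2f} > 1"
        )
    factor = z @ b + np.sqrt(max(0.0, 1.0 - explained)) * rng.normal(size=n)
    return factor


def generate_expression(
    config: SimulationConfig, tissue: str
) -> tuple[ExpressionDataset, GroundTruth]:
    """Simulate one tissue: traits, module factors, and the gene expression matrix."""
    if tissue not in config.tissues:
        raise ValueError(f"unknown tissue {tissue!r}; configured tissues are {config.tissues}")
    prefix = tissue[:2].upper()
    n = config.n_samples_per_tissue
    rng = _tissue_rng(config, tissue, stream=0)
    traits = _generate_traits(rng, n)

    gene_ids: list[str] = []
    rows: list[np.ndarray] = []
    gene_module: dict[str, str] = {}
    for spec in config.module_specs:
        factor = _module_factor(rng, traits, spec.trait_effects)
        for g in range(spec.n_genes):
            gid = f"{prefix}_{spec.module_id}_g{g:03d}"
            gene_ids.append(gid)
            gene_module[gid] = spec.module_id
            rows.append(spec.loading * factor + config.noise_sd * rng.normal(size=n))
    for g in range(config.n_background_genes):
        gid = f"{prefix}_bg_g{g:03d}"
        gene_ids.append(gid)
        gene_module[gid] = "background"
        rows.append(rng.normal(size=n))

    dataset = ExpressionDataset(
        gene_ids=gene_ids,
        sample_ids=list(traits.index),
        values=np.array(rows),
        traits=traits,
    )
    truth = GroundTruth(
        tissue=tissue,
        gene_module=gene_module,
        shared_functions={
            s.module_id: s.shared_function_id
            for s in config.module_specs
            if s.shared_function_id is not None
        },
        trait_effects={s.module_id: dict(s.trait_effects) for s in config.module_specs},
    )
    return dataset, truth


def function_annotation_concepts(config: SimulationConfig) -> dict[str, dict[str, list[str]]]:
    """function id -> category -> planted annotation concept IDs (shared across tissues)."""
    functions = sorted(
        {s.shared_function_id for s in config.module_specs if s.shared_function_id is not None}
    )
    out: dict[str, dict[str, list[str]]] = {}
    for f_idx, fn in enumerate(functions):
        per_cat: dict[str, list[str]] = {}
        for cat in CATEGORIES:
            start = f_idx * config.concepts_per_function
            per_cat[cat] = [
                f"{cat}:c{start + j:03d}" for j in range(config.concepts_per_function)
            ]
        out[fn] = per_cat
    return out


def generate_corpus(
    config: SimulationConfig, truths: dict[str, GroundTruth]
) -> tuple[Corpus, dict[str, dict[str, list[str]]]]:
    """Simulate the document corpus over gene and annotation concepts.

    Returns the corpus plus the planted function -> category -> annotation-concept map.
    Background occurrences are independent Bernoulli(concept_base_rate) per document.
    Every annotation concept then receives topic documents containing the concept and a
    random subset of its linked genes (shared-function concepts link to the carrying
    modules' genes in both tissues; background concepts link to
    ``background_link_size`` random genes), calibrated so a linked gene-annotation pair
    co-occurs at ``cooccurrence_enrichment`` times the independence rate.  Enrichment 1
    adds no topic documents: the corpus is pure noise and planted pairs are
    statistically indistinguishable from background pairs.
    """
    if config.cooccurrence_enrichment < 1:
        raise ValueError("cooccurrence_enrichment must be >= 1")
    for t in config.tissues:
        if t not in truths:
            raise ValueError(f"ground truth missing for tissue {t!r}")
    rng = np.random.default_rng([config.seed % (2**31), 997])

    gene_concepts: list[str] = []
    for t in config.tissues:
        gene_concepts.extend(sorted(truths[t].gene_module))
    fn_concepts = function_annotation_concepts(config)
    annotation_concepts: list[str] = []
    vocabulary: dict[str, str] = {g: "gene" for g in gene_concepts}
    planted_by_cat: dict[str, set[str]] = {cat: set() for cat in CATEGORIES}
    for fn in sorted(fn_concepts):
        for cat, ids in fn_concepts[fn].items():
            planted_by_cat[cat].update(ids)
    for cat in CATEGORIES:
        planted = sorted(planted_by_cat[cat])
        n_extra = config.n_annotations_per_category - len(planted)
        if n_extra < 0:
            raise ValueError("n_annotations_per_category too small for the planted functions")
        background = [f"{cat}:bg{j:03d}" for j in range(n_extra)]
        for c in planted + background:
            vocabulary[c] = cat
            annotation_concepts.append(c)
    concepts = gene_concepts + annotation_concepts
    concept_idx = {c: i for i, c in enumerate(concepts)}

    # gene-link sets: shared-function concepts link to the carrying modules' genes in
    # both tissues; background annotation concepts link to a few random genes
    fn_gene_links: dict[str, list[str]] = {}
    for t in config.tissues:
        truth = truths[t]
        for module_id, fn in sorted(truth.shared_functions.items()):
            fn_gene_links.setdefault(fn, []).extend(sorted(truth.module_genes(module_id)))
    links: dict[str, list[str]] = {}
    for fn in sorted(fn_concepts):
        for cat in CATEGORIES:
            for c in fn_concepts[fn][cat]:
                links[c] = fn_gene_links[fn]
    for c in annotation_concepts:
        if c not in links:
            size = min(config.background_link_size, len(gene_concepts))
            links[c] = [gene_concepts[i] for i in rng.choice(len(gene_concepts), size, replace=False)]

    # topic documents: each contains the annotation concept plus each linked gene with
    # probability q; their count is calibrated so a linked gene-annotation pair's
    # expected joint document count is enrichment * p^2 * N
    p = config.concept_base_rate
    q_link = 0.6
    extra_joint = (config.cooccurrence_enrichment - 1.0) * p * p * config.corpus_n_docs
    n_topic = int(np.round(extra_joint / q_link))
    topic_rows: list[np.ndarray] = []
    for c in annotation_concepts:
        for _ in range(n_topic):
            row = np.zeros(len(concepts), dtype=bool)
            row[concept_idx[c]] = True
            g_mask = rng.random(len(links[c])) < q_link
            for g, keep in zip(links[c], g_mask):
                if keep:
                    row[concept_idx[g]] = True
            topic_rows.append(row)

    n_background_docs = config.corpus_n_docs - len(topic_rows)
    if n_background_docs <= 0:
        raise ValueError("corpus_n_docs too small for the requested enrichment")
    occurrence = rng.random((n_background_docs, len(concepts))) < p
    if topic_rows:
        occurrence = np.vstack([occurrence, np.array(topic_rows)])

    # top up rare concepts so every concept earns a profile (>= docs_per_concept docs)
    doc_freq = occurrence.sum(axis=0)
    for j in np.flatnonzero(doc_freq < config.docs_per_concept):
        missing = config.docs_per_concept - doc_freq[j]
        candidates = np.flatnonzero(~occurrence[:, j])
        add = rng.choice(candidates, size=missing, replace=False)
        occurrence[add, j] = True

    documents = [
        (f"d{i:05d}", frozenset(concepts[j] for j in np.flatnonzero(occurrence[i])))
        for i in range(occurrence.shape[0])
    ]
    return Corpus(documents=documents, vocabulary=vocabulary), fn_concepts


def generate_study(
    config: SimulationConfig,
) -> tuple[
    dict[str, ExpressionDataset],
    dict[str, GroundTruth],
    Corpus,
    dict[str, dict[str, list[str]]],
]:
    """Simulate both tissues plus the corpus in one call."""
    datasets: dict[str, ExpressionDataset] = {}
    truths: dict[str, GroundTruth] = {}
    for t in config.tissues:
        datasets[t], truths[t] = generate_expression(config, t)
    corpus, fn_concepts = generate_corpus(config, truths)
    return datasets, truths, corpus, fn_concepts


def scenario_network_params() -> "NetworkParams":
    """Module-detection settings used for the simulated scenarios.

    Soft power 9 (the value used for blood-type data), minimum module size 10 for the
    15-gene planted modules, no deep splitting, cut height 0.98 (trait-sharing module
    factors correlate, so a slightly lower cut keeps their branches apart), and a
    moderate eigengene-merge threshold.
    """
    from .network import NetworkParams

    return NetworkParams(
        soft_power=9,
        min_module_size=10,
        deep_split=0,
        cut_height=0.98,
        me_diss_threshold=0.15,
    )


def scenario_analysis_params(seed: int = 0, k_a: int = 20, k_b: int = 20):
    """Reduced-scale analysis settings for simulation studies.

    Top-10 annotation lists over 40-concept categories keep the overlap score
    discriminative at this corpus size; 20 x 20 random-module sets give 400 null
    scores per pair.
    """
    from .pipeline import AnalysisParams

    return AnalysisParams(k_annotations=10, k_a=k_a, k_b=k_b, seed=seed)


def strong_scenario(seed: int = 0, **overrides) -> SimulationConfig:
    """Default strong-signal study: two shared functions, one tissue-specific module.

    Module factors correlate with disease traits at 0.5-0.6 so every planted module is
    trait-associated at n = 40; co-occurrence enrichment 5 makes the planted
    annotations recoverable from the corpus.
    """
    params = dict(
        n_samples_per_tissue=40,
        module_specs=[
            ModuleSpec("m1", 15, {"carrier": 0.6, "cag": 0.4}, shared_function_id="f1"),
            ModuleSpec("m2", 15, {"motor": 0.55, "tfc": -0.45}, shared_function_id="f2"),
            ModuleSpec("m3", 15, {"carrier": 0.5}),
        ],
        n_background_genes=60,
        noise_sd=0.5,
        corpus_n_docs=1500,
        docs_per_concept=5,
        cooccurrence_enrichment=5.0,
        seed=seed,
    )
    params.update(overrides)
    return SimulationConfig(**params)


def null_scenario(seed: int = 0, **overrides) -> SimulationConfig:
    """Global-null study: trait-associated modules exist but share no function and the
    corpus carries no planted gene-annotation enrichment."""
    params = dict(
        n_samples_per_tissue=40,
        module_specs=[
            ModuleSpec("m1", 15, {"carrier": 0.6, "cag": 0.4}),
            ModuleSpec("m2", 15, {"motor": 0.55, "tfc": -0.45}),
        ],
        n_background_genes=60,
        noise_sd=0.5,
        corpus_n_docs=1500,
        docs_per_concept=5,
        cooccurrence_enrichment=1.0,
        seed=seed,
    )
    params.update(overrides)
    return SimulationConfig(**params)
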