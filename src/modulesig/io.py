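"""Readers and writers for the pipeline's plain-text interchange formats.

All tables are tab-separated with a header line.  The corpus is line-delimited
(document ID followed by whitespace-separated concept IDs) with a separate
concept-category vocabulary table; concept sets use a GMT-like layout
(set name, category, then member concept IDs).
"""

from __future__ import annotations

import pandas as pd
import yaml

from .annotate import ModuleAnnotation
from .network import ExpressionDataset, ModuleSet, ModuleTraitResult
from .profiles import Corpus
from .significance import PairSignificance


def write_expression(data: ExpressionDataset, expr_path, trait_path) -> None:
    frame = data.to_frame()
    frame.index.name = "gene_id"
    frame.to_csv(expr_path, sep="\t")
    traits = data.traits.copy()
    traits.index.name = "sample_id"
    traits.to_csv(trait_path, sep="\t")


def read_expression(expr_path, trait_path) -> ExpressionDataset:
    frame = pd.read_csv(expr_path, sep="\t", index_col=0, float_precision="round_trip")
    traits = pd.read_csv(trait_path, sep="\t", index_col=0, float_precision="round_trip")
    traits.index = traits.index.astype(str)
    return ExpressionDataset(
        gene_ids=[str(g) for g in frame.index],
        sample_ids=[str(s) for s in frame.columns],
        values=frame.to_numpy(dtype=float),
        traits=traits,
    )


def write_corpus(corpus: Corpus, docs_path, vocab_path) -> None:
    with open(docs_path, "w") as fh:
        for doc_id, concepts in corpus.documents:
            fh.write(doc_id + "\t" + " ".join(sorted(concepts)) + "\n")
    vocab = pd.DataFrame(
        sorted(corpus.vocabulary.items()), columns=["concept", "category"]
    )
    vocab.to_csv(vocab_path, sep="\t", index=False)


def read_corpus(docs_path, vocab_path) -> Corpus:
    documents = []
    with open(docs_path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            documents.append((parts[0], frozenset(parts[1:])))
    vocab_frame = pd.read_csv(vocab_path, sep="\t")
    vocabulary = dict(zip(vocab_frame["concept"], vocab_frame["category"]))
    return Corpus(documents=documents, vocabulary=vocabulary)


def write_concept_sets(concept_sets: dict[str, list[str]], path) -> None:
    """GMT-like: one line per set — set name, category, then member concept IDs."""
    with open(path, "w") as fh:
        for cat in sorted(concept_sets):
            fh.write("\t".join([f"{cat}_set", cat, *concept_sets[cat]]) + "\n")


def read_concept_sets(path) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                continue
            out[parts[1]] = parts[2:]
    return out


def write_modules(modules: ModuleSet, path) -> None:
    frame = pd.DataFrame(
        sorted(modules.assignment.items()), columns=["gene_id", "module"]
    )
    frame.to_csv(path, sep="\t", index=False)


def read_modules(path) -> ModuleSet:
    frame = pd.read_csv(path, sep="\t")
    return ModuleSet(dict(zip(frame["gene_id"].astype(str), frame["module"].astype(str))))


def write_trait_result(result: ModuleTraitResult, eig_path, r_path, p_path) -> None:
    eig = pd.DataFrame(
        result.eigengenes, index=result.module_labels, columns=result.sample_ids
    )
    eig.index.name = "module"
    eig.to_csv(eig_path, sep="\t")
    for frame, path in ((result.r, r_path), (result.p, p_path)):
        out = frame.copy()
        out.index.name = "module"
        out.to_csv(path, sep="\t")


def write_annotations(
    annotations: dict[str, dict[str, ModuleAnnotation]], path
) -> None:
    """Per-module annotation table: module, category, rank, concept, score."""
    rows = []
    for cat in sorted(annotations):
        for module in sorted(annotations[cat]):
            for rank, (concept, score) in enumerate(annotations[cat][module].ranked, 1):
                rows.append(
                    {"module": module, "category": cat, "rank": rank,
                     "concept": concept, "score": score}
                )
    pd.DataFrame(rows, columns=["module", "category", "rank", "concept", "score"]).to_csv(
        path, sep="\t", index=False
    )


def write_significance(sig_by_category: dict[str, PairSignificance], path) -> None:
    frames = [sig_by_category[cat].frame() for cat in sorted(sig_by_category)]
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def write_manifest(path, **entries) -> None:
    """Run manifest: seed, parameters, package version — everything needed to rerun."""
    from . import __version__

    payload = {"modulesig_version": __version__}
    payload.update(entries)
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)
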