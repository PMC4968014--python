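"""Shared fixtures: one strong-signal simulated study and its analysis, computed once."""

import numpy as np
import pytest

import modulesig as ms


@pytest.fixture(scope="session")
def strong_study():
    """Simulated two-tissue study with two planted shared functions (seed 1)."""
    config = ms.strong_scenario(seed=1)
    datasets, truths, corpus, fn_concepts = ms.generate_study(config)
    return {
        "config": config,
        "datasets": datasets,
        "truths": truths,
        "corpus": corpus,
        "fn_concepts": fn_concepts,
    }


@pytest.fixture(scope="session")
def strong_report(strong_study):
    """Full analysis of the strong study at reduced scale."""
    datasets = strong_study["datasets"]
    net = {t: ms.scenario_network_params() for t in datasets}
    return ms.analyze_study(
        datasets, strong_study["corpus"], net, ms.scenario_analysis_params(seed=1)
    )


@pytest.fixture()
def tiny_corpus():
    """Hand-sized corpus: 3 documents over 4 concepts."""
    docs = [
        ("d1", frozenset({"A", "B"})),
        ("d2", frozenset({"A"})),
        ("d3", frozenset({"B", "C"})),
    ]
    vocab = {"A": "gene", "B": "gene", "C": "biological_process", "D": "biological_process"}
    return ms.Corpus(documents=docs, vocabulary=vocab)


def planted_module_map(modules: ms.ModuleSet, truth: ms.GroundTruth) -> dict[str, str]:
    """Detected module label -> majority planted module id."""
    from collections import Counter

    inv: dict[str, list[str]] = {}
    for g, m in modules.assignment.items():
        inv.setdefault(m, []).append(truth.gene_module[g])
    return {m: Counter(v).most_common(1)[0][0] for m, v in inv.items()}


def planted_pairs(report, truths) -> set[tuple[str, str]]:
    """Detected-label pairs that correspond to a planted shared function."""
    ta, tb = report.tissue_a, report.tissue_b
    map_a = planted_module_map(report.modules[ta], truths[ta])
    map_b = planted_module_map(report.modules[tb], truths[tb])
    out = set()
    for a, pa in map_a.items():
        for b, pb in map_b.items():
            if a == "unassigned" or b == "unassigned":
                continue
            fa = truths[ta].shared_functions.get(pa)
            fb = truths[tb].shared_functions.get(pb)
            if fa is not None and fa == fb:
                out.add((a, b))
    return out
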