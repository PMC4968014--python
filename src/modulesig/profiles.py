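"""Literature concept profiles from document co-occurrence.

A concept profile is a sparse weighted vector over vocabulary concepts: for an owner
concept X, every concept Y that co-occurs with X in at least one document gets weight
U(X, Y), the symmetric uncertainty coefficient of the two binary document-occurrence
indicators.  Profiles exist only for concepts appearing in at least ``min_docs``
documents.  Two profiles are matched by their inner product over shared concepts, so
two concepts never mentioned together can still match through shared profile
neighbours (indirect relations).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

#: the four annotation semantic categories used downstream
CATEGORIES = (
    "biological_process",
    "cellular_component",
    "molecular_function",
    "disease_or_syndrome",
)

GENE_CATEGORY = "gene"


@dataclass
class Corpus:
    """Documents as deduplicated concept sets plus a concept -> category vocabulary."""

    documents: list[tuple[str, frozenset[str]]]
    vocabulary: dict[str, str]

    def __post_init__(self) -> None:
        seen = set()
        for _, concepts in self.documents:
            seen.update(concepts)
        missing = seen - set(self.vocabulary)
        if missing:
            raise ValueError(
                f"{len(missing)} concepts appear in documents but not in the vocabulary, "
                f"e.g. {sorted(missing)[:5]}"
            )

    @property
    def n_docs(self) -> int:
        return len(self.documents)

    def concepts_in_category(self, category: str) -> list[str]:
        return sorted(c for c, cat in self.vocabulary.items() if cat == category)


@dataclass
class CooccurrenceCounts:
    """Exact document-frequency and joint-frequency counts for one corpus."""

    n_docs: int
    concepts: list[str]
    doc_freq: np.ndarray  # per-concept document frequency n_X
    joint: sparse.csr_matrix  # concepts x concepts joint document frequency n_XY
    _index: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._index:
            self._index = {c: i for i, c in enumerate(self.concepts)}

    def n(self, concept: str) -> int:
        return int(self.doc_freq[self._index[concept]])

    def n_joint(self, a: str, b: str) -> int:
        return int(self.joint[self._index[a], self._index[b]])

    def index(self, concept: str) -> int:
        return self._index[concept]


def cooccurrence_counts(corpus: Corpus) -> CooccurrenceCounts:
    """Count document frequencies and pairwise joint frequencies over the corpus."""
    if corpus.n_docs < 1:
        raise ValueError("empty corpus")
    concepts = sorted(corpus.vocabulary)
    index = {c: i for i, c in enumerate(concepts)}
    rows, cols = [], []
    for d, (_, doc_concepts) in enumerate(corpus.documents):
        for c in doc_concepts:
            rows.append(d)
            cols.append(index[c])
    occ = sparse.csr_matrix(
        (np.ones(len(rows), dtype=np.int64), (rows, cols)),
        shape=(corpus.n_docs, len(concepts)),
    )
    joint = (occ.T @ occ).tocsr()
    doc_freq = np.asarray(joint.diagonal(), dtype=np.int64)
    return CooccurrenceCounts(
        n_docs=corpus.n_docs, concepts=concepts, doc_freq=doc_freq, joint=joint
    )


def _entropy_bits(probs: np.ndarray) -> np.ndarray:
    """Shannon entropy in bits along the last axis, with 0 log 0 := 0."""
    p = np.asarray(probs, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, -p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
    return terms.sum(axis=-1)


def symmetric_uncertainty(n_x: int, n_y: int, n_xy: int, n_docs: int) -> float:
    """Symmetric uncertainty U = 2 I(X;Y) / (H(X) + H(Y)) of two occurrence indicators.

    X and Y are the binary document-occurrence indicators implied by the 2x2 table
    (n_xy, n_x - n_xy, n_y - n_xy, N - n_x - n_y + n_xy).  U is a normalized mutual
    information in [0, 1]: 1 for identical occurrence, 0 at exact independence.
    Returns 0 when H(X) + H(Y) = 0 (both indicators constant).
    """
    if n_docs <= 0:
        raise ValueError("corpus size must be positive")
    if not 0 <= n_xy <= min(n_x, n_y) or max(n_x, n_y) > n_docs:
        raise ValueError(f"inconsistent counts n_x={n_x}, n_y={n_y}, n_xy={n_xy}, N={n_docs}")
    if n_x + n_y - n_xy > n_docs:
        raise ValueError("inconsistent counts: union of occurrences exceeds corpus size")
    table = np.array(
        [n_xy, n_x - n_xy, n_y - n_xy, n_docs - n_x - n_y + n_xy], dtype=float
    )
    p = table / n_docs
    h_x = _entropy_bits(np.array([p[0] + p[1], p[2] + p[3]]))
    h_y = _entropy_bits(np.array([p[0] + p[2], p[1] + p[3]]))
    denom = h_x + h_y
    if denom == 0:
        return 0.0
    h_xy = _entropy_bits(p)
    mi = h_x + h_y - h_xy
    return float(np.clip(2.0 * mi / denom, 0.0, 1.0))


def _su_matrix(counts: CooccurrenceCounts) -> sparse.csr_matrix:
    """Symmetric-uncertainty weights for every co-occurring concept pair, vectorized.

    Only pairs with joint frequency >= 1 get an entry; the diagonal is dropped (a
    profile never contains its owner).
    """
    joint = sparse.coo_matrix(counts.joint)
    mask = joint.row != joint.col
    r, c, nxy = joint.row[mask], joint.col[mask], joint.data[mask].astype(float)
    n = float(counts.n_docs)
    nx = counts.doc_freq[r].astype(float)
    ny = counts.doc_freq[c].astype(float)
    cells = np.stack([nxy, nx - nxy, ny - nxy, n - nx - ny + nxy], axis=1) / n
    h_x = _entropy_bits(np.stack([nx / n, 1.0 - nx / n], axis=1))
    h_y = _entropy_bits(np.stack([ny / n, 1.0 - ny / n], axis=1))
    h_xy = _entropy_bits(cells)
    denom = h_x + h_y
    with np.errstate(divide="ignore", invalid="ignore"):
        u = np.where(denom > 0, 2.0 * (h_x + h_y - h_xy) / np.where(denom > 0, denom, 1.0), 0.0)
    u = np.clip(u, 0.0, 1.0)
    keep = u > 0
    m = len(counts.concepts)
    return sparse.csr_matrix((u[keep], (r[keep], c[keep])), shape=(m, m))


@dataclass
class ConceptProfile:
    """Sparse weighted relation vector of one owner concept."""

    owner: str
    weights: dict[str, float]

    def __post_init__(self) -> None:
        if self.owner in self.weights:
            raise ValueError("profile must not contain its owner")
        if any(w <= 0 for w in self.weights.values()):
            raise ValueError("profile weights must be positive (zero entries dropped)")


def build_profile(
    concept: str, counts: CooccurrenceCounts, min_docs: int = 5
) -> ConceptProfile | None:
    """Profile of one concept, or None when it appears in fewer than ``min_docs`` docs."""
    if counts.n(concept) < min_docs:
        return None
    i = counts.index(concept)
    row = counts.joint.getrow(i).tocoo()
    weights: dict[str, float] = {}
    for j, n_xy in zip(row.col, row.data):
        if j == i:
            continue
        other = counts.concepts[j]
        u = symmetric_uncertainty(counts.n(concept), counts.n(other), int(n_xy), counts.n_docs)
        if u > 0:
            weights[other] = u
    return ConceptProfile(owner=concept, weights=weights)


def match(p: ConceptProfile, q: ConceptProfile) -> float:
    """Inner product of two profiles over their shared concepts."""
    if len(p.weights) > len(q.weights):
        p, q = q, p
    return float(sum(w * q.weights[c] for c, w in p.weights.items() if c in q.weights))


class ProfileStore:
    """All eligible concept profiles of a corpus, held as one sparse weight matrix.

    Row i is the profile of ``concepts[i]`` over the whole vocabulary; rows of
    ineligible concepts (document frequency < min_docs) are empty and flagged.  This is
    the bulk interface the annotation stage uses; ``build_profile`` is the per-concept
    view of the same weights.
    """

    def __init__(self, counts: CooccurrenceCounts, min_docs: int = 5):
        self.concepts = list(counts.concepts)
        self.min_docs = min_docs
        self._index = {c: i for i, c in enumerate(self.concepts)}
        self.eligible = counts.doc_freq >= min_docs
        su = _su_matrix(counts)
        # blank rows of ineligible owners (their relations remain as columns of others)
        keep = sparse.diags(self.eligible.astype(float))
        self.weights = (keep @ su).tocsr()

    @classmethod
    def from_corpus(cls, corpus: Corpus, min_docs: int = 5) -> "ProfileStore":
        return cls(cooccurrence_counts(corpus), min_docs=min_docs)

    def has_profile(self, concept: str) -> bool:
        i = self._index.get(concept)
        return i is not None and bool(self.eligible[i])

    def profile(self, concept: str) -> ConceptProfile | None:
        if not self.has_profile(concept):
            return None
        i = self._index[concept]
        row = self.weights.getrow(i).tocoo()
        return ConceptProfile(
            owner=concept,
            weights={self.concepts[j]: float(w) for j, w in zip(row.col, row.data)},
        )

    def rows(self, concepts: list[str]) -> sparse.csr_matrix:
        idx = [self._index[c] for c in concepts]
        return self.weights[idx]

    def similarity_matrix(
        self, row_concepts: list[str], col_concepts: list[str]
    ) -> np.ndarray:
        """Dense inner-product match scores between two concept lists (rows x cols)."""
        return np.asarray(
            (self.rows(row_concepts) @ self.rows(col_concepts).T).todense(), dtype=float
        )
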