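"""Synthetic evidence matrices and corpora with known ground truth.

The matrix generator emulates the statistical structure the prioritizer
assumes: every category admits candidate genes at a background Bernoulli
rate, and genuinely phenotype-related (core) genes are enriched — their
membership rate is boosted by a per-category increment.  Categories with
a large boost are informative and should attract weight; categories with
no boost are noise and should not.

The corpus generator plants an exact number of documents per
(alias, phrase) pair, with all remaining text drawn from a fixed filler
vocabulary disjoint from every alias and phrase, so whole-word
co-occurrence counts on the generated corpus recover the planted counts
exactly rather than approximately.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .evidence import EvidenceMatrix
from .litscreen import AliasTable, Corpus, Document, tokenize

__all__ = ["MatrixSpec", "CorpusSpec", "gen_evidence_matrix", "gen_corpus"]


@dataclass(frozen=True)
class MatrixSpec:
    """Generative settings for a planted-enrichment evidence matrix.

    ``category_probs[i]`` is the background membership rate of category i;
    core genes use ``min(1, category_probs[i] + core_boost[i])``.
    """

    n_genes: int
    category_probs: tuple[float, ...]
    core_size: int
    core_boost: tuple[float, ...]
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if len(self.category_probs) < 2:
            raise ValueError("need at least 2 categories")
        if len(self.core_boost) != len(self.category_probs):
            raise ValueError("core_boost length must match category_probs")
        if not 0 <= self.core_size <= self.n_genes:
            raise ValueError("core_size must lie in [0, n_genes]")
        if any(not 0 <= p <= 1 for p in self.category_probs):
            raise ValueError("category_probs must lie in [0, 1]")
        if any(b < 0 for b in self.core_boost):
            raise ValueError("core_boost must be nonnegative")

    @property
    def n_categories(self) -> int:
        return len(self.category_probs)


def gen_evidence_matrix(spec: MatrixSpec) -> EvidenceMatrix:
    """Draw a Bernoulli evidence matrix with boosted core-gene rates.

    All-zero rows (possible at low rates) are repaired by switching one
    uniformly chosen category on, honoring the "at least one element is 1"
    matrix invariant while preserving per-category rates better than
    rejection sampling.  Fully reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    width = len(str(spec.n_genes))
    genes = tuple(f"G{i + 1:0{width}d}" for i in range(spec.n_genes))
    core_idx = rng.choice(spec.n_genes, size=spec.core_size, replace=False)
    core_mask = np.zeros(spec.n_genes, dtype=bool)
    core_mask[core_idx] = True

    probs = np.tile(np.asarray(spec.category_probs, dtype=float), (spec.n_genes, 1))
    probs[core_mask] = np.minimum(
        1.0, probs[core_mask] + np.asarray(spec.core_boost, dtype=float)
    )
    indicator = (rng.random(probs.shape) < probs).astype(np.int8)
    for i in np.flatnonzero(indicator.sum(axis=1) == 0):
        indicator[i, rng.integers(spec.n_categories)] = 1

    categories = tuple(f"source_{j + 1}" for j in range(spec.n_categories))
    core = frozenset(genes[i] for i in core_idx)
    return EvidenceMatrix(categories, genes, indicator, core)


# Filler vocabulary for noise text; screened at generation time against the
# alias/phrase token sets so no accidental co-occurrence can arise.
_FILLER_WORDS = (
    "analysis study report cohort cells tissue receptor pathway signal "
    "expression protein assay measurement control sample baseline model "
    "response observed variance experiment cortex neuron synapse membrane "
    "binding kinetics plasma treatment outcome subjects results methods"
).split()


@dataclass(frozen=True)
class CorpusSpec:
    """Generative settings for a corpus with planted co-occurrences.

    ``planted_counts[(alias, phrase)]`` documents are emitted containing
    exactly that alias and that phrase as whole words; ``n_noise_docs``
    additional documents contain filler text only.
    """

    aliases: AliasTable
    phrases: tuple[str, ...]
    planted_counts: tuple[tuple[tuple[str, str], int], ...]
    n_noise_docs: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(c < 0 for _, c in self.planted_counts):
            raise ValueError("planted counts must be nonnegative")
        if self.n_noise_docs < 0:
            raise ValueError("n_noise_docs must be nonnegative")

    @classmethod
    def from_mapping(
        cls,
        aliases: AliasTable | dict,
        phrases,
        planted: dict[tuple[str, str], int],
        n_noise_docs: int = 0,
        seed: int = 0,
    ) -> "CorpusSpec":
        if isinstance(aliases, dict):
            aliases = AliasTable.from_mapping(aliases)
        return cls(
            aliases=aliases,
            phrases=tuple(phrases),
            planted_counts=tuple(sorted(planted.items())),
            n_noise_docs=n_noise_docs,
            seed=seed,
        )

    def planted(self) -> dict[tuple[str, str], int]:
        return dict(self.planted_counts)


def _safe_fillers(spec: CorpusSpec) -> list[str]:
    reserved = set()
    for _, alias_set in spec.aliases:
        for a in alias_set:
            reserved.update(tokenize(a))
    for p in spec.phrases:
        reserved.update(tokenize(p))
    safe = [w for w in _FILLER_WORDS if w not in reserved]
    if not safe:
        raise ValueError("no filler words left after screening against alias/phrase tokens")
    return safe


def gen_corpus(spec: CorpusSpec) -> Corpus:
    """Emit a corpus whose whole-word co-occurrence counts are exactly planted.

    Each planted document mentions one alias and one phrase embedded in
    filler text; noise documents are pure filler.  Reproducible from
    ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    fillers = _safe_fillers(spec)
    docs: list[Document] = []

    def filler(n: int) -> str:
        return " ".join(rng.choice(fillers, size=n))

    serial = 0
    for (alias, phrase), count in spec.planted_counts:
        for _ in range(count):
            serial += 1
            text = f"{filler(3)} {alias} {filler(4)} {phrase} {filler(3)}."
            docs.append(Document(f"D{serial:06d}", text))
    for _ in range(spec.n_noise_docs):
        serial += 1
        docs.append(Document(f"D{serial:06d}", filler(12) + "."))
    return Corpus(docs)
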