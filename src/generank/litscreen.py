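"""Literature co-occurrence screening of genes against topic phrases.

Single-gene experimental evidence is scattered over thousands of
publications, so candidate genes are screened by co-occurrence: for each
gene, every alias is paired with each topic phrase (by default the four
phrases "nicotine", "nicotinic", "tobacco" and "smoking") and the number
of documents mentioning both is counted.  Per-pair hit counts are pooled
by summation — a gene with aliases DRD2 and D2R whose "nicotine" queries
return 106 and 9 hits contributes 115 — and genes are triaged on the
pooled total: at least ``min_hits`` (default 5) is accepted outright,
1 to ``min_hits - 1`` goes to manual abstract review, and 0 hits excludes
the gene.

A "hit" on the local corpus means the document's title+abstract text
contains both terms as case-insensitive whole-word token matches (tokens
split on any non-alphanumeric character, so hyphens separate).  This is a
transparent, deterministic stand-in for a search engine's retrieval;
because summed pooling can count one document once per matching pair, a
deduplicated distinct-document count is reported alongside.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field

from Bio import Medline

from .evidence import normalize_symbol

__all__ = [
    "DEFAULT_PHRASES",
    "Document",
    "Corpus",
    "AliasTable",
    "TriageReport",
    "tokenize",
    "build_queries",
    "count_hits",
    "pool_hits",
    "triage",
    "screen_genes",
    "read_alias_tsv",
    "write_alias_tsv",
    "read_corpus",
    "read_corpus_jsonl",
    "write_corpus_jsonl",
    "read_corpus_medline",
    "write_corpus_medline",
]

DEFAULT_PHRASES: tuple[str, ...] = ("nicotine", "nicotinic", "tobacco", "smoking")

_TOKEN = re.compile(r"[0-9a-z]+")


def tokenize(text: str) -> list[str]:
    """Lowercase word tokens; any non-alphanumeric character separates."""
    return _TOKEN.findall(text.lower())


@dataclass(frozen=True)
class Document:
    doc_id: str
    text: str


class Corpus:
    """Documents with searchable text, indexed for whole-word lookup."""

    def __init__(self, documents):
        self.documents: list[Document] = [
            d if isinstance(d, Document) else Document(*d) for d in documents
        ]
        ids = [d.doc_id for d in self.documents]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate doc_ids in corpus")
        self._tokens: list[list[str]] = [tokenize(d.text) for d in self.documents]
        self._index: dict[str, set[int]] = {}
        for i, toks in enumerate(self._tokens):
            for t in set(toks):
                self._index.setdefault(t, set()).add(i)

    def __len__(self) -> int:
        return len(self.documents)

    def __add__(self, other: "Corpus") -> "Corpus":
        return Corpus(self.documents + other.documents)

    def docs_with_term(self, term: str) -> set[int]:
        """Document positions containing `term` as whole word(s).

        Multi-word terms (e.g. the symbol "CHRNA 4") match as a contiguous
        token subsequence.
        """
        toks = tokenize(term)
        if not toks:
            return set()
        candidates = self._index.get(toks[0], set())
        for t in toks[1:]:
            candidates = candidates & self._index.get(t, set())
        if len(toks) == 1:
            return set(candidates)
        hits = set()
        for i in candidates:
            doc = self._tokens[i]
            if any(doc[j : j + len(toks)] == toks for j in range(len(doc) - len(toks) + 1)):
                hits.add(i)
        return hits

    def doc_ids(self, positions) -> list[str]:
        return sorted(self.documents[i].doc_id for i in positions)


@dataclass(frozen=True)
class AliasTable:
    """Gene symbols with their alias sets (each set includes the symbol)."""

    rows: tuple[tuple[str, tuple[str, ...]], ...]

    def __post_init__(self) -> None:
        symbols = [s for s, _ in self.rows]
        if len(set(symbols)) != len(symbols):
            raise ValueError("duplicate symbols in alias table")
        for sym, aliases in self.rows:
            if not aliases:
                raise ValueError(f"empty alias set for {sym}")
            if sym not in aliases:
                raise ValueError(f"alias set for {sym} must include the symbol itself")

    @classmethod
    def from_mapping(cls, mapping: dict) -> "AliasTable":
        rows = []
        for sym, aliases in mapping.items():
            sym = normalize_symbol(sym)
            norm = [normalize_symbol(a) for a in aliases]
            ordered = [sym] + [a for a in dict.fromkeys(norm) if a != sym]
            rows.append((sym, tuple(ordered)))
        return cls(tuple(rows))

    def __iter__(self):
        return iter(self.rows)

    def __len__(self) -> int:
        return len(self.rows)


def build_queries(aliases, phrases) -> list[tuple[str, str]]:
    """Full cross product alias x phrase, alias-major deterministic order."""
    if not phrases:
        raise ValueError("phrase list must be non-empty")
    return [(a, p) for a in aliases for p in phrases]


def count_hits(corpus: Corpus, pair: tuple[str, str]) -> int:
    """Documents containing both the alias and the phrase as whole words."""
    alias, phrase = pair
    return len(corpus.docs_with_term(alias) & corpus.docs_with_term(phrase))


def pool_hits(counts: dict[tuple[str, str], int]) -> int:
    """Pooled total over all (alias, phrase) pairs — plain summation.

    A document retrieved by several pairs counts once per pair, mirroring
    the convention of summing separate per-query hit counts.
    """
    return int(sum(counts.values()))


def triage(totals: dict[str, int], min_hits: int = 5) -> dict[str, str]:
    """Three-way triage on pooled totals.

    >= min_hits -> ``auto_include``; in [1, min_hits) -> ``manual_review``;
    0 -> ``excluded``.
    """
    if min_hits < 1:
        raise ValueError("min_hits must be >= 1")
    out = {}
    for sym, total in totals.items():
        if total < 0:
            raise ValueError(f"negative hit total for {sym}")
        if total >= min_hits:
            out[sym] = "auto_include"
        elif total >= 1:
            out[sym] = "manual_review"
        else:
            out[sym] = "excluded"
    return out


@dataclass(frozen=True)
class TriageReport:
    """Per-gene screening result.

    rows: (symbol, per-pair counts, total_hits, distinct_hits, status,
    matched doc ids).  ``total_hits`` sums per-pair counts; ``distinct_hits``
    is the deduplicated number of distinct matching documents.
    """

    rows: tuple[dict, ...]
    min_hits: int
    phrases: tuple[str, ...]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "symbol": r["symbol"],
                    "total_hits": r["total_hits"],
                    "distinct_hits": r["distinct_hits"],
                    "status": r["status"],
                }
                for r in self.rows
            ]
        )

    def matched_documents(self) -> dict[str, list[str]]:
        return {r["symbol"]: r["matched_doc_ids"] for r in self.rows}


def screen_genes(
    corpus: Corpus,
    aliases: AliasTable,
    phrases=DEFAULT_PHRASES,
    min_hits: int = 5,
) -> TriageReport:
    """Run the full per-gene screening: queries, counting, pooling, triage."""
    if len(aliases) == 0:
        warnings.warn("empty alias table: triage report has no rows", UserWarning)
    phrases = tuple(phrases)
    statuses_needed = []
    rows = []
    for sym, alias_set in aliases:
        pairs = build_queries(alias_set, phrases)
        counts = {pair: count_hits(corpus, pair) for pair in pairs}
        matched = set()
        for pair in pairs:
            matched |= corpus.docs_with_term(pair[0]) & corpus.docs_with_term(pair[1])
        rows.append(
            {
                "symbol": sym,
                "pair_counts": counts,
                "total_hits": pool_hits(counts),
                "distinct_hits": len(matched),
                "matched_doc_ids": corpus.doc_ids(matched),
            }
        )
        statuses_needed.append(sym)
    statuses = triage({r["symbol"]: r["total_hits"] for r in rows}, min_hits=min_hits)
    for r in rows:
        r["status"] = statuses[r["symbol"]]
    return TriageReport(rows=tuple(rows), min_hits=min_hits, phrases=phrases)


# ---------------------------------------------------------------------------
# file formats


def read_alias_tsv(path) -> AliasTable:
    """Two-column TSV: symbol <tab> pipe-separated aliases."""
    mapping: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            sym = parts[0]
            extra = parts[1].split("|") if len(parts) > 1 and parts[1].strip() else []
            mapping[sym] = [sym] + [a for a in extra if a.strip()]
    return AliasTable.from_mapping(mapping)


def write_alias_tsv(table: AliasTable, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for sym, alias_set in table:
            fh.write(f"{sym}\t{'|'.join(alias_set)}\n")


def read_corpus_jsonl(path) -> Corpus:
    """JSON-lines corpus: one {"id", "title", "abstract"} object per line."""
    docs = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            rec = json.loads(line)
            text = " ".join(filter(None, [rec.get("title", ""), rec.get("abstract", "")]))
            docs.append(Document(str(rec["id"]), text))
    return Corpus(docs)


def write_corpus_jsonl(corpus: Corpus, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for d in corpus.documents:
            fh.write(json.dumps({"id": d.doc_id, "title": "", "abstract": d.text}) + "\n")


def read_corpus_medline(path) -> Corpus:
    """MEDLINE flat-file corpus (PMID/TI/AB fields)."""
    docs = []
    with open(path, encoding="utf-8") as fh:
        for rec in Medline.parse(fh):
            pmid = rec.get("PMID")
            if pmid is None:
                continue
            text = " ".join(filter(None, [rec.get("TI", ""), rec.get("AB", "")]))
            docs.append(Document(str(pmid), text))
    return Corpus(docs)


def write_corpus_medline(corpus: Corpus, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for d in corpus.documents:
            fh.write(f"PMID- {d.doc_id}\n")
            fh.write(f"TI  - {d.text}\n")
            fh.write("\n")


def read_corpus(path) -> Corpus:
    """Dispatch on content: MEDLINE flat file or JSON-lines."""
    with open(path, encoding="utf-8") as fh:
        head = fh.read(6)
    if head.startswith("PMID-"):
        return read_corpus_medline(path)
    return read_corpus_jsonl(path)
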