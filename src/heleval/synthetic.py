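"""Synthetic vocabularies, corpora and corrupted predictions.

Every stage of the evaluator is testable without external corpora: this
module builds random rooted DAG vocabularies, samples gold PubTator corpora
from them, and produces predictions through a parameterised corruption
process whose realised outcome per pair is logged.  The log is ground truth:
running the full pipeline on the emitted files must reproduce its type
counts exactly, and the configured corruption mixture must be recovered by
the braveness/cautiousness/orthogonality characteristics up to sampling
noise.

Corruption draws one of four outcomes per pair — keep the gold id, move to
a strict descendant (overspecific), move to a strict ancestor
(underspecific), or jump to an unrelated entity (orthogonal) — with
hierarchy hops per corruption following a geometric law.  By default the
same decision is applied to every repetition of a (mention, entity) pair,
mimicking lexicon-driven linkers; per-occurrence corruption models
context-sensitive behaviour and re-opens a Global vs Global-Unique gap.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .corpus_io import Document, MentionEntityPair, Span, write_pubtator
from .ontology import Entity, HierVocabulary, write_edge_list, write_obo


class SyntheticConfigError(ValueError):
    """The corruption configuration cannot be realised on this vocabulary."""


# -- fixture vocabularies ----------------------------------------------------------

_FRUIT_EDGES = (
    ("Apple", "Fruit"),
    ("Pear", "Fruit"),
    ("Dessert apple", "Apple"),
    ("Granny Smith", "Apple"),
    ("Pink Lady", "Dessert apple"),
    ("Conference pear", "Pear"),
)


def fruit_fixture() -> HierVocabulary:
    """The 7-term fruit vocabulary used throughout docs and tests.

    Fruit -> {Apple, Pear}; Apple -> {Dessert apple, Granny Smith};
    Dessert apple -> {Pink Lady}; Pear -> {Conference pear}.
    """
    ids = {"Fruit"} | {c for c, _ in _FRUIT_EDGES}
    return HierVocabulary({i: Entity(i) for i in sorted(ids)}, _FRUIT_EDGES)


def random_dag(n_nodes: int, max_parents: int = 2, seed: int = 0) -> HierVocabulary:
    """Random single-root DAG: node i>0 draws 1..max_parents parents among 0..i-1.

    Node insertion order is a topological order, so acyclicity holds by
    construction; determinism per seed is part of the contract.
    """
    if n_nodes < 1 or max_parents < 1:
        raise SyntheticConfigError("need n_nodes >= 1 and max_parents >= 1")
    rng = np.random.default_rng(seed)
    width = len(str(n_nodes - 1)) if n_nodes > 1 else 1
    ids = [f"N{i:0{width}d}" for i in range(n_nodes)]
    edges: list[tuple[str, str]] = []
    for i in range(1, n_nodes):
        k = int(rng.integers(1, min(max_parents, i) + 1))
        parents = rng.choice(i, size=k, replace=False)
        edges.extend((ids[i], ids[int(p)]) for p in sorted(parents))
    return HierVocabulary({i: Entity(i) for i in ids}, edges)


# -- corpus generation -------------------------------------------------------------

@dataclass(frozen=True)
class CorruptionConfig:
    """Study conditions for one synthetic dataset.

    ``p_exact/p_over/p_under/p_orth`` must sum to 1; ``step_mean`` is the
    expected number of hierarchy hops per corruption (geometric, support
    >= 1); ``duplication_factor`` is the expected repetitions per unique
    (mention, entity) pair; ``train_overlap`` is the fraction of unique
    pairs also emitted into a synthetic training split.  ``entity_pool``
    restricts gold entities to ``internal`` nodes (those with both a parent
    and a child, so every corruption outcome is feasible) or allows ``all``.
    """

    p_exact: float = 0.8
    p_over: float = 0.05
    p_under: float = 0.1
    p_orth: float = 0.05
    step_mean: float = 1.5
    n_pairs: int = 2000
    duplication_factor: float = 1.0
    train_overlap: float = 0.0
    entity_pool: str = "internal"
    per_occurrence: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        probs = (self.p_exact, self.p_over, self.p_under, self.p_orth)
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise SyntheticConfigError("outcome probabilities must lie in [0, 1]")
        if abs(sum(probs) - 1.0) > 1e-9:
            raise SyntheticConfigError(f"outcome probabilities sum to {sum(probs)}, not 1")
        if self.n_pairs < 1:
            raise SyntheticConfigError("n_pairs must be >= 1")
        if self.step_mean < 1.0:
            raise SyntheticConfigError("step_mean must be >= 1 (at least one hop per corruption)")
        if not 0.0 <= self.train_overlap <= 1.0:
            raise SyntheticConfigError("train_overlap must lie in [0, 1]")
        if self.duplication_factor < 1.0:
            raise SyntheticConfigError("duplication_factor must be >= 1")
        if self.entity_pool not in ("internal", "all"):
            raise SyntheticConfigError("entity_pool must be 'internal' or 'all'")


@dataclass
class SynthCorpus:
    """Gold documents and annotations plus the overlapping train/dev splits."""

    docs: dict[str, Document]
    gold_pairs: list[MentionEntityPair]
    train_docs: dict[str, Document] = field(default_factory=dict)
    train_pairs: list[MentionEntityPair] = field(default_factory=list)
    dev_docs: dict[str, Document] = field(default_factory=dict)
    dev_pairs: list[MentionEntityPair] = field(default_factory=list)


@dataclass(frozen=True)
class OutcomeRecord:
    """Realised corruption outcome for one emitted gold annotation."""

    span: Span
    gold_id: str
    predicted_id: str
    outcome: str  # exact | overspecific | underspecific | orthogonal
    redraws: int


def _entity_pool(vocab: HierVocabulary, mode: str) -> list[str]:
    if mode == "internal":
        pool = sorted(
            e for e in vocab if vocab.parents(e) and vocab.children(e)
        )
        if pool:
            return pool
    return sorted(vocab)


def _build_documents(
    occurrences: Sequence[tuple[str, str]],
    rng: np.random.Generator,
    doc_prefix: str,
    mentions_per_doc: int = 25,
) -> tuple[dict[str, Document], list[MentionEntityPair], str]:
    """Pack (mention, entity) occurrences into PubTator-style documents."""
    order = rng.permutation(len(occurrences))
    docs: dict[str, Document] = {}
    pairs: list[MentionEntityPair] = []
    split = "train" if doc_prefix.startswith("tr") else "test"
    for chunk_no in range(0, len(order), mentions_per_doc):
        chunk = order[chunk_no: chunk_no + mentions_per_doc]
        doc_id = f"{doc_prefix}{chunk_no // mentions_per_doc:04d}"
        title = f"Synthetic document {doc_id}"
        tokens = [occurrences[int(i)][0] for i in chunk]
        abstract = " ".join(tokens)
        docs[doc_id] = Document(doc_id, title, abstract)
        offset = len(title) + 1
        for i in chunk:
            mention, entity = occurrences[int(i)]
            span = Span(doc_id, offset, offset + len(mention), mention)
            pairs.append(MentionEntityPair(span, entity, source="gold", split=split))
            offset += len(mention) + 1
    return docs, pairs, split


def generate_corpus(vocab: HierVocabulary, config: CorruptionConfig) -> SynthCorpus:
    """Sample a gold corpus (and optional train overlap) from a vocabulary.

    Unique (mention, entity) pairs get synthetic mention tokens; repetition
    counts follow a multinomial around ``duplication_factor``; the train
    split re-emits ``train_overlap`` of the unique pairs once each.
    Deterministic per ``config.seed``.
    """
    seeds = np.random.SeedSequence(config.seed).spawn(3)
    rng_sample, rng_layout, rng_train = (np.random.default_rng(s) for s in seeds)

    pool = _entity_pool(vocab, config.entity_pool)
    n_unique = max(1, round(config.n_pairs / config.duplication_factor))
    entity_draw = rng_sample.choice(len(pool), size=n_unique, replace=True)
    unique_pairs = [
        (f"mention{i:05d}", pool[int(j)]) for i, j in enumerate(entity_draw)
    ]
    extra = config.n_pairs - n_unique
    counts = np.ones(n_unique, dtype=int)
    if extra > 0:
        counts += rng_sample.multinomial(extra, np.full(n_unique, 1.0 / n_unique))
    occurrences = [up for up, c in zip(unique_pairs, counts) for _ in range(int(c))]

    docs, gold_pairs, _ = _build_documents(occurrences, rng_layout, "synth")

    n_train = int(round(config.train_overlap * n_unique))
    train_docs: dict[str, Document] = {}
    train_pairs: list[MentionEntityPair] = []
    if n_train > 0:
        chosen = rng_train.choice(n_unique, size=n_train, replace=False)
        train_occ = [unique_pairs[int(i)] for i in sorted(chosen)]
        train_docs, train_pairs, _ = _build_documents(train_occ, rng_train, "tr")
    return SynthCorpus(docs, gold_pairs, train_docs, train_pairs)


# -- corruption --------------------------------------------------------------------

def _geometric_steps(rng: np.random.Generator, step_mean: float) -> int:
    return int(rng.geometric(1.0 / step_mean))


def _walk_down(vocab: HierVocabulary, entity: str, steps: int, rng: np.random.Generator) -> Optional[str]:
    cur = entity
    for _ in range(steps):
        children = sorted(vocab.children(cur))
        if not children:
            break
        cur = children[int(rng.integers(len(children)))]
    return None if cur == entity else cur


def _walk_up(vocab: HierVocabulary, entity: str, steps: int, rng: np.random.Generator) -> Optional[str]:
    cur = entity
    for _ in range(steps):
        parents = sorted(vocab.parents(cur))
        if not parents:
            break
        cur = parents[int(rng.integers(len(parents)))]
    return None if cur == entity else cur


def _orthogonal_target(
    vocab: HierVocabulary, entity: str, step_mean: float, rng: np.random.Generator,
    attempts: int = 50,
) -> Optional[str]:
    """Sample an entity neither above nor below ``entity`` by up-then-down walks.

    Falls back to uniform sampling over the exact orthogonal complement if
    the walks keep landing inside the entity's closure.
    """
    related = vocab.ancestors(entity) | vocab.descendants(entity) | {entity}
    for _ in range(attempts):
        up = _walk_up(vocab, entity, _geometric_steps(rng, step_mean), rng)
        if up is None:
            break
        cand = _walk_down(vocab, up, max(1, _geometric_steps(rng, step_mean)), rng)
        if cand is not None and cand not in related:
            return cand
    complement = sorted(set(vocab) - related)
    if not complement:
        return None
    return complement[int(rng.integers(len(complement)))]


_OUTCOMES = ("exact", "overspecific", "underspecific", "orthogonal")


def _realise(
    vocab: HierVocabulary,
    entity: str,
    config: CorruptionConfig,
    rng: np.random.Generator,
) -> tuple[str, str, int]:
    """Draw an outcome for one pair, redrawing when infeasible for the entity."""
    probs = np.array([config.p_exact, config.p_over, config.p_under, config.p_orth])
    redraws = 0
    while True:
        outcome = _OUTCOMES[int(rng.choice(4, p=probs))]
        if outcome == "exact":
            return entity, "exact", redraws
        if outcome == "overspecific":
            cand = _walk_down(vocab, entity, _geometric_steps(rng, config.step_mean), rng)
        elif outcome == "underspecific":
            cand = _walk_up(vocab, entity, _geometric_steps(rng, config.step_mean), rng)
        else:
            cand = _orthogonal_target(vocab, entity, config.step_mean, rng)
        if cand is not None:
            return cand, outcome, redraws
        redraws += 1
        if redraws > 100:
            raise SyntheticConfigError(
                f"no feasible corruption for entity {entity!r} after 100 redraws"
            )


def corrupt(
    vocab: HierVocabulary,
    gold_pairs: Sequence[MentionEntityPair],
    config: CorruptionConfig,
    seed: Optional[int] = None,
) -> tuple[list[MentionEntityPair], list[OutcomeRecord]]:
    """Produce predictions for a gold corpus plus the realised outcome log.

    By default one decision is drawn per unique (mention text, entity) key
    and applied to all its occurrences; with ``config.per_occurrence`` every
    annotation is corrupted independently.  The returned log has one record
    per gold pair, in gold order, naming the realised outcome (which may
    differ from the drawn one only through redraws, which are counted).
    """
    if len(vocab) == 1 and config.p_exact < 1.0:
        raise SyntheticConfigError("single-entity vocabulary admits no corruption")
    rng = np.random.default_rng(np.random.SeedSequence(config.seed if seed is None else seed).spawn(1)[0])

    decisions: dict[tuple[str, str], tuple[str, str, int]] = {}
    if not config.per_occurrence:
        unique_keys = sorted({(p.span.text, p.entity_id) for p in gold_pairs})
        for key in unique_keys:
            decisions[key] = _realise(vocab, key[1], config, rng)

    predictions: list[MentionEntityPair] = []
    log: list[OutcomeRecord] = []
    for pair in gold_pairs:
        key = (pair.span.text, pair.entity_id)
        if config.per_occurrence:
            predicted, outcome, redraws = _realise(vocab, pair.entity_id, config, rng)
        else:
            predicted, outcome, redraws = decisions[key]
        predictions.append(
            MentionEntityPair(pair.span, predicted, source="predicted", split=pair.split)
        )
        log.append(OutcomeRecord(pair.span, pair.entity_id, predicted, outcome, redraws))
    return predictions, log


def write_outcome_log(log: Sequence[OutcomeRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("doc_id\tstart\tend\tmention\tgold_id\tpredicted_id\toutcome\tredraws\n")
        for r in log:
            fh.write(
                f"{r.span.doc_id}\t{r.span.start}\t{r.span.end}\t{r.span.text}\t"
                f"{r.gold_id}\t{r.predicted_id}\t{r.outcome}\t{r.redraws}\n"
            )


def write_dataset(
    out_dir: str | Path,
    vocab: HierVocabulary,
    corpus: SynthCorpus,
    predictions: Sequence[MentionEntityPair],
    log: Sequence[OutcomeRecord],
) -> dict[str, Path]:
    """Write vocabulary (OBO + TSV), PubTator splits and the outcome log."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vocab_obo": out / "vocabulary.obo",
        "vocab_tsv": out / "vocabulary.tsv",
        "gold": out / "gold.pubtator",
        "pred": out / "pred.pubtator",
        "train": out / "train.pubtator",
        "dev": out / "dev.pubtator",
        "outcomes": out / "outcomes.tsv",
    }
    write_obo(vocab, paths["vocab_obo"])
    write_edge_list(vocab, paths["vocab_tsv"])
    write_pubtator(corpus.docs, corpus.gold_pairs, paths["gold"])
    write_pubtator(corpus.docs, predictions, paths["pred"])
    write_pubtator(corpus.train_docs, corpus.train_pairs, paths["train"])
    write_pubtator(corpus.dev_docs, corpus.dev_pairs, paths["dev"])
    write_outcome_log(log, paths["outcomes"])
    return paths
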