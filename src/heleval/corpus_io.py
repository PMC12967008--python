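"""PubTator reading/writing, id normalisation, and gold/prediction alignment.

PubTator files interleave ``docid|t|title`` / ``docid|a|abstract`` lines with
tab-delimited annotation lines::

    docid <TAB> start <TAB> end <TAB> mention text <TAB> type <TAB> concept id

Character offsets are 0-based and end-exclusive, counted over
``title + " " + abstract``.  Because the evaluation isolates entity linking
from span finding, predictions are aligned to gold annotations by *exact*
(doc, start, end) span match; a gold span with no exactly-matching
prediction is scored as an unlinked (NIL) prediction and predictions with no
gold counterpart are reported, not scored.

Concept-id conventions handled here: ``MESH:``/``OMIM:`` prefixes are
stripped, the sentinels ``-1`` and ``CUI-less`` mean "no valid target"
(NIL), and a ``D009270|D010100`` composite is expanded into one pair per id
sharing the span.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from .ontology import HierVocabulary, NoCommonAncestorError

logger = logging.getLogger(__name__)

#: entity_id value for a mention with no valid vocabulary target
NIL = None


class PubTatorParseError(ValueError):
    """A PubTator line could not be interpreted; message carries the line number."""


@dataclass(frozen=True)
class Span:
    """A character span in one document (0-based, end-exclusive)."""

    doc_id: str
    start: int
    end: int
    text: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid span offsets {self.start}..{self.end}")

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.doc_id, self.start, self.end)


@dataclass(frozen=True)
class MentionEntityPair:
    """One gold or predicted (mention, entity) annotation."""

    span: Span
    entity_id: Optional[str]  # None encodes NIL
    source: str = "gold"  # gold | predicted
    split: str = "test"  # train | dev | test


@dataclass(frozen=True)
class AlignedPair:
    """A gold target paired with the prediction at the identical span.

    ``predicted_id`` is None when the model produced no link for the span
    (or produced no span at all); ``predicted_oov`` marks predictions whose
    id is absent from the vocabulary.
    """

    span: Span
    target_id: str
    predicted_id: Optional[str]
    predicted_oov: bool = False


@dataclass(frozen=True)
class Document:
    doc_id: str
    title: str
    abstract: str

    @property
    def text(self) -> str:
        return self.title + " " + self.abstract if self.abstract else self.title


@dataclass(frozen=True)
class NormConfig:
    """Identifier normalisation policy."""

    id_prefixes: tuple[str, ...] = ("MESH:", "OMIM:")
    nil_sentinels: frozenset[str] = frozenset({"-1", "CUI-less"})


DEFAULT_NORM = NormConfig()


@dataclass
class AlignmentReport:
    """Everything excluded from the profile, so no record vanishes silently."""

    gold_nil: int = 0
    duplicates_collapsed: int = 0
    missing_gold_ids: list[tuple[tuple[str, int, int], str]] = field(default_factory=list)
    unmatched_predicted: list[MentionEntityPair] = field(default_factory=list)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("kind\tdoc_id\tstart\tend\tdetail\n")
            fh.write(f"gold_nil_count\t\t\t\t{self.gold_nil}\n")
            fh.write(f"duplicates_collapsed\t\t\t\t{self.duplicates_collapsed}\n")
            for (doc, s, e), eid in self.missing_gold_ids:
                fh.write(f"gold_id_not_in_vocabulary\t{doc}\t{s}\t{e}\t{eid}\n")
            for p in self.unmatched_predicted:
                fh.write(
                    "unmatched_prediction\t"
                    f"{p.span.doc_id}\t{p.span.start}\t{p.span.end}\t{p.entity_id}\n"
                )


def normalise_id(raw: str, config: NormConfig = DEFAULT_NORM) -> Optional[str]:
    """Normalise one concept id: trim, strip known prefixes, map sentinels to NIL."""
    value = raw.strip()
    if value in config.nil_sentinels:
        return NIL
    for prefix in config.id_prefixes:
        if value.startswith(prefix):
            return value[len(prefix):].strip()
    return value


def parse_pubtator(
    path: str | Path,
    split: str = "test",
    source: str = "gold",
    config: NormConfig = DEFAULT_NORM,
) -> tuple[list[MentionEntityPair], dict[str, Document]]:
    """Parse a PubTator file into mention-entity pairs plus a document map.

    Composite ids (``A|B``) are expanded into one pair per id at the same
    span.  Offsets are validated against ``title + " " + abstract``; a
    span-text mismatch is a logged warning (real corpora drift), an
    annotation for an unknown document or a non-integer offset is a
    :class:`PubTatorParseError`.  Documents without annotations are kept in
    the document map.
    """
    titles: dict[str, str] = {}
    abstracts: dict[str, str] = {}
    pairs: list[MentionEntityPair] = []
    raw_annotations: list[tuple[int, Sequence[str]]] = []

    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        text_parts = line.split("|", 2)
        if len(text_parts) == 3 and text_parts[1] in ("t", "a"):
            (titles if text_parts[1] == "t" else abstracts)[text_parts[0]] = text_parts[2]
            continue
        fields = line.split("\t")
        if len(fields) == 6:
            raw_annotations.append((lineno, fields))
        else:
            # relation lines (e.g. BC5CDR "CID") and other extras are not annotations
            logger.debug("skipping non-annotation line %d (%d fields)", lineno, len(fields))

    docs = {
        doc_id: Document(doc_id, title, abstracts.get(doc_id, ""))
        for doc_id, title in titles.items()
    }

    for lineno, fields in raw_annotations:
        doc_id, start_s, end_s, mention, _etype, raw_id = fields
        if doc_id not in docs:
            raise PubTatorParseError(f"line {lineno}: annotation for unknown document {doc_id!r}")
        try:
            start, end = int(start_s), int(end_s)
        except ValueError as exc:
            raise PubTatorParseError(f"line {lineno}: non-integer offsets {start_s!r}/{end_s!r}") from exc
        doc_text = docs[doc_id].text
        if end > len(doc_text):
            logger.warning("line %d: span %d..%d exceeds document %s length %d",
                           lineno, start, end, doc_id, len(doc_text))
        elif doc_text[start:end] != mention:
            logger.warning("line %d: span text %r differs from document text %r",
                           lineno, mention, doc_text[start:end])
        span = Span(doc_id, start, end, mention)
        ids = [normalise_id(part, config) for part in raw_id.split("|")]
        for eid in ids:
            pairs.append(MentionEntityPair(span, eid, source=source, split=split))
    return pairs, docs


def write_pubtator(
    docs: Mapping[str, Document],
    pairs: Iterable[MentionEntityPair],
    path: str | Path,
    entity_type: str = "Entity",
    nil_token: str = "-1",
) -> None:
    """Write documents and annotations back to PubTator format."""
    by_doc: dict[str, list[MentionEntityPair]] = {d: [] for d in docs}
    for p in pairs:
        by_doc.setdefault(p.span.doc_id, []).append(p)
    with open(path, "w") as fh:
        for doc_id in docs:
            doc = docs[doc_id]
            fh.write(f"{doc_id}|t|{doc.title}\n")
            fh.write(f"{doc_id}|a|{doc.abstract}\n")
            for p in sorted(by_doc.get(doc_id, ()), key=lambda q: (q.span.start, q.span.end, str(q.entity_id))):
                eid = nil_token if p.entity_id is NIL else p.entity_id
                fh.write(f"{doc_id}\t{p.span.start}\t{p.span.end}\t{p.span.text}\t{entity_type}\t{eid}\n")
            fh.write("\n")


# -- alignment --------------------------------------------------------------------

# penalties ordering a brute-force assignment: any real hierarchical distance
# beats a disconnected pair, which beats an out-of-vocabulary prediction,
# which beats no prediction at all
_PENALTY_NO_LCA = 10**5
_PENALTY_OOV = 10**6
_PENALTY_NONE = 10**7


def _pair_cost(vocab: HierVocabulary, target: str, predicted: Optional[str]) -> int:
    if predicted is NIL:
        return _PENALTY_NONE
    if predicted not in vocab:
        return _PENALTY_OOV
    try:
        return vocab.lca_with_distance(target, predicted)[1]
    except NoCommonAncestorError:
        return _PENALTY_NO_LCA


def _assign(
    vocab: HierVocabulary,
    gold_ids: Sequence[str],
    pred_ids: Sequence[Optional[str]],
) -> tuple[list[Optional[str]], list[Optional[str]]]:
    """Assign predicted ids to gold ids minimising total match distance.

    Returns (prediction per gold id, leftover predictions).  Spans carry at
    most a handful of ids, so exhaustive permutation search is exact and
    cheap.
    """
    if len(gold_ids) == 1 and len(pred_ids) == 1:
        return [pred_ids[0]], []
    slots = list(pred_ids) + [NIL] * max(0, len(gold_ids) - len(pred_ids))
    best_cost = None
    best: tuple[Sequence[Optional[str]], list[Optional[str]]] | None = None
    for perm in itertools.permutations(range(len(slots)), len(gold_ids)):
        chosen = [slots[i] for i in perm]
        cost = sum(_pair_cost(vocab, g, p) for g, p in zip(gold_ids, chosen))
        if best_cost is None or cost < best_cost:
            leftover = [slots[i] for i in range(len(slots)) if i not in perm and slots[i] is not NIL]
            best_cost, best = cost, (chosen, leftover)
    assert best is not None
    return list(best[0]), best[1]


def align(
    gold: Sequence[MentionEntityPair],
    predicted: Sequence[MentionEntityPair],
    vocab: HierVocabulary,
) -> tuple[list[AlignedPair], AlignmentReport]:
    """Align predictions to gold annotations by exact span.

    Policy summary: gold NIL pairs are tallied and excluded; gold ids absent
    from the vocabulary are excluded with a report line (vocabulary drift is
    not a model error); a gold span with no prediction yields
    ``predicted_id=None``; multi-id spans are paired by minimal total match
    distance; predictions with no gold counterpart go to the report.
    Exact duplicate gold records are collapsed with a count.
    """
    report = AlignmentReport()

    seen: set[tuple[str, int, int, Optional[str]]] = set()
    gold_by_span: dict[tuple[str, int, int], list[MentionEntityPair]] = {}
    for p in gold:
        rec = (*p.span.key, p.entity_id)
        if rec in seen:
            report.duplicates_collapsed += 1
            continue
        seen.add(rec)
        gold_by_span.setdefault(p.span.key, []).append(p)

    pred_by_span: dict[tuple[str, int, int], list[MentionEntityPair]] = {}
    pred_seen: set[tuple[str, int, int, Optional[str]]] = set()
    for p in predicted:
        rec = (*p.span.key, p.entity_id)
        if rec in pred_seen:
            continue
        pred_seen.add(rec)
        pred_by_span.setdefault(p.span.key, []).append(p)

    aligned: list[AlignedPair] = []
    for span_key, gold_pairs in gold_by_span.items():
        span = gold_pairs[0].span
        gold_ids: list[str] = []
        for gp in gold_pairs:
            if gp.entity_id is NIL:
                report.gold_nil += 1
            elif gp.entity_id not in vocab:
                report.missing_gold_ids.append((span_key, gp.entity_id))
            else:
                gold_ids.append(gp.entity_id)
        preds_here = pred_by_span.pop(span_key, [])
        pred_ids = [p.entity_id for p in preds_here]
        if not gold_ids:
            report.unmatched_predicted.extend(preds_here)
            continue
        # deterministic order: sorted ids keep the assignment input-order free
        gold_ids.sort()
        chosen, leftover = _assign(vocab, gold_ids, sorted(pred_ids, key=str))
        for g, p in zip(gold_ids, chosen):
            aligned.append(
                AlignedPair(span, g, p, predicted_oov=p is not NIL and p not in vocab)
            )
        report.unmatched_predicted.extend(
            MentionEntityPair(span, p, source="predicted") for p in leftover
        )
    for leftover_preds in pred_by_span.values():
        report.unmatched_predicted.extend(leftover_preds)
    return aligned, report
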