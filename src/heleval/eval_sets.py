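"""Partition of aligned test pairs into the four target assessment sets.

* **Global** — every aligned pair in the test set.
* **Global Unique** — repetitions of the same (mention, entity) pair removed.
* **Novel** — pairs whose (mention, entity) key never occurs in the training
  or development annotations; with no train/dev supplied this equals Global.
* **Novel Unique** — the Novel set with repetitions removed.

Repetition is defined on a *pair key*: normalised mention text plus entity
id.  Mention normalisation defaults to casefolding with whitespace collapse
and can be switched to exact matching; novelty can alternatively be judged
on the mention alone or the entity alone for comparison with mention-level
generalisation studies.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass
from typing import Optional, Sequence

logger = logging.getLogger(__name__)

_WS = re.compile(r"\s+")


def normalise_mention(text: str, mode: str = "casefold") -> str:
    """Normalise mention text for pair-key comparison."""
    if mode == "exact":
        return text
    if mode == "casefold":
        return _WS.sub(" ", text.strip()).casefold()
    raise ValueError(f"unknown mention normalisation mode {mode!r}")


def _mention_entity(pair) -> tuple[str, Optional[str]]:
    """Mention text and gold entity id from either an aligned or a raw pair."""
    entity = getattr(pair, "target_id", None)
    if entity is None:
        entity = pair.entity_id
    return pair.span.text, entity


def pair_key(pair, mention_norm: str = "casefold", novelty: str = "pair"):
    """Deterministic repetition/novelty key for one pair.

    ``novelty`` selects what the key contains: the (mention, entity) pair
    (default), the mention alone, or the entity alone.
    """
    mention, entity = _mention_entity(pair)
    mention = normalise_mention(mention, mention_norm)
    if novelty == "pair":
        return (mention, entity)
    if novelty == "mention":
        return (mention,)
    if novelty == "entity":
        return (entity,)
    raise ValueError(f"unknown novelty mode {novelty!r}")


@dataclass
class EvalSetPartition:
    """Index lists (into the aligned-pair sequence) for the four sets."""

    global_idx: list[int]
    global_unique_idx: list[int]
    novel_idx: list[int]
    novel_unique_idx: list[int]
    novel_equals_global: bool = False

    def as_dict(self) -> dict[str, list[int]]:
        return {
            "global": self.global_idx,
            "global_unique": self.global_unique_idx,
            "novel": self.novel_idx,
            "novel_unique": self.novel_unique_idx,
        }


def _representative(indices: list[int], pairs: Sequence) -> int:
    """Pick the index that stands for a duplicate class in a unique set.

    Duplicates share mention text and entity, so a lexicon-driven model
    predicts identically across them and any representative works; for
    context-sensitive models the modal prediction decides, ties preferring a
    mismatching prediction (logged) so a split decision is not silently
    scored as correct.
    """
    preds = [getattr(pairs[i], "predicted_id", None) for i in indices]
    counts = Counter(preds)
    if len(counts) == 1:
        return indices[0]
    top = max(counts.values())
    modal = [p for p, c in counts.items() if c == top]
    if len(modal) > 1:
        target = _mention_entity(pairs[indices[0]])[1]
        mismatching = [p for p in modal if p != target]
        chosen = min(mismatching or modal, key=str)
        logger.info(
            "duplicate class %r: tie between predictions %s, scoring %r",
            pairs[indices[0]].span.text, sorted(map(str, modal)), chosen,
        )
    else:
        chosen = modal[0]
    return next(i for i, p in zip(indices, preds) if p == chosen)


def partition(
    test_pairs: Sequence,
    train_pairs: Sequence = (),
    dev_pairs: Sequence = (),
    *,
    mention_norm: str = "casefold",
    novelty: str = "pair",
) -> EvalSetPartition:
    """Build the four evaluation sets over aligned test pairs.

    ``train_pairs``/``dev_pairs`` are gold annotations from the respective
    splits and may be empty, in which case the Novel set is the Global set.
    Output is deterministic given input order: unique sets keep first-key
    (document, offset) order.
    """
    keys = [pair_key(p, mention_norm, novelty) for p in test_pairs]
    global_idx = list(range(len(test_pairs)))

    groups: dict[tuple, list[int]] = {}
    for i, k in enumerate(keys):
        groups.setdefault(k, []).append(i)
    global_unique_idx = [_representative(ix, test_pairs) for ix in groups.values()]

    seen_keys = {
        pair_key(p, mention_norm, novelty)
        for p in (*train_pairs, *dev_pairs)
        if _mention_entity(p)[1] is not None
    }
    novel_equals_global = not seen_keys
    novel_idx = [i for i in global_idx if keys[i] not in seen_keys]
    novel_unique_idx = [
        _representative(ix, test_pairs)
        for k, ix in groups.items()
        if k not in seen_keys
    ]
    if not novel_idx:
        logger.warning("novel set is empty: every test pair key occurs in train/dev")
    return EvalSetPartition(
        global_idx, global_unique_idx, novel_idx, novel_unique_idx, novel_equals_global
    )
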