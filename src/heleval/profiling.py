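"""Per-pair performance profile: match type, hierarchical distance, location.

Each aligned (target, prediction) pair is classified by its position in the
vocabulary hierarchy:

* **exact** — prediction equals the target;
* **overspecific** — the prediction is a strict descendant of the target
  (a subset of the target concept);
* **underspecific** — the prediction is a strict ancestor (a superset);
* **orthogonal** — neither contains the other (e.g. siblings).

Match distance counts subClassOf edges: the one-directional ancestor
distance for nested pairs, and for orthogonal pairs the minimal sum of
upward distances to a common ancestor (through the LCA).  Match location
places the *target* within its branch: 0 at a root, 1 at leaf level, so
errors near the root — mistakes about broad categories — can be separated
from fine-grained leaf confusions.

Three out-of-band outcomes are carried alongside the four types and never
enter the characteristic denominators: **missing** (the model produced no
link), **oov** (the predicted id is not in the vocabulary) and
**no_common_ancestor** (disconnected components without a virtual root).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .corpus_io import NIL, AlignedPair, Span
from .ontology import HierVocabulary, NoCommonAncestorError


class MatchType(str, enum.Enum):
    EXACT = "exact"
    OVERSPECIFIC = "overspecific"
    UNDERSPECIFIC = "underspecific"
    ORTHOGONAL = "orthogonal"
    # out-of-band outcomes
    MISSING = "missing"
    OOV = "oov"
    NO_COMMON_ANCESTOR = "no_common_ancestor"

    @property
    def in_scope(self) -> bool:
        """Whether this outcome enters the four-type counts."""
        return self in _IN_SCOPE

    @property
    def is_mismatch(self) -> bool:
        return self in _MISMATCH


_IN_SCOPE = frozenset(
    {MatchType.EXACT, MatchType.OVERSPECIFIC, MatchType.UNDERSPECIFIC, MatchType.ORTHOGONAL}
)
_MISMATCH = frozenset(
    {MatchType.OVERSPECIFIC, MatchType.UNDERSPECIFIC, MatchType.ORTHOGONAL}
)


def classify(vocab: HierVocabulary, target: str, predicted: str) -> MatchType:
    """Classify the hierarchical relationship of a predicted entity to the target."""
    if target == predicted:
        # touch both ids so unknown entities fail loudly
        vocab.entity(target)
        return MatchType.EXACT
    if vocab.ancestor_distance(predicted, target) is not None:
        return MatchType.OVERSPECIFIC
    if vocab.ancestor_distance(target, predicted) is not None:
        return MatchType.UNDERSPECIFIC
    try:
        vocab.lca_with_distance(target, predicted)
    except NoCommonAncestorError:
        return MatchType.NO_COMMON_ANCESTOR
    return MatchType.ORTHOGONAL


def match_distance(vocab: HierVocabulary, target: str, predicted: str) -> int:
    """Hierarchical match distance in subClassOf edges.

    0 for an exact match; the upward ancestor distance for nested pairs; for
    orthogonal pairs the minimum over common ancestors of the summed upward
    distances (paths run up-up through a common ancestor only, never zig-zag
    through unrelated descendants).

    Raises :class:`NoCommonAncestorError` for pairs in disconnected
    components when no virtual root was added.
    """
    if target == predicted:
        vocab.entity(target)
        return 0
    up = vocab.ancestor_distance(predicted, target)
    if up is not None:
        return up
    down = vocab.ancestor_distance(target, predicted)
    if down is not None:
        return down
    return vocab.lca_with_distance(target, predicted)[1]


def match_location(
    vocab: HierVocabulary, target: str, denominator: str = "branch"
) -> float:
    """Relative depth of the target entity within its branch, in [0, 1].

    The default ``branch`` denominator is the length of the shortest
    root-to-leaf path *through the target*: depth(target) plus the shortest
    downward distance from the target to a leaf descendant.  This pins a
    root at 0, every leaf at 1, and keeps the ratio within [0, 1] on any
    DAG.  ``denominator="global-min-leaf"`` instead divides by the depth of
    the globally shallowest leaf; that literal reading can exceed 1 and is
    provided for comparison only.
    """
    depth = vocab.depth(target)
    if denominator == "branch":
        total = depth + vocab.leaf_distance(target)
        return depth / total if total else 0.0
    if denominator == "global-min-leaf":
        shallowest = min(vocab.depth(leaf) for leaf in vocab.leaves)
        return depth / shallowest if shallowest else 0.0
    raise ValueError(f"unknown location denominator {denominator!r}")


@dataclass(frozen=True)
class MatchRecord:
    """One profile row: the outcome of a single aligned pair."""

    index: int
    type: MatchType
    distance: Optional[int]  # None for out-of-band outcomes
    location: float
    pair: AlignedPair


@dataclass
class PerformanceProfile:
    """Ordered per-pair outcome table for one evaluation set."""

    records: list[MatchRecord]
    set_label: str = "global"

    def __len__(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "doc_id": r.pair.span.doc_id,
                "start": r.pair.span.start,
                "end": r.pair.span.end,
                "mention": r.pair.span.text,
                "target_id": r.pair.target_id,
                "predicted_id": "" if r.pair.predicted_id is NIL else r.pair.predicted_id,
                "type": r.type.value,
                "distance": r.distance,
                "location": r.location,
            }
            for r in self.records
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "doc_id", "start", "end", "mention", "target_id",
                "predicted_id", "type", "distance", "location",
            ],
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, set_label: str | None = None) -> "PerformanceProfile":
        frame = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[""])
        records = []
        for i, row in frame.iterrows():
            pred = row["predicted_id"]
            pred = NIL if (pd.isna(pred) or pred == "") else str(pred)
            span = Span(str(row["doc_id"]), int(row["start"]), int(row["end"]), str(row["mention"]))
            distance = None if pd.isna(row["distance"]) else int(row["distance"])
            records.append(
                MatchRecord(
                    index=int(i),
                    type=MatchType(row["type"]),
                    distance=distance,
                    location=float(row["location"]),
                    pair=AlignedPair(span, str(row["target_id"]), pred, predicted_oov=row["type"] == "oov"),
                )
            )
        return cls(records, set_label or Path(path).stem)


def build_profile(
    vocab: HierVocabulary,
    aligned: Sequence[AlignedPair],
    subset: Sequence[int] | None = None,
    set_label: str = "global",
    loc_denominator: str = "branch",
) -> PerformanceProfile:
    """Assemble the profile for the chosen subset of aligned pairs.

    Order-preserving: one record per subset index.  Out-of-band pairs are
    carried with a null distance so their tallies stay auditable.
    """
    indices = range(len(aligned)) if subset is None else subset
    records = []
    for i in indices:
        pair = aligned[i]
        location = match_location(vocab, pair.target_id, loc_denominator)
        if pair.predicted_id is NIL:
            mtype, distance = MatchType.MISSING, None
        elif pair.predicted_oov or pair.predicted_id not in vocab:
            mtype, distance = MatchType.OOV, None
        else:
            mtype = classify(vocab, pair.target_id, pair.predicted_id)
            distance = (
                match_distance(vocab, pair.target_id, pair.predicted_id)
                if mtype.in_scope
                else None
            )
        records.append(MatchRecord(i, mtype, distance, location, pair))
    return PerformanceProfile(records, set_label)


DEFAULT_BINS = tuple(np.linspace(0.0, 1.0, 11))


def profile_by_location(
    profile: PerformanceProfile, bins: Sequence[float] = DEFAULT_BINS
) -> pd.DataFrame:
    """Mismatch counts per match type and location bin (exact matches excluded).

    Bins are right-closed intervals over [0, 1]; a location of exactly 0
    falls in the first bin.  Default: deciles.
    """
    edges = list(bins)
    if len(edges) < 2 or any(nxt <= prev for prev, nxt in zip(edges, edges[1:])) or edges[0] != 0.0 or edges[-1] != 1.0:
        raise ValueError("bins must be strictly increasing and cover [0, 1]")
    labels = [f"({lo:.2f},{hi:.2f}]" for lo, hi in zip(edges[:-1], edges[1:])]
    mismatch_types = [MatchType.OVERSPECIFIC, MatchType.UNDERSPECIFIC, MatchType.ORTHOGONAL]
    table = pd.DataFrame(0, index=[t.value for t in mismatch_types], columns=labels)
    for r in profile.records:
        if r.type not in mismatch_types:
            continue
        pos = int(np.searchsorted(edges, r.location, side="left")) - 1
        pos = max(pos, 0)
        table.iloc[table.index.get_loc(r.type.value), pos] += 1
    return table


def distance_matrix(profile: PerformanceProfile) -> pd.DataFrame:
    """Counts of mismatch records per (match type, distance), heatmap-ready."""
    rows = [
        (r.type.value, r.distance)
        for r in profile.records
        if r.type.is_mismatch and r.distance is not None
    ]
    if not rows:
        return pd.DataFrame()
    frame = pd.DataFrame(rows, columns=["type", "distance"])
    return frame.value_counts().unstack(fill_value=0).sort_index(axis=1)


def plot_profile_heatmap(profile: PerformanceProfile, path: str | Path) -> None:
    """Render the type x distance mismatch matrix as a heatmap image."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    matrix = distance_matrix(profile)
    fig, ax = plt.subplots(figsize=(6, 3))
    if matrix.empty:
        ax.text(0.5, 0.5, "no mismatches", ha="center", va="center")
        ax.set_axis_off()
    else:
        im = ax.imshow(matrix.to_numpy(), cmap="Reds", aspect="auto")
        ax.set_xticks(range(matrix.shape[1]), [str(c) for c in matrix.columns])
        ax.set_yticks(range(matrix.shape[0]), list(matrix.index))
        ax.set_xlabel("match distance")
        fig.colorbar(im, ax=ax, label="pairs")
    ax.set_title(f"Mismatches ({profile.set_label})")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
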