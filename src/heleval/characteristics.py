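"""Model characteristics: six summary metrics over a performance profile.

With :math:`N_E, N_O, N_U, N_T` the counts of exact, overspecific,
underspecific and orthogonal matches, :math:`N = N_E+N_O+N_U+N_T` and
:math:`M = N_O+N_U+N_T` (the mismatches):

==============  =============================  ==================================
metric          definition                     reading
==============  =============================  ==================================
accuracy        :math:`N_E / N`                exact agreement with the gold id
specificity     :math:`(N_E+N_O) / N`          accuracy also crediting finer ids
coverage        :math:`(N_E+N_U) / N`          accuracy also crediting broader ids
braveness       :math:`N_O / M`                share of too-specific errors
cautiousness    :math:`N_U / M`                share of too-general errors
orthogonality   :math:`N_T / M`                share of wrong-branch errors
==============  =============================  ==================================

Useful identities follow directly and hold to machine precision:
``coverage = accuracy + (1-accuracy) * cautiousness``,
``specificity = accuracy + (1-accuracy) * braveness`` and
``braveness + cautiousness + orthogonality = 1`` whenever ``M > 0``.

Out-of-band outcomes (missing link, out-of-vocabulary id, no common
ancestor) never enter the denominators by default; an option folds missing
links into the orthogonal count for users who want unlinked spans to hurt
accuracy.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .profiling import MatchType, PerformanceProfile

logger = logging.getLogger(__name__)


class EmptyReportError(ValueError):
    """No in-scope pairs: the metrics are undefined."""


@dataclass(frozen=True)
class MatchCounts:
    """Raw outcome tallies underlying a characteristics report."""

    n_exact: int
    n_over: int
    n_under: int
    n_orth: int
    n_missing: int = 0
    n_oov: int = 0
    n_no_lca: int = 0

    def __post_init__(self) -> None:
        if min(self.n_exact, self.n_over, self.n_under, self.n_orth,
               self.n_missing, self.n_oov, self.n_no_lca) < 0:
            raise ValueError("match counts must be non-negative")

    @property
    def n_total(self) -> int:
        """In-scope pairs: the four-type denominator N."""
        return self.n_exact + self.n_over + self.n_under + self.n_orth

    @property
    def n_mismatch(self) -> int:
        """Mismatch denominator M."""
        return self.n_over + self.n_under + self.n_orth

    @classmethod
    def from_profile(cls, profile: PerformanceProfile) -> "MatchCounts":
        tally = {t: 0 for t in MatchType}
        for r in profile.records:
            tally[r.type] += 1
        return cls(
            n_exact=tally[MatchType.EXACT],
            n_over=tally[MatchType.OVERSPECIFIC],
            n_under=tally[MatchType.UNDERSPECIFIC],
            n_orth=tally[MatchType.ORTHOGONAL],
            n_missing=tally[MatchType.MISSING],
            n_oov=tally[MatchType.OOV],
            n_no_lca=tally[MatchType.NO_COMMON_ANCESTOR],
        )


_METRICS = ("accuracy", "coverage", "specificity", "braveness", "cautiousness", "orthogonality")


@dataclass
class CharacteristicsReport:
    """The six characteristics (proportions in [0, 1]) plus their counts.

    The three error-profile metrics are None when the profile contains no
    mismatch.
    """

    set_label: str
    counts: MatchCounts
    accuracy: float
    coverage: float
    specificity: float
    braveness: Optional[float]
    cautiousness: Optional[float]
    orthogonality: Optional[float]

    def metric(self, name: str) -> Optional[float]:
        if name not in _METRICS:
            raise KeyError(name)
        return getattr(self, name)

    def as_percentages(self, decimals: int = 2) -> dict[str, Optional[float]]:
        """Paper-style rendering: percentages rounded to ``decimals``."""
        return {
            m: None if self.metric(m) is None else round(100 * self.metric(m), decimals)
            for m in _METRICS
        }

    def to_dict(self) -> dict:
        return {
            "set": self.set_label,
            "proportions": {m: self.metric(m) for m in _METRICS},
            "percentages": self.as_percentages(),
            "counts": {
                "exact": self.counts.n_exact,
                "overspecific": self.counts.n_over,
                "underspecific": self.counts.n_under,
                "orthogonal": self.counts.n_orth,
                "missing": self.counts.n_missing,
                "oov": self.counts.n_oov,
                "no_common_ancestor": self.counts.n_no_lca,
            },
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def characteristics(
    counts: MatchCounts,
    set_label: str = "global",
    count_missing_as_orthogonal: bool = False,
) -> CharacteristicsReport:
    """Compute the six characteristics from outcome counts.

    ``count_missing_as_orthogonal`` folds unlinked spans into the orthogonal
    tally for a stricter accuracy; by default they are reported separately.
    """
    if count_missing_as_orthogonal and counts.n_missing:
        counts = MatchCounts(
            counts.n_exact, counts.n_over, counts.n_under,
            counts.n_orth + counts.n_missing,
            0, counts.n_oov, counts.n_no_lca,
        )
    n = counts.n_total
    if n == 0:
        raise EmptyReportError("no in-scope pairs; characteristics are undefined")
    m = counts.n_mismatch
    if m == 0:
        logger.warning("no mismatches in %s: braveness/cautiousness/orthogonality undefined", set_label)
    return CharacteristicsReport(
        set_label=set_label,
        counts=counts,
        accuracy=counts.n_exact / n,
        coverage=(counts.n_exact + counts.n_under) / n,
        specificity=(counts.n_exact + counts.n_over) / n,
        braveness=counts.n_over / m if m else None,
        cautiousness=counts.n_under / m if m else None,
        orthogonality=counts.n_orth / m if m else None,
    )


def from_identities(accuracy: float, braveness: float, cautiousness: float) -> dict[str, float]:
    """Derive the dependent characteristics from the three independent ones.

    Given accuracy plus the braveness/cautiousness error shares, the
    remaining metrics are fixed:
    ``coverage = accuracy + (1-accuracy)*cautiousness``,
    ``specificity = accuracy + (1-accuracy)*braveness`` and
    ``orthogonality = 1 - braveness - cautiousness``.  Inputs and outputs
    are proportions in [0, 1].
    """
    return {
        "coverage": accuracy + (1.0 - accuracy) * cautiousness,
        "specificity": accuracy + (1.0 - accuracy) * braveness,
        "orthogonality": 1.0 - braveness - cautiousness,
    }


def compare(reports: Sequence[CharacteristicsReport]) -> pd.DataFrame:
    """Side-by-side table of characteristics, one row per report.

    Values are percentages rounded to two decimals.
    """
    if len(reports) < 2:
        raise ValueError("compare needs at least two reports")
    rows = {r.set_label: r.as_percentages() for r in reports}
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(_METRICS))


# -- scenario presets --------------------------------------------------------------

#: Metric subsets matched to application scenarios.  ``position_focus``
#: (e.g. evaluating inside one branch of a merged vocabulary) looks at where
#: mismatches sit and at accuracy; ``coverage_priority`` (e.g. claims coding,
#: where broader codes are tolerated but wrong branches are not) adds
#: coverage, cautiousness and orthogonality; ``neighbourhood`` (candidate
#: pre-selection for curators) favours short average distance to the target.
SCENARIOS: dict[str, tuple[str, ...]] = {
    "position_focus": ("accuracy", "location_table"),
    "coverage_priority": ("accuracy", "coverage", "cautiousness", "orthogonality", "mean_mismatch_distance"),
    "neighbourhood": ("accuracy", "mean_mismatch_distance", "location_table"),
}


def mean_mismatch_distance(profile: PerformanceProfile, include_exact: bool = False) -> Optional[float]:
    """Arithmetic mean match distance, over mismatches only by default.

    Exact rows (distance 0) would dilute the neighbourhood signal, so they
    are excluded unless ``include_exact`` is set.  A mismatch-free profile
    has mean mismatch distance 0; None only when the profile carries no
    in-scope row at all.
    """
    distances = [
        r.distance
        for r in profile.records
        if r.distance is not None and (include_exact or r.type.is_mismatch)
    ]
    if distances:
        return sum(distances) / len(distances)
    if any(r.type.in_scope for r in profile.records):
        return 0.0
    return None


def scenario_report(
    profile: PerformanceProfile,
    scenario: str | Sequence[str],
    count_missing_as_orthogonal: bool = False,
) -> dict:
    """Emit only the metrics marked for a scenario preset (or a custom list)."""
    if isinstance(scenario, str):
        try:
            wanted = SCENARIOS[scenario]
        except KeyError:
            raise KeyError(
                f"unknown scenario {scenario!r}; available: {sorted(SCENARIOS)}"
            ) from None
    else:
        wanted = tuple(scenario)
        unknown = [w for w in wanted if w not in _METRICS + ("mean_mismatch_distance", "location_table")]
        if unknown:
            raise KeyError(f"unknown metrics {unknown}")
    report = characteristics(
        MatchCounts.from_profile(profile),
        set_label=profile.set_label,
        count_missing_as_orthogonal=count_missing_as_orthogonal,
    )
    out: dict = {"set": profile.set_label}
    for name in wanted:
        if name in _METRICS:
            out[name] = report.metric(name)
        elif name == "mean_mismatch_distance":
            out[name] = mean_mismatch_distance(profile)
        elif name == "location_table":
            from .profiling import profile_by_location

            out[name] = profile_by_location(profile).to_dict()
    return out
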