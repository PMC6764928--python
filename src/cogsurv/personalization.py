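"""Personalized test selection and the two-of-three decline criterion.

For each patient the three tests with the *highest* reliable-change values over
the surgery-to-first-follow-up contrast (months 0 -> 3) are selected — the
tests showing most post-surgical recovery, hypothesized to be the ones most
burdened by the tumor and hence the first to deteriorate when disease recurs.
Selection is sign-blind: if fewer than three tests improved, the least-negative
tests are still selected.

All later contrasts are re-baselined at the first post-surgical assessment
(month 3).  Cognitive decline (CD) at a follow-up visit is an RCI at or below
-1.00 on at least two of the three selected tests at that visit; once a
patient declines, downstream survival analysis treats the status as absorbing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .cohort_io import DEFAULT_ROSTER
from .normative import RCIVector

__all__ = ["AnalysisCriteria", "Selection", "DeclineTimeline",
           "select_tests", "classify_decline"]


@dataclass(frozen=True)
class AnalysisCriteria:
    """Tunable thresholds of the personalized decline criterion.

    Defaults are the study criterion: top ``k_selected``=3 tests by month 0->3
    RCI, decline = RCI <= -1.00 (boundary inclusive) on >= 2 of the 3 at a
    follow-up visit, follow-up contrasts baselined at month 3.
    """

    k_selected: int = 3
    min_declined: int = 2
    rci_decline_threshold: float = -1.00
    baseline_timepoint: int = 3
    selection_baseline: int = 0

    def __post_init__(self) -> None:
        if not (1 <= self.min_declined <= self.k_selected):
            raise ValueError("need 1 <= min_declined <= k_selected")
        if not self.rci_decline_threshold < 0:
            raise ValueError("rci_decline_threshold must be negative")
        if not self.selection_baseline < self.baseline_timepoint:
            raise ValueError("selection contrast must precede the re-baselining visit")


@dataclass(frozen=True)
class Selection:
    """A patient's selected tests, ordered by descending selection RCI."""

    patient_id: str
    selected: tuple[str, ...]
    selection_rcis: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.selected) != len(self.selection_rcis):
            raise ValueError("selected and selection_rcis must align")
        if len(set(self.selected)) != len(self.selected):
            raise ValueError("duplicate tests in selection")
        if any(nxt > prev for nxt, prev in
               zip(self.selection_rcis[1:], self.selection_rcis[:-1])):
            raise ValueError("selection RCIs must be non-increasing")


@dataclass(frozen=True)
class DeclineTimeline:
    """Per-visit decline flags for one patient, plus the first decline time."""

    patient_id: str
    flags: Mapping[int, bool]
    declined_counts: Mapping[int, int]
    first_cd_time: int | None = field(default=None)

    def __post_init__(self) -> None:
        true_times = sorted(t for t, f in self.flags.items() if f)
        expected = true_times[0] if true_times else None
        if self.first_cd_time != expected:
            raise ValueError("first_cd_time inconsistent with flags")

    def status_at(self, timepoint: int) -> int:
        """Absorbing decline status applicable at a visit (1 once declined)."""
        return int(self.first_cd_time is not None and self.first_cd_time <= timepoint)


def select_tests(rci_vector: RCIVector, criteria: AnalysisCriteria = AnalysisCriteria(),
                 roster_order: Sequence[str] = DEFAULT_ROSTER.codes) -> Selection:
    """Pick the ``k_selected`` tests with the highest selection-contrast RCIs.

    Ties at the selection boundary break deterministically by roster order
    (tests outside the roster sort after it, alphabetically).
    """
    k = criteria.k_selected
    if len(rci_vector.values) < k:
        raise ValueError(
            f"patient {rci_vector.patient_id}: only {len(rci_vector.values)} "
            f"tests available, need {k}")

    def order_key(test: str):
        if test in roster_order:
            return (0, list(roster_order).index(test), test)
        return (1, 0, test)

    ranked = sorted(rci_vector.values, key=lambda t: (-rci_vector.values[t], order_key(t)))
    top = ranked[:k]
    return Selection(patient_id=rci_vector.patient_id, selected=tuple(top),
                     selection_rcis=tuple(rci_vector.values[t] for t in top))


def classify_decline(selection: Selection, followup_rcis: Iterable[RCIVector],
                     criteria: AnalysisCriteria = AnalysisCriteria()) -> DeclineTimeline:
    """Evaluate the decline criterion at every follow-up visit.

    Each visit is judged on its own re-baselined vector: the flag is true iff
    at least ``min_declined`` of the selected tests present in that vector sit
    at or below the threshold.  A selected test missing at a visit counts as
    not declined (conservative), so visits with fewer than ``min_declined``
    selected tests observed can never trigger decline.
    """
    flags: dict[int, bool] = {}
    counts: dict[int, int] = {}
    for vec in followup_rcis:
        if vec.patient_id != selection.patient_id:
            raise ValueError(f"timeline patient mismatch: {vec.patient_id} vs "
                             f"{selection.patient_id}")
        if vec.baseline_timepoint != criteria.baseline_timepoint:
            raise ValueError(
                f"follow-up vector baselined at {vec.baseline_timepoint}, "
                f"expected {criteria.baseline_timepoint}")
        t = vec.followup_timepoint
        if t in flags:
            raise ValueError(f"duplicate follow-up vector at month {t}")
        n_declined = sum(
            1 for test in selection.selected
            if test in vec.values and vec.values[test] <= criteria.rci_decline_threshold)
        counts[t] = n_declined
        flags[t] = n_declined >= criteria.min_declined
    true_times = sorted(t for t, f in flags.items() if f)
    return DeclineTimeline(patient_id=selection.patient_id, flags=flags,
                           declined_counts=counts,
                           first_cd_time=true_times[0] if true_times else None)
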