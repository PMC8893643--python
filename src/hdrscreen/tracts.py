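"""Gene-conversion-tract calling from donor-SNP states.

Recoded homology arms carry marker SNPs at known signed offsets from the
predicted Cas9 double-strand break (DSB at 0; 5' offsets negative). In a
canonically integrated individual, each marker is sequenced as either the
donor base (converted), the wild-type base (not converted) or unread.
From that pattern this module calls, per event:

* direction — non-conversion, unidirectional (5' or 3') or bidirectional,
  according to which sides carry at least one donor-state call;
* a censored tract extent per side — the true tract end is only known to
  lie between the outermost donor-state SNP (extent_min) and the next
  more distal wild-type SNP, or the sequenced boundary (extent_max);
* continuity — whether every marker strictly between the outermost donor
  call and the DSB is donor-state (unread markers are non-informative:
  they do not break continuity but are counted);
* a mechanism label, a pure function of direction: unidirectional tracts
  indicate synthesis-dependent strand annealing with a one-ended
  invasion, bidirectional tracts either two-ended SDSA or a migrated
  Holliday junction (the data cannot distinguish these).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Direction",
    "Mechanism",
    "CallState",
    "SNPMap",
    "ConversionCallSet",
    "ConversionEvent",
    "IndeterminateEventError",
    "call_event",
    "aggregate_events",
    "censoring_interval_report",
]


class Direction(str, enum.Enum):
    NON_CONVERSION = "non_conversion"
    UNI_5P = "uni_5p"
    UNI_3P = "uni_3p"
    BIDIRECTIONAL = "bidirectional"


class Mechanism(str, enum.Enum):
    SDSA_ONE_ENDED = "sdsa_one_ended"
    SDSA_TWO_ENDED_OR_HJ = "sdsa_two_ended_or_hj"
    NONE = "none"


class CallState(str, enum.Enum):
    DONOR = "donor"
    WILDTYPE = "wildtype"
    UNREAD = "unread"


_MECHANISM_OF = {
    Direction.NON_CONVERSION: Mechanism.NONE,
    Direction.UNI_5P: Mechanism.SDSA_ONE_ENDED,
    Direction.UNI_3P: Mechanism.SDSA_ONE_ENDED,
    Direction.BIDIRECTIONAL: Mechanism.SDSA_TWO_ENDED_OR_HJ,
}


class IndeterminateEventError(ValueError):
    """Raised when every marker is unread and no call can be made."""


@dataclass(frozen=True)
class SNPMap:
    """Marker SNPs on the homology arms, keyed by signed offset from the DSB.

    ``offsets`` are unique, nonzero, sorted ascending; negative offsets lie
    on the 5' arm. ``ref_base``/``donor_base`` follow ``offsets`` order.
    """

    offsets: tuple[int, ...]
    ref_base: tuple[str, ...] = ()
    donor_base: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        offs = tuple(int(o) for o in self.offsets)
        if any(o == 0 for o in offs):
            raise ValueError("SNP offset 0 would sit on the DSB itself")
        if len(set(offs)) != len(offs):
            raise ValueError("SNP offsets must be unique")
        object.__setattr__(self, "offsets", tuple(sorted(offs)))
        for name in ("ref_base", "donor_base"):
            bases = getattr(self, name)
            if bases and len(bases) != len(offs):
                raise ValueError(f"{name} length must match offsets")

    @property
    def offsets_5p(self) -> tuple[int, ...]:
        return tuple(o for o in self.offsets if o < 0)

    @property
    def offsets_3p(self) -> tuple[int, ...]:
        return tuple(o for o in self.offsets if o > 0)

    def __len__(self) -> int:
        return len(self.offsets)

    def to_frame(self) -> pd.DataFrame:
        n = len(self.offsets)
        return pd.DataFrame({
            "offset": self.offsets,
            "side": ["five_prime" if o < 0 else "three_prime"
                     for o in self.offsets],
            "ref_base": self.ref_base or [""] * n,
            "donor_base": self.donor_base or [""] * n,
        })

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SNPMap":
        df = df.sort_values("offset")
        if "side" in df.columns:
            expected = np.where(df["offset"] < 0, "five_prime", "three_prime")
            bad = df.loc[df["side"].to_numpy() != expected, "offset"]
            if len(bad):
                raise ValueError(
                    f"side labels inconsistent with offset signs at {list(bad)}")
        kw = {}
        for col in ("ref_base", "donor_base"):
            if col in df.columns:
                kw[col] = tuple(df[col].astype(str))
        return cls(offsets=tuple(int(o) for o in df["offset"]), **kw)


@dataclass(frozen=True)
class ConversionCallSet:
    """Per-individual marker states plus the span actually sequenced."""

    event_id: str
    calls: Mapping[int, CallState]
    sequenced_span: tuple[int, int]
    pool_id: str = ""

    def __post_init__(self) -> None:
        lo, hi = self.sequenced_span
        if lo > hi:
            raise ValueError("sequenced_span must be (min, max)")
        outside = [o for o in self.calls if not lo <= o <= hi]
        if outside:
            raise ValueError(
                f"calls outside sequenced_span {self.sequenced_span}: {outside}")
        object.__setattr__(
            self, "calls",
            {int(o): CallState(s) for o, s in self.calls.items()})


@dataclass(frozen=True)
class ConversionEvent:
    """A classified HDR event.

    Extents are nonnegative bp measured from the DSB; (extent_min,
    extent_max) is the censoring interval for the true tract end on that
    side, both 0 when the side has no donor-state call.
    """

    event_id: str
    direction: Direction
    extent_5p_min: int
    extent_5p_max: int
    extent_3p_min: int
    extent_3p_max: int
    continuous: bool
    mechanism: Mechanism
    pool_id: str = ""
    unread_inside_tract: int = 0

    def __post_init__(self) -> None:
        if self.extent_5p_min > self.extent_5p_max \
                or self.extent_3p_min > self.extent_3p_max:
            raise ValueError("extent_min must be <= extent_max")
        has_5p = self.extent_5p_min > 0
        has_3p = self.extent_3p_min > 0
        expected = {
            (False, False): Direction.NON_CONVERSION,
            (True, False): Direction.UNI_5P,
            (False, True): Direction.UNI_3P,
            (True, True): Direction.BIDIRECTIONAL,
        }[(has_5p, has_3p)]
        if self.direction != expected:
            raise ValueError(
                f"direction {self.direction} inconsistent with extents")
        if self.mechanism != _MECHANISM_OF[self.direction]:
            raise ValueError("mechanism must follow from direction")


def _side_extent(calls: Mapping[int, CallState], offsets: Sequence[int],
                 span_bound: int) -> tuple[int, int, bool, int]:
    """Censored extent and continuity for one arm.

    ``offsets`` are this side's map offsets; ``span_bound`` the sequenced
    boundary on this side. Works in absolute distance from the DSB.
    Returns (extent_min, extent_max, continuous, n_unread_inside).
    """
    dist = {abs(o): calls.get(o, CallState.UNREAD) for o in offsets}
    donor_d = [d for d, s in dist.items() if s is CallState.DONOR]
    if not donor_d:
        return 0, 0, True, 0
    ext_min = max(donor_d)
    beyond_wt = [d for d, s in dist.items()
                 if s is CallState.WILDTYPE and d > ext_min]
    ext_max = min(beyond_wt) if beyond_wt else abs(span_bound)
    inside = {d: s for d, s in dist.items() if d < ext_min}
    continuous = not any(s is CallState.WILDTYPE for s in inside.values())
    n_unread = sum(s is CallState.UNREAD for s in inside.values())
    return ext_min, ext_max, continuous, n_unread


def call_event(calls: ConversionCallSet, snp_map: SNPMap) -> ConversionEvent:
    """Classify one individual's marker pattern into a ConversionEvent.

    Raises ``IndeterminateEventError`` when every marker is unread, and
    ``ValueError`` for calls at offsets absent from the map.
    """
    unknown = set(calls.calls) - set(snp_map.offsets)
    if unknown:
        raise ValueError(f"calls at offsets not in SNP map: {sorted(unknown)}")
    if all(s is CallState.UNREAD for s in calls.calls.values()) \
            or not calls.calls:
        raise IndeterminateEventError(
            f"event {calls.event_id!r}: every marker unread")

    span_lo, span_hi = calls.sequenced_span
    e5_min, e5_max, cont5, un5 = _side_extent(
        calls.calls, snp_map.offsets_5p, span_lo)
    e3_min, e3_max, cont3, un3 = _side_extent(
        calls.calls, snp_map.offsets_3p, span_hi)

    direction = {
        (False, False): Direction.NON_CONVERSION,
        (True, False): Direction.UNI_5P,
        (False, True): Direction.UNI_3P,
        (True, True): Direction.BIDIRECTIONAL,
    }[(e5_min > 0, e3_min > 0)]

    return ConversionEvent(
        event_id=calls.event_id,
        pool_id=calls.pool_id,
        direction=direction,
        extent_5p_min=e5_min,
        extent_5p_max=e5_max,
        extent_3p_min=e3_min,
        extent_3p_max=e3_max,
        continuous=cont5 and cont3,
        mechanism=_MECHANISM_OF[direction],
        unread_inside_tract=un5 + un3,
    )


def aggregate_events(events: Sequence[ConversionEvent]) -> dict:
    """Summarise classified events: class counts/percentages, maxima,
    discontinuity flags and the across-event range of tract-end intervals."""
    events = list(events)
    if not events:
        raise ValueError("no events to aggregate")
    n = len(events)
    dir_counts = {d.value: 0 for d in Direction}
    mech_counts = {m.value: 0 for m in Mechanism}
    for ev in events:
        dir_counts[ev.direction.value] += 1
        mech_counts[ev.mechanism.value] += 1
    uni = dir_counts["uni_5p"] + dir_counts["uni_3p"]
    converted = [ev for ev in events
                 if ev.direction is not Direction.NON_CONVERSION]
    ends_min = [e for ev in converted
                for e in (ev.extent_5p_min, ev.extent_3p_min) if e > 0]
    ends_max = [mx for ev in converted
                for mn, mx in ((ev.extent_5p_min, ev.extent_5p_max),
                               (ev.extent_3p_min, ev.extent_3p_max)) if mn > 0]
    return {
        "n_events": n,
        "direction_counts": dir_counts,
        "direction_pct": {k: 100.0 * v / n for k, v in dir_counts.items()},
        "pct_unidirectional": 100.0 * uni / n,
        "pct_non_conversion": 100.0 * dir_counts["non_conversion"] / n,
        "pct_bidirectional": 100.0 * dir_counts["bidirectional"] / n,
        "mechanism_counts": mech_counts,
        "max_extent_5p": max((ev.extent_5p_min for ev in events), default=0),
        "max_extent_3p": max((ev.extent_3p_min for ev in events), default=0),
        "tract_end_range_bp": ((min(ends_min), max(ends_max))
                               if ends_min else None),
        "n_discontinuous": sum(not ev.continuous for ev in events),
        "discontinuous_event_ids": [ev.event_id for ev in events
                                    if not ev.continuous],
        "n_with_unread_inside_tract": sum(ev.unread_inside_tract > 0
                                          for ev in events),
    }


def censoring_interval_report(events: Sequence[ConversionEvent]
                              ) -> pd.DataFrame:
    """One row per event and converted side: the (extent_min, extent_max)
    interval in which the true tract end lies."""
    rows = []
    for ev in events:
        for side, mn, mx in (("five_prime", ev.extent_5p_min, ev.extent_5p_max),
                             ("three_prime", ev.extent_3p_min, ev.extent_3p_max)):
            if mn > 0:
                rows.append({"event_id": ev.event_id, "side": side,
                             "extent_min_bp": mn, "extent_max_bp": mx,
                             "direction": ev.direction.value})
    return pd.DataFrame(rows, columns=["event_id", "side", "extent_min_bp",
                                       "extent_max_bp", "direction"])
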