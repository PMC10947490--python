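"""Translate an activity-volume difference into minutes of real activity.

A 1 SD increase in average-acceleration is an abstract quantity; the
time-reallocation calculation converts it into the minutes/day of a
named activity (at a known acceleration anchor) that would produce it,
assuming the added activity replaces time spent at the current average
level:

    minutes/day = 1440 x SD / (anchor_acceleration - average_acceleration)

Anchors for children: running/jumping/skipping-type activity > 4 m/s^2,
brisk walking (5.2 km/h) ~ 1.5 m/s^2, slow walking (3.2 km/h) ~ 0.75
m/s^2.  Any combination of activities whose acceleration increments sum
to the SD achieves the same increase.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import pandas as pd

MINUTES_PER_DAY = 1440.0

#: Rounding convention for presentation: below this many minutes results
#: are given to the nearest minute, at or above it in hours to the
#: nearest half hour.
HOURS_CUTOVER_MIN = 120.0


@dataclass(frozen=True)
class ActivityAnchor:
    """A named activity and its representative acceleration (m/s^2)."""

    label: str
    acceleration: float

    def __post_init__(self):
        if self.acceleration <= 0:
            raise ValueError("anchor acceleration must be positive")


DEFAULT_ANCHORS = (
    ActivityAnchor("high-intensity activities (running, jumping, skipping)", 4.0),
    ActivityAnchor("brisk walking", 1.5),
    ActivityAnchor("slow walking/light activity", 0.75),
)


@dataclass
class ReallocationResult:
    """Minutes/day of one anchor activity yielding a 1 SD volume increase."""

    stratum: str
    label: str
    minutes: float  # unrounded
    display_value: float
    display_unit: str  # "min" or "h"
    sd: float
    mean_avg_acc: float
    anchor_acceleration: float

    @property
    def display(self) -> str:
        v = self.display_value
        text = f"{v:g}"
        return f"{text} {self.display_unit}"


def reallocation_minutes(sd: float, mean_avg_acc: float, anchor_acc: float) -> float:
    """Minutes/day of an anchor activity replacing average-level time
    needed to raise average-acceleration by one SD (unrounded)."""
    if sd <= 0:
        raise ValueError("sd must be positive")
    if anchor_acc <= mean_avg_acc:
        raise ValueError("activity not more intense than current average")
    return MINUTES_PER_DAY * sd / (anchor_acc - mean_avg_acc)


def _round_half_up(x: float) -> float:
    return math.floor(x + 0.5)


def round_for_display(minutes: float, cutover_min: float = HOURS_CUTOVER_MIN):
    """Apply the presentation rounding rule.

    Returns ``(value, unit)``: nearest whole minute below the cutover,
    otherwise hours to the nearest half hour.
    """
    if minutes < cutover_min:
        return float(_round_half_up(minutes)), "min"
    hours = minutes / 60.0
    return _round_half_up(hours * 2.0) / 2.0, "h"


def render_translation(
    stratum_stats: dict,
    anchors=DEFAULT_ANCHORS,
    rounding: bool = True,
) -> list:
    """Build the per-stratum activity-equivalence list.

    Parameters
    ----------
    stratum_stats : dict
        ``{stratum: (mean_average_acceleration, sd)}`` in m/s^2.
    anchors : iterable of ActivityAnchor
    rounding : bool
        Apply the display rounding rule; if False the display value is
        the unrounded minutes.

    Anchors not more intense than a stratum's mean are omitted with a
    warning.  Each stratum's list is implicitly completed by the note
    that any combination of activities summing to the SD achieves the
    same increase.
    """
    results = []
    for stratum, (mean, sd) in stratum_stats.items():
        for anchor in anchors:
            if anchor.acceleration <= mean:
                warnings.warn(
                    f"anchor {anchor.label!r} ({anchor.acceleration} m/s^2) "
                    f"omitted for {stratum}: not more intense than the "
                    f"stratum mean ({mean} m/s^2)"
                )
                continue
            minutes = reallocation_minutes(sd, mean, anchor.acceleration)
            if rounding:
                value, unit = round_for_display(minutes)
            else:
                value, unit = minutes, "min"
            results.append(
                ReallocationResult(
                    stratum=stratum,
                    label=anchor.label,
                    minutes=minutes,
                    display_value=value,
                    display_unit=unit,
                    sd=sd,
                    mean_avg_acc=mean,
                    anchor_acceleration=anchor.acceleration,
                )
            )
    return results


COMBINATION_NOTE = (
    "or any combination of the above such that the sum of the "
    "acceleration increases equals the SD"
)


def translation_frame(results: list) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "stratum": r.stratum,
                "activity": r.label,
                "anchor_m_s2": r.anchor_acceleration,
                "mean_avg_acc": r.mean_avg_acc,
                "sd": r.sd,
                "minutes_unrounded": r.minutes,
                "display": r.display,
            }
            for r in results
        ]
    )


def translation_markdown(results: list) -> str:
    lines = []
    for stratum in dict.fromkeys(r.stratum for r in results):
        rs = [r for r in results if r.stratum == stratum]
        sd = rs[0].sd
        lines.append(
            f"**{stratum}** — a 1 SD ({sd:g} m/s^2) increase in "
            "average-acceleration could be achieved with:"
        )
        for r in rs:
            lines.append(f"- {r.display} of {r.label}")
        lines.append(f"- {COMBINATION_NOTE}")
        lines.append("")
    return "\n".join(lines).rstrip() + "\n"
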