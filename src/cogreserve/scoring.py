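"""Scoring of raw socio-behavioural inputs into individual reserve proxies.

Covers occupational complexity from Dictionary of Occupational Titles (DOT)
data/people/things ratings, physical-activity metabolic scores (IPAQ-style
minutes and Godin-style session counts), Likert activity-frequency sums, and
reading-test (NART/AMNART) totals with the half-test gating rule. Years of
education and the Social Network Index are consumed as-is by the pipeline and
need no scoring here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

__all__ = [
    "DotRatings",
    "ActivityResponses",
    "IpaqReport",
    "GodinReport",
    "occupational_complexity",
    "ipaq_met_minutes",
    "godin_met_hours",
    "activity_sum",
    "nart_score",
    "DOT_DIMENSION_MAX",
    "IPAQ_DEFAULT_WEIGHTS",
    "GODIN_DURATIONS_H",
    "GODIN_MET_VALUES",
]

# DOT convention: each dimension is rated 0..max with LOWER = more complex.
DOT_DIMENSION_MAX = {"data": 6, "people": 8, "things": 7}

# Standard IPAQ short-form scoring-protocol MET weights per minute.
IPAQ_DEFAULT_WEIGHTS = {"vigorous": 8.0, "moderate": 4.0, "walking": 3.3}

# Godin leisure-time exercise: assumed session durations (hours) and MET values.
GODIN_DURATIONS_H = {"strenuous": 0.5, "moderate": 0.75, "mild": 1.0}
GODIN_MET_VALUES = {"strenuous": 9.0, "moderate": 5.0, "mild": 3.0}


@dataclass(frozen=True)
class DotRatings:
    """DOT complexity ratings for one occupation (lower = more complex)."""

    data: int
    people: int
    things: int

    def __post_init__(self) -> None:
        for dim in ("data", "people", "things"):
            val = getattr(self, dim)
            hi = DOT_DIMENSION_MAX[dim]
            if not (isinstance(val, (int,)) and 0 <= val <= hi):
                raise ValueError(
                    f"DOT {dim} rating {val!r} outside valid range 0-{hi}"
                )


@dataclass(frozen=True)
class ActivityResponses:
    """Likert responses for one activity instrument.

    `scale_min`/`scale_max` declare the per-item response range (0-7 for the
    8-point frequency scales; 1-3 for 3-point never/sometimes/often scales).
    The item count is whatever the instrument declares; it is not inferred.
    """

    responses: tuple
    scale_min: int = 0
    scale_max: int = 7

    def __init__(self, responses: Sequence, scale_min: int = 0, scale_max: int = 7):
        object.__setattr__(self, "responses", tuple(responses))
        object.__setattr__(self, "scale_min", int(scale_min))
        object.__setattr__(self, "scale_max", int(scale_max))
        if self.scale_max <= self.scale_min:
            raise ValueError("scale_max must exceed scale_min")


@dataclass(frozen=True)
class IpaqReport:
    """Self-reported activity minutes per week in three intensity bands."""

    vigorous: float
    moderate: float
    walking: float

    def __post_init__(self) -> None:
        for band in ("vigorous", "moderate", "walking"):
            if getattr(self, band) < 0:
                raise ValueError(f"IPAQ {band} minutes must be >= 0")


@dataclass(frozen=True)
class GodinReport:
    """Weekly counts of exercise sessions (> 15 min) in three bands."""

    strenuous: float
    moderate: float
    mild: float

    def __post_init__(self) -> None:
        for band in ("strenuous", "moderate", "mild"):
            if getattr(self, band) < 0:
                raise ValueError(f"Godin {band} session count must be >= 0")


def occupational_complexity(ratings: DotRatings) -> int:
    """Reverse each DOT rating on its dimension range and sum.

    Returns an integer from 0 (minimal complexity) to 21 (maximal
    complexity); higher = more complex work.
    """
    return (
        (DOT_DIMENSION_MAX["data"] - ratings.data)
        + (DOT_DIMENSION_MAX["people"] - ratings.people)
        + (DOT_DIMENSION_MAX["things"] - ratings.things)
    )


def ipaq_met_minutes(report: IpaqReport,
                     weights: Mapping[str, float] | None = None) -> float:
    """Total metabolic-equivalent minutes per week from an IPAQ-style report.

    Each intensity band's minutes are weighted by its MET value and summed.
    Weights default to the IPAQ scoring protocol (8.0 / 4.0 / 3.3) and can be
    overridden.
    """
    w = dict(IPAQ_DEFAULT_WEIGHTS)
    if weights is not None:
        w.update(weights)
    return (report.vigorous * w["vigorous"]
            + report.moderate * w["moderate"]
            + report.walking * w["walking"])


def godin_met_hours(report: GodinReport) -> float:
    """Total metabolic hours per week from a Godin-style session-count report.

    Session counts are weighted by the assumed duration per session
    (0.5 / 0.75 / 1 h) and the band's MET value (9 / 5 / 3).
    """
    total = 0.0
    for band, count in (("strenuous", report.strenuous),
                        ("moderate", report.moderate),
                        ("mild", report.mild)):
        total += count * GODIN_DURATIONS_H[band] * GODIN_MET_VALUES[band]
    return total


def activity_sum(responses: ActivityResponses) -> int:
    """Sum the item responses of an activity-frequency instrument.

    Every item must be present and inside the declared scale range; there is
    no prorating of missing items.
    """
    total = 0
    for i, r in enumerate(responses.responses):
        if r is None:
            raise ValueError(f"activity item {i} is missing; prorating is not supported")
        if not (responses.scale_min <= r <= responses.scale_max):
            raise ValueError(
                f"activity item {i} response {r!r} outside declared range "
                f"{responses.scale_min}-{responses.scale_max}"
            )
        total += int(r)
    return total


def nart_score(first_half_correct: int,
               second_half_correct: int | None = None,
               conversion: Mapping[int, int] | None = None,
               max_total: int = 50) -> int:
    """Reading-test total with the half-test gating rule.

    The second half is only administered when the first-half score exceeds
    20. When the second half is present the two halves are summed. When it is
    absent: first-half scores of 0-11 stand as full scores; scores of 12-20
    are corrected through an injected half-to-full conversion lookup (the
    published conversion table is not bundled); a first-half score above 20
    without a second half is an inconsistent record and is rejected.
    """
    half_max = max_total // 2 + max_total % 2
    if not (0 <= first_half_correct <= half_max):
        raise ValueError(f"first-half score {first_half_correct} outside 0-{half_max}")
    if second_half_correct is not None:
        if not (0 <= second_half_correct <= max_total - first_half_correct):
            raise ValueError("second-half score inconsistent with test length")
        return int(first_half_correct + second_half_correct)
    if first_half_correct <= 11:
        return int(first_half_correct)
    if first_half_correct <= 20:
        if conversion is None:
            raise ValueError(
                "first-half scores of 12-20 require a half-to-full conversion "
                "lookup; none was supplied"
            )
        try:
            return int(conversion[first_half_correct])
        except KeyError:
            raise ValueError(
                f"conversion lookup has no entry for first-half score "
                f"{first_half_correct}"
            ) from None
    raise ValueError(
        "first-half score > 20 requires the second half to have been administered"
    )
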