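"""Alternating-access state classification from funnel-radius profiles.

A transporter is called open on a side when the minimum mean radius over
that side's vestibule region clears ``r_open``; between ``r_semi`` and
``r_open`` the side is semi-open, and below ``r_semi`` it is closed.  An
optional third threshold ``r_quasi`` (between the two) splits the
partially open band into quasi-open (wider) and semi-open (narrower),
mirroring the quasi-open/semi-open/closed vocabulary used for the
inward-facing vestibule.  Default vestibule regions are z = +5..+15 Å
(outward-facing) and −15..−5 Å (inward-facing), flanking a binding site
at roughly −5..+5 Å.
"""

from __future__ import annotations

from dataclasses import dataclass

from .models import ConfigError
from .pore import FunnelProfile

__all__ = ["StateLabel", "classify_state"]

STATE_LABELS = (
    "OF_open",
    "IF_open",
    "occluded",
    "bilaterally_open",
    "OF_semi_open",
    "IF_semi_open",
    "OF_quasi_open",
    "IF_quasi_open",
)


@dataclass(frozen=True)
class StateLabel:
    """A conformational-state call: a pure function of two minima + thresholds."""

    label: str
    of_min_radius: float
    if_min_radius: float
    r_open: float
    r_semi: float
    r_quasi: float | None = None


def _side_category(r_min: float, r_open: float, r_semi: float, r_quasi: float | None) -> str:
    if r_min >= r_open:
        return "open"
    if r_min < r_semi:
        return "closed"
    if r_quasi is not None and r_min >= r_quasi:
        return "quasi"
    return "semi"


def classify_state(
    profile: FunnelProfile,
    of_region: tuple = (5.0, 15.0),
    if_region: tuple = (-15.0, -5.0),
    r_open: float = 2.0,
    r_semi: float = 1.2,
    r_quasi: float | None = None,
) -> StateLabel:
    """Classify the transporter state from a funnel profile.

    Each side is graded open / (quasi-) semi-open / closed from the
    minimum mean radius over its region; the two grades compose into the
    state label: both open → bilaterally_open, both closed → occluded,
    exactly one side open → that side's open label; otherwise the more
    open side names a semi- or quasi-open label.  Ties (both sides
    equally semi-open) fall to occluded.
    """
    if r_semi > r_open or (r_quasi is not None and not (r_semi <= r_quasi <= r_open)):
        raise ConfigError("thresholds must satisfy r_semi <= r_quasi <= r_open")
    of_min = profile.min_radius_in(*of_region)
    if_min = profile.min_radius_in(*if_region)
    of_cat = _side_category(of_min, r_open, r_semi, r_quasi)
    if_cat = _side_category(if_min, r_open, r_semi, r_quasi)

    if of_cat == "open" and if_cat == "open":
        label = "bilaterally_open"
    elif of_cat == "open":
        label = "OF_open"
    elif if_cat == "open":
        label = "IF_open"
    elif of_cat == "closed" and if_cat == "closed":
        label = "occluded"
    else:
        # neither side open, at least one partially open: the wider side names it
        if of_min > if_min:
            side, cat = "OF", of_cat
        elif if_min > of_min:
            side, cat = "IF", if_cat
        else:
            side, cat = None, None
        if side is None:
            label = "occluded"
        else:
            label = f"{side}_{'quasi' if cat == 'quasi' else 'semi'}_open"
    return StateLabel(
        label=label,
        of_min_radius=of_min,
        if_min_radius=if_min,
        r_open=r_open,
        r_semi=r_semi,
        r_quasi=r_quasi,
    )
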