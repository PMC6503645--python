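"""Benefit/harm ratios of non-nearest PSC transport destinations.

For a scene in the higher-order triage region, transporting to a farther
PSC (``PSC2``) instead of the nearest PSC (``PSC1``) trades a later start
of thrombolysis against an earlier thrombectomy; instead of the nearest
CSC, it trades a later thrombectomy against earlier thrombolysis. The two
ratios quantify those trades:

    BHR_PSC = [(d_PSC1 + d_Transfer1) - (d_PSC2 + d_Transfer2)]
              / (d_PSC2 - d_PSC1)

    BHR_CSC = (d_CSC - d_PSC2)
              / [(d_PSC2 + DIDO + d_Transfer2) - d_CSC]

where d_* are driving times in minutes and DIDO the door-in-door-out
time at the PSC. DIDO cancels in BHR_PSC (same constant at both PSCs).

If the BHR_CSC denominator is non-positive, the via-PSC route reaches the
CSC no later than direct transport: choosing the PSC has no harm axis.
Such options return the :data:`DOMINATES` sentinel instead of a ratio.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

from .destination_sets import DestinationSet
from .environments import Location
from .errors import ValidationError


class _Dominates:
    """Sentinel: via-PSC route weakly beats direct CSC transport."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "DOMINATES"


DOMINATES = _Dominates()

BhrCsc = Union[float, _Dominates]


def bhr_vs_nearest_psc(
    d_psc1: float, t1: float, d_psc2: float, t2: float
) -> float:
    """Benefit/harm ratio of PSC2 relative to the nearest PSC.

    Benefit: reduction in time-to-thrombectomy, (d_psc1+t1) - (d_psc2+t2).
    Harm: increase in time-to-thrombolysis, d_psc2 - d_psc1.
    """
    if not d_psc2 > d_psc1:
        raise ValidationError(
            f"option must be farther from the scene than the nearest PSC: "
            f"require d_psc2 > d_psc1, got {d_psc2} <= {d_psc1}"
        )
    if not (d_psc1 + t1) >= (d_psc2 + t2):
        raise ValidationError(
            f"option must shorten the via-PSC route: require "
            f"d_psc1 + t1 >= d_psc2 + t2, got {d_psc1 + t1} < {d_psc2 + t2}"
        )
    return ((d_psc1 + t1) - (d_psc2 + t2)) / (d_psc2 - d_psc1)


def bhr_vs_nearest_csc(
    d_csc: float, d_psc2: float, t2: float, dido: float
) -> BhrCsc:
    """Benefit/harm ratio of PSC2 relative to direct nearest-CSC transport.

    Benefit: reduction in time-to-thrombolysis, d_csc - d_psc2.
    Harm: increase in time-to-thrombectomy,
    (d_psc2 + dido + t2) - d_csc. Returns :data:`DOMINATES` when the harm
    is non-positive.
    """
    if not d_psc2 < d_csc:
        raise ValidationError(
            f"option must be closer than the nearest CSC: require "
            f"d_psc2 < d_csc, got {d_psc2} >= {d_csc}"
        )
    if dido <= 0:
        raise ValidationError(f"dido must be positive, got {dido}")
    denom = (d_psc2 + dido + t2) - d_csc
    if denom <= 0:
        return DOMINATES
    return (d_csc - d_psc2) / denom


@dataclass(frozen=True)
class OptionBhr:
    """Per-option ratios; both are None for the nearest PSC itself, which
    is not an "additionally considered" destination."""

    psc_id: str
    bhr_psc: float | None
    bhr_csc: BhrCsc | None


@dataclass(frozen=True)
class BhrResult:
    """Benefit/harm ratios at one higher-order scene location.

    ``bhr_psc_max`` / ``bhr_csc_max`` are the maxima over defined
    entries; ``bhr_csc_max`` is None when every option dominates direct
    CSC transport. ``n_dominates`` counts DOMINATES entries.
    """

    point: Location
    entries: tuple[OptionBhr, ...]
    bhr_psc_max: float
    bhr_csc_max: float | None
    n_dominates: int
    dido_used: float

    @property
    def dominates(self) -> bool:
        return self.n_dominates > 0


def point_bhr(point: Location, dest: DestinationSet, dido: float) -> BhrResult:
    """Evaluate both ratio families for every additionally considered
    option (each admissible PSC beyond the nearest one) at a higher-order
    scene (>= 2 admissible PSCs)."""
    if dest.option_count < 3:
        raise ValidationError(
            f"benefit/harm ratios are defined on higher-order points only "
            f"(option_count >= 3, got {dest.option_count})"
        )
    nearest = dest.options[0]
    entries: list[OptionBhr] = [OptionBhr(nearest.center_id, None, None)]
    psc_vals: list[float] = []
    csc_vals: list[float] = []
    n_dom = 0
    for opt in dest.options[1:]:
        b_psc = bhr_vs_nearest_psc(
            nearest.d_psc, nearest.d_transfer, opt.d_psc, opt.d_transfer
        )
        psc_vals.append(b_psc)
        b_csc = bhr_vs_nearest_csc(dest.d_csc, opt.d_psc, opt.d_transfer, dido)
        if b_csc is DOMINATES:
            n_dom += 1
        else:
            csc_vals.append(b_csc)
        entries.append(OptionBhr(opt.center_id, b_psc, b_csc))
    return BhrResult(
        point=point,
        entries=tuple(entries),
        bhr_psc_max=max(psc_vals),
        bhr_csc_max=max(csc_vals) if csc_vals else None,
        n_dominates=n_dom,
        dido_used=dido,
    )
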