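"""Admissible transport destinations and triage sub-region classification.

For a stroke scene, the candidate destinations are the nearest CSC, the
nearest PSC, and any farther PSC through which the total
time-to-CSC-via-PSC is shorter than through every PSC closer to the
scene. Equivalently, the admissible PSCs are the Pareto frontier of
(time to PSC, time to CSC via that PSC), restricted to PSCs closer to
the scene than the nearest CSC.

Each location is then labelled by how many destinations must be weighed:

* ``UNCONDITIONAL_CSC`` — the nearest center is a CSC; one destination.
* ``SIMPLE_TRIAGE`` — nearest PSC vs nearest CSC; two destinations.
* ``HIGHER_ORDER`` — three or more destinations (>= 2 admissible PSCs).

DIDO is the same at every PSC, so it cancels when PSCs are compared with
each other and is omitted from the via-PSC times here; it enters only the
benefit/harm ratio against direct CSC transport (see :mod:`.bhr`).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .environments import CSC, PSC, Environment, Location, StrokeCenter
from .errors import ValidationError


class RegionLabel(enum.IntEnum):
    UNCONDITIONAL_CSC = 1
    SIMPLE_TRIAGE = 2
    HIGHER_ORDER = 3


def label_for_option_count(option_count: int) -> RegionLabel:
    if option_count < 1:
        raise ValidationError(f"option_count must be >= 1, got {option_count}")
    if option_count == 1:
        return RegionLabel.UNCONDITIONAL_CSC
    if option_count == 2:
        return RegionLabel.SIMPLE_TRIAGE
    return RegionLabel.HIGHER_ORDER


@dataclass(frozen=True)
class PscOption:
    """One admissible PSC destination: scene->PSC time and the onward
    transfer time from that PSC to its best CSC (DIDO excluded)."""

    center_id: str
    d_psc: float
    d_transfer: float

    def __post_init__(self) -> None:
        if self.d_psc < 0 or self.d_transfer < 0:
            raise ValidationError(
                f"negative travel time in option {self.center_id!r}"
            )

    @property
    def via_time(self) -> float:
        return self.d_psc + self.d_transfer


@dataclass(frozen=True)
class DestinationSet:
    """All admissible destinations for one scene location.

    ``options`` are the admissible PSCs sorted by increasing scene->PSC
    time; by Pareto-optimality their via times strictly decrease. The
    nearest CSC is always an option, so ``option_count = 1 + len(options)``.
    """

    point: Location
    nearest_csc_id: str
    d_csc: float
    options: tuple[PscOption, ...]

    @property
    def option_count(self) -> int:
        return 1 + len(self.options)

    @property
    def label(self) -> RegionLabel:
        return label_for_option_count(self.option_count)


@dataclass(frozen=True)
class Classification:
    label: RegionLabel
    option_count: int


# ---------------------------------------------------------------------------
# scalar operations
# ---------------------------------------------------------------------------


def nearest_center(
    point: Location, env: Environment, level: str
) -> tuple[str, float]:
    """Nearest center of the given level; ties broken by lexicographic id."""
    candidates = env.centers_of(level)
    if not candidates:
        raise ValidationError(f"environment has no center of level {level!r}")
    best = min(candidates, key=lambda c: (env.travel_time(point, c.location), c.id))
    return best.id, env.travel_time(point, best.location)


def best_transfer_time(psc: StrokeCenter, env: Environment) -> tuple[str, float]:
    """Fastest secondary transfer from a PSC to any CSC (driving leg only)."""
    if psc.level != PSC:
        raise ValidationError(f"{psc.id!r} is not a PSC")
    cscs = env.cscs
    times = env.travel_time.center_matrix([psc], cscs)[0]
    order = sorted(range(len(cscs)), key=lambda i: (times[i], cscs[i].id))
    i = order[0]
    return cscs[i].id, float(times[i])


def pareto_options(
    d_csc: float, candidates: Iterable[PscOption]
) -> list[PscOption]:
    """Filter PSC candidates down to the admissible set.

    A PSC is admissible iff it is closer to the scene than the nearest
    CSC and no PSC strictly closer to the scene reaches a CSC via itself
    at least as fast (dominance with non-strict via-time comparison, so
    an equal-via farther PSC offers no strict benefit and is dropped).
    """
    ordered = sorted(candidates, key=lambda o: (o.d_psc, o.center_id))
    result: list[PscOption] = []
    best_via_closer = float("inf")  # best via_time among strictly closer PSCs
    i = 0
    while i < len(ordered):
        # process all candidates tied at the same scene distance together
        j = i
        while j < len(ordered) and ordered[j].d_psc == ordered[i].d_psc:
            j += 1
        group = ordered[i:j]
        for opt in group:
            if opt.d_psc < d_csc and opt.via_time < best_via_closer:
                result.append(opt)
        best_via_closer = min([best_via_closer] + [o.via_time for o in group])
        i = j
    return result


def psc_candidates(point: Location, env: Environment) -> list[PscOption]:
    """All PSCs with their scene and best-transfer times (no filtering)."""
    out = []
    for psc in env.pscs:
        _, transfer = best_transfer_time(psc, env)
        out.append(
            PscOption(psc.id, env.travel_time(point, psc.location), transfer)
        )
    return out


def admissible_psc_options(point: Location, env: Environment) -> list[PscOption]:
    """Admissible PSC destinations for a scene, sorted by scene->PSC time."""
    _, d_csc = nearest_center(point, env, CSC)
    return pareto_options(d_csc, psc_candidates(point, env))


def destination_set(point: Location, env: Environment) -> DestinationSet:
    csc_id, d_csc = nearest_center(point, env, CSC)
    options = pareto_options(d_csc, psc_candidates(point, env))
    return DestinationSet(point, csc_id, d_csc, tuple(options))


def classify_point(point: Location, env: Environment) -> Classification:
    """Triage sub-region label for a scene location."""
    n = destination_set(point, env).option_count
    return Classification(label_for_option_count(n), n)


# ---------------------------------------------------------------------------
# vectorized kernel (used by the raster evaluator)
# ---------------------------------------------------------------------------


def admissible_matrix(
    d_csc: np.ndarray, d_psc: np.ndarray, transfer: np.ndarray
) -> np.ndarray:
    """Vectorized admissibility over m points x p PSCs.

    ``d_csc``: (m,) scene->nearest-CSC times; ``d_psc``: (m, p) scene->PSC
    times; ``transfer``: (p,) PSC->best-CSC times. Returns a boolean
    (m, p) mask identical to per-point :func:`pareto_options`.
    """
    d_csc = np.asarray(d_csc, float)
    d_psc = np.asarray(d_psc, float)
    transfer = np.asarray(transfer, float)
    if d_psc.shape[1] == 0:
        return np.zeros_like(d_psc, dtype=bool)
    via = d_psc + transfer[None, :]
    # dominated[i, j]: some PSC l strictly closer to scene i with via <= via_j
    closer = d_psc[:, :, None] < d_psc[:, None, :]  # [i, l, j]
    dominated = (closer & (via[:, :, None] <= via[:, None, :])).any(axis=1)
    return (~dominated) & (d_psc < d_csc[:, None])
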