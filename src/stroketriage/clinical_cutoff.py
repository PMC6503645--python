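"""LVO-probability-dependent benefit/harm-ratio cutoff.

Whether a patient gains from a higher-order option depends on how likely
a large vessel occlusion (LVO) is: without LVO only thrombolysis timing
matters, with LVO thrombectomy timing dominates. Weighing the per-minute
outcome effects of faster thrombolysis and faster thrombectomy, the
expected benefit of a non-nearest PSC is positive when its BHR (vs the
nearest PSC) exceeds

    cutoff = (1 - p_LVO) / p_LVO * E_lysis / E_MT

where E_lysis and E_MT are the outcome gains per minute of faster
thrombolysis and thrombectomy. The defaults (1.8 and 4.2
disability-adjusted life-days per minute) follow the published
per-minute effect estimates of Meretoja and colleagues. The rule is
conditional on the patient not being triaged directly to the nearest CSC
in the first place.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ValidationError

DEFAULT_EFFECT_LYSIS = 1.8  # disability-adjusted life-days per minute
DEFAULT_EFFECT_MT = 4.2


@dataclass(frozen=True)
class CutoffParams:
    """``p_lvo``: probability of large vessel occlusion, in (0, 1);
    effects: outcome gain per minute of faster treatment (units cancel)."""

    p_lvo: float
    effect_lysis: float = DEFAULT_EFFECT_LYSIS
    effect_mt: float = DEFAULT_EFFECT_MT

    def __post_init__(self) -> None:
        if not 0.0 < self.p_lvo < 1.0:
            raise ValidationError(
                f"p_lvo must be strictly between 0 and 1, got {self.p_lvo}"
            )
        if self.effect_lysis <= 0 or self.effect_mt <= 0:
            raise ValidationError("treatment effects must be positive")


def bhr_cutoff(params: CutoffParams) -> float:
    """BHR (vs nearest PSC) above which a higher-order option is expected
    to benefit the patient."""
    return (1.0 - params.p_lvo) / params.p_lvo * params.effect_lysis / params.effect_mt


def benefits_from_option(bhr_psc: float, params: CutoffParams) -> bool:
    """True iff the option's BHR strictly exceeds the patient's cutoff.

    Applies only when the patient would not be transported directly to
    the nearest CSC anyway (the comparison is against the nearest PSC).
    """
    if bhr_psc <= 0:
        raise ValidationError(f"bhr_psc must be positive, got {bhr_psc}")
    return bhr_psc > bhr_cutoff(params)
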