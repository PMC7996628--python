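"""The frailty index: a fixed linear model over five kinematic features.

FI_raw = −1.7357×10⁻³·Ph1 − 1.2026×10⁻³·Ph2 + 0.36848×10⁻³·Ph3
         − 0.49396·Ph4 + 0.48974·Ph5 + 0.24495

where Ph1 is the range of motion (deg), Ph2 the percentage decline in power
(signed %), Ph3 the flexion time (milliseconds), and Ph4/Ph5 the flexion- and
extension-time variabilities (coefficients of variation as unitless
fractions).  The coefficients come from a previously published regression on
a geriatric cohort and are treated as constants; re-estimation is out of
scope.  The input unit conventions are a derived calibration: they are the
only convention under which the published cohort mean feature values
reproduce the published mean index (0.18) through the linear form — kept as
a regression test.

The reported index clamps the raw value to [0, 1]; both are returned.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import isfinite

from .errors import ValidationError
from .features import PhenotypeFeatureSet

COEF_RANGE_OF_MOTION = -1.7357e-3  # per degree
COEF_DELTA_POWER = -1.2026e-3  # per percent (signed)
COEF_FLEXION_TIME = 0.36848e-3  # per millisecond
COEF_CV_FLEXION_TIME = -0.49396  # per unit fraction
COEF_CV_EXTENSION_TIME = 0.48974  # per unit fraction
INTERCEPT = 0.24495


@dataclass(frozen=True)
class FrailtyInputs:
    """The five regressors, in the model's unit conventions."""

    ph1_range_of_motion: float  # deg
    ph2_decline_in_power: float  # signed percent
    ph3_flexion_time: float  # milliseconds
    ph4_cv_flexion_time: float  # fraction (e.g. 0.08 for 8 %)
    ph5_cv_extension_time: float  # fraction

    def __post_init__(self):
        vals = (
            self.ph1_range_of_motion,
            self.ph2_decline_in_power,
            self.ph3_flexion_time,
            self.ph4_cv_flexion_time,
            self.ph5_cv_extension_time,
        )
        if not all(isfinite(v) for v in vals):
            raise ValidationError("frailty inputs must be finite")
        for name in ("ph1_range_of_motion", "ph3_flexion_time", "ph4_cv_flexion_time", "ph5_cv_extension_time"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")


@dataclass(frozen=True)
class FrailtyResult:
    raw_linear_value: float
    frailty_index: float  # clamped to [0, 1]
    clamped: bool

    def to_json_dict(self, inputs: FrailtyInputs | None = None) -> dict:
        doc = {
            "raw_linear_value": self.raw_linear_value,
            "frailty_index": self.frailty_index,
            "clamped": self.clamped,
        }
        if inputs is not None:
            doc["inputs"] = {
                "range_of_motion_deg": inputs.ph1_range_of_motion,
                "decline_in_power_percent": inputs.ph2_decline_in_power,
                "flexion_time_ms": inputs.ph3_flexion_time,
                "cv_flexion_time_fraction": inputs.ph4_cv_flexion_time,
                "cv_extension_time_fraction": inputs.ph5_cv_extension_time,
            }
        return doc


def compute_frailty_index(inputs: FrailtyInputs) -> FrailtyResult:
    """Evaluate the linear model and clamp the index to [0, 1]."""
    raw = (
        COEF_RANGE_OF_MOTION * inputs.ph1_range_of_motion
        + COEF_DELTA_POWER * inputs.ph2_decline_in_power
        + COEF_FLEXION_TIME * inputs.ph3_flexion_time
        + COEF_CV_FLEXION_TIME * inputs.ph4_cv_flexion_time
        + COEF_CV_EXTENSION_TIME * inputs.ph5_cv_extension_time
        + INTERCEPT
    )
    index = min(1.0, max(0.0, raw))
    return FrailtyResult(raw_linear_value=raw, frailty_index=index, clamped=index != raw)


def features_to_inputs(features: PhenotypeFeatureSet) -> FrailtyInputs:
    """Convert the extracted feature set (s, %) to the model's units (ms, fractions).

    Raises :class:`FeatureUnavailable` naming the feature if any of the five
    sources is flagged unavailable.
    """
    return FrailtyInputs(
        ph1_range_of_motion=features.require("range_of_motion"),
        ph2_decline_in_power=features.require("delta_power"),
        ph3_flexion_time=features.require("flexion_time") * 1000.0,
        ph4_cv_flexion_time=features.require("cv_flexion_time") / 100.0,
        ph5_cv_extension_time=features.require("cv_extension_time") / 100.0,
    )
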