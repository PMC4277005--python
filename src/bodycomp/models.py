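"""Closed-form densitometric body-composition models.

Two models are implemented. The three-component model (3CM) partitions body
mass into fat, water and residual solids and computes the fat fraction from
body density, total body water (TBW) and body weight:

    f = 2.118 / D_B - 0.78 * TBW / weight - 1.354

The two-component model (2CM) partitions body mass into fat and fat-free mass
(FFM) and computes the fat fraction from body density alone, given assumed
densities of fat (0.9007 g/mL) and of FFM:

    1 / D_B = f / d_fat + (1 - f) / d_ffm

solved for f. Inverting the same relation for d_ffm at a 3CM fat fraction
yields a per-subject FFM density, the basis of the variability analysis in
:mod:`bodycomp.propagation`.

Densities are in g/mL, masses in kg, volumes in L throughout; with these
units body volume = weight / density holds exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping

import numpy as np

__all__ = [
    "Stage",
    "ModelConstants",
    "CONSTANTS",
    "STAGE_FFM_DENSITY",
    "POSTPARTUM_NONPREGNANT_FFM_DENSITY",
    "AnthropometricMeasurement",
    "BodyComposition",
    "InvalidInputError",
    "DegenerateModelError",
    "PhysiologicalRangeWarning",
    "tbw_from_deuterium_space",
    "fat_fraction_3cm",
    "fat_fraction_2cm",
    "ffm_density_from_fat_fraction",
    "body_composition",
]


class InvalidInputError(ValueError):
    """Raised when an input violates a model precondition."""


class DegenerateModelError(ValueError):
    """Raised when model parameters make the formula undefined.

    For the 2CM this happens when the assumed FFM density does not exceed
    the fat density (the denominator of the fat-fraction solution vanishes
    or flips sign); for the FFM-density inversion, when the implied FFM
    volume is non-positive.
    """


class PhysiologicalRangeWarning(UserWarning):
    """A value is outside the physiologically plausible window.

    Emitted, never raised: out-of-range fat fractions and densities are
    returned unclamped so population statistics remain faithful.
    """


class Stage(str, Enum):
    """Reproductive stage of a measurement occasion."""

    PRE_PREGNANCY = "pre_pregnancy"
    GW14 = "gw14"
    GW32 = "gw32"
    POSTPARTUM_2W = "postpartum_2w"


@dataclass(frozen=True)
class ModelConstants:
    """Fixed coefficients of the densitometric models.

    ``c1``, ``c2`` and ``c3`` are the three-component-model coefficients of
    1/D_B, TBW/weight and the intercept; ``fat_density`` is the assumed
    density of body fat; ``dilution_factor`` converts a deuterium dilution
    space to TBW (the isotope overestimates body water by ~4% through
    exchange with non-aqueous hydrogen).
    """

    c1: float = 2.118
    c2: float = 0.78
    c3: float = 1.354
    fat_density: float = 0.9007
    dilution_factor: float = 1.04


CONSTANTS = ModelConstants()

#: Reference FFM density (g/mL) by reproductive stage: 1.100 for non-pregnant
#: adults, gestational values from reference-body adjustments for pregnancy,
#: and an early-postpartum value.
STAGE_FFM_DENSITY: Mapping[Stage, float] = {
    Stage.PRE_PREGNANCY: 1.100,
    Stage.GW14: 1.099,
    Stage.GW32: 1.092,
    Stage.POSTPARTUM_2W: 1.094,
}

#: Alternative postpartum reference: the ordinary non-pregnant value.
POSTPARTUM_NONPREGNANT_FFM_DENSITY = 1.100

_DENSITY_SANITY = (0.9, 1.15)


@dataclass
class AnthropometricMeasurement:
    """One subject-stage record of weight, TBW and body density.

    Parameters
    ----------
    subject_id : str
        Subject identifier.
    stage : Stage
        Reproductive stage of the measurement occasion.
    body_weight : float
        Body weight in kg; must be positive.
    total_body_water : float
        Total body water in kg; must lie in (0, body_weight).
    body_density : float
        Body density in g/mL. Values outside (0.9, 1.15) trigger a
        :class:`PhysiologicalRangeWarning` but are kept.
    """

    subject_id: str
    stage: Stage
    body_weight: float
    total_body_water: float
    body_density: float

    def __post_init__(self) -> None:
        self.stage = Stage(self.stage)
        if not self.body_weight > 0:
            raise InvalidInputError(
                f"body_weight must be positive, got {self.body_weight}"
            )
        if not 0 < self.total_body_water < self.body_weight:
            raise InvalidInputError(
                "total_body_water must lie in (0, body_weight), got "
                f"{self.total_body_water} with weight {self.body_weight}"
            )
        if not self.body_density > 0:
            raise InvalidInputError(
                f"body_density must be positive, got {self.body_density}"
            )
        lo, hi = _DENSITY_SANITY
        if not lo < self.body_density < hi:
            warnings.warn(
                f"body_density {self.body_density} g/mL outside the sanity "
                f"window ({lo}, {hi}) for subject {self.subject_id}",
                PhysiologicalRangeWarning,
                stacklevel=2,
            )

    @property
    def body_volume(self) -> float:
        """Body volume in L (weight / density)."""
        return self.body_weight / self.body_density


@dataclass
class BodyComposition:
    """Derived body-composition record for one measurement.

    ``fat_mass + ffm_mass == body weight`` by construction; ``ffm_density``
    is either the per-subject value from the 3CM inversion or the reference
    value fed to the 2CM, depending on the method used.
    """

    fat_fraction: float
    fat_mass: float
    ffm_mass: float
    ffm_density: float
    ffm_hydration: float
    body_volume: float
    method: str = field(default="three_component")

    @property
    def tbf_percent(self) -> float:
        """Total body fat as percent of body weight."""
        return 100.0 * self.fat_fraction


def _check_plausible(f, context: str) -> None:
    f = np.asarray(f)
    if np.any((f < 0) | (f > 1)):
        warnings.warn(
            f"{context}: fat fraction outside [0, 1] "
            "(physiologically implausible; returned unclamped)",
            PhysiologicalRangeWarning,
            stacklevel=3,
        )


def tbw_from_deuterium_space(space):
    """Convert a deuterium dilution space (kg) to total body water (kg).

    The dilution space is divided by 1.04 to correct for deuterium exchange
    with non-aqueous hydrogen.
    """
    space = np.asarray(space, dtype=float)
    if np.any(space <= 0):
        raise InvalidInputError("deuterium space must be positive")
    out = space / CONSTANTS.dilution_factor
    return float(out) if out.ndim == 0 else out


def fat_fraction_3cm(body_weight, total_body_water, body_density):
    """Three-component-model fat fraction from weight, TBW and body density.

    f = c1 / D_B - c2 * TBW / weight - c3 with c1 = 2.118, c2 = 0.78,
    c3 = 1.354. Accepts scalars or arrays (broadcasting). Fat fractions
    outside [0, 1] are returned with a :class:`PhysiologicalRangeWarning`.
    """
    w = np.asarray(body_weight, dtype=float)
    tbw = np.asarray(total_body_water, dtype=float)
    d = np.asarray(body_density, dtype=float)
    if np.any(w <= 0) or np.any(d <= 0):
        raise InvalidInputError("weight and body density must be positive")
    f = CONSTANTS.c1 / d - CONSTANTS.c2 * tbw / w - CONSTANTS.c3
    _check_plausible(f, "fat_fraction_3cm")
    return float(f) if f.ndim == 0 else f


def fat_fraction_2cm(body_density, ffm_density):
    """Two-component-model fat fraction from body density alone.

    Solves 1/D_B = f/d_fat + (1 - f)/d_ffm for f:

        f = (1/D_B - 1/d_ffm) / (1/d_fat - 1/d_ffm)

    ``ffm_density`` must exceed the fat density 0.9007 g/mL or the model is
    degenerate (fat and FFM indistinguishable by density).
    """
    d_b = np.asarray(body_density, dtype=float)
    d_ffm = np.asarray(ffm_density, dtype=float)
    if np.any(d_b <= 0):
        raise InvalidInputError("body density must be positive")
    if np.any(d_ffm <= CONSTANTS.fat_density):
        raise DegenerateModelError(
            "FFM density must exceed the fat density "
            f"{CONSTANTS.fat_density} g/mL"
        )
    f = (1.0 / d_b - 1.0 / d_ffm) / (1.0 / CONSTANTS.fat_density - 1.0 / d_ffm)
    _check_plausible(f, "fat_fraction_2cm")
    return float(f) if f.ndim == 0 else f


def ffm_density_from_fat_fraction(body_density, fat_fraction):
    """FFM density implied by a body density and a known fat fraction.

    Inverts the 2CM relation for the FFM density:

        d_ffm = (1 - f) / (1/D_B - f/d_fat)

    The denominator is the FFM volume per kg of body mass and must be
    positive; round-trips with :func:`fat_fraction_2cm` to machine
    precision.
    """
    d_b = np.asarray(body_density, dtype=float)
    f = np.asarray(fat_fraction, dtype=float)
    if np.any(d_b <= 0):
        raise InvalidInputError("body density must be positive")
    if np.any(f >= 1):
        raise InvalidInputError("fat fraction must be < 1 to define an FFM")
    denom = 1.0 / d_b - f / CONSTANTS.fat_density
    if np.any(denom <= 0):
        raise DegenerateModelError(
            "implied FFM volume is non-positive (body denser than its fat "
            "content allows)"
        )
    out = (1.0 - f) / denom
    return float(out) if out.ndim == 0 else out


def _default_ffm_density(stage: Stage) -> float:
    try:
        return STAGE_FFM_DENSITY[Stage(stage)]
    except (KeyError, ValueError):
        raise InvalidInputError(
            f"no reference FFM density registered for stage {stage!r}; "
            "supply ffm_density_ref explicitly"
        ) from None


def body_composition(
    m: AnthropometricMeasurement,
    method: str = "three_component",
    ffm_density_ref: float | None = None,
) -> BodyComposition:
    """Full body-composition record for one measurement.

    Parameters
    ----------
    m : AnthropometricMeasurement
        The measurement record.
    method : {"three_component", "two_component"}
        With ``three_component`` the fat fraction comes from weight, TBW and
        density and the reported FFM density is the subject's own (by 2CM
        inversion). With ``two_component`` the fat fraction comes from body
        density and a reference FFM density (stage default from
        :data:`STAGE_FFM_DENSITY` unless ``ffm_density_ref`` is given).
    ffm_density_ref : float, optional
        Reference FFM density in g/mL for the two-component method.

    Returns
    -------
    BodyComposition
        With ``fat_mass + ffm_mass == body_weight`` exactly.
    """
    if method == "three_component":
        f = fat_fraction_3cm(m.body_weight, m.total_body_water, m.body_density)
        d_ffm = ffm_density_from_fat_fraction(m.body_density, f)
    elif method == "two_component":
        d_ffm = (
            _default_ffm_density(m.stage)
            if ffm_density_ref is None
            else float(ffm_density_ref)
        )
        f = fat_fraction_2cm(m.body_density, d_ffm)
    else:
        raise InvalidInputError(
            f"method must be 'two_component' or 'three_component', got {method!r}"
        )
    fat_mass = f * m.body_weight
    ffm_mass = m.body_weight - fat_mass
    hydration = m.total_body_water / ffm_mass if ffm_mass > 0 else float("nan")
    return BodyComposition(
        fat_fraction=f,
        fat_mass=fat_mass,
        ffm_mass=ffm_mass,
        ffm_density=d_ffm,
        ffm_hydration=hydration,
        body_volume=m.body_volume,
        method=method,
    )
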