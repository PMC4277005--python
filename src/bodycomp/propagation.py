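"""Propagation of measurement error into FFM density, and variance split.

The observed spread of per-subject FFM density mixes two sources: imprecision
of the underlying measurements (weight, total body water, body volume) and
genuine between-subject biology. The methodological part is obtained by
first-order propagation of the stated measurement SDs through the composite
map

    (weight, TBW, volume) -> D_B = weight/volume
                          -> f by the three-component model
                          -> FFM density by two-component inversion

evaluated at the cohort-mean measurement vector, with the three measurement
errors taken as independent zero-mean Gaussians. The biological part is then
the quadrature remainder: sqrt(total^2 - methodological^2), clamped at zero.

Two conventional precision specifications are provided: ``set1`` expresses
TBW and volume precision relative to the cohort mean (1.05% and 0.7%),
``set2`` as absolute SDs (0.331 kg and 0.371 L); weight precision is 0.01 kg
in both.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, NamedTuple

import numpy as np

from .models import (
    CONSTANTS,
    AnthropometricMeasurement,
    InvalidInputError,
)

__all__ = [
    "PrecisionSpec",
    "ResolvedPrecision",
    "VariabilityDecomposition",
    "PRECISION_PRESETS",
    "resolve_precision",
    "ffm_density_from_wtv",
    "methodological_sd_ffm_density",
    "decompose_variability",
    "density_precision_to_volume_sd",
]


@dataclass(frozen=True)
class PrecisionSpec:
    """Measurement-error magnitudes for weight, TBW and body volume.

    In ``relative`` mode ``tbw_sd`` and ``volume_sd`` are fractions of the
    cohort-mean TBW and volume (e.g. 0.0105 for 1.05%); in ``absolute`` mode
    they are kg and L. ``weight_sd`` is always kg.
    """

    mode: Literal["relative", "absolute"]
    weight_sd: float = 0.01
    tbw_sd: float = 0.0
    volume_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in ("relative", "absolute"):
            raise InvalidInputError(f"unknown precision mode {self.mode!r}")
        if min(self.weight_sd, self.tbw_sd, self.volume_sd) < 0:
            raise InvalidInputError("precision SDs must be non-negative")


#: Named precision presets: TBW 1.05% / volume 0.7% (relative) and
#: TBW 0.331 kg / volume 0.371 L (absolute); weight 0.01 kg in both.
PRECISION_PRESETS: dict[str, PrecisionSpec] = {
    "set1": PrecisionSpec(mode="relative", weight_sd=0.01, tbw_sd=0.0105, volume_sd=0.007),
    "set2": PrecisionSpec(mode="absolute", weight_sd=0.01, tbw_sd=0.331, volume_sd=0.371),
}


class ResolvedPrecision(NamedTuple):
    """Absolute measurement SDs: weight (kg), TBW (kg), volume (L)."""

    weight_sd: float
    tbw_sd: float
    volume_sd: float


@dataclass(frozen=True)
class VariabilityDecomposition:
    """Split of total FFM-density SD into methodological and biological parts.

    Shares are percent of total *variance*. When the propagated
    methodological SD exceeds the total observed SD the biological variance
    is clamped at zero, ``clamped`` is set, and the shares are reported as
    100/0.
    """

    total_sd: float
    methodological_sd: float
    biological_sd: float
    methodological_share: float
    biological_share: float
    clamped: bool = False


def resolve_precision(
    spec: PrecisionSpec, means: AnthropometricMeasurement
) -> ResolvedPrecision:
    """Resolve a precision spec to absolute SDs at the cohort means.

    Relative TBW and volume fractions are scaled by the mean TBW and the
    mean body volume (weight/density); absolute specs pass through
    unchanged.
    """
    if spec.mode == "absolute":
        return ResolvedPrecision(spec.weight_sd, spec.tbw_sd, spec.volume_sd)
    return ResolvedPrecision(
        weight_sd=spec.weight_sd,
        tbw_sd=spec.tbw_sd * means.total_body_water,
        volume_sd=spec.volume_sd * means.body_volume,
    )


def ffm_density_from_wtv(weight, tbw, volume):
    """FFM density from raw weight (kg), TBW (kg) and body volume (L).

    The composite measurement-to-density map: body density = weight/volume,
    fat fraction by the three-component model, FFM density by two-component
    inversion. Vectorised; this is the map whose partial derivatives drive
    the error propagation.
    """
    weight = np.asarray(weight, dtype=float)
    tbw = np.asarray(tbw, dtype=float)
    volume = np.asarray(volume, dtype=float)
    d_b = weight / volume
    f = CONSTANTS.c1 / d_b - CONSTANTS.c2 * tbw / weight - CONSTANTS.c3
    out = (1.0 - f) / (1.0 / d_b - f / CONSTANTS.fat_density)
    return float(out) if out.ndim == 0 else out


def methodological_sd_ffm_density(
    means: AnthropometricMeasurement, spec: PrecisionSpec
) -> float:
    """First-order propagated SD of FFM density at the cohort means.

    Central finite-difference partials of :func:`ffm_density_from_wtv` with
    respect to weight, TBW and volume (step ``max(1e-6*|x|, 1e-8)``),
    combined in quadrature with the resolved measurement SDs. Independence
    of the three measurement errors is assumed.
    """
    sds = resolve_precision(spec, means)
    x0 = np.array([means.body_weight, means.total_body_water, means.body_volume])
    if not np.isfinite(ffm_density_from_wtv(*x0)):
        raise InvalidInputError("FFM-density map undefined at the supplied means")
    var = 0.0
    for i, sd in enumerate(sds):
        h = max(1e-6 * abs(x0[i]), 1e-8)
        hi, lo = x0.copy(), x0.copy()
        hi[i] += h
        lo[i] -= h
        partial = (ffm_density_from_wtv(*hi) - ffm_density_from_wtv(*lo)) / (2 * h)
        var += (partial * sd) ** 2
    return float(np.sqrt(var))


def decompose_variability(
    total_sd: float, methodological_sd: float
) -> VariabilityDecomposition:
    """Split a total FFM-density SD into methodological and biological parts.

    biological_sd = sqrt(max(total^2 - methodological^2, 0)); shares are the
    component variances as percent of total variance. A methodological SD
    exceeding the total clamps the biological part at zero (``clamped``).
    """
    if total_sd < 0 or methodological_sd < 0:
        raise InvalidInputError("SDs must be non-negative")
    total_var = total_sd**2
    meth_var = methodological_sd**2
    clamped = meth_var > total_var
    bio_var = max(total_var - meth_var, 0.0)
    if clamped or total_var == 0.0:
        meth_share, bio_share = 100.0, 0.0
        clamped = clamped or methodological_sd > 0
        if total_var == 0.0 and methodological_sd == 0.0:
            meth_share = bio_share = 0.0
    else:
        meth_share = 100.0 * meth_var / total_var
        bio_share = 100.0 * bio_var / total_var
    return VariabilityDecomposition(
        total_sd=float(total_sd),
        methodological_sd=float(methodological_sd),
        biological_sd=float(np.sqrt(bio_var)),
        methodological_share=meth_share,
        biological_share=bio_share,
        clamped=bool(clamped),
    )


def density_precision_to_volume_sd(
    density_sd: float, weight: float, volume: float
) -> float:
    """First-order volume SD equivalent of a body-density SD.

    |dV/dD_B| * sd = (volume^2 / weight) * density_sd. Utility only: the
    variability analysis takes volume precision as its primary input, not a
    density precision converted this way.
    """
    if weight <= 0 or volume <= 0:
        raise InvalidInputError("weight and volume must be positive")
    if density_sd < 0:
        raise InvalidInputError("density_sd must be non-negative")
    return (volume**2 / weight) * density_sd
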