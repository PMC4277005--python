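"""Tabular input/output, configuration and the end-to-end analysis report.

Measurement tables are delimited text (comma by default, tab accepted) with
one row per subject-stage and headers ``subject_id, stage, weight_kg,
tbw_kg, body_density_g_ml``. A ``d2o_space_kg`` column may replace
``tbw_kg``; the deuterium dilution-space correction (division by 1.04) is
then applied on read. Rows violating record invariants are rejected with
row-numbered log messages; the remaining rows are kept.

:func:`run_analysis` ties the stages together: per-stage cohort summaries,
two- vs three-component agreement, per-subject FFM density and its
variance decomposition under the configured precision presets.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .agreement import AgreementResult, bland_altman
from .models import (
    AnthropometricMeasurement,
    InvalidInputError,
    Stage,
    STAGE_FFM_DENSITY,
    fat_fraction_2cm,
    fat_fraction_3cm,
    ffm_density_from_fat_fraction,
    tbw_from_deuterium_space,
)
from .propagation import (
    PRECISION_PRESETS,
    PrecisionSpec,
    VariabilityDecomposition,
    decompose_variability,
    methodological_sd_ffm_density,
)

__all__ = [
    "ConfigurationError",
    "AnalysisConfig",
    "load_config",
    "read_measurements",
    "write_measurements",
    "write_truth_table",
    "StageReport",
    "run_analysis",
    "render_report",
]

logger = logging.getLogger("bodycomp")

REQUIRED_COLUMNS = ("subject_id", "stage", "weight_kg", "body_density_g_ml")
WATER_COLUMNS = ("tbw_kg", "d2o_space_kg")


class ConfigurationError(ValueError):
    """A configuration file or table schema is invalid."""


@dataclass
class AnalysisConfig:
    """Flat configuration for the end-to-end analysis.

    ``ffm_density_source`` is either the string ``"registry"`` (stage
    defaults) or a mapping stage name -> density g/mL; ``precision_presets``
    name entries of :data:`bodycomp.propagation.PRECISION_PRESETS` or carry
    an inline custom spec.
    """

    input_path: str
    output_dir: str = "."
    ffm_density_source: str | Mapping[str, float] = "registry"
    precision_presets: Sequence[str] = ("set1", "set2")
    column_map: Mapping[str, str] = field(default_factory=dict)
    delimiter: str | None = None
    seed: int = 0
    verbosity: str = "INFO"


def load_config(path: str | Path) -> AnalysisConfig:
    """Load a flat YAML key-value config file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"config {path} is not a key-value mapping")
    if "input_path" not in raw:
        raise ConfigurationError("config must set input_path")
    known = set(AnalysisConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    cfg = AnalysisConfig(**raw)
    for name in cfg.precision_presets:
        if isinstance(name, str) and name not in PRECISION_PRESETS:
            raise ConfigurationError(
                f"unknown precision preset {name!r}; known: {sorted(PRECISION_PRESETS)}"
            )
    return cfg


def read_measurements(
    path: str | Path,
    delimiter: str | None = None,
    column_map: Mapping[str, str] | None = None,
) -> list[AnthropometricMeasurement]:
    """Read a delimited measurement table into typed records.

    A ``d2o_space_kg`` column substitutes for ``tbw_kg`` (the dilution
    correction is applied). Rows failing type or invariant checks are
    dropped with a row-numbered log warning; a missing required column
    raises :class:`ConfigurationError`, an empty table
    :class:`bodycomp.models.InvalidInputError`.
    """
    if Path(path).stat().st_size == 0:
        raise InvalidInputError(f"{path}: empty measurement file")
    if delimiter is None:
        with open(path, newline="") as fh:
            header = fh.readline()
        try:
            delimiter = csv.Sniffer().sniff(header, delimiters=",\t;").delimiter
        except csv.Error:
            delimiter = ","
    try:
        df = pd.read_csv(path, sep=delimiter, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise InvalidInputError(f"{path}: unreadable measurement file") from None
    if column_map:
        df = df.rename(columns=dict(column_map))
    df.columns = [c.strip() for c in df.columns]
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(f"{path}: missing required columns {missing}")
    if not any(c in df.columns for c in WATER_COLUMNS):
        raise ConfigurationError(
            f"{path}: need one of {WATER_COLUMNS} for total body water"
        )
    if df.empty:
        raise InvalidInputError(f"{path}: no data rows")

    records: list[AnthropometricMeasurement] = []
    for idx, row in df.iterrows():
        rowno = idx + 2  # 1-based, after the header line
        try:
            if "tbw_kg" in df.columns and pd.notna(row.get("tbw_kg")):
                tbw = float(row["tbw_kg"])
            elif "d2o_space_kg" in df.columns and pd.notna(row.get("d2o_space_kg")):
                tbw = tbw_from_deuterium_space(float(row["d2o_space_kg"]))
            else:
                raise InvalidInputError("no TBW or deuterium-space value")
            records.append(
                AnthropometricMeasurement(
                    subject_id=str(row["subject_id"]),
                    stage=Stage(str(row["stage"])),
                    body_weight=float(row["weight_kg"]),
                    total_body_water=tbw,
                    body_density=float(row["body_density_g_ml"]),
                )
            )
        except (InvalidInputError, ValueError) as exc:
            logger.warning("%s row %d rejected: %s", path, rowno, exc)
    if not records:
        raise InvalidInputError(f"{path}: no valid rows")
    return records


def write_measurements(
    measurements: Iterable[AnthropometricMeasurement],
    path: str | Path,
    delimiter: str = ",",
) -> None:
    """Write measurement records as a delimited table (read round-trips)."""
    df = pd.DataFrame(
        {
            "subject_id": [m.subject_id for m in measurements],
            "stage": [m.stage.value for m in measurements],
            "weight_kg": [repr(float(m.body_weight)) for m in measurements],
            "tbw_kg": [repr(float(m.total_body_water)) for m in measurements],
            "body_density_g_ml": [repr(float(m.body_density)) for m in measurements],
        }
    )
    df.to_csv(path, sep=delimiter, index=False)


def write_truth_table(bodies, path: str | Path, delimiter: str = ",") -> None:
    """Write latent synthetic-body truth (masses, densities) as a table."""
    df = pd.DataFrame(
        {
            "subject_id": [b.subject_id for b in bodies],
            "stage": [b.stage.value for b in bodies],
            "fat_mass_kg": [b.fat_mass for b in bodies],
            "water_mass_kg": [b.water_mass for b in bodies],
            "residual_mass_kg": [b.residual_mass for b in bodies],
            "weight_kg": [b.weight for b in bodies],
            "volume_l": [b.volume for b in bodies],
            "body_density_g_ml": [b.body_density for b in bodies],
            "fat_fraction": [b.fat_fraction for b in bodies],
            "ffm_density_g_ml": [b.ffm_density for b in bodies],
        }
    )
    df.to_csv(path, sep=delimiter, index=False)


@dataclass
class StageReport:
    """All per-stage analysis outputs."""

    stage: Stage
    n: int
    weight_mean: float
    weight_sd: float
    tbw_mean: float
    tbw_sd: float
    density_mean: float
    density_sd: float
    ffm_density_ref: float
    tbf2_mean: float
    tbf2_sd: float
    tbf3_mean: float
    tbf3_sd: float
    agreement: AgreementResult | None
    ffm_density_mean: float
    ffm_density_total_sd: float
    decompositions: dict[str, VariabilityDecomposition]


def _resolve_ref_density(source, stage: Stage) -> float:
    if source == "registry":
        return STAGE_FFM_DENSITY[stage]
    try:
        return float(source[stage.value])
    except (KeyError, TypeError) as exc:
        raise ConfigurationError(
            f"no 2CM reference density for stage {stage.value!r}"
        ) from exc


def run_analysis(
    measurements: Sequence[AnthropometricMeasurement],
    ffm_density_source: str | Mapping[str, float] = "registry",
    precision_presets: Sequence[str | PrecisionSpec] = ("set1", "set2"),
) -> dict[Stage, StageReport]:
    """Per-stage end-to-end analysis of a measurement table.

    For each stage present: cohort means +/- SD, two-component TBF% at the
    configured reference FFM density vs the three-component reference
    estimate (with Bland-Altman agreement where n >= 3), per-subject FFM
    density mean and total SD, and the variance decomposition under each
    precision preset. Deterministic in its inputs.
    """
    out: dict[Stage, StageReport] = {}
    for stage in Stage:
        ms = [m for m in measurements if m.stage == stage]
        if not ms:
            continue
        w = np.array([m.body_weight for m in ms])
        tbw = np.array([m.total_body_water for m in ms])
        d_b = np.array([m.body_density for m in ms])
        ref = _resolve_ref_density(ffm_density_source, stage)
        tbf2 = 100.0 * fat_fraction_2cm(d_b, ref)
        f3 = fat_fraction_3cm(w, tbw, d_b)
        tbf3 = 100.0 * f3
        d_ffm = ffm_density_from_fat_fraction(d_b, f3)

        if len(ms) >= 3:
            agreement = bland_altman(tbf2, tbf3)
        else:
            logger.warning(
                "stage %s has %d subjects (<3); agreement statistics skipped",
                stage.value,
                len(ms),
            )
            agreement = None

        sample_means = AnthropometricMeasurement(
            subject_id="<sample mean>",
            stage=stage,
            body_weight=float(np.mean(w)),
            total_body_water=float(np.mean(tbw)),
            body_density=float(np.mean(w) / np.mean(w / d_b)),
        )
        total_sd = float(np.std(d_ffm, ddof=1)) if len(ms) > 1 else 0.0
        decomps = {}
        for preset in precision_presets:
            spec = PRECISION_PRESETS[preset] if isinstance(preset, str) else preset
            name = preset if isinstance(preset, str) else spec.mode
            meth = methodological_sd_ffm_density(sample_means, spec)
            decomps[name] = decompose_variability(total_sd, meth)

        out[stage] = StageReport(
            stage=stage,
            n=len(ms),
            weight_mean=float(np.mean(w)),
            weight_sd=float(np.std(w, ddof=1)) if len(ms) > 1 else 0.0,
            tbw_mean=float(np.mean(tbw)),
            tbw_sd=float(np.std(tbw, ddof=1)) if len(ms) > 1 else 0.0,
            density_mean=float(np.mean(d_b)),
            density_sd=float(np.std(d_b, ddof=1)) if len(ms) > 1 else 0.0,
            ffm_density_ref=ref,
            tbf2_mean=float(np.mean(tbf2)),
            tbf2_sd=float(np.std(tbf2, ddof=1)) if len(ms) > 1 else 0.0,
            tbf3_mean=float(np.mean(tbf3)),
            tbf3_sd=float(np.std(tbf3, ddof=1)) if len(ms) > 1 else 0.0,
            agreement=agreement,
            ffm_density_mean=float(np.mean(d_ffm)),
            ffm_density_total_sd=total_sd,
            decompositions=decomps,
        )
    return out


_STAGE_LABEL = {
    Stage.PRE_PREGNANCY: "Before pregnancy",
    Stage.GW14: "Gestational week 14",
    Stage.GW32: "Gestational week 32",
    Stage.POSTPARTUM_2W: "2 weeks postpartum",
}


def render_report(reports: Mapping[Stage, StageReport]) -> str:
    """Render the per-stage analysis as deterministic delimited text.

    Percentages to 1 decimal, densities to 3 decimals.
    """
    lines: list[str] = []
    for stage, r in reports.items():
        lines.append(f"# {_STAGE_LABEL[stage]} (n={r.n})")
        lines.append("quantity\tvalue")
        lines.append(f"weight_kg\t{r.weight_mean:.1f} ± {r.weight_sd:.1f}")
        lines.append(f"tbw_kg\t{r.tbw_mean:.1f} ± {r.tbw_sd:.1f}")
        lines.append(f"body_density_g_ml\t{r.density_mean:.3f} ± {r.density_sd:.3f}")
        lines.append(f"ffm_density_ref_g_ml\t{r.ffm_density_ref:.3f}")
        lines.append(f"tbf_2cm_pct\t{r.tbf2_mean:.1f} ± {r.tbf2_sd:.1f}")
        lines.append(f"tbf_3cm_pct\t{r.tbf3_mean:.1f} ± {r.tbf3_sd:.1f}")
        if r.agreement is not None:
            a = r.agreement
            lines.append(f"agreement_mean_diff_pct\t{a.mean_diff:.2f}")
            lines.append(f"agreement_2sd_pct\t{2 * a.sd_diff:.2f}")
            lines.append(f"agreement_trend_r\t{a.trend_r:.2f}")
            lines.append(f"agreement_trend_p\t{a.trend_p:.3f}")
            lines.append(
                "agreement_trend_eq\ty = "
                f"{a.trend_slope:.2f}x + {a.trend_intercept:.1f}"
            )
            lines.append(f"paired_t_p\t{a.paired_t_p:.3f}")
            lines.append(
                "identity_eq\ty = "
                f"{a.identity_slope:.2f}x + {a.identity_intercept:.1f}, "
                f"r = {a.identity_r:.2f}"
            )
        lines.append(f"ffm_density_mean_g_ml\t{r.ffm_density_mean:.3f}")
        lines.append(f"ffm_density_total_sd_g_ml\t{r.ffm_density_total_sd:.3f}")
        for name, d in r.decompositions.items():
            lines.append(
                f"decomposition_{name}\tmethodological_sd={d.methodological_sd:.3f} "
                f"({d.methodological_share:.0f}%), biological_sd={d.biological_sd:.3f} "
                f"({d.biological_share:.0f}%)"
                + (", clamped" if d.clamped else "")
            )
        lines.append("")
    return "\n".join(lines)
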