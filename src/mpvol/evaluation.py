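"""Model evaluation against measured collective volumes.

A *throw* is one deposition of a particle mixture followed by image
analysis; each *batch* (replicate subsample) of a *group* (shape/size
category such as P25, S25, S12) is thrown several times.  For every
throw the summed modeled volume is compared with the measured collective
volume (pycnometer or displacement), giving a V_modeled/V_measured
ratio.  Aggregation follows the study design: throw ratios average into
a batch value; the group mean and standard deviation are taken over the
batch values (not over pooled throws).

Two models are compared per batch with a variance-ratio F-test on their
per-throw residuals (modeled - measured collective volume), and the
calibration-bearing models (Cozar, Isobe, Tanoiri) can be re-optimized
per throw against the measured volumes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .volume_models import ModelParams, estimate_volume

log = logging.getLogger(__name__)

__all__ = [
    "MixtureRecord",
    "RatioReport",
    "FTestResult",
    "RecalibrationResult",
    "modeled_collective",
    "ratio_table",
    "compare_models_ftest",
    "recalibrate",
    "UnsupportedModelError",
]

#: models recalibrate() accepts, mapped to (bounds, description of the free parameter)
_CALIBRATABLE = {
    "cozar": ((1e-6, 1.0), "K_c"),
    "isobe": ((1e-6, 1.0), "K_I"),
    "tanoiri": ((1e-6, 2.0), "height slope"),
}


class UnsupportedModelError(ValueError):
    """Raised when a model without free parameters is sent to recalibration."""


@dataclass
class MixtureRecord:
    """One throw: its particle metrics and the mixture's measured volume.

    ``particles`` is a metrics table with the per-particle CSV columns
    (``area_mm2``, ``perimeter_mm``, ``major_mm``, ``minor_mm``, and for
    fibers ``is_fiber``/``fiber_length_mm``/``fiber_width_mm``).  The
    measured volume is converted to mm^3 on construction.
    """

    group: str
    batch: int
    throw: int
    particles: pd.DataFrame
    measured_volume: float
    unit: str = "mm3"
    method: str = "pycnometer"

    def __post_init__(self) -> None:
        if self.measured_volume <= 0:
            raise ValueError("measured volume must be positive")
        if len(self.particles) == 0:
            raise ValueError("particle list must be nonempty")
        unit = self.unit.replace("^", "").replace("³", "3").lower()
        if unit == "cm3":
            self.measured_volume *= 1000.0
        elif unit != "mm3":
            raise ValueError(f"unknown volume unit {self.unit!r} (use mm3 or cm3)")
        self.unit = "mm3"
        if self.method not in ("pycnometer", "displacement"):
            raise ValueError(f"unknown measurement method {self.method!r}")

    @property
    def label(self) -> str:
        return f"T_{self.batch},{self.throw}^{self.group}"


@dataclass
class RatioReport:
    """V_modeled/V_measured at throw, batch and group level."""

    model: str
    throws: pd.DataFrame          # group, batch, throw, v_model_mm3, v_meas_mm3, ratio
    batches: pd.DataFrame         # group, batch, ratio_mean, throw_rel_sd_pct
    groups: pd.DataFrame          # group, ratio_mean, ratio_sd (over batch values)


@dataclass
class FTestResult:
    """Variance-ratio comparison of two models' residuals in one batch."""

    model_a: str
    model_b: str
    group: str
    batch: int
    f_statistic: float
    df: tuple[int, int]
    p_value: float
    larger_residual_model: str
    decisions: dict[float, bool] = field(default_factory=dict)


@dataclass
class RecalibrationResult:
    """Per-throw optimal parameter values for one model, with a summary."""

    model: str
    parameter: str
    original_value: float
    per_throw: pd.DataFrame       # group, batch, throw, optimum, converged
    mean: float
    sd: float
    rel_sd_pct: float

    def summary(self) -> str:
        lines = [
            f"Recalibration of the {self.model} model ({self.parameter})",
            f"  original value : {self.original_value:.4g}",
            f"  throws used    : {len(self.per_throw)}",
            f"  mean optimum   : {self.mean:.4g}",
            f"  SD             : {self.sd:.4g}",
            f"  relative SD    : {self.rel_sd_pct:.2f}%",
        ]
        return "\n".join(lines)


def modeled_collective(
    particles: pd.DataFrame,
    model: str,
    params: ModelParams | None = None,
    tanoiri_group: str = "fragments",
) -> float:
    """Summed modeled volume (mm^3) of a metrics table under one model.

    The fiber model only sees fiber rows and the particle models only
    non-fiber rows; skipped rows are logged.
    """
    params = params or ModelParams()
    if "is_fiber" in particles.columns:
        is_fiber = particles["is_fiber"].astype(bool)
    else:
        is_fiber = pd.Series(False, index=particles.index)
    use = is_fiber if model == "fiber" else ~is_fiber
    skipped = int((~use).sum())
    if skipped:
        log.info("model %s: skipped %d incompatible rows", model, skipped)
    if use.sum() == 0:
        raise ValueError(f"no rows measurable by model {model!r}")
    total = 0.0
    for _, row in particles.loc[use].iterrows():
        total += estimate_volume(row, model, params, tanoiri_group=tanoiri_group).volume_mm3
    return total


def _sample_sd(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1)) if len(x) > 1 else 0.0


def ratio_table(
    records: list[MixtureRecord],
    model: str,
    params: ModelParams | None = None,
    tanoiri_group: str = "fragments",
) -> RatioReport:
    """V_modeled/V_measured ratios aggregated per throw, batch and group.

    Batch value = mean of its throw ratios; group mean/SD are computed
    over batch values (sample SD).  The per-batch relative SD (%) over
    throws is reported alongside.
    """
    params = params or ModelParams()
    rows = []
    for rec in records:
        v_model = modeled_collective(rec.particles, model, params, tanoiri_group)
        rows.append({
            "group": rec.group, "batch": rec.batch, "throw": rec.throw,
            "v_model_mm3": v_model, "v_meas_mm3": rec.measured_volume,
            "ratio": v_model / rec.measured_volume,
        })
    throws = pd.DataFrame(rows).sort_values(["group", "batch", "throw"], ignore_index=True)
    batches = (
        throws.groupby(["group", "batch"], as_index=False)
        .agg(ratio_mean=("ratio", "mean"),
             throw_rel_sd_pct=("ratio", lambda r: 100.0 * _sample_sd(r.to_numpy()) / r.mean()))
    )
    groups = (
        batches.groupby("group", as_index=False)
        .agg(ratio_mean=("ratio_mean", "mean"),
             ratio_sd=("ratio_mean", lambda r: _sample_sd(r.to_numpy())))
    )
    return RatioReport(model=model, throws=throws, batches=batches, groups=groups)


def compare_models_ftest(
    records: list[MixtureRecord],
    model_a: str,
    model_b: str,
    params: ModelParams | None = None,
    alphas: tuple[float, ...] = (0.05, 0.1),
    tanoiri_group: str = "fragments",
) -> list[FTestResult]:
    """Per-batch F-test on the residual sums of squares of two models.

    Residuals are per-throw errors of the collective volume
    (modeled - measured).  F is the larger RSS over the smaller (the
    orientation is recorded); the two-sided p-value uses the F
    distribution with (n_throws, n_throws) degrees of freedom — the
    residuals are errors about zero, not deviations from a fitted mean.
    Batches with fewer than two throws are skipped with a warning (fibers
    were thrown only once).
    """
    params = params or ModelParams()
    results: list[FTestResult] = []
    key = lambda r: (r.group, r.batch)
    groups: dict[tuple, list[MixtureRecord]] = {}
    for rec in records:
        groups.setdefault(key(rec), []).append(rec)
    for (group, batch), recs in sorted(groups.items()):
        if len(recs) < 2:
            log.warning("batch %s/%s has a single throw; F-test skipped", group, batch)
            continue
        res = {}
        for model in (model_a, model_b):
            res[model] = np.array([
                modeled_collective(r.particles, model, params, tanoiri_group)
                - r.measured_volume
                for r in recs
            ])
        ss_a = float(np.sum(res[model_a] ** 2))
        ss_b = float(np.sum(res[model_b] ** 2))
        larger = model_a if ss_a >= ss_b else model_b
        hi, lo = max(ss_a, ss_b), min(ss_a, ss_b)
        n = len(recs)
        f = hi / lo if lo > 0 else math.inf
        if math.isinf(f):
            p = 0.0
        else:
            p = 2.0 * min(stats.f.sf(f, n, n), stats.f.cdf(f, n, n))
            p = min(p, 1.0)
        results.append(FTestResult(
            model_a=model_a, model_b=model_b, group=group, batch=batch,
            f_statistic=f, df=(n, n), p_value=p, larger_residual_model=larger,
            decisions={a: p < a for a in alphas},
        ))
    return results


def recalibrate(
    records: list[MixtureRecord],
    model: str,
    params: ModelParams | None = None,
    bounds: tuple[float, float] | None = None,
    tanoiri_group: str = "fragments",
) -> RecalibrationResult:
    """Per-throw optimum of a model's free parameter against measured volumes.

    For every throw the scalar parameter (K_c for Cozar, K_I for Isobe,
    the height slope for Tanoiri) minimizing the squared *relative* error
    of the collective volume is found by bounded search; the relative
    error makes large and small mixtures weigh equally.  The summary
    reports mean, SD and relative SD of the per-throw optima next to the
    original parameter value.  The corrected-ellipsoid (Barchiesi) model
    has no calibration parameter and is rejected, as are Simon and
    Medina.
    """
    params = params or ModelParams()
    if model not in _CALIBRATABLE:
        raise UnsupportedModelError(
            f"model {model!r} has no calibration parameter; calibratable: "
            f"{sorted(_CALIBRATABLE)}"
        )
    default_bounds, param_name = _CALIBRATABLE[model]
    bounds = bounds or default_bounds

    if model == "tanoiri":
        original = params.tanoiri_groups[tanoiri_group].slope
    else:
        original = params.k_c if model == "cozar" else params.k_i

    def with_param(k: float) -> ModelParams:
        if model == "tanoiri":
            import dataclasses
            groups = dict(params.tanoiri_groups)
            groups[tanoiri_group] = dataclasses.replace(
                groups[tanoiri_group], slope=k, placeholder=False)
            return dataclasses.replace(params, tanoiri_groups=groups)
        return params.with_value(model, k)

    rows = []
    for rec in records:
        v_meas = rec.measured_volume

        def objective(k: float) -> float:
            v = modeled_collective(rec.particles, model, with_param(k), tanoiri_group)
            return ((v - v_meas) / v_meas) ** 2

        opt = optimize.minimize_scalar(objective, bounds=bounds, method="bounded",
                                       options={"xatol": 1e-10})
        converged = bool(opt.success) and opt.fun < 1e6
        if not converged:
            log.warning("recalibration did not converge for throw %s", rec.label)
        rows.append({"group": rec.group, "batch": rec.batch, "throw": rec.throw,
                     "optimum": float(opt.x), "converged": converged})
    per_throw = pd.DataFrame(rows)
    ok = per_throw.loc[per_throw["converged"], "optimum"].to_numpy()
    mean = float(ok.mean()) if len(ok) else math.nan
    sd = _sample_sd(ok)
    return RecalibrationResult(
        model=model, parameter=param_name, original_value=original,
        per_throw=per_throw, mean=mean, sd=sd,
        rel_sd_pct=100.0 * sd / mean if mean else math.nan,
    )
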