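"""2D-to-3D particle volume models.

Each model converts descriptors obtained from a particle's 2D projection
(best-fit ellipse axes, area, outline perimeter) into an estimate of its
3D volume.  The models implemented are the established literature models

* **Cozar** — cube of side ``L`` with height ``H = K_c * L`` (default 0.1),
* **Isobe** — cylinder of diameter ``L`` with height ``H = K_I * L``
  (default 0.4),
* **Medina** — sphere with the equivalent-area diameter (ESD),
* **Simon** — ellipsoid whose third axis follows ``H/W = W/L``,
* **Tanoiri** — ellipsoid whose height is an empirically calibrated affine
  function of a best-fit-ellipse axis, per particle group,

plus the calibration-free corrected-ellipsoid (*Barchiesi*) model

    V = C_f * V_Simon,        C_f = (P_ell / P_MP) ** 3

where ``P_ell`` is the best-fit-ellipse perimeter (first Ramanujan
approximation) and ``P_MP`` the measured outline perimeter.  The cubed
perimeter ratio discounts the ellipsoid volume for surface irregularity
(micro-valleys, cracks and pores) that the best-fit ellipse cannot see.

A cylindrical model with a 40 % void fraction is provided for fibers.

All lengths are millimetres, areas mm^2, volumes mm^3.  ``M`` and ``m``
are *full* major/minor axes of the best-fit ellipse (ImageJ convention),
so ellipsoid volumes use ``pi/6 * (product of full axes)`` and the
Ramanujan perimeter takes semi-axes ``M/2`` and ``m/2``.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

log = logging.getLogger(__name__)

__all__ = [
    "TanoiriGroup",
    "ModelParams",
    "VolumeEstimate",
    "MODEL_NAMES",
    "ramanujan_perimeter",
    "correction_factor",
    "volume_cozar",
    "volume_isobe",
    "volume_medina",
    "volume_simon",
    "volume_tanoiri",
    "volume_barchiesi",
    "volume_fiber",
    "collective_volume",
]

#: models accepted by the dispatch helpers (CLI, evaluation)
MODEL_NAMES = ("cozar", "isobe", "medina", "simon", "tanoiri", "barchiesi", "fiber")

#: ratio-above-one beyond which a correction factor is logged as suspicious
_CF_SUSPICIOUS = 1.05


@dataclass(frozen=True)
class TanoiriGroup:
    """Affine height rule ``H = slope * axis + intercept`` for one particle group.

    ``axis`` selects which best-fit-ellipse axis drives the height
    (``"major"`` or ``"minor"``).  Coefficients are mm-consistent:
    ``slope`` is unitless, ``intercept`` is mm.
    """

    axis: str = "minor"
    slope: float = 0.5
    intercept: float = 0.0
    placeholder: bool = False

    def __post_init__(self) -> None:
        if self.axis not in ("major", "minor"):
            raise ValueError(f"axis must be 'major' or 'minor', got {self.axis!r}")

    def height(self, major: float, minor: float) -> float:
        x = major if self.axis == "major" else minor
        return self.slope * x + self.intercept


def _placeholder_groups() -> dict[str, TanoiriGroup]:
    # The original calibrated coefficients for "fragments" and "PE/PP
    # pellets" are not publicly tabulated; these stand-ins must be replaced
    # with real calibration values before quantitative use (a warning is
    # emitted on every use).
    return {
        "fragments": TanoiriGroup(axis="minor", slope=0.5, intercept=0.0, placeholder=True),
        "pellets": TanoiriGroup(axis="minor", slope=0.67, intercept=0.0, placeholder=True),
    }


@dataclass
class ModelParams:
    """All model constants in one place.

    Parameters
    ----------
    k_c : float
        Cozar height/length factor, default 0.1.
    k_i : float
        Isobe height/length factor, default 0.4.
    tanoiri_groups : mapping of str -> TanoiriGroup
        Per-group affine height rules.  Shipped defaults are placeholders.
    fiber_void_fraction : float
        Void fraction of the cylindrical fiber model, default 0.40.
    clamp_cf : bool
        If True the correction factor is clamped at 1.  Off by default:
        clamping would hide perimeter-estimator bias.
    """

    k_c: float = 0.1
    k_i: float = 0.4
    tanoiri_groups: dict[str, TanoiriGroup] = field(default_factory=_placeholder_groups)
    fiber_void_fraction: float = 0.40
    clamp_cf: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.k_c <= 1.0:
            raise ValueError(f"k_c must be in (0, 1], got {self.k_c}")
        if not 0.0 < self.k_i <= 1.0:
            raise ValueError(f"k_i must be in (0, 1], got {self.k_i}")
        if not 0.0 <= self.fiber_void_fraction < 1.0:
            raise ValueError(
                f"fiber_void_fraction must be in [0, 1), got {self.fiber_void_fraction}"
            )

    def with_value(self, model: str, value: float) -> "ModelParams":
        """Copy of the params with the named model's free parameter replaced."""
        if model == "cozar":
            return replace(self, k_c=value)
        if model == "isobe":
            return replace(self, k_i=value)
        raise ValueError(f"model {model!r} has no scalar free parameter here")


@dataclass
class VolumeEstimate:
    """A single particle's modeled volume with its intermediates."""

    model: str
    volume_mm3: float
    height_mm: float | None = None
    c_f: float | None = None
    p_ell_mm: float | None = None
    particle_id: str | None = None
    valid: bool = True


def _require_positive(**values: float) -> None:
    for name, v in values.items():
        if not (v > 0 and math.isfinite(v)):
            raise ValueError(f"{name} must be positive and finite, got {v}")


def ramanujan_perimeter(a: float, b: float) -> float:
    """Ellipse perimeter by Ramanujan's first approximation.

    ``a`` and ``b`` are the semi-axes in mm (order-free).  Exact for
    circles; relative error below 1e-4 for aspect ratios up to ~13.
    """
    _require_positive(a=a, b=b)
    return math.pi * (3.0 * (a + b) - math.sqrt((3.0 * a + b) * (a + 3.0 * b)))


def correction_factor(p_ell: float, p_mp: float, clamp: bool = False) -> float:
    """Surface-irregularity correction factor ``(P_ell / P_MP) ** 3``.

    Equal to 1 when the outline is a perfect ellipse or circle; below 1
    for irregular outlines whose measured perimeter exceeds the best-fit
    ellipse perimeter.  Values above 1.05 are logged as suspicious (they
    indicate perimeter-estimator bias rather than physics).
    """
    _require_positive(p_ell=p_ell, p_mp=p_mp)
    cf = (p_ell / p_mp) ** 3
    if cf > _CF_SUSPICIOUS:
        log.warning("suspicious correction factor %.4f (P_ell=%.4g, P_MP=%.4g)", cf, p_ell, p_mp)
    if clamp:
        cf = min(cf, 1.0)
    return cf


def volume_cozar(length: float, params: ModelParams | None = None,
                 particle_id: str | None = None) -> VolumeEstimate:
    """Cube of side ``L`` with height ``H = K_c * L``: ``V = K_c * L**3``."""
    params = params or ModelParams()
    _require_positive(length=length)
    h = params.k_c * length
    return VolumeEstimate("cozar", length * length * h, height_mm=h, particle_id=particle_id)


def volume_isobe(length: float, params: ModelParams | None = None,
                 particle_id: str | None = None) -> VolumeEstimate:
    """Cylinder of diameter ``L`` and height ``K_I * L``: ``V = pi/4 K_I L**3``."""
    params = params or ModelParams()
    _require_positive(length=length)
    h = params.k_i * length
    return VolumeEstimate("isobe", math.pi / 4.0 * length * length * h,
                          height_mm=h, particle_id=particle_id)


def volume_medina(area: float, particle_id: str | None = None) -> VolumeEstimate:
    """Sphere with the equivalent-area diameter ``ESD = 2 sqrt(A/pi)``."""
    _require_positive(area=area)
    esd = 2.0 * math.sqrt(area / math.pi)
    return VolumeEstimate("medina", math.pi / 6.0 * esd ** 3,
                          height_mm=esd, particle_id=particle_id)


def volume_simon(major: float, minor: float,
                 particle_id: str | None = None) -> VolumeEstimate:
    """Ellipsoid with the third axis from ``H/W = W/L``: ``H = m**2 / M``.

    With full axes as diameters, ``V = pi/6 * M * m * H = pi/6 * m**3``.
    """
    _require_positive(major=major, minor=minor)
    if minor > major * (1 + 1e-12):
        raise ValueError(f"minor axis {minor} exceeds major axis {major}")
    h = minor * minor / major
    return VolumeEstimate("simon", math.pi / 6.0 * major * minor * h,
                          height_mm=h, particle_id=particle_id)


def volume_tanoiri(major: float, minor: float, group: str,
                   params: ModelParams | None = None,
                   particle_id: str | None = None) -> VolumeEstimate:
    """Ellipsoid with a per-group calibrated affine height function."""
    params = params or ModelParams()
    _require_positive(major=major, minor=minor)
    if minor > major * (1 + 1e-12):
        raise ValueError(f"minor axis {minor} exceeds major axis {major}")
    try:
        rule = params.tanoiri_groups[group]
    except KeyError:
        raise KeyError(
            f"unknown Tanoiri group {group!r}; configured: {sorted(params.tanoiri_groups)}"
        ) from None
    if rule.placeholder:
        warnings.warn(
            f"Tanoiri group {group!r} uses PLACEHOLDER coefficients; supply "
            "calibrated values before quantitative use",
            UserWarning,
            stacklevel=2,
        )
    h = rule.height(major, minor)
    v = math.pi / 6.0 * major * minor * h
    valid = h > 0
    if not valid:
        log.warning("Tanoiri height %.4g <= 0 for group %r; estimate flagged invalid", h, group)
    return VolumeEstimate("tanoiri", v, height_mm=h, particle_id=particle_id, valid=valid)


def volume_barchiesi(major: float, minor: float, p_mp: float,
                     params: ModelParams | None = None,
                     particle_id: str | None = None) -> VolumeEstimate:
    """Correction-factor model: ``V = C_f * V_Simon`` with ``C_f = (P_ell/P_MP)**3``.

    ``P_ell`` is the Ramanujan perimeter of the best-fit ellipse (semi-axes
    ``M/2``, ``m/2``); ``P_MP`` the measured outline perimeter.  The returned
    estimate records both the correction factor and the ellipse perimeter,
    and the identity ``V == C_f * V_Simon`` holds bit-for-bit.
    """
    params = params or ModelParams()
    simon = volume_simon(major, minor, particle_id=particle_id)
    p_ell = ramanujan_perimeter(major / 2.0, minor / 2.0)
    cf = correction_factor(p_ell, p_mp, clamp=params.clamp_cf)
    return VolumeEstimate("barchiesi", cf * simon.volume_mm3, height_mm=simon.height_mm,
                          c_f=cf, p_ell_mm=p_ell, particle_id=particle_id)


def volume_fiber(length: float, width: float,
                 params: ModelParams | None = None,
                 particle_id: str | None = None) -> VolumeEstimate:
    """Cylindrical fiber with a void fraction: ``V = (1-f) pi/4 w**2 L``."""
    params = params or ModelParams()
    _require_positive(length=length, width=width)
    if width > length * (1 + 1e-12):
        raise ValueError(f"fiber width {width} exceeds length {length}")
    v = (1.0 - params.fiber_void_fraction) * math.pi / 4.0 * width * width * length
    return VolumeEstimate("fiber", v, particle_id=particle_id)


def collective_volume(estimates: Iterable[VolumeEstimate]) -> float:
    """Sum of per-particle volumes (mm^3) for a single model's estimates."""
    estimates = list(estimates)
    if not estimates:
        log.warning("collective_volume of empty estimate list -> 0")
        return 0.0
    models = {e.model for e in estimates}
    if len(models) > 1:
        raise ValueError(f"mixed models in collective volume: {sorted(models)}")
    return math.fsum(e.volume_mm3 for e in estimates)  # order-independent


def estimate_volume(row: Mapping, model: str, params: ModelParams | None = None,
                    tanoiri_group: str = "fragments") -> VolumeEstimate:
    """Dispatch a metrics-table row (CSV column names) to the named model.

    ``row`` must provide ``major_mm``/``minor_mm`` (all ellipsoid models),
    ``area_mm2`` (medina), ``perimeter_mm`` (barchiesi) or
    ``fiber_length_mm``/``fiber_width_mm`` (fiber).
    """
    params = params or ModelParams()
    pid = str(row.get("id")) if hasattr(row, "get") and row.get("id") is not None else None
    if model == "cozar":
        return volume_cozar(row["major_mm"], params, particle_id=pid)
    if model == "isobe":
        return volume_isobe(row["major_mm"], params, particle_id=pid)
    if model == "medina":
        return volume_medina(row["area_mm2"], particle_id=pid)
    if model == "simon":
        return volume_simon(row["major_mm"], row["minor_mm"], particle_id=pid)
    if model == "tanoiri":
        return volume_tanoiri(row["major_mm"], row["minor_mm"], tanoiri_group, params,
                              particle_id=pid)
    if model == "barchiesi":
        return volume_barchiesi(row["major_mm"], row["minor_mm"], row["perimeter_mm"],
                                params, particle_id=pid)
    if model == "fiber":
        return volume_fiber(row["fiber_length_mm"], row["fiber_width_mm"], params,
                            particle_id=pid)
    raise ValueError(f"unknown model {model!r}; valid: {', '.join(MODEL_NAMES)}")
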