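"""Displacement volumetry and measurement quality assurance.

Large particle mixtures are too big for a pycnometer, so their collective
volume is measured by weight differences in a fixed-volume flask filled
with ethanol: weigh the flask with liquid only (``W1``), weigh it with
particles topped up to the same nominal volume (``W2``), and weigh the
particles themselves (``W_MP``).  Assuming the filled volumes are equal,
the particle volume is

    V_MP = (W_MP + W1 - W2) / rho_et

with ``rho_et`` the liquid density (0.81 g/cm^3 for 96 % ethanol).

The QA helpers check the two protocol controls: the relative standard
deviation of replicate flask weighings, and the min-max drift of a
reference object's imaged area across a throw series (acceptance
threshold 1 %).
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import mean, stdev

__all__ = [
    "DisplacementRecord",
    "DisplacementVolume",
    "QAReport",
    "displacement_volume",
    "replicate_precision",
    "reference_drift_check",
    "DEFAULT_ETHANOL_DENSITY",
    "DEFAULT_NOMINAL_VOLUME_CM3",
    "DEFAULT_DRIFT_THRESHOLD_PCT",
]

DEFAULT_ETHANOL_DENSITY = 0.81  # g/cm^3, ethanol 96 %
DEFAULT_NOMINAL_VOLUME_CM3 = 25.0
DEFAULT_DRIFT_THRESHOLD_PCT = 1.0


@dataclass
class DisplacementRecord:
    """One displacement weighing: grams in, cm^3 out."""

    w1_g: float      # flask + liquid at nominal volume
    w2_g: float      # flask + particles + liquid at the same nominal volume
    w_mp_g: float    # particle mass
    rho_g_cm3: float = DEFAULT_ETHANOL_DENSITY
    nominal_volume_cm3: float = DEFAULT_NOMINAL_VOLUME_CM3

    def __post_init__(self) -> None:
        if self.rho_g_cm3 <= 0:
            raise ValueError(f"liquid density must be positive, got {self.rho_g_cm3}")
        if not 0.5 < self.rho_g_cm3 < 1.2:
            raise ValueError(
                f"liquid density {self.rho_g_cm3} g/cm^3 outside the plausible (0.5, 1.2) range"
            )
        for name in ("w1_g", "w2_g", "w_mp_g"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class DisplacementVolume:
    volume_cm3: float
    valid: bool

    @property
    def volume_mm3(self) -> float:
        return self.volume_cm3 * 1000.0


@dataclass
class QAReport:
    replicate_rel_sd_pct: float | None
    reference_spread_pct: float | None
    replicate_pass: bool | None
    reference_pass: bool | None


def displacement_volume(rec: DisplacementRecord) -> DisplacementVolume:
    """Particle volume (cm^3) from one displacement weighing.

    A negative result is physically impossible (it would mean the flask
    got *heavier* than particles plus displaced liquid allow) and is
    returned flagged invalid rather than clamped — it signals a weighing
    error upstream.
    """
    v = (rec.w_mp_g + rec.w1_g - rec.w2_g) / rec.rho_g_cm3
    return DisplacementVolume(volume_cm3=v, valid=v >= 0)


def replicate_precision(weights_g: list[float]) -> float:
    """Relative standard deviation (%) of replicate weighings.

    ``100 * sample SD / mean``; scale-invariant.  Needs at least two
    values.
    """
    if len(weights_g) < 2:
        raise ValueError("need at least 2 replicate weighings")
    return 100.0 * stdev(weights_g) / mean(weights_g)


def reference_drift_check(
    areas_mm2: list[float],
    threshold_pct: float = DEFAULT_DRIFT_THRESHOLD_PCT,
) -> tuple[bool, float]:
    """Min-max spread (%) of the reference object's area across a series.

    Returns ``(passed, spread_pct)`` with ``spread = 100 * (max-min)/min``
    and ``passed`` iff the spread is strictly below the threshold
    (default 1 %).
    """
    if len(areas_mm2) < 2:
        raise ValueError("need at least 2 reference areas")
    if min(areas_mm2) <= 0:
        raise ValueError("reference areas must be positive")
    spread = 100.0 * (max(areas_mm2) - min(areas_mm2)) / min(areas_mm2)
    return spread < threshold_pct, spread
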