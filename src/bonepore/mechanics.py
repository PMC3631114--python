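"""Bending-fatigue moduli and unconfined-compression descriptors.

Fatigue protocol: repeated three-point bending of prismatic bone slabs to
a fixed deflection. Stiffness per cycle is summarized by the secant
modulus at the cycle's peak via the Euler-Bernoulli beam formula

    E_sec = (F / delta) * L^3 / (48 * I),     I = w * h^3 / 12,

with span L, cross-section w x h, and (F, delta) the peak-force point of
the loading ramp. Fatigue effectiveness is the percent drop from the
first to the last complete cycle, 100*(M_first - M_last)/M_first.

Compression: ~5 mm demineralized cubes loaded at constant strain rate;
engineering stress = force / initial cross-section, engineering strain =
displacement / initial height. Transversely loaded (T) samples fail
within the test range, so descriptors are taken at the ultimate point
(global force maximum); longitudinally loaded (L) samples never fracture
and are evaluated at 50% strain by interpolation. Work is the trapezoidal
integral of force over displacement (N*mm = mJ) from the 0.1 N recording
trigger to the evaluation point.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "BendingCycleSeries",
    "FatigueResult",
    "MechanicalRecord",
    "NoFailureError",
    "InsufficientRangeError",
    "secant_modulus",
    "percent_modulus_change",
    "fatigue_summary",
    "compression_descriptors",
    "time_at_fraction_of_max_load",
]

FORCE_TRIGGER_N = 0.1  # recording starts when force passes this level


class NoFailureError(ValueError):
    """A T-direction record has no interior force maximum (no failure)."""


class InsufficientRangeError(ValueError):
    """An L-direction record does not reach the 50% evaluation strain."""


def secant_modulus(
    deflection_mm: np.ndarray,
    force_n: np.ndarray,
    span_mm: float = 32.0,
    width_mm: float = 10.0,
    height_mm: float = 4.0,
) -> float:
    """Secant modulus (MPa) of one bending cycle at its peak-force point.

    Uses the three-point-bending beam formula; with N and mm inputs the
    result is N/mm^2 = MPa. Non-monotone deflection within the ramp is
    tolerated: the peak-force sample defines the secant point.
    """
    f = np.asarray(force_n, dtype=float)
    d = np.asarray(deflection_mm, dtype=float)
    if f.size == 0 or f.size != d.size:
        raise ValueError("deflection and force must be equal-length, non-empty")
    if span_mm <= 0 or width_mm <= 0 or height_mm <= 0:
        raise ValueError("geometry must be positive")
    i_peak = int(np.argmax(f))
    if d[i_peak] <= 0:
        raise ValueError("invalid cycle: zero deflection at peak force")
    inertia = width_mm * height_mm**3 / 12.0
    return float(f[i_peak] / d[i_peak] * span_mm**3 / (48.0 * inertia))


def percent_modulus_change(m_first_mpa: float, m_last_mpa: float) -> float:
    """100 * (M_first - M_last) / M_first; negative when stiffness rose."""
    if m_first_mpa <= 0:
        raise ValueError("M_first must be positive")
    return 100.0 * (m_first_mpa - m_last_mpa) / m_first_mpa


@dataclass(frozen=True)
class BendingCycleSeries:
    """Per-cycle deflection-force tables of one fatigue run.

    ``cycles`` is a list of (deflection_mm, force_n) array pairs, one per
    loading cycle in order. Defaults match the protocol: 32 mm support
    span, 0.9 mm target deflection, at most 300 cycles.
    """

    cycles: list
    span_mm: float = 32.0
    width_mm: float = 10.0
    height_mm: float = 4.0
    max_deflection_mm: float = 0.9
    deflection_tol_mm: float = 0.05

    def __post_init__(self) -> None:
        if len(self.cycles) > 300:
            raise ValueError("more than 300 cycles in a fatigue series")

    def is_complete(self, i: int) -> bool:
        d, _ = self.cycles[i]
        return float(np.max(d)) >= self.max_deflection_mm - self.deflection_tol_mm


@dataclass(frozen=True)
class FatigueResult:
    m_first_mpa: float
    m_last_mpa: float
    percent_change: float
    n_complete_cycles: int
    failed_early: bool


def fatigue_summary(series: BendingCycleSeries) -> FatigueResult:
    """M_first from cycle 1, M_last from the last complete cycle.

    A sample failing mid-protocol (a cycle that no longer reaches the
    target deflection) contributes its last complete cycle and is flagged.
    """
    complete = [i for i in range(len(series.cycles)) if series.is_complete(i)]
    if len(complete) < 2:
        raise ValueError("need at least 2 complete cycles for a fatigue summary")
    geom = dict(span_mm=series.span_mm, width_mm=series.width_mm, height_mm=series.height_mm)
    m_first = secant_modulus(*series.cycles[complete[0]], **geom)
    m_last = secant_modulus(*series.cycles[complete[-1]], **geom)
    failed = complete[-1] != len(series.cycles) - 1
    return FatigueResult(
        m_first_mpa=m_first,
        m_last_mpa=m_last,
        percent_change=percent_modulus_change(m_first, m_last),
        n_complete_cycles=len(complete),
        failed_early=failed,
    )


@dataclass(frozen=True)
class MechanicalRecord:
    """A displacement-force record of one compression test.

    ``direction`` is "L" (loading parallel to the bone long axis; never
    fractures, analyzed at 50% strain) or "T" (perpendicular; fails within
    the test range, analyzed at the ultimate point). Derived descriptor
    fields are None until :func:`compression_descriptors` fills them.
    """

    displacement_mm: np.ndarray
    force_n: np.ndarray
    sample_height_mm: float
    cross_section_mm2: float
    direction: str
    ultimate_stress_mpa: float | None = None
    ultimate_strain: float | None = None
    work_to_failure_mj: float | None = None
    stress_at_50pct_mpa: float | None = None
    work_at_50pct_mj: float | None = None

    def __post_init__(self) -> None:
        d = np.asarray(self.displacement_mm, dtype=float)
        f = np.asarray(self.force_n, dtype=float)
        if d.size == 0 or d.size != f.size:
            raise ValueError("displacement and force must be equal-length, non-empty")
        if self.sample_height_mm <= 0 or self.cross_section_mm2 <= 0:
            raise ValueError("sample geometry must be positive")
        if self.direction not in ("L", "T"):
            raise ValueError("direction must be 'L' or 'T'")
        object.__setattr__(self, "displacement_mm", d)
        object.__setattr__(self, "force_n", f)

    @property
    def strain(self) -> np.ndarray:
        """Engineering strain, displacement / initial height."""
        return self.displacement_mm / self.sample_height_mm

    @property
    def stress_mpa(self) -> np.ndarray:
        """Engineering stress, force / initial cross-section (N/mm^2)."""
        return self.force_n / self.cross_section_mm2


def _work_mj(disp: np.ndarray, force: np.ndarray, i_end: int) -> float:
    return float(np.trapezoid(force[: i_end + 1], disp[: i_end + 1]))


def compression_descriptors(rec: MechanicalRecord) -> MechanicalRecord:
    """Fill the derived descriptor fields of a compression record.

    T: the ultimate point is the global force maximum; stress, strain and
    work are evaluated there. A record whose maximum sits at the last
    sample carries no failure event and is rejected.

    L: stress and work are evaluated at exactly 50% strain by linear
    interpolation between the bracketing samples; a record that never
    reaches 50% strain is rejected.
    """
    disp, force = rec.displacement_mm, rec.force_n
    if rec.direction == "T":
        i_ult = int(np.argmax(force))
        if i_ult == len(force) - 1 or i_ult == 0:
            raise NoFailureError("no interior force maximum: T sample did not fail in range")
        return replace(
            rec,
            ultimate_stress_mpa=float(force[i_ult]) / rec.cross_section_mm2,
            ultimate_strain=float(disp[i_ult]) / rec.sample_height_mm,
            work_to_failure_mj=_work_mj(disp, force, i_ult),
        )

    # L: interpolate the 50%-strain point into the series, then integrate
    strain = rec.strain
    if strain.max() < 0.5:
        raise InsufficientRangeError(
            f"L record reaches only {100 * strain.max():.1f}% strain (< 50%)"
        )
    d50 = 0.5 * rec.sample_height_mm
    f50 = float(np.interp(d50, disp, force))
    i_before = int(np.searchsorted(disp, d50, side="right")) - 1
    disp_cut = np.append(disp[: i_before + 1], d50)
    force_cut = np.append(force[: i_before + 1], f50)
    return replace(
        rec,
        stress_at_50pct_mpa=f50 / rec.cross_section_mm2,
        work_at_50pct_mj=float(np.trapezoid(force_cut, disp_cut)),
    )


def time_at_fraction_of_max_load(
    time_s: np.ndarray, force_n: np.ndarray, fraction: float = 0.95
) -> float:
    """Time of the last rising-branch crossing of ``fraction * F_max``.

    Used to truncate acoustic-emission accumulation before the final
    fracture of T samples: signals after 95% of maximum load are
    dominated by the fracture itself. The crossing time is linearly
    interpolated between the bracketing samples. Invariant to any samples
    appended after the force peak.
    """
    t = np.asarray(time_s, dtype=float)
    f = np.asarray(force_n, dtype=float)
    if f.size == 0 or f.size != t.size:
        raise ValueError("time and force must be equal-length, non-empty")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    i_max = int(np.argmax(f))
    level = fraction * f[i_max]
    below = np.flatnonzero(f[: i_max + 1] < level)
    if below.size == 0:  # force starts above the level
        return float(t[0])
    i = int(below[-1])  # last sample below the level before the peak
    # crossing between i and i+1
    f0, f1 = f[i], f[i + 1]
    if f1 == f0:
        return float(t[i + 1])
    return float(t[i] + (level - f0) / (f1 - f0) * (t[i + 1] - t[i]))
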