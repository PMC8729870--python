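"""FDG kinetics: arterial input model, irreversible two-tissue-compartment
tissue curves, Patlak graphical analysis, and CMRGlc.

The tracer model is the standard irreversible 2TCM for FDG (k4 = 0).  With
plasma input Cp and rate constants K1 (mL·mL^-1·min^-1), k2, k3 (min^-1), the
tissue concentration is

    C_T(t) = (1 - Vb) [ Ki * int_0^t Cp dτ
                        + (K1 k2 / (k2 + k3)) * exp(-(k2+k3) t) ⊛ Cp ]
             + Vb * C_blood(t),        Ki = K1 k3 / (k2 + k3).

Patlak graphical analysis linearises the late part of the curve:
y = C_T/Cp against x = int Cp / Cp has asymptotic slope Ki.  CMRGlc follows
from the slope, the plasma glucose level and the lumped constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .core import FrameSchedule, InputFunction

SECONDS_PER_MIN = 60.0


@dataclass(frozen=True)
class KineticParams:
    """Irreversible 2TCM rate constants.

    K1 in mL·mL^-1·min^-1; k2, k3 in min^-1; k4 fixed at 0 for FDG over a
    60-min scan; Vb is the unitless fractional blood volume.
    """

    K1: float
    k2: float
    k3: float
    Vb: float = 0.0

    def __post_init__(self) -> None:
        if min(self.K1, self.k2, self.k3) < 0 or not (0 <= self.Vb <= 1):
            raise ValueError("kinetic parameters out of range")
        if self.K1 > 0 and self.k2 + self.k3 == 0:
            raise ValueError("k2 + k3 must be > 0 when K1 > 0")

    @property
    def Ki(self) -> float:
        """Net influx constant K1*k3/(k2+k3) in mL·mL^-1·min^-1."""
        if self.K1 == 0:
            return 0.0
        return self.K1 * self.k3 / (self.k2 + self.k3)


@dataclass(frozen=True)
class PatlakConfig:
    t_star: float = 1500.0  # s; 25 min after injection
    lumped_constant: float = 0.65
    plasma_glucose: float = 5000.0  # µmol/L (= 5 mmol/L, normoglycaemia)

    def __post_init__(self) -> None:
        if self.lumped_constant <= 0:
            raise ValueError("lumped_constant must be > 0")
        if self.t_star <= 0:
            raise ValueError("t_star must be > 0")


# --------------------------------------------------------------------------- #
# Input function models
# --------------------------------------------------------------------------- #

#: Default bolus-input parameters: (A1 Bq/mL/min, A2 Bq/mL, A3 Bq/mL,
#: l1, l2, l3 min^-1, t0 s).  Chosen to give a realistic FDG bolus for a
#: ~350 MBq injection: sharp peak under a minute after appearance, a
#: distribution phase with ~2-min half-life, and a slow terminal tail — fast
#: enough that the Patlak plot is asymptotic from 25 min for brain-like
#: k2 + k3.
FENG_DEFAULTS = (80000.0, 2100.0, 2100.0, 1.6, 0.35, 0.01, 10.0)


def feng_aif(
    t: np.ndarray,
    params: tuple[float, ...] = FENG_DEFAULTS,
) -> InputFunction:
    """Tri-exponential bolus model of the arterial plasma input.

    ``Cp(t) = (A1 (t - t0) - A2 - A3) e^{-l1 (t-t0)} + A2 e^{-l2 (t-t0)}
    + A3 e^{-l3 (t-t0)}`` for t > t0, 0 before — a linear rise into a
    tri-exponential decay.  Rates are per minute, times in seconds.
    """
    a1, a2, a3, l1, l2, l3, t0 = params
    if min(l1, l2, l3) < 0:
        raise ValueError("negative rate constants")
    t = np.asarray(t, dtype=float)
    tm = np.maximum(t - t0, 0.0) / SECONDS_PER_MIN  # minutes since appearance
    cp = (
        (a1 * tm - a2 - a3) * np.exp(-l1 * tm)
        + a2 * np.exp(-l2 * tm)
        + a3 * np.exp(-l3 * tm)
    )
    cp = np.where(t > t0, np.maximum(cp, 0.0), 0.0)
    return InputFunction(t=t, value=cp, kind="plasma")


def plasma_blood_ratio(
    t: np.ndarray, r0: float = 1.0, r_inf: float = 1.25, tau_r: float = 600.0
) -> np.ndarray:
    """Time-dependent plasma-to-whole-blood concentration ratio.

    ``ratio(t) = r_inf - (r_inf - r0) exp(-t / tau_r)``: FDG equilibrates
    slowly into red cells, so the plasma/blood ratio drifts from r0 toward
    r_inf over the scan.
    """
    if r0 <= 0 or r_inf <= 0:
        raise ValueError("ratios must be > 0")
    if tau_r <= 0:
        raise ValueError("tau_r must be > 0")
    t = np.asarray(t, dtype=float)
    return r_inf - (r_inf - r0) * np.exp(-t / tau_r)


def whole_blood_from_plasma(
    plasma: InputFunction, r0: float = 1.0, r_inf: float = 1.25, tau_r: float = 600.0
) -> InputFunction:
    """Whole-blood curve = plasma / plasma-to-blood ratio."""
    ratio = plasma_blood_ratio(plasma.t, r0, r_inf, tau_r)
    return InputFunction(t=plasma.t, value=plasma.value / ratio, kind="whole_blood")


# --------------------------------------------------------------------------- #
# Tissue model
# --------------------------------------------------------------------------- #


def tissue_tac(
    params: KineticParams,
    aif: InputFunction,
    whole_blood: InputFunction | None,
    t: np.ndarray,
) -> np.ndarray:
    """Noise-free tissue concentration of the irreversible 2TCM on grid ``t``.

    Evaluated by trapezoid integration / discrete exponential convolution on a
    1-s internal grid, then linearly interpolated onto ``t``.
    """
    if aif.kind != "plasma":
        raise ValueError("aif must be a plasma curve")
    t = np.asarray(t, dtype=float)
    t_end = max(float(t[-1]), float(aif.t[-1]))
    grid = np.arange(0.0, t_end + 1.0, 1.0)
    cp = aif(grid)
    dt_min = 1.0 / SECONDS_PER_MIN  # rate constants are per-minute

    if params.K1 > 0:
        beta = params.k2 + params.k3
        int_cp = cumulative_trapezoid(cp, dx=dt_min, initial=0.0)
        # e^{-beta t} ⊛ Cp via trapezoid-weighted discrete convolution
        kern = np.exp(-beta * np.arange(len(grid)) * dt_min)
        w = np.full(len(grid), dt_min)
        w[0] = dt_min / 2.0
        conv = np.convolve(cp * w, kern)[: len(grid)]
        # trapezoid endpoint: the running upper limit j = i carries half weight
        conv -= 0.5 * dt_min * cp * kern[0]
        free = params.K1 * params.k2 / beta
        ct_tissue = params.Ki * int_cp + free * conv
    else:
        ct_tissue = np.zeros_like(grid)

    cb = whole_blood(grid) if whole_blood is not None else np.zeros_like(grid)
    ct = (1.0 - params.Vb) * ct_tissue + params.Vb * cb
    return np.interp(t, grid, ct)


def frame_average(curve_t: np.ndarray, curve_v: np.ndarray, schedule: FrameSchedule) -> np.ndarray:
    """Average a continuous curve over each frame interval (how PET frames
    integrate activity), via trapezoid on a 1-s grid."""
    out = np.empty(len(schedule))
    for i, (t0, t1) in enumerate(schedule.intervals):
        grid = np.arange(t0, t1 + 0.5, 1.0)
        if grid[-1] < t1:
            grid = np.append(grid, t1)
        v = np.interp(grid, curve_t, curve_v)
        out[i] = np.trapezoid(v, grid) / (t1 - t0)
    return out


# --------------------------------------------------------------------------- #
# Patlak analysis
# --------------------------------------------------------------------------- #


def patlak_points(
    tissue: np.ndarray,
    plasma: InputFunction,
    schedule: FrameSchedule,
    t_star: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Patlak-transformed coordinates for frames ending at or after t_star.

    Returns (x, y, frame_indices) with x = int_0^t Cp / Cp(t) and
    y = C_T(t)/Cp(t), both evaluated at frame mid-times.
    """
    tissue = np.asarray(tissue, dtype=float)
    if tissue.shape[0] != len(schedule):
        raise ValueError("one tissue value per frame required")
    grid = np.arange(0.0, schedule.total_duration + 1.0, 1.0)
    cp = plasma(grid)
    int_cp = cumulative_trapezoid(cp, dx=1.0 / SECONDS_PER_MIN, initial=0.0)
    idx = np.where(schedule.ends >= t_star - 1e-9)[0]
    mids = schedule.mid_times[idx]
    cp_mid = np.interp(mids, grid, cp)
    if np.any(cp_mid <= 0):
        raise ValueError("plasma activity must be positive over the fit window")
    x = np.interp(mids, grid, int_cp) / cp_mid
    y = tissue[idx] / cp_mid
    return x, y, idx


def patlak_fit(
    tissue: np.ndarray,
    plasma: InputFunction,
    config: PatlakConfig,
    schedule: FrameSchedule,
) -> tuple[float, float]:
    """Ordinary least squares on the Patlak plot.

    Returns ``(slope, intercept)``; the slope estimates the net influx
    constant Ki in mL·mL^-1·min^-1.  Uses frames whose interval ends at or
    after ``t_star`` (the 37-frame 60-min protocol yields 8 points at
    t_star = 25 min).
    """
    x, y, idx = patlak_points(tissue, plasma, schedule, config.t_star)
    if len(x) < 2:
        raise ValueError("insufficient late frames")
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept)


def cmrglc(slope: float, config: PatlakConfig) -> float:
    """CMRGlc in µmol/100 g/min from the Patlak slope.

    ``CMRGlc = 0.1 * slope * plasma_glucose / LC``; the 0.1 converts
    (mL·mL^-1·min^-1 × µmol/L) to µmol/100 g/min at tissue density 1 g/mL.
    """
    if not np.isfinite(slope):
        raise ValueError("slope must be finite")
    return 0.1 * slope * config.plasma_glucose / config.lumped_constant
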