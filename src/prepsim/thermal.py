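"""Capillary heat-transfer estimates and a setpoint-tracking trace simulator.

Reactions on the platform happen inside cylindrical fluid slugs held in
polyethylene capillary tubing pressed against a Peltier-heated copper
plate.  This module provides the closed-form scale estimates that
justify that geometry —

* conductive heat flow through a cylindrical shell,
  ``Q = 2 pi k r L (dT/dr)``;
* the radial thermal diffusion time of the slug, ``t_d ~ r^2 / 2 alpha``;
* the slug's thermal capacitance ``rho pi r^2 L c_p dT`` and the
  heating timescale ``capacitance / Q``;
* diffusional and convective well-mixing times ``tau_d ~ w^2/2D`` and
  ``tau_c ~ w^2 L / Q_flow``

— plus a lumped first-order plant with a PID heater controller that
emulates the logged thermocouple traces: each scripted setpoint segment
is tracked (ramp) then held for its scripted time, with Gaussian sensor
noise on the measured channel.  Traces round-trip through a plain-text
tab-separated log format.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from prepsim.protocols import AssayProtocol, builtin_protocol


@dataclass
class ThermalParams:
    """Geometry and material constants of the capillary/slug system (SI)."""

    k_wall: float = 0.33          # tube-wall conductivity, W/(m degC)
    k_liquid: float = 0.598       # water conductivity, W/(m degC)
    r_outer: float = 1.6e-3       # tube outer radius, m
    r_slug: float = 0.8e-3        # fluid-slug radius, m
    wall_thickness: float = 0.8e-3  # conduction length dr, m
    L_slug: float = 24.9e-3       # slug length, m
    dT: float = 73.0              # max temperature difference, degC
    alpha: float = 0.15e-6        # thermal diffusivity of water, m^2/s
    rho: float = 1000.0           # density, kg/m^3
    c_p: float = 4.18             # specific heat, J/(g degC)

    def __post_init__(self) -> None:
        for name in ("k_wall", "k_liquid", "r_outer", "r_slug",
                     "wall_thickness", "L_slug", "dT", "alpha", "rho", "c_p"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class MixingParams:
    """Well geometry and transport coefficients for mixing estimates (SI)."""

    w: float = 3.48e-3       # well width, m
    L_well: float = 19.3e-3  # well depth, m
    D: float = 1e-10         # molecular diffusivity, m^2/s
    Q_flow: float = 1e-8     # dispense flow rate, m^3/s (10 uL/s)

    def __post_init__(self) -> None:
        for name in ("w", "L_well", "D", "Q_flow"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


def conductive_heat_flow(
    k: float, r: float, L: float, dT: float, dr: float
) -> float:
    """Cylindrical-shell conduction rate ``2 pi k r L (dT/dr)`` in W."""
    if dr <= 0:
        raise ValueError("dr must be > 0")
    if k <= 0 or r <= 0 or L <= 0:
        raise ValueError("k, r and L must be > 0")
    return 2.0 * math.pi * k * r * L * (dT / dr)


def thermal_diffusion_time(r: float, alpha: float) -> float:
    """Radial thermal diffusion time ``r^2 / (2 alpha)`` in s."""
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    if r < 0:
        raise ValueError("r must be >= 0")
    return r * r / (2.0 * alpha)


def slug_heat_capacitance(
    rho: float, r: float, L: float, c_p: float, dT: float
) -> float:
    """Thermal capacitance ``rho pi r^2 L c_p dT`` in J.

    ``rho`` in kg/m^3, lengths in m, ``c_p`` in J/(g degC) — the slug
    mass is converted to grams, so 50 uL of water warmed by 1 degC
    stores 0.209 J.
    """
    if rho <= 0 or r <= 0 or L <= 0 or c_p <= 0:
        raise ValueError("rho, r, L and c_p must be > 0")
    if dT < 0:
        raise ValueError("dT must be >= 0")
    mass_g = rho * math.pi * r * r * L * 1e3
    return mass_g * c_p * dT


def heating_timescale(capacitance: float, Q: float) -> float:
    """Slug heating timescale ``capacitance / Q`` in s."""
    if Q <= 0:
        raise ValueError("Q must be > 0")
    if capacitance < 0:
        raise ValueError("capacitance must be >= 0")
    return capacitance / Q


def mixing_times(params: MixingParams) -> tuple[float, float]:
    """Diffusional and convective well-mixing times (tau_d, tau_c) in s."""
    tau_d = params.w ** 2 / (2.0 * params.D)
    tau_c = params.w ** 2 * params.L_well / params.Q_flow
    return tau_d, tau_c


@dataclass
class SetpointProfile:
    """Ordered (setpoint degC, hold s) segments of a scripted heat program."""

    segments: list[tuple[float, float]]
    name: str = ""

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("profile must contain at least one segment")
        self.segments = [(float(t), float(h)) for t, h in self.segments]
        if any(h < 0 for _, h in self.segments):
            raise ValueError("holds must be >= 0")

    def hold_total(self) -> float:
        return sum(h for _, h in self.segments)


def pcr_profile(protocol: AssayProtocol) -> SetpointProfile:
    """Build the PCR setpoint profile from a protocol's stored schedule."""
    return SetpointProfile(list(protocol.pcr_schedule),
                           name=f"{protocol.name}_pcr")


def builtin_profile(name: str) -> SetpointProfile:
    """Built-in setpoint profiles.

    ``mechanical_pcr`` / ``enzymatic_pcr`` are the two assays' full PCR
    schedules; ``pretreatment`` is the 10 min, 75 degC surface
    passivation hold.
    """
    if name in ("mechanical_pcr", "enzymatic_pcr"):
        return pcr_profile(builtin_protocol(name.removesuffix("_pcr")))
    if name == "pretreatment":
        return SetpointProfile([(75.0, 600.0)], name="pretreatment")
    raise KeyError(
        f"no such profile: {name!r} "
        "(built-ins: enzymatic_pcr, mechanical_pcr, pretreatment)"
    )


@dataclass
class PIDGains:
    """Heater PID gains: power output in W per degC of error."""

    kp: float = 20.0
    ki: float = 0.5
    kd: float = 0.0


@dataclass
class PlantParams:
    """Lumped thermal plant: ``C_th dT/dt = u(t) - h (T - T_amb)``.

    The defaults describe the thermocouple-bearing tubing segment
    clamped to the heater block: thermal mass ``C_th`` 13 J/degC,
    ambient-loss conductance ``h`` 0.10 W/degC, 20 degC ambient, and
    40 W peak heater power.  They give a 20->98 degC rise in under 30 s
    and passive (heat-only) cooling with a ~130 s time constant.
    """

    C_th: float = 13.0    # J/degC
    h: float = 0.10       # W/degC
    T_amb: float = 20.0   # degC
    u_max: float = 40.0   # peak heater power, W

    def __post_init__(self) -> None:
        if self.C_th <= 0 or self.h <= 0 or self.u_max <= 0:
            raise ValueError("C_th, h and u_max must be > 0")


@dataclass
class ThermalTrace:
    """Uniformly sampled (time, setpoint, measured) temperature series."""

    time: np.ndarray       # s
    setpoint: np.ndarray   # degC
    measured: np.ndarray   # degC
    dt: float              # sampling interval, s
    segment: Optional[np.ndarray] = None  # profile-segment index per sample

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.setpoint = np.asarray(self.setpoint, dtype=float)
        self.measured = np.asarray(self.measured, dtype=float)
        n = len(self.time)
        if not (len(self.setpoint) == len(self.measured) == n):
            raise ValueError("time, setpoint and measured must be parallel")
        if n > 1 and np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0]) + self.dt if len(self.time) else 0.0


def simulate_temperature_trace(
    profile: SetpointProfile,
    control: PIDGains | None = None,
    plant: PlantParams | None = None,
    dt: float = 0.1,
    noise_sd: float = 0.1,
    seed: int | None = None,
    settle_band: float = 1.0,
    max_ramp_time: float = 300.0,
    heat_only: bool = True,
    constant_power: float | None = None,
) -> ThermalTrace:
    """Integrate the lumped plant through a scripted setpoint profile.

    For each profile segment the controller first ramps until the
    temperature is within ``settle_band`` degC of the setpoint (bounded
    by ``max_ramp_time``), then holds for the segment's scripted time,
    so the total trace duration is scripted holds plus realised ramps —
    as on a thermal cycler.  Explicit Euler at step ``dt``; heater
    power is PID on (setpoint - measured), clipped to ``[0, u_max]``
    (``[-u_max, u_max]`` when ``heat_only=False``, modelling Peltier
    cooling), with integral anti-windup.  Gaussian sensor noise of SD
    ``noise_sd`` is added to the measured channel and fed back to the
    controller; the trace is reproducible from ``seed``.

    With ``constant_power`` set, the controller is bypassed and the
    plant integrates open-loop at that power for the profile's total
    hold time (no ramp phases) — the configuration whose closed-form
    response ``T_amb + (u0/h)(1 - exp(-h t / C_th))`` anchors the
    integrator's accuracy tests.
    """
    gains = control or PIDGains()
    pl = plant or PlantParams()
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if pl.h * dt >= 2.0 * pl.C_th:
        raise ValueError(
            f"dt={dt} unstable for explicit Euler: need h*dt < 2*C_th "
            f"(h={pl.h}, C_th={pl.C_th})"
        )
    rng = np.random.default_rng(seed)

    times: list[float] = []
    sps: list[float] = []
    meas: list[float] = []
    segs: list[int] = []

    T = pl.T_amb
    t = 0.0
    integ = 0.0
    prev_err = None
    u_lo = 0.0 if heat_only else -pl.u_max

    def step(u: float, T: float) -> float:
        return T + dt * (u - pl.h * (T - pl.T_amb)) / pl.C_th

    if constant_power is not None:
        n_steps = int(round(profile.hold_total() / dt))
        sp = profile.segments[0][0]
        for i in range(n_steps):
            noisy = T + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
            times.append(t); sps.append(sp); meas.append(noisy); segs.append(0)
            T = step(constant_power, T)
            t += dt
        return ThermalTrace(np.array(times), np.array(sps), np.array(meas),
                            dt, np.array(segs))

    for seg_idx, (sp, hold) in enumerate(profile.segments):
        ramp_elapsed = 0.0
        settled = abs(T - sp) <= settle_band
        hold_elapsed = 0.0
        while True:
            if not settled:
                if ramp_elapsed >= max_ramp_time:
                    settled = True  # give up ramping; start the hold
                    continue
            noisy = T + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
            times.append(t); sps.append(sp); meas.append(noisy)
            segs.append(seg_idx)
            err = sp - noisy
            integ_cand = integ + err * dt
            deriv = 0.0 if prev_err is None else (err - prev_err) / dt
            u_raw = gains.kp * err + gains.ki * integ_cand + gains.kd * deriv
            u = min(max(u_raw, u_lo), pl.u_max)
            if u == u_raw:  # anti-windup: integrate only when unsaturated
                integ = integ_cand
            prev_err = err
            T = step(u, T)
            t += dt
            if settled:
                hold_elapsed += dt
                if hold_elapsed >= hold:
                    break
            else:
                ramp_elapsed += dt
                if abs(T - sp) <= settle_band:
                    settled = True
                    if hold <= 0:
                        break
    return ThermalTrace(np.array(times), np.array(sps), np.array(meas),
                        dt, np.array(segs))


@dataclass
class SegmentMetrics:
    """Per-segment tracking metrics of a thermal trace."""

    setpoint: float
    ramp_rate: Optional[float]       # degC/s over the 10%->90% rise span
    settling_time: Optional[float]   # s from segment start to +-1 degC band
    steady_state_error: Optional[float]  # mean (sp - T) over final quarter
    max_overshoot: float             # degC beyond setpoint in ramp direction


def trace_metrics(
    trace: ThermalTrace,
    profile: SetpointProfile,
    band: float = 1.0,
) -> list[SegmentMetrics]:
    """Score a trace against its scripted profile, one record per segment.

    Segments are located from the trace's stored per-sample segment
    index when present, otherwise from setpoint changes (contiguous
    equal setpoints then merge into one observed segment).  A segment
    that never enters the ``+-band`` degC band reports its settling
    time as absent rather than raising.
    """
    if trace.segment is not None:
        ids = np.asarray(trace.segment)
    else:
        changes = np.flatnonzero(np.diff(trace.setpoint) != 0)
        ids = np.zeros(len(trace.setpoint), dtype=int)
        for c in changes:
            ids[c + 1:] += 1
    out: list[SegmentMetrics] = []
    for seg in np.unique(ids):
        m = ids == seg
        tt, T = trace.time[m], trace.measured[m]
        sp = float(trace.setpoint[m][0])
        T0 = T[0]
        rise = sp - T0
        ramp_rate = None
        if abs(rise) > 2 * band:
            lo_level = T0 + 0.1 * rise
            hi_level = T0 + 0.9 * rise
            if rise > 0:
                lo_hits = np.flatnonzero(T >= lo_level)
                hi_hits = np.flatnonzero(T >= hi_level)
            else:
                lo_hits = np.flatnonzero(T <= lo_level)
                hi_hits = np.flatnonzero(T <= hi_level)
            if len(lo_hits) and len(hi_hits) and hi_hits[0] > lo_hits[0]:
                span = tt[hi_hits[0]] - tt[lo_hits[0]]
                if span > 0:
                    ramp_rate = abs(0.8 * rise) / span
        inside = np.flatnonzero(np.abs(T - sp) <= band)
        settling = float(tt[inside[0]] - tt[0]) if len(inside) else None
        q = max(1, len(T) // 4)
        sse = float(np.mean(sp - T[-q:])) if len(inside) else None
        if rise >= 0:
            overshoot = float(max(np.max(T) - sp, 0.0))
        else:
            overshoot = float(max(sp - np.min(T), 0.0))
        out.append(SegmentMetrics(sp, ramp_rate, settling, sse, overshoot))
    return out


_LOG_HEADER = "time_s\tsetpoint_C\tmeasured_C"


def write_thermal_log(trace: ThermalTrace, path: str | Path) -> None:
    """Write a trace as tab-separated text with a one-line header."""
    df = pd.DataFrame({
        "time_s": trace.time,
        "setpoint_C": trace.setpoint,
        "measured_C": trace.measured,
    })
    df.to_csv(path, sep="\t", index=False, float_format="%.3f")


def read_thermal_log(path: str | Path) -> ThermalTrace:
    """Read a tab-separated thermal log back into a trace.

    Raises ``ValueError`` naming the offending line on malformed input;
    a header-only file yields an empty trace (``len(trace.time) == 0``).
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or lines[0].strip() != _LOG_HEADER:
        raise ValueError(f"{path}: line 1: expected header {_LOG_HEADER!r}")
    rows = []
    for i, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ValueError(f"{path}: line {i}: expected 3 tab-separated fields")
        try:
            rows.append(tuple(float(p) for p in parts))
        except ValueError:
            raise ValueError(f"{path}: line {i}: non-numeric field") from None
    if not rows:
        return ThermalTrace(np.zeros(0), np.zeros(0), np.zeros(0), dt=0.0)
    arr = np.array(rows)
    dt = float(np.median(np.diff(arr[:, 0]))) if len(arr) > 1 else 0.0
    return ThermalTrace(arr[:, 0], arr[:, 1], arr[:, 2], dt=dt)
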