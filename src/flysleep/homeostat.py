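"""The sleep homeostat as a relaxation oscillator.

Two models share the same switching logic:

* :func:`simulate_flasher` — the electrical analogue: a capacitor charged
  through a resistor toward a supply voltage and discharged through a
  neon bulb that ignites at one threshold and extinguishes at a lower
  one.  The charge-phase duration has the closed form
  ``T = R*C*ln((Vs - V_ext)/(Vs - V_ign))``, used as the convergence
  oracle for the integrator.

* :func:`simulate_homeostat` — the circuit-level model: sleep pressure
  accumulates while the fly is awake (driven by R2 ring-neuron activity,
  which helicon-cell input excites), and is cleared while it sleeps.
  Sleep-promoting dFB neurons switch ON when pressure reaches ``P_on``
  and OFF when it falls to ``P_off``; dFB activity inhibits helicon
  cells, closing the visual/locomotor gate, and the fly is asleep
  exactly when that gate is closed.  Perturbations force wakefulness
  (mechanical deprivation analogue), clamp helicon cells UP
  (optogenetic stimulation analogue) or silence them (Kir2.1 analogue).

All quantities are in arbitrary units; the model encodes the circuit
topology and two-threshold switching, not calibrated biophysics, so its
tests are property- and sign-based rather than numeric.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "OscillatorParams",
    "HomeostatParams",
    "FlasherResult",
    "simulate_flasher",
    "simulate_homeostat",
]


@dataclass
class OscillatorParams:
    """RC relaxation oscillator (neon-bulb flasher) parameters."""

    R: float = 1.0
    C: float = 1.0
    Vs: float = 10.0  # supply voltage
    V_ignite: float = 8.0
    V_extinguish: float = 2.0
    R_discharge: float = 0.05

    def __post_init__(self) -> None:
        if not (0 < self.V_extinguish < self.V_ignite):
            raise ValueError("need 0 < V_extinguish < V_ignite")
        for name in ("R", "C", "Vs", "R_discharge"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def charge_period(self) -> float:
        """Closed-form charge-phase duration (extinguish -> ignite)."""
        return self.R * self.C * np.log(
            (self.Vs - self.V_extinguish) / (self.Vs - self.V_ignite)
        )


@dataclass
class FlasherResult:
    t: np.ndarray
    voltage: np.ndarray
    flash_times: np.ndarray  # ignition crossings
    extinguish_times: np.ndarray
    never_fires: bool  # flagged when Vs <= V_ignite


def simulate_flasher(
    params: OscillatorParams, dt: float, duration: float
) -> FlasherResult:
    """Integrate the flasher circuit with fixed-step explicit Euler.

    While dark the capacitor charges through R toward Vs; while lit it
    additionally discharges through the bulb path R_discharge.  The bulb
    ignites on crossing ``V_ignite`` and goes dark on crossing
    ``V_extinguish``.  ``Vs <= V_ignite`` is a valid configuration that
    never flashes; the result is flagged, not an error.
    """
    if dt <= 0 or dt > params.R * params.C / 10.0:
        raise ValueError("dt must be positive and well below R*C")
    n = int(round(duration / dt))
    v = np.empty(n + 1)
    v[0] = 0.0
    lit = False
    flashes: list[float] = []
    extinguishes: list[float] = []
    rc = params.R * params.C
    rdc = params.R_discharge * params.C
    for i in range(n):
        dv = (params.Vs - v[i]) / rc
        if lit:
            dv -= v[i] / rdc
        v[i + 1] = v[i] + dv * dt
        if not lit and v[i + 1] >= params.V_ignite:
            lit = True
            flashes.append((i + 1) * dt)
        elif lit and v[i + 1] <= params.V_extinguish:
            lit = False
            extinguishes.append((i + 1) * dt)
    return FlasherResult(
        t=np.arange(n + 1) * dt,
        voltage=v,
        flash_times=np.asarray(flashes),
        extinguish_times=np.asarray(extinguishes),
        never_fires=params.Vs <= params.V_ignite,
    )


@dataclass
class HomeostatParams:
    """Sleep-pressure dynamics of the dFB/helicon/R2 loop.

    Pressure grows at ``pressure_gain * (r2_base_drive + helicon_gain)``
    per second of wake while helicon cells are UP (only
    ``r2_base_drive`` when they are silenced) and decays at
    ``clearance_rate`` per second of sleep.  dFB neurons switch ON at
    ``P_on`` and OFF at ``P_off`` (two thresholds -> relaxation
    oscillation); dFB ON forces helicon cells DOWN unless clamped.
    """

    pressure_gain: float = 1.0  # pressure units per second per drive unit
    clearance_rate: float = 2.0  # pressure units per second while asleep
    P_on: float = 10.0
    P_off: float = 2.0
    helicon_gain: float = 1.0  # helicon contribution to R2 drive
    r2_base_drive: float = 0.2  # visual-independent drive

    def __post_init__(self) -> None:
        if not self.P_off < self.P_on:
            raise ValueError("need P_off < P_on")
        for name in ("pressure_gain", "clearance_rate", "helicon_gain", "r2_base_drive"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


_PERTURBATION_KINDS = ("forced_wake", "helicon_clamp_up", "helicon_silenced")


def _active(perturbations, t: float) -> set[str]:
    return {k for s, e, k in perturbations if s <= t < e}


def simulate_homeostat(
    params: HomeostatParams,
    perturbations: list[tuple[float, float, str]] | None = None,
    duration: float = 200.0,
    dt: float = 0.01,
) -> pd.DataFrame:
    """Simulate the sleep-pressure relaxation oscillation.

    Returns a trajectory DataFrame (t, pressure, dfb_on, helicon_up,
    behavior).  The dynamics within a step are linear, so threshold
    crossings are located exactly inside the step and the switch happens
    at the threshold value; unperturbed pressure therefore stays inside
    ``[P_off, P_on]`` and the cycle is a strict limit cycle.

    Perturbation kinds: ``forced_wake`` keeps the behavioral readout
    awake (pressure keeps accumulating past P_on — the deprivation
    analogue); ``helicon_clamp_up`` holds helicon cells UP against dFB
    inhibition (sustained arousal plus extra R2 drive); and
    ``helicon_silenced`` holds them DOWN (gate closed -> behavioral
    quiescence).  Clamping and silencing cannot overlap.
    """
    perturbations = perturbations or []
    for s, e, k in perturbations:
        if k not in _PERTURBATION_KINDS:
            raise ValueError(f"unknown perturbation kind {k!r}")
        if not (0 <= s < e):
            raise ValueError("perturbation intervals must satisfy 0 <= start < end")
    for s1, e1, k1 in perturbations:
        for s2, e2, k2 in perturbations:
            if {k1, k2} == {"helicon_clamp_up", "helicon_silenced"} and s1 < e2 and s2 < e1:
                raise ValueError("helicon clamp and silencing overlap; incompatible")

    n = int(round(duration / dt))
    t_arr = np.arange(n + 1) * dt
    pressure = np.empty(n + 1)
    dfb = np.empty(n + 1, dtype=bool)
    hel = np.empty(n + 1, dtype=bool)
    beh = np.empty(n + 1, dtype=object)

    p = params.P_off
    dfb_on = False
    for i in range(n + 1):
        t = t_arr[i]
        active = _active(perturbations, t)
        if "helicon_clamp_up" in active:
            helicon_up = True
        elif "helicon_silenced" in active:
            helicon_up = False
        else:
            helicon_up = not dfb_on
        awake = ("forced_wake" in active) or helicon_up

        pressure[i] = p
        dfb[i] = dfb_on
        hel[i] = helicon_up
        beh[i] = "awake" if awake else "asleep"
        if i == n:
            break

        drive = params.r2_base_drive + (params.helicon_gain if helicon_up else 0.0)
        rate = params.pressure_gain * drive if awake else -params.clearance_rate
        p_next = p + rate * dt
        # exact in-step threshold switching (piecewise-linear dynamics)
        if not dfb_on and p < params.P_on <= p_next:
            frac = (params.P_on - p) / (rate * dt)
            dfb_on = True
            # recompute the remainder of the step under the new state,
            # unless a perturbation pins the behavioral readout
            active_mid = _active(perturbations, t + frac * dt)
            helicon_mid = (
                True if "helicon_clamp_up" in active_mid
                else False if "helicon_silenced" in active_mid
                else not dfb_on
            )
            awake_mid = ("forced_wake" in active_mid) or helicon_mid
            drive_mid = params.r2_base_drive + (params.helicon_gain if helicon_mid else 0.0)
            rate2 = params.pressure_gain * drive_mid if awake_mid else -params.clearance_rate
            p_next = params.P_on + rate2 * (1 - frac) * dt
        elif dfb_on and p > params.P_off >= p_next:
            frac = (params.P_off - p) / (rate * dt)
            dfb_on = False
            active_mid = _active(perturbations, t + frac * dt)
            helicon_mid = (
                True if "helicon_clamp_up" in active_mid
                else False if "helicon_silenced" in active_mid
                else not dfb_on
            )
            awake_mid = ("forced_wake" in active_mid) or helicon_mid
            drive_mid = params.r2_base_drive + (params.helicon_gain if helicon_mid else 0.0)
            rate2 = params.pressure_gain * drive_mid if awake_mid else -params.clearance_rate
            p_next = params.P_off + rate2 * (1 - frac) * dt
        p = max(p_next, 0.0)

    return pd.DataFrame(
        {"t": t_arr, "pressure": pressure, "dfb_on": dfb, "helicon_up": hel, "behavior": beh}
    )


def asleep_fraction(trajectory: pd.DataFrame, t_lo: float = 0.0, t_hi: float | None = None) -> float:
    """Fraction of time asleep in a window of a homeostat trajectory."""
    sel = trajectory["t"] >= t_lo
    if t_hi is not None:
        sel &= trajectory["t"] < t_hi
    sub = trajectory.loc[sel, "behavior"]
    return float((sub == "asleep").mean()) if len(sub) else float("nan")
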