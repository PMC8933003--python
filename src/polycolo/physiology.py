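"""Summary metrics for patch-clamp current traces and pressurized-artery myography.

Whole-cell currents recorded at a fixed holding potential are normalized by
membrane capacitance to current density (pA/pF).  Flow onto the cell evokes a
biphasic response: a fast transient increase in inward (negative) current,
then a sustained relaxation toward a new steady state.  The transient is
measured at its extremum relative to the pre-flow baseline; the steady state
is the average of a contiguous window of at least 45 s.

Myography metrics: myogenic tone is ``100 * (1 - D_active / D_passive)``,
with the passive diameter measured in Ca2+-free solution; the intraluminal
flow rate needed to impose a wall shear stress follows Poiseuille,
``tau = 4 * eta * Q / (pi * r^3)``, inverted for Q.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class CurrentTrace:
    """Time-stamped whole-cell current with capacitance and event markers.

    ``time_s`` must be strictly increasing; ``markers`` holds event times in
    seconds under keys such as ``flow_on``, ``flow_off``, ``ca_removed``.
    """

    time_s: np.ndarray
    current_pA: np.ndarray
    capacitance_pF: float
    markers: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.current_pA = np.asarray(self.current_pA, dtype=float)
        if self.time_s.shape != self.current_pA.shape:
            raise ValueError("time and current arrays must have equal length")
        if len(self.time_s) > 1 and np.any(np.diff(self.time_s) <= 0):
            raise ValueError("time must be strictly increasing")
        if self.capacitance_pF <= 0:
            raise ValueError("membrane capacitance must be positive")

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_s": self.time_s, "current_pA": self.current_pA}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path, capacitance_pF: float, markers: dict | None = None) -> "CurrentTrace":
        df = pd.read_csv(path)
        return cls(
            time_s=df["time_s"].to_numpy(),
            current_pA=df["current_pA"].to_numpy(),
            capacitance_pF=capacitance_pF,
            markers=markers or {},
        )


@dataclass
class DiameterPair:
    """Active lumen diameter and the passive diameter in Ca2+-free EGTA solution (um)."""

    d_active_um: float
    d_passive_um: float

    def __post_init__(self):
        if self.d_active_um < 0 or self.d_passive_um <= 0:
            raise ValueError("diameters must be positive (passive strictly)")


@dataclass
class ShearSpec:
    """Target wall shear stress, lumen diameter and perfusate viscosity."""

    tau_dyn_cm2: float
    diameter_um: float
    viscosity_poise: float = 0.007  # aqueous physiological salt solution at 37 C

    def __post_init__(self):
        if self.tau_dyn_cm2 <= 0 or self.diameter_um <= 0 or self.viscosity_poise <= 0:
            raise ValueError("shear spec values must be positive")


def current_density(trace: CurrentTrace) -> np.ndarray:
    """Pointwise current density (pA/pF)."""
    return trace.current_pA / trace.capacitance_pF


def _window_mean(trace: CurrentTrace, t0: float, t1: float) -> float:
    mask = (trace.time_s >= t0) & (trace.time_s < t1)
    if not np.any(mask):
        raise ValueError(f"no samples in window [{t0}, {t1}) s")
    return float(np.mean(current_density(trace)[mask]))


def transient_peak(
    trace: CurrentTrace,
    baseline_window_s: float = 10.0,
    search_window_s: float = 10.0,
    direction: str = "inward",
) -> float:
    """Flow-evoked transient current density, measured at its extremum.

    Returns the extremum of the density trace within ``search_window_s`` after
    the ``flow_on`` marker minus the mean density over ``baseline_window_s``
    before it.  ``direction='inward'`` takes the minimum (inward currents are
    negative); ``'outward'`` takes the maximum.  The sign is preserved.
    """
    if "flow_on" not in trace.markers:
        raise ValueError("trace has no flow_on marker")
    t_on = float(trace.markers["flow_on"])
    baseline = _window_mean(trace, t_on - baseline_window_s, t_on)
    mask = (trace.time_s >= t_on) & (trace.time_s <= t_on + search_window_s)
    if not np.any(mask):
        raise ValueError("search window contains no samples")
    seg = current_density(trace)[mask]
    extremum = float(np.min(seg) if direction == "inward" else np.max(seg))
    return extremum - baseline


def steady_state_current(
    trace: CurrentTrace,
    window_start_s: float,
    window_len_s: float,
    min_window_s: float = 45.0,
) -> float:
    """Mean current density over a contiguous window of at least 45 s.

    The window must lie fully inside the trace; windows shorter than
    ``min_window_s`` are rejected.
    """
    if window_len_s < min_window_s:
        raise ValueError(
            f"steady-state window must be at least {min_window_s} s (got {window_len_s})"
        )
    t0, t1 = window_start_s, window_start_s + window_len_s
    if t0 < trace.time_s[0] or t1 > trace.time_s[-1] + 1e-9:
        raise ValueError("steady-state window extends beyond the trace")
    return _window_mean(trace, t0, t1)


def myogenic_tone(d: DiameterPair) -> float:
    """Myogenic tone in percent: 100 * (1 - D_active / D_passive)."""
    return 100.0 * (1.0 - d.d_active_um / d.d_passive_um)


def flow_for_shear(spec: ShearSpec) -> float:
    """Volumetric flow rate (ul/min) producing the target wall shear stress.

    Poiseuille wall shear in a cylindrical lumen, tau = 4*eta*Q/(pi*r^3),
    inverted: Q = tau*pi*r^3/(4*eta).  Units: tau in dyn/cm^2, r in cm, eta in
    poise gives Q in cm^3/s, converted to ul/min (1 cm^3/s = 6e4 ul/min).
    """
    r_cm = (spec.diameter_um / 2.0) * 1e-4
    q_cm3_s = spec.tau_dyn_cm2 * np.pi * r_cm**3 / (4.0 * spec.viscosity_poise)
    return float(q_cm3_s * 6.0e4)


def percent_of_control(value: float, control: float) -> float:
    """Express ``value`` as a percentage of ``control`` (e.g. knockout vs floxed)."""
    if control == 0:
        raise ValueError("control value must be non-zero")
    return 100.0 * value / control
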