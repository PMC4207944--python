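"""Deterministic kinetics of a two-gate, two-site facilitated-diffusion channel.

The model is a minimal alternating-gate channel: an outer gate connects
the external solution (fixed concentration ``C_out``) to vestibule 1,
which contains a high-affinity binding site (``KD1``); a narrow central
isthmus with fixed conductance ``kc`` connects vestibule 1 to vestibule
2, which contains the lower-affinity site (``KD2``) and is bounded by
an inner gate to the internal solution (``C_in``).  Both gates are
driven by a sine-wave timer of frequency ``f`` with independent phases,
thresholded so each gate is open a fraction ``duty`` of every cycle.

State variables: free vestibular concentrations V1, V2 (mM) and
fractional site occupancies B1, B2.  Two parallel routes cross the
central isthmus: free diffusion between the vestibular pools
(conductance ``kc``) and a carrier route in which ligand bound at
site 1 crosses to site 2 directly (rate ``kh``), reflecting serial
transit through the binding sites.  With site capacities sigma1,
sigma2 (mM-equivalent):

    r1     = k1*V1*(1 - B1) - k2_1*B1
    r2     = k1*V2*(1 - B2) - k2_2*B2
    hop    = kh*k2_1*(B1*(1 - B2) - (KD2/KD1)*B2*(1 - B1))
    dV1/dt = g1(t)*kx*(C_out - V1) + kc*(V2 - V1) - sigma1*r1
    dB1/dt = r1 - hop
    dV2/dt = kc*(V1 - V2) - sigma2*r2 - g2(t)*ky*(V2 - C_in)
    dB2/dt = r2 + (sigma1/sigma2)*hop
    J(t)   = g2(t)*ky*(V2 - C_in)

with k2_i = KD_i * k1 (so KD is held fixed when the association rate
k1, in per-mM per-s, is varied).  The carrier rate is proportional to
the site-1 dissociation rate k2_1 — crossing the isthmus requires the
ligand to leave site 1 and be recaptured at site 2 — with ``kh`` the
dimensionless number of productive transits per dissociation.  The
``KD2/KD1`` factor makes the carrier route obey detailed balance: at
a uniform concentration with both gates open every term vanishes.
Setting ``kh = 0`` leaves the pure free-diffusion channel.  The net
transported amount is accumulated alongside the state so mean fluxes
are exact integrals.

The transfer constants kx, ky, kc, kh and site capacities sigma1,
sigma2 are not observable from structure; the shipped defaults are a
frozen calibration (see docs/methods.md) chosen so that at k1 = 1e8
the network is binding-limited rather than diffusion-limited.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

#: Frozen calibration of the unobservable transfer constants.
CALIBRATION = {
    "kx": 1.0e8,      # outer gate conductance, 1/s
    "ky": 1.0e9,      # inner gate conductance, 1/s
    "kc": 1.0e3,      # isthmus free-diffusion conductance, 1/s
    "kh": 0.5,        # carrier transits per site-1 dissociation, unitless
    "sigma1": 15.0,   # site-1 capacity, mM-equivalent
    "sigma2": 5.0,    # site-2 capacity, mM-equivalent
}


@dataclass
class GateChannelModel:
    """Parameters of the two-gate, two-site channel."""

    C_out: float = 50.0     # external ligand concentration, mM
    C_in: float = 0.0       # internal ligand concentration, mM
    KD1: float = 1.0        # site-1 dissociation constant, mM
    KD2: float = 20.0       # site-2 dissociation constant, mM
    k1: float = 1.0e8       # association rate, 1/(mM s)
    f: float = 1.0e6        # gate frequency, Hz
    phase1: float = 0.0     # gate-1 phase, degrees
    phase2: float = 0.0     # gate-2 phase, degrees
    duty: float = 0.5       # open fraction of each cycle
    kx: float = CALIBRATION["kx"]
    ky: float = CALIBRATION["ky"]
    kc: float = CALIBRATION["kc"]
    kh: float = CALIBRATION["kh"]
    sigma1: float = CALIBRATION["sigma1"]
    sigma2: float = CALIBRATION["sigma2"]
    gate_shape: str = "binary"      # "binary" or "smooth"
    smooth_sharpness: float = 10.0  # slope of the smooth-gate sigmoid

    def __post_init__(self) -> None:
        for name in ("KD1", "KD2", "k1", "f", "kx", "ky", "kc", "kh",
                     "sigma1", "sigma2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 < self.duty < 1.0:
            raise ValueError("duty must be in (0, 1)")
        if self.gate_shape not in ("binary", "smooth"):
            raise ValueError(f"unknown gate shape: {self.gate_shape!r}")

    @property
    def k2_1(self) -> float:
        return self.KD1 * self.k1

    @property
    def k2_2(self) -> float:
        return self.KD2 * self.k1

    def replace(self, **kwargs) -> "GateChannelModel":
        return dataclasses.replace(self, **kwargs)

    def total_content(self, state) -> float:
        """Ligand content of the channel (volume-weighted, mM-equivalent)."""
        v1, b1, v2, b2 = state[:4]
        return float(v1 + self.sigma1 * b1 + v2 + self.sigma2 * b2)


@dataclass
class SimResult:
    """Trajectories and cycle-averaged net flux of one simulation."""

    t: np.ndarray
    V1: np.ndarray
    B1: np.ndarray
    V2: np.ndarray
    B2: np.ndarray
    flux: np.ndarray           # instantaneous flux at the inner gate
    mean_net_flux: float       # averaged over integer cycles post-transient
    model: GateChannelModel
    n_cycles: int
    transient_cycles: int


def gate_state(t, f: float, phase: float, duty: float = 0.5):
    """Binary gate: open (1) iff the phase-shifted sine is above threshold.

    The threshold ``cos(pi*duty)`` makes the open fraction of each cycle
    exactly ``duty`` (duty 0.5 -> threshold 0).
    """
    if f <= 0:
        raise ValueError("gate frequency must be positive")
    theta = 2.0 * np.pi * f * np.asarray(t, dtype=float) + np.radians(phase)
    return (np.sin(theta) >= np.cos(np.pi * duty)).astype(float)


def smooth_gate_state(t, f: float, phase: float, duty: float, sharpness: float):
    """Clamped-sigmoid gate with the same threshold as the binary gate."""
    theta = 2.0 * np.pi * f * np.asarray(t, dtype=float) + np.radians(phase)
    s = np.sin(theta) - np.cos(np.pi * duty)
    return np.clip(0.5 + sharpness * s, 0.0, 1.0)


def _gate_transitions(f: float, phase: float, duty: float, t_end: float):
    """Times in (0, t_end) where the binary gate switches state."""
    c = np.cos(np.pi * duty)
    a = np.arcsin(np.clip(c, -1.0, 1.0))
    openings = (a - np.radians(phase)) / (2.0 * np.pi * f)
    closings = (np.pi - a - np.radians(phase)) / (2.0 * np.pi * f)
    period = 1.0 / f
    times = []
    for t0 in (openings, closings):
        k0 = int(np.floor(-t0 / period)) - 1
        k1 = int(np.ceil((t_end - t0) / period)) + 1
        for k in range(k0, k1 + 1):
            t = t0 + k * period
            if 0.0 < t < t_end:
                times.append(t)
    return times


def ode_rhs(t, state, model: GateChannelModel, g1: float, g2: float):
    """Right-hand side with the gate states supplied as numbers in [0, 1]."""
    v1, b1, v2, b2 = state[:4]
    r1 = model.k1 * v1 * (1.0 - b1) - model.k2_1 * b1
    r2 = model.k1 * v2 * (1.0 - b2) - model.k2_2 * b2
    hop = model.kh * model.k2_1 * (
        b1 * (1.0 - b2) - (model.KD2 / model.KD1) * b2 * (1.0 - b1))
    j_out = g2 * model.ky * (v2 - model.C_in)
    dv1 = g1 * model.kx * (model.C_out - v1) + model.kc * (v2 - v1) - model.sigma1 * r1
    db1 = r1 - hop
    dv2 = model.kc * (v1 - v2) - model.sigma2 * r2 - j_out
    db2 = r2 + (model.sigma1 / model.sigma2) * hop
    return [dv1, db1, dv2, db2, j_out]


def gate_states_at(model: GateChannelModel, t):
    """(g1, g2) arrays for the model's gate shape at times ``t``."""
    if model.gate_shape == "binary":
        g1 = gate_state(t, model.f, model.phase1, model.duty)
        g2 = gate_state(t, model.f, model.phase2, model.duty)
    else:
        g1 = smooth_gate_state(t, model.f, model.phase1, model.duty,
                               model.smooth_sharpness)
        g2 = smooth_gate_state(t, model.f, model.phase2, model.duty,
                               model.smooth_sharpness)
    return g1, g2


def simulate(
    model: GateChannelModel,
    n_cycles: int = 50,
    transient_fraction: float = 0.25,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    initial_state=None,
    samples_per_segment: int = 4,
    method: str = "BDF",
) -> SimResult:
    """Integrate the channel over ``n_cycles`` gate cycles.

    Gate transitions are used as integration breakpoints (the binary
    gates are constant between them, so the integrator never steps over
    a discontinuity).  The first ``transient_fraction`` of the cycles
    (rounded up to whole cycles) is discarded and the mean net flux is
    the transported amount over the remaining integer number of cycles
    divided by their duration.
    """
    if n_cycles < 20:
        raise ValueError("simulate needs at least 20 gate cycles")
    period = 1.0 / model.f
    t_end = n_cycles * period
    transient_cycles = int(np.ceil(transient_fraction * n_cycles))
    t_mark = transient_cycles * period

    breaks = {0.0, t_end, t_mark}
    if model.gate_shape == "binary":
        for phase in (model.phase1, model.phase2):
            breaks.update(_gate_transitions(model.f, phase, model.duty, t_end))
    else:
        breaks.update(k * period for k in range(1, n_cycles))
    # merge breakpoints closer than 1e-9 cycles (e.g. coincident gate switches)
    breaks = np.unique(np.round(np.array(sorted(breaks)) / period, 9)) * period

    if initial_state is None:
        initial_state = [model.C_in, model.C_in / (model.C_in + model.KD1),
                         model.C_in, model.C_in / (model.C_in + model.KD2)]
    y = np.array(list(initial_state) + [0.0], dtype=float)

    ts = [np.array([0.0])]
    ys = [y[:, None]]
    q_mark = None
    for a, b in zip(breaks[:-1], breaks[1:]):
        mid = 0.5 * (a + b)
        g1, g2 = gate_states_at(model, mid)
        if model.gate_shape == "binary":
            rhs = lambda t, s, _g1=float(g1), _g2=float(g2): ode_rhs(
                t, s, model, _g1, _g2)
        else:
            def rhs(t, s):
                h1, h2 = gate_states_at(model, t)
                return ode_rhs(t, s, model, float(h1), float(h2))
        t_eval = np.linspace(a, b, samples_per_segment + 1)[1:]
        sol = solve_ivp(rhs, (a, b), y, method=method, rtol=rtol, atol=atol,
                        t_eval=t_eval)
        if not sol.success:
            raise RuntimeError(
                f"integration failed in [{a:.3e}, {b:.3e}]: {sol.message}")
        y = sol.y[:, -1].copy()
        if np.min(y[:4]) < -1e-6 * max(model.C_out, 1.0):
            raise RuntimeError(
                f"integration produced negative state at t={b:.3e}")
        y[:4] = np.maximum(y[:4], 0.0)
        ts.append(sol.t)
        ys.append(sol.y)
        if np.isclose(b, t_mark):
            q_mark = y[4]
    t = np.concatenate(ts)
    Y = np.concatenate(ys, axis=1)
    if q_mark is None:  # t_mark coincided with an existing breakpoint midpoint
        q_mark = float(np.interp(t_mark, t, Y[4]))
    mean_net_flux = (y[4] - q_mark) / (t_end - t_mark)
    g1, g2 = gate_states_at(model, t)
    flux = g2 * model.ky * (Y[2] - model.C_in)
    return SimResult(
        t=t, V1=Y[0], B1=Y[1], V2=Y[2], B2=Y[3], flux=flux,
        mean_net_flux=float(mean_net_flux), model=model,
        n_cycles=n_cycles, transient_cycles=transient_cycles,
    )


def always_open_flux(model: GateChannelModel) -> float:
    """Closed-form steady flux of the free-diffusion chain, gates open.

    Valid for the pure free-diffusion channel (``kh = 0``): with
    g1 = g2 = 1 the free pools form a series of conductances kx, kc,
    ky between C_out and C_in and the bound pools carry no net flux.
    """
    if model.kh != 0:
        raise ValueError("closed form requires kh = 0 (no carrier route)")
    resistance = 1.0 / model.kx + 1.0 / model.kc + 1.0 / model.ky
    return (model.C_out - model.C_in) / resistance


def steady_state_open(model: GateChannelModel) -> np.ndarray:
    """Steady state (V1, B1, V2, B2) with both gates held open.

    Closed form for ``kh = 0``; otherwise solved numerically from the
    stationarity conditions.
    """
    if model.kh == 0:
        j = always_open_flux(model)
        v1 = model.C_out - j / model.kx
        v2 = model.C_in + j / model.ky
        b1 = v1 / (v1 + model.KD1)
        b2 = v2 / (v2 + model.KD2)
        return np.array([v1, b1, v2, b2])
    from scipy.optimize import fsolve

    def stationary(state):
        return ode_rhs(0.0, list(state) + [0.0], model, 1.0, 1.0)[:4]

    guess = [model.C_out * 0.8, 0.9, model.C_in + 1.0, 0.2]
    sol, info, ok, msg = fsolve(stationary, guess, full_output=True)
    if ok != 1:
        raise RuntimeError(f"steady-state solve failed: {msg}")
    return np.asarray(sol)


def phase_comparison(
    model: GateChannelModel,
    k1_values=(1.0e6, 1.0e8),
    phases=(0.0, 180.0),
    n_cycles: int = 50,
    **solver_opts,
) -> pd.DataFrame:
    """Mean net flux in-phase vs phase-shifted, per association rate.

    ``reduction_pct = 100 * (1 - flux_shifted / flux_inphase)``.
    """
    in_phase, shifted = phases
    rows = []
    for k1 in k1_values:
        base = model.replace(k1=k1, phase1=0.0, phase2=in_phase)
        alt = model.replace(k1=k1, phase1=0.0, phase2=shifted)
        flux_in = simulate(base, n_cycles=n_cycles, **solver_opts).mean_net_flux
        flux_alt = simulate(alt, n_cycles=n_cycles, **solver_opts).mean_net_flux
        reduction = 100.0 * (1.0 - flux_alt / flux_in) if flux_in != 0 else np.nan
        rows.append((k1, flux_in, flux_alt, reduction))
    return pd.DataFrame(
        rows, columns=["k1", "flux_inphase", "flux_shifted", "reduction_pct"]
    ).set_index("k1")
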