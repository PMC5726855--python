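"""Population dynamics: leak, persistent-sodium, synaptic, drive and noise
currents.

Each population is a non-spiking, activity-based unit with membrane
potential V (mV).  The rhythm-generator half-centers additionally carry a
slowly inactivating persistent sodium current INaP with inactivation
state h, which is the rhythmogenic mechanism: under sufficient tonic
drive a half-center produces limit-cycle bursting on its own.

Voltages are in mV, conductances in nS, currents in pA, times in ms; with
capacitance in pF, dV/dt = -I/C comes out in mV/ms.  The functions here
are the plain-numpy reference implementation; the numba kernel in
``_kernels`` reimplements the same arithmetic for speed and is pinned to
this module by a consistency test.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, replace

import numpy as np


@dataclass(frozen=True)
class CellConstants:
    """Shared membrane/synaptic constants of all populations.

    Defaults are the canonical parameter set of the model.  ``Vthr`` and
    ``Vmax`` are the breakpoints of the piecewise-linear output function;
    the ``V12_*``/``k_*`` pairs are the half-voltage (mV) and slope (mV)
    of the INaP activation (m), inactivation (h) and inactivation
    time-constant curves.
    """

    gSynE: float = 10.0      # nS
    gSynI: float = 10.0      # nS
    ESynE: float = -10.0     # mV
    ESynI: float = -75.0     # mV
    ENa: float = 50.0        # mV
    Vthr: float = -50.0      # mV
    Vmax: float = 0.0        # mV
    gNaP: float = 4.5        # nS
    V12_m: float = -40.0     # mV
    k_m: float = -6.0        # mV
    V12_h: float = -45.0     # mV
    k_h: float = 4.0         # mV
    V12_tau: float = -35.0   # mV
    k_tau: float = 15.0      # mV
    tau0: float = 80.0       # ms
    tau_max: float = 160.0   # ms
    tau_noise: float = 10.0  # ms

    def __post_init__(self) -> None:
        if not self.Vthr < self.Vmax:
            raise ValueError("Vthr must be below Vmax")
        if not self.tau0 < self.tau_max:
            raise ValueError("tau0 must be below tau_max")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, doc: dict) -> "CellConstants":
        return replace(cls(), **doc) if doc else cls()

    def as_array(self) -> np.ndarray:
        """Constants packed for the numba kernel (fixed field order)."""
        return np.array([
            self.gSynE, self.gSynI, self.ESynE, self.ESynI, self.ENa,
            self.Vthr, self.Vmax, self.gNaP, self.V12_m, self.k_m,
            self.V12_h, self.k_h, self.V12_tau, self.k_tau,
            self.tau0, self.tau_max,
        ])


@dataclass
class SystemState:
    """Instantaneous state: V per population, h per RG half-center,
    noise current per population."""

    V: np.ndarray
    h: np.ndarray
    I_noise: np.ndarray

    def copy(self) -> "SystemState":
        return SystemState(self.V.copy(), self.h.copy(), self.I_noise.copy())


def output(V, constants: CellConstants | None = None):
    """Piecewise-linear output function f(V) in [0, 1].

    0 below ``Vthr``, 1 above ``Vmax``, linear in between; translates the
    average membrane potential into the integrated population activity.
    """
    c = constants or CellConstants()
    return np.clip((np.asarray(V, dtype=float) - c.Vthr) / (c.Vmax - c.Vthr),
                   0.0, 1.0)


def rectify(x):
    """S(x) = max(x, 0); splits signed weights into E/I contributions."""
    return np.maximum(np.asarray(x, dtype=float), 0.0)


def drive(alpha: float, m, b):
    """Linear brainstem drive m*alpha + b (dimensionless conductance
    scale); alpha is the common speed-control parameter."""
    return np.asarray(m, dtype=float) * alpha + np.asarray(b, dtype=float)


def m_inf(V, c: CellConstants | None = None):
    """Steady-state INaP activation (instantaneous)."""
    c = c or CellConstants()
    return 1.0 / (1.0 + np.exp((np.asarray(V, float) - c.V12_m) / c.k_m))


def h_inf(V, c: CellConstants | None = None):
    """Steady-state INaP inactivation."""
    c = c or CellConstants()
    return 1.0 / (1.0 + np.exp((np.asarray(V, float) - c.V12_h) / c.k_h))


def tau_h(V, c: CellConstants | None = None):
    """Voltage-dependent INaP inactivation time constant (ms); peaks at
    ``tau_max`` at V = ``V12_tau``."""
    c = c or CellConstants()
    return c.tau0 + (c.tau_max - c.tau0) / np.cosh(
        (np.asarray(V, float) - c.V12_tau) / c.k_tau)


def inap_current(V, h, c: CellConstants | None = None):
    """Persistent sodium current gNaP * m_inf(V) * h * (V - ENa), pA."""
    c = c or CellConstants()
    return c.gNaP * m_inf(V, c) * np.asarray(h, float) * (
        np.asarray(V, float) - c.ENa)


def synaptic_currents(compiled, V: np.ndarray, alpha: float,
                      extra_DE: np.ndarray | None = None,
                      extra_DI: np.ndarray | None = None):
    """Excitatory and inhibitory synaptic currents for every population.

    I_SynE,i = gSynE * (sum_j S(w_ji) f(V_j) + D_E,i) * (V_i - ESynE) and
    analogously for inhibition with S(-w_ji) and D_I,i.  Outputs of
    deleted populations are clamped to zero before the sums.
    """
    c = compiled.constants
    f = output(V, c) * compiled.out_mask
    DE = drive(alpha, compiled.dE_m, compiled.dE_b)
    DI = drive(alpha, compiled.dI_m, compiled.dI_b)
    if extra_DE is not None:
        DE = DE + extra_DE
    if extra_DI is not None:
        DI = DI + extra_DI
    exc_in = DE + np.bincount(
        compiled.exc_tgt, weights=compiled.exc_w * f[compiled.exc_src],
        minlength=compiled.n_pop)
    inh_in = DI + np.bincount(
        compiled.inh_tgt, weights=compiled.inh_w * f[compiled.inh_src],
        minlength=compiled.n_pop)
    I_SynE = c.gSynE * exc_in * (V - c.ESynE)
    I_SynI = c.gSynI * inh_in * (V - c.ESynI)
    return I_SynE, I_SynI


def ou_step(I, dt: float, xi, sigma: float, tau: float | None = None):
    """One exact-discretization update of the Ornstein-Uhlenbeck noise.

    I[k+1] = a*I[k] + sigma*sqrt(1-a^2)*xi with a = exp(-dt/tau); the
    stationary standard deviation is exactly ``sigma`` and the lag-tau
    autocorrelation exactly e^-1, the two properties the noise current is
    used for.
    """
    tau = CellConstants().tau_noise if tau is None else tau
    a = np.exp(-dt / tau)
    return a * np.asarray(I, float) + sigma * np.sqrt(1.0 - a * a) * np.asarray(xi, float)


def rhs(state: SystemState, t: float, compiled, alpha: float,
        extra_DE: np.ndarray | None = None,
        extra_DI: np.ndarray | None = None) -> SystemState:
    """Time derivative of (V, h); the noise current is held as given.

    RG half-centers follow C dV/dt = -INaP - IL - ISynE - ISynI - INoise;
    all other populations omit INaP.  h relaxes toward h_inf(V) with time
    constant tau_h(V) for RG half-centers only.
    """
    c = compiled.constants
    V, h = state.V, state.h
    IL = compiled.gL * (V - compiled.EL)
    I_SynE, I_SynI = synaptic_currents(compiled, V, alpha, extra_DE, extra_DI)
    dV = -(IL + I_SynE + I_SynI + state.I_noise) / compiled.C
    Vrg = V[compiled.rg_idx]
    dV[compiled.rg_idx] -= inap_current(Vrg, h, c) / compiled.C
    dh = (h_inf(Vrg, c) - h) / tau_h(Vrg, c)
    return SystemState(dV, dh, np.zeros_like(state.I_noise))
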