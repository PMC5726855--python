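"""Time integration of the network with seeded Ornstein-Uhlenbeck noise.

A simulation advances the 56 membrane potentials plus 8 INaP inactivation
states with an adaptive Dormand-Prince 5(4) stepper (rtol=atol=1e-8 by
default).  The noise current of every population is pre-generated on a
fixed 1 ms grid with the exact OU update and held constant within each
cell; the state is recorded on the same grid.  The final state (including
the noise current) can be handed to the next protocol step, which is how
the drive sweeps chain their per-step simulations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.signal import lfilter

from . import _kernels
from .dynamics import SystemState
from .network import CompiledNetwork, NetworkSpec, resolve_selector

DEFAULT_NOISE_SD = 0.005   # pA; keeps the system off unstable trajectories
NOISE_DT = 1.0             # ms, fixed noise/recording grid
DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-8

#: initial-condition ranges (around the leak reversal, spanning sub- and
#: supra-threshold voltages); h covers the interior of its [0, 1] range
INIT_V_RANGE = (-65.0, -55.0)
INIT_H_RANGE = (0.2, 0.8)


class SimulationError(RuntimeError):
    """Solver failure (step-size underflow or non-finite state)."""

    def __init__(self, status: int, t_ms: float):
        kind = ("step-size underflow" if status == _kernels.FAIL_STEP_UNDERFLOW
                else "non-finite state")
        super().__init__(f"integration failed at t={t_ms:.3f} ms: {kind}")
        self.t_ms = t_ms


@dataclass
class Trajectory:
    """Recorded time series on the 1 ms grid.

    ``V`` has one column per entry of ``ids`` (the recorded populations,
    by default all); ``h`` one column per RG half-center.
    """

    t: np.ndarray                  # ms
    V: np.ndarray                  # (time, recorded populations), mV
    h: np.ndarray                  # (time, RG half-centers)
    alpha: np.ndarray              # drive at each sample
    ids: tuple[str, ...]
    final_state: SystemState
    nfev: int = 0

    def column(self, pop_id: str) -> np.ndarray:
        try:
            return self.V[:, self.ids.index(pop_id)]
        except ValueError:
            raise KeyError(pop_id) from None

    def flexor_outputs(self, constants) -> dict[str, np.ndarray]:
        """f(V) of the four RG flexor half-centers, keyed LF/RF/LH/RH."""
        from .dynamics import output
        key = {("fore", "left"): "LF", ("fore", "right"): "RF",
               ("hind", "left"): "LH", ("hind", "right"): "RH"}
        out = {}
        for (girdle, side), limb in key.items():
            pid = f"{girdle}-{side}-RG-F"
            if pid in self.ids:
                out[limb] = output(self.column(pid), constants)
        return out


def randomize_initial_state(net: NetworkSpec | CompiledNetwork,
                            seed: int | np.random.Generator = 0
                            ) -> SystemState:
    """Random initial state: V ~ U(-65, -55) mV, h ~ U(0.2, 0.8), no noise."""
    compiled = net if isinstance(net, CompiledNetwork) else net.compile()
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    V = rng.uniform(*INIT_V_RANGE, size=compiled.n_pop)
    h = rng.uniform(*INIT_H_RANGE, size=compiled.n_rg)
    return SystemState(V, h, np.zeros(compiled.n_pop))


def ou_series(n_ms: int, n_pop: int, sigma: float, tau: float,
              rng: np.random.Generator,
              I0: np.ndarray | None = None) -> np.ndarray:
    """OU noise sampled on the 1 ms grid, exact discretization.

    Returns an (n_ms, n_pop) array; row k is held constant over
    [k, k+1) ms.  ``I0`` is the value at the end of the previous segment
    so chained segments form one continuous process.
    """
    if sigma == 0.0:
        return np.zeros((n_ms, n_pop))
    a = np.exp(-NOISE_DT / tau)
    b = sigma * np.sqrt(1.0 - a * a)
    xi = rng.standard_normal((n_ms, n_pop))
    zi = (a * (I0 if I0 is not None else np.zeros(n_pop)))[np.newaxis, :]
    series, _ = lfilter([b], [1.0, -a], xi, axis=0, zi=zi)
    return series


def _extra_drive_arrays(compiled: CompiledNetwork,
                        extra_drive: Mapping | None
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Expand {selector: {"E": (m, b), "I": (m, b)}} into per-population
    additive drive coefficient arrays (slope, intercept stacked later)."""
    mE = np.zeros(compiled.n_pop); bE = np.zeros(compiled.n_pop)
    mI = np.zeros(compiled.n_pop); bI = np.zeros(compiled.n_pop)
    if extra_drive:
        for selector, terms in extra_drive.items():
            idx = [compiled.index_of(pid)
                   for pid in resolve_selector(compiled.spec, selector)]
            if "E" in terms:
                m, b = terms["E"]
                mE[idx] += m; bE[idx] += b
            if "I" in terms:
                m, b = terms["I"]
                mI[idx] += m; bI[idx] += b
    return np.stack([mE, bE]), np.stack([mI, bI])


def simulate(net: NetworkSpec | CompiledNetwork,
             duration_s: float,
             alpha: float,
             *,
             noise_sd: float = DEFAULT_NOISE_SD,
             seed: int | None = 0,
             rng: np.random.Generator | None = None,
             initial_state: SystemState | str | None = None,
             extra_drive: Mapping | None = None,
             record: Sequence[str] | None = None,
             rtol: float = DEFAULT_RTOL,
             atol: float = DEFAULT_ATOL) -> Trajectory:
    """Integrate the network for ``duration_s`` seconds at constant drive.

    Parameters
    ----------
    alpha : common brainstem drive (dimensionless, canonical range
        [0, 1.05]).
    noise_sd : stationary sd of the per-population OU noise current, pA.
    initial_state : a :class:`SystemState` (e.g. the final state of a
        previous call), ``"randomized"`` or None (randomized from the
        seed/rng).
    extra_drive : optional ``{selector: {"E": (m, b), "I": (m, b)}}``
        additive drive terms, e.g. drive-independent inputs to CIN/LPN
        populations.
    record : population ids to record (default: all).  h of all RG
        half-centers is always recorded.

    The trajectory is bit-reproducible for fixed (net, arguments, seed).
    """
    compiled = net if isinstance(net, CompiledNetwork) else net.compile()
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    n_ms = int(round(duration_s * 1000.0))
    if rng is None:
        rng = np.random.default_rng(seed)
    if initial_state is None or initial_state == "randomized":
        state = randomize_initial_state(compiled, rng)
    else:
        state = initial_state.copy()

    c = compiled.constants
    noise = ou_series(n_ms, compiled.n_pop, noise_sd, c.tau_noise, rng,
                      I0=state.I_noise)
    extra_m, extra_i = _extra_drive_arrays(compiled, extra_drive)
    DE = compiled.dE_m * alpha + compiled.dE_b + extra_m[0] * alpha + extra_m[1]
    DI = compiled.dI_m * alpha + compiled.dI_b + extra_i[0] * alpha + extra_i[1]

    rec_ids = tuple(record) if record is not None else compiled.ids
    rec_idx = np.array([compiled.index_of(pid) for pid in rec_ids],
                       dtype=np.int64)

    y0 = np.concatenate([state.V, state.h])
    status, t_fail, out_V, out_h, y_final, nfev = _kernels.integrate_grid(
        y0, noise, c.as_array(), compiled.C, compiled.gL, compiled.EL,
        DE, DI, compiled.out_mask, compiled.rg_idx,
        compiled.exc_src, compiled.exc_tgt, compiled.exc_w,
        compiled.inh_src, compiled.inh_tgt, compiled.inh_w,
        rec_idx, rtol, atol)
    if status != _kernels.OK:
        raise SimulationError(status, t_fail)

    final = SystemState(y_final[:compiled.n_pop].copy(),
                        y_final[compiled.n_pop:].copy(),
                        noise[-1].copy() if n_ms else state.I_noise)
    t = np.arange(n_ms + 1, dtype=float)
    return Trajectory(t=t, V=out_V, h=out_h,
                      alpha=np.full(n_ms + 1, float(alpha)),
                      ids=rec_ids, final_state=final, nfev=nfev)


def concatenate(trajectories: Iterable[Trajectory]) -> Trajectory:
    """Chain trajectories in time (dropping each duplicated seam sample)."""
    trajs = list(trajectories)
    if not trajs:
        raise ValueError("nothing to concatenate")
    parts_t = [trajs[0].t]
    parts_V = [trajs[0].V]
    parts_h = [trajs[0].h]
    parts_a = [trajs[0].alpha]
    for tr in trajs[1:]:
        if tr.ids != trajs[0].ids:
            raise ValueError("trajectories record different populations")
        offset = parts_t[-1][-1]
        parts_t.append(tr.t[1:] + offset)
        parts_V.append(tr.V[1:])
        parts_h.append(tr.h[1:])
        parts_a.append(tr.alpha[1:])
    return Trajectory(
        t=np.concatenate(parts_t), V=np.concatenate(parts_V),
        h=np.concatenate(parts_h), alpha=np.concatenate(parts_a),
        ids=trajs[0].ids, final_state=trajs[-1].final_state,
        nfev=sum(tr.nfev for tr in trajs))


def settle_then_step(net: NetworkSpec | CompiledNetwork,
                     alpha_before: float,
                     alpha_after: float,
                     *,
                     settle_s: float = 10.0,
                     run_s: float = 5.0,
                     extra_drive_after: Mapping | None = None,
                     noise_sd: float = DEFAULT_NOISE_SD,
                     seed: int = 0,
                     record: Sequence[str] | None = None,
                     rtol: float = DEFAULT_RTOL,
                     atol: float = DEFAULT_ATOL) -> tuple[Trajectory, float]:
    """Settle at ``alpha_before`` then switch abruptly to ``alpha_after``
    (optionally adding drive-independent inputs), carrying the state over.

    Returns the combined trajectory and the switch time in ms.
    """
    compiled = net if isinstance(net, CompiledNetwork) else net.compile()
    rng = np.random.default_rng(seed)
    first = simulate(compiled, settle_s, alpha_before, noise_sd=noise_sd,
                     rng=rng, record=record, rtol=rtol, atol=atol)
    second = simulate(compiled, run_s, alpha_after, noise_sd=noise_sd,
                      rng=rng, initial_state=first.final_state,
                      extra_drive=extra_drive_after, record=record,
                      rtol=rtol, atol=atol)
    return concatenate([first, second]), settle_s * 1000.0
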