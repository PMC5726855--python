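"""Protocol layer: drive sweeps with hysteresis detection, deletion
phenotyping, noise-driven variability, transition dynamics and weight
robustness screening.

All protocols operate by forward simulation only; stability of a phase
relationship is established operationally, by requiring the circular
standard deviation of the normalized phase differences over the last five
cycles of a 10 s step to stay below 1e-3.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .dynamics import SystemState
from .gait import (CycleSummary, GaitLabel, bin_percentages,
                   circular_distance, detect_phases, phase_differences,
                   summarize_cycles)
from .network import CompiledNetwork, NetworkSpec, delete_populations, \
    perturb_weights
from .simulate import DEFAULT_NOISE_SD, concatenate, simulate

log = logging.getLogger(__name__)

ALPHA_MAX = 1.05
SD_THRESHOLD = 1e-3         # circular-sd acceptance criterion per step
JUMP_THRESHOLD = 0.05       # adjacent-step phase jump triggering aux runs
PHASE_KEYS = ("hind_lr", "fore_lr", "homolateral", "diagonal")
REAL_GAITS = (GaitLabel.WALK, GaitLabel.TROT, GaitLabel.GALLOP,
              GaitLabel.BOUND)


def _flexor_ids(compiled: CompiledNetwork) -> tuple[str, ...]:
    return tuple(pid for pid in compiled.ids if pid.endswith("RG-F"))


def alpha_grid(n_points: int = 101, alpha_max: float = ALPHA_MAX) -> np.ndarray:
    """Equally spaced drive grid over [0, alpha_max]."""
    return np.linspace(0.0, alpha_max, n_points)


@dataclass
class BifurcationDiagram:
    """One sweep run: per-step circular summaries along an alpha path."""

    alphas: np.ndarray
    direction: str                      # "up", "down" or "auxiliary"
    summaries: list[CycleSummary]
    run: str = "main"

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for a, s in zip(self.alphas, self.summaries):
            row = {"alpha": a, "direction": self.direction, "run": self.run,
                   "frequency_hz": s.frequency,
                   "flexion_ms": s.flexion_ms, "extension_ms": s.extension_ms,
                   "gait": s.gait.value, "n_cycles": s.n_cycles,
                   "accepted": _accepted(s)}
            for k in PHASE_KEYS:
                row[f"pd_{k}"] = s.phase_means.get(k, float("nan"))
                row[f"sd_{k}"] = s.phase_sds.get(k, float("nan"))
            rows.append(row)
        return pd.DataFrame(rows)


def _accepted(s: CycleSummary) -> bool:
    if not s.has_rhythm or len(s.phase_sds) < len(PHASE_KEYS):
        return False
    return all(s.phase_sds[k] < SD_THRESHOLD for k in PHASE_KEYS)


@dataclass
class SweepResult:
    """Bidirectional sweep plus any auxiliary branch runs."""

    diagrams: list[BifurcationDiagram]
    n_points: int
    per_step_s: float
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.concat([d.to_frame() for d in self.diagrams],
                         ignore_index=True)

    def accepted(self) -> pd.DataFrame:
        df = self.to_frame()
        return df[df["accepted"]]

    def gait_inventory(self, main_only: bool = False) -> set[GaitLabel]:
        """Set of gaits expressed at accepted steps.

        With ``main_only`` the inventory reflects only the up/down main
        runs (the diagram's sweep lines); otherwise auxiliary branch runs
        contribute as well.
        """
        df = self.accepted()
        if main_only:
            df = df[df["run"] == "main"]
        labels = set(df["gait"])
        return {g for g in REAL_GAITS if g.value in labels}

    def gait_frequency_range(self, gait: GaitLabel) -> tuple[float, float]:
        """(min, max) locomotor frequency over accepted steps of a gait."""
        df = self.accepted()
        sel = df[df["gait"] == gait.value]["frequency_hz"]
        if sel.empty:
            return (float("nan"), float("nan"))
        return float(sel.min()), float(sel.max())

    def gait_alpha_range(self, gait: GaitLabel,
                         direction: str | None = None) -> tuple[float, float]:
        df = self.accepted()
        if direction is not None:
            df = df[df["direction"] == direction]
        sel = df[df["gait"] == gait.value]["alpha"]
        if sel.empty:
            return (float("nan"), float("nan"))
        return float(sel.min()), float(sel.max())

    def hysteresis_alphas(self, phase: str = "hind_lr",
                          threshold: float = JUMP_THRESHOLD) -> np.ndarray:
        """Drive values where the up and down main runs disagree (phase
        difference further apart than ``threshold``, or different gaits)."""
        df = self.to_frame()
        main = df[df["run"] == "main"]
        up = main[main["direction"] == "up"].set_index("alpha")
        dn = main[main["direction"] == "down"].set_index("alpha")
        out = []
        for a in up.index.intersection(dn.index):
            u, d = up.loc[a], dn.loc[a]
            if not (u["accepted"] and d["accepted"]):
                continue
            if (circular_distance(u[f"pd_{phase}"], d[f"pd_{phase}"])
                    > threshold or u["gait"] != d["gait"]):
                out.append(a)
        return np.array(sorted(out))


def _sweep_run(compiled: CompiledNetwork, alphas: np.ndarray,
               state: SystemState, rng: np.random.Generator,
               per_step_s: float, noise_sd: float, rec: tuple[str, ...],
               rtol: float, atol: float, n_last: int,
               stop_on_jump: bool = False
               ) -> tuple[list[CycleSummary], list[SystemState], int]:
    """Chained per-step simulations along an alpha path.

    Returns (summaries, post-step states, index of first jump or -1).
    """
    summaries: list[CycleSummary] = []
    states: list[SystemState] = []
    jump_at = -1
    prev: CycleSummary | None = None
    for i, a in enumerate(alphas):
        traj = simulate(compiled, per_step_s, a, noise_sd=noise_sd, rng=rng,
                        initial_state=state, record=rec, rtol=rtol, atol=atol)
        state = traj.final_state
        s = summarize_cycles(traj, compiled.constants, n_last=n_last)
        summaries.append(s)
        states.append(state.copy())
        if (prev is not None and prev.has_rhythm and s.has_rhythm
                and _is_jump(prev, s)):
            jump_at = i - 1
            if stop_on_jump:
                break
        prev = s
    return summaries, states, jump_at


def _is_jump(a: CycleSummary, b: CycleSummary,
             threshold: float = JUMP_THRESHOLD) -> bool:
    for k in PHASE_KEYS:
        if k in a.phase_means and k in b.phase_means:
            if circular_distance(a.phase_means[k], b.phase_means[k]) \
                    > threshold:
                return True
    return False


def bifurcation_sweep(net: NetworkSpec | CompiledNetwork,
                      *,
                      n_points: int = 101,
                      alpha_max: float = ALPHA_MAX,
                      per_step_s: float = 10.0,
                      noise_sd: float = DEFAULT_NOISE_SD,
                      seed: int = 0,
                      directions: Sequence[str] = ("up", "down"),
                      aux_runs: bool = True,
                      max_aux_runs: int = 8,
                      n_last: int = 5,
                      rtol: float = 1e-8,
                      atol: float = 1e-8) -> SweepResult:
    """Stepwise drive sweep with state carry-over and branch tracking.

    The drive is stepped up from 0 to ``alpha_max`` and (if requested)
    back down, 10 s per step, each step starting from the final state of
    the previous one (the downward run continues from the end of the
    upward run).  At every step the circular mean and sd of the four
    normalized phase differences over the last five cycles are recorded;
    steps with all sds below 1e-3 are the accepted stable solutions.
    Whenever a phase difference jumps by more than 0.05 between adjacent
    steps, an auxiliary run in the opposite direction is launched from
    the post-jump state to trace the extent of the newly reached branch.
    """
    compiled = net if isinstance(net, CompiledNetwork) else net.compile()
    rec = _flexor_ids(compiled)
    grid = alpha_grid(n_points, alpha_max)
    rng = np.random.default_rng(seed)
    from .simulate import randomize_initial_state
    state = randomize_initial_state(compiled, rng)

    diagrams: list[BifurcationDiagram] = []
    aux_jobs: list[tuple[np.ndarray, SystemState, str]] = []

    for direction in directions:
        path = grid if direction == "up" else grid[::-1]
        summaries, states, _ = _sweep_run(
            compiled, path, state, rng, per_step_s, noise_sd, rec,
            rtol, atol, n_last)
        state = states[-1]
        diagrams.append(BifurcationDiagram(path.copy(), direction, summaries))
        # queue auxiliary opposite-direction runs at every discrete jump
        if aux_runs:
            prev = None
            for i, s in enumerate(summaries):
                if (prev is not None and prev.has_rhythm and s.has_rhythm
                        and _is_jump(prev, s)):
                    back = path[:i][::-1]
                    if len(back):
                        aux_jobs.append((back, states[i].copy(),
                                         f"aux-{direction}-{i}"))
                prev = s

    for back, st, name in aux_jobs[:max_aux_runs]:
        summaries, _, jump_at = _sweep_run(
            compiled, back, st, rng, per_step_s, noise_sd, rec,
            rtol, atol, n_last, stop_on_jump=True)
        n = len(summaries) if jump_at < 0 else jump_at + 1
        diagrams.append(BifurcationDiagram(
            back[:n], "auxiliary", summaries[:n], run=name))

    return SweepResult(diagrams=diagrams, n_points=n_points,
                       per_step_s=per_step_s, seed=seed)


def deletion_phenotype(net: NetworkSpec,
                       selector: str | Iterable[str],
                       **sweep_kwargs) -> tuple[SweepResult, set[GaitLabel]]:
    """Sweep of the network after clamping the selected populations.

    Returns the sweep and the gait inventory (set of gaits expressed at
    accepted steps)."""
    deleted = delete_populations(net, selector)
    result = bifurcation_sweep(deleted, **sweep_kwargs)
    return result, result.gait_inventory()


def noise_variability(net: NetworkSpec | CompiledNetwork,
                      alphas: Sequence[float] = (0.3, 0.6, 0.75),
                      *,
                      noise_sd: float = 1.75,
                      duration_s: float = 1000.0,
                      discard_s: float = 5.0,
                      chunk_s: float = 100.0,
                      seed: int = 0) -> dict[float, dict]:
    """Step-to-step variability of left-right coordination under noise.

    For each drive value the model runs ``duration_s`` seconds with
    strong noise; each locomotor cycle's fore and hind left-right phase
    difference is assigned to one of three equal circular bins
    (trot-appropriate / quarter-off / synchronized) and the per-bin
    percentages of cycles are reported per girdle.
    """
    compiled = net if isinstance(net, CompiledNetwork) else net.compile()
    rec = _flexor_ids(compiled)
    out: dict[float, dict] = {}
    for alpha in alphas:
        rng = np.random.default_rng(seed)
        state = None
        chunks = []
        remaining = duration_s
        while remaining > 1e-9:
            seg = min(chunk_s, remaining)
            traj = simulate(compiled, seg, alpha, noise_sd=noise_sd,
                            rng=rng, initial_state=state, record=rec)
            state = traj.final_state
            chunks.append(traj)
            remaining -= seg
        traj = concatenate(chunks)
        ev = detect_phases(traj, compiled.constants)
        pdiff = phase_differences(ev)
        keep = ev.onsets["LH"][:-1] >= discard_s * 1000.0 \
            if ev.has_rhythm else np.array([], bool)
        out[alpha] = {
            "fore": bin_percentages(pdiff.fore_lr[keep]),
            "hind": bin_percentages(pdiff.hind_lr[keep]),
            "n_cycles": int(np.count_nonzero(keep)),
        }
    return out


@dataclass
class TransitionReport:
    """Dynamics of one abrupt parameter change."""

    t_change_ms: float
    gait_before: GaitLabel
    gait_after: GaitLabel
    frequency_before: float
    frequency_after: float
    cycles_to_stabilize: int
    cycle_onsets_ms: np.ndarray        # post-change LH cycle onsets
    cycle_frequencies: np.ndarray      # instantaneous 1/period, Hz
    cycle_gaits: list[GaitLabel] = field(default_factory=list)
    transient_gaits: set[GaitLabel] = field(default_factory=set)


@dataclass(frozen=True)
class Segment:
    """One constant-parameter stretch of a transition protocol."""

    alpha: float
    duration_s: float
    extra_drive: Mapping | None = None


def transition_dynamics(net: NetworkSpec | CompiledNetwork,
                        segments: Sequence[Segment],
                        *,
                        noise_sd: float = DEFAULT_NOISE_SD,
                        seed: int = 0,
                        freq_tolerance: float = 0.05,
                        n_asymptote: int = 3) -> list[TransitionReport]:
    """Simulate a chain of abrupt parameter changes and measure how many
    cycles each takes to restabilize.

    Each boundary between segments is an abrupt change of the brainstem
    drive and/or of additional drive-independent inputs to CIN/LPN
    populations.  A change counts as restabilized at the first post-change
    cycle from which on the per-cycle gait label equals the final label
    and the instantaneous frequency stays within ``freq_tolerance`` of
    the asymptotic (last ``n_asymptote`` cycles') frequency.
    """
    compiled = net if isinstance(net, CompiledNetwork) else net.compile()
    rec = _flexor_ids(compiled)
    rng = np.random.default_rng(seed)
    state = None
    trajs = []
    boundaries = []
    t_acc = 0.0
    for seg in segments:
        traj = simulate(compiled, seg.duration_s, seg.alpha,
                        noise_sd=noise_sd, rng=rng, initial_state=state,
                        extra_drive=seg.extra_drive, record=rec)
        state = traj.final_state
        trajs.append(traj)
        t_acc += seg.duration_s * 1000.0
        boundaries.append(t_acc)
    full = concatenate(trajs)
    ev = detect_phases(full, compiled.constants)
    pdiff = phase_differences(ev)
    from .gait import classify_cycles
    labels = classify_cycles(pdiff, ev)
    onsets = ev.onsets["LH"][:-1]
    periods = ev.periods
    freqs = 1000.0 / periods

    reports = []
    for b_idx, t_change in enumerate(boundaries[:-1]):
        t_next = boundaries[b_idx + 1]
        before = onsets < t_change
        after = (onsets >= t_change) & (onsets < t_next)
        ia = np.flatnonzero(after)
        ib = np.flatnonzero(before)
        if ia.size == 0 or ib.size == 0:
            reports.append(TransitionReport(
                t_change, GaitLabel.NO_RHYTHM, GaitLabel.NO_RHYTHM,
                float("nan"), float("nan"), -1, np.array([]), np.array([])))
            continue
        # the final pre-change cycle spans the boundary (its period and
        # its partners' onsets reach past t_change): exclude it from the
        # "before" statistics where earlier cycles exist
        ib_clean = ib[:-2] if ib.size > 2 else ib
        gait_before = labels[ib_clean[-1]]
        f_before = float(np.mean(
            freqs[ib_clean[-min(n_asymptote, ib_clean.size):]]))
        # likewise the last cycles of this window span the next boundary
        # (or the end of the recording): exclude them from the "after"
        # statistics where enough cycles exist
        ia_clean = ia[:-2] if ia.size > 2 else ia
        tail = ia_clean[-min(n_asymptote, ia_clean.size):]
        f_after = float(np.mean(freqs[tail]))
        gait_after = labels[ia_clean[-1]]
        stable_from = ia_clean.size
        for j in range(ia_clean.size - 1, -1, -1):
            i = ia_clean[j]
            if (labels[i] == gait_after
                    and abs(freqs[i] - f_after) <= freq_tolerance * f_after):
                stable_from = j
            else:
                break
        transient = {labels[i] for i in ia_clean[:stable_from]} - {gait_after}
        reports.append(TransitionReport(
            t_change_ms=t_change, gait_before=gait_before,
            gait_after=gait_after, frequency_before=f_before,
            frequency_after=f_after, cycles_to_stabilize=stable_from,
            cycle_onsets_ms=onsets[after], cycle_frequencies=freqs[after],
            cycle_gaits=[labels[i] for i in ia],
            transient_gaits=transient))
    return reports


def find_oscillation_ceiling(net: NetworkSpec | CompiledNetwork,
                             *,
                             lo: float = 0.9,
                             hi: float = 1.3,
                             tol: float = 2e-3,
                             settle_s: float = 5.0,
                             run_s: float = 10.0,
                             noise_sd: float = DEFAULT_NOISE_SD,
                             seed: int = 0) -> float:
    """Largest drive value still producing rhythm, located by bisection.

    Rhythm is present when the left-hind flexor output crosses the
    flexion threshold at least twice during ``run_s`` seconds following a
    settling period.
    """
    compiled = net if isinstance(net, CompiledNetwork) else net.compile()

    def rhythmic(alpha: float, seed_offset: int) -> bool:
        rng = np.random.default_rng(seed + seed_offset)
        rec = _flexor_ids(compiled)
        first = simulate(compiled, settle_s, alpha, noise_sd=noise_sd,
                         rng=rng, record=rec)
        second = simulate(compiled, run_s, alpha, noise_sd=noise_sd, rng=rng,
                          initial_state=first.final_state, record=rec)
        return detect_phases(second, compiled.constants).has_rhythm

    if not rhythmic(lo, 0):
        raise ValueError(f"no rhythm at lower bracket alpha={lo}")
    if rhythmic(hi, 1):
        raise ValueError(f"rhythm persists at upper bracket alpha={hi}")
    k = 2
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if rhythmic(mid, k):
            lo = mid
        else:
            hi = mid
        k += 1
    return lo


@dataclass
class RobustnessReport:
    """Outcome of the weight-perturbation screen at one sigma_p."""

    sigma_p: float
    n_models: int
    inventories: list[set[GaitLabel]]
    reference: set[GaitLabel]

    @property
    def lost_flags(self) -> list[bool]:
        return [bool(self.reference - inv) for inv in self.inventories]

    @property
    def fraction_lost(self) -> float:
        flags = self.lost_flags
        return sum(flags) / len(flags) if flags else float("nan")


def _refine_missing_gait(model, window: tuple[float, float],
                         per_step_s: float, seed: int,
                         noise_sd: float) -> set[GaitLabel]:
    """Focused fine upward sweep over a drive window (used to confirm a
    suspected gait loss is real and not a coarse-grid miss)."""
    compiled = model if isinstance(model, CompiledNetwork) \
        else model.compile()
    rec = _flexor_ids(compiled)
    lo, hi = window
    rng = np.random.default_rng(seed)
    from .simulate import randomize_initial_state
    state = randomize_initial_state(compiled, rng)
    found: set[GaitLabel] = set()
    grid = np.linspace(max(0.0, lo), min(ALPHA_MAX, hi), 16)
    # settle onto the branch below the window first
    traj = simulate(compiled, per_step_s, max(0.0, lo - 0.05),
                    noise_sd=noise_sd, rng=rng, initial_state=state,
                    record=rec)
    state = traj.final_state
    for a in grid:
        traj = simulate(compiled, per_step_s, a, noise_sd=noise_sd,
                        rng=rng, initial_state=state, record=rec)
        state = traj.final_state
        s = summarize_cycles(traj, compiled.constants)
        if _accepted(s):
            found.add(s.gait)
    return found


def robustness_screen(net: NetworkSpec,
                      sigma_ps: Sequence[float] = (0.01, 0.02, 0.05, 0.10),
                      *,
                      n_models: int = 100,
                      seed: int = 0,
                      n_points: int = 41,
                      per_step_s: float = 6.0,
                      directions: Sequence[str] = ("up",),
                      reference: set[GaitLabel] | None = None,
                      refine_windows: Mapping | None = None,
                      noise_sd: float = DEFAULT_NOISE_SD
                      ) -> list[RobustnessReport]:
    """Gait-inventory robustness under random weight perturbation.

    For each sigma_p, ``n_models`` networks are drawn with every weight
    multiplied by an independent N(1, sigma_p) factor, each is swept and
    its gait inventory compared with the reference (all four gaits by
    default).  A model "loses stable solutions" when any reference gait
    is absent from its inventory.

    ``refine_windows`` maps gait labels to (alpha_lo, alpha_hi) windows
    (typically the intact network's expression range for that gait).
    When given, a gait missing from a model's coarse inventory is
    re-checked with a focused fine upward sweep over its window before
    the loss is counted — narrow expression windows (gallop, bound)
    can otherwise slip between coarse grid points.
    """
    reference = reference if reference is not None else set(REAL_GAITS)
    ss = np.random.SeedSequence(seed)
    reports = []
    for sigma_p in sigma_ps:
        inventories = []
        for child in ss.spawn(n_models):
            rng = np.random.default_rng(child)
            model = perturb_weights(net, sigma_p, rng)
            sweep_seed = int(child.generate_state(1)[0] % (2 ** 31))
            res = bifurcation_sweep(
                model, n_points=n_points, per_step_s=per_step_s,
                directions=directions, aux_runs=False, seed=sweep_seed,
                noise_sd=noise_sd)
            inventory = res.gait_inventory()
            if refine_windows:
                compiled = model.compile()
                for gait in reference - inventory:
                    if gait in refine_windows:
                        lo, hi = refine_windows[gait]
                        inventory |= _refine_missing_gait(
                            compiled, (lo - 0.03, hi + 0.03), per_step_s,
                            sweep_seed + 1, noise_sd) & {gait}
            inventories.append(inventory)
        reports.append(RobustnessReport(sigma_p, n_models, inventories,
                                        set(reference)))
    return reports


def gait_alpha_windows(result: SweepResult) -> dict[GaitLabel,
                                                    tuple[float, float]]:
    """Per-gait drive-expression windows of a sweep (for screen
    refinement)."""
    out = {}
    for gait in REAL_GAITS:
        lo, hi = result.gait_alpha_range(gait)
        if np.isfinite(lo):
            out[gait] = (lo, hi)
    return out
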