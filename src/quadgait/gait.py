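"""Locomotor observables: phase events, phase differences, circular
statistics and operational gait classification.

A rhythm generator (RG) is "in flexion" while the output f(V) of its
flexor half-center is >= 0.1 and "in extension" otherwise.  The locomotor
period is the interval between consecutive left-hind flexion onsets;
normalized phase differences are delays between extension onsets of RG
pairs divided by the period, wrapped to [0, 1).  Gaits are assigned from
the hind left-right, homolateral and diagonal phase differences using
fixed interval regions (walk additionally requires a longer extension
than flexion phase).
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import circmean as _circmean, circstd as _circstd

from .dynamics import CellConstants, output
from .simulate import Trajectory

log = logging.getLogger(__name__)

FLEXION_THRESHOLD = 0.1
LIMBS = ("LF", "RF", "LH", "RH")


class GaitLabel(str, enum.Enum):
    WALK = "walk"
    TROT = "trot"
    GALLOP = "gallop"
    BOUND = "bound"
    UNCLASSIFIED = "unclassified"
    NO_RHYTHM = "no rhythm"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass
class PhaseEvents:
    """Flexion onset/offset times (ms) per limb plus derived cycle data.

    ``onsets[limb]`` and ``offsets[limb]`` strictly alternate, beginning
    with an onset.  Periods/frequency are referenced to the left-hind
    flexor onsets.  ``has_rhythm`` is False when fewer than two left-hind
    onsets were found ("no rhythm", not an error).
    """

    onsets: dict[str, np.ndarray]
    offsets: dict[str, np.ndarray]

    @property
    def has_rhythm(self) -> bool:
        return len(self.onsets.get("LH", ())) >= 2

    @property
    def periods(self) -> np.ndarray:
        """Cycle periods (ms) between consecutive left-hind flexion onsets."""
        return np.diff(self.onsets["LH"]) if self.has_rhythm else np.array([])

    @property
    def frequency(self) -> float:
        """Mean locomotor frequency, Hz (NaN without rhythm)."""
        p = self.periods
        return 1000.0 / p.mean() if p.size else float("nan")

    def flexion_durations(self, limb: str = "LH") -> np.ndarray:
        on, off = self.onsets[limb], self.offsets[limb]
        n = min(len(on), len(off))
        if n and off[0] < on[0]:
            off = off[1:]
            n = min(len(on), len(off))
        return (off[:n] - on[:n])

    def extension_durations(self, limb: str = "LH") -> np.ndarray:
        """Durations between flexion offset (extension onset) and the next
        flexion onset."""
        on, off = self.onsets[limb], self.offsets[limb]
        if off.size and on.size and off[0] < on[0]:
            off = off[1:]
        n = min(len(off), len(on) - 1) if len(on) > 1 else 0
        return on[1:n + 1] - off[:n]


@dataclass
class PhaseDifferences:
    """Per-cycle normalized phase differences in [0, 1) (NaN = partner
    onset missing in that cycle)."""

    hind_lr: np.ndarray        # right hind - left hind
    fore_lr: np.ndarray        # right fore - left fore
    homolateral: np.ndarray    # left fore - left hind
    diagonal: np.ndarray       # right fore - left hind

    def as_dict(self) -> dict[str, np.ndarray]:
        return {"hind_lr": self.hind_lr, "fore_lr": self.fore_lr,
                "homolateral": self.homolateral, "diagonal": self.diagonal}

    @property
    def n_cycles(self) -> int:
        return len(self.hind_lr)


def _crossings(t: np.ndarray, x: np.ndarray, level: float,
               rising: bool) -> np.ndarray:
    """Times where ``x`` crosses ``level`` (linear interpolation between
    samples).  A rising crossing is x[i] < level <= x[i+1]."""
    x0, x1 = x[:-1], x[1:]
    if rising:
        mask = (x0 < level) & (x1 >= level)
    else:
        mask = (x0 >= level) & (x1 < level)
    i = np.flatnonzero(mask)
    frac = (level - x0[i]) / (x1[i] - x0[i])
    return t[i] + frac * (t[i + 1] - t[i])


def detect_phases(traj: Trajectory,
                  constants: CellConstants | None = None) -> PhaseEvents:
    """Flexion onsets/offsets of all four RGs from flexor-center outputs.

    Onsets are upward, offsets downward crossings of f(V) through 0.1,
    located by linear interpolation between the 1 ms samples.
    """
    c = constants or CellConstants()
    outputs = traj.flexor_outputs(c)
    missing = [limb for limb in LIMBS if limb not in outputs]
    if missing:
        raise ValueError(f"trajectory lacks flexor centers for {missing}")
    onsets, offsets = {}, {}
    for limb, f in outputs.items():
        onsets[limb] = _crossings(traj.t, f, FLEXION_THRESHOLD, rising=True)
        offsets[limb] = _crossings(traj.t, f, FLEXION_THRESHOLD, rising=False)
    return PhaseEvents(onsets=onsets, offsets=offsets)


def extension_onsets(ev: PhaseEvents, limb: str) -> np.ndarray:
    """Extension onsets = flexion offsets of the limb's RG."""
    return ev.offsets[limb]


def _next_onset(onsets: np.ndarray, t0: float) -> float:
    i = np.searchsorted(onsets, t0)
    return onsets[i] if i < len(onsets) else np.nan


def phase_differences(ev: PhaseEvents) -> PhaseDifferences:
    """Per-cycle normalized phase differences between extension onsets.

    Cycles are delimited by consecutive left-hind flexion onsets.  Within
    each cycle the reference is the extension onset of the second-named
    RG of a pair (left hind, or left fore for the fore pair); the delay
    to the partner's next extension onset, divided by the cycle period,
    gives the phase difference wrapped to [0, 1).  Cycles with a missing
    partner onset yield NaN and are logged.
    """
    if not ev.has_rhythm:
        return PhaseDifferences(*(np.array([]) for _ in range(4)))
    lh_on = ev.onsets["LH"]
    ext = {limb: extension_onsets(ev, limb) for limb in LIMBS}
    n = len(lh_on) - 1
    cols = {k: np.full(n, np.nan) for k in
            ("hind_lr", "fore_lr", "homolateral", "diagonal")}
    skipped = 0
    for i in range(n):
        t0, t1 = lh_on[i], lh_on[i + 1]
        T = t1 - t0
        e_lh = _next_onset(ext["LH"], t0)
        if not np.isfinite(e_lh) or e_lh >= t1:
            skipped += 1
            continue
        for key, limb in (("hind_lr", "RH"), ("homolateral", "LF"),
                          ("diagonal", "RF")):
            tp = _next_onset(ext[limb], e_lh)
            if np.isfinite(tp):
                cols[key][i] = ((tp - e_lh) / T) % 1.0
        e_lf = _next_onset(ext["LF"], e_lh)
        if np.isfinite(e_lf):
            tp = _next_onset(ext["RF"], e_lf)
            if np.isfinite(tp):
                cols["fore_lr"][i] = ((tp - e_lf) / T) % 1.0
        if np.isnan(cols["hind_lr"][i]) or np.isnan(cols["fore_lr"][i]):
            skipped += 1
    if skipped:
        log.debug("phase_differences: %d cycle(s) missing partner onsets",
                  skipped)
    return PhaseDifferences(cols["hind_lr"], cols["fore_lr"],
                            cols["homolateral"], cols["diagonal"])


def circular_mean(values: np.ndarray) -> float:
    """Circular mean of normalized phases, in cycle units [0, 1)."""
    values = np.asarray(values, float)
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise ValueError("circular_mean of empty input")
    return float(_circmean(values, high=1.0, low=0.0))


def circular_sd(values: np.ndarray) -> float:
    """Circular standard deviation sqrt(-2 ln R) in cycle units."""
    values = np.asarray(values, float)
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise ValueError("circular_sd of empty input")
    return float(_circstd(values, high=1.0, low=0.0))


def circular_stats(values: np.ndarray) -> tuple[float, float]:
    """(circular mean, circular sd) of normalized phases."""
    return circular_mean(values), circular_sd(values)


def circular_distance(a: float, b: float) -> float:
    """Shortest distance on the unit circle (cycle units, in [0, 0.5])."""
    d = abs(a - b) % 1.0
    return min(d, 1.0 - d)


def _in(x: float, lo: float, hi: float,
        lo_open: bool = False, hi_open: bool = False) -> bool:
    if lo_open and x <= lo:
        return False
    if not lo_open and x < lo:
        return False
    if hi_open and x >= hi:
        return False
    if not hi_open and x > hi:
        return False
    return True


def _is_walk(hind, homo, diag) -> bool:
    return (_in(hind, 0.25, 0.75)
            and (_in(homo, 0.1, 0.4, hi_open=True)
                 or _in(homo, 0.6, 0.9, lo_open=True))
            and (_in(diag, 0.1, 0.4, lo_open=True)
                 or _in(diag, 0.6, 0.9, hi_open=True)))


def _is_trot(hind, homo, diag) -> bool:
    return (_in(hind, 0.25, 0.75) and _in(homo, 0.25, 0.75)
            and (_in(diag, 0.0, 0.1) or _in(diag, 0.9, 1.0, hi_open=True)))


def _is_gallop(hind, homo, diag) -> bool:
    return ((_in(hind, 0.025, 0.25, lo_open=True)
             or _in(hind, 0.75, 0.975, hi_open=True))
            and _in(homo, 0.25, 0.75) and _in(diag, 0.25, 0.75))


def _is_bound(hind, homo, diag) -> bool:
    return ((_in(hind, 0.0, 0.025) or _in(hind, 0.975, 1.0, hi_open=True))
            and _in(homo, 0.25, 0.75) and _in(diag, 0.25, 0.75))


def classify_gait(hind_lr: float, homolateral: float, diagonal: float,
                  extension_longer: bool = True) -> GaitLabel:
    """Operational gait label from one cycle's phase differences.

    Regions (normalized phase differences, interval closures as fixed):

    =======  ======================  ========================  =======================
    gait     hind left-right         homolateral               diagonal
    =======  ======================  ========================  =======================
    walk     [0.25, 0.75]            [0.1, 0.4) u (0.6, 0.9]   (0.1, 0.4] u [0.6, 0.9)
    trot     [0.25, 0.75]            [0.25, 0.75]              [0, 0.1] u [0.9, 1)
    gallop   (0.025,0.25] u [0.75,0.975)  [0.25, 0.75]         [0.25, 0.75]
    bound    [0, 0.025] u [0.975, 1)      [0.25, 0.75]         [0.25, 0.75]
    =======  ======================  ========================  =======================

    Walk additionally requires a longer extension than flexion phase.
    On the measure-zero region boundaries the labels are tried in the
    order walk, trot, gallop, bound.
    """
    for x in (hind_lr, homolateral, diagonal):
        if not np.isfinite(x):
            return GaitLabel.UNCLASSIFIED
    if extension_longer and _is_walk(hind_lr, homolateral, diagonal):
        return GaitLabel.WALK
    if _is_trot(hind_lr, homolateral, diagonal):
        return GaitLabel.TROT
    if _is_gallop(hind_lr, homolateral, diagonal):
        return GaitLabel.GALLOP
    if _is_bound(hind_lr, homolateral, diagonal):
        return GaitLabel.BOUND
    return GaitLabel.UNCLASSIFIED


def classify_cycles(pd: PhaseDifferences, ev: PhaseEvents) -> list[GaitLabel]:
    """Per-cycle gait labels (cycle i uses its own phase differences and
    flexion/extension durations)."""
    flex = ev.flexion_durations("LH")
    ext = ev.extension_durations("LH")
    labels = []
    for i in range(pd.n_cycles):
        longer = bool(ext[i] > flex[i]) if (i < len(ext) and i < len(flex)) \
            else True
        labels.append(classify_gait(pd.hind_lr[i], pd.homolateral[i],
                                    pd.diagonal[i], longer))
    return labels


class TrotBin(str, enum.Enum):
    TROT = "trot-appropriate"
    QUARTER = "quarter-off"
    SYNC = "antiphase-sync"


def bin_for_trot(phase: float) -> TrotBin:
    """Assign a left-right phase difference to one of three equal arcs.

    [1/3, 2/3) is appropriate for trot (centred on alternation);
    [1/6, 1/3) u [2/3, 5/6) is a quarter-phase off; the remaining third
    (centred on 0) is synchronized/antiphase-to-trot.
    """
    x = phase % 1.0
    if 1.0 / 3.0 <= x < 2.0 / 3.0:
        return TrotBin.TROT
    if 1.0 / 6.0 <= x < 1.0 / 3.0 or 2.0 / 3.0 <= x < 5.0 / 6.0:
        return TrotBin.QUARTER
    return TrotBin.SYNC


def bin_percentages(phases: np.ndarray) -> dict[str, float]:
    """Percentage of locomotor cycles falling into each of the three
    left-right coordination bins."""
    phases = np.asarray(phases, float)
    phases = phases[np.isfinite(phases)]
    total = len(phases)
    counts = {b: 0 for b in TrotBin}
    for x in phases:
        counts[bin_for_trot(x)] += 1
    return {b.value: (100.0 * n / total if total else float("nan"))
            for b, n in counts.items()}


@dataclass
class CycleSummary:
    """Circular summary of the last cycles of a simulation step."""

    frequency: float
    phase_means: dict[str, float] = field(default_factory=dict)
    phase_sds: dict[str, float] = field(default_factory=dict)
    flexion_ms: float = float("nan")
    extension_ms: float = float("nan")
    gait: GaitLabel = GaitLabel.NO_RHYTHM
    n_cycles: int = 0

    @property
    def has_rhythm(self) -> bool:
        return self.gait is not GaitLabel.NO_RHYTHM


def summarize_cycles(traj: Trajectory,
                     constants: CellConstants | None = None,
                     n_last: int = 5) -> CycleSummary:
    """Circular means/sds of the four phase differences, frequency and
    phase durations over the last ``n_last`` complete cycles."""
    ev = detect_phases(traj, constants)
    if not ev.has_rhythm:
        return CycleSummary(frequency=float("nan"))
    pd = phase_differences(ev)
    keep = min(n_last, pd.n_cycles)
    means, sds = {}, {}
    ok = True
    for key, vals in pd.as_dict().items():
        tail = vals[-keep:]
        tail = tail[np.isfinite(tail)]
        if tail.size == 0:
            ok = False
            continue
        means[key] = circular_mean(tail)
        sds[key] = circular_sd(tail)
    periods = ev.periods[-keep:]
    flex = ev.flexion_durations("LH")[-keep:]
    ext = ev.extension_durations("LH")[-keep:]
    freq = 1000.0 / periods.mean()
    if not ok or not flex.size or not ext.size:
        return CycleSummary(frequency=freq, phase_means=means, phase_sds=sds,
                            gait=GaitLabel.UNCLASSIFIED, n_cycles=keep)
    gait = classify_gait(means["hind_lr"], means["homolateral"],
                         means["diagonal"],
                         extension_longer=ext.mean() > flex.mean())
    return CycleSummary(frequency=freq, phase_means=means, phase_sds=sds,
                        flexion_ms=float(flex.mean()),
                        extension_ms=float(ext.mean()),
                        gait=gait, n_cycles=keep)
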