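# Methods

## Model

`quadgait` implements an activity-based (non-spiking) population model of
the spinal circuits coordinating the four limbs of a quadruped.  Each of
the four cord sections (fore/hind girdle × left/right side) contains a
rhythm generator (RG) built from a flexor (RG-F) and an extensor (RG-E)
half-center.  A population is described by its average membrane potential
V (mV); its output is the piecewise-linear function

    f(V) = clip((V − V_thr)/(V_max − V_thr), 0, 1),   V_thr = −50 mV, V_max = 0 mV,

interpreted as normalized population activity.  Membrane dynamics follow

    C dV/dt = −I_NaP − I_L − I_SynE − I_SynI − I_Noise       (RG half-centers)
    C dV/dt = −I_L − I_SynE − I_SynI − I_Noise               (all other populations)

with C = 10 pF, leak I_L = g_L (V − E_L) (g_L = 4.5 nS, E_L = −62.5 mV
for RG half-centers; 2.8 nS, −60 mV otherwise).  Synaptic currents pool
weighted presynaptic outputs and tonic drives:

    I_SynE,i = g_SynE (Σ_j S(w_ji) f(V_j) + D_E,i) (V_i − E_SynE)
    I_SynI,i = g_SynI (Σ_j S(−w_ji) f(V_j) + D_I,i) (V_i − E_SynI)

with g_SynE = g_SynI = 10 nS, E_SynE = −10 mV, E_SynI = −75 mV and the
rectifier S(x) = max(x, 0), so a signed weight contributes to exactly one
of the two terms.  Drives are linear in the common brainstem-drive
parameter α: D = m α + b.

The rhythmogenic mechanism is a slowly inactivating persistent sodium
current in the RG half-centers,

    I_NaP = ḡ_NaP m∞(V) h (V − E_Na),    ḡ_NaP = 4.5 nS, E_Na = 50 mV,

with instantaneous activation m∞ (half-voltage −40 mV, slope −6 mV),
first-order inactivation h relaxing to h∞ (−45 mV, 4 mV) with voltage-
dependent time constant τ_h(V) = τ0 + (τ_max − τ0)/cosh((V + 35)/15),
τ0 = 80 ms, τ_max = 160 ms.  Under sufficient drive a half-center is a
relaxation oscillator; the extensor half-centers receive a constant
drive (b_E = 0.1) that keeps them tonically active unless inhibited, so
the network rhythm is flexor-driven and its frequency is set by the
drive to the flexor half-centers (m_E = 0.1).

## Connectome

Within a girdle, left and right RGs are coupled by four commissural
pathways: inhibitory V0D (flexor → contralateral flexor, promoting
alternation), excitatory V0V acting through a V2a relay onto an
inhibitory IniV0V target (also promoting alternation), excitatory V3
(promoting synchronization), and inhibitory CINi from the extensor
half-center to the contralateral flexor (promoting synchronization).
Between girdles, long propriospinal neurons (LPNs) provide: homolateral
excitation from each extensor half-center to the other girdle's flexor
(Shox2, both directions, with the ascending weight an order of magnitude
stronger), homolateral descending inhibition between flexors (Ini-Hom),
diagonal descending inhibition (V0D-diag) and diagonal excitation in
both directions (V0V-diag through a V2a-diag relay).  Inhibitory LPNs
exist only in the descending (cervical→lumbar) direction, which is the
model's single fore–hind asymmetry; the connectome is exactly symmetric
under the left–right swap.  The intact network has 56 populations (15
per fore section, 13 per hind) and 84 directed connections.

The brainstem drive excites the flexor half-centers and *inhibits* the
alternation-promoting commissural populations: local V0D (m_I = 0.75),
the descending diagonal V0D LPNs (m_I = 0.75) and local V0V CINs
(m_I = 0.15).  Increasing α therefore both accelerates the rhythm and
progressively shifts the left–right and diagonal balance from
alternation toward synchronization — the mechanism of the walk → trot →
gallop → bound sequence.  Drive to the diagonal V0D LPNs is required for
the walk → trot mechanism and is included although one summary of the
drive targets mentions only the local CINs; the diagonal V0V LPNs
receive no direct drive (their speed dependence is inherited through
V2a-diag).  Both choices are configurable per population.

## Numerics

The 64 state variables (56 voltages + 8 inactivation states) are
integrated with an adaptive Dormand–Prince 5(4) stepper (rtol = atol =
1e-8 by default, compiled with numba).  The Ornstein–Uhlenbeck noise
current of every population (τ = 10 ms) is pre-generated on a fixed 1 ms
grid using the exact discretization I[k+1] = a I[k] + σ √(1−a²) ξ,
a = e^(−1 ms/τ), whose stationary standard deviation is exactly σ and
whose lag-τ autocorrelation is exactly e⁻¹; the solver never steps
across a grid boundary, so the held noise value is smooth within every
step, and the state is recorded at each boundary.  Trajectories are
reproducible bit-for-bit given the network, settings and seed.  A plain
numpy implementation of the right-hand side is kept alongside the
kernel and the two are pinned to each other by a machine-precision test.

Default σ_noise is 0.005 pA — orders of magnitude below the other
currents; it only prevents the system from riding unstable trajectories
(e.g. perfectly symmetric states).  The noise-variability experiment
raises it to 1.75 pA.

Deleting a population clamps its output to zero inside the synaptic
sums; its state is still integrated.  Weight perturbations multiply
every connection weight by an independent N(1, σ_p) draw, untruncated
(at σ_p ≤ 0.1 a sign flip has negligible probability).

## Observables

A RG is in flexion while its flexor half-center's output f(V) ≥ 0.1
(crossings located by linear interpolation between the 1 ms samples, to
avoid aliasing phase estimates at high cycle rates).  The locomotor
period is the interval between consecutive left-hind flexion onsets.
Normalized phase differences (hind left–right, fore left–right,
homolateral, diagonal) are delays between extension onsets of the paired
RGs divided by the period, wrapped to [0, 1); all averaging uses
circular statistics (mean direction; sd = √(−2 ln R)).  Gaits are
assigned per cycle from fixed interval regions of the (hind L–R,
homolateral, diagonal) triple — walk, trot, gallop, bound, otherwise
unclassified — with walk additionally requiring a longer extension than
flexion phase.  The printed interval closures are kept exactly; on the
measure-zero shared boundaries the labels are tried in the order walk,
trot, gallop, bound.  Left–right coordination is also summarized into
three equal circular arcs (alternation-appropriate, quarter-off,
synchronized) centred on 0.5, 0.25/0.75 and 0.

## Protocols

*Drive sweep.*  α is stepped from 0 to 1.05 and back on an equally
spaced grid (canonical 1001 points, step 0.00105; coarse desk-scale
101 points), 10 s per step, each step starting from the previous step's
final state.  A step is an accepted stable solution when the circular sd
of each of the four phase differences over the last five cycles is
below 1e-3.  When any phase difference jumps by more than 0.05 between
adjacent steps, an auxiliary run is launched from the post-jump state
stepping in the opposite direction, to trace the extent of the newly
reached branch; it stops at its own first jump.  Disagreement between
the up and down runs at the same α marks bi-/multistability
(hysteresis).  The 0.05 jump threshold is a design choice: small enough
to catch branch switches, large enough to ignore smooth drift.

*Deletions.*  Selectors expand genetic classes over sections ("all V0V"
= V0V CINs + V0V-diag LPNs; "all V2a" = V2a + V2a-diag;
"cervical-to-lumbar LPNs" = fore Ini-Hom, Sh2-Hom, V0D-diag, V0V-diag).
The gait inventory of a sweep is the set of gaits over accepted steps;
it can be restricted to the main up/down runs, which is what the
deletion phenotypes are compared on (auxiliary branch runs can uncover
additional coexisting attractors; see Limitations).

*Noise variability.*  σ_noise = 1.75 pA at α ∈ {0.3, 0.6, 0.75};
canonical duration 1000 s (the bundled tests use 100 s), first 5 s
discarded; per-cycle fore and hind left–right phases are binned into the
three arcs and reported as percentages of cycles.

*Transitions.*  A protocol is a chain of constant-parameter segments
(drive value and optional additive per-population drives); each boundary
is an abrupt change.  A change counts as restabilized at the first
post-change cycle from which the per-cycle gait label equals the final
label and the instantaneous frequency stays within 5% of the asymptotic
value.  The final pre-change cycle is excluded from "before" statistics
because its period and partner onsets reach past the boundary.  Low-
drive walk is always entered through a small drive staircase from α = 0
(10 s per stage), mirroring the sweep; a cold start directly at
α = 0.02 can land on a coexisting 2:1 stepping attractor (three limbs at
2 Hz, one fore limb double-stepping) that the staircase avoids.
Gallop starts use α = 0.95, inside this implementation's monostable
gallop band (the trot/gallop bistable band here is α ≈ 0.84–0.92, so a
cold start at 0.85 can settle into trot).

*Robustness screen.*  For each σ_p, models are drawn by perturbing all
84 weights and each is swept; a model "loses stable solutions" when its
gait inventory misses any gait of the intact reference.  The canonical
screen uses 100 models per σ_p and full sweeps; the bundled test runs a
scaled screen (25 models per σ_p ∈ {0.02, 0.05, 0.10}, upward-only
41-point grid, 6 s per step) — the upward pass already expresses all
four gaits, so the inventory does not need the downward pass.  Because
the gallop and bound expression windows are only a few coarse grid
steps wide, a gait missing from a coarse inventory is re-checked with a
focused fine upward sweep over that gait's intact expression window
before the loss is counted; only confirmed absences count.  The loss
fractions are stochastic; the scaled screen asserts zero loss at
σ_p ≤ 0.02 and monotone growth with σ_p rather than exact percentages.

## Problem sizes used by the bundled tests and acceptance script

Coarse 101-point bidirectional sweeps (10 s per step) for the intact
network and each deletion variant; 100 s noise runs; 25-model scaled
robustness screen; bisection of the oscillation ceiling with 5 s settle
+ 10 s test per candidate.  These sizes were chosen so the whole suite
reproduces every phenomenon on a single CPU in well under half an hour;
the canonical full-resolution protocols remain available through the API
and CLI.

## Known limitations

- No biomechanics, afferent feedback, motoneuron or pattern-formation
  layers: coordination is purely central, and "gaits" are phase
  relations of RG activity, not footfalls.
- Quantitative frequencies at the top of the drive range run ~5–10%
  below the published description of the original implementation
  (e.g. ≈11.1 Hz rather than 12 Hz at α = 1.05, bound onset ≈10.7 Hz
  rather than 11 Hz); band boundaries and all qualitative structure
  (gait order, hysteresis, deletion phenotypes, noise effects) match.
- This implementation has a few coexisting attractors not described for
  the original: the 2:1 stepping state near α = 0.02 reached from some
  cold starts, and a stable asymmetric branch at α ≈ 0.09–0.11 after
  V0V deletion (labeled trot by the interval regions) reached only
  through auxiliary branch tracing.  Whether the original possesses
  them is not determinable from its published description.
- The drive-independent manipulation "excite cervical local V0V CINs
  during fast gallop" does not reproduce the described fore-limb
  quarter-lag shift here: in this implementation the same input pushes
  the whole network to left-right synchronization (bound).  The two
  drive-independent switches that are described quantitatively
  (trot → bound by V0V inhibition, gallop → trot by V0V excitation) do
  reproduce, at nearly constant frequency.
- Circular sds below 1e-3 over five cycles accept a state as stable;
  very slow drifts can momentarily pass this gate (as they would in any
  forward-simulation stability assessment).
- Operational bound is fragile under weight perturbation here: the
  bound region requires the hind left-right phase within 0.025 of
  synchronization, and any weight asymmetry unfolds the
  gallop-to-bound pitchfork so the phase approaches synchronization
  without necessarily crossing that margin before the top of the drive
  range.  In this implementation even 2% weight jitter leaves a
  substantial fraction of models settled at hind phases of 0.92-0.97 at
  α = 1.05 (gallop, not bound) — confirmed by fine sweeps and long
  holds, not a grid artifact — whereas the original implementation is
  described as retaining all regimes at that perturbation level.  The
  screen's loss fractions are therefore higher here at every σ_p.
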