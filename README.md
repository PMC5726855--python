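# quadgait

A computational model of the spinal circuits that coordinate the four
limbs of a quadruped (mouse-scale parameters), for computational
neuroscientists studying locomotor gait control.

Each limb is driven by its own rhythm generator (RG): a flexor and an
extensor half-center whose rhythm arises from a slowly inactivating
persistent sodium current (I_NaP).  The four RGs are coupled by
commissural interneurons (V0D, V0V via a V2a relay, V3, CINi) within
each girdle and by homolateral and diagonal long propriospinal neurons
(Shox2, Ini-Hom, V0D-diag, V0V-diag) between the cervical and lumbar
girdles.  A single brainstem-drive parameter α excites the flexor
half-centers (setting cadence) and inhibits the alternation-promoting
commissural populations, so that increasing α reproduces the
speed-dependent gait sequence walk → trot → gallop → bound, with
hysteresis at the trot/gallop transition.  Populations are
activity-based (non-spiking) units:

    C dV/dt = −I_NaP − I_L − I_SynE − I_SynI − I_Noise,
    f(V) = clip((V − V_thr)/(V_max − V_thr), 0, 1),

with I_SynE,i = g_SynE (Σ_j S(w_ji) f(V_j) + D_E,i)(V_i − E_SynE) and the
analogous inhibitory term; D = m α + b.  See `docs/methods.md` for the
full model description, numerical choices and limitations.

The package provides the network builder (with deletions and weight
perturbations), a fast adaptive ODE integrator with seeded
Ornstein–Uhlenbeck noise, gait analysis (phase events, circular
statistics, operational gait classification), and the experiment
protocols: bifurcation sweeps with hysteresis detection, deletion
phenotyping, noise-driven variability, transition dynamics and a weight
robustness screen.

## A first simulation

```python
import quadgait as qg

net = qg.build_intact_network()          # 56 populations, 84 connections
traj = qg.simulate(net, duration_s=10.0, alpha=0.4, seed=1)
s = qg.summarize_cycles(traj, net.constants)
print(f"gait: {s.gait.value}")
print(f"frequency: {s.frequency:.2f} Hz")
for k, v in s.phase_means.items():
    print(f"{k:12s} {v:.3f}")
```

prints

```
gait: trot
frequency: 5.36 Hz
hind_lr      0.500
fore_lr      0.500
homolateral  0.514
diagonal     0.014
```

At α = 0.4 the model steps at 5.4 Hz in trot: both left–right phase
differences are exactly 0.5 (strict alternation), the diagonal pairs are
nearly synchronous (diagonal ≈ 0), and the homolateral pair alternates.
Lowering α toward 0.02 gives a 2 Hz lateral-sequence walk (homolateral
≈ 0.25, diagonal ≈ 0.75); raising it past ≈0.93 gives gallop and, above
≈0.99, bound.

The same protocols are available from the shell:

```
quadgait run --alpha 0.4 --duration 10 --seed 1 --out out/
quadgait bifurcate --coarse --seed 1 --out sweep/ --plot
quadgait delete --select "all V0V" --coarse --seed 1 --out v0v/
quadgait noise --alphas 0.3,0.6,0.75 --duration 100 --out noise.json
quadgait robustness --sigmas 0.02,0.05 --models 25 --out robust.json
```

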