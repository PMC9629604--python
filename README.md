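# jakstat

Stochastic modeling and analysis of the type-I interferon (IFN-alpha)
response through the JAK-STAT signaling pathway, at single-cell resolution.

## The scientific problem

When a population of genetically identical cells is stimulated with
IFN-alpha, the induction of interferon-stimulated genes (ISGs) such as MxA
and IFIT1 is strikingly heterogeneous: flow cytometry shows broad,
unimodal fluorescence distributions that shift with dose and time rather
than splitting into responder/non-responder subpopulations. This package
is for systems biologists who want to ask *where that variability comes
from*: how much is intrinsic (the randomness of discrete reaction events
along IFN → receptor → STAT phosphorylation → ISGF3 → transcription) and
how much is extrinsic (cell-to-cell differences in protein copy numbers),
and how robust the transmitted signal is to both and to parameter
perturbations.

At its core is a mass-action reaction network of 42 species in two
compartments and 62 reactions — receptor activation with SOCS negative
feedback, STAT1/STAT2 phosphorylation, ISGF3 assembly and shuttling,
constitutive STAT2-IRF9 complexes driving basal ISG expression, and
two-state promoter modules with competing transcription factors for the
four ISGs (irf9, socs, mxa, ifit1) — simulated exactly (Gillespie SSA) or
with adaptive tau-leaping. On top of the simulator sit the analyses:

* **extrinsic noise** — initial conditions drawn from N(mu, (sigma mu)^2),
  sigma in {0, 0.3, 0.6}; variability maps of the modified coefficient of
  variation cv = sd/(mean + 0.1); response conservation measured by the
  two-sample Kolmogorov distance D_KS = sup_x |F_a(x) − F_b(x)| between
  readout distributions;
* **distribution fitting** — empirical CDFs of single-cell snapshots, a
  KS-distance objective over time points, a first-moment (mean-field ODE)
  pre-screen, and a real-coded genetic algorithm in log10 parameter space;
* **parameter robustness** — every rate constant halved and doubled, the
  effect on MxA/IFIT1 scored by KS distance and relative mean change;
* **synthetic data** — a generator emulating the flow-cytometry snapshots
  (log-normal measurement noise, dose/time panels) and immunoblot-style
  population time courses (18% error), with known ground truth, so the
  whole pipeline is testable end to end.

See `docs/methods.md` for the model, conventions and design decisions.

## Worked example

Simulate 200 cells stimulated with 250 IU/mL IFN (5,000 molecules), with
and without moderate extrinsic noise, and quantify the response:

```python
import numpy as np
from jakstat import (
    build_canonical_model, ifn_units_to_molecules, run_ensemble,
    InitialConditionSampler, response_conservation, modified_cv,
)

net = build_canonical_model(ifn_molecules=ifn_units_to_molecules(250.0))
grid = np.linspace(0.0, 1920.0, 33)          # 32 h, hourly recording
intrinsic = run_ensemble(net, n_reps=200, t_grid=grid, master_seed=1,
                         sampler=InitialConditionSampler(sigma=0.0))
extrinsic = run_ensemble(net, n_reps=200, t_grid=grid, master_seed=2,
                         sampler=InitialConditionSampler(sigma=0.3))

mxa = intrinsic.marginal("MxA", 1920.0)       # copies/cell at 32 h
print(f"MxA at 32 h: {mxa.mean():.0f} +- {mxa.std():.0f} copies "
      f"({mxa.mean()/1582:.1f}-fold over the unstimulated level)")
rc = intrinsic.species_matrix("RC")
print(f"receptor complex RC: mean {rc.mean():.2f} copies, "
      f"time-averaged modified CV {np.mean(rc.std(0)/(rc.mean(0)+0.1)):.2f}")
print(response_conservation(extrinsic, intrinsic, "MxA")
      .round(3).to_string(index=False))
```

prints

```
MxA at 32 h: 8619 +- 2414 copies (5.4-fold over the unstimulated level)
receptor complex RC: mean 0.30 copies, time-averaged modified CV 1.30
 sigma  time_h species    ks
   0.3     8.0     MxA 0.150
   0.3    12.0     MxA 0.085
   0.3    16.0     MxA 0.080
   0.3    20.0     MxA 0.055
   0.3    32.0     MxA 0.080
```

Reading: stimulated cells end near a 5.4-fold MxA induction with a wide
single-cell spread; the short-lived receptor complex hovers below one copy
per cell yet is the noisiest species in the pathway; and adding 30%
extrinsic spread to the initial copy numbers moves the MxA distribution by
a Kolmogorov distance of roughly 0.1 or less at the measured times — the
pathway transmits the signal robustly (at 200 cells per ensemble these KS
values carry a two-sample sampling floor of ~0.14, which dominates the 8-h
entry; the packaged analyses use 600 repetitions).

The same analyses are scriptable from the shell (`jakstat simulate`,
`jakstat noise`, `jakstat fit`, `jakstat robustness`, `jakstat synth`);
every run writes a JSON manifest from which the artifact can be reproduced
byte for byte.

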