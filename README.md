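# morphotrack

Single-particle-tracking analysis and agent-based simulation of morphogen
dispersal in the extracellular space of embryonic tissue.

Secreted signaling molecules (morphogens) such as the Nodal/Lefty
activator–inhibitor pair spread through a developing embryo by *hindered
diffusion*: fast Brownian motion interrupted by the geometry of the
extracellular space — narrow cell–cell interfaces and larger cavities where
several cells meet — and by transient binding to cell-surface receptors.
Single-molecule imaging makes these processes measurable: per-frame
localizations are linked into tracks, and the statistics of the tracks
(jump distances, turning angles, mean squared displacements, binding
durations) report diffusion coefficients, bound fractions and residence
times. `morphotrack` implements that analysis chain, the agent-based
simulator used to interpret it, and synthetic-data generators with known
ground truth so every estimator can be validated by parameter recovery.

The package is a library: import it from Python; the `examples/` scripts
are short narrative entry points, one per capability.

## What's inside

| module | contents |
| --- | --- |
| `morphotrack.geometry` | binary extracellular masks, η (extracellular fraction), width morphing in 20 nm steps, receptor placement, tissue synthesis, interface/cavity classification |
| `morphotrack.simulator` | lattice random walk with receptor binding; jump law f(r) = r/(2Ddt)·exp(−r²/4Ddt); localization-density ratios ρc/ρi; the (σ, τ, η) parameter screen |
| `morphotrack.tracking` | nearest-neighbour linking with gap bridging, region assignment, TALM maps, tracking-radius prediction |
| `morphotrack.diffusion` | K-component Brownian mixture fits of jump-distance CDFs with tracking-radius cut-off, ΔAIC model selection, bootstrap errors |
| `morphotrack.angles_msd` | jump-angle distributions, fold anisotropy f180/0, angle-to-border, MSD fits (MSD = 4Dτ + c) |
| `morphotrack.kinetics` | survival-time distributions from time-lapse imaging; inversion into a 40-rate dissociation spectrum with a shared per-frame photobleaching probability; event↔state spectra; cluster summaries and resampling envelopes |
| `morphotrack.density` | per-movie cavity/interface spot-density ratios and cohort summaries |
| `morphotrack.synthetic` | generators for jump samples, time-lapse binding durations and detection movies, all seeded and carrying truth records |

## Worked example

Recover a bound-state spectrum from synthetic time-lapse data
(`examples/binding_spectrum.py`):

```text
events observed: 5182 (censored fraction 0.0%)
estimated bleaching per illuminated frame: 0.101 (truth 0.100)
slow cluster: residence time = 16.6 s (truth 16.2 s), state fraction = 53.8% (truth 50.0%)
resampling s.d.: residence +/- 2.2 s, fraction +/- 2.1 points
a single 10,000-event experiment carries ~25% uncertainty on the slow residence time; scripts/acceptance.py medians over replicates.
```

Half the bound molecules were given a 16.2 s residence time; observed
through four illumination conditions (11.7 ms – 1006 ms frame cycles) with
10% photobleaching per illuminated frame, the inversion separates true
unbinding from bleaching and returns the long-lived cluster's residence
time and state share with the quoted resampling spread.

Simulate dispersal in a synthetic tissue (`examples/simulate_tissue.py`):

```text
geometry: 5196 x 5196 px at 10 nm, eta = 8.0%
receptors: 2713 at sigma = 5 per um of membrane
tau =    0 s: density ratio rho_c/rho_i = 2.78, bound fraction = 0.00
tau =   16 s: density ratio rho_c/rho_i = 0.25, bound fraction = 0.85
ratio > 1 means accumulation in cavities (pure hindered diffusion); binding shifts weight toward interfaces.
```

Without binding, tissue geometry alone concentrates molecules in
extracellular cavities; strong receptor binding retains them at the narrow
cell–cell interfaces and inverts the ratio.

The other examples cover track linking and TALM maps
(`track_and_map.py`), jump-distance mixture fitting with AIC selection
(`jump_distance_fit.py`) and density-ratio cohorts (`density_ratios.py`).

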