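# etcomplex

Single-molecule analysis of transient electron-transfer (ET) complexes:
how the soluble cytochrome *c*₂ docks onto the reaction-center–light-
harvesting (RC-LH1) complex of purple photosynthetic bacteria. The package
implements the two computational halves of that problem:

1. **Force spectroscopy (SMFS/PF-QNM).** Retract force–distance curves are
   screened for unbinding events; rupture forces form a bimodal histogram
   that is deconvolved into a low-force component (the electrostatically
   steered *encounter complex*) and a high-force component (the productive
   ET complex). The histogram is probability-normalized, so its total area
   is the *cumulative interaction probability*
   `P = 100 · (event-bearing curves) / (complexes imaged)` and each fitted
   Gaussian's area `A·σ·√(2π)/Δ` is that component's probability. Because
   raw AFM data are not deposited, a tested synthetic generator
   (worm-like-chain tether, two-component Gaussian rupture-force mixture,
   baseline noise, nonspecific adhesion) reproduces each experimental
   condition, and the pipeline must recover the condition parameters blind.
2. **Rigid-body Brownian dynamics.** The cytochrome diffuses as a rigid
   body (Kirkwood bead hydrodynamics, Stokes–Einstein friction) over
   precomputed receptor grids — Debye–Hückel electrostatics plus
   three-category (H / O,N / C,S) Lennard-Jones potentials at 1 Å spacing
   with Gaussian smoothing — using an overdamped Ermak–McCammon propagator
   at a 100 fs step. Trajectories reduce to hysteretic contact kinetics
   (bound < 7 Å, released > 16 Å), proximal/distal binding-pose clusters,
   occupancy-based dissociation constants `KD = (1−p)/p · 1/(N_A V)`, and
   steered-pulling energy profiles with intermediate-state detection.

For whom: people analyzing single-molecule force spectroscopy of
protein–protein unbinding, and people prototyping grid-based Brownian
dynamics of protein association, who want a small, fully tested, pure-
Python reference implementation.

## Worked example

```bash
etcomplex simulate-curves --preset WT_10mM_oxred --n 2000 --seed 7 --out bundle/
etcomplex analyze-curves bundle/ --out events.tsv
etcomplex deconvolve events.tsv --n-complexes 2000 --out fit.json
```

which prints

```
wrote 2000 curves for WT_10mM_oxred to bundle/
897 events; cumulative interaction probability 32.2%
peaks at 158 pN / 331 pN; cumulative 32.2%
```

Reading: of 2000 imaged wild-type RC-LH1 complexes at 10 mM NaCl
(oxidized RC, reduced cytochrome), 32.2% of curves showed a specific
unbinding event (the condition was generated at 34%; binomial error ~1
point), and the two-Gaussian deconvolution put the encounter and
ET-complex components at 158 and 331 pN — recovering the 154/332 pN the
condition was built from. The same
library surface is importable (`etcomplex.workflows.smfs_condition_summary`),
and `fit.json` carries peak positions, widths, and per-component
probabilities.

The numbered drivers under `analysis/` run the larger stories and write
tables to `results/`: `01` a demonstration curve bundle, `02` blind
recovery across all 21 packaged conditions (peaks within a few pN,
probabilities within ~1 point, loading-rate mode ≈ 2.4 × 10⁶ pN/s), `03`
the two-site toy-receptor BD study (both pose clusters found;
KD proximal 5.7 mM < KD distal 18.9 mM in the toy volume), and `04` the
steered pull over two engineered wells (states detected at 8.6 and 39.7 Å
against wells at 10 and 38 Å).

## Layout

```
src/etcomplex/      synthetic_smfs, curve_analysis, force_deconvolution,
                    structure_props, grid_potentials, rigid_body_bd,
                    binding_analysis, workflows, toys, io, cli
analysis/           numbered narrative drivers (01..04)
tests/              pytest suite incl. acceptance-level checks
docs/methods.md     models, parameters, design choices, limitations
```
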