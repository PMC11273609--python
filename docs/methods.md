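# Methods

`etcomplex` models two complementary single-molecule views of how a small
soluble electron-donor cytochrome (cyt *c*₂) finds and binds its membrane
receptor, the reaction-center–light-harvesting (RC-LH1) complex: the
force-spectroscopy view (rupture of preformed complexes under load) and the
diffusional view (rigid-body Brownian dynamics over precomputed receptor
potentials). This note documents the models, the parameters that matter,
and the choices made where the design was open.

## 1. Synthetic force-spectroscopy data

Raw AFM affinity-mapping data are not deposited anywhere we can read them
from, so the package ships a generator that emulates PeakForce-QNM retract
curves with the statistical structure the downstream analysis assumes. Each
curve is Gaussian baseline noise plus, with per-condition probability
`p_event`, a worm-like-chain (WLC) tether stretch that terminates in a
one-sample force drop, plus, with probability `p_nonspecific` (default
0.10), a short adhesion spike below 5 nm separation.

**Rupture forces** are drawn from a two-component Gaussian mixture: the
low-force component is interpreted as the electrostatically steered
encounter complex, the high-force component as the productive
electron-transfer complex. Peak positions and cumulative probabilities per
condition (construct × NaCl concentration × redox pair) are taken from the
study's printed values: e.g. wild type at 10 mM, ox/red: 154 and 332 pN at
34% cumulative probability; 26% at 200 mM; 173/370 pN for the fully
oxidized pair; 124/247 pN for the RC with no LH1 ring; 24% for the
D(M184)K charge-reversal mutant.

Values the experiment reports only graphically or not at all are package
defaults, chosen once and fixed:

* component weights `w_low` (0.45 for WT at 10 mM, decreasing with salt and
  on oxidation, lower for D(M184)K, slightly higher for the
  higher-affinity mutants) — only the qualitative trends are published;
* component widths σ_low = 30 pN, σ_high = 42 pN, consistent with the
  ±19/±25 pN spreads reported for the same system previously;
* RC-only cumulative probability 30% (not printed);
* rupture offset uniform in 10–20 nm, matching the reported tether offset.

**Tether model.** WLC interpolation formula, persistence length 0.38 nm
(PEG), nominal contour 13 nm (9.5 nm spacer plus protein-height
allowance). For each event the effective contour is set so the WLC force
reaches the drawn rupture force exactly at the drawn offset; this keeps
rupture force and offset independently controllable.

**Acquisition defaults** follow the instrument regime: spring constant
0.15 N/m (reported range 0.087–0.262), modulation amplitude 25 nm (range
20–25), 512 samples per curve (digitization unstated; uniform in
separation), baseline noise 8 pN. The retract velocity (5.8 µm/s) is the
one free acquisition parameter; it was calibrated once so that the
pipeline's most probable loading rate — WLC slope at rupture × velocity —
sits at the reported 2.5 × 10⁶ pN/s, and then frozen.

## 2. Rupture detection and deconvolution

The detector estimates the baseline as the median of the outer 20% of the
retract trace and its noise as 1.4826 × MAD, making detection equivariant
under force offsets. An event is a sample that exceeds the baseline by
`force_threshold_multiple` (default 5) noise SDs *and* drops by the same
threshold within one sample. Event force is peak minus baseline; the
loading rate is the local quadratic force-vs-separation slope at the peak
(8-sample window — a straight line systematically underestimates the
stiffening tether) times the retract velocity. Events are specific iff
their separation lies in the closed window 8–25 nm, slightly wider than
the ~10–20 nm tether offset to tolerate linker polydispersity. A curve
with several events counts once toward the cumulative interaction
probability (events ÷ complexes imaged, in percent), and only its
largest-separation specific event enters the force histogram.

Histograms are probability-normalized: bin heights are scaled so their sum
equals the cumulative probability, hence fitted Gaussian areas are
component probabilities directly. The deconvolution is nonlinear least
squares of k ∈ {1, 2} Gaussians on bin heights (default bin width 20 pN),
with weighted-quantile initialization plus five jittered restarts at a
fixed seed; components are ordered by mean, "low" always the smaller. An
expectation–maximization fit on raw forces is used in the tests as an
independent cross-check, never as the implementation. A BIC rule
(`select_k`) guards against fitting two components to unimodal data; a fit
whose components overlap within one SD or whose amplitude ratio is below
0.1 is flagged degenerate.

At n = 2000 curves the pipeline recovers peak positions to a few pN and
cumulative probabilities to about one percentage point (binomial error);
the residual peak-position scatter is dominated by the 8 pN peak-sample
noise and by the finite event count per component.

## 3. Rigid-body model and hydrodynamics

Mass, center of mass and inertia tensor come directly from atomic
coordinates (PDB input; per-element masses from a packaged table). The
diffusion tensor uses a Kirkwood bead approximation rather than a Hydropro
port: solvent-exposed atoms (rolling-probe occupancy test, probe 1.4 Å,
1 Å grid) become Stokes beads of radius 2.3 Å (1.2 Å atomic + 1.1 Å
hydration, the Hydropro-style default), and

D_t = kBT/(6πηaN) + kBT/(8πηN²) Σ_{i≠j} 1/r_ij.

The translational tensor is taken isotropic and the rotational coefficient
comes from the sphere of equivalent translational mobility — adequate
because the propagator only needs a consistent positive mobility, and the
source method itself keeps only diagonal components. The single-sphere
Stokes–Einstein limit is exact and anchors the tests. Friction is
kBT/D componentwise, so fluctuation–dissipation holds by construction.

## 4. Receptor grids

The receptor is summarized by an electrostatic grid (energy of a unit
positive probe charge) and one Lennard-Jones grid per mobile-atom
category. Mobile atoms are clustered into three categories — H, O+N, C+S —
each carrying the arithmetic mean Rmin/2 and ε of its members, as in the
source method. Grids default to 1 Å spacing, receptor bounding box +30 Å
margin, and are smoothed with a 1 Å Gaussian filter.

Open choices, decided as follows:

* **Electrostatics**: Debye–Hückel screened Coulomb with ε_r = 78.5 and
  the Debye length from the ionic strength (30.4 Å at 10 mM, 4.8 Å at
  250 mM). Analytic, salinity-aware, and desk-scale; no Poisson–Boltzmann
  solver, no membrane dielectric. Node distances are floored at half a
  spacing so values stay finite inside atoms, where the LJ cap dominates
  anyway.
* **LJ grids**: direct pairwise 12-6 summation (Lorentz–Berthelot
  combination) instead of implicit-ligand-sampling free-energy maps, which
  require thermal sampling; values are capped at +100 kJ/mol so clash
  regions stay finite.
* **Evaluation**: trilinear interpolation with the analytic gradient of
  the trilinear form; grid energies converge monotonically to the direct
  pairwise sum as the spacing is halved (tested at 2/1/0.5 Å).

## 5. Brownian propagation

The propagator is an overdamped Ermak–McCammon rigid-body scheme at a
100 fs step: Δx = F/γ·Δt + √(2kBT Δt/γ)·ξ per axis, with the rotational
analogue applied in the principal body frame and the quaternion
renormalized each step. The source describes a "symplectic integrator" but
specifies friction rather than inertial dynamics; at protein-scale
friction and a 100 fs step the overdamped limit is the standard choice,
and an inertial mode is out of scope. Setting the propagation temperature
to zero recovers deterministic steepest descent (test hook). A harmonic
wall (10 kJ/mol/Å²) at the grid margin confines the particle — the
original system is confined by its periodic membrane patch instead. Frames
are recorded every 1 ns by default; every run is reproducible from its
seed.

Correctness is established by closed-form statistical mechanics rather
than trajectories to compare against: free-diffusion MSD = 6Dt (5%),
harmonic-well variance = kBT/k (5%), orientational correlation decay
exp(−2D_r t) (10%), and a χ² match of the visited-state histogram to
exp(−U/kBT) in a 1-D double well (500 000 steps, subsampled every 250
steps to decorrelate).

**Steered pulling** drags the COM with a harmonic restraint moving at
constant velocity (default 0.05 Å/ns as in the source; the toy analyses
use faster pulls) and records interaction energy vs distance to a site,
with orientation free. This grid-based mode reproduces the *shape* of
pulling experiments — troughs at engineered minima, intermediate-state
detection — and explicitly not all-atom energy magnitudes.

## 6. Binding analysis

Contact uses the hysteretic criterion of the source: bound when any
heavy-atom pair comes within 7 Å, released only when no pair is within
16 Å, which suppresses flicker at the boundary. Bound poses are clustered
by single linkage on COM positions (8 Å cut; the source's criterion is
unstated) and labelled proximal/distal by the nearest annotated site
marker; clusters with mean heavy-atom interface distance beyond 10 Å are
discarded, mirroring the 10 Å pose filter (the source does not say whether
that filter is atom–surface or COM–surface distance; heavy-atom minimum is
used here). Site affinity is estimated from single-molecule occupancy,
KD = (1−p)/p · 1/(N_A·V), with a percentile bootstrap over replicas — an
intentional replacement for the external Prodigy regression, which is a
separately published model. Absolute µM affinities of the real complex are
therefore *not* reproduction targets; the package reproduces the ordering
(proximal ≫ distal affinity) on toy fixtures.

## 7. Toy fixtures and what they do (not) show

`etcomplex.toys` builds synthetic bead models: a 7-bead mobile body with a
central +2e charge, and flat bead receptors carrying one or two charged
surface wells. The two-site receptor places the strong (proximal) and weak
(distal) wells on pads separated by a surface gap wider than the contact
threshold, so site exchange requires genuine unbinding — as when crossing
from the RC core to the antenna ring. The desk-scale BD study (6 replicas
× 4 ns, which at toy diffusivities covers many capture/escape events)
shows binding, escape and re-binding and yields KD(proximal) < KD(distal).

Passing tests on these fixtures demonstrate that the machinery —
generation, detection, deconvolution, propagation, contact kinetics,
clustering, occupancy affinity — is correct and internally consistent.
They do not demonstrate anything about real atomic structures: no
conformational flexibility, no membrane, no explicit solvent, no
double-interaction events, colored instrument noise, or loading-rate
spectra across decades.

## 8. Problem sizes

Defaults used by the analyses and tests: 2000 curves per condition
(matching the binomial error the printed probabilities imply), 512 samples
per curve; BD property checks use 10³–10⁵ step budgets per replica and the
two-well study 6 replicas × 4 ns at a 100 fs step. These sizes give
statistical errors comfortably inside every tolerance asserted, while the
full suite remains a desk-scale computation.
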