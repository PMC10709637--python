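# Methods

This note documents the models implemented in scramkit, the parameter
defaults and why they were chosen, what the synthetic-data generators do and
do not emulate, and the numerical choices that matter for reproducing
results.

## Assay models

All fluorescence readouts are normalized to the pre-addition baseline
(mean of all samples before reagent addition; at least three are required)
and read out 350 s after addition by linear interpolation.

**Dithionite (channel) assay.** Dithionite is membrane-impermeant: in a
protein-free vesicle it bleaches only outer-leaflet NBD probe, while a
vesicle carrying a channel is bleached completely. The synthetic trace for
a population with channel-active fraction `f_pore` decays from 1 to

    plateau = 1 − outer − f_pore·(1 − outer − floor)

where `outer` is the outer-leaflet probe fraction and `floor` the
refractory-vesicle floor (`f_refractory/2`; default 0 — the refractory
fraction is a recognised nuisance term but no canonical value exists, so it
is exposed as a parameter rather than defaulted on).

**BSA back-extraction (scramblase) assay.** Fatty-acid-free BSA extracts
outer-leaflet probe, which then fluoresces at the quench factor φ relative
to its membrane value. A scramblase-active vesicle keeps replenishing its
outer leaflet, so its entire probe pool ends up extracted. The protein-free
plateau is `1 − outer·(1 − φ)` (a 30% drop at outer = 0.5, φ = 0.4); the
fully scrambled plateau is `φ` (a 60% drop). The population plateau
interpolates linearly in the scramblase-active fraction `f_scr`. Two decay
phases are generated: a fast one (outer-leaflet extraction, default
half-time 7 s) and a slow one (transbilayer replenishment, default 50 s).

**Phase-count selection.** Traces are fitted with one- and two-phase
exponential decays (lmfit, Levenberg–Marquardt); the two-phase model is
kept only when the extra-sum-of-squares F-test rejects the one-phase model
at α = 0.05. α is a convention, not a measured quantity.

**Which protein-free readout feeds φ.** An idealised protein-free vesicle
bleaches 50% of its probe; the geometric expectation for a 150-nm vesicle
with a 5-nm bilayer is 53.4%. `compute_phi` takes the dithionite readout as
an explicit argument so either convention can be used; worked examples use
the idealised 0.50, which reproduces φ = 0.4 from the paired BSA readout of
0.70.

**Activity fractions.** `f = (F_L − F_P)/(F_L − F_Min)` with the BSA floor
derived from the dithionite floor and φ. Noise can push f above 1; such
values are clipped to 1 with a warning (they carry no extra information
about the vesicle population). `F_L ≤ F_Min` leaves no assay window and is
an error, not a clip.

## Poisson reconstitution statistics

Functional units distribute over vesicles as a Poisson process with mean
`PPR*/τ`. The occupancy curve is fitted unweighted, constrained through the
origin — a vesicle with no protein cannot show channel activity, so a
floating offset would only absorb the refractory correction already applied
through PPR*. The confidence interval is a seeded parametric bootstrap
(1000 resamples of residuals onto the fitted curve).

Geometry defaults: diameter 150 nm, bilayer thickness 5 nm, headgroup area
0.71 nm², protein monomer 31 kDa — all configurable. Units: PPR in mg/mmol
is numerically identical to µg/µmol; the copy-number chain converts τ to
grams per micromole before dividing by the molar mass.

## 4-state import kinetics

The model and its assumptions: deposition of aqueous probe onto the OMM
(k0, an effective constant absorbing micelle dissociation; the probe's CMC
of 0.165 µM is metadata only), desorption (k1), scrambling across the OMM
(k2 out→in, k3 in→out, tied equal — passive bidirectional transport), and
irreversible decarboxylation (k4, absorbing the enzyme kinetics and any
intra-IMS transfer). Defaults k0 = 1 s⁻¹ and k1 = 0.05 s⁻¹ come from
liposome partitioning and back-extraction measurements and are held fixed
during fitting.

**Integration.** The system is linear; `closed_form` (scipy `expm`) is the
exact solution and the ground truth. `integrate` (DOP853, rtol 1e-13,
atol 1e-14) exists as the generic forward solver; the test suite holds it
to ≤1e-8 agreement with the closed form and ≤1e-9 mass conservation. Inside
the fitting loop an eigendecomposition propagator evaluates P3(t)
vectorised over times, falling back to `expm` if the rate matrix is
numerically defective.

**Fitting.** Log-uniform grid over [1e-4, 1] s⁻¹ at 50 points per decade
(two-dimensional when k4 is co-fitted), then Nelder–Mead refinement in
log-rate space. The loss is weighted least squares with weights
`1/max(model, 1e-3)²` — the maximum-likelihood choice for multiplicative
noise, which is what TLC densitometry ratios exhibit and what the generator
produces. This matters: with unweighted squares the late, decarboxylation-
limited points dominate and the scrambling rate is poorly determined
(~11% median error, up to ~22%, at 2% noise and 4 replicates); with
relative weighting the precisely measured early points pin it to within a
few percent. `weighting="none"` restores plain least squares. Weights are
re-derived from the fitted model twice (IRLS).

**Identifiability.** The chain P1→P2→P3 is nearly symmetric in (k2/3, k4):
without prior information the two rates can trade places. Wild-type fits
therefore accept a lower bound on k2/3 (0.01 s⁻¹, from prior scramblase
literature) via `k23_min`; it is off by default. Separately, when
scrambling is much faster than the sampling cadence the likelihood profile
in k2/3 goes flat; the fit flags `identifiable=False` when a 4-fold move in
k2/3 raises the weighted RSS by less than 3×, or when the residual-bootstrap
SEM exceeds half the estimate.

**Half-times and fold changes.** `half_time = ln 2 / k`. For the slow
(porin-null) regime this gives 277 s at k2/3 = 0.0025 s⁻¹, whereas the
commonly quoted 265 s corresponds to an unrounded rate of ≈0.0026 s⁻¹; the
implementation reports ln2/k as computed and leaves the ~5% rounding
discrepancy to the reader. The fold change is a plain rate ratio.

**Sampling schedule.** The default synthetic TLC schedule is 12 aliquots
over 0–1800 s with minute-scale early points
(0, 30, 60, 90, 120, 180, 240, 300, 450, 600, 1200, 1800 s). An assay whose
fast step has a ~25-s half-time must be sampled on that time scale; evenly
spaced aliquots would put the first measurement after the scrambling step
has already equilibrated.

## Trajectory analysis

Frames are Martini-style beads in GRO text (single frames, per-frame files,
or concatenated streams; a `t=` tag on the title line carries the time).
The reader/writer is a small fixed-column implementation so that
multi-frame streams parse without an intermediate trajectory format; the
writer's output is validated against MDAnalysis in the test suite.

* **Leaflet assignment**: membrane center = mean phosphate z of the frame
  (robust to small leaflet imbalance; under gross imbalance, as after many
  one-way flips, the center shifts — the analyzers sample populations where
  flips are a few percent). A phosphate exactly at the center keeps its
  previous-frame label (hysteresis) to avoid chattering; with no history it
  is an error.
* **Scrambling series**: snapshots every 10 ns; a lipid counts as scrambled
  when its leaflet differs from the first frame. A 200-ns centered running
  average smooths the series; the rate is the least-squares slope of the raw
  series in % per µs. No cross-study numeric comparison is attached to the
  rate because published bar charts of this quantity do not state their
  normalization.
* **Water-defect map**: per 0.1-nm xy bin, the average number of water beads
  within 1 nm of the membrane center along z, sampled every 100 ps. Every
  sampled frame contributes one sample to every bin, so the <100-sample
  exclusion masks the whole map for trajectories shorter than 100 samples.
* **Thickness map**: mean upper-leaflet minus mean lower-leaflet phosphate z
  per bin; bins with fewer than 100 phosphate observations, or with only one
  leaflet observed, are masked.
* **Centering**: frames are translated so the protein centroid sits at the
  xy box center, then re-wrapped. Rotational (RMSD) alignment is
  intentionally not performed: for maps around a roughly isotropic barrel
  the xy translation dominates, and rotation can be added upstream if an
  asymmetric protein demands it.

Coordinates are wrapped into the primary box before binning; translating
all beads by an integer number of bins translates the maps identically
(tested).

## Synthetic data: what it does and does not show

The generators reproduce the *kinetic and statistical structure* the
analyses assume — exponential phases with the stated plateaus, Poisson
occupancy counts, the exact linear-model P3(t), planted flip events with
unambiguous leaflet geometry (z-jitter σ 0.3 nm against a 2-nm leaflet
offset, clipped so a jitter excursion can never cross the midplane).
Noise is multiplicative Gaussian, σ = 0.02 by default; real traces add
photobleaching drift, inner-filter effects, instrument steps at reagent
addition, and real bilayers add undulations, protein-shaped defects and
force-field physics none of which are modeled. Passing tests therefore
demonstrate that the analysis chain is correct and well-conditioned under
its own assumptions, not that those assumptions hold for any particular
instrument or force field.

## Problem sizes

Recovery studies use 4 replicates × 12 time points (kinetics), 10⁴
vesicles per reconstitution point × 6 points (occupancy), and bilayers of
16–100 lipids over 100–120 frames (trajectory analyzers) — sizes at which
the statistical behavior is already asymptotic for the quantities checked,
chosen so the whole suite runs comfortably on a laptop.
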