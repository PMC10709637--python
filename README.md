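# scramkit

Quantitation of phospholipid scramblase activity in reconstituted vesicles
and mitochondria, plus the coarse-grained trajectory analysis used to locate
the scrambling pathway on a membrane protein.

Phospholipids delivered to the cytoplasmic face of the outer mitochondrial
membrane (OMM) must flip to the inner leaflet before they can move on into
the organelle. Proteins that catalyze this ATP-independent flip-flop are
scramblases. Establishing that a candidate protein (here, the β-barrel
channel VDAC and its relatives) is a scramblase takes a chain of
quantitative arguments, and this package implements each link as tested,
reusable code:

1. **Fluorescence assay analysis** (`scramkit.assay`) — dithionite bleaching
   (channel readout), BSA back-extraction (scramblase readout),
   phospholipase protection and slow-scrambling assays. Traces are
   normalized to baseline, read out 350 s after reagent addition, and
   summarized with one- or two-phase exponential fits (phase count chosen by
   extra-sum-of-squares F-test). Activity fractions follow

       f = (F_L − F_P) / (F_L − F_Min),
       F_BSA_Min = (1 − F_Dith_Min)·φ + F_Dith_Min,
       φ = (F_BSA_L − F_Dith_L) / (1 − F_Dith_L),
       Q = f_scr / f_pore,

   with φ the fluorescence of BSA-complexed probe relative to its membrane
   value (≈ 0.4).

2. **Poisson reconstitution statistics** (`scramkit.reconstitution`) — the
   occupancy model `f = 1 − exp(−PPR*/τ)` with the refractory-vesicle
   correction `PPR* = PPR/(1 − 2·F_Dith_Min)`, and the sphere-geometry chain

       L = (4π(d/2)² + 4π(d/2 − h)²)/a,   V = N_A·10⁻⁶/L,
       C = τ·10⁻⁶/MW·N_A,   copies per vesicle = C/V,

   that converts the fit constant τ (µg protein/µmol lipid) into the copy
   number of the functional unit.

3. **4-state import kinetics** (`scramkit.kinetics`) — aqueous probe S,
   OMM outer-leaflet pool P1, inner-leaflet pool P2 and decarboxylated
   product P3, linked by rates k0 (deposition), k1 (desorption), k2 = k3
   (scrambling) and k4 (irreversible decarboxylation):

       dS/dt  = k1·P1 − k0·S
       dP1/dt = k0·S + k3·P2 − (k1 + k2)·P1
       dP2/dt = k2·P1 − (k3 + k4)·P2
       dP3/dt = k4·P2

   The system is linear, so a matrix-exponential closed form serves as the
   exact oracle for the adaptive integrator and as the fast evaluator inside
   the fitting loop (log-grid search plus Nelder–Mead, residual-bootstrap
   SEM, profile-flatness identifiability check).

4. **Coarse-grained trajectory analyzers** (`scramkit.trajectory`) — GRO
   text I/O, leaflet assignment by phosphate z-position, scrambled-lipid
   time series (10-ns cadence, 200-ns running average, slope-based rate),
   and xy-gridded water-defect and membrane-thickness maps (0.1-nm bins,
   100-ps sampling, bins with fewer than 100 samples masked).

5. **Synthetic data generators** (`scramkit.synth`) — seeded, analytically
   exact generators for every input class, so the whole pipeline is testable
   without instrument data.

## Worked example

`examples/03_import_kinetics.py` generates wild-type and porin-null PE
production curves at 2% noise and re-fits the scrambling rate:

```
wild-type: k2/3 = 0.0266 +/- 0.0004 1/s, k4 = 0.00180 1/s
           scrambling half-time ln2/k2/3 = 26.1 s
porin-null: k2/3 = 0.00250 +/- 0.00001 1/s
            scrambling half-time = 278 s
fold reduction = 10.6: losing the porins slows transbilayer PS movement
by more than an order of magnitude, even though PE production only drops
a few-fold (the decarboxylation step is rate-limiting)
```

The point of the model: PE production is limited by the slow
decarboxylation step (k4 ≈ 0.0018 s⁻¹), so an order-of-magnitude loss of
scrambling shows up as only a modest change in the raw time course — the
fit is what exposes it. The other examples cover the assay readouts
(`01_scramblase_assay.py`), the occupancy analysis with its ≈12
copies-per-vesicle result (`02_poisson_occupancy.py`) and the trajectory
analyzers (`04_trajectory_analysis.py`).

A thin CLI wraps the same functions:

```sh
scramkit simulate --kind decarb --seed 5 --out run/
scramkit fit-kinetics run/decarb.csv --out run/
```

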