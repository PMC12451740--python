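# Methods

## Feature model

Both CVs are signed sums of per-contact switching functions,

s^HB = Σ F_i^HB,F − Σ F_i^HB,U,  s^SC = Σ F_i^SC,F − Σ F_i^SC,U,

with coefficients fixed at +1 for native features (harvested from the folded
basin) and −1 for non-native features (harvested from the unfolded basin).
The switching function everywhere is the PLUMED RATIONAL form

s(r) = (1 − x^n)/(1 − x^m), x = (r − d0)/r0,

chosen so that the emitted PLUMED input evaluates identically to the Python
evaluator. Internally it is computed in the factored form
(Σ_{k<n} x^k)/(Σ_{k<m} x^k), which is the same rational function with the
removable singularity at x = 1 eliminated; the value at x = 1 is exactly n/m
(0.6 for the default exponents n = 6, m = 10). A consequence worth keeping in
mind: a contact *at* its reference distance scores ≈ 0.6, the "formed"
plateau of this functional form, not 1. Occupancy-based decisions therefore
use the threshold 0.5 rather than a value near 1.

### Hydrogen-bond features

A native feature for donor D(–H)···A evaluates as

F = s(r_DA) · a(θ) − λ_w (W_D + W_A) − λ_p Σ_c s(r_Dc),

where

* s(r_DA) is the rational switch on the heavy-donor–acceptor distance
  (default r0 = 3.0 Å, n = 6, m = 10, d0 = 0);
* a(θ) is the same rational switch applied to (1 + cos θ)/2 with reference
  a0 = (1 + cos 150°)/2, so a straight D–H···A bond (θ = 180°) scores 1, the
  value passes 0.6 at θ = 150°, and drops below 0.05 by θ = 120°;
* W_X = Σ_waters s(r_XO) is the protein–water competition (coordination of
  the donor heavy atom / acceptor with water oxygens, same switch defaults);
* the last sum runs over competing protein acceptors: acceptors within 6 Å of
  the donor in ≥ 5% of unfolded-basin frames, capped at the 4 most frequent,
  excluding the feature's own acceptor and residues closer than the sequence
  separation floor;
* λ_w, λ_p ∈ [0, 1] (default 1) weight the two competition channels.

The value is bounded above by 1 and goes negative when water or a rival
acceptor has seized the native partners — this is what lets s^HB place
misfolded states *below* unfolded ones. Whole contacts that are formed only
in the unfolded basin additionally enter as separate non-native features
(bare switch × angular, no competition terms) subtracted at CV level; the
per-feature competition terms and the −F^U sum are complementary mechanisms,
not duplicates.

Donors are protein N/O/S heavy atoms with a covalent hydrogen (assigned by
distance < 1.2 Å when coordinates are available, else by PDB naming
convention); acceptors are all protein N/O/S. Candidate pairs respect a
sequence-separation floor of 2 residues (config) — nearer pairs are
always-on and carry no discriminative signal.

### Side-chain features

F = s(‖COM_i − COM_j‖) with default r0 = 6.5 Å, n = 6, m = 10. The COM is the
mass-weighted centre of the residue's non-backbone atoms, hydrogens included
(backbone = N, CA, C, O, terminal oxygens, and their hydrogens); glycine
falls back to its Cα so that glycines participating in hydrophobic cores
remain representable. Side-chain features never touch the solvent.

All distances use the minimum-image convention in orthorhombic boxes;
coordinates are Å, times ps, energies kcal/mol, angles radians, converted at
I/O boundaries only.

## Harvesting and filtering

From two short unbiased end-state runs (uniform frame weights — the runs are
unbiased), every candidate contact is evaluated on every frame of both.
Occupancy is the fraction of frames with bare switch value > 0.5, so
harvesting and CV evaluation share one geometric definition of "contact".
Classification thresholds (all config-exposed, recorded in the manifest):

* native: folded occupancy ≥ 0.6;
* non-native: unfolded occupancy ≥ 0.25 **and** folded occupancy ≤ 0.1.

Candidates are scored with a per-feature Fisher discriminant ratio

J = (μ_F − μ_U)² / (σ_F² + σ_U² + ε), ε = 1e-6,

the one-dimensional form of the LDA criterion; features with J ≥ 1.0
(default) are retained, ranked by score with a deterministic lexicographic
tie-break on the contact identity. ε regularises zero-variance features; it
also makes the score only approximately scale-invariant at very small value
scales (irrelevant for switch values of order one). The retained set is
serialised as a JSON manifest whose SHA-256 prefix is embedded in the PLUMED
header, making any COLVAR file traceable to its defining features.

## Ablations

* `native_only` — non-native features dropped, λ_w = λ_p = 0 (the abridged
  CV that retains only native contacts);
* `no_water_nonnative` — λ_w = 0 only;
* `no_protein_nonnative` — λ_p = 0 and harvested non-native features dropped
  (both channels describe protein–protein competition).

## PLUMED emission

One file defines both CVs from primitive actions: DISTANCE + ANGLE + CUSTOM
for hydrogen-bond features (VAR declared explicitly beyond three arguments),
COORDINATION with a RATIONAL switch for the competition sums, COM + DISTANCE
+ CUSTOM for side-chain features, COMBINE with ±1 coefficients for the CVs,
and a PRINT action. Serials are 1-based and Å units are declared (PLUMED's
native unit is nm). The CUSTOM expressions use the direct rational form,
which is singular exactly at r = r0 — a measure-zero point that an MD
trajectory does not hit; the internal evaluator uses the factored form and is
total. The internal evaluator and `plumed driver` agree to 1e-3 on fixture
trajectories (validated automatically when a `plumed` binary is present).

## Landscape analysis

* **Cα RMSD** after optimal rigid superposition (Kabsch, via
  scipy's `Rotation.align_vectors`); requires ≥ 3 Cα atoms.
* **Dual-cutoff assignment**: the state flips to folded only after the RMSD
  dwells ≤ the folded cutoff for a full time window, and to unfolded only
  after a full-window dwell ≥ the unfolded cutoff; the flip is recorded at
  the frame where the dwell completes, frames between flips inherit the
  current state, frames before the first commitment are transit. This
  "minimum dwell before commitment" reading of the windowed rule is an
  interpretation (window-on-entry); it is config-exposed. Hysteresis
  guarantees the transition count never exceeds a naive single-threshold
  crossing count.
* **Transitions / residence times**: folding = U→F flip; the mean folding
  time is the mean duration of unfolded residence segments, reported in µs;
  zero-event cases report absent times, never 0.
* **ΔF** = −k_B T ln(P_F/P_U) with k_B = 0.0019872041 kcal/mol/K; negative
  means folded is favoured. Transit frames are excluded from both
  populations (an assign-to-last-state alternative is available by
  construction of the labels). Empty basins raise rather than returning ±∞.
* **ΔH** = ⟨E⟩_U − ⟨E⟩_F over frame-aligned energy series, transit excluded;
  the energy column is whatever the caller supplies (potential or total).
* **FES**: F(bin) = −kT ln(Σw_bin/Σw), min-shifted to 0, empty bins +∞;
  biased input is reweighted by w = exp(V_bias/kT) (max-shifted before
  exponentiation). Default 50 bins per axis over the observed range.
* **Replica aggregation**: element-wise mean and population standard
  deviation; grid bins empty in any replica are flagged and reported as +∞,
  never silently averaged over the populated subset.

## Synthetic fixture

The generator builds a 6-residue (two 3-residue strands) antiparallel
β-hairpin, alanine-like with one glycine, with hydrogens, in a 36 Å cubic
box with 30 waters. The folded frame realises four cross-strand native
hydrogen bonds at ideal geometry (D–A ≈ 2.9 Å, θ = 180°) and two native
side-chain pairs at ≈ 0.8 of the side-chain switch reference; the misfolded
frame shifts the register of the second strand so a non-native set of four
hydrogen bonds and two side-chain contacts forms instead (the strand-B
residue whose misfolded partner would coincide with its folded partner is
displaced out of plane). Planted geometry is asserted at generation time.
Waters occupy a seeded site pool kept ≥ 6 Å from the protein in both
reference configurations and are repositioned and relabelled every frame.
Frames are reference geometry + isotropic Gaussian noise (default
σ = 0.05 Å, small relative to the ≈ 0.3 Å half-width of the distance switch
so planted-contact occupancies saturate); `telegraph` sampling switches
basins as a two-state Markov chain with stationary folded probability
p_fold = 0.7 and per-frame flip scale 0.1, giving
ΔF_true = −kT ln(p_fold/(1−p_fold)) exactly and closed-form residence-time
expectations.

These are geometric constructions, not molecular dynamics: they contain no
force-field energetics, no realistic water structure, no gradual
transition-path frames, and their noise is isotropic and uncorrelated.
Passing tests therefore demonstrate the correctness of featurization,
selection and estimators — not that the CVs are optimal for any real
protein, which depends on the sampling quality of the end-state runs.

## Problem sizes and numerical choices

The test suite and acceptance script use end-state runs of 150–200 frames,
telegraph trajectories of 2×10⁴–10⁵ frames, 10⁶ draws for the FES
reconstruction, and 100 trials for the Fisher-recovery rate; these sizes put
Monte-Carlo errors well inside the asserted tolerances (e.g. the ΔF check at
±0.1 kcal/mol has a sampling error of ≈ 0.02 kcal/mol). Ties in feature
ranking break lexicographically; switch evaluation clamps x below 0 (r < d0
counts as fully formed); the angular term raises on coincident points;
single-frame trajectories report stride 0 and the dual-cutoff window then
defaults to one frame.

## Known limitations

* Orthorhombic boxes only; no triclinic minimum image.
* Donor identification relies on naming/distance heuristics, not a bond
  table; exotic hydrogen names may need the coordinate-based path.
* Non-native features are evaluated without their own competition terms;
  only native features carry water/protein competition.
* The harvest is O(donors × acceptors × frames); for large proteins use the
  frame stride and the sequence-separation floor.
* The score threshold, occupancy thresholds and switch parameters are
  declared defaults of this implementation, exposed in `HarvestConfig`, and
  recorded in every manifest — they are the knobs to recalibrate per system.
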