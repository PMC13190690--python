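# Methods

`mdstab` implements a pipeline for detecting temporally stable conformational
ensembles in long molecular-dynamics (MD) trajectories of the MALT1
paracaspase–Ig3 construct (author residue numbering 339–725) and for ranking
candidate ensembles against experimental NMR spin-relaxation data.  This note
records the models, conventions, numerical choices and limitations.

## Stable-ensemble detection

**Clustering.** Frames are down-sampled to uniform spacing (default 1 ns) and
clustered with a GROMOS-style greedy neighbour-count algorithm at a backbone
RMSD cutoff (default 0.1 nm; 0.105 nm preset for representative-ensemble
extraction).  All pairwise RMSDs are Kabsch/quaternion-minimized over the
selected region (mdtraj's QCP kernel).  We add a *pairwise admission rule* to
plain GROMOS: a frame joins a cluster only if it is within the cutoff of
*every* member already admitted (candidates considered in ascending RMSD from
the seed).  Plain GROMOS guarantees only member–seed distances; the admission
rule makes the stronger contract — maximum intra-cluster pairwise RMSD ≤
cutoff — hold by construction, and the test suite verifies it exhaustively.
Ties in neighbour counts resolve to the lowest frame index, so clustering is
deterministic.  Clusters are numbered 1..K by descending population; a pooled
"other" bucket (ranks beyond 20 by default) exists only in population
reports, never in the analysis.

**Windowed population vectors.** The trajectory is partitioned into
overlapping windows of duration W = 10·τc advanced in 15 ns steps, where τc
is the molecule's overall rotational correlation time.  τc must be supplied
by the user (config `tau_c_ns`); there is deliberately no default, since W
sets the physical meaning of "stable".  Each window counts the preassigned
cluster identities of frames with start ≤ t < start + W (half-open, so edge
frames are never double-counted) and yields a fractional occupancy vector
over *all* clusters, zero-population clusters included.

**Cosine-distance stability criterion.** Similarity between windows i, j is
the cosine distance d(a, b) = 1 − a·b/(|a||b|): 0 for identical population
distributions, 1 for disjoint cluster support.  A stable ensemble is a
contiguous diagonal block of the window-by-window distance matrix in which
*all* pairwise distances are strictly below a threshold (default 0.1).
Blocks are found by greedy left-to-right expansion (extend while the new
window stays within threshold of every block member; resume after the
block).  Greedy maximal non-overlapping search was chosen for determinism;
overlapping maximal blocks are possible in principle and are not enumerated.
A segment spanning windows [tₐ, t_b] covers the time interval
[tₐ, t_b + W], so its duration is t_b − tₐ + W.

Windows that straddle a regime switch interpolate between the flanking
population distributions and can form short spurious runs; `min_windows`
(the shortest reportable block) filters them.  The packaged stability
scenario uses `min_windows = 8` (a 355 ns persistence requirement at
W = 250 ns, step 15 ns), which suppresses transition fragments whose span is
bounded by roughly one third of a window length.

## Synthetic study conditions

The planted-truth generators define the conditions under which every claim
is tested:

* **Markov conformer trajectories.** Toy geometry: one CA bead per residue
  at 0.38 nm spacing on a gentle helix (self-avoiding); conformational
  states displace a contiguous loop segment smoothly in distinct directions.
  Frames follow a discrete-time Markov chain over K templates plus isotropic
  Gaussian jitter (default SD 0.01 nm).  Templates must be separated by more
  than 4× the jitter SD (checked at construction) so states are resolvable.
  The canonical two-state condition uses 0.5 nm template separation with
  stationary populations 0.7/0.3.  The canonical stability scenario is a
  3-state chain: regime A mixes states {0, 1} at stationary (0.8, 0.2),
  regime B mixes {1, 2} at (0.2, 0.8); both mix within a few frames, so
  250 ns windows carry small occupancy fluctuations (SD ≈ 0.04), keeping
  within-regime distances well under the 0.1 threshold while the regimes
  are nearly orthogonal in population space.
* **Model-free bond vectors.** Internal motion is diffusion in a cone: the
  cone semi-angle θ₀ follows from the order parameter via
  S = cosθ₀(1 + cosθ₀)/2 and the wobble diffusion constant D_w is set from
  the Lipari–Szabo closed form for the effective internal correlation time,
  so the generated ensemble P2 autocorrelation converges to
  S² + (1 − S²)e^(−t/τe).  The cone model was chosen over a two-site jump
  because it gives a one-parameter map from S² to geometry.  The simulation
  uses singularity-free tangent-plane steps on the unit sphere with polar
  reflection at the cone boundary; vectors are unit-norm to 1e-12 at every
  step.  Overall tumbling is one shared isotropic rotational diffusion with
  D_r = 1/(6τc) (all vectors ride the same molecule); τc = ∞ disables it,
  producing pure internal motion as used for chain validation.
* **Relaxation tables and dihedral flips.** Experimental-style tables are
  truth + Gaussian noise with the noise SD reported as the uncertainty.
  Ring-flip traces are wrapped-normal noise (SD in degrees) around a mean
  that shifts once, mimicking a χ2 transition from +80° to −100°.

What the generators deliberately do **not** emulate: force-field energetics,
solvent/ion effects, anisotropic tumbling, rotamer jumps superimposed on
loop motion, and chemical-exchange line broadening.  Passing tests therefore
demonstrate correctness of the *analysis machinery* under the stated
statistical assumptions, not fidelity of any particular MD force field.

## Conformational descriptors

RMSD series use Kabsch superposition (uniform weights by default) over a
named region; regions ship for the structured core (Reg1: 342–467, 484–491,
509–562, 572–717), the construct minus termini (Reg2: 342–717), the β3
hairpin (416–425), loop 2 (464–485) and loop 3 (both the 491–509 and the
496–510 definitions; reports must name which was used).  RMSF is computed
after two-pass alignment (align to frame 0, form the mean, re-align to the
mean) and reported in Å; aligning to the mean removes reference bias, and a
flag restores frame-0 alignment.  Cartesian PCA runs on superposed region
coordinates via scikit-learn; projections are mean-centred by construction.
Dihedrals use the standard signed atan2 formula, degrees, branch
(−180, 180].  Ring-state classification labels χ2 frames by circular
distance to the inward (−100°) and outward (+90°) centres within a 60°
half-width and applies hysteresis: a transition counts only when the new
state persists ≥ `min_dwell` frames (default 10), which suppresses flicker
when noise straddles a window edge.

## Relaxation back-calculation

The internal N–H P2 autocorrelation C_I(t) = ⟨P2(û(t₀)·û(t₀+t))⟩ is computed
by direct origin averaging on a log-spaced lag grid after superposing frames
on the amide-nitrogen positions (superposition removes global rotation, so
the computed ACF is the *internal* correlation function).  Residues lacking
an amide proton (prolines, termini) are skipped.  C_I is fitted to
S² + Σᵢ Aᵢe^(−t/τᵢ) (≤3 components, S² + ΣAᵢ = 1) by bounded least squares
with multi-start over log-spaced initial times; failed fits fall back to
fewer components.  The spectral density folds in isotropic overall tumbling
supplied as τc (not extracted from the trajectory — the standard decoupling
approximation):

J(ω) = (2/5)[S²τc/(1+(ωτc)²) + Σᵢ Aᵢτᵢ′/(1+(ωτᵢ′)²)], 1/τᵢ′ = 1/τᵢ + 1/τc.

Backbone ¹⁵N rates use the standard Redfield expressions with the dipolar
constant d = (μ₀/4π)ħγHγN/r³ and CSA constant c = |Δσ|ω_N/√3.  Conventions,
all config-exposed: r_NH = 1.02 Å, ¹⁵N CSA Δσ = −170 ppm, CSA/dipole angle
θ = 17°, methyl C–H/symmetry-axis angle β = 110.5°.  The CSA/dipole
cross-correlation rate is η_xy = (1/6)·d·c·P2(cosθ)·[4J(0) + 3J(ω_N)]
(magnitude convention).  Methyl ¹³C rates are computed from the symmetry-axis
spectral density with fast methyl spinning folded in analytically — the
three C–H dipolar interactions see the axis motion scaled by [P2(cosβ)]²
(≈ 0.0999 at 110.5°) — with R1 summing the three C–H couplings and
Γ2 = (d_CH²/8)[4J_eff(0) + 3J_eff(ω_C)].  These prefactor conventions are
validated against an independent literal-formula oracle in the tests, not
against any published absolute values; users comparing to data processed
under a different η_xy/Γ2 convention should rescale accordingly (cosine
scoring is insensitive to a uniform rescale).

Uncertainties come from a circular block bootstrap over contiguous
trajectory blocks (default 10 ns blocks, 200 replicates, ≥10 blocks
required), which respects temporal correlation within a block.

## Scoring and ranking

For each observable (R1, R2, NOE, η_xy) the calculated and experimental
vectors are matched on common finite residues (≥3 required) and compared by
the same cosine distance as the stability analysis, plus RMSE and MAE.
Cosine scoring is scale-invariant; RMSE/MAE are not — both are reported
because they answer different questions (shape vs absolute agreement).
NOE values can be negative for flexible residues, so NOE vectors are shifted
by +1 before cosine scoring (raw values feed RMSE/MAE).  The combined score
is the unweighted mean of per-observable cosine distances over whichever
observables are available (weights configurable); ensembles rank ascending
by it, ties broken by mean z-scored RMSE, then ensemble id.  RMSE/MAE are
reported for every ensemble against experiment (a flag also supports
comparing against the best-scoring ensemble's values).

## Numerical choices and degenerate inputs

* Lengths in nm internally; Å at the PDB boundary (round-trip accurate to
  the format's 0.001 Å precision).  Times in ns; multi-model PDB carries no
  time stamps, so times are synthesized from a configurable stride
  (default 1 ns).
* Down-sampling requires the target interval to be an integer multiple of
  the native spacing (tolerance 1e-6 ns).
* Kabsch superposition enforces a proper rotation (det = +1) even for
  mirror-image inputs and rejects collinear/coincident selections.
* Cosine distance returns exactly 0 for bitwise-identical vectors and raises
  on zero-norm or mismatched cluster sets; values are clipped to [0, 1].
* Stable-segment detection uses strict `< threshold` (the inclusive variant
  is a one-character change; strict was chosen and documented).
* All generators take explicit integer seeds and are bit-reproducible; the
  pipeline writes its resolved config and seeds next to its outputs, and a
  rerun is byte-identical.

## Problem sizes used in the packaged checks

The packaged verification runs use desk-scale problem sizes chosen to make
each statistical claim testable with comfortable margins: 500–10⁴ frames of
50-residue chains for clustering and population recovery, a 3000 ns
trajectory (W = 250 ns, step 15 ns) for stable-segment recovery, and 200
vectors × 10⁵ steps (dt = 1 ps) for the relaxation-chain validation, where
the sampling-limited agreement with analytic Lipari–Szabo rates is well
inside the 10% band.

## Known limitations

* Chemical exchange (Rex) is not modelled; back-calculated R2 omits slow
  conformational-exchange contributions by design.
* Overall tumbling is isotropic with user-supplied τc; anisotropic diffusion
  tensors are out of scope.
* The greedy segment search reports non-overlapping maximal blocks only.
* Window/report edges: a regime switch is localized only to within roughly
  a third of a window length by the distance-matrix geometry; the packaged
  scenario quantifies this (later-segment start within two window steps of
  the planted switch).
* Methyl rates operate on a supplied axis spectral density; automatic
  methyl-group extraction from side-chain geometry is not implemented.
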