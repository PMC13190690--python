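# mdstab

Detection of **temporally stable conformational ensembles** in molecular-
dynamics trajectories and **back-calculation of NMR spin-relaxation
observables**, built around the analysis of the MALT1 paracaspase–Ig3
construct (residues 339–725) but applicable to any protein trajectory.

Long MD trajectories of multi-domain proteins drift between conformational
basins; picking a representative ensemble by eye (or by a single global
clustering) conflates states that are only transiently populated.  `mdstab`
asks a sharper question: *over which time interval do the cluster
populations stop changing?*  It then validates candidate ensembles against
experimental ¹⁵N relaxation data (R₁, R₂, heteronuclear NOE, and the
CSA/dipole cross-correlation rate η_xy, which is insensitive to slow
chemical exchange).

## Method in brief

1. **Cluster** the down-sampled trajectory (1 ns frames) with a GROMOS-style
   greedy algorithm at a backbone RMSD cutoff of 0.1 nm, with a pairwise
   admission rule so every two frames in a cluster are within the cutoff.
2. **Window** the trajectory into overlapping segments of length W = 10·τc
   (τc = overall rotational correlation time), advanced in 15 ns steps, and
   form a cluster **population vector** x = (x₁, …, x_K) per window.
3. **Compare** all window pairs with the cosine distance

       d(a, b) = 1 − a·b / (|a||b|)

   (0 = identical population distributions, 1 = disjoint support) and find
   contiguous diagonal blocks of the distance matrix with all pairwise
   d < 0.1: each block [tₐ, t_b] is a **stable segment** covering
   tₐ … t_b + W.
4. **Extract** the 20 medoid structures of the most populated clusters
   (0.105 nm cutoff preset) as the representative ensemble, **back-calculate**
   relaxation rates from the segment via the Lipari–Szabo model-free chain
   (P2 bond-vector autocorrelation → S², τᵢ fit → spectral density J(ω) →
   ¹⁵N Redfield expressions), and **rank** candidate ensembles against
   experiment by per-observable cosine distance plus RMSE/MAE.

A first-class synthetic-data module generates planted-truth inputs (Markov
jump dynamics over conformer templates, wobble-in-a-cone bond vectors with
exact model-free statistics, noisy relaxation tables, dihedral flip traces)
so the entire pipeline is verifiable offline.  See `docs/methods.md` for
models, conventions and limitations.

## Worked example

Detect the planted regime switch in a synthetic 3000 ns, 3-state trajectory
(regimes switch at 1000 ns; W = 250 ns, step 15 ns):

```python
import numpy as np
from mdstab import synthetic as syn, ensemble as ens
from mdstab.io_core import RegionSpec

traj, truth = syn.stability_scenario(n_frames=3000, switch_frame=1000, seed=1)
region = RegionSpec("chain50", ((339, 388),))

assignment = ens.gromos_cluster(traj, region, cutoff_nm=0.1)
vectors = ens.window_population_vectors(assignment, W_ns=250.0, step_ns=15.0)
dm = ens.distance_matrix(vectors)
for s in ens.find_stable_segments(dm, threshold=0.1, min_windows=8):
    print(f"segment: t_a={s.t_a_ns:.0f} ns  t_b={s.t_b_ns:.0f} ns  "
          f"duration={s.duration_ns:.0f} ns  max_d={s.max_internal_distance:.3f}")
```

prints

```
segment: t_a=0 ns  t_b=825 ns  duration=1075 ns  max_d=0.084
segment: t_a=990 ns  t_b=2745 ns  duration=2005 ns  max_d=0.051
```

Two stable segments are found; the second begins at 990 ns, one window step
before the planted 1000 ns switch (windows overlapping the switch mix both
regimes and belong to neither block).  Within each segment every pair of
windows has cosine distance below the 0.1 threshold (maxima 0.084 and
0.051); across segments distances approach 1 because the regimes occupy
nearly disjoint clusters.  The same analysis on a stationary control yields
a single segment spanning the whole run.

The command-line interface wraps the same library:

```bash
mdstab simulate --n-frames 3000 --seed 1 --out-dir sim
mdstab cluster-stability --topology sim/trajectory.pdb --tau-c 25 --out-dir stab
mdstab relax-backcalc --topology traj.pdb --trajectory run.xtc \
    --time-range 2500 3000 --tau-c 12 --field 900 --out rates.tsv
mdstab score --exp exp.csv --calc rates1.tsv --calc rates2.tsv --out scores.tsv
```

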