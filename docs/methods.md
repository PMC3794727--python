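# Methods

## Model

All non-hydrogen atoms are hard spheres of unit mass.  Pair energetics is
piecewise constant:

* **Excluded volume.** Any pair closer than σ_ij = α(r_i + r_j) is forbidden
  (r_i: van der Waals radius, α = 0.80).
* **Native contacts.** Pairs in residues with sequence separation > 2 whose
  *native* distance lies in [σ_ij, λσ_ij), λ = 1.6, carry a well of depth 1
  (reduced units).  Non-native pairs have depth 0 — they only repel.
  Disulfide-bonded cysteine pairs are treated as ordinary contacts, never as
  covalent bonds.
* **Bonds.** Covalent bonds (residue templates plus peptide C–N links) and
  covalent-like pseudo-bonds are infinite wells [0.9 L, 1.1 L] around the
  native length L.

"Backbone distance" is interpreted as residue-number separation
(|res_i − res_j| > 2 for contact eligibility).

### Radii table

The vdW set is element-based (Bondi values: N 1.55, O 1.52, S 1.80 Å) with
three carbon classes: sp2/carbonyl 1.70, aromatic 1.77, and aliphatic
pinned to **1.836 Å** so that the attraction cutoff for a methyl-carbon pair
is λ·α·2r = 4.70 Å.  The table lives in `data/vdw_radii.tsv`; only the
aliphatic-carbon value is constrained by the cutoff, the rest is a
documented choice.

### Covalent-like pseudo-bonds

Bond wells alone leave angles and dihedrals free, so the builder adds
pseudo-bonds (same ±10% wells) for (a) every 1–3 pair of the covalent graph
(fixes angles), (b) CA(i)–CA(i+1) across each peptide bond (fixes the
peptide plane), and (c) any remaining short-range pair (separation ≤ 2)
whose *native* distance violates its hard core — local geometry such as
aromatic-ring 1–4 distances that the α-scaled cores cannot accommodate is
held by a constraint instead of aborting the build.  Sep > 2 native clashes
are still a hard error, since they would corrupt the contact set itself.

## Event-driven dynamics

Between discontinuities atoms move ballistically; event times are the
analytic roots of |r_rel + v_rel t| = d for each relevant discontinuity d.
Scheduling keeps one next-event record per atom (pair partner, wall, or
thermostat); after each event only the rows of the affected atoms — and of
atoms whose stored event referenced them — are recomputed.  There is no
cell decomposition: each update is O(N), which is the right trade-off for
the desk-scale systems (≤ ~100 atoms) this package targets; positions are
advanced globally at every event, so all roots are exact in the current
state.  Shell membership (inside/outside each well) is explicit state, so
boundary decisions never depend on floating-point distance comparisons;
negative roots from rounding are clamped to zero-time events, which resolve
harmlessly.

Event resolution, for equal masses, updates only the radial component v_r of
the relative velocity: elastic reflection (cores, bond walls, failed well
escapes) reverses it; well capture sets v_r' = −√(v_r² + 4) (the factor 4 =
2ΔU/μ with reduced mass ½ and depth 1); escape succeeds only if v_r² > 4,
paying the depth.  Momentum is conserved identically and energy to rounding
(measured drift ≈ 10⁻¹⁴ relative over 10⁶ events; the acceptance bound is
10⁻⁸).

**Thermostat.** Andersen-style: each atom redraws its velocity from the
Maxwell–Boltzmann distribution at Poisson-scheduled times (default rate 0.1
per atom per reduced time; the pipeline uses 0.2).  It is the simplest
scheme that provably samples the canonical ensemble for DMD and is easy to
switch off for conservation tests.

**Sampling.** Observables (E, R_g, RMSD-to-native, frames) are recorded
every `sample_every` events.  Event-stratified samples over-weight states
with high collision rates; the kernel therefore also accumulates exact time
integrals of U and U², and time averages are used where a canonical average
is compared against a closed form (the two-particle oracle).  The
event-sampled route is retained for ensemble construction because the
analyses built on it (WHAM consistency, populations, clustering) compare
samples with samples.

## Replica exchange

Replicas at a strictly increasing temperature ladder alternate DMD segments
(default 10⁴ events) with swap sweeps over adjacent pairs, odd/even pairs
alternating.  Acceptance is min(1, exp[(1/T_i − 1/T_j)(E_i − E_j)]);
temperatures (not configurations) are relabeled and velocities rescaled by
√(T_new/T_old) on acceptance.  Exchange is thus a Monte-Carlo move layer
over deterministic DMD segments; no configuration-space MC moves are used.

## WHAM and landscapes

Energy histograms (default bin width 2 — the contact quantum is 1, so this
resolves basins without empty-bin noise) are combined by the standard
self-consistent pair of equations, iterated in log space until the
per-temperature offsets change by < 10⁻⁸ (sup-norm, max 10⁵ iterations).
Non-overlap shows up as non-convergence and is reported, not hidden.
F(x) = −T ln P(x) is computed on 1D/2D grids (E, R_g, RMSD), with
multi-temperature input reweighted through the fitted density of states;
empty bins are masked, never interpolated.  Basins of the 1D profile are
watershed windows bounded at barrier tops; adjacent basins whose barrier
prominence is below `min_basin_barrier` (default 1.0 reduced units) are
merged to suppress binning noise.  Macrostate populations are window
occupancies of the energy samples; a cluster-based population (clusters
assigned to basins by their representative's energy) is reported alongside
as a cross-check.

Cv uses the fluctuation formula (⟨E²⟩ − ⟨E⟩²)/T²; T_m is the Cv-curve
argmax refined by a local parabola, with boundary maxima flagged as "no
interior peak" rather than returned.

## Ensemble analyses

* **Superposition/RMSD:** Kabsch (SVD with determinant correction); the
  test oracle is Horn's quaternion method.  Degenerate selections (< 3
  atoms, rank < 2) are rejected.
* **Equilibration rule:** frames before the first folding transition (first
  sample with E at or below the native-basin upper edge) are dropped, then
  every stride-th frame is kept.
* **Clustering:** k-means on mutually superposed, flattened coordinates,
  k grown from 1 until every frame lies within the target radius (RMSD) of
  its cluster's medoid; seed-pinned initialisation makes it deterministic.
* **SASA:** Shrake–Rupley with 960 deterministic golden-spiral points per
  atom and a 1.4 Å probe; per-residue sums, and ensemble/native ratio
  profiles with standard errors (zero-native-SASA residues flagged
  infinite and excluded from percentage summaries).
* **Dihedrals:** the peptide ω (CA–C–N–CA) distinguishes cis (~0°) from
  trans (~180°) isomers.
* **Essential dynamics:** frames are superposed onto the reference over the
  Cα selection; the non-mass-weighted 3n×3n covariance uses deviations from
  the ensemble mean (configurable to the reference — the convention is an
  open choice and both are supported).  Total MSF is the trace; per-atom
  RMSF along the top-k modes projects deviations onto the mode subspace.

## Synthetic systems

The generators define the study conditions for everything the tests
measure:

* **Two-particle square well** in a reflecting cubic box.  The canonical
  ⟨U⟩(T) has a closed form from configuration-volume ratios: for two
  independent uniform points the relative-separation weight is
  Π_k(L − |Δ_k|), whose integral over a ball has an explicit polynomial,
  making the bound/unbound weights exact (no uniform-volume approximation).
* **Minifold** (default: 12 residues): a poly-glycine antiparallel
  β-hairpin built from ideal backbone geometry, with two turn residues
  whose dihedrals were fixed once, by a clash-screened search, to maximise
  cross-strand contacts.  Nearly all its 41 contacts are cross-strand, so
  folding is cooperative: at the Cv peak (T_m ≈ 1.49) the F(E) profile has
  a folded/collapsed basin and a free-coil basin at E ≈ 0 separated by the
  entropic barrier of nucleating the first contact.  An α-helix topology is
  also provided; its purely local contact pattern melts gradually
  (helix–coil-like), which is itself used to test that basin extraction
  does not invent barriers.  The generator emits PDB text and re-parses it
  through the standard loaders, so fixtures satisfy exactly the invariants
  real input must.
* **Two-level sampler:** exact Boltzmann draws from a two-level system with
  degeneracies — the enumeration oracle for WHAM (ln g recovery), Cv and
  populations.
* **Gaussian ensembles** with planted covariances — the PCA oracle.

What the minifold does *not* emulate: side chains (and hence realistic
packing and segment tables at protein scale), the β-sandwich topology,
disulfides, or 99-residue system size.  Tests passing on it validate the
*mechanics* (model construction rules, exact dynamics, statistical
estimators, geometric analyses), not biological conclusions about any real
protein; protein-scale thermodynamics additionally needs the deposited
structures and event budgets orders of magnitude beyond a desk run
(the replicas parallelise trivially; the pipeline config exposes the
budgets).

## Problem sizes and numerical defaults

The shipped study conditions: 12-residue minifold (48 atoms, 41 contacts);
ladder 1.10–1.85 in six steps spanning the transition; 80 sweeps × 10⁴
events per replica; fixed-temperature ensemble of 600k events sampled every
5k; cluster radius 3 Å; WHAM bin width 2, tolerance 10⁻⁸; basin prominence
1.0; 5 principal modes.  The full desk study completes in about two
minutes; conservation checks run 10⁶ events.  All randomness flows from
explicit seeds (engine, thermostat, swaps, clustering, generators), and
repeated runs produce byte-identical tables.

## Known limitations

* Event scheduling is O(N) per event (no cell lists); protein-scale
  all-atom runs are possible but slow — the design optimises testability
  and exactness at desk scale.
* Event-count sampling is not time-uniform; time-averaged accumulators are
  exact but currently cover U and U² only.
* The radii table beyond the aliphatic carbon is a convention; absolute
  contact counts for real structures depend on it.
* No solvent, no non-native attractions, no electrostatics: the model's
  landscape is native-centric by construction.
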