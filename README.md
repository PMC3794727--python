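# gofold

Event-driven (discrete) molecular dynamics for **all-atom Gō models** of
protein folding, with the complete thermodynamic and structural analysis
chain: replica exchange, WHAM free-energy landscapes, heat-capacity melting
curves, conformational clustering, solvent-accessibility profiles and
essential dynamics (PCA).

It is aimed at people who study folding intermediates with native-centric
models: build the model from a PDB structure, sample its equilibrium across
the folding transition, and characterise the basins that appear.

## The model

Every non-hydrogen atom is a hard sphere of unit mass.  With r_i the van der
Waals radius of atom *i* and σ = α(r_i + r_j), atom pairs in residues more
than two sequence positions apart interact through a square well

    ε_ij(r) = ∞      r < σ
            = Δ_ij   σ ≤ r < λσ
            = 0      r ≥ λσ

with Δ_ij = −1 if the pair is in contact in the native structure and 0
otherwise (α = 0.80, λ = 1.6; for a methyl-carbon pair this puts the
attraction cutoff at 4.7 Å).  The total energy of a conformation is
E = Σ ε_ij, so the native state has E = −(number of native contacts).
Covalent and covalent-like bonds are infinitely high wells [0.9 L, 1.1 L]
around the native bond length L; disulfides are ordinary contacts, not bonds.
Dynamics is event-driven: atoms fly ballistically between potential
discontinuities, every event conserves momentum exactly and energy to
rounding, and an Andersen thermostat (Poisson velocity redraws) imposes
temperature.  Reduced units throughout: mass 1, well depth 1, k_B = 1,
temperature in units of depth/k_B, lengths in Å.

Equilibrium sampling uses temperature replica exchange with Metropolis swap
acceptance min(1, exp[(1/T_i − 1/T_j)(E_i − E_j)]); the weighted histogram
analysis method combines the per-temperature histograms into one density of
states, giving Cv(T) = (⟨E²⟩ − ⟨E⟩²)/T², the melting temperature T_m (the Cv
peak) and free-energy profiles F = −T ln P over E, R_g or RMSD.  Ensembles
at fixed temperature feed k-means clustering (smallest k meeting a target
cluster radius), per-residue SASA ratios (Shrake–Rupley, 1.4 Å probe),
native-contact ratio maps, basin populations, and Cα covariance analysis
(principal components, total MSF = trace, per-residue RMSF along modes).

## Worked example

Because the deposited structures a study would use are a download away, the
package ships a synthetic *minifold* — a 12-residue poly-glycine β-hairpin
emitted as PDB text with an atom-level contact map and a genuinely two-state
folding equilibrium — so the whole pipeline runs from nothing:

```
$ python examples/06_full_pipeline.py
{
  "n_contacts": 41,
  "native_energy": -41.0,
  "swap_acceptance": 0.655,
  "melting_temperature": 1.4948,
  "basins": {"basin0": [-39.0, -3.0], "basin1": [-3.0, 1.0]},
  "populations": {"basin0": 0.825, "basin1": 0.175},
  "cluster_populations": {"basin0": 0.8167, "basin1": 0.1833},
  "n_clusters": 36,
  "pca": {"total_msf": 113.11, "top_k": 5, "msf_fraction_top_k": 0.7175}
}
```

Reading: the hairpin has 41 native contacts (native energy −41); its heat
capacity peaks at T_m ≈ 1.49, where the free-energy profile over E shows a
folded/collapsed basin (E from −39 to −3) and a free-coil basin at E ≈ 0
separated by the nucleation barrier of the first cross-strand contact.  At
T_m the collapsed basin holds 82.5% of the equilibrium ensemble — and the
same populations emerge from structural clustering (81.7%), the cross-check
between energetic and geometric state definitions.  The top five principal
components carry 72% of the mean square fluctuations: melting is dominated
by a few collective strand-fraying motions.

The other examples isolate one capability each (model building, conservation
checks against a closed-form two-particle system, replica exchange + WHAM,
ensemble analysis, essential dynamics).  The same pipeline runs from a shell:

```
gofold run --config my_study.yaml --seed 1 --out results/
```

where the YAML config selects the structure (a PDB path or the minifold
fixture), the temperature ladder, event budgets, cluster radius and seeds;
`--stage build|simulate|thermo|analyze|pca` runs a single stage.

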