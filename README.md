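# dimerscope

Trajectory analysis for coarse-grained self-assembly ensembles of membrane
receptors — in particular G protein coupled chemokine receptors (CXCR4,
CCR5, CCR2) dimerizing in POPC and POPC/cholesterol bilayers.

Such studies run hundreds of independent coarse-grained MD replicas in
which two receptors diffuse, collide and dimerize. `dimerscope` implements
the complete downstream analysis:

* **Association kinetics** — two receptors count as a dimer once their
  TM–TM interaction energy (Lennard-Jones + Coulomb) falls below
  −50 kJ/mol; a dimer dissociates when it rises above −1 kJ/mol (the band
  in between is hysteretic). The first-order association rate *k* comes
  from fitting the surviving-monomer fraction f(t) = e^(−kt) over the
  replica ensemble, with a censored-exponential maximum-likelihood
  estimate as a cross-check.
* **Lower-bound binding free energies** — from the ratio P₀/P₁ of
  post-dissociation monomeric time to dimeric time:
  K_D = (P₀/P₁)/(N_Av·V) and ΔG = RT·ln(K_D/c°), with V the volume of the
  protein–lipid slab and c° = 1 mol/L.
* **Dimer-interface classification** — each protomer carries a molecular
  frame (principal in-plane axes of its TM backbone beads); the relative
  orientation of a dimer is (β, φ, χ) with χ = (180° + β − φ) mod 360.
  Last-window (β, χ) samples are turned into a doubly periodic kernel
  density height-field; watershed segmentation of the field assigns every
  replica to an interface basin, and basins are named by the contacting
  helices (e.g. `TM1,H8/TM4,5`). Representative structures are the basin
  members closest to the maximum with the strongest interaction energy.
* **Binding-position densities** — circular KDEs of β/χ mapped onto the
  angular footprints of helices TM1–TM7 and H8.
* **Cholesterol contacts** — residue-resolved occupancy (any of the 8
  cholesterol beads within 0.62 nm of any residue bead) and 3D spatial
  densities of the 5 nearest cholesterol molecules and their polar ROH
  headgroups in the receptor-fixed frame.
* **Lateral diffusion** — Einstein-relation D = slope(MSD)/4 on a 5–20 ns
  lag window, with protein–membrane centre-of-mass motion removed.
* **Structure metrics** — superposed (Kabsch) RMSD including a
  partial-fit mode, Shrake–Rupley buried surface area, percent identity
  from supplied alignments, and the rubber-band elastic network
  k_ij = f·exp(−a·d_ij^(2p)) between backbone beads within 0.9 nm.
* **Synthetic data** — generators for every stage (energy ensembles,
  idealised 7-TM bundles, exact dimer placements, angle mixtures,
  cholesterol hotspot fields, Brownian walks) with machine-readable
  ground truth, so the full pipeline is testable without MD runs.

## Worked example

```python
from dimerscope import DimerKinetics, synthetic

ens = synthetic.gen_energy_ensemble(k_on_per_us=0.25, n_replicas=500,
                                    t_sim_us=3.0, seed=0)
res = DimerKinetics(ens.traces, t_sim_us=3.0, volume_nm3=484.0,
                    ensemble_id="synthetic-popc").fit()
print(res.summary())
```

```
Dimerization kinetics: synthetic-popc
----------------------------------------------
replicas                 500
simulation length        3 us
dimerization criterion   -50 kJ/mol
k (survivor fit)         0.262 /us (se 0.001)
k (censored MLE)         0.272 /us
final dimers             280
dimerization events      323
dissociation events      43
dimerization propensity  0.187 /us
dissociation propensity  0.133
P0/P1                    0.0093
slab volume              484.0 nm^3
K_D                      3.185e-05 M
dG lower bound           -26.69 kJ/mol
```

The generator planted an association rate of 0.25 µs⁻¹; both estimators
recover it within a few percent at this ensemble size. `final dimers` is
the number of replicas ending dimeric; the propensity divides it by the
replica count and the per-replica simulation time. P₀/P₁ is small because
only a fifth of formed dimers ever dissociate under the generator's
defaults, which translates into the strongly negative ΔG lower bound.

A command-line layer mirrors the library:
`dimerscope validate|kinetics|orient|interfaces|chol|diffusion|rmsd|bsa|rubberbands|pid|simulate`
(see `dimerscope --help`).

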