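# mdnetics

Post-simulation inference for protein-complex trajectory ensembles,
built for the question "why does variant B of this complex bind tighter
than variant A?" — the comparison one faces with a parental versus an
affinity-engineered T-cell receptor bound to the same peptide–MHC. Given
replica trajectory ensembles of the two systems, the package computes:

- **Flexibility**: RMSD after Kabsch superposition, block-averaged RMSF,
  radius of gyration, hydrogen-bond counts, residue-pair distance
  distributions with contact occupancy.
- **End-state energetics**: ΔE = E_complex − (E_receptor + E_ligand) for
  short-range and full-range Coulomb/LJ terms, γ·SAS + b apolar
  solvation from Shrake–Rupley SASA, and polar solvation from a built-in
  finite-difference linearized Poisson–Boltzmann solver; plus
  residue-pairwise energies gated by a 6 Å any-frame contact rule.
- **Correlation networks**: generalized correlation
  r_MI = √(1 − e^(−2I/3)) from a Kraskov kNN mutual-information
  estimator, filtered by a 5 Å / 70% occupancy contact map, with
  Dijkstra shortest "allosteric" paths on −log10(r) edge weights.
- **Entropy and ΔΔG**: Schlitter configurational entropy with binding
  cycles, and BAR / Crooks-Gaussian-intersection estimates from
  forward/backward nonequilibrium work ensembles combined through
  ΔΔG_b = ΔG_mut(complex) − ΔG_mut(isolated).

A synthetic-data module generates trajectory ensembles with planted,
analytically known structure (correlations, contact geometry, interface
electrostatics, Crooks-consistent work distributions), so the whole stack
is validated end-to-end without external data. See `docs/methods.md` for
the models, conventions and limitations.

## Worked example

Run the pipeline on the bundled synthetic parent/mutant pair (the mutant
carries a planted tighter interface salt bridge):

```sh
mdnetics run --seed 1 --outdir results/run
```

or drive the stages individually with the numbered scripts:

```sh
python analysis/01_generate_systems.py --seed 1
python analysis/03_energetics.py --seed 1
python analysis/05_entropy_free_energy.py --seed 1
```

`03_energetics.py` prints, per system, the four binding-energy terms with
the standard deviation of the replica mean in parentheses:

```
mutant:
  dE E_SR             -223.178 (0.484) kJ/mol
  dE E_Coul/LJ        -223.178 (0.484) kJ/mol
  dE E_solv-apolar      -4.971 (0.002) kJ/mol
  dE E_solv-polar       43.048 (3.522) kJ/mol
```

The parent's E_SR is −156.985 (0.287) kJ/mol: the mutant's planted salt
bridge (one charged ligand bead moved 0.1 nm closer to its partner) makes
its interaction energy ~66 kJ/mol more favourable, partially opposed by a
higher polar-solvation penalty — the signature pattern of an
electrostatics-driven affinity gain. `05_entropy_free_energy.py` closes
the loop with the work-based cycle:

```
BAR: dG(complex) = -10.11 +- 0.08, dG(isolated) = -6.11 +- 0.08,
     ddG = -3.99 +- 0.11 kJ/mol (planted -4.0)
```

and `04_correlation_network.py` recovers the planted allosteric route
`0 → 3 → 6 → 9` (total weight ≈ 0.18) against the decoy bridges.

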