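# membind

Residue-level analysis of cationic antimicrobial peptides binding to lipid
bilayers, built around the indolicidin–DMPC system (indolicidin:
ILPWKWPWWPWRR-NH2, +4 charge; DMPC: a zwitterionic bilayer-forming lipid
with choline G1, phosphate G2, glycerol G3 and two myristoyl tails G4/G5).

The package is aimed at simulators who have peptide + bilayer trajectories
(PDB topology, DCD/XTC coordinates) and want the standard battery of
membrane-binding observables with per-trajectory standard errors:

- **Peptide structure** — intrapeptide contact probabilities `<C(i,j)>`
  (heavy-atom pairs < 4.5 Å, |j−i| ≥ 2), ranked top contacts and their
  Spearman comparison between environments, turn content from STRIDE
  assignment records, radius of gyration (mean-distance convention),
  end-to-end distance, Wimley–White hydrophobic moments.
- **Binding profile** — side-chain center-of-mass depths `z(i)` from the
  bilayer midplane; inserted / surface-bound / unbound states relative to
  the leaflet phosphorus plane `z_P` with a 6.5 Å interfacial margin;
  lipid coordination `<C_l(i)>`, structural-group resolution
  `<C_l(i,k)>`, hydrogen-bonded contact fractions, tandem coordination,
  water contacts.
- **Bilayer response** — cylindrical lipid/water density fields `n(r,z)`
  around the peptide, equal-density thickness `D(r)` with the indentation
  ΔD relative to the footprint radius `r_c = 13 Å`, and sn-2
  carbon-deuterium order parameters `S_CD = <(3 cos²θ − 1)/2>`, split by
  peptide contact.
- **Bilayer-aware clustering** — a 2D Kabsch superposition (in-plane
  rotation/translation only; z is never touched, so insertion depth
  contributes to the RMSD) feeding Daura-style greedy clustering at a
  5.4 Å cutoff, with cluster-conditioned structural profiles.
- **REST** — the replica-exchange-with-solute-tempering formalism:
  geometric temperature ladder, scaled enthalpies
  `H_r = E_ss + √(T_r/T_0)·E_sv + (T_r/T_0)·E_vv`, the exchange criterion
  `α = min(1, e^−Δ)`, and a 1-D harmonic toy simulator validating its
  statistical properties.
- **Synthetic data** — a generator that emulates the two-leaflet DMPC-like
  system (49 lipids/leaflet, `z_P ≈ ±17.4 Å`, one peptide per leaflet, a
  water slab) from a stated noise model with fully recorded ground truth,
  so every estimator is testable end to end without MD.

Both peptide copies are pooled by canonicalizing each frame into an
"upper-leaflet" convention (reflection about the midplane, which preserves
all distances); the trajectory — never the peptide copy — is the
independent-sample unit for standard errors.

## Worked example

```python
from membind import (SyntheticConfig, generate_trajectory, residue_depths,
                     classify_states, s_cd, IL_TOP_CONTACTS,
                     rank_top_contacts, spearman_rank_correlation)

cfg = SyntheticConfig(frames=200, n_trajectories=2, seed=7)
trajset, truth = generate_trajectory(cfg)

states = classify_states(residue_depths(trajset))
print(f"binding probability: {states.binding_probability:.2f}")
print(f"mean P_inserted:     {states.P_inserted.mean():.2f} "
      f"(planted {truth.state_weights[:, 0].mean():.2f})")

op = s_cd(trajset, contact_split=True)
print(f"-<S_CD> bulk / in-contact: {op.mean_minus_scd():.3f} / "
      f"{op.mean_minus_scd(contact=True):.3f}")

bil = rank_top_contacts(IL_TOP_CONTACTS["bilayer"])
wat = rank_top_contacts(IL_TOP_CONTACTS["water"])
print(f"Spearman rho (excl. top 3 / all): "
      f"{spearman_rank_correlation(bil, wat, exclude_top_k=3):.2f} / "
      f"{spearman_rank_correlation(bil, wat):.2f}")
```

prints

```
binding probability: 1.00
mean P_inserted:     0.56 (planted 0.56)
-<S_CD> bulk / in-contact: 0.164 / 0.123
Spearman rho (excl. top 3 / all): 0.26 / 0.69
```

The binding probability is the fraction of frames in which at least one
residue is inserted or surface-bound; `P_inserted` recovers the planted
depth-state mixture; the in-contact chains are less ordered than bulk
chains because footprint lipids carry a lower planted tilt concentration
(plus a geometric selection toward tilted chains); and the rank statistics
compare the reference top-contact listings for the bilayer-bound and
aqueous peptide.

A command-line interface mirrors the library:

```bash
membind generate --frames 200 --trajectories 2 --seed 7 --out sys
membind analyze --topology sys.pdb --trajectory sys.dcd --out results/
membind rest-demo --replicas 10 --steps 20000
```

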