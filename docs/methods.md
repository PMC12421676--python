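# Methods

This note documents the models, conventions and numerical choices behind
`membind`, and what the synthetic-data generator does and does not emulate.

## Coordinate conventions and leaflet canonicalization

All analyses run in a canonical frame: the bilayer midplane (midpoint of
the two leaflet phosphorus planes) sits at z = 0 and the analyzed peptide's
leaflet is mapped to positive z. When the analyzed peptide lives in the
lower leaflet, the whole frame is reflected, z → 2·z_mid − z, which is an
involution and preserves every pairwise distance; x and y are untouched.
Both peptide copies of the symmetric two-peptide system therefore
contribute samples in one convention. The lateral minimum-image convention
is applied in x and y only (orthorhombic box, bilayer normal along z).

`z_P` is the mass-weighted z center of the phosphorus atoms of a leaflet.
Mass weighting is a formal choice — phosphorus atoms are identical, so it
coincides with the arithmetic mean; geometric centers are used wherever an
observable is defined through a geometric center (e.g. the radius of
gyration).

Leaflets are assigned from each lipid's phosphorus side of the midplane at
frame 0 and reassigned only if a lipid persists on the other side for every
later frame supplied; such flips are logged and are not expected in
restrained bilayers.

## Structural probes

- Contacts: two groups are in contact in a frame iff any heavy-atom pair is
  closer than 4.5 Å. Intrapeptide contacts are restricted to |j − i| ≥ 2.
- Hydrogen bonds: d(D, A) < 3.5 Å and ∠DHA > 120°.
- Radius of gyration: the **mean distance** of peptide heavy atoms from
  their geometric center. This differs from the conventional
  root-mean-square radius (always ≥ the mean-distance value, by Jensen's
  inequality), which is available as `radius_of_gyration_rms` to avoid
  silent divergence.
- Spearman rank correlation between top-contact listings uses the printed
  integer ranks (no mid-rank tie correction); within a pre-ranked listing
  the listed order is the rank, including among tied probabilities. With
  `exclude_top_k`, the top-k sets of both rankings must coincide and the
  remainder is re-ranked 1..n.
- Hydrophobic moment: μ = |Σ h_i (r_i − r̄)| with the Wimley–White
  interfacial scale (kcal/mol) and one position per residue
  (side-chain centroid, or CA on an ideal helix built at 100°/residue,
  1.5 Å rise). The value depends on the structure and sign convention
  supplied; the package fixes neither beyond these defaults.
- Secondary structure is consumed from STRIDE ASG records (a multi-frame
  dialect separated by `REM FRAME` lines); `LOC Turn*` records count as
  β-turns and `LOC Gamma*` as γ-turns. A simplified built-in turn assigner
  (β: d(CAᵢ, CAᵢ₊₃) < 7 Å; γ: an i→i+2 backbone H-bond) is provided for
  STRIDE-free operation and is explicitly approximate.

## Binding classification

Per frame and residue, with z(i) the side-chain center of mass:
inserted if z(i) < z_P; surface-bound if z_P ≤ z(i) < z_P + 6.5 Å;
unbound otherwise. The peptide-level binding probability is the fraction
of frames with ≥ 1 residue inserted or surface-bound; this is the simplest
definition consistent with the 6.5 Å margin (an any-residue-lipid-contact
variant can be built from `lipid_contacts`). A whole-residue
center-of-mass depth is available as an option. Depth histograms default
to 0.5 Å bins (unstated in the source analyses; results are insensitive at
this scale).

## Bilayer response

Density fields n(r, z) are accumulated per canonical view with r measured
from the per-frame lateral geometric center of the peptide's heavy atoms,
counts divided by exact annulus volumes π(r₂² − r₁²)Δz and frames; default
grid Δr = Δz = 1 Å. Region averages near/away of the footprint radius
r_c = 13 Å are volume-weighted over annuli. The default leaflet slab for
region densities is z ∈ [0, 17.4] Å; depression-recovery checks use a
head-group slab (z ∈ [10, 20] Å) because the sn-2 chains tilt laterally by
up to ~10 Å and smear the near/away partition.

Thickness D(r) = z⁺(r) − z⁻(r) traces the z at which lipid and water
densities are equal, found per radial bin by the first strict sign change
of (lipid − water) scanning outward from the midplane, located by linear
interpolation between bracketing bins (symmetric under swapping the two
fields). Radii without a crossing are masked with a warning. ΔD_near is
mean D(r ≥ r_c) − mean D(r < r_c); ΔD_center uses the mean of the
innermost annuli (r < 3 Å) as "D(r ≈ 0)" to suppress small-bin counting
noise.

S_CD(i) = ⟨(3cos²θ − 1)/2⟩ over both hydrogens of each sn-2 carbon, with θ
the C–H angle to the bilayer normal; −S_CD is reported by convention and
is bounded in [−1, 0.5]. The contact split partitions lipids per frame by
any-heavy-atom contact with the peptide.

## Bilayer-aware clustering

Structures (peptide heavy atoms by default; CA-only available) are strided
(every 10th frame) from all trajectories and both copies in the canonical
convention. Alignment is a two-dimensional Kabsch superposition: the 2×2
cross-covariance SVD with a reflection guard yields the optimal in-plane
rotation + translation; z coordinates are never rotated or translated, so
insertion-depth differences contribute fully to the 3D RMSD (which is then
not a metric, but is symmetric and never exceeds the unaligned RMSD).
Daura clustering repeatedly extracts the structure with the most neighbors
within the 5.4 Å cutoff; ties in neighbor count break toward the lower
structure index so the result is deterministic. Clusters with probability
of occurrence > 1% count as populated; the centroid reported is the
max-neighbor structure.

## REST

The temperature ladder is geometric, T_r = T_min (T_max/T_min)^(r/(N_R−1)),
over 330–430 K (10 replicas for the bilayer system, 6 for the aqueous one).
Replica enthalpies scale the solute–solvent energy by √(T_r/T_0) and the
solvent–solvent energy by T_r/T_0, so the unmodified enthalpy is recovered
only at r = 0, and the solvent–solvent term cancels exactly from the
exchange exponent Δ (because β_r·(T_r/T_0) = 1/(R̄T_0) for every replica);
this cancellation is enforced as a property test. "Enthalpy" is
configurational energy only — the PV term cancels between the equal-volume
toy states and is omitted. R̄ = 1.98720425864×10⁻³ kcal/(mol·K).

The toy demonstrator samples a 1-D harmonic solute/solvent pair per replica
by Metropolis Monte Carlo under the scaled enthalpy and attempts
alternating neighbor exchanges every 2 sweeps. Its oracles are exact:
each replica's equilibrium is a bivariate Gaussian, so acceptance can be
checked against independent exact sampling, and detailed balance implies
uniform walker-temperature occupancy. Real exchange rates of molecular
systems depend on their energy fluctuations and are out of scope.

## Synthetic generator: what it emulates, and what it does not

The generator draws statistically independent frames from a stated noise
model — no energies, no Boltzmann sampling, no dynamics. It emulates:

- 49 lipids per leaflet on a jittered 7×7 lattice (spacing from the
  56.6 Å box), per-lipid phosphorus z ~ N(±17.4, 0.8²) Å, emulating the
  leaflet restraints of the source simulations.
- Reduced-resolution molecules: peptides as backbone (N, CA, C, O) plus a
  side-chain centroid pseudo-atom sized by residue bulk, with explicit
  polar hydrogens on backbone N and charged side chains; lipids with named
  CHARMM36 atoms covering G1–G5 including sn-2 carbons C2₂–C2₁₄ carrying
  two hydrogens each built from ideal tetrahedral geometry; waters as
  single beads at the bulk oxygen number density 0.0334 Å⁻³; 4 chloride
  counterions per +4 peptide copy.
- Per-residue depth states drawn from an (inserted, surface, unbound)
  mixture with truncated-normal depths relative to the *final* per-frame
  z_P (a per-frame fixed point accounts for planted lipid translations, so
  the classifier's thresholds are exact and the sampled states are
  recovered to machine precision). Default weights emulate a C-terminally
  anchored profile (mean ≈ 0.56/0.21/0.23, residue 5 least inserted).
- Three lateral pose templates (arc, hairpin, compact coil) with
  occupancies 0.45/0.35/0.20 and 0.4 Å coordinate noise. In the default
  `depth_mode="mixture"` the iid depth draws dominate the pairwise z-RMSD,
  so poses are intentionally *not* clean clusters; `depth_mode="template"`
  ties depths to templates for pose-recovery tests.
- sn-2 chain directors tilted by β with density ∝ exp(κ·cosβ) on
  cosβ ∈ [0, 1]. With hydrogens azimuthally uniform about the director,
  S_CD = (1 − 3⟨cos²β⟩)/4 in closed form; κ = 2.7 gives −S_CD ≈ 0.164
  (an ordered fluid-phase chain) and footprint lipids get κ = 2.3
  (−S_CD ≈ 0.142, a ~13% disordering). The footprint assignment is an
  exogenous rule (lipid P within r_c of the peptide center), *not* the
  measured 4.5 Å contact criterion, to avoid a selection feedback between
  sampled tilt and contact classification; closed-form checks therefore
  run on uniform-κ systems, and the measured contact split shows a larger
  contrast than planted because contact selection favors tilted chains.
- A lateral density depression (each unplanted footprint lipid displaced
  beyond r_c with probability 0.21 per frame) and a thickness dimple (the
  leaflet surface and the water slab's lower edge pulled down by
  11.9·max(0, 1 − (r/r_c)²) Å). Planted coordination: designated lipids
  near the footprint boundary are translated under Ile1, Lys5, Arg12 and
  Arg13 (phosphate-oxygen targets, two of them shared by the tandem
  Arg12/Arg13 pair) at per-frame rates, with collinear D–H···A geometry at
  the planted hydrogen-bond rates.
- The two peptide copies sit at maximally separated lateral centers so
  each leaflet's density field is unperturbed around the opposing peptide.
- STRIDE-dialect secondary-structure files with per-residue turn
  probabilities (default: elevated for residues 3–6 and 9) and Poisson
  β/γ-turn records (means 0.60/0.12 per frame).

It does **not** emulate: excluded volume (water beads may overlap peptide
atoms), peptide desolvation on binding (water-contact counts are
shell-geometry dominated, so the bound/free comparison does not reproduce
a physical desolvation magnitude), correlated dynamics or autocorrelation
times, area-per-lipid elasticity, or any force field. Passing recovery
tests therefore demonstrates estimator correctness on known ground truth,
not fidelity to real bilayer physics.

## Problem sizes and statistical checks

Recovery checks use 5000 frames (5 trajectories × 1000 frames, both
copies) for depth states, 6×200 frames for the order-parameter closed
form, 3×200 frames for the density depression (quotient against an
unperturbed run, tolerance 0.04 on the ratio — chosen a priori to cover
lateral smearing across the r_c boundary), 3×300 frames for the dimple
(tolerance 2 Å, covering grid interpolation and center wobble), and
3×170 frames at stride 10 for pose recovery. Standard errors treat each
trajectory as one independent sample; binomial/multinomial standard errors
are used where a planted rate gives them in closed form. The toy-REST
occupancy check estimates errors from 10 block means.

## Known limitations

- Trajectories are loaded fully into memory (float32); canonical views are
  produced lazily, one float64 copy at a time.
- The thickness tracer assumes a single lipid/water interface per leaflet
  per radial bin; strongly non-monotonic density profiles (e.g. pore
  formation) would need a different definition.
- The reduced peptide model has no Gly; the CA fallback for absent side
  chains is implemented but exercised only synthetically.
- Average ΔC between environments is reported unitless (a contact-count
  difference); the hydrophobic-moment magnitudes depend on the structure
  convention supplied and are not pinned to any particular published value.
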