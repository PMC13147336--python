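# Methods

This note documents the models, conventions, numerical choices and known
limitations of `hemebundle`. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Coordinate conventions

Coordinates are Å in right-handed axes; residue numbering is 1-based per
chain. Multi-model PDB files are read/written through biotite; atom
identity (chain, residue number, atom name) must be identical across
models — a mismatch raises a consistency error and is never silently
repaired. Nonstandard residues are accepted through a user-extensible
registry (defaults: AIB, DAB, the DPX deuteroporphyrin hetero-residue and
the CO/FE metal); deposited files using other codes supply a JSON registry.

## Geometric descriptors

**Helix axes.** Local helix centers are estimated from sliding windows of
four consecutive Cα atoms: the angle bisectors at the two inner atoms both
point toward the axis, and the center is the midpoint of closest approach
of the two bisector lines (Kahn-style). A total-least-squares line through
the centers gives the axis, oriented N→C; the rise per residue is the mean
step of Cα projections onto it. PCA on raw Cα positions is biased by the
helical winding for 8–12-residue helices, which is why the bisector
construction is used. Default axis residue ranges are TD 2–13 and D 2–9,
the helical stretches of the two chains; both are configurable. (The
reported helical regions and the φ/ψ residue ranges in the source study
differ slightly; the defaults follow the φ/ψ statement.)

**Interhelical angle** is arccos of the dot product of the two oriented
axis directions, in [0°, 180°] — deliberately not folded to [0°, 90°],
because with N→C orientation the two bundle families of a crossed sandwich
(≈64° vs ≈96°) are distinct and a fold would alias them.

**Family clustering** of per-model angles is 1-D single linkage: the
sorted values are split at the largest gap iff it exceeds a threshold
(default 20°), else one family. The larger family gets label 1; ties go to
the lower mean. The threshold is a design choice — the study reports
families without naming a method — and with per-model angle noise of a few
degrees the largest-gap statistic for families ~30° apart sits near this
threshold, so the default is best treated as a tunable.

**Axial-His orientation θ.** The porphyrin plane is fitted (total least
squares) to the 24 macrocycle heavy atoms, the imidazole plane to the 5
ring atoms. The porphyrin normal is oriented toward the His-bearing side;
θ is the signed angle, by the right-hand rule about that normal, from the
N21→N23 unit vector (projected into the porphyrin plane) to the projection
of the imidazole normal, folded into (−90°, 90°]. The sign convention is
ours — the printed values it must reproduce are signed but their convention
is not defined in the source — and it was validated jointly against the two
printed values (−33.4° / +35.1°) via the generator round-trip and a mirror
test (reflection flips the sign; rigid motions do not). When the imidazole
normal is within 10° of the porphyrin normal the in-plane projection
direction is meaningless and an error is raised. θ can be computed either
per model and averaged, or on a single (e.g. lowest-energy) model; the
descriptor table reports per-model values plus the ensemble mean.

**RMSD of the bundle** follows the NMR-ensemble convention: all models are
superposed (Kabsch, proper rotations only) onto model 1, a mean structure
is formed, models are re-superposed onto the mean, iterating until the mean
moves < 1e-4 Å; reported are mean ± sd of per-model RMSDs to the converged
mean. Whether the source study used the mean-structure or the pairwise
convention is unknown; the two differ by roughly √2, which its printed sd
absorbs.

**SASA** is Shrake–Rupley with quasi-uniform (golden-spiral) sphere points:
probe 1.4 Å, 960 points per atom, Bondi-type radii shipped as package data
(all configurable). Context atoms are always the whole model; the
selection only chooses which atoms are reported, so removing a context
atom can only increase reported areas. The porphyrin-exposure descriptor
sums the 24 macrocycle atoms plus the metal; the atom set the original
analysis used is unknown, and the ±2 Å² spread it printed absorbs
radii-set differences.

**Hydrogen bonds** use the geometric criterion D···A ≤ 3.5 Å and
D−H···A ≥ 120°. Hydrogens present in the file are used; missing backbone
amide hydrogens are built at 1.01 Å opposite the CA/C(i−1) bisector; other
donors without a buildable hydrogen are skipped with a warning. Identical
donor/acceptor pairs are merged across models and occupancy is the
fraction of models containing the contact; occupancies of different bonds
are independent and not normalized.

**Rotamers** map χ1/χ2 to the nearest of +60° (p), 180° (t), −60° (m) on
the circle, concatenated to the familiar two-letter labels. **Ramachandran
regions** come from a packaged 10°×10° grid (favored / additionally /
generously allowed / disallowed) built by dilating rectangular core
regions; it is a deliberately simplified map for bookkeeping, not a
stereochemical audit.

## NOE calibration and isomer rules

Upper limits follow the r⁻⁶ law with a single reference pair,
d = d_ref (I_ref/I)^{1/6}, clamped to [1.8, 7.0] Å. The original workflow
used per-class calibration curves whose constants are unpublished; a
single-reference calibration is scale-invariant and reproduces noiseless
generator intensities exactly, and class-specific references can be passed
per call. Sequence-separation classes are the standard |i−j| = 0 / 1 /
2–4 / ≥5 partition; inter-chain and peptide↔porphyrin contacts are
long-range, with the inter-moiety contacts also tallied separately.
Per-residue counts report both the nearest-integer and the raw ratio,
since printed per-residue figures can reflect truncation.

The **regioisomer rule**: the distal-chain position-9 side-chain amine
proton (Dab9 NHδ) lies next to its own anchoring propionate, so contacts
to propionyl-2 methylenes imply the TD chain sits on propionate 18
(isomer 1) and vice versa; contacts to both propionyls raise an ambiguity
error rather than a guess. The **diastereomer rule** combines the TD
anchor position with which side of the macrocycle (ring positions 3–10 vs
12–17) the proximal Leu5 contacts, for right-handed helices: anchor 18 +
3–10-side contacts → Δ; anchor 2 + 12–17-side → Δ; the mirrored
combinations → Λ; left-handed helices invert every call.

## Mössbauer and EPR analysis

The zero-field forward model is a constant baseline minus a sum of
quadrupole doublets, each two equal-depth unit-peak Lorentzians at
δ ± ΔE_Q/2 sharing one FWHM Γ (standard thin-absorber model; the source
does not state a lineshape). A doublet's integrated area is proportional
to amplitude × Γ, and area fractions are defined on that scale, so
unequal linewidths are handled correctly. Fitting is bounded nonlinear
least squares (scipy `least_squares`) with a seeded multistart — default
20 starts, the first data-driven (baseline from the 90th percentile,
moment-based center/spread), the rest random — keeping the best optimum.
Parameters are canonicalized by ascending ΔE_Q and area fractions
normalized to 1. Diagnostics: asymptotic standard errors from the
Jacobian, a boundary warning when a parameter sits on a bound, and an
identifiability warning when the ΔE_Q separation is below the linewidth.
With 1% noise on a 512-point grid the two-doublet simulate→fit round trip
recovers δ to ~0.01 and ΔE_Q to ~0.02 mm/s (asserted at 0.02/0.05 in the
suite).

**Spin-state classification** checks (δ, ΔE_Q) against shipped literature
ranges: five-coordinate HS Fe(III) (δ 0.25–0.43, ΔE_Q 0.4–1.0 mm/s),
six-coordinate HS (δ 0.32–0.45, ΔE_Q 1.22–2.07 mm/s), and a
quantum-admixed (QS) candidate window (HS-like δ with ΔE_Q > 2.5 mm/s —
the threshold sits between the six-coordinate upper bound 2.07 and the
smallest QS splitting reported for these systems, 2.64, and is
configurable). All matching labels are returned with distances to the
missed ranges; nothing is silently disambiguated, and `unclassified` is a
legitimate call. No correction for the different S = 5/2 vs S = 3/2
spin-transition moments is applied to relative intensities: only raw
fitted fractions are reported.

**Maltempo admixture**: a²₅/₂ = (g⊥ − 4)/2 with g⊥ the arithmetic mean of
the two perpendicular effective g-values (this convention reproduces the
published worked example 0.37 from g = 5.92, 3.56 and is overridable);
g⊥ = 4 and 6 are the pure S = 3/2 and S = 5/2 limits, values outside
[3.5, 6.5] are rejected, and mild excursions past the limits are clamped
with a flag.

## Synthetic generator: what it emulates, and what not

`assemble_sandwich` builds the stated world of the analyses: an idealized
planar DPIX (24 coplanar ring atoms, orthogonal N21–N23 / N22–N24 axes,
methyl/propionyl/H substituent stubs, metal at the center), a proximal
14-mer helix whose His6 imidazole is placed as a rigid planar ring bonded
to the metal (Nε2 at 2.1 Å) at an exact target θ, and a distal 10-mer
(with Aib3/Aib7 and Dab9) at an exact target interhelical angle with its
backbone center of mass at the target metal distance. Default sequences
are plausible stand-ins reconstructed from the residues the analyses
name, with unnamed positions filled by Gln. Per-model noise is i.i.d.
isotropic N(0, jitter_sd²) per coordinate, seeded; defaults (20 models,
0.3 Å jitter — matching the descriptor-recovery noise level the tests
state) are fixed. Non-bonded heavy-atom pairs closer than 2.4 Å between
assembly groups abort with an assembly error (the metal–imidazole
coordination contact is exempt).

Green recovery tests therefore establish that the descriptor estimators
are unbiased and correctly signed under coordinate noise on an idealized
geometry. They do **not** establish robustness to what real bundles add:
correlated (rigid-body-like) model-to-model variation, bent or frayed
helices, real side-chain packing (side chains here are mostly Cβ/proton
stubs, so the synthetic porphyrin SASA is far larger than a real bundle's
~24 Å², and H-bond networks are sparser), or nomenclature variation in
deposited files. Per-model θ noise deserves emphasis: a plane fit through
five ring atoms of ~1.2 Å radius turns 0.3 Å atomic noise into ≈12° of
per-model θ scatter, so θ comparisons should always quote the ensemble
mean and its error, which is why the recovery tests use hundreds of
models per grid point.

NOE peaks are generated as I = c/d⁶ per proton pair within a cutoff
(default 5 Å), with optional multiplicative Gaussian noise and a positive
intensity floor; noiseless output calibrates back to exact distances,
which is the round-trip the suite asserts.

## Reproducibility

Every stochastic step (jitter, NOE noise, spectral noise, multistart
initialization) takes an explicit seed; identical configuration + seeds
reproduce all numeric outputs bit-exactly, including through the CLI.
`scripts/acceptance.py --seed N --out f.json` derives its 10 spectral
noise seeds from N and reports the mean recovered major-doublet area
percentage of the two-doublet model described above.

## Known limitations

- No mmCIF support; no structure editing; validation limited to atom
  consistency.
- Analytic (non-sampled) SASA, flexible superposition and full secondary-
  structure assignment are out of scope.
- Magnetic (applied-field) Mössbauer and full spin-Hamiltonian EPR
  simulation are out of scope; EPR enters only through effective g-values.
- The Ramachandran map is a simplified 10° grid, not a PROCHECK audit.
- Comparisons against the deposited experimental ensembles require
  downloading them and supplying the appropriate residue registry; the
  shipped tests rely on generator ground truth instead.
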