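# hemebundle

Quantitative analysis of NMR structure ensembles of **helix–porphyrin–helix
miniproteins** (mimochrome-type synthetic hemeproteins) and of the Fe(III)
spin-state spectroscopy used to characterize them.

These miniproteins sandwich a deuteroporphyrin IX (DPIX) cofactor between
two short helical peptides: a proximal tetradecapeptide (**TD**) whose His6
provides the axial metal ligand, and a distal decapeptide (**D**) that covers
the other porphyrin face. Because the two DPIX propionates (ring positions 2
and 18) each anchor one chain, the conjugates exist as **regioisomers**
(which propionate carries which chain) and **Δ/Λ diastereomers** (which face
a chain occupies). The package is written for structural chemists who solve
such bundles by NMR and want the ensemble descriptors, restraint
bookkeeping and spin-state analysis reproducible in code.

## What it computes

**Ensemble descriptors** (`hemebundle.descriptors`)
- interhelical angle between the N→C oriented TD and D helix axes
  (4-Cα bisector construction + total-least-squares line), with
  single-linkage family clustering of the per-model angles;
- the signed axial-His orientation θ: the acute angle between the porphyrin
  N21→N23 reference axis and the projection of the imidazole plane normal
  onto the porphyrin plane, θ ∈ (−90°, 90°];
- metal-to-chain distance |Co − CoM(D backbone)|, porphyrin solvent
  exposure (Shrake–Rupley SASA), χ1/χ2 rotamer letters (p/t/m), φ/ψ
  statistics with simplified Ramachandran region labels, hydrogen bonds
  with ensemble occupancy, and conformational shifts Δδ = δ_obs − δ_rc.

**NOE restraints** (`hemebundle.noe`) — intensity→distance calibration by
the r⁻⁶ law, d = d_ref (I_ref/I)^{1/6} clamped to [1.8, 7.0] Å; restraint
classes (intraresidue / sequential / medium / long, plus an inter-moiety
peptide↔porphyrin tally); rule tables mapping porphyrin contact patterns to
the regioisomer and the Δ/Λ diastereomer.

**Spin spectroscopy** (`hemebundle.spin`) — zero-field Mössbauer spectra as
sums of Lorentzian quadrupole doublets (two equal-depth lines at
δ ± ΔE_Q/2, shared Γ); `MossbauerModel(spectrum, n_doublets).fit()` returns
a `MossbauerResults` with parameters, standard errors and `summary()`;
(δ, ΔE_Q) classification against ferric-heme literature ranges; and the
Maltempo quantum-admixed-spin estimate a²₅/₂ = (g⊥ − 4)/2.

**Synthetic ground truth** (`hemebundle.synthetic`) — ideal helices with
exact φ/ψ, an idealized planar DPIX template, and fully assembled sandwich
ensembles with controllable interhelical angle, θ, metal offset and
per-model coordinate jitter, so every analysis stage is testable without
downloading deposited structures.

## Worked example

```python
import numpy as np
from hemebundle import SandwichBlueprint, assemble_sandwich, MossbauerModel
from hemebundle.descriptors import descriptor_table
from hemebundle.spin import MossbauerDoublet, simulate_mossbauer

bp = SandwichBlueprint(target_interhelical_angle=64.0, target_theta_his=35.0,
                       jitter_sd=0.3, n_models=20, seed=1)
ensemble, truth = assemble_sandwich(bp)
df = descriptor_table(ensemble)
agg = df.attrs["aggregates"][1]
for k in ("interhelical_angle", "theta_his", "co_to_com_distance"):
    print(f"{k}: {agg[k][0]:.1f} +/- {agg[k][1]:.1f}")
```

prints (family 1 mean ± sd over the 20 jittered models)

```
interhelical_angle: 64.6 +/- 2.6
theta_his: 40.0 +/- 13.2
co_to_com_distance: 7.0 +/- 0.3
```

— the 64° blueprint angle and the 7.0 Å metal offset are recovered within
the jitter-induced spread; θ is the noisiest descriptor because it rests on
a plane fit through only five imidazole atoms (see `docs/methods.md`).

Fitting a simulated two-doublet Mössbauer spectrum:

```python
truth = [MossbauerDoublet(0.42, 1.47, 0.30, 0.53),
         MossbauerDoublet(0.40, 3.20, 0.30, 0.47)]
spec = simulate_mossbauer(truth, np.linspace(-4, 4, 512),
                          total_depth=0.1, noise_sd=0.001, seed=1)
print(MossbauerModel(spec, n_doublets=2).fit(seed=0).summary())
```

```
Mössbauer quadrupole-doublet fit
================================================================
n_points: 512   n_doublets: 2   starts used: 20
baseline: +0.00002   RMSE: 0.00091   RSS: 0.000426253
----------------------------------------------------------------
doublet   δ (mm/s)  ΔE_Q (mm/s)   Γ (mm/s)   area %
      1      0.419        1.469      0.302     53.2
      2      0.400        3.201      0.302     46.8
================================================================
```

Both doublets (a six-coordinate high-spin species at ΔE_Q = 1.47 mm/s and
a quantum-admixed-spin candidate at 3.20 mm/s) are recovered with the
53:47 area split intact at 1% noise.

## Command line

```bash
hemebundle simulate --angle 64 --theta 35 --n-models 20 --seed 1 --out-dir sim
hemebundle descriptors sim/sandwich.pdb --out-dir out
hemebundle maltempo --gx 5.92 --gy 3.56        # -> a_5/2^2 = 0.37
hemebundle moessbauer-fit spectrum.dat --n-doublets 2
```

Subcommands: `descriptors`, `hbonds`, `restraints`, `assign-isomer`,
`moessbauer-fit`, `maltempo`, `simulate`. Re-running with the same
configuration and seeds reproduces every numeric output bit-exactly.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the package's headline recovery quantity from scratch: it
simulates the two-doublet spectrum at the solid-state regioisomer-1
parameters (δ(ΔE_Q) = 0.42(1.47) / 0.40(3.20) mm/s, areas 53:47,
Γ = 0.30 mm/s, 512-point grid, 1% Gaussian noise), fits it with the
two-doublet model over 10 derived noise seeds, and writes the mean
recovered major-doublet area percentage as JSON.
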