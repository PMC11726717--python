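# allodyn

Contact-gated dynamical network analysis of GPCR molecular-dynamics
trajectories, plus operational-model fitting of allosteric pharmacology.

`allodyn` is aimed at molecular pharmacologists and computational
structural biologists studying positive allosteric modulators (PAMs) of
class A GPCRs — the motivating system is the adenosine A1 receptor
(A1R), its agonists (adenosine, CPA, BnOCPA, NECA) and the PAM MIPS521.
It covers the two halves of such a study:

- **Trajectory analysis.** RMSD/RMSF after Kabsch superposition,
  side-chain dihedrals and rotamer-state occupancies, contact and
  hydrogen-bond persistency (% of frames, merged over replicas), and a
  residue-level **dynamical network**: Cα nodes, edges gated by contact
  persistency (within 4.5 Å in ≥ 75% of frames, non-consecutive
  residues) and weighted by the correlation of motion,

      W_ij = −log(|C_ij|),   C_ij = ⟨Δr_i·Δr_j⟩ / √(⟨Δr_i²⟩⟨Δr_j²⟩),

  interrogated through shortest/suboptimal paths, edge betweenness,
  Girvan–Newman communities and per-helix subnetworks. Selections
  understand Ballesteros–Weinstein labels (`bw 7.40-7.49`) via a sidecar
  residue map.

- **Allosteric pharmacology.** Unit-slope 3-parameter logistic fits
  (pEC50 per replicate, mean ± SEM per group) and a global fit of the
  **operational model of allosterism**

      E = Em·num^n / (den^n + num^n)
      num = τ_A[A](K_B + αβ[B]) + τ_B[B]K_A
      den = [A]K_B + K_A·K_B + K_A[B] + α[A][B]

  reporting the composite cooperativity **Logαβ = log10(αβ)** with a
  standard error, plus two-way ANOVA / Dunnett condition comparisons.

A first-class synthetic-data module generates every input with known
ground truth — harmonic Cα ensembles with a prescribed correlation of
motion (written as standard PDB/DCD so they flow through the same
readers as real data), planted-community graphs, geometric fixtures and
operational-model concentration–response tables.

## Worked example

Simulate a 4-replicate cAMP-style concentration–response surface for
adenosine with MIPS521 at 0–10 µM, then fit each curve and the global
operational model:

```python
from allodyn import synthetic as syn
from allodyn.pharm import fit_logistic3, fit_operational_allosterism

spec = syn.DoseResponseSimSpec(
    true_parameters=syn.agonist_params("adenosine"),
    seed=1, agonist="adenosine",
)
dataset = syn.gen_dose_response(spec)

for fit in fit_logistic3(dataset):
    agonist, mod = fit.group
    label = "vehicle" if mod == 0 else f"{mod*1e9:g} nM MIPS521"
    print(f"{agonist} + {label:16s} pEC50 = {fit.summary()}")

fit = fit_operational_allosterism(dataset, agonist="adenosine")
print(fit.summary())
```

```
adenosine + vehicle          pEC50 = 7.82 ± 0.07
adenosine + 10 nM MIPS521    pEC50 = 8.24 ± 0.05
adenosine + 100 nM MIPS521   pEC50 = 8.76 ± 0.05
adenosine + 1000 nM MIPS521  pEC50 = 8.93 ± 0.03
adenosine + 10000 nM MIPS521 pEC50 = 8.94 ± 0.04
Logαβ = 1.30 ± 0.04
```

The modulator left-shifts the agonist curve by about 1.1 log units at
saturation, and the global fit recovers the generating cooperativity
(Logαβ = 1.30) from the noisy surface. Each pEC50 line is the
mean ± SEM over the four simulated replicates.

The same analyses run from the shell: `allodyn synth dose-response`,
`allodyn pharm fit-allosterism`, `allodyn metrics rmsd|rmsf|contacts`,
`allodyn network build`, and `allodyn run config.yaml` for a full
YAML-configured pipeline over one or more trajectory conditions (see
`allodyn --help`).

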