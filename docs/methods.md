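# Methods

`allodyn` implements two loosely coupled analysis layers for studying
positive allosteric modulation of a GPCR (the motivating system is the
adenosine A1 receptor with the PAM MIPS521): a trajectory layer that
turns molecular-dynamics ensembles into structural descriptors and a
contact-gated dynamical network, and a pharmacology layer that fits
concentration–response data with the 3-parameter logistic equation and
the operational model of allosterism. A synthetic-data layer generates
every input with known ground truth so that each estimator can be
checked against a closed form or an exhaustive oracle.

## Trajectory layer

**Superposition and RMSD/RMSF.** Rigid-body fits use the Kabsch
algorithm with the determinant correction, so the returned rotation is
always proper. RMSD is reported per frame over an analysis selection,
optionally after fitting on a separate selection; both conventions for
ligand RMSD (receptor-superposed and ligand-frame) are available because
published ligand RMSDs do not always state which frame they use. RMSF
is computed per residue about the mean structure of the merged replicas
with a two-pass convention (align to a reference, take the mean,
re-align to that mean, re-measure). Superposing frames absorbs six
rigid-body degrees of freedom, deflating apparent fluctuations by about
`sqrt(1 − 6/(3N))` for an N-atom fit selection; for synthetic ensembles,
whose frames are generated in a common laboratory frame, fitting is
therefore optional (`fit_selection=None`), and that mode is the one the
analytic checks use.

**Dihedrals and rotamers.** Signed dihedrals follow the IUPAC
convention (calibrated against MDAnalysis) and live in (−180°, 180°].
Rotamer occupancies bin χ angles into g+ = (0°, 120°],
trans = (120°, 180°] ∪ (−180°, −120°], g− = (−120°, 0°].

**Contacts and hydrogen bonds.** A residue pair is in contact in a
frame when any heavy-atom pair across the residues lies within the
cutoff, default 4.5 Å, with the boundary value counting as a contact
(closed interval). Persistency is the percentage of frames in contact,
computed per replica and merged with frame weighting; per-replica values
are retained so condition differences can report a replica-level SD.
Hydrogen bonds use a donor–acceptor distance gate (default 3.5 Å) plus a
donor–H–acceptor angle gate (default ≥ 120°); the defaults are exposed in
configuration because geometric criteria vary between tools. Topologies
without explicit hydrogens must opt into a distance-only criterion.

## Network layer

Nodes are Cα residues. The correlation of motion is
`C_ij = <Δr_i·Δr_j> / sqrt(<Δr_i²><Δr_j²>)` over merged, optionally
superposed frames, with Δr the displacement from the time-mean position.
An edge joins residues i, j when (i) their contact persistency reaches
the threshold (default 75%, inclusive), (ii) they are not consecutive in
sequence (exclusion on by default), and (iii) `|C_ij|` exceeds a small
floor (default 1e-6) that prevents effectively infinite weights; gated
pairs below the floor are dropped with a warning. Edge weight is
`W_ij = −log(|C_ij|)`, natural log by default. The base is configurable
and provably irrelevant to shortest-path node sequences, betweenness
ranking and communities, because changing base rescales every weight by
one constant.

Shortest paths use Dijkstra with a deterministic lexicographic
reconstruction: among equal-cost optimal paths the lexicographically
smallest node sequence is returned. Suboptimal paths enumerate all
simple paths within a user tolerance of the optimum by depth-first
search pruned with the exact cost-to-go bound, with a configurable path
cap and an explicit truncation flag. Per-edge usage counts over the
ensemble are the "structural information" rendered as edge thickness in
network figures; that reading is a convention of the suboptimal-path
methodology and is recorded in the ensemble's metadata rather than
asserted as the only possible one.

Communities come from Girvan–Newman: the edge of highest weighted-path
betweenness is removed iteratively (ties broken by lexicographic edge
label) and the partition of maximum modularity over the removal
hierarchy is returned. Betweenness treats W as a distance; modularity
treats `|C|` as a connection strength. Mixing the two is deliberate:
information transfer is a path phenomenon (W), community cohesion a
coupling phenomenon (|C|), and both choices are invariant to the
logarithm base.

## Pharmacology layer

The operational model of allosterism predicts the response to agonist A
in the presence of modulator B as

    E = Em·num^n / (den^n + num^n)
    num = τ_A[A](K_B + αβ[B]) + τ_B[B]K_A
    den = [A]K_B + K_A K_B + K_A[B] + α[A][B]

At [B] = 0 this reduces algebraically to the operational model of
agonism, a property the tests verify to 1e-12 relative error. The
headline quantity is the composite cooperativity Logαβ = log10(αβ).
With functional data alone α and β are essentially aliased through
their product, so the default constraint set fixes the transducer slope
n = 1, shares Em across curves, fixes α = 1 and carries all cooperativity
in one log10(αβ) parameter, and ties K_A to the vehicle-curve potency
through K_A = EC50_vehicle·(1 + τ_A) (the n = 1 agonism relation); (α, β)
are reported separately only under user-supplied constraints. The global
fit runs over all curves simultaneously with multi-start initialization
on a fixed log-spaced grid; parameter bounds are derived from the data's
concentration span so results are invariant to the concentration unit
(switching M to nM shifts pK values by exactly 9 and leaves Logαβ
unchanged). The 3-parameter logistic (unit slope) is fitted per
replicate, and groups are summarized as mean ± SEM across replicates.
Condition comparisons use a two-way ANOVA (agonist × condition) on
per-replicate potencies with Dunnett tests against the control;
single-replicate conditions are excluded with a warning, and the
reported adjusted p is never below the raw two-sample p.

## Synthetic ground truth

**Harmonic ensembles.** For each Cartesian axis independently, frames
are i.i.d. draws from a multivariate normal over residues with
covariance `σ_i σ_j C_ij`. Consequently the per-coordinate SD of residue
i is σ_i, its 3-D RMSF converges to `sqrt(3)·σ_i`, and the correlation
of motion equals the prescribed target exactly in expectation — the
estimators can be checked against closed forms. Non-PSD targets are
rejected. What this generator deliberately omits: time autocorrelation
(every frame independent), anharmonicity, rigid-body diffusion, and any
force-field physics. Passing the recovery tests therefore shows the
estimators are correct, not that microsecond membrane-protein
trajectories would be reproduced.

**Other fixtures.** Dihedral fixtures place four atoms whose dihedral
equals a requested angle to 1e-6°; toy two-residue systems put probe
atoms at prescribed distances so contact gates can be toggled by
construction; the H-bond fixture builds a donor–H–acceptor triad with
exact distance and angle. Planted-partition graphs carry ground-truth
block labels, with within-block correlation magnitudes drawn from
[0.5, 0.9] and between-block from [0.1, 0.4].

**Concentration–response simulation.** The study conditions are: agonist
grids of 1 pM–1 µM (cAMP, half-log spacing) or 10 pM–10 µM (BRET-style G
protein dissociation), modulator at 0/10 nM/100 nM/1 µM/10 µM, four
replicates, responses on a 0–100 normalized scale. The published panel
potencies and cooperativities parameterize the generating model: the
vehicle pEC50 pins K_A via EC50 = K_A/(1+τ_A), and Logαβ pins β with
α = 1. Parameters the assays do not constrain are fixed once at
realistic values: Em = 100, τ_A = 10 (full agonists), τ_B = 0.3 (the
modulator's weak direct agonism), K_B = 100 nM. Additive Gaussian noise
with SD 8 response units was calibrated by simulation so the
per-replicate pEC50 scatter (SD ≈ 0.15 log units, SEM ≈ 0.07 over four
replicates) matches the published assay precision; the BRET-style
simulations reuse the same noise level even though the published BRET
SEMs are larger.

## Numerical choices and degenerate inputs

- Seeded determinism throughout: replica streams are spawned from a
  `SeedSequence`, so identical spec + seed is bit-identical output.
- Collinear fit selections, zero-variance residues, constant response
  curves, disconnected source/sink pairs and non-PSD covariance targets
  all raise named errors instead of returning garbage.
- Tie-breaks (path choice, edge removal) are lexicographic so repeated
  runs and node relabelings agree.
- Fit convergence: least squares with `ftol=1e-10`; logistic fits bound
  pEC50 to within 6 log units of the tested span.
- Contact boundary: a pair exactly at the cutoff counts as in contact.

## Problem sizes

The test-suite and acceptance-script runs use 25-seed recovery protocols
with 4 replicates per dataset, 100k-frame ensembles of 10 residues for
the estimator-convergence checks, 200 random ≤ 12-node graphs for the
path/betweenness oracles and 20-seed 3-block planted graphs for the
community checks — sizes chosen so every check rests on enough sampling
for its stated tolerance while the whole suite runs in about a minute.

## Known limitations

- The PDB dialect is strict (no insertion codes, no altlocs, no
  multi-model conformers); unsupported files fail loudly by design.
- Periodic-boundary effects are not handled; frames must contain whole
  molecules.
- The pipeline YAML does not express H-bond donor/acceptor lists; H-bond
  persistency is a library-level operation.
- Interaction typing is binary contact/H-bond only; π-stacking,
  salt bridges and water bridges are out of scope.
- Fitting α and β separately requires binding-style constraints the
  functional assays cannot supply; the package reports Logαβ as primary.
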