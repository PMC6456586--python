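# Methods

This note documents the models implemented in `cerna_emt`, their
assumptions, the parameters that matter, and what the synthetic-data tests
do and do not establish.

## MRE census

The census treats the pool of miRNA response elements (MREs) available to
one miRNA as a weighted sum of transcript abundances: each gene contributes
`abundance(g, t) × n_sites(g, c)` to site class `c`. Assumptions: input
rows are already aggregated to one abundance per gene (no isoform
resolution); sites act independently; abundance is proportional to molecule
count. The last assumption is made explicit by the anchoring step, which
rescales a TPM census by `copies_per_cell / TPM` measured for one anchor
species at one time by absolute qPCR. When several anchors are supplied the
geometric mean of their scales is used — a symmetric choice that treats the
anchors as log-scale replicates of a single proportionality constant.

TargetScan- and pictar-derived censuses are always computed separately and
never pooled, since the two predictors differ systematically in site counts.
Site classes outside {8mer, 7mer-m8, 7mer-A1} are binned as "other"; pictar
annotations carry no class labels and default to 7mer-m8.

Accounting of the MRE *expansion* between two times uses only positive
per-gene changes in the denominator: a gene whose MRE contribution shrinks
does not offset another gene's increase. The differential-expression gates
for candidate regulators are strict inequalities (FDR < 0.05,
|log2FC| > 1), and the functional-abundance filter keeps miRNAs with more
than 100 copies/cell — below that, target-site dilution makes repression
ineffective. Stoichiometry ratios are reported to two decimals.

## Equilibrium occupancy model

One miRNA species is distributed at thermodynamic equilibrium over site
pools with class-specific dissociation constants. Free miRNA `m` is the
unique non-negative root of

    m_total = m + Σ_c N_c · m / (Kd_c + m),

whose left side is strictly increasing in `m`; the solver brackets on
`[0, m_total]` (Brent, relative tolerance 1e-10), so convergence is
guaranteed and seed-free. Occupancy of class `c` is `m / (m + Kd_c)`.

Each time point is an independent equilibrium: no binding kinetics, target
turnover, dilution, or catalytic miRNA action (those belong to the circuit
model). The absolute affinity scale is a free parameter of this kind of
analysis; the defaults, Kd(8mer) = 25 copies/cell with relative affinities
8mer : 7mer-m8 : 7mer-A1 : other = 1 : 5 : 25 : 125, preserve the known
affinity ordering of seed classes and are fully overridable. Consequently
tests and the acceptance script assert *shape* properties of occupancy
(conservation, monotonicity, the dip-then-recover time course, the effect of
ablating the dominant ceRNA) rather than absolute occupancy values. A
brute-force mass-action relaxation (`equilibrium_oracle`) provides an
independent check of the algebraic solver; the two agree to < 1e-6 on random
instances.

## EMT circuit model

### Structure

The circuit couples two double-negative feedback loops in cascade, with an
integrated ceRNA:

* exogenous TGF-β signal activates snail1 transcription (Hill, with SNAIL1
  self-repression); miR-34 represses SNAIL1 translation and is
  transcriptionally repressed by SNAIL1 and ZEB1;
* SNAIL1 activates zeb1 transcription; zeb1 mRNA carries five miR-200 sites
  and is tracked together with its complexes c1..c5 (mass-action sequential
  binding with combinatorial factors); translation efficiency decreases
  steeply with the number of bound miRNAs; complex degradation returns a
  fraction λ_i of the bound miR-200 to the free pool (miRNA recycling);
* ZEB1 and SNAIL1 repress miR-200 transcription; miR-200 also has a basal,
  ZEB-independent transcription term;
* zeb1 transcription has a ZEB1 self-activation component;
* the ceRNA (FN1-like) carries one miR-200 site, forms a single complex
  species, and is transcribed under Hill control by SNAIL1 and ZEB1
  (multiplicative, each edge configurable as activation or repression with
  its own leak);
* an exogenous decoy 3′UTR with one site is part of the state vector with
  zero production unless a decoy perturbation switches it on.

Two structural choices deserve comment because the paper's phenomena depend
on them. First, ZEB1 self-activation is what lets a mesenchymal state
persist after signal withdrawal — without it, SNAIL1 (and hence zeb1
transcription) collapses at zero signal and EMT would always revert, so
irreversibility could not be represented. Second, the basal miR-200
transcription term defines the steady miRNA influx that the mesenchymal
state must dispose of. With 90% recycling the zeb1-complex route destroys
only 10% of the miRNA it processes, so this influx can only be absorbed by
the ceRNA's complex-degradation flux — which is precisely why the
mesenchymal state exists only when the ceRNA is present. Both motifs are
standard components of published EMT circuit models.

### Phenotypes

States are classified from (ZEB1, free miR-200): epithelial (E) if ZEB1 is
below a low threshold and miR-200 above a high one; mesenchymal (M) if the
converse; hybrid otherwise. The thresholds shipped in the parameter file
(ZEB1 0.3 / 1.0; miR-200 0.5 / 2.0, in the model's concentration units)
were set between the E and M branches of the tuned model, near their
geometric midpoints.

### Parameterization

All parameters live in editable YAML files shipped with the package
(`data/default.yaml`, `data/a549_like.yaml`); nothing is hard-coded. Units:
hours and arbitrary concentration units; "4 ng/ml TGF-β" maps to the
saturating dimensionless signal 1.0. Degradation rates follow the usual
hierarchy (mRNA half-lives of about an hour, proteins a few hours, miR-200
intrinsically long-lived at γ_m = 0.01 h⁻¹ with its effective lifetime set
by the recycling ratio λ). The recycling ratios of the five zeb1 complexes
default to λ = 0.9 — the long-miRNA-half-life regime — with
`with_recycling(0.5)` recovering the historical parameterization. The
remaining rate constants were tuned, by numerical bifurcation analysis, to
reproduce the qualitative behaviors that define the circuit:

* with the ceRNA, λ = 0.9: three coexisting stable states (E, a
  SNAIL1-high/ZEB1-low hybrid, M) in a window of low signal; only M stable
  at saturating signal; M persists at zero signal;
* without the ceRNA at λ = 0.9: no stable mesenchymal branch anywhere in
  the scanned signal range;
* with the ceRNA but its free-mRNA degradation rate raised to 1 h⁻¹
  (knockdown): no stable mesenchymal branch;
* without the ceRNA at λ = 0.5: the mesenchymal branch returns (the
  short-half-life regime does not need a ceRNA);
* fast ZEB1 versus slow miRNA: under induction, ZEB1 crosses half-maximum
  (~70 h) long before the total (free + bound) miR-200 pool halves — the
  measured miRNA declines only modestly over 300 h because most of it is
  recycled or parked in slowly degrading ceRNA complexes. Free miR-200, by
  contrast, must fall before ZEB1 can rise; the "slow miRNA" of the
  experimental record is the total pool, which is what qPCR measures.

The A549-like preset re-parameterizes the same topology (per the design
decision that both cell systems share the TF ⊣ miRNA ⊣ TF + one-site ceRNA
motif): its ceRNA is SNAIL1-activated with a small leak and ZEB1-*repressed*
(K = 3, so the repression is partial), reproducing the rise-then-partial-
fall of the ceRNA during EMT and its collapse after signal withdrawal. That
collapse floods the circuit with free miRNA and drives spontaneous
mesenchymal-to-epithelial reversion, which a decoy 3′UTR (production 2.0
during withdrawal) blocks. The MCF10A-like default keeps the ceRNA
ZEB1-activated, so the mesenchymal state feeds its own miRNA sink and EMT is
irreversible unless the ceRNA is knocked down (degradation ×20 during
withdrawal).

### Numerics

The right-hand side and its analytic Jacobian are hand-coded; Hill terms
clip negative inputs to zero (finite-difference agreement < 1e-5 on random
positive states). Integration is LSODA with rtol 1e-8 / atol 1e-10, split
at every signal or perturbation boundary; trajectories are required to stay
above −1e-8 (violations fail the run rather than being masked). Steady
states are found by polishing relaxation endpoints (canonical E / M / hybrid
initial conditions) and Latin-hypercube starts with scipy's `hybr`
root-finder using the analytic Jacobian; roots within relative distance 1e-4
are merged; stability requires every Jacobian eigenvalue real part below
−1e-9. Bifurcation scans reuse each grid level's roots as starts for the
next (grid continuation), which is robust and dependency-free; pseudo-
arclength continuation is out of scope. Conservation is exact: with all λ
set to 1 and zero miRNA production/decay, total miR-200 (free + bound,
weighted by bound count) drifts by < 1e-12 relative over 200 h.

### Trajectory fitting

`CircuitTrajectoryFit` estimates chosen scalar rates (default: the ceRNA
degradation and transcription rates γ_f, k_f) by Levenberg–Marquardt least
squares on log abundances, in log-parameter space (positivity for free).
Standard errors come from the Gauss–Newton covariance with a delta-method
back-transform. Identifiability matters: late-time ceRNA levels constrain
only the ratio k_f/γ_f, so the recovery experiment observes the ceRNA
trajectory on a geometric time grid (25 points, 2–150 h) that captures the
early accumulation transient; with 5% multiplicative log-normal noise this
recovers both parameters within 20% in well over 90% of replicates.

## Synthetic data

The generator emulates: (i) background transcripts drawn log-normally with
mild multiplicative drift; (ii) one dominant ceRNA following a Hill-in-time
induction — rise half-time 12 h with a 25% late decline (A549-like) or a
slower monotonic rise (MCF10A-like); (iii) binding sites on a small random
subset of background genes with a mixed class distribution; (iv)
multiplicative log-normal observation noise (keeping abundances positive).
Defaults are set so the programmed MRE pool expansion is about fourfold and
the dominant gene owns > 90% of the increase, matching the regimes the
census stage is meant to detect; both numbers are recorded exactly in the
returned ground truth, and on noiseless data the census recovers them to
numerical precision.

What passing these tests shows: the census, occupancy and circuit stages
compute what they claim on data with exactly the assumed structure. What it
does not show: robustness to features of real data the generator omits —
isoform structure, normalization artifacts, probe effects, heteroskedastic
count noise, miRNA measurement error, and any mismatch between predicted
and functional binding sites.

## Known limitations

* The occupancy model's absolute affinities are conventional, not fitted;
  only shape conclusions are supported.
* The circuit is deterministic (no stochastic simulation) and not fitted to
  wet-lab time courses; its parameter set is one member of the family that
  produces the qualitative phenotype structure.
* Phenotype thresholds are parameterization-specific.
* The A549 system is represented by re-parameterizing the miR-200/ZEB1
  topology rather than by a FOXP1/miR-21-specific model.
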