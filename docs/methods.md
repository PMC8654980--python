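# Methods

`rigidflex` models multi-domain protein complexes in which a well-resolved,
quasi-rigid core coexists with large flexible regions that deposited
structures leave without coordinates. The package builds a Cα-bead model of
the whole sequence, samples conformations of the flexible regions with
Langevin dynamics under stochastically switched cross-link restraints, and
confronts the resulting ensembles with two kinds of experimental data:
cross-linking mass spectrometry (XL-MS) distance limits and small-angle
X-ray scattering (SAXS) curves.

## Coarse-grained model

Every residue is one bead at its Cα position. Residues with deposited
coordinates form the core; residues missing from the model (or listed in a
flexible override) are flexible.

Flexible-chain terms use quadratic bond and bending potentials,

    V_b = K_b (b − b_0)²,      K_b = 50 kcal/mol/Å²,  b_0 = 3.8 Å
    V_α = K_α (α − α_0)²,      K_α = 1.75 kcal/mol/rad², α_0 = 112°

with the bending term applied only to consecutive triples that contain at
least one flexible bead; the internal geometry of the core is maintained by
the structure-based terms below, so adding V_α there would double-count.
K_α is interpreted as per rad² for dimensional consistency with the
quadratic form.

Excluded volume between non-bonded beads is purely repulsive,

    V_R = ε_R (σ_R / r)¹²,     ε_R = 2.0 kcal/mol,  σ_R = 4 Å,

truncated without shifting at 12 Å where it is below 2·10⁻⁶ kcal/mol. The
pair list excludes bonded pairs, 1–3 pairs that share a bending term, and
native-contact pairs. At the system sizes this package targets (tens to a
few hundred beads) the pair list is evaluated directly; no cell list is
used because it would be pure overhead below a few thousand beads.

The core is kept quasi-rigid by a structure-based (Gō-type) treatment:
harmonic pseudo-bonds at the reference length between consecutive core
beads, plus a 12-10 native-contact well

    V_Gō = ε [5 (r₀/r)¹² − 6 (r₀/r)¹⁰]

for core pairs within 8 Å in the reference, at least 3 residues apart along
a chain. The default well depth is ε = 3 kcal/mol (≈5 k_BT at 300 K).
Quasi-rigidity is a tested contract, not a construction: on a 60-bead
three-helix bundle at 300 K the core Cα RMSD to the reference stays below
2 Å over 10⁵ steps. A well depth of 1 k_BT–2 k_BT lets individual contacts
open faster than they reform and the core drifts; 5 k_BT holds the
near-native basin without freezing internal fluctuations. A frozen-core
mode (core beads pinned at reference, only flexible beads integrated) is
available for speed; because all reported observables are relative to the
core (tail statistics, restraint satisfaction, contact frequencies), fixing
the core frame rather than moving it as a mobile rigid body changes none of
them.

## Switched cross-link restraints

Cross-links are upper-bound distance restraints (l₀ = 25 Å for the
lysine-reactive PhoX reagent, Cα–Cα). Because flexible-region cross-links
are mutually incompatible — no single conformation satisfies all of them —
a random subset of N_c = 5 restraints is active at any time and the subset
is re-drawn every τ_XL = 0.5 ns. Each active restraint contributes a
sigmoidal potential

    V_l = K_XL / (1 + exp(−β (l − l₀))),  K_XL = 10 kcal/mol, β = 0.5 Å⁻¹.

The force peaks at l = l₀ and vanishes both for satisfied links and at
large distance, so a freshly drawn restraint that is far from satisfied
cannot blow up the integration — the property that makes random switching
viable. Subsets are drawn uniformly without replacement: the alternative
(with replacement) would silently double K_XL whenever an index repeats.

## Dynamics

The integrator is BAOAB Langevin with timestep 10 fs, friction 1 ps⁻¹,
uniform bead mass 110 Da, default temperature 300 K. With friction zero it
reduces to velocity Verlet, which the energy-conservation checks use
(drift < 0.1% over 10⁴ steps at 1 fs). All randomness — initial
velocities, thermostat noise, restraint schedules, flexible-chain growth —
derives from one integer seed through independent Philox streams, so a run
is exactly reproducible from (topology, parameters, config, seed).

Flexible regions are initialized by self-avoiding random walks of step b₀
from their rigid anchors (runs bridging two anchors are laid along the
anchor–anchor line with jitter), followed by a short steepest-descent
relaxation that moves only the flexible beads.

Frames are saved on a fixed interval; the published protocol of an 800 ns
trajectory saved every 100 ps (8000 models) and ~2000 restraint re-draws
over ~1000 ns are reproduced as scheduler identities at desk scale.

## Cross-link analysis

Cross-link tables are filtered at identification score > 40 (strict
inequality), collapsed to unique unordered residue pairs keeping the best
score, and mapped onto a structure as Cα–Cα distances. Records with an
unresolved endpoint are "unmappable" — a state, not an error — and are
excluded from the mean/max statistics, which therefore describe the
resolved regions only. On ensembles, the contact frequency of a pair is
the weight-weighted fraction of frames within the threshold.

## SAXS

Profiles are computed with a Debye sum over Cα beads with a uniform form
factor (f = 1): I(q) = f² Σᵢⱼ sin(q rᵢⱼ)/(q rᵢⱼ), so I(0) = (N f)².
Excluded-volume and hydration-layer terms are omitted; absolute
intensities are arbitrary and the supported uses are relative — Guinier
R_g, dimensionless Kratky shapes, P(r), χ ranking and ensemble weights.

Goodness of fit is

    χ_SAXS = sqrt( (1/N_q) Σ [(I_exp − α·I_avrg)/σ]² ),

with the scale α = Σ I_exp·I_avrg / Σ I_exp·I_exp as published
("as_printed"). That ratio is not the least-squares minimizer of the
residual (which divides by Σ I_avrg·I_avrg instead); both variants are
implemented, agree when I_avrg = I_exp, and neither is silently
substituted for the other.

Ensemble weights are fitted by non-negative least squares on σ-weighted
profiles followed by iterative support pruning — remove the
smallest-amplitude conformer and re-fit until at most `sparsity` weights
remain. This realizes the stated objective (sparse, non-negative weights
minimizing χ) with a transparent algorithm. On noiseless mixtures with
linearly independent profiles recovery is exact to 1e-6; identifiability
under noise depends on how distinguishable the conformers' profiles are,
which is why the recovery benchmarks construct well-separated states and
require decoys to be genuinely distinct from them (a decoy whose profile
nearly duplicates a true state is indistinguishable in principle, and
weight assigned to it is not a fitting error).

P(r) is obtained by a Tikhonov-regularized indirect Fourier transform:
non-negative least squares on I(q) ≈ Σ P(r) sinc(qr) Δr with clamped
endpoints, a second-derivative smoothness penalty, and the regularization
weight chosen at the L-curve corner (maximum distance to the endpoint
chord). Real-space R_g = sqrt(∫r²P dr / 2∫P dr) is reported as a
consistency diagnostic against the Guinier value.

Guinier fits use the window 0.015 < q < 0.025 Å⁻¹ by default and the
weight fit uses 0 < q < 0.30 Å⁻¹, both following the published analysis.

## Synthetic data

The generator emulates the three experimental inputs with known ground
truth:

- **Structure.** A deterministic ideal α-helix bundle core (rise 1.5
  Å/residue, 100°/residue turn, helix radius 2.3 Å, default 60 residues in
  three antiparallel helices with axes 5.5 Å from the bundle axis — packed
  tightly enough that inter-helix native contacts exist, as in a real
  globular core) with flexible runs at configurable attachment points,
  emitted exactly the way deposited models show unresolved residues: in
  SEQRES, without ATOM records. Every 7th residue is a cross-linkable
  lysine, giving realistic restraint sparsity without sequence modelling.
- **Cross-links.** Sampled from a ground-truth ensemble's contact
  frequencies: true links from lysine pairs with weighted frequency ≥ 0.5
  at the 25 Å threshold, decoys from pairs ≤ 0.05, scores placed above the
  identification cutoff. Restraint-efficacy experiments additionally cap
  the true-link frequency at 0.95, because a link at frequency 1.0 (e.g.
  between a tail residue and the core residue it is anchored next to) is
  satisfied by any trajectory and cannot show whether restraints help. Ground-truth ensembles come from the package's
  own engine at a different seed and temperature (280 K) than any test
  run, so recovery is not circular at the trajectory level.
- **SAXS.** A noisy curve from a known weighted mixture of conformations,
  with multiplicative Gaussian noise (default σ = 1% of I, matching
  well-measured synchrotron data) and the σ column written alongside.

What the toys do not emulate: real sequence-dependent chain stiffness,
side-chain chemistry of the cross-linker, instrument smearing, buffer
subtraction artefacts, or the ~3500-residue scale of a real HEAT-repeat
complex. Passing tests therefore demonstrate the correctness and internal
consistency of the machinery at reduced scale, not quantitative transfer
to any particular protein.

## Problem sizes

The shipped study runs 20–80-bead systems: 10⁴-step NVE checks, 5·10⁴–10⁵
step thermostatted runs, 150-frame ground-truth ensembles, five paired
200 ps restrained/unconstrained replicates, and 52-profile weight fits on
120-point q grids. These sizes give stable statistics for every contract
tested while keeping the full suite in the minutes range on one CPU.

## Known limitations

- The Gō parameters (well depth, 8 Å cutoff, 12-10 form) are package
  choices; the publication this model family follows does not print them.
- The Debye calculator's uniform form factor makes absolute I(q) scales
  and mid-q fine structure unreliable against experiment; use it for
  relative and ensemble quantities.
- The sparse-weight fit is a pruned NNLS, not a combinatorial search; with
  strongly collinear conformer profiles it returns one representative of a
  degenerate set.
- Insertion codes are rejected rather than handled; altloc handling takes
  the first conformer.
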