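# Methods

This note records the models, conventions, and design choices behind
dropletkit, in the spirit of a methods appendix: what each estimator
assumes, which knobs matter, and what the synthetic generators do and do
not emulate.

## Data model and units

Trajectories are loaded through MDAnalysis into a `BeadSystem`: per-bead
coordinates (nm), an integer chain id, a 1-based residue index within the
chain, a mass (amu), and per-frame orthorhombic box edges (nm) and times
(ps). Coordinates are nm internally (GRO convention); Å-based inputs are
converted on load. Frame selection by time is half-open `[start, end)` and
idempotent.

Chain identity comes from topology segment records; when a topology has a
single segment, chains are inferred from residue-index resets, which is how
concatenated coarse-grained chains are usually written. GRO/PDB files carry
no masses, and element guesses from coarse-grained bead names are
meaningless, so absent masses default to 72 amu (the regular Martini bead)
with a logged warning; real masses are used whenever the topology provides
them, and all gyration tensors are mass-weighted.

Whether analysis coordinates are wrapped is tracked explicitly: cluster and
contact detection is wrap-agnostic (minimum image), shape analysis unwraps
internally, and MSD refuses wrapped input outright rather than silently
producing jump artifacts.

## Contacts, clusters, phases

Two chains are bound when the minimum over all bead pairs of the
minimum-image distance is below a cutoff, 0.8 nm by default — the single
distance criterion used throughout (chain contacts, residue contacts,
droplet-graph edges, nearest-neighbour search). Clusters are connected
components of the boolean contact matrix. Phase labels follow the cluster
size: ≤ 3 chains (trimers or lower) → dilute, ≥ 6 chains → dense.
Tetramers and pentamers fall between the two operational definitions; they
are labelled *intermediate* and excluded from both phase concentrations
(both thresholds are configurable). Free monomers are strict singletons.

All inter-chain distances use the orthorhombic minimum-image convention, so
clusters may span the periodic boundary; a `use_pbc=False` flag exists for
pre-unwrapped data. A bounding-sphere prune accelerates the all-pairs scan
and is disabled automatically when a chain's extent approaches half the
box, where the bound would be invalid.

## Gyration-tensor geometry

The mass-weighted gyration tensor of a bead set has eigenvalues
λ₁ ≥ λ₂ ≥ λ₃ (nm²) and Rg² = Σλ. Before a droplet's tensor is computed,
each chain is made whole by minimum-image continuation along its backbone
and chains are assembled across the boundary by minimum-image growth from
the largest chain — a split droplet would corrupt every shape quantity.
This assumes the droplet is smaller than half the box in each direction.

Droplet semi-axes use two related conventions:

* **Instantaneous** semi-axes â = √(5λ) (a uniform-density ellipsoid with
  semi-axis a has λ = a²/5). The mean droplet radius is the time average
  R = ⟨(â b̂ ĉ)^{1/3}⟩.
* **Volume-normalized** per-frame semi-axes
  a = R λ₁^{1/3}/(λ₂λ₃)^{1/6} (cyclically for b, c), which satisfy
  a·b·c = R³ analytically. Only eigenvalue *ratios* enter, so the √5 factor
  affects R but cancels from the normalized axes — the surface-tension
  inputs are scale-free, and we state this because it is easy to get wrong.

Orientation angles between neighbouring droplet chains use the major
gyration axis of each chain. Principal axes carry no sign, so the angle is
folded to [0°, 90°] via arccos|û·v̂|; a 0–180° presentation of the same
data is simply the mirrored histogram. Each chain's nearest neighbour is
the cluster chain at minimum approach distance, required to be below the
cutoff, and each unordered pair is counted once per frame to avoid
over-counting. For isotropically oriented axes the folded angle density is
sin θ, which the test suite checks quantitatively at 10⁴ samples.

RMSD uses Kabsch superposition (centering + optimal rotation) by default,
with `superpose=False` for a plain coordinate RMSD.

## Phase thermodynamics

Droplet volume from eigenvalues is V = (4π/3)√(λ₁λ₂λ₃) by default. The
alternative `sqrt-5-lambda` convention uses the physical uniform-density
semi-axes √(5λ) and is larger by 5^{3/2} ≈ 11.18. The default follows the
dimensionally consistent reading of the eigenvalue-product expression used
in the condensate literature; the choice shifts absolute concentrations by
a constant factor but not the dense ≫ dilute contrast, and comparisons
against geometrically constructed fixtures should use `sqrt-5-lambda`.

Concentrations are c = N/(N_A V) with dense chains counted against the
summed droplet volumes and dilute chains against the remaining box volume;
intermediate chains enter neither numerator. A frame with no dense cluster
reports the dense concentration as missing, not zero. The transfer free
energy is ΔG = RT ln(c_dilute/c_dense) (kJ/mol, negative when the droplet
is favoured), with T = 310.15 K by default.

### Surface tension from shape fluctuations

For a droplet with volume-normalized semi-axes fluctuating about R,
δa = a − R etc., the quadrupolar estimates are

γ₂₀ = 5 k_B T / (16π ⟨(δa+δb)²⟩),  γ₂₂ = 15 k_B T / (16π ⟨(δa−δb)²⟩),

where ⟨(δa±δb)²⟩ = (1/3) Σ_{i<j} ⟨(δ_i±δ_j)²⟩ averages the three
unordered axis pairs. Both pair statistics are symmetric functions of the
axis multiset, so the descending eigenvalue sort cannot distort them.
Results are reported in mN/m; a rigid droplet (zero fluctuation) is
flagged as infinite rather than failing. For volume-conserving
fluctuations with per-axis variance v the closed forms are
⟨(δa+δb)²⟩ = 2v/3, ⟨(δa−δb)²⟩ = 2v, hence γ₂₀ = γ₂₂ = 15k_BT/(32πv) —
the estimator's parameter-recovery test.

Fluctuation statistics require a persistent droplet, so droplets are
tracked across frames by maximal chain-membership overlap; merges and
splits terminate a tracking segment, and segments shorter than
`min_droplet_frames` (default 10) are discarded. The averaging domain of
⟨·⟩ is ambiguous when several droplets coexist; both pooled summaries are
reported (unweighted per-droplet mean of γ, and frame-weighted pooling of
the mean squares).

### Steady state and transport

The dilute-phase concentration time series carries a drift statistic (last
minus first sliding-window mean, relative to the overall mean) as a simple
stationarity check. MSD(τ) averages squared displacements over particles
and time origins; the diffusion coefficient is the least-squares slope/6
(Einstein relation), and the fit window is explicit.

## Residue contact maps

A residue pair is in contact when any bead of one residue is within the
cutoff of any bead of the other; the chain-contact cutoff (0.8 nm) is
reused because it is the only distance criterion the underlying model
defines, with a flag to change it. Intra-chain maps sample each chain in
each frame of the requested phase once; inter-chain maps sample ordered
chain pairs within a droplet per frame (both directions contribute, which
symmetrizes the matrix). Probabilities are exact frequencies —
probability × sample count is an integer. The dense-minus-dilute
difference map isolates interactions gained or lost on entering a droplet.
Region reductions default to the standard α-synuclein domains, 1-based:
Nter 1–60, NAC 61–95, Cter 96–140.

## Droplet graphs and small-worldness

Droplet graphs take the cluster's chains as nodes and the same < cutoff
contact criterion as edges, so a graph is connected by construction and a
disconnected result signals inconsistent cutoffs (and raises). C is the
mean local clustering coefficient (degree-< 2 nodes contribute 0; a global
transitivity variant is selectable), L the mean shortest path length, and

S = (C/C_rand)/(L/L_rand)

with the null statistics averaged over connected Erdős–Rényi G(n, m)
samples of identical node and edge counts (disconnected draws are rejected
and resampled up to a cap — L is undefined otherwise). The ensemble size
defaults to 500 and results are reproducible under a seed; a cache shares
one null ensemble among droplets of equal size, which is what makes
per-frame small-worldness affordable over a trajectory. On ER inputs the
S distribution concentrates near 1 (mean within [0.8, 1.2] at n = 30,
m = 90 over 200 replicates); Watts–Strogatz graphs score S > 1 — the two
calibration anchors of the statistic.

## Sequence metrics

Shannon entropy is the standard positive-valued H = −Σ p_i ln p_i over
observed residue frequencies (natural log by default, base 2 optional).
Kyte–Doolittle hydropathy is the mean per-residue index, min–max
normalized from the raw scale range [−4.5, 4.5] to [0, 1] when requested —
the normalization choice is documented because several conventions
circulate. The comparison harness reports set quantiles and the query's
midrank percentile; externally computed score columns (e.g. PLAAC NLLR,
catGRANULE) can be supplied but are deliberately not reimplemented. The
wild-type human α-synuclein sequence (140 residues, net charge −9 with
neutral histidine) ships as a packaged FASTA.

## Setup arithmetic

Box edge a = (N/(N_A C))^{1/3} with N_A = 6.02214076×10²³ exactly. Crowder
counts round to the nearest integer of (volume fraction × box volume /
0.55 nm³); ion counts floor the salt term ⌊c_salt N_A V⌋ and then add the
exact integer neutralization, making every `SystemPlan` electro-neutral as
an exact integer identity. These conventions reproduce the published
reference counts (20,128 crowders; 3783/3333 ions; 450 neutralizing ions)
from the analytic volume; printed post-equilibration box edges are ~1%
larger than the analytic value and are not used for counting. The
water–protein Lennard-Jones tune scales both σ and ε by a common λ
(λ = 1.01 is the published operating point), and the crowder–crowder
potential is the purely repulsive V(r) = 4γε(σ/r)¹² (γ = 1.2 reproduces
the reference crowder dynamics).

## Synthetic data: what it does and does not emulate

The generators produce statistical structure only — no forces, no
thermostat.

* **Chains** are freely rotating walks with fixed bond length; bond
  directions follow a von Mises–Fisher distribution about the previous
  direction with concentration `stiffness` (0 = ideal random walk,
  ∞ = rod, with the discrete-rod Rg closed form as anchor).
* **Droplet systems** place dense-chain centers uniformly inside a
  prescribed ellipsoid and resample whole configurations until the contact
  graph is a single connected cluster, so detection is guaranteed by
  construction while the droplet still fills its nominal volume. Dilute
  chains keep pairwise minimum distances above twice the cutoff from
  everything. Defaults (10 dense + 5 dilute chains of 20 beads,
  bond 0.38 nm, droplet semi-axes 4 nm in a 25 nm box) are sized like a
  small coarse-grained condensate at the hundreds-of-µM scale.
  Connectivity conditioning and the small number of chains bias the
  measured droplet volume somewhat below the nominal ellipsoid, which is
  why concentration recovery is validated to a factor-of-two band rather
  than percent-level.
* **Fluctuating ellipsoids** draw per-frame semi-axes R + δ, δ i.i.d.
  Gaussian with sd `fluct_sigma`, renormalized to a·b·c = R³
  (volume-conserving modes, matching what the γ estimator assumes). The
  default fill draws one scrambled-Sobol uniform fill of the ball and
  deforms it affinely with the shape — beads act as material points of
  the deforming droplet, so recovered statistics are limited by the
  prescribed fluctuations, not bead shot noise (~10% inflation of the
  mean squares at 5000 independently resampled beads, the
  `resample-random` mode kept for realism studies).
* **Brownian tracers** use Gaussian displacements with per-axis variance
  2 D dt, unwrapped.
* **Reference graphs** are the standard ER/Watts–Strogatz/complete/path
  constructions.

Everything is fully determined by its seed. What passing tests show is
that the estimators recover known construction parameters under the
models' own assumptions (uniform-density droplets, volume-conserving
fluctuations, ideal chains, independent tracers); they do not show
robustness to features of real trajectories the generators omit —
correlated bead positions along chains, droplet exchange dynamics,
non-ellipsoidal droplets, or force-field specifics.

## Numerical choices and degenerate inputs

Eigenvalues are clipped at 0 before use and sorted descending; operations
that require strictly positive eigenvalues (ellipsoid axes, droplet
volume) raise a degenerate-shape error on collinear/planar bead sets
rather than returning zeros. Zero fluctuation yields an infinite-γ flag;
a single droplet frame is an error for surface tension. Concentration and
ΔG functions reject non-positive inputs. Cluster ordering is
deterministic (largest first, ties by smallest member id) so outputs are
byte-stable across reruns; all stochastic components (null ensembles,
generators) take explicit seeds. The acceptance script scales its
problem sizes (10⁴ droplet frames × 5000 beads, 200 + 100 calibration
graphs, 10³ tracers × 10³ steps, 10⁵-bead sphere) to run in well under a
minute-scale budget on one CPU while keeping Monte-Carlo errors a factor
of a few below the tolerances being checked.

## Known limitations

* Orthorhombic boxes only; triclinic cells are not supported.
* Droplet unwrapping assumes droplets smaller than half the box.
* No pressure-tensor (mechanical) surface-tension route — shape
  fluctuations only.
* No kinetic analyses: no dwell times, no droplet fusion statistics, no
  Markov-state machinery.
* The residue-contact cutoff equals the chain cutoff by default; bead
  models with very different residue granularities may warrant a
  different choice.
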