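# Methods

This note records the models, numerical choices and limitations behind
`profdesign`, in the order the pipeline runs them.

## Scaffold features

**Secondary structure.** Assignment is hydrogen-bond based in the
Kabsch–Sander style: amide hydrogens are placed 1 Å from N opposite the
preceding carbonyl C→O vector, an N–H···O=C bond exists when the
electrostatic energy 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) falls
below −0.5 kcal/mol, and n-turns (n = 3, 4, 5) and parallel/antiparallel
bridge patterns are detected from the bond matrix. The 8-state repertoire
is collapsed to 3 states — H, G, I → H; E, B → E; everything else C —
with 4-helices taking precedence over bridges over 3/5-helices. Donors
and acceptors closer than two positions in sequence are skipped, and a
9 Å Cα neighbour cut-off bounds the search.

**Torsions.** φ/ψ are standard backbone dihedrals in degrees, (−180,
180]; φ of the first and ψ of the last residue are undefined (NaN) and
excluded from all averages.

**Relative solvent accessibility.** Shrake–Rupley sphere sampling with
960 points per atom, probe radius 1.4 Å, element van-der-Waals radii
(C 1.70, N 1.55, O 1.52, S 1.80 Å), normalized by the per-residue-type
theoretical maximum areas of Tien et al. (2013) and clamped to [0, 1].
The sample sphere is oriented in the molecule's own principal-axis frame
(eigenvectors of the coordinate covariance, signs fixed deterministically),
which makes RSA *exactly* invariant under rigid rotation/translation
instead of merely approximately so. Totals agree with an independent
sphere-sampling implementation (Biopython's) to within 5%, which is the
expected spread between point lattices. Backbone-only structures are
scored on backbone atoms alone, so absolute RSA values are smaller than
full-atom conventions; the design energy only ever compares these values
against predictions trained/tuned on the same convention, so the scale
cancels.

**Cα-only input.** When any residue lacks N/CA/C, backbone heavy atoms
are rebuilt: each peptide unit CA(i)→CA(i+1) gets C(i) and N(i+1) at
fixed in-plane offsets solved once from the ideal bond lengths
(N–CA 1.46, CA–C 1.52, C–N 1.33, C=O 1.23 Å, trans peptide, symmetric
out-of-axis displacement), in the plane spanned by the local CA trace;
carbonyl O follows the bisector rule. This is a deliberately simple
internal-coordinate reconstruction: its contract is that downstream
feature assignment runs, not that it reproduces any particular
statistical rebuilding scheme. Side chains are not built (the energy
terms need backbone only). Residues that already carry a full backbone
are left untouched, making the operation idempotent and the identity on
full-atom input.

## Structural alignment and profile

**Aligner.** A simplified TM-score-maximizing aligner: five seed
correspondences (full diagonal, two terminal fragments, two shifted
diagonals) are each refined by alternating (a) Kabsch superposition on
the current pair set and (b) Needleman–Wunsch under position scores
1/(1 + (d_ij/d0)²) with gap penalty −0.6, until the pair set is stable or
20 rounds; the best result over seeds is kept. TM-score =
(1/L_scaffold) Σ 1/(1 + (d_i/d0)²) with d0 = 1.24·(L−15)^(1/3) − 1.8
clamped to ≥ 0.5. The aligner is validated for formula correctness
(self-alignment = 1, analytic d_i = d0 construction = 0.5, agreement with
a brute-force Kabsch oracle on the final pair set) and monotone behaviour
on fixtures; equivalence with published alignment binaries is not
claimed.

**Homolog selection.** The acceptance threshold starts at 0.7 and drops
in 0.05 steps until strictly more than 10 library members pass or the 0.5
floor is reached. The step size is our choice (only the endpoints and
"gradual" relaxation are prescribed by the method); 0.05 terminates in at
most 4 steps while respecting both bounds. Whether "more than 10" is
strict is ambiguous in the source description; we implement strictly
greater, configurable. The scaffold's own self-alignment is always
included (and not counted toward the 10), so a profile exists even with
an empty library.

**Profile.** Column counts use Henikoff position-based sequence weights
rescaled to sum to the number of *distinct* rows, so exact duplicate
homologs share weight rather than inflating counts (this bounds the
effect of re-adding a homolog at < 0.05 per log-odds cell). Pseudocounts:
p_ja = (c_ja + β·bg_a)/(C_j + β) with β = 5 effective counts and the
BLOSUM62 background frequencies; log-odds are natural logs. Weighting and
β are our choices (the source is silent) and are configurable.

## Design energy and Z-score

Four per-residue-normalized cost terms (lower = better):

- e_profile = −(1/L) Σ_j log-odds[j, seq_j]
- e_ss = (1/L) Σ_j (1 − P_j[ss_scaffold_j]) with P the predictor's
  3-state probabilities
- e_ta = (1/n_def) Σ_j √(Δφ_j² + Δψ_j²)/180 over the n_def positions
  where the scaffold defines both angles (wrapped differences); bounded
  by √2. Normalizing by n_def rather than L keeps the bound exact for
  every chain length.
- e_sa = (1/L) Σ_j |rsa_pred_j − rsa_scaffold_j|

The total is an unweighted sum by default (term weights configurable; the
source states a linear combination without printing weights). Search is
guided by Z = (E − Ē)/δE with Ē, δE the mean and (n−1)-std of the total
energy of 1,000 uniform-random sequences (composition configurable to
background frequencies; the source says only "random protein
sequences"). A registered physics callback contributes w·(E_phys −
Ē_phys)/δE_phys with its own random baseline and w = −2.44; Z-scoring the
physics term separately keeps both contributions dimensionless — whether
the original formulation normalizes jointly or separately cannot be
determined from the text, and this reading is flagged as ours. No physics
scorer ships with the package; the FoldX/side-chain-packing pipeline is
out of scope by design.

A degenerate baseline (zero energy spread, e.g. a flat profile under the
echo predictor) is an error rather than a silent division by zero.

## Feature predictors

The search calls the predictor for every candidate mutation, so
prediction must cost O(window) per affected position. Two variants share
one interface (window 15 by default, odd, edges use partial windows):

- **propensity** (default, training-free): per-residue Chou–Fasman H/E/C
  propensities averaged over the window and renormalized per position
  give P(H/E/C); RSA is a window-smoothed linear map of Kyte–Doolittle
  hydropathy onto [0, 1].
- **neural**: one-hidden-layer feedforward nets (scikit-learn MLPs, 32
  hidden units, one-hot window + padding channel) for SS class
  probabilities and RSA, trained on synthetic chains labelled by this
  package's own feature assignment. Training is deterministic per seed
  and reports held-out Q3 (≈ 0.98 on the synthetic distribution — which
  says the nets learn this generator, not that they rival real-protein
  predictors). Architecture, window and training data are entirely our
  choices; the source specifies none of them. The same in-repo predictor
  serves both design-time scoring and report-time NRE (the original
  system uses different external predictors for the two roles — a
  documented divergence).

Both variants derive φ/ψ as the circular probability-weighted mean of
three class bin centers (helix −62/−41, sheet −120/135, coil −75/150)
rather than direct regression — the simplest model that makes the
torsion-match term behave (a one-hot prediction hits the center exactly);
a regression variant would slot into the same interface.

## Monte Carlo engine

One sweep = L attempted moves: position uniform over non-frozen
positions, proposal uniform over the allowed residues minus the current
one, acceptance by the Metropolis rule on ΔZ at constant T = 0.03 (no
schedule; a single temperature is prescribed). One decoy is recorded per
sweep. This move-set/bookkeeping definition is the only one consistent
with the printed arithmetic: 30,000 sweeps → 30,000 decoys per
trajectory → 10 × (30,000 − 1,000) = 290,000 pooled. The proposal
distribution is symmetric, so the chain's stationary law is
exp(−Z/T)/partition — verified against brute-force enumeration on a
4-state toy.

Per-trajectory RNGs derive from (seed, trajectory index) via
`numpy.random.SeedSequence` spawn keys, so serial and parallel execution
are bit-identical. The engine keeps per-position caches of all four
energy terms and re-evaluates only the prediction window around a
proposed mutation; for the propensity predictor this reduces to running
window sums, compiled with numba (a pure-numpy fallback path produces
identical trajectories, asserted in tests up to float summation order at
1e−9). Incremental totals are checked against full recomputation after
whole trajectories (agreement to 1e−9). Full-size runs take ≈ 20 s
(40-residue scaffold, one processor).

Freezing every position is well-defined: sweeps attempt nothing and every
decoy is the scaffold sequence (the job-level contract requires 100%
identity reports rather than an error).

## Clustering and selection

Sequence distance d(a, b) = (1/L) Σ_j [B(a_j, a_j) + B(b_j, b_j) −
2B(a_j, b_j)]/2 with B = BLOSUM62 — the standard score-to-distance
transform (zero on identity, symmetric, non-negative). The threshold
starts at 0 and grows in steps of 0.25 (our step; the expansion rule
fixes only start and stop) until the largest neighbour ball covers ≥ 40%
of the pool; that ball is the primary cluster (ties: lowest decoy index),
it is removed, and the procedure repeats at the same threshold for up to
10 clusters. Membership equals a brute-force all-pairs neighbour count
oracle on small pools (asserted). Cluster representatives are the
lowest-Z members, ties broken on (Z, sequence) so pool order cannot
change reported designs of well-separated clusters.

Pools larger than 20,000 decoys are clustered on a seeded uniform
subsample of 20,000 (the all-pairs matrix is quadratic in time and
memory: 20,000² float32 ≈ 1.6 GB, computed by a compiled pair-table
kernel in ≈ 25 s; the stop criterion applies to the subsample). The
subsample size is configurable.

The reported confidence score is the representative's Z. It preserves the
intended ordering (lower = more confident) but is *uncalibrated*: the
original server's mapping of score < 1.0 to expected model quality
derives from a benchmark we cannot reproduce, so no such interpretation
is attached here.

## Synthetic data

All tests and the acceptance script run on structures from the fixtures
module; no downloads. Chains are built by internal-coordinate (NeRF)
construction from ideal torsions (helix −62/−41, strand −140/135, loops
from a fixed turn table), with SS-class-biased residue pools (helix
formers in helices, β-branched/aromatic in strands, turn formers in
loops) so sequence composition carries a learnable signal. Families jitter
every atom with Gaussian noise (default σ = 0.5 Å, which keeps TM-scores
of members ≈ 0.85, comfortably above the 0.7 selection threshold) and
mutate sequences at a per-position rate (default 10%; profile-recovery
tests use 50 members at 20%), returning the generating per-position
distribution as ground truth. A dedicated antiparallel two-strand fixture
pairs a flattened strand (φ/ψ −119/113) with its 2-fold-rotated copy at
tuned registration offsets so the hydrogen-bond assignment produces
contiguous E labels — a fully twisted strand pair registers only
alternating bonds under rigid pairing.

What the synthetic distribution does *not* emulate: real side-chain
packing (structures are backbone + pseudo-ligand only), realistic loop
geometry, sequence divergence beyond point mutations (no indels in family
members), or the composition statistics of real protein families. Tests
passing on it demonstrate the machinery's correctness and the pipeline's
printed arithmetic, not design accuracy on real scaffolds: on these
families the profile optimum is the scaffold sequence itself, so designs
converging to high scaffold identity are a positive control, not evidence
of novelty.

## Problem sizes

The acceptance script and the heaviest test run the standard operating
point — 10 trajectories × 30,000 sweeps on a 40-residue scaffold with the
propensity predictor, 1,000-sequence baseline, 20,000-decoy clustering
subsample — which completes in a few minutes on one processor. Unit tests
use 2–3 trajectories of 40–500 sweeps, 100–500-sequence baselines and
pools ≤ 2,000, sizes at which every brute-force oracle is exact and fast.

## Known limitations

- The homolog aligner is a simplified reimplementation; on hard remote
  homology it will underestimate TM-scores relative to mature aligners.
- No physics term ships; w = −2.44 is honoured only when a user registers
  a scorer callback.
- NRE is computed with the in-repo predictor, so its absolute values are
  not comparable with numbers produced by external predictor stacks.
- Multi-model NMR files: model 1 only. Multi-chain files: one chain is
  designed (first with CA atoms, or selected by flag); hetero atoms are
  collected model-wide for binding-site analysis.
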