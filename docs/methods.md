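# Methods

## Problem setting

Algorithm selection over a docking portfolio is cast as multi-label score
prediction: for a portfolio 𝒜 of m solver configurations and an instance
x = (x_P, x_L), the selector learns φ̂(·, x) = g(f(x)) ∈ ℝ^m and selects
argmax. Supervision comes from per-instance, per-solver pose evaluations:
an RMSD (Å, symmetry-corrected, computed upstream) and a binary
PoseBusters-validity flag (the 18 physical-plausibility checks, consumed as
a precomputed boolean — this package never re-derives either).

## Composite pose score

`s_RMSD(x; λ) = (1 + e^{−2λ}) / (1 + e^{λ(x−2)})`, multiplied by the PB
gate. Properties relied on throughout: value 1 at x = 0, strict
monotonicity, inflection (maximum |gradient|) at the 2 Å threshold, and
strictly positive tails (no hard cutoff). λ defaults to 3; 1 and 5 are the
standard sensitivity ablations. The centre is fixed at 2 Å. Success
criteria (strict 1 Å / relaxed 2 Å, both requiring PB-validity) use
*inclusive* thresholds — poses at exactly 1.0 or 2.0 Å count as successes.
A missing PB flag is a hard error, never an implicit pass or fail: silent
coercion would bias composite scores. RMSD may be exactly 0 (self-pose).

## Data model

Performance tables are dense n×m matrices (raw RMSD/PB plus derived scores
and both success labels) over an *ordered* portfolio; the solver order is
the tie-break priority for every argmax in the package. Missing
(instance, solver) cells — a pipeline that produced no pose — are scored 0
and counted as failures, with an explicit missing-mask retained for
sensitivity analyses; a solver that returns nothing cannot succeed, and the
mask keeps the convention auditable. Mixed post-processing regimes are
modelled by widening the portfolio (each base pipeline × each
post-processing variant is a distinct solver) rather than duplicating
instances; the separated regime evaluates disjoint portfolios
independently. K-fold splits are a seeded shuffle followed by round-robin
assignment (fold sizes differ by ≤ 1); k = 5 gives the 8–2 protocol.
On-disk formats are plain: pose-evaluation CSV (`%.17g` floats so tables
round-trip bit-exactly), an HDF5 embedding store
(`/<id>/protein`, `/<id>/ligand`, float32), and a YAML manifest.

## Curation

Two-stage filter on descriptor records: proteins must use only the 20
canonical one-letter residue codes (ambiguity codes B/Z/X and noncanonical
U/O fail); ligands must satisfy MW ≤ 500 Da, logP ≤ 5, HBD ≤ 5, HBA ≤ 10,
all inclusive. The filter consumes numeric records so it is testable
without a chemistry toolkit; the optional RDKit adapter computes MW,
Crippen logP and Lipinski donor/acceptor counts from SMILES (the logP
dialect is thus Crippen's atom-contribution estimate). The protein check is
applied first, so a doubly failing complex is reported once.

## Selector architecture

Residue matrices are variable-length, so the pooler must be a set
function: per head, a learned query q_h ∈ ℝ^{d_attn} and key projection
K_h ∈ ℝ^{d_attn×d_P} give attention logits (K_h x_i)·q_h / √d_attn; the
softmax-weighted sum of that head's *slice* of the raw residue vectors is
the head output, and heads concatenate back to d_P. The value map is the
identity on the head slice: a full d_P×d_P value projection would, at
d_P = 1152, cost ~1.3M parameters by itself and dominate the model;
with d_attn = 128 the whole pooler is ~148k parameters and the default
model totals ~614k — a deliberately light design. No positional encoding:
pooling is permutation-invariant by construction (property-tested to 1e-6).

Fusion is a single linear map of [pooled; x_L] into a 128-dim joint space.
The decoder is n residual blocks (linear 128→256, batch norm, ReLU, linear
256→128, skip); *all* block outputs are concatenated (not just the last)
and a linear head maps to m logits. The block count defaults to 4 with 3
reachable via config — the reference description is ambiguous between the
two, and 4 is the configuration the ablation grid perturbs around. Batch
norm uses batch statistics (biased variance for normalisation, unbiased for
the running average, momentum 0.1) during training and running averages at
inference, so batch-size-1 inference is exact and deterministic.
Initialisation is fan-in uniform for all linear maps, zero biases, BN at
identity, all from the config seed. Argmax ties select the earliest
portfolio index.

The network and its backward pass are written directly in numpy; gradient
correctness is enforced by numeric-vs-analytic checks at both the loss
level (1e-4) and through the full network (1e-5 on sampled coordinates).

## Objectives and training

BCE-with-logits on composite-score soft labels is the primary objective
(sum over solvers, mean over the mini-batch), computed in the
`max(z,0) − zt + log(1+e^{−|z|})` form. Alternatives, combinable through a
weighted mix: MSE on sigmoid outputs; pairwise logistic loss over ordered
pairs whose target gap exceeds τ_tie = 1e-6 (near-ties excluded — ranking
supervision on ties amplifies noise); and 1 − ApproxNDCG@3 with a sigmoid
rank surrogate (approximate rank 1 + Σ σ((z_b−z_a)/T), smooth top-3
membership σ((3.5−rank)/T), temperature T = 1 by default, exact NDCG@3
reported separately). Uniform targets short-circuit the NDCG loss to 0
(every ordering is ideal).

Optimisation: Adam (β = 0.9/0.999), base lr 1e-3, batch 64, cosine decay
over max_epochs (200 default, no restarts), early stopping with patience 20
on the held-out fold's relaxed-criterion top-1 selection success —
"validation accuracy" is not otherwise pinned down, and relaxed selection
success is the headline reported metric. Best-epoch parameters are
restored. All shuffling derives from the training seed; identical seeds
give bit-identical loss trajectories.

The paired comparison between a selector and the SBS is a two-sided exact
sign test on discordant per-instance success pairs (binomial p = ½),
returning 1.0 when no pairs are discordant — the appropriate exact test for
paired binary outcomes; whether the original comparison used indicators or
scores is not specified, so the indicator form was chosen and the score
vectors remain available.

## Evaluation metrics and diagnostics

SBS is the argmax column mean (ties → earliest index); VBS the row-max
oracle; VBS@K the per-row k-th order statistic; Selected@K the k-th most
frequent selection. Gap closure is 100·(AS−SBS)/(VBS−SBS), reported as NaN
(never ±∞) when VBS = SBS, and may be negative (gap widening). Oracle-winner
entropy splits tied row maxima fractionally before taking Shannon entropy
(base 2) of the aggregate win mass; agreement flags instead count any tied
maximum as agreement, matching the observation that the success region is
often flat near the top. Rank stability between two protocols compares
mean-composite-score solver rankings: Spearman ρ via midranks, Kendall τ_b
via tie-corrected pair enumeration (both hand-implemented and cross-checked
against scipy to 1e-9 in tests), and top-k Jaccard overlaps J_k with
deterministic solver-index tie-breaks, J̄ = mean over k = 1..m. Margin
reliability sorts predictions by top-1/top-2 probability margin into
equal-mass bins (remainders absorbed by the lowest-margin bins,
deterministic) and reports per-bin oracle agreement and advantage over the
SBS column. Success-indicator variants of the "mean per-solver scores"
ranking are available; composite scores are the default reading.

## Synthetic benchmarks

The generator plants `n_regimes` latent regimes (assigned uniformly at
random). Regime centroids are mutually orthogonal directions scaled by
δ/√2, so every centroid pair is exactly δ apart in units of the unit
isotropic noise SD — δ is the single separability dial. Protein embeddings
are drawn per residue around the regime centroid (lengths uniform in a
configurable range, default 20–60), ligand vectors likewise in their own
space. RMSDs are truncated-at-0 normal draws from a (regime × solver) skill
matrix (log-normal alternative available; the truncated normal was chosen
for its analytic tails, which serve as test oracles via
`analytic_success_prob`); PB flags are Bernoulli. Default embedding
dimensions are 64/32 for fast tests; full-size 1152/384 is a config change.

The canonical `planted_spec` gives each regime one dominant solver
(mean RMSD 0.5 Å vs 4.0 Å background, PB pass 0.95 everywhere): the oracle
winner is the planted solver for ≥90% of instances, the SBS captures only
one regime (~⅓ of instances), and a selector that recovers the regimes from
the embeddings can close nearly the whole relaxed-criterion gap.
`perturb_protocol` applies per-solver RMSD offsets (floored at 0) and PB
flips with fixed embeddings, emulating a post-processing change; with two
near-tied leading solvers a small shift reproduces the characteristic
pattern of high global rank correlation (ρ > 0.9) with a flipped top-1
(J₁ = 0).

What the generator does *not* emulate: real embedding geometry (no
evolutionary or chemical structure, just Gaussian clusters), correlated
solver errors within an instance, heteroscedastic RMSD noise, or
benchmark-specific curation artefacts. Passing tests therefore demonstrate
that the machinery — scoring, training, selection, evaluation — is correct
and that the selector can exploit embedding-resolvable structure when it
exists; they do not certify gains on any real docking benchmark, where
separability is far weaker and oracle labels are noisier.

## Problem sizes and reproducibility

The standard training checks use n = 1500 instances, m = 6 solvers,
3 regimes, 5-fold splits, 64/32-dim embeddings, max 40 epochs with
patience 8 — sizes at which full 5-fold training completes in well under a
minute on one CPU while leaving the conclusions unchanged at larger n.
At δ = 6 the trained selector's mean held-out relaxed gap closure exceeds
60% by a wide margin (~97–99% across seeds); at δ = 0 it stays within a few
points of the SBS (no pathological gap widening). Every stochastic
component (generation, splits, initialisation, batch order, perturbations)
is driven by explicit integer seeds.

## Known limitations

- Real embeddings and real solver portfolios are out of reach of the
  synthetic model; transfer behaviour across protocols is only emulated
  qualitatively.
- The pooler's internals (query/key attention with identity values) are one
  reasonable realisation of a lightly specified design; alternatives
  (full value projections, more heads) are configurable but not the default.
- Training is CPU-bound numpy; it is sized for thousands of instances, not
  millions.
- The curation step consumes descriptors; structure parsing and descriptor
  extraction beyond the SMILES adapter are out of scope, as are the
  docking engines and PoseBusters checks themselves.
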