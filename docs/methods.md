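# Methods

## Model

lincRNAs of two species are partitioned into three latent pools: a
shared orthologous pool of size *Nb* and species-specific pools of
sizes *Nh − Nb* (human) and *Nm − Nb* (mouse). The validated
catalogues are modelled as uniform, without-replacement, mutually
independent samples of sizes *Lh* and *Lm* from their lincRNomes, and
orthology is strictly one-to-one (no lineage-specific duplications).
Under these assumptions the probability of observing the overlap
counts (*Kh*, *Km*, *Kb*) is a product of hypergeometric terms: the
human sample hits the shared pool *Kh* times, the mouse sample *Km*
times, and the *Km* shared draws of the mouse sample intersect the
*Kh* shared draws of the human sample in *Kb* members.

`log_likelihood` evaluates this probability with exact log-gamma
binomial coefficients. Pool sizes incompatible with the observed
counts (e.g. *Nh − Nb < Lh − Kh*) have probability zero and return
−∞ rather than raising: infeasibility is a statement about parameter
values, not malformed input.

## Estimation

Applying the first-order Stirling approximation `d log n!/dn ≈ log n`
to the score equations yields the closed forms
`N̂h = Lh·Km/Kb`, `N̂m = Lm·Kh/Kb`, `N̂b = Kh·Km/Kb`.

`mle_numeric` maximizes the Stirling-approximated log-likelihood
numerically (L-BFGS with analytic gradients on a slack
parametrization that keeps every iterate strictly feasible, followed
by Newton polishing of the score), reproducing the closed forms to
machine precision from an independent starting point. This is the
default because it is the estimator the closed forms are derived
from. Two numerical caveats motivated the design:

* Root-finding on the score alone is ill-posed — the score also
  vanishes as the pools diverge — so the implementation maximizes the
  objective first and only then polishes the root.
* The *exact* log-gamma likelihood has a very flat ridge whose
  continuous maximizer sits a few tens of units away from the Stirling
  closed form at realistic count magnitudes (the log-likelihood
  difference is ~2×10⁻⁵), and its integer argmax on tiny instances can
  differ visibly (e.g. counts (3,3,2,2,1) give (4,4,3) against the
  closed form's (6,6,4)). `mle_numeric(..., likelihood="exact")`
  exposes this variant as greedy integer ascent; the default follows
  the Stirling route.

Counts with *Kb = 0* leave the pool sizes unbounded and raise a hard
error. Counts on the feasibility boundary (*Kh = Lh* etc.) return the
boundary solution with a warning.

Printed point estimates truncate toward zero (`integerize`), matching
the published tables (a real-valued estimate of 55,999.98 is printed
as 55,999); conservation percentages `100·Nb/Nh`, `100·Nb/Nm` round
to the nearest integer and are computed from the unrounded estimates.
Both conventions are selectable (`rounding="floor" | "nearest"`).

## Confidence regions

`analytic_confidence` computes the Hessian of the exact
log-likelihood at the MLE by central finite differences (step
`max(1, 1e-4·x)`), eigendecomposes it, and reports

* ellipsoid axes: eigenvectors with half-widths `1/sqrt(−λ)`;
* per-parameter 95% half-widths: `1.96·sqrt(diag((−H)⁻¹))` (Wald).

The ellipsoid is highly elongated (largest/smallest axis ratio > 20 on
the published counts), i.e. the three estimates are strongly
correlated. The Wald convention reproduces the published ±8,099
half-width for *Nh* on the ORF<120 counts to within 1.5%; since the
published interval convention is not fully specified, the package
reports both the per-parameter intervals and the raw axes.

`bootstrap` reconstructs membership labels consistent with the counts
(*Kb* identity-preserving pairs, *Kh − Kb* / *Km − Kb*
expressed-ortholog-only members, the remainder ortholog-free),
resamples each species independently with replacement, reduces each
replicate to its unique members (a resampled catalogue contains a
lincRNA at most once, as after cluster merging) and recounts the five
counts. This is the variant whose replicate distribution is centred
on the point estimate: the resampling retention factors cancel in the
ratio estimator. Replicates with *Kb = 0* are excluded and counted.
Note the resulting percentile intervals are *wider* (by ~30% here)
than the analytic Wald intervals: any nonparametric resample adds
pair-thinning noise on top of the ~√Kb Poisson floor that already
saturates the Fisher information, so a bootstrap narrower than the
analytic interval is not reproducible from the five counts alone.

## Pipeline

Coordinates are 0-based half-open (BED). All merging and pairing is
strand-forced. The stages of `assemble_counts`, in order:

1. **ORF filter** on each validated set. An ORF runs from an ATG — or
   from the cDNA start in any of the three frames, to allow truncated
   5′ ends — to an in-frame stop (stop included in the length); a
   stretch without a stop does not qualify. Records whose longest ORF
   is ≥ the threshold (90/120/150 nt, or none) are removed: the kept
   set has ORFs strictly below the threshold. Records without a
   sequence are conservatively retained with a warning.
2. **Expressed orthologs** (*Kh*, *Km*). A query needs a row in the
   cross-species mapping table (liftOver-style output, consumed not
   computed), a resolvable counterpart exon model (`exon_len > 0`),
   strictly positive maximal RPKM across the counterpart species'
   tissues, an indel percentage
   `100·|len_q − len_c| / max(len_q, len_c)` at most the cutoff
   (default 95%), and counterpart expression at or above the
   percentile threshold. That threshold is the nearest-rank
   (100−q)-th percentile of the counterpart expressions of the
   doubly-validated pairs (q = 95 keeps the top 95%); nearest-rank was
   chosen to avoid interpolation ambiguity.
3. **Doubly-validated pairs** (*Kb*): one-to-one, largest-overlap
   matching of mapped queries against the counterpart validated set at
   ≥100 bp same-strand overlap, ties broken by coordinate order.

Indel and expression cutoffs apply to the expressed-ortholog counts
only (the published table convention); *Kb* responds only to the ORF
filter and the overlap rule. A consequence worth knowing: thresholds
tight enough to expel a doubly-validated pair from *Kh* while it
remains in *Kb* push the five counts outside the model's support
(*Kb > Kh*), and count assembly raises an invalid-counts error. The
published data sit far from this regime (*Kh/Kb ≈ 13*).

`genome_fraction` extrapolates the validated set's total genomic
length by `estimated_count / validated_count`. On the printed inputs
the mouse lincRNome extrapolates to 81.9 Mb (matching the published
value); the human analogue computes to 71.3 Mb against a printed
72.5 Mb, consistent with the publication's own note that the human
lengths are underestimated — the discrepancy is reported, not
asserted.

## Synthetic data

`simulate_counts` draws the validated sets uniformly without
replacement from the three pools and applies an independent Bernoulli
detection (`ortholog_detection_prob`) per shared member and species to
model counterparts whose expression is missed; *Kb* requires both
detections. Reducing detection below 1 inflates the pool-size
estimates (*Kb* shrinks quadratically in the detection probability
while *Km* shrinks linearly) — a documented, directionally-tested
property. An optional `correlated_sampling` mode forces part of the
mouse sample to reuse human-sampled shared members, probing the
independence assumption.

`simulate_transcriptome` materializes a dataset as BED, FASTA,
per-tissue expression TSVs and mapping tables. Design choices:

* Every transcript occupies a non-overlapping slot (one synthetic
  chromosome per 1,000 slots), so cluster merging is trivial unless
  overlap is explicitly planted; shared members use the same slot
  index in both genomes, guaranteeing ≥200 bp same-strand overlap for
  doubly-validated pairs.
* Sequences are tiled from a stop-rich, ATG-free background, so the
  longest ORF of a sequence is exactly the planted one (or ≤12 nt of
  cDNA-start read-through) — planted ORF bookkeeping is exact.
* Indel noise shrinks the counterpart *exon-model length* (what the
  indel filter consumes) while the mapped genomic span still covers
  the counterpart slot, keeping pair-overlap bookkeeping exact.
* A counterpart is expressed if its detection Bernoulli succeeded or
  it is itself a validated (hence expressed) lincRNA; expression
  values are log-normal RPKM (default location 0, scale 1.5), zeros
  for undetected counterparts.
* Defaults mirror the study conditions: pools (50,000; 40,000;
  30,000), samples (3,600; 3,300), 16 human and 10 mouse tissues.
  Detection defaults to 1.0 — the study does not quantify it, so it
  is a sensitivity-analysis dial, not an estimate.

All randomness flows from the single config seed; fixture files are
byte-identical across runs with the same config.

What the generator does *not* emulate: read-level noise and alignment
error, genome rearrangements and synteny breaks, multi-exon
structure (generated models are single-exon, though the pipeline
accepts BED12), expression-dependent validation bias (except through
the optional correlated-sampling mode), and many-to-many orthology.
Passing recovery tests therefore demonstrate correctness of the
estimator and plumbing under the model's own assumptions, not
robustness to their violation in real data.

## Problem sizes used in the test-suite

Likelihood/enumeration equivalence runs exhaustively over all pools
with *Nh, Nm ≤ 6*; parameter recovery uses 500 replicates at the
study-scale pool sizes; bootstrap checks use 1,000 resamples;
pipeline fixtures use pools of 80–150 members, where every filter
stage still removes a nontrivial fraction.
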