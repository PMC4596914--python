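# Methods

## Statistical model

Each KIR locus is imputed by its own random-forest classifier over phased
binary SNP alleles.  A tree is a recursive partition: internal nodes test a
SNP, branches correspond to its two alleles, leaves predict a type.  Trees
are decorrelated two ways: each is grown on a bootstrap resample of the
reference panel of the same size N (bagging), and at every node only a
random subset of `m_try` SNPs, drawn without replacement, is eligible for
the split (attribute bagging / random subspace).  Splits maximize the Gini
impurity decrease; growth stops at class purity, when no candidate split has
positive gain, or at an optional node limit.  Because every predictor is a
binary allele, all splits are two-way and a root-to-leaf path can use a SNP
at most once (re-splitting a used SNP has zero gain and is therefore never
chosen).

Prediction aggregates hard per-tree votes: the reported probability of a
type is exactly the fraction of trees voting for it, and the MAP call is the
vote winner.  This is deliberately not a posterior from a generative model;
the calibration analysis below treats the vote fractions empirically.

### Parameters

| parameter | default | meaning |
|---|---|---|
| `n_trees` | 1000 | ensemble size; accuracy is insensitive above a few hundred |
| `m_try` | 100 for ≥100 SNPs, 10 for ≥10, else all | per-node candidate subspace size |
| `max_nodes` | unlimited | optional cap on nodes per tree |
| `seed` | 0 | single seed driving bootstraps and candidate draws |

The tuned `m_try` default is much larger than the classical `⌊√p⌋` fallback
(17 at p=300, exposed as `sqrt_m_try`): for several KIR loci only a handful
of SNPs are informative, and with small `m` many trees never see them.  The
larger subspace trades a little inter-tree diversity for guaranteed access
to the informative SNPs.  Models on the 12-SNP selected set use `m = 10`.

### Determinism and ties

All five forest operations are bit-reproducible given the seed: one
`numpy` generator drives bootstrap draws and per-node candidate draws in a
fixed order (the hot loop is JIT-compiled with numba, which passes the
generator through unchanged).  Ties are broken deterministically: equal-gain
splits go to the smallest SNP index among the sorted candidates; leaf
majorities and MAP calls go to the smallest class label in canonical sorted
order.  Degenerate inputs are handled explicitly: a single-class target
yields a warning and a single-leaf "always that class" model (probability 1),
and fitting refuses matrices with missing alleles rather than imputing
silently — missing data must be resolved upstream.

## Out-of-bag machinery

Each tree records its bootstrap index multiset.  A haplotype's OOB
distribution uses only trees whose bootstrap excluded it (about
(1−1/N)^N ≈ 36.8% of trees each); rows excluded by no tree are flagged
uncovered rather than silently filled.  OOB accuracy serves as a cheap proxy
for cross-validation and is used throughout the SNP-selection experiments.

Permutation importance follows Breiman's scheme: per tree and per SNP used
by that tree, the SNP's column is permuted within the tree's OOB rows (one
permutation each) and the accuracy drop recorded; unused SNPs contribute an
exact zero.  The score is the mean drop divided by the SD of drops; a zero
SD is treated as a unit denominator so scores stay finite, which also makes
a never-used SNP score exactly 0.  The normalization is by SD (not standard
error), so scores are comparable within a locus, not across ensemble sizes.

## Panel construction from families

Family cohorts yield haplotypes identical by descent, and some members lack
either KIR or SNP data.  The builder (1) assigns each offspring haplotype a
parent of origin twice — from KIR types by exact vector match, and from SNPs
by Hamming distance strictly below 20 mismatches — (2) merges the two
assignments, excluding any haplotype whose evidence is ambiguous or
conflicting, and (3) prunes within families: with both parents typed, only
the ≤4 parental haplotypes are kept; with one parent, that parent's
haplotypes plus offspring haplotypes not present in the typed parent
(deduplicated by the same matching rules); with none, deduplicated offspring
haplotypes.  Haplotypes missing either data type participate in matching but
are excluded from the final panel and logged.  The 20-mismatch budget
presumes a region-scale SNP count (hundreds); on toy panels with fewer than
20 SNPs it must be lowered or every pair "matches".

Pseudo-individuals (for emulating unphased-input methods) are formed by a
seeded shuffle and consecutive pairing; with an odd count the last shuffled
haplotype is discarded — the choice of discard is not specified by the
procedure's description, so the seeded shuffle's remainder is used for
determinism.

## Evaluation conventions

- Cross-validation folds are near-equal seeded partitions of haplotypes;
  the unit is the haplotype, so the two haplotypes of one individual may
  fall on opposite sides of a fold boundary (documented, not prevented).
  A class absent from a training fold is simply unpredictable in that fold.
- Per-allele sensitivity is #(call=a ∧ truth=a)/#(truth=a) and PPV the same
  over #(call=a); zero denominators yield flagged NaNs.
- Credible intervals are equal-tailed Beta(k+1, n−k+1) quantiles (binomial
  likelihood, uniform prior); under cross-validation the independence
  assumption is only approximate because training folds overlap, and the
  intervals are reported as approximations, not exact coverage statements.
- Calibration bins MAP probabilities into ten equal-width bins spanning the
  *observed* MAP range (not [0,1]); a degenerate range collapses to one bin.
  Empty bins are reported with n = 0.
- Expected per-individual accuracy averages, over 100 seeded random disjoint
  pairings, the fraction of pairs whose summed copy-number call equals the
  summed truth.  Per-individual calls sum the two per-haplotype MAP calls by
  default; convolving the two distributions and taking the MAP of the total
  is exposed as `mode="map_of_sum"` since either convention is defensible
  for unphased validation data.

## SNP selection

Selection runs per locus: rank SNPs by permutation importance, then
iteratively move the top-ranked SNP from the remaining set to the removed
set, refitting a model on each side at every step (the removed-set model
uses `m_try` equal to its size).  The importance ranking is recomputed after
each removal by default — "remove the most important SNP" is read as
recompute-then-remove — with a frozen-initial-ranking mode available.  The
per-locus number of SNPs to take is a user input (originally a visual
judgement); `suggest_counts` offers a default rule — the smallest k whose
removed-set model is within 1 percentage point of the full-panel OOB
accuracy.  The union of per-locus choices minus SNPs flagged for poor
intensity clustering forms the selected set; the clustering flag is an
upstream QC input (a boolean per SNP), since intensity data are outside this
package's scope.  The accuracy trajectories are reported as measured, with
no smoothing, so mild non-monotonicity from ensemble stochasticity is
visible.

The tag-SNP baseline is an exhaustive search: each SNP's rule maps each
allele to its majority class in training, the SNP with the best training
accuracy wins, ties to the smallest genomic position.  Training accuracy —
not Pearson correlation — is used so the baseline is scored by the same
metric as the forest.

## Allele alignment between panels

Query SNPs are matched to the reference by GRCh37 position (identifiers are
not comparable across array naming schemes).  Coding is reconciled by exact
nucleotide match, then by strand complement.  For strand-ambiguous pairs
(A/T, C/G) nucleotides cannot distinguish a strand flip from a coding swap,
so allele-1 frequencies are compared: the orientation agreeing within
`freq_tol` (default 0.1) is taken, and pairs matching in neither
orientation — including near-0.5-frequency SNPs where the comparison is
uninformative — are dropped rather than guessed.

## The synthetic region

The simulator generates what the method assumes about the real region and
nothing more: each haplotype is an independent draw of a centromeric motif
(cA01 0.55, cB01 0.35, cB02 0.10) and a telomeric motif (tA01 0.60, tB01
0.40) — European-like A/B frequencies — joined at the hotspot; per-locus
copy numbers are the sum of the two motifs' gene content; `KIRhaplotype` is
the motif-pair name and `AvsB` is A exactly for cA01+tA01.  Each side
carries 150 SNPs (mirroring the ~300-SNP density of a dense immune-region
array over the 400 kb region): one one-vs-rest tag per motif guarantees
separability, the rest tag random motif subsets.  A SNP reflects its
motif's tag with probability `tagging_strength` (default 0.95) and is
further flipped by genotyping error (default 0.005); both are independent
per haplotype per SNP.  Framework loci (KIR3DP1, KIR2DL4) have copy
number 1 on every motif, deliberately exercising the degenerate
single-class model path.  An optional `linkage` parameter correlates the
two motif draws; the default is free recombination at the hotspot.  The
long-tail preset adds geometrically rare centromeric motifs so training
allele counts span <10 to >100 copies.

What the simulator does **not** emulate: recombination within motifs,
allelic (sequence-level) variation, genotype-intensity artifacts, population
structure, and realistic LD decay — SNP noise is independent across sites,
whereas array errors cluster.  Consequently, passing tests demonstrate that
the algorithms are implemented correctly and behave as expected under the
stated generative model; they do not certify accuracy levels on real
cohorts, where class ambiguity is genuinely higher (fine-grained haplotype
classes are the clearest example).

One consequence deserves emphasis: under strong tagging (0.99) the simulated
task is nearly noiseless, so essentially every imputation is correct while
hard-vote OOB probabilities still scatter below 1 through bootstrap and
subspace randomness.  The binned calibration check then fails in
well-populated mid-probability bins — observed accuracy 1.0 sits above the
credible interval around what the conservative vote fractions predict.  This
is a property of vote-fraction probabilities in a near-deterministic regime
(real-data analyses of this method describe the same probabilities as
"slightly conservative"), not of the binning code, and the package reports
it honestly rather than recalibrating the probabilities.

## Numerical choices

- Gini comparisons use a 1e-12 tolerance; "no positive gain" becomes a leaf.
- Bootstrap size equals N, with replacement.
- Thresholded calling uses ≥ (a call is made at exactly the threshold).
- Region filters are closed intervals on 1-based GRCh37 coordinates.
- Model files are versioned JSON with SNP definitions, class labels,
  parameters and seeds embedded, so `train` and `impute` can run as separate
  processes and reruns are byte-identical.

## Known limitations

- Hard-vote probabilities are conservative where the task is easy (see
  above); no probability recalibration is provided.
- The forest carries no missing-data handling at predict time; inputs must
  be complete and aligned (the alignment report says what was dropped).
- Permutation importance is computed serially per tree and SNP; for panels
  much larger than ~300 SNPs the selection experiments dominate runtime.
- Reproducibility is guaranteed for a fixed single-threaded execution order
  only; there is no parallel-RNG contract.
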