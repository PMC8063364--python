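# Methods

## The model

`pederr` estimates per-individual genotype-error profiles from nuclear
families (mother, father, k ≥ 1 children) genotyped at biallelic SNVs. The
observable call space is C = {0/0, 0/1, 1/1, ./.}; true genotypes live in
G = {0/0, 0/1, 1/1}. For each individual *i* the method estimates nine
parameters

    P(C_g^(i) = c),   g ∈ G, c ∈ C, c ≠ g,

i.e. three wrong observations (including a missing call) for each of three
true genotypes.

A *family genotype* is the ordered tuple of calls (mother, father,
children…) at one site. A tuple is *valid* if it has no missing call and
every child's genotype can be assembled from one allele of each parent;
all other tuples are *invalid*. Under three assumptions — errors are rare,
Mendelian inconsistencies are caused by genotyping error (de novo point
mutations are ~3 orders of magnitude rarer than call errors), and errors
strike family members independently so double errors at one site are
negligible — the count Y_w of each invalid tuple w is, by a Le Cam-type
Poissonization of the underlying sum of multinomials, approximately

    Y_w ~ Pois( Σ_v  x_v · P(C_g^(i) = c) ),

where v ranges over the *valid neighbors* of w (valid tuples differing from
w at exactly one member), i is the differing member, g its true genotype in
v and c its observed call in w. The true count x_v of each valid tuple is
approximated by its observed count y_v. The total-variation error of the
Poisson approximation is bounded by 2·Σ_v x_v·δ_v², with δ_v the
probability that any member of tuple v is miscalled; `lecam_bound` reports
this with y_v and fitted rates plugged in.

Because the rate is *linear* in the parameters, the MLE is an identity-link
Poisson regression with nonnegativity constraints. Structural
identifiability has one notable gap: a parent miscalled 0/0→0/1 or 1/1→0/1
still carries a genotype compatible with every child it could truly have
had, so these two parameters per parent can never generate an invalid tuple.
They are reported as unidentifiable markers (`None`/`NA`), never as zeros,
and summaries touching them are computed for children only.

## Fitting

The log-likelihood Σ_w [y_w·log μ_w − μ_w], μ = A·p, is concave in p, so a
box-constrained quasi-Newton search finds the global optimum. Numerical
choices that matter:

* **Design rows.** For families of m ≤ 8 members the full 4^m tuple space
  is enumerated and every invalid tuple with ≥ 1 valid neighbor forms a
  row, including rows with y_w = 0 (their −μ_w term sharpens the fit).
  Larger families fall back to rows for observed invalid tuples only.
  Invalid tuples with no valid neighbor (e.g. two missing calls) cannot be
  attributed to a single error and are set aside as dropped rows.
* **Scaling.** Raw rates (1e-4…1e-2) against exposures of order n_sites
  condition the problem badly enough that line searches fail far from the
  optimum. The optimizer therefore works in column-scaled coordinates
  q_k = p_k · (Σ_w A_wk) — the expected number of events each parameter
  accounts for — with box [0, exposure] (i.e. p ∈ [0, 1]). This was
  validated against an independent multiplicative-update (EM) solve of the
  same likelihood.
* **Initialization** at the moment estimate (events in a column's rows over
  the column's exposure), floored at 1e-12. **Convergence** at relative
  log-likelihood change < 1e-10 (default) or 10,000 iterations; tests that
  assert exact scale invariance tighten to 1e-12. log(0) is guarded by
  clipping μ at 1e-300; parameters pinned at 0 by all-zero event rows come
  out exactly 0.
* Columns that are identically zero in the design (the structural parental
  gaps above, plus anything a tiny dataset happens not to expose) are
  excluded from optimization and reported unidentifiable.

Each family is fitted independently; its parameter set is disjoint from
every other family's, and no pooling across families or sharing across
sites is modeled.

## From rates to precision and recall

With x̂_g^(i) the number of sites where individual i was *called* g (a
plug-in for the true count, errors being rare), expected error counts are
E[W_{g→c}] = x̂_g·P(C_g = c), and the correct-call diagonal absorbs the
remainder so each row sums to x̂_g. Precision and recall at heterozygous
and homozygous-alternate sites are ratios of these expected counts
(precision_het = E[W_{0/1→0/1}] / Σ_g E[W_{g→0/1}]; recall_het =
E[W_{0/1→0/1}] / Σ_c E[W_{0/1→c}]; analogously for 1/1), F1 the harmonic
mean (0 when precision + recall = 0), and NA wherever an unidentifiable
rate or an empty denominator enters. The same ratio formulas applied to
exact confusion counts give reference metrics from a simulator truth log or
from replicate-consensus calls.

**Twin validation.** For monozygotic twins A and B, any call mismatch is an
error in one of them, so E[M_{a,b}] = E[W_{b→a}^(A)] + E[W_{a→b}^(B)] per
ordered call pair (terms whose "true" genotype would be ./. do not exist
and contribute 0). Each twin's rates are fitted with the co-twin removed
from the family, keeping prediction and observation as independent as
family data allows. Totals are reported both over all categories and
restricted to genotype–genotype mismatches, since the treatment of missing
calls in mismatch tallies is a reporting choice.

**Consensus comparison.** For groups of replicate samples of one individual
(monozygotic quadruplets), the call shared by ≥ 3 of 4 replicates is taken
as ground truth (missing calls never vote; sites without a strict majority
are excluded), and per-replicate precision/recall follow from the resulting
confusion counts. The family-based route fits the quadruplet family as
constituted — parents plus all four replicates — which is how the method
would be applied to such a family in practice.

## Region restriction

Interval sets are stored per chromosome as sorted, merged half-open
[start, end) arrays (BED convention, 0-based); VCF positions are 1-based
and converted exactly once at the membership boundary; `chr` prefixes are
stripped for matching. Off-target WES sites are binned by distance to the
nearest target edge into (0,25], (25,50], (50,75] and (75,∞) bp — the bin
edges are treated half-open, a choice declared here because the convention
at exactly 25/50/75 bp is otherwise ambiguous. High-complexity regions are
the exact per-chromosome complement of a low-complexity BED. Region
stratification reruns count→fit→metrics per stratum on the same samples.

## The synthetic cohort

The generator realizes exactly the model's assumed generative process, with
defaults chosen as a desk-scale analogue of a family sequencing cohort:

| parameter | default | rationale |
|---|---|---|
| families | 50 quads (2 parents + 2 children) | enough children (100) for stable medians |
| sites | 1e6 | desk-scale stand-in for the tens of millions of informative sites in WGS cohorts |
| allele frequency | uniform on [0.01, 0.5] per site | spans rare to common variation |
| error rates | each of the 9 per-member rates log-uniform on [1e-4, 1e-2] | the magnitude range of short-read genotyping error |
| parental genotypes | Hardy–Weinberg at the site's allele frequency | |
| transmission | one uniformly random allele per parent | |

Observed calls are drawn per member from the 3×4 confusion distribution;
monozygotic children share a single transmission draw but get independent
errors. A `duplicate_first_child` mode adds an MZ copy of the first child
to each family — the twin-validation design, in which excluding the co-twin
still leaves an ordinary sibling in the fit. A single seed drives a
spawned-stream hierarchy (site properties / rates / one stream per family),
so any family regenerates independently. All sites are emitted, including
uninformative ones, so the informative-site filter (≥ 1 non-reference call
in the dataset) is exercised realistically.

What the generator does *not* emulate: linkage between sites, read-level
effects (depth, mapping bias), region-dependent error inflation, de novo
mutations, or relatedness structure beyond the nuclear family. Passing
recovery tests therefore demonstrate correctness of the estimator under the
model's own assumptions, not robustness to their violation on real data.

## Study sizes used by the test suite and acceptance script

* Rate/metric recovery: 50 quad families × 1e6 sites (≈ 25 s). Median
  relative error of the 900 child rate estimates and median absolute error
  of child precision/recall versus simulator truth.
* Twin bands: 30 families with a duplicated first child × 5e5 sites.
* Consensus: 4 MZ-quadruplet families × 1e6 sites.

## Known limitations

* The 3σ-band twin check is sensitive to the sampling error of the fitted
  rates, not just Poisson noise in the mismatch counts: a genotype-flip
  error is only observable in the design when the wrong call is
  incompatible with the parents (child 0/1→0/0 needs a 1/1 parent;
  1/1→0/1 needs two 1/1 parents), so those rates carry 10–70% relative
  error under the default allele-frequency spectrum, and predicted totals
  deviate from observed ones by several Poisson σ for a substantial
  minority of pairs. Both the band and the estimation error scale as
  1/√n_sites, so this is intrinsic to the study conditions rather than
  curable by more sites; the corresponding acceptance test documents the
  achieved coverage.
* Parents receive NA het-site precision (and children-only summaries) by
  construction; there is no way around the structural identifiability gap
  within a single nuclear family.
* Estimates are point MLEs; no confidence intervals are produced.
* The autosomal inheritance model is applied everywhere it is run; X/Y
  dosage is not modeled, and the default site filter keeps autosomes only.
* Multiallelic sites, indels and structural variants are excluded at
  streaming time; half-called genotypes are treated as missing; phase is
  ignored.
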