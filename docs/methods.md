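# Methods

## The screening model

A pooled knock-in screen observes, per construct, a set of G0 pools with
known founder counts and a binary positivity outcome. The package models
each founder as independently producing at least one detectable transgenic
G1 with probability *p* (the "individual integration rate"), detected with
probability *d*; a pool of *n* founders is then positive with probability

    q(p) = 1 − (1 − p·d)^n.

Assumptions: founders integrate independently; pool positivity is read
without error (screening several ovipositions is collapsed into the single
per-founder detection probability *d*, default 1); founders do not migrate
between pools. The number of insertions per founder does not affect
positivity, which is why the screen's "minimum integration rate"
100·k/n (positive pools over surviving G0) is a lower bound and why its
expectation, 100·q(p)/n for equal pools, never exceeds 100·p·d
(1 − (1 − x)^n ≤ nx).

## Estimation and compatibility intervals

The log-likelihood of a pool pattern is Σ log q_i over positive pools plus
Σ log(1 − q_i) over negative ones. The MLE is located on a uniform grid of
step 10⁻⁴ over [0, 1] and refined by bounded scalar maximisation between the
neighbouring grid points; with equal pools this agrees with the closed-form
inversion p̂ = 1 − (1 − X/K)^(1/n) to well below grid resolution, and
all-positive (all-negative) data put p̂ on the boundary 1 (0), where only
one interval bound is informative.

Three interval constructions are computed:

* **Score (primary).** Inversion of the Rao score test
  {p : U(p)²/I(p) ≤ χ²₁(level)}, with U and I the score and Fisher
  information of the pool-outcome likelihood. For equal pools this is
  exactly the Wilson interval on pool positivity q transformed through
  p = 1 − (1 − q)^(1/n), and it is boundary-aware without special cases:
  with all K pools positive the lower bound solves q(p) = K/(K + z²).
* **Profile likelihood.** {p : ℓ(p) ≥ ℓ(p̂) − χ²₁(level)/2} on the grid.
* **Exact.** Clopper–Pearson on the positive-pool count (equal pools only),
  transformed through the same monotone map; one-sided at the full level on
  the boundaries, so 13/13 positive pools report the exact bound solving
  (1 − (1 − p)^20)^13 = 0.05.

The score interval is primary because with few pools the outcome space is
small and coverage is dominated by discreteness: enumerating all outcomes at
the validation settings (15 pools of 20, p ∈ {0.01, 0.05, 0.10}) gives true
coverage 0.959/0.973/0.972 for the score interval, versus 0.910/0.931/0.829
for the likelihood-ratio cutoff (its all-positive lower bound 0.1006 just
excludes a true rate of 0.10) and 0.989/0.973/0.994 for the exact interval,
which overcovers by construction. All three are reported so users can prefer
the guaranteed-coverage exact form when conservatism matters.

Two constructs "overlap" when their score intervals intersect; the report
also gives the maximum probability of one construct's exact pool outcome
over rates inside the other's interval, which is the quantity that makes
"no common rate could have produced both" precise.

Because the authors' own pooling analysis script was not published, this
module asserts only qualitative agreement with the screen's two published
conclusions (the 13/13-positive construct is incompatible with the others'
rates, which are mutually compatible); numeric agreement with the original
analysis cannot be checked.

## Exact binomial conventions

Construct comparisons use the exact binomial test with the null proportion
set to the comparator's point estimate k_ref/n_ref and the two-sided p-value
under the minimum-likelihood definition (sum of P(X = j) over all j with
P(j) ≤ P(k), relative tolerance 10⁻⁷ for float ties). These two conventions
are what reproduce the published comparison p-values at two decimals; the
central (doubled one-sided) definition is available as an option but does
not reproduce them. Percentages round half away from zero. No
multiple-testing correction is applied, matching the original analysis.

## Conversion-tract calling

Coordinates are signed bp offsets anchored at the predicted blunt DSB
(3 bp 5′ of the PAM), 5′ negative; this convention is written into every
output header. Per side of an event:

* extent_min = |outermost donor-state SNP| (0 if none);
* extent_max = |innermost read wildtype SNP beyond it|, or the sequenced
  boundary when no such SNP exists — a censoring interval for the true
  tract end, the quantity drawn as error bars in tract-length figures;
* continuity requires every read SNP strictly inside the tract to be
  donor-state. Unread SNPs never break continuity (a Sanger coverage gap
  should not fabricate a discontinuous call) but widen censoring intervals
  and are counted per event.

Direction follows from which sides carry donor calls, and the mechanism
label is a pure function of direction: unidirectional → one-ended SDSA,
bidirectional → two-ended SDSA or Holliday-junction branch migration
(indistinguishable here), non-conversion → none. Discontinuous events,
reported in other species, are flagged rather than rejected. An event whose
markers are all unread raises an "indeterminate" error. Whether a published
"tract ends within 220–319 bp" statement denotes one censoring interval or
an across-event range is ambiguous; the per-event report and the aggregate's
across-event range are emitted separately so either reading is available.

## Synthetic data

`SimDesign` defaults mirror the screen's structure: 20 founders per pool
(the cages held "approximately 20"), detection probability 1 (any
fluorescent G1 counts), and about 9–17 pools per construct in the packaged
example. `TractModel` draws an event class from
(non-conversion, uni-5′, uni-3′, bidirectional) with defaults
0.2/0.3/0.3/0.2 — matching the observed 20/60/20 split with no side bias,
since none was reported — and a Geometric(1/mean) tract length per converted
side (mean 150 bp by default, the order of the observed sub-320 bp tracts;
memoryless per-base extension is the simplest model consistent with
short-heavy, long-tailed extents). Generated SNP maps place markers
uniformly outside a 50 bp guard window on each side of the cut,
reproducing the recoded constructs' uninterrupted perfect homology next to
the DSB; ~25 SNPs per 2 kb arm gives the constructs' ~1.2% heterology.

What the simulator does **not** model: mosaicism and per-oviposition
screening structure (collapsed into *d*), NHEJ indel spectra, off-target
integration sites, sequence-level donors (no FASTA), discontinuous
conversion, and multiple insertions per founder affect nothing downstream
of positivity. Passing round-trip tests therefore validate the estimators
under the stated independence model, not against those real-data
complications.

The packaged example tables are labelled synthetic: the per-construct
positive-pool counts and survivor totals are the published ones, but the
pool-level composition and all SNP coordinates are invented (the original
coordinate tables are not in the available text) while honouring each
construct's guard side and the reported extreme events (725/16 bp and
94/149 bp bidirectional tracts).

## Numerical choices and degenerate inputs

* Grid step 10⁻⁴ with Brent refinement; score-interval roots by `brentq`
  between the interior statistic minimum and the relevant boundary, with
  the pool-survival factor (1 − p·d)^n kept unexpanded so the variance
  q(1 − q) does not underflow near p = 1.
* Validation of experiment tables is row-addressed (missing columns,
  non-numeric counts, duplicate pool ids, pooled founders exceeding the
  survivor total) and fails loudly; a reference construct with zero
  positive pools degrades comparisons to a warning, not an error.
* Coverage/aggregation test sizes (500 replicates per rate; 10⁴ random
  call patterns; 2 000-event simulation checks) were chosen as the smallest
  sizes at which binomial Monte-Carlo error is well below the effects being
  checked.

## Known limitations

* No hierarchical model across constructs; each is analysed independently.
* The score interval's coverage is discreteness-dominated below ~10 pools;
  the exact interval is the safer choice there.
* Tract calling assumes pre-made base calls; chromatogram/read-level errors
  propagate silently as wrong SNP states.
* Crossover vs non-crossover resolution cannot be distinguished beyond the
  direction-based ambiguity class.
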