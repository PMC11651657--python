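# Methods

## The model

Somatic evolution runs in parallel in every patient, so a positively
selected point mutation recurs across a cohort while neutral mutations
almost never do.  `cdnscan` quantifies "almost never": it computes the
largest recurrence level i* attainable by neutral mutations in a cohort of
n tumors, and classifies any identical nucleotide change (chrom, pos,
ref>alt) seen in i >= i* distinct patients as a cancer-driving nucleotide
(CDN).

The per-site, per-patient mutation rate u is modeled as
Gamma(shape k, scale E(u)/k), mean E(u).  The number of patients carrying a
given neutral change is Binomial(n, u) ~ Poisson(n u); mixing over the
gamma gives a negative binomial with mean nE(u) and shape k.  Two regimes
are implemented:

- **small-mass closed form** (nE(u) << 1): the expected number of
  synonymous sites hit exactly i times is
  `S_i = L_S * g(i,k) * (nE(u))^i`, with `g(i,k) = C(k+i-1, i)/k^i`
  (g -> 1/i! as k -> inf, the fixed-rate Poisson limit).  Missense sites
  follow the same form with L_A.
- **exact tail** (any n): `P(X >= i)` from the negative binomial; for k = 1
  the geometric closed form `P(X >= i) = q^i`, `q = nE(u)/(1+nE(u))`.

The threshold is the smallest integer i with `L_A * P(X >= i) <= epsilon`,
i.e. fewer than epsilon neutral sites genome-wide are expected at or above
it.  For k = 1 this is `i* = ceil( ln(epsilon/L_A) / ln q )` with exact
integer boundaries counted as satisfying the bound.  As n grows, the
detectable prevalence frontier i*/n falls toward `ln(L_A) * E(u)` (natural
log; ~5e-5 at exome scale).  Convergence is slow: the relative gap of the
exact solution over the asymptote is `1/(nE(u) ln(1+1/nE(u))) - 1`, still
~16% at nE(u) = 3 (n = 1e6 at the default rate) and below 10% only for
nE(u) >~ 5.  The asymptote is therefore quoted as a limit, not as the
value at n = 1e6.

### Default parameters

| parameter | default | units | why |
|---|---|---|---|
| E(u) | 3e-6 | mutations/site/patient | midpoint of the 1e-6..5e-6 range typical of exome cohorts; the unique value for which ln(L_A)E(u) ~ 5e-5 |
| k | 1 | — | the closed-form (geometric) case; any k > 0 supported, and published estimates of rate dispersion typically have k >= 1 |
| epsilon | 1 | false CDN sites exome-wide | makes the threshold formula reduce to the asymptote formula; exposed as a flag |
| L_S | 0.9e7 | weighted synonymous sites | exome scale |
| L_A | 2.3 * L_S = 2.07e7 | weighted missense sites | the conventional missense/synonymous opportunity ratio |
| germline filter | 1e-3 max population frequency | — | maximum over sub-populations when several are annotated (panel-style filtering uses 5e-4) |
| hypermutator cutoff | 3000 coding mutations | per patient | panel loads scaled to exome first (`n_l * L / l`) |

## Site opportunities

"Synonymous sites" are not positions: each coding position offers three
single-base changes, weighted by the relative probability of each mutation
path m>v.  Path probabilities are calibrated on fourfold-degenerate third
codon positions (`r_{m>v} = n_{m>v}/N_m`, normalized to sum 1 over the 12
paths).  When apportioning a position among the synonymous / missense /
nonsense classes, the weights are conditioned on the position's reference
base (each row of the path matrix renormalized to 1) — the established
single-base site-counting convention — so every analyzed position
contributes exactly one site and `L_S + L_A + L_N = L` holds exactly.
Classification is codon-resolved against the standard genetic code (kept
as data, so alternate codes could be swapped in); stop-codon positions are
excluded, internal stops with a warning.  A position is CpG when its
reference base is the C or the G of a CG dinucleotide (both strands); this
definition is a documented convention, not a community standard.

Motif tables extend the same weighting to k-mer contexts (k = 3, 5, 7)
centered on the mutated base.  For k in {3, 5} the denominators use
synonymous path mass and numerators count synonymous mutations; for k = 7,
where synonymous coverage of 16,384 contexts is too sparse, both use all
singleton (1-patient) mutations of either class.  Positions lacking a full
window at a CDS edge are excluded from motif tables but retained in
L_S/L_A.

## Spectra and A/S ratios

The recurrence key is the identical nucleotide change, (chrom, pos, ref,
alt); per-site (any-alt) counting exists as a non-default diagnostic.  A
patient contributes at most once per key, which is what guarantees
i <= n.  A_i counts missense sites only; nonsense sites are tallied in a
parallel map and can be merged for a combined "nonsynonymous" reading —
both conventions are available because published tabulations differ in
whether nonsense is folded in.  A_0/S_0 close the spectrum against the
opportunity (`A_0 = L_A - sum A_i`), and a cohort whose observed site
count exceeds its opportunity is rejected as inconsistent.  A/S ratios
over recurrence bins return the pair (A, 0) flagged undefined rather than
a number when the synonymous bin is empty.

## Outlier model

To ask whether high recurrence could be mutational rather than selective,
a two-class mixture puts a fraction p of sites at alpha-fold the bulk
rate:

    S_i = (1-p) L_S (nE(u))^i + p L_S (alpha nE(u))^i

The bulk term is fixed-rate, matching the plain mixture form; a gamma-bulk
mode adds g(i,k) for consistency with the dispersion model (off by
default).  The grid fit calibrates E(u) on the observed S_1 for every
(p, alpha) pair (31 x 31 log-spaced by default, p in [1e-5, 1e-2], alpha
in [1.1, 1000]) and accepts a pair when its implied S_2 and S_3 both lie
in the closed central 95% interval of Poisson(lambda = observed count)
(integer inverse-CDF quantiles; central rather than one-sided is a choice,
flagged here).  Accepted pairs project S_4, S_5, summarized as mean and
sample SD.  An empty acceptance region is reported as the degenerate p = 0
fit.

Numerical notes: an observed count of 0 anchors its interval at {0}, so
any pair implying a materially positive expectation is rejected — that is
the route by which a cohort earns the p = 0 report.  With exome-scale
counts (S_2 in the hundreds) the +/-6% acceptance windows are narrower
than the default grid pitch (one alpha step moves expected S_2 by ~50%),
so the default grid can reject everything near a true generating pair; the
grid resolution is configurable and recovery analyses use 121 points per
axis.  A single synthetic draw propagates the Poisson noise of S_2/S_3
into tens of percent on the fitted p, so calibration tests assert recovery
on the mean over replicate draws.  The qualitative conclusion the model
supports is that with realistic observed S_1..S_3 no accepted outlier
scenario projects S_4 above ~1 — hypermutable outliers cannot manufacture
recurrence >= 4.

## Hotspot diagnostics

- **Motif rates**: per-motif rate = mutations / site number, scaled per
  1e5 motif sites; the spread statistic alpha = max/mean over motifs with
  nonzero site number.
- **Consensus lengths**: windows (21..101 bp, odd, centered) around
  recurrence sites are compared pairwise at matching 10-bp-stride offsets;
  consensus = window length minus Hamming distance, i.e. the match count —
  the match-count reading is adopted because the Poisson(W/4) null only
  fits matches.  Same-gene pairs and listed homologous gene pairs (the
  list is an input, not computed) are skipped.  The K-S test against
  Poisson(W/4) is one-sided for a heavy right tail and is computed on the
  integer support with right-continuous CDFs (a continuous-data K-S
  routine overstates the discrepancy of heavily tied counts); the p-value
  is the one-sided Smirnov tail exp(-2 n D^2).  Caveat: the true null of
  i.i.d. windows is Binomial(W, 1/4), whose narrower body registers as a
  small systematic D against the Poisson reference at large pair counts;
  the diagnostic is meant for right-tail outliers, not for exact
  goodness-of-fit.
- **Resampled K-S**: the raw one-sided p0 (group stochastically greater
  than pool) is adjusted by drawing same-size subsets of the pool; the
  adjusted p is the fraction of resamples at least as extreme (p_j <= p0),
  the standard permutation convention — the literal complementary reading
  is available behind a flag.  Because subset sizes are equal, p_j is
  monotone in the K-S statistic, so the implementation compares statistics
  directly (verified against scipy) and stays tractable at the default
  100,000 resamples.  Deterministic under a fixed seed.

## The simulator

`simulate` generates cohorts with exactly the structure the theory
assumes: gamma rates per site (constant across patients — the theory's
reading of per-site heterogeneity), a CpG stratum (default 6.5% of sites
at 7-fold, the midpoint of the reported 5..10-fold elevation), optional
hypermutable outliers (p, alpha), and planted selected sites whose rate is
multiplied by w (= 2Ns) at cohort time.  After strata multipliers the
rates are renormalized so the grand mean is exactly E(u): strata shift
relative, not absolute, mutation mass, keeping all E(u)-anchored
expectations valid (this deliberately differs from naive multiplication).
Hits are Bernoulli per patient below 1e8 patient-site trials and
per-site Poisson(n u) above, with draws exceeding n redrawn (logged) so
i <= n always holds.  Bit-reproducible per seed (three independent
streams: rates, hit counts, patient assignment).

What it does not emulate: clonal structure and within-tumor
heterogeneity, copy number, patient-level rate heterogeneity (a mutator
patient is a load-filter test case, not a default), regional
(epigenomic) rate covariates, and real codon structure — simulated sites
are pre-labeled synonymous/missense rather than derived from sequence.
Passing calibration tests therefore validate the statistical machinery
under the model's own assumptions, not the model's adequacy for any real
cohort.

## Problem sizes in the test suite

The suite runs the simulator at L = 1e6 sites (100 replicates for
goodness-of-fit against the negative binomial, 200 for the false-positive
budget) and n = 500..1000 patients, with expectations recomputed for
those L — the calibration logic is scale-free, and these sizes keep the
whole suite to about a minute.  The threshold and opportunity
computations are closed-form and run at full exome scale.

## Known limitations

- The exact-binomial spectrum mode integrates the gamma density
  numerically; it is intended for cross-checking the closed form, not for
  bulk computation.
- Per-gene thresholds keep the exome-wide L_A by default (false-positive
  control over the whole coding region); a panel-restricted L_A is
  supported but non-canonical.
- The reader handles single-nucleotide substitutions only: no indels,
  MNVs, liftover, or consequence annotation from raw genome context.
- Estimating the selection parameters (w, f) from data is out of scope;
  the selection model is forward-only.
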