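# Methods

## The problem

Differential methylation hybridization (DMH) assays the methylation
state of every known CpG island (CGI) on two-channel tiling arrays: a
test sample labelled Cy5 (red) is co-hybridized with a common normal
reference labelled Cy3 (green), and the per-probe signal is the
normalized log ratio M = log2(Cy5/Cy3).  Hypermethylation shows up as
elevated M.  Short probes (45–60 bp) make individual probe signals
unreliable — probe affinity, PCR and scanner effects inject large,
partly unmeasurable noise — so calling has to aggregate probes per
island while absorbing probe-specific offsets.

## The model

For each CGI, all non-missing probe × sample log ratios are stacked and
the conditional τ-quantile is modelled additively:

    Q_{Y_sp}(τ) = sample_s(τ) + probe_p(τ)

* `sample_s` — the tested quantity: the τ-quantile methylation signal
  of sample *s* at the island's "average probe".
* `probe_p` — probe affinity, constrained to sum to zero across the
  island's probes.

Encoding: full sample dummies (no intercept) plus sum-to-zero probe
contrasts, so every one of the N samples has a directly testable
coefficient.  Single-probe islands get no probe columns.  Quantile
levels above 0.5 focus the fit on the upper tail, where
hypermethylation signal concentrates even when most probes of a truly
methylated island stay unremarkable.

Estimation minimizes the check loss Σ ρ_τ(y − Xb),
ρ_τ(u) = u(τ − 1{u<0}), which is a linear program.

## Solvers

Two routes solve the same LP:

1. **Exact vertex fits** (point estimates): the sparse primal LP is
   handed to the HiGHS simplex (`scipy.optimize.linprog`).  A basic
   solution interpolates k observations exactly, which gives the
   classical residual pattern (≥ k zero residuals, at most nτ strictly
   negative and n(1−τ) strictly positive residuals) and deterministic
   output.
2. **Fast interior point** (bootstrap refits): a structure-exploiting
   Frisch–Newton primal-dual scheme on the bounded dual
   max{y'a : X'a = (1−τ)X'e, a ∈ [0,1]^n}.  Because each design row
   holds exactly one sample indicator and one probe contrast, the
   weighted normal matrix collapses to a diagonal sample block plus a
   (P−1)×(P−1) probe Schur complement, making one fit ~0.2 ms — cheap
   enough for hundreds of bootstrap refits per CGI per τ.  Mehrotra
   predictor-corrector steps; convergence at complementarity gap
   < 1e-10·(1+|objective|).  Near a degenerate optimum the Newton
   system can break down; the iterate is then accepted if the gap is
   already below 1e-6·(1+|objective|), which bounds the objective error
   around 1e-8 while coefficients on a flat optimal face may carry a
   small residual wobble — immaterial against the sampling spread the
   bootstrap is there to measure.

A brute-force oracle (`oracle_fit`) enumerates every k-subset of
observations with an invertible subdesign on tiny instances; the test
suite holds the LP path to the oracle minimum within 1e-8.

## Inference and scoring

Each sample effect is tested against `sample_s(τ) = 0` with the xy-pair
bootstrap: B = 200 resamples of design rows with replacement, refit,
normal-approximation p-value from the bootstrap standard error.
One-sided (`greater`) is the default, matching the hypermethylation
direction; resamples that lose a sample level (or are otherwise
degenerate) are redrawn, up to 10·B attempts.  Bootstrap seeds derive
deterministically from the master seed and the CGI id, so results are
independent of execution order and worker count.

The methylation score of a CGI at cutoff p₀ is the number of samples
with p-value strictly below p₀, over p₀ ∈ {0.01, …, 0.05} — raw
p-values, no multiple-testing correction across CGIs, because the
counting score itself is the aggregate statistic of interest.

Note the null hypothesis is about the *quantile*, not the mean: for
centred noise the τ-quantile of a truly unmethylated sample is positive
at τ > 0.5, so some "null" rejections at high τ reflect genuine
positive noise quantiles rather than miscalibration.  Calibration is
therefore checked at τ = 0.5 (where symmetric noise makes the null
exactly true); there the one-sided rejection rate at 0.05 must stay in
[0.02, 0.08].

A CGI is fitted only when its non-missing cell count exceeds the
parameter count by more than 5; otherwise it is reported "not called"
with a reason code.  Samples with no data for an island are scored not
significant and flagged.

## Evaluation

Known methylated genes (positive controls, N_m ≈ 30) and housekeeping
genes (negative controls, N_HK = 47) anchor the comparison of quantile
levels τ ∈ {0.60, …, 0.95}.  At each (τ, p₀) cell three statistics
compare the control score sets: trapezoidal ROC AUC (threshold sweep
C₀ = 0…N+1, classify methylated when score ≥ C₀; identical to the
tie-corrected Mann–Whitney statistic), mean.diff = x̄_m − x̄_HK, and the
Welch-type T.stat with unbiased variances.  Controls are matched by CGI
id; gene symbols resolve through the annotation to all associated CGIs
(optionally collapsed to the per-gene maximum).  The grid summary
averages each measurement over p₀ per τ and reports the maximising τ
plus a recommended band (τ within 5% of the maximum average); when even
the best average AUC is below 0.55 the recommendation is withheld as
"no separation".

## Baseline

The probe-level comparison method calls a (CGI, sample) pair methylated
when at least a fraction f ∈ {30%, 50%, 100%} of its non-missing probes
has M strictly greater than 1.5; its per-CGI score (number of samples
called) feeds the same control AUC.

## Normalization

`compute_ma` forms M = log2(R/G) and A = (log2 R + log2 G)/2;
`loess_normalize` subtracts a robust LOESS trend of M on A per array
(span 0.3, local linear, tricube weights, 3 bisquare iterations —
conventional two-channel defaults; the smoother parameters are a stated
choice, not a reconstruction).  Arrays are corrected independently; no
between-array normalization.  Pipelines may start from precomputed M
values and skip this stage.

## Synthetic data: what it emulates and what it does not

The generator draws probe-level log ratios

    M[p, s] = effect·1{cell methylated}·1{probe informative}
              + affinity[p] + block[c, s] + noise[p, s]

with defaults chosen as the study conditions: 40 samples, 500 CGIs,
6–10 probes per island (a 244K array tiling ~28k islands carries ~8
probes per island), 10% of islands methylated, prevalence 0.7
(round(0.7·N) methylated samples per methylated island), effect 1.0
carried by 40% of the island's probes, probe affinity sd 0.15,
scaled-t₃ noise (scale 0.10), and a per-(CGI, sample) block effect
(sd 0.25) shared by all probes of an island.  Partial probe
informativeness and heavy tails deliberately violate the fitted
additive model — truly methylated islands mostly show several
moderately elevated probes rather than many probes beyond a hard 1.5
cutoff, which is the regime in which high-τ quantile calling beats
per-probe thresholding.

The noise magnitudes deserve comment, because no quantitative noise
parameters are recoverable from real DMH arrays and they were fixed
once from two empirical anchors:

* **Per-probe dispersion** (affinity sd 0.15 + t₃ scale 0.10, total
  ≈ 0.25): anchored on the reported behaviour of the probe-level 1.5
  cutoff — methylated probes peak "relatively large but below 1.5", so
  the cutoff baseline scores almost nobody and its control AUC sits
  near chance.  Much larger per-probe noise also inverts the τ-ordering
  outright: the methylated-sample elevation at high τ is an *absolute*
  effect minus a scale-proportional term, while near τ = 0.5 the
  elevation is purely scale-proportional (its z-statistic is
  scale-invariant), so inflating probe noise erases precisely the
  high-τ advantage the method exhibits on real arrays.
* **Block sd 0.25**: sample-level regional artifacts (digestion
  efficiency, PCR, copy number) that shift a whole island within one
  sample.  Without this term, unmethylated islands are implausibly
  silent at low τ and any weak positive signal separates the controls
  perfectly at τ = 0.6 — the opposite of real-array behaviour, where
  housekeeping genes accumulate scores at every quantile level and low
  τ discriminates worst.  Because the block shift is a genuine sample
  effect, calibration runs that require the null `sample_s(τ) = 0` to
  hold exactly set it to zero.

Control lists are sampled from ground truth: 30 methylated islands as
positives and 47 null islands as negatives (32 for ovarian-like runs).
With `dye_bias` set, raw two-channel intensities with a smooth
intensity-dependent M trend are emitted so the LOESS stage is exercised
end to end.

Passing benchmarks on these data show the pipeline recovers the
qualitative regime the method was designed for; they do not certify
performance on real arrays, whose noise need not be additive,
symmetric, or island-independent, and whose control genes carry
biological (not simulated) uncertainty.

## Numerical and design choices

* Strict inequalities follow the method's wording: p < p₀ for scores,
  M > 1.5 for the baseline probe rule; "at least 30%" is ≥ on the
  fraction.
* ROC sweep includes C₀ = N+1 so the curve closes at (0,0).
* Unbiased (n−1) sample variances in T.stat; equal-mean zero-variance
  sets raise an error from `t_stat` itself and are reported as 0 (no
  separation) inside the grid.
* Degenerate bootstrap standard errors (se = 0) give p = 1 unless the
  estimate is strictly positive (one-sided).
* Quantile levels below 0.5 are accepted by the fitter and the CLI
  (hypomethylation calling) but evaluation is not wired to control
  sets — no negative controls are defined for that direction.
* Per-CGI work is embarrassingly parallel (`--workers`); results are
  bit-identical for any worker count because seeds attach to (CGI, τ),
  not to threads.

## Problem sizes

Default test and benchmark sizes (500 CGIs × 8 τ × 200 bootstrap
refits; 500 null CGIs for calibration) were chosen so a complete run
finishes in minutes on one core while keeping Monte-Carlo error on AUC
summaries near ±0.01–0.02.

## Known limitations

* Bootstrap-normal p-values at extreme τ with few probes per sample
  (≈ 1–2 effective tail observations) are approximate; the rank-score
  inference slot (`method="rank"`) is reserved but not implemented.
* Coefficient (not objective) uniqueness is not guaranteed when nτ is
  an integer; ties are resolved by the solver's deterministic pivoting.
* No FDR control across CGIs, no region merging, no between-array
  normalization — matching the method being implemented, not a
  recommendation.
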