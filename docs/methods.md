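# Methods

## Model and likelihood

mlsemfit fits two-level covariance structure models for p observed variables
measured on N level-1 units in J clusters. The data model is the usual
decomposition y_ij = μ + y_Bj + y_Wij with mutually independent multivariate
normal components, a homogeneous within-cluster covariance Σ_W, and a
between-cluster covariance Σ_B; cluster means then have covariance
Σ_B + Σ_W/n_j. Each level's structure is expressed in the reticular (RAM)
parameterization: directed paths in A, symmetric (co)variances in S, implied
covariance F(I−A)⁻¹S(I−A)⁻ᵀFᵀ. This one formulation covers path models,
factor models, and the saturated and independence variants the fit indices
need, and the saturate/independence transformations are purely mechanical
(replace a level's pattern, leave the other level bit-identical).

Estimation minimizes the two-level ML discrepancy

F(θ) = Σ_j [log|Σ_gj| + tr(Σ_gj⁻¹ S_Bj)] + Σ_j (n_j−1)[log|Σ_W| + tr(Σ_W⁻¹ S_Wj)],

Σ_gj = Σ_W + n_j Σ_B, S_Bj = n_j(ȳ_j−ȳ)(ȳ_j−ȳ)′. Since Σ_gj depends on j
only through n_j, the sum collapses to one term per distinct cluster size
plus a single pooled-within term; this grouped evaluation is exact and makes
the cost of one evaluation independent of J. The exact log-likelihood
(for reporting) adds the normal constants and profiles the mean vector by
GLS; with the saturated mean structure used throughout, means cancel from
every chi-square. The exact-fit statistic is the difference of minimized
discrepancies between the hypothesized and fully saturated models; for
balanced data this equals the −2 log-likelihood-ratio identically (a tested
identity), and for unbalanced data it is the discrepancy-difference form
stated with the fitting function above (the grand mean takes the place of
the profiled GLS mean inside S_Bj; the two differ only at O(1/N) for
unbalanced data). The segregating step 1, by contrast, maximizes the full
likelihood jointly in (μ, vech Σ_W, vech Σ_B), because its products — the
unrestricted estimates and their asymptotic covariances — are defined by
that likelihood.

## Optimization

Free parameters live on the raw scale. Σ_W (and every Σ_gj) must be
positive definite: the objective returns a large finite barrier value
outside that region. Σ_B is deliberately *not* constrained — the
unrestricted between estimate (S̄_B − S_pw)/n may be indefinite, and forcing
it positive would change the level-specific and segregated chi-squares.
Gradients are analytic via the chain rule through the RAM structure
(dF = tr(W_W dΣ_W) + tr(W_B dΣ_B) with closed-form weight matrices), and
were verified against central differences.

Three numerical choices matter in practice:

* **Whitening.** Variables on very different scales (a test score with
  variance ≈ 70 next to a binary indicator with variance 0.25) make the
  Hessian ill-conditioned. Each parameter is internally rescaled by its
  typical magnitude — √(C_ii C_jj) for a covariance entry, √(C_ii/C_jj) for
  a path j→i — where C is the observed analog of that level's covariance
  matrix (pooled within; balanced-form between).
* **Trust-region polish.** The hard feasibility barrier can defeat the
  quasi-Newton line search when an iterate hugs the PD boundary (the line
  search interpolates against the barrier's flat +∞ face and stalls). If
  L-BFGS-B terminates with a non-small gradient, a trust-region Newton
  refinement (Hessian-vector products by differencing the analytic
  gradient) finishes the job; trust regions simply shrink on rejected
  steps and are immune to the barrier.
* **Closed forms and profiling.** Balanced data: the fully saturated model
  is solved exactly (Σ̂_W = pooled within S_pw with divisor N−J;
  Σ̂_B = S̄_B/n − S_pw/n with S̄_B the average between matrix), and any model
  whose between level is saturated profiles that level out exactly
  (Σ̂_g = S̄_B for any Σ_W), reducing the fit to a single-level problem in
  the within parameters. A corollary worth stating: on balanced data the
  partially saturated within statistic and the segregated within statistic
  coincide *exactly*, which is why the two approaches agree so closely in
  applications.

Starting values are deterministic and data-based: per-equation OLS solves on
the level target matrices for paths and residual variances, observed
(co)variances for saturated levels, zeros elsewhere. Convergence requires
the projected gradient below 10⁻⁷·(1+|F|) (relative, since F scales with N)
with a relative function tolerance of 10⁻¹²; non-convergence is flagged on
the result, and reported cells are downgraded rather than fabricated.

Degrees of freedom are moment counts: each level offers p(p+1)/2
covariances; a level's df is that minus its distinct free parameters
(labels shared across levels are counted once and attributed to the within
level). The saturated mean structure contributes nothing.

## Fit indices

All three approaches share the same index arithmetic: p-values from the
central chi-square upper tail (printed as "<0.001" below that threshold),
CFI = 1 − max(χ²_H−df_H,0)/max(χ²_B−df_B,0) clipped to [0,1], and
RMSEA = √(max((χ²−df)/(df·m),0)) with the approach's multiplier m:

| approach | chi-square | baseline for CFI | RMSEA multiplier |
|---|---|---|---|
| standard | hypothesized vs saturated | independence at both levels | N−1 |
| PS_B | [Σ_B(θ), Σ_W(θ_S)] vs saturated | between-independence + within-saturated | J (option J−1) |
| PS_W | [Σ_B(θ_S), Σ_W(θ)] vs saturated | between-saturated + within-independence | N−J (option N−J−1) |
| YB_W | single-level fit to Σ̂_W | single-level independence (closed form −(n_eff−1)log|R|) | n_eff−1 = N−J |
| YB_B | single-level fit to Σ̂_B | single-level independence | n_eff−1 = J−1 |

The RMSEA multipliers follow the level-specific formulas literally (J and
N−J); the `rmsea_small_sample: subtract_one` switch applies the single-level
small-sample convention (J−1, N−J−1) instead. Both conventions appear in
published applications — worked-example tables for the segregated between
level back-compute to J−1, while the level-specific formula prints J — so
both are reachable, with the literal form as default.

Step 2 of the segregating procedure needs effective sample sizes that no
formula in the source material fixes; the defaults n_eff = N−J+1 (within)
and n_eff = J (between) reproduce the observed near-identity of the
segregated and level-specific within statistics and the J−1-consistent
between RMSEA, and are overridable (`neff_within`, `neff_between`).
Parameter estimates from partially saturated or segregated fits are
computed but marked not recommended for inference; estimates should come
from the full two-level model.

## Simulator

The generator draws y_Bj once per cluster and y_Wij per unit, adds μ, and is
fully reproducible from a seed (replication studies spawn per-replication
child seeds). Non-normal components use Fleishman third-order polynomials
per margin with Vale–Maurelli intermediate correlations, solved at design
construction so infeasible moment targets fail before any sampling; the
default targets of interest are skewness 2 / excess kurtosis 7, the
rule-of-thumb cutoffs above which normal-theory ML statistics become
appreciably biased. Cluster sizes may be constant, explicit, or uniform on
[low, high] — optionally adjusted within bounds to hit an exact total, which
is how the 5928-student/164-school fixture reproduces its printed
dimensions.

Two presets define the study conditions used by the test suite:

* **mediation** — a three-variable chain x → med → y at both levels
  (paths 0.5 and 0.6, unit within variances, Σ_B = 0.25·Σ_W, so ICC = 0.2),
  used for type-I error calibration at J = 200 clusters of n = 10 with 500
  replications.
* **timss_like** — the five-variable path model of gender, mathematics
  motivation and achievement with published two-level path estimates as
  generating values (J = 164, n = 36 balanced for simulations; school sizes
  26–42 summing to 5928 for the empirical-dimensions fixture). The residual
  variances and covariances are *fixture choices, not published values*:
  they were set once to give intraclass correlations near 0.2 for gender and
  the motivation composites (the achievement ICC comes out ≈ 0.55, the
  large between-level regression coefficients acting on school-mean
  motivation explain most school-level score variance — high, but in the
  range reported for this school system). Misfit conditions drop the
  within confidence→achievement path or the between gender→achievement path
  from the *fitted* model while the generator keeps them.

What the simulator does not emulate: sampling weights and survey design
effects, missing data, categorical measurement of the motivation composites
(generated as continuous), heterogeneous within-cluster covariances, and
more than two levels. Passing calibration and detection tests on these
conditions therefore demonstrates correctness of the statistics under the
model's own assumptions, not robustness to their violation (the non-normal
generator exists precisely to study the latter).

## Known limitations

* Complete data only; rows with missing cells are rejected at ingestion.
* Recursive (acyclic) structural models; no MLR/robust rescaling, no
  residual-based or F statistics, no sandwich standard errors.
* The asymptotic covariance matrices of the saturated estimates use the
  observed information (central differences of the analytic gradient);
  expected-information versions may differ slightly in small samples.
* With J ≤ p the average between matrix is singular and saturated
  between-level fits are correctly refused; degenerate between variation
  (identical cluster means) yields flagged estimates with an unbounded
  likelihood rather than an error.
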