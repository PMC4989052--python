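# Methods

## Models

All three structures are exponential families over binary patterns
σ ∈ {0,1}^N with energy Σᵢ h_{i,K(σ)} σᵢ, where K(σ) = Σᵢ σᵢ is the
population rate.  They are the maximum-entropy distributions consistent with,
respectively: the firing rates P(σᵢ=1) and the population-rate distribution
P(K) (*minimal*, h_{iK} = αᵢ + β_K); additionally the linear couplings
⟨Kσᵢ⟩ (*linear*, h_{iK} = αᵢ + β_K + γᵢK); or the complete set of joints
P(σᵢ=1, K) (*complete*, unconstrained h).  The structures are nested:
a minimal model is a linear model with γ = 0, and any structured model is a
complete model, with identical predictions — the test suite asserts this.

### Gauge conventions

The distribution is invariant under αᵢ → αᵢ + c, β_K → β_K − c, and (linear
only) additionally β_K → β_K + dK, γᵢ → γᵢ − d.  The canonical gauge pins
β₀ = 0 and β₁ = 0 for all structured models, and additionally β₂ = 0 for the
linear model.  Pinning β₁ alone leaves the one-parameter family
(α + c, β_K + c(K−1), γ − c) unresolved; β₁ = β₂ = 0 removes both
degeneracies uniquely, leaving exactly 2N−1 (minimal) and 3N−2 (linear)
identifiable parameters.  For the complete model, h_{i0} never enters any
probability (no neuron spikes when K = 0) and is pinned to 0, and only
Σᵢ h_{iN} enters (through the all-ones pattern), leaving N(N−1)+1 free
parameters: h_{iK} for K = 1..N−1 plus the pooled K = N field.

### Tractability

The partition function decomposes over the population rate,
Z = Σ_K Z_K with Z_K = Coeff[∏ᵢ(1 + X e^{h_{iK}}), X^K], and each coefficient
follows from the recursion Coeff[(1+bX)F, X^l] = Coeff[F, X^l] + b·Coeff[F, X^{l−1}].
All coefficients are positive, so the recursion is carried in the log domain
with log-sum-exp; this never overflows, whatever the field magnitudes.  The
joints are derivatives of log Z, P(σᵢ=1, K) = ∂logZ/∂h_{iK}, evaluated as
leave-one-out coefficients via prefix/suffix tables (deconvolving a single
factor is numerically unstable and is avoided).  Pairwise second moments
⟨σᵢσⱼδ_{K,k}⟩ use leave-two-out coefficients, excluding *both* neurons from
the product; the total cost of all predictions is O(N³), with the pairwise
moments O(N⁴) in the worst case.

Tuning curves use p(σᵢ=1 | K_{\i}) with P(σᵢ=1, K_{\i}) = P(σᵢ=1, K=K_{\i}+1)
and P(σᵢ=0, K_{\i}) = P(K_{\i}) − P(σᵢ=1, K_{\i}).  Entries whose
conditioning event has zero probability are reported as missing (NaN), never
as 0.

## Empirical statistics and regularization

Statistics are plug-in averages over time bins, treated as exchangeable
patterns.  Before fitting, P(K) and the conditionals P(σᵢ=1|K) are
regularized with pseudocounts shaped by an independent-neuron model carrying
the empirical rates:

    P(K)          = (n_K  + λ P_indep(K)) / (n + λ)
    P(σᵢ=1|K=k)   = (n_{ik} + λ P_indep(σᵢ=1|K=k)) / (n_k + λ)

with λ = 1 by default (one observed pattern's worth of prior mass).  The two
denominators follow different totals, so the regularized conditionals are not
exactly the conditionals of one mixture distribution; the inconsistency
carries total weight of order λ/n and is accepted as is.  Joints and
couplings are recomputed from the regularized P(K) and conditionals, which
preserves the identity Σᵢ P(σᵢ=1, K) = K·P(K) exactly (the pseudo-conditional
column sums equal K).  The identities P(σᵢ=1|K=N) = 1 and P(σᵢ=1|K=0) = 0 are
re-imposed against floating-point noise so that states with exactly zero
probability stay exactly zero on both the data and the model side of KL
divergences.

## Inference

The normalized log-likelihood L(μ) = ⟨Σᵢ h_{iK}σᵢ⟩_data − log Z is concave;
its gradient is the observed-minus-predicted mean of each parameter's
observable and its Hessian is minus the model covariance of the observables.
Every structured observable is a linear projection of the complete-model
features σᵢδ_{K,k}, so one moment computation serves all three structures.

Newton updates μ ← μ − a·H⁻¹∇L use step size a = 1 with halving backtracking
whenever a step would decrease L (the step resets each iteration; halving may
go below 0.1 in early, ill-conditioned iterations — ascent is preferred over
a hard floor).  The Hessian is refreshed every 100 iterations and reused in
between.  Convergence is declared on the *fitting error*: the maximum
absolute discrepancy on P(K) and P(σᵢ) (minimal); plus ⟨Kσᵢ⟩ (linear); or on
P(K) and the conditionals P(σᵢ|K) (complete), with tolerance 10⁻⁶ by
default.  Non-convergence is always reported explicitly.

Numerical choices that matter:

* **Scale-relative ridge.**  Second moments at rarely visited population
  rates are tens of orders of magnitude below 1, while the convergence
  criterion includes *conditionals* at those rates.  The Newton step is
  scale-invariant per rate block, so damping is applied relative to each
  block's own diagonal scale (default 10⁻⁸, escalating ×100 until the
  Cholesky succeeds — blocks are near-singular because the covariance of σ
  conditioned on a fixed K has the all-ones null vector).  An absolute ridge
  would freeze the parameters of rare rates and stall the complete model far
  from its tolerance.
* **Block + rank-one Hessian for the complete model.**  Second moments of
  σᵢδ_{K,k} vanish across different k, so −H = blockdiag_k(S_k) − m mᵀ; the
  solve uses per-block Cholesky factors and the Woodbury identity, avoiding a
  dense N(N−1)+1 square system.
* **Initialization.**  Minimal/linear start at the independent model,
  αᵢ = logit⟨σᵢ⟩, β = γ = 0.  The complete model starts at
  h_{ik} = logit P(σᵢ=1|K=k) + c_k, where the per-column offsets c_k are
  chosen so the initial P(K) equals the empirical one exactly (adding c_k to
  column k rescales Z_k by e^{k·c_k}).  Without the offsets the logit start
  concentrates P(K) near K = N and the likelihood surface is numerically
  degenerate there; with them the complete model typically converges in
  under ten iterations.

## Sampling

Sampling is exact and two-stage: K is drawn from Z_K/Z, then the
configuration by sequential inclusion — neuron i spikes with probability
e^{h_{iK}}·C_{i+1}[r−1] / C_i[r], where C_i are the suffix coefficients of
the remaining factors and r the number of spikes still to place.  Every draw
has exactly K spikes and follows P(σ|K) exactly; cost is O(N) per sample
after an O(N²) setup per distinct K.  A single named random generator is
threaded through; there is no global random state.

## Synthetic data

The generator stands in for a long multielectrode recording binned at 20 ms.
Its `known-model` mode draws a random model — defaults α ~ U(−4,−2)
(per-bin spike probabilities ≈ 2–12%, typical of retinal ganglion cells at
this bin width), β_K ~ U(−0.3, 0.3), γ ~ U(−0.1, 0.1) — and samples from it
exactly, returning the ground truth.  Its `independent-with-gain` mode draws
a shared Gaussian gain per bin (σᵢ = 1 with probability sigmoid(αᵢ + g_t)),
producing population-rate coupling without any direct interactions.  Neither
mode has temporal structure, refractoriness, or stimulus drive: passing
tests demonstrate the correctness of the estimators and inference on
i.i.d. bins, not robustness to the temporal correlations of real recordings.

**Recovery study conditions.**  The ground-truth recovery study (N = 15
linear model, n = 2×10⁵ bins) uses α ~ U(−3,−1) and γ ~ U(−0.2, 0.2).  These
were set by a Fisher-information power analysis: the inverse exact Hessian at
the truth gives a γ estimation error floor of ≈ 0.008–0.015 at this sample
size (dominated by the collinearity of Kσᵢ with σᵢ, largely independent of
firing rate), so the truth spread must be well above that floor for a
correlation-based recovery check to probe the inference machinery rather
than sampling noise; sd(γ) ≈ 0.115 predicts a recovery correlation ≈ 0.996.

## Evaluation statistics

* **KL divergences** are in bits.  The cross-validated z statistic is
  mean(D_KL(test‖model) − D_KL(test‖train)) / sd(·) across random half
  splits (sample SD, n−1 denominator; the choice is a convention).  z = 0
  when the vectors are identical; equal nonzero differences leave z
  undefined (zero SD) and are flagged as NaN.
* **Goodness-of-fit** C = [Σc²_test − Σ(c_test−c_model)²] /
  [Σc²_test − Σ(c_test−c_train)²] over neuron pairs; 1 when the model matches
  the training correlations, 0 when it predicts none, NaN when the
  denominator vanishes.
* **Extrema detection** declares a tuning-curve point a significant maximum
  when it exceeds its immediate neighbours (window configurable, default 1)
  by at least 5 cross-split SDs on both sides; minima are symmetric.  The
  location is the median across splits of the per-split extremum within the
  window; when several significant extrema coexist all are reported, ordered
  by height.
* **Multi-information** I = S_indep − S_data uses the plug-in pattern
  entropy (limited to ≤ 20 neurons) with no bias correction — a known
  limitation: S_data is biased down by up to ≈ 2^N/(2n ln2) bits, so
  I_model/I_data is biased slightly toward 0.  Model entropies are exact:
  S_model = log₂Z − ⟨energy⟩/ln 2.

## Known limitations

* Time bins are modelled as i.i.d. patterns; temporal correlations,
  refractoriness and sub-bin structure are out of scope.
* Hessian assembly is O(N⁴) in pure NumPy; fits are seconds-scale up to a
  few tens of neurons and minutes-scale for populations in the low hundreds.
* Plug-in entropies carry no bias correction (see above).
* The pseudocount scheme's small mass inconsistency between P(K) and the
  conditionals (order λ/n) is retained by design.
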