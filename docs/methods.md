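# Methods

## Model

`methylhmm` fits a two-state Hidden Markov Model to the ordered sequence
of per-cytosine bisulfite read counts of a genome.  States are U
(unmethylated) and M (methylated).  Both strands are interleaved on one
coordinate axis per chromosome, sorted by (position, strand with + before
−); the distance between neighbours is the plain position difference, so a
CG pair on opposite strands at adjacent positions is one 1 bp step of the
chain.  Each chromosome is an independent chain started from the initial
distribution π.

Emissions are binomial with success probability p indexed by (state,
sequence context).  The six contexts — CG, CCG, CWG, CAA, CTA and the
pooled remainder of CHH (CCA plus CHY) — are a pure function of the two
bases 3' of the cytosine on its own strand; minus-strand contexts are read
from the complemented reference bases at position−1, position−2.
Cytosines whose downstream bases run off the chromosome or contain N keep
no context: they stay in the methylome for bookkeeping but are excluded
from fitting and from every summary.  A site with r = 0 emits probability
1 in both states (the binomial of zero trials), which is precisely what
makes imputation fall out of the smoothing recursion for free.

Transitions interpolate between a zero-distance stochastic matrix A° and
the uniform matrix with an exponential decay e^(−d/D), one (A°, D) pair
per transition context (ordered pair of neighbour contexts; 36 matrices in
6-context mode).  D is **not** estimated inside EM: it is pre-fit from
data (below) and then treated as a constant, which keeps the M-step
tractable and the likelihood well-behaved.

## Decay pre-fit

For each transition context, the Pearson correlation y(d) of raw levels
m/r between *adjacent* covered cytosines (consecutive in the methylome, no
other cytosine between them, both with r ≥ 1) is tabulated per distance
d ∈ [1, max_distance], and a0·e^(−d/D) is fit by `scipy.optimize.curve_fit`
with multi-start D ∈ {5, 30, 100} bp (best kept by weighted SSE), a0
started at y(min d), and D clamped to [1, 1000] bp.  Rows are weighted by
√n_pairs, since the sampling error of a correlation scales as 1/√n.
Defaults: max_distance 100 bp (the spatial dependency of plant methylation
decays within roughly 10–40 bp, so 100 bp spans the signal), min_pairs 100.

Raw levels of covered sites are used — not status calls — because levels
are the only per-site quantity available before the model is fit; coverage
≥ 1 per pair member, unweighted pairs.

Sparse transition contexts (fewer than 3 distinct distances, or optimizer
failure) inherit a pooled all-contexts fit.  The pooled fit is computed
from a *pooled correlation table* (all pairs per distance, one correlation)
rather than from the union of per-context rows: gap lengths are
independent of context composition, so the pooled y(d) keeps a clean
single-exponential shape, whereas the union of rows loses sparse
high-amplitude contexts at large d first and fakes a faster decay.  If
even the pooled fit is impossible the decay defaults to 30 bp.

## Fitting

Parameters (p, A°, π) are estimated by Baum-Welch with a scaled
forward-backward E-step (per-position scaling constants in linear space;
the scaled recursion is verified against exhaustive path enumeration to
1e-9 in the test suite, which is why log-space was not needed).  The
numerically critical recursion is compiled with numba.

The distance dependence modifies the transition M-step.  Solving the
Lagrange-constrained stationarity of the expected complete-data
log-likelihood in A°, with ∂A/∂A° = e^(−d/D) from the affine form of the
kernel, gives

    A'°_ijc ∝ Σ_t δ(c, c_{t,t+1}) ξ_ijt (A°_ijc / A_ij(d_t)) e^(−d_t/D_c)

with rows renormalized to 1.  At d = 0 this reduces to the classical
Baum-Welch update.  It is a fixed-point (generalized EM) step rather than
an exact argmax; the log-likelihood trace is asserted non-decreasing
(tolerance 1e-8) at run time and across 100 simulated datasets in the
tests, and a decrease raises an error rather than being silently accepted.
Transition contexts with zero weight and emission contexts with zero
posterior-weighted coverage keep their previous values.  π is re-estimated
from the posteriors at chain starts.

Initialization: p_U = 0.05, p_M = 0.80 in every context, A° diagonal 0.9,
π uniform.  This breaks the label symmetry toward the conventional U/M
meaning; as a safety net, labels (p rows, A° axes, π, γ columns) are
swapped after convergence if the mean of p_U exceeds the mean of p_M.
Convergence: absolute log-likelihood change below tol = 1e-4, max_iter
500.  Binomial coefficients are included in the emissions; they cancel in
all posteriors and updates but make the reported trace the true data
log-likelihood, which the monotonicity contract needs.

Status is the posterior argmax; an exact tie goes to U (conservative
toward the unmethylated background).  The recalibrated level
m' = p_U,c γ_U + p_M,c γ_M is bounded by [p_U,c, p_M,c] by construction
and defined at every site.  Conversion rates: 1 − p_U,CG (unmethylated
conversion rate) and 1 − p_M,CG (upper bound for methylated cytosines;
biased upward because p_M absorbs intermediate methylation from tissue
heterogeneity).  CG is used to avoid the fuzzier CHG/CHH maintenance.

A useful identity: at the EM fixed point the emission update forces
Σ_t m'_t r_t = Σ_t m_t within each context, so the coverage-weighted mean
of m' (the recalibrated wGML) coincides with the naive read-count wGML on
the data the model was fit to.  The two measures are therefore reported
separately but expected to agree closely — their joint robustness under
thinning is what distinguishes them from call-based GML.

## Baseline caller

The comparison method: sites with r ≥ 3 get an exact one-sided binomial
test of H0: P(methylated read) = error_rate (default 0.01 ≈ 1 − typical
conversion rate, overridable with the HMM estimate) against greater,
Benjamini-Hochberg-corrected at α = 0.05 by default (toggleable; the
correction choice is declared, not canonical).  Sites with r < 3 take the
majority status of directly tested same-context sites within ±100 bp
(a "200 bp neighbourhood"); ties and empty electorates stay undefined,
and undefined counts as a false negative in F1 scoring.  Neighbour votes
are not strand-restricted — context match only.

## Synthetic data

The simulator runs the generative model forward: geometric inter-cytosine
gaps (default mean 3 bp, the dense spacing of a GC-rich-both-strands plant
genome), i.i.d. contexts with weights (0.14, 0.05, 0.09, 0.17, 0.12, 0.43)
for (CG, CCG, CWG, CAA, CTA, CHH_rest) — a CHH-heavy composition typical
of plant genomes — states from the distance-dependent chain, and counts
r ~ Poisson(λ), m ~ Binomial(r, p_{state,ctx}).  Default truth: p_U = 0.01
(1% conversion failure), p_M graded 0.80/0.70/0.60/0.45/0.40/0.30 across
the six contexts to mirror the known ordering of context methylation
levels, A° diagonal 0.9, D = 30 bp, λ = 6.  These are synthetic defaults
chosen once for realism, not values fitted to any particular dataset.

What the simulator does *not* emulate: mappability structure (coverage is
i.i.d. Poisson, real coverage is spatially autocorrelated and depleted in
repeats), annotation-dependent methylation (genes vs TEs), cellular
heterogeneity beyond p_M < 1, PCR duplicates, and context mis-assignment
from genotype differences.  Passing tests therefore demonstrate
correctness of the algorithm under the model's own assumptions and its
statistical behaviour (recovery, saturation, robustness), not performance
on any particular organism.

## Problem sizes and numerical choices

Test and acceptance workloads use 200,000 sites at 6X for parameter
recovery (recovery tolerances: p_U,CG ±0.005, p_M,CG ±0.03, conversion
rate ±0.003), 40,000 sites at 20X for saturation analyses, and 100 × 2,000
sites for EM monotonicity — sizes at which the Monte-Carlo error of every
asserted quantity is comfortably below its tolerance.  Forward-backward
correctness is checked against exhaustive 2^T path enumeration for chains
up to length 10; M-step formulas against literal term-by-term
transcriptions in exact loops; the binomial pmf against exact rational
arithmetic.

Degenerate inputs: an empty or all-invalid-context methylome is rejected;
a forward pass reaching zero probability (possible only with degenerate
p ∈ {0, 1} inconsistent with the data) raises a numerical error; contexts
with no data keep previous parameter values with a log message.

## Known limitations

- D is fixed from the pre-fit; a misspecified decay length degrades
  imputation confidence calibration (though status calls are robust, as
  the saturation tests show).
- Confidence for sites deep inside long uncovered gaps tends to the
  stationary distribution — such calls carry no information beyond
  background methylation frequency and can be filtered by posterior.
- 1 − p_M,CG systematically overstates the inappropriate conversion rate
  whenever tissues are heterogeneous.
- The transition M-step is a generalized-EM fixed-point step; monotonicity
  is enforced empirically (error on violation), not proved.
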