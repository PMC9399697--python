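# Methods

`locomorph` infers the locomotor ecology of extinct rodents from linear
measurements of the astragalus (ankle bone) and places those inferences in
a macroevolutionary context: ancestral locomotor states on a time-calibrated
phylogeny and model selection for body-size evolution. This note documents
the models, the numerical choices, and what the synthetic-data experiments
do and do not demonstrate.

## Shape variables and size proxies

Each specimen contributes 15 linear measurements (mm). Shape is separated
from size with log-shape ratios: `v_i = ln(m_i / GM)` where GM is the
geometric mean of the same 15 measurements. Every shape vector therefore
sums to zero and is invariant to isometric rescaling. The GM is computed
over the 15 retained measurements only (the astragalar neck length, often
excluded as hard to replicate, never enters); the measurement set is
configurable through a column map because abbreviation schemes differ
between labs.

Natural logs are used for shape: the base only rescales all variables by a
common factor and cannot change any discriminant result. Size proxies are
reported in base 10 — `LogGM = log10(GM)` for astragali, `log10(LTRL)` for
lower toothrow lengths — because size comparisons are conventionally read
in decades.

Analyses run at the species level: specimen shape vectors are averaged per
species (specimen-level tables are accepted everywhere a species-mean table
is). Specimens with a missing measurement are excluded with a warning, not
imputed; non-positive values are rejected outright.

Because the 15 shape variables satisfy one exact linear constraint, all
covariance-based computations work in the data-carrying subspace (an SVD
basis of the centred data) and map axes back to the original variables.
This is equivalent to using any fixed 14-dimensional contrast basis and
avoids ad hoc variable deletion.

## Canonical variate analysis

The CVA is the classical multi-group linear discriminant: axes are
eigenvectors of `W^-1 B` (pooled within-class vs between-class covariance),
ordered by eigenvalue; the per-axis "variance explained" is the eigenvalue
share. Classification is Gaussian with the pooled covariance:
`posterior_c ∝ prior_c · exp(-½ D²(x, μ_c))` with Mahalanobis distance `D`.
Default priors are the training class frequencies, which makes the
posterior-to-prior classification-rate ratio interpretable as improvement
over assigning by class share; equal priors are a flag away. Axes are
oriented so the strongest trait correlation on each axis is positive.

Validation is leave-one-species-out: each species is withheld, the model
refit, and the species classified. With ~140 species and 15 variables the
naive refit loop is cheap, so no downdating shortcuts are used. Species
whose class would vanish from the training set are skipped with a warning.

Group separation is tested with a MANOVA on the shape variables (Pillai's
trace reported first; Wilks' lambda alongside, since sources rarely state
which was used) plus per-axis one-way ANOVAs and Tukey HSD pairwise
comparisons on the leading canonical axes.

## Phylogenetically informed flexible discriminant analysis (pFDA)

Species are not independent samples: under Brownian motion the covariance
of a trait between two tips equals the root-to-MRCA path length. Pagel's
lambda scales the off-diagonal of that matrix — `C(λ)` has untouched
root-to-tip depths on the diagonal, shared paths multiplied by `λ ∈ [0,1]`.

Lambda is estimated class-blind on the predictors: for each grid value
(default 0, 0.1, …, 1) the GLS log-likelihood of a single-mean model with
covariance `σ²_t C(λ)` is evaluated per trait with `σ²_t` profiled out
analytically, summed over the 15 traits, and the grid argmax taken. The
alternative of choosing lambda to minimise training misclassification
exists in some published scripts; profile likelihood was chosen because it
is class-blind (no leakage into the discriminant) and matches the common
description of the method.

The discriminant then runs on whitened data: with `L L' = C(λ)` over the
training **and** target tips, all rows are premultiplied by `L^-1`, the
whitened intercept (the transformed ones vector) is projected out of the
whitened predictors — the GLS analogue of mean-centring — and the CVA is
fit on the training rows only. Fossil targets participate in the whitening
(their tree position matters) but never in lambda estimation or the fit.
Whitening uses a Cholesky factor with a symmetric-eigendecomposition
fallback (eigenvalues floored at 1e-10) for near-singular matrices. Either
factor orientation gives identical discriminant geometry; axes are
sign-normalised as in the CVA.

When `C ∝ I` — a star phylogeny, or `λ = 0` on a tree with equal
root-to-tip depths — the whitening is a scalar rescaling and the pFDA
reduces exactly to the ordinary CVA. On non-ultrametric trees `λ = 0`
leaves a diagonal depth matrix, so the reduction is only approximate; the
regression tests assert exact equality on ultrametric fixtures.

Tree uncertainty is propagated by repeating the whole procedure (lambda
estimation included) over an ensemble of candidate trees, reporting
per-tree posteriors, their arithmetic means, and the count of trees on
which each class is the argmax. Single-tree failures are surfaced; the run
aborts if more than 10% of trees fail.

**What the phylogenetic correction buys, and when.** Simulation shows the
direction of the effect depends on where the phylogenetic signal sits.
When within-class variation is phylogenetically correlated while classes
are distributed across the tree, whitening removes correlated noise and
the pFDA matches or beats the CVA jackknife rate in a majority of
replicates. When the *classes themselves* cluster phylogenetically,
whitening removes exactly the class-aligned signal and the pFDA rate
drops — the method is then answering a different question ("does shape
discriminate beyond ancestry?"), which is its purpose. Users comparing the
two rates should keep this interpretation in mind.

## Time-calibration ("equal" method)

A cladogram is time-scaled from tip first-appearance data (FAD, Ma): tips
sit at their FAD (a FAD/LAD midpoint option exists), each internal node
starts at the oldest FAD among its descendants, and the root is pushed back
by a configured root length. The recommended root length is the gap between
the oldest ingroup FAD and the FAD of the next-oldest outgroup taxon
(`root_length_from_fads`). Zero-length branches are then removed by the
"equal" rule: each chain of zero-length branches shares the time of the
nearest ancestral branch with positive slack, implemented as an even
re-spacing of the chain's node ages between that ancestor and the chain
bottom, in preorder. With a positive root length the procedure cannot
deadlock, and it preserves the total tree span by construction. A worked
four-tip fixture with hand-computed ages is frozen in the tests.

Polytomies are resolved uniformly at random over all rooted binary
topologies of each polytomy's children (random sequential addition with a
uniform choice among the 2j−1 insertion positions). Inserted branches get
length zero and acquire duration during dating.

## Ancestral states of locomotion (Mk/ER)

Locomotor mode evolves by a continuous-time Markov chain with k states and
a single rate q per Myr (equal rates). Transition probabilities use the
closed form `P_same = 1/k + (k−1)/k · e^(−kqt)`. The likelihood is computed
by Felsenstein pruning with per-node rescaling; `q` is fitted by bounded
1-D optimisation on log q. Node marginals ("scaled likelihoods") come from
the standard two-pass inside–outside computation with a flat root prior
(a stationary prior is the same thing for the ER chain). Both likelihood
and marginals are verified against brute-force enumeration over internal
state assignments with explicit matrix exponentials on small trees.

## Body-size evolution: five Gaussian models

With `t_i` the root-to-tip depth and `t_ij` the MRCA depth, the tip vector
is multivariate normal with:

| model | covariance `V_ij` | mean `μ_i` | free params |
|---|---|---|---|
| BM    | `σ² t_ij` | `z0` | σ², z0 |
| OU    | `σ²/(2α) e^(−α(t_i+t_j−2t_ij)) (1−e^(−2α t_ij))` | `z0` | σ², z0, α |
| EB    | `σ² (e^(a t_ij)−1)/a` | `z0` | σ², z0, a |
| trend | `σ² t_ij + b t_ij²/2` | `z0` | σ², z0, b |
| drift | `σ² t_ij` | `z0 + h t_i` | σ², z0, h |

The OU ancestral state and optimum are collapsed into a single `z0` (the
common three-parameter formulation). The trend model's time-varying rate
`σ²(t) = σ² + b t` must stay positive over the tree span; this is enforced
through the reparameterisation `b = σ²β` with `β > −1/T`. EB and OU kernels
use `expm1` so their `a, α → 0` limits reproduce BM to machine precision.
On an ultrametric tree the drift term is absorbed by the ancestral state
(all depths equal), so `h` is unidentifiable there — drift is only
meaningful with fossil tips, which is exactly where it is used.

Fitting profiles the mean coefficients and σ² analytically (GLS through a
Cholesky solve, ML variance `/n`), leaving at most one nonlinear parameter,
which is optimised by a 40-point grid plus bounded local refinement —
deterministic, and robust on the nearly flat likelihood surfaces these
small trees produce. Model comparison uses AICc by default (n = 16 taxa
makes the small-sample correction material; plain AIC is a flag) and
Akaike weights `w_m = exp(−Δ_m/2)/Σ exp(−Δ/2)`. Weight computations refuse
to mix fits of different data (hash check).

Continuous ancestral states under BM are GLS/ML: the root estimate is the
GLS grand mean; other nodes get their conditional expectation given the
tips, with conditional variances reported (the extra uncertainty from
estimating the mean is not folded in; variances are therefore mild
underestimates, as in the standard ML formulation).

## Mass from toothrow length

Body mass (g) comes from a log10–log10 regression on LTRL (mm). The
literature regression for non-muroid rodents under 5 kg is cited in
sources without printed coefficients, so the shipped default is a
**reconstruction**: a least-squares back-fit to three published
(LTRL, mass) anchor pairs — (12.82, 597), (13.60, 696), (14.17, 774) —
giving slope 2.59372 and intercept −0.09755, which reproduces the anchors
to <0.2 g. It is labelled as such and should be replaced by the published
coefficients where available; predictions above 5 kg trigger a warning.
Per-taxon LTRL summaries use the median of the available complete and
reconstructed toothrows, reported with its log10.

## Synthetic data: what it emulates, what it does not

The generator produces the full input bundle: a forward birth–death tree
(stopping either at a fixed tip count, with the clock run out to the next
would-be event so no zero branches arise, or at a fixed horizon), fossil
tips (retained extinct lineages plus an optional truncated fraction of
extant tips) with a consistent occurrence table; ER-evolved locomotor
states; specimen-level measurement tables; and continuous traits drawn
from any of the five models.

Species-level log-shape means combine a class signature with a per-trait
phylogenetic component drawn from `MVN(0, σ_p² C(λ_true))` on the
depth-normalised tree; each trait gets equal phylogenetic variance and
there is no trait–trait covariance in the phylogenetic component — the
simplest structure consistent with the single-lambda assumption of the
pFDA. Specimen rows add iid log-scale noise, are exponentiated, and are
multiplied by per-specimen size factors spanning three orders of magnitude
so the GM-normalisation step has real work to do. Two class-signature sets
exist: a versioned ecomorphological caricature (semi-aquatic = wide body,
expanded fibular facet, short trochlea, long ectal facet; overlapping
weakly specialised terrestrial/semi-fossorial classes) and orthogonal
contrasts with exactly equal pairwise separation for calibrated recovery
experiments. `class_sep` is expressed in units of the combined
species-level SD.

Default conditions mirror the empirical study design: 139 species sampled
by ~343 specimens across 8 locomotor classes, λ_true = 0.1, Mk rate 0.05
per Myr, and a drift size model (σ² = 0.01, h = 0.01 per Myr on log10
LTRL, z0 = 1.0 ≈ a 10 mm toothrow).

Passing tests on these data show the machinery recovers known structure
under its own assumptions. They do not show that real astragali satisfy
those assumptions: real measurement error is not iid log-normal, real
class signatures are not equidistant, locomotor classes are unbalanced,
and real trees carry calibration error that no ensemble over topologies
fully captures.

## Problem sizes and tolerances

Recovery experiments run at: lambda — 20 replicates × 100 tips × 15 traits
(mean |λ̂ − λ| within one grid step); Mk rate — 50 replicates × 200 tips
(median q̂ within 25% of truth); model selection — 200 replicates × 16 tips
under BM (BM preferred by AICc in a majority and by median weight). The
classification experiment holds out one species per class from a 96-species
dataset. Numerical tolerances: shape zero-sum 1e-10; pFDA/CVA reduction
1e-8; enumeration-oracle agreement 1e-10; eigenvalue floor for whitening
1e-10; Mk optimiser xatol 1e-8 on log q.
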