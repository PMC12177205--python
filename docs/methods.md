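# Methods

## Model

`copulaboost` fits joint distributional regression models for a bivariate
response $(Y_1, Y_2)$ whose margins are binary, counts, or one binary and
one continuous component.  The joint distribution follows the Sklar
construction

$$F(y_1, y_2 \mid \mathbf{x}) = C\bigl(F_1(y_1 \mid \mathbf{x}),\, F_2(y_2 \mid \mathbf{x});\, \theta(\mathbf{x})\bigr),$$

with one-parameter copula $C$ and parametric margins $F_1, F_2$.  Every
distribution parameter — each marginal parameter and the copula dependence
parameter $\theta$ — has its own additive predictor
$\eta_k(\mathbf{x}) = \beta_{0k} + \sum_j f_{jk}(x_j)$ mapped to its natural
range by a fixed link.

Three likelihoods cover the supported response kinds:

- **binary–binary**: the four cell probabilities are built from the copula
  evaluated at the success probabilities,
  $p_{11} = C(p_1, p_2; \theta)$, $p_{10} = p_1 - p_{11}$,
  $p_{01} = p_2 - p_{11}$, $p_{00} = 1 - p_1 - p_2 + p_{11}$.
- **count–count**: the rectangle probability
  $C(F_1, F_2) - C(F_1 - f_1, F_2) - C(F_1, F_2 - f_2) + C(F_1 - f_1, F_2 - f_2)$,
  where writing the lower corner as $F - f$ (instead of $F(y-1)$) avoids
  evaluating a CDF at $-1$.
- **binary–continuous**: the latent-variable mixed likelihood
  $\ell = (1 - y_1)\log h + y_1 \log(1 - h) + \log f_2$ with
  $h = \partial C(F_1(0), F_2(y_2); \theta)/\partial F_2$.

All analytic score vectors (derivatives of $\ell$ with respect to every
$\eta_k$) are implemented in closed form and verified against central
finite differences in the test suite.

## Copula families and links

Gaussian, Clayton, Gumbel, Frank, FGM and AMH, plus 90/180/270-degree
rotations of any family (used in practice for Clayton to capture negative
or upper-tail dependence).  Dependence-parameter links: $\tanh$ for
Gaussian ($\rho \in (-1,1)$), $\exp$ for Clayton ($\theta > 0$, capped at
30), $1 + \exp$ for Gumbel ($\theta \ge 1$, capped at 30), identity for
Frank (clipped to $[-35, 35]$), $\tanh$ for FGM and $0.99\tanh$ for AMH.
Where clipping is active the link derivative is set to zero, so boosting
cannot push a predictor further into the cap.

The Gaussian copula CDF uses the one-dimensional integral representation
$\Phi_2(x, y; \rho) = \Phi(x)\Phi(y) + \int_0^\rho \phi_2(x, y; r)\,dr$
with a fixed 64-node Gauss–Legendre rule, vectorised over observations with
per-observation $\rho$; $\partial C/\partial \rho = \phi_2$ is then exactly
consistent with the CDF.  Clayton and Gumbel are evaluated in log space
with independence-series branches near their independence points; AMH uses
a series for Kendall's $\tau$ at small $|\theta|$.  Copula arguments are
clipped to $[10^{-12}, 1 - 10^{-12}]$ and probabilities entering a
logarithm are floored at $10^{-15}$.

## Margins

Bernoulli (logit, probit or cloglog link), heteroscedastic Gaussian
(identity/log), Poisson, geometric (mean parameterisation
$f(y) = \mu^y/(1+\mu)^{y+1}$), negative binomial type I (mean $\mu$,
variance $\mu(1 + \sigma\mu)$), zero-inflated Poisson and negative
binomial, zero-adjusted (hurdle) logarithmic and negative binomial.
Discrete CDFs are cumulative pmf sums on a grid, which makes the
$F - f$ identity of the count likelihood exact to machine precision;
quantiles are generalized inverses by grid scan.

## Boosting

Non-cyclical component-wise gradient boosting.  Per iteration: (1) the
negative gradient of the empirical risk (mean negative joint
log-likelihood) is computed for every predictor and L2-stabilised (divided
by its root mean square) so step sizes are comparable across parameters;
(2) within each parameter, every base-learner is fitted to the gradient by
(penalized) least squares and the best by residual sum of squares is kept;
(3) across parameters, the single update with the largest realized risk
reduction is committed, scaled by the step length (default 0.1).  The
stopping iteration is the validation-risk minimiser over the whole path
(including iteration 0, the offset model), so early stopping performs both
variable selection and shrinkage.  Offsets are intercept-only marginal
maximum-likelihood fits plus a one-dimensional profile search for the
copula predictor.

Base-learners: intercept, centered linear effects, cubic P-splines with 20
interior knots and second-order difference penalties, varying coefficients
(spline times binary modifier), tensor-product splines, and Gaussian
Markov random fields over a region adjacency graph.  Penalties are
calibrated so every penalized learner has the same initial degrees of
freedom (default 4), keeping the base-learner competition unbiased.  One
deviation: the tensor-product penalty has a four-dimensional null space, so
its attainable minimum df is above 4; the target is raised to
nullity + 1 = 5 for that learner only.

## Synthetic-data generator

`DGPSpec`/`make_dgp` generate train/validation/test sets from a declarative
specification: iid Uniform(−1, 1) (or standard normal) covariates, linear
and/or smooth effects on any subset of the distribution parameters, and
responses drawn by conditional inversion — $U$ uniform, $V$ solving
$\partial C/\partial u = W$ (closed forms for Gaussian and Clayton,
45-step bisection otherwise), then margin quantiles.  Ground truth
(informative sets, coefficients, true predictors) is returned alongside the
data for selection-rate and recovery studies.

## Evaluation

Joint negative log-likelihood, the Monte-Carlo energy score
$\mathrm{ES} = \mathbb{E}\lVert X - y\rVert - \tfrac12 \mathbb{E}\lVert X - X'\rVert$
(the second expectation pairs each draw with its neighbour — independent
copies, not antithetic ones, which would bias the estimate), Brier score
and AUC for binary margins, mean squared error of prediction otherwise.
`select_structure` refits every candidate copula family with its own
validation-tuned stopping iteration and ranks by held-out joint NLL.

## Limitations

- Only one-parameter copulas; no time-varying or > 2-dimensional responses.
- Count CDFs by grid summation become slow for means far above ~10⁴.
- The copula-parameter predictor is harder to estimate than marginal
  predictors; its effects are noticeably shrunk at realistic sample sizes
  (this is visible in the acceptance studies and expected of boosting with
  early stopping).
- No inference (standard errors, tests); uncertainty statements require
  resampling, which is out of scope.
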