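"""Quantify what modelling the dependence buys on held-out count data.

Two count responses are generated with Clayton dependence (tau = 0.5).  The
joint boosted fit is compared with two independent univariate boosted fits
using the joint negative log-likelihood and the energy score — both proper
scoring rules, lower is better.
"""

import numpy as np

from copulaboost import (
    BivariateCopulaModel, BoostConfig, DGPSpec, energy_score,
    energy_score_independent, fit_boost, get_copula, joint_nll, make_dgp,
    univariate_benchmarks,
)

model = BivariateCopulaModel("poisson", "poisson", get_copula("clayton"))
spec = DGPSpec(
    model=model, p=10, n_train=1000, n_val=1500, n_test=1000,
    intercepts={0: 0.5, 1: 0.5, 2: np.log(2.0)},  # theta = 2 <-> tau = 0.5
    coefs={0: {1: 0.8}, 1: {2: -0.8}, 2: {3: 0.5}},
    seed=2,
)
train, val, test, _ = make_dgp(spec)

cfg = BoostConfig(mstop_max=200)
joint = fit_boost(model, train, ("y1", "y2"), val=val, config=cfg)
u1, u2 = univariate_benchmarks(model, train, val, config=cfg)

nll_j = joint_nll(joint, test)
nll_u = joint_nll(u1, test, "y1") + joint_nll(u2, test, "y2")
es_j = energy_score(joint, test, n_samples=500, seed=0)
es_u = energy_score_independent(u1, u2, test, n_samples=500, seed=0)

print(f"test joint NLL : copula fit {nll_j:.4f}  vs  independent fits {nll_u:.4f}")
print(f"test energy ES : copula fit {es_j:.4f}  vs  independent fits {es_u:.4f}")
print()
if nll_j < nll_u and es_j < es_u:
    print("the copula fit wins on both scores: ignoring the dependence "
          "costs predictive accuracy even though the margins are identical")
else:
    print("scores are close on this draw; rerun with another seed to see "
          "the typical ordering")
tau = joint.predict(test, what="tau")
print(f"recovered Kendall's tau: mean {tau.mean():.3f} (truth at the "
      "intercept: 0.5, modulated by x3)")
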