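"""Choose the copula family by out-of-sample likelihood.

Data are generated from a Clayton copula (lower-tail dependence).  Four
candidate families are fitted — each tuned on its own validation-risk
path — and ranked by test negative log-likelihood.
"""

import numpy as np

from copulaboost import (
    BivariateCopulaModel, BoostConfig, DGPSpec, get_copula, make_dgp,
    select_structure,
)

model = BivariateCopulaModel("poisson", "poisson", get_copula("clayton"))
spec = DGPSpec(
    model=model, p=6, n_train=1000, n_val=1500, n_test=1000,
    intercepts={0: 0.5, 1: 0.5, 2: np.log(2.0)},
    coefs={0: {1: 0.8}, 1: {2: -0.8}, 2: {3: 0.5}},
    seed=3,
)
train, val, test, _ = make_dgp(spec)

candidates = {
    name: BivariateCopulaModel("poisson", "poisson", get_copula(name))
    for name in ("clayton", "gaussian", "frank", "gumbel")
}
table, winner, fits = select_structure(
    candidates, train, val, test, config=BoostConfig(mstop_max=150)
)
print(table.to_string(index=False))
print(f"\nselected family: {winner} (data were generated from clayton)")
print("the ranking is on held-out joint NLL, so families that get the "
      "tail behaviour wrong pay even when margins fit equally well")
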