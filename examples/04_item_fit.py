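"""Absolute item-fit statistics: log odds ratio, transformed correlation,
proportion correct.

Fits the true (saturated) model and a misspecified conjunctive model to the
same interactive data and compares the residual statistics: means near zero
indicate that the model reproduces the pairwise response structure.
"""

import numpy as np

import cdmkit as ck

rng = np.random.default_rng(11)
q = ck.default_qmatrix(J=10, K=2)
# strongly interactive truth: success is likely only under full mastery
probs = []
for j in range(q.J):
    n = 1 << int(q.item_attr_count[j])
    p = np.full(n, 0.15)
    p[-1] = 0.85
    probs.append(p)
truth = ck.ItemResponseFunction(model="gdina", q=q, probs=probs)
profiles = ck.generate_profiles(2000, 2, rng=rng)
X = ck.simulate_responses(truth, profiles, rng)

for model in ("gdina", "dino"):
    fit = ck.em_fit(X, q, model=model)
    rep = ck.itemfit_report(fit, X, alpha=0.1, bonferroni=True)
    n_sig = int(rep.pairs["sig_l"].sum())
    print(f"\n{model} item-fit summary (mean / max / SE at max):")
    print(rep.summary.round(4).to_string())
    print(f"pairs flagged on l at Bonferroni-adjusted level 0.1: {n_sig}")

print("\nThe disjunctive model cannot reproduce the conjunctive interaction, "
      "so its l and r residuals run larger, most visibly in the maxima.")
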