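"""Power-adjusted transferability of discovery loci in a target group.

Simulates a well-powered discovery cohort and a smaller target cohort in
which only 40% of loci share the causal effect, then runs the full PAT
workflow: credible sets, penalization factor from a null trait, the
penalized threshold, per-locus power and the PAT ratio with its
bootstrap confidence interval.
"""

import numpy as np

from magwas.simulate import (
    AncestryConfig, CausalModel, balding_nichols_af, generate_known_loci,
    simulate_ld_matrix, simulate_study,
)
from magwas.transfer import (
    PF_CONSTANTS, assess_transferability, known_loci_from_frame,
)

rng = np.random.default_rng(23)
n_loci, block = 30, 15
blocks_d = [(block, 0.97)] * n_loci
blocks_t = [(block, 0.7)] * n_loci
ld_d = simulate_ld_matrix([b[0] for b in blocks_d], [b[1] for b in blocks_d])
ld_t = simulate_ld_matrix([b[0] for b in blocks_t], [b[1] for b in blocks_t])
nv = len(ld_d)

ancestral = rng.uniform(0.2, 0.8, nv)
causal_idx = np.arange(block // 2, nv, block)
disc = simulate_study(
    ld_d, CausalModel(causal_idx, {"EUR": np.full(n_loci, 0.1)}),
    AncestryConfig("EUR", 50_000, 50_000,
                   balding_nichols_af(ancestral, 0.05, rng), blocks_d),
    rng)

shared = np.where(np.arange(n_loci) < 12, 0.1, 0.0)   # 40% transferable
target = simulate_study(
    ld_t, CausalModel(causal_idx, {"AFR": shared}, shared=False),
    AncestryConfig("AFR", 20_000, 20_000,
                   balding_nichols_af(ancestral, 0.10, rng), blocks_t),
    rng)

catalogue = known_loci_from_frame(generate_known_loci(disc, blocks_d))
res = assess_transferability(catalogue, disc, target, ld_d,
                             p_f=PF_CONSTANTS["AFR"],
                             n_cases=20_000, n_controls=20_000, seed=rng)
print(f"catalogue: {len(catalogue)} discovery loci")
print(f"observed transferable: {res.observed}")
print(f"expected from power:   {res.expected:.1f}")
print(f"PAT ratio = {res.ratio:.2f} (95% CI {res.ci_low:.2f}-{res.ci_high:.2f})")
n_nontrans = sum(r.nontransferable for r in res.records)
print(f"nontransferable calls: {n_nontrans}")
print("With every locus well powered, the PAT ratio estimates the true "
      "shared fraction (0.40 here); nontransferable loci are powered but "
      "signal-free in the target data.")
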