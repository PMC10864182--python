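"""Two-sample MR with all five estimators and outlier pruning.

Generates a synthetic exposure/outcome instrument table with a known
causal effect (theta = 0.25) plus one pleiotropic outlier, runs the five
estimators, the heterogeneity test, and the iterative outlier removal.
"""

from magwas.mr import all_estimators, heterogeneity_q, ivw, remove_outliers
from magwas.simulate import generate_mr_pair

df = generate_mr_pair(40, theta=0.25, pleiotropy="outlier", seed=5)
cols = ["SNP", "BETA_EXP", "SE_EXP", "BETA_OUT", "SE_OUT", "EAF", "P_EXP"]
instruments = df[cols]

print("method            beta      se       p         n")
for r in all_estimators(instruments, seed=1):
    print(f"{r.method:<16} {r.beta:+.3f}  {r.se:.3f}  {r.pvalue:.2e}  {r.n_snps}")

q, q_p = heterogeneity_q(instruments)
print(f"Cochran Q = {q:.1f} (p = {q_p:.2e}): the planted outlier drives "
      "significant heterogeneity")

pruned, audit = remove_outliers(instruments)
planted = df.loc[df["ALPHA"] != 0, "SNP"].iloc[0]
print(f"removed {len(audit)} instrument(s): "
      f"{[a['SNP'] for a in audit]} (planted outlier was {planted})")
print(f"IVW after pruning: {ivw(pruned).beta:+.3f} "
      "(closer to the true causal effect 0.25)")
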