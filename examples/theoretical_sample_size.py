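"""How many participants does a replicable brain-behavior effect need?

Given a Pearson correlation r between model predictions and observed
phenotype, the K-prime predictive distribution of the replication
t statistic yields the probability that an equally sized, independent
replication is significant (P_srep).  Inverting over n gives the smallest
sample size at which that probability reaches 80%.
"""

from repliconn import p_srep, theoretical_n

for r in (0.14, 0.19, 0.32):
    est = theoretical_n(r, alpha=0.05, target_prob=0.8)
    print(
        f"r = {r:.2f} ({r * r * 100:4.1f}% variance explained): "
        f"n = {est.n_required} participants "
        f"(P_srep at that n = {est.p_srep_at_n:.3f})"
    )

# P_srep for a modest effect across candidate sample sizes
print("\nP_srep for r = 0.2:")
for n in (50, 100, 200, 400, 800):
    print(f"  n = {n:4d}: {p_srep(0.2, n):.3f}")

print(
    "\nSmaller effects need disproportionately larger samples (n ~ 1/r^2): "
    "an association explaining 2% of variance needs hundreds of subjects "
    "per half to replicate reliably, one explaining 10% fewer than 100."
)
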