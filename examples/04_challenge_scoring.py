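"""Combine per-network AUPR/AUROC p-values into challenge scores.

Each network contributes −0.5·log10(p_aupr · p_auroc); the overall score is
the same transform of the geometric-mean p-values, and the total over
networks equals n times the overall score.
"""

from kflr import dream_scores

# per-network (p_aupr, p_auroc) pairs for a five-network evaluation
pvalues = [
    (1.63e-33, 1.21e-27),
    (7.43e-46, 4.12e-32),
    (4.43e-58, 3.22e-39),
    (2.81e-53, 7.63e-35),
    (3.61e-51, 1.35e-37),
]

score = dream_scores(pvalues)
for k, s in enumerate(score.per_network, start=1):
    print(f"network {k}: score {s.net_score:.3g}")
print(f"overall: {score.overall:.3g}  total: {score.total:.3g}")
# smaller p-values mean the ranking is harder to match by chance; the log
# transform turns the product of ten tiny p-values into an additive score
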