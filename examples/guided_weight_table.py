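"""Relative proposal weights of the parsimony-guided moves.

Builds the reference table of candidate weights for both weighting
schemes: variant 1 uses omega = exp(-epsilon * S) directly, variant 2
dampens the parsimony score S through a JC69-style change probability
evaluated at the pseudo branch length S/N + 1e-4, so short alignments
(small N) are penalised less steeply.
"""

import math

from treewarp import MoveTuning, guide_weights

scores = {s: s for s in range(10, 17)}
columns = {
    "pSPR1 e=0.5": (MoveTuning(variant=1, epsilon=0.5), 0),
    "pSPR2 N=2000": (MoveTuning(variant=2, epsilon=0.1), 2000),
    "pSPR2 N=500": (MoveTuning(variant=2, epsilon=0.1), 500),
    "pSPR2 N=100": (MoveTuning(variant=2, epsilon=0.1), 100),
}

table = {
    name: guide_weights(scores, tuning, n) for name, (tuning, n) in columns.items()
}
print("S\t" + "\t".join(columns))
for s in range(10, 17):
    row = "\t".join(f"{math.exp(table[name][s]):.3f}" for name in columns)
    print(f"{s}\t{row}")

print()
print("Each column is scaled to the weight at parsimony score 10: a value of")
print("0.585 means a candidate regraft costing one extra parsimony step is")
print("proposed 0.585 times as often as the best candidate.")
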