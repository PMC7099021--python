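"""Expected accuracy vs the biased fraction f, and the optimum f*.

A little bias protects minority information from being censored; too much
polarizes the population. Accuracy therefore peaks at an interior f*.
"""

import numpy as np

import biasnet as bn

n, p, q, k = 1000, 0.53, 1.0, 8
print(f"unbiased-network accuracy: {bn.accuracy_unbiased(n, p):.4f}")
print("\n  f     expected accuracy")
for f in (0.02, 0.05, 0.1, 0.2, 0.4, 0.7, 1.0):
    print(f" {f:.2f}        {bn.expected_accuracy(n, p, f, q, k):.4f}")

for kk in (4, 8, 16):
    f_star, acc = bn.optimal_bias_fraction(n, p, q, kk)
    print(f"k={kk:2d}: f* = {f_star:.3f}, accuracy at f* = {acc:.4f}")

# The curve rises, peaks near f* ~ 0.1 and falls; denser networks (larger k)
# tolerate more bias before fragmenting into echo chambers, so both f* and
# the achievable accuracy increase with k.
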