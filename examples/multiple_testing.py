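"""Adjusted p-values: gamma-tail maxT versus the exact references.

Runs the same small scan through all three multiple-testing backends with a
shared permutation stream and prints the leading adjusted p-values side by
side.  The classical and memory-bounded backends agree exactly; the gamma
backend replaces each permutation's remainder maximum with a model draw and
should differ only slightly.
"""

import numpy as np

from gammamaxt import SimConfig, run_maxt, simulate_epistasis, table_model

model = table_model()
config = SimConfig(n_snps=60, n_individuals=600, trait_type="binary")
data = simulate_epistasis(model, config, np.random.default_rng(11))

results = {
    backend: run_maxt(
        data.dataset, n=10, B=199, backend=backend, S=2000, seed=42
    )
    for backend in ("classical", "maxt", "gammamaxt")
}

print(f"causal pair (0-based): {data.causal_pair}\n")
print("rank  pair        classical    maxt   gammamaxt")
ref = results["classical"]
for j in range(5):
    a, b = ref.pairs[j]
    row = f"{j + 1:4d}  ({a:3d},{b:3d})"
    for backend in ("classical", "maxt", "gammamaxt"):
        row += f"  {results[backend].pvalues[j]:9.4f}"
    print(row)

# p = 0.005 is the smallest attainable value with B = 199 permutations
# (p >= 1/(B+1)).  Identical 'classical' and 'maxt' columns demonstrate the
# memory-bounded rewrite is exact; the gammaMAXT column matches to within
# permutation-sampling noise at a fraction of the cost on large scans.
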