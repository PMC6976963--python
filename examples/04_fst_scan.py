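"""Bayesian F_ST outlier scan on pooled counts.

Builds a founder-vs-LD80-survivors contrast with 200 weakly drifted neutral
loci and 5 planted selected loci, runs the reversible-jump MCMC scan at a
short desk preset, and prints the per-locus posterior selection
probabilities and q-values of the top loci.
"""

import numpy as np
import pandas as pd

from poolcross import bayes_scan, pooled_fst
from poolcross.conditions import ALL_LABELS, Line
from poolcross.fst import Contrast, ScanConfig
from poolcross.tables import AlleleCountTable

rng = np.random.default_rng(5)
L, depth, F_bg = 200, 200, 0.01

p_anc = rng.uniform(0.1, 0.9, L)
a, b = p_anc * (1 - F_bg) / F_bg, (1 - p_anc) * (1 - F_bg) / F_bg
p_f0, p_ld80 = rng.beta(a, b), rng.beta(a, b)
p_f0[:5], p_ld80[:5] = 0.25, 0.80  # planted selected loci

contrast = Contrast.f0(Line.DELT)
data = {
    "chrom": ["chr1"] * L,
    "pos": np.arange(L) * 1000,
    "ref": ["A"] * L,
    "alt": ["T"] * L,
    "effect": ["unknown"] * L,
}
for lbl in ALL_LABELS:
    p = {contrast.members[0]: p_f0, contrast.members[1]: p_ld80}.get(lbl)
    alt = rng.binomial(depth, p) if p is not None else np.zeros(L, dtype=int)
    data[f"{lbl}:alt"] = alt
    data[f"{lbl}:ref"] = depth - alt
counts = AlleleCountTable(pd.DataFrame(data))

result = bayes_scan(counts, contrast, ScanConfig.desk(chain_factor=0.05, seed=5))
top = result.nsmallest(8, "q_value")
print(top[["locus_id", "fst", "posterior_prob", "alpha", "q_value"]].to_string(index=False))
print(
    "\nThe five planted loci dominate the ranking: their posterior"
    "\nprobability of selection (alpha included in the model) approaches 1"
    "\nand their q-values fall below 0.05, while neutral loci sit near the"
    "\nprior inclusion rate of 1/11."
)
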