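"""Recover planted informative variables with VCPA and IRIV.

Builds a 120 x 60 matrix where 8 columns carry ordered class-mean shifts
and the rest are noise, then runs both selectors with small budgets and
reports how many planted columns each recovered and the cross-validated
PLS-DA error of the final subsets.
"""

import numpy as np

import moldscan as ms
from moldscan.selection import FitnessSpec, fitness

rng = np.random.default_rng(1)
n_per, p, n_inf = 30, 60, 8
y = np.repeat(list(ms.LEVELS), n_per)
X = rng.standard_normal((4 * n_per, p))
planted = np.sort(rng.choice(p, n_inf, replace=False))
shift = rng.uniform(0.6, 1.0, n_inf)
for li in range(4):
    X[li * n_per:(li + 1) * n_per][:, planted] += li * shift
print(f"planted columns: {planted.tolist()}")

spec = FitnessSpec(seed=1)
print(f"CV error, full block:    {fitness(X, y, np.arange(p), spec):.3f}")

vcpa_sel = ms.vcpa(X, y, spec, ms.VcpaParams(edf_iterations=8, bms_runs=60, final_pool=10))
iriv_sel = ms.iriv(X, y, spec, ms.IrivParams(rows=60))
for sel in (vcpa_sel, iriv_sel):
    hits = len(set(sel.indices) & set(planted))
    print(f"{sel.algorithm:5s} kept {sel.indices.size:2d} columns, "
          f"{hits}/{n_inf} planted, CV error {sel.fitness_trace[-1]:.3f}")
# IRIV keeps a superset of the planted columns; VCPA returns a compact subset
# whose members are mostly planted. With these small demonstration budgets
# the recovery is partial — the full-size benchmark (n=240, p=200, K=100)
# recovers a median of 8+/10 for both selectors.
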