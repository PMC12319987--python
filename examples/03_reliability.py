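"""Reliability of NSAR estimates: two-session ICC and run-split tests.

Renders a subject's parcellation, perturbs it into noisy "runs", measures
NSAR per run, and quantifies (a) two-session ICC across a small cohort and
(b) whether run-splitting schemes produce dice differences by the exact
Wilcoxon signed-rank test.
"""

import numpy as np

import latnet

left = latnet.icosphere_mesh(2, 100.0, "left")
right = latnet.icosphere_mesh(2, 100.0, "right")
rng = np.random.default_rng(5)

table = {1: "netA", 2: "netB"}
session1, session2 = [], []
within_minus_between = []
for s in range(12):
    target = float(np.clip(rng.normal(-0.2, 0.15), -0.8, 0.8))
    base = latnet.render_parcellation(
        {1: target, 2: -target / 2}, left, right,
        seed=int(rng.integers(2**31)), label_table=table,
        area_fractions={1: 0.3, 2: 0.3},
    )
    runs = latnet.generate_runs(
        base, left, right, n_runs=4, boundary_noise=0.1,
        seed=int(rng.integers(2**31)),
    )
    a, b = latnet.split_runs([0, 1, 2, 3], "even_odd")
    session1.append(latnet.compute_nsar(runs[a[0]], left, right)[1])
    session2.append(latnet.compute_nsar(runs[b[0]], left, right)[1])
    within_minus_between.append(
        latnet.dice(runs[a[0]], runs[a[1]]) - latnet.dice(runs[a[0]], runs[b[1]])
    )

icc = latnet.icc_two_session(np.array(session1), np.array(session2))
print(
    f"two-session ICC = {icc.icc:.2f}, F({icc.df1},{icc.df2}) = {icc.F:.2f}, "
    f"95% CI [{icc.ci_lower:.2f}, {icc.ci_upper:.2f}]"
)
V, p = latnet.wilcoxon_signed_rank_exact(np.array(within_minus_between))
print(f"within- vs between-split dice: V = {V:.0f}, exact p = {p:.3f}")
print(
    "\nHigh ICC says between-subject NSAR differences dominate run noise; "
    "a non-significant Wilcoxon p says the split scheme itself introduces "
    "no dice difference when all runs share one generative process."
)
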