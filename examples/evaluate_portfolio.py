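"""Portfolio baselines on a synthetic benchmark: SBS, VBS, gap closure.

The single best solver (SBS) is the best fixed choice in hindsight; the
virtual best solver (VBS) is the per-instance oracle.  The VBS-SBS gap is
the headroom any selector can exploit; gap closure measures how much of it a
selection policy captures.
"""

import numpy as np

from dockselect import generate, planted_spec
from dockselect.evaluation import evaluate, sbs, vbs_at_k, vbs_curve, vbs_entropy

bench = generate(planted_spec(n_instances=600, m_solvers=6, n_regimes=3, seed=0))
table = bench.table

sbs_idx = sbs(table, "relaxed")
sbs_rate = table.success_relaxed[:, sbs_idx].mean()
_, vbs_rate = vbs_curve(table, "relaxed")
print(f"SBS = {table.portfolio.solver_ids[sbs_idx]}: "
      f"relaxed success {100 * sbs_rate:.1f}%")
print(f"VBS (oracle): relaxed success {100 * vbs_rate:.1f}%")
print(f"oracle-winner entropy: {vbs_entropy(table):.2f} bits "
      f"(log2 m = {np.log2(table.m):.2f})")
for k in (1, 2, 3):
    print(f"VBS@{k}: {100 * vbs_at_k(table, k, 'relaxed')[1]:.1f}%")

# An oracle selector closes 100% of the gap; replaying the SBS closes 0%.
oracle = np.argmax(table.metric_matrix("relaxed"), axis=1)
print("oracle gap closure:",
      evaluate(oracle, table).gap_closed_percent["relaxed"], "%")
print("SBS gap closure:",
      evaluate(np.full(table.n, sbs_idx), table).gap_closed_percent["relaxed"], "%")
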