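"""Benchmark estimator bias against coverage of the species pool.

Communities with heterogeneous site occupancy are sampled at increasing
effort; the benchmark table records each estimator's log-scale bias, which
is then summarised per coverage bin.
"""

import pandas as pd

from specrich import CommunitySpec, benchmark, simulate_community

POOL = 200
datasets = []
seed = 0
for effort in (5, 20, 80, 320):
    for _ in range(25):
        community = simulate_community(
            CommunitySpec(pool_size=POOL, n_sites=15, effort_per_site=effort, seed=seed)
        )
        seed += 1
        datasets.append((community.sampled, float(POOL), f"effort{effort}_{seed}"))

table = benchmark(
    datasets, estimators=("chao1", "chao2", "cne"), min_specimens=0, min_sites=0
)
bins = pd.cut(table.coverage, [0, 0.3, 0.6, 1.0], labels=["<30%", "30-60%", ">60%"])
summary = table.groupby([bins, "estimator"], observed=True).log_bias.mean().unstack()
print(summary.round(3))

print(
    "\nNegative values mean underestimation. At low coverage all estimators"
    "\nare biased downwards, Chao1 most severely; the combined estimator"
    "\n(cne) stays closest to zero because it corrects the observed unique/"
    "\nduplicate counts for within-site undersampling before extrapolating."
)
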