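"""An expected-improvement screening campaign over a discrete ligand pool.

A Gaussian process (Matérn-5/2) is warm-started on a handful of "literature"
measurements; each round proposes a 5-ligand batch by greedy constant-liar
expected improvement, the oracle (here: the hidden truth) returns measured
ΔΔG‡ values, and the campaign stops when the mean EI of a batch falls below
5% of the incumbent — diminishing return on more experiments.
"""

import numpy as np

from enantiokit import run_campaign
from enantiokit.synthgen import smooth_pool_landscape

pool, truth = smooth_pool_landscape(n_candidates=100, n_features=4, seed=100)
rng = np.random.default_rng(3)
warm_ids = [str(i) for i in rng.choice(pool.index, size=5, replace=False)]
warm = {i: truth[i] for i in warm_ids}
print(f"warm start: {len(warm)} ligands, best ΔΔG‡ {max(warm.values()):.3f} kcal/mol")
print(f"pool optimum (hidden): {max(truth.values()):.3f} kcal/mol")

state = run_campaign(
    pool, lambda cid: truth[cid], warm,
    batch_size=5, stop_rel_ei=0.05, max_rounds=8, seed=0,
)
for r in state.rounds[1:]:
    print(f"round {r.round}: batch {len(r.batch)}, incumbent {r.incumbent:.3f}, "
          f"mean relative EI {r.mean_rel_ei:.3f}")
print(f"stopped: {state.stop_reason or 'round budget reached'}; "
      f"{len(state.evaluated_ids)} of {len(pool)} ligands evaluated")
# the incumbent trajectory never decreases; the stop rule trades experiments
# against the expected value of the next batch
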