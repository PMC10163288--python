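"""Screen a synthetic design pool with the two-stage filter and compare
against pareto-front selection on externally supplied score columns.
"""

import numpy as np

from binderscreen import (
    BenchmarkSpec,
    FilterCriteria,
    apply_filter,
    make_benchmark,
    pareto_select,
)

records = make_benchmark(BenchmarkSpec(n_designs=500, seed=1))

verdicts = apply_filter(records, FilterCriteria.default())
n_pass = sum(v.passed for v in verdicts)
print(f"{n_pass}/{len(records)} designs pass pae_interaction < 10 and af2_complex_rmsd < 5 A")

# pareto selection over energy-like columns (here: stand-in random scores)
rng = np.random.default_rng(0)
for rec in records:
    rec.metrics["ddg_like"] = float(rng.normal())
    rec.metrics["sap_like"] = float(rng.normal())
chosen = pareto_select(
    records, [("ddg_like", "min"), ("sap_like", "min")], quota=50
)
print(f"pareto peeling selected {len(chosen)} designs; first 3: {chosen[:3]}")
# The threshold filter is the confidence-based screen; pareto peeling is
# the physically-based alternative that balances several score columns
# without fixed cutoffs.
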