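"""Bayesian hyperparameter optimization with EI and local penalization.

Shows the per-architecture search domain and runs the optimizer on a cheap
1-D toy objective so the mechanics — Sobol initial design, GP surrogate,
Expected Improvement, batch diversification — are visible in seconds. The
same `optimize` call wraps a real training objective via
`domain.to_config(params)`.
"""

import molmpnn as mm
from molmpnn.hyperopt import Dimension, SearchDomain, optimize

domain = mm.build_domain("emnn")
print("EMNN search domain:")
for d in domain.dimensions:
    rng = d.choices if d.kind == "discrete" else \
        f"[{d.low:g}, {d.high:g}]" + (" log" if d.log else "")
    print(f"  {d.name}: {rng}")

toy = SearchDomain("ampnn", [Dimension("x", "continuous", 0.0, 1.0)])
record = optimize(lambda p: (p["x"] - 0.3) ** 2, toy, budget=15,
                  maximize=False, seed=1)
print(f"\ntoy objective (x - 0.3)^2, budget 15:")
print(f"best x found: {record.best_params['x']:.4f} (optimum 0.3)")
print(f"evaluations recorded: {len(record.evaluations)}")
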