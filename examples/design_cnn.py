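"""Search the 11-gene CNN design space with the enhanced optimizer.

Runs the full design protocol (population 50, 800 fitness evaluations,
psi=200, bt=12) against the bundled surrogate fitness, which hides an ideal
architecture behind a deterministic error surface.  The printed error is
the surrogate's classification-error estimate of the best decoded design;
the design itself is a valid member of the discrete space.
"""

import json

import numpy as np

from hawkopt import (
    decode,
    default_search_space,
    make_design_problem,
    run_ehho,
    surrogate_fitness,
)

space = default_search_space()
backend = surrogate_fitness(seed=2024)
problem = make_design_problem(backend, space)

record = run_ehho(problem, n=50, max_ffes=800,
                  rng=np.random.default_rng(1), psi=200, bt=12, variant="cnn")
best = decode(record.best_position, space)

print(f"best surrogate error: {record.best_fitness:.4f}")
print("best decoded design:")
print(json.dumps(best.to_dict(), indent=2))
print("hidden ideal design (for reference):")
print(json.dumps(backend.ideal.to_dict(), indent=2))
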