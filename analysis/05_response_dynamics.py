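#!/usr/bin/env python
"""Response kinetics: why buffered high-turnover genes respond faster.

Compares two genes with the same steady-state mRNA level but 4-fold
different turnover (TR and kd co-scaled) responding to a doubling of
transcription. The steady states match; the relaxation half-times
differ 4-fold — the kinetic payoff of the synthesis/decay coupling.
"""

import pathlib

import numpy as np
import pandas as pd

from kisflux import dynamics
from kisflux.dynamics import KineticModel

results = pathlib.Path(__file__).resolve().parent.parent / "results"
results.mkdir(exist_ok=True)

t = np.linspace(0.0, 120.0, 1201)
rows = []
for label, tr, kd in (("slow_turnover", 1.0, 0.05), ("fast_turnover", 4.0, 0.2)):
    m0 = dynamics.steady_state(tr, kd)  # both start at M* = 20 a.u.
    model = KineticModel(((0.0, 2 * tr),), kd, m0)  # TR doubles at t=0
    traj = dynamics.simulate_response(model, t)
    half = dynamics.response_halftime(kd)
    rows.append(pd.DataFrame({"gene": label, "t_min": t, "M": traj}))
    print(f"{label}: M* {m0:.1f} -> {2 * m0:.1f} a.u., "
          f"response half-time {half:.1f} min")

pd.concat(rows, ignore_index=True).to_csv(
    results / "response_trajectories.tsv", sep="\t", index=False
)
print(f"wrote {results / 'response_trajectories.tsv'}")
print("equal steady states, 4x faster relaxation for the high-turnover gene.")
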