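#!/usr/bin/env python
"""Alchemical leg on the harmonic λ ladder: EXP vs MBAR vs analytic truth.

The ladder K=(1,2,4,8) has exact step free energies of 0.5 ln 2 in reduced
units.  MBAR recovers each step to a few hundredths of kT at 2000 samples
per state; one-sided EXP shows its direction-dependent bias.  The overlap
matrix diagnoses schedule quality (bottleneck ~0.25 here: well overlapped).
Writes results/alchemical_ladder.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from bindfe.alchemical import exp_estimate, mbar_overlap, mbar_solve
from bindfe.core import ThermoContext
from bindfe.synthetic import harmonic_ladder_ensemble

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 11

if __name__ == "__main__":
    ctx = ThermoContext()
    springs = np.array([1.0, 2.0, 4.0, 8.0])
    matrix, truth = harmonic_ladder_ensemble(springs, 2000, seed=SEED, ctx=ctx)
    est = mbar_solve(matrix, tol=1e-10)
    overlap = mbar_overlap(matrix, est)

    rows = []
    n = 2000
    for k in range(len(springs) - 1):
        sl_from = slice(k * n, (k + 1) * n)
        sl_to = slice((k + 1) * n, (k + 2) * n)
        fwd = exp_estimate(matrix.u[k + 1, sl_from] - matrix.u[k, sl_from],
                           ctx, n_boot=100, seed=SEED + k).value / ctx.kT
        rev = -exp_estimate(matrix.u[k, sl_to] - matrix.u[k + 1, sl_to],
                            ctx, n_boot=100, seed=SEED + 10 + k).value / ctx.kT
        rows.append({
            "interval": f"{k}->{k+1}",
            "exact_kT": truth.payload["f"][k + 1] - truth.payload["f"][k],
            "mbar_kT": est.per_interval[k + 1] - est.per_interval[k],
            "exp_forward_kT": fwd,
            "exp_reverse_kT": rev,
            "neighbour_overlap": min(overlap.matrix[k, k + 1],
                                     overlap.matrix[k + 1, k]),
        })
    df = pd.DataFrame(rows)
    RESULTS.mkdir(exist_ok=True)
    df.to_csv(RESULTS / "alchemical_ladder.csv", index=False)
    print(df.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
    err = np.abs(df["mbar_kT"] - df["exact_kT"]).max()
    print(f"\nMBAR max |error| = {err:.4f} kT over {len(df)} intervals "
          f"(bottleneck overlap {overlap.bottleneck:.3f})")
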