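#!/usr/bin/env python
"""Generate the synthetic input datasets every later stage consumes.

Writes, under results/data/: a reduced-potential ladder (u_kn.tsv / n_k.tsv),
umbrella-window XVG series with a windows.tsv manifest, a multi-model PDB of
the toy complex with its params.tsv sidecar, the IC50/affinity CSV tables,
and ground_truth.json recording every generator's seed and analytic truth.
"""

from pathlib import Path

from bindfe.cli import run

OUT = Path(__file__).resolve().parent.parent / "results" / "data"

if __name__ == "__main__":
    code = run(["simulate", "--out", str(OUT), "--seed", "1"])
    if code == 0:
        print(f"wrote synthetic dataset to {OUT}")
        for f in sorted(OUT.iterdir()):
            print(f"  {f.name}")
    raise SystemExit(code)
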