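#!/usr/bin/env python
"""Map the fixed-point structure of the circuit.

Lists every fixed point (state, stability, outcome label) for the wild-type
parameters and for a series of autocrine-loop reductions, showing the
saddle-node collision that removes the cold-fibrosis state.
"""

import argparse
from pathlib import Path

import pandas as pd

from fibrocircuit import CircuitParameters, find_fixed_points, perturb_parameter


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    wt = CircuitParameters.wildtype()
    rows = []
    for decrease in (0.0, 0.2, 0.39, 0.41, 0.5):
        p = wt if decrease == 0 else perturb_parameter(wt, "lambda1", 1.0 - decrease)
        for fp in find_fixed_points(p):
            rows.append({
                "lambda1_decrease": decrease,
                "F": fp.state.F, "M": fp.state.M,
                "c12": fp.state.c12, "c21": fp.state.c21,
                "stability": fp.stability.value, "label": fp.label.value,
                "residual": fp.residual_norm,
            })
    df = pd.DataFrame(rows)
    path = args.out / "fixed_points.csv"
    df.to_csv(path, index=False, float_format="%.10g")
    print(df.to_string(index=False,
                       formatters={"F": "{:.4g}".format, "M": "{:.4g}".format,
                                   "c12": "{:.4g}".format, "c21": "{:.4g}".format,
                                   "residual": "{:.1e}".format}))
    print(f"\nwrote {path}")


if __name__ == "__main__":
    main()
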