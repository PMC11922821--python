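#!/usr/bin/env python
"""Signature-fraction deconvolution of synthetic paired bulk samples.

Generates bulk count matrices mixed from known cell-type fractions in the
paired infarct/remote design (2 conditions x 2 timepoints, n=4), scores the
myofibroblast and macrophage signatures on fraction-normalised counts, and
compares the recovered infarct/remote fold changes with the generator
truth: macrophages transiently elevated (FC 3 -> 1), myofibroblasts
persistently elevated (FC 4 at both times).
"""

import argparse
from pathlib import Path

import pandas as pd

from fibrocircuit import fraction_normalize, signature_score, zone_fold_change
from fibrocircuit.synth import BulkConfig, gen_bulk_counts


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    cfg = BulkConfig()
    counts, meta, true_fracs, sigs = gen_bulk_counts(cfg, seed=args.seed)
    fractions = fraction_normalize(counts)
    truth = {(ct, tp): f for ct, tp, f in cfg.infarct_fold}

    tables = []
    for ct in ("myofibroblast", "macrophage"):
        scores = signature_score(fractions, sigs[ct], mode="mean")
        fc = zone_fold_change(scores, meta)
        fc.insert(0, "signature", ct)
        fc["true_fold"] = [truth.get((ct, tp), 1.0) for tp in fc["timepoint"]]
        fc["rel_error"] = fc["fold_change"] / fc["true_fold"] - 1.0
        tables.append(fc)
    out = pd.concat(tables, ignore_index=True)
    path = args.out / "deconvolution_fold_changes.csv"
    out.to_csv(path, index=False, float_format="%.6g")
    print(out.to_string(index=False, float_format="%.4g".__mod__))
    print(f"\nmax |relative error| = {out['rel_error'].abs().max():.3f}  ({path})")


if __name__ == "__main__":
    main()
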