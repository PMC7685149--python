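#!/usr/bin/env python
"""Simulation 1: linear marking order and category structure.

Trains premarking and postmarking delta-rule learners on role-swapped
encodings of one matched noun-token stream, then evaluates pairwise-mean
choice probabilities on the distinct meaning dimension and the partly
overlapping form dimension, at the behavioral trial count (412) and at
asymptote (1,600 trials).  The expected pattern: a clear postmarking
advantage on the overlapping form dimension, and no advantage (a small
premarking edge) on the distinct meaning dimension.
"""

import argparse
from pathlib import Path

from marklearn.interface import write_tables
from marklearn.sims import run_sim1


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--trials", type=int, default=1600)
    ap.add_argument("--eta", type=float, default=0.01)
    ap.add_argument("--out-dir", type=Path, default=Path("results/sim1"))
    args = ap.parse_args()

    result = run_sim1(seed=args.seed, n_trials=args.trials, eta=args.eta)
    paths = write_tables(result, args.out_dir)

    table = result.table.query("checkpoint == 'asymptote'").pivot_table(
        index="noun_class", columns=["dimension", "marking"], values="probability"
    )
    print(f"per-class correct-choice probabilities at asymptote ({args.trials} trials):")
    print(table.round(3).to_string())
    for dim in ("form", "meaning"):
        d = result.difference(dim)
        d412 = result.difference(dim, "behavioral")
        print(f"{dim:>8}: post - pre = {d:+.3f} at asymptote ({d412:+.3f} at 412 trials)")
    print("-> postmarking helps only where category features overlap")
    print("wrote:", *map(str, paths))


if __name__ == "__main__":
    main()
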