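#!/usr/bin/env python
"""Simulation 2: linear marking order and levels of abstraction.

Trains noun-to-object learners under two uncertainty regimes on the same
event stream: the postmarking condition discriminates among all 32 objects
throughout, while the premarking condition -- after a shared first quarter
in which marker-class associations are assumed to form -- continues as four
class-restricted learners whose outcome sets shrink to the 8 within-class
objects.  The expected pattern: a premarking advantage in the probability
of choosing the correct object once the frequent nouns' weights have
reached asymptote, and no advantage at the behavioral trial count (412),
where both conditions are still the same full-set learner.
"""

import argparse
from pathlib import Path

from marklearn.interface import write_tables
from marklearn.sims import run_sim2


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--epochs", type=int, default=73,
                    help="training budget in 412-trial epochs")
    ap.add_argument("--eta", type=float, default=0.01)
    ap.add_argument("--fresh-learners", action="store_true",
                    help="sensitivity mode: class learners start from zero "
                         "instead of the shared quarter-point weights")
    ap.add_argument("--out-dir", type=Path, default=Path("results/sim2"))
    args = ap.parse_args()

    result = run_sim2(seed=args.seed, n_epochs=args.epochs, eta=args.eta,
                      fresh_learners=args.fresh_learners, check_asymptote=True)
    paths = write_tables(result, args.out_dir)

    asym = result.table.query("checkpoint == 'asymptote'")
    summary = asym.groupby("marking")["probability"].agg(["mean", "median"])
    print(f"correct-object probability after {result.n_trials} trials "
          f"(first quarter = {result.quarter} shared):")
    print(summary.round(3).to_string())
    print("by training frequency:")
    print(asym.pivot_table(index="frequency", columns="marking",
                           values="probability").round(3).to_string())
    print(f"premarking - postmarking mean difference: "
          f"{result.difference('asymptote'):+.3f} at asymptote, "
          f"{result.difference('behavioral'):+.3f} at 412 trials")
    print(f"high-frequency weights at asymptote from trial: {result.asymptote_trial}")
    print("-> set-size reduction pays off at the subordinate (noun) level")
    print("wrote:", *map(str, paths))


if __name__ == "__main__":
    main()
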