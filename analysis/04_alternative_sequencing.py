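#!/usr/bin/env python
"""Sequencing-robustness check: swap the second/third-line biologics.

Under the alternative rule, failures transition to guselkumab then
ixekizumab (risankizumab as third line for cohorts starting on those two).
Writes both rules' arm totals side by side to confirm the first-line
ranking is not an artefact of the downstream sequence.
"""

import dataclasses
from pathlib import Path

import pandas as pd

from psorcea import (RewardConvention, build_strategies, builtin_base_case,
                     classify, evaluate_arm)

OUT = Path(__file__).resolve().parents[1] / "results"


def run_rule(rule: str) -> pd.DataFrame:
    config = dataclasses.replace(builtin_base_case(), sequencing_rule=rule)
    results = [evaluate_arm(s, config, RewardConvention(), want_trace=False)
               for s in build_strategies(config)]
    rep = classify(results)
    df = rep.table[["strategy", "cost", "qaly", "status"]].copy()
    df.columns = ["strategy", f"cost_{rule}", f"qaly_{rule}", f"status_{rule}"]
    return df.set_index("strategy"), rep


def main() -> None:
    OUT.mkdir(exist_ok=True)
    base, rep_base = run_rule("base")
    alt, rep_alt = run_rule("alternative")
    both = base.join(alt).reset_index()
    both.to_csv(OUT / "sequencing_comparison.csv", index=False)
    print(both.to_string(index=False, float_format=lambda v: f"{v:,.3f}"))
    print(f"\nreference under base rule:        {rep_base.reference}")
    print(f"reference under alternative rule: {rep_alt.reference}")
    print(f"frontier (alternative rule): {' -> '.join(rep_alt.frontier)}")


if __name__ == "__main__":
    main()
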