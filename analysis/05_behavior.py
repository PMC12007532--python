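#!/usr/bin/env python
"""Behavioral pipeline over a simulated pre/post cohort.

Simulates 25 participants per group on both assessments, filters the
attention task (correct trials, 100-1000 ms), computes per-participant
harmonic means and the reorienting effect (invalid - valid within the
invalid blocks), vPT accuracy/RT summaries, and the group x time cells
with within-group effect sizes and the Welch test on the change scores.
"""

from pathlib import Path

import pandas as pd

from fnirs_nfb.behavior import attention_summaries, filter_attention_trials, \
    prepost_effects, vpt_summaries
from fnirs_nfb.io import write_results_json
from fnirs_nfb.simulate import BehaviorSimConfig, simulate_behavior

SEED = 1
N_PER_GROUP = 25
RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    cfg = BehaviorSimConfig()
    tables = []
    for g_idx, group in enumerate(("up", "down")):
        for i in range(N_PER_GROUP):
            for t_idx, time in enumerate(("pre", "post")):
                tables.append(simulate_behavior(
                    cfg, group, time, participant=f"{group}{i:02d}",
                    seed=SEED * 100_000 + g_idx * 1000 + i * 2 + t_idx))
    table = pd.concat(tables, ignore_index=True)

    filtered, counts = filter_attention_trials(table)
    print(f"attention filtering: {counts['excluded_total']} of "
          f"{(table['task'] == 'attention').sum()} trials excluded "
          f"({counts['incorrect']} errors, {counts['rt_below_100']} fast, "
          f"{counts['rt_above_1000']} slow)")

    att = attention_summaries(filtered)
    vpt = vpt_summaries(filtered)

    cells = att.groupby(["group", "time"])[
        ["hm_valid", "hm_invalid", "hm_across", "reorienting_effect"]
    ].mean().round(1)
    cells.to_csv(RESULTS / "05_attention_cells.tsv", sep="\t")
    print(cells.to_string())

    effects = {
        "attention_across_conditions": prepost_effects(att, "hm_across"),
        "reorienting_effect": prepost_effects(att, "reorienting_effect"),
        "vpt_rt": prepost_effects(vpt, "hm_rt"),
        "vpt_accuracy": prepost_effects(vpt, "accuracy"),
    }
    write_results_json(effects, RESULTS / "05_effects.json")

    up = effects["attention_across_conditions"]["within_group"]["up"]
    down = effects["attention_across_conditions"]["within_group"]["down"]
    bg = effects["attention_across_conditions"]["between_group_on_delta"]
    print(f"up group RT change (pre-post): {up['mean_delta']:+.1f} ms "
          f"(d = {up['d']:.2f}); down group: {-down['mean_delta']:+.1f} ms "
          f"increase (d = {down['d']:.2f})")
    print(f"group difference on the change scores: t = {bg['t']:.2f}, "
          f"p = {bg['p']:.2g}")
    print("the simulated dissociation (faster after upregulation, slower "
          "after downregulation) is recovered; the reorienting cost itself "
          "does not differ between groups, matching the generating model")


if __name__ == "__main__":
    main()
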