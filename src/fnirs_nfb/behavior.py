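"""Behavioral analysis: Posner cueing and visual perspective taking.

Attention-task reaction times are filtered (correct responses with
100-1000 ms RT), summarized per participant with harmonic means, and the
reorienting effect (invalid minus valid RT within the invalid blocks) is
the attentional cost of shifting from a miscued location.  vPT trials are
summarized as harmonic-mean RT and accuracy per condition.  Pre/post group
effects are descriptive cells plus paired within-group effect sizes and a
Welch test on the between-group change contrast.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .metrics import welch_test

RT_MIN_MS = 100.0
RT_MAX_MS = 1000.0


def harmonic_mean(rts) -> float:
    """Harmonic mean n / sum(1/rt); all RTs must be positive."""
    x = np.asarray(rts, dtype=float)
    if x.size == 0:
        raise ValueError("need at least one RT")
    if np.any(x <= 0):
        raise ValueError("harmonic mean requires positive RTs")
    return float(x.size / np.sum(1.0 / x))


def filter_attention_trials(table: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Exclude incorrect attention trials and RTs outside [100, 1000] ms.

    The window boundaries are retained (the exclusion rules are strictly
    <100 and >1000).  Non-attention rows pass through unchanged.  Returns
    the filtered table and per-reason exclusion counts.
    """
    att = table["task"] == "attention"
    too_fast = att & (table["rt"] < RT_MIN_MS)
    too_slow = att & (table["rt"] > RT_MAX_MS)
    incorrect = att & ~table["correct"].astype(bool)
    drop = too_fast | too_slow | incorrect
    counts = {
        "rt_below_100": int(too_fast.sum()),
        "rt_above_1000": int(too_slow.sum()),
        "incorrect": int(incorrect.sum()),
        "excluded_total": int(drop.sum()),
    }
    return table.loc[~drop].reset_index(drop=True), counts


def reorienting_effect(table: pd.DataFrame, participant: str,
                       time: str) -> float:
    """Reorienting cost in ms: HM(invalid) - HM(valid), invalid blocks only.

    Positive values are the cost of shifting attention from the cued to
    the non-cued location.  The table should already be filtered.
    """
    sel = table[(table["task"] == "attention")
                & (table["block_type"] == "invalid_block")
                & (table["participant"] == participant)
                & (table["time"] == time)]
    hm = {}
    for validity in ("invalid", "valid"):
        rts = sel.loc[sel["trial_validity"] == validity, "rt"]
        if rts.empty:
            raise ValueError(
                f"no {validity} trials for {participant}/{time} after filtering"
            )
        hm[validity] = harmonic_mean(rts)
    return hm["invalid"] - hm["valid"]


def attention_summaries(table: pd.DataFrame) -> pd.DataFrame:
    """Per participant x time: condition harmonic means (invalid blocks),
    their across-condition mean, and the reorienting effect."""
    rows = []
    sel = table[(table["task"] == "attention")
                & (table["block_type"] == "invalid_block")]
    for (p, g, t), grp in sel.groupby(["participant", "group", "time"]):
        hm_valid = harmonic_mean(grp.loc[grp["trial_validity"] == "valid", "rt"])
        hm_invalid = harmonic_mean(grp.loc[grp["trial_validity"] == "invalid", "rt"])
        rows.append({
            "participant": p, "group": g, "time": t,
            "hm_valid": hm_valid, "hm_invalid": hm_invalid,
            "hm_across": (hm_valid + hm_invalid) / 2.0,
            "reorienting_effect": hm_invalid - hm_valid,
        })
    return pd.DataFrame(rows)


def vpt_summaries(table: pd.DataFrame) -> pd.DataFrame:
    """Per participant x time x condition: harmonic-mean RT and accuracy.

    No RT exclusion window is applied for this task; RTs are summarized
    over all trials, and a ceiling flag marks cells at 100% accuracy.
    """
    sel = table[table["task"] == "vpt"]
    rows = []
    for (p, g, t, c), grp in sel.groupby(
            ["participant", "group", "time", "condition"]):
        if grp.empty:
            continue
        acc = float(grp["correct"].astype(bool).mean())
        rows.append({
            "participant": p, "group": g, "time": t, "condition": c,
            "hm_rt": harmonic_mean(grp["rt"]),
            "accuracy": acc,
            "ceiling": acc == 1.0,
        })
    return pd.DataFrame(rows)


def prepost_effects(summaries: pd.DataFrame,
                    value: str = "hm_across") -> dict:
    """Group x time cells, within-group change, and the Welch group test.

    ``summaries`` holds one row per participant x time with a ``value``
    column.  The change is pre - post, so a positive paired d denotes an
    RT decrease (improvement).  Participants lacking either time point are
    dropped (logged).  Returns a dict with the descriptive cells, the
    within-group paired effects and the between-group Welch test on the
    change scores.
    """
    wide = summaries.pivot_table(index=["participant", "group"],
                                 columns="time", values=value,
                                 aggfunc="mean").reset_index()
    dropped = wide[wide[["pre", "post"]].isna().any(axis=1)]
    wide = wide.dropna(subset=["pre", "post"])

    cells = {}
    for (g, t), grp in summaries.groupby(["group", "time"]):
        n = int(grp[value].notna().sum())
        cells[(g, t)] = {"mean": float(grp[value].mean()),
                         "sd": float(grp[value].std(ddof=1)) if n > 1 else 0.0,
                         "n": n}

    within = {}
    deltas = {}
    for g, grp in wide.groupby("group"):
        diff = (grp["pre"] - grp["post"]).to_numpy(dtype=float)
        deltas[g] = diff
        sd = diff.std(ddof=1) if diff.size > 1 else 0.0
        within[g] = {
            "mean_delta": float(diff.mean()),
            "sd_delta": float(sd),
            "d": float(diff.mean() / sd) if sd > 0 else 0.0,
            "n": int(diff.size),
        }

    between = None
    groups = sorted(deltas)
    if len(groups) == 2:
        t, p, d = welch_test(deltas[groups[0]], deltas[groups[1]])
        between = {"groups": groups, "t": t, "p": p, "d": d}

    return {
        "value": value,
        "cells": cells,
        "within_group": within,
        "between_group_on_delta": between,
        "dropped_unpaired": list(dropped["participant"]) if not dropped.empty else [],
    }
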