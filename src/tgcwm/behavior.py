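"""Behavioral summaries: accuracy, reaction time and Cowan's K.

In the change-detection task, capacity is estimated as
K = load x (hit rate - false-alarm rate), where the hit rate is the
probability of responding "match" on match trials and the false-alarm
rate that of responding "match" on mismatch trials. Accuracy is computed
over responded trials only (omissions excluded), and mean RT over
correct responded trials by default.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import CONDITION_LOAD

__all__ = ["cowan_k", "summarize"]


def cowan_k(
    load: int,
    hit_rate: float,
    fa_rate: float,
    allowed_loads: tuple[int, ...] = (2, 4),
) -> float:
    """Working-memory capacity K = load x (hit - fa); K in [-load, load]."""
    if load not in allowed_loads:
        raise ValueError(f"load {load} not in allowed set {allowed_loads}")
    for name, r in (("hit_rate", hit_rate), ("fa_rate", fa_rate)):
        if not 0.0 <= r <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {r}")
    return load * (hit_rate - fa_rate)


def summarize(log: pd.DataFrame, rt_correct_only: bool = True) -> pd.DataFrame:
    """Per (subject, session, condition) accuracy, mean RT and K.

    ``log`` follows the trial-log dialect: columns subject, session,
    condition, trial, truth (match/mismatch), response (match/mismatch
    or missing), rt_ms. Raises if a cell has no mismatch trials (the
    false-alarm rate would be undefined).
    """
    required = {"subject", "session", "condition", "truth", "response"}
    missing = required - set(log.columns)
    if missing:
        raise ValueError(f"trial log missing columns: {sorted(missing)}")
    rows = []
    for (subject, session, cond), g in log.groupby(
        ["subject", "session", "condition"], sort=True
    ):
        responded = g[g["response"].isin(["match", "mismatch"])]
        if len(responded) == 0:
            raise ValueError(f"no responded trials for {(subject, session, cond)}")
        match_trials = responded[responded["truth"] == "match"]
        mismatch_trials = responded[responded["truth"] == "mismatch"]
        if len(mismatch_trials) == 0:
            raise ValueError(
                f"false-alarm rate undefined: no mismatch trials in "
                f"{(subject, session, cond)}"
            )
        if len(match_trials) == 0:
            raise ValueError(
                f"hit rate undefined: no match trials in {(subject, session, cond)}"
            )
        hit = (match_trials["response"] == "match").mean()
        fa = (mismatch_trials["response"] == "match").mean()
        correct = responded["response"] == responded["truth"]
        accuracy = correct.mean()
        rt_pool = responded[correct] if rt_correct_only else responded
        mean_rt = float(rt_pool["rt_ms"].mean()) if len(rt_pool) else np.nan
        load = CONDITION_LOAD[cond]
        rows.append(
            dict(
                subject=subject,
                session=session,
                condition=cond,
                n_trials=len(g),
                n_responded=len(responded),
                hit_rate=float(hit),
                fa_rate=float(fa),
                accuracy=float(accuracy),
                mean_rt=mean_rt,
                K=cowan_k(load, float(hit), float(fa)),
            )
        )
    return pd.DataFrame(rows)
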