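"""Independent brute-force oracles used to pin the implementation.

These deliberately share no code with the package: the night oracle
labels every minute of the night and counts; the Shapley oracle
enumerates all feature subsets.
"""

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd


def minute_grid_night(bedrest, asleep):
    """Brute-force night metrics by labelling each minute of the night.

    ``bedrest`` and ``asleep`` are lists of (start, end) pandas Timestamps
    on a whole-minute grid.  The longest bed-rest block is the night; each
    of its minutes is labelled asleep or in-bed-awake, and every metric is
    recovered by counting minutes.  Returns a dict of NightRecord-style
    fields.
    """
    blocks = [(s, e) for s, e in bedrest if e > s]
    if not blocks:
        return None
    b_start, b_end = max(blocks, key=lambda b: (b[1] - b[0], -b[0].value))
    n_min = int((b_end - b_start).total_seconds() // 60)
    lab = np.zeros(n_min, dtype=bool)  # True = asleep
    for s, e in asleep:
        s2, e2 = max(s, b_start), min(e, b_end)
        if e2 > s2:
            i = int((s2 - b_start).total_seconds() // 60)
            j = int((e2 - b_start).total_seconds() // 60)
            lab[i:j] = True
    sleep_min = int(lab.sum())
    bed_h = n_min / 60.0
    sleep_h = sleep_min / 60.0

    def clock(ts):
        # single division of whole minutes, exact on the minute grid
        return (ts.hour * 60 + ts.minute) / 60.0

    out = {
        "bedrest_onset": clock(b_start),
        "bedrest_offset": clock(b_end),
        "bedrest_duration": bed_h,
        "sleep_duration": sleep_h,
        "sleep_efficiency": sleep_h / bed_h,
    }
    if sleep_min == 0:
        out.update(
            sleep_onset=float("nan"), sleep_offset=float("nan"),
            sleep_onset_latency=float("nan"), night_awake_time=0.0, awakenings_count=0,
        )
        return out
    first = int(np.argmax(lab))
    last = n_min - 1 - int(np.argmax(lab[::-1]))
    # awakenings: awake runs strictly between the first and last asleep minute
    inner = lab[first : last + 1]
    transitions = np.diff(inner.astype(int))
    n_awake_runs = int((transitions == -1).sum())  # each awake run ends in sleep again
    awake_min = int((~inner).sum())
    out.update(
        sleep_onset=clock(b_start + pd.Timedelta(minutes=first)),
        sleep_offset=clock(b_start + pd.Timedelta(minutes=last + 1)),
        sleep_onset_latency=float(first),
        night_awake_time=awake_min / 60.0,
        awakenings_count=n_awake_runs,
    )
    return out


def exact_shapley(score_fn, background, x):
    """Exact Shapley values by enumerating all feature subsets.

    The value of a coalition S is the mean of ``score_fn`` over the
    background with the features in S replaced by x's values.
    """
    background = np.atleast_2d(np.asarray(background, dtype=float))
    x = np.asarray(x, dtype=float)
    d = x.size
    values = np.zeros(d)
    all_features = range(d)
    cache = {}

    def coalition_value(S):
        if S not in cache:
            z = background.copy()
            for j in S:
                z[:, j] = x[j]
            cache[S] = float(np.mean(score_fn(z)))
        return cache[S]

    for j in all_features:
        others = [k for k in all_features if k != j]
        for size in range(d):
            w = 1.0 / (d * comb(d - 1, size))
            for S in combinations(others, size):
                values[j] += w * (coalition_value(tuple(sorted(S + (j,)))) - coalition_value(S))
    return values
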