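"""Independent brute-force oracles used to cross-check the package.

Everything here is deliberately naive — exhaustive enumeration, direct
sums — and shares no code with the implementation it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy import stats as sps
from scipy.optimize import linear_sum_assignment


def brute_force_segment(positions, dt, tol, pause_min_frames, run_threshold):
    """Exhaustive run/pause segmentation of one contiguous track.

    Enumerates every window of >= pause_min_frames consecutive frames whose
    internal steps are all <= tol (stalls), then groups the remaining
    above-tolerance steps by sign without crossing a stall.  Returns
    (runs, pauses) where runs are (direction, start_frame, end_frame,
    displacement, duration) and pauses are (start_frame, end_frame,
    duration).
    """
    x = [float(v) for v in positions]
    n = len(x)
    stall_steps = set()
    for i in range(n):
        for j in range(i + pause_min_frames - 1, n):
            if all(abs(x[k + 1] - x[k]) <= tol for k in range(i, j)):
                stall_steps.update(range(i, j))

    pauses = []
    k = 0
    while k < n - 1:
        if k in stall_steps:
            j = k
            while j in stall_steps:
                j += 1
            pauses.append((k, j, (j - k) * dt))
            k = j
        else:
            k += 1

    groups = []
    cur = None
    for k in range(n - 1):
        if k in stall_steps:
            if cur is not None:
                groups.append(cur)
                cur = None
            continue
        if abs(x[k + 1] - x[k]) <= tol:
            continue
        sign = 1 if x[k + 1] > x[k] else -1
        if cur is not None and cur[0] != sign:
            groups.append(cur)
            cur = None
        if cur is None:
            cur = [sign, k, k, 0]
        cur[2] = k
        cur[3] += 1
    if cur is not None:
        groups.append(cur)

    runs = []
    for sign, a, b, n_moving in groups:
        disp = abs(x[b + 1] - x[a])
        if disp >= run_threshold:
            direction = "anterograde" if sign > 0 else "retrograde"
            runs.append((direction, a, b + 1, disp, n_moving * dt))
    return runs, pauses


def flux_by_accumulation(track_positions_list, dt, tol, pause_min_frames,
                         run_threshold, axon_length_um, duration_min):
    """Per-frame displacement accumulation over directed-run frames.

    For every track, segments with :func:`brute_force_segment` and adds up
    |dx| of each above-tolerance step inside each directed run, per
    direction, then divides by (l x t).
    """
    totals = {"anterograde": 0.0, "retrograde": 0.0}
    for x in track_positions_list:
        runs, _ = brute_force_segment(x, dt, tol, pause_min_frames, run_threshold)
        for direction, a, b, _disp, _dur in runs:
            for k in range(a, b):
                step = abs(x[k + 1] - x[k])
                if step > tol:
                    totals[direction] += step
    return {d: v / (axon_length_um * duration_min) for d, v in totals.items()}


def optimal_pair_count(centers_a, centers_b, max_distance):
    """Maximum-cardinality (min-cost) one-to-one matching within max_distance."""
    a = np.atleast_2d(np.asarray(centers_a, dtype=float))
    b = np.atleast_2d(np.asarray(centers_b, dtype=float))
    if a.size == 0 or b.size == 0:
        return 0
    d = np.sqrt(((a[:, None, :] - b[None, :, :]) ** 2).sum(-1))
    big = 1e9
    cost = np.where(d <= max_distance, d, big)
    rows, cols = linear_sum_assignment(cost)
    return int((cost[rows, cols] < big).sum())


def anova_oracle(groups):
    """One-way ANOVA by direct sum-of-squares decomposition."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    n_total = sum(len(g) for g in groups)
    grand = np.concatenate(groups).mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b, df_w = k - 1, n_total - k
    f = (ss_between / df_b) / (ss_within / df_w)
    p = sps.f.sf(f, df_b, df_w)
    return f, p, df_b, df_w, ss_within


def tukey_oracle(groups):
    """Tukey-Kramer adjusted p per pair via the studentized range."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    _, _, _, df_w, ss_within = anova_oracle(groups)
    msw = ss_within / df_w
    out = {}
    for i, j in itertools.combinations(range(k), 2):
        se = math.sqrt(msw / 2.0 * (1.0 / len(groups[i]) + 1.0 / len(groups[j])))
        q = abs(groups[i].mean() - groups[j].mean()) / se
        out[(i, j)] = float(sps.studentized_range.sf(q, k, df_w))
    return out


def pooled_t_oracle(a, b):
    """Textbook pooled-variance two-sample t statistic."""
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    sp2 = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / (na + nb - 2)
    return (a.mean() - b.mean()) / math.sqrt(sp2 * (1.0 / na + 1.0 / nb))
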