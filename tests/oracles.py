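"""Independent brute-force reference implementations for the test suite.

Everything here is written as plain Python loops over the stated rules,
deliberately sharing no code with the package's vectorised implementations.
"""

from __future__ import annotations

import math


def brute_classify(magnitudes, min_limit, max_limit):
    lows = [i for i, m in enumerate(magnitudes) if m < min_limit]
    highs = [i for i, m in enumerate(magnitudes) if m > max_limit]
    return lows, highs


def brute_group(indices, entries, sub_1):
    """Maximal runs whose consecutive entry gaps are <= sub_1 (member lists)."""
    groups = []
    for i in indices:
        if groups and entries[i] - entries[groups[-1][-1]] <= sub_1:
            groups[-1].append(i)
        else:
            groups.append([i])
    return groups


def brute_pipeline(magnitudes, entries, th, g=9.80665):
    """Full two-stage reference: returns (candidate spans, accepted spans).

    ``th`` is a mapping with the eight thresholds plus stability_window,
    mean_tol, std_tol.  Spans are (start_index, end_index) pairs sorted by
    (start entry, end entry).
    """
    m = list(magnitudes)
    e = list(entries)
    lows, highs = brute_classify(m, th["min_limit"], th["max_limit"])
    if not lows or not highs:
        return [], []
    lgroups = brute_group(lows, e, th["sub_1"])
    hgroups = brute_group(highs, e, th["sub_1"])

    cands = []
    for li, L in enumerate(lgroups):
        for hi, H in enumerate(hgroups):
            span = e[H[-1]] - e[L[0]]
            if 0 < span <= th["fall_duration"]:
                cands.append({"s": L[0], "t": H[-1], "lg": li, "hg": hi})
    for c in cands:
        c["span"] = e[c["t"]] - e[c["s"]]
    cands.sort(key=lambda c: (e[c["s"]], e[c["t"]]))
    candidate_spans = [(c["s"], c["t"]) for c in cands]

    # check 1: shared extremes -- shortest survives, ties to earlier start/end
    remaining = list(cands)
    survivors = []
    while remaining:
        best = remaining[0]
        for c in remaining[1:]:
            if (c["span"], e[c["s"]], e[c["t"]]) < (best["span"], e[best["s"]], e[best["t"]]):
                best = c
        survivors.append(best)
        remaining = [
            c for c in remaining
            if c is not best and c["lg"] != best["lg"] and c["hg"] != best["hg"]
        ]
    survivors.sort(key=lambda c: (e[c["s"]], e[c["t"]]))

    # check 2: long falls are shrunk toward the impact or rejected
    after_shrink = []
    for c in survivors:
        span = e[c["t"]] - e[c["s"]]
        if span <= th["fall_limitation"]:
            after_shrink.append(c)
            continue
        best_j = None
        for j in lows:
            if e[c["s"]] < e[j] < e[c["t"]] and e[c["t"]] - e[j] <= th["fall_limitation"]:
                if best_j is None or e[j] > e[best_j]:
                    best_j = j
        if best_j is not None:
            after_shrink.append({**c, "s": best_j})

    # check 3: post-fall stability near g OR peak dominance
    accepted = []
    for c in after_shrink:
        start_e, end_e = e[c["s"]], e[c["t"]]
        window = [m[k] for k in range(len(m)) if end_e < e[k] <= end_e + th["stability_window"]]
        stable = False
        if window:
            mean = sum(window) / len(window)
            var = sum((v - mean) ** 2 for v in window) / len(window)
            stable = abs(mean - g) <= th["mean_tol"] and math.sqrt(var) <= th["std_tol"]
        peak = max(m[c["s"] : c["t"] + 1])
        dominant = True
        for k in range(len(m)):
            if c["s"] <= k <= c["t"] or m[k] <= th["max_limit_2"]:
                continue
            near = (start_e - th["dist_1"] <= e[k] < start_e) or (end_e < e[k] <= end_e + th["dist_2"])
            if near and not peak > m[k]:
                dominant = False
                break
        if stable or dominant:
            accepted.append((c["s"], c["t"]))
    accepted.sort(key=lambda st: (e[st[0]], e[st[1]]))
    return candidate_spans, accepted


def random_instance(rng, max_len=500):
    """A random magnitude/entry series plus random-but-sane thresholds."""
    n = int(rng.integers(5, max_len + 1))
    magnitudes = rng.uniform(0.0, 45.0, n)
    dt = rng.uniform(0.005, 0.02, n - 1) if n > 1 else []
    t = [0.0]
    for d in dt:
        t.append(t[-1] + d)
    f = float(rng.choice([50.0, 60.0, 100.0]))
    entries = [0.0]
    for i in range(1, n):
        entries.append((t[i] - t[i - 1]) / 10 + entries[i - 1] + 100.0 / f)
    th = {
        "min_limit": float(rng.uniform(2.0, 8.0)),
        "max_limit": float(rng.uniform(20.0, 38.0)),
        "sub_1": float(rng.uniform(10.0, 60.0)),
        "fall_duration": float(rng.uniform(60.0, 150.0)),
        "fall_limitation": float(rng.uniform(40.0, 120.0)),
        "dist_1": float(rng.uniform(50.0, 150.0)),
        "dist_2": float(rng.uniform(50.0, 150.0)),
        "max_limit_2": float(rng.uniform(20.0, 45.0)),
        "stability_window": float(rng.uniform(50.0, 150.0)),
        "mean_tol": float(rng.uniform(0.5, 3.0)),
        "std_tol": float(rng.uniform(0.5, 4.0)),
    }
    return magnitudes, t, entries, f, th
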