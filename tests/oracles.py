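"""Independent brute-force re-implementations of the six baselines.

Pure-Python loops over plain dicts — no numpy, no shared code with the
package — used as the second route in oracle-equivalence tests.  Data is
a mapping (year, week) -> value.
"""

from __future__ import annotations

import math


def oracle_quantile(values, p):
    """Type-7 quantile from the closed form h = 1 + (n-1)p."""
    s = sorted(values)
    n = len(s)
    h = 1 + (n - 1) * p
    lo = math.floor(h)
    hi = math.ceil(h)
    return s[lo - 1] + (h - lo) * (s[hi - 1] - s[lo - 1])


def _week_vals(data, period, week):
    out = []
    for j in sorted(period):
        if (j, week) in data:
            out.append((j, data[(j, week)]))
    return out


def oracle_week_average(data, period, weeks):
    level = {}
    for w in weeks:
        vals = [v for _, v in _week_vals(data, period, w)]
        level[w] = sum(vals) / len(vals)
    return level


def oracle_week_trend(data, period, target, weeks):
    level = {}
    for w in weeks:
        pairs = _week_vals(data, period, w)
        n = len(pairs)
        sy = sum(j for j, _ in pairs)
        sx = sum(v for _, v in pairs)
        syy = sum(j * j for j, _ in pairs)
        sxy = sum(j * v for j, v in pairs)
        b = (n * sxy - sy * sx) / (n * syy - sy * sy)
        a = (sx - b * sy) / n
        level[w] = a + b * target
    return level


def oracle_week_lower_quartile(data, period, weeks):
    level = {}
    for w in weeks:
        vals = [v for _, v in _week_vals(data, period, w)]
        q1 = oracle_quantile(vals, 0.25)
        low = [v for v in vals if v <= q1]
        level[w] = sum(low) / len(low)
    return level


def oracle_yearly_average(data, period, weeks):
    wa = oracle_week_average(data, period, weeks)
    return sum(wa.values()) / len(wa)


def oracle_summer_average(data, period, weeks, nonwinter):
    summer = [w for w in weeks if w in nonwinter]
    wa = oracle_week_average(data, period, summer)
    return sum(wa.values()) / len(wa)


def oracle_yearly_lower_quartile(data, period):
    pool = [v for (j, i), v in data.items() if j in set(period)]
    q1 = oracle_quantile(pool, 0.25)
    low = [v for v in pool if v <= q1]
    return sum(low) / len(low)


def oracle_polygons(weeks, diffs):
    """Runs of consecutive same-sign weeks as (sign, start, end) tuples."""
    out = []
    cur = None
    prev_w = None
    for w, d in zip(weeks, diffs):
        sign = "excess" if d > 0 else ("deficit" if d < 0 else None)
        if cur is not None and (sign != cur[0] or prev_w is None or w != prev_w + 1):
            out.append(tuple(cur))
            cur = None
        if sign is not None and cur is None:
            cur = [sign, w, w]
        elif sign is not None:
            cur[2] = w
        prev_w = w
    if cur is not None:
        out.append(tuple(cur))
    return out
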