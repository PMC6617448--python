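"""Kaplan-Meier estimation and the two-group log-rank test.

Both are implemented from first principles (product-limit estimator and the
observed-vs-expected chi-square), so group comparisons of hub-gene expression
strata need no external survival service.  Records carry a time in months, an
event flag (1 = death/progression, 0 = censored) and a group label.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def split_by_expression(values: pd.Series, rule: str = "median") -> pd.Series:
    """Dichotomize samples by expression: high = strictly above the median.

    Ties at the median go to "low".  Raises on constant input (no split
    exists).
    """
    if rule != "median":
        raise ValueError(f"unknown split rule: {rule!r}")
    if len(values) < 2:
        raise ValueError("need >= 2 samples to split")
    if values.nunique() == 1:
        raise ValueError("cannot split: constant expression")
    med = values.median()
    return pd.Series(np.where(values > med, "high", "low"), index=values.index, name="group")


def km_estimate(records: pd.DataFrame) -> pd.DataFrame:
    """Product-limit survival estimate.

    ``records`` needs columns ``time`` (>= 0) and ``event`` (0/1).  Returns a
    step table (time, n_at_risk, n_events, survival) over distinct event
    times, with S(0) = 1 prepended; S is right-continuous and non-increasing:
    S(t) = prod_{t_i <= t} (1 - d_i / n_i).
    """
    if len(records) == 0:
        raise ValueError("no survival records")
    t = records["time"].to_numpy(float)
    e = records["event"].to_numpy(int)
    if (t < 0).any():
        raise ValueError("negative survival time")
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    n_total = len(t)
    rows = [(0.0, n_total, 0, 1.0)]
    surv = 1.0
    for ti in np.unique(t[e == 1]):
        n_at_risk = int((t >= ti).sum())
        d = int(((t == ti) & (e == 1)).sum())
        surv *= 1.0 - d / n_at_risk
        rows.append((float(ti), n_at_risk, d, surv))
    return pd.DataFrame(rows, columns=["time", "n_at_risk", "n_events", "survival"])


def logrank_test(group_a: pd.DataFrame, group_b: pd.DataFrame) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p).

    At each distinct event time, the observed events in group A are compared
    with the hypergeometric expectation under a common hazard:
    U = sum(d_Ai - n_Ai * d_i / n_i), V = sum of hypergeometric variances,
    chi2 = U^2 / V with 1 df.  Zero variance (e.g. no events) yields p = 1.
    """
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValueError("both groups must be nonempty")
    ta, ea = group_a["time"].to_numpy(float), group_a["event"].to_numpy(int)
    tb, eb = group_b["time"].to_numpy(float), group_b["event"].to_numpy(int)
    if ea.sum() + eb.sum() == 0:
        raise ValueError("need at least one event overall")
    event_times = np.unique(np.concatenate([ta[ea == 1], tb[eb == 1]]))
    U = 0.0
    V = 0.0
    for ti in event_times:
        n_a = (ta >= ti).sum()
        n_b = (tb >= ti).sum()
        n = n_a + n_b
        d_a = ((ta == ti) & (ea == 1)).sum()
        d = d_a + ((tb == ti) & (eb == 1)).sum()
        U += d_a - n_a * d / n
        if n > 1:
            V += d * (n_a / n) * (n_b / n) * (n - d) / (n - 1)
    if V == 0:
        return 0.0, 1.0
    chi2 = U * U / V
    return float(chi2), float(stats.chi2.sf(chi2, df=1))
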