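"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the code paths under test: Welch and one-sample t
statistics are computed from the textbook formulas with the t-distribution
CDF as the only library call, and BH adjustment is a literal step-up over
the sorted p-values.
"""

import math

import numpy as np
from scipy.stats import t as t_dist


def welch_oracle(a, b):
    """Textbook Welch: t, Welch-Satterthwaite df, upper-tail p."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = len(a), len(b)
    va = sum((x - a.mean()) ** 2 for x in a) / (na - 1)
    vb = sum((x - b.mean()) ** 2 for x in b) / (nb - 1)
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = float(t_dist.sf(t, df))
    return t, df, p


def one_sample_t_oracle(values):
    """Two-sided one-sample t vs 0 from the closed form t = mean/(sd/sqrt(n))."""
    x = np.asarray(values, float)
    n = len(x)
    sd = math.sqrt(sum((v - x.mean()) ** 2 for v in x) / (n - 1))
    t = x.mean() / (sd / math.sqrt(n))
    p = 2.0 * float(t_dist.sf(abs(t), n - 1))
    return t, n - 1, p


def bh_oracle(p_values):
    """Literal BH step-up: q_(i) = min_{j>=i}(p_(j) * m / j), capped at 1."""
    p = list(map(float, p_values))
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q_sorted = [0.0] * m
    running_min = math.inf
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running_min = min(running_min, p[idx] * m / rank)
        q_sorted[rank - 1] = min(running_min, 1.0)
    q = [0.0] * m
    for rank, idx in enumerate(order, start=1):
        q[idx] = q_sorted[rank - 1]
    return np.array(q)


def pearson_oracle(x, y):
    """Pearson r from the covariance / sd definition."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xc = x - x.mean()
    yc = y - y.mean()
    return float((xc * yc).sum() / math.sqrt((xc**2).sum() * (yc**2).sum()))
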