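"""Independent brute-force reference implementations used only by tests.

These deliberately use the slowest, most literal formulation (explicit
double loops, no vectorisation) so they share no code path with the
package.
"""

import math


def msd_mad_naive(xs, ys):
    """Per-lag MSD and MAD via explicit O(N²) loops.

    Returns (msd, mad, n_pairs) lists indexed by lag-1, for lags 1..N−1:
    at lag i, average over start points j = 0..N−i−1 of the squared
    (resp. absolute) displacement between points j and j+i.
    """
    n = len(xs)
    msd, mad, n_pairs = [], [], []
    for i in range(1, n):
        sq_sum = 0.0
        abs_sum = 0.0
        count = 0
        for j in range(0, n - i):
            dx = xs[j + i] - xs[j]
            dy = ys[j + i] - ys[j]
            d2 = dx * dx + dy * dy
            sq_sum += d2
            abs_sum += math.sqrt(d2)
            count += 1
        msd.append(sq_sum / count)
        mad.append(abs_sum / count)
        n_pairs.append(count)
    return msd, mad, n_pairs


def ols_naive(x, y):
    """Textbook simple linear regression; returns (slope, intercept, r2)."""
    n = len(x)
    xm = sum(x) / n
    ym = sum(y) / n
    sxx = sum((xi - xm) ** 2 for xi in x)
    sxy = sum((xi - xm) * (yi - ym) for xi, yi in zip(x, y))
    slope = sxy / sxx
    intercept = ym - slope * xm
    ss_tot = sum((yi - ym) ** 2 for yi in y)
    ss_res = sum((yi - slope * xi - intercept) ** 2 for xi, yi in zip(x, y))
    r2 = float("nan") if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return slope, intercept, r2
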