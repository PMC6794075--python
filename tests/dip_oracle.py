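"""Independent brute-force oracle for the dip statistic (small n).

For each candidate mode position an LP finds the minimal band half-width d
such that a unimodal distribution function (convex rising flank, concave
falling flank, an atom permitted at the mode) fits within d of the ECDF
everywhere; the dip is the minimum over modes.  Derived directly from the
sup-norm constraints of the step ECDF; independent of the sweep-based
implementation under test.
"""

import numpy as np
from scipy.optimize import linprog


def dip_oracle(sample):
    x = np.sort(np.asarray(sample, dtype=float))
    n = len(x)
    v, counts = np.unique(x, return_counts=True)
    c = np.cumsum(counts).astype(float)
    K = len(v)
    if K == 1:
        return 0.0
    best = np.inf
    for m in range(K):
        # variables: d, G_0..G_{m-1}, A, B, G_{m+1}..G_{K-1}
        nv = 1 + K + 1  # one extra because the mode point has two values
        def gidx(j):  # value of G at v_j (right value at mode)
            return 1 + j + (1 if j >= m else 0)
        aidx = 1 + m  # left limit at mode
        A_ub, b_ub = [], []

        def add(coeffs, rhs):
            row = np.zeros(nv)
            for i, co in coeffs:
                row[i] += co
            A_ub.append(row)
            b_ub.append(rhs)

        for j in range(K):
            prev = c[j - 1] / n if j > 0 else 0.0
            if j == m:
                # A in [prev - d, prev + d]; B in [c_m/n - d, c_m/n + d]
                add([(aidx, 1.0), (0, -1.0)], prev)
                add([(aidx, -1.0), (0, -1.0)], -prev)
                add([(gidx(j), 1.0), (0, -1.0)], c[j] / n)
                add([(gidx(j), -1.0), (0, -1.0)], -c[j] / n)
            else:
                add([(gidx(j), -1.0), (0, -1.0)], -c[j] / n)  # G_j >= c_j/n - d
                add([(gidx(j), 1.0), (0, -1.0)], prev)  # G_j <= prev + d
        # monotonicity chain incl. A <= B
        chain = [gidx(j) for j in range(m)] + [aidx, gidx(m)] + [
            gidx(j) for j in range(m + 1, K)
        ]
        for a, b in zip(chain, chain[1:]):
            add([(a, 1.0), (b, -1.0)], 0.0)
        # convexity on the left flank (values at v_0..v_{m-1}, A at v_m)
        left_pts = [(v[j], gidx(j)) for j in range(m)] + [(v[m], aidx)]
        for (xa, ia), (xb, ib), (xc2, ic) in zip(left_pts, left_pts[1:], left_pts[2:]):
            # (Gb-Ga)/(xb-xa) <= (Gc-Gb)/(xc-xb)
            h1, h2 = xb - xa, xc2 - xb
            add([(ia, -h2), (ib, h1 + h2), (ic, -h1)], 0.0)
        # concavity on the right flank (B at v_m, values v_{m+1}..)
        right_pts = [(v[m], gidx(m))] + [(v[j], gidx(j)) for j in range(m + 1, K)]
        for (xa, ia), (xb, ib), (xc2, ic) in zip(right_pts, right_pts[1:], right_pts[2:]):
            h1, h2 = xb - xa, xc2 - xb
            add([(ia, h2), (ib, -(h1 + h2)), (ic, h1)], 0.0)
        bounds = [(0, None)] + [(0.0, 1.0)] * (nv - 1)
        cvec = np.zeros(nv)
        cvec[0] = 1.0
        res = linprog(cvec, A_ub=np.array(A_ub), b_ub=np.array(b_ub),
                      bounds=bounds, method="highs")
        if res.status == 0:
            best = min(best, res.fun)
    return float(best)
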