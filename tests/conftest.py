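import numpy as np
import pytest

from etype_sync import rl
from etype_sync.synthetic import gen_session, gen_spiketrain


@pytest.fixture(scope="session")
def poisson_train():
    """Long Poisson train (rate 5 Hz, 600 s) shared across statistics tests."""
    return gen_spiketrain(rate=5.0, duration=600.0, shape=1.0, seed=101)


@pytest.fixture(scope="session")
def agent_session():
    """One simulated task session from the canonical agent (eta=.5, w=.2, b=5)."""
    params = rl.RlParams(0.5, 0.2, 5.0)
    trials, gt = gen_session(params, n_blocks=40, seed=7)
    return params, trials


def dip_lp_oracle(x):
    """Brute-force Hartigan dip via linear programming (tiny n only).

    Minimizes the sup-norm band half-width d over unimodal cdf fits,
    enumerating every between-point and at-point mode split.  The fitted
    cdf must pass within d of both one-sided ecdf limits at every unique
    value, be nondecreasing, and be convex left / concave right of the
    mode (a unimodal cdf may jump at its mode, which relaxes the at-point
    constraint to the matching one-sided limit).
    """
    from scipy.optimize import linprog

    x = np.sort(np.asarray(x, float))
    n = x.size
    ux, first = np.unique(x, return_index=True)
    last = np.r_[first[1:], n] - 1
    hi0 = first / n
    lo0 = (last + 1) / n
    m = ux.size

    def solve(left_idx, right_idx, hi_pair, lo_pair):
        nl, nr = len(left_idx), len(right_idx)
        nv = nl + nr + 1
        c = np.zeros(nv)
        c[-1] = 1.0
        A, b = [], []

        def corridor(pos, hi, lo):
            row = np.zeros(nv)
            row[pos] = 1
            row[-1] = -1
            A.append(row)
            b.append(hi)
            row = np.zeros(nv)
            row[pos] = -1
            row[-1] = -1
            A.append(row)
            b.append(-lo)

        for p in range(nl):
            corridor(p, hi_pair[0][p], lo_pair[0][p])
        for p in range(nr):
            corridor(nl + p, hi_pair[1][p], lo_pair[1][p])
        order = list(range(nl + nr))
        for a_, b_ in zip(order[:-1], order[1:]):
            row = np.zeros(nv)
            row[a_] = 1
            row[b_] = -1
            A.append(row)
            b.append(0.0)
        xl = ux[left_idx]
        for i in range(nl - 2):
            x0, x1, x2 = xl[i], xl[i + 1], xl[i + 2]
            row = np.zeros(nv)
            row[i] = 1 / (x1 - x0)
            row[i + 1] = -1 / (x1 - x0) - 1 / (x2 - x1)
            row[i + 2] = 1 / (x2 - x1)
            A.append(-row)
            b.append(0.0)
        xr = ux[right_idx]
        for i in range(nr - 2):
            x0, x1, x2 = xr[i], xr[i + 1], xr[i + 2]
            row = np.zeros(nv)
            row[nl + i] = 1 / (x1 - x0)
            row[nl + i + 1] = -1 / (x1 - x0) - 1 / (x2 - x1)
            row[nl + i + 2] = 1 / (x2 - x1)
            A.append(row)
            b.append(0.0)
        res = linprog(
            c,
            A_ub=np.array(A),
            b_ub=np.array(b),
            bounds=[(0, 1)] * (nl + nr) + [(0, None)],
            method="highs",
        )
        return res.fun if res.success else np.inf

    best = np.inf
    for k in range(m + 1):
        best = min(
            best,
            solve(
                list(range(k)),
                list(range(k, m)),
                (hi0[:k], hi0[k:]),
                (lo0[:k], lo0[k:]),
            ),
        )
    for j in range(m):
        ch_l, cl_l = hi0[: j + 1].copy(), lo0[: j + 1].copy()
        cl_l[j] = hi0[j]
        ch_r, cl_r = hi0[j:].copy(), lo0[j:].copy()
        ch_r[0] = lo0[j]
        best = min(
            best,
            solve(
                list(range(j + 1)),
                list(range(j, m)),
                (ch_l, ch_r),
                (cl_l, cl_r),
            ),
        )
    return best
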