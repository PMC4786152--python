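"""Independent brute-force oracles used by unit and acceptance tests.

These are deliberately naive re-derivations — loops over definitions, normal
equations instead of least-squares solvers — kept separate from the package
so the two routes share no code.
"""

import numpy as np


def km_brute_force(times, events):
    """Product-limit survival by direct counting at each distinct event time.

    At a tied event/censoring time the censored subjects still count as at
    risk for the deaths at that time.  Returns (event_times, survival).
    """
    times = list(map(float, times))
    events = list(map(bool, events))
    etimes = sorted({t for t, e in zip(times, events) if e})
    surv = []
    s = 1.0
    for t in etimes:
        n_at_risk = sum(1 for u in times if u >= t)
        d = sum(1 for u, e in zip(times, events) if u == t and e)
        s *= 1.0 - d / n_at_risk
        surv.append(s)
    return np.array(etimes), np.array(surv)


def km_survival_at(times, events, t):
    etimes, surv = km_brute_force(times, events)
    s = 1.0
    for ti, si in zip(etimes, surv):
        if ti <= t:
            s = si
    return s


def loess_brute_force(x, y, span, degree, grid):
    """Local polynomial regression via explicit weighted normal equations."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    k = int(np.ceil(span * n))
    fitted = []
    for g in grid:
        dist = sorted(abs(xi - g) for xi in x)
        dmax = dist[k - 1]
        if dmax == 0:
            w = np.array([1.0 if abs(xi - g) == 0 else 0.0 for xi in x])
        else:
            w = np.array([
                (1 - min(abs(xi - g) / dmax, 1.0) ** 3) ** 3
                if abs(xi - g) <= dmax else 0.0
                for xi in x
            ])
        # weighted normal equations for a polynomial in (x - g)
        p = degree + 1
        X = np.vander(x - g, p, increasing=True)
        A = X.T @ (w[:, None] * X)
        b = X.T @ (w * y)
        beta = np.linalg.solve(A, b)
        fitted.append(beta[0])
    return np.array(fitted)
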