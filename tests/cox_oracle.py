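"""Brute-force Efron partial-likelihood oracle for small instances.

Implements the log partial likelihood directly from its definition
(explicit risk-set loops, no shared code with the package's vectorized
fitter) and maximizes it with a generic quasi-Newton optimizer.  Used
to verify the production fitter's coefficients to tight tolerance.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize


def efron_loglik(beta, X, start, stop, event):
    """Log partial likelihood with Efron tie handling and late entry."""
    beta = np.asarray(beta, dtype=float)
    eta = X @ beta
    r = np.exp(eta)
    ll = 0.0
    for t in np.unique(stop[event == 1]):
        D = (event == 1) & (stop == t)
        R = (start < t) & (stop >= t)
        d = int(D.sum())
        S0 = r[R].sum()
        s0 = r[D].sum()
        ll += eta[D].sum()
        for l in range(d):
            ll -= np.log(S0 - (l / d) * s0)
    return ll


def maximize_efron(X, start, stop, event, x0=None):
    """High-precision maximizer of the oracle likelihood."""
    X = np.asarray(X, dtype=float)
    start = np.asarray(start, dtype=float)
    stop = np.asarray(stop, dtype=float)
    event = np.asarray(event, dtype=int)
    p = X.shape[1]
    x0 = np.zeros(p) if x0 is None else x0
    res = minimize(
        lambda b: -efron_loglik(b, X, start, stop, event),
        x0,
        method="BFGS",
        options={"gtol": 1e-12, "maxiter": 500},
    )
    # polish with Nelder-Mead in case BFGS stalls on a flat ridge
    res2 = minimize(
        lambda b: -efron_loglik(b, X, start, stop, event),
        res.x,
        method="Nelder-Mead",
        options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 4000},
    )
    return res2.x if res2.fun < res.fun else res.x


def random_small_instance(rng, n_patients=None):
    """A random counting-process dataset with <=10 patients.

    Mixes delayed entry, multiple rows per patient, tied event days and
    one or two covariates.
    """
    n_patients = n_patients or int(rng.integers(3, 11))
    p = int(rng.integers(1, 3))
    rows = []
    for pid in range(n_patients):
        t = int(rng.integers(0, 4))  # possible delayed entry
        for _ in range(int(rng.integers(1, 4))):
            dur = int(rng.integers(1, 8))
            x = rng.integers(0, 2, size=p).astype(float)
            if p == 2:
                x[1] = np.round(rng.normal(), 2)
            ev = int(rng.random() < 0.45)
            rows.append((f"P{pid}", t, t + dur, ev, *x))
            t += dur
    cols = ["cluster_id", "t_start", "t_stop", "event"] + [f"x{i}" for i in range(p)]
    import pandas as pd

    df = pd.DataFrame(rows, columns=cols)
    # ensure at least one event and covariate variation
    if df["event"].sum() == 0:
        df.loc[df.index[0], "event"] = 1
    return df, [f"x{i}" for i in range(p)]
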