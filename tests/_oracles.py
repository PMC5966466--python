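"""Independent reference implementations used only to check the package.

These deliberately share no code with ``narrsync``: the restricted
likelihood is written in its dense, unprofiled form and optimized with a
generic simplex search, so agreement with the package's profiled
eigendecomposition fit is a genuine two-route check.
"""

import numpy as np
from scipy import optimize


def dense_reml_fit(y: np.ndarray, X: np.ndarray, n_subjects: int):
    """Brute-force REML for the crossed random-effects pair model.

    Minimizes −2 restricted log-likelihood over (log tau², log sigma²) with
    Nelder–Mead on the dense covariance V = sigma² I + tau² Z Z'.
    Returns (beta, tau2, sigma2).
    """
    n = n_subjects
    iu, ju = np.triu_indices(n, 1)
    m = len(iu)
    Z = np.zeros((m, n))
    Z[np.arange(m), iu] = 1.0
    Z[np.arange(m), ju] = 1.0
    K = Z @ Z.T
    N = len(y)

    def neg2reml(params):
        t2, s2 = np.exp(params)
        V = s2 * np.eye(N) + t2 * K
        Vi = np.linalg.inv(V)
        A = X.T @ Vi @ X
        beta = np.linalg.solve(A, X.T @ Vi @ y)
        r = y - X @ beta
        _, ld_v = np.linalg.slogdet(V)
        _, ld_a = np.linalg.slogdet(A)
        return ld_v + ld_a + float(r @ Vi @ r)

    best = None
    for start in [(-3.0, -3.0), (-5.0, -2.0), (-2.0, -5.0), (-8.0, -3.0)]:
        res = optimize.minimize(
            neg2reml, start, method="Nelder-Mead",
            options={"xatol": 1e-13, "fatol": 1e-14, "maxiter": 5000},
        )
        if best is None or res.fun < best.fun:
            best = res
    t2, s2 = np.exp(best.x)
    V = s2 * np.eye(N) + t2 * K
    Vi = np.linalg.inv(V)
    A = X.T @ Vi @ X
    beta = np.linalg.solve(A, X.T @ Vi @ y)
    return beta, float(t2), float(s2)


def pearson_by_hand(x, y) -> float:
    """Textbook covariance-over-variances Pearson correlation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xm, ym = x - x.mean(), y - y.mean()
    return float((xm * ym).sum() / np.sqrt((xm**2).sum() * (ym**2).sum()))


def consensus_probability(base_rate: float, agreement: float,
                          n_raters: int, min_raters: int) -> float:
    """Exact P(at least min_raters positive labels) for one sentence under
    the latent-truth-with-agreement annotation model."""
    from math import comb

    def tail(p):
        return sum(
            comb(n_raters, k) * p**k * (1 - p) ** (n_raters - k)
            for k in range(min_raters, n_raters + 1)
        )

    return base_rate * tail(agreement) + (1 - base_rate) * tail(1 - agreement)
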