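"""Independent numerical oracles shared by the test suite.

These deliberately avoid the package's own likelihood/fitting code paths:
brute-force trapezoid integration for the marginal likelihood and a
hand-rolled IRLS for the Poisson GLM limit.
"""

import math

import numpy as np

from pahrank.nbglmm import _ModelData, _nb_log_pmf_core


def brute_force_marginal_ll(spec, beta, sigma_b, k, df,
                            n_points=10001, half_width=10.0):
    """Trapezoid integration of the random intercept over
    [-half_width*sigma, half_width*sigma] per facility."""
    md = _ModelData.from_frame(df, spec)
    eta0 = md.X @ np.asarray(beta) + md.offset
    bs = np.linspace(-half_width * sigma_b, half_width * sigma_b, n_points)
    total = 0.0
    for g in range(md.n_groups):
        sel = md.gidx == g
        # (n_points, n_units_in_group) evaluation of the joint log density
        mu = np.exp(eta0[sel][None, :] + bs[:, None])
        lp = _nb_log_pmf_core(
            np.broadcast_to(md.y[sel], mu.shape).copy(), mu, k
        ).sum(axis=1)
        lp += -0.5 * math.log(2 * math.pi * sigma_b**2) - bs**2 / (2 * sigma_b**2)
        m = lp.max()
        total += m + math.log(np.trapezoid(np.exp(lp - m), bs))
    return total


def irls_poisson(df, covariates, tol=1e-12, maxit=100):
    """Iteratively reweighted least squares for a Poisson GLM with log link
    and log person-time offset."""
    X = np.column_stack(
        [np.ones(len(df))] + [df[c].to_numpy(float) for c in covariates]
    )
    y = df["pah_count"].to_numpy(float)
    off = np.log(df["person_years"].to_numpy(float))
    beta = np.zeros(X.shape[1])
    for _ in range(maxit):
        mu = np.exp(X @ beta + off)
        z = X @ beta + (y - mu) / mu
        new = np.linalg.solve(X.T @ (mu[:, None] * X), X.T @ (mu * z))
        if np.max(np.abs(new - beta)) < tol:
            return new
        beta = new
    return beta
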