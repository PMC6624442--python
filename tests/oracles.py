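"""Independent numerical oracles used by the Bayes-factor tests.

These deliberately avoid the package's analytic marginalisation: the
conditional marginal is rebuilt by brute-force quadrature (Gauss-Hermite
over the effects, trapezoid over the grand mean and log error variance),
and the g integral by a dense tensor grid in log-g space.
"""

import numpy as np
from numpy.polynomial.hermite import hermgauss
from scipy.special import gammaln, logsumexp

from illusim.bayes import _conditional_logm, build_design


def gh_conditional_log_marginal(table, family_names, g_per_family,
                                gh_nodes=12, n_sigma=100, n_mu=101):
    """Brute-force log m(y | g) for a small table.

    Integrates the effect coefficients by tensor-product Gauss-Hermite
    (against their normal priors), the grand mean by trapezoid, and the
    error variance by trapezoid in log sigma^2 against the Jeffreys prior.
    """
    design = build_design(table)
    fams = [design.families[f] for f in family_names]
    x = np.hstack([f.x for f in fams])
    gs = np.concatenate(
        [np.full(f.p, g_per_family[f.name]) for f in fams]
    )
    yraw = table.to_wide().reshape(-1)
    n_obs = yraw.size
    p = x.shape[1]

    nodes, weights = hermgauss(gh_nodes)
    grids = np.meshgrid(*([nodes] * p), indexing="ij")
    wgrids = np.meshgrid(*([weights] * p), indexing="ij")
    xk = np.stack([m.ravel() for m in grids], axis=1)
    wk = np.prod(np.stack([m.ravel() for m in wgrids]), axis=0)

    sd = yraw.std()
    logs2 = np.linspace(np.log((0.05 * sd) ** 2), np.log((30 * sd) ** 2),
                        n_sigma)
    vals = []
    for ls2 in logs2:
        s2 = np.exp(ls2)
        s = np.sqrt(s2)
        theta = xk * np.sqrt(2.0 * s2 * gs)[None, :]
        resid = yraw[None, :] - theta @ x.T
        a = np.sum(resid**2, axis=1)
        b = np.sum(resid, axis=1)
        mu = np.linspace(yraw.mean() - 8 * s, yraw.mean() + 8 * s, n_mu)
        expo = -(
            a[:, None] - 2 * mu[None, :] * b[:, None] + n_obs * mu[None, :] ** 2
        ) / (2 * s2)
        m = np.max(expo)
        inner_mu = np.trapezoid(np.exp(expo - m), mu, axis=1)
        e_theta = np.pi ** (-p / 2) * np.sum(wk * inner_mu)
        vals.append(
            np.log(max(e_theta, 1e-300)) + m
            - (n_obs / 2) * np.log(2 * np.pi * s2)
        )
    vals = np.array(vals)
    mmax = vals.max()
    return float(np.log(np.trapezoid(np.exp(vals - mmax), logs2)) + mmax)


def grid_log_marginal(table, spec, n_points=401, z_lo=-18.0, z_hi=18.0):
    """Dense tensor-grid integration of the g prior times m(y | g).

    Works in z = log g with a fixed wide grid, independent of the
    package's mode-centred quadrature and importance sampler.
    """
    design = build_design(table)
    names = list(spec.families)
    r2 = np.array([spec.r_scale(f) ** 2 for f in names])
    axes = [np.linspace(z_lo, z_hi, n_points)] * len(names)
    mesh = np.meshgrid(*axes, indexing="ij")
    z = np.stack([m.ravel() for m in mesh], axis=1)
    g = np.exp(z)
    # scaled inverse chi-square(1, r^2) density on g, times Jacobian g
    log_prior = np.sum(
        0.5 * np.log(r2 / 2.0)
        - gammaln(0.5)
        - 0.5 * z
        - r2 / (2.0 * g),
        axis=1,
    )
    log_int = log_prior + _conditional_logm(design, names, g)
    step = axes[0][1] - axes[0][0]
    return float(logsumexp(log_int) + len(names) * np.log(step))


def grid_bayes_factor(table, alt_spec, null_spec, **kw):
    return np.exp(
        grid_log_marginal(table, alt_spec, **kw)
        - grid_log_marginal(table, null_spec, **kw)
    )
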