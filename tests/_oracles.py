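"""Brute-force reference implementations used only by the tests.

These were written before (and independently of) the package's quadrature
code: each computes the same Bayes factor through a different derivation or
a naive dense-grid integration, so agreement is a genuine two-route check.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import simpson
from scipy.special import gammaln
from scipy.stats import binom, cauchy, nct, t as t_dist


def jzs_bf01_gprior_trapezoid(t, df, n_eff, r, nodes=200_001):
    """JZS BF01 via the Zellner g-prior mixture representation.

    delta | g ~ N(0, g) with g ~ InverseGamma(1/2, r^2/2) is exactly the
    Cauchy(0, r) prior, and integrating delta and the variance analytically
    leaves a one-dimensional integral over g (Rouder et al.'s classic form):

        BF10 = Int_0^inf (1+N*g)^(-1/2)
               * [ (1 + t^2/v) / (1 + t^2/(v*(1+N*g))) ]^((v+1)/2)
               * pi(g) dg

    evaluated here by dense trapezoid on the compactifying substitution
    g = x/(1-x), x in (0,1), with the integrand assembled in log space.
    """
    x = np.linspace(1e-9, 1.0 - 1e-9, nodes)
    g = x / (1.0 - x)
    jac = 1.0 / (1.0 - x) ** 2
    log_prior = (
        0.5 * np.log(r**2 / 2.0)
        - gammaln(0.5)
        - 1.5 * np.log(g)
        - r**2 / (2.0 * g)
    )
    log_lik_ratio = -0.5 * np.log1p(n_eff * g) + 0.5 * (df + 1.0) * (
        np.log1p(t**2 / df) - np.log1p(t**2 / (df * (1.0 + n_eff * g)))
    )
    integrand = np.exp(log_prior + log_lik_ratio) * jac
    bf10 = np.trapezoid(integrand, x)
    return 1.0 / bf10


def jzs_bf01_delta_trapezoid(t, df, n_eff, r, lo=-15.0, hi=15.0, nodes=200_001):
    """JZS BF01 by dense trapezoid over the effect size delta.

    Directly integrates the noncentral-t sampling density (scipy's) against
    the Cauchy prior.  Only usable where scipy's boost-based density is
    stable (roughly df <= ~300 for the noncentralities reached here).
    """
    delta = np.linspace(lo, hi, nodes)
    like = nct.pdf(t, df, delta * np.sqrt(n_eff))
    prior = cauchy.pdf(delta, 0.0, r)
    marginal_h1 = np.trapezoid(like * prior, delta)
    return t_dist.pdf(t, df) / marginal_h1


def contingency_bf01_grid(n1, y1, n2, y2, null_beta_a=1.0, nodes=801):
    """2x2 table BF01 by naive grid integration.

    H1 marginal: genuine 2-D Simpson grid over (theta1, theta2) in (0,1)^2
    with independent Beta(1,1) (uniform) priors.  H0 marginal: 1-D Simpson
    over the shared rate with a Beta(a, a) prior — a=1 for the independent-
    binomial model, a=2 for the Gunel-Dickey independent-multinomial model
    (the column-collapsed Dirichlet prior of a unit-concentration 2x2 cell
    prior).
    """
    theta = np.linspace(0.0, 1.0, nodes)
    l1 = binom.pmf(y1, n1, theta)
    l2 = binom.pmf(y2, n2, theta)
    # H1: 2-D Simpson of the product surface (uniform priors)
    surface = np.outer(l1, l2)
    m1 = simpson(simpson(surface, x=theta, axis=1), x=theta)
    # H0: shared theta with Beta(a,a) prior
    a = null_beta_a
    log_norm = gammaln(2 * a) - 2 * gammaln(a)
    prior0 = np.exp(log_norm) * theta ** (a - 1) * (1 - theta) ** (a - 1)
    if a < 1:
        raise ValueError("grid oracle needs a >= 1 (integrable endpoints)")
    m0 = simpson(l1 * l2 * prior0, x=theta)
    return m0 / m1
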