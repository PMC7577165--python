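"""Independent oracles used by the tests.

Everything here deliberately avoids the package's vectorized kernels: the
concentration model is an explicit superposition loop over doses, posterior
modes come from scipy's simplex search, and the marginal likelihood is
adaptive Gauss-Hermite quadrature assembled from numpy's Hermite nodes.
"""

from __future__ import annotations

import numpy as np
from numpy.polynomial.hermite import hermgauss
from scipy import optimize


def conc_superposition(t_after_dose, n_doses, cl, v, ka, dose, tau):
    """Single-dose closed form summed dose by dose (the brute-force path)."""
    ke = cl / v
    total = 0.0
    for j in range(int(n_doses)):
        t = t_after_dose + j * tau
        if abs(ka - ke) < 1e-12 * ke:
            total += dose / v * ke * t * np.exp(-ke * t)
        else:
            total += dose * ka / (v * (ka - ke)) * (np.exp(-ke * t) - np.exp(-ka * t))
    return total


def conc_ss_superposition(t_after_dose, cl, v, ka, dose, tau, n_doses=400):
    """Steady state approximated by a long superposition."""
    return conc_superposition(t_after_dose, n_doses, cl, v, ka, dose, tau)


def subject_joint_nll(y, u, n_dose, cl_typ, v_typ, ka_typ, omega2, sigma_prop, dose, tau):
    """g(eta): negative log joint density of one subject's data and eta."""
    om2 = np.asarray(omega2, float)

    def g(eta):
        cl = cl_typ * np.exp(eta[0])
        v = v_typ * np.exp(eta[1])
        ka = ka_typ * np.exp(eta[2])
        f = np.array(
            [conc_superposition(u[k], n_dose[k], cl, v, ka, dose, tau) for k in range(len(y))]
        )
        var = (sigma_prop * f) ** 2
        res = 0.5 * np.sum((y - f) ** 2 / var + np.log(2 * np.pi * var))
        pri = 0.5 * np.sum(eta**2 / om2 + np.log(2 * np.pi * om2))
        return res + pri

    return g


def neg2ll_agq(model, design, subjects, age_ref, weight_ref, n_nodes=9):
    """-2 log marginal likelihood by 3-D adaptive Gauss-Hermite quadrature.

    `design` is the package's PKDesign (used only as a data container).
    """
    th = model.theta
    z, w = hermgauss(n_nodes)
    Z = np.array(np.meshgrid(z, z, z)).reshape(3, -1).T
    W = np.array(np.meshgrid(w, w, w)).reshape(3, -1).T.prod(axis=1)
    total = 0.0
    for i, s in enumerate(subjects):
        mask = design.sub_idx == i
        y, u, nd = design.y[mask], design.u[mask], design.n_dose[mask]
        cl_typ = th.tvcl * (s.age / age_ref) ** th.beta_age_cl
        v_typ = th.tvv * (s.weight / weight_ref) ** th.beta_wt_v
        if s.status == "hiv":
            v_typ *= th.beta_hiv_v
        g = subject_joint_nll(
            y, u, nd, cl_typ, v_typ, th.tvka, model.omega2, model.sigma_prop,
            design.dose, design.tau,
        )
        res = optimize.minimize(
            g, np.zeros(3), method="Nelder-Mead",
            options=dict(xatol=1e-9, fatol=1e-12, maxiter=4000, maxfev=6000),
        )
        eta0, g0 = res.x, res.fun
        h = 1e-4
        H = np.zeros((3, 3))
        for a in range(3):
            for b in range(3):
                ea = np.eye(3)[a] * h
                eb = np.eye(3)[b] * h
                H[a, b] = (g(eta0 + ea + eb) - g(eta0 + ea - eb) - g(eta0 - ea + eb)
                           + g(eta0 - ea - eb)) / (4 * h * h)
        L = np.linalg.cholesky(np.linalg.inv(H))
        integ = 0.0
        for k in range(len(Z)):
            eta = eta0 + np.sqrt(2.0) * L @ Z[k]
            integ += W[k] * np.exp(np.sum(Z[k] ** 2)) * np.exp(-(g(eta) - g0))
        log_li = -g0 + 1.5 * np.log(2.0) + np.log(abs(np.linalg.det(L))) + np.log(integ)
        total += -2.0 * log_li
    return total
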