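"""Independent numerical oracles used only by the test suite.

These deliberately avoid the package's closed-form prox operators and
ADMM updates: nonsmooth convex problems are rewritten exactly as smooth
NLPs via epigraph variables (t_ij >= |q_ij| through two linear
inequalities; s_l >= ||block||_2 through s_l^2 >= ||block||^2, s_l >= 0)
and solved with scipy's trust-constr, a generic constrained convex
solver.  Brute-force loop implementations of the norms follow their
definitions term by term.
"""

from __future__ import annotations

import warnings

import numpy as np
import scipy.sparse as sp
from scipy.optimize import LinearConstraint, NonlinearConstraint, minimize

OPTIONS = {"gtol": 1e-12, "xtol": 1e-14, "maxiter": 4000,
           "sparse_jacobian": False}


# ------------------------------------------------------- brute-force norms

def bf_norm_l21(theta):
    return sum(np.sqrt(sum(theta[j, m] ** 2 for m in range(theta.shape[1])))
               for j in range(theta.shape[0]))


def bf_norm_g21_common(theta, groups, weights):
    total = 0.0
    for g, w in zip(groups, weights):
        acc = 0.0
        for j in g:
            acc += sum(theta[j, m] ** 2 for m in range(theta.shape[1]))
        total += w * np.sqrt(acc)
    return total


def bf_norm_g21_specific(theta, groups, weights):
    total = 0.0
    for g, w in zip(groups, weights):
        for m in range(theta.shape[1]):
            total += w * np.sqrt(sum(theta[j, m] ** 2 for j in g))
    return total


def bf_norm_fused_lasso(theta):
    k = theta.shape[1]
    return sum(abs(theta[j, m] - theta[j, m + 1])
               for m in range(k - 1) for j in range(theta.shape[0]))


def bf_norm_gfl(theta, groups, weights, W):
    """Explicit double sum over tasks and groups of the fused deviations."""
    k = theta.shape[1]
    total = 0.0
    for t in range(k):
        for g, w in zip(groups, weights):
            dev = theta[g, t].astype(float).copy()
            for l in range(k):
                if l != t:
                    dev -= W[l, t] * theta[g, l]
            total += w * np.sqrt(np.sum(dev ** 2))
    return total


# -------------------------------------------------- epigraph NLP machinery

def _group_col_indices(groups, k):
    """Flat (row-major) indices of each group's rows, all columns."""
    return [np.concatenate([np.arange(j * k, (j + 1) * k) for j in g])
            for g in groups]


def _solve(fun, grad, z0, bounds, constraints):
    with warnings.catch_warnings():
        # quasi-Newton updates on the linear epigraph rows emit benign
        # delta_grad warnings; singular-Jacobian fallbacks are expected
        # at degenerate (zero-block) solutions
        warnings.simplefilter("ignore", UserWarning)
        res = minimize(fun, z0, jac=grad, method="trust-constr",
                       constraints=constraints, bounds=bounds,
                       options=OPTIONS)
    return res


def prox_sgl_oracle(x, tau1, tau2, groups, weights):
    """argmin_q 1/2||q-x||_F^2 + tau1||q||_1 + tau2 sum_l w_l||q_Gl||_F.

    Separable over groups.  Each group subproblem is solved three ways —
    the zero block, an epigraph trust-constr solve, and a smooth L-BFGS
    polish on the support/orthant found by trust-constr — and the
    candidate with the lowest true objective wins.
    """
    out = np.zeros_like(x, dtype=float)
    for g, w in zip(groups, weights):
        out[g, :] = _sgl_group_prox(x[g, :].astype(float), tau1, tau2 * w)
    return out


def _sgl_group_prox(xb, tau1, r):
    """min over q of 1/2||q - xb||^2 + tau1||q||_1 + r||q||_F (one group)."""
    shape = xb.shape
    xf = xb.ravel()
    m = xf.size

    def f_true(qf):
        return (0.5 * np.sum((qf - xf) ** 2) + tau1 * np.abs(qf).sum()
                + r * np.linalg.norm(qf))

    candidates = [np.zeros(m)]

    # epigraph NLP: variables (q, t, s)
    nv = 2 * m + 1

    def fun(z):
        return (0.5 * np.sum((z[:m] - xf) ** 2) + tau1 * z[m:2 * m].sum()
                + r * z[-1])

    def grad(z):
        g = np.empty(nv)
        g[:m] = z[:m] - xf
        g[m:2 * m] = tau1
        g[-1] = r
        return g

    I = sp.eye(m)
    A = sp.hstack([sp.bmat([[-I, I], [I, I]]),
                   sp.csr_matrix((2 * m, 1))]).toarray()
    lin = LinearConstraint(A, 0, np.inf)

    def cfun(z):
        return np.array([z[-1] ** 2 - np.sum(z[:m] ** 2)])

    def cjac(z):
        J = np.zeros((1, nv))
        J[0, :m] = -2 * z[:m]
        J[0, -1] = 2 * z[-1]
        return J

    nl = NonlinearConstraint(cfun, 0, np.inf, jac=cjac)
    z0 = np.concatenate([xf, np.abs(xf) + 0.1, [np.linalg.norm(xf) + 0.1]])
    bounds = [(None, None)] * m + [(0, None)] * (m + 1)
    res = _solve(fun, grad, z0, bounds, [lin, nl])
    q_tc = res.x[:m]
    candidates.append(q_tc)

    # polish: fix the support and signs seen by trust-constr, minimize the
    # then-smooth objective, re-checking against the true objective
    eps = 1e-7 * max(1.0, np.abs(xf).max())
    support = np.abs(q_tc) > eps
    if support.any():
        signs = np.sign(q_tc[support])
        base = 0.5 * np.sum(xf[~support] ** 2)

        def fg(qs):
            nrm = np.linalg.norm(qs)
            val = (base + 0.5 * np.sum((qs - xf[support]) ** 2)
                   + tau1 * signs @ qs + r * nrm)
            grad = (qs - xf[support]) + tau1 * signs
            if nrm > 0:
                grad = grad + r * qs / nrm
            return val, grad

        pol = minimize(fg, q_tc[support], jac=True, method="L-BFGS-B",
                       options={"maxiter": 500, "ftol": 1e-18, "gtol": 1e-14})
        q_pol = np.zeros(m)
        q_pol[support] = pol.x
        candidates.append(q_pol)

    best = min(candidates, key=f_true)
    return best.reshape(shape)


def prox_gfl_oracle(z_in, tau, groups, weights):
    """argmin_g 1/2||g-z||_F^2 + tau sum_{l,t} w_l ||g[G_l, t]||_2.

    The objective separates over (group, task) blocks.  Each block's
    subproblem ``1/2||g - z_b||^2 + r||g||_2`` is solved by L-BFGS (the
    norm is smooth wherever g != 0) and the result is compared, by
    objective value, against the candidate g = 0; strong convexity turns
    an objective gap d into a solution error of at most sqrt(2 d).
    """
    out = np.zeros_like(z_in, dtype=float)
    k = z_in.shape[1]
    for g, w in zip(groups, weights):
        for t in range(k):
            zb = z_in[g, t].astype(float)
            out[g, t] = _block_norm_prox(zb, tau * w)
    return out


def _block_norm_prox(zb, r):
    def f(v):
        return 0.5 * np.sum((v - zb) ** 2) + r * np.linalg.norm(v)

    def fg(v):
        nrm = np.linalg.norm(v)
        grad = (v - zb) + (r * v / nrm if nrm > 0 else 0.0)
        return f(v), grad

    best_v, best_f = np.zeros_like(zb), f(np.zeros_like(zb))
    for start in (zb, 0.5 * zb):
        if np.linalg.norm(start) == 0:
            continue
        res = minimize(fg, start, jac=True, method="L-BFGS-B",
                       options={"maxiter": 500, "ftol": 1e-18, "gtol": 1e-14})
        if f(res.x) < best_f:
            best_v, best_f = res.x, f(res.x)
    return best_v


def full_objective_oracle(X, Y, mask, D, groups, weights,
                          lam1, lam2, lam3):
    """Optimal value of the full penalized objective, via trust-constr.

    min_T 1/2||mask.(Y - X T)||_F^2 + lam1||T||_1
          + lam2 sum_l w_l ||T[G_l,:]||_F
          + lam3 sum_{l,t} w_l ||(T D)[G_l,t]||_2
    """
    n, p = X.shape
    k = Y.shape[1]
    pk = p * k
    q = len(groups)
    weights = np.asarray(weights, float)
    obs = mask.astype(bool)
    Y0 = np.where(obs, Y, 0.0)

    nv = 2 * pk + q + q * k  # theta, t_abs, s_common, s_fused

    def unpack(z):
        return (z[:pk].reshape(p, k), z[pk:2 * pk],
                z[2 * pk:2 * pk + q], z[2 * pk + q:])

    def fun(z):
        T, tb, sc, sf = unpack(z)
        R = np.where(obs, Y0 - X @ T, 0.0)
        return (0.5 * np.sum(R * R) + lam1 * tb.sum()
                + lam2 * weights @ sc
                + lam3 * np.repeat(weights, k) @ sf)

    def grad(z):
        T, tb, sc, sf = unpack(z)
        R = np.where(obs, Y0 - X @ T, 0.0)
        g = np.empty(nv)
        g[:pk] = (-X.T @ R).ravel()
        g[pk:2 * pk] = lam1
        g[2 * pk:2 * pk + q] = lam2 * weights
        g[2 * pk + q:] = lam3 * np.repeat(weights, k)
        return g

    I = sp.eye(pk)
    A = sp.hstack([sp.bmat([[-I, I], [I, I]]),
                   sp.csr_matrix((2 * pk, q + q * k))])
    lin = LinearConstraint(A.toarray(), 0, np.inf)

    gidx = _group_col_indices(groups, k)
    fidx = [(l, t) for l in range(q) for t in range(k)]

    def cfun(z):
        T, _, sc, sf = unpack(z)
        TD = T @ D
        out = np.empty(q + q * k)
        for l in range(q):
            out[l] = sc[l] ** 2 - np.sum(T[groups[l], :] ** 2)
        for b, (l, t) in enumerate(fidx):
            out[q + b] = sf[b] ** 2 - np.sum(TD[groups[l], t] ** 2)
        return out

    def cjac(z):
        T, _, sc, sf = unpack(z)
        TD = T @ D
        J = np.zeros((q + q * k, nv))
        for l in range(q):
            Jt = np.zeros((p, k))
            Jt[groups[l], :] = -2 * T[groups[l], :]
            J[l, :pk] = Jt.ravel()
            J[l, 2 * pk + l] = 2 * sc[l]
        for b, (l, t) in enumerate(fidx):
            # d/dT of -||(T D)[G_l, t]||^2 = -2 (TD)[G_l,t] outer D[:,t]
            Jt = np.zeros((p, k))
            Jt[np.ix_(groups[l], range(k))] = \
                -2 * np.outer(TD[groups[l], t], D[:, t])
            J[q + b, :pk] = Jt.ravel()
            J[q + b, 2 * pk + q + b] = 2 * sf[b]
        return J

    nl = NonlinearConstraint(cfun, 0, np.inf, jac=cjac)
    # warm start at masked ridge
    T0 = np.column_stack([
        np.linalg.solve(X[obs[:, t]].T @ X[obs[:, t]] + 1e-3 * np.eye(p),
                        X[obs[:, t]].T @ Y0[obs[:, t], t])
        for t in range(k)])
    TD0 = T0 @ D
    z0 = np.concatenate([
        T0.ravel(), np.abs(T0).ravel() + 0.05,
        [np.linalg.norm(T0[g, :]) + 0.05 for g in groups],
        [np.linalg.norm(TD0[groups[l], t]) + 0.05 for l, t in fidx]])
    bounds = [(None, None)] * pk + [(0, None)] * (pk + q + q * k)
    res = _solve(fun, grad, z0, bounds, [lin, nl])
    T, tb, sc, sf = unpack(res.x)
    # report the true objective at the solver's theta (epigraph slack-free)
    TD = T @ D
    val = 0.5 * np.sum(np.where(obs, Y0 - X @ T, 0.0) ** 2)
    val += lam1 * np.abs(T).sum()
    val += lam2 * sum(w * np.linalg.norm(T[g, :])
                      for g, w in zip(groups, weights))
    val += lam3 * sum(w * np.linalg.norm(TD[g, t])
                      for g, w in zip(groups, weights) for t in range(k))
    return val, T


def numeric_grad(f, x, eps=1e-6):
    """Central finite-difference gradient of a scalar function on an array."""
    g = np.zeros_like(x, dtype=float)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        i = it.multi_index
        x0 = x[i]
        x[i] = x0 + eps
        fp = f(x)
        x[i] = x0 - eps
        fm = f(x)
        x[i] = x0
        g[i] = (fp - fm) / (2 * eps)
        it.iternext()
    return g
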