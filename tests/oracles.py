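"""Independent numerical oracles for the closed-form update tests.

Everything here is written directly from the sub-problem definitions (explicit
Frobenius norms) and never calls into the package's update formulas, so it can
arbitrate them.
"""

import numpy as np


def frob2(M):
    return float(np.sum(np.asarray(M) ** 2))


def sub_objective_W(W, stats_prev, X, V, alpha, delta):
    past = (
        np.trace(stats_prev.C3)
        - 2 * np.sum(W * stats_prev.C2)
        + np.sum(W * (stats_prev.C1 @ W))
    )
    return alpha * (past + frob2(V - X.T @ W)) + delta * frob2(W)


def sub_objective_G(G, stats_prev, X, V, beta, delta):
    past = (
        np.trace(stats_prev.C1)
        - 2 * np.sum(G * stats_prev.C2)
        + np.sum((G.T @ G) * stats_prev.C3)
    )
    return beta * (past + frob2(X - G @ V.T)) + delta * frob2(G)


def sub_objective_R(R, V, A, H, gamma, theta):
    return theta * frob2(R - V) + gamma * frob2(A - H @ R.T)


def sub_objective_V(V, X, W, G, R, S, V_mem, alpha, beta, theta, eta):
    val = alpha * frob2(V - X.T @ W) + beta * frob2(X - G @ V.T) + theta * frob2(R - V)
    if V_mem is not None and V_mem.shape[0] > 0 and eta > 0:
        val += eta * frob2(S - V_mem @ V.T)
    return val


def numeric_gradient(f, M, h=1e-5):
    """Central differences; exact for quadratics up to roundoff."""
    M = np.asarray(M, dtype=float)
    g = np.zeros_like(M)
    it = np.nditer(M, flags=["multi_index"])
    while not it.finished:
        idx = it.multi_index
        Mp, Mm = M.copy(), M.copy()
        Mp[idx] += h
        Mm[idx] -= h
        g[idx] = (f(Mp) - f(Mm)) / (2 * h)
        it.iternext()
    return g


def iterative_minimizer(f, shape, x0=None, maxiter=None):
    """Independent iterative quadratic solver on the explicit sub-objective.

    The gradient of a quadratic f is affine, g(x) = A x - b, and central
    differences recover it exactly (third derivatives vanish), so conjugate
    gradients on the probed gradient minimize f to machine precision without
    touching any closed-form solution.
    """
    dim = int(np.prod(shape))

    # central differences carry no truncation error on a quadratic, so a
    # large step minimizes floating-point cancellation
    def grad(v):
        return numeric_gradient(f, v.reshape(shape), h=1e-2).ravel()

    g0 = grad(np.zeros(dim))
    b = -g0
    x = np.zeros(dim) if x0 is None else np.asarray(x0, dtype=float).ravel().copy()
    r = b - (grad(x) - g0) if x.any() else b.copy()
    p = r.copy()
    rs = r @ r
    for _ in range(maxiter or 2 * dim):
        Ap = grad(p) - g0
        denom = p @ Ap
        if denom <= 0 or rs == 0:
            break
        alpha = rs / denom
        x += alpha * p
        r -= alpha * Ap
        rs_new = r @ r
        if np.sqrt(rs_new) < 1e-13 * (1 + np.linalg.norm(b)):
            break
        p = r + (rs_new / rs) * p
        rs = rs_new
    return x.reshape(shape)
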