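"""Independent brute-force reference implementation used by the tests.

Everything here is written from the model definition with plain dense
linear algebra (explicit inverses and pseudo-inverses, elementwise
loops where that is the most literal transcription), deliberately
avoiding the package's factorization/identity shortcuts, so it can act
as an oracle for both engines.
"""

from __future__ import annotations

import numpy as np


def naive_grm(T: np.ndarray) -> np.ndarray:
    """Double-loop Gram matrix sum_i t_ai t_bi."""
    q, m = T.shape
    G = np.zeros((q, q))
    for a in range(q):
        for b in range(q):
            G[a, b] = sum(T[a, i] * T[b, i] for i in range(m))
    return G


def naive_V(theta, Z, Ag, Dg):
    sa, sd, se = theta
    return sa * Z @ Ag @ Z.T + sd * Z @ Dg @ Z.T + se * np.eye(Z.shape[0])


def naive_P(V, X):
    Vinv = np.linalg.inv(V)
    return Vinv - Vinv @ X @ np.linalg.pinv(X.T @ Vinv @ X) @ X.T @ Vinv


def naive_logL(theta, Z, Ag, Dg, X, y):
    """Restricted log-likelihood -1/2 [log|V| + log|X'V^-1 X|+ + y'Py]."""
    V = naive_V(theta, Z, Ag, Dg)
    P = naive_P(V, X)
    _, logdetV = np.linalg.slogdet(V)
    XtVinvX = X.T @ np.linalg.inv(V) @ X
    w = np.linalg.eigvalsh(XtVinvX)
    w = w[w > 1e-10 * max(w.max(), 0.0)]
    logdetXVX = float(np.sum(np.log(w)))
    return -0.5 * (logdetV + logdetXVX + float(y @ P @ y))


def naive_quadratics(theta, Z, Ag, Dg, X, y):
    """(yPHPy, trPH, AI, logL) from explicit matrix products."""
    V = naive_V(theta, Z, Ag, Dg)
    P = naive_P(V, X)
    H = [Z @ Ag @ Z.T, Z @ Dg @ Z.T, np.eye(len(y))]
    Py = P @ y
    yPHPy = np.array([float(Py @ Hi @ Py) for Hi in H])
    trPH = np.array([float(np.trace(P @ Hi)) for Hi in H])
    AI = np.zeros((3, 3))
    for i in range(3):
        for j in range(3):
            AI[i, j] = 0.5 * float((H[i] @ Py) @ P @ (H[j] @ Py))
    return yPHPy, trPH, AI, naive_logL(theta, Z, Ag, Dg, X, y)


def naive_em_step(theta, Z, Ag, Dg, X, y, m):
    yPHPy, trPH, _, _ = naive_quadratics(theta, Z, Ag, Dg, X, y)
    n = np.array([m, m, len(y)], dtype=float)
    theta = np.asarray(theta, dtype=float)
    return theta + theta**2 * (yPHPy - trPH) / n


def naive_ai_step(theta, Z, Ag, Dg, X, y):
    yPHPy, trPH, AI, _ = naive_quadratics(theta, Z, Ag, Dg, X, y)
    s = 0.5 * (yPHPy - trPH)
    return np.asarray(theta, dtype=float) + np.linalg.solve(AI, s)


def naive_gblup(theta, Z, Ag, Dg, X, y):
    """(a_hat, d_hat) = (sigma2_a Ag Z'Py, sigma2_d Dg Z'Py)."""
    sa, sd, _ = theta
    P = naive_P(naive_V(theta, Z, Ag, Dg), X)
    ZtPy = Z.T @ P @ y
    return sa * Ag @ ZtPy, sd * Dg @ ZtPy


def naive_snp_effects(theta, Z, Ta, Td, Ag, Dg, X, y):
    sa, sd, _ = theta
    P = naive_P(naive_V(theta, Z, Ag, Dg), X)
    ZtPy = Z.T @ P @ y
    return sa * Ta.T @ ZtPy, sd * Td.T @ ZtPy


def naive_snp_variances(theta, Z, Ta, Td, Ag, Dg, X, y):
    """Per-SNP variance contributions via explicit t_i' Z'PZ t_i."""
    sa, sd, _ = theta
    m = Ta.shape[1]
    P = naive_P(naive_V(theta, Z, Ag, Dg), X)
    alpha, delta = naive_snp_effects(theta, Z, Ta, Td, Ag, Dg, X, y)
    ZtPZ = Z.T @ P @ Z
    s2a = np.array([
        (alpha[i] ** 2 + sa - sa**2 * float(Ta[:, i] @ ZtPZ @ Ta[:, i])) / m
        for i in range(m)
    ])
    s2d = np.array([
        (delta[i] ** 2 + sd - sd**2 * float(Td[:, i] @ ZtPZ @ Td[:, i])) / m
        for i in range(m)
    ])
    return s2a, s2d
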