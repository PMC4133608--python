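"""Engine-agnostic REML driver for the additive + dominance model.

The driver never touches V or the mixed-model equations directly: an
engine (CE or QM formulation) supplies, for any variance-component
vector theta = (sigma2_a, sigma2_d, sigma2_e), the quadratic forms

    yPHPy_i = y' P H_i P y          H_a = Z A_g Z', H_d = Z D_g Z', H_e = I
    trPH_i  = tr(P H_i)
    AI_ij   = 1/2 (H_i P y)' P (H_j P y)      (average-information matrix)
    logL    = -1/2 [ log|V| + log|X' V^-1 X| + y' P y ]

From these the EM-REML and AI-REML updates are

    EM:  sigma2_i' = sigma2_i + sigma2_i^2 (yPHPy_i - trPH_i) / n_i
         with n_a = n_d = m (marker-effect space) and n_e = N
    AI:  theta' = theta + AI^-1 s,  s_i = 1/2 (yPHPy_i - trPH_i)

Both updates share the REML score s, so the EM fixed point
yPHPy_i = trPH_i and the AI stationary point s = 0 coincide.

The hybrid scheme runs at least two EM warm-start iterations (EM is
slow but cannot leave the parameter space), then switches to AI; an AI
step that produces a negative component or meets a numerically singular
AI matrix is discarded and replaced by an EM step for that iteration,
and after five consecutive AI failures the run finishes EM-only.  All
components are floored at 1e-10 of their sum so V and the mixed-model
equations stay nonsingular.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Protocol

import numpy as np

__all__ = [
    "VarianceComponents",
    "RemlQuadratics",
    "IterationRecord",
    "Heritabilities",
    "RemlEngine",
    "AI_FAILURE",
    "FLOOR_FRACTION",
    "em_step",
    "ai_step",
    "hybrid_driver",
    "standard_errors",
    "heritabilities",
]

#: components are floored at FLOOR_FRACTION * (sigma2_a+sigma2_d+sigma2_e)
FLOOR_FRACTION = 1e-10

#: AI matrices with condition number above this are treated as singular
AI_CONDITION_LIMIT = 1e12

#: after this many consecutive AI failures the driver finishes EM-only
MAX_CONSECUTIVE_AI_FAILURES = 5

AI_FAILURE = object()


@dataclass(frozen=True)
class VarianceComponents:
    sigma2_a: float
    sigma2_d: float
    sigma2_e: float
    se_a: float | None = None
    se_d: float | None = None
    se_e: float | None = None

    def as_array(self) -> np.ndarray:
        return np.array([self.sigma2_a, self.sigma2_d, self.sigma2_e])

    @staticmethod
    def from_array(theta: np.ndarray, **kw) -> "VarianceComponents":
        return VarianceComponents(float(theta[0]), float(theta[1]), float(theta[2]), **kw)

    @property
    def total(self) -> float:
        return self.sigma2_a + self.sigma2_d + self.sigma2_e


@dataclass(frozen=True)
class RemlQuadratics:
    """Quadratic forms at one theta, ordered (additive, dominance, residual)."""

    yPHPy: np.ndarray   # length 3
    trPH: np.ndarray    # length 3
    AI: np.ndarray      # 3 x 3
    logL: float

    @property
    def score(self) -> np.ndarray:
        return 0.5 * (self.yPHPy - self.trPH)


@dataclass(frozen=True)
class IterationRecord:
    index: int
    algorithm: str          # em | ai | ai_fallback_em
    theta: VarianceComponents
    logL: float
    conv: float


@dataclass(frozen=True)
class Heritabilities:
    h2_alpha: float
    h2_delta: float
    H2: float
    se_h2_alpha: float | None
    se_h2_delta: float | None
    se_H2: float | None
    sigma2_p: float


class RemlEngine(Protocol):
    """Contract every REML engine implements."""

    n_markers: int
    n_records: int
    rank_X: int

    def quadratics(self, theta: np.ndarray) -> RemlQuadratics: ...


def _floor(theta: np.ndarray, ref_total: float | None = None) -> np.ndarray:
    total = float(np.sum(theta)) if ref_total is None else ref_total
    return np.maximum(theta, FLOOR_FRACTION * total)


def em_step(
    theta: np.ndarray,
    quad: RemlQuadratics,
    n_divisors: tuple[int, int, int],
) -> np.ndarray:
    """One EM-REML update; always stays in the parameter space."""
    n = np.asarray(n_divisors, dtype=float)
    new = theta + theta**2 * (quad.yPHPy - quad.trPH) / n
    return _floor(new, float(np.sum(theta)))


def ai_step(theta: np.ndarray, quad: RemlQuadratics):
    """One AI-REML (quasi-Newton) update, or AI_FAILURE.

    Failure is signalled when the AI matrix is numerically singular or
    the proposed step leaves the parameter space.
    """
    AI = quad.AI
    if not np.all(np.isfinite(AI)) or np.linalg.cond(AI) > AI_CONDITION_LIMIT:
        return AI_FAILURE
    new = theta + np.linalg.solve(AI, quad.score)
    if np.any(new < 0):
        return AI_FAILURE
    return _floor(new, float(np.sum(theta)))


@dataclass
class RemlResult:
    components: VarianceComponents
    heritabilities: Heritabilities
    records: list[IterationRecord]
    converged: bool
    final_quadratics: RemlQuadratics
    em_only_triggered: bool

    @property
    def n_iterations(self) -> int:
        return len(self.records)


def _conv_measure(old: np.ndarray, new: np.ndarray) -> float:
    return float(np.sum((new - old) ** 2) / np.sum(new**2))


def hybrid_driver(
    engine: RemlEngine,
    y: np.ndarray,
    em_iterations: int = 2,
    max_iterations: int = 200,
    tolerance: float = 1e-8,
    init: tuple[float, float, float] | str = "auto",
    algorithm: str = "hybrid",
) -> RemlResult:
    """Run hybrid EM/AI REML (or pure EM with ``algorithm='em'``).

    Stops when the squared relative change of the component vector,
    sum((theta' - theta)^2) / sum(theta'^2), drops below ``tolerance``
    or ``max_iterations`` is reached (result then carries
    ``converged=False``).
    """
    if em_iterations < 2:
        raise ValueError("em_iterations must be >= 2")
    if algorithm not in ("hybrid", "em"):
        raise ValueError(f"unknown algorithm '{algorithm}'")
    m, N = engine.n_markers, engine.n_records
    divisors = (m, m, N)
    if init == "auto":
        v = float(np.var(y, ddof=1))
        theta = np.array([v / 3.0, v / 3.0, v / 3.0])
    else:
        theta = np.asarray(init, dtype=float)
        if theta.shape != (3,) or np.any(theta <= 0):
            raise ValueError("init variances must be three positive values")
    theta = _floor(theta)

    records: list[IterationRecord] = []
    quad = engine.quadratics(theta)
    consecutive_failures = 0
    em_only = algorithm == "em"
    em_only_triggered = False
    converged = False

    for it in range(1, max_iterations + 1):
        use_em = em_only or it <= em_iterations
        if use_em:
            tag = "em"
            theta_new = em_step(theta, quad, divisors)
        else:
            proposal = ai_step(theta, quad)
            if proposal is AI_FAILURE:
                tag = "ai_fallback_em"
                theta_new = em_step(theta, quad, divisors)
                consecutive_failures += 1
                if consecutive_failures >= MAX_CONSECUTIVE_AI_FAILURES:
                    em_only = True
                    em_only_triggered = True
            else:
                tag = "ai"
                theta_new = proposal
                consecutive_failures = 0
        conv = _conv_measure(theta, theta_new)
        quad = engine.quadratics(theta_new)
        records.append(
            IterationRecord(it, tag, VarianceComponents.from_array(theta_new), quad.logL, conv)
        )
        theta = theta_new
        if conv < tolerance:
            converged = True
            break

    ses = standard_errors(quad.AI)
    comps = VarianceComponents.from_array(theta, se_a=ses[0], se_d=ses[1], se_e=ses[2])
    h2 = heritabilities(comps, quad.AI)
    return RemlResult(comps, h2, records, converged, quad, em_only_triggered)


def standard_errors(AI: np.ndarray) -> tuple[float | None, float | None, float | None]:
    """Asymptotic standard errors: sqrt of the diagonal of AI^-1.

    A numerically singular AI matrix yields (None, None, None) with a
    warning, mirroring runs that never left EM.
    """
    if not np.all(np.isfinite(AI)) or np.linalg.cond(AI) > AI_CONDITION_LIMIT:
        import warnings

        warnings.warn("AI matrix singular: standard errors unavailable", stacklevel=2)
        return None, None, None
    cov = np.linalg.inv(AI)
    diag = np.diag(cov)
    if np.any(diag < 0):
        import warnings

        warnings.warn("AI inverse has negative diagonal: standard errors unavailable",
                      stacklevel=2)
        return None, None, None
    se = np.sqrt(diag)
    return float(se[0]), float(se[1]), float(se[2])


def heritabilities(theta: VarianceComponents, AI: np.ndarray | None) -> Heritabilities:
    """Point estimates and delta-method standard errors of h2_alpha =
    sigma2_a / sigma2_p, h2_delta = sigma2_d / sigma2_p and their sum H2
    (sigma2_p = sigma2_a + sigma2_d + sigma2_e)."""
    sa, sd, se_ = theta.sigma2_a, theta.sigma2_d, theta.sigma2_e
    sp = sa + sd + se_
    h2a, h2d = sa / sp, sd / sp
    se_h2a = se_h2d = se_H2 = None
    if AI is not None and np.all(np.isfinite(AI)) and np.linalg.cond(AI) <= AI_CONDITION_LIMIT:
        cov = np.linalg.inv(AI)
        if np.all(np.diag(cov) >= 0):
            g_a = np.array([sd + se_, -sa, -sa]) / sp**2
            g_d = np.array([-sd, sa + se_, -sd]) / sp**2
            g_H = np.array([se_, se_, -(sa + sd)]) / sp**2
            def _se(g):
                v = float(g @ cov @ g)
                return float(np.sqrt(v)) if v >= 0 else None
            se_h2a, se_h2d, se_H2 = _se(g_a), _se(g_d), _se(g_H)
    return Heritabilities(
        h2_alpha=float(h2a),
        h2_delta=float(h2d),
        H2=float(h2a + h2d),
        se_h2_alpha=se_h2a,
        se_h2_delta=se_h2d,
        se_H2=se_H2,
        sigma2_p=float(sp),
    )
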