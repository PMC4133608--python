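"""CE-formulation engine: dense V and P in the record (individual)
dimension.

The model is y = X b + Z a + Z d + e with a ~ N(0, sigma2_a A_g),
d ~ N(0, sigma2_d D_g), so

    V = sigma2_a Z A_g Z' + sigma2_d Z D_g Z' + sigma2_e I
    P = V^-1 - V^-1 X (X' V^-1 X)^- X' V^-1

Every quadratic the REML driver needs is an O(N^3) dense computation
independent of the number of markers once A_g and D_g are formed, which
is why this route wins when markers far outnumber individuals
(2m > q).  (X'V^-1 X)^- is a pseudo-inverse so rank-deficient
fixed-effect designs are handled without reparameterization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .model_matrices import GrmPair, ModelMatrices
from .reml_core import RemlQuadratics

__all__ = ["CeEngine", "GblupResult", "SnpEffectTable", "logpdet_psd"]

#: eigenvalues below cutoff * max are treated as zero in pseudo-determinants
PDET_CUTOFF = 1e-10


@dataclass
class GblupResult:
    """Per-individual genomic predictions with reliabilities."""

    individual_ids: list[str]
    sets: list[str]          # training | validation
    a_hat: np.ndarray        # breeding values
    rel_a: np.ndarray
    d_hat: np.ndarray        # dominance deviations
    rel_d: np.ndarray
    g_hat: np.ndarray        # genotypic values a_hat + d_hat
    rel_g: np.ndarray


@dataclass
class SnpEffectTable:
    """Per-SNP effects, variance contributions and heritabilities."""

    marker_ids: list[str]
    alpha_hat: np.ndarray
    delta_hat: np.ndarray
    sigma2_alpha_i: np.ndarray
    sigma2_delta_i: np.ndarray
    h2_alpha_i: np.ndarray
    h2_delta_i: np.ndarray


def logpdet_psd(M: np.ndarray, cutoff: float = PDET_CUTOFF) -> tuple[float, int]:
    """Log pseudo-determinant and rank of a symmetric PSD matrix."""
    w = linalg.eigvalsh(0.5 * (M + M.T))
    keep = w > cutoff * max(w.max(), 0.0) if w.size else w > 0
    return float(np.sum(np.log(w[keep]))), int(keep.sum())


class CeEngine:
    """REML engine on the individual-dimension (V, P) formulation."""

    def __init__(self, mm: ModelMatrices, grm: GrmPair, y: np.ndarray):
        self.mm = mm
        self.grm = grm
        self.y = np.asarray(y, dtype=float)
        idx = mm.train_idx
        # H_a = Z A_g Z' and H_d = Z D_g Z' restricted to training records
        self.HA = grm.A_g[np.ix_(idx, idx)]
        self.HD = grm.D_g[np.ix_(idx, idx)]
        self.n_markers = mm.n_markers
        self.n_records = mm.n_records
        self.rank_X = mm.rank_X
        self._cache_theta: tuple | None = None
        self._state: dict | None = None

    # -- state ---------------------------------------------------------

    def _factor(self, theta: np.ndarray) -> dict:
        """Build V, V^-1, P and log-determinants at theta (cached)."""
        key = tuple(np.asarray(theta, dtype=float))
        if self._cache_theta == key:
            return self._state
        sa, sd, se = key
        N = self.n_records
        X = self.mm.X
        V = sa * self.HA + sd * self.HD + se * np.eye(N)
        c, low = linalg.cho_factor(V, lower=True)
        logdetV = 2.0 * float(np.sum(np.log(np.diag(c))))
        Vinv = linalg.cho_solve((c, low), np.eye(N))
        VinvX = Vinv @ X
        XtVinvX = X.T @ VinvX
        logdetXVX, _ = logpdet_psd(XtVinvX)
        XtVinvX_pinv = linalg.pinvh(XtVinvX)
        P = Vinv - VinvX @ XtVinvX_pinv @ VinvX.T
        P = 0.5 * (P + P.T)
        Py = P @ self.y
        state = {
            "theta": key, "V": V, "Vinv": Vinv, "P": P, "Py": Py,
            "logdetV": logdetV, "logdetXVX": logdetXVX,
        }
        self._cache_theta = key
        self._state = state
        return state

    # -- engine contract -----------------------------------------------

    def quadratics(self, theta: np.ndarray) -> RemlQuadratics:
        st = self._factor(theta)
        P, Py = st["P"], st["Py"]
        f = [self.HA @ Py, self.HD @ Py, Py]          # H_i P y
        yPHPy = np.array([float(Py @ fi) for fi in f])
        trPH = np.array([
            float(np.sum(P * self.HA)),
            float(np.sum(P * self.HD)),
            float(np.trace(P)),
        ])
        Pf = [P @ fi for fi in f]
        AI = 0.5 * np.array([[float(f[i] @ Pf[j]) for j in range(3)] for i in range(3)])
        AI = 0.5 * (AI + AI.T)
        logL = -0.5 * (st["logdetV"] + st["logdetXVX"] + float(self.y @ Py))
        return RemlQuadratics(yPHPy=yPHPy, trPH=trPH, AI=AI, logL=logL)

    def apply_P(self, v: np.ndarray) -> np.ndarray:
        if self._state is None:
            raise RuntimeError("apply_P requires a prior quadratics() call")
        return self._state["P"] @ v

    # -- predictions ----------------------------------------------------

    def gblup(self, theta: np.ndarray, training_ids: set[str] | None = None) -> GblupResult:
        """GBLUP of breeding values, dominance deviations and genotypic
        values with reliabilities, for training and validation
        individuals alike."""
        st = self._factor(theta)
        sa, sd, _ = st["theta"]
        P, Py = st["P"], st["Py"]
        mm, grm = self.mm, self.grm
        idx = mm.train_idx
        q = mm.n_individuals
        ZtPy = np.zeros(q)
        np.add.at(ZtPy, idx, Py)
        a_hat = sa * (grm.A_g @ ZtPy)
        d_hat = sd * (grm.D_g @ ZtPy)

        QA = grm.A_g[:, idx]                  # q x N
        QD = grm.D_g[:, idx]
        PA = P @ QA.T                          # N x q
        PD = P @ QD.T
        var_a = sa**2 * np.einsum("qn,nq->q", QA, PA)
        var_d = sd**2 * np.einsum("qn,nq->q", QD, PD)
        cov_ad = sa * sd * np.einsum("qn,nq->q", QA, PD)
        diag_A = np.diag(grm.A_g)
        diag_D = np.diag(grm.D_g)
        with np.errstate(divide="ignore", invalid="ignore"):
            rel_a = np.where(diag_A > 0, var_a / (sa * diag_A), 0.0)
            rel_d = np.where(diag_D > 0, var_d / (sd * diag_D), 0.0)
            denom_g = sa * diag_A + sd * diag_D
            rel_g = np.where(denom_g > 0, (var_a + var_d + 2.0 * cov_ad) / denom_g, 0.0)
        train = set(np.asarray(mm.individual_ids)[idx]) if training_ids is None else training_ids
        sets = ["training" if ind in train else "validation" for ind in mm.individual_ids]
        return GblupResult(
            individual_ids=list(mm.individual_ids), sets=sets,
            a_hat=a_hat, rel_a=rel_a, d_hat=d_hat, rel_d=rel_d,
            g_hat=a_hat + d_hat, rel_g=rel_g,
        )

    def snp_effects(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Back-solved marker effects alpha_hat = sigma2_a T_alpha' Z' P y
        and delta_hat = sigma2_d T_delta' Z' P y."""
        st = self._factor(theta)
        sa, sd, _ = st["theta"]
        Py = st["Py"]
        idx = self.mm.train_idx
        q = self.mm.n_individuals
        ZtPy = np.zeros(q)
        np.add.at(ZtPy, idx, Py)
        alpha_hat = sa * (self.mm.T_alpha.T @ ZtPy)
        delta_hat = sd * (self.mm.T_delta.T @ ZtPy)
        return alpha_hat, delta_hat

    def snp_variances(
        self,
        theta: np.ndarray,
        alpha_hat: np.ndarray,
        delta_hat: np.ndarray,
        sigma2_p: float,
    ) -> SnpEffectTable:
        """Per-SNP variance contributions: marker i's share of the
        whole-genome EM variance update,

            sigma2_alpha_i = [alpha_hat_i^2 + sigma2_a
                              - sigma2_a^2 (t_i' Z' P Z t_i)] / m

        so the contributions sum exactly to the EM update of sigma2_a
        (= sigma2_a at convergence); dominance analogous.  Individual
        contributions may be slightly negative away from convergence —
        only the sum is constrained.
        """
        st = self._factor(theta)
        sa, sd, _ = st["theta"]
        P = st["P"]
        mm = self.mm
        m = mm.n_markers
        idx = mm.train_idx
        U = mm.T_alpha[idx]                    # N x m = Z T_alpha
        Vv = mm.T_delta[idx]
        quad_a = np.einsum("nm,nm->m", U, P @ U)
        quad_d = np.einsum("nm,nm->m", Vv, P @ Vv)
        s2a_i = (alpha_hat**2 + sa - sa**2 * quad_a) / m
        s2d_i = (delta_hat**2 + sd - sd**2 * quad_d) / m
        return SnpEffectTable(
            marker_ids=list(mm.marker_ids),
            alpha_hat=alpha_hat, delta_hat=delta_hat,
            sigma2_alpha_i=s2a_i, sigma2_delta_i=s2d_i,
            h2_alpha_i=s2a_i / sigma2_p, h2_delta_i=s2d_i / sigma2_p,
        )
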