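"""QM-formulation engine: mixed-model equations in the marker-effect
dimension with fixed effects absorbed.

The equivalent marker-effect model is y = X b + Z1 alpha + Z2 delta + e
with Z1 = Z T_alpha, Z2 = Z T_delta, alpha ~ N(0, sigma2_a I_m),
delta ~ N(0, sigma2_d I_m).  Absorbing the fixed effects with
M = I - X (X'X)^- X' gives the 2m x 2m coefficient matrix

    C = [[Z1'M Z1 + lam_a I, Z1'M Z2        ],
         [Z2'M Z1,           Z2'M Z2 + lam_d I]]

with lam_a = sigma2_e/sigma2_a, lam_d = sigma2_e/sigma2_d.  Solving
C u = (Z1'M y, Z2'M y) yields the marker-effect BLUPs directly, and the
REML quadratics follow from MME identities:

    P y        = M (y - Z1 alpha_hat - Z2 delta_hat) / sigma2_e
    y'P H_a P y = alpha_hat' alpha_hat / sigma2_a^2
    tr(P H_a)  = [m sigma2_a - sigma2_e tr(Caa)] / sigma2_a^2
    tr(P)      = [N - rank(X) - sigma2_a tr(PH_a) sigma2_a ...] via tr(PV)

where Caa, Cdd are the diagonal blocks of C^-1.  Everything scales with
the marker count and is independent of the number of individuals once
the cross-product blocks are formed, so this route wins when
individuals far outnumber markers (q > 2m).

The restricted log-likelihood is assembled from determinant identities
on the unabsorbed marker equations C0 = Ztilde'Ztilde + sigma2_e G^-1:

    log|V|         = (N - 2m) log sigma2_e + m log sigma2_a
                     + m log sigma2_d + log|C0|
    X'V^-1 X       = (X'X - X'Ztilde C0^-1 Ztilde'X) / sigma2_e

matching the CE engine's values exactly, including rank-deficient X
(pseudo-determinant with the same eigenvalue cutoff).
"""

from __future__ import annotations

import numpy as np
from scipy import linalg

from .engine_ce import GblupResult, SnpEffectTable, logpdet_psd
from .model_matrices import GrmPair, ModelMatrices
from .reml_core import RemlQuadratics

__all__ = ["QmEngine"]


class QmEngine:
    """REML engine on the absorbed marker-dimension mixed-model equations."""

    def __init__(self, mm: ModelMatrices, grm: GrmPair, y: np.ndarray):
        self.mm = mm
        self.grm = grm   # only diagonals are used (reliability denominators)
        self.y = np.asarray(y, dtype=float)
        self.n_markers = mm.n_markers
        self.n_records = mm.n_records
        self.rank_X = mm.rank_X

        idx = mm.train_idx
        X = mm.X
        Z1 = mm.T_alpha[idx]               # N x m
        Z2 = mm.T_delta[idx]
        Zt = np.hstack([Z1, Z2])           # N x 2m
        self.Zt = Zt
        self.X = X
        XtX = X.T @ X
        self.XtX_pinv = linalg.pinvh(XtX)
        self.logpdet_XtX, _ = logpdet_psd(XtX)
        XtZ = X.T @ Zt                     # c x 2m
        self.XtZ = XtZ
        # cross products formed once; only the ridge diagonal changes per theta
        self.K0 = Zt.T @ Zt                            # Ztilde'Ztilde
        self.K = self.K0 - XtZ.T @ (self.XtX_pinv @ XtZ)  # Ztilde'M Ztilde
        self.My = self._apply_M(self.y)
        self.r_y = Zt.T @ self.My                      # Ztilde'M y
        self._cache_theta: tuple | None = None
        self._state: dict | None = None

    def _apply_M(self, v: np.ndarray) -> np.ndarray:
        return v - self.X @ (self.XtX_pinv @ (self.X.T @ v))

    # -- state ---------------------------------------------------------

    def _solve(self, theta: np.ndarray) -> dict:
        key = tuple(np.asarray(theta, dtype=float))
        if self._cache_theta == key:
            return self._state
        sa, sd, se = key
        m = self.n_markers
        lam = np.concatenate([np.full(m, se / sa), np.full(m, se / sd)])
        C = self.K + np.diag(lam)
        cf = linalg.cho_factor(C, lower=True)
        u = linalg.cho_solve(cf, self.r_y)
        alpha_hat, delta_hat = u[:m], u[m:]
        resid = self.y - self.Zt @ u
        Py = self._apply_M(resid) / se
        Cinv = linalg.cho_solve(cf, np.eye(2 * m))
        trCaa = float(np.trace(Cinv[:m, :m]))
        trCdd = float(np.trace(Cinv[m:, m:]))
        # determinant bookkeeping on the unabsorbed equations
        C0 = self.K0 + np.diag(lam)
        cf0 = linalg.cho_factor(C0, lower=True)
        logdetC0 = 2.0 * float(np.sum(np.log(np.diag(cf0[0]))))
        N = self.n_records
        logdetV = (N - 2 * m) * np.log(se) + m * np.log(sa) + m * np.log(sd) + logdetC0
        S = self.XtZ @ linalg.cho_solve(cf0, self.XtZ.T)
        XtVinvX = (self.X.T @ self.X - S) / se
        logdetXVX, _ = logpdet_psd(XtVinvX)
        state = {
            "theta": key, "cf": cf, "Cinv": Cinv, "alpha_hat": alpha_hat,
            "delta_hat": delta_hat, "u": u, "Py": Py, "trCaa": trCaa,
            "trCdd": trCdd, "logdetV": float(logdetV), "logdetXVX": logdetXVX,
        }
        self._cache_theta = key
        self._state = state
        return state

    # -- engine contract -----------------------------------------------

    def apply_P(self, v: np.ndarray, state: dict | None = None) -> np.ndarray:
        """P v through the absorbed equations: solve C w = Ztilde'M v and
        project the residual; identical to the dense P product."""
        st = state if state is not None else self._state
        if st is None:
            raise RuntimeError("apply_P requires a prior quadratics() call")
        se = st["theta"][2]
        Mv = self._apply_M(v)
        w = linalg.cho_solve(st["cf"], self.Zt.T @ Mv)
        return self._apply_M(v - self.Zt @ w) / se

    def quadratics(self, theta: np.ndarray) -> RemlQuadratics:
        st = self._solve(theta)
        sa, sd, se = st["theta"]
        m, N, rX = self.n_markers, self.n_records, self.rank_X
        alpha_hat, delta_hat, Py = st["alpha_hat"], st["delta_hat"], st["Py"]
        yPHPy = np.array([
            float(alpha_hat @ alpha_hat) / sa**2,
            float(delta_hat @ delta_hat) / sd**2,
            float(Py @ Py),
        ])
        trPH_a = (m * sa - se * st["trCaa"]) / sa**2
        trPH_d = (m * sd - se * st["trCdd"]) / sd**2
        trPH_e = (N - rX - sa * trPH_a - sd * trPH_d) / se
        trPH = np.array([trPH_a, trPH_d, trPH_e])
        # AI matrix from P-projections of the three vectors H_i P y
        f = [
            self.Zt[:, :m] @ (alpha_hat / sa),     # Z1 Z1' P y
            self.Zt[:, m:] @ (delta_hat / sd),     # Z2 Z2' P y
            Py,
        ]
        Pf = [self.apply_P(fi, st) for fi in f]
        AI = 0.5 * np.array([[float(f[i] @ Pf[j]) for j in range(3)] for i in range(3)])
        AI = 0.5 * (AI + AI.T)
        logL = -0.5 * (st["logdetV"] + st["logdetXVX"] + float(self.y @ Py))
        return RemlQuadratics(yPHPy=yPHPy, trPH=trPH, AI=AI, logL=logL)

    # -- predictions ----------------------------------------------------

    def gblup(self, theta: np.ndarray, training_ids: set[str] | None = None) -> GblupResult:
        """GBLUP for all genotyped individuals from the marker-effect
        solutions: a_hat = T_alpha alpha_hat, d_hat = T_delta delta_hat,
        with reliabilities from var(alpha_hat) = sigma2_a I - sigma2_e Caa."""
        st = self._solve(theta)
        sa, sd, se = st["theta"]
        m = self.n_markers
        mm = self.mm
        Ta, Td = mm.T_alpha, mm.T_delta
        a_hat = Ta @ st["alpha_hat"]
        d_hat = Td @ st["delta_hat"]
        Cinv = st["Cinv"]
        Caa, Cad, Cdd = Cinv[:m, :m], Cinv[:m, m:], Cinv[m:, m:]
        # var(a_hat)_ii = [T_alpha (sigma2_a I - sigma2_e Caa) T_alpha']_ii
        var_a = sa * np.einsum("qm,qm->q", Ta, Ta) - se * np.einsum(
            "qm,qm->q", Ta @ Caa, Ta)
        var_d = sd * np.einsum("qm,qm->q", Td, Td) - se * np.einsum(
            "qm,qm->q", Td @ Cdd, Td)
        cov_ad = -se * np.einsum("qm,qm->q", Ta @ Cad, Td)
        diag_A = np.diag(self.grm.A_g)
        diag_D = np.diag(self.grm.D_g)
        with np.errstate(divide="ignore", invalid="ignore"):
            rel_a = np.where(diag_A > 0, var_a / (sa * diag_A), 0.0)
            rel_d = np.where(diag_D > 0, var_d / (sd * diag_D), 0.0)
            denom_g = sa * diag_A + sd * diag_D
            rel_g = np.where(denom_g > 0, (var_a + var_d + 2.0 * cov_ad) / denom_g, 0.0)
        idx = mm.train_idx
        train = set(np.asarray(mm.individual_ids)[idx]) if training_ids is None else training_ids
        sets = ["training" if ind in train else "validation" for ind in mm.individual_ids]
        return GblupResult(
            individual_ids=list(mm.individual_ids), sets=sets,
            a_hat=a_hat, rel_a=rel_a, d_hat=d_hat, rel_d=rel_d,
            g_hat=a_hat + d_hat, rel_g=rel_g,
        )

    def snp_effects(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        st = self._solve(theta)
        return st["alpha_hat"].copy(), st["delta_hat"].copy()

    def snp_variances(
        self,
        theta: np.ndarray,
        alpha_hat: np.ndarray,
        delta_hat: np.ndarray,
        sigma2_p: float,
    ) -> SnpEffectTable:
        """Per-SNP variances sigma2_alpha_i = (alpha_hat_i^2 +
        sigma2_e Caa_ii)/m (dominance analogous); identical to the CE
        engine's values through sigma2_e Caa_ii = sigma2_a -
        sigma2_a^2 t_i'Z'PZ t_i."""
        st = self._solve(theta)
        _, _, se = st["theta"]
        m = self.n_markers
        Cinv = st["Cinv"]
        s2a_i = (alpha_hat**2 + se * np.diag(Cinv[:m, :m])) / m
        s2d_i = (delta_hat**2 + se * np.diag(Cinv[m:, m:])) / m
        return SnpEffectTable(
            marker_ids=list(self.mm.marker_ids),
            alpha_hat=alpha_hat, delta_hat=delta_hat,
            sigma2_alpha_i=s2a_i, sigma2_delta_i=s2d_i,
            h2_alpha_i=s2a_i / sigma2_p, h2_delta_i=s2d_i / sigma2_p,
        )
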