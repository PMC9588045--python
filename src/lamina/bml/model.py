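"""Student-t multilevel model with crossed condition/region/subject effects.

The observed effect estimate of condition ``c`` in region ``r`` for
subject ``s`` is modeled as

    y_crs ~ StudentT(nu, b_c + xi_cs + eta_cr + gamma_rs, sigma)

with population condition effects ``b_c`` (flat prior), subject-by-
condition effects ``(xi_1s..xi_Cs)' ~ N(0, Theta)``, region-by-condition
effects ``(eta_1r..eta_Cr)' ~ N(0, Omega)``, and region-by-subject
interactions ``gamma_rs ~ N(0, lambda^2)``.  Priors: LKJ(1) (jointly
uniform) on the correlation parts of Theta and Omega, half-t(3, 0, 1) on
all hierarchical standard deviations, Gamma(2, 0.1) on ``nu``, and
half-Cauchy on ``sigma`` scaled by the standard deviation of the data.

The posterior is explored on an unconstrained parameterization:
non-centered standardized effects, log standard deviations, log ``nu``,
and tanh-transformed canonical partial correlations (CPC) of the
correlation Cholesky factors.  Under the C-vine factorization the LKJ(1)
density plus the tanh Jacobian reduce to ``sum_j a_j log(1 - z_ij^2)``
with ``a_j = 1 + (C - 2 - j)/2`` for 0-indexed column ``j``; analytic
gradients of the full log posterior are implemented below and verified
against finite differences in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import digamma, gammaln

HALF_T_DF = 3.0  # df of the half-t prior on hierarchical SDs
NU_SHAPE, NU_RATE = 2.0, 0.1  # Gamma prior on Student-t df


def cpc_to_cholesky(z: np.ndarray, dim: int) -> np.ndarray:
    """Cholesky factor of a correlation matrix from canonical partial
    correlations ``z`` (row-major lower-triangle order, values in (-1,1))."""
    L = np.zeros((dim, dim))
    L[0, 0] = 1.0
    pos = 0
    for i in range(1, dim):
        cum = 1.0
        for j in range(i):
            zj = z[pos + j]
            L[i, j] = zj * np.sqrt(cum)
            cum *= 1.0 - zj * zj
        L[i, i] = np.sqrt(cum)
        pos += i
    return L


def cholesky_grad_to_cpc(z: np.ndarray, L: np.ndarray, gL: np.ndarray, dim: int) -> np.ndarray:
    """Backpropagate d(target)/dL to the unconstrained CPC variables ``x``
    (where ``z = tanh(x)``); returns d(target)/dx in flat order."""
    gx = np.zeros_like(z)
    pos = 0
    for i in range(1, dim):
        zi = z[pos : pos + i]
        # c_j = prod_{k<j} sqrt(1 - z_k^2)
        c = np.ones(i)
        for j in range(1, i):
            c[j] = c[j - 1] * np.sqrt(1.0 - zi[j - 1] ** 2)
        terms = gL[i, :i] * L[i, :i]
        suffix = np.concatenate([np.cumsum(terms[::-1])[::-1], [0.0]])  # sum_{j>=m} terms
        diag_term = gL[i, i] * L[i, i]
        for m in range(i):
            tail = suffix[m + 1] + diag_term
            gx[pos + m] = gL[i, m] * c[m] * (1.0 - zi[m] ** 2) - zi[m] * tail
        pos += i
    return gx


def lkj_cpc_coefficients(dim: int, eta: float = 1.0) -> np.ndarray:
    """Per-CPC exponents a_j (including the tanh Jacobian) in flat order."""
    out = []
    for i in range(1, dim):
        for j in range(i):
            out.append(eta + (dim - 2 - j) / 2.0)
    return np.asarray(out)


@dataclass
class ParamLayout:
    C: int
    R: int
    S: int
    student_t: bool

    def __post_init__(self):
        C = self.C
        self.n_cpc = C * (C - 1) // 2
        sizes = {
            "b": C,
            "z_subject": C * self.S,
            "z_region": C * self.R,
            "z_inter": self.R * self.S,
            "log_tau_subject": C,
            "log_tau_region": C,
            "cpc_subject": self.n_cpc,
            "cpc_region": self.n_cpc,
            "log_lambda": 1,
            "log_sigma": 1,
        }
        if self.student_t:
            sizes["log_nu"] = 1
        self.slices: dict[str, slice] = {}
        off = 0
        for name, size in sizes.items():
            self.slices[name] = slice(off, off + size)
            off += size
        self.size = off

    def get(self, theta: np.ndarray, name: str) -> np.ndarray:
        return theta[self.slices[name]]


class StudentTMultilevel:
    """Log posterior and gradient of the crossed multilevel model."""

    def __init__(self, y: np.ndarray, likelihood: str = "student_t", sigma_scale: float | None = None):
        y = np.asarray(y, dtype=float)
        if y.ndim != 3:
            raise ValueError("y must be a (conditions, regions, subjects) array")
        if not np.all(np.isfinite(y)):
            raise ValueError("y contains non-finite values (data must be complete)")
        C, R, S = y.shape
        if C < 2:
            raise ValueError("need at least 2 conditions")
        if S < 2:
            raise ValueError("varying effects are unidentifiable with a single subject")
        if R < 2:
            raise ValueError("need at least 2 regions")
        if likelihood not in ("student_t", "normal"):
            raise ValueError(f"unknown likelihood {likelihood!r}")
        self.y = y
        self.C, self.R, self.S = C, R, S
        self.likelihood = likelihood
        self.layout = ParamLayout(C, R, S, student_t=likelihood == "student_t")
        self.sigma_scale = float(np.std(y)) if sigma_scale is None else float(sigma_scale)
        if self.sigma_scale <= 0:
            self.sigma_scale = 1.0
        self.lkj_coef = lkj_cpc_coefficients(C)
        self.n_obs = C * R * S

    # -- parameter handling ------------------------------------------------

    def initial_value(self, rng: np.random.Generator, jitter: float = 0.5) -> np.ndarray:
        lay = self.layout
        theta = 0.1 * rng.standard_normal(lay.size)
        theta[lay.slices["b"]] = self.y.mean(axis=(1, 2)) + 0.05 * rng.standard_normal(self.C)
        resid_sd = max(float(self.y.std()), 1e-3)
        theta[lay.slices["log_sigma"]] = np.log(resid_sd) + jitter * 0.2 * rng.standard_normal()
        theta[lay.slices["log_tau_subject"]] = np.log(0.25 * resid_sd)
        theta[lay.slices["log_tau_region"]] = np.log(0.25 * resid_sd)
        theta[lay.slices["log_lambda"]] = np.log(0.25 * resid_sd)
        if self.likelihood == "student_t":
            theta[lay.slices["log_nu"]] = np.log(20.0) + jitter * 0.2 * rng.standard_normal()
        return theta

    def mass_hint(self) -> np.ndarray:
        """Rough per-parameter posterior variances on the unconstrained scale.

        Standardized effects sit near unit variance; population effects are
        estimated from ~R*S observations each; log-scale and correlation
        parameters move on an O(0.1)-O(0.5) scale.
        """
        lay = self.layout
        hint = np.ones(lay.size)
        resid_var = max(float(self.y.var()), 1e-6)
        hint[lay.slices["b"]] = resid_var / (self.R * self.S) + 1e-4
        for name in ("log_tau_subject", "log_tau_region", "log_lambda", "log_sigma"):
            hint[lay.slices[name]] = 0.1
        for name in ("cpc_subject", "cpc_region"):
            hint[lay.slices[name]] = 0.25
        if self.likelihood == "student_t":
            hint[lay.slices["log_nu"]] = 0.25
        return hint

    def constrain(self, theta: np.ndarray) -> dict[str, np.ndarray]:
        """Named constrained parameters (including the varying effects)."""
        lay = self.layout
        C, R, S = self.C, self.R, self.S
        b = lay.get(theta, "b").copy()
        tau_s = np.exp(lay.get(theta, "log_tau_subject"))
        tau_r = np.exp(lay.get(theta, "log_tau_region"))
        lam = float(np.exp(lay.get(theta, "log_lambda")[0]))
        sigma = float(np.exp(lay.get(theta, "log_sigma")[0]))
        z_cpc_s = np.tanh(lay.get(theta, "cpc_subject"))
        z_cpc_r = np.tanh(lay.get(theta, "cpc_region"))
        L_s = cpc_to_cholesky(z_cpc_s, C)
        L_r = cpc_to_cholesky(z_cpc_r, C)
        xi = tau_s[:, None] * (L_s @ lay.get(theta, "z_subject").reshape(C, S))
        eta = tau_r[:, None] * (L_r @ lay.get(theta, "z_region").reshape(C, R))
        gam = lam * lay.get(theta, "z_inter").reshape(R, S)
        corr_s = L_s @ L_s.T
        corr_r = L_r @ L_r.T
        tri = np.tril_indices(C, -1)
        out = {
            "b": b,
            "sigma": np.asarray(sigma),
            "lambda": np.asarray(lam),
            "tau_subject": tau_s,
            "tau_region": tau_r,
            "corr_subject": corr_s[tri],
            "corr_region": corr_r[tri],
            "xi": xi,
            "eta": eta,
            "gamma": gam,
        }
        if self.likelihood == "student_t":
            out["nu"] = np.asarray(float(np.exp(lay.get(theta, "log_nu")[0])))
        return out

    # -- log posterior -----------------------------------------------------

    def logp_and_grad(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        lay = self.layout
        C, R, S = self.C, self.R, self.S
        y = self.y
        N = self.n_obs

        b = lay.get(theta, "b")
        Zs = lay.get(theta, "z_subject").reshape(C, S)
        Zr = lay.get(theta, "z_region").reshape(C, R)
        Zg = lay.get(theta, "z_inter").reshape(R, S)
        lts = lay.get(theta, "log_tau_subject")
        ltr = lay.get(theta, "log_tau_region")
        xs = lay.get(theta, "cpc_subject")
        xr = lay.get(theta, "cpc_region")
        llam = lay.get(theta, "log_lambda")[0]
        lsig = lay.get(theta, "log_sigma")[0]
        tau_s, tau_r = np.exp(lts), np.exp(ltr)
        lam, sigma = np.exp(llam), np.exp(lsig)
        # clip |z| away from 1 so the LKJ term stays finite under extreme proposals
        zs = np.clip(np.tanh(xs), -1 + 1e-12, 1 - 1e-12)
        zr = np.clip(np.tanh(xr), -1 + 1e-12, 1 - 1e-12)
        Ls = cpc_to_cholesky(zs, C)
        Lr = cpc_to_cholesky(zr, C)

        Ms = tau_s[:, None] * Ls
        Mr = tau_r[:, None] * Lr
        xi = Ms @ Zs  # C x S
        eta = Mr @ Zr  # C x R
        gam = lam * Zg  # R x S
        mu = b[:, None, None] + xi[:, None, :] + eta[:, :, None] + gam[None, :, :]
        e = y - mu

        if self.likelihood == "student_t":
            nu = np.exp(lay.get(theta, "log_nu")[0])
            denom = nu * sigma**2 + e**2
            ll = N * (
                gammaln((nu + 1) / 2) - gammaln(nu / 2) - 0.5 * np.log(nu * np.pi) - lsig
            ) - 0.5 * (nu + 1) * np.sum(np.log1p(e**2 / (nu * sigma**2)))
            G = (nu + 1) * e / denom  # d ll / d mu
            eG = e * G
            g_lsig = -N + np.sum(eG)
            dll_dnu = (
                N * 0.5 * (digamma((nu + 1) / 2) - digamma(nu / 2) - 1.0 / nu)
                - 0.5 * np.sum(np.log1p(e**2 / (nu * sigma**2)))
                + np.sum(eG) / (2.0 * nu)
            )
            g_lnu = nu * dll_dnu + (NU_SHAPE - NU_RATE * nu)  # includes Gamma prior + Jacobian
        else:
            ll = -N * (lsig + 0.5 * np.log(2 * np.pi)) - 0.5 * np.sum(e**2) / sigma**2
            G = e / sigma**2
            g_lsig = -N + np.sum(e**2) / sigma**2
            g_lnu = None

        # standard-normal priors on the non-centered effects
        lp = ll - 0.5 * (np.sum(Zs**2) + np.sum(Zr**2) + np.sum(Zg**2))
        # half-t(3,0,1) on hierarchical SDs (+ log Jacobian)
        for t_arr, lt_arr in ((tau_s, lts), (tau_r, ltr), (np.array([lam]), np.array([llam]))):
            lp += np.sum(-((HALF_T_DF + 1) / 2) * np.log1p(t_arr**2 / HALF_T_DF) + lt_arr)
        # half-Cauchy(sigma_scale) on sigma (+ Jacobian)
        lp += -np.log1p((sigma / self.sigma_scale) ** 2) + lsig
        # LKJ(1) on the correlation CPCs (tanh Jacobian folded in)
        lp += np.sum(self.lkj_coef * np.log1p(-zs**2)) + np.sum(self.lkj_coef * np.log1p(-zr**2))
        if self.likelihood == "student_t":
            # Gamma(shape, rate) prior: (shape-1) log nu - rate nu, plus the
            # +log nu Jacobian of nu = exp(log_nu)
            lp += NU_SHAPE * np.log(nu) - NU_RATE * nu

        grad = np.zeros(lay.size)
        grad[lay.slices["b"]] = G.sum(axis=(1, 2))
        Gs = G.sum(axis=1)  # C x S
        Gr = G.sum(axis=2)  # C x R
        Gg = G.sum(axis=0)  # R x S

        grad[lay.slices["z_subject"]] = (Ms.T @ Gs - Zs).ravel()
        grad[lay.slices["z_region"]] = (Mr.T @ Gr - Zr).ravel()
        grad[lay.slices["z_inter"]] = (lam * Gg - Zg).ravel()

        GM_s = Gs @ Zs.T  # C x C, d ll / d Ms
        GM_r = Gr @ Zr.T
        # tau gradients (likelihood part) + half-t prior + Jacobian
        g_tau_s = np.sum(GM_s * Ls, axis=1) * tau_s
        g_tau_r = np.sum(GM_r * Lr, axis=1) * tau_r
        ht = lambda t: 1.0 - (HALF_T_DF + 1) * t**2 / (HALF_T_DF + t**2)
        grad[lay.slices["log_tau_subject"]] = g_tau_s + ht(tau_s)
        grad[lay.slices["log_tau_region"]] = g_tau_r + ht(tau_r)
        g_lam = lam * np.sum(Gg * Zg) + ht(lam)
        grad[lay.slices["log_lambda"]] = g_lam
        grad[lay.slices["log_sigma"]] = g_lsig + 1.0 - 2.0 * sigma**2 / (self.sigma_scale**2 + sigma**2)

        gL_s = tau_s[:, None] * GM_s
        gL_r = tau_r[:, None] * GM_r
        grad[lay.slices["cpc_subject"]] = (
            cholesky_grad_to_cpc(zs, Ls, gL_s, C) - 2.0 * self.lkj_coef * zs
        )
        grad[lay.slices["cpc_region"]] = (
            cholesky_grad_to_cpc(zr, Lr, gL_r, C) - 2.0 * self.lkj_coef * zr
        )
        if self.likelihood == "student_t":
            grad[lay.slices["log_nu"]] = g_lnu
        return float(lp), grad
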