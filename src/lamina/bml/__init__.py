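"""Region-based Bayesian multilevel modeling of condition effects.

Fits the crossed Student-t multilevel model (see :mod:`.model`) by NUTS
MCMC (see :mod:`.nuts`), and derives the quantities reported per region:
``P+`` (the posterior probability that an effect is positive) and the
dimensionless valence modulation index ``(C1 - C2)/(|C1| + |C2|)``.
Convergence is monitored with the split R-hat statistic (< 1.05) and the
effective sample size (> 200) of the posterior draws.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import arviz as az
import numpy as np
import pandas as pd

from .model import StudentTMultilevel, cpc_to_cholesky
from .nuts import SamplerStats, nuts_sample

RHAT_THRESHOLD = 1.05
ESS_THRESHOLD = 200.0

__all__ = [
    "BmlData",
    "BmlPosterior",
    "fit_bml",
    "diagnostics",
    "modulation_index",
    "posterior_positive_prob",
    "posterior_predictive_check",
    "simulate_dataset",
    "StudentTMultilevel",
    "nuts_sample",
    "RHAT_THRESHOLD",
    "ESS_THRESHOLD",
]


@dataclass
class BmlData:
    """Complete (condition x region x subject) table of effect estimates.

    ``y[c, r, s]`` is the GLM beta (percent signal change, or percent CBV
    for laminar data) of condition ``c`` in region ``r`` for subject ``s``.
    """

    y: np.ndarray
    conditions: list[str]
    regions: list[str]
    subjects: list[str]

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float)
        if self.y.shape != (len(self.conditions), len(self.regions), len(self.subjects)):
            raise ValueError("y shape does not match labels")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "BmlData":
        """Build from a long-format table with columns
        (condition, region, subject, y); every crossing must be present."""
        required = {"condition", "region", "subject", "y"}
        if not required.issubset(df.columns):
            raise ValueError(f"long table needs columns {sorted(required)}")
        pivot = df.pivot_table(index=["condition", "region", "subject"], values="y")
        conditions = sorted(df["condition"].unique())
        regions = sorted(df["region"].unique())
        subjects = sorted(df["subject"].unique())
        y = np.full((len(conditions), len(regions), len(subjects)), np.nan)
        for (c, r, s), row in pivot.iterrows():
            y[conditions.index(c), regions.index(r), subjects.index(s)] = row["y"]
        if np.isnan(y).any():
            raise ValueError("incomplete crossing: every (condition, region, subject) needed")
        return cls(y=y, conditions=list(conditions), regions=list(regions), subjects=list(subjects))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for ic, c in enumerate(self.conditions):
            for ir, r in enumerate(self.regions):
                for isub, s in enumerate(self.subjects):
                    rows.append((c, r, s, self.y[ic, ir, isub]))
        return pd.DataFrame(rows, columns=["condition", "region", "subject", "y"])


@dataclass
class BmlPosterior:
    """Posterior draws (chains x draws x ...) plus sampler metadata."""

    draws: dict[str, np.ndarray]
    conditions: list[str]
    regions: list[str]
    subjects: list[str]
    likelihood: str
    seed: int
    n_warmup: int
    sampler_stats: list[SamplerStats] = field(default_factory=list)

    @property
    def n_chains(self) -> int:
        return next(iter(self.draws.values())).shape[0]

    @property
    def n_draws(self) -> int:
        return next(iter(self.draws.values())).shape[1]

    def to_inference_data(self) -> az.InferenceData:
        return az.from_dict(posterior=self.draws)

    def flat(self, name: str) -> np.ndarray:
        """Draws of one parameter pooled over chains: (chains*draws, ...)."""
        arr = self.draws[name]
        return arr.reshape((-1,) + arr.shape[2:])

    def condition_effect(self, condition: str) -> np.ndarray:
        """Population-level draws of one condition (b_c)."""
        return self.flat("b")[:, self.conditions.index(condition)]

    def region_condition_effect(self, condition: str, region: str) -> np.ndarray:
        """Region-level condition draws, b_c + eta_cr."""
        ic = self.conditions.index(condition)
        ir = self.regions.index(region)
        return self.flat("b")[:, ic] + self.flat("eta")[:, ic, ir]

    def region_contrast(self, c1: str, c2: str, region: str) -> np.ndarray:
        return self.region_condition_effect(c1, region) - self.region_condition_effect(c2, region)

    def region_modulation_index(self, c1: str, c2: str, region: str) -> np.ndarray:
        return modulation_index(
            self.region_condition_effect(c1, region), self.region_condition_effect(c2, region)
        )

    def summary(self) -> pd.DataFrame:
        return az.summary(self.to_inference_data())


def simulate_dataset(
    rng: np.random.Generator,
    b: np.ndarray,
    R: int,
    S: int,
    nu: float = 30.0,
    sigma: float = 0.1,
    lam: float = 0.05,
    theta_subject: np.ndarray | None = None,
    omega_region: np.ndarray | None = None,
) -> np.ndarray:
    """Draw a (C, R, S) dataset from the generative model.

    ``theta_subject`` and ``omega_region`` default to ``0.01 * I`` (SD 0.1,
    uncorrelated conditions).  ``nu = inf`` gives Gaussian residuals.
    """
    b = np.asarray(b, dtype=float)
    C = b.size
    theta = 0.01 * np.eye(C) if theta_subject is None else np.asarray(theta_subject)
    omega = 0.01 * np.eye(C) if omega_region is None else np.asarray(omega_region)
    xi = rng.multivariate_normal(np.zeros(C), theta, size=S).T  # C x S
    eta = rng.multivariate_normal(np.zeros(C), omega, size=R).T  # C x R
    gam = lam * rng.standard_normal((R, S))
    mu = b[:, None, None] + xi[:, None, :] + eta[:, :, None] + gam[None, :, :]
    if np.isinf(nu):
        resid = sigma * rng.standard_normal(mu.shape)
    else:
        resid = sigma * rng.standard_t(nu, size=mu.shape)
    return mu + resid


def fit_bml(
    data: BmlData | np.ndarray,
    chains: int = 4,
    iterations: int = 1000,
    warmup: int | None = None,
    seed: int = 0,
    likelihood: str = "student_t",
    target_accept: float = 0.9,
    max_treedepth: int = 10,
    sigma_scale: float | None = None,
    check_convergence: bool = True,
) -> BmlPosterior:
    """Fit the multilevel model with NUTS.

    ``iterations`` is the per-chain chain length; the first half (by
    default) is warmup and discarded, the rest are posterior draws.
    Non-convergence (max split R-hat above 1.05) triggers a prominent
    warning but still returns the posterior.
    """
    if isinstance(data, np.ndarray):
        C, R, S = data.shape
        data = BmlData(
            y=data,
            conditions=[f"c{i+1}" for i in range(C)],
            regions=[f"r{i+1}" for i in range(R)],
            subjects=[f"s{i+1}" for i in range(S)],
        )
    if chains < 2:
        raise ValueError("need at least 2 chains for split-chain diagnostics")
    warmup = iterations // 2 if warmup is None else warmup
    if warmup >= iterations:
        raise ValueError("warmup must be smaller than iterations")
    model = StudentTMultilevel(data.y, likelihood=likelihood, sigma_scale=sigma_scale)

    seed_seq = np.random.SeedSequence(seed)
    chain_samples = []
    stats = []
    for child in seed_seq.spawn(chains):
        rng = np.random.default_rng(child)
        x0 = model.initial_value(rng)
        samples, st = nuts_sample(
            model.logp_and_grad,
            x0,
            n_warmup=warmup,
            n_samples=iterations - warmup,
            rng=rng,
            target_accept=target_accept,
            max_treedepth=max_treedepth,
            inv_mass0=model.mass_hint(),
        )
        chain_samples.append(samples)
        stats.append(st)

    # constrain every draw into named parameter arrays
    first = model.constrain(chain_samples[0][0])
    draws: dict[str, np.ndarray] = {
        name: np.empty((chains, iterations - warmup) + np.shape(val))
        for name, val in first.items()
    }
    for ci, samples in enumerate(chain_samples):
        for di in range(samples.shape[0]):
            con = model.constrain(samples[di])
            for name, val in con.items():
                draws[name][ci, di] = val

    post = BmlPosterior(
        draws=draws,
        conditions=data.conditions,
        regions=data.regions,
        subjects=data.subjects,
        likelihood=likelihood,
        seed=seed,
        n_warmup=warmup,
        sampler_stats=stats,
    )
    if check_convergence:
        diag = diagnostics(post)
        max_rhat = float(diag["rhat"].max())
        if max_rhat > RHAT_THRESHOLD:
            warnings.warn(
                f"MCMC has not converged: max split R-hat {max_rhat:.3f} > {RHAT_THRESHOLD}; "
                "inspect the chains before interpreting the posterior",
                stacklevel=2,
            )
    return post


def diagnostics(posterior: BmlPosterior) -> pd.DataFrame:
    """Split R-hat and effective sample size for every stored parameter.

    Returns one row per scalar parameter element with columns
    (parameter, rhat, ess).
    """
    if posterior.n_chains < 2:
        raise ValueError("split R-hat requires at least 2 chains")
    idata = posterior.to_inference_data()
    rhat = az.rhat(idata)
    ess = az.ess(idata)
    rows = []
    for name in posterior.draws:
        r = np.atleast_1d(np.asarray(rhat[name]))
        e = np.atleast_1d(np.asarray(ess[name]))
        for idx, (rv, ev) in enumerate(zip(r.ravel(), e.ravel())):
            label = name if r.size == 1 else f"{name}[{idx}]"
            rows.append((label, float(rv), float(ev)))
    return pd.DataFrame(rows, columns=["parameter", "rhat", "ess"])


def modulation_index(draws_c1: np.ndarray, draws_c2: np.ndarray) -> np.ndarray:
    """Dimensionless valence modulation index (C1 - C2)/(|C1| + |C2|).

    Antisymmetric in its arguments and bounded in [-1, 1]; the degenerate
    both-zero case is defined as 0 (and flagged with a warning).
    """
    c1 = np.asarray(draws_c1, dtype=float)
    c2 = np.asarray(draws_c2, dtype=float)
    if c1.shape != c2.shape:
        raise ValueError("draw counts differ between conditions")
    denom = np.abs(c1) + np.abs(c2)
    both_zero = denom == 0
    if np.any(both_zero):
        warnings.warn(f"{int(both_zero.sum())} draws with C1 = C2 = 0 set to index 0")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(both_zero, 0.0, (c1 - c2) / np.where(both_zero, 1.0, denom))
    return out


def posterior_positive_prob(draws: np.ndarray) -> float:
    """P+: fraction of posterior draws strictly greater than zero."""
    draws = np.asarray(draws)
    if draws.size < 100:
        raise ValueError("need at least 100 draws for a stable P+")
    return float(np.mean(draws > 0))


@dataclass
class PpcResult:
    """Posterior predictive summaries against the observed data."""

    observed_condition_means: np.ndarray
    replicated_condition_means: np.ndarray  # (n_rep, C)
    observed_mean_quantile: np.ndarray  # per condition, position of obs within reps
    tail_prob: np.ndarray  # per observation, min one-sided predictive tail prob
    outliers: np.ndarray  # boolean (C, R, S)


def posterior_predictive_check(
    posterior: BmlPosterior,
    data: BmlData | np.ndarray,
    n_replicates: int = 200,
    seed: int = 0,
    outlier_tail: float = 0.01,
) -> PpcResult:
    """Simulate replicate datasets from the fitted model and compare.

    For each selected posterior draw a replicate ``y`` is generated from
    the likelihood at that draw's cell means; observed per-condition means
    are located within the replicated distribution, and each observation
    gets a predictive tail probability (small values flag outliers).
    """
    if n_replicates <= 0:
        raise ValueError("need a positive number of replicates")
    y = data.y if isinstance(data, BmlData) else np.asarray(data, dtype=float)
    rng = np.random.default_rng(seed)
    total = posterior.n_chains * posterior.n_draws
    take = np.linspace(0, total - 1, min(n_replicates, total)).astype(int)

    b = posterior.flat("b")[take]
    xi = posterior.flat("xi")[take]
    eta = posterior.flat("eta")[take]
    gam = posterior.flat("gamma")[take]
    sigma = posterior.flat("sigma")[take]
    reps = np.empty((take.size,) + y.shape)
    for i in range(take.size):
        mu = b[i][:, None, None] + xi[i][:, None, :] + eta[i][:, :, None] + gam[i][None, :, :]
        if posterior.likelihood == "student_t":
            nu = posterior.flat("nu")[take][i]
            resid = float(sigma[i]) * rng.standard_t(float(nu), size=y.shape)
        else:
            resid = float(sigma[i]) * rng.standard_normal(y.shape)
        reps[i] = mu + resid

    obs_means = y.mean(axis=(1, 2))
    rep_means = reps.mean(axis=(2, 3))
    quantile = np.mean(rep_means < obs_means[None, :], axis=0)
    upper = np.mean(reps >= y[None], axis=0)
    lower = np.mean(reps <= y[None], axis=0)
    tail = np.minimum(upper, lower)
    return PpcResult(
        observed_condition_means=obs_means,
        replicated_condition_means=rep_means,
        observed_mean_quantile=quantile,
        tail_prob=tail,
        outliers=tail < outlier_tail,
    )
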