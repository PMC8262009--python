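"""Hierarchical trait layer over individual movement parameters, and MCMC.

Individuals' transformed parameter vectors (rows of the n_i x 7 matrix
Theta) are modelled as multivariate normal around trait-driven expectations:

    vec(Theta) ~ N(vec(M), Sigma (x) I_{n_i}),     M = T zeta,

where T is the n_i x 3 trait design (intercept, sex with males coded 1,
centred log weight in grams), zeta the 3 x 7 trait-effect matrix and Sigma
the 7 x 7 between-individual covariance.  Estimation is Metropolis-within-
Gibbs: adaptive random-walk Metropolis on each Theta row against the
movement likelihood times its row prior, and conjugate Gibbs draws of zeta
(matrix normal) and Sigma (inverse Wishart).

Priors (the source analysis does not publish its hyperpriors; these are
weakly informative defaults, configurable): zeta_ap ~ N(0, 10^2) iid and
Sigma ~ InvWishart(df = 9, scale = I).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .landscape import Datalogger, Mesh
from .likelihood import (
    DetectionHistory,
    IndividualParams,
    LikelihoodEvaluator,
    LoggerLayout,
)

N_PARAMS = 7
N_TRAITS = 3

#: hard support box on the transformed scale; outside it the prior is zero.
#: Generous around any biologically plausible value; mainly guards the
#: linear algebra against absurd proposals early in adaptation.
SUPPORT_LO = np.array([-5.0, -5.0, -5.0, -15.0, -15.0, -12.0, -15.0])
SUPPORT_HI = np.array([25.0, 25.0, 25.0, 15.0, 15.0, 5.0, 15.0])


# ---------------------------------------------------------------------------
# traits


@dataclass
class TraitMatrix:
    """Trait design matrix: intercept, sex (1 = male), centred log weight."""

    ids: list[str]
    matrix: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != N_TRAITS:
            raise ValueError(f"trait matrix must have {N_TRAITS} columns")
        if not np.all(self.matrix[:, 0] == 1.0):
            raise ValueError("first trait column must be the intercept (all ones)")
        if not np.all(np.isin(self.matrix[:, 1], (0.0, 1.0))):
            raise ValueError("sex column must be binary (1 male, 0 female)")

    @property
    def n_individuals(self) -> int:
        return self.matrix.shape[0]

    @classmethod
    def from_traits(cls, traits: pd.DataFrame) -> "TraitMatrix":
        """Build from a traits table with columns individual_id, sex, weight_g."""
        ids = [str(v) for v in traits["individual_id"]]
        sex = traits["sex"].map({"M": 1.0, "F": 0.0, 1: 1.0, 0: 0.0}).to_numpy(dtype=float)
        if np.any(np.isnan(sex)):
            raise ValueError("sex must be coded M/F")
        logw = np.log(traits["weight_g"].to_numpy(dtype=float))
        logw = logw - logw.mean()
        mat = np.column_stack([np.ones(len(ids)), sex, logw])
        return cls(ids=ids, matrix=mat)


def trait_expectation(T: TraitMatrix | np.ndarray, zeta: np.ndarray) -> np.ndarray:
    """Expected parameter matrix M = T zeta (n_i x 7)."""
    mat = T.matrix if isinstance(T, TraitMatrix) else np.asarray(T, dtype=float)
    zeta = np.asarray(zeta, dtype=float)
    if mat.shape[1] != zeta.shape[0]:
        raise ValueError(f"shape mismatch: T is {mat.shape}, zeta is {zeta.shape}")
    return mat @ zeta


def log_prior_theta(Theta: np.ndarray, M: np.ndarray, Sigma: np.ndarray) -> float:
    """Row-independent MVN log density sum_i log N(Theta_i | M_i, Sigma).

    Equivalent to the dense vec(Theta) ~ N(vec(M), Sigma (x) I) density.
    """
    Theta = np.asarray(Theta, dtype=float)
    M = np.asarray(M, dtype=float)
    Sigma = np.asarray(Sigma, dtype=float)
    if Theta.shape != M.shape:
        raise ValueError("Theta and M shapes differ")
    try:
        chol = np.linalg.cholesky(Sigma)
    except np.linalg.LinAlgError as err:
        raise ValueError("Sigma is not positive definite") from err
    resid = Theta - M
    y = np.linalg.solve(chol, resid.T)
    quad = float((y**2).sum())
    n_i, n_p = Theta.shape
    logdet = 2.0 * float(np.log(np.diag(chol)).sum())
    return -0.5 * (n_i * n_p * np.log(2.0 * np.pi) + n_i * logdet + quad)


@dataclass
class HierarchicalState:
    """One joint state of the hierarchical model."""

    Theta: np.ndarray
    zeta: np.ndarray
    Sigma: np.ndarray

    def __post_init__(self):
        self.Theta = np.asarray(self.Theta, dtype=float)
        self.zeta = np.asarray(self.zeta, dtype=float)
        self.Sigma = np.asarray(self.Sigma, dtype=float)
        if self.Theta.shape[1] != N_PARAMS or self.zeta.shape != (N_TRAITS, N_PARAMS):
            raise ValueError("inconsistent hierarchical dimensions")
        if not np.allclose(self.Sigma, self.Sigma.T):
            raise ValueError("Sigma must be symmetric")


# ---------------------------------------------------------------------------
# study data and configuration


@dataclass
class StudyData:
    """Everything the sampler needs: histories, traits, mesh and loggers."""

    histories: list[DetectionHistory]
    traits: TraitMatrix
    mesh: Mesh
    loggers: list[Datalogger]

    def __post_init__(self):
        if len(self.histories) != self.traits.n_individuals:
            raise ValueError("histories and trait rows do not match")
        for h in self.histories:
            if h.n_detections < 1:
                raise ValueError(f"{h.individual_id}: no detections")


@dataclass
class MCMCConfig:
    n_adapt: int = 2000
    n_iter: int = 8000
    n_chains: int = 2
    seed: int = 0
    thin: int = 1
    method: str = "exact"
    substeps: int = 8
    window: str = "study_end"
    zeta_sd: float = 10.0
    iw_df: float = N_PARAMS + 2
    iw_scale: float = 1.0
    target_accept: float = 0.234
    init_jitter: float = 0.3
    max_init_attempts: int = 50
    #: periods of the joint translation moves per trait row: shift zeta
    #: row a and every Theta row by its trait loading t_ia times a common
    #: 7-vector delta.  In the centred parameterization the population
    #: location and the trait-group contrasts otherwise mix very slowly
    #: when individual histories are short (the classic hierarchical-model
    #: pathology); these interweaving-style moves cure it at the cost of
    #: up to n_i extra likelihood evaluations per move.  Proposals adapt
    #: to the running covariance of the corresponding group-mean
    #: statistic.  Keys are trait-column indices, values the period in
    #: iterations; an absent row gets no joint move, and joint_every = 0
    #: disables all of them.
    joint_every: int = 1
    joint_periods: tuple = ((0, 1), (1, 2), (2, 4))


@dataclass
class PosteriorChains:
    """Thinned posterior draws from all chains.

    ``theta``: (n_chains, n_kept, n_i, 7); ``zeta``: (n_chains, n_kept, 3, 7);
    ``sigma``: (n_chains, n_kept, 7, 7).
    """

    theta: np.ndarray
    zeta: np.ndarray
    sigma: np.ndarray
    acceptance: np.ndarray
    config: MCMCConfig
    individual_ids: list[str]

    @property
    def n_chains(self) -> int:
        return self.theta.shape[0]

    @property
    def n_draws(self) -> int:
        return self.theta.shape[1]

    def theta_pooled(self) -> np.ndarray:
        """All chains pooled: (n_chains * n_kept, n_i, 7)."""
        return self.theta.reshape(-1, *self.theta.shape[2:])

    def zeta_pooled(self) -> np.ndarray:
        return self.zeta.reshape(-1, *self.zeta.shape[2:])

    def theta_posterior_mean(self) -> np.ndarray:
        return self.theta_pooled().mean(axis=0)

    def scalar_chains(self) -> dict[str, np.ndarray]:
        """Every scalar parameter as an (n_chains, n_draws) array."""
        out: dict[str, np.ndarray] = {}
        names = IndividualParams.NAMES
        for i, ind in enumerate(self.individual_ids):
            for p in range(N_PARAMS):
                out[f"theta[{ind},{names[p]}]"] = self.theta[:, :, i, p]
        for a, trait in enumerate(("intercept", "sex", "logweight")):
            for p in range(N_PARAMS):
                out[f"zeta[{trait},{names[p]}]"] = self.zeta[:, :, a, p]
        for p in range(N_PARAMS):
            out[f"sigma[{names[p]},{names[p]}]"] = self.sigma[:, :, p, p]
        return out

    def summary_table(self) -> pd.DataFrame:
        """Population-level posterior summary in natural units.

        Rows k1, k2, k3, D1, D2, D3, m, q with posterior mean and the 2.5 %
        and 97.5 % quantiles.  The population value of a draw is the
        back-transformed across-individual mean of the transformed
        parameter (geometric mean for log-scale parameters); k1 is pinned
        at 1 by the forest normalization.
        """
        pooled = self.theta_pooled()  # (draws, n_i, 7)
        popmean = pooled.mean(axis=1)  # (draws, 7)
        nat = {
            "k2": np.exp(popmean[:, 3]),
            "k3": np.exp(popmean[:, 4]),
            "D1": np.exp(popmean[:, 0]),
            "D2": np.exp(popmean[:, 1]),
            "D3": np.exp(popmean[:, 2]),
            "m": np.exp(popmean[:, 5]),
            "q": 1.0 / (1.0 + np.exp(-popmean[:, 6])),
        }
        rows = [("k1", 1.0, 1.0, 1.0)]
        for name in ("k2", "k3", "D1", "D2", "D3", "m", "q"):
            v = nat[name]
            rows.append((name, v.mean(), np.quantile(v, 0.025), np.quantile(v, 0.975)))
        return pd.DataFrame(rows, columns=["parameter", "mean", "q0.025", "q0.975"]).set_index(
            "parameter"
        )

    def to_frame(self) -> pd.DataFrame:
        """Tidy draws table (chain, iter, parameter, value)."""
        recs = []
        for name, arr in self.scalar_chains().items():
            for c in range(self.n_chains):
                recs.append(
                    pd.DataFrame(
                        {
                            "chain": c,
                            "iter": np.arange(arr.shape[1]),
                            "parameter": name,
                            "value": arr[c],
                        }
                    )
                )
        return pd.concat(recs, ignore_index=True)


# ---------------------------------------------------------------------------
# sampler internals


def _row_logprior(theta_row, mean_row, sigma_chol):
    y = np.linalg.solve(sigma_chol, theta_row - mean_row)
    logdet = 2.0 * np.log(np.diag(sigma_chol)).sum()
    return -0.5 * (N_PARAMS * np.log(2 * np.pi) + logdet + y @ y)


def _draw_zeta(rng, Theta, T, Sigma, zeta_sd):
    n_a = T.shape[1]
    Sinv = np.linalg.inv(Sigma)
    A = T.T @ T
    prec = np.kron(Sinv, A) + np.eye(n_a * N_PARAMS) / zeta_sd**2
    b = (T.T @ Theta @ Sinv).ravel(order="F")
    chol = np.linalg.cholesky(prec)
    mean = np.linalg.solve(chol.T, np.linalg.solve(chol, b))
    z = rng.standard_normal(n_a * N_PARAMS)
    draw = mean + np.linalg.solve(chol.T, z)
    return draw.reshape(n_a, N_PARAMS, order="F")

def _draw_sigma(rng, Theta, T, zeta, iw_df, iw_scale):
    E = Theta - T @ zeta
    scale = iw_scale * np.eye(N_PARAMS) + E.T @ E
    df = iw_df + Theta.shape[0]
    return stats.invwishart.rvs(df=df, scale=scale, random_state=rng)


def default_theta_init() -> np.ndarray:
    """A diffuse but finite starting point on the transformed scale."""
    return np.array([np.log(2e5), np.log(2e5), np.log(2e5), 0.0, 0.0, np.log(0.1), 1.5])


def _init_theta(rng, loglik, n_i, config):
    base = default_theta_init()
    Theta = np.empty((n_i, N_PARAMS))
    for i in range(n_i):
        ok = False
        for attempt in range(config.max_init_attempts):
            jitter = config.init_jitter * (1 + attempt / 10.0)
            cand = base + jitter * rng.standard_normal(N_PARAMS)
            if np.isfinite(loglik(i, cand)):
                Theta[i] = cand
                ok = True
                break
        if not ok:
            raise RuntimeError(
                f"could not find a finite starting likelihood for individual {i} "
                f"after {config.max_init_attempts} attempts"
            )
    return Theta


def run_mcmc(
    data: StudyData | None,
    config: MCMCConfig,
    loglik_fn=None,
    n_individuals: int | None = None,
    trait_matrix: TraitMatrix | None = None,
) -> PosteriorChains:
    """Metropolis-within-Gibbs sampler for the hierarchical movement model.

    ``loglik_fn(i, theta_row) -> float`` overrides the movement likelihood
    (e.g. a flat function for prior-recovery checks); by default it is the
    filtering likelihood of individual i's detection history.  Draws after
    ``n_adapt`` adaptation iterations are kept (thinned by ``config.thin``);
    runs are bit-reproducible for a fixed config and seed.
    """
    if data is not None:
        T = data.traits
        n_i = T.n_individuals
        layout = LoggerLayout(data.loggers, data.mesh)
        evaluators = [
            LikelihoodEvaluator(
                h, data.mesh, layout,
                method=config.method, substeps=config.substeps, window=config.window,
            )
            for h in data.histories
        ]

        def movement_loglik(i, theta_row):
            if np.any(theta_row < SUPPORT_LO) or np.any(theta_row > SUPPORT_HI):
                return -np.inf
            return evaluators[i](theta_row)

        loglik = loglik_fn if loglik_fn is not None else movement_loglik
        ids = T.ids
    else:
        if loglik_fn is None or n_individuals is None or trait_matrix is None:
            raise ValueError("without data, provide loglik_fn, n_individuals and trait_matrix")
        T = trait_matrix
        n_i = n_individuals
        loglik = loglik_fn
        ids = T.ids
    Tm = T.matrix

    n_kept = config.n_iter // config.thin
    theta_out = np.empty((config.n_chains, n_kept, n_i, N_PARAMS))
    zeta_out = np.empty((config.n_chains, n_kept, N_TRAITS, N_PARAMS))
    sigma_out = np.empty((config.n_chains, n_kept, N_PARAMS, N_PARAMS))
    accept_out = np.zeros((config.n_chains, n_i))

    for chain in range(config.n_chains):
        rng = np.random.default_rng([int(config.seed), chain])
        Theta = _init_theta(rng, loglik, n_i, config)
        zeta = np.zeros((N_TRAITS, N_PARAMS))
        zeta[0] = Theta.mean(axis=0)
        Sigma = np.eye(N_PARAMS)

        cur_ll = np.array([loglik(i, Theta[i]) for i in range(n_i)])
        # adaptive proposal state (Haario-style) per individual
        prop_chol = [0.3 * np.eye(N_PARAMS) for _ in range(n_i)]
        log_scale = np.zeros(n_i)
        # separate scale for the (m, q)-subblock proposals; these two
        # coordinates trade off against each other in sparse histories and
        # mix poorly inside full-vector proposals, where well-identified
        # coordinates veto the move
        MQ = np.array([5, 6])
        DK = np.array([0, 1, 2, 3, 4])
        log_scale_mq = np.zeros(n_i)
        log_scale_dk = np.zeros(n_i)
        n_a = Tm.shape[1]
        joint_log_scale = np.full(n_a, np.log(0.5 / np.sqrt(n_i)))
        joint_log_scale_mq = np.log(0.5 / np.sqrt(n_i))
        # adaptive proposals for the joint moves: running moments of the
        # least-squares group-shift statistic s_a = (T' Theta)_a / (T'T)_aa
        tt_diag = np.einsum("ia,ia->a", Tm, Tm)
        js_mean = np.zeros((n_a, N_PARAMS))
        js_cov = np.tile(0.05 * np.eye(N_PARAMS), (n_a, 1, 1))
        js_chol = [None] * n_a
        run_mean = Theta.copy()
        run_cov = np.tile(0.01 * np.eye(N_PARAMS), (n_i, 1, 1))
        n_acc = np.zeros(n_i)
        n_try = np.zeros(n_i)

        total_iter = config.n_adapt + config.n_iter
        kept = 0
        for it in range(total_iter):
            M = Tm @ zeta
            sig_chol = np.linalg.cholesky(Sigma)
            adapting = it < config.n_adapt
            # proposal variants cycle: full vector, the (m, q) block, the
            # movement (D, k) block.  Sub-block moves stop well-identified
            # coordinates from vetoing steps along weakly-identified ones.
            variant = it % 3
            mq_iter = variant == 1
            for i in range(n_i):
                if rng.uniform() < 0.2:
                    # independence proposal from the row prior: acceptance
                    # is a pure likelihood ratio, so weakly-identified
                    # individuals are resampled almost i.i.d. -- this is
                    # what keeps the Sigma diagonals mixing
                    cand = M[i] + sig_chol @ rng.standard_normal(N_PARAMS)
                    cand_ll = loglik(i, cand)
                    if np.isfinite(cand_ll):
                        accept = np.log(rng.uniform()) < (cand_ll - cur_ll[i])
                    else:
                        rng.uniform()
                        accept = False
                    if accept:
                        Theta[i] = cand
                        cur_ll[i] = cand_ll
                    n_try[i] += 1
                    n_acc[i] += accept
                    delta = Theta[i] - run_mean[i]
                    run_mean[i] += delta / (it + 2.0)
                    run_cov[i] += (np.outer(delta, Theta[i] - run_mean[i]) - run_cov[i]) / (it + 2.0)
                    continue
                # 15 % heavy-tailed component helps hop between modes of
                # the mortality/detection trade-off in sparse histories
                boost = 3.0 if rng.uniform() < 0.15 else 1.0
                if variant == 1:
                    sub = run_cov[i][np.ix_(MQ, MQ)] + 1e-8 * np.eye(2)
                    L2 = np.linalg.cholesky((2.38**2 / 2) * sub)
                    step = np.zeros(N_PARAMS)
                    step[MQ] = boost * np.exp(log_scale_mq[i]) * (L2 @ rng.standard_normal(2))
                elif variant == 2:
                    sub = run_cov[i][np.ix_(DK, DK)] + 1e-8 * np.eye(5)
                    L5 = np.linalg.cholesky((2.38**2 / 5) * sub)
                    step = np.zeros(N_PARAMS)
                    step[DK] = boost * np.exp(log_scale_dk[i]) * (L5 @ rng.standard_normal(5))
                else:
                    step = boost * np.exp(log_scale[i]) * (
                        prop_chol[i] @ rng.standard_normal(N_PARAMS)
                    )
                cand = Theta[i] + step
                cand_ll = loglik(i, cand)
                if np.isfinite(cand_ll):
                    cur_lp = _row_logprior(Theta[i], M[i], sig_chol)
                    cand_lp = _row_logprior(cand, M[i], sig_chol)
                    log_alpha = (cand_ll + cand_lp) - (cur_ll[i] + cur_lp)
                    accept = np.log(rng.uniform()) < log_alpha
                else:
                    rng.uniform()  # keep the stream aligned
                    accept = False
                if accept:
                    Theta[i] = cand
                    cur_ll[i] = cand_ll
                n_try[i] += 1
                n_acc[i] += accept
                # diminishing adaptation (continues through sampling with
                # step sizes shrinking to zero, preserving ergodicity)
                gamma = min(0.1, 5.0 / np.sqrt(it + 10.0))
                inc = gamma * ((1.0 if accept else 0.0) - config.target_accept)
                if variant == 1:
                    log_scale_mq[i] += inc
                elif variant == 2:
                    log_scale_dk[i] += inc
                else:
                    log_scale[i] += inc
                delta = Theta[i] - run_mean[i]
                run_mean[i] += delta / (it + 2.0)
                run_cov[i] += (np.outer(delta, Theta[i] - run_mean[i]) - run_cov[i]) / (it + 2.0)
                if it >= 100 and (it % 50) == 0:
                    try:
                        prop_chol[i] = np.linalg.cholesky(
                            (2.38**2 / N_PARAMS) * run_cov[i] + 1e-8 * np.eye(N_PARAMS)
                        )
                    except np.linalg.LinAlgError:
                        pass
            if config.joint_every:
                # track the group-shift statistics for proposal adaptation
                s_all = (Tm.T @ Theta) / tt_diag[:, None]
                for a in range(n_a):
                    d = s_all[a] - js_mean[a]
                    js_mean[a] += d / (it + 2.0)
                    js_cov[a] += (np.outer(d, s_all[a] - js_mean[a]) - js_cov[a]) / (it + 2.0)
                if it >= 100 and (it % 50) == 0:
                    for a in range(n_a):
                        try:
                            js_chol[a] = np.linalg.cholesky(
                                (2.38**2 / N_PARAMS) * js_cov[a] + 1e-9 * np.eye(N_PARAMS)
                            )
                        except np.linalg.LinAlgError:
                            pass
                for a, period in config.joint_periods:
                    if (it % (period * config.joint_every)) != 0:
                        continue
                    load = Tm[:, a]
                    movers = np.flatnonzero(load != 0.0)
                    boost = 3.0 if rng.uniform() < 0.15 else 1.0
                    if a == 0 and mq_iter:
                        # intercept move restricted to the (m, q) subblock
                        sub = js_cov[a][np.ix_(MQ, MQ)] + 1e-10 * np.eye(2)
                        L2 = np.linalg.cholesky((2.38**2 / 2) * sub)
                        delta = np.zeros(N_PARAMS)
                        delta[MQ] = boost * np.exp(joint_log_scale_mq) * (
                            L2 @ rng.standard_normal(2)
                        )
                    else:
                        base = js_chol[a] if js_chol[a] is not None else sig_chol
                        delta = boost * np.exp(joint_log_scale[a]) * (
                            base @ rng.standard_normal(N_PARAMS)
                        )
                    cand_ll = cur_ll.copy()
                    for i in movers:
                        cand_ll[i] = loglik(i, Theta[i] + load[i] * delta)
                    if np.all(np.isfinite(cand_ll[movers])):
                        za = zeta[a]
                        dlp = -((za + delta) @ (za + delta) - za @ za) / (2 * config.zeta_sd**2)
                        log_alpha = cand_ll[movers].sum() - cur_ll[movers].sum() + dlp
                        jacc = np.log(rng.uniform()) < log_alpha
                    else:
                        rng.uniform()
                        jacc = False
                    if jacc:
                        Theta = Theta + np.outer(load, delta)
                        zeta = zeta.copy()
                        zeta[a] = zeta[a] + delta
                        cur_ll = cand_ll
                    gamma = min(0.05, 5.0 / np.sqrt(it + 10.0))
                    if a == 0 and mq_iter:
                        joint_log_scale_mq += gamma * ((1.0 if jacc else 0.0) - config.target_accept)
                    else:
                        joint_log_scale[a] += gamma * ((1.0 if jacc else 0.0) - config.target_accept)
            zeta = _draw_zeta(rng, Theta, Tm, Sigma, config.zeta_sd)
            Sigma = _draw_sigma(rng, Theta, Tm, zeta, config.iw_df, config.iw_scale)
            if not adapting:
                j = it - config.n_adapt
                if (j % config.thin) == 0 and kept < n_kept:
                    theta_out[chain, kept] = Theta
                    zeta_out[chain, kept] = zeta
                    sigma_out[chain, kept] = Sigma
                    kept += 1
        accept_out[chain] = n_acc / np.maximum(n_try, 1)

    return PosteriorChains(
        theta=theta_out,
        zeta=zeta_out,
        sigma=sigma_out,
        acceptance=accept_out,
        config=config,
        individual_ids=list(ids),
    )


# ---------------------------------------------------------------------------
# diagnostics and trait summaries


def psrf(x: np.ndarray) -> float:
    """Gelman-Rubin potential scale reduction factor for one scalar.

    ``x`` has shape (n_chains, n_draws).  Returns NaN when the within-chain
    variance is zero (PSRF undefined).
    """
    x = np.asarray(x, dtype=float)
    m, n = x.shape
    if m < 2:
        raise ValueError("PSRF requires at least 2 chains")
    if n < 10:
        raise ValueError("PSRF requires chains of length >= 10")
    W = x.var(axis=1, ddof=1).mean()
    B_over_n = x.mean(axis=1).var(ddof=1)
    if W <= 0:
        return float("nan")
    var_hat = (n - 1) / n * W + (1.0 + 1.0 / m) * B_over_n
    return float(np.sqrt(var_hat / W))


def gelman_rubin(chains: PosteriorChains | dict[str, np.ndarray]) -> pd.Series:
    """PSRF for every scalar parameter.

    Accepts a PosteriorChains object or a mapping name -> (n_chains,
    n_draws) array.  Identical (duplicated) chains are rejected: the
    diagnostic requires independently run chains.
    """
    scal = chains.scalar_chains() if isinstance(chains, PosteriorChains) else dict(chains)
    for name, arr in scal.items():
        arr = np.asarray(arr)
        for a in range(arr.shape[0]):
            for b in range(a + 1, arr.shape[0]):
                if np.array_equal(arr[a], arr[b]):
                    raise ValueError(
                        f"{name}: chains {a} and {b} are identical; "
                        "Gelman-Rubin requires independent chains"
                    )
    return pd.Series({name: psrf(np.asarray(arr)) for name, arr in scal.items()})


def trait_summaries(chains: PosteriorChains, T: TraitMatrix) -> pd.DataFrame:
    """Per-parameter trait effects: p_w, p_s, r2_w, r2_s, r2_i.

    p_w (p_s) is the posterior probability that the weight (sex) effect is
    positive.  r2_w (r2_s) is the share of across-individual variance of
    the parameter explained by the weight (sex) component of the trait
    expectation, averaged over posterior draws; r2_i = 1 - r2_w - r2_s
    (floored at zero) is the idiosyncratic share.
    """
    zeta = chains.zeta_pooled()  # (draws, 3, 7)
    theta = chains.theta_pooled()  # (draws, n_i, 7)
    sex = T.matrix[:, 1]
    logw = T.matrix[:, 2]
    names = IndividualParams.NAMES
    rows = []
    sex_ok = len(np.unique(sex)) > 1
    w_ok = len(np.unique(logw)) > 1
    if not sex_ok:
        warnings.warn("fewer than 2 distinct sex values; r2_s reported as 0")
    if not w_ok:
        warnings.warn("fewer than 2 distinct weights; r2_w reported as 0")
    for p in range(N_PARAMS):
        p_s = float((zeta[:, 1, p] > 0).mean())
        p_w = float((zeta[:, 2, p] > 0).mean())
        var_theta = theta[:, :, p].var(axis=1, ddof=1)
        good = var_theta > 0
        with np.errstate(divide="ignore", invalid="ignore"):
            r2w_draws = np.var(np.outer(zeta[:, 2, p], logw), axis=1, ddof=1) / var_theta
            r2s_draws = np.var(np.outer(zeta[:, 1, p], sex), axis=1, ddof=1) / var_theta
        r2_w = float(np.clip(r2w_draws[good], 0, 1).mean()) if (w_ok and good.any()) else 0.0
        r2_s = float(np.clip(r2s_draws[good], 0, 1).mean()) if (sex_ok and good.any()) else 0.0
        r2_i = max(0.0, 1.0 - r2_w - r2_s)
        rows.append((names[p], p_w, p_s, r2_w, r2_s, r2_i))
    return pd.DataFrame(rows, columns=["parameter", "p_w", "p_s", "r2_w", "r2_s", "r2_i"]).set_index(
        "parameter"
    )
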