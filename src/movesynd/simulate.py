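"""Forward simulation of movement tracks and detection histories.

Tracks are simulated as a continuous-time Markov chain on mesh vertices
whose generator is the lumped-mass finite-element discretization of the
diffusion operator -- the very same generator whose exponential the
likelihood uses as its transition kernel.  Simulator and likelihood thus
share one discrete model, and agreement between the two is exact up to
Monte-Carlo error (the equivalence is at the discretization level, not the
continuum level).  An independent exponential clock with rate m truncates
each track at the battery-death time.

Two samplers are provided: :func:`simulate_track` draws the full jump path
(Gillespie), while :func:`simulate_slot_positions` draws only the 12-hour
slot marginals of many replicate tracks at once from the dense transition
matrix -- the workhorse of the posterior-predictive machinery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diffusion import DiffusionParams, Propagator, generator_rates
from .landscape import Mesh
from .likelihood import (
    NO_DETECTION,
    RELEASE,
    DetectionHistory,
    IndividualParams,
    LoggerLayout,
)


@dataclass
class Track:
    """A continuous-time jump path on mesh vertices.

    ``times[j]`` (days) is the arrival time at ``vertices[j]``; the first
    entry is the release (time 0).  ``death_time`` may exceed the horizon,
    in which case the individual outlived the study window.
    """

    individual_id: str
    times: np.ndarray
    vertices: np.ndarray
    mesh: Mesh
    death_time: float

    @property
    def coords(self) -> np.ndarray:
        return self.mesh.vertices[self.vertices]

    def vertex_at(self, t: float) -> int:
        """Vertex occupied at time t (days since release)."""
        j = int(np.searchsorted(self.times, t, side="right")) - 1
        return int(self.vertices[max(j, 0)])

    def to_frame(self) -> pd.DataFrame:
        xy = self.coords
        return pd.DataFrame(
            {
                "id": self.individual_id,
                "t_days": self.times,
                "x": xy[:, 0],
                "y": xy[:, 1],
            }
        )


def _column_tables(rates):
    """Per-vertex outflow rate and cumulative neighbour probabilities."""
    R = rates.tocsc()
    n = R.shape[1]
    out_rate = np.asarray(R.sum(axis=0)).ravel()
    nbrs, cums = [], []
    for v in range(n):
        lo, hi = R.indptr[v], R.indptr[v + 1]
        idx = R.indices[lo:hi]
        val = R.data[lo:hi]
        nbrs.append(idx)
        cums.append(np.cumsum(val) / val.sum() if val.size else np.empty(0))
    return out_rate, nbrs, cums


def simulate_track(
    theta: IndividualParams | DiffusionParams,
    mesh: Mesh,
    start_vertex: int,
    horizon_days: float,
    rng: np.random.Generator,
    individual_id: str = "sim",
) -> Track:
    """Gillespie simulation of one track up to the horizon or death."""
    if horizon_days <= 0:
        raise ValueError("horizon must be positive")
    params = theta.to_diffusion() if isinstance(theta, IndividualParams) else theta
    rates, _ = generator_rates(mesh, params)
    out_rate, nbrs, cums = _column_tables(rates)
    if out_rate[start_vertex] <= 0:
        raise ValueError(f"start vertex {start_vertex} has no positive outflow rate")
    death = rng.exponential(1.0 / params.m) if params.m > 0 else np.inf
    stop = min(horizon_days, death)
    t = 0.0
    v = int(start_vertex)
    times, verts = [0.0], [v]
    while True:
        r = out_rate[v]
        if r <= 0:
            raise ValueError(f"vertex {v} has no positive outflow rate")
        t += rng.exponential(1.0 / r)
        if t >= stop:
            break
        v = int(nbrs[v][np.searchsorted(cums[v], rng.uniform())])
        times.append(t)
        verts.append(v)
    return Track(
        individual_id=individual_id,
        times=np.array(times),
        vertices=np.array(verts, dtype=np.int64),
        mesh=mesh,
        death_time=float(death),
    )


def simulate_detections(
    track: Track,
    layout: LoggerLayout,
    q: float,
    rng: np.random.Generator,
    n_steps: int,
    step_days: float = 0.5,
) -> DetectionHistory:
    """Thin a track into a 12-hour-slot detection history.

    At each slot after release the individual is detected with probability
    q if it is alive and inside some detection region; the detecting logger
    is the nearest one whose region covers the occupied vertex.  Slot 0 is
    the release observation.
    """
    obs = np.full(n_steps + 1, NO_DETECTION, dtype=np.int64)
    obs[0] = RELEASE
    for t in range(1, n_steps + 1):
        tt = t * step_days
        if tt >= track.death_time:
            break
        v = track.vertex_at(tt)
        j = layout.vertex_logger[v]
        if j >= 0 and rng.uniform() < q:
            obs[t] = j
    release_xy = tuple(track.mesh.vertices[track.vertices[0]])
    return DetectionHistory(
        individual_id=track.individual_id,
        release_xy=release_xy,
        obs=obs,
        step_days=step_days,
    )


# ---------------------------------------------------------------------------
# batch slot-marginal sampling


def slot_transition_matrix(
    theta: IndividualParams, mesh: Mesh, step_days: float = 0.5
) -> np.ndarray:
    """Row-stochastic 12-hour transition matrix of the vertex CTMC."""
    prop = Propagator(mesh, theta.to_diffusion(), step_days=step_days, method="exact")
    return prop.transition_matrix()


def simulate_slot_histories(
    theta: IndividualParams,
    mesh: Mesh,
    layout: LoggerLayout,
    start_vertex: int,
    n_steps: int,
    n_rep: int,
    rng: np.random.Generator,
    step_days: float = 0.5,
    transition: np.ndarray | None = None,
) -> np.ndarray:
    """Slot observations of ``n_rep`` replicate tracks of one individual.

    Returns an (n_rep, n_steps + 1) int array in the DetectionHistory
    coding (RELEASE at slot 0, logger index or -1 afterwards).  Sampling
    uses the exact CTMC slot marginals (dense transition matrix, shared
    across replicates) and the exact exp(-m dt) per-slot survival, so the
    output distribution coincides with the likelihood filter's model.
    """
    P = transition if transition is not None else slot_transition_matrix(theta, mesh, step_days)
    cum = np.cumsum(P, axis=1)
    params = theta.to_diffusion()
    q = theta.q
    survive = np.exp(-params.m * step_days)
    obs = np.full((n_rep, n_steps + 1), NO_DETECTION, dtype=np.int64)
    obs[:, 0] = RELEASE
    cur = np.full(n_rep, start_vertex, dtype=np.int64)
    alive = np.ones(n_rep, dtype=bool)
    for t in range(1, n_steps + 1):
        alive &= rng.uniform(size=n_rep) < survive
        u = rng.uniform(size=n_rep)
        rows = cum[cur]
        cur = (rows < u[:, None]).sum(axis=1).astype(np.int64)
        logger = layout.vertex_logger[cur]
        detected = alive & (logger >= 0) & (rng.uniform(size=n_rep) < q)
        obs[detected, t] = logger[detected]
    return obs


def slot_occupancy(
    theta: IndividualParams,
    mesh: Mesh,
    start_vertex: int,
    n_steps: int,
    n_rep: int,
    rng: np.random.Generator,
    step_days: float = 0.5,
) -> np.ndarray:
    """Empirical vertex-occupancy histograms of Gillespie tracks per slot.

    Conditions on survival (m is ignored); used to cross-check the full
    jump-path simulator against the propagated FE densities.
    """
    params = theta.to_diffusion() if isinstance(theta, IndividualParams) else theta
    params = DiffusionParams(D=params.D, k=params.k, m=0.0)
    rates, _ = generator_rates(mesh, params)
    out_rate, nbrs, cums = _column_tables(rates)
    horizon = n_steps * step_days
    counts = np.zeros((n_steps + 1, mesh.n_vertices))
    for _ in range(n_rep):
        t, v = 0.0, int(start_vertex)
        next_slot = 0
        while next_slot <= n_steps:
            t_jump = t + rng.exponential(1.0 / out_rate[v])
            while next_slot <= n_steps and next_slot * step_days < t_jump:
                counts[next_slot, v] += 1
                next_slot += 1
            if t_jump > horizon:
                break
            v = int(nbrs[v][np.searchsorted(cums[v], rng.uniform())])
            t = t_jump
    return counts / n_rep


# ---------------------------------------------------------------------------
# posterior predictive


def posterior_predictive(
    chains,
    study,
    n_rep: int = 1000,
    seed: int = 0,
    at: str = "draws",
    step_days: float = 0.5,
):
    """Replicate the observed study design under the fitted model.

    For each of ``n_rep`` replicates, individual parameters are taken from
    a random posterior draw (``at='draws'``) or fixed at the posterior mean
    (``at='mean'``), every individual is re-released at its observed
    release location for the same number of slots, and the S1-S16
    statistics are recomputed.  Returns ``(population, per_individual)``:
    the (n_rep, 16) population-mean statistic table (individuals with no
    detections dropped from the mean) and the (n_i, 16) across-replicate
    mean per individual, the predictive baseline for the residual matrix.
    """
    from .stats import STAT_NAMES, compute_stats, logger_habitats

    rng = np.random.default_rng(seed)
    layout = LoggerLayout(study.loggers, study.mesh)
    hab = study.logger_habitat
    n_i = len(study.histories)
    theta_draws = chains.theta_pooled() if hasattr(chains, "theta_pooled") else np.asarray(chains)
    theta_mean = theta_draws.mean(axis=0)

    start_vertices = [study.mesh.nearest_vertex(*h.release_xy) for h in study.histories]
    n_steps = [h.n_steps for h in study.histories]

    pop = np.full((n_rep, 16), np.nan)
    ind_sum = np.zeros((n_i, 16))
    ind_cnt = np.zeros((n_i, 16))

    if at == "mean":
        transitions = [
            slot_transition_matrix(IndividualParams.from_array(theta_mean[i]), study.mesh, step_days)
            for i in range(n_i)
        ]
    elif at != "draws":
        raise ValueError(f"unknown predictive mode {at!r}")

    for r in range(n_rep):
        if at == "draws":
            d = rng.integers(theta_draws.shape[0])
            thetas = theta_draws[d]
            transitions = [None] * n_i
        else:
            thetas = theta_mean
        rows = np.full((n_i, 16), np.nan)
        for i in range(n_i):
            th = IndividualParams.from_array(thetas[i])
            obs = simulate_slot_histories(
                th,
                study.mesh,
                layout,
                start_vertices[i],
                n_steps[i],
                1,
                rng,
                step_days,
                transition=transitions[i],
            )[0]
            if (obs >= 0).sum() == 0:
                continue  # never detected: statistics undefined, dropped
            h = DetectionHistory(
                individual_id=study.histories[i].individual_id,
                release_xy=study.histories[i].release_xy,
                obs=obs,
                step_days=step_days,
            )
            rows[i] = compute_stats(h, study.loggers, hab).to_numpy()
        if np.any(~np.isnan(rows)):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                pop[r] = np.nanmean(rows, axis=0)
        got = ~np.isnan(rows)
        ind_sum[got] += rows[got]
        ind_cnt[got] += 1

    with np.errstate(invalid="ignore"):
        ind_mean = np.where(ind_cnt > 0, ind_sum / np.maximum(ind_cnt, 1), np.nan)
    ids = [h.individual_id for h in study.histories]
    population = pd.DataFrame(pop, columns=STAT_NAMES)
    per_individual = pd.DataFrame(ind_mean, index=ids, columns=STAT_NAMES)
    return population, per_individual
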