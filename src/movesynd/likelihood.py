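"""Observation model: filtering likelihood of a detection history.

A detection history records, for 12-hour slots from release to the study
end, either the datalogger that detected the individual or no detection.
The likelihood alternates diffusion propagation with observation updates of
a forward filter over (live location density, dead probability):

* detection by logger j: the individual is alive inside A_j and detected
  with probability q, so the filter increment is q times the live mass in
  A_j and the posterior mass is confined to A_j;
* no detection: the individual is either dead (batteries never report), or
  alive outside every detection area, or alive inside one but missed with
  probability 1 - q.

Detection regions are resolved to mesh-vertex sets, so the filter and the
continuous-time track simulator (which jumps between the same vertices)
describe one and the same discrete state space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diffusion import DensityField, DiffusionParams, Propagator
from .landscape import Datalogger, Mesh

NO_DETECTION = -1
#: slot-0 marker: the individual was observed at its known release location
#: (the capture), which need not be a datalogger.
RELEASE = -2


class DataError(ValueError):
    """Raised for malformed or inconsistent detection data."""


# ---------------------------------------------------------------------------
# parameter vector


@dataclass
class IndividualParams:
    """The seven per-individual movement parameters on transformed scales.

    Order: log D^1, log D^2, log D^3, log k^2, log k^3, log m, logit q.
    """

    log_D1: float
    log_D2: float
    log_D3: float
    log_k2: float
    log_k3: float
    log_m: float
    logit_q: float

    #: canonical parameter labels, matching the transformed-scale order
    NAMES = ("D1", "D2", "D3", "K2", "K3", "m", "q")

    def to_array(self) -> np.ndarray:
        return np.array(
            [self.log_D1, self.log_D2, self.log_D3, self.log_k2,
             self.log_k3, self.log_m, self.logit_q]
        )

    @classmethod
    def from_array(cls, theta) -> "IndividualParams":
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (7,):
            raise ValueError(f"expected 7 parameters, got shape {theta.shape}")
        return cls(*theta)

    @property
    def q(self) -> float:
        return float(1.0 / (1.0 + np.exp(-self.logit_q)))

    def to_diffusion(self) -> DiffusionParams:
        from .landscape import FOREST, MATRIX, OPEN

        return DiffusionParams(
            D={FOREST: np.exp(self.log_D1), MATRIX: np.exp(self.log_D2), OPEN: np.exp(self.log_D3)},
            k={FOREST: 1.0, MATRIX: np.exp(self.log_k2), OPEN: np.exp(self.log_k3)},
            m=float(np.exp(self.log_m)),
        )


# ---------------------------------------------------------------------------
# detection histories


@dataclass
class DetectionHistory:
    """Per-individual sequence of 12-hour observation slots.

    ``obs[t]`` for t = 0..n_steps is the logger *index* (into the study's
    logger list) that detected the individual at slot t, -1 for no
    detection, or the RELEASE marker (-2), allowed only at slot 0.  Slot 0
    is always an observation of the individual -- either its release
    (capture) at the known ``release_xy``, or a detection by a logger --
    and the filter conditions on it rather than scoring it.
    """

    individual_id: str
    release_xy: tuple[float, float]
    obs: np.ndarray
    step_days: float = 0.5

    def __post_init__(self):
        self.obs = np.asarray(self.obs, dtype=np.int64)
        if self.obs.ndim != 1 or len(self.obs) < 1:
            raise DataError(f"{self.individual_id}: empty observation sequence")
        if self.obs[0] == NO_DETECTION:
            raise DataError(f"{self.individual_id}: first observation must be a detection/release")
        if np.any(self.obs[1:] < NO_DETECTION):
            raise DataError(f"{self.individual_id}: RELEASE marker allowed only at slot 0")

    @property
    def n_steps(self) -> int:
        return len(self.obs) - 1

    @property
    def detection_steps(self) -> np.ndarray:
        """Slots with a datalogger detection (the release marker is not one)."""
        return np.flatnonzero(self.obs >= 0)

    @property
    def n_detections(self) -> int:
        return int((self.obs >= 0).sum())

    @property
    def last_detection_step(self) -> int:
        det = self.detection_steps
        return int(det[-1]) if len(det) else 0


RELEASE_LABEL = "__release__"


def histories_to_frame(histories: list[DetectionHistory], logger_ids: list[str]) -> pd.DataFrame:
    """Tidy CSV dialect: individual_id, step_index, logger_id, x, y.

    ``logger_id`` is empty for undetected slots and ``__release__`` for a
    slot-0 release observation; the release coordinates are written in the
    x/y columns of slot 0.
    """
    rows = []
    for h in histories:
        for t, o in enumerate(h.obs):
            label = RELEASE_LABEL if o == RELEASE else (logger_ids[o] if o >= 0 else "")
            rows.append(
                {
                    "individual_id": h.individual_id,
                    "step_index": t,
                    "logger_id": label,
                    "x": h.release_xy[0] if t == 0 else "",
                    "y": h.release_xy[1] if t == 0 else "",
                }
            )
    return pd.DataFrame(rows)


def write_histories_csv(histories, logger_ids, path) -> None:
    histories_to_frame(histories, logger_ids).to_csv(path, index=False)


def read_histories_csv(path, loggers: list[Datalogger]) -> list[DetectionHistory]:
    """Read the detections CSV dialect written by :func:`write_histories_csv`.

    Multiple raw records within one slot collapse to a single detection; if
    records name different loggers, the most frequent one wins (ties go to
    the logger nearest the previous detection).
    """
    df = pd.read_csv(path, dtype={"individual_id": str, "logger_id": str}, keep_default_na=False)
    index_of = {lg.id: i for i, lg in enumerate(loggers)}
    out = []
    for ind, grp in df.groupby("individual_id", sort=True):
        n = int(grp["step_index"].max())
        obs = np.full(n + 1, NO_DETECTION, dtype=np.int64)
        release = None
        prev_xy = None
        for t in sorted(grp["step_index"].unique()):
            sel = grp["step_index"] == t
            if t == 0 and (grp.loc[sel, "logger_id"] == RELEASE_LABEL).any():
                obs[0] = RELEASE
                r = grp.loc[sel].iloc[0]
                release = (float(r["x"]), float(r["y"]))
                continue
            recs = grp.loc[sel & (grp["logger_id"] != ""), "logger_id"]
            if recs.empty:
                continue
            counts = recs.value_counts()
            best = counts[counts == counts.max()].index.tolist()
            for lid in best:
                if lid not in index_of:
                    raise DataError(f"{ind}: detection by unknown logger {lid!r}")
            if len(best) > 1 and prev_xy is not None:
                best.sort(
                    key=lambda lid: (loggers[index_of[lid]].x - prev_xy[0]) ** 2
                    + (loggers[index_of[lid]].y - prev_xy[1]) ** 2
                )
            choice = index_of[best[0]]
            obs[int(t)] = choice
            prev_xy = (loggers[choice].x, loggers[choice].y)
        if obs[0] == NO_DETECTION:
            raise DataError(f"{ind}: history does not start with a detection or release")
        if release is None:
            lg = loggers[obs[0]]
            release = (lg.x, lg.y)
        out.append(DetectionHistory(individual_id=str(ind), release_xy=release, obs=obs))
    return out


# ---------------------------------------------------------------------------
# logger layout on a mesh


class LoggerLayout:
    """Mesh-resolved detection regions.

    ``membership[j]`` is the boolean vertex-indicator of logger j's
    (area-doubled) detection disc; ``union`` the indicator of any region;
    ``vertex_logger[v]`` the logger claiming vertex v (nearest centre among
    covering loggers; -1 outside all regions) -- used by the simulator to
    attribute a detection when regions overlap.
    """

    def __init__(self, loggers: list[Datalogger], mesh: Mesh):
        if not loggers:
            raise DataError("empty logger list")
        self.loggers = loggers
        self.mesh = mesh
        self.ids = [lg.id for lg in loggers]
        self.xy = np.array([[lg.x, lg.y] for lg in loggers])
        n_v = mesh.n_vertices
        self.membership = np.zeros((len(loggers), n_v), dtype=bool)
        for j, lg in enumerate(loggers):
            d2 = ((mesh.vertices - self.xy[j]) ** 2).sum(axis=1)
            self.membership[j] = d2 <= lg.effective_radius**2
            if not self.membership[j].any():
                # on a coarse mesh a small disc may cover no vertex; the
                # region is then resolved to the nearest vertex so the
                # logger keeps a nonempty discrete footprint
                self.membership[j, int(np.argmin(d2))] = True
        self.union = self.membership.any(axis=0)
        dist2 = ((mesh.vertices[None, :, :] - self.xy[:, None, :]) ** 2).sum(axis=2)
        dist2[~self.membership] = np.inf
        self.vertex_logger = np.where(self.union, dist2.argmin(axis=0), -1).astype(np.int64)

    @property
    def n_loggers(self) -> int:
        return len(self.loggers)


# ---------------------------------------------------------------------------
# filter


def step_update(mass, dead_mass, obs, q, layout: LoggerLayout):
    """One (unnormalized) observation update of the forward filter.

    Parameters are the live mass vector, the scalar dead mass, the observed
    logger index (or -1), the detection probability and the mesh-resolved
    logger layout.  Returns ``(mass', dead_mass', likelihood)`` where the
    likelihood is the unnormalized filter increment for this slot.
    """
    mass = np.asarray(mass, dtype=float)
    total = mass.sum() + dead_mass
    if total > 1 + 1e-9:
        raise ValueError("filter mass exceeds 1")
    if obs is None:
        obs = NO_DETECTION
    if obs >= 0:
        if obs >= layout.n_loggers:
            raise DataError(f"detection by unknown logger index {obs}")
        ind = layout.membership[obs]
        new_mass = np.where(ind, q * mass, 0.0)
        lik = float(new_mass.sum())
        return new_mass, 0.0, lik
    weight = np.where(layout.union, 1.0 - q, 1.0)
    new_mass = mass * weight
    lik = float(new_mass.sum() + dead_mass)
    return new_mass, dead_mass, lik


class LikelihoodEvaluator:
    """Reusable filtering-likelihood evaluator for one detection history.

    Precomputes everything that does not depend on the parameters (the
    windowed observation sequence, the release start vector, the
    mesh-resolved detection regions and the per-habitat unit operators) so
    that repeated evaluation inside the sampler costs only the
    parameter-dependent linear algebra.  ``__call__`` takes the 7-vector
    on the transformed scale and returns the log-likelihood (-inf for an
    impossible detection, never raising).
    """

    def __init__(
        self,
        history: DetectionHistory,
        mesh: Mesh,
        layout: LoggerLayout,
        *,
        method: str = "exact",
        substeps: int = 8,
        window: str = "study_end",
        smooth_release: bool = False,
    ):
        from .diffusion import HABITATS, unit_operators

        if history.obs.max() >= layout.n_loggers:
            raise DataError(f"{history.individual_id}: detection by unknown logger index")
        if window == "last_detection":
            self.obs = history.obs[: history.last_detection_step + 1]
        elif window == "study_end":
            self.obs = history.obs
        else:
            raise ValueError(f"unknown likelihood window {window!r}")
        self.mesh = mesh
        self.layout = layout
        self.method = method
        self.substeps = substeps
        self.step_days = history.step_days
        start = DensityField.point_mass(mesh, *history.release_xy, smooth=smooth_release)
        self.start_mass = start.mass / start.mass.sum()
        ops = unit_operators(mesh)
        self._dense = method == "exact" and ops.K_dense is not None
        if self._dense:
            self._K_dense = ops.K_dense
            self._a_dense = ops.a_dense
        self._habitats = HABITATS

    def _dense_kernel(self, D, k):
        from scipy.linalg import eigh

        kvec = np.array([1.0, k[0], k[1]])
        dk = np.array([D[0], D[1] * k[0], D[2] * k[1]])
        M = kvec @ self._a_dense
        K = np.tensordot(dk, self._K_dense, axes=1)
        s = 1.0 / np.sqrt(M)
        sym = K * (-s[:, None] * s[None, :])
        sym += sym.T
        sym *= 0.5
        lam, V = eigh(sym, check_finite=False, overwrite_a=True)
        lam = np.minimum(lam, 0.0)
        core = (V * np.exp(lam * self.step_days)) @ V.T
        P = core * (np.sqrt(M)[:, None] * s[None, :])
        np.maximum(P, 0.0, out=P)
        P /= P.sum(axis=0, keepdims=True)
        return P

    def __call__(self, theta) -> float:
        theta = np.asarray(theta, dtype=float)
        D = np.exp(theta[:3])
        k = np.exp(theta[3:5])
        m = np.exp(theta[5])
        q = 1.0 / (1.0 + np.exp(-theta[6]))
        survival = np.exp(-m * self.step_days)
        if self._dense:
            P = self._dense_kernel(D, k)
            step_live = P.__matmul__
        else:
            from .landscape import FOREST, MATRIX, OPEN

            params = DiffusionParams(
                D={FOREST: D[0], MATRIX: D[1], OPEN: D[2]},
                k={FOREST: 1.0, MATRIX: k[0], OPEN: k[1]},
                m=m,
            )
            prop = Propagator(
                self.mesh, params, step_days=self.step_days,
                method=self.method, substeps=self.substeps,
            )
            step_live = prop.step_live

        membership = self.layout.membership
        union = self.layout.union
        none_weight = np.where(union, 1.0 - q, 1.0)
        mass = self.start_mass
        dead = 0.0
        logL = 0.0
        obs = self.obs
        for t in range(1, len(obs)):
            live = step_live(mass)
            total_live = live.sum()
            dead = dead + (1.0 - survival) * total_live
            o = obs[t]
            if o >= 0:
                inside = membership[o]
                lik = survival * q * live[inside].sum()
                if not (lik > 0.0) or not np.isfinite(lik):
                    return -np.inf
                full = np.zeros_like(live)
                full[inside] = survival * q * live[inside]
                mass = full / lik
                dead = 0.0
            else:
                mass = survival * live * none_weight
                lik = mass.sum() + dead
                if not (lik > 0.0) or not np.isfinite(lik):
                    return -np.inf
                mass /= lik
                dead /= lik
            logL += np.log(lik)
        return float(logL)


def log_likelihood(
    theta: IndividualParams,
    history: DetectionHistory,
    mesh: Mesh,
    loggers,
    *,
    method: str = "exact",
    substeps: int = 8,
    window: str = "study_end",
    layout: LoggerLayout | None = None,
    smooth_release: bool = False,
) -> float:
    """Log-likelihood log p(y | theta) of one detection history.

    The filter starts as a point mass at the release vertex (unsmoothed by
    default, matching the track simulator's point start; see
    ``smooth_release``), conditioned on the slot-0 observation, then
    alternates 12-hour propagation (with the exact exp(-m dt) survival
    factor moved into the dead mass) and observation updates.
    ``window='study_end'`` scores every slot to the end of the history so
    trailing non-detections inform mortality; ``window='last_detection'``
    stops at the last detection.

    Returns -inf (never raises) when an observed detection has zero filter
    mass in the detecting region.
    """
    layout = layout or LoggerLayout(loggers, mesh)
    evaluator = LikelihoodEvaluator(
        history, mesh, layout,
        method=method, substeps=substeps, window=window, smooth_release=smooth_release,
    )
    return evaluator(theta.to_array() if isinstance(theta, IndividualParams) else theta)
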