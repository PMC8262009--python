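"""The sixteen movement statistics and the residual matrix for clustering.

S1-S8 are the means, over the slots in which the individual was detected,
of the detecting loggers' landscape attributes (FC, OA, MA, HE, NN, PI, SO,
CE).  S9/S10 are the fractions of detections at loggers in forest / open
habitat, S11 the fraction of consecutive detections with a habitat change,
S12 the mean distance between consecutive detections (m), S13 the distance
from first to last detection (m), S14 the number of distinct receivers, S15
the share of detections at the modal receiver, and S16 the fraction of
slots with a detection within the first-to-last-detection window.

"Consecutive" always means consecutive *detections*: intervening
undetected slots are skipped.  For a single-detection history S11 and S12
are undefined (NaN), S13 = 0 and S16 = 1.

The residual matrix for syndrome detection has 23 columns: the 16
residual statistics (observed minus posterior-predictive mean) followed by
the posterior means of the 7 transformed movement parameters, each column
z-scored across individuals.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .landscape import FOREST, LOGGER_ATTRIBUTES, OPEN, Datalogger, HabitatPolygonSet
from .likelihood import DetectionHistory

STAT_NAMES = [f"S{i}" for i in range(1, 17)]
PARAM_COLUMNS = ["K2", "K3", "m", "D1", "D2", "D3", "q"]
#: Theta column index (transformed-scale order) of each residual-matrix
#: parameter column
_PARAM_THETA_INDEX = {"K2": 3, "K3": 4, "m": 5, "D1": 0, "D2": 1, "D3": 2, "q": 6}


def logger_habitats(loggers: list[Datalogger], habitat: HabitatPolygonSet) -> np.ndarray:
    """Habitat class at each logger location."""
    return np.array([habitat.habitat_at(lg.x, lg.y) for lg in loggers], dtype=np.int64)


def compute_stats(
    history: DetectionHistory,
    loggers: list[Datalogger],
    logger_habitat: np.ndarray,
) -> pd.Series:
    """The S1-S16 summary vector of one detection history.

    ``logger_habitat[j]`` is the habitat class at logger j (see
    :func:`logger_habitats`).  Statistics are detection-weighted: a logger
    detecting the individual in five slots contributes five times.
    """
    det = history.detection_steps
    if len(det) == 0:
        raise ValueError(f"{history.individual_id}: empty history")
    idx = history.obs[det]
    attr = pd.DataFrame(
        [[loggers[j].attributes[k] for k in LOGGER_ATTRIBUTES] for j in idx],
        columns=LOGGER_ATTRIBUTES,
    )
    xy = np.array([[loggers[j].x, loggers[j].y] for j in idx])
    hab = logger_habitat[idx]

    out = {}
    for s, col in zip(STAT_NAMES[:8], LOGGER_ATTRIBUTES):
        out[s] = float(attr[col].mean())
    out["S9"] = float((hab == FOREST).mean())
    out["S10"] = float((hab == OPEN).mean())
    n = len(det)
    if n >= 2:
        out["S11"] = float((hab[1:] != hab[:-1]).mean())
        out["S12"] = float(np.linalg.norm(np.diff(xy, axis=0), axis=1).mean())
    else:
        out["S11"] = np.nan
        out["S12"] = np.nan
    out["S13"] = float(np.linalg.norm(xy[-1] - xy[0]))
    out["S14"] = float(len(np.unique(idx)))
    out["S15"] = float(pd.Series(idx).value_counts().iloc[0] / n)
    span = det[-1] - det[0] + 1
    out["S16"] = float(n / span)
    return pd.Series(out, index=STAT_NAMES)


def stats_table(
    histories: list[DetectionHistory],
    loggers: list[Datalogger],
    logger_habitat: np.ndarray,
) -> pd.DataFrame:
    """S1-S16 per individual; individuals with no detections are skipped."""
    rows, ids = [], []
    for h in histories:
        if h.n_detections == 0:
            continue
        rows.append(compute_stats(h, loggers, logger_habitat))
        ids.append(h.individual_id)
    return pd.DataFrame(rows, index=ids)


def zscore_columns(df: pd.DataFrame) -> pd.DataFrame:
    """Column-wise z-scoring; zero-variance columns are dropped with a warning.

    NaN cells (undefined statistics of single-detection individuals) are
    excluded from the moments and mean-imputed to 0 afterwards.
    """
    out = {}
    dropped = []
    for col in df.columns:
        v = df[col].to_numpy(dtype=float)
        mu = np.nanmean(v)
        sd = np.nanstd(v, ddof=1)
        if not np.isfinite(sd) or sd <= 0:
            dropped.append(col)
            continue
        z = (v - mu) / sd
        out[col] = np.where(np.isnan(z), 0.0, z)
    if dropped:
        warnings.warn(f"zero-variance columns excluded from z-scoring: {dropped}")
    return pd.DataFrame(out, index=df.index)


def residual_stats(
    observed: pd.DataFrame,
    predictive_means: pd.DataFrame,
    theta_posterior_mean: np.ndarray,
    normalize: bool = True,
) -> pd.DataFrame:
    """The n_i x 23 residual matrix for syndrome detection.

    ``observed`` and ``predictive_means`` are S1-S16 tables indexed by
    individual; ``theta_posterior_mean`` the (n_i, 7) posterior means of
    the transformed parameters, rows aligned with ``observed``.  Residual =
    observed - predictive mean; the parameter columns are appended under
    their conventional labels (K2, K3, m, D1, D2, D3, q, still on the
    log / logit scale) and all columns are z-scored across individuals.
    """
    if list(observed.columns) != STAT_NAMES or list(predictive_means.columns) != STAT_NAMES:
        raise ValueError("observed and predictive tables must have columns S1..S16")
    if not observed.index.equals(predictive_means.index):
        raise ValueError("observed and predictive tables must be indexed identically")
    theta = np.asarray(theta_posterior_mean, dtype=float)
    if theta.shape != (len(observed), 7):
        raise ValueError("theta_posterior_mean must be (n_individuals, 7)")
    resid = observed - predictive_means
    params = pd.DataFrame(
        {c: theta[:, _PARAM_THETA_INDEX[c]] for c in PARAM_COLUMNS}, index=observed.index
    )
    full = pd.concat([resid, params], axis=1)
    if not normalize:
        return full
    return zscore_columns(full)
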