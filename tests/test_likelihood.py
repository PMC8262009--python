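"""Observation model: filter updates, likelihood, simulation oracle."""

import numpy as np
import pytest

from movesynd.likelihood import (
    NO_DETECTION,
    RELEASE,
    DataError,
    DetectionHistory,
    IndividualParams,
    LoggerLayout,
    log_likelihood,
    step_update,
)
from movesynd.landscape import Datalogger, Mesh
from movesynd.simulate import simulate_slot_histories


def make_logger(id, x, y, radius):
    # detect_radius is area-doubled internally; undo so the effective
    # radius equals the requested one
    return Datalogger(id=id, x=x, y=y, detect_radius_m=radius / np.sqrt(2), attributes={})


def theta(D=2e5, k2=1.0, k3=1.0, m=0.1, q=0.8):
    return IndividualParams(
        log_D1=np.log(D),
        log_D2=np.log(D),
        log_D3=np.log(D),
        log_k2=np.log(k2),
        log_k3=np.log(k3),
        log_m=np.log(m),
        logit_q=np.log(q / (1 - q)),
    )


@pytest.fixture(scope="module")
def whole_domain_layout(tiny_mesh):
    lg = make_logger("L0", 1000, 1000, 5000)
    return LoggerLayout([lg], tiny_mesh)


@pytest.fixture(scope="module")
def two_logger_layout(tiny_mesh):
    # two disjoint single-vertex detection regions at mesh vertices
    a = make_logger("A", 500, 500, 400)
    b = make_logger("B", 1500, 1500, 400)
    layout = LoggerLayout([a, b], tiny_mesh)
    assert not (layout.membership[0] & layout.membership[1]).any()
    return layout


class TestStepUpdate:
    def test_whole_domain_detection_returns_live_mass(self, tiny_mesh, whole_domain_layout):
        rng = np.random.default_rng(0)
        w = rng.uniform(size=tiny_mesh.n_vertices)
        w *= 0.7 / w.sum()
        w2, dead2, lik = step_update(w, 0.2, 0, 1.0, whole_domain_layout)
        assert lik == pytest.approx(0.7)
        assert dead2 == 0.0
        assert np.allclose(w2 / lik, w / w.sum())  # shape unchanged

    def test_zero_detection_probability_kills_likelihood(self, tiny_mesh, whole_domain_layout):
        w = np.full(tiny_mesh.n_vertices, 1.0 / tiny_mesh.n_vertices)
        _, _, lik = step_update(w, 0.0, 0, 0.0, whole_domain_layout)
        assert lik == 0.0

    def test_detection_inside_region_scales_by_q(self, tiny_mesh, two_logger_layout):
        w = np.zeros(tiny_mesh.n_vertices)
        w[two_logger_layout.membership[0]] = 0.9 / two_logger_layout.membership[0].sum()
        _, dead, lik = step_update(w, 0.1, 0, 0.86, two_logger_layout)
        assert lik == pytest.approx(0.86 * 0.9)
        assert dead == 0.0

    def test_non_detection_keeps_dead_mass(self, tiny_mesh, two_logger_layout):
        w = np.full(tiny_mesh.n_vertices, 0.8 / tiny_mesh.n_vertices)
        w2, dead2, lik = step_update(w, 0.2, NO_DETECTION, 0.5, two_logger_layout)
        inside = w[two_logger_layout.union].sum()
        assert lik == pytest.approx(0.8 - 0.5 * inside + 0.2)
        assert dead2 == pytest.approx(0.2)

    def test_unknown_logger_rejected(self, tiny_mesh, whole_domain_layout):
        w = np.full(tiny_mesh.n_vertices, 1.0 / tiny_mesh.n_vertices)
        with pytest.raises(DataError):
            step_update(w, 0.0, 5, 0.5, whole_domain_layout)

    def test_outcome_likelihoods_sum_to_total_mass(self, tiny_mesh, two_logger_layout):
        """Filter consistency: detection-by-each-logger plus none exhaust
        the probability of the pre-observation state."""
        rng = np.random.default_rng(1)
        w = rng.uniform(size=tiny_mesh.n_vertices)
        w *= 0.85 / w.sum()
        dead = 0.1
        q = 0.63
        total = 0.0
        for j in range(two_logger_layout.n_loggers):
            total += step_update(w, dead, j, q, two_logger_layout)[2]
        total += step_update(w, dead, NO_DETECTION, q, two_logger_layout)[2]
        assert total == pytest.approx(w.sum() + dead, abs=1e-8)


class TestLogLikelihood:
    def test_degenerate_one_step_history(self, tiny_mesh, whole_domain_layout):
        h = DetectionHistory("x", (1000, 1000), np.array([RELEASE, 0]))
        ll = log_likelihood(
            theta(m=1e-9, q=1 - 1e-12), h, tiny_mesh, whole_domain_layout.loggers,
            layout=whole_domain_layout,
        )
        assert ll == pytest.approx(0.0, abs=1e-6)

    def test_impossible_detection_gives_minus_inf(self, tiny_mesh, two_logger_layout):
        # zero detection probability makes any detection impossible
        h = DetectionHistory("x", (500, 500), np.array([RELEASE, 0]))
        ll = log_likelihood(
            theta(q=1e-12), h, tiny_mesh, two_logger_layout.loggers, layout=two_logger_layout
        )
        assert ll < -20

    def test_invariance_under_logger_relabeling(self, tiny_mesh, two_logger_layout):
        obs = np.array([RELEASE, 0, NO_DETECTION, 1, 1])
        h = DetectionHistory("x", (500, 500), obs)
        ll = log_likelihood(theta(), h, tiny_mesh, two_logger_layout.loggers)
        swapped = [two_logger_layout.loggers[1], two_logger_layout.loggers[0]]
        h2 = DetectionHistory("x", (500, 500), np.array([RELEASE, 1, NO_DETECTION, 0, 0]))
        ll2 = log_likelihood(theta(), h2, tiny_mesh, swapped)
        assert ll == pytest.approx(ll2, abs=1e-12)

    def test_invariance_under_rigid_translation(self, tiny_mesh, two_logger_layout):
        obs = np.array([RELEASE, 0, NO_DETECTION, 1])
        h = DetectionHistory("x", (500, 500), obs)
        ll = log_likelihood(theta(), h, tiny_mesh, two_logger_layout.loggers)
        dx, dy = 4321.0, -987.0
        mesh2 = Mesh(
            tiny_mesh.vertices + np.array([dx, dy]),
            tiny_mesh.triangles,
            tiny_mesh.habitat,
            tiny_mesh.areas,
        )
        loggers2 = [
            Datalogger(lg.id, lg.x + dx, lg.y + dy, lg.detect_radius_m, {})
            for lg in two_logger_layout.loggers
        ]
        h2 = DetectionHistory("x", (500 + dx, 500 + dy), obs)
        ll2 = log_likelihood(theta(), h2, mesh2, loggers2)
        assert ll == pytest.approx(ll2, abs=1e-9)

    def test_trailing_nones_favour_higher_mortality(self, tiny_mesh, whole_domain_layout):
        """With near-certain detection, a trailing all-none block can only
        be explained by death, so its likelihood rises with m."""
        obs = np.array([RELEASE, 0, 0] + [NO_DETECTION] * 8)
        h = DetectionHistory("x", (1000, 1000), obs)
        vals = []
        for m in (0.05, 0.15, 0.5, 1.0):
            th = theta(m=m, q=0.999)
            full = log_likelihood(th, h, tiny_mesh, whole_domain_layout.loggers,
                                  layout=whole_domain_layout, window="study_end")
            head = log_likelihood(th, h, tiny_mesh, whole_domain_layout.loggers,
                                  layout=whole_domain_layout, window="last_detection")
            vals.append(full - head)
        assert all(b >= a - 1e-9 for a, b in zip(vals, vals[1:]))

    def test_likelihood_matches_simulation_frequency(self, tiny_mesh, two_logger_layout):
        """Brute-force oracle: exp(log L) of a short history equals the
        frequency of that exact detection pattern among simulated tracks."""
        th = theta(D=2.5e5, m=0.12, q=0.75)
        layout = two_logger_layout
        start = tiny_mesh.nearest_vertex(500, 500)
        rng = np.random.default_rng(7)
        n = 200_000
        sims = simulate_slot_histories(th, tiny_mesh, layout, start, 3, n, rng)
        # the most frequent full pattern among the replicates
        pats, counts = np.unique(sims[:, 1:], axis=0, return_counts=True)
        order = np.argsort(-counts)
        pat, cnt = pats[order[1]], counts[order[1]]  # a non-trivial pattern
        freq = cnt / n
        h = DetectionHistory("x", tuple(tiny_mesh.vertices[start]), np.array([RELEASE, *pat]))
        ll = log_likelihood(th, h, tiny_mesh, layout.loggers, layout=layout)
        se = np.sqrt(freq * (1 - freq) / n)
        assert np.exp(ll) == pytest.approx(freq, abs=3 * se)


class TestDetectionHistory:
    def test_first_observation_must_exist(self):
        with pytest.raises(DataError):
            DetectionHistory("x", (0, 0), np.array([NO_DETECTION, 1]))

    def test_release_marker_only_at_slot_zero(self):
        with pytest.raises(DataError):
            DetectionHistory("x", (0, 0), np.array([RELEASE, RELEASE]))

    def test_detection_bookkeeping(self):
        h = DetectionHistory("x", (0, 0), np.array([RELEASE, 2, NO_DETECTION, 0]))
        assert h.n_steps == 3
        assert h.n_detections == 2
        assert list(h.detection_steps) == [1, 3]
        assert h.last_detection_step == 3
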