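import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from zebranvu import WellGeometry

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def well() -> WellGeometry:
    """12-well-plate well, divider along y, dark half at x > 0."""
    return WellGeometry(centre=(0.0, 0.0), radius=11.0, divider_normal=(1.0, 0.0))


def brute_force_ellipse_area(points: np.ndarray) -> float:
    """Independent minimum-enclosing-ellipse oracle.

    Parametric minimisation of ellipse area over (centre, Cholesky factor of
    the shape matrix) under one containment constraint per point, via SLSQP.
    Completely independent of the production solver.
    """
    from scipy.optimize import minimize

    pts = np.asarray(points, dtype=float)
    c0 = pts.mean(axis=0)
    cov = np.cov(pts.T) * 2.5 + 1e-6 * np.eye(2)
    L0 = np.linalg.cholesky(np.linalg.inv(cov))

    def unpack(z):
        cx, cy, l11, l21, l22 = z
        L = np.array([[l11, 0.0], [l21, l22]])
        return np.array([cx, cy]), L

    def objective(z):
        # area = pi / det(L); minimise -log det
        return -(np.log(abs(z[2])) + np.log(abs(z[4])))

    def constraints(z):
        c, L = unpack(z)
        d = pts - c
        v = d @ L  # forms = ||d L||^2 since A = L L^T
        return 1.0 - np.einsum("ij,ij->i", v, v)

    z0 = np.array([c0[0], c0[1], L0[0, 0], L0[1, 0], L0[1, 1]])
    # inflate the start until feasible
    for _ in range(60):
        if constraints(z0).min() >= 0:
            break
        z0[2:] *= 0.8
    res = minimize(
        objective,
        z0,
        method="SLSQP",
        constraints=[{"type": "ineq", "fun": constraints}],
        options={"maxiter": 500, "ftol": 1e-12},
    )
    assert res.success, res.message
    _, L = unpack(res.x)
    return float(np.pi / abs(np.linalg.det(L)))
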