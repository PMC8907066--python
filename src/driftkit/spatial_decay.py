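"""Great-circle distances and the inverse-variance-weighted decay-curve fit
y = 1/(m*x + a) + b relating excess relatedness to geographic distance."""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize

EARTH_RADIUS_KM = 6371.0
DUMMY_KM = 0.001
E_MINUS_1 = math.e - 1.0


class FitFailureError(RuntimeError):
    pass


@dataclass
class DecayPoint:
    id1: str
    id2: str
    x: float  # km, dummy-adjusted
    y: float  # excess relatedness score
    var_y: float

    def __post_init__(self):
        if self.x < DUMMY_KM - 1e-12:
            raise ValueError("distance below the 0.001 km dummy offset")
        if self.var_y <= 0:
            raise ValueError("var_y must be positive")


@dataclass
class DecayFit:
    m: float
    a: float
    b: float
    cov: np.ndarray  # (3, 3) for (m, a, b)
    rss: float  # weighted residual sum of squares
    n_points: int

    @property
    def decay_scale_km(self) -> float:
        return decay_scale(self.m, self.a)

    def predict(self, x):
        return 1.0 / (self.m * np.asarray(x, float) + self.a) + self.b


def haversine_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance (haversine, R = 6371 km) plus a 0.001 km dummy
    offset; identical coordinates therefore give exactly 0.001 km."""
    for lat in (lat1, lat2):
        if not -90.0 <= lat <= 90.0:
            raise ValueError(f"latitude {lat} out of range")
    for lon in (lon1, lon2):
        if not -360.0 <= lon <= 360.0:
            raise ValueError(f"longitude {lon} out of range")
    if (lat1, lon1) == (lat2, lon2):
        return DUMMY_KM
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dphi = p2 - p1
    dlmb = math.radians(lon2 - lon1)
    h = math.sin(dphi / 2.0) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dlmb / 2.0) ** 2
    h = min(h, 1.0)
    return 2.0 * EARTH_RADIUS_KM * math.asin(math.sqrt(h)) + DUMMY_KM


def decay_scale(m: float, a: float) -> float:
    """Distance at which the curve's amplitude above baseline falls to 1/e:
    (e - 1) * a / m."""
    if m <= 0:
        raise ValueError("decay scale undefined for m <= 0 (curve non-decaying)")
    if a <= 0:
        raise ValueError("decay scale undefined for a <= 0")
    return E_MINUS_1 * a / m


def fit_decay_curve(points, exclusions=(), drop_same_site: bool = False) -> DecayFit:
    """Fit y = 1/(m*x + a) + b by inverse-variance-weighted least squares
    with deterministic multi-start nonlinear minimization.

    ``exclusions`` lists pair-id tuples to drop (e.g. kin pairs);
    ``drop_same_site`` additionally drops points at the dummy distance.
    """
    excl = {frozenset(p) for p in exclusions}
    pts = [p for p in points if frozenset((p.id1, p.id2)) not in excl]
    if drop_same_site:
        pts = [p for p in pts if p.x > DUMMY_KM + 1e-9]
    if len(pts) < 4:
        raise ValueError(f"need at least 4 points after exclusions, got {len(pts)}")
    x = np.array([p.x for p in pts])
    y = np.array([p.y for p in pts])
    w = 1.0 / np.array([p.var_y for p in pts])
    sw = np.sqrt(w)

    def residuals(theta):
        m, a, b = theta
        return sw * (y - (1.0 / (m * x + a) + b))

    # deterministic starts: m over a log grid, a from the y-range, b from the
    # far-distance tail mean
    order = np.argsort(x)
    tail = order[-max(len(pts) // 4, 2) :]
    b0 = float(np.average(y[tail], weights=w[tail]))
    amp = max(float(np.max(y) - b0), 1e-8)
    a0 = 1.0 / amp
    starts = []
    for m0 in np.logspace(-4, 1, 8):
        starts.append((m0, a0, b0))
        starts.append((m0, 2.0 * a0, b0))
    best = None
    for theta0 in starts:
        try:
            sol = optimize.least_squares(
                residuals,
                theta0,
                bounds=([1e-12, 1e-12, -np.inf], [np.inf, np.inf, np.inf]),
                xtol=1e-15,
                ftol=1e-15,
                gtol=1e-15,
                max_nfev=2000,
            )
        except Exception:
            continue
        if sol.success or sol.status > 0:
            if best is None or sol.cost < best.cost:
                best = sol
    if best is None:
        raise FitFailureError(
            f"decay fit failed from all {len(starts)} starts on {len(pts)} points"
        )
    m, a, b = best.x
    J = best.jac
    JtJ = J.T @ J
    try:
        cov = np.linalg.pinv(JtJ, rcond=1e-12)
    except np.linalg.LinAlgError:
        cov = np.full((3, 3), np.nan)
        warnings.warn("singular decay-fit Jacobian; covariance unavailable")
    return DecayFit(
        m=float(m), a=float(a), b=float(b), cov=cov, rss=float(2.0 * best.cost), n_points=len(pts)
    )
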