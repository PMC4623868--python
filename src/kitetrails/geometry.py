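"""Nest-centred map projection, polar coordinates and velocity features.

Sparse satellite-tag fixes are analysed in a local Cartesian frame whose
origin is the bird's nest (the chronologically first fix, since tags are
fitted in the nest). Geographic coordinates are mapped to that frame with a
spherical Lambert azimuthal equal-area projection tangent at the nest and
rescaled to kilometres; the equal-area property matters because home-range
areas are measured in this plane. From the Cartesian frame each fix gets
polar coordinates (r, theta) and, by backward differencing, a radial
velocity v_r (km/h, positive moving away from the nest) and an angular
velocity v_theta (deg/h, rate of rotation about the nest). Directional
travel shows up as large |v_r| with small |v_theta|; movement inside a
settlement area as the opposite.

Units throughout: kilometres, hours, degrees.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Authalic (equal-area) sphere radius in km. A spherical projection is
#: accurate to <0.1 % at the sub-1000-km scales of raptor dispersal; the
#: routines below are the only place the figure of the Earth enters, so an
#: ellipsoidal backend could be swapped in without touching callers.
EARTH_RADIUS_KM = 6371.0072

KM_PER_MILE = 1.0 / 0.621371
MILES_PER_KM = 0.621371


class ProjectionError(ValueError):
    """Raised when a point cannot be projected (antipodal to the nest)."""


def laea_project(lat, lon, lat0: float, lon0: float):
    """Forward spherical Lambert azimuthal equal-area projection, in km.

    Parameters
    ----------
    lat, lon : array_like
        Geographic coordinates (decimal degrees, WGS84 treated as spherical).
    lat0, lon0 : float
        Tangent point (the nest).

    Returns
    -------
    x, y : ndarray
        Kilometres east/north of the tangent point.
    """
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    phi, lam = np.radians(lat), np.radians(lon)
    phi0, lam0 = np.radians(lat0), np.radians(lon0)
    dlam = lam - lam0
    cosc = np.sin(phi0) * np.sin(phi) + np.cos(phi0) * np.cos(phi) * np.cos(dlam)
    denom = 1.0 + cosc
    if np.any(denom <= 1e-12):
        raise ProjectionError("point antipodal to the nest: projection undefined")
    kprime = np.sqrt(2.0 / denom)
    x = EARTH_RADIUS_KM * kprime * np.cos(phi) * np.sin(dlam)
    y = EARTH_RADIUS_KM * kprime * (
        np.cos(phi0) * np.sin(phi) - np.sin(phi0) * np.cos(phi) * np.cos(dlam)
    )
    return x, y


def laea_inverse(x, y, lat0: float, lon0: float):
    """Inverse of :func:`laea_project` (km east/north -> lat, lon degrees)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    phi0, lam0 = np.radians(lat0), np.radians(lon0)
    rho = np.hypot(x, y)
    # Guard rho=0 (the nest itself) against division by zero.
    safe_rho = np.where(rho == 0.0, 1.0, rho)
    c = 2.0 * np.arcsin(np.clip(rho / (2.0 * EARTH_RADIUS_KM), -1.0, 1.0))
    phi = np.arcsin(
        np.clip(
            np.cos(c) * np.sin(phi0) + y * np.sin(c) * np.cos(phi0) / safe_rho,
            -1.0,
            1.0,
        )
    )
    lam = lam0 + np.arctan2(
        x * np.sin(c), safe_rho * np.cos(c) * np.cos(phi0) - y * np.sin(c) * np.sin(phi0)
    )
    lat = np.where(rho == 0.0, lat0, np.degrees(phi))
    lon = np.where(rho == 0.0, lon0, np.degrees(lam))
    lon = (lon + 180.0) % 360.0 - 180.0
    return lat, lon


def great_circle_km(lat1, lon1, lat2, lon2):
    """Great-circle distance on the authalic sphere (haversine), km."""
    lat1, lon1 = np.radians(np.asarray(lat1, float)), np.radians(np.asarray(lon1, float))
    lat2, lon2 = np.radians(np.asarray(lat2, float)), np.radians(np.asarray(lon2, float))
    dphi = lat2 - lat1
    dlam = lon2 - lon1
    a = np.sin(dphi / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlam / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


@dataclass
class ProjectedTrack:
    """A trajectory in the nest-centred equal-area frame.

    Attributes
    ----------
    x, y : ndarray
        Kilometres east/north of the nest.
    t_hours : ndarray
        Hours since the bird's first fix.
    nest_lat, nest_lon : float
        Geographic tangent point used for the projection.
    """

    x: np.ndarray
    y: np.ndarray
    t_hours: np.ndarray
    nest_lat: float
    nest_lon: float

    def __len__(self) -> int:
        return len(self.x)

    @property
    def xy(self) -> np.ndarray:
        """(n, 2) array of projected coordinates in km."""
        return np.column_stack([self.x, self.y])


@dataclass
class PolarTrack:
    """Polar coordinates (r km, theta deg in (-180, 180]) plus time in hours."""

    r: np.ndarray
    theta: np.ndarray
    t_hours: np.ndarray

    def __len__(self) -> int:
        return len(self.r)


@dataclass
class Velocities:
    """Per-fix backward-difference velocities in the polar frame.

    ``defined[i]`` is False for the first fix (no predecessor); where it is
    False, ``v_r``/``v_theta``/``dt`` hold NaN. ``v_theta`` is computed from
    the angle increment wrapped into (-180, 180], so a bird crossing the
    -180/180 branch cut does not register a spurious near-360-degree turn.
    """

    v_r: np.ndarray
    v_theta: np.ndarray
    dt: np.ndarray
    defined: np.ndarray

    def __len__(self) -> int:
        return len(self.v_r)


def project(traj) -> ProjectedTrack:
    """Project a :class:`~kitetrails.telemetry_io.Trajectory` to the nest frame.

    The nest (tangent point) is the bird's first fix, so the first projected
    point is (0, 0) up to GPS noise and t=0 exactly.
    """
    if len(traj.lat) == 0:
        raise ValueError("empty trajectory")
    nest_lat, nest_lon = float(traj.lat[0]), float(traj.lon[0])
    x, y = laea_project(traj.lat, traj.lon, nest_lat, nest_lon)
    t0 = traj.times[0]
    t_hours = (traj.times - t0).total_seconds().to_numpy() / 3600.0
    return ProjectedTrack(x=x, y=y, t_hours=t_hours, nest_lat=nest_lat, nest_lon=nest_lon)


def to_polar(track: ProjectedTrack) -> PolarTrack:
    """Convert projected points to nest-centred polar coordinates.

    theta is measured counter-clockwise from the +x (east) axis in degrees,
    in (-180, 180]; theta at the origin is 0 by convention (it can never
    influence classification, since r=0 is inside the nest buffer).
    """
    r = np.hypot(track.x, track.y)
    theta = np.degrees(np.arctan2(track.y, track.x))
    theta = np.where(r == 0.0, 0.0, theta)
    theta = np.where(theta <= -180.0, theta + 360.0, theta)
    return PolarTrack(r=r, theta=theta, t_hours=track.t_hours)


def wrap_angle_deg(d):
    """Wrap angle differences into (-180, 180] degrees."""
    d = np.asarray(d, dtype=float)
    w = (d + 180.0) % 360.0 - 180.0
    return np.where(w == -180.0, 180.0, w)


def velocities(polar: PolarTrack) -> Velocities:
    """Backward-difference radial and angular velocities.

    v_r[n] = (r[n] - r[n-1]) / (t[n] - t[n-1])  (km/h)
    v_theta[n] = wrap(theta[n] - theta[n-1]) / (t[n] - t[n-1])  (deg/h)

    Differences are taken between consecutive fixes as recorded, including
    across multi-day winter gaps (large dt then simply yields near-zero
    velocities; no interpolation is attempted).
    """
    n = len(polar)
    v_r = np.full(n, np.nan)
    v_theta = np.full(n, np.nan)
    dt = np.full(n, np.nan)
    defined = np.zeros(n, dtype=bool)
    if n >= 2:
        d = np.diff(polar.t_hours)
        if np.any(d <= 0):
            raise ValueError("timestamps must be strictly increasing")
        dt[1:] = d
        v_r[1:] = np.diff(polar.r) / d
        v_theta[1:] = wrap_angle_deg(np.diff(polar.theta)) / d
        defined[1:] = True
    return Velocities(v_r=v_r, v_theta=v_theta, dt=dt, defined=defined)


def step_distances_km(lat, lon) -> np.ndarray:
    """Great-circle distance (km) between consecutive fixes; length n-1."""
    lat = np.asarray(lat, float)
    lon = np.asarray(lon, float)
    if len(lat) < 2:
        return np.zeros(0)
    return great_circle_km(lat[:-1], lon[:-1], lat[1:], lon[1:])


def total_distance_km(lat, lon) -> float:
    return float(np.sum(step_distances_km(lat, lon)))


def km_to_miles(km) -> float:
    return float(km) * MILES_PER_KM
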