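"""Geometric model families: manifolds of 2D Gaussian centers.

A candidate "model" for a cloud of points is a family of isotropic 2D
Gaussians whose center lives on a zero- or one-dimensional manifold embedded
in the data plane: a single point, a straight segment, or a circular arc.
All one-dimensional manifolds are arc-length (unit-speed) parameterized, so
the Jeffreys prior over the parameter is uniform and the expected Fisher
information is constant along the curve.

Conventions
-----------
* The parameter ``s`` is arc length, with domain ``[0, length]``.
* Fisher information is reported *per datum*: for observation noise sigma the
  expected information of a unit-speed curve is ``1 / sigma**2`` regardless of
  curvature; the number of observations N enters the evidence terms
  explicitly.
* ``mirrored()`` reflects a manifold about the horizontal axis (y -> -y),
  which is how the task places the same shape "up" or "down".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

__all__ = [
    "NoiseModel",
    "ModelManifold",
    "PointManifold",
    "SegmentManifold",
    "ArcManifold",
    "manifold_from_dict",
    "expected_fisher",
    "observed_fisher",
    "jeffreys_density",
    "curvature",
]

_TWO_PI = 2.0 * math.pi


@dataclass(frozen=True)
class NoiseModel:
    """Isotropic 2D Gaussian observation noise: std ``sigma``, ``n_obs`` points per trial."""

    sigma: float
    n_obs: int = 10

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")
        if self.n_obs < 1:
            raise ValueError(f"n_obs must be >= 1, got {self.n_obs}")


@dataclass(frozen=True)
class ModelManifold:
    """Base class; use :class:`PointManifold`, :class:`SegmentManifold` or :class:`ArcManifold`."""

    label: str = field(default="", kw_only=True)

    kind: Literal["point", "segment", "arc"] = field(init=False, default="point")
    d: int = field(init=False, default=0)

    # -- geometry interface -------------------------------------------------
    @property
    def length(self) -> float:
        """Arc length Lambda of the parameter domain (0 for a point)."""
        raise NotImplementedError

    def embed(self, s):
        """Map arc-length coordinate(s) ``s`` to 2D point(s) mu(s) on the manifold."""
        raise NotImplementedError

    def tangent(self, s):
        """Unit tangent dmu/ds at ``s`` (d=1 only)."""
        raise NotImplementedError

    def second_derivative(self, s):
        """d^2 mu / ds^2 at ``s`` (the curvature vector; zero for segments)."""
        raise NotImplementedError

    def project(self, centroid):
        """Maximum-likelihood projection of ``centroid`` onto the manifold.

        Returns ``(s_hat, on_boundary)``; accepts a single point ``(2,)`` or a
        batch ``(..., 2)`` and returns arrays of matching leading shape.
        Ties between the two endpoints break toward ``s = 0``.
        """
        raise NotImplementedError

    def mirrored(self) -> "ModelManifold":
        """The manifold reflected about y = 0 (same arc-length parameter)."""
        raise NotImplementedError

    # -- plumbing -----------------------------------------------------------
    def _check_domain(self, s):
        s = np.asarray(s, dtype=float)
        if np.any(s < -1e-12) or np.any(s > self.length + 1e-12):
            raise ValueError(
                f"arc-length coordinate outside [0, {self.length!r}] for {self.kind} manifold"
            )
        return np.clip(s, 0.0, self.length)

    def to_dict(self) -> dict:
        raise NotImplementedError


@dataclass(frozen=True)
class PointManifold(ModelManifold):
    """A zero-dimensional model: a single Gaussian center."""

    location: tuple[float, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", "point")
        object.__setattr__(self, "d", 0)
        object.__setattr__(self, "location", tuple(float(v) for v in self.location))

    @property
    def length(self) -> float:
        return 0.0

    def embed(self, s):
        s = self._check_domain(s)
        loc = np.asarray(self.location)
        return np.broadcast_to(loc, s.shape + (2,)).copy()

    def project(self, centroid):
        centroid = np.asarray(centroid, dtype=float)
        shape = centroid.shape[:-1]
        return np.zeros(shape), np.zeros(shape, dtype=bool)

    def mirrored(self) -> "PointManifold":
        x, y = self.location
        return replace(self, location=(x, -y))

    def to_dict(self) -> dict:
        return {"kind": "point", "location": list(self.location), "label": self.label}


@dataclass(frozen=True)
class SegmentManifold(ModelManifold):
    """Gaussian centers on the straight segment from ``a`` to ``b``."""

    a: tuple[float, float]
    b: tuple[float, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", "segment")
        object.__setattr__(self, "d", 1)
        object.__setattr__(self, "a", tuple(float(v) for v in self.a))
        object.__setattr__(self, "b", tuple(float(v) for v in self.b))
        if self.length <= 0:
            raise ValueError("segment endpoints must be distinct")

    @property
    def length(self) -> float:
        return float(np.hypot(self.b[0] - self.a[0], self.b[1] - self.a[1]))

    @property
    def _unit(self) -> np.ndarray:
        v = np.asarray(self.b) - np.asarray(self.a)
        return v / np.linalg.norm(v)

    def embed(self, s):
        s = self._check_domain(s)
        return np.asarray(self.a) + s[..., None] * self._unit

    def tangent(self, s):
        s = self._check_domain(s)
        return np.broadcast_to(self._unit, s.shape + (2,)).copy()

    def second_derivative(self, s):
        s = self._check_domain(s)
        return np.zeros(s.shape + (2,))

    def project(self, centroid):
        centroid = np.asarray(centroid, dtype=float)
        t = (centroid - np.asarray(self.a)) @ self._unit
        s_hat = np.clip(t, 0.0, self.length)
        on_boundary = (t <= 0.0) | (t >= self.length)
        return s_hat, on_boundary

    def mirrored(self) -> "SegmentManifold":
        return replace(self, a=(self.a[0], -self.a[1]), b=(self.b[0], -self.b[1]))

    def to_dict(self) -> dict:
        return {"kind": "segment", "a": list(self.a), "b": list(self.b), "label": self.label}


@dataclass(frozen=True)
class ArcManifold(ModelManifold):
    """Gaussian centers on a circular arc.

    The arc starts at polar angle ``angle0`` (radians, measured from the
    center) and sweeps an angular ``span`` in the direction of ``orientation``
    (+1 counterclockwise, -1 clockwise). The arc-length coordinate is
    ``s = radius * swept angle``, so the embedding is unit speed.
    """

    center: tuple[float, float]
    radius: float
    angle0: float
    span: float
    orientation: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", "arc")
        object.__setattr__(self, "d", 1)
        object.__setattr__(self, "center", tuple(float(v) for v in self.center))
        if not self.radius > 0:
            raise ValueError("arc radius must be positive")
        if not (0.0 < self.span <= _TWO_PI):
            raise ValueError("arc angular span must be in (0, 2*pi]")
        if self.orientation not in (+1, -1):
            raise ValueError("orientation must be +1 or -1")

    @property
    def length(self) -> float:
        return float(self.radius * self.span)

    def _angle(self, s):
        return self.angle0 + self.orientation * np.asarray(s, dtype=float) / self.radius

    def embed(self, s):
        s = self._check_domain(s)
        th = self._angle(s)
        return np.asarray(self.center) + self.radius * np.stack(
            [np.cos(th), np.sin(th)], axis=-1
        )

    def tangent(self, s):
        s = self._check_domain(s)
        th = self._angle(s)
        return self.orientation * np.stack([-np.sin(th), np.cos(th)], axis=-1)

    def second_derivative(self, s):
        # centripetal: points from the curve toward the center, magnitude 1/r
        s = self._check_domain(s)
        th = self._angle(s)
        return -np.stack([np.cos(th), np.sin(th)], axis=-1) / self.radius

    def project(self, centroid):
        centroid = np.asarray(centroid, dtype=float)
        rel = centroid - np.asarray(self.center)
        phi = np.arctan2(rel[..., 1], rel[..., 0])
        # swept angle from the arc start, folded into [0, 2*pi)
        t = np.mod(self.orientation * (phi - self.angle0), _TWO_PI)
        interior = t <= self.span
        s_interior = np.clip(t * self.radius, 0.0, self.length)
        # outside the span: nearer endpoint wins, ties toward s = 0
        p0 = self.embed(0.0)
        p1 = self.embed(self.length)
        d0 = np.linalg.norm(centroid - p0, axis=-1)
        d1 = np.linalg.norm(centroid - p1, axis=-1)
        s_clamped = np.where(d1 < d0, self.length, 0.0)
        s_hat = np.where(interior, s_interior, s_clamped)
        on_boundary = ~interior | (s_interior <= 0.0) | (s_interior >= self.length)
        return s_hat, on_boundary

    def mirrored(self) -> "ArcManifold":
        return replace(
            self,
            center=(self.center[0], -self.center[1]),
            angle0=-self.angle0,
            orientation=-self.orientation,
        )

    def to_dict(self) -> dict:
        return {
            "kind": "arc",
            "center": list(self.center),
            "radius": self.radius,
            "angle0": self.angle0,
            "span": self.span,
            "orientation": self.orientation,
            "label": self.label,
        }


def manifold_from_dict(spec: dict):
    """Rebuild a manifold from its ``to_dict`` structured-config entry."""
    spec = dict(spec)
    kind = spec.pop("kind")
    if kind == "point":
        return PointManifold(location=tuple(spec["location"]), label=spec.get("label", ""))
    if kind == "segment":
        return SegmentManifold(
            a=tuple(spec["a"]), b=tuple(spec["b"]), label=spec.get("label", "")
        )
    if kind == "arc":
        return ArcManifold(
            center=tuple(spec["center"]),
            radius=float(spec["radius"]),
            angle0=float(spec["angle0"]),
            span=float(spec["span"]),
            orientation=int(spec.get("orientation", 1)),
            label=spec.get("label", ""),
        )
    raise ValueError(f"unknown manifold kind {kind!r}")


# ---------------------------------------------------------------------------
# Differential-geometric quantities
# ---------------------------------------------------------------------------

def expected_fisher(m, s, noise: NoiseModel):
    """Expected per-datum Fisher information g at ``s``.

    For a unit-speed curve in an isotropic Gaussian location family this is
    ``1 / sigma**2`` independent of position and curvature. Point models
    return the 0-dimensional determinant convention, 1.
    """
    s = np.asarray(s, dtype=float)
    if m.d == 0:
        return np.ones_like(s)
    m._check_domain(s)
    return np.full_like(s, 1.0 / noise.sigma**2)


def observed_fisher(m, X, s, noise: NoiseModel):
    """Observed per-datum Fisher information h at ``s`` for data ``X``.

    h(s) = -(1/N) d^2/ds^2 log p(X | mu(s)) =
    (1/sigma^2) * (1 + (mu(s) - xbar) . mu''(s)); it equals g for straight
    segments and is a data-dependent, noisy version of g on curved manifolds.
    """
    if m.d == 0:
        return np.ones_like(np.asarray(s, dtype=float))
    X = np.asarray(X, dtype=float)
    centroid = X.mean(axis=0) if X.ndim == 2 else X
    s = np.asarray(s, dtype=float)
    mu = m.embed(s)
    dd = m.second_derivative(s)
    return (1.0 + np.einsum("...i,...i->...", mu - centroid, dd)) / noise.sigma**2


def jeffreys_density(m, s=None):
    """Jeffreys prior density over arc length: uniform, 1 / length.

    With ``s`` given, returns the density evaluated there (validating the
    domain); point models have no parameter to integrate (raises).
    """
    if m.d == 0:
        raise ValueError("point manifold carries a point-mass prior, not a density")
    if s is None:
        return 1.0 / m.length
    s = m._check_domain(s)
    return np.full_like(s, 1.0 / m.length)


def curvature(m, s):
    """Signed curvature at ``s``: 0 for segments, orientation/radius for arcs."""
    if m.d == 0:
        raise ValueError("curvature undefined for a 0-dimensional manifold")
    s = m._check_domain(s)
    if m.kind == "segment":
        return np.zeros_like(s)
    return np.full_like(s, m.orientation / m.radius)
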