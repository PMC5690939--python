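"""Smooth Gaussian scalar random fields for boundary-noise simulation.

Delineation noise is spatially coherent: an observer who over-draws one
part of a boundary over-draws its neighbourhood too.  The fields here model
that with a stationary Gaussian process with squared-exponential
covariance sigma^2 * exp(-|dx|^2 / (2 * l^2)), realized with random Fourier
features: f(x) = sigma * sqrt(2/M) * sum_m cos(k_m . x + phi_m) with
k_m ~ N(0, I / l^2) and uniform phases.  The construction is smooth (C-inf),
seeded, cheap to evaluate at arbitrary 3D points, and its pointwise SD
equals sigma up to O(1/sqrt(M)) feature noise.
"""

from __future__ import annotations

import numpy as np

__all__ = ["GaussianScalarField", "ZeroField"]


class ZeroField:
    """The zero field; stands in when a noise SD is exactly zero."""

    sigma = 0.0

    def __call__(self, points: np.ndarray) -> np.ndarray:
        return np.zeros(len(points))


class GaussianScalarField:
    """Seeded smooth Gaussian scalar field on R^3.

    Parameters
    ----------
    sigma:
        Pointwise standard deviation (mm when used as boundary offset).
    correlation_length_mm:
        Length scale of the squared-exponential covariance.
    seed:
        Integer or :class:`numpy.random.SeedSequence`; same seed gives the
        identical field.
    n_features:
        Number of random Fourier features; pointwise SD error shrinks as
        1/sqrt(n_features).
    """

    def __init__(self, sigma: float, correlation_length_mm: float, seed,
                 n_features: int = 384):
        if sigma < 0:
            raise ValueError("sigma must be >= 0")
        if not correlation_length_mm > 0:
            raise ValueError("correlation_length_mm must be > 0")
        self.sigma = float(sigma)
        self.correlation_length_mm = float(correlation_length_mm)
        rng = np.random.default_rng(seed)
        self._k = rng.normal(0.0, 1.0 / correlation_length_mm, size=(n_features, 3))
        self._phase = rng.uniform(0.0, 2.0 * np.pi, size=n_features)
        self._amp = self.sigma * np.sqrt(2.0 / n_features)

    def __call__(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        if self.sigma == 0.0:
            return np.zeros(len(points))
        # single precision suffices for a noise field and halves the cost
        arg = points.astype(np.float32) @ self._k.T.astype(np.float32)
        arg += self._phase.astype(np.float32)
        return self._amp * np.cos(arg).sum(axis=1, dtype=np.float64)
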