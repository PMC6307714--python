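"""Uniform cubic B-spline curves, linear in their trainable coefficients.

Curves are sums of shifted cubic B-spline bumps,

    f(x) = sum_k  c_k * B3((x - x0)/h - (k - 1)),

where B3 is the standard cubic B-spline kernel with support (-2, 2).
Because the coefficient list is finite and implicitly zero outside its
range, a radial curve with h = cutoff/K is *exactly* zero, with exactly
zero derivative, at and beyond its cutoff -- no clamping or special-casing
is needed to satisfy the cutoff contract.  Angular and environment curves
use h = span/(K-3) so the four-bump partition of unity covers their whole
domain (constants are exactly representable everywhere).

The parameter gradient of any energy built from these curves is just the
basis-function evaluation (the curve is linear in c), which the pair
potentials exploit for exact parameter derivatives.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SplineCurve", "bspline_basis", "smoothstep"]


def _b3(s: np.ndarray) -> np.ndarray:
    a = np.abs(s)
    out = np.zeros_like(a)
    m1 = a <= 1.0
    m2 = (a > 1.0) & (a < 2.0)
    out[m1] = (4.0 - 6.0 * a[m1] ** 2 + 3.0 * a[m1] ** 3) / 6.0
    out[m2] = (2.0 - a[m2]) ** 3 / 6.0
    return out


def _b3p(s: np.ndarray) -> np.ndarray:
    a = np.abs(s)
    sg = np.sign(s)
    out = np.zeros_like(a)
    m1 = a <= 1.0
    m2 = (a > 1.0) & (a < 2.0)
    out[m1] = sg[m1] * (-12.0 * a[m1] + 9.0 * a[m1] ** 2) / 6.0
    out[m2] = -sg[m2] * (2.0 - a[m2]) ** 2 / 2.0
    return out


def bspline_basis(x, x0: float, h: float, n_coef: int):
    """Nonzero basis values at ``x``: returns (idx (m,4), w (m,4), wp (m,4)).

    ``idx`` may contain -1 for out-of-range coefficients (weight forced 0).
    ``wp`` is d(weight)/dx.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    u = (x - x0) / h
    j = np.floor(u).astype(int)
    centers = j[:, None] + np.arange(-1, 3)[None, :]  # center m = k - 1
    k = centers + 1
    s = u[:, None] - centers
    w = _b3(s)
    wp = _b3p(s) / h
    bad = (k < 0) | (k >= n_coef)
    w[bad] = 0.0
    wp[bad] = 0.0
    k = np.where(bad, -1, k)
    return k, w, wp


@dataclass
class SplineCurve:
    """A trainable 1-D curve on a uniform grid.

    kind "radial": domain [0, cutoff], h = cutoff/K, identically zero (value
    and slope) at and beyond the cutoff.  kind "open": domain
    [x0, x0 + span], h = span/(K-3), clamped with zero slope outside.
    """

    coef: np.ndarray
    x0: float
    h: float
    kind: str = "radial"  # "radial" | "open"

    def __post_init__(self):
        self.coef = np.asarray(self.coef, dtype=float)

    @classmethod
    def radial(cls, coef, cutoff: float) -> "SplineCurve":
        coef = np.asarray(coef, dtype=float)
        return cls(coef, 0.0, cutoff / len(coef), "radial")

    @classmethod
    def open(cls, coef, lo: float, hi: float) -> "SplineCurve":
        coef = np.asarray(coef, dtype=float)
        return cls(coef, lo, (hi - lo) / (len(coef) - 3), "open")

    @property
    def n_coef(self) -> int:
        return len(self.coef)

    @property
    def upper(self) -> float:
        if self.kind == "radial":
            return self.x0 + self.h * self.n_coef
        return self.x0 + self.h * (self.n_coef - 3)

    def _clamped(self, x):
        x = np.atleast_1d(np.asarray(x, dtype=float))
        if self.kind == "open":
            inside = (x >= self.x0) & (x <= self.upper)
            xc = np.clip(x, self.x0, self.upper)
        else:
            inside = np.ones(x.shape, dtype=bool)
            xc = x
        return xc, inside

    def evaluate(self, x):
        """Values and derivatives at ``x`` (arrays, any shape)."""
        shape = np.shape(x)
        xc, inside = self._clamped(x)
        k, w, wp = bspline_basis(xc, self.x0, self.h, self.n_coef)
        c = np.where(k >= 0, self.coef[np.clip(k, 0, None)], 0.0)
        f = np.sum(c * w, axis=1)
        df = np.sum(c * wp, axis=1) * inside  # zero slope outside (open)
        return f.reshape(shape), df.reshape(shape)

    def basis(self, x):
        """Basis indices/weights at ``x`` (for exact parameter gradients)."""
        xc, _ = self._clamped(x)
        return bspline_basis(xc, self.x0, self.h, self.n_coef)[:2]

    def __call__(self, x):
        return self.evaluate(x)[0]


def smoothstep(x, lo: float, hi: float):
    """C1 cubic step: 0 below lo, 1 above hi.  Returns (s, ds/dx)."""
    x = np.asarray(x, dtype=float)
    t = np.clip((x - lo) / (hi - lo), 0.0, 1.0)
    s = t * t * (3.0 - 2.0 * t)
    ds = 6.0 * t * (1.0 - t) / (hi - lo)
    return s, ds
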