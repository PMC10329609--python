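"""Forward-mode automatic differentiation with first and second derivatives.

The pose objective of this package depends on a single small parameter
vector (the six components of an se(3) twist).  Forward mode with a
fixed number of tangent "lanes" is then both simpler and cheaper than
reverse mode: every intermediate quantity carries its value, its
Jacobian with respect to the six parameters, and (optionally) the stack
of second derivatives.  All element arithmetic is vectorised numpy, so a
whole residual field is differentiated in a handful of array operations.

`HD` instances hold

* ``v`` -- the value, an array of arbitrary shape ``S``
* ``g`` -- the Jacobian, shape ``S + (K,)``
* ``h`` -- the Hessian stack, shape ``S + (K, K)`` or ``None`` for
  first-order-only computations.

Mixing an `HD` with a plain scalar / ndarray treats the latter as a
constant.  Binary operations between two `HD` values require the same
derivative order.
"""

from __future__ import annotations

import numpy as np

__all__ = ["HD", "seed", "sqrt", "sin", "cos", "value"]


class HD:
    __slots__ = ("v", "g", "h")

    # make `ndarray <op> HD` defer to the reflected HD operators instead
    # of numpy building an object array elementwise
    __array_ufunc__ = None

    def __init__(self, v, g, h=None):
        self.v = np.asarray(v, dtype=float)
        self.g = np.asarray(g, dtype=float)
        self.h = None if h is None else np.asarray(h, dtype=float)

    # ------------------------------------------------------------------
    @property
    def nparam(self) -> int:
        return self.g.shape[-1]

    @property
    def shape(self):
        return self.v.shape

    def __getitem__(self, idx):
        return HD(self.v[idx], self.g[idx], None if self.h is None else self.h[idx])

    # -- helpers -------------------------------------------------------
    def _unary(self, f0, f1, f2):
        """Elementwise function with value/1st/2nd derivative at ``v``."""
        g = f1[..., None] * self.g
        h = None
        if self.h is not None:
            outer = self.g[..., :, None] * self.g[..., None, :]
            h = f1[..., None, None] * self.h + f2[..., None, None] * outer
        return HD(f0, g, h)

    # -- arithmetic ----------------------------------------------------
    def __add__(self, o):
        if isinstance(o, HD):
            h = None if self.h is None else self.h + o.h
            return HD(self.v + o.v, self.g + o.g, h)
        o = np.asarray(o, dtype=float)
        h = None if self.h is None else self.h + np.zeros(o.shape + (1, 1))
        return HD(self.v + o, self.g + np.zeros(o.shape + (1,)), h)

    __radd__ = __add__

    def __neg__(self):
        return HD(-self.v, -self.g, None if self.h is None else -self.h)

    def __sub__(self, o):
        return self + (-o if isinstance(o, HD) else -np.asarray(o, dtype=float))

    def __rsub__(self, o):
        return (-self) + o

    def __mul__(self, o):
        if isinstance(o, HD):
            v = self.v * o.v
            g = self.g * o.v[..., None] + o.g * self.v[..., None]
            h = None
            if self.h is not None:
                cross = self.g[..., :, None] * o.g[..., None, :]
                h = (
                    self.h * o.v[..., None, None]
                    + o.h * self.v[..., None, None]
                    + cross
                    + np.swapaxes(cross, -1, -2)
                )
            return HD(v, g, h)
        o = np.asarray(o, dtype=float)
        return HD(
            self.v * o,
            self.g * o[..., None],
            None if self.h is None else self.h * o[..., None, None],
        )

    __rmul__ = __mul__

    def reciprocal(self):
        inv = 1.0 / self.v
        return self._unary(inv, -(inv**2), 2.0 * inv**3)

    def __truediv__(self, o):
        if isinstance(o, HD):
            return self * o.reciprocal()
        return self * (1.0 / np.asarray(o, dtype=float))

    def __rtruediv__(self, o):
        return self.reciprocal() * o

    def sqrt(self):
        s = np.sqrt(self.v)
        return self._unary(s, 0.5 / s, -0.25 / s**3)

    def sin(self):
        s, c = np.sin(self.v), np.cos(self.v)
        return self._unary(s, c, -s)

    def cos(self):
        s, c = np.sin(self.v), np.cos(self.v)
        return self._unary(c, -s, -c)

    def sum(self):
        """Sum over all element axes, keeping derivative axes."""
        n = self.v.ndim
        axes = tuple(range(n))
        g = self.g.sum(axis=axes) if n else self.g
        h = None
        if self.h is not None:
            h = self.h.sum(axis=axes) if n else self.h
        return HD(self.v.sum(), g, h)

    def __repr__(self):  # pragma: no cover - debugging aid
        order = 1 if self.h is None else 2
        return f"HD(shape={self.v.shape}, order={order})"


# ----------------------------------------------------------------------
def seed(p, order: int = 2) -> HD:
    """Lift a parameter vector into `HD` with identity Jacobian."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("seed expects a 1-D parameter vector")
    k = p.shape[0]
    g = np.eye(k)
    h = np.zeros((k, k, k)) if order == 2 else None
    return HD(p, g, h)


def _dispatch(x, name):
    if isinstance(x, HD):
        return getattr(x, name)()
    return getattr(np, name)(x)


def sqrt(x):
    return _dispatch(x, "sqrt")


def sin(x):
    return _dispatch(x, "sin")


def cos(x):
    return _dispatch(x, "cos")


def value(x):
    """The plain value of an `HD` or array."""
    return x.v if isinstance(x, HD) else np.asarray(x, dtype=float)
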