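"""Rate-coded neural components, stepped by forward Euler.

Five component types drive the brain model populations:

* ``LINlinear`` -- leaky integrator with shunting inhibition, additive
  Gaussian noise and a piecewise-linear output with offset ``c``
  (``c < 0`` yields tonic output, ``c > 0`` a firing threshold).
* ``LINret`` -- noiseless, shunt-free leaky integrator (retina).
* ``LINexp`` -- leaky integrator with an exponential transfer function
  and a reversal-potential-modulated input port (subthalamic nucleus).
* ``D1MSN`` / ``D2MSN`` -- striatal medium spiny neurons whose input
  gain is modulated by the dopamine level ``d``: (0.2 + d) for D1,
  (1 - d) for D2.
* ``SBGUnit`` -- single-element brainstem unit: a leaky integrator (or,
  for tonic neurons, a pure integrator) of a piecewise-linear function
  of its summed input.

All outputs saturate in [0, 1].  Each population owns a named, seedable
noise stream so that experiments are reproducible under re-wiring.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Population", "LINlinear", "LINret", "LINexp", "D1MSN", "D2MSN", "SBGUnit"]

DT_NEURAL = 0.001  # s; the neural solver timestep


def _pwl(x, lo=0.0, hi=1.0):
    return np.clip(x, lo, hi)


class Population:
    """Base class: a vector of activations with a seedable noise stream."""

    transmits = "y"  # signal seen by efferent projections

    def __init__(self, n: int, tau: float, seed: int | None = 0, name: str = "") -> None:
        if tau <= 0:
            raise ValueError("time constant tau must be positive")
        self.n = int(n)
        self.tau = float(tau)
        self.name = name
        self.rng = np.random.default_rng(seed)
        self.a = np.zeros(self.n)

    @property
    def y(self) -> np.ndarray:  # pragma: no cover - overridden
        raise NotImplementedError

    @property
    def output(self) -> np.ndarray:
        return self.y if self.transmits == "y" else self.a

    def reset(self) -> None:
        self.a = np.zeros(self.n)

    def _integrate(self, a_in, dt: float) -> None:
        self.a = self.a + (dt / self.tau) * (a_in - self.a)


class LINlinear(Population):
    def __init__(self, n, tau, c=0.0, alpha=0.0, seed=0, name=""):
        super().__init__(n, tau, seed, name)
        self.c = float(c)
        self.alpha = float(alpha)

    @property
    def y(self) -> np.ndarray:
        return _pwl(self.a - self.c)

    def step(self, A=0.0, S=0.0, dt: float = DT_NEURAL) -> None:
        s_a = np.minimum(S, 1.0)
        a_in = A * (1.0 - s_a)
        if self.alpha:
            a_in = a_in + self.alpha * self.rng.standard_normal(self.n)
        self._integrate(a_in, dt)


class LINret(Population):
    """Retinal leaky integrator: no noise, no shunting."""

    @property
    def y(self) -> np.ndarray:
        return _pwl(self.a)

    def step(self, A=0.0, dt: float = DT_NEURAL) -> None:
        self._integrate(A, dt)


class LINexp(Population):
    """Leaky integrator with exponential transfer (used for STN).

    a_in = [A + N (a - V_r-)] (1 - S) + 0.01 R_N;  y = e^a - 0.9,
    clamped to 1 when e^a exceeds 1.9 and floored at 0.
    """

    def __init__(self, n, tau, V_r_minus=-0.5, noise=0.01, seed=0, name=""):
        super().__init__(n, tau, seed, name)
        self.V_r_minus = float(V_r_minus)
        self.noise = float(noise)

    @property
    def y(self) -> np.ndarray:
        return np.clip(np.exp(self.a) - 0.9, 0.0, 1.0)

    def step(self, A=0.0, S=0.0, N=0.0, dt: float = DT_NEURAL) -> None:
        a_in = (A + N * (self.a - self.V_r_minus)) * (1.0 - S)
        if self.noise:
            a_in = a_in + self.noise * self.rng.standard_normal(self.n)
        self._integrate(a_in, dt)


class _MSN(Population):
    """Striatal medium spiny neuron base; c > 0 models the down-state."""

    def __init__(self, n, tau, c=0.2, d=0.7, noise=0.01, seed=0, name=""):
        super().__init__(n, tau, seed, name)
        if not 0.0 <= d <= 1.0:
            raise ValueError("dopamine level d must lie in [0, 1]")
        self.c = float(c)
        self.d = float(d)
        self.noise = float(noise)

    @property
    def y(self) -> np.ndarray:
        return _pwl(self.a - self.c)

    def _gain(self) -> float:  # pragma: no cover - overridden
        raise NotImplementedError

    def step(self, A=0.0, dt: float = DT_NEURAL) -> None:
        a_in = self._gain() * A
        if self.noise:
            a_in = a_in + self.noise * self.rng.standard_normal(self.n)
        self._integrate(a_in, dt)


class D1MSN(_MSN):
    def _gain(self) -> float:
        return 0.2 + self.d


class D2MSN(_MSN):
    def _gain(self) -> float:
        return 1.0 - self.d


class SBGUnit(Population):
    """Single-element burst-generator unit.

    ``kind='leaky'``: da/dt = (y_in - a)/tau with y_in the piecewise
    linear function of the summed input IN offset by b.  ``kind=
    'integrator'`` (tonic neurons): da/dt = y_in/tau.  When ``signed``
    is set (the tonic-neuron reset variant), y_in is allowed to go
    negative (clipped to [-1, 1]) so that contralateral burst activity
    can extinguish accumulated tonic activity; the activation itself is
    floored at 0.

    SBG units transmit their activation ``a``, not ``y``.
    """

    transmits = "a"

    def __init__(self, tau, b=0.0, kind="leaky", signed=False, name=""):
        super().__init__(1, tau, None, name)
        if kind not in ("leaky", "integrator"):
            raise ValueError("kind must be 'leaky' or 'integrator'")
        self.b = float(b)
        self.kind = kind
        self.signed = bool(signed)

    @property
    def value(self) -> float:
        return float(self.a[0])

    @property
    def y(self) -> np.ndarray:
        return _pwl(self.a)

    def transfer(self, IN):
        lo = -1.0 if self.signed else 0.0
        return _pwl(IN - self.b, lo, 1.0)

    def step(self, IN=0.0, dt: float = DT_NEURAL) -> None:
        y_in = self.transfer(IN)
        if self.kind == "leaky":
            self.a = self.a + (dt / self.tau) * (y_in - self.a)
        else:
            self.a = self.a + (dt / self.tau) * np.asarray(y_in, dtype=float).reshape(self.a.shape)
            if self.signed:
                np.maximum(self.a, 0.0, out=self.a)
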