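"""Projection-kernel builders for the oculomotor network.

Every builder returns a :class:`ProjectionSpec`: an explicit weighted
edge list between two populations laid out on the 50x50 collicular
grid (row-major, r fastest-varying ... cells are indexed
``idx = (r_index - 1) * W + (phi_index - 1)`` with 1-based grid
coordinates).  Weights are non-negative; excitatory/inhibitory sign and
the input port (activation / shunting / reversal) are carried
separately.  In-plane distances along the phi axis are computed modulo
the map width (the phi axis wraps).

Kernels implemented: one-to-one, thresholded Gaussian, diffuse
(channel-wise sum), one-to-one decaying at the fovea (sigmoid in r),
widening Gaussian (width grows with eccentricity in inverse proportion
to the cortical magnification factor), the six saccadic-burst-generator
weight maps, and tecto-tectal (opposite-hemifield) inhibition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from sacsim.world import MappingParams

__all__ = [
    "ProjectionSpec",
    "WeightMapParams",
    "WideningParams",
    "build_one_to_one",
    "build_gaussian_kernel",
    "build_diffuse",
    "build_decaying_at_fovea",
    "build_widening_gaussian",
    "build_sbg_weight_map",
    "build_tecto_tectal_inhibition",
    "CHANNELS",
    "CHANNEL_PHI",
]

GRID_SHAPE = (50, 50)

#: SBG channel names in motoneuron order.
CHANNELS = ("up", "down", "left", "right", "z_plus", "z_minus")

#: phi grid coordinate (1-based) at which a target moving the eye in the
#: channel's direction lands under the forward mapping.
CHANNEL_PHI = {"up": 1.0, "left": 13.5, "down": 26.0, "right": 38.5}


@dataclass
class ProjectionSpec:
    """Source->target connectivity as a sparse weight matrix plus metadata.

    ``matrix`` has shape (n_target, n_source) and non-negative entries;
    ``kind='diffuse'`` projections instead store a scalar ``weight`` and
    deliver ``weight * sum(source)`` to every target (numerically equal
    to the full bipartite edge list).
    """

    source: str
    target: str
    matrix: sp.csr_matrix | None = None
    weight: float = 0.0
    kind: str = "matrix"
    delay: float = 0.0
    port: str = "activation"
    sign: int = 1
    n_source: int = 0
    n_target: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("matrix", "diffuse"):
            raise ValueError(f"unknown projection kind {self.kind!r}")
        if self.port not in ("activation", "shunting", "reversal"):
            raise ValueError(f"unknown port {self.port!r}")
        if self.sign not in (-1, 1):
            raise ValueError("sign must be +1 (excitatory) or -1 (inhibitory)")
        if self.kind == "matrix":
            if self.matrix is None:
                raise ValueError("matrix kind requires a weight matrix")
            self.matrix = sp.csr_matrix(self.matrix)
            if self.matrix.nnz and self.matrix.data.min() < 0:
                raise ValueError("weights must be non-negative (sign is separate)")
            self.n_target, self.n_source = self.matrix.shape

    def apply(self, x: np.ndarray) -> np.ndarray:
        """Drive delivered to each target for source signal x (unsigned)."""
        if self.kind == "diffuse":
            return np.full(self.n_target, self.weight * float(np.sum(x)))
        return self.matrix @ x

    def edges(self) -> pd.DataFrame:
        """Explicit (src, tgt, weight, delay) edge list for inspection."""
        if self.kind == "diffuse":
            tgt, src = np.meshgrid(range(self.n_target), range(self.n_source), indexing="ij")
            w = np.full(tgt.size, self.weight)
            return pd.DataFrame(
                {"src": src.ravel(), "tgt": tgt.ravel(), "weight": w, "delay": self.delay}
            )
        coo = self.matrix.tocoo()
        return pd.DataFrame(
            {"src": coo.col, "tgt": coo.row, "weight": coo.data, "delay": self.delay}
        )


@dataclass(frozen=True)
class WeightMapParams:
    """Parameters of an SBG weight map w(r, phi) = i e^{j r} sin_+(l phi + k)."""

    i: float
    j: float
    k: float | None = None  # derived from the channel direction when None
    l: float = 2.0 * math.pi / 50.0


@dataclass(frozen=True)
class WideningParams:
    """Widening-Gaussian parameters.

    sigma(r) = sigma_0 for r <= r_0, else
    m_sigma / M(eps(r)) - m_sigma / M_0 + sigma_0, clamped below at
    sigma_0, with M the cortical magnification factor evaluated at the
    eccentricity eps(r) of the source cell.
    """

    m_sigma: float = 50.0
    sigma_0: float = 0.3
    M_0: float = 12.43
    r_0: float = 20.0


def _grid_coords(grid_shape=GRID_SHAPE):
    nr, nphi = grid_shape
    r_idx, phi_idx = np.meshgrid(
        np.arange(1, nr + 1), np.arange(1, nphi + 1), indexing="ij"
    )
    return r_idx.ravel(), phi_idx.ravel()


def build_one_to_one(size: int, weight, *, source="", target="", sign=1,
                     delay=0.0, port="activation") -> ProjectionSpec:
    """Identity connectivity; ``weight`` may be a scalar or per-cell vector."""
    w = np.broadcast_to(np.asarray(weight, dtype=float), (size,))
    mat = sp.diags(w.copy(), format="csr")
    return ProjectionSpec(source, target, matrix=mat, sign=sign, delay=delay, port=port)


def _offsets_within(max_d: float):
    m = int(math.floor(max_d))
    di, dj = np.meshgrid(np.arange(-m, m + 1), np.arange(-m, m + 1), indexing="ij")
    return di.ravel(), dj.ravel()


def _kernel_matrix(sigma_per_src: np.ndarray, w_max: float, threshold: float,
                   grid_shape=GRID_SHAPE) -> sp.csr_matrix:
    """Gaussian fan-out with per-source width; phi wraps, r clips."""
    nr, nphi = grid_shape
    n = nr * nphi
    src_r = np.repeat(np.arange(nr), nphi)
    src_phi = np.tile(np.arange(nphi), nr)
    rows, cols, data = [], [], []
    for sig in np.unique(sigma_per_src):
        sel = sigma_per_src == sig
        src = np.nonzero(sel)[0]
        max_d = sig * math.sqrt(2.0 * math.log(w_max / threshold)) if w_max > threshold else 0.0
        di, dj = _offsets_within(max_d)
        w = w_max * np.exp(-(di**2 + dj**2) / (2.0 * sig**2))
        keep = w >= threshold
        di, dj, w = di[keep], dj[keep], w[keep]
        for ddi, ddj, ww in zip(di, dj, w):
            tr = src_r[src] + ddi
            ok = (tr >= 0) & (tr < nr)
            tphi = (src_phi[src[ok]] + ddj) % nphi
            rows.append(tr[ok] * nphi + tphi)
            cols.append(src[ok])
            data.append(np.full(ok.sum(), ww))
    if rows:
        rows = np.concatenate(rows)
        cols = np.concatenate(cols)
        data = np.concatenate(data)
    return sp.csr_matrix((data, (rows, cols)), shape=(n, n))


def build_gaussian_kernel(sigma: float, w_max: float = 1.0, threshold: float | None = None,
                          grid_shape=GRID_SHAPE, *, source="", target="", sign=1,
                          delay=0.0, port="activation") -> ProjectionSpec:
    """Thresholded circular 2-D Gaussian fan-out on the grid plane."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if threshold is None:
        threshold = 0.02 * w_max
    if not 0 < threshold < w_max:
        raise ValueError("need 0 < threshold < w_max")
    n = grid_shape[0] * grid_shape[1]
    mat = _kernel_matrix(np.full(n, float(sigma)), w_max, threshold, grid_shape)
    return ProjectionSpec(source, target, matrix=mat, sign=sign, delay=delay, port=port)


def build_diffuse(src_size: int, tgt_size: int, weight: float, *, source="", target="",
                  sign=1, delay=0.0, port="activation") -> ProjectionSpec:
    """Channel-wise sum: every target receives weight * sum(source)."""
    return ProjectionSpec(source, target, weight=float(weight), kind="diffuse",
                          sign=sign, delay=delay, port=port,
                          n_source=src_size, n_target=tgt_size)


def fovea_decay_profile(r, midpoint: float = 12.0, steepness: float = 0.5):
    """S-curve g(r) in [0, 1]: ~0 at the fovea, ~1 in the periphery."""
    return 1.0 / (1.0 + np.exp(-steepness * (np.asarray(r, dtype=float) - midpoint)))


def build_decaying_at_fovea(grid_shape=GRID_SHAPE, midpoint: float = 12.0,
                            steepness: float = 0.5, w_max: float = 1.0, *, source="",
                            target="", sign=1, delay=0.0, port="activation") -> ProjectionSpec:
    """One-to-one connection whose weight decays sigmoidally at the fovea."""
    r_idx, _ = _grid_coords(grid_shape)
    g = w_max * fovea_decay_profile(r_idx, midpoint, steepness)
    return build_one_to_one(grid_shape[0] * grid_shape[1], g, source=source,
                            target=target, sign=sign, delay=delay, port=port)


def widening_sigma(r, widening: WideningParams = WideningParams(),
                   mapping: MappingParams = MappingParams(), use_eccentricity: bool = True):
    """Width sigma(r) of the widening Gaussian projection field."""
    r = np.asarray(r, dtype=float)
    if use_eccentricity:
        M = mapping.magnification(mapping.eccentricity_of_r(r))
    else:
        M = mapping.magnification(r)
    sig = widening.m_sigma / M - widening.m_sigma / widening.M_0 + widening.sigma_0
    sig = np.maximum(sig, widening.sigma_0)
    return np.where(r <= widening.r_0, widening.sigma_0, sig)


def build_widening_gaussian(widening: WideningParams = WideningParams(),
                            mapping: MappingParams = MappingParams(),
                            threshold: float = 0.02, grid_shape=GRID_SHAPE,
                            use_eccentricity: bool = True, *, source="", target="",
                            sign=1, delay=0.0, port="activation") -> ProjectionSpec:
    """Gaussian fan-out whose width grows with the source's eccentricity.

    Per-edge weight exp(-d^2 / 2 sigma(r)^2) (unit peak), thresholded.
    """
    nr, nphi = grid_shape
    r_of_src = np.repeat(np.arange(1, nr + 1, dtype=float), nphi)
    sig = widening_sigma(r_of_src, widening, mapping, use_eccentricity)
    mat = _kernel_matrix(sig, 1.0, threshold, grid_shape)
    return ProjectionSpec(source, target, matrix=mat, sign=sign, delay=delay, port=port)


def build_sbg_weight_map(channel: str, params: WeightMapParams | None = None,
                         mapping: MappingParams = MappingParams(),
                         grid_shape=GRID_SHAPE) -> np.ndarray:
    """Weight vector from the collicular output layer to one SBG channel.

    w(r, phi) = i e^{j r} max(0, sin(2 pi (phi-1)/W_nfs + k)) with k set
    so the positive half-sine is centred on the channel's preferred
    direction.  The oblique (z+/z-) maps are 1/10 of the down/up maps.
    """
    if channel not in CHANNELS:
        raise ValueError(f"unknown channel {channel!r}")
    if channel == "z_plus":
        base = build_sbg_weight_map("down", params, mapping, grid_shape)
        return 0.1 * base
    if channel == "z_minus":
        base = build_sbg_weight_map("up", params, mapping, grid_shape)
        return 0.1 * base
    if params is None:
        params = REFERENCE_WEIGHT_MAPS[channel]
    W = float(grid_shape[1])
    phi_c = CHANNEL_PHI[channel]
    k = params.k if params.k is not None else math.pi / 2.0 - 2.0 * math.pi * (phi_c - 1.0) / W
    r_idx, phi_idx = _grid_coords(grid_shape)
    phase = 2.0 * math.pi * (phi_idx - 1.0) / W + k
    w = params.i * np.exp(params.j * r_idx) * np.maximum(0.0, np.sin(phase))
    return w


#: Tuned amplitude/exponent pairs for the rectus-channel weight maps.
REFERENCE_WEIGHT_MAPS = {
    "left": WeightMapParams(i=0.0016, j=0.067),
    "right": WeightMapParams(i=0.0016, j=0.067),
    "up": WeightMapParams(i=0.00195, j=0.075),
    "down": WeightMapParams(i=0.00195, j=0.075),
}


def build_tecto_tectal_inhibition(grid_shape=GRID_SHAPE, gain: float = 1.0,
                                  sigma: float | None = None, *, source="SC_deep",
                                  target="SC_deep", delay=0.0,
                                  port="activation") -> ProjectionSpec:
    """Inhibition between cells in opposite hemifields (phi offset by W/2).

    With ``sigma`` set, the inhibition spreads as a Gaussian around the
    antipodal cell; otherwise each cell inhibits exactly its antipode.
    """
    nr, nphi = grid_shape
    n = nr * nphi
    half = nphi // 2
    src_r = np.repeat(np.arange(nr), nphi)
    src_phi = np.tile(np.arange(nphi), nr)
    src = np.arange(n)
    if sigma is None:
        rows = src_r * nphi + (src_phi + half) % nphi
        mat = sp.csr_matrix((np.full(n, gain), (rows, src)), shape=(n, n))
    else:
        max_d = sigma * math.sqrt(2.0 * math.log(1.0 / 0.02))
        di, dj = _offsets_within(max_d)
        w = gain * np.exp(-(di**2 + dj**2) / (2.0 * sigma**2))
        keep = w >= 0.02 * gain
        rows, cols, data = [], [], []
        for ddi, ddj, ww in zip(di[keep], dj[keep], w[keep]):
            tr = src_r + ddi
            ok = (tr >= 0) & (tr < nr)
            tphi = (src_phi[ok] + half + ddj) % nphi
            rows.append(tr[ok] * nphi + tphi)
            cols.append(src[ok])
            data.append(np.full(int(ok.sum()), ww))
        mat = sp.csr_matrix(
            (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))), shape=(n, n)
        )
    return ProjectionSpec(source, target, matrix=mat, sign=-1, delay=delay, port=port)
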