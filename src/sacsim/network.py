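"""The full rate-coded brain network for saccade-target selection.

Architecture (each population a 50x50 retinotopic grid of 2500
elements):  the World input drives a fast/slow retinal pair whose
difference produces a phasic onset response into the superficial
superior colliculus (the express pathway), and, via a noisy delayed
sustained pathway, the frontal eye fields (FEF).  FEF, thalamus and the
basal ganglia (striatal D1/D2 populations, subthalamic nucleus, globus
pallidus externus and substantia nigra reticulata) form cortical and
subcortical selection loops; the SNr tonically inhibits the deep
colliculus and releases it only at the winning locus.  SC_deep carries
recurrent excitation plus tecto-tectal (opposite-hemifield) inhibition,
and projects through a widening Gaussian field to SC_deep2 and on to the
output layer SC_avg read by the brainstem burst generator.  A scalar
inhibitory feedback tap from the brainstem's inhibitory burst neurons
enters SC_deep, thalamus and FEF (shunting) to extinguish the motor
command after each saccade.

The update is synchronous with double buffering: every population reads
its afferents' outputs from the previous 1 ms step, so results do not
depend on population ordering.
"""

from __future__ import annotations

from collections import deque

import numpy as np

from sacsim.components import D1MSN, D2MSN, LINexp, LINlinear, LINret
from sacsim.config import default_config
from sacsim.connectivity import (
    ProjectionSpec,
    WeightMapParams,
    WideningParams,
    build_decaying_at_fovea,
    build_diffuse,
    build_gaussian_kernel,
    build_one_to_one,
    build_tecto_tectal_inhibition,
    build_widening_gaussian,
)
from sacsim.world import MappingParams

__all__ = ["POPULATIONS", "OculomotorNetwork", "build_network", "validate_topology"]

#: The frozen population manifest (World and FEF_add_noise are input
#: stages; the rest are dynamical populations).
POPULATIONS = (
    "World",
    "FEF_add_noise",
    "FEF",
    "Retina_1",
    "Retina_2",
    "Thalamus",
    "Str_D1",
    "Str_D2",
    "STN",
    "GPe",
    "SNr",
    "SC_sup",
    "SC_deep",
    "SC_deep2",
    "SC_avg",
)

#: The frozen edge manifest: (source, target, kernel) triples that a
#: valid configuration must reproduce exactly.
EDGE_MANIFEST = frozenset(
    {
        ("World", "Retina_1", "one_to_one"),
        ("World", "Retina_2", "one_to_one"),
        ("Retina_2", "Retina_1", "one_to_one"),
        ("Retina_1", "SC_sup", "gaussian"),
        ("FEF_add_noise", "FEF", "gaussian"),
        ("Thalamus", "FEF", "one_to_one"),
        ("FEF", "Thalamus", "one_to_one"),
        ("SC_deep", "Thalamus", "gaussian"),
        ("SNr", "Thalamus", "one_to_one"),
        ("FEF", "Str_D1", "decaying"),
        ("FEF", "Str_D2", "decaying"),
        ("Thalamus", "Str_D1", "decaying"),
        ("Thalamus", "Str_D2", "decaying"),
        ("FEF", "STN", "one_to_one"),
        ("STN", "SNr", "diffuse"),
        ("STN", "GPe", "diffuse"),
        ("Str_D1", "SNr", "gaussian"),
        ("Str_D2", "GPe", "gaussian"),
        ("GPe", "STN", "one_to_one"),
        ("GPe", "SNr", "one_to_one"),
        ("SNr", "SC_deep", "one_to_one"),
        ("SC_sup", "SC_deep", "gaussian"),
        ("FEF", "SC_deep", "gaussian"),
        ("SC_deep", "SC_deep", "gaussian"),
        ("SC_deep", "SC_deep", "tecto_tectal"),
        ("SC_deep", "SC_deep2", "widening"),
        ("SC_deep2", "SC_avg", "one_to_one"),
    }
)

_COMPONENTS = {
    "LINlinear": LINlinear,
    "LINret": LINret,
    "LINexp": LINexp,
    "D1MSN": D1MSN,
    "D2MSN": D2MSN,
}


class TopologyError(ValueError):
    """Raised when a configuration does not match the frozen manifest."""


def validate_topology(config: dict) -> None:
    edges = {
        (p["source"], p["target"], p["kernel"]) for p in config["projections"]
    }
    missing = EDGE_MANIFEST - edges
    extra = edges - EDGE_MANIFEST
    if missing or extra:
        raise TopologyError(
            f"projection topology mismatch; missing={sorted(missing)}, extra={sorted(extra)}"
        )
    pops = set(config["populations"]) | {"World", "FEF_add_noise"}
    if pops != set(POPULATIONS):
        raise TopologyError(
            f"population set mismatch; missing={set(POPULATIONS) - pops}, "
            f"extra={pops - set(POPULATIONS)}"
        )


def _gaussian_mass(sigma: float, threshold_frac: float = 0.02) -> float:
    """Sum of the thresholded discrete Gaussian kernel (unit peak)."""
    import math

    m = int(math.floor(sigma * math.sqrt(2.0 * math.log(1.0 / threshold_frac))))
    di = np.arange(-m, m + 1)
    w = np.exp(-(di[:, None] ** 2 + di[None, :] ** 2) / (2.0 * sigma**2))
    return float(w[w >= threshold_frac].sum())


def _build_projection(p: dict, config: dict, n: int) -> ProjectionSpec:
    kernel = p["kernel"]
    sign = int(p.get("sign", 1))
    port = p.get("port", "activation")
    delay = float(p.get("delay", 0.0))
    common = dict(source=p["source"], target=p["target"], sign=sign, port=port, delay=delay)
    if kernel == "one_to_one":
        return build_one_to_one(n, p["weight"], **common)
    if kernel == "gaussian":
        sigma = float(p["sigma"])
        if p["weight"] == 0:
            return build_one_to_one(n, 0.0, **common)
        peak = float(p["weight"]) / _gaussian_mass(sigma)
        return build_gaussian_kernel(sigma, w_max=peak, threshold=0.02 * peak, **common)
    if kernel == "diffuse":
        return build_diffuse(n, n, float(p["weight"]) / n, **common)
    if kernel == "decaying":
        d = config["decaying"]
        return build_decaying_at_fovea(
            midpoint=d["midpoint"], steepness=d["steepness"], w_max=p["weight"], **common
        )
    if kernel == "widening":
        wcfg = config["widening"]
        widening = WideningParams(
            m_sigma=wcfg["m_sigma"], sigma_0=wcfg["sigma_0"], M_0=wcfg["M_0"], r_0=wcfg["r_0"]
        )
        mapping = MappingParams(**config["mapping"])
        spec = build_widening_gaussian(
            widening,
            mapping,
            threshold=wcfg["threshold"],
            use_eccentricity=wcfg["use_eccentricity"],
            **common,
        )
        spec.matrix = spec.matrix * float(p.get("weight", 1.0))
        return spec
    if kernel == "tecto_tectal":
        return build_tecto_tectal_inhibition(
            gain=float(p["gain"]), sigma=p.get("sigma"), delay=delay, port=port
        )
    raise ValueError(f"unknown kernel {kernel!r}")


class OculomotorNetwork:
    """Builds and steps the selection network at the 1 ms neural timestep."""

    def __init__(self, config: dict | None = None, seed: int = 0) -> None:
        self.config = config or default_config()
        validate_topology(self.config)
        self.mapping = MappingParams(**self.config["mapping"])
        self.n = int(self.mapping.W_nfs) ** 2
        self.dt = float(self.config["dt"])
        flags = self.config["flags"]
        self.projections: list[ProjectionSpec] = []
        for p in self.config["projections"]:
            spec = _build_projection(p, self.config, self.n)
            if p["kernel"] == "tecto_tectal" and not flags.get("tecto_tectal", True):
                spec.matrix = spec.matrix * 0.0
            if p["kernel"] == "widening" and not flags.get("widening", True):
                # ablation: the projection field keeps its foveal width
                # everywhere (r_0 -> edge of map), so near-foveal gain is
                # unchanged but the fan-out no longer widens
                wcfg = self.config["widening"]
                ab = WideningParams(m_sigma=wcfg["m_sigma"], sigma_0=wcfg["sigma_0"],
                                    M_0=wcfg["M_0"], r_0=1e9)
                spec = build_widening_gaussian(
                    ab, MappingParams(**self.config["mapping"]),
                    threshold=wcfg["threshold"], source=p["source"], target=p["target"],
                )
                spec.matrix = spec.matrix * float(p.get("weight", 1.0))
            self.projections.append(spec)
        self._make_populations(seed)
        self._init_buffers()

    # -- construction -------------------------------------------------
    def _make_populations(self, seed: int) -> None:
        self.populations = {}
        d = float(self.config["dopamine"])
        for idx, (name, spec) in enumerate(sorted(self.config["populations"].items())):
            cls = _COMPONENTS[spec["component"]]
            kwargs = {k: v for k, v in spec.items() if k != "component"}
            if cls in (D1MSN, D2MSN):
                kwargs["d"] = d
            pop = cls(n=self.n, seed=seed * 1000 + idx + 1, name=name, **kwargs)
            self.populations[name] = pop
        self._noise_rng = np.random.default_rng(seed * 1000)
        self._fef_noise_alpha = float(self.config["fef_add_noise_alpha"])

    def _init_buffers(self) -> None:
        self.outputs = {name: np.zeros(self.n) for name in POPULATIONS}
        self._delay_bufs = []
        for spec in self.projections:
            steps = int(round(spec.delay / self.dt))
            buf = deque([np.zeros(self.n)] * steps, maxlen=steps) if steps else None
            self._delay_bufs.append(buf)
        self.clock = 0.0

    def reset(self, seed: int | None = None) -> None:
        """Zero all state; with ``seed``, reseed every noise stream."""
        if seed is not None:
            self._make_populations(seed)
        else:
            for pop in self.populations.values():
                pop.reset()
        self._init_buffers()

    def set_dopamine(self, d: float) -> None:
        for name in ("Str_D1", "Str_D2"):
            pop = self.populations[name]
            if not 0.0 <= d <= 1.0:
                raise ValueError("dopamine level d must lie in [0, 1]")
            pop.d = float(d)

    # -- dynamics ------------------------------------------------------
    def step(self, world_grid: np.ndarray, ibn_feedback: float = 0.0) -> None:
        """One synchronous 1 ms update given the current retinal image."""
        dt = self.dt
        world = np.asarray(world_grid, dtype=float).reshape(self.n)
        self.outputs["World"] = world
        fan = world + self._fef_noise_alpha * self._noise_rng.standard_normal(self.n)
        self.outputs["FEF_add_noise"] = np.maximum(fan, 0.0)

        sums: dict[tuple[str, str], np.ndarray] = {}
        for spec, buf in zip(self.projections, self._delay_bufs):
            x = self.outputs[spec.source]
            if buf is not None:
                delayed = buf.popleft()
                buf.append(x)
                x = delayed
            drive = spec.apply(x)
            key = (spec.target, spec.port)
            if spec.port == "activation":
                drive = spec.sign * drive
            if key in sums:
                sums[key] = sums[key] + drive
            else:
                sums[key] = drive

        if self.config["flags"].get("ibn_feedback", True) and ibn_feedback > 0.0:
            fb = self.config["feedback"]
            for tgt in fb["targets"]:
                key = (tgt, fb["port"])
                extra = fb["weight"] * ibn_feedback
                sums[key] = sums.get(key, 0.0) + extra

        zero = 0.0
        for name, pop in self.populations.items():
            A = sums.get((name, "activation"), zero)
            if isinstance(pop, (LINret,)):
                pop.step(A=A, dt=dt)
            elif isinstance(pop, (D1MSN, D2MSN)):
                pop.step(A=A, dt=dt)
            elif isinstance(pop, LINexp):
                pop.step(A=A, S=sums.get((name, "shunting"), zero),
                         N=sums.get((name, "reversal"), zero), dt=dt)
            else:
                pop.step(A=A, S=sums.get((name, "shunting"), zero), dt=dt)
            if not np.all(np.isfinite(pop.a)):
                raise FloatingPointError(f"non-finite activation in population {name}")
            self.outputs[name] = pop.output
        self.clock += dt

    def read_sc_avg(self) -> np.ndarray:
        """Instantaneous output of the collicular output layer (50x50)."""
        side = int(self.mapping.W_nfs)
        return self.populations["SC_avg"].y.reshape(side, side)

    def probe(self, name: str) -> np.ndarray:
        """Current output of any population as a 50x50 array."""
        side = int(self.mapping.W_nfs)
        return np.asarray(self.outputs[name]).reshape(side, side)


def build_network(config: dict | None = None, seed: int = 0) -> OculomotorNetwork:
    """Build the reference network (validates against the frozen manifest)."""
    return OculomotorNetwork(config, seed)
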