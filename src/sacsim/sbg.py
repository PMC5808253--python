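"""Six-channel saccadic burst generator (SBG).

Each channel (up, down, left, right, z_plus, z_minus — one per
extraocular muscle of a left eye) contains single-element populations of
long-lead burst neurons (LLBN), excitatory burst neurons (EBN),
inhibitory burst neurons (IBN), tonic neurons (TN, a pure integrator)
and motoneurons (MN).  Collicular output excites the LLBNs through the
channel's weight map.  EBNs are excited by the LLBN and inhibited by a
single, globally shared omnipause (OPN) unit, itself tonically active
and inhibited by the summed LLBN activity — the latch that prevents
movements in response to neural noise.  IBNs follow the EBN and inhibit
the LLBN after a transmission delay, terminating the burst; the TN
integrates the EBN bump into a sustained step (with an optional
inhibitory reset input from the contralateral EBN), and the MN sums
burst and step into the "bump and tonic" drive sent to the muscle.

The summed IBN activity is also exposed as the inhibitory feedback tap
to the brain model (SC_deep, thalamus, FEF).

Channel -> muscle assignment (left eye): up = superior rectus, down =
inferior rectus, right = medial rectus, left = lateral rectus,
z_plus = superior oblique, z_minus = inferior oblique.
"""

from __future__ import annotations

from collections import deque

import numpy as np

from sacsim.components import SBGUnit
from sacsim.connectivity import CHANNELS, WeightMapParams, build_sbg_weight_map
from sacsim.world import MappingParams

__all__ = ["SBGChannel", "BurstGenerator", "CHANNELS", "ANTAGONIST"]

ANTAGONIST = {
    "up": "down", "down": "up",
    "left": "right", "right": "left",
    "z_plus": "z_minus", "z_minus": "z_plus",
}


class SBGChannel:
    """The unit populations and weight map for one muscle channel."""

    def __init__(self, name: str, weight_map: np.ndarray, cfg: dict) -> None:
        self.name = name
        self.weight_map = np.asarray(weight_map, dtype=float)
        signed = bool(cfg.get("tn_reset", True))
        self.llbn = SBGUnit(cfg["tau_llbn"], cfg["b_llbn"], name=f"{name}.LLBN")
        self.ebn = SBGUnit(cfg["tau_ebn"], cfg["b_ebn"], name=f"{name}.EBN")
        self.ibn = SBGUnit(cfg["tau_ibn"], cfg["b_ibn"], name=f"{name}.IBN")
        self.tn = SBGUnit(cfg["tau_tn"], cfg["b_tn"], kind="integrator",
                          signed=signed, name=f"{name}.TN")
        self.mn = SBGUnit(cfg["tau_mn"], cfg["b_mn"], name=f"{name}.MN")
        delay_steps = max(1, int(round(cfg["ibn_delay"] / cfg.get("dt", 0.001))))
        self._ibn_buf = deque([0.0] * delay_steps, maxlen=delay_steps)

    def units(self):
        return {"LLBN": self.llbn, "EBN": self.ebn, "IBN": self.ibn,
                "TN": self.tn, "MN": self.mn}

    def state(self) -> dict[str, float]:
        return {k: u.value for k, u in self.units().items()}

    def reset(self) -> None:
        for u in self.units().values():
            u.reset()
        self._ibn_buf = deque([0.0] * self._ibn_buf.maxlen, maxlen=self._ibn_buf.maxlen)


class BurstGenerator:
    """The six channels plus the shared omnipause unit."""

    def __init__(self, cfg: dict, mapping: MappingParams = MappingParams()) -> None:
        self.cfg = dict(cfg)
        self.mapping = mapping
        maps = {}
        wm = cfg.get("weight_maps", {})
        for ch in ("up", "down", "left", "right"):
            p = wm.get(ch)
            params = WeightMapParams(i=p["i"], j=p["j"]) if p else None
            maps[ch] = build_sbg_weight_map(ch, params, mapping)
        maps["z_plus"] = 0.1 * maps["down"]
        maps["z_minus"] = 0.1 * maps["up"]
        self.channels = {ch: SBGChannel(ch, maps[ch], cfg) for ch in CHANNELS}
        self.opn = SBGUnit(cfg["tau_opn"], cfg["b_opn"], name="OPN")
        self.opn.a[:] = 1.0  # tonically active from the start

    def reset(self) -> None:
        for ch in self.channels.values():
            ch.reset()
        self.opn.reset()
        self.opn.a[:] = 1.0

    @property
    def tn_values(self) -> dict[str, float]:
        return {name: ch.tn.value for name, ch in self.channels.items()}

    def step(self, sc_avg: np.ndarray, dt: float = 0.001):
        """One 1 ms update.

        Parameters
        ----------
        sc_avg : flat (2500,) or (50, 50) collicular output activity.

        Returns
        -------
        mn : 6-vector of motoneuron activations in [0, 1] in channel
            order (up, down, left, right, z_plus, z_minus).
        ibn_feedback : non-negative scalar feedback tap for the brain.
        """
        c = self.cfg
        sc = np.asarray(sc_avg, dtype=float).ravel()
        llbn_prev = {n: ch.llbn.value for n, ch in self.channels.items()}
        ebn_prev = {n: ch.ebn.value for n, ch in self.channels.items()}
        ibn_prev = {n: ch.ibn.value for n, ch in self.channels.items()}
        tn_prev = {n: ch.tn.value for n, ch in self.channels.items()}
        opn_prev = self.opn.value

        opn_in = -c["w_llbn_opn"] * sum(llbn_prev.values()) \
            - c.get("w_ebn_opn", 0.0) * sum(ebn_prev.values())
        self.opn.step(opn_in, dt)
        mn_out = np.zeros(6)
        for idx, name in enumerate(CHANNELS):
            ch = self.channels[name]
            ibn_delayed = ch._ibn_buf.popleft()
            ch._ibn_buf.append(ibn_prev[name])
            drive = float(ch.weight_map @ sc) * c["w_sc"]
            ch.llbn.step(drive - c["w_ibn_llbn"] * ibn_delayed, dt)
            ch.ebn.step(c["w_llbn_ebn"] * llbn_prev[name] - c["w_opn_ebn"] * opn_prev, dt)
            ch.ibn.step(c["w_ebn_ibn"] * ebn_prev[name], dt)
            tn_in = c["g_tn"] * ebn_prev[name]
            if c.get("tn_reset", True):
                tn_in -= c["g_reset"] * ebn_prev[ANTAGONIST[name]]
            ch.tn.step(tn_in, dt)
            ch.mn.step(c["w_ebn_mn"] * ebn_prev[name] + c["w_tn_mn"] * tn_prev[name], dt)
            mn_out[idx] = np.clip(ch.mn.value, 0.0, 1.0)
            if not np.isfinite(mn_out[idx]):
                raise FloatingPointError(f"non-finite activation in SBG channel {name}")
        ibn_feedback = c["w_fb"] * sum(ch.ibn.value for ch in self.channels.values())
        return mn_out, max(ibn_feedback, 0.0)
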