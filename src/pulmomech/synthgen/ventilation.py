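"""Synthetic volume-controlled ventilation with end-inspiratory occlusions.

Forward model: a single-compartment linear lung with one Maxwell body,

    Ptr = PEEP + Raw*V' + Est_true*V + Pve,
    dPve/dt = E2*V' - Pve/tau,   tau = R2/E2,

so after an occlusion (V' = 0) the viscoelastic pressure decays
exponentially toward the plateau Pel = PEEP + Est_true*VT.  The generator
additionally adds the intubation-cannula drop k1*V' + k2*V'|V'| so the
analysis-side correction is exercised, plus optional Gaussian pressure
noise.  Inspiration is constant-flow; expiration is a passive first-order
decay scaled to return the volume exactly to zero each breath.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from ..errors import InvalidSpecError
from ..ventmech import VentilationRecording


@dataclass
class LungModelParams:
    """Mechanical ground truth of one synthetic animal.

    Units: elastances cmH2O/ml, resistances cmH2O.s/ml, pressures cmH2O.
    """

    Est_true: float
    Raw: float = 0.5
    E2: float = 0.0
    R2: float = 0.0
    PEEP: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.Est_true <= 0:
            raise InvalidSpecError("Est_true must be positive")
        for name in ("Raw", "E2", "R2", "noise_sd"):
            if getattr(self, name) < 0:
                raise InvalidSpecError(f"{name} must be non-negative")

    @property
    def tau(self) -> float:
        """Viscoelastic time constant R2/E2 (s); 0 when the Maxwell body is off."""
        return self.R2 / self.E2 if self.E2 > 0 else 0.0


@dataclass
class ManeuverSpec:
    """Ventilator maneuver: tidal breathing plus end-inspiratory occlusions."""

    VT: float                   # ml
    rate: float = 100.0         # breaths/min
    fs: float = 100.0           # Hz
    n_breaths_before_occlusion: int = 100   # 1 min equivalent at 100 bpm
    occlusion_duration: float = 5.0         # s
    n_occlusions: int = 2
    cannula_k1: float = 0.0     # cmH2O.s/ml
    cannula_k2: float = 0.0     # cmH2O.s^2/ml^2
    insp_fraction: float = 0.4  # inspiratory fraction of the breath cycle
    n_recovery_breaths: int = 2

    def __post_init__(self):
        if self.VT <= 0:
            raise InvalidSpecError("VT must be positive")
        if self.fs <= 0 or self.rate <= 0:
            raise InvalidSpecError("fs and rate must be positive")
        if self.occlusion_duration <= 0:
            raise InvalidSpecError("occlusion_duration must be positive")
        if not 0 < self.insp_fraction < 1:
            raise InvalidSpecError("insp_fraction must lie in (0, 1)")
        if self.n_occlusions < 1 or self.n_breaths_before_occlusion < 1:
            raise InvalidSpecError("need >= 1 occlusion and >= 1 breath before each")


def _build_flow_volume(spec: ManeuverSpec):
    """Sample-wise flow (zero-order hold) and pre-update volume arrays.

    Volume bookkeeping is exact under the forward-Euler convention
    V[n+1] = V[n] + flow[n]*dt, so the occluded samples sit exactly at VT.
    Returns (flow, volume, occlusion_onset_indices).
    """
    dt = 1.0 / spec.fs
    period = 60.0 / spec.rate
    n_ti = max(int(round(spec.insp_fraction * period * spec.fs)), 1)
    n_te = max(int(round(period * spec.fs)) - n_ti, 1)
    n_occ = int(round(spec.occlusion_duration * spec.fs))
    tau_e = (n_te * dt) / 6.0
    a = np.exp(-dt / tau_e)

    flow: list[float] = []
    vol: list[float] = []
    onsets: list[int] = []
    v = 0.0

    def inspire():
        nonlocal v
        q = spec.VT / (n_ti * dt)
        for _ in range(n_ti):
            flow.append(q)
            vol.append(v)
            v += q * dt

    def expire():
        nonlocal v
        for i in range(n_te):
            q = -v / dt if i == n_te - 1 else v * (a - 1.0) / dt
            flow.append(q)
            vol.append(v)
            v += q * dt
        v = 0.0

    for _ in range(spec.n_occlusions):
        for _ in range(spec.n_breaths_before_occlusion):
            inspire()
            expire()
        inspire()
        onsets.append(len(flow))
        for _ in range(n_occ):
            flow.append(0.0)
            vol.append(v)
        expire()
    for _ in range(spec.n_recovery_breaths):
        inspire()
        expire()
    return np.asarray(flow), np.asarray(vol), np.asarray(onsets, dtype=int)


def _forward(params: LungModelParams, spec: ManeuverSpec):
    """Noise-free forward simulation; returns a dict of internal signals."""
    flow, vol, onsets = _build_flow_volume(spec)
    n = flow.size
    dt = 1.0 / spec.fs
    pve = np.zeros(n)
    if params.E2 > 0 and params.R2 > 0:
        tau = params.tau
        a = np.exp(-dt / tau)
        gain = params.E2 * tau * (1.0 - a)
        acc = 0.0
        for i in range(n - 1):
            acc = acc * a + gain * flow[i]
            pve[i + 1] = acc
    ptr = (params.PEEP + params.Raw * flow + params.Est_true * vol + pve
           + spec.cannula_k1 * flow + spec.cannula_k2 * flow * np.abs(flow))
    t = np.arange(n) * dt
    return {"t": t, "flow": flow, "volume": vol, "pve": pve,
            "ptr_clean": ptr, "onsets": onsets}


def simulate_ventilation(params: LungModelParams, spec: ManeuverSpec,
                         compartment_label: str = "lung") -> VentilationRecording:
    """Generate a ventilation recording with ``spec.n_occlusions`` occlusions.

    Flow is exactly zero throughout each occlusion window; the noiseless
    output is reproducible from ``params.seed``.  True occlusion onset
    indices are stored in ``meta['occlusion_onsets']``.
    """
    sig = _forward(params, spec)
    ptr = sig["ptr_clean"].copy()
    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        ptr = ptr + rng.normal(0.0, params.noise_sd, ptr.size)
    meta = {
        "VT": spec.VT, "PEEP": params.PEEP, "fs": spec.fs,
        "cannula_k1": spec.cannula_k1, "cannula_k2": spec.cannula_k2,
        "compartment_label": compartment_label,
        "occlusion_onsets": sig["onsets"].tolist(),
    }
    return VentilationRecording(t=sig["t"], flow=sig["flow"], ptr=ptr, meta=meta)


def params_for_ratio(Est_true: float, spec: ManeuverSpec, ratio: float = 1.15,
                     tau: float = 0.3, **kwargs) -> LungModelParams:
    """Choose (E2, R2) so the viscoelastic pressure at occlusion onset gives
    the requested Edyn/Est ratio: Pve(onset) = (ratio - 1) * Est_true * VT.

    With tau fixed, Pve is linear in E2, so one unit-gain forward run
    suffices to solve for E2 exactly.
    """
    if ratio < 1:
        raise InvalidSpecError("Edyn/Est ratio must be >= 1")
    probe = LungModelParams(Est_true=Est_true, E2=1.0, R2=tau, **kwargs)
    sig = _forward(probe, spec)
    pve_unit = float(sig["pve"][sig["onsets"][0]])
    if pve_unit <= 0:
        raise InvalidSpecError("no viscoelastic build-up at occlusion onset")
    e2 = (ratio - 1.0) * Est_true * spec.VT / pve_unit
    return replace(probe, E2=e2, R2=tau * e2)
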