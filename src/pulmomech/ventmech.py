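"""End-inspiratory occlusion respiratory mechanics.

Extracts static (Est) and dynamic (Edyn) elastances from volume-controlled
ventilation recordings by the end-inspiratory airway occlusion method.  After
an occlusion, tracheal pressure shows a fast initial drop (dP1, resistive)
from the pre-occlusion value to an inflection point Pi, followed by a slow
viscoelastic decay (dP2) to a plateau Pel.  Then

    Est  = (Pel - PEEP) / VT        Edyn = (Pi - PEEP) / VT

with Pel read after 5 s of occlusion and PEEP taken from recording metadata.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.integrate import cumulative_trapezoid

from ._fitutil import hinge_fit
from .errors import (AnalysisError, ConfigurationError,
                     InsufficientOcclusionError, InvalidSpecError, UsageError)

#: metadata keys required for a complete analysis
_REQUIRED_META = ("VT", "PEEP", "fs")


@dataclass
class VentilationRecording:
    """Uniformly sampled flow and tracheal pressure with maneuver metadata.

    Channels: ``t`` (s), ``flow`` (ml/s, inspiration positive) and ``ptr``
    (cmH2O).  ``meta`` carries VT (ml), PEEP (cmH2O), fs (Hz), cannula
    coefficients (cmH2O.s/ml and cmH2O.s^2/ml^2) and a compartment label
    (``total``, ``lung`` or ``scaffold``).
    """

    t: np.ndarray
    flow: np.ndarray
    ptr: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.flow = np.asarray(self.flow, dtype=float)
        self.ptr = np.asarray(self.ptr, dtype=float)
        if not (self.t.size == self.flow.size == self.ptr.size):
            raise InvalidSpecError("t, flow and ptr must have equal length")
        if self.t.size < 2:
            raise InvalidSpecError("recording needs at least two samples")
        steps = np.diff(self.t)
        if np.any(steps <= 0) or not np.allclose(steps, steps[0], rtol=1e-6):
            raise InvalidSpecError("t must increase with a constant step")
        fs = self.meta.get("fs")
        if fs is not None and fs <= 0:
            raise InvalidSpecError("fs must be positive")

    @property
    def fs(self) -> float:
        return float(self.meta.get("fs") or 1.0 / (self.t[1] - self.t[0]))

    # ------------------------------------------------------------------ I/O
    def to_tsv(self, path: str | Path, meta_path: str | Path | None = None) -> None:
        """Write the channels as TSV (time_s, flow_ml_s, ptr_cmH2O) plus a
        YAML metadata sidecar."""
        path = Path(path)
        df = pd.DataFrame({"time_s": self.t, "flow_ml_s": self.flow,
                           "ptr_cmH2O": self.ptr})
        df.to_csv(path, sep="\t", index=False, float_format="%.10g")
        meta_path = Path(meta_path) if meta_path else path.with_suffix(".meta.yaml")
        meta = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                for k, v in self.meta.items()}
        meta_path.write_text(yaml.safe_dump(meta, sort_keys=True))

    @classmethod
    def from_tsv(cls, path: str | Path,
                 meta_path: str | Path | None = None) -> "VentilationRecording":
        path = Path(path)
        df = pd.read_csv(path, sep="\t")
        meta_path = Path(meta_path) if meta_path else path.with_suffix(".meta.yaml")
        meta = yaml.safe_load(meta_path.read_text()) if meta_path.exists() else {}
        return cls(t=df["time_s"].to_numpy(), flow=df["flow_ml_s"].to_numpy(),
                   ptr=df["ptr_cmH2O"].to_numpy(), meta=meta or {})


@dataclass(frozen=True)
class OcclusionWindow:
    """A zero-flow window, with the volume held at its start."""

    start: int
    end: int                      # exclusive
    v_start: float                # integrated volume at the first zero-flow sample, ml
    preceded_by_inspiration: bool

    @property
    def n(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class OcclusionMeasures:
    """Pressure landmarks and elastances of one end-inspiratory occlusion."""

    onset_idx: int
    dP1: float
    dP2: float
    Pi: float
    Pel: float
    Est: float
    Edyn: float
    negative_dp2_warning: bool = False


@dataclass
class ElastanceResult:
    """Per-occlusion elastances and their means for one compartment."""

    est_values: np.ndarray
    edyn_values: np.ndarray
    compartment_label: str = "lung"
    per_occlusion: list = field(default_factory=list)

    def __post_init__(self):
        self.est_values = np.atleast_1d(np.asarray(self.est_values, dtype=float))
        self.edyn_values = np.atleast_1d(np.asarray(self.edyn_values, dtype=float))
        if self.est_values.size != self.edyn_values.size:
            raise InvalidSpecError("Est/Edyn per-occlusion lists differ in length")

    @property
    def Est_mean(self) -> float:
        return float(np.mean(self.est_values))

    @property
    def Edyn_mean(self) -> float:
        return float(np.mean(self.edyn_values))

    @property
    def ratio_dyn_st(self) -> float:
        return self.Edyn_mean / self.Est_mean


@dataclass
class VentConfig:
    """Thresholds of the occlusion analysis; all defaults overridable."""

    flow_zero_frac: float = 0.02      # fraction of peak inspiratory flow
    flow_zero_abs: float = 1e-9       # ml/s, floor so an all-zero trace qualifies
    min_occlusion_s: float = 2.0      # shortest zero-flow run treated as occlusion
    occlusion_read_s: float = 5.0     # Pel is read at onset + this interval
    plateau_window_s: float = 0.2     # averaging window ending at the read-out
    fast_phase_s: float = 0.5         # post-onset extent of the Pi breakpoint fit
    pre_window_s: float = 0.05        # pre-onset samples anchoring the fast segment
    insp_onset_frac: float = 0.25     # flow threshold for inspiration-onset rezeroing
    vt_match_tol: float = 0.25        # |V - VT|/VT accepted as "preceded by inspiration"
    negative_dp2_tol: float = 0.05    # cmH2O


# --------------------------------------------------------------------------
def correct_cannula(rec: VentilationRecording) -> VentilationRecording:
    """Subtract the nonlinear cannula pressure drop k1*V' + k2*V'*|V'|.

    Coefficients come from recording metadata (``cannula_k1``/``cannula_k2``).
    """
    k1 = rec.meta.get("cannula_k1")
    k2 = rec.meta.get("cannula_k2")
    if k1 is None or k2 is None:
        raise ConfigurationError("cannula coefficients missing from metadata")
    ptr = rec.ptr - (k1 * rec.flow + k2 * rec.flow * np.abs(rec.flow))
    meta = dict(rec.meta)
    meta["cannula_corrected"] = True
    return VentilationRecording(t=rec.t, flow=rec.flow, ptr=ptr, meta=meta)


def integrate_flow(rec: VentilationRecording,
                   config: VentConfig | None = None,
                   rezero: bool = True) -> np.ndarray:
    """Volume (ml) by trapezoidal integration of flow, re-zeroed at each
    detected inspiration onset to suppress integration drift (disable with
    ``rezero=False`` for a plain cumulative integral)."""
    config = config or VentConfig()
    dt = 1.0 / rec.fs
    v = cumulative_trapezoid(rec.flow, dx=dt, initial=0.0)
    peak = float(np.max(rec.flow, initial=0.0))
    if rezero and peak > 0:
        thr = config.insp_onset_frac * peak
        above = rec.flow >= thr
        onsets = np.flatnonzero(above[1:] & ~above[:-1]) + 1
        for i in onsets:
            v[i:] -= v[i]
    return v


def detect_occlusions(rec: VentilationRecording,
                      config: VentConfig | None = None) -> list[OcclusionWindow]:
    """Locate sustained zero-flow windows beginning at end-inspiration.

    A window is a maximal run with |V'| below ``flow_zero_frac`` of the peak
    inspiratory flow lasting at least ``min_occlusion_s``.  Each window is
    checked against the integrated volume: an occlusion proper starts with
    the lung inflated to ~VT.
    """
    config = config or VentConfig()
    peak = float(np.max(rec.flow, initial=0.0))
    thr = max(config.flow_zero_frac * peak, config.flow_zero_abs)
    quiet = np.abs(rec.flow) <= thr
    v = integrate_flow(rec, config)
    vt = rec.meta.get("VT")
    min_n = int(round(config.min_occlusion_s * rec.fs))

    windows: list[OcclusionWindow] = []
    edges = np.flatnonzero(np.diff(quiet.astype(np.int8)))
    starts = [0] if quiet[0] else []
    starts += list(edges[~quiet[edges]] + 1)        # False -> True transitions
    ends = list(edges[quiet[edges]] + 1)            # True -> False transitions
    if quiet[-1]:
        ends.append(quiet.size)
    for s, e in zip(starts, ends):
        if e - s < max(min_n, 2):
            continue
        v0 = float(v[s])
        preceded = vt is not None and vt > 0 and abs(v0 - vt) <= config.vt_match_tol * vt
        windows.append(OcclusionWindow(start=s, end=e, v_start=v0,
                                       preceded_by_inspiration=preceded))
    return windows


def measure_occlusion(rec: VentilationRecording, window: OcclusionWindow,
                      config: VentConfig | None = None) -> OcclusionMeasures:
    """Pressure landmarks (dP1, dP2, Pi, Pel) and elastances for one occlusion.

    Pel is the mean pressure over the last ``plateau_window_s`` of the 5-s
    read-out interval.  Pi is the breakpoint pressure of a two-segment
    continuous piecewise-linear fit spanning ``pre_window_s`` before to
    ``fast_phase_s`` after the onset; the breakpoint is chosen by least
    squares over post-onset sample positions.
    """
    config = config or VentConfig()
    for key in _REQUIRED_META:
        if rec.meta.get(key) is None:
            raise ConfigurationError(f"metadata key {key!r} required")
    fs = rec.fs
    onset = window.start
    n_read = int(round(config.occlusion_read_s * fs))
    if window.n < n_read:
        raise InsufficientOcclusionError(
            f"occlusion lasts {window.n / fs:.2f} s < {config.occlusion_read_s} s")

    # plateau pressure after 5 s of occlusion
    i_end = onset + n_read
    n_plat = max(int(round(config.plateau_window_s * fs)), 1)
    pel = float(np.mean(rec.ptr[i_end - n_plat:i_end]))

    # breakpoint (inflection-point) fit over the fast phase
    n_pre = min(int(round(config.pre_window_s * fs)), onset)
    n_fast = int(round(config.fast_phase_s * fs))
    i0, i1 = onset - n_pre, min(onset + n_fast, window.end)
    seg_t = rec.t[i0:i1]
    seg_p = rec.ptr[i0:i1]
    candidates = np.arange(max(onset - i0, 1), seg_t.size - 2)
    fit = hinge_fit(seg_t, seg_p, candidates=candidates, min_seg=1)
    pi = fit.y_break

    p_pre = float(rec.ptr[onset - 1]) if onset > 0 else float(rec.ptr[onset])
    dp1 = p_pre - pi
    dp2 = pi - pel
    peep = float(rec.meta["PEEP"])
    vt = float(rec.meta["VT"])
    if vt <= 0:
        raise InvalidSpecError("VT must be positive")
    return OcclusionMeasures(
        onset_idx=onset, dP1=dp1, dP2=dp2, Pi=pi, Pel=pel,
        Est=(pel - peep) / vt, Edyn=(pi - peep) / vt,
        negative_dp2_warning=dp2 < -config.negative_dp2_tol)


def compute_elastances(rec: VentilationRecording,
                       config: VentConfig | None = None,
                       correct: bool | None = None) -> ElastanceResult:
    """Full single-recording pipeline: cannula correction, occlusion
    detection, per-occlusion measures and their arithmetic mean.

    ``correct`` forces/disables cannula correction; by default it is applied
    when coefficients are present and the trace is not already corrected.
    """
    config = config or VentConfig()
    if correct is None:
        correct = (rec.meta.get("cannula_k1") is not None
                   and not rec.meta.get("cannula_corrected", False))
    if correct:
        rec = correct_cannula(rec)
    windows = [w for w in detect_occlusions(rec, config)
               if w.preceded_by_inspiration]
    if not windows:
        raise AnalysisError("no end-inspiratory occlusion detected")
    measures = [measure_occlusion(rec, w, config) for w in windows]
    return ElastanceResult(
        est_values=np.array([m.Est for m in measures]),
        edyn_values=np.array([m.Edyn for m in measures]),
        compartment_label=str(rec.meta.get("compartment_label", "lung")),
        per_occlusion=measures)


def chest_wall_elastance(total: ElastanceResult,
                         lung: ElastanceResult) -> ElastanceResult:
    """Chest-wall elastances as the per-occlusion difference between the
    total respiratory system and the lung (same animal, same maneuvers)."""
    if total.compartment_label != "total" or lung.compartment_label != "lung":
        raise UsageError("expected a 'total' and a 'lung' ElastanceResult")
    if total.est_values.size != lung.est_values.size:
        raise UsageError("mismatched number of occlusions")
    return ElastanceResult(
        est_values=total.est_values - lung.est_values,
        edyn_values=total.edyn_values - lung.edyn_values,
        compartment_label="chest_wall")


def result_to_dict(res: ElastanceResult) -> dict:
    """JSON-serializable summary of an ElastanceResult."""
    return {
        "compartment_label": res.compartment_label,
        "Est_mean": res.Est_mean,
        "Edyn_mean": res.Edyn_mean,
        "ratio_dyn_st": res.ratio_dyn_st,
        "per_occlusion": [dataclasses.asdict(m) for m in res.per_occlusion],
        "est_values": res.est_values.tolist(),
        "edyn_values": res.edyn_values.tolist(),
    }
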