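"""AFM nanomechanics of soft matrices.

Three estimators:

* pyramidal Hertz fit of approach force curves,
      F = 3*E*tan(theta) / (4*(1 - nu^2)) * delta^2,
  expressed in piezo/deflection coordinates
      d = d0 + 3*E*tan(theta) / (4*k*(1 - nu^2)) * [(z - z0) - (d - d0)]^2,
  solved by bounded nonlinear least squares for (E, z0, d0) with the fit
  restricted to indentations <= 500 nm (re-masked each outer iteration);

* complex shear modulus from a small-amplitude multifrequency oscillation
  around an operating indentation delta0,
      G*(f) = (1 - nu) / (3*delta0*tan(theta)) * [F(f)/delta(f) - i*f*b(h)],
  with F(f), delta(f) estimated by least-squares sinusoidal regression and
  the cantilever drag i*f*b(h) subtracted;

* the two power-law viscoelastic model fitted in the complex plane,
      G*(f) = A*(i f)^alpha + B*(i f)^(3/4),   f normalized to 1 Hz.

Unit conventions: z, d, delta in nm; F in nN; k in N/m; E, G in Pa
(power-law amplitudes A, B in kPa); b(h) in N.s/m.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from ._fitutil import hinge_fit
from .errors import (AnalysisError, CalibrationError, DegenerateExcitationError,
                     InvalidSpecError)

DEFAULT_FREQS = (0.35, 1.15, 3.55, 11.45)  # Hz, pairwise non-sum/non-difference


def hertz_coefficient(E: float, k: float, theta_deg: float, nu: float) -> float:
    """Deflection-space Hertz coefficient c (1/nm): d - d0 = c * delta^2.

    E in Pa, k in N/m, lengths in nm.
    """
    return 3.0 * E * np.tan(np.radians(theta_deg)) / (4.0 * k * (1.0 - nu**2)) * 1e-9


def hertz_force(E: float, delta_nm: np.ndarray, theta_deg: float = 20.0,
                nu: float = 0.5) -> np.ndarray:
    """Contact force (nN) of an ideal pyramid at indentation delta (nm)."""
    delta_m = np.asarray(delta_nm, dtype=float) * 1e-9
    f_N = 3.0 * E * np.tan(np.radians(theta_deg)) / (4.0 * (1.0 - nu**2)) * delta_m**2
    return f_N * 1e9


@dataclass
class ForceCurve:
    """AFM approach curve: piezo displacement z vs cantilever deflection d (nm)."""

    z: np.ndarray
    d: np.ndarray
    k: float = 0.03          # N/m
    theta: float = 20.0      # deg, semi-included tip angle
    nu: float = 0.5
    sensitivity: float | None = None  # V->nm, set when d is still raw photodiode

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=float)
        self.d = np.asarray(self.d, dtype=float)
        if self.z.size != self.d.size:
            raise InvalidSpecError("z and d must have equal length")
        if self.k <= 0:
            raise InvalidSpecError("spring constant must be positive")
        if not 0 < self.theta < 90:
            raise InvalidSpecError("theta must lie in (0, 90) degrees")
        if not 0 <= self.nu <= 0.5:
            raise InvalidSpecError("Poisson ratio must lie in [0, 0.5]")

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame({"z_nm": self.z, "d_nm": self.d}).to_csv(
            path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_tsv(cls, path: str | Path, **cantilever) -> "ForceCurve":
        df = pd.read_csv(path, sep="\t")
        return cls(z=df["z_nm"].to_numpy(), d=df["d_nm"].to_numpy(), **cantilever)


@dataclass(frozen=True)
class HertzFit:
    E: float                    # Pa
    z0: float                   # nm
    d0: float                   # nm
    max_indentation_used: float  # nm
    rss: float
    converged: bool
    n_used: int = 0


@dataclass
class HertzFitConfig:
    max_indentation: float = 500.0   # nm
    min_indentation: float = 0.0     # nm; set ~300 for blunted-tip validity
    e_inits: tuple = (1e3, 2e4)      # Pa, multi-start guard against local minima
    max_mask_iter: int = 10
    min_contact_samples: int = 10


def predict_deflection(z: np.ndarray, E: float, z0: float, d0: float,
                       k: float, theta: float, nu: float) -> np.ndarray:
    """Closed-form deflection of the pyramidal Hertz model at piezo positions z.

    For x = z - z0 > 0 the quadratic in u = d - d0 has the physical root
    u = [(2cx + 1) - sqrt(4cx + 1)] / (2c); before contact d = d0.
    """
    c = hertz_coefficient(E, k, theta, nu)
    x = np.asarray(z, dtype=float) - z0
    u = np.zeros_like(x)
    pos = x > 0
    if c > 0:
        xp = x[pos]
        u[pos] = ((2 * c * xp + 1) - np.sqrt(4 * c * xp + 1)) / (2 * c)
    return d0 + u


def _indentation(z, d, z0, d0):
    return (z - z0) - (d - d0)


def fit_hertz(curve: ForceCurve, config: HertzFitConfig | None = None) -> HertzFit:
    """Nonlinear least-squares fit of (E, z0, d0) to an approach curve.

    The data window is restricted to predicted indentations within
    [min_indentation, max_indentation]; because the indentation depends on
    (z0, d0), the mask is recomputed after each inner fit until stable.
    Pre-contact samples are always kept (they anchor d0 and z0).
    A fit that ends with fewer than ``min_contact_samples`` in contact or a
    failed optimizer status is returned with ``converged=False``.
    """
    config = config or HertzFitConfig()
    z, d = curve.z, curve.d
    if z.size < 50:
        raise InvalidSpecError("approach segment needs >= 50 samples")

    # initial guesses: baseline deflection from the first decile, contact
    # point at the maximum curvature of d(z)
    n10 = max(z.size // 10, 3)
    d0_init = float(np.median(d[:n10]))
    dd = np.gradient(np.gradient(d))
    z0_init = float(z[int(np.argmax(dd))])

    span = float(np.ptp(d)) + 1.0
    lo = [1.0, float(z.min()) - 1.0, float(d.min()) - span]
    hi = [1e8, float(z.max()) + 1.0, float(d.max()) + span]

    best = None
    for e0 in config.e_inits:
        p = np.array([e0, z0_init, d0_init])
        p = np.clip(p, lo, hi)
        mask = np.ones(z.size, dtype=bool)
        res = None
        for _ in range(config.max_mask_iter):
            res = least_squares(
                lambda q: predict_deflection(z[mask], q[0], q[1], q[2],
                                             curve.k, curve.theta, curve.nu) - d[mask],
                p, bounds=(lo, hi), method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14)
            p = res.x
            delta = _indentation(z, predict_deflection(z, *p, curve.k, curve.theta,
                                                       curve.nu), p[1], p[2])
            new_mask = (delta <= config.max_indentation) & (
                (delta >= config.min_indentation) | (z - p[1] <= 0))
            if new_mask.sum() < 3 * 3:
                break
            if np.array_equal(new_mask, mask):
                break
            mask = new_mask
        rss = float(np.sum(res.fun**2))
        n_contact = int(np.sum((z[mask] - p[1]) > 0))
        cand = (rss, p, mask, bool(res.success), n_contact)
        if best is None or rss < best[0]:
            best = cand

    rss, p, mask, success, n_contact = best
    delta_used = _indentation(z[mask], d[mask], p[1], p[2])
    converged = success and n_contact >= config.min_contact_samples
    return HertzFit(E=float(p[0]), z0=float(p[1]), d0=float(p[2]),
                    max_indentation_used=float(np.max(delta_used, initial=0.0)),
                    rss=rss, converged=converged, n_used=int(mask.sum()))


# ------------------------------------------------------------- calibration
@dataclass(frozen=True)
class CalibrationResult:
    sensitivity: float       # deflection units per piezo unit on hard contact
    r_squared: float         # linearity of the contact segment
    contact_index: int
    sharpness: float         # fraction of RSS removed by the kink vs one line
    clean: bool              # R^2 >= 0.999 on the contact segment


def calibrate_deflection(z: np.ndarray, d: np.ndarray,
                         clean_r2: float = 0.999) -> CalibrationResult:
    """Photodiode sensitivity from a deflection-piezo curve on bare glass.

    On a rigid surface the post-contact segment is a straight line whose
    slope calibrates the photodiode; its R-squared and the sharpness of the
    contact kink diagnose tip condition.
    """
    z = np.asarray(z, dtype=float)
    d = np.asarray(d, dtype=float)
    if z.size < 10:
        raise CalibrationError("too few samples")
    fit = hinge_fit(z, d, min_seg=3)
    # residual of a single straight line, for the sharpness score
    X1 = np.column_stack([np.ones(z.size), z])
    coef1, _, _, _ = np.linalg.lstsq(X1, d, rcond=None)
    rss1 = float(np.sum((X1 @ coef1 - d) ** 2))
    sharpness = 1.0 - fit.rss / rss1 if rss1 > 0 else 0.0
    if abs(fit.slope_post) < 1e-6 or sharpness < 0.5:
        raise CalibrationError("no detectable contact in calibration curve")
    ci = fit.break_idx
    zc, dc = z[ci:], d[ci:]
    Xc = np.column_stack([np.ones(zc.size), zc])
    coefc, _, _, _ = np.linalg.lstsq(Xc, dc, rcond=None)
    resid = Xc @ coefc - dc
    ss_tot = float(np.sum((dc - dc.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 0.0
    return CalibrationResult(sensitivity=float(coefc[1]), r_squared=r2,
                             contact_index=ci, sharpness=float(sharpness),
                             clean=r2 >= clean_r2)


# -------------------------------------------------------------- hierarchy
@dataclass
class StiffnessHierarchy:
    """Nested means of per-curve Young's moduli: curve -> point -> site -> region."""

    curve_table: pd.DataFrame       # region, site, point, curve, E, converged
    point_means: pd.DataFrame
    site_means: pd.DataFrame
    region_means: pd.DataFrame
    n_failed: int
    missing_points: list = field(default_factory=list)


def aggregate_E(curve_table: pd.DataFrame) -> StiffnessHierarchy:
    """Hierarchical averaging of Hertz fits.

    ``curve_table`` needs columns region, site, point, curve, E and
    (optionally) converged.  Point E = mean of its curve E's; site E = mean
    of its point E's; region E = mean across sites.  Non-converged fits are
    dropped; points left with no successful curve are reported as missing.
    """
    df = curve_table.copy()
    for col in ("region", "site", "point", "curve", "E"):
        if col not in df.columns:
            raise InvalidSpecError(f"curve table lacks column {col!r}")
    if "converged" not in df.columns:
        df["converged"] = True
    ok = df[df["converged"].astype(bool)]
    n_failed = int(len(df) - len(ok))
    all_points = df[["region", "site", "point"]].drop_duplicates()
    point = (ok.groupby(["region", "site", "point"], as_index=False)["E"]
             .mean())
    merged = all_points.merge(point, on=["region", "site", "point"], how="left")
    missing = [tuple(r) for r in
               merged[merged["E"].isna()][["region", "site", "point"]].itertuples(index=False)]
    site = point.groupby(["region", "site"], as_index=False)["E"].mean()
    region = site.groupby(["region"], as_index=False)["E"].mean()
    return StiffnessHierarchy(curve_table=df, point_means=point,
                              site_means=site, region_means=region,
                              n_failed=n_failed, missing_points=missing)


# ---------------------------------------------------------------- G*(f)
@dataclass
class MultifreqRecord:
    """Force/indentation oscillation record around an operating indentation."""

    t: np.ndarray            # s
    F: np.ndarray            # nN
    delta: np.ndarray        # nm
    delta0: float = 500.0    # nm
    freqs: tuple = DEFAULT_FREQS
    b_h: float = 0.0         # N.s/m, drag coefficient at sample thickness h
    theta: float = 20.0
    nu: float = 0.5

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        self.delta = np.asarray(self.delta, dtype=float)
        if not (self.t.size == self.F.size == self.delta.size):
            raise InvalidSpecError("t, F and delta must have equal length")
        if len(self.freqs) == 0:
            raise InvalidSpecError("at least one stimulus frequency required")

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame({"t_s": self.t, "F_nN": self.F, "delta_nm": self.delta}
                     ).to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_tsv(cls, path: str | Path, **meta) -> "MultifreqRecord":
        df = pd.read_csv(path, sep="\t")
        return cls(t=df["t_s"].to_numpy(), F=df["F_nN"].to_numpy(),
                   delta=df["delta_nm"].to_numpy(), **meta)


@dataclass
class ComplexModulus:
    """Storage and loss moduli (Pa) at the stimulus frequencies."""

    freqs: np.ndarray
    g_storage: np.ndarray
    g_loss: np.ndarray
    degenerate: np.ndarray = None  # per-frequency degenerate-excitation flag

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.g_storage = np.asarray(self.g_storage, dtype=float)
        self.g_loss = np.asarray(self.g_loss, dtype=float)
        if self.degenerate is None:
            self.degenerate = np.zeros(self.freqs.size, dtype=bool)
        self.degenerate = np.asarray(self.degenerate, dtype=bool)

    @property
    def gstar(self) -> np.ndarray:
        return self.g_storage + 1j * self.g_loss

    def to_dict(self) -> dict:
        return {"freqs_hz": self.freqs.tolist(),
                "g_storage_pa": self.g_storage.tolist(),
                "g_loss_pa": self.g_loss.tolist(),
                "degenerate": self.degenerate.tolist()}

    @classmethod
    def from_dict(cls, obj: dict) -> "ComplexModulus":
        return cls(freqs=obj["freqs_hz"], g_storage=obj["g_storage_pa"],
                   g_loss=obj["g_loss_pa"], degenerate=obj.get("degenerate"))


def compute_gstar(rec: MultifreqRecord, amp_floor_nm: float = 1e-3,
                  snr_min: float = 5.0) -> ComplexModulus:
    """Complex shear modulus at each stimulus frequency.

    The force and indentation phasors are obtained by one joint least-squares
    regression on [constant, linear drift, cos/sin at every stimulus
    frequency], which is leakage-free for arbitrary record lengths.  With the
    phasor convention x(t) = Re[X exp(i 2 pi f t)], X = a - i b for
    x = a cos + b sin.  A frequency whose indentation amplitude falls below
    ``amp_floor_nm`` or below ``snr_min`` times its regression standard error
    is flagged degenerate (NaN moduli); if all are degenerate a
    DegenerateExcitationError is raised.
    """
    t = rec.t
    freqs = np.asarray(rec.freqs, dtype=float)
    if t[-1] - t[0] < 1.0 / freqs.min():
        raise AnalysisError("record shorter than one period of the lowest frequency")
    cols = [np.ones_like(t), t - t.mean()]
    for f in freqs:
        w = 2 * np.pi * f * t
        cols += [np.cos(w), np.sin(w)]
    X = np.column_stack(cols)
    coefF, _, _, _ = np.linalg.lstsq(X, rec.F, rcond=None)
    coefD, _, _, _ = np.linalg.lstsq(X, rec.delta, rcond=None)
    residD = rec.delta - X @ coefD
    dof = max(t.size - X.shape[1], 1)
    sdD = float(np.sqrt(np.sum(residD**2) / dof))
    amp_se = sdD * np.sqrt(2.0 / t.size)

    prefac = (1.0 - rec.nu) / (3.0 * (rec.delta0 * 1e-9) * np.tan(np.radians(rec.theta)))
    gs = np.full(freqs.size, np.nan)
    gl = np.full(freqs.size, np.nan)
    degen = np.zeros(freqs.size, dtype=bool)
    for j, f in enumerate(freqs):
        aF, bF = coefF[2 + 2 * j], coefF[3 + 2 * j]
        aD, bD = coefD[2 + 2 * j], coefD[3 + 2 * j]
        Fj = aF - 1j * bF            # nN
        Dj = aD - 1j * bD            # nm
        if abs(Dj) < max(amp_floor_nm, snr_min * amp_se):
            degen[j] = True
            continue
        # F/delta in nN/nm == N/m; drag subtraction in the same units
        g = prefac * (Fj / Dj - 1j * f * rec.b_h)
        gs[j], gl[j] = g.real, g.imag
    if degen.all():
        raise DegenerateExcitationError(
            "indentation oscillation below the noise floor at every frequency")
    return ComplexModulus(freqs=freqs, g_storage=gs, g_loss=gl, degenerate=degen)


# ---------------------------------------------------------- two power laws
@dataclass(frozen=True)
class PowerLawFit:
    """Parameters of G*(f) = A (i f)^alpha + B (i f)^(3/4), f in units of f0."""

    A: float                 # kPa
    B: float                 # kPa
    alpha: float
    rss: float = float("nan")
    converged: bool = True
    f0: float = 1.0          # Hz, frequency normalization

    def __post_init__(self):
        if self.A <= 0 or self.B < 0 or not 0 <= self.alpha < 1:
            raise InvalidSpecError("require A > 0, B >= 0, 0 <= alpha < 1")


def gstar_model(freqs: np.ndarray, A: float, B: float, alpha: float,
                f0: float = 1.0) -> np.ndarray:
    """Two power-law model evaluated at freqs (Hz); A, B in kPa, result in Pa.

    (i f)^x is expanded as f^x (cos(pi x / 2) + i sin(pi x / 2)).
    """
    fn = np.asarray(freqs, dtype=float) / f0
    term1 = A * fn**alpha * np.exp(1j * np.pi * alpha / 2.0)
    term2 = B * fn**0.75 * np.exp(1j * np.pi * 0.75 / 2.0)
    return 1e3 * (term1 + term2)


def simulate_gstar(fit: PowerLawFit, freqs=DEFAULT_FREQS) -> ComplexModulus:
    """Noise-free ComplexModulus sampled from a two power-law parameter set."""
    g = gstar_model(freqs, fit.A, fit.B, fit.alpha, fit.f0)
    return ComplexModulus(freqs=freqs, g_storage=g.real, g_loss=g.imag)


def fit_two_powerlaw(gs: ComplexModulus, f0: float = 1.0,
                     alpha_grid: np.ndarray | None = None) -> PowerLawFit:
    """Complex-plane least squares for (A, B, alpha) with bounds
    A > 0, B >= 0, alpha in [0, 1); multi-start over an alpha grid."""
    valid = ~gs.degenerate & np.isfinite(gs.g_storage) & np.isfinite(gs.g_loss)
    freqs = gs.freqs[valid]
    data_kpa = (gs.g_storage[valid] + 1j * gs.g_loss[valid]) / 1e3
    if freqs.size < 3:
        raise AnalysisError("two power-law fit needs >= 3 valid frequencies")
    if alpha_grid is None:
        alpha_grid = np.array([0.01, 0.05, 0.1, 0.2, 0.3, 0.5])

    def resid(p):
        model = gstar_model(freqs, p[0], p[1], p[2], f0) / 1e3
        r = model - data_kpa
        return np.concatenate([r.real, r.imag])

    a0 = max(float(np.abs(data_kpa[np.argmin(freqs)])), 1e-3)
    best = None
    for al0 in alpha_grid:
        res = least_squares(resid, np.array([a0, 1e-3, al0]),
                            bounds=([1e-9, 0.0, 0.0], [np.inf, np.inf, 0.999]),
                            method="trf", xtol=1e-15, ftol=1e-15, gtol=1e-15)
        rss = float(np.sum(res.fun**2))
        if best is None or rss < best[0]:
            best = (rss, res)
    rss, res = best
    return PowerLawFit(A=float(res.x[0]), B=float(res.x[1]),
                       alpha=float(res.x[2]), rss=rss,
                       converged=bool(res.success), f0=f0)


def powerlaw_to_dict(fit: PowerLawFit) -> dict:
    return dataclasses.asdict(fit)
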