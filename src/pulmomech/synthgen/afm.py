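"""Synthetic AFM curves and multifrequency oscillation records.

Approach curves invert the pyramidal Hertz measurement model (for a piezo
position past contact, the deflection solves the implicit quadratic; before
contact the deflection stays at its baseline).  Multifrequency records are
the exact linear response of a two power-law complex shear modulus plus the
cantilever drag term, so the analysis roundtrip has a closed-form truth.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np

from ..afmmech import (DEFAULT_FREQS, ForceCurve, MultifreqRecord, PowerLawFit,
                       gstar_model, hertz_coefficient, predict_deflection)
from ..errors import InvalidSpecError


def simulate_force_curve(E_true: float, z0: float = 1000.0, d0: float = 5.0,
                         k: float = 0.03, theta: float = 20.0, nu: float = 0.5,
                         max_indentation: float = 1000.0,
                         pre_contact_span: float = 500.0, n_samples: int = 400,
                         noise_sd: float = 0.0, seed: int = 0) -> ForceCurve:
    """Approach curve (z, d) of an ideal pyramid on a sample of modulus E_true.

    z spans from ``pre_contact_span`` nm before contact to the piezo position
    at which the indentation reaches ``max_indentation`` nm.  With
    ``noise_sd = 0`` the samples satisfy the Hertz deflection equation
    exactly.
    """
    if E_true <= 0:
        raise InvalidSpecError("E_true must be positive")
    if not 0 < theta < 90:
        raise InvalidSpecError("theta must lie in (0, 90) degrees")
    if not 0 <= nu <= 0.5:
        raise InvalidSpecError("Poisson ratio must lie in [0, 0.5]")
    if k <= 0 or max_indentation <= 0 or n_samples < 50:
        raise InvalidSpecError("non-physical cantilever or sampling constants")
    c = hertz_coefficient(E_true, k, theta, nu)
    x_max = max_indentation + c * max_indentation**2
    z = np.linspace(z0 - pre_contact_span, z0 + x_max, n_samples)
    d = predict_deflection(z, E_true, z0, d0, k, theta, nu)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        d = d + rng.normal(0.0, noise_sd, d.size)
    return ForceCurve(z=z, d=d, k=k, theta=theta, nu=nu)


def simulate_calibration_curve(slope: float = 1.0, z_contact: float = 500.0,
                               d0: float = 0.0, z_span: float = 1000.0,
                               n_samples: int = 201, noise_sd: float = 0.0,
                               curvature: float = 0.0, seed: int = 0):
    """Deflection-piezo curve on bare glass: flat baseline, then a line of
    the given slope.  ``curvature`` bends the contact segment (a dirty/soft
    contact) for diagnostics tests.  Returns (z, d) arrays."""
    z = np.linspace(z_contact - z_span / 2, z_contact + z_span / 2, n_samples)
    x = np.maximum(z - z_contact, 0.0)
    d = d0 + slope * x + curvature * x**2
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        d = d + rng.normal(0.0, noise_sd, d.size)
    return z, d


def _check_nonharmonic(freqs) -> None:
    fs = sorted(freqs)
    for a, b in itertools.combinations(fs, 2):
        for target in (a + b, abs(a - b)):
            if any(abs(target - f) < 1e-9 for f in fs):
                warnings.warn(
                    f"stimulus frequencies are not sum/difference free "
                    f"({a} and {b} interact)", stacklevel=3)
                return


def simulate_multifreq(fit: PowerLawFit, delta0: float = 500.0,
                       freqs=DEFAULT_FREQS, duration: float = 140.0,
                       amplitude: float = 75.0, b_h: float = 0.0,
                       fs: float = 100.0, noise_sd: float = 0.0,
                       theta: float = 20.0, nu: float = 0.5,
                       f_offset_nN: float = 1.0, drift_nN_per_s: float = 0.0,
                       seed: int = 0) -> MultifreqRecord:
    """Force/indentation record of a two power-law material under a
    multifrequency indentation oscillation.

    The indentation is delta0 plus equal-amplitude sine components
    (``amplitude``/n per component so the composite peak stays near
    ``amplitude``).  The force trace is the exact G* response at each
    stimulus frequency plus the drag term i*f*b(h), a static offset, an
    optional linear drift, and Gaussian noise.
    """
    freqs = tuple(freqs)
    if len(freqs) == 0:
        raise InvalidSpecError("freqs must not be empty")
    if duration < 1.0 / min(freqs):
        raise InvalidSpecError("duration must cover one period of the lowest frequency")
    if fs <= 2 * max(freqs):
        raise InvalidSpecError("sampling rate below Nyquist for the stimulus")
    _check_nonharmonic(freqs)

    t = np.arange(int(round(duration * fs))) / fs
    amp = amplitude / len(freqs)
    delta = np.full_like(t, float(delta0))
    force = f_offset_nN + drift_nN_per_s * t
    prefac = 3.0 * (delta0 * 1e-9) * np.tan(np.radians(theta)) / (1.0 - nu)
    g = gstar_model(np.asarray(freqs), fit.A, fit.B, fit.alpha, fit.f0)  # Pa
    for j, f in enumerate(freqs):
        w = 2 * np.pi * f * t
        delta += amp * np.sin(w)
        h = prefac * g[j] + 1j * f * b_h          # N/m == nN/nm
        phasor = h * (-1j * amp)                  # sin has phasor -i*amp
        force += phasor.real * np.cos(w) - phasor.imag * np.sin(w)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        force = force + rng.normal(0.0, noise_sd, force.size)
    return MultifreqRecord(t=t, F=force, delta=delta, delta0=delta0,
                           freqs=freqs, b_h=b_h, theta=theta, nu=nu)
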