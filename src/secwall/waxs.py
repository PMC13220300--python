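"""Wide-angle (equatorial diffraction) peak analysis.

Equatorial WAXS profiles of cellulose show a composite 110/1-10 peak
and the 200 reflection.  Peaks are fitted as pseudo-Voigt lineshapes on
a linear background; crystallite size follows the Scherrer relation and
lattice spacings the Bragg relation, both expressed in Q-space (Å⁻¹):

    L = 2 pi K / B        (B = FWHM in Å⁻¹, K = 0.90 shape factor)
    d = 2 pi / q_center

Note the Q-space Scherrer form carries no explicit wavelength: the
familiar K·λ/(β·cosθ) expression reduces to 2πK/B once the peak width
is measured in Q rather than 2θ.  The Cu Kα wavelength 1.542 Å used to
record such data is kept in report metadata only.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import least_squares

from .scattering import ScatteringProfile

__all__ = [
    "DiffractionPeak",
    "pseudo_voigt",
    "fit_equatorial_peaks",
    "scherrer_size",
    "d_spacing",
    "relative_expansion",
]

CU_KALPHA = 1.542  # Å, metadata only — the Q-space Scherrer form needs no λ
DEFAULT_FIT_WINDOW = (0.8, 2.0)  # Å⁻¹


@dataclass(frozen=True)
class DiffractionPeak:
    """A pseudo-Voigt diffraction peak.

    ``center`` and ``fwhm`` in Å⁻¹; ``eta`` the Lorentzian fraction in
    [0, 1]; ``amplitude`` the peak height (both components unit height).
    """

    center: float
    fwhm: float
    eta: float
    amplitude: float

    def __post_init__(self) -> None:
        if not self.fwhm > 0:
            raise ValueError("fwhm must be positive")
        if not 0.0 <= self.eta <= 1.0:
            raise ValueError("eta must be in [0, 1]")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")

    @property
    def area(self) -> float:
        """Closed-form integrated area of the lineshape."""
        lor = self.eta * (np.pi / 2.0) * self.fwhm
        gau = (1.0 - self.eta) * self.fwhm * np.sqrt(np.pi / (4.0 * np.log(2.0)))
        return self.amplitude * (lor + gau)


def pseudo_voigt(x, peak: DiffractionPeak):
    """eta-weighted sum of unit-height Lorentzian and Gaussian of common FWHM."""
    x = np.asarray(x, dtype=float)
    u = (x - peak.center) / peak.fwhm
    lor = 1.0 / (1.0 + 4.0 * u * u)
    gau = np.exp(-4.0 * np.log(2.0) * u * u)
    out = peak.amplitude * (peak.eta * lor + (1.0 - peak.eta) * gau)
    return out if out.ndim else float(out)


def _profile_model(x, params, n_peaks):
    y = params[-2] + params[-1] * x  # linear background
    for i in range(n_peaks):
        c, w, e, a = params[4 * i : 4 * i + 4]
        y = y + pseudo_voigt(x, DiffractionPeak(c, w, e, a))
    return y


def fit_equatorial_peaks(
    profile: ScatteringProfile,
    n_peaks: int,
    init: Sequence[DiffractionPeak],
    fit_window: Optional[Tuple[float, float]] = DEFAULT_FIT_WINDOW,
    background_init: Tuple[float, float] = (0.0, 0.0),
) -> Tuple[List[DiffractionPeak], dict]:
    """Nonlinear least-squares fit of 2-3 pseudo-Voigt peaks + linear background.

    Returns the fitted peaks sorted by centre and a diagnostics dict with
    the background, residual norm and solver status.  Non-convergence
    raises with the solver's last iterate embedded in the message.
    """
    if n_peaks not in (2, 3):
        raise ValueError("n_peaks must be 2 or 3 (110/1-10 composite plus 200)")
    if len(init) != n_peaks:
        raise ValueError("need one initial guess per peak")
    data = profile.window(*fit_window) if fit_window else profile
    if np.ptp(data.intensity) < 1e-12 * max(1.0, np.abs(data.intensity).max()):
        raise ValueError("flat profile in the fit window: nothing to fit")
    for pk in init:
        if not data.q[0] <= pk.center <= data.q[-1]:
            raise ValueError(f"initial centre {pk.center} outside fit window")

    p0, lo, hi = [], [], []
    span = data.q[-1] - data.q[0]
    for pk in init:
        p0 += [pk.center, pk.fwhm, pk.eta, pk.amplitude]
        lo += [data.q[0], 1e-4, 0.0, 0.0]
        hi += [data.q[-1], span, 1.0, np.inf]
    p0 += list(background_init)
    lo += [-np.inf, -np.inf]
    hi += [np.inf, np.inf]

    res = least_squares(
        lambda p: _profile_model(data.q, p, n_peaks) - data.intensity,
        p0, bounds=(lo, hi), xtol=1e-14, ftol=1e-14, gtol=1e-14,
    )
    if not res.success:
        raise RuntimeError(
            f"peak fit failed to converge (status {res.status}); last iterate {res.x}"
        )
    peaks = [
        DiffractionPeak(*res.x[4 * i : 4 * i + 4]) for i in range(n_peaks)
    ]
    peaks.sort(key=lambda p: p.center)
    diag = {
        "background": (float(res.x[-2]), float(res.x[-1])),
        "residual_norm": float(np.sqrt(2.0 * res.cost)),
        "status": int(res.status),
        "n_points": len(data),
    }
    return peaks, diag


def scherrer_size(fwhm_q: float, shape_factor: float = 0.90) -> float:
    """Scherrer crystallite size L = 2 pi K / B with B the FWHM in Å⁻¹."""
    if not fwhm_q > 0:
        raise ValueError("FWHM must be positive")
    if not shape_factor > 0:
        raise ValueError("shape factor must be positive")
    return 2.0 * np.pi * shape_factor / fwhm_q


def d_spacing(q_center: float) -> float:
    """Bragg lattice spacing d = 2 pi / q."""
    if not q_center > 0:
        raise ValueError("peak position must be positive")
    return 2.0 * np.pi / q_center


def relative_expansion(d_obs: float, d_ref: float) -> float:
    """Lattice swelling in percent: 100 (d_obs - d_ref) / d_ref."""
    if not d_obs > 0 or not d_ref > 0:
        raise ValueError("spacings must be positive")
    return 100.0 * (d_obs - d_ref) / d_ref
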