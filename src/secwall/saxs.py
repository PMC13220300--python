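"""Fitting the cylinder + hard-disk model to equatorial SAXS profiles.

The fit mirrors how fibre-diffraction practitioners compare such
curves: the low-q surface-scattering power law (c·q⁻³) is fitted and
subtracted first, then a discrete grid of candidate cylinder radii is
scanned; for each radius the scale A and flat background B are solved
linearly and the goodness is the sum of squared log-intensity residuals
on Lorentz-corrected (I·q) curves, which is what a double-log
Lorentz-corrected overlay judges by eye.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

from .harddisk import StructureFactorTable, effective_radius
from .scattering import CylinderModel, ScatteringProfile, lorentz_correct, model_intensity

__all__ = [
    "RadiusScanResult",
    "fit_surface_powerlaw",
    "solve_scale_background",
    "radius_scan",
]

DEFAULT_Q_WINDOW = (0.05, 0.7)  # Å⁻¹; below 0.05 surface scattering dominates
DEFAULT_SURFACE_WINDOW = (0.01, 0.05)


@dataclass
class RadiusScanResult:
    radii: np.ndarray
    residuals: np.ndarray
    scales: np.ndarray
    backgrounds: np.ndarray
    best_radius: float
    best_model: CylinderModel
    q_window: Tuple[float, float]
    metadata: dict = field(default_factory=dict)


def fit_surface_powerlaw(
    profile: ScatteringProfile, q_window: Tuple[float, float] = DEFAULT_SURFACE_WINDOW
) -> float:
    """Least-squares coefficient c of I = c·q⁻³ over a low-q window.

    The exponent is fixed at -3; c is the closed-form projection
    c = Σ I·q⁻³ / Σ q⁻⁶, clipped at 0.
    """
    sub = profile.window(*q_window)
    if len(sub) < 5:
        raise ValueError(
            f"surface-powerlaw window {q_window} holds {len(sub)} points; need >= 5"
        )
    basis = sub.q ** -3.0
    c = float(basis @ sub.intensity / (basis @ basis))
    return max(c, 0.0)


def solve_scale_background(model_shape, data: ScatteringProfile) -> Tuple[float, float]:
    """Ordinary least squares for (A, B) in data ≈ A·shape + B.

    A is clipped at zero (a negative scale is unphysical); when clipped,
    B is refit as the data mean.
    """
    shape = np.asarray(model_shape, dtype=float)
    if shape.shape != data.q.shape:
        raise ValueError("model shape and data must have the same length")
    if np.ptp(shape) < 1e-14 * max(1.0, np.abs(shape).max()):
        raise ValueError("constant model shape: scale/background are not identifiable")
    design = np.column_stack([shape, np.ones_like(shape)])
    (a, b), *_ = np.linalg.lstsq(design, data.intensity, rcond=None)
    if a < 0:
        return 0.0, float(data.intensity.mean())
    return float(a), float(b)


def radius_scan(
    data: ScatteringProfile,
    radii: Sequence[float],
    phi_eff: float,
    sheath: float,
    sf_table: StructureFactorTable,
    q_window: Tuple[float, float] = DEFAULT_Q_WINDOW,
    surface_coeff: Optional[float] = None,
    surface_window: Tuple[float, float] = DEFAULT_SURFACE_WINDOW,
) -> RadiusScanResult:
    """Scan candidate cylinder radii against an equatorial SAXS profile.

    For each radius R the effective radius is R + sheath/2, the model
    shape S(q; phi, qR_e)·P(q; R) is evaluated from the structure-factor
    table, (A, B) are solved linearly, and the residual is the sum of
    squared differences of log10 intensity after Lorentz correction over
    ``q_window``.  If ``surface_coeff`` is None and the profile extends
    below the fit window, the c·q⁻³ term is pre-fitted on
    ``surface_window`` and subtracted from the data before scanning.
    """
    radii = np.asarray(sorted(radii), dtype=float)
    if radii.size == 0:
        raise ValueError("empty radius grid")
    c = surface_coeff
    if c is None:
        c = (
            fit_surface_powerlaw(data, surface_window)
            if data.q[0] < surface_window[1] and (data.q < surface_window[1]).sum() >= 5
            else 0.0
        )
    work = data.window(*q_window)
    intensity = work.intensity - c * work.q ** -3.0 if c > 0 else work.intensity
    bad = np.nonzero(intensity <= 0)[0]
    if bad.size:
        raise ValueError(
            f"non-positive intensities in fit window at indices {bad.tolist()[:10]}; "
            "clean or re-window the data"
        )
    clean = ScatteringProfile(work.q, intensity)
    log_data = np.log10(lorentz_correct(clean).intensity)

    residuals = np.empty(radii.size)
    scales = np.empty(radii.size)
    backgrounds = np.empty(radii.size)
    for i, r in enumerate(radii):
        r_e = effective_radius(r, sheath)
        model = CylinderModel(radius_phys=r, radius_eff=r_e, phi_eff=phi_eff)
        shape = model_intensity(clean.q, model, sf_table)
        a, b = solve_scale_background(shape, clean)
        fit = np.maximum(a * shape + b, 1e-300)
        residuals[i] = float(np.sum((np.log10(fit * clean.q) - log_data) ** 2))
        scales[i] = a
        backgrounds[i] = b
    best = int(np.argmin(residuals))
    best_model = CylinderModel(
        radius_phys=float(radii[best]),
        radius_eff=effective_radius(float(radii[best]), sheath),
        phi_eff=phi_eff,
        scale=scales[best],
        background=backgrounds[best],
        surface_coeff=c,
    )
    return RadiusScanResult(
        radii=radii,
        residuals=residuals,
        scales=scales,
        backgrounds=backgrounds,
        best_radius=float(radii[best]),
        best_model=best_model,
        q_window=q_window,
        metadata={"surface_coeff": c, "phi_eff": phi_eff, "sheath": sheath},
    )
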