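"""Parametric petal-reflectance model.

A petal spectrum is described as a specular offset plus a sigmoidal
long-pass flank, with an optional Gaussian pigment absorption dip acting
multiplicatively on the diffuse (long-pass) component:

    R(lam) = r_spec + r_diff * LP(lam) * (1 - dip_depth * G(lam))
    LP(lam) = 1 / (1 + (lambda_half / lam) ** gamma)
    G(lam)  = exp(-(lam - dip_center)**2 / (2 * dip_width**2))

The dip multiplies only the long-pass term so that the shared specular
floor is preserved across morphs.  All reflectances are fractions in
[0, 1]; percent inputs must be converted explicitly by the reader.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "MORPHS",
    "Spectrum",
    "PetalModelParams",
    "PetalFitResult",
    "default_grid",
    "long_pass",
    "evaluate_petal_model",
    "fit_petal_model",
    "classify_morph_from_depth",
    "resample_spectrum",
    "average_replicates",
]

#: Morph labels ordered from least to most pigmented.
MORPHS = ("white", "light pink", "dark pink", "violet")

#: Instrument wavelength limits (nm) accepted on input.
WAVELENGTH_MIN = 230.0
WAVELENGTH_MAX = 830.0

#: Reflectance ceiling; small excursions above 1 are tolerated (specular
#: artifacts, noise) but flagged.
REFLECTANCE_MAX = 1.5


def default_grid() -> np.ndarray:
    """Default analysis grid: 300-700 nm at 1-nm steps."""
    return np.arange(300.0, 701.0)


@dataclass(frozen=True)
class Spectrum:
    """A reflectance spectrum on a strictly increasing wavelength grid.

    Parameters
    ----------
    wavelengths
        Strictly increasing wavelengths in nm, within [230, 830].
    values
        Reflectance fractions, finite, in [0, 1.5].
    meta
        Free-form metadata (sample_id, flower_id, target, morph, ...).
    """

    wavelengths: np.ndarray
    values: np.ndarray
    meta: Mapping = field(default_factory=dict)

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "values", vals)
        if wl.ndim != 1 or vals.ndim != 1 or wl.size != vals.size:
            raise ValueError("wavelengths and values must be 1-D and equal length")
        if wl.size < 2:
            raise ValueError("a spectrum needs at least 2 samples")
        if not np.all(np.diff(wl) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if wl[0] < WAVELENGTH_MIN or wl[-1] > WAVELENGTH_MAX:
            raise ValueError(
                f"wavelengths must lie within [{WAVELENGTH_MIN}, {WAVELENGTH_MAX}] nm"
            )
        if not np.all(np.isfinite(vals)):
            raise ValueError("reflectance values must be finite")
        if vals.min() < 0 or vals.max() > REFLECTANCE_MAX:
            raise ValueError(f"reflectance must lie within [0, {REFLECTANCE_MAX}]")

    @property
    def flagged_above_unity(self) -> bool:
        """True when any value exceeds 1 (specular/noise artifact)."""
        return bool(np.any(self.values > 1.0))

    def with_meta(self, **kwargs) -> "Spectrum":
        meta = dict(self.meta)
        meta.update(kwargs)
        return replace(self, meta=meta)


@dataclass(frozen=True)
class PetalModelParams:
    """Parameters of the specular + long-pass + pigment-dip model."""

    r_spec: float = 0.06
    r_diff: float = 0.35
    lambda_half: float = 420.0
    gamma: float = 17.0
    dip_center: float = 550.0
    dip_width: float = 60.0
    dip_depth: float = 0.0

    def __post_init__(self) -> None:
        if self.r_spec < 0:
            raise ValueError("r_spec must be >= 0")
        if self.r_diff < 0:
            raise ValueError("r_diff must be >= 0")
        if not 300.0 < self.lambda_half < 700.0:
            raise ValueError("lambda_half must lie in (300, 700) nm")
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")
        if not 0.0 <= self.dip_depth <= 1.0:
            raise ValueError("dip_depth must lie in [0, 1]")
        if self.dip_width <= 0:
            raise ValueError("dip_width must be > 0")

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                self.r_spec,
                self.r_diff,
                self.lambda_half,
                self.gamma,
                self.dip_center,
                self.dip_width,
                self.dip_depth,
            ]
        )

    @classmethod
    def from_array(cls, x: Sequence[float]) -> "PetalModelParams":
        return cls(*[float(v) for v in x])


def long_pass(lam: np.ndarray, lambda_half: float, gamma: float) -> np.ndarray:
    """Sigmoidal long-pass factor; equals 1/2 exactly at ``lambda_half``."""
    lam = np.asarray(lam, dtype=float)
    return 1.0 / (1.0 + (lambda_half / lam) ** gamma)


def _model_values(lam: np.ndarray, p: PetalModelParams) -> np.ndarray:
    lp = long_pass(lam, p.lambda_half, p.gamma)
    dip = 1.0 - p.dip_depth * np.exp(
        -((lam - p.dip_center) ** 2) / (2.0 * p.dip_width**2)
    )
    return p.r_spec + p.r_diff * lp * dip


def evaluate_petal_model(
    params: PetalModelParams, grid: np.ndarray | None = None, meta: Mapping | None = None
) -> Spectrum:
    """Evaluate the petal model on a wavelength grid.

    Returned values are guaranteed to lie in [0, r_spec + r_diff].
    """
    if grid is None:
        grid = default_grid()
    grid = np.asarray(grid, dtype=float)
    return Spectrum(grid, _model_values(grid, params), meta=dict(meta or {}))


@dataclass(frozen=True)
class PetalFitResult:
    """Outcome of a least-squares petal-model fit."""

    params: PetalModelParams
    residual_rms: float
    converged: bool
    n_points: int
    message: str = ""


_DEFAULT_BOUNDS = {
    "r_spec": (0.0, 1.0),
    "r_diff": (0.0, 1.5),
    "lambda_half": (300.0 + 1e-6, 700.0 - 1e-6),
    "gamma": (0.5, 80.0),
    "dip_center": (450.0, 650.0),
    "dip_width": (10.0, 200.0),
    "dip_depth": (0.0, 1.0),
}

_PARAM_NAMES = tuple(_DEFAULT_BOUNDS)


def _data_driven_init(spectrum: Spectrum) -> PetalModelParams:
    """Deterministic starting point from the data.

    r_spec from the spectrum minimum, r_diff from its range, lambda_half
    at the steepest ascent, gamma fixed at 10, and a dip guess from the
    residual at 550 nm relative to the dip-free model.
    """
    wl, vals = spectrum.wavelengths, spectrum.values
    r_spec = float(vals.min())
    r_diff = float(max(vals.max() - vals.min(), 1e-3))
    slopes = np.gradient(vals, wl)
    lam_half = float(np.clip(wl[int(np.argmax(slopes))], 310.0, 690.0))
    gamma = 10.0
    lp550 = long_pass(np.array([550.0]), lam_half, gamma)[0]
    r550 = float(np.interp(550.0, wl, vals))
    with np.errstate(divide="ignore", invalid="ignore"):
        depth = 1.0 - (r550 - r_spec) / (r_diff * lp550)
    depth = float(np.clip(depth, 0.0, 1.0)) if np.isfinite(depth) else 0.0
    return PetalModelParams(r_spec, r_diff, lam_half, gamma, 550.0, 60.0, depth)


def fit_petal_model(
    spectrum: Spectrum,
    init: PetalModelParams | None = None,
    bounds: Mapping[str, tuple] | None = None,
    fix_dip_depth: float | None = None,
) -> PetalFitResult:
    """Least-squares fit of the petal model to a spectrum.

    Parameters
    ----------
    spectrum
        Must cover at least [350, 700] nm and contain >= 10 points.
    init
        Starting parameters; a data-driven start is derived if omitted.
    bounds
        Per-parameter (low, high) overrides of the default box bounds.
    fix_dip_depth
        If given, the dip depth is held at this value (the dip position
        and width are then also frozen, since a zero-depth dip leaves
        them unidentifiable).

    Returns
    -------
    PetalFitResult
        Fitted parameters, residual RMS and a convergence flag.
        Non-convergence is flagged, never silent.
    """
    wl, vals = spectrum.wavelengths, spectrum.values
    if wl.size < 10:
        raise ValueError("need at least 10 spectral points to fit")
    if wl[0] > 350.0 or wl[-1] < 700.0:
        raise ValueError("spectrum must cover at least [350, 700] nm")

    if init is None:
        init = _data_driven_init(spectrum)
    box = dict(_DEFAULT_BOUNDS)
    if bounds:
        box.update(bounds)

    free = list(_PARAM_NAMES)
    fixed: dict[str, float] = {}
    if fix_dip_depth is not None:
        fixed = {
            "dip_depth": float(fix_dip_depth),
            "dip_center": init.dip_center,
            "dip_width": init.dip_width,
        }
        free = [n for n in free if n not in fixed]

    init_map = dict(zip(_PARAM_NAMES, init.as_array()))
    x0 = np.array([np.clip(init_map[n], *box[n]) for n in free])
    lo = np.array([box[n][0] for n in free])
    hi = np.array([box[n][1] for n in free])

    def unpack(x: np.ndarray) -> PetalModelParams:
        kv = dict(zip(free, x))
        kv.update(fixed)
        return PetalModelParams(**kv)

    def resid(x: np.ndarray) -> np.ndarray:
        return _model_values(wl, unpack(x)) - vals

    sol = least_squares(
        resid, x0, bounds=(lo, hi), method="trf",
        xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=20000,
    )
    rms = float(np.sqrt(np.mean(sol.fun**2)))
    return PetalFitResult(
        params=unpack(sol.x),
        residual_rms=rms,
        converged=bool(sol.success),
        n_points=int(wl.size),
        message=str(sol.message),
    )


#: Default dip-depth class boundaries; a boundary value is assigned to
#: the more-pigmented class.
DEPTH_THRESHOLDS = (0.10, 0.45, 0.75)


def classify_morph_from_depth(
    dip_depth: float, thresholds: Sequence[float] = DEPTH_THRESHOLDS
) -> str:
    """Map a fitted dip depth to a morph label (monotone in depth)."""
    if not 0.0 <= dip_depth <= 1.0:
        raise ValueError("dip_depth must lie in [0, 1]")
    t1, t2, t3 = thresholds
    if not t1 < t2 < t3:
        raise ValueError("thresholds must be strictly increasing")
    if dip_depth < t1:
        return "white"
    if dip_depth < t2:
        return "light pink"
    if dip_depth < t3:
        return "dark pink"
    return "violet"


def resample_spectrum(spectrum: Spectrum, grid: np.ndarray) -> Spectrum:
    """Linearly interpolate onto ``grid``; exact at shared nodes.

    Extrapolation outside the source span is refused.
    """
    grid = np.asarray(grid, dtype=float)
    wl = spectrum.wavelengths
    if grid.size and (grid[0] < wl[0] or grid[-1] > wl[-1]):
        raise ValueError(
            f"target grid [{grid[0]}, {grid[-1]}] exceeds source span "
            f"[{wl[0]}, {wl[-1]}]; refusing to extrapolate"
        )
    vals = np.interp(grid, wl, spectrum.values)
    return Spectrum(grid, vals, meta=dict(spectrum.meta))


def average_replicates(spectra: Sequence[Spectrum]) -> Spectrum:
    """Pointwise mean of replicate spectra sharing one grid."""
    if not spectra:
        raise ValueError("cannot average an empty list of spectra")
    wl = spectra[0].wavelengths
    for s in spectra[1:]:
        if s.wavelengths.size != wl.size or not np.array_equal(s.wavelengths, wl):
            raise ValueError("replicates must share an identical grid; resample first")
    mean_vals = np.mean([s.values for s in spectra], axis=0)
    meta = dict(spectra[0].meta)
    meta["n_replicates"] = len(spectra)
    return Spectrum(wl, mean_vals, meta=meta)
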