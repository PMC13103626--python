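"""Bumblebee trichromatic vision model and hexagon color space.

Pipeline: receptor sensitivity templates (UV/blue/green), ground-level
daylight illuminant, band contributions (sensitivity- and
illuminant-weighted mean reflectance), optional von Kries adaptation to a
green-foliage background with a hyperbolic excitation transform, and the
2-D hexagon projection with Euclidean chromatic distances.

Two excitation modes are supported and always recorded in outputs:

``literal``
    E = integral(R*S*I) / integral(S*I) — a weighted mean of reflectance,
    bounded by the spectrum's min/max.
``adapted``
    quantum-catch ratio against the background, D = Q/Q_bg, transformed
    as E = D / (D + 1); the background maps to 0.5 in every band and
    hence to the achromatic center.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .spectra import Spectrum, default_grid

__all__ = [
    "BANDS",
    "DEFAULT_LAMBDA_MAX",
    "DISCRIMINATION_THRESHOLD",
    "DEFAULT_MODE",
    "ReceptorTemplate",
    "Illuminant",
    "Background",
    "ExcitationTriplet",
    "HexagonPoint",
    "make_receptor_templates",
    "solar_irradiance",
    "band_contribution",
    "adapted_excitation",
    "excitation_triplet",
    "hexagon_project",
    "chromatic_contrast",
    "chromatic_distance",
    "pairwise_morph_distances",
    "spectral_locus",
    "green_leaf_background",
]

BANDS = ("uv", "blue", "green")

#: Default receptor peak wavelengths (nm) for the bumblebee model.
DEFAULT_LAMBDA_MAX = (347.0, 424.0, 539.0)

#: Chromatic distance (hexagon units) above which two stimuli are taken
#: to be discriminable.  Used only for flagging, never for filtering.
DISCRIMINATION_THRESHOLD = 0.09

#: Default excitation mode.  The printed band-contribution formula is a
#: weighted mean with no background term ("literal"); the von Kries +
#: hyperbolic pipeline remains available as "adapted".
DEFAULT_MODE = "literal"


# --------------------------------------------------------------------------
# Receptor templates

def _pigment_template(lam: np.ndarray, lambda_max: float) -> np.ndarray:
    """A1 visual-pigment alpha-band template (Govardovskii-style).

    Parameterized only by the peak wavelength; returns relative
    sensitivity (unnormalized) on ``lam``.
    """
    x = lambda_max / np.asarray(lam, dtype=float)
    a = 0.8795 + 0.0459 * math.exp(-((lambda_max - 300.0) ** 2) / 11940.0)
    with np.errstate(over="ignore"):
        denom = (
            np.exp(69.7 * (a - x))
            + np.exp(28.0 * (0.922 - x))
            + np.exp(-14.9 * (1.104 - x))
            + 0.674
        )
    return 1.0 / denom


@dataclass(frozen=True)
class ReceptorTemplate:
    """A receptor sensitivity curve normalized to 1 at its peak."""

    band: str
    lambda_max: float
    sensitivity: Callable[[np.ndarray], np.ndarray]

    def __call__(self, lam: np.ndarray) -> np.ndarray:
        return self.sensitivity(lam)


def _make_template(band: str, lambda_max: float) -> ReceptorTemplate:
    # The raw pigment template peaks slightly off its nominal parameter;
    # shift the wavelength axis so the scanned peak lands exactly on
    # lambda_max, then normalize to unit sensitivity there.
    fine = np.arange(max(lambda_max - 80.0, 240.0), lambda_max + 80.0, 0.01)
    shift = float(fine[int(np.argmax(_pigment_template(fine, lambda_max)))]) - lambda_max
    peak_value = float(_pigment_template(np.array([lambda_max + shift]), lambda_max)[0])

    def sensitivity(lam: np.ndarray) -> np.ndarray:
        s = _pigment_template(np.asarray(lam, dtype=float) + shift, lambda_max)
        return np.clip(s / peak_value, 0.0, 1.0)

    return ReceptorTemplate(band=band, lambda_max=lambda_max, sensitivity=sensitivity)


def make_receptor_templates(
    lambda_maxes: Sequence[float] = DEFAULT_LAMBDA_MAX,
) -> tuple[ReceptorTemplate, ReceptorTemplate, ReceptorTemplate]:
    """Build the UV/blue/green templates peaking exactly at the given nm.

    The triplet must be strictly increasing and lie in (300, 700) nm.
    """
    lm = tuple(float(v) for v in lambda_maxes)
    if len(lm) != 3:
        raise ValueError("exactly three lambda_max values are required")
    if not (lm[0] < lm[1] < lm[2]):
        raise ValueError("lambda_max triplet must be strictly increasing")
    if not all(300.0 < v < 700.0 for v in lm):
        raise ValueError("lambda_max values must lie in (300, 700) nm")
    return tuple(_make_template(b, v) for b, v in zip(BANDS, lm))  # type: ignore[return-value]


# --------------------------------------------------------------------------
# Illuminant

#: Coarse (10-nm) tabulated approximation of ground-level daylight
#: (atmosphere-filtered global irradiance, relative units).  Zero below
#: the 310-nm ozone cutoff.
_DAYLIGHT_TABLE = np.array([
    (310, 0.07), (320, 0.30), (330, 0.46), (340, 0.52), (350, 0.57),
    (360, 0.52), (370, 0.64), (380, 0.67), (390, 0.71), (400, 1.12),
    (410, 1.10), (420, 1.14), (430, 1.05), (440, 1.33), (450, 1.53),
    (460, 1.55), (470, 1.50), (480, 1.56), (490, 1.49), (500, 1.54),
    (510, 1.50), (520, 1.48), (530, 1.53), (540, 1.46), (550, 1.48),
    (560, 1.44), (570, 1.43), (580, 1.43), (590, 1.39), (600, 1.40),
    (610, 1.37), (620, 1.35), (630, 1.31), (640, 1.30), (650, 1.28),
    (660, 1.26), (670, 1.26), (680, 1.22), (690, 1.17), (700, 1.18),
    (710, 1.15), (720, 1.05), (730, 1.09), (740, 1.08), (750, 1.07),
    (760, 0.96), (770, 1.00), (780, 0.99), (790, 0.96), (800, 0.93),
    (810, 0.90), (820, 0.86), (830, 0.86),
])


@dataclass(frozen=True)
class Illuminant:
    """Relative spectral irradiance, identically zero below ``cutoff_nm``."""

    irradiance: Callable[[np.ndarray], np.ndarray]
    cutoff_nm: float = 310.0

    def __call__(self, lam: np.ndarray) -> np.ndarray:
        lam = np.asarray(lam, dtype=float)
        out = np.asarray(self.irradiance(lam), dtype=float)
        return np.where(lam < self.cutoff_nm, 0.0, out)


def solar_irradiance(grid: np.ndarray | None = None, cutoff_nm: float = 310.0) -> Illuminant:
    """Bundled daylight approximation, normalized to max 1 on ``grid``.

    Hard zero below the ozone cutoff (default 310 nm); smooth and
    positive above it.
    """
    if grid is None:
        grid = default_grid()
    grid = np.asarray(grid, dtype=float)
    wl, rel = _DAYLIGHT_TABLE[:, 0], _DAYLIGHT_TABLE[:, 1]

    def raw(lam: np.ndarray) -> np.ndarray:
        lam = np.asarray(lam, dtype=float)
        return np.where(lam < cutoff_nm, 0.0, np.interp(lam, wl, rel))

    on_grid = raw(grid)
    scale = float(on_grid.max()) if on_grid.max() > 0 else 1.0
    return Illuminant(irradiance=lambda lam: raw(lam) / scale, cutoff_nm=cutoff_nm)


# --------------------------------------------------------------------------
# Background

@dataclass(frozen=True)
class Background:
    """Adapting background reflectance, strictly positive on its grid."""

    reflectance: Spectrum

    def __post_init__(self) -> None:
        vals = self.reflectance.values
        if vals.min() <= 0 or vals.max() > 1:
            raise ValueError("background reflectance must lie in (0, 1]")


def green_leaf_background(
    grid: np.ndarray | None = None,
    floor: float = 0.05,
    bump_peak: float = 0.15,
    bump_center: float = 550.0,
    bump_width: float = 45.0,
    red_edge_nm: float = 700.0,
    red_edge_level: float = 0.45,
) -> Background:
    """Parametric green-foliage reflectance stand-in.

    Low UV/blue floor, a Gaussian green bump peaking near 550 nm, and a
    sigmoidal red-edge rise beyond ~680 nm.  Strictly positive.
    """
    if grid is None:
        grid = default_grid()
    lam = np.asarray(grid, dtype=float)
    bump = (bump_peak - floor) * np.exp(
        -((lam - bump_center) ** 2) / (2.0 * bump_width**2)
    )
    red_edge = (red_edge_level - floor) / (1.0 + np.exp(-(lam - red_edge_nm) / 8.0))
    vals = np.clip(floor + bump + red_edge, 1e-6, 1.0)
    return Background(Spectrum(lam, vals, meta={"kind": "green_leaf_background"}))


# --------------------------------------------------------------------------
# Excitations

@dataclass(frozen=True)
class ExcitationTriplet:
    """Receptor excitations for the UV, blue, and green bands."""

    e_uv: float
    e_blue: float
    e_green: float
    mode: str = "literal"

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.e_uv, self.e_blue, self.e_green)


def _quantum_catch(
    spectrum: Spectrum, template: ReceptorTemplate, illuminant: Illuminant
) -> tuple[float, float]:
    """(integral R*S*I, integral S*I) by trapezoidal quadrature."""
    lam = spectrum.wavelengths
    weight = template(lam) * illuminant(lam)
    catch = float(np.trapezoid(spectrum.values * weight, lam))
    norm = float(np.trapezoid(weight, lam))
    return catch, norm


def band_contribution(
    spectrum: Spectrum, template: ReceptorTemplate, illuminant: Illuminant
) -> float:
    """Literal-mode band contribution: S*I-weighted mean reflectance.

    Always lies within [min R, max R]; raises if the band weight is
    degenerate (integral of S*I vanishes on the grid).
    """
    catch, norm = _quantum_catch(spectrum, template, illuminant)
    if norm <= 0:
        raise ValueError(
            f"degenerate band {template.band!r}: integral of S*I is zero on the grid"
        )
    return catch / norm


def adapted_excitation(
    spectrum: Spectrum,
    template: ReceptorTemplate,
    illuminant: Illuminant,
    background: Background,
) -> float:
    """Adapted-mode excitation via von Kries ratio + hyperbolic transform.

    D = catch(spectrum) / catch(background); E = D / (D + 1), in [0, 1).
    The background itself yields E = 0.5 in every band.
    """
    catch, _ = _quantum_catch(spectrum, template, illuminant)
    bg = background.reflectance
    if bg.wavelengths.size != spectrum.wavelengths.size or not np.array_equal(
        bg.wavelengths, spectrum.wavelengths
    ):
        from .spectra import resample_spectrum

        bg = resample_spectrum(bg, spectrum.wavelengths)
    bg_catch, _ = _quantum_catch(bg, template, illuminant)
    if bg_catch <= 0:
        raise ValueError(f"zero background catch in band {template.band!r}")
    d = catch / bg_catch
    return d / (d + 1.0)


def excitation_triplet(
    spectrum: Spectrum,
    templates: Sequence[ReceptorTemplate],
    illuminant: Illuminant,
    background: Background | None = None,
    mode: str = DEFAULT_MODE,
) -> ExcitationTriplet:
    """Compute all three band excitations in the requested mode."""
    if mode == "literal":
        e = [band_contribution(spectrum, t, illuminant) for t in templates]
    elif mode == "adapted":
        if background is None:
            raise ValueError("adapted mode requires a background")
        e = [adapted_excitation(spectrum, t, illuminant, background) for t in templates]
    else:
        raise ValueError(f"unknown excitation mode {mode!r}")
    return ExcitationTriplet(e_uv=e[0], e_blue=e[1], e_green=e[2], mode=mode)


# --------------------------------------------------------------------------
# Hexagon geometry

@dataclass(frozen=True)
class HexagonPoint:
    """2-D hexagon coordinates; the origin is the achromatic center."""

    x: float
    y: float


def hexagon_project(e: ExcitationTriplet) -> HexagonPoint:
    """Project excitations onto the hexagon.

    x = (sqrt(3)/2) * (e_green - e_uv); y = e_blue - (e_uv + e_green)/2.
    Equal excitations map to the center; a single fully excited receptor
    maps to a vertex at distance 1.
    """
    x = (math.sqrt(3.0) / 2.0) * (e.e_green - e.e_uv)
    y = e.e_blue - (e.e_uv + e.e_green) / 2.0
    return HexagonPoint(x=x, y=y)


def chromatic_contrast(p: HexagonPoint) -> float:
    """Euclidean distance to the achromatic center, in hexagon units."""
    return math.hypot(p.x, p.y)


def chromatic_distance(p: HexagonPoint, q: HexagonPoint) -> float:
    """Euclidean distance between two hexagon points."""
    return math.hypot(p.x - q.x, p.y - q.y)


def pairwise_morph_distances(
    points: Sequence[HexagonPoint],
    morphs: Sequence[str],
    threshold: float = DISCRIMINATION_THRESHOLD,
    expected_morphs: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Median + IQR of all cross-pair distances for each morph pair.

    For every unordered pair of distinct morphs, all point-to-point
    distances across the two groups are enumerated; the median, the
    25th/75th percentiles and a discriminability flag
    (median > threshold) are reported.  Morphs with zero points are
    excluded with a warning.
    """
    if len(points) != len(morphs):
        raise ValueError("points and morphs must have equal length")
    groups: dict[str, list[HexagonPoint]] = {m: [] for m in (expected_morphs or ())}
    for p, m in zip(points, morphs):
        groups.setdefault(m, []).append(p)
    empty = [m for m, pts in groups.items() if not pts]
    for m in empty:
        warnings.warn(f"morph {m!r} has no points; excluded from pairwise table")
        del groups[m]
    labels = list(groups)
    if len(labels) < 2:
        warnings.warn("fewer than 2 morphs with points; empty pairwise table")
    rows = []
    for a, b in itertools.combinations(labels, 2):
        dists = np.array(
            [chromatic_distance(p, q) for p in groups[a] for q in groups[b]]
        )
        q25, q50, q75 = np.percentile(dists, [25.0, 50.0, 75.0])
        rows.append(
            {
                "morph_a": a,
                "morph_b": b,
                "n_pairs": dists.size,
                "median": float(q50),
                "iqr_low": float(q25),
                "iqr_high": float(q75),
                "above_threshold": bool(q50 > threshold),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "morph_a", "morph_b", "n_pairs", "median",
            "iqr_low", "iqr_high", "above_threshold",
        ],
    )


def spectral_locus(
    grid: np.ndarray,
    templates: Sequence[ReceptorTemplate] | None = None,
    illuminant: Illuminant | None = None,
    background: Background | None = None,
    mode: str = DEFAULT_MODE,
) -> pd.DataFrame:
    """Hexagon trajectory of narrowband (1-nm bin) stimuli.

    Each wavelength on ``grid`` is a delta-like stimulus one grid step
    wide.  A monochromatic light has a free intensity, so each point is
    placed at its maximal possible chromatic saturation: in literal mode
    the stimulus is scaled so the most-excited band reaches excitation 1;
    in adapted mode the intensity maximizing the contrast under the
    hyperbolic transform is found by a log-scale scan.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        return pd.DataFrame(columns=["wavelength_nm", "x", "y", "contrast"])
    full = default_grid()
    if templates is None:
        templates = make_receptor_templates()
    if illuminant is None:
        illuminant = solar_irradiance(full)
    if mode == "adapted" and background is None:
        background = green_leaf_background(full)
    elif mode not in ("literal", "adapted"):
        raise ValueError(f"unknown excitation mode {mode!r}")

    bg_catches = None
    if mode == "adapted":
        bg = background.reflectance
        bg_catches = np.array(
            [_quantum_catch(bg, t, illuminant)[0] for t in templates]
        )
        if np.any(bg_catches <= 0):
            raise ValueError("zero background catch; cannot build adapted locus")
    norms = np.array(
        [float(np.trapezoid(t(full) * illuminant(full), full)) for t in templates]
    )

    rows = []
    scales = np.logspace(-4.0, 6.0, 241)
    for lam0 in grid:
        vals = np.where(np.abs(full - lam0) <= 0.5, 1.0, 0.0)
        if vals.sum() == 0:
            continue
        spec = Spectrum(full, vals, meta={"kind": "monochromatic"})
        raw = np.array(
            [_quantum_catch(spec, t, illuminant)[0] for t in templates]
        )
        if raw.max() <= 0:
            continue  # outside receptor/illuminant support
        if mode == "literal":
            w = raw / norms
            e = w / w.max()  # scale intensity so the top band reaches 1
        else:
            d = raw / bg_catches
            cand = d[None, :] * scales[:, None]
            exc = cand / (cand + 1.0)
            xs = (math.sqrt(3.0) / 2.0) * (exc[:, 2] - exc[:, 0])
            ys = exc[:, 1] - (exc[:, 0] + exc[:, 2]) / 2.0
            e = exc[int(np.argmax(np.hypot(xs, ys)))]
        pt = hexagon_project(ExcitationTriplet(e[0], e[1], e[2], mode=mode))
        rows.append(
            {"wavelength_nm": float(lam0), "x": pt.x, "y": pt.y,
             "contrast": chromatic_contrast(pt)}
        )
    return pd.DataFrame(rows, columns=["wavelength_nm", "x", "y", "contrast"])
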