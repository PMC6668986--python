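"""Seeded generators for every input the analysis pipeline consumes.

The generators emulate the raw data behind iron-core quantification of
encapsulin nanocompartments:

* :func:`project_sphere` turns a spherical mineral-core phantom of known
  diameter and volumetric Fe density into a projected areal-density map
  (atoms/nm^2 per pixel), the ground truth the EELS chain must recover.
* :func:`make_eels_cube` builds a paired low-loss / core-loss DualEELS
  spectrum image from that map: a Gaussian zero-loss peak carrying the
  incident intensity I0, a power-law pre-edge background, and an Fe-L
  edge whose integrated counts obey I_edge = I0 * N * sigma, with
  optional channel-wise Poisson noise.
* :func:`make_micrograph` renders electron-dense cores as dark disks on
  a noisy bright background for threshold/Feret sizing.
* :func:`make_progress_curve` and :func:`make_melt_curve` produce
  ferroxidase A315 progress curves (via the kinetics rate law in
  :mod:`encapquant.curves`) and two-state DSF melt curves.

Every generator is a pure function of its spec and seed, and ground
truth is always returned alongside the data, never embedded in it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .constants import (
    BARN_TO_NM2,
    FE_CROSS_SECTION_BARNS,
    FE_L3_ONSET_EV,
    FE_L_INTEGRATION_UPPER_EV,
)
from .curves import Curve, KineticsParams, simulate_kinetics

__all__ = [
    "PhantomSpec",
    "BeamSpec",
    "SpectrumImage",
    "project_sphere",
    "make_eels_cube",
    "make_micrograph",
    "make_progress_curve",
    "make_melt_curve",
]


@dataclass(frozen=True)
class PhantomSpec:
    """A spherical mineral-core phantom.

    Defaults describe the largest core quantified in the study
    conditions: 23.6 nm diameter at 3.385 Fe atoms/nm^3, which holds
    (pi/6) * 23.6^3 * 3.385 ~ 23,297 atoms.
    """

    diameter_nm: float = 23.6
    volumetric_density: float = 3.385  # Fe atoms / nm^3
    center_nm: tuple[float, float] = (0.0, 0.0)  # (x, y) relative to grid center
    pixel_size_nm: float = 0.5

    def __post_init__(self) -> None:
        if self.diameter_nm <= 0:
            raise ValueError("phantom diameter must be positive")
        if self.volumetric_density < 0:
            raise ValueError("volumetric density must be non-negative")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel size must be positive")


@dataclass(frozen=True)
class BeamSpec:
    """Acquisition model for a synthetic DualEELS spectrum image.

    The low-loss cube holds a Gaussian zero-loss peak whose per-pixel
    integral is ``i0_per_pixel`` counts; the core-loss cube holds a
    power-law background ``A * E**(-r)`` plus an Fe-L edge.  The
    default dispersion is 0.25 eV/channel and the core-loss axis spans
    [coreloss_offset, coreloss_offset + n_channels * dispersion).
    """

    i0_per_pixel: float = 1e8
    zlp_center_ev: float = 0.0
    zlp_fwhm_ev: float = 1.0
    dispersion_ev: float = 0.25
    coreloss_offset_ev: float = 600.0
    n_channels: int = 880
    lowloss_halfwidth_ev: float = 10.0
    background_amplitude: float = 100.0  # counts/channel at offset, per 1e8 incident
    background_exponent: float = 3.0
    edge_onset_ev: float = FE_L3_ONSET_EV
    edge_width_ev: float = 2.0
    edge_decay_ev: float = 60.0
    noise: str = "poisson"  # "none" or "poisson"

    def __post_init__(self) -> None:
        if self.i0_per_pixel <= 0:
            raise ValueError("i0_per_pixel must be positive")
        if self.dispersion_ev <= 0:
            raise ValueError("dispersion must be positive")
        if self.background_exponent <= 0:
            raise ValueError("background exponent must be positive")
        if not self.edge_onset_ev < FE_L_INTEGRATION_UPPER_EV:
            raise ValueError("edge onset must lie below the 780 eV integration limit")
        if self.noise not in ("none", "poisson"):
            raise ValueError("noise must be 'none' or 'poisson'")
        if self.zlp_fwhm_ev <= 0 or self.edge_width_ev <= 0 or self.edge_decay_ev <= 0:
            raise ValueError("widths must be positive")

    @property
    def coreloss_axis_ev(self) -> np.ndarray:
        return self.coreloss_offset_ev + self.dispersion_ev * np.arange(self.n_channels)

    @property
    def lowloss_axis_ev(self) -> np.ndarray:
        n = int(round(2 * self.lowloss_halfwidth_ev / self.dispersion_ev)) + 1
        return self.zlp_center_ev - self.lowloss_halfwidth_ev + self.dispersion_ev * np.arange(n)


@dataclass
class SpectrumImage:
    """Paired core-loss and low-loss datacubes with shared scan grid.

    Cubes are indexed ``(row, col, channel)``; the two energy axes are
    in eV and the scan pixel size in nm.  ``metadata`` records the
    generation parameters (never the per-pixel ground truth, which
    travels separately).
    """

    coreloss: np.ndarray
    lowloss: np.ndarray
    coreloss_axis_ev: np.ndarray
    lowloss_axis_ev: np.ndarray
    pixel_size_nm: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.coreloss.shape[:2] != self.lowloss.shape[:2]:
            raise ValueError("core-loss and low-loss scan grids differ")
        if self.coreloss.shape[2] != self.coreloss_axis_ev.size:
            raise ValueError("core-loss axis length mismatch")
        if self.lowloss.shape[2] != self.lowloss_axis_ev.size:
            raise ValueError("low-loss axis length mismatch")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel size must be positive")

    @property
    def scan_shape(self) -> tuple[int, int]:
        return self.coreloss.shape[:2]


def project_sphere(
    spec: PhantomSpec,
    grid_shape: tuple[int, int],
    subsample: int = 4,
) -> np.ndarray:
    """Project a spherical phantom to per-pixel areal density.

    A sphere of radius r and uniform volumetric density rho projects to
    ``rho * 2 * sqrt(r^2 - s^2)`` atoms/nm^2 at in-plane distance s
    from its center, and 0 outside.  Pixels are averaged over a
    ``subsample x subsample`` sub-grid so the summed map converges to
    the closed-form total ``(pi/6) * d^3 * rho``.

    Parameters
    ----------
    spec : PhantomSpec
    grid_shape : (rows, cols)
        Image dimensions in pixels; must fully contain the sphere.
    subsample : int
        Sub-pixel sampling factor (1 = pixel-center sampling).

    Returns
    -------
    ndarray
        ``grid_shape`` map of atoms/nm^2.
    """
    ny, nx = grid_shape
    if subsample < 1:
        raise ValueError("subsample must be >= 1")
    r = spec.diameter_nm / 2.0
    p = spec.pixel_size_nm
    # Pixel centers at integer indices; grid center at the mid-index.
    cx = (nx - 1) / 2.0 + spec.center_nm[0] / p
    cy = (ny - 1) / 2.0 + spec.center_nm[1] / p
    r_px = r / p
    if (
        cx - r_px < -0.5
        or cy - r_px < -0.5
        or cx + r_px > nx - 0.5
        or cy + r_px > ny - 0.5
    ):
        need = int(np.ceil(2 * r_px + 1))
        raise ValueError(
            f"phantom (diameter {spec.diameter_nm} nm at {p} nm/px) extends "
            f"beyond the {ny}x{nx} grid; need at least {need}x{need} pixels "
            "around its center"
        )
    offs = (np.arange(subsample) + 0.5) / subsample - 0.5
    xs = np.arange(nx)[None, :, None, None] + offs[None, None, None, :]
    ys = np.arange(ny)[:, None, None, None] + offs[None, None, :, None]
    s2 = ((xs - cx) ** 2 + (ys - cy) ** 2) * p**2
    chord = 2.0 * np.sqrt(np.clip(r**2 - s2, 0.0, None))
    return spec.volumetric_density * chord.mean(axis=(2, 3))


def _gaussian(x: np.ndarray, amplitude: float, center: float, fwhm: float) -> np.ndarray:
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    return amplitude * np.exp(-0.5 * ((x - center) / sigma) ** 2)


def _edge_profile(beam: BeamSpec) -> np.ndarray:
    """Unit-integral Fe-L edge shape over the quantification window.

    A sigmoid onset of width ``edge_width_ev`` followed by an
    exponential decay.  Only the integral over
    [edge_onset, 780 eV] matters for quantification, so the profile is
    normalised to unit channel-sum over exactly that window.
    """
    e = beam.coreloss_axis_ev
    shape = 1.0 / (1.0 + np.exp(-(e - beam.edge_onset_ev) / (beam.edge_width_ev / 4.0)))
    shape = shape * np.exp(-np.clip(e - beam.edge_onset_ev, 0.0, None) / beam.edge_decay_ev)
    window = (e >= beam.edge_onset_ev) & (e <= FE_L_INTEGRATION_UPPER_EV)
    norm = shape[window].sum()
    return shape / norm


def make_eels_cube(
    areal_map: np.ndarray,
    beam: BeamSpec,
    pixel_size_nm: float,
    seed: int | None = 0,
) -> SpectrumImage:
    """Build a DualEELS spectrum image from an areal-density map.

    Per pixel, the low-loss spectrum is a Gaussian zero-loss peak whose
    channel-sum equals ``beam.i0_per_pixel``; the core-loss spectrum is
    the power-law background plus an edge whose channel-sum over
    [edge_onset, 780 eV] equals ``I0 * N * sigma`` with
    sigma = 2664.9 barn = 2.6649e-7 nm^2.  With ``beam.noise ==
    'poisson'`` both cubes receive channel-wise Poisson noise drawn
    from the stated seed; identical (map, beam, seed) inputs yield
    bit-identical cubes.
    """
    areal_map = np.asarray(areal_map, dtype=float)
    if areal_map.ndim != 2:
        raise ValueError("areal map must be 2-D")
    if np.any(areal_map < 0):
        raise ValueError("areal map must be non-negative")
    e_core = beam.coreloss_axis_ev
    if e_core[0] > beam.edge_onset_ev or e_core[-1] < FE_L_INTEGRATION_UPPER_EV:
        raise ValueError(
            "core-loss channel range "
            f"[{e_core[0]:g}, {e_core[-1]:g}] eV does not cover the "
            f"[{beam.edge_onset_ev:g}, {FE_L_INTEGRATION_UPPER_EV:g}] eV "
            "quantification window"
        )

    ny, nx = areal_map.shape
    sigma_nm2 = FE_CROSS_SECTION_BARNS * BARN_TO_NM2

    # Low loss: Gaussian ZLP with channel-sum I0.
    e_low = beam.lowloss_axis_ev
    zlp_shape = _gaussian(e_low, 1.0, beam.zlp_center_ev, beam.zlp_fwhm_ev)
    zlp = beam.i0_per_pixel * zlp_shape / zlp_shape.sum()
    lowloss = np.broadcast_to(zlp, (ny, nx, e_low.size)).copy()

    # Core loss: power-law background + edge scaled to I0 * N * sigma.
    # The carbon/substrate background is dose-proportional: the stated
    # amplitude applies at the 1e8-count reference dose.
    background = (
        beam.background_amplitude
        * (beam.i0_per_pixel / 1e8)
        * (e_core / beam.coreloss_offset_ev) ** (-beam.background_exponent)
    )
    edge_counts = beam.i0_per_pixel * areal_map * sigma_nm2  # (ny, nx)
    coreloss = background[None, None, :] + edge_counts[:, :, None] * _edge_profile(beam)[None, None, :]

    if beam.noise == "poisson":
        rng = np.random.default_rng(seed)
        lowloss = rng.poisson(lowloss).astype(float)
        coreloss = rng.poisson(coreloss).astype(float)

    meta = {"generator": "make_eels_cube", "seed": seed, **asdict(beam)}
    return SpectrumImage(
        coreloss=coreloss,
        lowloss=lowloss,
        coreloss_axis_ev=e_core.copy(),
        lowloss_axis_ev=e_low.copy(),
        pixel_size_nm=pixel_size_nm,
        metadata=meta,
    )


def make_micrograph(
    particles: list[tuple[tuple[float, float], float, float]],
    shape: tuple[int, int] = (512, 512),
    pixel_size_nm: float = 1.0,
    background_level: float = 30000.0,
    noise_sd: float = 0.0,
    seed: int | None = 0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render electron-dense particles as dark disks on a bright field.

    Parameters
    ----------
    particles : list of ((x_nm, y_nm), diameter_nm, contrast)
        Centers in nm from the image origin (pixel (0,0) center),
        diameters in nm, and contrast as the fractional darkening of
        the background (0 < contrast <= 1).
    shape : (rows, cols)
    noise_sd : float
        Additive Gaussian noise, gray levels.
    seed : int
        Noise seed.

    Returns
    -------
    (image, ground_truth)
        Float image (clip/convert downstream for 16-bit TIFF) and a
        DataFrame of true centers/diameters/contrasts.
    """
    ny, nx = shape
    img = np.full((ny, nx), float(background_level))
    yy, xx = np.mgrid[0:ny, 0:nx]
    rows = []
    for (x_nm, y_nm), d_nm, contrast in particles:
        if d_nm <= 0:
            raise ValueError("particle diameter must be positive")
        r_px = d_nm / 2.0 / pixel_size_nm
        cx = x_nm / pixel_size_nm
        cy = y_nm / pixel_size_nm
        if not (0 <= cx - r_px and cx + r_px <= nx - 1 and 0 <= cy - r_px and cy + r_px <= ny - 1):
            raise ValueError(
                f"particle at ({x_nm}, {y_nm}) nm, d={d_nm} nm extends beyond the image"
            )
        inside = (xx - cx) ** 2 + (yy - cy) ** 2 <= r_px**2
        img[inside] = background_level * (1.0 - contrast)
        rows.append(
            {
                "center_x_nm": x_nm,
                "center_y_nm": y_nm,
                "diameter_nm": d_nm,
                "contrast": contrast,
            }
        )
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    truth = pd.DataFrame(rows, columns=["center_x_nm", "center_y_nm", "diameter_nm", "contrast"])
    return img, truth


def make_progress_curve(
    model: str,
    params: KineticsParams | None = None,
    t_end_s: float = 1500.0,
    n_points: int = 300,
    noise_sd: float = 0.0,
    seed: int | None = 0,
) -> tuple[Curve, Curve]:
    """Generate a ferroxidase progress curve in one of two regimes.

    ``model='hyperbolic'`` uses sub-saturating Michaelis-Menten
    oxidation (k_auto = 0, Km > S0), the regime of the cargo-loaded
    compartment where the shell limits iron flux so the enzyme never
    saturates and the progress curve is concave from the start;
    ``model='autocatalytic'`` uses pure mineral-surface autocatalysis
    (vmax ~ 0), the regime of the free cargo protein, yielding a
    sigmoidal lag-burst curve.  The 25-min default window matches a
    standard assay read and captures most, not all, of the conversion.

    Returns ``(noisy_curve, clean_curve)``; the clean curve is the
    ground truth.
    """
    if model not in ("hyperbolic", "autocatalytic"):
        raise ValueError("model must be 'hyperbolic' or 'autocatalytic'")
    if params is None:
        if model == "hyperbolic":
            params = KineticsParams(vmax=0.35, km=250.0, k_auto=0.0, s0=100.0)
        else:
            params = KineticsParams(vmax=0.0, km=250.0, k_auto=3e-3, s0=100.0)
    if model == "hyperbolic" and params.k_auto != 0:
        raise ValueError("hyperbolic regime requires k_auto = 0")
    t = np.linspace(0.0, t_end_s, n_points)
    clean = simulate_kinetics(params, t)
    noisy = clean.ordinate.copy()
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        noisy = noisy + rng.normal(0.0, noise_sd, size=noisy.shape)
    return (
        Curve(t, noisy, abscissa_name="time_s", ordinate_name="A315"),
        clean,
    )


def make_melt_curve(
    tm_c: float,
    steepness_c: float = 2.0,
    pre_baseline: tuple[float, float] = (1.0, 0.0),
    post_baseline: tuple[float, float] = (2.0, 0.0),
    ramp_c: tuple[float, float] = (35.0, 95.0),
    step_c: float = 0.25,
    noise_sd: float = 0.0,
    seed: int | None = 0,
) -> Curve:
    """Generate a two-state DSF melt curve over a 35-95 degC ramp.

    The fluorescence-ratio signal is
    ``pre(T) * (1 - theta) + post(T) * theta`` with the unfolded
    fraction ``theta = 1 / (1 + exp(-(T - tm) / (steepness/4)))`` and
    linear pre/post baselines given as (intercept-at-tm, slope).  With
    flat baselines the first-derivative peak sits at ``tm_c`` by
    construction.

    Raises
    ------
    ValueError
        If ``tm_c`` lies outside the open ramp interval or
        ``steepness_c`` is not positive.
    """
    lo, hi = ramp_c
    if not lo < tm_c < hi:
        raise ValueError(f"tm={tm_c} degC outside the ({lo}, {hi}) degC ramp")
    if steepness_c <= 0:
        raise ValueError("steepness must be positive (degC)")
    t = np.arange(lo, hi + step_c / 2, step_c)
    theta = 1.0 / (1.0 + np.exp(-(t - tm_c) / (steepness_c / 4.0)))
    pre = pre_baseline[0] + pre_baseline[1] * (t - tm_c)
    post = post_baseline[0] + post_baseline[1] * (t - tm_c)
    y = pre * (1.0 - theta) + post * theta
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd, size=y.shape)
    return Curve(t, y, abscissa_name="temperature_C", ordinate_name="ratio_350_330")
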