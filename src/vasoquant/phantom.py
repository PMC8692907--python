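"""Synthetic vascular phantoms with exact ground truth.

The generator emulates hemoglobin-contrast microscopy of skin
microvasculature: a dark background, bright curvilinear vessels of
roughly 1–15 px width at 5–50 µm pixel pitch, blurred by the optical
point-spread function and degraded by additive Gaussian noise.  Every
phantom carries its generating truth — continuous centerline polylines,
widths, analytic tortuosity, the rasterized truth mask and the true
fill fraction — recorded *before* blur and noise, so each pipeline
stage can be scored against a well-defined quantity.

Centerlines are sinusoidally perturbed random walks: the heading
integrates a sinusoidal curvature wave (random wavelength and phase)
carrying most of the requested turning rate, plus von Mises white
heading jitter whose concentration κ is calibrated numerically so the
jitter contributes its share of expected absolute turning per unit arc
length.  Widths are chosen so the centerline curvature radius stays at
or above the vessel half-width, keeping the truth expressible in the
raster.  The walk vertices are interpolated with a parametric cubic
spline and truth tortuosity is evaluated on the resulting fine
polyline.

Two morphology presets bracket the biological contrast of interest:

* ``wt_like`` — sparse, straighter network: fill ≈ 9.6 %, turning rate
  1.5 °/µm, width median 30 µm.
* ``vegf_like`` — dense, tortuous network: fill ≈ 17.1 %, turning rate
  1.57× the sparse preset, width median 18 µm.

The fill fractions and the 1.57× turning-rate ratio are the group
contrasts of interest (hypervascularised versus normal skin); the
absolute turning rates and widths are set so every centerline's
curvature radius stays above its tube half-width and above the PSF
scale — otherwise the raster could not express its own truth.  The
presets exist so that recovery of a known group contrast can be tested
end to end.

The default field of view is a 340×340 px scan at 5 µm pitch
(1.7 × 1.7 mm²), a typical fine-resolution region-of-interest scan.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import integrate, ndimage, optimize, special
from scipy.spatial import cKDTree

from vasoquant.imaging_io import RasterImage, VolumeScan
from vasoquant.metrics import MetricsRecord, turning_angles_deg
from vasoquant.segmentation import VesselMask
from vasoquant.vessel_graph import VesselGraph

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "generate_phantom",
    "score_against_truth",
    "truth_metrics",
    "kappa_for_turning_rate",
]


@dataclass
class PhantomSpec:
    """Parameters of a synthetic vascular phantom.

    Either ``n_vessels`` or ``target_fill_pct`` drives vessel placement:
    with a fill target, vessels are added until the rasterized truth
    mask reaches the target (within ±10 % relative).

    Attributes
    ----------
    shape_px : (rows, cols)
    pixel_size_um : float
        Scan pitch; 5, 20 and 50 µm are typical.
    n_vessels : int or None
        Fixed vessel count (used when ``target_fill_pct`` is None).
    target_fill_pct : float or None
        Truth-mask fill fraction to aim for, %.
    width_median_um, width_sigma : float
        Lognormal vessel-width distribution (median in µm, log-sd).
    turning_rate_deg_per_um : float
        Target expected |turning| per arc length of the centerlines.
    psf_fwhm_um : float
        Gaussian PSF full width at half maximum (optical spot size).
    snr : float
        Peak vessel amplitude over noise SD; 0 disables noise.
    background : float
        Background level as a fraction of peak vessel amplitude.
    n_depth_layers : int
        1 → 2D :class:`RasterImage`; ≥2 → vessels distributed over this
        many depth layers of a :class:`VolumeScan`.
    axial_spacing_um : float
        Depth pitch for volumetric phantoms.
    seed : int
        Identical spec + seed reproduces bit-identical output.
    fixed_widths_um : tuple of float, optional
        Deterministic per-vessel widths (cycled); overrides the
        lognormal draw.  Useful for controlled width sweeps.
    """

    shape_px: tuple[int, int] = (340, 340)
    pixel_size_um: float = 5.0
    n_vessels: int | None = None
    target_fill_pct: float | None = None
    width_median_um: float = 30.0
    width_sigma: float = 0.25
    turning_rate_deg_per_um: float = 2.44
    psf_fwhm_um: float = 7.5
    snr: float = 10.0
    background: float = 0.05
    n_depth_layers: int = 1
    axial_spacing_um: float = 50.0
    seed: int = 0
    fixed_widths_um: tuple[float, ...] | None = None
    layout: str = "random"  # 'random' walks | 'parallel' straight bars

    @classmethod
    def wt_like(cls, seed: int = 0, **overrides) -> "PhantomSpec":
        """Sparse, straighter network (normal-skin-like morphology)."""
        params = dict(
            target_fill_pct=9.6,
            turning_rate_deg_per_um=1.5,
            width_median_um=30.0,
            seed=seed,
        )
        params.update(overrides)
        return cls(**params)

    @classmethod
    def vegf_like(cls, seed: int = 0, **overrides) -> "PhantomSpec":
        """Dense, tortuous network (hypervascularised morphology)."""
        params = dict(
            target_fill_pct=17.1,
            turning_rate_deg_per_um=1.5 * 1.57,
            width_median_um=18.0,
            seed=seed,
        )
        params.update(overrides)
        return cls(**params)

    def __post_init__(self) -> None:
        if self.n_vessels is None and self.target_fill_pct is None:
            raise ValueError("specify n_vessels or target_fill_pct")
        if self.target_fill_pct is not None and not (0 < self.target_fill_pct < 60):
            raise ValueError("target_fill_pct must be in (0, 60)")
        if self.pixel_size_um <= 0 or self.width_median_um <= 0:
            raise ValueError("pixel size and width median must be > 0")
        if self.turning_rate_deg_per_um < 0:
            raise ValueError("turning rate must be >= 0")
        if self.snr < 0 or self.background < 0:
            raise ValueError("snr and background must be >= 0")
        if self.n_depth_layers < 1:
            raise ValueError("n_depth_layers must be >= 1")
        if self.layout not in ("random", "parallel"):
            raise ValueError(f"unknown layout {self.layout!r}")
        if self.layout == "parallel" and self.n_vessels is None:
            raise ValueError("parallel layout requires n_vessels")


@dataclass
class PhantomTruth:
    """Generating truth of a phantom, recorded before blur and noise."""

    centerlines_um: list[np.ndarray]
    widths_um: list[float]
    tortuosities_deg_per_um: list[float]
    lengths_um: list[float]
    mask: np.ndarray  # rasterized union of tubes, bool
    pixel_size_um: float

    @property
    def vessel_count(self) -> int:
        return len(self.centerlines_um)

    @property
    def fill_fraction_pct(self) -> float:
        return 100.0 * float(np.count_nonzero(self.mask)) / self.mask.size

    def as_mask(self) -> VesselMask:
        return VesselMask(
            mask=self.mask.copy(),
            pixel_size_um=self.pixel_size_um,
            method="truth",
        )


def _mean_abs_vonmises_rad(kappa: float) -> float:
    """E|θ| for θ ~ von Mises(0, κ), via the exponentially scaled integrand."""
    if kappa == 0:
        return math.pi / 2
    val, _ = integrate.quad(
        lambda t: t * math.exp(kappa * (math.cos(t) - 1.0)), 0.0, math.pi,
        limit=200,
    )
    return val / (math.pi * special.i0e(kappa))


@lru_cache(maxsize=256)
def kappa_for_turning_rate(turning_rate_deg_per_um: float, step_um: float) -> float:
    """von Mises concentration giving E|Δθ| = turning_rate · step per step.

    Inverts the exact E|θ|(κ) relation numerically; results are cached.
    A target at or above the uniform-distribution mean (90°·step) maps
    to κ = 0.
    """
    target_rad = math.radians(turning_rate_deg_per_um * step_um)
    if target_rad >= math.pi / 2:
        return 0.0
    if target_rad <= 0:
        return 1e9
    return float(
        optimize.brentq(
            lambda k: _mean_abs_vonmises_rad(k) - target_rad, 1e-6, 1e9, xtol=1e-9
        )
    )


def _spline_fine(points: np.ndarray, fine_step_um: float) -> np.ndarray:
    """Parametric cubic-spline interpolation of walk vertices.

    Chord-length parameterisation, evaluated at ~``fine_step_um``
    spacing; falls back to the raw polyline for < 4 vertices.
    """
    from scipy.interpolate import CubicSpline

    if len(points) < 4:
        return points.copy()
    chord = np.hypot(*np.diff(points, axis=0).T)
    t = np.concatenate([[0.0], np.cumsum(chord)])
    cs = CubicSpline(t, points, axis=0)
    n = max(2, int(t[-1] / fine_step_um) + 1)
    return cs(np.linspace(0.0, t[-1], n))


#: share of the turning budget carried by the smooth sinusoidal meander;
#: the remainder is white von Mises heading jitter
_MEANDER_SHARE = 0.85


def _draw_centerline(
    rng: np.random.Generator,
    extent_um: tuple[float, float],
    turning_rate: float,
    pixel_size_um: float,
) -> np.ndarray:
    """One meandering centerline entering from a border, in µm coords.

    The heading integrates a sinusoidal curvature wave (random
    wavelength 120–240 µm and phase) that carries most of the requested
    turning rate, plus von Mises white jitter for the rest.  A sinusoid
    of peak curvature c has mean |curvature| 2c/π, so c is set to
    (π/2)·share·rate.  Putting the turning at these wavelengths keeps
    the centerline's curvature radius above the vessel half-width for
    realistic widths, i.e. the rasterized tube can actually express its
    own centerline's tortuosity — white-noise headings would concentrate
    the turning below the tube width, where the medial axis cannot
    follow it.
    """
    h_um, w_um = extent_um
    step = 2.0 * pixel_size_um
    rate_rad = math.radians(turning_rate)
    c_peak = (math.pi / 2) * _MEANDER_SHARE * rate_rad  # rad/µm
    wavelength = rng.uniform(120.0, 240.0)
    phase = rng.uniform(0.0, 2 * math.pi)
    jitter_rate = (1.0 - _MEANDER_SHARE) * turning_rate
    kappa = kappa_for_turning_rate(round(jitter_rate, 6), round(step, 6))

    # enter from a random border point heading inward (±45° jitter)
    side = rng.integers(4)
    u = rng.uniform(0.05, 0.95)
    if side == 0:    # top edge, heading down
        pos, base = np.array([0.0, u * w_um]), math.pi / 2
    elif side == 1:  # bottom edge, heading up
        pos, base = np.array([h_um, u * w_um]), -math.pi / 2
    elif side == 2:  # left edge, heading right
        pos, base = np.array([u * h_um, 0.0]), 0.0
    else:            # right edge, heading left
        pos, base = np.array([u * h_um, w_um]), math.pi
    heading = base + rng.uniform(-math.pi / 4, math.pi / 4)

    max_steps = int(3 * (h_um + w_um) / step)
    pts = [pos.copy()]
    arc = 0.0
    for _ in range(max_steps):
        heading += c_peak * math.sin(2 * math.pi * arc / wavelength + phase) * step
        if kappa < 1e9:
            heading += rng.vonmises(0.0, kappa)
        pos = pos + step * np.array([math.sin(heading), math.cos(heading)])
        arc += step
        pts.append(pos.copy())
        if not (0 <= pos[0] <= h_um and 0 <= pos[1] <= w_um):
            break
    walk = np.array(pts)
    fine = _spline_fine(walk, fine_step_um=pixel_size_um / 2)
    # clip trailing out-of-bounds points but keep one exit vertex
    inside = (
        (fine[:, 0] >= -pixel_size_um)
        & (fine[:, 0] <= h_um + pixel_size_um)
        & (fine[:, 1] >= -pixel_size_um)
        & (fine[:, 1] <= w_um + pixel_size_um)
    )
    if not inside.all():
        last = int(np.argmin(inside))
        fine = fine[: max(last + 1, 2)]
    return fine


def _rasterize_tube(
    canvas: np.ndarray, polyline_um: np.ndarray, width_um: float, pixel_size_um: float
) -> None:
    """Stamp a tube (union of disks along the polyline) into ``canvas``."""
    radius_px = max(0.5, width_um / 2 / pixel_size_um)
    h, w = canvas.shape
    r_int = int(math.ceil(radius_px))
    pts_px = polyline_um / pixel_size_um
    yy, xx = np.mgrid[-r_int : r_int + 1, -r_int : r_int + 1]
    for (cy, cx) in pts_px:
        iy, ix = int(round(cy)), int(round(cx))
        if iy < -r_int or iy >= h + r_int or ix < -r_int or ix >= w + r_int:
            continue
        stamp = (yy + iy - cy) ** 2 + (xx + ix - cx) ** 2 <= radius_px**2
        y0, y1 = max(0, iy - r_int), min(h, iy + r_int + 1)
        x0, x1 = max(0, ix - r_int), min(w, ix + r_int + 1)
        if y0 >= y1 or x0 >= x1:
            continue
        canvas[y0:y1, x0:x1] |= stamp[
            y0 - (iy - r_int) : y1 - (iy - r_int),
            x0 - (ix - r_int) : x1 - (ix - r_int),
        ]


def _polyline_stats(poly: np.ndarray) -> tuple[float, float]:
    """(length_um, tortuosity_deg_per_um) of a µm polyline."""
    seg = np.diff(poly, axis=0)
    length = float(np.hypot(seg[:, 0], seg[:, 1]).sum())
    if length == 0:
        return 0.0, 0.0
    angle_sum = float(turning_angles_deg(poly).sum())
    return length, angle_sum / length


def generate_phantom(
    spec: PhantomSpec,
) -> tuple[RasterImage | VolumeScan, PhantomTruth]:
    """Generate a synthetic vascular image (or volume) and its truth.

    Raises
    ------
    ValueError
        When a fill target cannot be reached (message reports the fill
        actually achieved).
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.shape_px
    extent = (h * spec.pixel_size_um, w * spec.pixel_size_um)

    mask = np.zeros((h, w), dtype=bool)
    centerlines: list[np.ndarray] = []
    widths: list[float] = []

    def fill_pct() -> float:
        return 100.0 * mask.sum() / mask.size

    def draw_width(i: int) -> float:
        if spec.fixed_widths_um is not None:
            return float(spec.fixed_widths_um[i % len(spec.fixed_widths_um)])
        return float(spec.width_median_um * math.exp(rng.normal(0.0, spec.width_sigma)))

    if spec.layout == "parallel":
        # evenly spaced horizontal bars: well-separated, non-crossing
        h_um, w_um = extent
        xs = np.arange(0.0, w_um + spec.pixel_size_um / 2, spec.pixel_size_um / 2)
        for i in range(spec.n_vessels):
            y = (i + 1) * h_um / (spec.n_vessels + 1)
            poly = np.column_stack([np.full_like(xs, y), xs])
            width = draw_width(i)
            _rasterize_tube(mask, poly, width, spec.pixel_size_um)
            centerlines.append(poly)
            widths.append(width)
    elif spec.target_fill_pct is None:
        for i in range(spec.n_vessels):
            poly = _draw_centerline(
                rng, extent, spec.turning_rate_deg_per_um, spec.pixel_size_um
            )
            width = draw_width(i)
            _rasterize_tube(mask, poly, width, spec.pixel_size_um)
            centerlines.append(poly)
            widths.append(width)
    else:
        target = spec.target_fill_pct
        attempts = 0
        max_attempts = 400
        while fill_pct() < 0.9 * target and attempts < max_attempts:
            attempts += 1
            poly = _draw_centerline(
                rng, extent, spec.turning_rate_deg_per_um, spec.pixel_size_um
            )
            width = draw_width(len(widths))
            trial = mask.copy()
            _rasterize_tube(trial, poly, width, spec.pixel_size_um)
            new_fill = 100.0 * trial.sum() / trial.size
            if new_fill > 1.1 * target:
                continue  # would overshoot: redraw
            mask = trial
            centerlines.append(poly)
            widths.append(width)
        if fill_pct() < 0.9 * target:
            raise ValueError(
                f"infeasible fill fraction: target {target:.2f}% not reachable, "
                f"achieved {fill_pct():.2f}% after {attempts} placements"
            )

    lengths, torts = [], []
    for poly in centerlines:
        length, tort = _polyline_stats(poly)
        lengths.append(length)
        torts.append(tort)

    truth = PhantomTruth(
        centerlines_um=centerlines,
        widths_um=widths,
        tortuosities_deg_per_um=torts,
        lengths_um=lengths,
        mask=mask,
        pixel_size_um=spec.pixel_size_um,
    )

    sigma_px = spec.psf_fwhm_um / (2.0 * math.sqrt(2.0 * math.log(2.0))) / spec.pixel_size_um
    noise_sd = 1.0 / spec.snr if spec.snr > 0 else 0.0

    if spec.n_depth_layers == 1:
        signal = ndimage.gaussian_filter(mask.astype(float), sigma=sigma_px)
        img = signal + spec.background
        if noise_sd:
            img = img + rng.normal(0.0, noise_sd, size=img.shape)
        return (
            RasterImage(
                pixels=np.clip(img, 0.0, None),
                pixel_size_um=spec.pixel_size_um,
                stage="raw",
            ),
            truth,
        )

    # volumetric phantom: vessels on 2-3 depth layers, intensity spread
    # axially so the depth MIP recovers the 2D picture
    layers = spec.n_depth_layers
    layer_of = rng.integers(0, layers, size=len(centerlines))
    depth = 4 * layers + 3
    centers = np.linspace(2, depth - 3, layers).round().astype(int)
    axial_w = np.array([0.2, 0.6, 1.0, 0.6, 0.2])
    vol = np.zeros((depth, h, w), dtype=float)
    for li in range(layers):
        lmask = np.zeros((h, w), dtype=bool)
        for poly, width, lab in zip(centerlines, widths, layer_of):
            if lab == li:
                _rasterize_tube(lmask, poly, width, spec.pixel_size_um)
        signal = ndimage.gaussian_filter(lmask.astype(float), sigma=sigma_px)
        for off, wt in zip(range(-2, 3), axial_w):
            vol[centers[li] + off] = np.maximum(vol[centers[li] + off], wt * signal)
    vol += spec.background
    if noise_sd:
        vol = vol + rng.normal(0.0, noise_sd, size=vol.shape)
    return (
        VolumeScan(
            voxels=np.clip(vol, 0.0, None),
            lateral_spacing_um=spec.pixel_size_um,
            axial_spacing_um=spec.axial_spacing_um,
        ),
        truth,
    )


def truth_metrics(truth: PhantomTruth) -> MetricsRecord:
    """Metrics record computed directly from the generating truth."""
    import pandas as pd

    rows = [
        {
            "segment_id": i + 1,
            "length_um": truth.lengths_um[i],
            "mean_diameter_um": truth.widths_um[i],
            "tortuosity_deg_per_um": truth.tortuosities_deg_per_um[i],
            "angle_sum_deg": truth.tortuosities_deg_per_um[i] * truth.lengths_um[i],
            "diameter_used_all_points": False,
        }
        for i in range(truth.vessel_count)
    ]
    table = pd.DataFrame(rows)
    return MetricsRecord(
        image_id="truth",
        fill_fraction_pct=truth.fill_fraction_pct,
        vessel_count=truth.vessel_count,
        median_diameter_um=float(np.median(truth.widths_um)) if truth.widths_um else None,
        median_tortuosity_deg_per_um=(
            float(np.median(truth.tortuosities_deg_per_um))
            if truth.tortuosities_deg_per_um
            else None
        ),
        segments=table,
    )


def score_against_truth(
    metrics: MetricsRecord,
    truth: PhantomTruth,
    segments: VesselGraph | list[tuple[np.ndarray, float, float | None]] | None = None,
) -> dict:
    """Score pipeline output against the phantom's generating truth.

    Parameters
    ----------
    metrics : MetricsRecord
        Pipeline (or truth) metrics for the phantom image.
    truth : PhantomTruth
    segments : VesselGraph or list of (path_um, diameter_um, tortuosity), optional
        Centerline geometry used for per-vessel matching.  Each measured
        segment is assigned to the truth vessel whose centerline it is
        closest to (mean nearest-point distance, accepted within one
        vessel width); per-vessel estimates are length-weighted means of
        the assigned segments.

    Returns
    -------
    dict with keys ``count_error``, ``fill_abs_error_pct``, and — when
    geometry was supplied — ``per_vessel`` (DataFrame),
    ``diameter_mae_um``, ``tortuosity_mae_deg_per_um``, ``n_matched``.
    """
    import pandas as pd

    out: dict = {
        "count_error": int(metrics.vessel_count - truth.vessel_count),
        "fill_abs_error_pct": abs(metrics.fill_fraction_pct - truth.fill_fraction_pct),
    }
    if segments is None:
        return out

    if isinstance(segments, VesselGraph):
        seg_info = [
            (s.path_um, s.mean_diameter_um, s.tortuosity_deg_per_um)
            for s in segments.metric_segments
        ]
    else:
        seg_info = list(segments)

    trees = [cKDTree(poly) for poly in truth.centerlines_um]
    assigned: dict[int, list[tuple[float, float | None, float | None]]] = {}
    for path_um, diam, tort in seg_info:
        path_um = np.asarray(path_um, dtype=float)
        seg_len = float(np.hypot(*np.diff(path_um, axis=0).T).sum())
        dists = [t.query(path_um)[0].mean() for t in trees]
        best = int(np.argmin(dists))
        if dists[best] <= truth.widths_um[best]:
            assigned.setdefault(best, []).append((seg_len, diam, tort))

    rows = []
    for i in range(truth.vessel_count):
        parts = assigned.get(i, [])
        if parts:
            wsum = sum(p[0] for p in parts)
            d_est = sum(p[0] * p[1] for p in parts if p[1] is not None)
            d_w = sum(p[0] for p in parts if p[1] is not None)
            t_est = sum(p[0] * p[2] for p in parts if p[2] is not None)
            t_w = sum(p[0] for p in parts if p[2] is not None)
            diam_est = d_est / d_w if d_w else np.nan
            tort_est = t_est / t_w if t_w else np.nan
        else:
            wsum, diam_est, tort_est = 0.0, np.nan, np.nan
        rows.append(
            {
                "vessel": i,
                "true_width_um": truth.widths_um[i],
                "est_diameter_um": diam_est,
                "diameter_error_um": diam_est - truth.widths_um[i],
                "true_tortuosity": truth.tortuosities_deg_per_um[i],
                "est_tortuosity": tort_est,
                "tortuosity_error": tort_est - truth.tortuosities_deg_per_um[i],
                "matched_length_um": wsum,
            }
        )
    per_vessel = pd.DataFrame(rows)
    out["per_vessel"] = per_vessel
    out["n_matched"] = int(per_vessel["est_diameter_um"].notna().sum())
    out["diameter_mae_um"] = float(per_vessel["diameter_error_um"].abs().mean())
    out["tortuosity_mae_deg_per_um"] = float(per_vessel["tortuosity_error"].abs().mean())
    return out
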