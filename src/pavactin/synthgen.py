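"""Synthetic fluorescence microscopy: cortical filament movies and lobed-cell mosaics.

The generator supplies ground-truth inputs for every downstream stage of the
pipeline.  Two simulators are provided:

``simulate_filament_movie``
    A Lifeact-GFP-like cortical actin movie.  Filaments are static 2D
    persistent random walks rendered with a Gaussian PSF; temporal dynamics
    come exclusively from stochastic turnover (exponential lifetimes, with
    immediate rebirth so the expected filament count is stationary).  A
    configurable fraction of filaments carries a "bundle" intensity
    multiplier, and the camera model adds exponential photobleaching and
    additive Gaussian noise on a [0, 1] intensity scale.

``generate_lobed_cells``
    A propidium-iodide-like mosaic of non-overlapping epidermal cells whose
    boundaries follow r(theta) = R * (1 + a * sin(m * theta + phi)), i.e. a
    disc with ``m`` sinusoidal lobes of relative amplitude ``a``.  The exact
    boundary polygon of every cell is kept as ground truth so raster
    morphometrics can be validated against an analytic oracle.

Randomness is driven by a single root seed that is hierarchically split
(`numpy.random.SeedSequence.spawn`) per filament slot / per cell, so changing
the number of filaments does not reshuffle the geometry of existing ones.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy.ndimage import gaussian_filter
from skimage.draw import polygon as draw_polygon

from .preprocess import ImageStack

logger = logging.getLogger(__name__)

# Peak intensity of a single unbundled filament after PSF blur, on the
# canonical [0, 1] scale.  Chosen so that a 3x bundle stays below saturation.
_BASE_PEAK = 0.25
# Arc-length sampling step (px) used when depositing filament intensity.
_SAMPLE_STEP = 0.5


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FilamentSimParams:
    """Parameters of the synthetic cortical-filament movie.

    Defaults emulate the acquisition conditions of the live-imaging assay the
    pipeline targets: 149 frames at 400 ms per frame, ~0.2 um pixels.
    """

    width_px: int = 256
    height_px: int = 256
    n_frames: int = 149
    pixel_size_um: float = 0.2
    frame_interval_s: float = 0.4
    n_filaments: int = 60
    persistence_px: float = 20.0
    turnover_rate_per_s: float = 0.03
    bundling_factor: float = 1.0
    psf_sigma_px: float = 1.5
    # peak-signal (0.25) to noise ratio of 25, mid-range for spinning-disc
    # confocal acquisitions of a bright live-cell filament marker
    noise_sd: float = 0.01
    bleach_rate_per_frame: float = 0.0
    seed: int = 0
    # filament length drawn uniformly in this range (px)
    length_range_px: tuple[float, float] = (15.0, 45.0)
    # fraction of filaments carrying the bundling multiplier
    bundled_fraction: float = 0.3
    # von Mises concentration of initial headings; 0 = isotropic
    orientation_kappa: float = 0.0

    def __post_init__(self) -> None:
        for name in ("width_px", "height_px", "n_frames", "n_filaments"):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        for name in ("pixel_size_um", "frame_interval_s", "persistence_px", "psf_sigma_px"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        for name in ("turnover_rate_per_s", "noise_sd", "bleach_rate_per_frame"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.bundling_factor < 1:
            raise ValueError(f"bundling_factor must be >= 1, got {self.bundling_factor}")
        lo, hi = self.length_range_px
        if not (0 < lo <= hi):
            raise ValueError(f"invalid length_range_px {self.length_range_px}")
        if not (0 <= self.bundled_fraction <= 1):
            raise ValueError(f"bundled_fraction must be in [0, 1], got {self.bundled_fraction}")
        if self.orientation_kappa < 0:
            raise ValueError("orientation_kappa must be >= 0")


@dataclass(frozen=True)
class LobedCellParams:
    """Parameters of the synthetic lobed-cell mosaic.

    Each cell boundary is r(theta) = R_i * (1 + lobe_amplitude * sin(
    lobe_count * theta + phi_i)) with random phase phi_i; R_i is jittered
    around ``base_radius_um`` by ``radius_jitter`` so cells within one mosaic
    vary in size, as they do in real epidermis.
    """

    n_cells: int = 16
    base_radius_um: float = 20.0
    lobe_count: int = 6
    lobe_amplitude: float = 0.3
    pixel_size_um: float = 0.4
    seed: int = 0
    radius_jitter: float = 0.08  # relative, uniform in [1-j, 1+j]
    n_vertices: int = 720

    def __post_init__(self) -> None:
        if int(self.n_cells) < 1:
            raise ValueError("n_cells must be >= 1")
        if self.base_radius_um <= 0 or self.pixel_size_um <= 0:
            raise ValueError("base_radius_um and pixel_size_um must be > 0")
        if self.lobe_count < 0:
            raise ValueError("lobe_count must be >= 0")
        if not (0 <= self.lobe_amplitude <= 0.9):
            raise ValueError(
                f"lobe_amplitude must be in [0, 0.9] (>= 1 self-intersects), "
                f"got {self.lobe_amplitude}"
            )
        if not (0 <= self.radius_jitter < 1):
            raise ValueError("radius_jitter must be in [0, 1)")
        if self.n_vertices < 720:
            raise ValueError("n_vertices must be >= 720")


@dataclass
class FilamentRecord:
    """Ground truth for one filament (one generation of one slot)."""

    slot: int
    generation: int
    birth_frame: int
    death_frame: int  # exclusive; may exceed n_frames if censored by movie end
    bundled: bool
    lifetime_s: float  # the raw exponential draw (inf when turnover = 0)


@dataclass
class MovieGroundTruth:
    """Everything the movie simulator knows that the analysis must recover."""

    params: FilamentSimParams
    filaments: list[FilamentRecord]

    def lifetimes_s(self) -> np.ndarray:
        """Raw exponential lifetime draws of every filament ever created."""
        return np.array([f.lifetime_s for f in self.filaments])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(f) for f in self.filaments])


@dataclass
class MosaicGroundTruth:
    """Analytic boundary polygons (um) and generating parameters of a mosaic."""

    params: LobedCellParams
    polygons_um: list[np.ndarray]  # (n_vertices, 2) arrays, (x, y) in um
    labels: list[int] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Filament movie
# ---------------------------------------------------------------------------

def _sample_path(rng: np.random.Generator, params: FilamentSimParams) -> np.ndarray:
    """Persistent random walk: fixed unit step, von-Mises-perturbed heading."""
    lo, hi = params.length_range_px
    length = rng.uniform(lo, hi)
    n_steps = max(1, int(round(length)))
    start = rng.uniform([0, 0], [params.height_px, params.width_px])
    if params.orientation_kappa > 0:
        heading = rng.vonmises(0.0, params.orientation_kappa)
    else:
        heading = rng.uniform(-np.pi, np.pi)
    # per-px angular diffusion so the decorrelation length is persistence_px
    kappa = params.persistence_px
    turns = rng.vonmises(0.0, kappa, size=n_steps)
    headings = heading + np.cumsum(turns)
    steps = np.stack([np.sin(headings), np.cos(headings)], axis=1)
    return np.vstack([start, start + np.cumsum(steps, axis=0)])


def _render_filament(
    path: np.ndarray, amplitude: float, params: FilamentSimParams
) -> tuple[np.ndarray, int, int]:
    """Rasterize one filament into a blurred crop; returns (crop, r0, c0)."""
    sigma = params.psf_sigma_px
    margin = int(np.ceil(4 * sigma)) + 1
    # resample the polyline at _SAMPLE_STEP arc-length spacing
    seg = np.diff(path, axis=0)
    seglen = np.hypot(seg[:, 0], seg[:, 1])
    arclen = np.concatenate([[0.0], np.cumsum(seglen)])
    total = arclen[-1]
    n_samples = max(2, int(total / _SAMPLE_STEP) + 1)
    s = np.linspace(0.0, total, n_samples)
    rows = np.interp(s, arclen, path[:, 0])
    cols = np.interp(s, arclen, path[:, 1])

    r0 = max(0, int(np.floor(rows.min())) - margin)
    c0 = max(0, int(np.floor(cols.min())) - margin)
    r1 = min(params.height_px, int(np.ceil(rows.max())) + margin + 1)
    c1 = min(params.width_px, int(np.ceil(cols.max())) + margin + 1)
    crop = np.zeros((max(r1 - r0, 1), max(c1 - c0, 1)))
    # bilinear deposit; per-sample weight = arc length * linear density, with
    # density chosen so the post-blur line peak equals `amplitude`
    density = amplitude * sigma * np.sqrt(2 * np.pi)
    w = np.full(n_samples, density * (total / max(n_samples - 1, 1)))
    rr = rows - r0
    cc = cols - c0
    ir = np.floor(rr).astype(int)
    ic = np.floor(cc).astype(int)
    fr = rr - ir
    fc = cc - ic
    h, wdt = crop.shape
    for dr, dc, wt in (
        (0, 0, (1 - fr) * (1 - fc)),
        (0, 1, (1 - fr) * fc),
        (1, 0, fr * (1 - fc)),
        (1, 1, fr * fc),
    ):
        r = ir + dr
        c = ic + dc
        ok = (r >= 0) & (r < h) & (c >= 0) & (c < wdt)
        np.add.at(crop, (r[ok], c[ok]), w[ok] * wt[ok])
    return gaussian_filter(crop, sigma, mode="constant"), r0, c0


def simulate_filament_movie(
    params: FilamentSimParams,
) -> tuple[ImageStack, MovieGroundTruth]:
    """Simulate a cortical-filament time series with known turnover ground truth.

    Each of ``n_filaments`` slots holds a chain of filament generations: a
    filament's lifetime is an exponential draw at ``turnover_rate_per_s`` and
    on death it is immediately replaced by a freshly sampled filament, so the
    expected filament count is constant and frame-to-frame decorrelation
    reflects turnover only.  The clean summed canvas is clipped to [0, 1],
    multiplied by exp(-bleach_rate_per_frame * t), Gaussian noise of sd
    ``noise_sd`` is added, and the result is clipped to [0, 1] again.

    Returns the movie as an :class:`~pavactin.preprocess.ImageStack` together
    with per-filament ground truth (birth/death frames, bundling flags and the
    raw lifetime draws).
    """
    root = np.random.SeedSequence(params.seed)
    noise_ss, *slot_ss = root.spawn(params.n_filaments + 1)
    dt = params.frame_interval_s
    movie_s = params.n_frames * dt

    # event-driven canvas: list of (frame, crop, r0, c0, sign)
    records: list[FilamentRecord] = []
    births: dict[int, list[tuple[np.ndarray, int, int]]] = {}
    deaths: dict[int, list[tuple[np.ndarray, int, int]]] = {}
    for slot, ss in enumerate(slot_ss):
        rng = np.random.Generator(np.random.PCG64(ss))
        t_birth = 0.0
        gen = 0
        while t_birth < movie_s:
            bundled = bool(rng.random() < params.bundled_fraction)
            path = _sample_path(rng, params)
            if params.turnover_rate_per_s > 0:
                lifetime = rng.exponential(1.0 / params.turnover_rate_per_s)
            else:
                lifetime = np.inf
            birth_f = int(np.ceil(t_birth / dt - 1e-9))
            t_death = t_birth + lifetime
            death_f = params.n_frames if np.isinf(t_death) else int(
                np.ceil(t_death / dt - 1e-9)
            )
            death_f = max(death_f, birth_f + 1)
            amp = _BASE_PEAK * (params.bundling_factor if bundled else 1.0)
            if birth_f < params.n_frames:
                crop, r0, c0 = _render_filament(path, amp, params)
                births.setdefault(birth_f, []).append((crop, r0, c0))
                if death_f < params.n_frames:
                    deaths.setdefault(death_f, []).append((crop, r0, c0))
            records.append(
                FilamentRecord(slot, gen, birth_f, death_f, bundled, float(lifetime))
            )
            t_birth = t_death
            gen += 1

    noise_rng = np.random.Generator(np.random.PCG64(noise_ss))
    canvas = np.zeros((params.height_px, params.width_px))
    frames = np.empty((params.n_frames, params.height_px, params.width_px))
    for t in range(params.n_frames):
        for crop, r0, c0 in deaths.get(t, ()):
            canvas[r0 : r0 + crop.shape[0], c0 : c0 + crop.shape[1]] -= crop
        for crop, r0, c0 in births.get(t, ()):
            canvas[r0 : r0 + crop.shape[0], c0 : c0 + crop.shape[1]] += crop
        frame = np.clip(canvas, 0.0, 1.0) * np.exp(-params.bleach_rate_per_frame * t)
        if params.noise_sd > 0:
            frame = frame + noise_rng.normal(0.0, params.noise_sd, frame.shape)
        frames[t] = np.clip(frame, 0.0, 1.0)

    stack = ImageStack(frames, params.pixel_size_um, params.frame_interval_s)
    return stack, MovieGroundTruth(params, records)


# ---------------------------------------------------------------------------
# Lobed-cell mosaic
# ---------------------------------------------------------------------------

def lobed_polygon(
    radius_um: float,
    lobe_count: int,
    lobe_amplitude: float,
    phase: float,
    center_um: tuple[float, float] = (0.0, 0.0),
    n_vertices: int = 720,
) -> np.ndarray:
    """Analytic boundary polygon of one lobed cell, (x, y) vertices in um."""
    theta = np.linspace(0.0, 2 * np.pi, n_vertices, endpoint=False)
    r = radius_um * (1.0 + lobe_amplitude * np.sin(lobe_count * theta + phase))
    x = center_um[0] + r * np.cos(theta)
    y = center_um[1] + r * np.sin(theta)
    return np.column_stack([x, y])


def generate_lobed_cells(
    params: LobedCellParams,
) -> tuple[np.ndarray, MosaicGroundTruth]:
    """Generate a non-overlapping mosaic of lobed cells as a label image.

    Cells are placed on a square grid with a pitch large enough that the
    maximal boundary radius of adjacent cells cannot touch, so labels never
    overlap by construction.  Returns the uint16 label mask (background 0,
    cells 1..n) and the ground truth holding each cell's exact polygon.
    """
    root = np.random.SeedSequence(params.seed)
    cell_ss = root.spawn(params.n_cells)
    px = params.pixel_size_um
    r_max_um = params.base_radius_um * (1 + params.radius_jitter) * (
        1 + params.lobe_amplitude
    )
    pitch_um = 2 * r_max_um + 4 * px  # >= 4 px clearance between cells
    n_cols = int(np.ceil(np.sqrt(params.n_cells)))
    n_rows = int(np.ceil(params.n_cells / n_cols))
    width_um = n_cols * pitch_um
    height_um = n_rows * pitch_um
    shape = (int(np.ceil(height_um / px)), int(np.ceil(width_um / px)))
    mask = np.zeros(shape, dtype=np.uint16)

    polygons: list[np.ndarray] = []
    labels: list[int] = []
    for i, ss in enumerate(cell_ss):
        rng = np.random.Generator(np.random.PCG64(ss))
        phase = rng.uniform(0.0, 2 * np.pi)
        radius = params.base_radius_um * rng.uniform(
            1 - params.radius_jitter, 1 + params.radius_jitter
        )
        row, col = divmod(i, n_cols)
        center = ((col + 0.5) * pitch_um, (row + 0.5) * pitch_um)
        poly = lobed_polygon(
            radius, params.lobe_count, params.lobe_amplitude, phase, center,
            params.n_vertices,
        )
        rr, cc = draw_polygon(poly[:, 1] / px, poly[:, 0] / px, shape)
        if np.any(mask[rr, cc]):  # guaranteed not to happen by construction
            raise RuntimeError("cell rasterization overlapped an existing cell")
        mask[rr, cc] = i + 1
        polygons.append(poly)
        labels.append(i + 1)

    return mask, MosaicGroundTruth(params, polygons, labels)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def save_movie(
    path: str | Path, stack: ImageStack, truth: MovieGroundTruth
) -> None:
    """Write the movie as multi-page float32 TIFF plus JSON/CSV ground truth."""
    path = Path(path)
    tifffile.imwrite(
        path,
        stack.frames.astype(np.float32),
        imagej=True,
        resolution=(1 / stack.pixel_size_um, 1 / stack.pixel_size_um),
        metadata={"unit": "um", "finterval": stack.frame_interval_s, "axes": "TYX"},
    )
    truth.to_frame().to_csv(path.with_suffix(".truth.csv"), index=False)
    with open(path.with_suffix(".params.json"), "w") as fh:
        json.dump(dataclasses.asdict(truth.params), fh, indent=2)


def save_mosaic(
    path: str | Path, mask: np.ndarray, truth: MosaicGroundTruth
) -> None:
    """Write the label mask as 16-bit TIFF plus JSON params and CSV polygons."""
    path = Path(path)
    px = truth.params.pixel_size_um
    tifffile.imwrite(
        path, mask.astype(np.uint16), resolution=(1 / px, 1 / px)
    )
    rows = []
    for label, poly in zip(truth.labels, truth.polygons_um):
        for j, (x, y) in enumerate(poly):
            rows.append({"label": label, "vertex": j, "x_um": x, "y_um": y})
    pd.DataFrame(rows).to_csv(path.with_suffix(".truth.csv"), index=False)
    with open(path.with_suffix(".params.json"), "w") as fh:
        json.dump(dataclasses.asdict(truth.params), fh, indent=2)
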