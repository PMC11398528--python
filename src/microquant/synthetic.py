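"""Synthetic yeast fluorescence scenes with exact ground truth.

The generator emulates the two imaging products the quantification
pipelines consume:

* **LD scenes** — BODIPY/MDH-type fields: dim cytoplasmic haze inside
  quasi-circular cells, bright quasi-circular lipid-droplet spots (2–20 px
  radius), a smooth background gradient, Poisson shot noise and Gaussian
  read noise, rendered on a display-scaled 8-bit grid.
* **ER scenes** — Sec63-type mid-section z-stacks at super-resolution
  pixel pitch: a bright perinuclear ring, cortical rim arcs, and thin
  (1–2 px) tubules connecting them, distributed over three central
  z-slices with out-of-focus attenuation.
* **Time-lapse series** — an LD-like field whose fluorescent signal
  decays as exp(−k·t) across frames while the camera offset stays fixed;
  the brightest droplets slightly exceed the 8-bit range at t = 0
  (the usual exposure choice for a 2-h movie) and clip at 255.

Every scene is fully determined by its seed.  Independent random
sub-streams are used per object class (cells, droplets, tubules, noise)
so that, e.g., increasing the tubule count does not move the cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage as ndi

from .image import Image2D, TimeSeries, ZStack

__all__ = [
    "LDSceneParams", "ERSceneParams", "TimelapseParams", "GroundTruth",
    "make_ld_scene", "make_er_scene", "make_timelapse",
]

# sub-stream keys: changing one object class never reseeds another
_KEY_CELLS, _KEY_LDS, _KEY_NOISE, _KEY_TUBULES, _KEY_ER, _KEY_ARTIFACT = range(6)


def _rng(seed: int, *keys: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), *keys])


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

@dataclass
class LDSceneParams:
    """Scene layout and camera model for a BODIPY/MDH-type LD field.

    Geometry defaults follow the imaging setup the pipelines target:
    0.065 µm widefield pixels, cells of ~2 µm radius, droplets of 3–8 px
    radius.  Noise levels give a spot SNR of ≈ 15 (amplitude over the
    shot+read noise standard deviation at the spot).
    """

    shape: Tuple[int, int] = (448, 448)
    pixel_size: float = 0.065          # µm/px, widefield
    n_cells: int = 10
    cell_radius_um: Tuple[float, float] = (1.8, 2.4)
    lds_per_cell: Tuple[int, int] = (2, 5)      # inclusive range
    ld_radius_px: Tuple[float, float] = (3.0, 8.0)
    ld_amplitude: float = 190.0        # above the cytoplasmic haze
    cell_haze: float = 30.0
    background: float = 20.0
    gradient_amplitude: float = 8.0
    psf_sigma_px: float = 1.2
    poisson_gain: float = 2.0          # photons per grey level
    read_noise_sd: float = 3.0
    ld_min_separation_px: float = 3.0
    # contract fixtures: structures that exercise specific pipeline gates
    n_touching_pairs: int = 0          # fused droplet pairs (watershed gate)
    bar_artifact: bool = False         # elongated 2×30 bar (circularity gate)
    vacuole: bool = False              # dim hole in the haze (fill-holes case)

    def __post_init__(self) -> None:
        if self.ld_amplitude < 0 or self.cell_haze < 0 or self.background < 0:
            raise ValueError("amplitudes must be >= 0")
        if self.n_cells < 1:
            raise ValueError("need at least one cell")


@dataclass
class ERSceneParams:
    """Scene layout for a Sec63-type mid-section ER z-stack (super-res)."""

    shape: Tuple[int, int] = (512, 512)
    pixel_size: float = 0.031          # µm/px, super-resolution
    n_cells: int = 3
    cell_radius_um: Tuple[float, float] = (1.8, 2.3)
    nuclear_radius_frac: float = 0.35  # perinuclear ring radius / cell radius
    ring_width_px: float = 3.0
    ring_amplitude: float = 200.0
    cortical_width_px: float = 3.0
    cortical_coverage: float = 0.65    # fraction of the perimeter with rim
    cortical_amplitude: float = 170.0
    n_tubules: int = 6
    tubule_amplitude: float = 45.0     # dim: near the coarse-mask threshold
    tubule_width_px: Tuple[int, int] = (1, 2)
    background: float = 12.0
    cell_haze: float = 10.0
    psf_sigma_px: float = 1.0
    defocus_sigma_px: float = 1.6      # extra blur on the off-centre slices
    defocus_attenuation: float = 0.55
    n_slices: int = 3
    slice_spacing_um: float = 0.316
    poisson_gain: float = 2.0
    read_noise_sd: float = 3.0


@dataclass
class TimelapseParams:
    """A bleaching LD-like movie: 24 frames at 5-min intervals by default."""

    shape: Tuple[int, int] = (256, 256)
    pixel_size: float = 0.065
    n_cells: int = 4
    cell_radius_um: Tuple[float, float] = (1.8, 2.2)
    lds_per_cell: Tuple[int, int] = (2, 4)
    ld_radius_px: Tuple[float, float] = (3.5, 5.5)
    ld_amplitude: float = 500.0        # ideal peak >> 255: early frames clip
    cell_haze: float = 12.0
    background: float = 12.0           # camera offset — does not bleach
    psf_sigma_px: float = 1.2
    poisson_gain: float = 2.0
    read_noise_sd: float = 3.0
    bleach_k_per_min: float = 0.02
    n_frames: int = 24
    frame_interval_min: float = 5.0
    ld_min_separation_px: float = 3.0


@dataclass
class GroundTruth:
    """Exact truth accompanying a rendered scene."""

    cell_labels: np.ndarray
    ld_area_px2_per_cell: Dict[int, float] = field(default_factory=dict)
    ld_disks: List[Tuple[float, float, float, int]] = field(default_factory=list)
    # (cx, cy, radius_px, cell_id) per droplet
    er_mask: Optional[np.ndarray] = None
    #: interior of the perinuclear ring
    nuclear_interior_mask: Optional[np.ndarray] = None
    #: non-ER regions enclosed by closed ER circuits (nuclear interior and
    #: tubule/ring/rim-bounded cytoplasmic pockets).  Hole filling floods
    #: them, so this is the canonical exclusion mask — the scripted
    #: stand-in for the manual artifact-removal step of a cortical-ER
    #: measurement, in which an annotator marks enclosed lumen/cytoplasm.
    enclosed_pocket_mask: Optional[np.ndarray] = None
    er_fraction_per_cell: Dict[int, float] = field(default_factory=dict)
    bleach_k_per_min: Optional[float] = None
    foreground_mask: Optional[np.ndarray] = None
    background_mask: Optional[np.ndarray] = None

    def to_jsonable(self) -> dict:
        out = {
            "ld_area_px2_per_cell": {str(k): v for k, v in self.ld_area_px2_per_cell.items()},
            "ld_disks": [list(map(float, d[:3])) + [int(d[3])] for d in self.ld_disks],
            "er_fraction_per_cell": {str(k): v for k, v in self.er_fraction_per_cell.items()},
            "bleach_k_per_min": self.bleach_k_per_min,
            "n_cells": int(self.cell_labels.max()),
        }
        return out


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def _place_cells(rng: np.random.Generator, shape: Tuple[int, int],
                 n_cells: int, radius_px: Tuple[float, float],
                 max_tries: int = 4000):
    """Sample non-overlapping cell centres/radii; error when space runs out."""
    h, w = shape
    placed: List[Tuple[float, float, float]] = []
    tries = 0
    while len(placed) < n_cells:
        if tries >= max_tries:
            raise RuntimeError(
                f"could not place {n_cells} non-overlapping cells in {shape} "
                f"after {max_tries} tries"
            )
        tries += 1
        r = rng.uniform(*radius_px)
        if r + 2 >= w - r - 2 or r + 2 >= h - r - 2:
            continue  # this radius cannot fit in the field at all
        cx = rng.uniform(r + 2, w - r - 2)
        cy = rng.uniform(r + 2, h - r - 2)
        if all(math.hypot(cx - x, cy - y) > r + pr + 2 for x, y, pr in placed):
            placed.append((cx, cy, r))
    return placed


def _disk_mask(shape: Tuple[int, int], cx: float, cy: float, r: float) -> np.ndarray:
    h, w = shape
    yy, xx = np.ogrid[:h, :w]
    return (xx - cx) ** 2 + (yy - cy) ** 2 <= r * r


def _cell_label_map(shape, cells) -> np.ndarray:
    labels = np.zeros(shape, dtype=np.int32)
    for i, (cx, cy, r) in enumerate(cells, start=1):
        labels[_disk_mask(shape, cx, cy, r)] = i
    return labels


def _camera(ideal: np.ndarray, rng: np.random.Generator, gain: float,
            read_sd: float, clip_hi: float = 255.0) -> np.ndarray:
    """Poisson shot noise on a photon proxy, then Gaussian read noise,
    then 8-bit quantisation with saturation."""
    photons = rng.poisson(np.clip(ideal, 0, None) * gain) / gain
    noisy = photons + rng.normal(0.0, read_sd, size=ideal.shape)
    return np.clip(np.round(noisy), 0.0, clip_hi)


# ---------------------------------------------------------------------------
# LD scenes
# ---------------------------------------------------------------------------

def _sample_lds(rng: np.random.Generator, params: LDSceneParams, cells,
                shape) -> List[Tuple[float, float, float, int]]:
    disks: List[Tuple[float, float, float, int]] = []
    lo_n, hi_n = params.lds_per_cell
    sep = params.ld_min_separation_px
    for cell_id, (ccx, ccy, cr) in enumerate(cells, start=1):
        n_ld = int(rng.integers(lo_n, hi_n + 1))
        cell_disks: List[Tuple[float, float, float]] = []
        for _ in range(n_ld):
            for _try in range(500):
                r = rng.uniform(*params.ld_radius_px)
                if r + 2 >= cr:
                    continue
                rho = rng.uniform(0, cr - r - 2)
                phi = rng.uniform(0, 2 * np.pi)
                x, y = ccx + rho * np.cos(phi), ccy + rho * np.sin(phi)
                if all(math.hypot(x - px, y - py) > r + pr + sep
                       for px, py, pr in cell_disks):
                    cell_disks.append((x, y, r))
                    break
            # if a droplet cannot be placed it is dropped — the truth table
            # only ever records what was actually rendered
        disks.extend((x, y, r, cell_id) for x, y, r in cell_disks)
    return disks


def _ld_ideal_and_truth(params: LDSceneParams, seed: int):
    shape = params.shape
    r_px = tuple(r / params.pixel_size for r in params.cell_radius_um)
    cells = _place_cells(_rng(seed, _KEY_CELLS), shape, params.n_cells, r_px)
    cell_labels = _cell_label_map(shape, cells)
    disks = _sample_lds(_rng(seed, _KEY_LDS), params, cells, shape)

    art_rng = _rng(seed, _KEY_ARTIFACT)
    ideal = np.full(shape, float(params.background))
    gy, gx = art_rng.uniform(-1, 1, 2)
    norm = max(abs(gx) + abs(gy), 1e-9)
    yy, xx = np.mgrid[:shape[0], :shape[1]]
    ideal += params.gradient_amplitude * (
        0.5 + (gx * (xx / shape[1] - 0.5) + gy * (yy / shape[0] - 0.5)) / norm
    )
    haze = np.where(cell_labels > 0, float(params.cell_haze), 0.0)

    if params.vacuole and cells:
        cx, cy, cr = cells[0]
        haze[_disk_mask(shape, cx + cr * 0.3, cy, cr * 0.35)] *= 0.3

    truth_areas = {i: 0.0 for i in range(1, len(cells) + 1)}
    spot = np.zeros(shape)
    for x, y, r, cid in disks:
        dm = _disk_mask(shape, x, y, r)
        spot[dm] = params.ld_amplitude
        truth_areas[cid] += float(dm.sum())

    if params.n_touching_pairs and cells:
        # fused droplet pairs in the last cells: centres closer than 2r
        for k in range(min(params.n_touching_pairs, len(cells))):
            ccx, ccy, cr = cells[-1 - k]
            r = 6.0
            d = 10.0  # centre separation < 2r: the pair overlaps
            m = _disk_mask(shape, ccx - d / 2, ccy, r) | _disk_mask(shape, ccx + d / 2, ccy, r)
            spot[m] = params.ld_amplitude
            cid = len(cells) - k
            truth_areas[cid] += float(m.sum())

    if params.bar_artifact:
        # bright elongated bar outside every cell (circularity-gate probe)
        y0, x0 = 6, 6
        spot[y0:y0 + 2, x0:x0 + 30] = params.ld_amplitude

    ideal = ideal + haze + spot
    if params.psf_sigma_px > 0:
        ideal = ndi.gaussian_filter(ideal, params.psf_sigma_px, mode="reflect")
    truth = GroundTruth(cell_labels=cell_labels,
                        ld_area_px2_per_cell=truth_areas, ld_disks=disks,
                        foreground_mask=spot > 0,
                        background_mask=cell_labels == 0)
    return ideal, truth


def make_ld_scene(params: Optional[LDSceneParams] = None,
                  seed: int = 0) -> Tuple[Image2D, GroundTruth]:
    """Render one LD field and its exact per-cell droplet areas."""
    params = params or LDSceneParams()
    ideal, truth = _ld_ideal_and_truth(params, seed)
    pix = _camera(ideal, _rng(seed, _KEY_NOISE), params.poisson_gain,
                  params.read_noise_sd)
    img = Image2D(pix, pixel_size=params.pixel_size, bit_depth_hint="8bit")
    return img, truth


# ---------------------------------------------------------------------------
# ER scenes
# ---------------------------------------------------------------------------

def _band_mask(shape, cx, cy, radius, width) -> np.ndarray:
    h, w = shape
    yy, xx = np.ogrid[:h, :w]
    d = np.sqrt((xx - cx) ** 2 + (yy - cy) ** 2)
    return np.abs(d - radius) <= width / 2.0


def _arc_mask(shape, cx, cy, radius, width, arcs) -> np.ndarray:
    h, w = shape
    yy, xx = np.mgrid[:h, :w]
    d = np.sqrt((xx - cx) ** 2 + (yy - cy) ** 2)
    ang = np.mod(np.arctan2(yy - cy, xx - cx), 2 * np.pi)
    band = np.abs(d - radius) <= width / 2.0
    in_arc = np.zeros(shape, dtype=bool)
    for a0, a1 in arcs:
        if a1 <= 2 * np.pi:
            in_arc |= (ang >= a0) & (ang <= a1)
        else:
            in_arc |= (ang >= a0) | (ang <= a1 - 2 * np.pi)
    return band & in_arc


def _tubule_mask(shape, p0, p1, ctrl, width, n_samples: int = 400) -> np.ndarray:
    """Rasterise a quadratic Bézier curve of width 1–2 px."""
    t = np.linspace(0.0, 1.0, n_samples)
    x = (1 - t) ** 2 * p0[0] + 2 * (1 - t) * t * ctrl[0] + t ** 2 * p1[0]
    y = (1 - t) ** 2 * p0[1] + 2 * (1 - t) * t * ctrl[1] + t ** 2 * p1[1]
    xi = np.clip(np.round(x).astype(int), 0, shape[1] - 1)
    yi = np.clip(np.round(y).astype(int), 0, shape[0] - 1)
    m = np.zeros(shape, dtype=bool)
    m[yi, xi] = True
    if width >= 2:
        m = ndi.binary_dilation(m, structure=ndi.generate_binary_structure(2, 1))
    return m


def _er_truth(params: ERSceneParams, seed: int):
    shape = params.shape
    r_px = tuple(r / params.pixel_size for r in params.cell_radius_um)
    cells = _place_cells(_rng(seed, _KEY_CELLS), shape, params.n_cells, r_px)
    cell_labels = _cell_label_map(shape, cells)

    er_rng = _rng(seed, _KEY_ER)
    amp = np.zeros(shape)
    er_mask = np.zeros(shape, dtype=bool)
    nuclear_interior = np.zeros(shape, dtype=bool)
    tubule_anchor = []
    for cid, (cx, cy, cr) in enumerate(cells, start=1):
        rn = params.nuclear_radius_frac * cr
        ring = _band_mask(shape, cx, cy, rn, params.ring_width_px)
        nuclear_interior |= _disk_mask(shape, cx, cy, rn - params.ring_width_px / 2.0 - 1.0)
        # cortical rim: random arcs covering ~coverage of the perimeter
        arcs = []
        covered = 0.0
        while covered < params.cortical_coverage * 2 * np.pi:
            a0 = er_rng.uniform(0, 2 * np.pi)
            length = er_rng.uniform(0.4, 1.4)
            arcs.append((a0, a0 + length))
            covered += length
        rim = _arc_mask(shape, cx, cy, cr - params.cortical_width_px, params.cortical_width_px, arcs)
        er_mask |= ring | rim
        amp[ring] = np.maximum(amp[ring], params.ring_amplitude)
        amp[rim] = np.maximum(amp[rim], params.cortical_amplitude)
        tubule_anchor.append((cid, cx, cy, rn, cr))

    # tubules: each drawn from its own child stream so that a scene with
    # n tubules is a strict superset of the same scene with fewer
    for i in range(params.n_tubules):
        trng = _rng(seed, _KEY_TUBULES, i)
        cid, cx, cy, rn, cr = tubule_anchor[i % len(tubule_anchor)]
        a = trng.uniform(0, 2 * np.pi)
        b = a + trng.uniform(-0.9, 0.9)
        p0 = (cx + rn * np.cos(a), cy + rn * np.sin(a))
        p1 = (cx + (cr - params.cortical_width_px) * np.cos(b),
              cy + (cr - params.cortical_width_px) * np.sin(b))
        mid = ((p0[0] + p1[0]) / 2, (p0[1] + p1[1]) / 2)
        bend = trng.uniform(0.15, 0.45) * cr
        phi = trng.uniform(0, 2 * np.pi)
        ctrl = (mid[0] + bend * np.cos(phi), mid[1] + bend * np.sin(phi))
        width = int(trng.integers(params.tubule_width_px[0], params.tubule_width_px[1] + 1))
        tm = _tubule_mask(shape, p0, p1, ctrl, width) & (cell_labels == cid)
        er_mask |= tm
        amp[tm] = np.maximum(amp[tm], params.tubule_amplitude)

    fractions = {}
    for cid in range(1, len(cells) + 1):
        cell_px = cell_labels == cid
        fractions[cid] = float((er_mask & cell_px).sum() / cell_px.sum())
    # regions fully enclosed by true ER circuits, slightly dilated so that
    # the detected (blurred) boundaries still enclose them
    closed = ndi.binary_dilation(er_mask, iterations=2)
    pockets = (ndi.binary_fill_holes(closed) & ~closed) | nuclear_interior
    truth = GroundTruth(cell_labels=cell_labels, er_mask=er_mask,
                        nuclear_interior_mask=nuclear_interior,
                        enclosed_pocket_mask=pockets,
                        er_fraction_per_cell=fractions,
                        foreground_mask=er_mask,
                        background_mask=cell_labels == 0)
    return amp, truth


def make_er_scene(params: Optional[ERSceneParams] = None,
                  seed: int = 0) -> Tuple[ZStack, GroundTruth]:
    """Render a 3-slice (by default) mid-section ER stack plus truth mask."""
    params = params or ERSceneParams()
    amp, truth = _er_truth(params, seed)
    haze = np.where(truth.cell_labels > 0, params.cell_haze, 0.0)
    noise_rng = _rng(seed, _KEY_NOISE)
    centre = (params.n_slices - 1) // 2
    slices = []
    for i in range(params.n_slices):
        off = abs(i - centre)
        attenuation = params.defocus_attenuation ** off
        sigma = params.psf_sigma_px + params.defocus_sigma_px * off
        ideal = params.background + ndi.gaussian_filter(
            haze + amp * attenuation, sigma, mode="reflect")
        pix = _camera(ideal, noise_rng, params.poisson_gain, params.read_noise_sd)
        slices.append(Image2D(pix, pixel_size=params.pixel_size, bit_depth_hint="8bit"))
    return ZStack(slices, slice_spacing_um=params.slice_spacing_um), truth


# ---------------------------------------------------------------------------
# time-lapse
# ---------------------------------------------------------------------------

def make_timelapse(params: Optional[TimelapseParams] = None,
                   seed: int = 0) -> Tuple[TimeSeries, GroundTruth]:
    """Render a bleaching movie: fluorescence scales by exp(−k·t) pre-noise.

    The camera offset (``background``) does not bleach; the cytoplasmic
    haze and droplet signal do.  Frames are display-scaled 8-bit, and the
    droplet peaks slightly exceed the range at t = 0 so early frames clip.
    """
    params = params or TimelapseParams()
    ld_like = LDSceneParams(
        shape=params.shape, pixel_size=params.pixel_size, n_cells=params.n_cells,
        cell_radius_um=params.cell_radius_um, lds_per_cell=params.lds_per_cell,
        ld_radius_px=params.ld_radius_px, ld_amplitude=params.ld_amplitude,
        cell_haze=params.cell_haze, background=0.0, gradient_amplitude=0.0,
        psf_sigma_px=0.0, ld_min_separation_px=params.ld_min_separation_px,
    )
    fluor, truth = _ld_ideal_and_truth(ld_like, seed)  # unblurred fluorophores
    if params.psf_sigma_px > 0:
        fluor = ndi.gaussian_filter(fluor, params.psf_sigma_px, mode="reflect")
    noise_rng = _rng(seed, _KEY_NOISE)
    frames = []
    for f in range(params.n_frames):
        t = f * params.frame_interval_min
        ideal = params.background + fluor * math.exp(-params.bleach_k_per_min * t)
        pix = _camera(ideal, noise_rng, params.poisson_gain, params.read_noise_sd)
        frames.append(Image2D(pix, pixel_size=params.pixel_size, bit_depth_hint="8bit"))
    truth = replace(truth, bleach_k_per_min=params.bleach_k_per_min)
    series = TimeSeries(frames, frame_interval_min=params.frame_interval_min)
    return series, truth
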