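"""Synthetic three-channel confocal stacks with exact ground truth.

The generator emulates what the quantification pipeline assumes about a
dye-stained live cell imaged as a z-stack:

* an ellipsoidal cell body (Calcein-like channel, optionally with internal
  "vacuole" cavities to exercise hole filling) containing an ellipsoidal
  nucleus (Hoechst-like channel);
* tens to hundreds of mitochondrial objects — curvature-bounded random-walk
  tubules plus a globular fraction of compact spheres — confined to
  the cytoplasm, each carrying an intensity drawn around ``potential_mean``
  (a membrane-potential proxy, as for TMRM);
* a diffuse additive background (mimicking the residual background of
  JC-1/CMXRos staining), isotropic-in-µm Gaussian PSF blur, then
  photon-limited Poisson noise plus Gaussian read noise;
* repetitive-imaging series: the same field re-rendered with a per-
  acquisition multiplicative intensity decay and fresh noise, optionally
  with rod-to-globular fragmentation from the sixth acquisition on.

Objects are painted in physical units and voxelized on the anisotropic
grid, so geometry handling is exercised for real. Planted objects that
touch are merged in the ground truth, mirroring the definition of a
mitochondrial object as one connected region.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .photostability import IntensitySeries
from .segmentation import LabelMap, label_objects, measure_objects, BinaryMask
from .stack_io import ChannelSet, RoiRect, VoxelGrid


@dataclass
class SimCellParams:
    """Geometry, content and noise model of one synthetic cell.

    Lengths in µm, intensities in camera units. The defaults describe a
    test-scale mesoangioblast-like cell: a 32x128x128 stack at the 20x
    acquisition geometry (0.35 x 0.325 x 0.325 µm voxels), 30 mitochondrial
    objects kept farther apart than the top-hat element so that object
    counts are recoverable exactly.
    """

    shape: tuple[int, int, int] = (32, 128, 128)
    geometry: tuple[float, float, float] = (0.35, 0.325, 0.325)
    n_mito: int = 30
    mito_radius_um: float = 0.5
    mito_length_um: tuple[float, float] = (2.0, 10.0)
    fraction_globular: float = 0.2
    min_separation_um: float = 1.2  # surface-to-surface distance between objects
    potential_mean: float = 600.0
    potential_sd: float = 60.0
    nucleus_radii_um: tuple[float, float, float] = (2.0, 4.5, 4.5)
    cell_radii_um: tuple[float, float, float] = (4.5, 15.0, 15.0)
    background_level: float = 20.0
    gaussian_sd: float = 3.0
    poisson_scaling: float = 0.5  # photons per intensity unit
    psf_sigma_um: float = 0.15
    nucleus_intensity: float = 500.0
    cell_intensity: float = 300.0
    n_vacuoles: int = 2
    vacuole_radius_um: float = 1.2
    step_um: float = 0.2
    curvature: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mito < 0:
            raise ValueError("n_mito must be >= 0")
        if self.mito_radius_um <= 0 or min(self.nucleus_radii_um) <= 0 or min(self.cell_radii_um) <= 0:
            raise ValueError("radii must be > 0")
        if not 0 <= self.fraction_globular <= 1:
            raise ValueError("fraction_globular in [0, 1]")

    @property
    def voxel_volume_um3(self) -> float:
        dz, dy, dx = self.geometry
        return dz * dy * dx


@dataclass
class SimSeriesParams:
    """Repetitive-imaging series of one field of view."""

    cell: SimCellParams = field(default_factory=SimCellParams)
    n_acquisitions: int = 10
    decay_slope: float = -0.14  # relative intensity change over the whole series
    between_roi_sd: float = 0.0  # SD of the smooth per-acquisition gain field
    morphology_change: bool = False
    fragment_fraction: float = 0.5  # tubules fragmented when morphology_change

    def __post_init__(self) -> None:
        if self.n_acquisitions < 2:
            raise ValueError("need >= 2 acquisitions")
        if self.decay_slope < -1:
            raise ValueError("decay_slope < -1 would drive intensity negative")


@dataclass
class GroundTruth:
    """Exact truth for one simulated cell (or series).

    ``label_volume`` labels the planted voxel sets after merging touching
    objects (26-connectivity); ``per_object`` carries voxel counts, volumes
    and the planted mean intensities of the merged objects.
    """

    label_volume: LabelMap
    per_object: pd.DataFrame
    nucleus_volume_um3: float
    cell_volume_um3: float
    decay_factors: Optional[np.ndarray] = None

    @property
    def n_objects(self) -> int:
        return self.label_volume.n_labels

    @property
    def total_mito_volume_um3(self) -> float:
        return float(self.per_object["volume_um3"].sum()) if len(self.per_object) else 0.0


# ---------------------------------------------------------------------------
# geometry helpers


def _voxel_centers_um(shape, geometry):
    dz, dy, dx = geometry
    z = np.arange(shape[0]) * dz
    y = np.arange(shape[1]) * dy
    x = np.arange(shape[2]) * dx
    return z, y, x


def _ellipsoid_mask(shape, geometry, center_um, radii_um) -> np.ndarray:
    z, y, x = _voxel_centers_um(shape, geometry)
    cz, cy, cx = center_um
    rz, ry, rx = radii_um
    return (
        ((z[:, None, None] - cz) / rz) ** 2
        + ((y[None, :, None] - cy) / ry) ** 2
        + ((x[None, None, :] - cx) / rx) ** 2
    ) <= 1.0


def _inside_ellipsoid(p, center, radii, margin=0.0) -> bool:
    r = [max(a + margin, 1e-6) for a in radii]
    return sum(((pi - ci) / ri) ** 2 for pi, ci, ri in zip(p, center, r)) <= 1.0


_BALL_CACHE: dict = {}


def _ball_offsets(radius_um: float, geometry) -> np.ndarray:
    """Voxel-index offsets of an anisotropic ball of physical radius."""
    key = (round(radius_um, 6), tuple(round(g, 6) for g in geometry))
    if key not in _BALL_CACHE:
        dz, dy, dx = geometry
        hz, hy, hx = (int(np.ceil(radius_um / d)) for d in geometry)
        oz, oy, ox = np.mgrid[-hz : hz + 1, -hy : hy + 1, -hx : hx + 1]
        keep = (oz * dz) ** 2 + (oy * dy) ** 2 + (ox * dx) ** 2 <= radius_um**2 + 1e-9
        _BALL_CACHE[key] = np.stack([oz[keep], oy[keep], ox[keep]], axis=1)
    return _BALL_CACHE[key]


def _paint_points(points_um, radius_um, shape, geometry) -> np.ndarray:
    """Flat voxel indices of the union of balls stamped at each point."""
    offs = _ball_offsets(radius_um, geometry)
    d = np.asarray(geometry)
    centers = np.rint(np.asarray(points_um) / d).astype(np.int64)
    idx = centers[:, None, :] + offs[None, :, :]
    idx = idx.reshape(-1, 3)
    ok = np.all((idx >= 0) & (idx < np.asarray(shape)), axis=1)
    idx = idx[ok]
    flat = np.ravel_multi_index((idx[:, 0], idx[:, 1], idx[:, 2]), shape)
    return np.unique(flat)


# ---------------------------------------------------------------------------
# object placement


class _PlacementError(RuntimeError):
    pass


def _walk_tubule(
    rng: np.random.Generator,
    params: SimCellParams,
    center: np.ndarray,
    length_um: float,
    occupied: Optional[cKDTree],
    min_dist: float,
) -> Optional[np.ndarray]:
    """One curvature-bounded random walk inside the cytoplasm, avoiding
    previously placed objects; None if the walk gets stuck."""
    margin = params.mito_radius_um + 0.35  # 0.35 covers stamp quantization

    def valid(p):
        if not _inside_ellipsoid(p, center, params.cell_radii_um, -margin):
            return False
        if _inside_ellipsoid(p, center, params.nucleus_radii_um, margin):
            return False
        if occupied is not None and min_dist > 0:
            if occupied.query(p, k=1)[0] < min_dist:
                return False
        return True

    for _ in range(60):
        start = center + (rng.random(3) * 2 - 1) * np.asarray(params.cell_radii_um)
        if valid(start):
            break
    else:
        return None
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    pts = [start]
    n_steps = max(int(length_um / params.step_um), 1)
    for _ in range(n_steps):
        for _retry in range(12):
            bend = direction + params.curvature * rng.normal(size=3)
            bend /= np.linalg.norm(bend)
            p = pts[-1] + params.step_um * bend
            if valid(p):
                direction = bend
                pts.append(p)
                break
        else:
            return None
    return np.asarray(pts)


def _place_objects(rng: np.random.Generator, params: SimCellParams):
    """Place tubules and globules; returns (list of flat-index arrays,
    list of is_globular flags, list of centerline point arrays)."""
    shape, geometry = params.shape, params.geometry
    dz, dy, dx = geometry
    center = np.array([(shape[0] - 1) * dz / 2, (shape[1] - 1) * dy / 2, (shape[2] - 1) * dx / 2])
    n_glob = int(round(params.fraction_globular * params.n_mito))
    kinds = ["glob"] * n_glob + ["tube"] * (params.n_mito - n_glob)
    rng.shuffle(kinds)

    all_points: list[np.ndarray] = []
    voxel_sets, flags, centerlines = [], [], []
    tree: Optional[cKDTree] = None
    min_dist = params.min_separation_um + 2 * params.mito_radius_um if params.min_separation_um > 0 else 0.0

    for kind in kinds:
        length = rng.uniform(*params.mito_length_um)
        placed = False
        for _attempt in range(400):
            if kind == "tube":
                pts = _walk_tubule(rng, params, center, length, tree, min_dist)
                radius = params.mito_radius_um
            else:
                # fragmented globular mitochondrion: a compact sphere somewhat
                # thicker than a tubule, kept below the top-hat element scale
                radius = rng.uniform(1.0, 1.5) * params.mito_radius_um
                margin = radius + 0.35
                p = center + (rng.random(3) * 2 - 1) * np.asarray(params.cell_radii_um)
                ok = _inside_ellipsoid(p, center, params.cell_radii_um, -margin) and not _inside_ellipsoid(
                    p, center, params.nucleus_radii_um, margin
                )
                if ok and tree is not None and min_dist > 0:
                    extra = radius - params.mito_radius_um
                    ok = tree.query(p, k=1)[0] >= min_dist + max(extra, 0)
                pts = p[None, :] if ok else None
            if pts is None:
                continue
            voxel_sets.append(_paint_points(pts, radius, shape, geometry))
            flags.append(kind == "glob")
            centerlines.append(pts)
            all_points.append(pts)
            if min_dist > 0:
                tree = cKDTree(np.concatenate(all_points))
            placed = True
            break
        if not placed:
            raise _PlacementError(
                f"could not place {params.n_mito} objects of length {params.mito_length_um} µm "
                f"in the cytoplasm; reduce n_mito, object size or min_separation_um"
            )
    return voxel_sets, flags, centerlines, center


# ---------------------------------------------------------------------------
# rendering


def _blur_sigma_vox(params: SimCellParams):
    return tuple(params.psf_sigma_um / d for d in params.geometry)


def _render(clean: np.ndarray, params: SimCellParams, rng: np.random.Generator) -> np.ndarray:
    """PSF blur, then Poisson shot noise and Gaussian read noise -> uint16."""
    blurred = ndimage.gaussian_filter(clean, sigma=_blur_sigma_vox(params))
    p = params.poisson_scaling
    noisy = rng.poisson(np.clip(blurred, 0, None) * p) / p
    noisy = noisy + rng.normal(0.0, params.gaussian_sd, size=noisy.shape)
    return np.clip(np.rint(noisy), 0, 65535).astype(np.uint16)


def _object_images(voxel_sets, intensities, shape):
    """Clean (pre-blur) object intensity image and union mask."""
    obj_img = np.zeros(shape, dtype=np.float64).ravel()
    mask = np.zeros(int(np.prod(shape)), dtype=bool)
    for vox, inten in zip(voxel_sets, intensities):
        obj_img[vox] += inten
        mask[vox] = True
    return obj_img.reshape(shape), mask.reshape(shape)


def _ground_truth(obj_img, union_mask, params, nucleus_mask, cell_mask) -> GroundTruth:
    dz, dy, dx = params.geometry
    labels = label_objects(BinaryMask(union_mask, dz, dy, dx), connectivity=26)
    records = measure_objects(labels, VoxelGrid(obj_img, dz, dy, dx, channel="mito"))
    per_object = pd.DataFrame(
        {
            "object_id": [r.object_id for r in records],
            "voxel_count": [r.voxel_count for r in records],
            "volume_um3": [r.volume_um3 for r in records],
            "mean_intensity": [r.mean_intensity for r in records],
            "size_class": [r.size_class for r in records],
        }
    )
    voxvol = params.voxel_volume_um3
    return GroundTruth(
        label_volume=labels,
        per_object=per_object,
        nucleus_volume_um3=float(np.count_nonzero(nucleus_mask)) * voxvol,
        cell_volume_um3=float(np.count_nonzero(cell_mask)) * voxvol,
    )


def _cell_nucleus_masks(params: SimCellParams, center):
    nucleus = _ellipsoid_mask(params.shape, params.geometry, center, params.nucleus_radii_um)
    cell = _ellipsoid_mask(params.shape, params.geometry, center, params.cell_radii_um)
    return nucleus, cell


def _vacuole_image(cell_img, params, center, rng):
    """Zero out spherical cavities strictly inside the cell body."""
    out = cell_img.copy().ravel()
    for _ in range(params.n_vacuoles):
        for _try in range(100):
            p = center + (rng.random(3) * 2 - 1) * np.asarray(params.cell_radii_um)
            if _inside_ellipsoid(p, center, params.cell_radii_um, -(params.vacuole_radius_um + 0.6)) and not _inside_ellipsoid(
                p, center, params.nucleus_radii_um, params.vacuole_radius_um
            ):
                vox = _paint_points(p[None, :], params.vacuole_radius_um, params.shape, params.geometry)
                out[vox] = 0.0
                break
    return out.reshape(cell_img.shape)


def simulate_cell(
    params: SimCellParams, rng: Optional[np.random.Generator] = None
) -> tuple[ChannelSet, GroundTruth]:
    """Simulate one three-channel stack with exact ground truth.

    All randomness flows from ``params.seed`` (or the supplied generator):
    identical seeds give bit-identical stacks.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    dz, dy, dx = params.geometry
    voxel_sets, _flags, _lines, center = _place_objects(rng, params) if params.n_mito else ([], [], [], None)
    if center is None:
        shape = params.shape
        center = np.array(
            [(shape[0] - 1) * dz / 2, (shape[1] - 1) * dy / 2, (shape[2] - 1) * dx / 2]
        )
    intensities = np.clip(
        rng.normal(params.potential_mean, params.potential_sd, size=len(voxel_sets)),
        0.05 * params.potential_mean,
        None,
    )
    obj_img, union_mask = _object_images(voxel_sets, intensities, params.shape)
    nucleus_mask, cell_mask = _cell_nucleus_masks(params, center)

    mito = _render(obj_img + params.background_level, params, rng)
    nuc_clean = nucleus_mask * params.nucleus_intensity + 0.5 * params.background_level
    nucleus = _render(nuc_clean, params, rng)
    cell_clean = cell_mask * params.cell_intensity + 0.5 * params.background_level
    cell_clean = _vacuole_image(cell_clean, params, center, rng)
    cell = _render(cell_clean, params, rng)

    channels = ChannelSet(
        mito=VoxelGrid(mito, dz, dy, dx, channel="mito"),
        nucleus=VoxelGrid(nucleus, dz, dy, dx, channel="nucleus"),
        cell=VoxelGrid(cell, dz, dy, dx, channel="cell"),
    )
    truth = _ground_truth(obj_img, union_mask, params, nucleus_mask, cell_mask)
    return channels, truth


# ---------------------------------------------------------------------------
# populations


def mesoangioblast_preset() -> tuple[SimCellParams, dict]:
    """Test-scale mesoangioblast-like cell population.

    Object count is drawn as round(Normal(30, 12)) per cell, the center and
    spread reported for undifferentiated mesoangioblasts; object sizes span
    the <2 / 2-10 µm³ classes (with occasional larger networks) at a size
    scaled to the test field.
    """
    return SimCellParams(), {"n_mito": ("normal_int", 30, 12)}


def recovery_preset() -> SimCellParams:
    """Conditions under which per-object volume recovery is guaranteed.

    Volume fidelity of constant-threshold segmentation requires objects
    resolvable on the voxel grid (tubule radius ~2 voxels here) and nearly
    uniform per-object intensity; this preset plants 15 well-separated
    (>= 2 µm) straight-ish tubules at SNR well above 10. Thinner or dimmer
    objects segment reliably by count but with larger volume bias — see the
    package methods note.
    """
    return SimCellParams(
        n_mito=15,
        mito_radius_um=0.7,
        mito_length_um=(5.0, 10.0),
        fraction_globular=0.0,
        min_separation_um=2.0,
        potential_sd=20.0,
        curvature=0.25,
    )


def myotube_preset() -> tuple[SimCellParams, dict]:
    """Test-scale multi-nucleated myotube-like population.

    Bigger field and cell, Normal(167, 71) objects per cell, and a mean
    per-object volume chosen so the expected total mitochondrial volume is
    ~12x the mesoangioblast preset's, matching the fold change seen upon
    myogenic differentiation. Dense networks are allowed to touch (and hence
    merge into fewer, larger objects), as in real myotubes.
    """
    params = SimCellParams(
        shape=(48, 192, 192),
        n_mito=167,
        mito_radius_um=0.55,
        mito_length_um=(6.0, 25.0),
        min_separation_um=0.0,
        nucleus_radii_um=(2.5, 8.0, 8.0),
        cell_radii_um=(7.5, 29.0, 29.0),
    )
    return params, {"n_mito": ("normal_int", 167, 71)}


def _draw_value(rng, spec_tuple):
    kind = spec_tuple[0]
    if kind == "normal":
        return float(rng.normal(spec_tuple[1], spec_tuple[2]))
    if kind == "normal_int":
        return max(1, int(round(rng.normal(spec_tuple[1], spec_tuple[2]))))
    if kind == "uniform":
        return float(rng.uniform(spec_tuple[1], spec_tuple[2]))
    raise ValueError(f"unknown variability kind {kind!r}")


def simulate_population(
    params: SimCellParams,
    n_cells: int,
    variability: Optional[dict] = None,
    seed: int = 0,
) -> list[tuple[ChannelSet, GroundTruth]]:
    """Simulate a population with per-cell parameters drawn from ``variability``.

    ``variability`` maps SimCellParams field names to ``("normal", mu, sd)``,
    ``("normal_int", mu, sd)`` or ``("uniform", lo, hi)``. Each cell gets a
    deterministic sub-seed derived from ``seed``.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    variability = variability or {}
    children = np.random.SeedSequence(seed).spawn(n_cells)
    out = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        overrides = {name: _draw_value(rng, spec) for name, spec in variability.items()}
        cell_params = replace(params, **overrides)
        out.append(simulate_cell(cell_params, rng=rng))
    return out


# ---------------------------------------------------------------------------
# repetitive-imaging series


def _fragment_objects(voxel_sets, flags, centerlines, params: SimCellParams, fraction, rng):
    """Replace a fraction of the long tubules by 3 spheres of a third the
    volume each, spaced at 10/50/90% of the former centerline (total volume
    preserved). Only tubules >= ~7 µm fragment: shorter ones would leave the
    spheres close enough to re-merge under the PSF, which is not the
    morphology change being emulated."""
    new_sets, new_flags = [], []
    eligible = [
        i
        for i, (g, line) in enumerate(zip(flags, centerlines))
        if not g and len(line) * params.step_um >= 7.0
    ]
    n_frag = int(round(fraction * len(eligible)))
    frag = set(rng.choice(eligible, size=n_frag, replace=False)) if n_frag else set()
    for i, (vox, is_glob, line) in enumerate(zip(voxel_sets, flags, centerlines)):
        if i not in frag:
            new_sets.append(vox)
            new_flags.append(is_glob)
            continue
        vol = len(vox) * params.voxel_volume_um3
        r = (vol / (4 * np.pi)) ** (1 / 3)  # sphere of volume vol/3
        n = len(line)
        anchors = [line[max(int(0.1 * n), 0)], line[n // 2], line[min(int(0.9 * n), n - 1)]]
        pieces = [
            _paint_points(a[None, :], r, params.shape, params.geometry) for a in anchors
        ]
        new_sets.extend(pieces)
        new_flags.extend([True] * 3)
    return new_sets, new_flags


def _gain_field(shape_yx, sd, rng):
    """Smooth multiplicative gain field with approximately the given SD."""
    if sd <= 0:
        return np.ones(shape_yx)
    noise = rng.normal(size=shape_yx)
    smooth = ndimage.gaussian_filter(noise, sigma=min(shape_yx) / 6)
    s = smooth.std()
    if s < 1e-12:
        return np.ones(shape_yx)
    return 1.0 + sd * smooth / s


def simulate_series(
    params: SimSeriesParams,
) -> tuple[list[ChannelSet], GroundTruth]:
    """Simulate consecutive acquisitions of one field of view.

    Acquisition i (time t_i = i/(n-1)) scales the clean signal by
    ``1 + decay_slope * t_i``; noise is drawn fresh per acquisition. With
    ``morphology_change`` a fraction of tubules fragments into globules from
    the sixth acquisition on.
    """
    cell = params.cell
    rng = np.random.default_rng(cell.seed)
    dz, dy, dx = cell.geometry
    voxel_sets, flags, lines, center = _place_objects(rng, cell)
    intensities = np.clip(
        rng.normal(cell.potential_mean, cell.potential_sd, size=len(voxel_sets)),
        0.05 * cell.potential_mean,
        None,
    )
    obj_img, union_mask = _object_images(voxel_sets, intensities, cell.shape)
    nucleus_mask, cell_mask = _cell_nucleus_masks(cell, center)

    late_img = obj_img
    if params.morphology_change:
        frag_sets, _ = _fragment_objects(
            voxel_sets, flags, lines, cell, params.fragment_fraction, rng
        )
        late_img, _ = _object_images(frag_sets, np.resize(intensities, len(frag_sets)), cell.shape)

    n = params.n_acquisitions
    t = np.arange(n) / (n - 1)
    factors = 1.0 + params.decay_slope * t
    stacks = []
    for i in range(n):
        # the diffuse background is dye too and bleaches with everything else
        base = late_img if (params.morphology_change and i >= 5) else obj_img
        clean = (base + cell.background_level) * factors[i]
        gain = _gain_field(cell.shape[1:], params.between_roi_sd, rng)
        clean = clean * gain[None, :, :]
        mito = _render(clean, cell, rng)
        stacks.append(ChannelSet(mito=VoxelGrid(mito, dz, dy, dx, channel="mito")))

    truth = _ground_truth(obj_img, union_mask, cell, nucleus_mask, cell_mask)
    truth.decay_factors = factors
    return stacks, truth


def simulate_intensity_series(
    slope: float,
    sigma: float,
    n_rois: int = 5,
    n_acquisitions: int = 10,
    baseline: float = 200.0,
    roi_effect_sd: float = 0.0,
    dye: str = "TMRM",
    microscope: str = "SDCM",
    rng: Optional[np.random.Generator] = None,
    seed: int = 0,
) -> list[IntensitySeries]:
    """Direct generator of ROI mean-intensity trajectories.

    Raw means follow ``baseline * (1 + (slope + b_r)*t + eps)`` with
    per-ROI slope effects ``b_r ~ N(0, roi_effect_sd)`` (ROIs and cells do
    not bleach identically, which is what spreads relative trajectories
    apart by the tenth acquisition) and per-observation noise
    ``eps ~ N(0, sigma)``; normalization to the first acquisition happens in
    IntensitySeries exactly as for measured data. A static per-ROI gain
    would cancel under that normalization, so it is not simulated.
    Orders of magnitude faster than rendering full stacks — the workhorse
    for trend-recovery and model-selection studies.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    t = np.arange(n_acquisitions) / (n_acquisitions - 1)
    out = []
    for r in range(n_rois):
        b_r = rng.normal(0.0, roi_effect_sd) if roi_effect_sd > 0 else 0.0
        raw = baseline * (1.0 + (slope + b_r) * t + rng.normal(0.0, sigma, size=n_acquisitions))
        if raw[0] <= 0:
            raw[0] = 1e-6  # pathological draw; keep the series usable
        roi = RoiRect(f"roi{r + 1}", 0, 0, 31, 31)
        out.append(IntensitySeries(roi=roi, dye=dye, microscope=microscope, raw=raw))
    return out
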