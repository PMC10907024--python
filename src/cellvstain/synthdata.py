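"""Procedural paired DIC-like / fluorescence scenes with known ground truth.

The generator emulates the structure of the real training data — adherent
cells imaged label-free (relief-like DIC contrast) alongside F-actin and
nuclear fluorescence channels — while keeping every cell's geometry known
exactly.  Two morphology styles mirror the round/textured versus
protrusive/irregular contrast that drives dataset diversity in practice:

``round``
    near-elliptical boundary with small perturbation and multiplicative
    speckle in the F-actin channel.
``protrusive``
    elongated, low-order Fourier boundary perturbation plus 1-3 narrow
    lobes (pseudopod-like protrusions), weaker speckle.

The DIC appearance model is a signed directional gradient (shear axis 45
degrees) of a smooth per-cell phase map, offset to mid-gray — the relief
look of DIC without simulating optics.  Radial boundary perturbations are
normalized to preserve area, so the rasterized cell mask area stays within
a few percent of pi*a*b and morphometry ground truth is analytic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .core import (
    DatasetDescriptor,
    ImagePair,
    Manifest,
    ManifestRow,
    PlacementError,
    ValidationError,
    write_image_stack,
    write_prediction,
    logger,
)
from .singlecell import FEATURE_NAMES

STYLES = ("round", "protrusive")


@dataclass
class SyntheticCellSpec:
    """Geometry and intensity of one synthetic cell (ground truth)."""

    center: tuple[float, float]          # (row, col)
    a: float                             # cell semi-major axis, px
    b: float                             # cell semi-minor axis, px
    theta: float                         # orientation, radians from row axis
    nucleus_a: float
    nucleus_b: float
    nucleus_offset: tuple[float, float] = (0.0, 0.0)
    perturb_amp: float = 0.05            # Fourier amplitude, fraction of radius
    fourier_amps: tuple[float, ...] = ()
    fourier_phases: tuple[float, ...] = ()
    lobes: tuple[tuple[float, float, float], ...] = ()  # (angle, amp, width)
    factin_level: float = 0.7
    nuclei_level: float = 0.8

    def __post_init__(self) -> None:
        if not (self.a >= self.b > 0):
            raise ValidationError(f"need a >= b > 0, got a={self.a}, b={self.b}")
        if not (0.0 <= self.perturb_amp <= 0.3):
            raise ValidationError("perturbation amplitude must be in [0, 0.3]")
        if self.nucleus_a > self.a or self.nucleus_b > self.b:
            raise ValidationError("nucleus semi-axes must not exceed cell semi-axes")


@dataclass
class SyntheticScene:
    """A rendered field of view plus per-cell ground truth."""

    size: tuple[int, int]
    cells: list[SyntheticCellSpec]
    background: float
    noise_sigma: float
    magnification: str
    dic_render: np.ndarray
    factin: np.ndarray
    nuclei: np.ndarray
    cell_masks: list[np.ndarray] = field(default_factory=list)
    nucleus_masks: list[np.ndarray] = field(default_factory=list)

    @property
    def cell_mask_union(self) -> np.ndarray:
        if not self.cell_masks:
            return np.zeros(self.size, dtype=bool)
        return np.logical_or.reduce(self.cell_masks)


def _radial_factor(spec: SyntheticCellSpec, phi: np.ndarray) -> np.ndarray:
    """Area-normalized radial boundary modulation r(phi)."""
    r = np.ones_like(phi)
    for k, (amp, ph) in enumerate(zip(spec.fourier_amps, spec.fourier_phases), start=2):
        r += amp * np.cos(k * phi + ph)
    for ang, amp, width in spec.lobes:
        d = np.angle(np.exp(1j * (phi - ang)))
        r += amp * np.exp(-0.5 * (d / width) ** 2)
    r = np.maximum(r, 0.3)
    # normalize so the enclosed area stays pi*a*b
    grid = np.linspace(-np.pi, np.pi, 256, endpoint=False)
    rg = np.ones_like(grid)
    for k, (amp, ph) in enumerate(zip(spec.fourier_amps, spec.fourier_phases), start=2):
        rg += amp * np.cos(k * grid + ph)
    for ang, amp, width in spec.lobes:
        d = np.angle(np.exp(1j * (grid - ang)))
        rg += amp * np.exp(-0.5 * (d / width) ** 2)
    rg = np.maximum(rg, 0.3)
    return r / np.sqrt(np.mean(rg ** 2))


def _elliptic_coords(spec: SyntheticCellSpec, shape: tuple[int, int]):
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]].astype(np.float64)
    dr = rr - spec.center[0]
    dc = cc - spec.center[1]
    u = dr * np.cos(spec.theta) + dc * np.sin(spec.theta)
    v = -dr * np.sin(spec.theta) + dc * np.cos(spec.theta)
    rho = np.sqrt((u / spec.a) ** 2 + (v / spec.b) ** 2)
    phi = np.arctan2(v / spec.b, u / spec.a)
    return rho, phi


def rasterize_cell(spec: SyntheticCellSpec, shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of the (perturbed) cell boundary."""
    rho, phi = _elliptic_coords(spec, shape)
    return rho <= _radial_factor(spec, phi)


def rasterize_nucleus(spec: SyntheticCellSpec, shape: tuple[int, int]) -> np.ndarray:
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]].astype(np.float64)
    cr = spec.center[0] + spec.nucleus_offset[0]
    cc0 = spec.center[1] + spec.nucleus_offset[1]
    dr = rr - cr
    dc = cc - cc0
    u = dr * np.cos(spec.theta) + dc * np.sin(spec.theta)
    v = -dr * np.sin(spec.theta) + dc * np.cos(spec.theta)
    return (u / spec.nucleus_a) ** 2 + (v / spec.nucleus_b) ** 2 <= 1.0


def _sample_cell(style: str, rng: np.random.Generator, size_scale: float,
                 center: tuple[float, float]) -> SyntheticCellSpec:
    if style == "round":
        a = rng.uniform(8.0, 12.0) * size_scale
        b = a * rng.uniform(0.85, 0.98)
        amps = tuple(rng.uniform(0.01, 0.05, size=2))
        lobes: tuple = ()
    elif style == "protrusive":
        a = rng.uniform(9.0, 13.0) * size_scale
        b = a * rng.uniform(0.3, 0.5)
        amps = tuple(rng.uniform(0.04, 0.12, size=3))
        n_lobes = int(rng.integers(1, 4))
        lobes = tuple(
            (float(rng.uniform(-np.pi, np.pi)), float(rng.uniform(0.2, 0.35)),
             float(rng.uniform(0.2, 0.35)))
            for _ in range(n_lobes)
        )
    else:
        raise ValidationError(f"unknown style {style!r}; choose from {STYLES}")
    phases = tuple(rng.uniform(0, 2 * np.pi, size=len(amps)))
    nf = rng.uniform(0.38, 0.5)
    off_r = rng.uniform(-0.15, 0.15) * b
    off_c = rng.uniform(-0.15, 0.15) * b
    return SyntheticCellSpec(
        center=center,
        a=a,
        b=b,
        theta=float(rng.uniform(-np.pi / 2, np.pi / 2)),
        nucleus_a=nf * a,
        nucleus_b=nf * b,
        nucleus_offset=(off_r, off_c),
        perturb_amp=float(max(amps)) if amps else 0.0,
        fourier_amps=amps,
        fourier_phases=phases,
        lobes=lobes,
        factin_level=float(rng.uniform(0.55, 0.85)),
        nuclei_level=float(rng.uniform(0.65, 0.95)),
    )


def _render(cells: list[SyntheticCellSpec], size: tuple[int, int],
            background: float, noise_sigma: float, style: str,
            rng: np.random.Generator):
    """Render F-actin, nuclei and DIC channels from cell specs."""
    factin = np.full(size, background)
    nuclei = np.full(size, background)
    height = np.zeros(size)
    cell_masks, nucleus_masks = [], []
    for spec in cells:
        rho, phi = _elliptic_coords(spec, size)
        rf = _radial_factor(spec, phi)
        mask = rho <= rf
        nmask = rasterize_nucleus(spec, size) & mask
        cell_masks.append(mask)
        nucleus_masks.append(nmask)
        # smooth paraboloid cap as the optical-path (phase) contribution;
        # the nucleus adds its own relief (higher refractive index), as in
        # real DIC where the nucleus is visible in the label-free channel
        cap = np.clip(1.0 - (rho / np.maximum(rf, 1e-9)) ** 2, 0.0, None)
        height += cap * (0.6 + 0.4 * spec.nuclei_level)
        rr_n, cc_n = np.mgrid[0:size[0], 0:size[1]].astype(np.float64)
        dr_n = rr_n - (spec.center[0] + spec.nucleus_offset[0])
        dc_n = cc_n - (spec.center[1] + spec.nucleus_offset[1])
        u_n = dr_n * np.cos(spec.theta) + dc_n * np.sin(spec.theta)
        v_n = -dr_n * np.sin(spec.theta) + dc_n * np.cos(spec.theta)
        rho_n2 = (u_n / spec.nucleus_a) ** 2 + (v_n / spec.nucleus_b) ** 2
        # flat-top plateau: the optical-path step of the nuclear envelope
        # concentrates the DIC gradient at the nucleus boundary
        height += np.clip((1.0 - rho_n2) * 4.0, 0.0, 1.0) * 0.8
        fa = np.where(mask, spec.factin_level, 0.0)
        if style == "round":
            speckle = np.clip(rng.lognormal(0.0, 0.25, size=size), 0.3, 3.0)
            speckle = ndi.gaussian_filter(speckle, 1.0)
            fa = fa * speckle
        else:
            speckle = np.clip(rng.lognormal(0.0, 0.1, size=size), 0.5, 2.0)
            fa = fa * speckle
        factin = np.where(mask, np.clip(background + fa, 0, 1), factin)
        nuclei = np.where(nmask, np.clip(background + spec.nuclei_level, 0, 1), nuclei)
    factin = ndi.gaussian_filter(factin, 0.7)
    nuclei = ndi.gaussian_filter(nuclei, 0.7)
    if cells:
        # the "round" phenotype is textured: fine optical-path roughness
        # inside the cell body, visible as granular DIC relief
        tex_amp = 0.30 if style == "round" else 0.05
        tex = ndi.gaussian_filter(rng.normal(0, 1.0, size), 1.0)
        union = np.logical_or.reduce(cell_masks)
        height = height + tex * tex_amp * union
    phase = ndi.gaussian_filter(height, 1.2)
    gr, gc = np.gradient(phase)
    shear = (gr + gc) / np.sqrt(2.0)
    scale = max(np.percentile(np.abs(shear), 99.5), 1e-6)
    # besides the signed 45-degree shear relief, real DIC keeps faint
    # orientation-independent edge contrast (finite bias retardation);
    # without it, edges parallel to the shear axis would be invisible
    mag = np.hypot(gr, gc)
    mscale = max(np.percentile(mag, 99.5), 1e-6)
    dic = (0.5 + 0.45 * np.clip(shear / scale, -1, 1)
           - 0.12 * np.clip(mag / mscale, 0, 1))
    if noise_sigma > 0:
        factin = factin + rng.normal(0, noise_sigma, size)
        nuclei = nuclei + rng.normal(0, noise_sigma, size)
        dic = dic + rng.normal(0, noise_sigma, size)
    return (np.clip(factin, 0, 1), np.clip(nuclei, 0, 1), np.clip(dic, 0, 1),
            cell_masks, nucleus_masks)


def generate_scene(
    n_cells: int,
    style: str = "round",
    size: tuple[int, int] = (64, 64),
    rng: np.random.Generator | None = None,
    overlap_allowed: bool = False,
    background: float = 0.08,
    noise_sigma: float = 0.02,
    size_scale: float = 1.0,
    magnification: str = "10x",
    max_attempts: int = 50,
    min_gap: int = 3,
    allow_partial: bool = False,
) -> SyntheticScene:
    """Place ``n_cells`` cells of the given style and render all channels.

    Raises
    ------
    PlacementError
        when non-overlapping placement fails; the exception carries the
        number of successfully placed cells in ``achieved``.
    """
    if style not in STYLES:
        raise ValidationError(f"unknown style {style!r}; choose from {STYLES}")
    if size[0] < 64 or size[1] < 64:
        raise ValidationError("scene size must be at least 64x64")
    rng = rng or np.random.default_rng(0)
    cells: list[SyntheticCellSpec] = []
    occupied = np.zeros(size, dtype=bool)
    for i in range(n_cells):
        placed = False
        for _ in range(max_attempts):
            margin = 16.0 * size_scale
            center = (
                float(rng.uniform(margin, size[0] - margin)),
                float(rng.uniform(margin, size[1] - margin)),
            )
            spec = _sample_cell(style, rng, size_scale, center)
            mask = rasterize_cell(spec, size)
            # keep a small gap so cells stay separable after smoothing
            fat = ndi.binary_dilation(mask, iterations=min_gap) if min_gap else mask
            if overlap_allowed or not (fat & occupied).any():
                cells.append(spec)
                occupied |= fat
                placed = True
                break
        if not placed:
            if allow_partial:
                logger.info("scene: placed %d/%d cells, continuing", len(cells), n_cells)
                break
            err = PlacementError(
                f"placed only {len(cells)}/{n_cells} cells after "
                f"{max_attempts} attempts each"
            )
            err.achieved = len(cells)
            raise err
    factin, nuclei, dic, cmasks, nmasks = _render(
        cells, size, background, noise_sigma, style, rng
    )
    return SyntheticScene(
        size=size,
        cells=cells,
        background=background,
        noise_sigma=noise_sigma,
        magnification=magnification,
        dic_render=dic,
        factin=factin,
        nuclei=nuclei,
        cell_masks=cmasks,
        nucleus_masks=nmasks,
    )


def scene_to_pair(scene: SyntheticScene, n_slices: int = 3, pair_id: str = "scene",
                  dataset_id: str = "", pixel_size_um: float = 1.0,
                  defocus_step: float = 0.8) -> ImagePair:
    """Build a defocus z-stack: slice i is the DIC render blurred with
    sigma = i * defocus_step (slice 0 is the in-focus render)."""
    if n_slices < 1:
        raise ValidationError("n_slices must be >= 1")
    slices = [scene.dic_render]
    for i in range(1, n_slices):
        slices.append(ndi.gaussian_filter(scene.dic_render, i * defocus_step))
    return ImagePair(
        id=pair_id,
        dic_stack=np.stack(slices),
        targets={"factin": scene.factin, "nuclei": scene.nuclei},
        dataset_id=dataset_id,
        pixel_size_um=pixel_size_um,
    )


# backwards-friendly alias matching the two names used in docs
scene_to_pairs = scene_to_pair


def make_dataset(
    descriptor: DatasetDescriptor,
    n_pairs: int,
    style: str,
    rng: np.random.Generator,
    out_dir: str | Path,
    size: tuple[int, int] = (64, 64),
    n_slices: int = 3,
    cells_range: tuple[int, int] = (2, 4),
    size_scale: float = 1.0,
    n_test: int | None = None,
    noise_sigma: float = 0.02,
) -> Manifest:
    """Write a paired dataset (TIFFs + CSV manifest + ground-truth JSON).

    The last ``n_test`` pairs are tagged ``test``; the rest ``train``.
    A JSON sidecar stores every cell spec for morphometry-recovery tests.
    """
    if n_pairs < 1:
        raise ValidationError("n_pairs must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if n_test is None:
        n_test = max(1, n_pairs // 5) if n_pairs > 1 else 0
    rows = []
    truth: dict[str, list[dict]] = {}
    for i in range(n_pairs):
        n_cells = int(rng.integers(cells_range[0], cells_range[1] + 1))
        scene = generate_scene(
            n_cells, style=style, size=size, rng=rng,
            size_scale=size_scale, magnification=descriptor.magnification,
            noise_sigma=noise_sigma, allow_partial=True,
        )
        pair_id = f"{descriptor.dataset_id}_{i:03d}"
        pair = scene_to_pair(scene, n_slices=n_slices, pair_id=pair_id,
                             dataset_id=descriptor.dataset_id,
                             pixel_size_um=descriptor.pixel_size_um)
        dic_path = f"{pair_id}_dic.tif"
        fa_path = f"{pair_id}_factin.tif"
        nu_path = f"{pair_id}_nuclei.tif"
        write_image_stack(pair.dic_stack, out_dir / dic_path)
        write_prediction(pair.targets["factin"], out_dir / fa_path)
        write_prediction(pair.targets["nuclei"], out_dir / nu_path)
        rows.append(ManifestRow(
            pair_id=pair_id,
            dic_path=dic_path,
            target_paths={"factin": fa_path, "nuclei": nu_path},
            dataset_id=descriptor.dataset_id,
            split="test" if i >= n_pairs - n_test else "train",
            pixel_size_um=descriptor.pixel_size_um,
        ))
        truth[pair_id] = [asdict(c) for c in scene.cells]
    manifest = Manifest(rows=rows, root=out_dir)
    manifest.save(out_dir / "manifest.csv")
    (out_dir / "ground_truth.json").write_text(json.dumps(truth, indent=1))
    descriptor.n_pairs = n_pairs
    return manifest


def _ellipse_perimeter(a: float, b: float) -> float:
    """Ramanujan's approximation, accurate to ~1e-5 for cell-like ratios."""
    h = ((a - b) / (a + b)) ** 2
    return np.pi * (a + b) * (1 + 3 * h / (10 + np.sqrt(4 - 3 * h)))


def simulate_yap_samples(
    n: int,
    rng: np.random.Generator,
    noise_frac: float = 0.10,
    n_groups: int = 0,
    group_effects: tuple[float, ...] = (0.0, 0.6, 0.25),
) -> pd.DataFrame:
    """Linear-response YAP benchmark: 17 coherent morphometric features
    plus a ground-truth n/c ratio that depends linearly on three of them.

    The true ratio is ``1.6 + 0.35*z(nuc_area) + 0.3*z(cell_ecc)
    - 0.25*z(nc_ratio)`` plus Gaussian noise with standard deviation
    ``noise_frac`` times the signal's standard deviation.  With
    ``n_groups`` > 0 a condition tag is added and the designated group
    effects (default: middle group highest, mimicking an optimal-stiffness
    response) shift the driver features.
    """
    a = rng.uniform(12, 30, n)
    b = a * rng.uniform(0.45, 0.95, n)
    nf = rng.uniform(0.35, 0.55, n)
    groups = None
    group_shift = np.zeros(n)
    if n_groups:
        groups = rng.integers(0, n_groups, n)
        # the group effect elongates cells (higher eccentricity, a driver
        # the predictor can see) and shifts the response directly
        for g in range(n_groups):
            eff = group_effects[g % len(group_effects)]
            b = np.where(groups == g, np.maximum(b * (1 - 0.3 * eff), 0.35 * a), b)
            group_shift = np.where(groups == g, eff * 0.4, group_shift)
    na, nb = nf * a, nf * b
    cell_area = np.pi * a * b
    nuc_area = np.pi * na * nb
    cell_perim = _ellipse_perimeter(a, b)
    nuc_perim = _ellipse_perimeter(na, nb)
    df = pd.DataFrame({
        "cell_area": cell_area,
        "cell_perimeter": cell_perim,
        "cell_minor_axis": 2 * b,
        "cell_major_axis": 2 * a,
        "nuc_area": nuc_area,
        "nuc_perimeter": nuc_perim,
        "nuc_minor_axis": 2 * nb,
        "nuc_major_axis": 2 * na,
        "cell_compactness": 4 * np.pi * cell_area / cell_perim ** 2,
        "nuc_compactness": 4 * np.pi * nuc_area / nuc_perim ** 2,
        "cell_eccentricity": np.sqrt(1 - (b / a) ** 2),
        "nuc_eccentricity": np.sqrt(1 - (nb / na) ** 2),
        "cell_angle": rng.uniform(-90, 90, n),
        "nuc_angle": rng.uniform(-90, 90, n),
        "cell_mean_intensity": rng.uniform(0.3, 0.8, n),
        "nuc_mean_intensity": rng.uniform(0.4, 0.9, n),
        "nc_ratio": nuc_area / (cell_area - nuc_area),
    })
    df = df[list(FEATURE_NAMES)]

    # fixed normalization constants of the response function (population
    # mean/std of each driver under the sampling distribution), so the
    # ground-truth map is identical across draws
    ref = {"nuc_area": (211.78, 125.83), "cell_eccentricity": (0.681, 0.158),
           "nc_ratio": (0.265, 0.084)}

    def z(name):
        mu, sdv = ref[name]
        return (df[name] - mu) / sdv

    signal = (0.35 * z("nuc_area") + 0.30 * z("cell_eccentricity")
              - 0.25 * z("nc_ratio") + group_shift)
    noise = rng.normal(0, noise_frac * signal.std(), n)
    df["yap_nc_true"] = np.clip(1.6 + signal + noise, 0.05, None)
    if groups is not None:
        df["condition"] = [f"group{g}" for g in groups]
    return df
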