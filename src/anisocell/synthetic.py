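"""Synthetic cylindrical-tissue generator with known ground truth.

Emulates a segment of an embryonic axis (hypocotyl): a roughly cylindrical
organ built from an outer epidermis plus concentric cortical shells, each
shell tiled by longitudinal slabs and angular sectors, around a central
axis that runs through the stele. Every generated cell's organ-frame
dimensions (longitudinal, radial, circumferential extents) and volume are
known in closed form, so each downstream stage — segmentation, geometric
measurement, growth statistics — can be tested against exact truth.

The default organ has 12 shells (epidermis plus 11 cortical layers) with a
radial cell-size gradient peaking in mid-cortex, mirroring the tissue
organisation of a legume embryonic axis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .core import CELL_CSV_COLUMNS, LabeledVolume, as_label_array

#: Directional growth metrics understood by GrowthSpec.
GROWTH_METRICS = ("long", "rad", "circ")

_METRIC_COLUMN = {
    "long": "len_long_um",
    "rad": "len_rad_um",
    "circ": "len_circ_um",
}


def default_layer_dims(n_layers: int = 12) -> list[tuple[float, float, float]]:
    """Per-layer target cell dimensions (longitudinal, radial, circumferential), µm.

    Epidermal cells (layer 1) are smallest; cortical cell size rises to a
    mid-cortex peak and falls again toward the innermost shell, producing
    the unimodal radial size gradient typical of a thick embryonic axis.
    """
    dims = []
    mid = (n_layers + 1) / 2.0
    for k in range(1, n_layers + 1):
        # triangular profile in [0, 1], peaking at mid-cortex
        w = 1.0 - abs(k - mid) / mid
        radial = 4.0 + 6.0 * w
        longitudinal = 12.0 + 8.0 * w
        circumferential = 6.0 + 6.0 * w
        dims.append((longitudinal, radial, circumferential))
    return dims


@dataclass(frozen=True)
class OrganSpec:
    """Geometry of the synthetic organ segment.

    Parameters
    ----------
    organ_radius : float
        Outer radius of the organ in µm.
    segment_length : float
        Length of the imaged segment along the organ axis, µm.
    n_layers : int
        Number of concentric cell shells (layer 1 = epidermis, outermost;
        layers 2.. are cortex, numbered inward). Default 12: epidermis plus
        11 cortical layers.
    per_layer_cell_dims : sequence of (long, rad, circ) µm, one per layer
        Target cell dimensions at the initial time point. ``None`` selects
        :func:`default_layer_dims`.
    voxel_spacing : (z, y, x) µm per voxel.
    axis_curvature : float
        Amplitude (µm) of a gentle sinusoidal bend of the central axis in
        the x direction; 0 gives a straight organ.
    """

    organ_radius: float = 60.0
    segment_length: float = 80.0
    n_layers: int = 12
    per_layer_cell_dims: tuple[tuple[float, float, float], ...] | None = None
    voxel_spacing: tuple[float, float, float] = (0.5, 0.5, 0.5)
    axis_curvature: float = 0.0

    def __post_init__(self):
        if self.organ_radius <= 0 or self.segment_length <= 0:
            raise ValueError("organ_radius and segment_length must be positive")
        if self.n_layers < 2:
            raise ValueError("need at least 2 layers (epidermis + 1 cortex shell)")
        dims = self.per_layer_cell_dims
        if dims is None:
            dims = tuple(tuple(d) for d in default_layer_dims(self.n_layers))
            object.__setattr__(self, "per_layer_cell_dims", dims)
        else:
            dims = tuple(tuple(float(v) for v in d) for d in dims)
            object.__setattr__(self, "per_layer_cell_dims", dims)
        if len(dims) != self.n_layers:
            raise ValueError(
                f"per_layer_cell_dims has {len(dims)} entries for {self.n_layers} layers"
            )
        if any(v <= 0 for d in dims for v in d):
            raise ValueError("all cell dimensions must be positive")
        total_thickness = sum(d[1] for d in dims)
        if total_thickness > self.organ_radius:
            raise ValueError(
                f"sum of layer radial thicknesses ({total_thickness:.1f} µm) exceeds "
                f"organ radius ({self.organ_radius:.1f} µm)"
            )
        spacing = tuple(float(s) for s in self.voxel_spacing)
        object.__setattr__(self, "voxel_spacing", spacing)
        if any(s <= 0 for s in spacing):
            raise ValueError("voxel spacing must be positive")

    def layer_radii(self) -> list[tuple[float, float]]:
        """(r_outer, r_inner) bounds per layer, outermost first."""
        bounds = []
        r = self.organ_radius
        for _, radial, _ in self.per_layer_cell_dims:
            bounds.append((r, r - radial))
            r -= radial
        return bounds


@dataclass(frozen=True)
class GrowthSpec:
    """Layer- and position-specific multiplicative growth between time points.

    ``ratios`` maps ``(layer, position, metric)`` — metric one of
    ``"long"``, ``"rad"``, ``"circ"`` — to the true multiplicative ratio of
    that directional dimension between the later and earlier time point.
    A (layer, position) pair must appear for at least one metric; metrics
    not listed for a covered pair default to 1 (no growth in that
    direction). Multiplicative lognormal noise with log-sd ``sigma`` is
    applied per cell and metric; cell volume scales by the product of the
    three realised directional factors.
    """

    ratios: dict[tuple[int, str, str], float] = field(default_factory=dict)
    sigma: float = 0.1
    n_replicates: int = 4

    def __post_init__(self):
        for key, r in self.ratios.items():
            layer, position, metric = key
            if metric not in GROWTH_METRICS:
                raise ValueError(f"unknown metric {metric!r} in growth ratio key {key}")
            if r <= 0:
                raise ValueError(f"growth ratio must be positive, got {r} for {key}")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    @classmethod
    def uniform(cls, layers, positions=("H1", "H2"), long=1.0, rad=1.0, circ=1.0,
                sigma=0.1, n_replicates=4) -> "GrowthSpec":
        """Same directional ratios for every (layer, position)."""
        ratios = {}
        for lay in layers:
            for pos in positions:
                ratios[(lay, pos, "long")] = float(long)
                ratios[(lay, pos, "rad")] = float(rad)
                ratios[(lay, pos, "circ")] = float(circ)
        return cls(ratios=ratios, sigma=sigma, n_replicates=n_replicates)

    def covered_pairs(self) -> set[tuple[int, str]]:
        return {(lay, pos) for (lay, pos, _m) in self.ratios}

    def factor(self, layer: int, position: str, metric: str) -> float:
        """True ratio for a (layer, position, metric); 1.0 for omitted metrics."""
        if (layer, position) not in self.covered_pairs():
            raise KeyError(
                f"growth spec has no entry for layer {layer}, position {position!r}"
            )
        return self.ratios.get((layer, position, metric), 1.0)


@dataclass
class GroundTruthTissue:
    """Generated tissue: label volume, per-cell truth table, true axis points.

    ``records`` uses the canonical per-cell CSV schema; its dimensions are
    the *true* closed-form organ-frame extents, not measurements.
    ``axis_points`` are ordered (z, y, x) µm points on the true central
    axis, radicle end first.
    """

    label_volume: LabeledVolume
    records: pd.DataFrame
    axis_points: np.ndarray

    def __post_init__(self):
        labels_present = set(self.label_volume.label_ids().tolist())
        ids = self.records["cell_id"]
        if ids.duplicated().any():
            raise ValueError("duplicate cell_id in ground-truth records")
        recorded = set(int(i) for i in ids)
        if labels_present - recorded:
            raise ValueError(
                f"labels without records: {sorted(labels_present - recorded)[:5]} ..."
            )


def _sector_truth(r_out: float, r_in: float, height: float, n_sect: int):
    """Closed-form organ-frame extents and volume of one annular-sector cell.

    The radial extent is the spread of the sector's boundary points along
    the radial direction through its centroid (the angular bisector), the
    circumferential extent is the chord width perpendicular to it.
    """
    theta = 2.0 * np.pi / n_sect
    half = theta / 2.0
    len_rad = r_out - r_in * np.cos(half)
    len_circ = 2.0 * r_out * np.sin(half) if n_sect > 1 else 2.0 * r_out
    volume = height * half * (r_out**2 - r_in**2)
    # centroid radius of an annular sector
    r_c = (2.0 / 3.0) * (r_out**3 - r_in**3) / (r_out**2 - r_in**2) * np.sin(half) / half
    return len_rad, len_circ, volume, r_c


def _axis_x_offset(spec: OrganSpec, z: np.ndarray) -> np.ndarray:
    """x-offset of the organ axis at axial coordinate z (µm)."""
    if spec.axis_curvature == 0.0:
        return np.zeros_like(z)
    return spec.axis_curvature * np.sin(np.pi * z / spec.segment_length)


def build_tissue(spec: OrganSpec, seed: int = 0, replicate_id: int = 1,
                 time_hai: float = 4.0, position_cut: float = 0.5,
                 margin_voxels: int = 3) -> GroundTruthTissue:
    """Generate a labelled cylindrical tissue with closed-form cell truth.

    Each shell is tiled by longitudinal slabs of height ≈ the layer's target
    longitudinal dimension and angular sectors of arc ≈ its circumferential
    target. Each ring's angular phase is randomised (seeded) so cell walls
    do not align radially across layers. The stele core (inside the
    innermost shell) is left as background; the axis runs through it.

    Cells whose slab centre lies at axis parameter t < ``position_cut`` are
    labelled position H1 (radicle end, t = 0), the rest H2.

    Raises
    ------
    ValueError
        If the voxel spacing is too coarse to resolve the smallest cell
        dimension with at least 3 voxels.
    """
    rng = np.random.default_rng(seed)
    smallest = min(min(d) for d in spec.per_layer_cell_dims)
    coarsest = max(spec.voxel_spacing)
    if smallest < 3.0 * coarsest:
        raise ValueError(
            f"voxel spacing {coarsest:g} µm too coarse to resolve the smallest cell "
            f"dimension {smallest:g} µm with >= 3 voxels; refine the grid"
        )

    sz, sy, sx = spec.voxel_spacing
    pad_z = margin_voxels * sz
    pad_xy = margin_voxels * max(sy, sx)
    extent_xy = 2.0 * (spec.organ_radius + abs(spec.axis_curvature) + pad_xy)
    nz = int(np.ceil((spec.segment_length + 2 * pad_z) / sz))
    ny = int(np.ceil(extent_xy / sy))
    nx = int(np.ceil(extent_xy / sx))

    zc = (np.arange(nz) + 0.5) * sz - pad_z          # axial coordinate, 0 at segment start
    yc = (np.arange(ny) + 0.5) * sy - extent_xy / 2.0
    xc = (np.arange(nx) + 0.5) * sx - extent_xy / 2.0

    # per-voxel cylindrical coordinates relative to the (possibly bent) axis
    ax_off = _axis_x_offset(spec, np.clip(zc, 0.0, spec.segment_length))
    Y = yc[None, :, None]
    X = xc[None, None, :] - ax_off[:, None, None]
    R = np.sqrt(X**2 + Y**2)
    PHI = np.arctan2(Y, X)  # in (-pi, pi]

    labels = np.zeros((nz, ny, nx), dtype=np.int32)
    in_segment = (zc >= 0.0) & (zc < spec.segment_length)

    rows = []
    next_label = 1
    radii = spec.layer_radii()
    L = spec.segment_length
    for layer_idx, ((r_out, r_in), (d_long, _d_rad, d_circ)) in enumerate(
        zip(radii, spec.per_layer_cell_dims), start=1
    ):
        n_slab = max(1, int(round(L / d_long)))
        height = L / n_slab
        r_mid = 0.5 * (r_out + r_in)
        n_sect = max(3, int(round(2.0 * np.pi * r_mid / d_circ)))
        theta = 2.0 * np.pi / n_sect
        in_shell = (R > r_in) & (R <= r_out)
        for j in range(n_slab):
            z_lo, z_hi = j * height, (j + 1) * height
            t_center = (z_lo + z_hi) / (2.0 * L)
            pos = "H1" if t_center < position_cut else "H2"
            phase = rng.uniform(0.0, theta)
            sector_of = np.floor(((PHI - phase) % (2.0 * np.pi)) / theta).astype(np.int32)
            slab_mask = in_shell & in_segment[:, None, None] & (
                (zc[:, None, None] >= z_lo) & (zc[:, None, None] < z_hi)
            )
            len_rad, len_circ, volume, r_c = _sector_truth(r_out, r_in, height, n_sect)
            labels_for_slab = next_label + sector_of
            labels[slab_mask] = labels_for_slab[slab_mask]
            for s in range(n_sect):
                rows.append(
                    {
                        "cell_id": next_label + s,
                        "replicate_id": replicate_id,
                        "time_hai": time_hai,
                        "position": pos,
                        "layer": layer_idx,
                        "volume_um3": volume,
                        "len_long_um": height,
                        "len_rad_um": len_rad,
                        "len_circ_um": len_circ,
                        "radial_dist_um": r_c,
                        "axis_t": t_center,
                    }
                )
            next_label += n_sect

    records = pd.DataFrame(rows, columns=CELL_CSV_COLUMNS)
    # drop records whose cell got no voxels (possible only for extreme specs)
    present = np.unique(labels)
    present = set(present[present > 0].tolist())
    records = records[records["cell_id"].isin(present)].reset_index(drop=True)

    t_axis = np.linspace(0.0, 1.0, 33)
    z_axis = t_axis * L
    axis_points = np.column_stack(
        [z_axis, np.zeros_like(z_axis), _axis_x_offset(spec, z_axis)]
    )  # (z, y, x) µm, in the volume's world frame after recentering below
    # shift into the voxel world frame: z starts at pad_z, x/y centred
    axis_points[:, 0] += pad_z
    axis_points[:, 1] += extent_xy / 2.0
    axis_points[:, 2] += extent_xy / 2.0

    return GroundTruthTissue(
        label_volume=LabeledVolume(labels, spec.voxel_spacing),
        records=records,
        axis_points=axis_points,
    )


def build_grid_labels(n_cells=(3, 3, 3), cell_voxels=(14, 14, 14), margin=4,
                      spacing=(1.0, 1.0, 1.0)) -> LabeledVolume:
    """Rectangular-grid phantom: a block of cuboidal cells with a background rim.

    A simple benchmark for the segmentation stage: ``n_cells`` cells per
    axis, each ``cell_voxels`` voxels, surrounded by ``margin`` background
    voxels so every cell is interior to the stack. Labels are 1..N in
    z-major order.
    """
    ncz, ncy, ncx = n_cells
    cz, cy, cx = cell_voxels
    shape = (ncz * cz + 2 * margin, ncy * cy + 2 * margin, ncx * cx + 2 * margin)
    labels = np.zeros(shape, dtype=np.int32)
    lab = 1
    for iz in range(ncz):
        for iy in range(ncy):
            for ix in range(ncx):
                labels[
                    margin + iz * cz : margin + (iz + 1) * cz,
                    margin + iy * cy : margin + (iy + 1) * cy,
                    margin + ix * cx : margin + (ix + 1) * cx,
                ] = lab
                lab += 1
    return LabeledVolume(labels, spacing)


def apply_growth(tissue: GroundTruthTissue, growth: GrowthSpec, seed: int = 0,
                 time_hai: float = 18.0) -> GroundTruthTissue:
    """Apply multiplicative directional growth to the ground-truth records.

    Each cell's directional dimension is multiplied by its
    (layer, position, metric) true ratio times a lognormal factor with
    log-sd ``growth.sigma`` (sigma 0 gives the exact multiplicative map);
    volume is multiplied by the product of the three realised directional
    factors, so volume growth is consistent with directional growth by
    construction. The label volume is carried over unchanged — growth acts
    on the truth table, which is the input to the statistics stage.

    Raises
    ------
    KeyError
        If a (layer, position) pair present in the tissue has no entry in
        the growth spec.
    """
    rec = apply_growth_records(tissue.records, growth, seed=seed, time_hai=time_hai)
    return GroundTruthTissue(
        label_volume=tissue.label_volume, records=rec, axis_points=tissue.axis_points
    )


def apply_growth_records(records: pd.DataFrame, growth: GrowthSpec, seed: int = 0,
                         time_hai: float = 18.0) -> pd.DataFrame:
    """Record-level core of :func:`apply_growth`: works on any per-cell table
    with populated layer/position/dimension columns."""
    rng = np.random.default_rng(seed)
    rec = records.copy()
    needed = set(zip(rec["layer"].astype(int), rec["position"]))
    missing = sorted(needed - growth.covered_pairs())
    if missing:
        raise KeyError(f"growth spec missing (layer, position) entries: {missing}")

    n = len(rec)
    vol_factor = np.ones(n)
    for metric in GROWTH_METRICS:
        true_ratio = np.array(
            [growth.factor(int(l), p, metric) for l, p in zip(rec["layer"], rec["position"])]
        )
        noise = (
            np.exp(rng.normal(0.0, growth.sigma, size=n)) if growth.sigma > 0 else np.ones(n)
        )
        factor = true_ratio * noise
        rec[_METRIC_COLUMN[metric]] = rec[_METRIC_COLUMN[metric]] * factor
        vol_factor *= factor
    rec["volume_um3"] = rec["volume_um3"] * vol_factor
    rec["time_hai"] = time_hai
    return rec


def render_membrane_stack(volume, blur_sigma: float = 1.0, noise_sd: float = 0.0,
                          seed: int = 0) -> np.ndarray:
    """Render a membrane-stained intensity stack from a label volume.

    Voxels on label–label or label–background interfaces get intensity 1
    (emulating a cell-wall stain such as propidium iodide), the rest 0;
    the image is then Gaussian-blurred with ``blur_sigma`` voxels and
    corrupted with additive Gaussian noise of sd ``noise_sd``. Deterministic
    for a fixed seed. Returns a float32 stack.
    """
    if blur_sigma < 0:
        raise ValueError("blur_sigma must be >= 0")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    labels = as_label_array(volume)
    wall = np.zeros(labels.shape, dtype=bool)
    fg = labels > 0
    for axis in range(3):
        a = np.swapaxes(labels, 0, axis)
        m = np.swapaxes(wall, 0, axis)
        diff = a[1:] != a[:-1]
        m[1:] |= diff
        m[:-1] |= diff
    wall &= fg  # the stain marks cell walls, not the bathing medium
    img = wall.astype(np.float32)
    if blur_sigma > 0:
        img = ndi.gaussian_filter(img, sigma=blur_sigma)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_sd, size=img.shape).astype(np.float32)
    return img.astype(np.float32)
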