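"""Synthetic microscope fields, screen tables and flow events with truth.

The image generator emulates the screening assay's optical layout: cells
on a non-overlapping grid, each with a nuclear disk, a single bright
MTOC spot adjacent to the nucleus, and lysosomal puncta whose radial
placement is controlled by a clustered fraction κ — each punctum lands
(with probability κ) uniformly inside the measurement circle about the
MTOC, otherwise uniformly in the cytoplasm.  Because puncta are rendered
as finite-size Gaussians, centres keep a 3σ margin from the circle edge
and the cell edge so a punctum's intensity stays inside its region; the
per-cell circle-to-cytoplasm area fraction ``a`` is computed in closed
form on the placement region, making the expected in-circle intensity
fraction exactly κ + (1−κ)·a.

Noise is photon-limited (Poisson) by default; Gaussian read noise can be
added but defaults to zero because the simulated background is exactly
dark, so summed read noise would add a spurious pedestal to whole-cell
denominators that real images spread into their background estimate.

All generators are pure functions of (spec, seed): a fixed seed gives
bit-identical output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .errors import ValidationError
from .io import FieldImage


# --------------------------------------------------------------------------
# specs and truth containers


@dataclass
class SyntheticCellSpec:
    """Geometry, intensity and noise parameters of one synthetic field."""

    image_size: tuple[int, int] = (256, 256)
    pixel_size_um: float = 0.325
    n_cells: int = 9
    cell_radius_um: float = 10.0
    cell_radius_jitter_um: float = 0.5
    nucleus_radius_um: float = 4.0
    mtoc_offset_um: float = 1.5
    n_puncta: int = 60
    clustered_fraction: float = 0.5
    clustered_region_diameter_um: float = 7.0
    punctum_sigma_um: float = 0.3
    punctum_amplitude: float = 400.0
    nuclear_amplitude: float = 300.0
    tubulin_spot_amplitude: float = 800.0
    tubulin_spot_sigma_um: float = 0.4
    cytoplasm_fill: float = 30.0
    photon_noise: bool = True
    read_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.clustered_fraction <= 1:
            raise ValidationError("clustered_fraction must lie in [0, 1]")
        for name in (
            "pixel_size_um",
            "cell_radius_um",
            "nucleus_radius_um",
            "mtoc_offset_um",
            "clustered_region_diameter_um",
            "punctum_sigma_um",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if self.n_cells < 1 or self.n_puncta < 1:
            raise ValidationError("n_cells and n_puncta must be >= 1")
        if self.read_noise_sd < 0:
            raise ValidationError("read_noise_sd must be >= 0")
        min_radius = self.cell_radius_um - self.cell_radius_jitter_um
        margin = 3 * self.punctum_sigma_um
        reach = (
            self.nucleus_radius_um
            + self.mtoc_offset_um
            + self.clustered_region_diameter_um / 2
        )
        # clustered puncta sample from the circle shrunk by 3σ, so the
        # circle itself only needs to fit inside the smallest cell
        if reach > min_radius:
            raise ValidationError(
                "measurement circle does not fit inside the smallest cell: "
                f"nucleus + offset + circle radius = {reach:.2f} um exceeds "
                f"{min_radius:.2f} um"
            )
        if margin >= self.clustered_region_diameter_um / 2:
            raise ValidationError(
                "punctum size (3 sigma) exceeds the clustered-region radius"
            )
        if self.nucleus_radius_um >= min_radius:
            raise ValidationError("nucleus must be smaller than the cell")


@dataclass
class CellTruth:
    """Ground truth for one generated cell (pixel coordinates)."""

    label: int
    center: tuple[float, float]
    radius_um: float
    mtoc_position: tuple[float, float]
    puncta: np.ndarray  # (n, 2) punctum centres
    in_circle: np.ndarray  # bool per punctum
    circle_area_fraction: float  # a: |circle ∩ placement region| / |region|
    expected_in_circle_fraction: float  # κ + (1 − κ)·a
    true_in_circle_fraction: float  # realised fraction of puncta in circle

    def cell_mask(self, shape: tuple[int, int], pixel_size_um: float) -> np.ndarray:
        rr = np.arange(shape[0])[:, None] - self.center[0]
        cc = np.arange(shape[1])[None, :] - self.center[1]
        radius_px = self.radius_um / pixel_size_um
        return rr * rr + cc * cc <= radius_px * radius_px


@dataclass
class SyntheticTruth:
    """Everything the generator knows about one field."""

    spec: SyntheticCellSpec
    seed: int
    cells: list[CellTruth] = field(default_factory=list)

    def match_labels(self, labels: np.ndarray) -> dict[int, int]:
        """Map truth cell label -> label of a segmentation raster.

        Segmentation numbers objects in scan order, which need not agree
        with generation order; the recovered label is read off at each
        truth cell's nucleus centre (0 where segmentation missed it).
        """
        out = {}
        for cell in self.cells:
            r, c = int(round(cell.center[0])), int(round(cell.center[1]))
            out[cell.label] = int(labels[r, c])
        return out


# --------------------------------------------------------------------------
# geometry helpers


def _disk_overlap_area(d: float, r1: float, r2: float) -> float:
    """Area of intersection of two disks with radii r1, r2 at distance d."""
    if d >= r1 + r2:
        return 0.0
    if d <= abs(r1 - r2):
        r = min(r1, r2)
        return np.pi * r * r
    a1 = r1 * r1 * np.arccos((d * d + r1 * r1 - r2 * r2) / (2 * d * r1))
    a2 = r2 * r2 * np.arccos((d * d + r2 * r2 - r1 * r1) / (2 * d * r2))
    k = 0.5 * np.sqrt(
        (-d + r1 + r2) * (d + r1 - r2) * (d - r1 + r2) * (d + r1 + r2)
    )
    return float(a1 + a2 - k)


def _circle_annulus_fraction(
    d0: float, rc: float, r_inner: float, r_outer: float
) -> float:
    """|disk(rc) at distance d0 ∩ annulus(r_inner, r_outer)| / |annulus|."""
    annulus = np.pi * (r_outer**2 - r_inner**2)
    overlap = _disk_overlap_area(d0, rc, r_outer) - _disk_overlap_area(
        d0, rc, r_inner
    )
    return float(overlap / annulus)


def _add_gaussian(
    img: np.ndarray, r: float, c: float, amplitude: float, sigma_px: float
) -> None:
    """Accumulate an isotropic Gaussian spot sampled at pixel centres."""
    half = int(np.ceil(4 * sigma_px)) + 1
    r0, r1 = int(np.floor(r)) - half, int(np.floor(r)) + half + 1
    c0, c1 = int(np.floor(c)) - half, int(np.floor(c)) + half + 1
    r0, c0 = max(r0, 0), max(c0, 0)
    r1, c1 = min(r1, img.shape[0]), min(c1, img.shape[1])
    if r0 >= r1 or c0 >= c1:
        return
    rr = np.arange(r0, r1)[:, None] - r
    cc = np.arange(c0, c1)[None, :] - c
    img[r0:r1, c0:c1] += amplitude * np.exp(
        -(rr * rr + cc * cc) / (2 * sigma_px * sigma_px)
    )


def _sample_in_annulus(
    rng: np.random.Generator,
    n: int,
    r_inner: float,
    r_outer: float,
) -> np.ndarray:
    """Uniform points in an annulus, as (n, 2) offsets from its centre."""
    u = rng.uniform(r_inner**2, r_outer**2, size=n)
    radius = np.sqrt(u)
    theta = rng.uniform(0, 2 * np.pi, size=n)
    return np.column_stack([radius * np.sin(theta), radius * np.cos(theta)])


# --------------------------------------------------------------------------
# field generation


def generate_field(spec: SyntheticCellSpec) -> tuple[FieldImage, SyntheticTruth]:
    """Render one multi-channel field and its ground truth.

    Cells sit on a jittered grid and never overlap; a grid too small for
    ``n_cells`` raises a validation error suggesting a larger image.
    """
    px = spec.pixel_size_um
    h, w = spec.image_size
    r_max_px = (spec.cell_radius_um + spec.cell_radius_jitter_um) / px
    spacing = int(np.ceil(2 * r_max_px)) + 4
    # keep cells (and their smoothing halos) clear of the frame so border
    # exclusion never fires on construction-complete cells
    border = 8
    ny, nx = (h - 2 * border) // spacing, (w - 2 * border) // spacing
    if nx * ny < spec.n_cells:
        raise ValidationError(
            f"cannot place {spec.n_cells} non-overlapping cells on a "
            f"{h}x{w} image (grid fits {nx * ny}); use a larger image"
        )

    ss = np.random.SeedSequence(spec.seed)
    children = ss.spawn(spec.n_cells + 2)
    place_rng = np.random.default_rng(children[-2])
    noise_rng = np.random.default_rng(children[-1])

    nuclear = np.zeros((h, w))
    tubulin = np.zeros((h, w))
    lysosome = np.zeros((h, w))
    truth = SyntheticTruth(spec=spec, seed=spec.seed)

    rc = spec.clustered_region_diameter_um / 2  # analysis-circle radius, um
    sigma_margin = 3 * spec.punctum_sigma_um
    grid_sites = [(gy, gx) for gy in range(ny) for gx in range(nx)]

    yy = np.arange(h)[:, None]
    xx = np.arange(w)[None, :]

    for label, (gy, gx) in enumerate(grid_sites[: spec.n_cells], start=1):
        rng = np.random.default_rng(children[label - 1])
        radius_um = spec.cell_radius_um + rng.uniform(
            -spec.cell_radius_jitter_um, spec.cell_radius_jitter_um
        )
        cy = border + (gy + 0.5) * spacing + place_rng.uniform(-2, 2)
        cx = border + (gx + 0.5) * spacing + place_rng.uniform(-2, 2)

        # MTOC: fixed distance from the nucleus centre, random direction
        d0 = spec.nucleus_radius_um + spec.mtoc_offset_um
        theta = rng.uniform(0, 2 * np.pi)
        mtoc = (cy + d0 / px * np.sin(theta), cx + d0 / px * np.cos(theta))

        # placement region: cytoplasmic annulus with a 3σ inner margin at
        # the cell edge so rendered puncta stay inside the cell
        r_outer = radius_um - sigma_margin
        a = _circle_annulus_fraction(d0, rc, spec.nucleus_radius_um, r_outer)

        clustered = rng.random(spec.n_puncta) < spec.clustered_fraction
        puncta = np.empty((spec.n_puncta, 2))
        n_clustered = int(clustered.sum())
        if n_clustered:
            # uniform in the circle shrunk by 3σ, rejected into the annulus
            pts = []
            while len(pts) < n_clustered:
                cand = _sample_in_annulus(
                    rng, n_clustered, 0.0, rc - sigma_margin
                )
                cand_abs = cand + np.array(
                    [mtoc[0] * px - cy * px, mtoc[1] * px - cx * px]
                )
                dist = np.hypot(cand_abs[:, 0], cand_abs[:, 1])
                ok = (dist >= spec.nucleus_radius_um) & (dist <= r_outer)
                pts.extend(cand[ok].tolist())
            offsets = np.asarray(pts[:n_clustered])
            puncta[clustered, 0] = mtoc[0] + offsets[:, 0] / px
            puncta[clustered, 1] = mtoc[1] + offsets[:, 1] / px
        n_disp = spec.n_puncta - n_clustered
        if n_disp:
            offsets = _sample_in_annulus(
                rng, n_disp, spec.nucleus_radius_um, r_outer
            )
            puncta[~clustered, 0] = cy + offsets[:, 0] / px
            puncta[~clustered, 1] = cx + offsets[:, 1] / px

        dist_to_mtoc = (
            np.hypot(puncta[:, 0] - mtoc[0], puncta[:, 1] - mtoc[1]) * px
        )
        in_circle = dist_to_mtoc <= rc

        # render
        cell_px = radius_um / px
        cell_disk = ((yy - cy) ** 2 + (xx - cx) ** 2) <= cell_px**2
        nuc_px = spec.nucleus_radius_um / px
        nuc_disk = ((yy - cy) ** 2 + (xx - cx) ** 2) <= nuc_px**2
        nuclear[nuc_disk] += spec.nuclear_amplitude
        tubulin[cell_disk] += spec.cytoplasm_fill
        _add_gaussian(
            tubulin,
            mtoc[0],
            mtoc[1],
            spec.tubulin_spot_amplitude,
            spec.tubulin_spot_sigma_um / px,
        )
        for pr, pc in puncta:
            _add_gaussian(
                lysosome, pr, pc, spec.punctum_amplitude,
                spec.punctum_sigma_um / px,
            )

        truth.cells.append(
            CellTruth(
                label=label,
                center=(cy, cx),
                radius_um=float(radius_um),
                mtoc_position=mtoc,
                puncta=puncta,
                in_circle=in_circle,
                circle_area_fraction=a,
                expected_in_circle_fraction=(
                    spec.clustered_fraction
                    + (1 - spec.clustered_fraction) * a
                ),
                true_in_circle_fraction=float(in_circle.mean()),
            )
        )

    nuclear = ndi.gaussian_filter(nuclear, sigma=1.5)
    channels = {}
    for role, img in (
        ("nuclear", nuclear),
        ("tubulin", tubulin),
        ("lysosome", lysosome),
    ):
        if spec.photon_noise:
            img = noise_rng.poisson(img).astype(float)
        if spec.read_noise_sd > 0:
            img = img + noise_rng.normal(0, spec.read_noise_sd, img.shape)
        channels[role] = np.clip(np.round(img), 0, 65535).astype(np.uint16)

    field_img = FieldImage(
        field_id=f"synthetic-{spec.seed}",
        well_id="",
        channels=channels,
        pixel_size_um=px,
    )
    return field_img, truth


def generate_fields(
    spec: SyntheticCellSpec, n_fields: int
) -> list[tuple[FieldImage, SyntheticTruth]]:
    """Independent fields with per-field seeds derived from ``spec.seed``."""
    out = []
    for child in np.random.SeedSequence(spec.seed).spawn(n_fields):
        seed = int(child.generate_state(1)[0] & 0x7FFFFFFF)
        out.append(generate_field(dataclasses.replace(spec, seed=seed)))
    return out


# --------------------------------------------------------------------------
# screen tables


def generate_screen_table(
    n_compounds: int,
    n_planted_hits: int,
    seed: int,
    threshold: float = 1.1,
    hit_margin: float = 0.05,
    effect_scale: float = 0.15,
    control_noise_sd: float = 0.01,
    compound_ids: Optional[Sequence[str]] = None,
    prefix: str = "C",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-compound fold-change table with planted hits.

    Planted hits draw fold changes from ``threshold + hit_margin +
    Exp(effect_scale)``; non-hits are centred at 1 with Gaussian noise,
    clipped at the threshold so the planted labels are exact.  Returns
    (table, truth) where truth carries the ``is_hit`` labels.
    """
    if n_planted_hits > n_compounds:
        raise ValidationError("n_planted_hits cannot exceed n_compounds")
    if hit_margin < 0:
        raise ValidationError(
            "hit_margin must be >= 0: the hit effect distribution would "
            "put mass below the threshold"
        )
    if control_noise_sd < 0:
        raise ValidationError("control_noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    if compound_ids is None:
        width = len(str(n_compounds))
        compound_ids = [f"{prefix}{i + 1:0{width}d}" for i in range(n_compounds)]
    elif len(compound_ids) != n_compounds:
        raise ValidationError("compound_ids length must equal n_compounds")
    is_hit = np.zeros(n_compounds, dtype=bool)
    if n_planted_hits:
        is_hit[rng.choice(n_compounds, size=n_planted_hits, replace=False)] = True
    fold = np.empty(n_compounds)
    n_null = n_compounds - n_planted_hits
    fold[~is_hit] = np.minimum(
        1.0 + rng.normal(0, control_noise_sd, n_null), threshold
    )
    fold[is_hit] = (
        threshold + hit_margin + rng.exponential(effect_scale, n_planted_hits)
    )
    table = pd.DataFrame(
        {"compound_id": list(compound_ids), "fold_change": fold}
    )
    labels = pd.DataFrame(
        {"compound_id": list(compound_ids), "is_hit": is_hit}
    )
    return table, labels


# --------------------------------------------------------------------------
# flow events


def generate_flow_events(
    n_events: int,
    dead_fraction: float,
    rfp_negative_fraction: float,
    seed: int,
    median_ratio: float = 1.0,
    ratio_sigma: float = 0.4,
    dapi_max: float = 1000.0,
    rfp_min: float = 100.0,
) -> tuple[pd.DataFrame, dict]:
    """Per-event GFP/RFP/DAPI intensities with planted gate outcomes.

    Dead events exceed the DAPI gate; RFP-negative events fall below
    ``rfp_min``; live reporter-positive events carry per-event RFP/GFP
    ratios log-normally distributed about ``median_ratio``.  Planted
    category counts are exact, so gating recovers them identically.
    """
    for name, val in (
        ("dead_fraction", dead_fraction),
        ("rfp_negative_fraction", rfp_negative_fraction),
    ):
        if not 0 <= val <= 1:
            raise ValidationError(f"{name} must lie in [0, 1]")
    if dead_fraction + rfp_negative_fraction > 1:
        raise ValidationError("dead + RFP-negative fractions exceed 1")
    rng = np.random.default_rng(seed)
    n_dead = int(round(n_events * dead_fraction))
    n_neg = int(round(n_events * rfp_negative_fraction))
    n_live = n_events - n_dead - n_neg

    gfp = np.empty(n_events)
    rfp = np.empty(n_events)
    dapi = np.empty(n_events)

    idx = rng.permutation(n_events)
    dead_idx = idx[:n_dead]
    neg_idx = idx[n_dead : n_dead + n_neg]
    live_idx = idx[n_dead + n_neg :]

    dapi[dead_idx] = dapi_max * rng.uniform(2, 10, n_dead)
    dapi[neg_idx] = dapi_max * rng.uniform(0, 0.5, n_neg)
    dapi[live_idx] = dapi_max * rng.uniform(0, 0.5, n_live)

    gfp[dead_idx] = rng.lognormal(np.log(500), 0.3, n_dead)
    rfp[dead_idx] = rng.lognormal(np.log(500), 0.3, n_dead)

    gfp[neg_idx] = rng.lognormal(np.log(500), 0.3, n_neg)
    rfp[neg_idx] = rfp_min * rng.uniform(0, 0.8, n_neg)

    # live reporter-positive: RFP strictly above the gate, ratio exact
    ratios = median_ratio * rng.lognormal(0.0, ratio_sigma, n_live)
    rfp_live = rfp_min * (1.0 + rng.lognormal(np.log(5), 0.5, n_live))
    rfp[live_idx] = rfp_live
    gfp[live_idx] = rfp_live / ratios

    events = pd.DataFrame({"gfp": gfp, "rfp": rfp, "dapi": dapi})
    truth = {
        "n_events": n_events,
        "n_dead": n_dead,
        "n_rfp_negative": n_neg,
        "n_live_positive": n_live,
        "median_ratio": median_ratio,
        "dapi_max": dapi_max,
        "rfp_min": rfp_min,
        "seed": seed,
    }
    return events, truth
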