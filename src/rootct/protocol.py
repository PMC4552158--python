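"""The five-step segmentation protocol and root-volume quantification.

The protocol segments roots *indirectly*: minerals are far easier to separate
from air than roots are, so the soil is segmented first and removed, together
with its shell of partial-volume ("mixed") voxels whose gray values mimic
roots.  Only roots and air/water-filled pores remain, where a second surface
determination cleanly isolates the roots; residual debris and noise are
removed by a connected-component size threshold.

Steps
-----
1. Gradient-refined surface determination of all mineral structures
   (air = background, minerals = material) on the whole volume.
2. Dilation of the mineral ROI by a fractional voxel radius (default 1) to
   absorb the mixed-voxel shell.
3. Subtraction of the dilated ROI from the whole-volume ROI: the remaining
   domain holds only roots and pores.
4. Gradient-refined surface determination of the roots inside that domain.
5. Connected-component labeling and deletion of every structure smaller than
   ``min_component_voxels`` (default 10,000) connected voxels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy import stats

from .io import ROIMask, VoxelVolume
from .morphology import dilate_roi, label_components, size_filter, subtract_roi
from .surface import (MaterialExample, SurfaceDeterminationParams,
                      advanced_surface_determination, define_material_by_example)

__all__ = [
    "ProtocolParams",
    "SegmentationResult",
    "RegressionReport",
    "run_protocol",
    "root_volume",
    "regress_volume_vs_mass",
]


class ConfigurationError(ValueError):
    """Raised when protocol parameters cannot produce a meaningful run."""


@dataclass
class ProtocolParams:
    """All tunables of the five-step protocol.

    Either example areas or explicit thresholds may be given per stage; a
    threshold, when present, overrides the example-derived midpoint (this is
    how one sample's interactively found threshold is reused across a batch).
    """

    soil_examples: MaterialExample | None = None
    root_examples: MaterialExample | None = None
    soil_threshold: float | None = None
    root_threshold: float | None = None
    dilation_radius_voxels: float = 1.0
    min_component_voxels: int = 10_000
    connectivity: int = 26
    surface_params: SurfaceDeterminationParams = field(
        default_factory=SurfaceDeterminationParams)
    whole_volume_margin: int = 1

    def __post_init__(self) -> None:
        if self.dilation_radius_voxels < 0:
            raise ValueError("dilation_radius_voxels must be non-negative")
        if self.min_component_voxels < 1:
            raise ValueError("min_component_voxels must be >= 1")


@dataclass
class SegmentationResult:
    """Final root mask plus the per-step audit trail of the protocol run."""

    root_mask: ROIMask
    root_volume_mm3: float
    component_count: int
    step_log: list


def root_volume(mask: ROIMask, voxel_size_mm: float | None = None) -> float:
    """Physical root volume in mm³: foreground voxels times the voxel volume."""
    vs = voxel_size_mm if voxel_size_mm is not None else mask.voxel_size_mm
    return int(mask.data.sum()) * vs**3


def _resolve_threshold(volume, examples, override, stage: str):
    if override is not None:
        return float(override), True
    if examples is None:
        raise ConfigurationError(
            f"{stage}: provide example areas or an explicit threshold")
    res = define_material_by_example(volume, examples)
    return res.threshold, res.material_brighter


def run_protocol(volume: VoxelVolume, params: ProtocolParams) -> SegmentationResult:
    """Run the five-step protocol end to end on one volume.

    Deterministic: identical volume and parameters give a bit-identical root
    mask.  The final mask is disjoint from the dilated mineral ROI by
    construction of step 3 (asserted).
    """
    vs = volume.voxel_size_mm
    log: list[dict] = []
    m = params.whole_volume_margin
    whole = np.zeros(volume.shape, bool)
    whole[m:volume.shape[0] - m, m:volume.shape[1] - m, m:volume.shape[2] - m] = True
    whole_roi = ROIMask(whole, vs, label="whole_volume")

    # step 1: mineral surface determination on the whole volume
    soil_thr, _ = _resolve_threshold(volume, params.soil_examples,
                                     params.soil_threshold, "step 1 (soil)")
    mineral = advanced_surface_determination(
        volume, whole_roi, soil_thr, params.surface_params,
        material_brighter=True, label="mineral")
    log.append({"step": 1, "name": "mineral_surface_determination",
                "threshold": soil_thr, "foreground_voxels": mineral.voxel_count()})

    # step 2: dilate to absorb the mixed-voxel shell
    mineral_dil = dilate_roi(mineral, params.dilation_radius_voxels)
    log.append({"step": 2, "name": "mineral_dilation",
                "radius_voxels": params.dilation_radius_voxels,
                "foreground_voxels": mineral_dil.voxel_count()})

    # step 3: only roots and air/water-filled pores remain
    domain = subtract_roi(whole_roi, mineral_dil)
    domain.label = "roots_and_pores_domain"
    if not domain.data.any():
        raise ConfigurationError("roots-and-pores domain is empty after step 3; "
                                 "check the soil threshold and dilation radius")
    log.append({"step": 3, "name": "roi_subtraction",
                "foreground_voxels": domain.voxel_count()})

    # step 4: root surface determination inside the domain
    root_thr, _ = _resolve_threshold(volume, params.root_examples,
                                     params.root_threshold, "step 4 (roots)")
    roots_raw = advanced_surface_determination(
        volume, domain, root_thr, params.surface_params,
        material_brighter=True, label="roots_raw")
    log.append({"step": 4, "name": "root_surface_determination",
                "threshold": root_thr, "foreground_voxels": roots_raw.voxel_count()})

    # step 5: size-threshold noise elimination
    labeling = label_components(roots_raw, params.connectivity)
    root_mask, report = size_filter(labeling, params.min_component_voxels)
    log.append({"step": 5, "name": "size_filter",
                "foreground_voxels": root_mask.voxel_count(), **report})

    assert not (root_mask.data & mineral_dil.data).any(), \
        "root mask overlaps the dilated mineral ROI"
    return SegmentationResult(
        root_mask=root_mask,
        root_volume_mm3=root_volume(root_mask, vs),
        component_count=report["retained_components"],
        step_log=log,
    )


class RegressionReport(NamedTuple):
    """OLS fit of washed-root dry mass against CT root volume."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int
    dry_matter_fraction: float


def regress_volume_vs_mass(pairs) -> RegressionReport:
    """Ordinary least squares of dry mass (g) on CT root volume (mm³).

    CT volume is closely correlated with fresh mass (root density is near
    1 g/cm³ = 0.001 g/mm³), so the slope, expressed per gram of
    fresh-weight-equivalent, is an implied dry-matter content:
    ``dry_matter_fraction = slope * 1000``.
    """
    arr = np.asarray(pairs, dtype=np.float64)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValueError("need at least 3 (ct_volume_mm3, dry_mass_g) pairs")
    x, y = arr[:, 0], arr[:, 1]
    if np.ptp(x) == 0:
        raise ValueError("degenerate regressor: all CT volumes are equal")
    fit = stats.linregress(x, y)
    return RegressionReport(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        p_value=float(fit.pvalue),
        n=len(x),
        dry_matter_fraction=float(fit.slope) * 1000.0,
    )
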