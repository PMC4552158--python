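"""Evaluation of segmentation results against phantom ground truth."""

from __future__ import annotations

from dataclasses import dataclass, asdict

from .io import ROIMask
from .morphology import label_components
from .phantom import PhantomTruth
from .protocol import SegmentationResult
from .region_growing import compare_masks

__all__ = ["EvaluationReport", "evaluate"]


@dataclass
class EvaluationReport:
    """Voxel-overlap and volume-recovery metrics for one phantom run."""

    dice: float
    precision: float
    recall: float
    volume_error_fraction: float
    component_count_true: int
    component_count_found: int
    true_voxels: int
    found_voxels: int
    step_log: list

    def to_dict(self) -> dict:
        return asdict(self)


def evaluate(result: SegmentationResult, truth: PhantomTruth,
             connectivity: int = 26) -> EvaluationReport:
    """Compare a protocol result with phantom truth.

    ``volume_error_fraction`` is signed: (found - true) / true.
    """
    found = result.root_mask
    true = truth.root_mask
    if found.shape != true.shape:
        raise ValueError(f"shape mismatch: {found.shape} vs {true.shape}")
    if not true.data.any():
        raise ValueError("ground-truth root mask is empty; volume error undefined")
    ov = compare_masks(found, true)
    n_true = label_components(true, connectivity).n_components
    return EvaluationReport(
        dice=ov.dice,
        precision=ov.precision,
        recall=ov.recall,
        volume_error_fraction=(found.voxel_count() - true.voxel_count())
        / true.voxel_count(),
        component_count_true=n_true,
        component_count_found=result.component_count,
        true_voxels=true.voxel_count(),
        found_voxels=found.voxel_count(),
        step_log=result.step_log,
    )
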