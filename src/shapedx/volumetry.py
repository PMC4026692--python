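"""Structure volumes and head-size (ICV) regression normalization.

Gross atrophy is measured as the volume of the binary segmentation.  Raw
volumes scale with head size, so they are normalized against intracranial
volume with the covariance method::

    V_norm = V_abs - k * (ICV - ICV_mean)

where ``k`` is the OLS slope of structure volume on ICV over a reference
group (normal controls by default) and ``ICV_mean`` is that group's mean ICV.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import BinaryMask, CohortTable

__all__ = [
    "NormalizationModel",
    "mask_volume",
    "fit_normalization",
    "normalize_volume",
    "cohort_volumes",
]


@dataclass(frozen=True)
class NormalizationModel:
    """Fitted ICV regression: slope ``k``, reference-group mean ICV."""

    k: float
    icv_mean: float
    reference_group: str = "NC"

    def __post_init__(self) -> None:
        if not np.isfinite(self.k):
            raise ValueError("k must be finite")
        if self.icv_mean <= 0:
            raise ValueError("icv_mean must be positive")


def mask_volume(mask: BinaryMask) -> float:
    """Volume in mm³: foreground voxel count times voxel volume."""
    return mask.n_foreground * mask.voxel_volume


def fit_normalization(
    volumes: np.ndarray | list[float],
    icvs: np.ndarray | list[float],
    reference_group: str = "NC",
) -> NormalizationModel:
    """OLS fit of structure volume on ICV over the reference subjects.

    ``k`` is the slope of a simple linear regression (with intercept) of
    ``volumes`` on ``icvs``; ``icv_mean`` is the mean of ``icvs``.
    """
    v = np.asarray(volumes, dtype=float)
    icv = np.asarray(icvs, dtype=float)
    if v.shape != icv.shape or v.ndim != 1:
        raise ValueError("volumes and icvs must be 1D and equal length")
    if len(v) < 3:
        raise ValueError(f"need >= 3 reference subjects, got {len(v)}")
    if np.ptp(icv) == 0:
        raise ValueError("degenerate regression: constant ICV")
    slope = stats.linregress(icv, v).slope
    return NormalizationModel(k=float(slope), icv_mean=float(icv.mean()),
                              reference_group=reference_group)


def normalize_volume(v_abs: float, icv: float, model: NormalizationModel) -> float:
    """Apply ``V_norm = V_abs - k * (ICV - ICV_mean)``."""
    return float(v_abs) - model.k * (float(icv) - model.icv_mean)


def cohort_volumes(
    cohort: CohortTable,
    masks: dict[str, BinaryMask],
    structure: str = "structure",
    reference_group: str = "NC",
    fit_on_all: bool = False,
) -> tuple[pd.DataFrame, NormalizationModel]:
    """Per-subject absolute and normalized volumes for one structure.

    ``masks`` maps subject_id to that subject's binary mask.  The slope is
    fitted on the reference group unless ``fit_on_all`` is set.

    Returns a table with columns subject_id, structure, v_abs_mm3, v_norm_mm3
    and the fitted model.
    """
    rows = []
    for sid in cohort.subject_ids:
        rows.append({"subject_id": sid, "structure": structure,
                     "v_abs_mm3": mask_volume(masks[sid])})
    vol = pd.DataFrame(rows).merge(
        cohort.table[["subject_id", "group", "icv"]], on="subject_id"
    )
    ref = vol if fit_on_all else vol[vol["group"] == reference_group]
    model = fit_normalization(ref["v_abs_mm3"], ref["icv"], reference_group)
    vol["v_norm_mm3"] = [
        normalize_volume(v, icv, model) for v, icv in zip(vol["v_abs_mm3"], vol["icv"])
    ]
    return vol[["subject_id", "structure", "v_abs_mm3", "v_norm_mm3"]], model
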