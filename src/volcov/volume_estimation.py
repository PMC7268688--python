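"""Atlas-based regional volume estimation from registration outputs.

A subject's image is registered to a labelled template by a rigid rotation,
an affine transform, and a nonlinear warp.  The volume of region *i* in the
subject is then recovered from template space as

    V_i = (Σ_{voxels of region i} J_F) · v  /  (|det A_rigid| · |det A_affine|)

where the sum runs over template voxels carrying the region's label, ``J_F``
is the Jacobian-determinant field of the *nonlinear* component of the warp
sampled on the template grid, ``v`` is the template voxel volume (mm³), and
the 3×3 upper-left blocks of the rigid and affine matrices supply the linear
determinants.  Under a purely linear registration J_F ≡ 1 and linear scaling
enters solely through the denominator; an individual that is an exact affine
scaling *s* of the template therefore gets volume (template volume)/s³.

A ``literal_linear_jacobian`` switch replaces the field by the constant
1/(|det rigid|·|det affine|) — the alternative reading in which the linear
determinant also enters the numerator — for comparison; it double-counts
linear scaling and is off by default.

Transforms map individual → template.  Voxels are counted by exact label
equality (no partial-volume weighting), and summation is exact (compensated),
so the result is independent of voxel iteration order.
"""

from __future__ import annotations

import math
from typing import Mapping

import numpy as np

from .core_data import Region, RegionAtlas, RegistrationFixture, VolumeTable

__all__ = ["region_volume", "all_region_volumes", "RegionVolumeResult"]


def _linear_determinants(fixture: RegistrationFixture) -> tuple[float, float]:
    det_r = abs(float(np.linalg.det(fixture.rigid[:3, :3])))
    det_a = abs(float(np.linalg.det(fixture.affine[:3, :3])))
    if det_r <= 0 or det_a <= 0:
        raise ValueError(
            f"linear transform determinants must be positive, got "
            f"rigid={det_r}, affine={det_a}"
        )
    return det_r, det_a


def region_volume(
    fixture: RegistrationFixture,
    label_code: int,
    literal_linear_jacobian: bool = False,
) -> float:
    """Estimated volume (mm³) of the region with the given label code."""
    mask = fixture.label_map == label_code
    if not mask.any():
        raise ValueError(f"label code {label_code} not present in label map")
    det_r, det_a = _linear_determinants(fixture)
    if literal_linear_jacobian:
        jac_sum = mask.sum() / (det_r * det_a)
    else:
        # math.fsum is correctly rounded: permutation-invariant by construction
        jac_sum = math.fsum(fixture.jacobian[mask].tolist())
    return jac_sum * fixture.voxel_volume / (det_r * det_a)


class RegionVolumeResult(dict):
    """Mapping region column name → volume, plus the regions left missing.

    Regions absent from the label map are *reported*, never imputed as zero:
    a missing region is a coverage defect of the label map, not an empty
    structure.
    """

    def __init__(self, volumes: Mapping[str, float], missing: list[Region]):
        super().__init__(volumes)
        self.missing = missing


def all_region_volumes(
    fixture: RegistrationFixture,
    atlas: RegionAtlas,
    subject_id: str,
    literal_linear_jacobian: bool = False,
) -> RegionVolumeResult:
    """Estimate every atlas region's volume for one subject.

    Returns a mapping of region column name → volume for the regions present
    in the label map, with the absent regions listed in ``.missing``.
    """
    fixture.validate_against(atlas)
    present = set(np.unique(fixture.label_map).tolist()) - {0}
    volumes: dict[str, float] = {}
    missing: list[Region] = []
    for region, col in zip(atlas.regions, atlas.column_names):
        if region.label_code in present:
            volumes[col] = region_volume(
                fixture, region.label_code, literal_linear_jacobian
            )
        else:
            missing.append(region)
    return RegionVolumeResult(volumes, missing)


def volumes_to_table(
    rows: Mapping[str, RegionVolumeResult],
    atlas: RegionAtlas,
    workflow: str = "unspecified",
    measurement_id: int = 1,
) -> VolumeTable:
    """Assemble per-subject volume results into a VolumeTable.

    Every subject must cover all 64 regions; missing regions abort with the
    subjects and regions named.
    """
    bad = {
        sid: [f"{r.name} ({r.hemisphere})" for r in res.missing]
        for sid, res in rows.items()
        if res.missing
    }
    if bad:
        raise ValueError(f"incomplete atlas coverage: {bad}")
    cols = atlas.column_names
    values = np.array([[rows[sid][c] for c in cols] for sid in rows])
    return VolumeTable(
        subject_ids=list(rows),
        region_names=cols,
        values=values,
        workflow=workflow,
        measurement_id=measurement_id,
    )
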