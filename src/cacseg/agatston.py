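"""Agatston calcium scoring: lesion extraction, per-lesion scores, risk categories.

The Agatston score of a lesion is the sum over axial slices of the calcified
plaque area (mm^2) times a density weight derived from the peak attenuation on
that slice (130-199 HU -> 1, 200-299 -> 2, 300-399 -> 3, >= 400 -> 4). Slice
contributions below 1 mm^2 are ignored, the standard minimum-size rule. The
patient score is the sum over lesions; cardiovascular risk categories are
I: 0 AU, II: (0, 100), III: [100, 300], IV: > 300 AU (category boundaries are
a configurable policy, since conventions differ on whether exactly 100 or
300 AU falls in the lower or upper group).

Lesions are maximal 26-connected 3-D components of the thresholded volume:
a calcification spanning several slices is one object for segment-level
counting, with per-slice areas computed inside the component.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .phantom import CTVolume, LabelVolume, CALCIUM_THRESHOLD_HU
from .segments import SegmentDiagram, SEGMENT_LABELS, load_default_diagram

__all__ = [
    "Lesion",
    "ScoreReport",
    "RiskPolicy",
    "candidate_mask",
    "find_lesions",
    "density_weight",
    "agatston_score",
    "risk_category",
    "score_report",
]

MIN_SLICE_AREA_MM2 = 1.0


@dataclass
class Lesion:
    """One connected calcified component.

    ``per_slice_areas`` holds ``(slice_index, area_mm2, peak_hu)`` for every
    slice the component intersects; ``segment`` is an adapted segment label or
    None if unassigned.
    """

    lesion_id: int
    voxel_set: np.ndarray  # (n, 3) int indices (slice, row, column)
    per_slice_areas: list[tuple[int, float, float]]
    peak_hu: float
    volume_mm3: float
    segment: str | None = None

    @property
    def n_voxels(self) -> int:
        return len(self.voxel_set)


@dataclass(frozen=True)
class RiskPolicy:
    """Boundary policy for the four CVD risk categories.

    With the defaults a total of exactly 100 AU falls in category III and
    exactly 300 AU in category III (i.e. II = (0, 100), III = [100, 300],
    IV = (300, inf)).
    """

    cat_iii_lower: float = 100.0
    cat_iv_lower: float = 300.0
    iii_includes_lower: bool = True
    iv_excludes_lower: bool = True

    def category(self, total: float) -> str:
        if total < 0:
            raise ValueError("Agatston total must be non-negative")
        if total == 0:
            return "I"
        if (total < self.cat_iii_lower
                or (total == self.cat_iii_lower and not self.iii_includes_lower)):
            return "II"
        if (total < self.cat_iv_lower
                or (total == self.cat_iv_lower and self.iv_excludes_lower)):
            return "III"
        return "IV"


@dataclass
class ScoreReport:
    """Agatston scores aggregated per segment, per vessel and per patient."""

    per_segment: dict[str, float]
    per_vessel: dict[str, float]
    total: float
    risk_category: str
    lesions: list[Lesion] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "total": self.total,
            "risk_category": self.risk_category,
            "per_segment": self.per_segment,
            "per_vessel": self.per_vessel,
            "n_lesions": len(self.lesions),
        }


def candidate_mask(image: CTVolume) -> np.ndarray:
    """Binary candidate lesion mask: voxels at or above 130 HU."""
    return image.voxels >= CALCIUM_THRESHOLD_HU


def density_weight(peak_hu: float) -> int:
    """Agatston density weight from the peak attenuation of a slice."""
    if peak_hu < CALCIUM_THRESHOLD_HU:
        raise ValueError(f"peak {peak_hu} HU below the 130 HU scoring threshold")
    if peak_hu < 200:
        return 1
    if peak_hu < 300:
        return 2
    if peak_hu < 400:
        return 3
    return 4


def find_lesions(
    mask: np.ndarray | LabelVolume,
    image: CTVolume,
    min_slice_area_mm2: float = MIN_SLICE_AREA_MM2,
) -> list[Lesion]:
    """Extract lesions as maximal 26-connected 3-D components of ``mask``.

    ``mask`` may be binary or a segment-labeled volume (any nonzero voxel is
    foreground; labels are ignored here, lesion-to-segment assignment is a
    separate step). Components whose in-plane area is below
    ``min_slice_area_mm2`` on every slice are discarded; qualifying components
    keep all their slices, but sub-threshold slices contribute 0 to the score.
    """
    m = mask.voxels if isinstance(mask, LabelVolume) else np.asarray(mask)
    if m.shape != image.shape:
        raise ValueError(f"mask shape {m.shape} != image shape {image.shape}")
    labeled, n = ndimage.label(m != 0, structure=np.ones((3, 3, 3)))
    area = image.pixel_area_mm2
    lesions: list[Lesion] = []
    lesion_id = 0
    for cid in range(1, n + 1):
        idx = np.argwhere(labeled == cid)
        slices = np.unique(idx[:, 0])
        per_slice = []
        for z in slices:
            sel = idx[idx[:, 0] == z]
            a = len(sel) * area
            peak = float(image.voxels[sel[:, 0], sel[:, 1], sel[:, 2]].max())
            per_slice.append((int(z), float(a), peak))
        if max(a for _, a, _ in per_slice) < min_slice_area_mm2:
            continue  # too small on every slice: noise speck, not a lesion
        lesion_id += 1
        lesions.append(Lesion(
            lesion_id=lesion_id,
            voxel_set=idx,
            per_slice_areas=per_slice,
            peak_hu=float(image.voxels[idx[:, 0], idx[:, 1], idx[:, 2]].max()),
            volume_mm3=len(idx) * image.voxel_volume_mm3,
        ))
    return lesions


def agatston_score(lesion: Lesion,
                   min_slice_area_mm2: float = MIN_SLICE_AREA_MM2) -> float:
    """Agatston contribution of one lesion.

    Sum over slices of (area mm^2 x density weight of the slice peak HU);
    slices below the minimum area contribute nothing.
    """
    score = 0.0
    for _, area, peak in lesion.per_slice_areas:
        if area < min_slice_area_mm2:
            continue
        score += area * density_weight(peak)
    return score


def risk_category(total: float, policy: RiskPolicy | None = None) -> str:
    """CVD risk category (I-IV) for a patient-level Agatston total."""
    return (policy or RiskPolicy()).category(total)


def assign_segments_from_mask(lesions: list[Lesion], cac_mask: LabelVolume) -> None:
    """Set each lesion's segment to the majority nonzero label over its voxels."""
    vox = cac_mask.voxels
    for les in lesions:
        labels = vox[les.voxel_set[:, 0], les.voxel_set[:, 1], les.voxel_set[:, 2]]
        labels = labels[labels > 0]
        if labels.size:
            les.segment = SEGMENT_LABELS[np.bincount(labels).argmax() - 1]


def score_report(
    lesions: list[Lesion],
    diagram: SegmentDiagram | None = None,
    policy: RiskPolicy | None = None,
) -> ScoreReport:
    """Aggregate per-lesion Agatston scores to segment, vessel and patient level."""
    diagram = diagram or load_default_diagram()
    per_segment = {lab: 0.0 for lab in diagram.labels}
    per_vessel = {v: 0.0 for v in ("RCA", "LM", "LAD", "LCX")}
    for les in lesions:
        if les.segment is None:
            raise ValueError(f"lesion {les.lesion_id} has no segment assignment")
        s = agatston_score(les)
        per_segment[les.segment] += s
        per_vessel[diagram.vessel_of(les.segment)] += s
    total = sum(per_segment.values())
    return ScoreReport(
        per_segment=per_segment,
        per_vessel=per_vessel,
        total=total,
        risk_category=risk_category(total, policy),
        lesions=list(lesions),
    )
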