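"""Adapted 13-segment coronary diagram for segment-level calcium scoring.

The standard SCCT coronary segmentation diagram is defined for contrast-enhanced
CT angiography. On non-contrast calcium-scoring CT, small side branches (e.g. the
obtuse marginals, or PDA/PLB) cannot be separated reliably, so the diagram is
collapsed to 13 classes: proximal/mid/distal/side branches of RCA, LAD and LCX,
plus the left main (LM). This module encodes the label set, the mapping from SCCT
segment identifiers, vessel grouping, adjacency of anatomically contiguous
segments, and the disagreement-weight matrix used by the weighted Cohen's kappa.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = [
    "SEGMENT_LABELS",
    "VESSELS",
    "SegmentDiagram",
    "load_default_diagram",
]

#: Canonical segment order; confusion matrices and label volumes use this order
#: (label volume code ``i+1`` is ``SEGMENT_LABELS[i]``, 0 is background).
SEGMENT_LABELS = (
    "p-RCA", "m-RCA", "d-RCA", "s-RCA",
    "LM",
    "p-LAD", "m-LAD", "d-LAD", "s-LAD",
    "p-LCX", "m-LCX", "d-LCX", "s-LCX",
)

VESSELS = ("RCA", "LM", "LAD", "LCX")


@dataclass(frozen=True)
class SegmentDiagram:
    """The adapted coronary segment diagram.

    Parameters
    ----------
    labels : tuple of str
        The 13 adapted segment labels in canonical order.
    scct_map : dict
        Mapping from SCCT segment identifier (string, e.g. ``"4a"``) to an
        adapted label.
    vessel_map : dict
        Mapping from adapted label to vessel (``RCA``/``LM``/``LAD``/``LCX``).
    adjacency : frozenset of frozenset
        Unordered pairs of adjoining segment labels.
    """

    labels: tuple[str, ...]
    scct_map: dict[str, str]
    vessel_map: dict[str, str]
    adjacency: frozenset[frozenset[str]] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if len(self.labels) != 13 or len(set(self.labels)) != 13:
            raise ValueError("diagram requires exactly 13 unique segment labels")
        for tgt in self.scct_map.values():
            if tgt not in self.labels:
                raise ValueError(f"scct_map target {tgt!r} is not a diagram label")
        if set(self.scct_map.values()) != set(self.labels):
            raise ValueError("scct_map must cover every adapted label")
        if set(self.vessel_map) != set(self.labels):
            raise ValueError("vessel_map must cover every adapted label")
        for pair in self.adjacency:
            if len(pair) != 2:
                raise ValueError("adjacency pairs must contain two distinct labels")
            if not pair <= set(self.labels):
                raise ValueError(f"adjacency pair {set(pair)} outside diagram labels")

    # -- lookups -----------------------------------------------------------

    def index(self, label: str) -> int:
        """Canonical 0-based index of an adapted segment label."""
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown segment label {label!r}") from None

    def map_scct_segment(self, scct_id: str | int) -> str:
        """Map an SCCT segment identifier to its adapted segment label.

        Accepts integers for purely numeric identifiers (``5 -> "LM"``).
        """
        key = str(scct_id)
        try:
            return self.scct_map[key]
        except KeyError:
            raise KeyError(f"unknown SCCT segment identifier {key!r}") from None

    def vessel_of(self, label: str) -> str:
        """Vessel (RCA, LM, LAD, LCX) a segment belongs to."""
        try:
            return self.vessel_map[label]
        except KeyError:
            raise KeyError(f"unknown segment label {label!r}") from None

    def is_adjoining(self, a: str, b: str) -> bool:
        """Whether two distinct segments adjoin anatomically."""
        for lab in (a, b):
            if lab not in self.labels:
                raise KeyError(f"unknown segment label {lab!r}")
        return frozenset((a, b)) in self.adjacency

    def disagreement_weights(self) -> np.ndarray:
        """13x13 disagreement weight matrix for the weighted Cohen's kappa.

        Correct assignments carry weight 0, misclassification between adjoining
        segments 0.5, and all other misclassifications 1.0. Symmetric.
        """
        k = len(self.labels)
        w = np.ones((k, k))
        np.fill_diagonal(w, 0.0)
        for pair in self.adjacency:
            a, b = tuple(pair)
            i, j = self.index(a), self.index(b)
            w[i, j] = w[j, i] = 0.5
        return w


def load_default_diagram() -> SegmentDiagram:
    """Load the adapted 13-segment diagram shipped with the package."""
    ref = importlib.resources.files("cacseg.data") / "segment_diagram.yaml"
    cfg = yaml.safe_load(ref.read_text())
    return SegmentDiagram(
        labels=tuple(cfg["labels"]),
        scct_map={str(k): v for k, v in cfg["scct_map"].items()},
        vessel_map=dict(cfg["vessel_map"]),
        adjacency=frozenset(frozenset(p) for p in cfg["adjacency"]),
    )
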