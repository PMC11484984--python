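import numpy as np
import pytest

import cacseg
from cacseg import PhantomConfig


@pytest.fixture(scope="session")
def diagram():
    return cacseg.load_default_diagram()


@pytest.fixture(scope="session")
def phantom_case():
    """One default phantom, shared across read-only tests."""
    return cacseg.generate_phantom(seed=42)


@pytest.fixture(scope="session")
def zero_cac_case():
    return cacseg.generate_phantom(PhantomConfig(zero_cac=True), seed=7)


@pytest.fixture(scope="session")
def segment_cm():
    return cacseg.load_reference_segment_confusion()


@pytest.fixture(scope="session")
def risk_cm():
    return cacseg.load_reference_risk_confusion()


def brute_force_agatston(image, mask, min_area_mm2=1.0):
    """Independent per-voxel Agatston oracle: pure-python flood fill over a
    boolean mask, per-slice areas and density weights recomputed from scratch.
    Only suitable for small volumes."""
    vox = image.voxels
    fg = np.asarray(mask) != 0
    area = image.in_plane_spacing[0] * image.in_plane_spacing[1]
    visited = np.zeros_like(fg, dtype=bool)
    shape = fg.shape
    offsets = [(dz, dy, dx)
               for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
               if (dz, dy, dx) != (0, 0, 0)]
    total = 0.0
    comps = 0
    for start in zip(*np.nonzero(fg)):
        if visited[start]:
            continue
        stack, comp = [start], []
        visited[start] = True
        while stack:
            v = stack.pop()
            comp.append(v)
            for dz, dy, dx in offsets:
                w = (v[0] + dz, v[1] + dy, v[2] + dx)
                if (0 <= w[0] < shape[0] and 0 <= w[1] < shape[1]
                        and 0 <= w[2] < shape[2] and fg[w] and not visited[w]):
                    visited[w] = True
                    stack.append(w)
        by_slice = {}
        for v in comp:
            by_slice.setdefault(v[0], []).append(v)
        slice_scores = []
        for z, voxels in by_slice.items():
            a = len(voxels) * area
            peak = max(vox[v] for v in voxels)
            if peak < 130:
                weight = None
            elif peak < 200:
                weight = 1
            elif peak < 300:
                weight = 2
            elif peak < 400:
                weight = 3
            else:
                weight = 4
            slice_scores.append((a, weight))
        if max(a for a, _ in slice_scores) < min_area_mm2:
            continue  # component too small on every slice
        comps += 1
        total += sum(a * w for a, w in slice_scores
                     if a >= min_area_mm2 and w is not None)
    return total, comps
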