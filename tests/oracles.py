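"""Brute-force reference implementations used only to cross-check the package.

Everything here is written independently of the library code paths it
verifies: plain per-point loops, direct counting, explicit weight formulas.
"""

import numpy as np


def trilinear_point(values, origin, spacing, point, fill=0.0):
    """Interpolate one point on an axis-aligned grid by explicit corner weights."""
    values = np.asarray(values, dtype=float)
    f = (np.asarray(point, dtype=float) - np.asarray(origin)) / np.asarray(spacing)
    n = np.asarray(values.shape)
    if np.any(f < -1e-9) or np.any(f > n - 1 + 1e-9):
        return fill
    f = np.clip(f, 0, n - 1)
    i0 = np.minimum(np.floor(f).astype(int), n - 2)
    i0 = np.maximum(i0, 0)
    w = f - i0
    total = 0.0
    for cx in (0, 1):
        for cy in (0, 1):
            for cz in (0, 1):
                wx = w[0] if cx else 1.0 - w[0]
                wy = w[1] if cy else 1.0 - w[1]
                wz = w[2] if cz else 1.0 - w[2]
                ix = min(i0[0] + cx, n[0] - 1)
                iy = min(i0[1] + cy, n[1] - 1)
                iz = min(i0[2] + cz, n[2] - 1)
                total += wx * wy * wz * values[ix, iy, iz]
    return total


def trilinear_points(values, origin, spacing, points, fill=0.0):
    return np.array([trilinear_point(values, origin, spacing, p, fill) for p in points])


def weighted_sum(arrays, weights):
    """Direct per-voxel weighted summation."""
    out = np.zeros_like(np.asarray(arrays[0], dtype=float))
    for w, a in zip(weights, arrays):
        out = out + w * np.asarray(a, dtype=float)
    return out


def volume_fraction_at_least(doses, threshold):
    """Fraction of entries with dose >= threshold, by direct count."""
    doses = np.asarray(doses)
    return np.count_nonzero(doses >= threshold) / doses.size


def conformity_oracle(dose_grid, target_mask, coverage):
    """Scan candidate isodose levels (the target doses themselves) for the
    largest level covering at least ``coverage`` of the target, then count."""
    target = np.sort(np.asarray(dose_grid)[np.asarray(target_mask)])
    n = len(target)
    best = None
    for level in target[::-1]:
        if np.count_nonzero(target >= level) >= int(np.ceil(coverage * n)):
            best = level
            break
    iso = np.count_nonzero(np.asarray(dose_grid) >= best)
    return iso / n


def jaccard_oracle(a, b):
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    return np.logical_and(a, b).sum() / np.logical_or(a, b).sum()
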