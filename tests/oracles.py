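"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (explicit loops, direct formulas) and
shares no code path with the package implementation it checks.
"""

from __future__ import annotations

import math

import numpy as np


def naive_area_fraction(mask, roi_set, evaluable):
    """Direct pixel loop version of the ROI area fraction."""
    num = den = 0
    H, W = mask.shape
    for r in range(H):
        for c in range(W):
            if roi_set[r, c] and evaluable[r, c]:
                den += 1
                if mask[r, c]:
                    num += 1
    return 100.0 * num / den


def brute_force_otsu(values, nbins=256):
    """Exhaustive between-class-variance maximization over histogram splits.

    Returns ``(threshold, best_variance)``: the bin centre whose split
    maximizes w0*w1*(mu0-mu1)^2, computed with direct loops.
    """
    values = np.asarray(values, dtype=float).ravel()
    counts, edges = np.histogram(values, bins=nbins)
    centers = (edges[:-1] + edges[1:]) / 2.0
    total = counts.sum()
    best_t, best_v = centers[0], -1.0
    for i in range(1, nbins):
        w0 = counts[:i].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = float((counts[:i] * centers[:i]).sum()) / w0
        mu1 = float((counts[i:] * centers[i:]).sum()) / w1
        v = (w0 / total) * (w1 / total) * (mu0 - mu1) ** 2
        if v > best_v:
            best_v = v
            best_t = centers[i - 1]
    return best_t, best_v


def otsu_between_class_variance(values, threshold):
    values = np.asarray(values, dtype=float).ravel()
    g0 = values[values <= threshold]
    g1 = values[values > threshold]
    if g0.size == 0 or g1.size == 0:
        return 0.0
    w0 = g0.size / values.size
    w1 = 1.0 - w0
    return w0 * w1 * (g0.mean() - g1.mean()) ** 2


def bfs_label_count(mask):
    """8-connected component count by explicit breadth-first search."""
    H, W = mask.shape
    seen = np.zeros_like(mask, dtype=bool)
    count = 0
    for r0 in range(H):
        for c0 in range(W):
            if mask[r0, c0] and not seen[r0, c0]:
                count += 1
                stack = [(r0, c0)]
                seen[r0, c0] = True
                while stack:
                    r, c = stack.pop()
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            rr, cc = r + dr, c + dc
                            if (0 <= rr < H and 0 <= cc < W
                                    and mask[rr, cc] and not seen[rr, cc]):
                                seen[rr, cc] = True
                                stack.append((rr, cc))
    return count


def naive_chalkley(mask, center_mm, field_radius_mm, dot_offsets, mpp,
                   n_rotations, n_offsets, jitter_fraction):
    """Exhaustive placement search over the same rotation/offset grid."""
    s = mpp / 1000.0
    H, W = mask.shape
    offsets = [(0.0, 0.0)]
    if n_offsets > 1:
        jr = jitter_fraction * field_radius_mm
        for k in range(n_offsets - 1):
            phi = 2.0 * math.pi * k / (n_offsets - 1)
            offsets.append((jr * math.cos(phi), jr * math.sin(phi)))
    best = 0
    for i in range(n_rotations):
        theta = 2.0 * math.pi * i / n_rotations
        ct, st = math.cos(theta), math.sin(theta)
        for ox, oy in offsets:
            hits = 0
            for dx, dy in dot_offsets:
                x = center_mm[0] + ox + field_radius_mm * (dx * ct - dy * st)
                y = center_mm[1] + oy + field_radius_mm * (dx * st + dy * ct)
                col = min(max(int(round(x / s - 0.5)), 0), W - 1)
                row = min(max(int(round(y / s - 0.5)), 0), H - 1)
                if mask[row, col]:
                    hits += 1
            best = max(best, hits)
    return best


def naive_greedy_hotspots(mask, evaluable, k, radius_px, stride, min_coverage):
    """Independent greedy densest-circle selection (direct convolution loops).

    Returns a list of ``(row, col, count)`` in selection order.
    """
    H, W = mask.shape
    r_int = int(math.ceil(radius_px))
    offs = [(dr, dc) for dr in range(-r_int, r_int + 1)
            for dc in range(-r_int, r_int + 1)
            if dr * dr + dc * dc <= radius_px * radius_px]
    kernel_px = len(offs)

    def disk_sum(arr, r0, c0):
        total = 0
        for dr, dc in offs:
            rr, cc = r0 + dr, c0 + dc
            if 0 <= rr < H and 0 <= cc < W and arr[rr, cc]:
                total += 1
        return total

    candidates = []  # (row, col, count) in scan order
    for r0 in range(0, H, stride):
        for c0 in range(0, W, stride):
            if disk_sum(evaluable, r0, c0) >= min_coverage * kernel_px:
                candidates.append((r0, c0, disk_sum(mask, r0, c0)))

    selected = []
    min_d2 = (2.0 * radius_px) ** 2
    while len(selected) < k:
        best = None
        for r0, c0, cnt in candidates:  # scan order breaks ties
            if any((r0 - rs) ** 2 + (c0 - cs) ** 2 < min_d2
                   for rs, cs, _ in selected):
                continue
            if best is None or cnt > best[2]:
                best = (r0, c0, cnt)
        if best is None:
            break
        selected.append(best)
    return selected


def hand_pearson(x, y):
    """Product-moment correlation from the textbook formula."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    dx = x - x.mean()
    dy = y - y.mean()
    return float((dx * dy).sum() / math.sqrt((dx * dx).sum() * (dy * dy).sum()))
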