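"""Independent brute-force oracles used by the test suite.

Deliberately naive (explicit loops, definitions applied literally) and kept
separate from the package code paths they check.
"""

import math

import numpy as np


def brute_dice(a, b):
    inter = na = nb = 0
    for idx in np.ndindex(a.shape):
        if a[idx]:
            na += 1
        if b[idx]:
            nb += 1
        if a[idx] and b[idx]:
            inter += 1
    if na + nb == 0:
        return 1.0
    return 2.0 * inter / (na + nb)


def brute_wdsc(counts_a, counts_b):
    ta = float(sum(counts_a[idx] for idx in np.ndindex(counts_a.shape)))
    tb = float(sum(counts_b[idx] for idx in np.ndindex(counts_b.shape)))
    num = 0.0
    for idx in np.ndindex(counts_a.shape):
        if counts_a[idx] > 0 and counts_b[idx] > 0:
            num += counts_a[idx] / ta + counts_b[idx] / tb
    return num / 2.0


def brute_overlap_overreach(cand, ref):
    n_ref = n_inter = n_extra = 0
    for idx in np.ndindex(ref.shape):
        if ref[idx]:
            n_ref += 1
            if cand[idx]:
                n_inter += 1
        elif cand[idx]:
            n_extra += 1
    return n_inter / n_ref, n_extra / n_ref


def brute_bundle_adjacency(a, b, affine):
    def world(idx):
        v = np.array([*idx, 1.0])
        return (affine @ v)[:3]

    va = [world(i) for i in np.ndindex(a.shape) if a[i]]
    vb = [world(i) for i in np.ndindex(b.shape) if b[i]]
    only_a = [world(i) for i in np.ndindex(a.shape) if a[i] and not b[i]]
    only_b = [world(i) for i in np.ndindex(b.shape) if b[i] and not a[i]]

    def mean_nearest(pts, others):
        if not pts:
            return 0.0
        total = 0.0
        for p in pts:
            total += min(math.dist(p, q) for q in others)
        return total / len(pts)

    return 0.5 * (mean_nearest(only_a, vb) + mean_nearest(only_b, va))


def brute_icc_single_agreement(x):
    """ICC(2,1) from sums of squares applied by definition."""
    x = np.asarray(x, dtype=float)
    n, k = x.shape
    grand = sum(x[i, j] for i in range(n) for j in range(k)) / (n * k)
    row = [sum(x[i, j] for j in range(k)) / k for i in range(n)]
    col = [sum(x[i, j] for i in range(n)) / n for j in range(k)]
    ssr = k * sum((r - grand) ** 2 for r in row)
    ssc = n * sum((c - grand) ** 2 for c in col)
    sst = sum((x[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


def brute_select(streamlines, include_masks, exclude_masks, affine, step):
    """Per-segment rasterization membership check.

    Every polyline segment is sampled at spacing ``step``; a streamline is
    kept iff its samples hit every include mask and no exclude mask.
    """
    inv = np.linalg.inv(affine)
    shape = include_masks[0].shape if include_masks else exclude_masks[0].shape

    def voxels_hit(pts):
        hit = set()
        for p0, p1 in zip(pts[:-1], pts[1:]):
            seg_len = math.dist(p0, p1)
            n = max(int(math.ceil(seg_len / step)), 1) + 1
            for t in np.linspace(0.0, 1.0, n):
                p = (1 - t) * np.asarray(p0) + t * np.asarray(p1)
                v = inv[:3, :3] @ p + inv[:3, 3]
                idx = tuple(int(math.floor(c + 0.5)) for c in v)
                if all(0 <= idx[d] < shape[d] for d in range(3)):
                    hit.add(idx)
        return hit

    kept = []
    for i, s in enumerate(streamlines):
        hit = voxels_hit(np.asarray(s))
        if not all(any(m[v] for v in hit) for m in include_masks):
            continue
        if any(any(m[v] for v in hit) for m in exclude_masks):
            continue
        kept.append(i)
    return kept
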