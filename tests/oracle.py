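"""Literal nested-loop reference implementation used as an independent oracle.

Everything here is written with explicit Python loops over voxels, candidates
and patch offsets, straight from the weight and correction formulas, sharing
no code with the package implementation.  It is intentionally slow and only
usable on toy volumes.
"""

from __future__ import annotations

import math

import numpy as np


def patch_bounds(size: int) -> tuple[int, int]:
    lo = -(size // 2)
    return lo, size - 1 + lo


def pair_patch_distance(x, i, j, size):
    """Squared distance and overlap count over the truncated patch window:
    only offsets t with both i+t and j+t in bounds contribute."""
    lo, hi = patch_bounds(size)
    sl_i, sl_j = [], []
    for a in range(3):
        t_lo = max(lo, -i[a], -j[a])
        t_hi = min(hi, x.shape[a] - 1 - i[a], x.shape[a] - 1 - j[a])
        sl_i.append(slice(i[a] + t_lo, i[a] + t_hi + 1))
        sl_j.append(slice(j[a] + t_lo, j[a] + t_hi + 1))
    pi = x[tuple(sl_i)]
    pj = x[tuple(sl_j)]
    return float(np.sum((pi - pj) ** 2)), pi.size


def pseudo_residuals(x):
    eps = np.zeros_like(x)
    for i in np.ndindex(x.shape):
        acc = 0.0
        cnt = 0
        for axis in range(3):
            for d in (-1, 1):
                j = list(i)
                j[axis] += d
                if 0 <= j[axis] < x.shape[axis]:
                    acc += x[tuple(j)]
                    cnt += 1
        eps[i] = math.sqrt(6.0 / 7.0) * (x[i] - acc / cnt)
    return eps


def noise_field(x, search_radius, h_floor=None):
    """h_i^2 = mean pseudo-residual^2 over the in-bounds search cube."""
    eps = pseudo_residuals(x)
    h = np.zeros_like(x)
    r = search_radius
    for i in np.ndindex(x.shape):
        acc = 0.0
        cnt = 0
        for j in iter_search(i, x.shape, r):
            acc += eps[j] ** 2
            cnt += 1
        h[i] = math.sqrt(acc / cnt)
    floor = h_floor
    if floor is None:
        floor = 1e-6 * float(np.median(np.abs(x)))
    if floor <= 0:
        floor = 1e-12
    return np.maximum(h, floor)


def patch_sd_field(x, patch_size, h_floor=None):
    """Standard deviation of the in-bounds patch intensities at every voxel."""
    lo, hi = patch_bounds(patch_size)
    h = np.zeros_like(x)
    for i in np.ndindex(x.shape):
        sl = tuple(
            slice(max(0, i[a] + lo), min(x.shape[a], i[a] + hi + 1))
            for a in range(3)
        )
        v = x[sl].ravel()
        h[i] = math.sqrt(max(np.mean(v * v) - np.mean(v) ** 2, 0.0))
    floor = h_floor
    if floor is None:
        floor = 1e-6 * float(np.median(np.abs(x)))
    if floor <= 0:
        floor = 1e-12
    return np.maximum(h, floor)


def iter_search(center, shape, radius):
    for dx in range(-radius, radius + 1):
        for dy in range(-radius, radius + 1):
            for dz in range(-radius, radius + 1):
                j = (center[0] + dx, center[1] + dy, center[2] + dz)
                if all(0 <= j[k] < shape[k] for k in range(3)):
                    yield j


def mrsi_weights(x, center, h, patch_size, radius):
    cands, w = [], []
    h2 = h[center] ** 2
    for j in iter_search(center, x.shape, radius):
        s, n = pair_patch_distance(x, center, j, patch_size)
        cands.append(j)
        w.append(math.exp(-s / (2.0 * n * h2)))
    w = np.asarray(w)
    return cands, w / w.sum()


def mri_weights(channels, probs, center, h_list, patch_size, radius):
    """probs: (K, X, Y, Z); returns candidates and normalized weights
    (all-zero if no candidate shares a tissue class)."""
    k_classes = probs.shape[0]
    cands, w = [], []
    for j in iter_search(center, channels[0].shape, radius):
        dist = 0.0
        n_tot = 0
        for ch, h in zip(channels, h_list):
            s, n = pair_patch_distance(ch, center, j, patch_size)
            dist += s / (h[center] ** 2)
            n_tot += n
        gate = 0.0
        for k in range(k_classes):
            gate += probs[k][center] * probs[k][j]
        cands.append(j)
        w.append((gate / k_classes) * math.exp(-dist / (2.0 * n_tot)))
    w = np.asarray(w)
    total = w.sum()
    if total > 0:
        w = w / total
    return cands, w


def reconstruct(x, channels, probs, alpha, patch_size, radius):
    h_mrsi = noise_field(x, radius)
    h_ch = [patch_sd_field(c, patch_size) for c in channels]
    out = np.zeros_like(x)
    for i in np.ndindex(x.shape):
        c_mri, w_mri = mri_weights(channels, probs, i, h_ch, patch_size, radius)
        c_srs, w_srs = mrsi_weights(x, i, h_mrsi, patch_size, radius)
        val_srs = sum(w * x[j] for j, w in zip(c_srs, w_srs))
        if w_mri.sum() <= 0:
            out[i] = val_srs
            continue
        val_mri = sum(w * x[j] for j, w in zip(c_mri, w_mri))
        out[i] = (1.0 - alpha[i]) * val_mri + alpha[i] * val_srs
    return out


def block_means(x, scale):
    shape = tuple(n // s for n, s in zip(x.shape, scale))
    out = np.zeros(shape)
    for p in np.ndindex(shape):
        acc = 0.0
        cnt = 0
        for q in np.ndindex(tuple(scale)):
            acc += x[tuple(p[a] * scale[a] + q[a] for a in range(3))]
            cnt += 1
        out[p] = acc / cnt
    return out


def mean_correct(x, y, scale):
    out = x.copy()
    bm = block_means(x, scale)
    for p in np.ndindex(bm.shape):
        r = y[p] - bm[p]
        for q in np.ndindex(tuple(scale)):
            out[tuple(p[a] * scale[a] + q[a] for a in range(3))] += r
    return out


def linear_upsample_1d(vals, factor):
    n = len(vals)
    u = (np.arange(n * factor) + 0.5) / factor - 0.5
    return np.interp(u, np.arange(n), vals)


def run_pipeline(y, channels, probs, alpha, scale, patch_size, radius, iters):
    """Linear init + (reconstruct, mean-correct) iterations, identity PSF."""
    x = y.copy()
    for axis, f in enumerate(scale):
        x = np.apply_along_axis(linear_upsample_1d, axis, x, f)
    for _ in range(iters):
        x = reconstruct(x, channels, probs, alpha, patch_size, radius)
        x = mean_correct(x, y, scale)
    return x
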