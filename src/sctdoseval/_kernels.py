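"""Numba kernels for the gamma-index search.

Two search paths are provided on purpose:

* :func:`gamma_search_sorted` — the production path: per reference voxel it
  walks candidate offsets sorted by radius and stops as soon as the spatial
  term alone can no longer beat the running minimum (a provably lossless
  prune, since the dose term is non-negative).
* :func:`gamma_search_exhaustive` — the brute-force reference path: it
  visits every candidate offset unconditionally.  Used as the in-package
  oracle the optimized path is checked against.

Both paths share only the trilinear interpolation primitive and the same
candidate-offset set, so equality between them validates the pruning logic,
not a shared search strategy.
"""

from __future__ import annotations

import numpy as np
from numba import njit

BIG = 1e30


@njit(cache=True, inline="always")
def _interp3(vals, o0, o1, o2, s0, s1, s2, x, y, z):
    """Trilinear interpolation at a physical point; returns (value, inside)."""
    n0, n1, n2 = vals.shape
    fx = (x - o0) / s0
    fy = (y - o1) / s1
    fz = (z - o2) / s2
    if fx < 0.0 or fx > n0 - 1 or fy < 0.0 or fy > n1 - 1 or fz < 0.0 or fz > n2 - 1:
        return 0.0, False
    i0 = int(fx)
    j0 = int(fy)
    k0 = int(fz)
    if i0 > n0 - 2:
        i0 = n0 - 2
    if j0 > n1 - 2:
        j0 = n1 - 2
    if k0 > n2 - 2:
        k0 = n2 - 2
    if n0 == 1:
        i0 = 0
    if n1 == 1:
        j0 = 0
    if n2 == 1:
        k0 = 0
    tx = fx - i0
    ty = fy - j0
    tz = fz - k0
    i1 = i0 + 1 if n0 > 1 else i0
    j1 = j0 + 1 if n1 > 1 else j0
    k1 = k0 + 1 if n2 > 1 else k0
    c000 = vals[i0, j0, k0]
    c100 = vals[i1, j0, k0]
    c010 = vals[i0, j1, k0]
    c110 = vals[i1, j1, k0]
    c001 = vals[i0, j0, k1]
    c101 = vals[i1, j0, k1]
    c011 = vals[i0, j1, k1]
    c111 = vals[i1, j1, k1]
    c00 = c000 * (1 - tx) + c100 * tx
    c10 = c010 * (1 - tx) + c110 * tx
    c01 = c001 * (1 - tx) + c101 * tx
    c11 = c011 * (1 - tx) + c111 * tx
    c0 = c00 * (1 - ty) + c10 * ty
    c1 = c01 * (1 - ty) + c11 * ty
    return c0 * (1 - tz) + c1 * tz, True


@njit(cache=True)
def gamma_search_sorted(
    pos, dref, evals, eorig, espace, offsets, off_rsq, dd_abs, dta
):
    """Pruned coarse search over radius-sorted offsets.

    Returns (gamma_sq, best_offset_index); index −1 marks a voxel where no
    candidate position fell inside the evaluated volume.
    """
    n = pos.shape[0]
    m = offsets.shape[0]
    inv_dd2 = 1.0 / (dd_abs * dd_abs)
    inv_dta2 = 1.0 / (dta * dta)
    gsq = np.empty(n)
    bidx = np.full(n, -1, dtype=np.int64)
    for i in range(n):
        best = BIG
        bi = -1
        x = pos[i, 0]
        y = pos[i, 1]
        z = pos[i, 2]
        d0 = dref[i]
        for mi in range(m):
            dist2 = off_rsq[mi] * inv_dta2
            if dist2 >= best:
                break  # offsets sorted by radius: no later one can win
            v, inside = _interp3(
                evals, eorig[0], eorig[1], eorig[2],
                espace[0], espace[1], espace[2],
                x + offsets[mi, 0], y + offsets[mi, 1], z + offsets[mi, 2],
            )
            if not inside:
                continue
            dd = v - d0
            g = dd * dd * inv_dd2 + dist2
            if g < best:
                best = g
                bi = mi
        gsq[i] = best
        bidx[i] = bi
    return gsq, bidx


@njit(cache=True)
def gamma_search_exhaustive(
    pos, dref, evals, eorig, espace, offsets, off_rsq, dd_abs, dta
):
    """Unpruned brute-force counterpart of :func:`gamma_search_sorted`."""
    n = pos.shape[0]
    m = offsets.shape[0]
    inv_dd2 = 1.0 / (dd_abs * dd_abs)
    inv_dta2 = 1.0 / (dta * dta)
    gsq = np.empty(n)
    bidx = np.full(n, -1, dtype=np.int64)
    for i in range(n):
        best = BIG
        bi = -1
        x = pos[i, 0]
        y = pos[i, 1]
        z = pos[i, 2]
        d0 = dref[i]
        for mi in range(m):
            v, inside = _interp3(
                evals, eorig[0], eorig[1], eorig[2],
                espace[0], espace[1], espace[2],
                x + offsets[mi, 0], y + offsets[mi, 1], z + offsets[mi, 2],
            )
            if not inside:
                continue
            dd = v - d0
            g = dd * dd * inv_dd2 + off_rsq[mi] * inv_dta2
            if g < best:
                best = g
                bi = mi
        gsq[i] = best
        bidx[i] = bi
    return gsq, bidx


@njit(cache=True)
def gamma_refine(
    pos, dref, gsq, base_off, evals, eorig, espace, fine_offsets, dd_abs, dta,
    rmax, refine_mask,
):
    """Fine local search (in place) around each voxel's best coarse offset.

    Only voxels with ``refine_mask`` set are refined; candidates beyond the
    overall search radius ``rmax`` are skipped.  Refinement can only lower
    gamma.
    """
    n = pos.shape[0]
    k = fine_offsets.shape[0]
    inv_dd2 = 1.0 / (dd_abs * dd_abs)
    inv_dta2 = 1.0 / (dta * dta)
    rmax2 = rmax * rmax
    for i in range(n):
        if not refine_mask[i]:
            continue
        best = gsq[i]
        x = pos[i, 0]
        y = pos[i, 1]
        z = pos[i, 2]
        d0 = dref[i]
        bx = base_off[i, 0]
        by = base_off[i, 1]
        bz = base_off[i, 2]
        for ki in range(k):
            ox = bx + fine_offsets[ki, 0]
            oy = by + fine_offsets[ki, 1]
            oz = bz + fine_offsets[ki, 2]
            r2 = ox * ox + oy * oy + oz * oz
            if r2 > rmax2:
                continue
            dist2 = r2 * inv_dta2
            if dist2 >= best:
                continue
            v, inside = _interp3(
                evals, eorig[0], eorig[1], eorig[2],
                espace[0], espace[1], espace[2],
                x + ox, y + oy, z + oz,
            )
            if not inside:
                continue
            dd = v - d0
            g = dd * dd * inv_dd2 + dist2
            if g < best:
                best = g
        gsq[i] = best


@njit(cache=True)
def resample_axes(src, so0, so1, so2, ss0, ss1, ss2, ax0, ax1, ax2, order, fill):
    """Resample ``src`` at the tensor grid spanned by three axis-coordinate
    vectors (physical mm); ``order`` 0 = nearest, 1 = trilinear."""
    n0 = ax0.shape[0]
    n1 = ax1.shape[0]
    n2 = ax2.shape[0]
    out = np.empty((n0, n1, n2), dtype=np.float32)
    for i in range(n0):
        x = ax0[i]
        for j in range(n1):
            y = ax1[j]
            for k in range(n2):
                z = ax2[k]
                if order == 1:
                    v, inside = _interp3(src, so0, so1, so2, ss0, ss1, ss2, x, y, z)
                    out[i, j, k] = v if inside else fill
                else:
                    fi = (x - so0) / ss0
                    fj = (y - so1) / ss1
                    fk = (z - so2) / ss2
                    ii = int(np.floor(fi + 0.5))
                    jj = int(np.floor(fj + 0.5))
                    kk = int(np.floor(fk + 0.5))
                    m0, m1, m2 = src.shape
                    if (
                        ii < 0 or ii >= m0 or jj < 0 or jj >= m1
                        or kk < 0 or kk >= m2
                    ):
                        out[i, j, k] = fill
                    else:
                        out[i, j, k] = src[ii, jj, kk]
    return out
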