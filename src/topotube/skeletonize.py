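"""Skeletonization of 3D tubular structures.

Four routes to a centerline, with different trade-offs:

``soft_skeleton``
    The differentiable morphological scheme of the clDice family: iterated
    soft erosion/opening built from min/max filters. Fast and almost-
    everywhere differentiable, but the result is neither guaranteed thin
    nor topologically faithful.
``skeletonize_toppreserving``
    Sequential deletion of *simple points* — voxels whose removal provably
    preserves the topology of the object — until only a unit-width core
    remains. Simplicity is decided either through an Euler-characteristic
    test (``method="euler"``) or through the Boolean characterization by
    topological numbers T26/T6 (``method="boolean"``). Exact topology, but
    iterative and therefore slower.
``lee_skeleton``
    Classical sequential 3D thinning (Lee et al. 1994, via scikit-image),
    used as the reference skeleton for synthetic ground truth.
``soft_binarize``
    Reparametrized thresholding (logistic noise on the logit, temperature
    sigmoid) that turns a probability map into a near-binary map while
    keeping gradients — the bridge between a network output and the binary
    thinning routines.

Conventions: foreground 26-connectivity, background 6-connectivity.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import skeletonize as _sk_skeletonize

try:
    from numba import njit
except ImportError:  # pragma: no cover - numba is a hard dependency in practice
    def njit(*a, **k):
        if a and callable(a[0]):
            return a[0]
        return lambda f: f

__all__ = [
    "BinarizationParams",
    "soft_skeleton",
    "soft_binarize",
    "is_simple_euler",
    "is_simple_boolean",
    "skeletonize_toppreserving",
    "lee_skeleton",
]


# ---------------------------------------------------------------------------
# neighborhood tables (built programmatically at import time)
#
# Cells of the 3x3x3 neighborhood are indexed in C order of their offsets
# (a, b, c) in {0,1,2}^3; the center voxel is index 13.

_OFFS = np.array([(a, b, c) for a in range(3) for b in range(3) for c in range(3)], np.int64)
_CENTER = 13

# 26 neighbors and their mutual 26-adjacency
_NB26 = np.array([i for i in range(27) if i != _CENTER], np.int64)
_ADJ26 = np.zeros((27, 27), np.bool_)
for _i in range(27):
    for _j in range(27):
        d = np.abs(_OFFS[_i] - _OFFS[_j])
        _ADJ26[_i, _j] = _i != _j and d.max() <= 1

# 18-neighborhood (face or edge sharing) and 6-adjacency inside it
_N18 = np.array(
    [i for i in range(27) if i != _CENTER and int(np.sum(_OFFS[i] != 1)) <= 2],
    np.int64,
)
_ADJ6 = np.zeros((27, 27), np.bool_)
for _i in range(27):
    for _j in range(27):
        _ADJ6[_i, _j] = int(np.abs(_OFFS[_i] - _OFFS[_j]).sum()) == 1
_FACES = np.array(
    [i for i in range(27) if int(np.abs(_OFFS[i] - 1).sum()) == 1], np.int64
)

# Cells of the center voxel's cube and the neighbors able to keep them
# covered after the center is deleted:
#   each of the 8 cube vertices is shared with 7 neighbors (an octant),
#   each of the 12 edges with 3 neighbors, each of the 6 faces with 1.
_VERT_COVER = np.zeros((8, 7), np.int64)
_EDGE_COVER = np.zeros((12, 3), np.int64)
_FACE_COVER = np.zeros((6, 1), np.int64)


def _build_cover_tables():
    def idx(off):
        return (off[0] + 1) * 9 + (off[1] + 1) * 3 + (off[2] + 1)

    vrow = 0
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                col = 0
                for ox in (dx - 1, dx):
                    for oy in (dy - 1, dy):
                        for oz in (dz - 1, dz):
                            if (ox, oy, oz) != (0, 0, 0):
                                _VERT_COVER[vrow, col] = idx((ox, oy, oz))
                                col += 1
                vrow += 1
    erow = 0
    for ax in range(3):
        for d1 in (0, 1):
            for d2 in (0, 1):
                col = 0
                perp = [a for a in range(3) if a != ax]
                for o1 in (d1 - 1, d1):
                    for o2 in (d2 - 1, d2):
                        off = [0, 0, 0]
                        off[perp[0]], off[perp[1]] = o1, o2
                        if tuple(off) != (0, 0, 0):
                            _EDGE_COVER[erow, col] = idx(off)
                            col += 1
                erow += 1
    frow = 0
    for ax in range(3):
        for d in (-1, 1):
            off = [0, 0, 0]
            off[ax] = d
            _FACE_COVER[frow, 0] = idx(off)
            frow += 1


_build_cover_tables()


# ---------------------------------------------------------------------------
# simple-point kernels


@njit(cache=True)
def _t26(nb):
    """Number of 26-connected components of the foreground 26-neighbors."""
    visited = np.zeros(27, np.bool_)
    ncomp = 0
    stack = np.empty(27, np.int64)
    for s in range(26):
        i = _NB26[s]
        if nb[i] and not visited[i]:
            ncomp += 1
            visited[i] = True
            top = 0
            stack[top] = i
            top += 1
            while top > 0:
                top -= 1
                u = stack[top]
                for t in range(26):
                    v = _NB26[t]
                    if nb[v] and not visited[v] and _ADJ26[u, v]:
                        visited[v] = True
                        stack[top] = v
                        top += 1
    return ncomp


@njit(cache=True)
def _t6(nb):
    """Number of 6-connected components of background cells in the
    18-neighborhood that touch the center through a face."""
    visited = np.zeros(27, np.bool_)
    ncomp = 0
    stack = np.empty(27, np.int64)
    for s in range(6):
        i = _FACES[s]
        if (not nb[i]) and not visited[i]:
            ncomp += 1
            visited[i] = True
            top = 0
            stack[top] = i
            top += 1
            while top > 0:
                top -= 1
                u = stack[top]
                for t in range(18):
                    v = _N18[t]
                    if (not nb[v]) and not visited[v] and _ADJ6[u, v]:
                        visited[v] = True
                        stack[top] = v
                        top += 1
    return ncomp


@njit(cache=True)
def _delta_chi(nb):
    """Change of the Euler characteristic when the center voxel is deleted.

    Only cells of the center voxel's cube can lose coverage; counting the
    vertices/edges/faces kept alive by octant / edge / face neighborhoods
    gives the exact local decomposition.
    """
    u_v = 0
    for r in range(8):
        covered = False
        for c in range(7):
            if nb[_VERT_COVER[r, c]]:
                covered = True
                break
        if not covered:
            u_v += 1
    u_e = 0
    for r in range(12):
        covered = False
        for c in range(3):
            if nb[_EDGE_COVER[r, c]]:
                covered = True
                break
        if not covered:
            u_e += 1
    u_f = 0
    for r in range(6):
        if not nb[_FACE_COVER[r, 0]]:
            u_f += 1
    return -u_v + u_e - u_f + 1


@njit(cache=True)
def _simple_euler(nb):
    # Euler invariance + single foreground component (Lee-style condition);
    # equivalent to the T26/T6 characterization, cross-checked in the tests
    # against brute-force patch homology
    return _t26(nb) == 1 and _delta_chi(nb) == 0


@njit(cache=True)
def _simple_boolean(nb):
    return _t26(nb) == 1 and _t6(nb) == 1


def _neighborhood(patch, name):
    patch = np.asarray(patch)
    if patch.shape != (3, 3, 3):
        raise ValueError(f"{name} expects a 3x3x3 patch, got {patch.shape}")
    nb = patch.astype(bool).ravel()
    if not nb[_CENTER]:
        raise ValueError("center voxel must be foreground to test simplicity")
    return nb


def is_simple_euler(nbh) -> bool:
    """Simple-point test through the Euler characteristic.

    The center voxel of the 3×3×3 patch is simple iff its foreground
    26-neighbors form a single 26-component and deleting it leaves the
    Euler characteristic unchanged (computed by the local octant/edge/face
    decomposition).
    """
    return bool(_simple_euler(_neighborhood(nbh, "is_simple_euler")))


def is_simple_boolean(nbh) -> bool:
    """Simple-point test through the Boolean characterization: the
    topological numbers T26 (foreground) and T6 (background) both equal 1."""
    return bool(_simple_boolean(_neighborhood(nbh, "is_simple_boolean")))


# ---------------------------------------------------------------------------
# topology-preserving thinning


@njit(cache=True)
def _thin_pass(vol, use_euler):
    """One raster-order pass of sequential simple-point deletion over a
    zero-padded uint8 volume; returns the number of deletions."""
    nx, ny, nz = vol.shape
    nb = np.empty(27, np.bool_)
    ndel = 0
    for x in range(1, nx - 1):
        for y in range(1, ny - 1):
            for z in range(1, nz - 1):
                if vol[x, y, z] == 0:
                    continue
                # border check: an interior voxel is never simple
                if (
                    vol[x - 1, y, z] and vol[x + 1, y, z]
                    and vol[x, y - 1, z] and vol[x, y + 1, z]
                    and vol[x, y, z - 1] and vol[x, y, z + 1]
                ):
                    continue
                nfg = 0
                k = 0
                for a in range(-1, 2):
                    for b in range(-1, 2):
                        for c in range(-1, 2):
                            v = vol[x + a, y + b, z + c] != 0
                            nb[k] = v
                            if v and k != 13:
                                nfg += 1
                            k += 1
                if nfg <= 1:
                    continue  # endpoint (or isolated): protected
                if use_euler:
                    ok = _simple_euler(nb)
                else:
                    ok = _simple_boolean(nb)
                if ok:
                    vol[x, y, z] = 0
                    ndel += 1
    return ndel


def skeletonize_toppreserving(mask, method: str = "euler") -> np.ndarray:
    """Thin a binary mask to a unit-width skeleton by sequential deletion
    of simple points, preserving the Betti numbers exactly.

    Voxels are visited in raster order and re-tested against the current
    state of the volume, so every single deletion is topology-preserving.
    Endpoints (≤ 1 foreground 26-neighbor) are protected to keep curve
    geometry. Iterates until a full pass deletes nothing; the result is a
    subset of the input and idempotent under re-application.
    """
    if method not in ("euler", "boolean"):
        raise ValueError(f"unknown method {method!r}")
    mask = np.asarray(mask).astype(bool)
    if mask.ndim != 3:
        raise ValueError("mask must be 3D")
    vol = np.pad(mask, 1).astype(np.uint8)
    use_euler = method == "euler"
    while _thin_pass(vol, use_euler) > 0:
        pass
    return vol[1:-1, 1:-1, 1:-1].astype(bool)


# ---------------------------------------------------------------------------
# soft (differentiable) skeleton


def _soft_erode(p):
    # separable 3x3x3 min filter; outside the volume counts as background
    for ax in range(3):
        size = [1, 1, 1]
        size[ax] = 3
        p = ndi.minimum_filter(p, size=tuple(size), mode="constant", cval=0.0)
    return p


def _soft_dilate(p):
    for ax in range(3):
        size = [1, 1, 1]
        size[ax] = 3
        p = ndi.maximum_filter(p, size=tuple(size), mode="constant", cval=0.0)
    return p


def soft_skeleton(prob, iterations: int = 10) -> np.ndarray:
    """Soft skeleton of a probability map by iterated min/max filtering.

    Each round erodes the map and accumulates the residue of a soft
    morphological opening; after ``iterations`` rounds (which must exceed
    the largest tube radius in voxels for full thinning) the accumulated
    residues approximate a centerline. Composed purely of order statistics
    and elementwise arithmetic, hence differentiable almost everywhere.
    """
    p = np.asarray(prob, np.float32)
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    if p.min() < -1e-6 or p.max() > 1 + 1e-6:
        raise ValueError("probabilities must lie in [0, 1]")
    p = np.clip(p, 0.0, 1.0)
    skel = np.maximum(p - _soft_dilate(_soft_erode(p)), 0.0)
    for _ in range(iterations):
        p = _soft_erode(p)
        delta = np.maximum(p - _soft_dilate(_soft_erode(p)), 0.0)
        skel = skel + np.maximum(delta - skel * delta, 0.0)
    return skel


# ---------------------------------------------------------------------------
# differentiable binarization


class BinarizationParams:
    """Parameters of the reparametrized thresholding: ``beta`` scales the
    logistic noise added to the logit, ``tau`` is the sigmoid temperature
    (hard threshold in the limit tau → 0). Defaults follow the values used
    with the Euler/Boolean thinning during training: beta=0.33, tau=1.0."""

    def __init__(self, beta: float = 0.33, tau: float = 1.0):
        if tau <= 0:
            raise ValueError("tau must be > 0")
        self.beta = float(beta)
        self.tau = float(tau)

    def __repr__(self):
        return f"BinarizationParams(beta={self.beta}, tau={self.tau})"


def soft_binarize(prob, params: BinarizationParams, rng) -> np.ndarray:
    """Reparametrized thresholding of a probability map.

    Adds logistic noise scaled by ``params.beta`` to the logit of the input
    and squashes it back through a sigmoid with temperature ``params.tau``.
    Output lies in (0, 1); values ≥ 0.5 may be treated as foreground while
    gradients flow through the soft map (straight-through contract).
    """
    p = np.asarray(prob, np.float64)
    if params.tau <= 0:
        raise ValueError("tau must be > 0")
    eps = 1e-7
    p = np.clip(p, eps, 1 - eps)
    logit = np.log(p) - np.log1p(-p)
    noise = rng.logistic(0.0, 1.0, size=p.shape) if params.beta != 0 else 0.0
    z = (logit + params.beta * noise) / params.tau
    return (1.0 / (1.0 + np.exp(-z))).astype(np.float32)


# ---------------------------------------------------------------------------
# reference thinning


def lee_skeleton(mask) -> np.ndarray:
    """Reference 1-voxel-thick skeleton by Lee et al. (1994) sequential
    thinning, used to generate ground-truth centerlines."""
    mask = np.asarray(mask).astype(bool)
    if mask.ndim != 3:
        raise ValueError("mask must be 3D")
    if not mask.any():
        return np.zeros_like(mask)
    return _sk_skeletonize(mask, method="lee").astype(bool)
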