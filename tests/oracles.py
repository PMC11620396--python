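"""Independent brute-force oracles used only by the test suite.

Everything here is deliberately naive and slow: homology from explicit
GF(2) boundary matrices, surface distances from all-pairs enumeration.
These implementations share no code with the package and serve as the
ground truth the fast implementations are checked against.
"""

from __future__ import annotations

import itertools

import numpy as np


# ---------------------------------------------------------------------------
# GF(2) linear algebra


def gf2_rank(columns: list[int]) -> int:
    """Rank of a GF(2) matrix whose columns are given as int bitmasks."""
    rank = 0
    pivots: list[int] = []
    for col in columns:
        for p in pivots:
            col = min(col, col ^ p)
        if col:
            pivots.append(col)
            rank += 1
    return rank


def _betti_from_complex(cells_by_dim: list[list], boundary) -> list[int]:
    """Betti numbers from cell lists and a boundary function.

    ``boundary(cell)`` returns the list of (dim-1)-cells on the boundary of
    ``cell``; β_k = #cells_k − rank ∂_k − rank ∂_{k+1} over GF(2).
    """
    ranks = []
    for dim in range(1, len(cells_by_dim)):
        index = {c: i for i, c in enumerate(cells_by_dim[dim - 1])}
        cols = []
        for cell in cells_by_dim[dim]:
            bits = 0
            for f in boundary(cell):
                bits ^= 1 << index[f]
            cols.append(bits)
        ranks.append(gf2_rank(cols))
    ranks.append(0)  # ∂_{top+1}
    betti = []
    for dim, cells in enumerate(cells_by_dim):
        lower = ranks[dim - 1] if dim > 0 else 0
        betti.append(len(cells) - lower - ranks[dim])
    return betti


# ---------------------------------------------------------------------------
# cubical homology, closed-cube (26-connectivity) construction


def betti_closed_cubes(mask) -> tuple[int, int, int]:
    """Betti numbers of the union of closed unit cubes over foreground
    voxels (foreground 26-connectivity), via Khalimsky doubled coordinates:
    a grid cell (a, b, c) has dimension = number of odd coordinates and is
    present when some foreground voxel's closed cube contains it."""
    mask = np.asarray(mask).astype(bool)
    cells: set[tuple[int, int, int]] = set()
    for i, j, k in zip(*np.nonzero(mask)):
        for a in (2 * i, 2 * i + 1, 2 * i + 2):
            for b in (2 * j, 2 * j + 1, 2 * j + 2):
                for c in (2 * k, 2 * k + 1, 2 * k + 2):
                    cells.add((a, b, c))

    def dim(cell):
        return sum(x % 2 for x in cell)

    cells_by_dim = [[], [], [], []]
    for cell in cells:
        cells_by_dim[dim(cell)].append(cell)

    def boundary(cell):
        out = []
        for ax in range(3):
            if cell[ax] % 2:
                for d in (-1, 1):
                    f = list(cell)
                    f[ax] += d
                    out.append(tuple(f))
        return out

    b = _betti_from_complex(cells_by_dim, boundary)
    return (b[0], b[1], b[2])


# ---------------------------------------------------------------------------
# cubical homology, vertex (6-connectivity) construction


def betti_open_adjacency(mask) -> tuple[int, int, int]:
    """Betti numbers under 6-connectivity: voxels are vertices, with an
    edge / square / cube for every 2·1·1 / 2·2·1 / 2·2·2 block of
    foreground voxels."""
    mask = np.asarray(mask).astype(bool)
    verts = set(map(tuple, np.argwhere(mask)))

    def block(v, axes):
        offs = [(0, 0, 0)]
        for ax in axes:
            offs = offs + [tuple(o[i] + (1 if i == ax else 0) for i in range(3)) for o in offs]
        return [tuple(v[i] + o[i] for i in range(3)) for o in offs]

    edges, squares, cubes = [], [], []
    for v in verts:
        for axes in ((0,), (1,), (2,)):
            if all(w in verts for w in block(v, axes)):
                edges.append((v, axes))
        for axes in ((0, 1), (0, 2), (1, 2)):
            if all(w in verts for w in block(v, axes)):
                squares.append((v, axes))
        if all(w in verts for w in block(v, (0, 1, 2))):
            cubes.append((v, (0, 1, 2)))

    def boundary(cell):
        v, axes = cell
        if len(axes) == 1:
            w = list(v)
            w[axes[0]] += 1
            return [(v, ()), (tuple(w), ())]
        out = []
        for drop in axes:
            rest = tuple(a for a in axes if a != drop)
            w = list(v)
            w[drop] += 1
            out.append((v, rest))
            out.append((tuple(w), rest))
        return out

    cells_by_dim = [[(v, ()) for v in verts], edges, squares, cubes]
    b = _betti_from_complex(cells_by_dim, boundary)
    return (b[0], b[1], b[2])


# ---------------------------------------------------------------------------
# simple-point oracle


def is_simple_bruteforce(patch) -> bool:
    """Brute-force simplicity of the centre voxel of a 3×3×3 patch.

    The patch is embedded in a background-padded 5×5×5 block; the voxel is
    simple iff deleting it changes neither the foreground Betti numbers
    (26-connectivity, closed-cube complex) nor the background Betti numbers
    (6-connectivity, vertex complex).
    """
    patch = np.asarray(patch).astype(bool)
    assert patch.shape == (3, 3, 3) and patch[1, 1, 1]
    before = np.pad(patch, 1)
    after = before.copy()
    after[2, 2, 2] = False
    if betti_closed_cubes(before) != betti_closed_cubes(after):
        return False
    if betti_open_adjacency(~before) != betti_open_adjacency(~after):
        return False
    return True


# ---------------------------------------------------------------------------
# brute-force surface distances


def _surface(mask):
    mask = np.asarray(mask).astype(bool)
    out = []
    for idx in np.argwhere(mask):
        on_border = False
        for ax in range(3):
            for d in (-1, 1):
                j = idx.copy()
                j[ax] += d
                if (j < 0).any() or (j >= np.array(mask.shape)).any():
                    on_border = True
                elif not mask[tuple(j)]:
                    on_border = True
        if on_border:
            out.append(idx)
    return np.array(out, float)


def assd_bruteforce(P, R, spacing=(1.0, 1.0, 1.0)) -> float:
    sp, sr = _surface(P) * spacing, _surface(R) * spacing
    d = np.sqrt(((sp[:, None, :] - sr[None, :, :]) ** 2).sum(-1))
    return float((d.min(1).sum() + d.min(0).sum()) / (len(sp) + len(sr)))


def hd95_bruteforce(P, R, spacing=(1.0, 1.0, 1.0)) -> float:
    sp, sr = _surface(P) * spacing, _surface(R) * spacing
    d = np.sqrt(((sp[:, None, :] - sr[None, :, :]) ** 2).sum(-1))
    return float(max(np.percentile(d.min(1), 95), np.percentile(d.min(0), 95)))


def dice_bruteforce(P, R) -> float:
    P = np.asarray(P).astype(bool)
    R = np.asarray(R).astype(bool)
    tp = (P & R).sum()
    fp = (P & ~R).sum()
    fn = (~P & R).sum()
    if tp + fp + fn == 0:
        return 1.0
    return float(2 * tp / (2 * tp + fp + fn))


def cl_dice_bruteforce(S_P, S_G, C_P, C_G) -> float:
    S_P, S_G = np.asarray(S_P).astype(bool), np.asarray(S_G).astype(bool)
    C_P, C_G = np.asarray(C_P).astype(bool), np.asarray(C_G).astype(bool)
    tprec = (C_P & S_G).sum() / C_P.sum() if C_P.any() else (1.0 if not S_G.any() else 0.0)
    tsens = (C_G & S_P).sum() / C_G.sum() if C_G.any() else (1.0 if not S_P.any() else 0.0)
    if tprec + tsens == 0:
        return 0.0
    return float(2 * tprec * tsens / (tprec + tsens))
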