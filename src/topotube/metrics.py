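"""Evaluation metrics for tubular-structure segmentation.

Overlap metrics (Dice, clDice), symmetric surface distances (ASSD, HD95,
in millimeters) and the Betti numbers (β0, β1, β2) of a binary volume.

Conventions, fixed once for the whole package:

* foreground connectivity 26, background connectivity 6 — the standard
  dual pair for 3D digital topology;
* the Euler characteristic of a binary volume is that of the union of
  closed unit voxel cubes (vertices, edges and faces shared between
  adjacent cubes are counted once), which realises 26-connectivity of
  the foreground;
* surface voxels are foreground voxels with at least one background
  6-neighbour or lying on the volume border, and distances are measured
  between voxel centres scaled by the voxel spacing;
* the 95th percentile uses linear interpolation between order statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage as ndi

__all__ = [
    "BettiProfile",
    "SegPair",
    "MetricReport",
    "topology_precision",
    "topology_sensitivity",
    "cl_dice",
    "dice_coefficient",
    "assd",
    "hd95",
    "euler_characteristic",
    "betti_numbers",
    "evaluate_pair",
]

_STRUCT_26 = np.ones((3, 3, 3), bool)
_STRUCT_6 = ndi.generate_binary_structure(3, 1)


# ---------------------------------------------------------------------------
# small helpers


def _as_bool(mask, name="mask"):
    a = np.asarray(mask)
    if a.ndim != 3:
        raise ValueError(f"{name} must be 3D, got shape {a.shape}")
    if a.dtype != bool:
        vals = np.unique(a)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError(f"{name} must be binary, found values {vals[:5]}")
        a = a.astype(bool)
    return a


def _check_shapes(*masks):
    shapes = {m.shape for m in masks}
    if len(shapes) > 1:
        raise ValueError(f"mask shapes differ: {sorted(shapes)}")


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class BettiProfile:
    """Betti numbers of a binary volume: components, tunnels, cavities."""

    b0: int
    b1: int
    b2: int

    def __post_init__(self):
        if min(self.b0, self.b1, self.b2) < 0:
            raise ValueError(f"Betti numbers must be non-negative: {self}")

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.b0, self.b1, self.b2)

    def __iter__(self):
        return iter(self.as_tuple())


@dataclass
class SegPair:
    """A predicted/reference segmentation pair with their centerlines."""

    S_P: np.ndarray
    S_G: np.ndarray
    C_P: np.ndarray
    C_G: np.ndarray
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.S_P = _as_bool(self.S_P, "S_P")
        self.S_G = _as_bool(self.S_G, "S_G")
        self.C_P = _as_bool(self.C_P, "C_P")
        self.C_G = _as_bool(self.C_G, "C_G")
        _check_shapes(self.S_P, self.S_G, self.C_P, self.C_G)
        if min(self.spacing_mm) <= 0:
            raise ValueError(f"spacing must be positive: {self.spacing_mm}")


@dataclass
class MetricReport:
    """Per-case evaluation record (distances in mm)."""

    dsc: float
    cldice: float
    assd_mm: float
    hd95_mm: float
    betti: BettiProfile
    case_id: str = ""

    def to_dict(self) -> dict:
        d = asdict(self)
        d["betti"] = self.betti.as_tuple()
        return d


# ---------------------------------------------------------------------------
# overlap metrics


def topology_precision(C_P, S_G) -> float:
    """Fraction of the predicted centerline lying inside the reference
    segmentation: |C_P ∩ S_G| / |C_P|.

    Empty-set convention: 1.0 when both structures are empty, 0.0 when only
    the centerline is empty.
    """
    C_P, S_G = _as_bool(C_P, "C_P"), _as_bool(S_G, "S_G")
    _check_shapes(C_P, S_G)
    n = int(C_P.sum())
    if n == 0:
        return 1.0 if not S_G.any() else 0.0
    return float((C_P & S_G).sum() / n)


def topology_sensitivity(C_G, S_P) -> float:
    """Fraction of the reference centerline covered by the predicted
    segmentation: |C_G ∩ S_P| / |C_G|."""
    return topology_precision(C_G, S_P)


def cl_dice(pair: SegPair) -> float:
    """Centerline Dice: harmonic mean of topology precision and sensitivity.

    Defined as 0 when both terms vanish.
    """
    tprec = topology_precision(pair.C_P, pair.S_G)
    tsens = topology_sensitivity(pair.C_G, pair.S_P)
    if tprec + tsens == 0:
        return 0.0
    return 2.0 * tprec * tsens / (tprec + tsens)


def dice_coefficient(P, R) -> float:
    """Dice similarity coefficient 2·tp / (2·tp + fp + fn); 1 if both empty."""
    P, R = _as_bool(P, "P"), _as_bool(R, "R")
    _check_shapes(P, R)
    tp = int((P & R).sum())
    denom = int(P.sum()) + int(R.sum())
    if denom == 0:
        return 1.0
    return 2.0 * tp / denom


# ---------------------------------------------------------------------------
# surface distances


def surface_voxels(mask) -> np.ndarray:
    """Boundary of a mask: foreground voxels with a background 6-neighbour
    or touching the volume border."""
    mask = _as_bool(mask)
    interior = ndi.binary_erosion(mask, structure=_STRUCT_6, border_value=0)
    return mask & ~interior


def _surface_distances(src_surf, dst_surf, spacing):
    """Distance from every voxel of ``src_surf`` to the nearest voxel of
    ``dst_surf`` (voxel centres, mm)."""
    # EDT of the complement gives the distance to the nearest surface voxel
    dist_to_dst = ndi.distance_transform_edt(~dst_surf, sampling=spacing)
    return dist_to_dst[src_surf]


def assd(P, R, spacing_mm=(1.0, 1.0, 1.0)) -> float:
    """Average symmetric surface distance between two masks, in mm."""
    P, R = _as_bool(P, "P"), _as_bool(R, "R")
    _check_shapes(P, R)
    if not P.any() or not R.any():
        raise ValueError("assd is undefined for an empty mask")
    sp, sr = surface_voxels(P), surface_voxels(R)
    d_pr = _surface_distances(sp, sr, spacing_mm)
    d_rp = _surface_distances(sr, sp, spacing_mm)
    return float((d_pr.sum() + d_rp.sum()) / (d_pr.size + d_rp.size))


def hd95(P, R, spacing_mm=(1.0, 1.0, 1.0)) -> float:
    """95th-percentile symmetric Hausdorff distance between two masks, mm."""
    P, R = _as_bool(P, "P"), _as_bool(R, "R")
    _check_shapes(P, R)
    if not P.any() or not R.any():
        raise ValueError("hd95 is undefined for an empty mask")
    sp, sr = surface_voxels(P), surface_voxels(R)
    d_pr = _surface_distances(sp, sr, spacing_mm)
    d_rp = _surface_distances(sr, sp, spacing_mm)
    return float(max(np.percentile(d_pr, 95), np.percentile(d_rp, 95)))


# ---------------------------------------------------------------------------
# topology


def euler_characteristic(mask) -> int:
    """Euler characteristic χ = V − E + F − C of the union of closed unit
    cubes centred on the foreground voxels.

    A grid vertex / edge / face is counted when at least one incident
    voxel is foreground; this cell complex is homotopy-equivalent to the
    26-connected digitisation of the object.
    """
    mask = _as_bool(mask)
    p = np.pad(mask, 1).astype(np.uint8)

    def covered(axes):
        # OR over the 2^len(axes) shifts that share a grid cell
        out = p
        for ax in axes:
            a = np.swapaxes(out, 0, ax)
            a = a[:-1] | a[1:]
            out = np.swapaxes(a, 0, ax)
        return int(out.sum())

    C = int(mask.sum())
    F = covered([0]) + covered([1]) + covered([2])
    E = covered([0, 1]) + covered([0, 2]) + covered([1, 2])
    V = covered([0, 1, 2])
    return V - E + F - C


def betti_numbers(mask) -> BettiProfile:
    """Betti numbers of a binary volume under the (26, 6) convention.

    β0 is the number of 26-connected foreground components, β2 the number of
    6-connected background components not reaching the volume border
    (cavities), and β1 = β0 + β2 − χ.
    """
    mask = _as_bool(mask)
    if not mask.any():
        return BettiProfile(0, 0, 0)
    b0 = int(ndi.label(mask, structure=_STRUCT_26)[1])

    bg, n_bg = ndi.label(~mask, structure=_STRUCT_6)
    border_labels = np.unique(
        np.concatenate(
            [
                bg[0].ravel(), bg[-1].ravel(),
                bg[:, 0].ravel(), bg[:, -1].ravel(),
                bg[:, :, 0].ravel(), bg[:, :, -1].ravel(),
            ]
        )
    )
    border_labels = set(border_labels.tolist()) - {0}
    b2 = n_bg - len(border_labels)

    chi = euler_characteristic(mask)
    b1 = b0 + b2 - chi
    return BettiProfile(b0, int(b1), int(b2))


# ---------------------------------------------------------------------------
# case-level evaluation


def evaluate_pair(pair: SegPair, case_id: str = "") -> MetricReport:
    """Full per-case report: DSC, clDice, ASSD, HD95 and the Betti profile
    of the predicted segmentation."""
    return MetricReport(
        dsc=dice_coefficient(pair.S_P, pair.S_G),
        cldice=cl_dice(pair),
        assd_mm=assd(pair.S_P, pair.S_G, pair.spacing_mm),
        hd95_mm=hd95(pair.S_P, pair.S_G, pair.spacing_mm),
        betti=betti_numbers(pair.S_P),
        case_id=case_id,
    )
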