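"""Patch augmentation policy for 3D angiography training.

The transform chain (applied in this order, each gated by its own
probability) mirrors the widely used nnU-Net recipe:

* rotation — per axis, p=0.2, angle U(−30°, 30°)
* scaling — p=0.2, factor U(0.7, 1.4)
* Gaussian noise — p=0.1, variance U(0.0, 0.1)
* Gaussian blur — p=0.1, kernel width U(0.5, 1.0)
* brightness — p=0.15, multiplicative factor U(0.75, 1.25)
* contrast — p=0.15, factor U(0.75, 1.25), clipped to the original range
* simulated low resolution — p=0.125, downsample factor U(0.5, 1.0)
  (nearest-neighbour down, cubic up)
* gamma — p=0.1, γ U(0.7, 1.5) after normalising intensities to [0, 1]
* mirroring — p=0.5 per axis

Geometric transforms act on the image (linear interpolation) and every
label channel (nearest neighbour, re-binarized at 0.5); photometric
transforms act on the image only. Output shape always equals input shape.
The random plan is sampled separately from its application so draw
statistics can be audited cheaply.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

__all__ = ["AugmentationPolicy", "sample_plan", "apply_plan", "apply_augmentations"]


@dataclass(frozen=True)
class AugmentationPolicy:
    """Gating probabilities and uniform parameter ranges of each transform."""

    p_rotation: float = 0.2          # per axis
    rotation_deg: tuple = (-30.0, 30.0)
    p_scaling: float = 0.2
    scale_range: tuple = (0.7, 1.4)
    p_noise: float = 0.1
    noise_variance: tuple = (0.0, 0.1)
    p_blur: float = 0.1
    blur_sigma: tuple = (0.5, 1.0)
    p_brightness: float = 0.15
    brightness_range: tuple = (0.75, 1.25)
    p_contrast: float = 0.15
    contrast_range: tuple = (0.75, 1.25)
    p_lowres: float = 0.125
    lowres_factor: tuple = (0.5, 1.0)
    p_gamma: float = 0.1
    gamma_range: tuple = (0.7, 1.5)
    p_mirror: float = 0.5            # per axis

    def __post_init__(self):
        for name in (
            "p_rotation", "p_scaling", "p_noise", "p_blur", "p_brightness",
            "p_contrast", "p_lowres", "p_gamma", "p_mirror",
        ):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be a probability, got {p}")

    @classmethod
    def disabled(cls) -> "AugmentationPolicy":
        """All probabilities zero — identity augmentation for debugging."""
        return cls(
            p_rotation=0, p_scaling=0, p_noise=0, p_blur=0, p_brightness=0,
            p_contrast=0, p_lowres=0, p_gamma=0, p_mirror=0,
        )


def sample_plan(policy: AugmentationPolicy, rng) -> list[tuple[str, dict]]:
    """Draw the gated transform plan for one patch.

    Returns the ordered list of (transform name, parameters) that
    ``apply_plan`` will execute. Sampling is separated from application so
    gating frequencies and parameter ranges can be checked over many draws
    without touching voxel data.
    """
    plan: list[tuple[str, dict]] = []
    angles = {}
    for ax in range(3):
        if rng.random() < policy.p_rotation:
            angles[ax] = rng.uniform(*policy.rotation_deg)
    if angles:
        plan.append(("rotation", {"angles_deg": angles}))
    if rng.random() < policy.p_scaling:
        plan.append(("scaling", {"factor": rng.uniform(*policy.scale_range)}))
    if rng.random() < policy.p_noise:
        plan.append(("gaussian_noise", {"variance": rng.uniform(*policy.noise_variance),
                                        "seed": int(rng.integers(2**31))}))
    if rng.random() < policy.p_blur:
        plan.append(("gaussian_blur", {"sigma": rng.uniform(*policy.blur_sigma)}))
    if rng.random() < policy.p_brightness:
        plan.append(("brightness", {"factor": rng.uniform(*policy.brightness_range)}))
    if rng.random() < policy.p_contrast:
        plan.append(("contrast", {"factor": rng.uniform(*policy.contrast_range)}))
    if rng.random() < policy.p_lowres:
        plan.append(("low_resolution", {"factor": rng.uniform(*policy.lowres_factor)}))
    if rng.random() < policy.p_gamma:
        plan.append(("gamma", {"gamma": rng.uniform(*policy.gamma_range)}))
    flips = [ax for ax in range(3) if rng.random() < policy.p_mirror]
    if flips:
        plan.append(("mirror", {"axes": tuple(flips)}))
    return plan


# ---------------------------------------------------------------------------
# transform application


def _geometric(image, labels, fn_img, fn_lab):
    image = fn_img(image)
    labels = [fn_lab(lab) for lab in labels]
    return image, labels


def _rotate(vol, angles_deg, order):
    planes = {0: (1, 2), 1: (0, 2), 2: (0, 1)}
    out = vol
    for ax, ang in sorted(angles_deg.items()):
        out = ndi.rotate(
            out, ang, axes=planes[ax], reshape=False, order=order,
            mode="constant", cval=0.0, prefilter=order > 1,
        )
    return out


def _zoom_keep_shape(vol, factor, order):
    """Zoom about the patch center, then crop or zero-pad back to shape."""
    shape = np.array(vol.shape)
    z = ndi.zoom(vol, factor, order=order, mode="constant", cval=0.0, prefilter=order > 1)
    out = np.zeros_like(vol)
    zs = np.array(z.shape)
    src_lo = np.maximum((zs - shape) // 2, 0)
    dst_lo = np.maximum((shape - zs) // 2, 0)
    span = np.minimum(shape, zs)
    out[
        dst_lo[0]:dst_lo[0] + span[0],
        dst_lo[1]:dst_lo[1] + span[1],
        dst_lo[2]:dst_lo[2] + span[2],
    ] = z[
        src_lo[0]:src_lo[0] + span[0],
        src_lo[1]:src_lo[1] + span[1],
        src_lo[2]:src_lo[2] + span[2],
    ]
    return out


def apply_plan(image, labels, plan):
    """Execute a sampled plan on an image patch and its label patches."""
    image = np.asarray(image, np.float32).copy()
    labels = [np.asarray(lab).astype(bool) for lab in labels]
    for lab in labels:
        if lab.shape != image.shape:
            raise ValueError("image and label shapes differ")

    for name, p in plan:
        if name == "rotation":
            image, labs = _geometric(
                image, labels,
                lambda v: _rotate(v, p["angles_deg"], order=1),
                lambda v: _rotate(v.astype(np.float32), p["angles_deg"], order=0) >= 0.5,
            )
            labels = labs
        elif name == "scaling":
            image, labs = _geometric(
                image, labels,
                lambda v: _zoom_keep_shape(v, p["factor"], order=1),
                lambda v: _zoom_keep_shape(v.astype(np.float32), p["factor"], order=0) >= 0.5,
            )
            labels = labs
        elif name == "gaussian_noise":
            noise_rng = np.random.default_rng(p["seed"])
            image = image + noise_rng.normal(
                0.0, np.sqrt(p["variance"]), image.shape
            ).astype(np.float32)
        elif name == "gaussian_blur":
            image = ndi.gaussian_filter(image, p["sigma"])
        elif name == "brightness":
            image = image * p["factor"]
        elif name == "contrast":
            lo, hi = float(image.min()), float(image.max())
            mean = float(image.mean())
            image = np.clip((image - mean) * p["factor"] + mean, lo, hi)
        elif name == "low_resolution":
            shape = image.shape
            small = ndi.zoom(image, p["factor"], order=0, mode="nearest")
            back = ndi.zoom(
                small, np.array(shape) / np.array(small.shape), order=3, mode="nearest"
            )
            image = _match_shape(back, shape)
        elif name == "gamma":
            lo, hi = float(image.min()), float(image.max())
            span = hi - lo
            if span > 0:
                image = ((image - lo) / span) ** p["gamma"] * span + lo
        elif name == "mirror":
            for ax in p["axes"]:
                image = np.flip(image, ax)
                labels = [np.flip(lab, ax) for lab in labels]
        else:  # pragma: no cover
            raise ValueError(f"unknown transform {name!r}")
    return np.ascontiguousarray(image), [np.ascontiguousarray(lab) for lab in labels]


def _match_shape(vol, shape):
    out = np.zeros(shape, vol.dtype)
    span = np.minimum(shape, vol.shape)
    out[: span[0], : span[1], : span[2]] = vol[: span[0], : span[1], : span[2]]
    return out


def apply_augmentations(image, labels, policy: AugmentationPolicy, rng, log=None):
    """Sample a gated plan and apply it to an image and its label channels.

    ``log``, if given, collects the executed plan for auditing. Fully
    deterministic for a seeded ``rng``.
    """
    plan = sample_plan(policy, rng)
    if log is not None:
        log.extend(plan)
    return apply_plan(image, labels, plan)
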