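"""2D registration of projected aBMD maps onto measured scout aBMD maps.

Both images carry the same physical quantity (areal BMD in g/cm^2), so a
mean-squared-difference metric is appropriate.  Optimisation is two-stage
— translation only, then full affine — with a regular-step gradient
descent over a 3-level coarse-to-fine pyramid (SimpleITK backend, dense
sampling, hence deterministic for a fixed configuration).

Transforms map fixed-image points to moving-image points (the resampling
convention); labels are resampled nearest-neighbour so identities survive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import SimpleITK as sitk

__all__ = ["AffineTransform2D", "RegistrationConfig", "register_2d", "apply_transform"]


class RegistrationError(RuntimeError):
    """Raised when registration diverges or yields an implausible solution."""


@dataclass
class AffineTransform2D:
    """Affine map p -> linear @ (p - center) + center + translation,
    with p = (row, col) in pixel units."""

    linear: np.ndarray
    translation: np.ndarray
    fixed_center: np.ndarray

    def __post_init__(self):
        self.linear = np.asarray(self.linear, dtype=float).reshape(2, 2)
        self.translation = np.asarray(self.translation, dtype=float).reshape(2)
        self.fixed_center = np.asarray(self.fixed_center, dtype=float).reshape(2)
        det = float(np.linalg.det(self.linear))
        if not 0.5 < det < 2.0:
            raise RegistrationError(
                f"affine determinant {det:.3f} outside the accepted (0.5, 2.0) band"
            )

    @property
    def determinant(self) -> float:
        return float(np.linalg.det(self.linear))

    @property
    def rotation_deg(self) -> float:
        """Rotation angle of the polar decomposition of the linear part."""
        u, _, vt = np.linalg.svd(self.linear)
        r = u @ vt
        return float(np.degrees(np.arctan2(r[1, 0], r[0, 0])))

    def to_sitk(self) -> sitk.AffineTransform:
        t = sitk.AffineTransform(2)
        # sitk index order is (x=col, y=row): swap axes
        swap = np.array([[0, 1], [1, 0]])
        lin = swap @ self.linear @ swap
        t.SetMatrix(lin.ravel())
        t.SetCenter(tuple(self.fixed_center[::-1]))
        t.SetTranslation(tuple(self.translation[::-1]))
        return t

    @classmethod
    def from_sitk(cls, transform: sitk.Transform) -> "AffineTransform2D":
        transform = sitk.AffineTransform(transform)
        swap = np.array([[0, 1], [1, 0]])
        lin = swap @ np.asarray(transform.GetMatrix()).reshape(2, 2) @ swap
        return cls(
            linear=lin,
            translation=np.asarray(transform.GetTranslation())[::-1],
            fixed_center=np.asarray(transform.GetCenter())[::-1],
        )

    def as_dict(self) -> dict:
        return {
            "linear": self.linear.tolist(),
            "translation": self.translation.tolist(),
            "fixed_center": self.fixed_center.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AffineTransform2D":
        return cls(
            linear=np.asarray(d["linear"]),
            translation=np.asarray(d["translation"]),
            fixed_center=np.asarray(d["fixed_center"]),
        )


@dataclass(frozen=True)
class RegistrationConfig:
    pyramid_shrink: tuple = (4, 2, 1)
    pyramid_smoothing: tuple = (2.0, 1.0, 0.0)
    learning_rate: float = 1.0
    min_step: float = 1e-6
    iterations: int = 200
    require_improvement: bool = True


def _to_image(arr: np.ndarray) -> sitk.Image:
    return sitk.GetImageFromArray(np.ascontiguousarray(arr, dtype=np.float64))


def _mean_squares(fixed: sitk.Image, moving: sitk.Image, transform) -> float:
    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMeanSquares()
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetInitialTransform(transform, inPlace=False)
    return reg.MetricEvaluate(fixed, moving)


def _run_stage(fixed, moving, transform, config, optimizer: str):
    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMeanSquares()
    reg.SetInterpolator(sitk.sitkLinear)
    if optimizer == "rsgd":
        # robust for the translation stage: large capture range
        reg.SetOptimizerAsRegularStepGradientDescent(
            learningRate=config.learning_rate,
            minStep=config.min_step,
            numberOfIterations=config.iterations,
        )
        reg.SetOptimizerScalesFromPhysicalShift()
    else:
        # quasi-Newton refinement: the affine matrix parameters live on a
        # very different scale from translations, which first-order
        # regular-step descent handles poorly
        reg.SetOptimizerAsLBFGSB(numberOfIterations=config.iterations)
    reg.SetShrinkFactorsPerLevel(list(config.pyramid_shrink))
    reg.SetSmoothingSigmasPerLevel(list(config.pyramid_smoothing))
    reg.SetInitialTransform(transform, inPlace=True)
    reg.Execute(fixed, moving)
    return transform, reg.GetMetricValue()


def register_2d(
    moving,
    fixed,
    config: RegistrationConfig = RegistrationConfig(),
) -> tuple[AffineTransform2D, np.ndarray, float]:
    """Two-stage (translation, then affine) registration.

    Parameters are 2D aBMD arrays (or objects with an ``abmd`` attribute).
    Returns the accepted transform, the moving image warped onto the fixed
    grid, and the final mean-squared-difference metric.  Divergence — a
    final metric above the identity-transform metric — and implausible
    determinants are rejected.
    """
    mov_arr = np.asarray(getattr(moving, "abmd", moving), dtype=float)
    fix_arr = np.asarray(getattr(fixed, "abmd", fixed), dtype=float)
    if not (np.all(np.isfinite(mov_arr)) and np.all(np.isfinite(fix_arr))):
        raise RegistrationError("registration inputs must be finite")
    fixed_img = _to_image(fix_arr)
    moving_img = _to_image(mov_arr)

    initial_metric = _mean_squares(fixed_img, moving_img, sitk.TranslationTransform(2))

    translation = sitk.TranslationTransform(2)
    translation, _ = _run_stage(fixed_img, moving_img, translation, config, "rsgd")

    affine = sitk.AffineTransform(2)
    center = [(s - 1) / 2.0 for s in fixed_img.GetSize()]
    affine.SetCenter(center)
    affine.SetTranslation(translation.GetOffset())
    affine, final_metric = _run_stage(fixed_img, moving_img, affine, config, "lbfgs")

    if config.require_improvement and final_metric > initial_metric * (1 + 1e-9):
        raise RegistrationError(
            f"registration diverged: final metric {final_metric:.6g} exceeds "
            f"initial {initial_metric:.6g}"
        )
    result = AffineTransform2D.from_sitk(affine)  # validates the determinant
    warped = sitk.GetArrayFromImage(
        sitk.Resample(moving_img, fixed_img, affine, sitk.sitkLinear, 0.0)
    )
    return result, warped, float(final_metric)


def apply_transform(mask2d: np.ndarray, transform: AffineTransform2D) -> np.ndarray:
    """Resample a labelled 2D mask with nearest-neighbour interpolation;
    out-of-bounds pixels become background (0)."""
    img = sitk.GetImageFromArray(np.ascontiguousarray(mask2d, dtype=np.int32))
    out = sitk.Resample(img, img, transform.to_sitk(), sitk.sitkNearestNeighbor, 0)
    return sitk.GetArrayFromImage(out).astype(mask2d.dtype)
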