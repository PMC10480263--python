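"""Clinical-style preprocessing of CT / setup-CBCT pairs.

Before a planning CT and a setup CBCT can form a training pair they must
share a grid: the CBCT (smaller field of view) is zero-padded up to the
target grid, the CT is resized and rigidly registered onto the padded CBCT,
and the treatment couch is erased from the CT target (set to -1024 HU below
the couch surface) so the model never learns to hallucinate it.

Registration is 2D rigid plus isotropic scale, with the similarity metric
evaluated only over the CBCT's nonzero (field-of-view) region so the zero
padding cannot bias the alignment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import SimpleITK as sitk

from .phantom import CTVolume, body_mask


@dataclass(frozen=True)
class RegistrationResult:
    """Recovered rigid+scale transform and the CT resampled onto the CBCT grid.

    ``rotation_deg`` is in degrees, ``translation`` is (row, col) in px,
    ``scale`` is the isotropic resize factor. ``final_metric`` is the
    correlation achieved over the field-of-view mask.
    """

    rotation_deg: float
    translation: tuple[float, float]
    scale: float
    resampled_ct: np.ndarray
    final_metric: float


@dataclass(frozen=True)
class PairedSample:
    input_img: np.ndarray  # padded CBCT
    target_img: np.ndarray  # registered, couch-removed CT
    patient_id: str = "anon"
    slice_index: int = 0
    stage_tag: str = ""

    def __post_init__(self):
        if self.input_img.shape != self.target_img.shape:
            raise ValueError("input and target dimensions differ")


def pad_to_grid(cbct: np.ndarray, target_size: int) -> np.ndarray:
    """Centre ``cbct`` on a ``target_size`` square grid, padding with zeros."""
    h, w = cbct.shape
    if target_size < h or target_size < w:
        raise ValueError(f"target_size {target_size} smaller than image {cbct.shape}")
    if (h, w) == (target_size, target_size):
        return cbct
    out = np.zeros((target_size, target_size), dtype=cbct.dtype)
    r0 = (target_size - h) // 2
    c0 = (target_size - w) // 2
    out[r0 : r0 + h, c0 : c0 + w] = cbct
    return out


def register_ct_to_cbct(
    moving_ct: np.ndarray, fixed_cbct: np.ndarray, config: dict | None = None
) -> RegistrationResult:
    """Register the CT onto the padded CBCT grid (2D rigid + isotropic scale).

    Correlation is maximised over the nonzero region of ``fixed_cbct`` with a
    multi-resolution gradient-descent scheme. Raises ``RuntimeError`` if the
    optimiser stops without improving the metric past ``min_correlation``.
    """
    cfg = {"iterations": 200, "min_correlation": 0.2, "shrink": [4, 2, 1]}
    cfg.update(config or {})
    if not np.any(fixed_cbct):
        raise ValueError("fixed CBCT has no nonzero content")

    fixed = sitk.GetImageFromArray(np.ascontiguousarray(fixed_cbct, dtype=np.float32))
    moving = sitk.GetImageFromArray(np.ascontiguousarray(moving_ct, dtype=np.float32))
    mask = sitk.GetImageFromArray((fixed_cbct != 0).astype(np.uint8))

    tx0 = sitk.CenteredTransformInitializer(
        fixed, moving, sitk.Similarity2DTransform(), sitk.CenteredTransformInitializerFilter.GEOMETRY
    )
    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsCorrelation()
    reg.SetMetricFixedMask(mask)
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=1.0,
        minStep=1e-4,
        numberOfIterations=int(cfg["iterations"]),
        relaxationFactor=0.6,
    )
    reg.SetOptimizerScalesFromPhysicalShift()
    shrink = list(cfg["shrink"])
    reg.SetShrinkFactorsPerLevel(shrink)
    reg.SetSmoothingSigmasPerLevel([max(0, s // 2) for s in shrink])
    reg.SetInitialTransform(tx0, inPlace=False)
    out_tx = reg.Execute(fixed, moving)

    corr = -float(reg.GetMetricValue())  # sitk minimises the negative correlation
    if corr < float(cfg["min_correlation"]):
        raise RuntimeError(
            f"registration did not converge: correlation {corr:.3f} over the FOV mask"
        )

    resampled = sitk.Resample(
        moving, fixed, out_tx, sitk.sitkLinear, float(np.min(moving_ct)), sitk.sitkFloat32
    )
    sim = sitk.Similarity2DTransform()
    sim.SetParameters(out_tx.GetParameters() if not isinstance(out_tx, sitk.CompositeTransform)
                      else out_tx.GetNthTransform(0).GetParameters())
    scale, angle, tx, ty = sim.GetParameters()
    return RegistrationResult(
        rotation_deg=float(np.degrees(angle)),
        translation=(float(ty), float(tx)),  # (row, col)
        scale=float(scale),
        resampled_ct=sitk.GetArrayFromImage(resampled),
        final_metric=corr,
    )


def detect_couch_surface(ct: np.ndarray, fallback_row: int | None = None) -> int:
    """Locate the top row of the treatment couch.

    Scans rows below the body's lowest extent for the first whose above-air
    (> -900 HU) run covers at least 60% of the image width. Falls back to
    ``fallback_row`` when no couch-like row exists.
    """
    h, w = ct.shape
    body = body_mask(ct)
    start = int(np.max(np.nonzero(body.any(axis=1))[0])) + 1 if body.any() else 0
    for r in range(start, h):
        if (ct[r] > -900).mean() >= 0.6:
            return r
    if fallback_row is not None:
        return int(fallback_row)
    raise ValueError("no couch surface found and no fallback row configured")


def remove_couch(ct: np.ndarray, couch_row: int) -> np.ndarray:
    """Set every pixel strictly below the couch surface row to -1024 HU."""
    h = ct.shape[0]
    if not 0 <= couch_row < h:
        raise ValueError("couch_row outside the image")
    out = ct.copy()
    out[couch_row + 1 :, :] = -1024.0
    return out


def build_training_pairs(
    ct_vol: CTVolume, cbct_vols: list[CTVolume], config: dict | None = None
) -> list[PairedSample]:
    """Assemble index-aligned (padded CBCT, registered couch-removed CT) pairs.

    Both image sets must share slice thickness — otherwise slices cannot
    correspond one-to-one and pairing is refused. Per slice: the CBCT is
    zero-padded to the target grid, the CT is registered onto it (skippable
    for already-aligned simulated data via ``{"registration": False}``),
    and the couch is removed from the registered CT.
    """
    cfg = {"target_size": None, "registration": True, "couch_fallback_row": None}
    cfg.update(config or {})
    pairs: list[PairedSample] = []
    for cbct_vol in cbct_vols:
        if abs(cbct_vol.slice_thickness - ct_vol.slice_thickness) > 1e-6:
            raise ValueError(
                "slice thickness mismatch: CT and CBCT image sets must share "
                f"slice thickness ({ct_vol.slice_thickness} vs {cbct_vol.slice_thickness} mm)"
            )
        if len(cbct_vol) != len(ct_vol):
            raise ValueError("CT and CBCT volumes have different slice counts")
        target = cfg["target_size"] or max(ct_vol.data.shape[1], cbct_vol.data.shape[1])
        for i in range(len(cbct_vol)):
            padded = pad_to_grid(cbct_vol[i], target)
            if cfg["registration"]:
                ct_reg = register_ct_to_cbct(ct_vol[i], padded).resampled_ct
            else:
                ct_reg = pad_to_grid(ct_vol[i], target)
            row = detect_couch_surface(ct_reg, fallback_row=cfg["couch_fallback_row"])
            target_img = remove_couch(ct_reg, row)
            pairs.append(
                PairedSample(
                    input_img=padded.astype(np.float32),
                    target_img=target_img.astype(np.float32),
                    patient_id=ct_vol.patient_id,
                    slice_index=i,
                    stage_tag=cbct_vol.patient_id,
                )
            )
    return pairs
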