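"""Synthetic CBCT simulation by sinogram-domain corruption.

A clean CT slice is turned into a streaked, field-of-view-truncated synthetic
CBCT in five steps:

1. a coarse random elastic deformation produces a distorted copy of the slice;
2. both slices are radon-transformed into sinograms (after shifting
   intensities so air contributes ~zero attenuation);
3. up to ``max_replace_fraction`` of the original sinogram entries — the
   realised fraction is drawn uniformly per image — are replaced with the
   distorted sinogram's values, creating inconsistent projection data;
4. filtered back-projection of the mixed sinogram reconstructs the slice with
   streak artifacts, the hallmark of inconsistent projections;
5. a circular field of view of radius ``fov_radius`` about a randomly chosen,
   deliberately lateralised isocentre is applied: everything outside the disc
   is set to stored intensity 0, emulating partial CBCT acquisition. The
   image is not recentred and keeps its original dimensions.

The ground truth for streak removal is the clean CT under the same circular
mask; the ground truth for anatomy imputation is the full clean CT.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import map_coordinates, zoom
from skimage.transform import iradon, radon

from .phantom import HU_MAX, HU_MIN, body_mask


@dataclass(frozen=True)
class SimParams:
    """Knobs of the synthetic-CBCT simulator.

    max_replace_fraction : upper bound of the per-image uniform draw of the
        sinogram replacement fraction (dimensionless, default 0.10).
    fov_radius : radius of the circular field of view in px (default 128,
        matched to a 512-px slice; scale down with the image).
    n_angles : projection angles, evenly spaced over [0, 180) degrees.
    deform_grid_spacing / deform_max_disp : coarse displacement-field grid
        spacing and per-node maximum displacement, px.
    min_outside_fraction : an isocentre is accepted only if at least this
        fraction of body pixels falls outside the field of view, so every
        simulated acquisition is genuinely partial.
    attenuation_offset : HU shift applied before projection so that air
        (-1000 HU) carries ~zero attenuation; undone after reconstruction.
    """

    max_replace_fraction: float = 0.10
    fov_radius: float = 128.0
    n_angles: int = 180
    deform_grid_spacing: int = 64
    deform_max_disp: float = 15.0
    min_outside_fraction: float = 0.05
    attenuation_offset: float = 1024.0
    entrywise: bool = True  # False replaces whole projection views instead

    def __post_init__(self):
        if not 0.0 <= self.max_replace_fraction <= 1.0:
            raise ValueError("max_replace_fraction must be in [0, 1]")
        if self.fov_radius <= 0:
            raise ValueError("fov_radius must be > 0")
        if self.n_angles < 2:
            raise ValueError("n_angles must be >= 2")
        if not 0.0 < self.min_outside_fraction < 1.0:
            raise ValueError("min_outside_fraction must be in (0, 1)")

    @property
    def angles(self) -> np.ndarray:
        return np.linspace(0.0, 180.0, self.n_angles, endpoint=False)


@dataclass(frozen=True)
class Sinogram:
    """Line integrals, one row per projection angle, one column per detector bin."""

    values: np.ndarray  # (n_angles, n_bins)
    angles: np.ndarray  # degrees

    def __post_init__(self):
        if self.values.ndim != 2 or self.values.shape[0] != len(self.angles):
            raise ValueError("sinogram must be n_angles x n_bins")
        if not np.isfinite(self.values).all():
            raise ValueError("sinogram contains non-finite values")


@dataclass(frozen=True)
class IsocentrePoint:
    row: float
    col: float


@dataclass(frozen=True)
class SimPair:
    """One simulated training example.

    scbct     : streaked, FOV-masked synthetic CBCT (model input)
    streak_gt : clean CT under the same FOV mask (streak-removal target)
    full_gt   : original clean CT (imputation target)
    """

    scbct: np.ndarray
    streak_gt: np.ndarray
    full_gt: np.ndarray
    isocentre: IsocentrePoint
    seed: int
    replaced_fraction: float


def elastic_deform(img: np.ndarray, params: SimParams, seed: int) -> np.ndarray:
    """Warp ``img`` with a smooth random displacement field.

    Displacements are drawn per node of a coarse grid (spacing
    ``deform_grid_spacing``), uniform in +-``deform_max_disp`` px,
    bilinearly upsampled to pixel resolution and applied with edge clamping.
    """
    h, w = img.shape
    gs = params.deform_grid_spacing
    if gs >= min(h, w):
        raise ValueError("deform_grid_spacing must be smaller than the image")
    if params.deform_max_disp == 0:
        return img.copy()
    rng = np.random.default_rng(seed)
    nodes = (h // gs + 2, w // gs + 2)
    disp = rng.uniform(-params.deform_max_disp, params.deform_max_disp, size=(2, *nodes))
    field = np.stack(
        [zoom(disp[i], (h / nodes[0], w / nodes[1]), order=1) for i in range(2)]
    )
    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    coords = np.stack([rr + field[0], cc + field[1]])
    return map_coordinates(img.astype(np.float64), coords, order=1, mode="nearest").astype(
        np.float32
    )


def forward_project(img: np.ndarray, params: SimParams) -> Sinogram:
    """Radon-transform an HU slice into a sinogram.

    The image is shifted by ``attenuation_offset`` first so that air is ~0
    and line integrals are non-negative for anatomy.
    """
    shifted = img.astype(np.float64) + params.attenuation_offset
    sino = radon(shifted, theta=params.angles, circle=False)  # (bins, angles)
    return Sinogram(values=np.ascontiguousarray(sino.T), angles=params.angles)


def mix_sinograms(
    s_orig: Sinogram, s_dist: Sinogram, params: SimParams, seed: int
) -> tuple[Sinogram, float]:
    """Replace a random subset of ``s_orig`` entries with ``s_dist`` values.

    The replacement fraction f is drawn Uniform(0, max_replace_fraction) per
    call; round(f*N) entry positions are chosen uniformly without replacement
    (N = total entries). With ``entrywise=False`` whole projection rows are
    replaced instead, keeping the realised fraction as close to f as the row
    granularity allows.
    """
    if s_orig.values.shape != s_dist.values.shape:
        raise ValueError("sinogram shapes differ")
    rng = np.random.default_rng(seed)
    f = rng.uniform(0.0, params.max_replace_fraction)
    out = s_orig.values.copy()
    n = out.size
    if params.entrywise:
        k = int(round(f * n))
        idx = rng.choice(n, size=k, replace=False)
        out.ravel()[idx] = s_dist.values.ravel()[idx]
        realised = k / n
    else:
        n_rows = out.shape[0]
        k = int(round(f * n_rows))
        rows = rng.choice(n_rows, size=k, replace=False)
        out[rows] = s_dist.values[rows]
        realised = k / n_rows
    return Sinogram(values=out, angles=s_orig.angles), realised


def back_project(s: Sinogram, out_size: int, params: SimParams) -> np.ndarray:
    """Filtered back-projection (ramp filter, linear interpolation).

    The attenuation offset is removed and values are clamped to the valid
    HU range [-1024, 3071].
    """
    recon = iradon(
        np.ascontiguousarray(s.values.T),
        theta=s.angles,
        circle=False,
        output_size=out_size,
        filter_name="ramp",
        interpolation="linear",
    )
    recon = recon - params.attenuation_offset
    return np.clip(recon, HU_MIN, HU_MAX).astype(np.float32)


def sample_isocentre(
    mask: np.ndarray, params: SimParams, seed: int, max_attempts: int = 1000
) -> IsocentrePoint:
    """Draw an isocentre uniformly over the body mask, rejecting candidates
    that would not truncate the body.

    A candidate is accepted when at least ``min_outside_fraction`` of the
    body pixels lie farther than ``fov_radius`` from it — i.e. the resulting
    acquisition is genuinely partial, as for a lateralised target.
    """
    mask = np.asarray(mask, bool)
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise ValueError("body mask is empty")
    rng = np.random.default_rng(seed)
    n_body = rows.size
    for _ in range(max_attempts):
        i = rng.integers(0, n_body)
        r, c = float(rows[i]), float(cols[i])
        outside = ((rows - r) ** 2 + (cols - c) ** 2) > params.fov_radius**2
        if outside.sum() >= params.min_outside_fraction * n_body:
            return IsocentrePoint(row=r, col=c)
    raise RuntimeError(
        "cannot truncate: no isocentre leaves enough of the body outside the "
        f"field of view (radius {params.fov_radius} px) after {max_attempts} attempts"
    )


def apply_fov_mask(img: np.ndarray, iso: IsocentrePoint, params: SimParams) -> np.ndarray:
    """Zero every pixel farther than ``fov_radius`` from the isocentre.

    Stored intensity 0 (not -1024 HU) marks the exterior. The output keeps
    the input's dimensions: no recentring, no cropping.
    """
    h, w = img.shape
    if not (0 <= iso.row < h and 0 <= iso.col < w):
        raise ValueError("isocentre outside the image")
    rr, cc = np.ogrid[:h, :w]
    out = img.copy()
    out[((rr - iso.row) ** 2 + (cc - iso.col) ** 2) > params.fov_radius**2] = 0.0
    return out


def simulate_scbct_slice(
    ct: np.ndarray,
    params: SimParams | None = None,
    seed: int = 0,
    isocentre: IsocentrePoint | None = None,
    force_fraction: float | None = None,
) -> SimPair:
    """Full simulation chain for one slice; deterministic per (ct, params, seed).

    ``isocentre`` pins the field-of-view centre (otherwise sampled from the
    body mask); ``force_fraction`` pins the sinogram replacement fraction
    (otherwise drawn uniformly below ``max_replace_fraction``).
    """
    params = params or SimParams()
    ss = np.random.SeedSequence(seed).spawn(3)
    sub = [int(s.generate_state(1)[0] % (2**31)) for s in ss]

    distorted = elastic_deform(ct, params, seed=sub[0])
    s_orig = forward_project(ct, params)
    s_dist = forward_project(distorted, params)
    if force_fraction is not None:
        forced = replace(params, max_replace_fraction=force_fraction)
        # degenerate uniform draw: Uniform(0, f) replaced by exactly f
        rng = np.random.default_rng(sub[1])
        out = s_orig.values.copy()
        k = int(round(force_fraction * out.size))
        idx = rng.choice(out.size, size=k, replace=False)
        out.ravel()[idx] = s_dist.values.ravel()[idx]
        mixed, fraction = Sinogram(out, s_orig.angles), k / out.size
        params = forced
    else:
        mixed, fraction = mix_sinograms(s_orig, s_dist, params, seed=sub[1])
    streaked = back_project(mixed, out_size=ct.shape[0], params=params)

    if isocentre is None:
        isocentre = sample_isocentre(body_mask(ct), params, seed=sub[2])
    scbct = apply_fov_mask(streaked, isocentre, params)
    streak_gt = apply_fov_mask(ct.astype(np.float32), isocentre, params)
    return SimPair(
        scbct=scbct,
        streak_gt=streak_gt,
        full_gt=ct.astype(np.float32),
        isocentre=isocentre,
        seed=seed,
        replaced_fraction=float(fraction),
    )
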