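"""Synthetic thorax phantoms.

Generates seeded, HU-valued axial chest slices with the gross anatomy the
repair pipeline assumes: an elliptical body with a fat rim, two lungs, bone
sites (spine, sternum, ribs) and a flat treatment couch below the patient.
Phantoms stand in for clinical chest CT so that every stage of the pipeline
— streak simulation, preprocessing, model training and evaluation — can be
exercised end to end with exact, analytically known masks.

All intensities are in Hounsfield units; the background is air (-1000 HU).
Structures are analytic ellipses and rectangles rasterised at pixel-centre
resolution, so tests can recompute every mask exactly.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

HU_MIN = -1024.0
HU_MAX = 3071.0

DEFAULT_HU = {
    "air": -1000.0,
    "lung": -750.0,
    "soft_tissue": 40.0,
    "fat": -90.0,
    "bone": 700.0,
    "couch": 100.0,
}

COUCH_THICKNESS_FRACTION = 10.0 / 512.0  # couch slab is 10 px thick at 512


@dataclass
class Ellipse:
    """Axis-aligned ellipse: centre (row, col) and semi-axes (rows, cols) in px."""

    center: tuple[float, float]
    axes: tuple[float, float]

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        rr, cc = np.ogrid[: shape[0], : shape[1]]
        (r0, c0), (ar, ac) = self.center, self.axes
        return ((rr - r0) / ar) ** 2 + ((cc - c0) / ac) ** 2 <= 1.0


@dataclass
class PhantomSpec:
    """Geometry and intensity description of one thorax phantom.

    All geometry is in pixels on an ``image_size`` x ``image_size`` grid.
    ``jitter`` is the fractional scale of per-structure size/position
    perturbation used by :func:`make_thorax_phantom` and, per patient, by
    :func:`make_cohort`.
    """

    image_size: int = 512
    body: Ellipse = None
    fat_rim_fraction: float = 0.90  # inner soft-tissue ellipse scale; rim is fat
    lungs: list[Ellipse] = None
    bone_sites: list[Ellipse] = None
    couch_row: int = None
    hu_values: dict = field(default_factory=lambda: dict(DEFAULT_HU))
    jitter: float = 0.03
    slice_drift: float = 0.01
    edge_smoothing: bool = False

    def __post_init__(self):
        s = self.image_size / 512.0
        if self.body is None:
            self.body = Ellipse((230 * s, 256 * s), (145 * s, 205 * s))
        if self.lungs is None:
            self.lungs = [
                Ellipse((225 * s, 165 * s), (90 * s, 62 * s)),
                Ellipse((225 * s, 347 * s), (90 * s, 62 * s)),
            ]
        if self.bone_sites is None:
            self.bone_sites = _default_bone_sites(s)
        if self.couch_row is None:
            self.couch_row = int(round(400 * s))

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        n = self.image_size
        if n < 32:
            raise ValueError("image_size must be at least 32 px")
        for name, e in self._named_structures():
            (r0, c0), (ar, ac) = e.center, e.axes
            if ar <= 0 or ac <= 0:
                raise ValueError(f"structure {name!r} has non-positive axes")
            if r0 - ar < 0 or r0 + ar >= n or c0 - ac < 0 or c0 + ac >= n:
                raise ValueError(f"structure {name!r} extends outside the image")
        for lung_i, lung in enumerate(self.lungs):
            if not self._inside_body(lung):
                raise ValueError(f"structure 'lung{lung_i}' is not inside the body")
        body_bottom = self.body.center[0] + self.body.axes[0]
        if self.couch_row <= body_bottom:
            raise ValueError("structure 'couch': couch_row is not below the body")
        if not 0 <= self.couch_row < n:
            raise ValueError("structure 'couch': couch_row outside the image")
        for k, v in self.hu_values.items():
            if not HU_MIN <= v <= HU_MAX:
                raise ValueError(f"hu_values[{k!r}]={v} outside [{HU_MIN}, {HU_MAX}]")

    def _named_structures(self):
        yield "body", self.body
        for i, e in enumerate(self.lungs):
            yield f"lung{i}", e
        for i, e in enumerate(self.bone_sites):
            yield f"bone{i}", e

    def _inside_body(self, e: Ellipse) -> bool:
        (r0, c0), (ar, ac) = self.body.center, self.body.axes
        (r1, c1), (br, bc) = e.center, e.axes
        # conservative: ellipse bounding box corners inside body ellipse
        for dr in (-br, br):
            for dc in (-bc, bc):
                if ((r1 + dr - r0) / ar) ** 2 + ((c1 + dc - c0) / ac) ** 2 > 1.0:
                    return False
        return True


def _default_bone_sites(s: float) -> list[Ellipse]:
    sites = [
        Ellipse((330 * s, 256 * s), (24 * s, 24 * s)),  # vertebral body
        Ellipse((105 * s, 256 * s), (11 * s, 22 * s)),  # sternum
    ]
    # rib cross-sections along the body margin
    for r0, c0 in [(150, 95), (150, 417), (230, 72), (230, 440), (310, 100), (310, 412)]:
        sites.append(Ellipse((r0 * s, c0 * s), (9 * s, 9 * s)))
    return sites


def _jittered(spec: PhantomSpec, rng: np.random.Generator, scale: float) -> PhantomSpec:
    """Return a deep copy of ``spec`` with every structure perturbed.

    Each centre coordinate moves by U(-scale, +scale) x its semi-axis and each
    semi-axis is multiplied by 1 + U(-scale, +scale); one draw per parameter.
    """
    out = copy.deepcopy(spec)
    if scale == 0:
        return out
    for _, e in out._named_structures():
        (r0, c0), (ar, ac) = e.center, e.axes
        e.center = (
            r0 + rng.uniform(-scale, scale) * ar,
            c0 + rng.uniform(-scale, scale) * ac,
        )
        e.axes = (
            ar * (1 + rng.uniform(-scale, scale)),
            ac * (1 + rng.uniform(-scale, scale)),
        )
    return out


def rasterize(spec: PhantomSpec) -> np.ndarray:
    """Paint the phantom exactly as specified (no jitter). Returns HU float32."""
    n = spec.image_size
    hu = spec.hu_values
    img = np.full((n, n), hu["air"], dtype=np.float32)
    body = spec.body.mask((n, n))
    img[body] = hu["fat"]
    inner = Ellipse(
        spec.body.center,
        (spec.body.axes[0] * spec.fat_rim_fraction, spec.body.axes[1] * spec.fat_rim_fraction),
    )
    img[inner.mask((n, n))] = hu["soft_tissue"]
    for lung in spec.lungs:
        img[lung.mask((n, n))] = hu["lung"]
    for bone in spec.bone_sites:
        img[bone.mask((n, n))] = hu["bone"]
    thickness = max(2, int(round(COUCH_THICKNESS_FRACTION * n)))
    img[spec.couch_row : min(n, spec.couch_row + thickness), :] = hu["couch"]
    if spec.edge_smoothing:
        from scipy.ndimage import gaussian_filter

        img = gaussian_filter(img, 0.7).astype(np.float32)
    return img


def make_thorax_phantom(spec: PhantomSpec | None = None, seed: int = 0) -> np.ndarray:
    """Generate one seeded thorax slice.

    Deterministic for a fixed (spec, seed). Jitter (``spec.jitter``) perturbs
    every structure once, so different seeds give different anatomy.
    """
    spec = spec or PhantomSpec()
    spec.validate()
    rng = np.random.default_rng(seed)
    jspec = _jittered(spec, rng, spec.jitter)
    return rasterize(jspec)


class CTVolume:
    """An ordered stack of axial HU slices with a slice thickness in mm."""

    def __init__(self, data: np.ndarray, slice_thickness: float = 3.0, patient_id: str = "anon"):
        data = np.asarray(data, dtype=np.float32)
        if data.ndim != 3:
            raise ValueError("CTVolume data must be (n_slices, H, W)")
        if slice_thickness <= 0:
            raise ValueError("slice_thickness must be > 0")
        self.data = data
        self.slice_thickness = float(slice_thickness)
        self.patient_id = str(patient_id)

    def __len__(self) -> int:
        return self.data.shape[0]

    def __getitem__(self, i: int) -> np.ndarray:
        return self.data[i]

    @property
    def slices(self) -> list[np.ndarray]:
        return list(self.data)

    @property
    def shape(self):
        return self.data.shape


def make_cohort(
    n_patients: int,
    slices_per_patient: int,
    spec: PhantomSpec | None = None,
    seed: int = 0,
    slice_thickness: float = 3.0,
) -> list[CTVolume]:
    """Generate a cohort of phantom patients.

    Per-patient anatomy is one jitter draw from a seeded stream; within a
    patient, structures drift smoothly from slice to slice (sinusoidal
    modulation of amplitude ``spec.slice_drift``), emulating the gradual
    cranio-caudal change of a real chest volume.
    """
    if n_patients < 1 or slices_per_patient < 1:
        raise ValueError("counts must be >= 1")
    spec = spec or PhantomSpec()
    spec.validate()
    streams = np.random.SeedSequence(seed).spawn(n_patients)
    volumes = []
    for p, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        base = _jittered(spec, rng, spec.jitter)
        phases = rng.uniform(0, 2 * np.pi, size=64)
        stack = np.empty((slices_per_patient, spec.image_size, spec.image_size), np.float32)
        for i in range(slices_per_patient):
            t = i / max(1, slices_per_patient - 1)
            sl = copy.deepcopy(base)
            for k, (_, e) in enumerate(sl._named_structures()):
                d = spec.slice_drift * np.sin(2 * np.pi * t + phases[k % 64])
                e.axes = (e.axes[0] * (1 + d), e.axes[1] * (1 + d))
                e.center = (e.center[0] + d * e.axes[0], e.center[1] + d * e.axes[1])
            stack[i] = rasterize(sl)
        volumes.append(CTVolume(stack, slice_thickness, patient_id=f"phantom-{p:03d}"))
    return volumes


def body_mask(img: np.ndarray, threshold: float = -500.0) -> np.ndarray:
    """Binary body segmentation: pixels above ``threshold`` HU, largest component."""
    from scipy import ndimage

    raw = img > threshold
    if not raw.any():
        return raw
    labels, nlab = ndimage.label(raw)
    sizes = ndimage.sum_labels(raw, labels, index=np.arange(1, nlab + 1))
    return labels == (1 + int(np.argmax(sizes)))
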