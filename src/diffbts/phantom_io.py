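"""Synthetic multimodal brain-lesion phantoms and BraTS-style NIfTI I/O.

The phantom generator emulates the structure of BraTS cases at desk scale:
four co-registered intensity volumes (T1, T1ce, T2, FLAIR surrogates) and
three nested binary targets, Whole Tumor > Tumor Core > Enhancing Tumor
(``ET <= TC <= WT`` voxel-wise).  Each case places one or more ellipsoidal
lesions with three concentric regions on a homogeneous tissue background;
every modality renders the regions with its own contrast offsets (the ET
core brightest in the T1ce surrogate, the WT edema rim brightest in the
FLAIR surrogate), additive Gaussian noise is applied, and each modality is
z-score normalized.  Labels are derived exactly from the generating
geometry, so ground truth is analytic.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = [
    "PhantomSpec",
    "VolumeSample",
    "generate_phantom",
    "brats_label_encode",
    "brats_label_decode",
    "read_case",
    "write_case",
]

MODALITIES = ("t1", "t1ce", "t2", "flair")

# Region contrast offsets per modality, relative to unit tissue background,
# for (edema = WT\TC, core = TC\ET, enhancing = ET).
_CONTRASTS = {
    "t1": (-0.25, -0.45, 0.20),
    "t1ce": (-0.10, -0.30, 1.00),
    "t2": (0.60, 0.30, 0.10),
    "flair": (1.00, 0.40, 0.20),
}


@dataclass(frozen=True)
class PhantomSpec:
    """Generation parameters for a batch of synthetic cases.

    Radius ranges are semi-axis bounds in voxels for each nested region;
    the ranges must be disjoint and ordered WT > TC > ET so nesting holds
    for every draw.
    """

    shape: tuple = (32, 32, 32)
    n_cases: int = 10
    lesions: tuple = (1, 2)
    radius_wt: tuple = (6.0, 10.0)
    radius_tc: tuple = (3.5, 5.5)
    radius_et: tuple = (1.5, 3.0)
    noise_std: float = 0.1
    spacing: tuple = (1.0, 1.0, 1.0)
    seed: int = 0

    def __post_init__(self):
        for name, (lo, hi) in (("radius_wt", self.radius_wt),
                               ("radius_tc", self.radius_tc),
                               ("radius_et", self.radius_et)):
            if not (0 < lo <= hi):
                raise ValueError(f"{name} range must satisfy 0 < lo <= hi")
        if not (self.radius_et[1] < self.radius_tc[0] and
                self.radius_tc[1] < self.radius_wt[0]):
            raise ValueError("radius ranges violate the ET < TC < WT nesting order")
        if not (1 <= self.lesions[0] <= self.lesions[1]):
            raise ValueError("invalid lesion count range")
        if self.noise_std < 0:
            raise ValueError("noise_std must be non-negative")


@dataclass
class VolumeSample:
    """One case: 4 modality channels + 3 nested binary label channels."""

    modalities: np.ndarray  # (4, D, H, W) float
    labels: np.ndarray  # (3, D, H, W) uint8, (WT, TC, ET)
    case_id: str = "case"
    spacing: tuple = (1.0, 1.0, 1.0)
    affine: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.modalities.shape[0] != 4 or self.labels.shape[0] != 3:
            raise ValueError("expected 4 modality and 3 label channels")
        if self.modalities.shape[1:] != self.labels.shape[1:]:
            raise ValueError("modalities and labels must share a grid")
        wt, tc, et = (self.labels[i].astype(bool) for i in range(3))
        if np.any(et & ~tc) or np.any(tc & ~wt):
            raise ValueError("label nesting ET <= TC <= WT violated")
        if self.affine is None:
            self.affine = np.diag(list(self.spacing) + [1.0])


def _ellipsoid(shape, center, semiaxes):
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    q = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, semiaxes))
    return q <= 1.0


def generate_phantom(spec: PhantomSpec) -> list[VolumeSample]:
    """Generate ``spec.n_cases`` reproducible synthetic cases."""
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.shape)
    cases = []
    for ci in range(spec.n_cases):
        wt = np.zeros(shape, dtype=bool)
        tc = np.zeros(shape, dtype=bool)
        et = np.zeros(shape, dtype=bool)
        n_lesions = int(rng.integers(spec.lesions[0], spec.lesions[1] + 1))
        for _ in range(n_lesions):
            r_wt = rng.uniform(*spec.radius_wt, size=3)
            r_tc = rng.uniform(*spec.radius_tc, size=3)
            r_et = rng.uniform(*spec.radius_et, size=3)
            center = [rng.uniform(r, s - 1 - r) if s - 1 > 2 * r else (s - 1) / 2
                      for r, s in zip(r_wt, shape)]
            wt |= _ellipsoid(shape, center, r_wt)
            tc |= _ellipsoid(shape, center, r_tc)
            et |= _ellipsoid(shape, center, r_et)
        labels = np.stack([wt, tc, et]).astype(np.uint8)
        edema, core = wt & ~tc, tc & ~et
        mods = np.empty((4,) + shape)
        for m, name in enumerate(MODALITIES):
            c_ed, c_co, c_et = _CONTRASTS[name]
            vol = np.ones(shape)
            vol[edema] += c_ed
            vol[core] += c_co
            vol[et] += c_et
            if spec.noise_std > 0:
                vol = vol + rng.normal(0.0, spec.noise_std, shape)
            vol = (vol - vol.mean()) / max(vol.std(), 1e-8)  # z-score per channel
            mods[m] = vol
        cases.append(
            VolumeSample(
                modalities=mods,
                labels=labels,
                case_id=f"phantom_{spec.seed:05d}_{ci:03d}",
                spacing=spec.spacing,
            )
        )
    return cases


def brats_label_encode(raw: np.ndarray) -> np.ndarray:
    """Integer label volume {0, 1, 2, 4} -> 3 nested binary channels.

    Region composition follows the BraTS standard: WT = {1, 2, 4} (whole
    tumor), TC = {1, 4} (tumor core), ET = {4} (enhancing tumor).
    """
    raw = np.asarray(raw)
    bad = np.setdiff1d(np.unique(raw), [0, 1, 2, 4])
    if bad.size:
        raise ValueError(f"unexpected label values {bad.tolist()}; allowed {{0, 1, 2, 4}}")
    wt = np.isin(raw, (1, 2, 4))
    tc = np.isin(raw, (1, 4))
    et = raw == 4
    return np.stack([wt, tc, et]).astype(np.uint8)


def brats_label_decode(labels: np.ndarray) -> np.ndarray:
    """Inverse of :func:`brats_label_encode` for valid nested channels."""
    wt, tc, et = (np.asarray(labels[i]).astype(bool) for i in range(3))
    raw = np.zeros(wt.shape, dtype=np.int16)
    raw[wt & ~tc] = 2  # edema
    raw[tc & ~et] = 1  # necrotic / non-enhancing core
    raw[et] = 4  # enhancing tumor
    return raw


def write_case(directory: str | os.PathLike, sample: VolumeSample) -> str:
    """Write one case as BraTS-style NIfTI files.

    Layout: ``<dir>/<case_id>/<case_id>_<modality>.nii.gz`` plus
    ``<case_id>_seg.nii.gz`` holding the integer-encoded labels.
    """
    case_dir = os.path.join(os.fspath(directory), sample.case_id)
    os.makedirs(case_dir, exist_ok=True)
    for m, name in enumerate(MODALITIES):
        img = nib.Nifti1Image(np.asarray(sample.modalities[m], dtype=np.float32),
                              sample.affine)
        nib.save(img, os.path.join(case_dir, f"{sample.case_id}_{name}.nii.gz"))
    seg = nib.Nifti1Image(brats_label_decode(sample.labels), sample.affine)
    nib.save(seg, os.path.join(case_dir, f"{sample.case_id}_seg.nii.gz"))
    return case_dir


def read_case(case_dir: str | os.PathLike, require_seg: bool = True) -> VolumeSample:
    """Read one BraTS-style case directory back into a :class:`VolumeSample`."""
    case_dir = os.fspath(case_dir)
    case_id = os.path.basename(os.path.normpath(case_dir))
    mods, affine = [], None
    for name in MODALITIES:
        path = os.path.join(case_dir, f"{case_id}_{name}.nii.gz")
        if not os.path.exists(path):
            raise FileNotFoundError(f"missing modality file: {path}")
        try:
            img = nib.load(path)
            data = np.asarray(img.dataobj, dtype=np.float64)
        except Exception as exc:  # corrupt header or payload
            raise IOError(f"failed to read NIfTI file {path}: {exc}") from exc
        mods.append(data)
        if affine is None:
            affine = img.affine
    seg_path = os.path.join(case_dir, f"{case_id}_seg.nii.gz")
    if os.path.exists(seg_path):
        try:
            raw = np.asarray(nib.load(seg_path).dataobj).astype(np.int16)
        except Exception as exc:
            raise IOError(f"failed to read NIfTI file {seg_path}: {exc}") from exc
        labels = brats_label_encode(raw)
    elif require_seg:
        raise FileNotFoundError(f"missing segmentation file: {seg_path}")
    else:
        labels = np.zeros((3,) + mods[0].shape, dtype=np.uint8)
    spacing = tuple(float(s) for s in nib.affines.voxel_sizes(affine))
    return VolumeSample(
        modalities=np.stack(mods),
        labels=labels,
        case_id=case_id,
        spacing=spacing,
        affine=affine,
    )
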