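"""Synthetic two-class, multi-scanner slice datasets.

The generator emulates the statistical structure the decorrelation method
assumes, at desk scale and with every effect independently switchable:

* an elliptical "brain" phantom with smooth per-subject texture (slices of
  one subject share texture, so subject-grouped splitting matters);
* a *class effect*: the patient class adds a Gaussian intensity blob of
  configurable amplitude at a configurable location;
* a *scanner effect*: each scanner profile applies its own Gaussian
  smoothing, multiplicative gain and additive sensor noise, and stamps its
  own voxel-size metadata into the manifest;
* an optional *temporal axis*: per-frame noise whose level is scanner
  specific (the lever for the temporal-std bias variable).

Two cohort layouts mirror the study designs: a single-scanner cohort with
~9:1 patient:control imbalance, and a two-scanner cohort where patients
appear on one scanner only while controls appear on both (scanner identity
is then a shortcut for the class label).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .dataio import SliceDataset

__all__ = ["ScannerProfile", "CohortSpec", "default_profiles",
           "render_subject", "generate_singlescanner_imbalanced",
           "generate_multiscanner"]

CONTROL, PATIENT = 0, 1


@dataclass
class ScannerProfile:
    name: str
    smoothing_sigma: float      # px
    gain: float                 # multiplicative
    noise_sigma: float          # intensity units (images live in [0,1])
    temporal_noise_sigma: float
    slice_thickness_mm: float
    pixel_spacing_mm: tuple     # (x, y)

    def __post_init__(self):
        if min(self.smoothing_sigma, self.gain, self.noise_sigma,
               self.temporal_noise_sigma, self.slice_thickness_mm,
               *self.pixel_spacing_mm) <= 0:
            raise ValueError("all scanner profile parameters must be positive")


def default_profiles() -> tuple[ScannerProfile, ScannerProfile]:
    """Two profiles with distinct smoothing/gain/noise and voxel metadata.

    Voxel sizes follow the published acquisition parameters of the two
    cohorts the layout emulates (3.2999/3.2941 mm vs 3.0/2.5 mm)."""
    a = ScannerProfile("scannerA", smoothing_sigma=0.8, gain=1.0,
                       noise_sigma=0.08, temporal_noise_sigma=0.05,
                       slice_thickness_mm=3.2999,
                       pixel_spacing_mm=(3.2941, 3.2941))
    b = ScannerProfile("scannerB", smoothing_sigma=1.6, gain=1.12,
                       noise_sigma=0.11, temporal_noise_sigma=0.15,
                       slice_thickness_mm=3.0, pixel_spacing_mm=(2.5, 2.5))
    return a, b


@dataclass
class CohortSpec:
    image_size: tuple = (66, 66)
    slices_per_subject: int = 5
    volumes_per_subject: int = 1        # T; > 1 adds the temporal axis
    class_effect_amplitude: float = 0.22
    class_effect_region: tuple | None = None   # (row, col, sigma_px); None = default
    subject_texture_sigma: float = 0.12        # per-subject smooth field amplitude
    seed: int = 0

    def region(self) -> tuple:
        if self.class_effect_region is not None:
            return self.class_effect_region
        h, w = self.image_size
        return (int(0.40 * h), int(0.60 * w), h / 9.0)


def _phantom_base(spec: CohortSpec, rng: np.random.Generator) -> tuple:
    h, w = spec.image_size
    yy, xx = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    ell = ((yy - cy) / (0.44 * h)) ** 2 + ((xx - cx) / (0.40 * w)) ** 2
    mask = ell <= 1.0
    base = 0.55 * np.exp(-0.5 * ell) * mask
    texture = ndimage.gaussian_filter(rng.standard_normal((h, w)), h / 12.0)
    texture *= spec.subject_texture_sigma / max(texture.std(), 1e-12)
    return mask, base + texture * mask


def render_subject(label: int, profile: ScannerProfile, spec: CohortSpec,
                   rng: np.random.Generator):
    """Render one subject: ``(slices (S,H,W), frames (S,T,H,W) or None)``."""
    h, w = spec.image_size
    mask, anatomy = _phantom_base(spec, rng)
    ry, rx, rs = spec.region()
    if not (0 <= ry < h and 0 <= rx < w) or not mask[int(ry), int(rx)]:
        raise ValueError(f"class-effect region ({ry},{rx}) outside the phantom mask")
    if label == PATIENT and spec.class_effect_amplitude != 0:
        yy, xx = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
        blob = np.exp(-((yy - ry) ** 2 + (xx - rx) ** 2) / (2.0 * rs ** 2))
        anatomy = anatomy + spec.class_effect_amplitude * blob * mask
    slices = np.empty((spec.slices_per_subject, h, w))
    frames = (np.empty((spec.slices_per_subject, spec.volumes_per_subject, h, w))
              if spec.volumes_per_subject > 1 else None)
    for s in range(spec.slices_per_subject):
        # mild slice-to-slice anatomical variation
        local = anatomy * (1.0 + 0.03 * rng.standard_normal())
        clean = ndimage.gaussian_filter(local, profile.smoothing_sigma) * profile.gain
        noisy = clean + rng.normal(0.0, profile.noise_sigma, size=(h, w))
        slices[s] = np.clip(noisy, 0.0, 1.0)
        if frames is not None:
            tnoise = rng.normal(0.0, profile.temporal_noise_sigma,
                                size=(spec.volumes_per_subject, h, w))
            frames[s] = np.clip(noisy[None] + tnoise, 0.0, 1.0)
    return slices, frames


def _assemble(groups, spec: CohortSpec) -> SliceDataset:
    """``groups``: list of (subject_id, label, profile).  Renders everything."""
    rng = np.random.default_rng(spec.seed)
    images, frame_list, rows = [], [], []
    for subject_id, label, profile in groups:
        slices, frames = render_subject(label, profile, spec, rng)
        for s in range(spec.slices_per_subject):
            images.append(slices[s])
            if frames is not None:
                frame_list.append(frames[s])
            rows.append(dict(
                subject_id=subject_id, scanner_id=profile.name, slice_idx=s,
                volume_idx=0, slice_thickness_mm=profile.slice_thickness_mm,
                pixel_spacing_x_mm=profile.pixel_spacing_mm[0],
                pixel_spacing_y_mm=profile.pixel_spacing_mm[1], path="",
                **{"class": label}))
    manifest = pd.DataFrame(rows)[["subject_id", "class", "scanner_id",
                                   "slice_idx", "volume_idx",
                                   "slice_thickness_mm", "pixel_spacing_x_mm",
                                   "pixel_spacing_y_mm", "path"]]
    return SliceDataset(np.stack(images), manifest,
                        np.stack(frame_list) if frame_list else None)


def generate_singlescanner_imbalanced(spec: CohortSpec,
                                      n_majority: int = 90,
                                      n_minority: int = 10,
                                      profile: ScannerProfile | None = None
                                      ) -> SliceDataset:
    """Single-scanner cohort, patients the ~9:1 majority class."""
    if n_majority < n_minority:
        raise ValueError("majority count must be >= minority count")
    profile = profile or default_profiles()[0]
    groups = ([(f"pd{i:03d}", PATIENT, profile) for i in range(n_majority)]
              + [(f"hc{i:03d}", CONTROL, profile) for i in range(n_minority)])
    return _assemble(groups, spec)


def generate_multiscanner(spec: CohortSpec,
                          n_patient_a: int = 40,
                          n_control_a: int = 4,
                          n_control_b: int = 36,
                          profiles: tuple | None = None,
                          n_patient_b: int = 0,
                          allow_patients_on_b: bool = False) -> SliceDataset:
    """Two-scanner cohort: patients on scanner A only, controls on both.

    The default 1:9 control split between scanners mirrors the imbalance of
    the control groups in the emulated cohorts (19 vs 215 subjects).
    Patients on scanner B are refused unless explicitly overridden — the
    confounded layout is the design under study.
    """
    if n_patient_b > 0 and not allow_patients_on_b:
        raise ValueError("patients on both scanners break the confounded "
                         "design; pass allow_patients_on_b=True to override")
    pa, pb = profiles or default_profiles()
    groups = ([(f"pdA{i:03d}", PATIENT, pa) for i in range(n_patient_a)]
              + [(f"hcA{i:03d}", CONTROL, pa) for i in range(n_control_a)]
              + [(f"hcB{i:03d}", CONTROL, pb) for i in range(n_control_b)]
              + [(f"pdB{i:03d}", PATIENT, pb) for i in range(n_patient_b)])
    return _assemble(groups, spec)
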