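"""Synthetic labeled cohorts of two-channel 3D lesion patches.

The generator stands in for a clinical mpMRI cohort: each lesion is a
Gaussian-random-field texture phantom whose heterogeneity depends on class.
csPCa-like lesions use a small blur sigma (fine-grained texture) plus a
hypointense spherical core in the ADC-like channel; benign-like lesions use
a large sigma (smooth texture). Radiologist-score metadata (PI-RADS 3-5) is
sampled from a class-conditional confusion table so that the PI-RADS >= 4
rule is an informative but imperfect baseline, and zone / focality / PSA
metadata follow the composition of a prostatectomy cohort (roughly 65%
csPCa lesions, ~1.16 lesions per patient, PZ-dominant).

Everything is driven by one seed: identical config + seed reproduces the
cohort bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .preprocess import VolumetricPatch

__all__ = ["PhantomConfig", "LesionRecord", "generate_cohort", "split_cohort",
           "RECORD_COLUMNS"]

RECORD_COLUMNS = ["lesion_id", "patient_id", "label", "pirads", "zone",
                  "focality", "is_index", "psa", "split"]

ZONES = ("PZ", "TZ", "AFS")
FOCALITIES = ("solitary", "multifocal")

# P(PI-RADS = 3, 4, 5 | class); row 0 = non-csPCa, row 1 = csPCa.
# P(>=4 | csPCa) = 0.83 and P(>=4 | non-csPCa) = 0.53, the sensitivity /
# 1-specificity pattern of an expert PI-RADS >= 4 rule.
_DEFAULT_PIRADS_CONFUSION = ((0.47, 0.35, 0.18),
                             (0.17, 0.43, 0.40))


@dataclass
class PhantomConfig:
    """Generator settings; defaults emulate the reference cohort composition."""

    n_patients: int = 402
    lesions_per_patient: tuple[int, int] = (1, 2)
    extra_lesion_prob: float = 0.16     # P(one extra lesion) within the range
    patch_shape_range: tuple[int, int] = (8, 24)
    class_prevalence: float = 0.65      # fraction csPCa (303/466)
    class_counts: tuple[int, int] | None = None   # exact (n_csPCa, n_non)
    smoothness_pos: float = 0.7         # blur sigma (voxels) for csPCa-like
    smoothness_neg: float = 2.5         # blur sigma for non-csPCa-like
    core_contrast: float = 0.4          # relative ADC drop in csPCa cores
    core_radius_frac: float = 0.3       # core radius / min patch dimension
    noise_sd: float = 5.0               # additive noise SD, 0-255 intensity units
    pirads_confusion: tuple = _DEFAULT_PIRADS_CONFUSION
    zone_probs: tuple[float, float, float] = (0.78, 0.21, 0.01)
    focality_probs: tuple[float, float] = (0.41, 0.59)
    psa_log_mean: float = 2.08          # lognormal PSA, median ~8 ng/mL
    psa_log_sd: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        lo, hi = self.lesions_per_patient
        if not (1 <= lo <= hi):
            raise ValueError("lesions_per_patient must satisfy 1 <= lo <= hi")
        if not 0 <= self.extra_lesion_prob <= 1:
            raise ValueError("extra_lesion_prob must be a probability")
        if self.patch_shape_range[0] < 4:
            raise ValueError("patch_shape_range minimum must be >= 4")
        if self.class_counts is None and not 0 < self.class_prevalence < 1:
            raise ValueError("class_prevalence must lie in (0, 1)")
        if not self.smoothness_pos < self.smoothness_neg:
            raise ValueError("smoothness_pos must be < smoothness_neg "
                             "(csPCa-like textures are more heterogeneous)")
        for name, probs in (("pirads_confusion", self.pirads_confusion),
                            ("zone_probs", (self.zone_probs,)),
                            ("focality_probs", (self.focality_probs,))):
            for row in probs:
                row = np.asarray(row, dtype=float)
                if (row < 0).any() or (row > 1).any() or abs(row.sum() - 1.0) > 1e-9:
                    raise ValueError(f"{name} rows must be probabilities summing to 1")


@dataclass
class LesionRecord:
    """Label and metadata for one synthetic lesion."""

    lesion_id: str
    patient_id: str
    label: int
    pirads: int
    zone: str
    focality: str
    is_index: bool
    psa: float
    split: str = ""


def _texture_field(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    """Gaussian random field min-max stretched to [0, 255]."""
    noise = rng.standard_normal(shape)
    if not np.isfinite(sigma):
        return np.zeros(shape)   # infinite smoothing: uniform field
    f = gaussian_filter(noise, sigma=sigma, mode="reflect")
    lo, hi = f.min(), f.max()
    if hi == lo:
        return np.zeros(shape)
    return (f - lo) * (255.0 / (hi - lo))


def _core_mask(shape, radius_frac: float) -> np.ndarray:
    center = [(s - 1) / 2.0 for s in shape]
    radius = radius_frac * min(shape)
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    dist2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return dist2 <= radius ** 2


def generate_cohort(config: PhantomConfig) -> tuple[list[VolumetricPatch], pd.DataFrame]:
    """Generate one patch and one record per lesion.

    Returns ``(patches, records)`` with records as a DataFrame in
    :data:`RECORD_COLUMNS` order (split unassigned). Labels follow
    ``class_counts`` exactly when given, otherwise i.i.d. Bernoulli with
    ``class_prevalence``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    lo, hi = config.lesions_per_patient
    n_lesions_per_patient = [
        int(lo + (rng.binomial(hi - lo, config.extra_lesion_prob) if hi > lo else 0))
        for _ in range(config.n_patients)
    ]
    n_total = int(sum(n_lesions_per_patient))

    if config.class_counts is not None:
        n_pos, n_neg = config.class_counts
        if n_pos + n_neg != n_total:
            raise ValueError(
                f"class_counts sum to {n_pos + n_neg} but the cohort has "
                f"{n_total} lesions; fix lesions_per_patient or n_patients")
        labels = np.array([1] * n_pos + [0] * n_neg)
        rng.shuffle(labels)
    else:
        labels = (rng.random(n_total) < config.class_prevalence).astype(int)

    confusion = np.asarray(config.pirads_confusion, dtype=float)
    patches: list[VolumetricPatch] = []
    records: list[LesionRecord] = []
    li = 0
    for pi in range(config.n_patients):
        patient_id = f"P{pi:04d}"
        psa = float(np.exp(rng.normal(config.psa_log_mean, config.psa_log_sd)))
        patient_rows = []
        for _ in range(n_lesions_per_patient[pi]):
            lesion_id = f"L{li:05d}"
            label = int(labels[li])
            shape = tuple(rng.integers(config.patch_shape_range[0],
                                       config.patch_shape_range[1] + 1, size=3))
            sigma = config.smoothness_pos if label else config.smoothness_neg
            t2w = _texture_field(rng, shape, sigma)
            adc = _texture_field(rng, shape, sigma)
            if label:
                adc = adc * np.where(_core_mask(shape, config.core_radius_frac),
                                     1.0 - config.core_contrast, 1.0)
            if config.noise_sd > 0:
                t2w = t2w + rng.normal(0, config.noise_sd, shape)
                adc = adc + rng.normal(0, config.noise_sd, shape)
            pirads = int(3 + rng.choice(3, p=confusion[label]))
            zone = ZONES[rng.choice(3, p=np.asarray(config.zone_probs, dtype=float))]
            focality = FOCALITIES[rng.choice(2, p=np.asarray(config.focality_probs,
                                                             dtype=float))]
            patches.append(VolumetricPatch(lesion_id, t2w, adc))
            patient_rows.append(LesionRecord(lesion_id, patient_id, label, pirads,
                                             zone, focality, False, psa))
            li += 1
        # index lesion: the first csPCa lesion of the patient, else the first
        idx = next((k for k, r in enumerate(patient_rows) if r.label == 1), 0)
        patient_rows[idx].is_index = True
        records.extend(patient_rows)

    frame = pd.DataFrame([vars(r) for r in records], columns=RECORD_COLUMNS)
    return patches, frame


def _largest_remainder(n: int, fractions) -> list[int]:
    raw = [n * f for f in fractions]
    counts = [int(np.floor(r)) for r in raw]
    rem = n - sum(counts)
    order = sorted(range(len(raw)), key=lambda i: (-(raw[i] - counts[i]), i))
    for i in order[:rem]:
        counts[i] += 1
    return counts


def split_cohort(records: pd.DataFrame,
                 fractions: tuple[float, float, float] = (0.60, 0.10, 0.30),
                 seed: int = 0) -> pd.DataFrame:
    """Assign train/validation/test splits at the patient level.

    Patients are shuffled with the given seed and partitioned by
    largest-remainder rounding of the nominal fractions, so every lesion of
    a patient shares a split and achieved patient counts are within one of
    nominal. Returns a copy of ``records`` with the split column filled.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    patients = records["patient_id"].unique()
    if len(patients) < len(fractions):
        raise ValueError("fewer patients than splits")
    rng = np.random.default_rng(seed)
    shuffled = np.array(sorted(patients))
    rng.shuffle(shuffled)
    counts = _largest_remainder(len(shuffled), fractions)
    assignment = {}
    start = 0
    for name, c in zip(("train", "validation", "test"), counts):
        for p in shuffled[start:start + c]:
            assignment[p] = name
        start += c
    out = records.copy()
    out["split"] = out["patient_id"].map(assignment)
    return out
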