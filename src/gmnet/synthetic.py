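"""Synthetic cohort generation.

Produces three-group cohorts (HC / DM / DKD) of per-ROI gray-matter voxel
samples plus a clinical covariate table, with a controllable group effect
on a designated set of ROIs. Voxel values are log-normal per ROI (positive
support, right skew, as for modulated GM volumes); the group effect
perturbs the location/scale of the affected ROIs so that distributional
similarity involving those ROIs degrades progressively HC -> DM -> DKD,
exercising the full KDE -> KLD -> graph chain rather than the statistics
alone. A per-subject latent severity factor couples the realized network
effect to kidney markers (eGFR negatively, Scr positively), making
degree <-> eGFR correlations recoverable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .exceptions import ConfigError
from .samples import ROISampleSet

DEFAULT_GROUP_SIZES = {"HC": 70, "DM": 65, "DKD": 50}
DEFAULT_AFFECTED_ROIS = (3, 6, 46, 47, 66, 67)
DEFAULT_EFFECT_GRADES = {"HC": 0.0, "DM": 0.5, "DKD": 1.0}

# Per-variable (mean, sd) per group. HC kidney markers and TIV are not
# tabulated in the source population description; plausible values are used.
DEFAULT_CLINICAL_PARAMS = {
    "age": {"HC": (51.36, 11.05), "DM": (53.88, 8.80), "DKD": (52.82, 8.00)},
    "education": {"HC": (10.71, 5.56), "DM": (9.89, 3.35), "DKD": (10.38, 3.72)},
    "TIV": {"HC": (1480.0, 130.0), "DM": (1480.0, 130.0), "DKD": (1480.0, 130.0)},
    "eGFR": {"HC": (112.0, 14.0), "DM": (107.84, 11.27), "DKD": (56.14, 13.54)},
    "Scr": {"HC": (58.0, 12.0), "DM": (61.31, 14.09), "DKD": (216.54, 31.52)},
    "MoCA": {"HC": (27.06, 1.35), "DM": (25.20, 3.58), "DKD": (23.22, 3.84)},
    "NCT_A": {"HC": (41.17, 17.01), "DM": (46.40, 16.02), "DKD": (61.12, 27.69)},
}
DEFAULT_MALE_FREQ = {"HC": 48 / 70, "DM": 39 / 65, "DKD": 31 / 50}
# Loading of each clinical variable on the latent severity factor. Marginal
# mean/SD are preserved: x = m + sd * (rho * L + sqrt(1 - rho^2) * eps).
DEFAULT_SEVERITY_LOADINGS = {"eGFR": -0.6, "Scr": 0.6, "NCT_A": 0.45, "MoCA": -0.35}
CLINICAL_BOUNDS = {
    "age": (18.0, 90.0), "education": (0.0, 30.0), "TIV": (900.0, 2300.0),
    "eGFR": (5.0, 180.0), "Scr": (20.0, 1200.0), "MoCA": (0.0, 30.0),
    "NCT_A": (10.0, 300.0),
}

_GROUP_ORDER = ("HC", "DM", "DKD")


@dataclass
class CohortConfig:
    """All knobs of the synthetic cohort generator."""

    group_sizes: dict = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    n_rois: int = 90
    voxels_per_roi: tuple = (200, 2000)
    affected_rois: tuple = DEFAULT_AFFECTED_ROIS
    effect_grades: dict = field(default_factory=lambda: dict(DEFAULT_EFFECT_GRADES))
    clinical_params: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_CLINICAL_PARAMS.items()}
    )
    male_freq: dict = field(default_factory=lambda: dict(DEFAULT_MALE_FREQ))
    severity_loadings: dict = field(
        default_factory=lambda: dict(DEFAULT_SEVERITY_LOADINGS)
    )
    seed: int = 0
    min_voxels: int = 10
    atlas_name: str = "synthetic-aal90"
    severity_noise: float = 0.15  # lognormal sd of subject severity multiplier
    mu_shift_scale: float = 0.8   # base log-mean shift (in units of sigma_r)
    sigma_inflation: float = 0.6  # relative sigma inflation at severity 1

    def validate(self) -> None:
        for g, n in self.group_sizes.items():
            if n < 2:
                raise ConfigError(f"group {g!r} size must be >= 2 (got {n})")
        grades = [self.effect_grades.get(g, 0.0) for g in _GROUP_ORDER
                  if g in self.group_sizes]
        if any(e < 0 for e in self.effect_grades.values()):
            raise ConfigError("effect grades must be non-negative")
        if any(a > b for a, b in zip(grades, grades[1:])):
            raise ConfigError(
                "effect grades must be monotone non-decreasing HC <= DM <= DKD"
            )
        if any(not 0 <= r < self.n_rois for r in self.affected_rois):
            raise ConfigError("affected_rois must lie in [0, n_rois)")
        lo, hi = self.voxels_per_roi
        if not (0 < lo <= hi):
            raise ConfigError("invalid voxels_per_roi range")
        if lo < self.min_voxels:
            raise ConfigError("voxels_per_roi minimum below min_voxels")

    def to_yaml(self, path) -> None:
        data = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in self.__dict__.items()
        }
        data["clinical_params"] = {
            var: {g: list(ms) for g, ms in per.items()}
            for var, per in self.clinical_params.items()
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh)

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        for key in ("voxels_per_roi", "affected_rois"):
            if key in data:
                data[key] = tuple(data[key])
        if "clinical_params" in data:
            data["clinical_params"] = {
                var: {g: tuple(ms) for g, ms in per.items()}
                for var, per in data["clinical_params"].items()
            }
        return cls(**data)


_N_COMPONENTS = 3
_BASE_LOG_MEAN = np.log(0.45)


def _roi_base_params(rng, n_rois):
    """ROI-specific mixture parameters shared across subjects.

    Each ROI's voxel distribution is a 3-component log-normal mixture:
    multi-dimensional regional variation keeps the strongest-edge graphs
    from collapsing into cliques of near-identical ROIs, and truncating the
    location draws avoids outlier ROIs dissimilar to the whole brain.
    """
    mu = np.clip(
        rng.normal(_BASE_LOG_MEAN, 0.12, size=(n_rois, _N_COMPONENTS)),
        _BASE_LOG_MEAN - 0.18, _BASE_LOG_MEAN + 0.18,
    )
    sigma = rng.uniform(0.20, 0.28, size=(n_rois, _N_COMPONENTS))
    weights = rng.dirichlet([4.0] * _N_COMPONENTS, size=n_rois)
    return mu, sigma, weights


def _affected_shifts(affected_rois):
    """Deterministic per-ROI perturbation directions/magnitudes.

    Alternating signs with growing magnitude make affected ROIs diverge
    both from unaffected ROIs and from each other.
    """
    shifts = {}
    for idx, roi in enumerate(sorted(affected_rois)):
        sign = 1.0 if idx % 2 == 0 else -1.0
        shifts[roi] = sign * (1.0 + 0.25 * idx)
    return shifts


def generate_cohort(config: CohortConfig):
    """Generate a full synthetic cohort.

    Returns
    -------
    cohort : DataFrame
        One row per subject: subject_id, group, gender and the configured
        clinical variables, plus the (latent) severity column for auditing.
    subjects : list of ROISampleSet
        Per-subject per-ROI voxel-value vectors, aligned with ``cohort``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_rois = config.n_rois

    base_mu, base_sigma, base_weights = _roi_base_params(rng, n_rois)
    lo, hi = config.voxels_per_roi
    voxel_counts = rng.integers(lo, hi + 1, size=n_rois)
    shifts = _affected_shifts(config.affected_rois)

    rows = []
    subjects = []
    counter = 0
    for group in [g for g in _GROUP_ORDER if g in config.group_sizes]:
        grade = float(config.effect_grades.get(group, 0.0))
        for _ in range(config.group_sizes[group]):
            counter += 1
            sid = f"sub-{counter:04d}"
            latent = rng.normal()  # shared severity driver
            severity = grade * np.exp(config.severity_noise * latent
                                      - config.severity_noise**2 / 2)

            samples = []
            for r in range(n_rois):
                mu = base_mu[r] + rng.normal(0.0, 0.02)
                sigma = base_sigma[r] * np.exp(rng.normal(0.0, 0.03))
                if r in shifts:
                    mu = mu + (severity * config.mu_shift_scale * shifts[r]
                               * sigma.mean())
                    sigma = sigma * (1.0 + config.sigma_inflation * severity)
                comp = rng.choice(_N_COMPONENTS, size=voxel_counts[r],
                                  p=base_weights[r])
                samples.append(rng.lognormal(mu[comp], sigma[comp]))

            row = {"subject_id": sid, "group": group, "severity": severity}
            row["gender"] = int(rng.random() < config.male_freq.get(group, 0.5))
            for var, per_group in config.clinical_params.items():
                m, sd = per_group[group]
                rho = float(config.severity_loadings.get(var, 0.0))
                eps = rng.normal()
                value = m + sd * (rho * latent + np.sqrt(1 - rho**2) * eps)
                if var in CLINICAL_BOUNDS:
                    value = float(np.clip(value, *CLINICAL_BOUNDS[var]))
                row[var] = value
            rows.append(row)
            subjects.append(ROISampleSet(subject_id=sid,
                                         atlas_name=config.atlas_name,
                                         samples=samples))

    cohort = pd.DataFrame(rows)
    lead = ["subject_id", "group", "age", "gender", "education", "TIV"]
    rest = [c for c in cohort.columns if c not in lead]
    return cohort[[c for c in lead if c in cohort.columns] + rest], subjects


def generate_toy_volumes(n_rois: int, shape, seed: int, out_dir=None,
                         min_voxels: int = 10):
    """Write a spatially aligned toy GM map + integer label atlas pair.

    Labels 1..n_rois tile the volume in raster order; the GM map is positive
    inside labeled voxels and zero outside. Returns the two file paths when
    ``out_dir`` is given, else the in-memory arrays.
    """
    shape = tuple(int(v) for v in shape)
    if any(v < 8 for v in shape):
        raise ValueError("shape must be at least (8, 8, 8)")
    n_vox = int(np.prod(shape))
    if n_rois * min_voxels > n_vox:
        raise ValueError(
            f"{n_rois} ROIs x {min_voxels} voxels do not fit in {shape}"
        )
    rng = np.random.default_rng(seed)

    # Contiguous equal-sized blocks in raster order; remainder stays background.
    per_roi = n_vox // (n_rois + 1)  # reserve a background share
    per_roi = max(per_roi, min_voxels)
    labels = np.zeros(n_vox, dtype=np.int16)
    for r in range(n_rois):
        labels[r * per_roi:(r + 1) * per_roi] = r + 1
    labels = labels.reshape(shape)

    gm = np.zeros(n_vox)
    inside = labels.ravel() > 0
    gm[inside] = rng.lognormal(np.log(0.5), 0.25, size=inside.sum())
    gm = gm.reshape(shape)

    if out_dir is None:
        return gm, labels

    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    affine = np.eye(4)
    gm_path = out_dir / "toy_gm.nii"
    atlas_path = out_dir / "toy_atlas.nii"
    nib.save(nib.Nifti1Image(gm.astype(np.float32), affine), str(gm_path))
    nib.save(nib.Nifti1Image(labels, affine), str(atlas_path))
    return gm_path, atlas_path
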