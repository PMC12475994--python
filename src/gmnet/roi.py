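"""ROI voxel-value extraction from a GM volume map and a label atlas.

No resampling is performed: the GM map and atlas must already live on the
same voxel grid with matching affines. Misaligned inputs are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import yaml

from .exceptions import AlignmentError, DegenerateROIError
from .samples import DEFAULT_MIN_VOXELS, ROISampleSet

AFFINE_TOL = 1e-4


@dataclass
class AtlasSpec:
    """Parcellation metadata: which integer labels define the network nodes.

    ROI order in every downstream artifact follows ``label_values``; it is a
    pure function of this spec, never of data content.
    """

    name: str
    n_rois: int
    label_values: list = None
    roi_names: list = None

    def __post_init__(self):
        if self.label_values is None:
            self.label_values = list(range(1, self.n_rois + 1))
        self.label_values = sorted(int(v) for v in self.label_values)
        if len(set(self.label_values)) != len(self.label_values):
            raise ValueError("label_values must be distinct")
        if len(self.label_values) != self.n_rois:
            raise ValueError(
                f"label_values has {len(self.label_values)} entries, "
                f"expected n_rois={self.n_rois}"
            )
        if any(v <= 0 for v in self.label_values):
            raise ValueError("label_values must be positive integers")
        if self.roi_names is not None and len(self.roi_names) != self.n_rois:
            raise ValueError("roi_names length must equal n_rois")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {"name": self.name, "n_rois": self.n_rois,
                 "label_values": self.label_values, "roi_names": self.roi_names},
                fh,
            )

    @classmethod
    def from_yaml(cls, path) -> "AtlasSpec":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def load_nifti(path):
    """Load a 3-D NIfTI volume.

    Returns
    -------
    data : ndarray
        The voxel array. Integer label volumes (no scaling, or identity
        scaling) are returned with their on-disk integer dtype so label
        values are preserved exactly.
    affine : ndarray, shape (4, 4)
    header : nibabel header
    """
    img = nib.load(str(path))
    if img.ndim != 3:
        raise ValueError(f"expected a 3-D volume, got {img.ndim}-D: {path}")
    hdr = img.header
    slope, inter = hdr.get_slope_inter()
    on_disk = img.get_data_dtype()
    if np.issubdtype(on_disk, np.integer) and (slope in (None, 1.0)) and (
        inter in (None, 0.0)
    ):
        data = np.asanyarray(img.dataobj).astype(on_disk)
    else:
        data = img.get_fdata()
    return data, img.affine, hdr


def extract_roi_samples(
    gm_map: np.ndarray,
    atlas: np.ndarray,
    atlas_spec: AtlasSpec,
    gm_floor: float = 0.0,
    min_voxels: int = DEFAULT_MIN_VOXELS,
    subject_id: str = "subject",
    gm_affine: np.ndarray = None,
    atlas_affine: np.ndarray = None,
) -> ROISampleSet:
    """Collect, per atlas label, the GM values at voxels carrying that label.

    Voxels with GM value <= ``gm_floor`` are excluded (strict inequality;
    zeros are outside-brain padding in modulated GM maps). Any ROI left with
    fewer than ``min_voxels`` voxels aborts with :class:`DegenerateROIError`
    naming the ROI.
    """
    gm_map = np.asarray(gm_map)
    atlas = np.asarray(atlas)
    if gm_map.shape != atlas.shape:
        raise AlignmentError(
            f"GM map shape {gm_map.shape} != atlas shape {atlas.shape}"
        )
    if gm_affine is not None and atlas_affine is not None:
        if not np.allclose(gm_affine, atlas_affine, atol=AFFINE_TOL, rtol=0):
            raise AlignmentError("GM map and atlas affines differ beyond tolerance")

    samples = []
    for label in atlas_spec.label_values:
        values = gm_map[(atlas == label) & (gm_map > gm_floor)]
        if len(values) < min_voxels:
            raise DegenerateROIError(label, len(values), min_voxels)
        samples.append(values.astype(float))

    out = ROISampleSet(
        subject_id=subject_id,
        atlas_name=atlas_spec.name,
        samples=samples,
        roi_labels=list(atlas_spec.label_values),
    )
    out.validate(min_voxels=min_voxels)
    return out


def extract_from_files(gm_path, atlas_path, atlas_spec: AtlasSpec, **kwargs):
    """File-based wrapper around :func:`extract_roi_samples`."""
    gm, gm_aff, _ = load_nifti(gm_path)
    labels, at_aff, _ = load_nifti(atlas_path)
    return extract_roi_samples(
        gm, labels, atlas_spec, gm_affine=gm_aff, atlas_affine=at_aff, **kwargs
    )
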