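"""Per-subject, per-ROI vectors of gray-matter voxel values."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DegenerateROIError

DEFAULT_MIN_VOXELS = 10


@dataclass
class ROISampleSet:
    """One subject's per-ROI vectors of GM voxel values.

    Parameters
    ----------
    subject_id : str
        Unique subject identifier.
    atlas_name : str
        Name of the parcellation that defines ROI order.
    samples : list of ndarray
        One 1-D float array per ROI, in atlas label order. Values are
        modulated GM volumes (arbitrary positive units).
    roi_labels : list, optional
        Atlas label value for each ROI; defaults to ``1..n_rois``.
    voxel_counts : ndarray
        Length of each ROI vector (derived).
    """

    subject_id: str
    atlas_name: str
    samples: list
    roi_labels: list = None
    voxel_counts: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        self.samples = [np.asarray(s, dtype=float).ravel() for s in self.samples]
        if self.roi_labels is None:
            self.roi_labels = list(range(1, len(self.samples) + 1))
        if len(self.roi_labels) != len(self.samples):
            raise ValueError("roi_labels length must match number of ROIs")
        self.voxel_counts = np.array([len(s) for s in self.samples])

    @property
    def n_rois(self) -> int:
        return len(self.samples)

    def validate(self, min_voxels: int = DEFAULT_MIN_VOXELS) -> None:
        """Check non-emptiness, finiteness and non-negativity of every ROI."""
        for label, vec in zip(self.roi_labels, self.samples):
            if len(vec) < min_voxels:
                raise DegenerateROIError(label, len(vec), min_voxels)
            if not np.all(np.isfinite(vec)):
                raise ValueError(f"ROI {label!r} contains non-finite values")
            if np.any(vec < 0):
                raise ValueError(f"ROI {label!r} contains negative values")

    def to_tsv(self, path) -> None:
        """Write as two-column TSV (roi_label, value), one row per voxel."""
        frames = [
            pd.DataFrame({"roi_label": label, "value": vec})
            for label, vec in zip(self.roi_labels, self.samples)
        ]
        pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, subject_id: str, atlas_name: str = "unknown",
                 roi_labels=None) -> "ROISampleSet":
        df = pd.read_csv(path, sep="\t")
        if roi_labels is None:
            roi_labels = sorted(df["roi_label"].unique())
        samples = [
            df.loc[df["roi_label"] == label, "value"].to_numpy(dtype=float)
            for label in roi_labels
        ]
        return cls(subject_id=subject_id, atlas_name=atlas_name,
                   samples=samples, roi_labels=list(roi_labels))
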