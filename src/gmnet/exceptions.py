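"""Exception hierarchy for gmnet."""


class GmnetError(Exception):
    """Base class for all gmnet errors."""


class AlignmentError(GmnetError):
    """GM map and atlas volumes are not on the same voxel grid."""


class DegenerateROIError(GmnetError):
    """An ROI has too few usable voxels to support density estimation."""

    def __init__(self, roi_label, n_voxels, min_voxels):
        self.roi_label = roi_label
        self.n_voxels = n_voxels
        self.min_voxels = min_voxels
        super().__init__(
            f"ROI {roi_label!r} has {n_voxels} usable voxels "
            f"(minimum required: {min_voxels})"
        )


class DegenerateDistributionError(GmnetError):
    """Sample has zero variance; no density can be estimated."""


class GridMismatchError(GmnetError):
    """Two density estimates do not share an evaluation grid."""


class EmptyGraphError(GmnetError):
    """Sparsity threshold retains zero edges."""


class RewiringError(GmnetError):
    """Degree-preserving rewiring failed to reach the requested swap count."""


class DisconnectedGraphError(GmnetError):
    """Graph too fragmented for the requested computation."""


class ConfigError(GmnetError):
    """Invalid configuration."""


class RankDeficiencyError(GmnetError):
    """Design matrix is rank deficient."""


class StageError(GmnetError):
    """A pipeline stage failed."""

    def __init__(self, stage, message, subject_id=None):
        self.stage = stage
        self.subject_id = subject_id
        detail = f" (subject {subject_id})" if subject_id else ""
        super().__init__(f"stage {stage!r}{detail}: {message}")
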