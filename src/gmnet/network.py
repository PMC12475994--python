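"""Single-subject morphological similarity networks.

Each ROI's voxel-value distribution is summarized by a Gaussian kernel
density estimate; every unordered ROI pair is compared with the symmetrized
Kullback-Leibler divergence on a shared evaluation grid, and the divergence
is mapped to an edge weight in (0, 1] via exp(-d).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import (
    DegenerateDistributionError,
    DegenerateROIError,
    GridMismatchError,
)
from .samples import ROISampleSet

DEFAULT_GRID_SIZE = 128
KLD_EPS = 1e-12
GRID_MARGIN_BANDWIDTHS = 3.0
_FINE_GRID_SIZE = 2048


@dataclass
class DensityEstimate:
    """A probability density evaluated on a uniform grid."""

    grid: np.ndarray
    density: np.ndarray
    bandwidth: float

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if self.grid.shape != self.density.shape:
            raise ValueError("grid and density must have equal length")
        if self.bandwidth <= 0:
            raise ValueError("bandwidth must be positive")
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        if np.any(self.density < 0):
            raise ValueError("density must be non-negative")

    @property
    def integral(self) -> float:
        """Trapezoidal integral of the density over the grid."""
        return float(np.trapezoid(self.density, self.grid))


def silverman_bandwidth(values: np.ndarray) -> float:
    """Robust rule-of-thumb bandwidth: 0.9 * min(sd, IQR/1.34) * n^(-1/5)."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    sd = float(np.std(values, ddof=1))
    q75, q25 = np.percentile(values, [75, 25])
    iqr = float(q75 - q25)
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    if spread <= 0:
        raise DegenerateDistributionError("sample has zero spread")
    return 0.9 * spread * n ** (-0.2)


def _gaussian_kde_eval(values: np.ndarray, grid: np.ndarray, h: float) -> np.ndarray:
    z = (grid[None, :] - values[:, None]) / h
    return np.exp(-0.5 * z * z).sum(axis=0) / (len(values) * h * np.sqrt(2 * np.pi))


def estimate_pdf(
    values,
    grid=None,
    bandwidth_rule: str = "silverman",
    grid_size: int = DEFAULT_GRID_SIZE,
) -> DensityEstimate:
    """Gaussian-kernel density estimate of a sample.

    Parameters
    ----------
    values : array-like
        Sample of GM voxel values; must be finite with positive variance.
    grid : array-like, optional
        Evaluation points. When omitted, a uniform grid of ``grid_size``
        points spanning the data range extended by 3 bandwidths is used.
    bandwidth_rule : {"silverman"}
        Bandwidth selector. Silverman's robust rule is
        ``h = 0.9 * min(sd, IQR/1.34) * n**(-1/5)``.
    """
    values = np.asarray(values, dtype=float).ravel()
    if not np.all(np.isfinite(values)):
        raise ValueError("values must be finite")
    if np.var(values) == 0:
        raise DegenerateDistributionError("all sample values are identical")
    if bandwidth_rule != "silverman":
        raise ValueError(f"unknown bandwidth rule: {bandwidth_rule!r}")
    h = silverman_bandwidth(values)
    if grid is None:
        lo = values.min() - GRID_MARGIN_BANDWIDTHS * h
        hi = values.max() + GRID_MARGIN_BANDWIDTHS * h
        grid = np.linspace(lo, hi, grid_size)
    else:
        grid = np.asarray(grid, dtype=float)
    return DensityEstimate(grid=grid, density=_gaussian_kde_eval(values, grid, h),
                           bandwidth=h)


def _binned_logdensity(vals_list, bandwidths, fine: np.ndarray) -> np.ndarray:
    """log KDE of every ROI on one shared uniform grid, via FFT convolution.

    Samples are linearly binned onto the grid and smoothed with the exact
    Gaussian frequency response (zero-padded to avoid wrap-around). Matches
    direct evaluation to well below the KDE's own sampling error.
    """
    f_size = fine.size
    dx = fine[1] - fine[0]
    nfft = 2 * f_size
    freqs = np.fft.rfftfreq(nfft, d=dx)
    logd = np.empty((len(vals_list), f_size))
    for r, (v, h) in enumerate(zip(vals_list, bandwidths)):
        pos = (v - fine[0]) / dx
        i0 = np.clip(pos.astype(np.int64), 0, f_size - 2)
        t = pos - i0
        counts = np.bincount(i0, weights=1.0 - t, minlength=nfft)
        counts += np.bincount(i0 + 1, weights=t, minlength=nfft)
        ft = np.fft.rfft(counts)
        ft *= np.exp(-2.0 * (np.pi * freqs * h) ** 2)
        dens = np.fft.irfft(ft, nfft)[:f_size] / (len(v) * dx)
        logd[r] = np.log(np.maximum(dens, 1e-300))
    return logd


def _to_masses(density: np.ndarray) -> np.ndarray:
    # Sum-normalize first so the epsilon floor acts on unitless masses;
    # this keeps the discrete KL invariant to grid spacing AND data scale.
    d = np.asarray(density, dtype=float)
    d = d / d.sum() + KLD_EPS
    return d / d.sum()


def symmetrized_kld(p: DensityEstimate, q: DensityEstimate) -> float:
    """Symmetric Kullback-Leibler divergence KL(P||Q) + KL(Q||P), in nats.

    Densities are discretized to probability masses (epsilon-floored and
    renormalized on the shared grid), which makes the result invariant to
    grid spacing.
    """
    if p.grid.shape != q.grid.shape or not np.allclose(p.grid, q.grid):
        raise GridMismatchError("density estimates do not share a grid")
    pm, qm = _to_masses(p.density), _to_masses(q.density)
    log_ratio = np.log(pm) - np.log(qm)
    return float(np.sum(pm * log_ratio) - np.sum(qm * log_ratio))


def kld_to_similarity(d) -> float:
    """Map a non-negative divergence to a similarity in (0, 1] via exp(-d)."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("divergence must be non-negative")
    out = np.exp(-d)
    return float(out) if out.ndim == 0 else out


@dataclass
class SimilarityMatrix:
    """Symmetric N x N morphological connectivity matrix for one subject.

    Off-diagonal entries lie in (0, 1]; the diagonal is fixed to 0
    (self-loops are excluded from graphs).
    """

    values: np.ndarray
    atlas_name: str = "unknown"
    subject_id: str = "subject"
    roi_labels: list = None
    metadata: dict = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("similarity matrix must be square")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("similarity matrix must be symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("diagonal must be zero")
        off = self.values[~np.eye(n, dtype=bool)]
        if np.any(off <= 0) or np.any(off > 1):
            raise ValueError("off-diagonal similarities must lie in (0, 1]")
        if self.roi_labels is None:
            self.roi_labels = list(range(1, n + 1))
        if self.metadata is None:
            self.metadata = {}

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]

    def to_tsv(self, path) -> None:
        cols = [str(label) for label in self.roi_labels]
        pd.DataFrame(self.values, columns=cols).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, subject_id="subject", atlas_name="unknown"):
        df = pd.read_csv(path, sep="\t")
        return cls(values=df.to_numpy(dtype=float), subject_id=subject_id,
                   atlas_name=atlas_name,
                   roi_labels=[int(c) for c in df.columns])


def build_network(
    s: ROISampleSet,
    grid_size: int = DEFAULT_GRID_SIZE,
    bandwidth_rule: str = "silverman",
    min_voxels: int = 10,
    pair_eval: str = "interp",
) -> SimilarityMatrix:
    """Build the similarity-weighted connectivity matrix for one subject.

    For each unordered ROI pair both PDFs are evaluated on one shared
    uniform grid spanning the pooled value range extended by 3 pooled
    bandwidths; the entry is ``exp(-sKLD)``.

    ``pair_eval`` selects how per-pair densities are obtained:

    - ``"interp"`` (default): each ROI's KDE is evaluated once on a fine
      private grid (1024 points, 4-bandwidth margin) and linearly
      interpolated onto each pair grid. The interpolation error is far
      below the KDE's own sampling error and this path is an order of
      magnitude faster for a 90-ROI subject.
    - ``"exact"``: the Gaussian mixture is re-evaluated on every pair grid.
    """
    if bandwidth_rule != "silverman":
        raise ValueError(f"unknown bandwidth rule: {bandwidth_rule!r}")
    if pair_eval not in ("interp", "exact"):
        raise ValueError(f"unknown pair_eval mode: {pair_eval!r}")
    s.validate(min_voxels=min_voxels)
    n = s.n_rois
    vals = s.samples

    bandwidths = []
    for label, v in zip(s.roi_labels, vals):
        if np.var(v) == 0:
            raise DegenerateROIError(label, len(v), min_voxels)
        bandwidths.append(silverman_bandwidth(v))

    h = np.asarray(bandwidths)
    mins = np.array([v.min() for v in vals])
    maxs = np.array([v.max() for v in vals])

    # All pair grids at once: (n_pairs, grid_size).
    iu, ju = np.triu_indices(n, k=1)
    h_pair = np.maximum(h[iu], h[ju])
    lo = np.minimum(mins[iu], mins[ju]) - GRID_MARGIN_BANDWIDTHS * h_pair
    hi = np.maximum(maxs[iu], maxs[ju]) + GRID_MARGIN_BANDWIDTHS * h_pair
    unit = np.linspace(0.0, 1.0, grid_size)
    grids = lo[:, None] + (hi - lo)[:, None] * unit[None, :]

    if pair_eval == "interp":
        # Every ROI's KDE is evaluated once on one shared fine grid that
        # covers all pair grids, then log-density is interpolated linearly
        # onto each pair grid. log-density of a Gaussian mixture is smooth
        # (near-quadratic in the tails), so the interpolation error is far
        # below the KDE's own sampling error.
        margin = GRID_MARGIN_BANDWIDTHS * h.max()
        x0 = mins.min() - margin
        x1 = maxs.max() + margin
        fine = np.linspace(x0, x1, _FINE_GRID_SIZE)
        logd = _binned_logdensity(vals, h, fine)
        dx = (x1 - x0) / (_FINE_GRID_SIZE - 1)
        pos = (grids - x0) / dx
        i0 = np.clip(pos.astype(np.int64), 0, _FINE_GRID_SIZE - 2)
        t = np.clip(pos - i0, 0.0, 1.0)

        def _interp_rows(rows):
            a = logd[rows[:, None], i0]
            b = logd[rows[:, None], i0 + 1]
            return np.exp(a * (1.0 - t) + b * t)

        dens_left = _interp_rows(iu)
        dens_right = _interp_rows(ju)
    else:
        dens_left = np.empty_like(grids)
        dens_right = np.empty_like(grids)
        for k in range(len(iu)):
            dens_left[k] = _gaussian_kde_eval(vals[iu[k]], grids[k], h[iu[k]])
            dens_right[k] = _gaussian_kde_eval(vals[ju[k]], grids[k], h[ju[k]])

    pm = dens_left / dens_left.sum(axis=1, keepdims=True) + KLD_EPS
    pm /= pm.sum(axis=1, keepdims=True)
    qm = dens_right / dens_right.sum(axis=1, keepdims=True) + KLD_EPS
    qm /= qm.sum(axis=1, keepdims=True)
    log_ratio = np.log(pm / qm)
    d = np.sum((pm - qm) * log_ratio, axis=1)

    out = np.zeros((n, n))
    out[iu, ju] = out[ju, iu] = np.exp(-np.maximum(d, 0.0))

    return SimilarityMatrix(
        values=out,
        atlas_name=s.atlas_name,
        subject_id=s.subject_id,
        roi_labels=list(s.roi_labels),
        metadata={
            "grid_size": grid_size,
            "bandwidth_rule": bandwidth_rule,
            "pair_eval": pair_eval,
            "similarity_transform": "exp(-sKLD)",
        },
    )
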