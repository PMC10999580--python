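"""Center-of-mass source localization and positioning-error statistics.

The source position is the intensity-weighted centroid of the reconstructed
volume,

    (x, y, z) = ( sum w_i x_i, sum w_i y_i, sum w_i z_i ) / sum w_i,

optionally restricted to voxels above a fraction of the maximum weight to
suppress reconstruction-background bias.  Accuracy is quantified per axis as
the absolute error |reconstructed - original| and overall as the Euclidean
distance between the two position vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np

from .errors import MetricError
from .recon import Volume

__all__ = [
    "TrackResult",
    "ErrorSummary",
    "centroid",
    "position_error",
    "summarize_errors",
]


@dataclass
class TrackResult:
    """Original vs. reconstructed 3D coordinates for one source position."""

    original: np.ndarray
    reconstructed: np.ndarray
    abs_error: np.ndarray
    euclidean_distance: float
    label: str = ""

    def rounded(self, ndigits: int = 3) -> dict:
        """Display form: round-half-even to ``ndigits`` decimals, as printed
        in result tables."""
        r = lambda v: float(np.round(v, ndigits))
        return {
            "label": self.label,
            "original": [r(v) for v in self.original],
            "reconstructed": [r(v) for v in self.reconstructed],
            "abs_error": [r(v) for v in self.abs_error],
            "euclidean_distance": r(self.euclidean_distance),
        }


@dataclass
class ErrorSummary:
    """Arithmetic means and ranges over a set of tracking results."""

    n: int
    mean_abs_error: np.ndarray  # (|dx|, |dy|, |dz|) means, mm
    mean_distance: float
    abs_error_range: np.ndarray  # (2, 3): min/max per axis
    distance_range: tuple[float, float]


def centroid(volume: Volume, threshold_fraction: float = 0.1) -> np.ndarray:
    """Intensity-weighted centroid (world mm) of the volume.

    Only voxels with weight >= ``threshold_fraction * max(w)`` contribute;
    0.0 reproduces the plain center of mass over all voxels.
    """
    w = np.asarray(volume.values, dtype=float)
    if w.size == 0 or not np.any(w > 0):
        raise MetricError("empty volume: no positive weights to take a centroid of")
    if threshold_fraction > 0:
        w = np.where(w >= threshold_fraction * w.max(), w, 0.0)
    total = w.sum()
    if total <= 0:
        raise MetricError("volume is empty after thresholding")
    out = np.empty(3)
    for ax in range(3):
        coords = volume.grid.voxel_centers_1d(ax)
        shape = [1, 1, 1]
        shape[ax] = -1
        out[ax] = (w * coords.reshape(shape)).sum() / total
    return out


def position_error(
    original: Sequence[float], reconstructed: Sequence[float], label: str = ""
) -> TrackResult:
    """Per-axis absolute errors and Euclidean distance between two positions."""
    o = np.asarray(original, dtype=float)
    r = np.asarray(reconstructed, dtype=float)
    delta = r - o
    return TrackResult(
        original=o,
        reconstructed=r,
        abs_error=np.abs(delta),
        euclidean_distance=float(np.linalg.norm(delta)),
        label=label,
    )


def summarize_errors(
    results: Iterable[TrackResult],
    dedupe: bool = True,
    exclude_labels: Iterable[str] | None = None,
    keep: Callable[[TrackResult], bool] | None = None,
) -> ErrorSummary:
    """Mean absolute error per axis, mean distance and ranges.

    With ``dedupe`` on, repeated original coordinates (e.g. a shared origin
    row across several scan tables) are counted once — the convention that
    reproduces the printed summary averages.  ``exclude_labels`` drops
    results by label; ``keep`` is an arbitrary retain-predicate.
    """
    excl = set(exclude_labels) if exclude_labels else set()
    retained: list[TrackResult] = []
    seen: set[tuple] = set()
    for res in results:
        if res.label in excl:
            continue
        if keep is not None and not keep(res):
            continue
        if dedupe:
            key = tuple(np.round(res.original, 9))
            if key in seen:
                continue
            seen.add(key)
        retained.append(res)
    if not retained:
        raise MetricError("no tracking results left after filtering")
    err = np.array([r.abs_error for r in retained])
    dist = np.array([r.euclidean_distance for r in retained])
    return ErrorSummary(
        n=len(retained),
        mean_abs_error=err.mean(axis=0),
        mean_distance=float(dist.mean()),
        abs_error_range=np.stack([err.min(axis=0), err.max(axis=0)]),
        distance_range=(float(dist.min()), float(dist.max())),
    )
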