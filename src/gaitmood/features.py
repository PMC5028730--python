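"""Fourier gait features, z-score normalization and PCA reduction.

Walking is periodic, so each of a segment's 42 motion channels is
summarized by its *main frequency* -- the DFT bin (DC excluded) with the
largest magnitude, in Hz -- and the complex argument (*phase*) at that
bin.  A segment therefore yields 42 frequencies + 42 phases; averaging
segment features within each walking orientation and concatenating

    [front freqs (42) | front phases (42) | back freqs (42) | back phases (42)]

gives the 168-value descriptor of one recording.  Feature tables are
z-score normalized column-wise and reduced with PCA, keeping the minimal
leading components whose cumulative explained variance reaches a
threshold (default 0.95).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA as _SkPCA

from .errors import (
    ConfigError,
    MissingOrientationError,
    TooShortError,
    ValidationError,
)
from .joints import MOTION_COLUMNS_42
from .preprocess import Segment
from .skeleton_io import FeatureTable

#: Ordered names of the 168 per-record features.
FEATURE_NAMES_168: tuple[str, ...] = tuple(
    f"{orient}_{kind}_{col}"
    for orient in ("front", "back")
    for kind in ("freq", "phase")
    for col in MOTION_COLUMNS_42
)


@dataclass
class SegmentFeatures:
    """Per-segment spectral summary: 42 main frequencies + 42 phases."""

    main_freqs: np.ndarray
    phases: np.ndarray
    orientation: str

    def __post_init__(self) -> None:
        self.main_freqs = np.asarray(self.main_freqs, dtype=float)
        self.phases = np.asarray(self.phases, dtype=float)
        if self.main_freqs.shape != (42,) or self.phases.shape != (42,):
            raise ValidationError("expected 42 frequencies and 42 phases")


@dataclass
class FeatureVector:
    """The 168-value per-record descriptor."""

    values: np.ndarray
    provenance: str
    n_front: int
    n_back: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (168,):
            raise ValidationError("a feature vector has exactly 168 values")


@dataclass
class PCAModel:
    """Fitted PCA: centering mean, orthonormal loadings, variance shares."""

    mean: np.ndarray
    components: np.ndarray  # (k, d), rows orthonormal
    explained_variance_ratio: np.ndarray  # (k,), non-increasing
    variance_threshold: float

    @property
    def n_components(self) -> int:
        return self.components.shape[0]


def main_frequency_and_phase(
    signal: np.ndarray, frame_rate: float, window: str | None = None
) -> tuple[float, float]:
    """Dominant non-DC frequency (Hz) and its phase (radians, (-pi, pi]).

    Searches DFT bins k = 1 .. floor(N/2); ties break toward the lowest
    bin.  An exactly constant (or all-zero) signal returns (0, 0).

    Parameters
    ----------
    window
        ``None`` (raw samples) or ``"hann"``.
    """
    x = np.asarray(signal, dtype=float)
    n = x.size
    if n < 2:
        raise TooShortError("need at least 2 samples for a spectrum")
    if np.ptp(x) == 0.0:
        return 0.0, 0.0
    if window == "hann":
        x = x * np.hanning(n)
    elif window not in (None, "none"):
        raise ConfigError(f"unknown FFT window {window!r}")
    spectrum = np.fft.rfft(x)
    kmax = n // 2
    mags = np.abs(spectrum[1 : kmax + 1])
    if mags.size == 0 or np.max(mags) == 0.0:
        return 0.0, 0.0
    k = 1 + int(np.argmax(mags))
    phase = float(np.angle(spectrum[k]))
    if phase <= -math.pi:
        phase = math.pi
    return k * frame_rate / n, phase


def segment_features(
    segment: Segment, frame_rate: float, window: str | None = None
) -> SegmentFeatures:
    """Apply :func:`main_frequency_and_phase` to each of the 42 channels."""
    freqs = np.empty(42)
    phases = np.empty(42)
    for j in range(42):
        freqs[j], phases[j] = main_frequency_and_phase(
            segment.values[:, j], frame_rate, window=window
        )
    return SegmentFeatures(
        main_freqs=freqs, phases=phases, orientation=segment.orientation
    )


def _circular_mean(angles: np.ndarray, axis: int = 0) -> np.ndarray:
    return np.angle(np.mean(np.exp(1j * angles), axis=axis))


def aggregate_record(
    features: list[SegmentFeatures],
    provenance: str = "",
    phase_mean: str = "arithmetic",
) -> FeatureVector:
    """Average segment features per orientation and concatenate to 168.

    Raises
    ------
    MissingOrientationError
        If the record has no front or no back segments.
    """
    if phase_mean not in ("arithmetic", "circular"):
        raise ConfigError(f"unknown phase_mean {phase_mean!r}")
    groups = {"front": [], "back": []}
    for sf in features:
        groups[sf.orientation].append(sf)
    parts = []
    for orient in ("front", "back"):
        group = groups[orient]
        if not group:
            raise MissingOrientationError(
                f"record {provenance!r} has no {orient} segments"
            )
        freqs = np.mean([sf.main_freqs for sf in group], axis=0)
        phase_stack = np.array([sf.phases for sf in group])
        if phase_mean == "circular":
            phases = _circular_mean(phase_stack, axis=0)
        else:
            phases = np.mean(phase_stack, axis=0)
        parts.extend([freqs, phases])
    return FeatureVector(
        values=np.concatenate(parts),
        provenance=provenance,
        n_front=len(groups["front"]),
        n_back=len(groups["back"]),
    )


def zscore_fit(table: FeatureTable) -> tuple[np.ndarray, np.ndarray]:
    """Column means and (population) standard deviations of a table."""
    if table.n_instances < 2:
        raise ValidationError("need at least 2 instances to fit z-scores")
    return zscore_fit_array(table.values)


def zscore_fit_array(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    values = np.asarray(values, dtype=float)
    if values.shape[0] < 2:
        raise ValidationError("need at least 2 instances to fit z-scores")
    return values.mean(axis=0), values.std(axis=0)


def zscore_apply_array(
    values: np.ndarray, means: np.ndarray, sds: np.ndarray
) -> np.ndarray:
    """(x - mean)/sd per column; zero-variance columns map to 0."""
    safe = np.where(sds == 0, 1.0, sds)
    out = (np.asarray(values, dtype=float) - means) / safe
    out[:, sds == 0] = 0.0
    return out


def zscore_apply(
    table: FeatureTable, means: np.ndarray, sds: np.ndarray
) -> FeatureTable:
    return FeatureTable(
        instance_ids=list(table.instance_ids),
        values=zscore_apply_array(table.values, means, sds),
        feature_names=list(table.feature_names),
        labels=list(table.labels),
    )


def pca_fit_array(
    values: np.ndarray, variance_threshold: float = 0.95
) -> PCAModel:
    """Fit PCA, retaining the minimal components reaching the threshold."""
    if not 0.0 < variance_threshold <= 1.0:
        raise ConfigError("variance_threshold must be in (0, 1]")
    values = np.asarray(values, dtype=float)
    pca = _SkPCA(svd_solver="full")
    pca.fit(values)
    ratios = pca.explained_variance_ratio_
    cumulative = np.cumsum(ratios)
    # minimal k with cumulative share >= threshold; keep everything when
    # rounding keeps the cumulative sum fractionally below 1.0
    reached = np.flatnonzero(cumulative >= variance_threshold - 1e-12)
    k = int(reached[0]) + 1 if reached.size else len(ratios)
    return PCAModel(
        mean=pca.mean_,
        components=pca.components_[:k],
        explained_variance_ratio=ratios[:k],
        variance_threshold=variance_threshold,
    )


def pca_fit(table: FeatureTable, variance_threshold: float = 0.95) -> PCAModel:
    return pca_fit_array(table.values, variance_threshold)


def pca_apply_array(values: np.ndarray, model: PCAModel) -> np.ndarray:
    return (np.asarray(values, dtype=float) - model.mean) @ model.components.T


def pca_apply(table: FeatureTable, model: PCAModel) -> FeatureTable:
    """Project a table onto the retained components (columns PC1..PCk)."""
    projected = pca_apply_array(table.values, model)
    return FeatureTable(
        instance_ids=list(table.instance_ids),
        values=projected,
        feature_names=[f"PC{i + 1}" for i in range(model.n_components)],
        labels=list(table.labels),
    )


def records_to_table(
    vectors: list[FeatureVector],
    instance_ids: list[tuple[str, str, str]],
    labels: list[str],
) -> FeatureTable:
    """Stack per-record feature vectors into a FeatureTable."""
    values = (
        np.array([v.values for v in vectors])
        if vectors
        else np.empty((0, 168))
    )
    return FeatureTable(
        instance_ids=instance_ids,
        values=values,
        feature_names=list(FEATURE_NAMES_168),
        labels=labels,
    )
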