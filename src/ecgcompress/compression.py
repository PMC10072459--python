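"""Learned compression network plan and classical dimensionality-reduction
baselines.

The compression ratio is defined as ``CR = k / n`` where ``n`` is the original
beat length (260 samples for the MIT-BIH-style segmentation) and ``k`` the
compressed length.  The learned compressor is three convolution/max-pool
stages followed by a single dense layer that sets the compressed dimension:

    input(n×1) → conv1d(16,3,same) → pool(2) → conv1d(16,3) → pool(2)
               → conv1d(16,3) → pool(5) → flatten → dense(k)

At n=260 this yields the printed shape chain 260→130→65→13 and a dense layer
of (13·16+1)·k parameters (10,868 at CR=0.2, k=52).  The compressor has no
decoder: it is trained jointly with the classifier on the classification
cross-entropy, and its output is consumed directly in the compressed domain.

SVD and PCA baselines project beats onto the top-k right singular vectors of
the training matrix — raw for SVD, mean-centered for PCA.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA

from .io import BeatDataset
from .nn import Network, NetworkPlan, PlanBuilder, PlanError

logger = logging.getLogger(__name__)

__all__ = [
    "SUPPORTED_CRS",
    "CompressionConfig",
    "compressed_length",
    "build_compressor_plan",
    "compress_forward",
    "pca_fit",
    "pca_transform",
    "SVDBasis",
    "svd_fit",
    "svd_transform",
]

#: The compression-ratio sweep the benchmark grids use.
SUPPORTED_CRS = (0.5, 0.4, 0.3, 0.2, 0.1, 0.05)


def compressed_length(n: int, cr: float) -> int:
    """Compressed beat length ``k = round(cr * n)``, at least 1.

    Rounding is half-away-from-zero so sweep values are reproducible across
    platforms (e.g. ``n=205, cr=0.05 -> 10``).
    """
    if not 0.0 < cr <= 1.0:
        raise ValueError(f"compression ratio must be in (0, 1], got {cr}")
    return max(1, int(math.floor(cr * n + 0.5)))


@dataclass(frozen=True)
class CompressionConfig:
    """Original length ``n``, ratio ``cr`` and derived compressed length ``k``."""

    n: int = 260
    cr: float = 0.2
    k: int = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "k", compressed_length(self.n, self.cr))
        if self.cr not in SUPPORTED_CRS and self.cr != 1.0:
            logger.info("compression ratio %g outside the usual sweep %s", self.cr, SUPPORTED_CRS)


def build_compressor_plan(config: CompressionConfig) -> NetworkPlan:
    """Build the compression-network plan for ``config``.

    Requires ``n >= 20`` so all three pooling stages (2, 2, 5) are
    non-degenerate.
    """
    n = config.n
    pools = (2, 2, 5)
    length = n
    for stage, pool in enumerate(pools, start=1):
        if length < pool:
            raise PlanError(
                f"input length {n} too short: pooling stage {stage} (size {pool}) "
                f"would act on a length-{length} sequence"
            )
        length //= pool
    if n < 20:
        raise PlanError(f"compressor requires n >= 20, got {n}")
    b = PlanBuilder()
    b.input(n, 1, name="beat")
    b.conv1d(16, 3, name="conv1")
    b.maxpool(2, name="pool1")
    b.conv1d(16, 3, name="conv2")
    b.maxpool(2, name="pool2")
    b.conv1d(16, 3, name="conv3")
    b.maxpool(5, name="pool3")
    b.flatten(name="flatten")
    b.dense(config.k, activation=None, name="compressed")
    return b.build()


def compress_forward(model: Network, beats: BeatDataset | np.ndarray) -> np.ndarray:
    """Run the compressor in inference mode over a beat matrix or dataset."""
    matrix = beats.beats if isinstance(beats, BeatDataset) else np.asarray(beats, dtype=float)
    expected = model.plan.input_shape[0]
    if matrix.ndim != 2 or matrix.shape[1] != expected:
        raise ValueError(
            f"compressor expects beats of length {expected}, got shape {matrix.shape}"
        )
    return model.forward(matrix[:, :, None], training=False)


# ---------------------------------------------------------------------------
# Classical baselines
# ---------------------------------------------------------------------------

def _check_k(train_beats: np.ndarray, k: int) -> np.ndarray:
    train_beats = np.asarray(train_beats, dtype=float)
    if train_beats.ndim != 2 or len(train_beats) < 2:
        raise ValueError("baseline fitting needs a 2-D matrix with at least 2 beats")
    if not 1 <= k <= train_beats.shape[1]:
        raise ValueError(f"k={k} out of range for beat length {train_beats.shape[1]}")
    return train_beats


def pca_fit(train_beats: np.ndarray, k: int) -> PCA:
    """Top-k principal directions of the mean-centered training matrix."""
    train_beats = _check_k(train_beats, k)
    if k > min(train_beats.shape):
        raise ValueError(f"k={k} exceeds the rank bound min{train_beats.shape}")
    pca = PCA(n_components=k, svd_solver="full")
    pca.fit(train_beats)
    return pca


def pca_transform(basis: PCA, beats: np.ndarray) -> np.ndarray:
    return basis.transform(np.asarray(beats, dtype=float))


@dataclass
class SVDBasis:
    """Top-k right singular vectors of the raw (uncentered) training matrix."""

    components: np.ndarray  # (k, beat_length)
    singular_values: np.ndarray  # (k,)


def svd_fit(train_beats: np.ndarray, k: int) -> SVDBasis:
    train_beats = _check_k(train_beats, k)
    _, s, vt = np.linalg.svd(train_beats, full_matrices=False)
    if k > vt.shape[0]:
        raise ValueError(f"k={k} exceeds the rank bound {vt.shape[0]}")
    return SVDBasis(vt[:k].copy(), s[:k].copy())


def svd_transform(basis: SVDBasis, beats: np.ndarray) -> np.ndarray:
    return np.asarray(beats, dtype=float) @ basis.components.T
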