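"""Fixture and synthetic landscape generators.

Provides the worked 4x4 toy matrix, the XOR landscape, block-structured
random synergistic matrices with known ground-truth encoders, additively
separable control matrices, and grayscale-image-like "blob" landscapes
quantized to a few affordance levels by 1-D k-means — emulating small
natural images (32x32, 5 levels) in which a standing figure concentrates
vertical variance in a few columns while horizontal variance spreads over
many rows.

All stochastic generators are pure functions of (spec, seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .landscape import AffordanceLandscape, EncoderMap

__all__ = [
    "GeneratorSpec",
    "SynergisticLandscape",
    "toy_landscape",
    "toy_swapped",
    "xor_landscape",
    "random_synergistic_landscape",
    "separable_landscape",
    "blob_image_landscape",
    "quantize_matrix",
    "load_grayscale_image",
]

_KINDS = ("toy", "toy_swapped", "xor", "random_synergistic", "blob_image")


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of one synthetic landscape family.

    ``levels`` is the number of distinct affordance values after generation
    (post-quantization for blob images); ``blocks`` the per-axis block count
    for the synergistic family; ``noise`` the fraction of cells resampled at
    random; ``blob_range`` the (inclusive) min/max number of blobs.
    """

    kind: str = "blob_image"
    m: int = 32
    n: int = 32
    levels: int = 5
    seed: int | None = None
    blocks: int = 2
    noise: float = 0.0
    blob_range: tuple = (1, 3)

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ValueError(f"unknown kind {self.kind!r}")
        if self.kind in ("xor", "random_synergistic", "blob_image") and self.levels < 2:
            raise ValueError("synergistic kinds need at least 2 levels")
        if self.kind in ("random_synergistic", "blob_image") and self.seed is None:
            raise ValueError("stochastic kinds require a seed")
        if not 0.0 <= self.noise <= 1.0:
            raise ValueError("noise must be a fraction in [0, 1]")


def toy_landscape() -> AffordanceLandscape:
    """The worked 4x4 synergistic matrix with observation axes 1..4."""
    return AffordanceLandscape(
        np.array(
            [
                [0, 0, 1, 1],
                [0, 0, 2, 1],
                [1, 2, 0, 0],
                [1, 1, 0, 0],
            ],
            dtype=float,
        )
    )


def toy_swapped() -> AffordanceLandscape:
    """Toy matrix with entries a_23 and a_42 exchanged.

    On this variant the optimal direct and indirect codings coincide: the
    synergistic advantage of relaying sensory information disappears.
    """
    matrix = toy_landscape().matrix.copy()
    matrix[1, 2], matrix[3, 1] = matrix[3, 1], matrix[1, 2]
    return AffordanceLandscape(matrix)


def xor_landscape(levels: int = 2) -> AffordanceLandscape:
    """2x2 XOR landscape [[0,1],[1,0]]: all affordance information is synergistic."""
    if levels != 2:
        raise ValueError("the XOR landscape has exactly two levels")
    return AffordanceLandscape(np.array([[0.0, 1.0], [1.0, 0.0]]))


@dataclass(frozen=True)
class SynergisticLandscape:
    """A generated landscape plus the ground-truth block structure."""

    landscape: AffordanceLandscape
    row_blocks: np.ndarray
    col_blocks: np.ndarray

    def ground_truth_encoders(self) -> tuple:
        B = int(self.row_blocks.max()) + 1
        C = int(self.col_blocks.max()) + 1
        return (EncoderMap(self.row_blocks, B), EncoderMap(self.col_blocks, C))


def random_synergistic_landscape(spec: GeneratorSpec) -> SynergisticLandscape:
    """Block-structured matrix whose value depends only on the *interaction*
    of row-block and column-block labels (an XOR-style coupling), so no
    single axis predicts the affordance but the pair does.  A ``noise``
    fraction of cells is resampled uniformly from the value set.
    """
    if spec.blocks < 2:
        raise ValueError("need at least 2 blocks per axis")
    rng = np.random.default_rng(spec.seed)
    B = spec.blocks
    if B > min(spec.m, spec.n):
        raise ValueError("more blocks than axis states")
    # balanced contiguous blocks: unbalanced blocks would leak the block
    # identity through the row/column means, letting a per-axis encoder
    # recover the structure and defeating the generator's purpose
    row_blocks = np.arange(spec.m) * B // spec.m
    col_blocks = np.arange(spec.n) * B // spec.n
    values = np.arange(B, dtype=float) % spec.levels
    matrix = values[(row_blocks[:, None] + col_blocks[None, :]) % B]
    if spec.noise > 0:
        mask = rng.random((spec.m, spec.n)) < spec.noise
        matrix = np.where(mask, rng.choice(values, size=(spec.m, spec.n)), matrix)
    return SynergisticLandscape(AffordanceLandscape(matrix), row_blocks, col_blocks)


def separable_landscape(m: int, n: int, seed: int, scale: float = 4.0) -> AffordanceLandscape:
    """Additively separable control: a_bc = f(b) + g(c), continuous values.

    Such a landscape carries no synergistic structure — each axis's
    contribution can be recovered on its own — so direct and indirect
    codings are equally good on it.  f and g are drawn from a continuous
    uniform so that no two sums coincide: value collisions (f_b − f_b' =
    g_c' − g_c) would alias the separable structure into a sum-type gate,
    which carries genuine synergy even though the matrix is separable.
    """
    rng = np.random.default_rng(seed)
    f = rng.uniform(0.0, scale, size=m)
    g = rng.uniform(0.0, scale, size=n)
    return AffordanceLandscape(f[:, None] + g[None, :])


def blob_image_landscape(spec: GeneratorSpec) -> AffordanceLandscape:
    """Grayscale-like matrix with vertically elongated blobs, quantized.

    Draws a low-amplitude noise background and superimposes 1-3 bright
    Gaussian blobs that are tall (covering most rows) and narrow (a few
    columns), mimicking small photographs of standing figures.  The value
    multiset is then reduced to ``spec.levels`` unique values by 1-D
    k-means, since exact synergy computation needs a small target alphabet.
    """
    rng = np.random.default_rng(spec.seed)
    m, n = spec.m, spec.n
    img = rng.normal(60.0, 15.0, size=(m, n))
    lo, hi = spec.blob_range
    n_blobs = int(rng.integers(lo, hi + 1))
    rows = np.arange(m)[:, None]
    cols = np.arange(n)[None, :]
    for _ in range(n_blobs):
        r0 = rng.uniform(0.3 * m, 0.7 * m)
        c0 = rng.uniform(0.1 * n, 0.9 * n)
        sig_r = rng.uniform(0.25, 0.45) * m  # tall
        sig_c = rng.uniform(0.03, 0.08) * n  # narrow
        amp = rng.uniform(120.0, 180.0)
        img = img + amp * np.exp(
            -((rows - r0) ** 2) / (2 * sig_r**2) - ((cols - c0) ** 2) / (2 * sig_c**2)
        )
    img = np.clip(img, 0.0, 255.0)
    # derived sub-seed keeps quantization coupled to the landscape draw
    return quantize_matrix(img, spec.levels, seed=int(rng.integers(2**31)))


def quantize_matrix(matrix: np.ndarray, k: int, seed: int | None = None) -> AffordanceLandscape:
    """Reduce a matrix to at most k unique values by 1-D k-means (Lloyd).

    Each value is replaced by its cluster centroid, so quantized affordance
    values remain numeric and averageable.  If the input already has <= k
    unique values it is returned unchanged with a warning.
    """
    if k < 2:
        raise ValueError("need at least 2 levels")
    matrix = np.asarray(matrix, float)
    if not np.isfinite(matrix).all():
        raise ValueError("matrix entries must be finite")
    uniq = np.unique(matrix)
    if uniq.size <= k:
        warnings.warn(
            f"matrix already has {uniq.size} <= {k} unique values; returned unchanged",
            stacklevel=2,
        )
        return AffordanceLandscape(matrix)
    km = KMeans(n_clusters=k, n_init=10, max_iter=100, tol=1e-6, random_state=seed)
    labels = km.fit_predict(matrix.reshape(-1, 1))
    quantized = km.cluster_centers_.ravel()[labels].reshape(matrix.shape)
    return AffordanceLandscape(quantized)


def load_grayscale_image(path) -> np.ndarray:
    """Load an image file as a grayscale matrix (Rec. 601 luma for RGB)."""
    from PIL import Image

    with Image.open(path) as im:
        arr = np.asarray(im, dtype=float)
    if arr.ndim == 3:
        arr = arr[..., 0] * 0.299 + arr[..., 1] * 0.587 + arr[..., 2] * 0.114
    return arr


def generate(spec: GeneratorSpec):
    """Dispatch on ``spec.kind``; synergistic kind returns ground truth too."""
    if spec.kind == "toy":
        return toy_landscape()
    if spec.kind == "toy_swapped":
        return toy_swapped()
    if spec.kind == "xor":
        return xor_landscape(2)
    if spec.kind == "random_synergistic":
        return random_synergistic_landscape(spec)
    return blob_image_landscape(spec)
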