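"""Waveform feature extractors for single-channel averaged EEG segments.

Five descriptions of the *shape* of a 1-s averaged segment ``x(n)``,
``n = 1..N``:

* **MP1 / MP2** — greedy matching-pursuit decomposition of the segment on
  a dictionary of unit-norm atoms.  MP1 uses normalized signal templates
  as atoms and scores a segment by its residual norm; MP2 uses dyadically
  scaled and translated least-asymmetric Daubechies (symlet-2) wavelet
  atoms and returns the length-D weight vector as the feature.
* **PE** — permutation entropy: Shannon entropy of the ordinal-pattern
  histogram of order ``m`` at lag ``tau``, slid sample-by-sample over the
  segment.
* **SHCC** — slope horizontal chain code: the segment is resampled to G
  points, both coordinates are min-max normalized to [0, 1], and the
  feature is the sequence of point-to-point slopes.
* **SIFT** — the segment is rasterized into a binary line plot (Bresenham
  interpolation) and a single upright SIFT-style descriptor (4x4 grid of
  8-bin gradient-orientation histograms, L2-normalized, clamped at 0.2,
  re-normalized) is computed on a square patch at the plot center.
* **RAW** — the z-scored sample vector, the control feature for the
  linear-margin classifier.

All extractors are deterministic: identical input yields a bit-identical
feature.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pywt
from scipy import ndimage
from skimage.draw import line as bresenham_line

from .preprocess import AveragedSegment


class Method(str, Enum):
    """Feature-extraction method tags."""

    MP1 = "MP1"
    MP2 = "MP2"
    PE = "PE"
    SHCC = "SHCC"
    SIFT = "SIFT"
    RAW = "RAW"


@dataclass(frozen=True)
class FeatureVector:
    """A method-tagged numeric feature for one channel of one segment."""

    values: np.ndarray
    method: Method
    channel: str = ""
    stimulus_id: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature vector contains non-finite values")


# --- matching pursuit -------------------------------------------------------


@dataclass
class MPDictionary:
    """Unit-norm atom dictionary for matching pursuit."""

    atoms: np.ndarray           #: (D, N), each row unit L2 norm
    source: str                 #: "signal_templates" (MP1) or "wavelet_atoms" (MP2)

    def __post_init__(self) -> None:
        self.atoms = np.atleast_2d(np.asarray(self.atoms, dtype=float))
        if self.atoms.shape[0] == 0 or self.atoms.shape[1] == 0:
            raise ValueError("dictionary needs at least one non-empty atom")
        norms = np.linalg.norm(self.atoms, axis=1)
        if np.any(norms == 0):
            raise ValueError("dictionary contains a zero-norm atom")
        self.atoms = self.atoms / norms[:, None]

    @property
    def size(self) -> int:
        return self.atoms.shape[0]

    @property
    def atom_length(self) -> int:
        return self.atoms.shape[1]


@dataclass
class MPResult:
    selected_indices: list[int]
    weights: np.ndarray
    residual: np.ndarray
    epsilon: float              #: L2 norm of the residual


def build_mp1_dictionary(
    templates: list[AveragedSegment] | list[np.ndarray],
    channel: int = 0,
) -> MPDictionary:
    """Dictionary of normalized signal templates (the MP1 variant).

    One atom per template, taken from row ``channel`` of each averaged
    segment (or from each template directly when plain vectors are given)
    and scaled to unit norm.  Zero-norm templates are rejected.
    """
    if not templates:
        raise ValueError("need at least one template")
    rows = [
        (t.data[channel] if isinstance(t, AveragedSegment) else np.asarray(t, dtype=float))
        for t in templates
    ]
    atoms = np.vstack(rows)
    if np.any(np.linalg.norm(atoms, axis=1) == 0):
        raise ValueError("zero-norm template cannot be an atom")
    return MPDictionary(atoms=atoms, source="signal_templates")


def symlet_atom_supports(N: int, wavelet: str = "sym2", max_level: int | None = None):
    """Yield ``(kind, level, support)`` for wavelet atoms fitting within N samples."""
    levels = []
    level = 1
    while True:
        support = len(pywt.upcoef("d", [1.0], wavelet, level=level))
        if support > N or (max_level is not None and level > max_level):
            break
        levels.append(("d", level, support))
        level += 1
    if levels:
        _, top, _ = levels[-1]
        support = len(pywt.upcoef("a", [1.0], wavelet, level=top))
        if support <= N:
            levels.append(("a", top, support))
    return levels


def build_mp2_dictionary(
    N: int,
    wavelet: str = "sym2",
    max_level: int | None = None,
) -> MPDictionary:
    """Dictionary of dyadic symlet-2 wavelet atoms (the MP2 variant).

    For every decomposition level whose atom support fits in ``N``, the
    detail atom is translated on the dyadic grid (step ``2**level``) over
    all positions fully inside ``[0, N)``; the scaling (approximation)
    atom of the coarsest level is added the same way.  All atoms are
    unit-normalized; none wraps around the segment edge.
    """
    if N < len(pywt.upcoef("d", [1.0], wavelet, level=1)):
        raise ValueError(f"segment length {N} is below the shortest atom support")
    specs = symlet_atom_supports(N, wavelet, max_level)
    if not specs:
        raise ValueError("no wavelet atom fits the requested segment length")
    atoms = []
    for kind, level, support in specs:
        proto = pywt.upcoef(kind, [1.0], wavelet, level=level)
        step = 2**level
        for start in range(0, N - support + 1, step):
            atom = np.zeros(N)
            atom[start : start + support] = proto
            atoms.append(atom)
    return MPDictionary(atoms=np.vstack(atoms), source="wavelet_atoms")


def mp_decompose(
    x: np.ndarray,
    dictionary: MPDictionary,
    m_atoms: int = 5,
    epsilon: float | None = None,
) -> MPResult:
    """Greedy matching pursuit of ``x`` on a unit-norm dictionary.

    At each step the atom maximizing ``|<residual, g_i>|`` is selected,
    its weight is the inner product with the residual, and its
    contribution is subtracted.  Iteration stops after ``m_atoms`` steps
    or as soon as the residual norm drops to ``epsilon`` (when given).
    Because each residual is orthogonal to its selected atom,
    ``||x||^2 = sum(w_k^2) + epsilon^2`` holds to numerical precision.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (dictionary.atom_length,):
        raise ValueError(
            f"signal length {x.shape} does not match atom length {dictionary.atom_length}"
        )
    if m_atoms < 1:
        raise ValueError("m_atoms must be >= 1")
    residual = x.copy()
    indices: list[int] = []
    weights: list[float] = []
    for _ in range(m_atoms):
        corr = dictionary.atoms @ residual
        k = int(np.argmax(np.abs(corr)))
        w = float(corr[k])
        if w == 0.0:
            break
        residual = residual - w * dictionary.atoms[k]
        indices.append(k)
        weights.append(w)
        if epsilon is not None and np.linalg.norm(residual) <= epsilon:
            break
    return MPResult(
        selected_indices=indices,
        weights=np.asarray(weights),
        residual=residual,
        epsilon=float(np.linalg.norm(residual)),
    )


def mp1_score(
    x: np.ndarray,
    template_dict: MPDictionary,
    m_atoms: int = 5,
) -> float:
    """MP1 matching score: the residual norm after greedy decomposition.

    Lower is better — a segment well explained by the template atoms
    leaves little residual energy.  Classification ranks candidate classes
    by this score directly rather than by a feature distance.
    """
    return mp_decompose(x, template_dict, m_atoms=m_atoms).epsilon


def mp2_feature(
    x: np.ndarray,
    dictionary: MPDictionary,
    m_atoms: int = 5,
) -> np.ndarray:
    """MP2 feature: the length-D weight vector of the decomposition.

    Weights of the selected atoms sit at their dictionary indices, zeros
    elsewhere, so the feature length equals the dictionary size D
    regardless of how many atoms were selected.
    """
    result = mp_decompose(x, dictionary, m_atoms=m_atoms)
    f = np.zeros(dictionary.size)
    for k, w in zip(result.selected_indices, result.weights):
        f[k] += w
    return f


# --- permutation entropy ----------------------------------------------------


@dataclass(frozen=True)
class PEConfig:
    """Permutation-entropy parameters: window W, order m, lag tau (samples)."""

    W: int = 8
    m: int = 3
    tau: int = 1

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ValueError("pattern order m must be >= 2")
        if self.tau < 1:
            raise ValueError("lag tau must be >= 1")
        if self.W < (self.m - 1) * self.tau + 1:
            raise ValueError("window W must cover at least one ordinal pattern")

    @property
    def span(self) -> int:
        """Samples consumed beyond the window by the sliding-feature layout."""
        return self.W + self.tau * (self.m - 1)


def ordinal_pattern(window: np.ndarray) -> tuple[int, ...]:
    """Rank pattern of ``m`` samples under a decreasing-order relationship.

    Entry ``i`` is the rank of sample ``i`` when the samples are sorted in
    decreasing order (largest -> 1).  Ties are broken earlier-index-wins
    (stable sort), the standard Bandt-Pompe convention.  E.g. for
    (3, 1, 2) the pattern is (1, 3, 2).
    """
    window = np.asarray(window, dtype=float)
    if window.ndim != 1 or window.size < 2:
        raise ValueError("ordinal pattern needs a 1-D window of >= 2 samples")
    order = np.argsort(-window, kind="stable")
    ranks = np.empty(window.size, dtype=int)
    ranks[order] = np.arange(1, window.size + 1)
    return tuple(int(r) for r in ranks)


def permutation_entropy(window: np.ndarray, cfg: PEConfig) -> float:
    """Shannon entropy of the ordinal-pattern histogram of one window.

    The window of length W yields ``k = W - (m - 1) tau`` overlapping
    ordinal patterns; their relative frequencies ``p_i`` give
    ``H = sum p_i log(1 / p_i)`` in nats, with ``0 log(1/0) = 0``.
    H is 0 for a monotone window and at most ``log(m!)``.
    """
    window = np.asarray(window, dtype=float)
    if window.size < cfg.W:
        raise ValueError(f"window shorter than W={cfg.W}")
    window = window[: cfg.W]
    k = cfg.W - (cfg.m - 1) * cfg.tau
    counts = Counter(
        ordinal_pattern(window[s : s + (cfg.m - 1) * cfg.tau + 1 : cfg.tau])
        for s in range(k)
    )
    p = np.array(list(counts.values()), dtype=float) / k
    return float(-np.sum(p * np.log(p)))


def pe_feature(x: np.ndarray, cfg: PEConfig) -> np.ndarray:
    """Sliding-window permutation entropy over a length-N segment.

    The window advances sample by sample; the feature holds
    ``N - (W + tau (m - 1))`` entropies.
    """
    x = np.asarray(x, dtype=float)
    n_out = x.size - cfg.span
    if n_out < 1:
        raise ValueError(
            f"segment of {x.size} samples too short for W={cfg.W}, m={cfg.m}, tau={cfg.tau}"
        )
    return np.array([permutation_entropy(x[u : u + cfg.W], cfg) for u in range(n_out)])


# --- slope horizontal chain code --------------------------------------------


@dataclass(frozen=True)
class SHCCConfig:
    """Slope-chain-code parameter: number of resampled blocks G."""

    G: int = 32

    def __post_init__(self) -> None:
        if self.G < 2:
            raise ValueError("G must be > 1")


def shcc_resample(x: np.ndarray, cfg: SHCCConfig) -> tuple[np.ndarray, np.ndarray]:
    """Resample the (index, value) curve to G uniformly spaced points.

    Points are placed on a uniform grid along the index axis with both
    endpoints included; values are linearly interpolated.  Requires
    ``1 < G < N``.
    """
    y = np.asarray(x, dtype=float)
    n = y.size
    if not 1 < cfg.G < n:
        raise ValueError(f"require 1 < G < N (got G={cfg.G}, N={n})")
    grid = np.linspace(0.0, n - 1.0, cfg.G)
    return grid, np.interp(grid, np.arange(n), y)


def shcc_feature(x: np.ndarray, cfg: SHCCConfig) -> np.ndarray:
    """Slope chain code: G - 1 point-to-point slopes of the normalized curve.

    After resampling, both coordinates are min-max normalized to [0, 1]
    and the feature is the slope between consecutive points.  Min-max
    normalization makes the code invariant to amplitude scaling and offset
    of the input.  A constant segment has no shape to encode and is
    rejected.
    """
    xs, ys = shcc_resample(x, cfg)
    if ys.max() == ys.min():
        raise ValueError("constant signal: slope chain code is undefined")
    xn = (xs - xs.min()) / (xs.max() - xs.min())
    yn = (ys - ys.min()) / (ys.max() - ys.min())
    return np.diff(yn) / np.diff(xn)


# --- plot rasterization + SIFT descriptor -----------------------------------


@dataclass
class PlotImage:
    """Binary (0/255) raster of a 1-s signal plot."""

    pixels: np.ndarray          #: (h, w) uint8, row 0 at the bottom
    zero_row: float             #: image row of the signal's zero value
    delta: int                  #: horizontal magnification factor

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


def render_plot(x: np.ndarray, delta: int = 4) -> PlotImage:
    """Rasterize a 1-s segment into a binary black-and-white line plot.

    The segment is z-scored and magnified by ``delta``; the image is
    ``delta * Fs`` pixels wide (Fs = samples in the 1-s segment) and as
    tall as the peak-to-peak amplitude of the normalized trace (rounded up
    to whole pixels).  Sample ``n`` maps to column ``delta * n`` and to
    the row of its normalized value offset so that zero sits mid-range;
    consecutive samples are joined with Bresenham lines.  White is 255 on
    a 0 background.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("render_plot needs a 1-D segment of >= 2 samples")
    sigma = x.std()
    if sigma == 0:
        raise ValueError("constant signal cannot be rendered (sigma = 0)")
    if delta < 1:
        raise ValueError("magnification delta must be >= 1")
    xt = delta * (x - x.mean()) / sigma
    w = delta * x.size
    h = int(math.ceil(xt.max() - xt.min()))
    z = h / 2.0 - (xt.max() + xt.min()) / 2.0
    rows = np.clip(np.round(xt + z).astype(int), 0, h - 1)
    cols = delta * np.arange(x.size)

    pixels = np.zeros((h, w), dtype=np.uint8)
    pixels[rows, cols] = 255
    for i in range(x.size - 1):
        rr, cc = bresenham_line(rows[i], cols[i], rows[i + 1], cols[i + 1])
        pixels[rr, cc] = 255
    return PlotImage(pixels=pixels, zero_row=z, delta=delta)


@dataclass(frozen=True)
class SIFTConfig:
    """Descriptor geometry: 4x4 blocks x 8 orientations = 128 values."""

    n_blocks: int = 4
    n_orientations: int = 8
    smooth_sigma: float = 1.0   #: Gaussian pre-smoothing of the raster, pixels
    clamp: float = 0.2


def sift_descriptor(
    img: PlotImage | np.ndarray,
    cfg: SIFTConfig | None = None,
    stage: str = "final",
) -> np.ndarray:
    """Upright SIFT-style descriptor of the square patch at the plot center.

    The raster is Gaussian-smoothed, a ``min(w, h)``-sided patch centered
    on the image is cut (padding with background when needed), and each
    cell of a 4x4 grid contributes an 8-bin histogram of gradient
    orientations (equidistant angles 0..315 degrees) weighted by gradient
    magnitude.  The 128-vector is L2-normalized, clamped at 0.2 per
    component, and re-normalized.  A gradient-free patch yields the zero
    vector — there is never a division by zero.

    ``stage`` selects an intermediate product instead of the final
    descriptor: ``"histogram"`` (raw magnitude-weighted histograms),
    ``"normalized"`` (after the first L2 normalization) or ``"clamped"``
    (after componentwise clamping, before re-normalization).
    """
    if stage not in ("histogram", "normalized", "clamped", "final"):
        raise ValueError(f"unknown stage {stage!r}")
    cfg = cfg or SIFTConfig()
    pixels = img.pixels if isinstance(img, PlotImage) else np.asarray(img)
    if pixels.size == 0:
        raise ValueError("empty image")
    smoothed = ndimage.gaussian_filter(pixels.astype(float), sigma=cfg.smooth_sigma)

    h, w = smoothed.shape
    side = min(h, w)
    if side < cfg.n_blocks:
        pad_h = max(0, cfg.n_blocks - h)
        pad_w = max(0, cfg.n_blocks - w)
        smoothed = np.pad(smoothed, ((0, pad_h), (0, pad_w)))
        h, w = smoothed.shape
        side = min(h, w)
    r0 = (h - side) // 2
    c0 = (w - side) // 2
    patch = smoothed[r0 : r0 + side, c0 : c0 + side]

    gy, gx = np.gradient(patch)
    magnitude = np.hypot(gx, gy)
    angle = np.degrees(np.arctan2(gy, gx)) % 360.0
    bin_width = 360.0 / cfg.n_orientations
    bins = np.round(angle / bin_width).astype(int) % cfg.n_orientations

    edges = np.linspace(0, side, cfg.n_blocks + 1).astype(int)
    descriptor = np.zeros(cfg.n_blocks * cfg.n_blocks * cfg.n_orientations)
    pos = 0
    for i in range(cfg.n_blocks):
        for j in range(cfg.n_blocks):
            block = slice(edges[i], edges[i + 1]), slice(edges[j], edges[j + 1])
            descriptor[pos : pos + cfg.n_orientations] = np.bincount(
                bins[block].ravel(),
                weights=magnitude[block].ravel(),
                minlength=cfg.n_orientations,
            )
            pos += cfg.n_orientations

    if stage == "histogram":
        return descriptor
    norm = np.linalg.norm(descriptor)
    if norm == 0:
        return descriptor
    descriptor /= norm
    if stage == "normalized":
        return descriptor
    np.minimum(descriptor, cfg.clamp, out=descriptor)
    if stage == "clamped":
        return descriptor
    norm = np.linalg.norm(descriptor)
    return descriptor / norm if norm > 0 else descriptor


# --- control feature --------------------------------------------------------


def raw_feature(x: np.ndarray) -> np.ndarray:
    """Z-scored sample vector (control feature for the linear-margin SVM)."""
    x = np.asarray(x, dtype=float)
    sigma = x.std()
    if sigma == 0:
        raise ValueError("constant signal cannot be z-scored")
    return (x - x.mean()) / sigma


# --- dispatcher -------------------------------------------------------------


@dataclass(frozen=True)
class FeatureConfig:
    """Every feature tunable in one place (defaults used by the pipeline).

    ``shcc.G`` is clamped to ``N - 1`` for segments shorter than ``G + 1``
    samples (at the 16 Hz decoding rate a 1-s segment has only 16
    samples), so the chain code always remains well defined.
    """

    mp_atoms: int = 5
    pe: PEConfig = field(default_factory=PEConfig)
    shcc: SHCCConfig = field(default_factory=SHCCConfig)
    sift: SIFTConfig = field(default_factory=SIFTConfig)
    delta: int = 4
    pe_window_fraction: float = 0.5     #: W = fraction * N when pe.W is oversized


def extract_feature(
    x: np.ndarray,
    method: Method | str,
    cfg: FeatureConfig | None = None,
    mp2_dict: MPDictionary | None = None,
) -> np.ndarray:
    """Apply one feature extractor to a single-channel segment.

    MP1 has no feature-space embedding (classification uses its residual
    score directly) and is rejected here.
    """
    cfg = cfg or FeatureConfig()
    method = Method(method)
    x = np.asarray(x, dtype=float)
    if method is Method.MP2:
        if mp2_dict is None:
            mp2_dict = build_mp2_dictionary(x.size)
        return mp2_feature(x, mp2_dict, m_atoms=cfg.mp_atoms)
    if method is Method.PE:
        pe_cfg = cfg.pe
        if pe_cfg.span >= x.size:
            pe_cfg = PEConfig(
                W=max(int(x.size * cfg.pe_window_fraction), (pe_cfg.m - 1) * pe_cfg.tau + 1),
                m=pe_cfg.m,
                tau=pe_cfg.tau,
            )
        return pe_feature(x, pe_cfg)
    if method is Method.SHCC:
        shcc_cfg = cfg.shcc if cfg.shcc.G < x.size else SHCCConfig(G=x.size - 1)
        return shcc_feature(x, shcc_cfg)
    if method is Method.SIFT:
        return sift_descriptor(render_plot(x, delta=cfg.delta), cfg.sift)
    if method is Method.RAW:
        return raw_feature(x)
    raise ValueError("MP1 is score-based; use mp1_score with a template dictionary")
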