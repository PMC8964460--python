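"""Fixed-length feature descriptors computed from a PSSM evolutionary profile.

Five descriptors summarise an L x 20 profile independently of the sequence
length L, and are concatenated in a fixed order into one vector:

========== ===================================================== =======
segment    construction                                          length
========== ===================================================== =======
pse_pssm   column means of the row-standardised profile plus       40
           squared lag-difference terms (pseudo-PSSM, lag 1)
avblock    column means over 20 consecutive row blocks             400
           (~5% of the sequence each)
dwt        mean/sd/max/min of detail and approximation             640
           coefficients of a 4-level wavelet cascade per column
dct        top-left 20 x 20 block of the orthonormal 2-D DCT-II    400
hog        magnitude-weighted orientation histograms (10 bins      250
           in [0, pi)) over a 5 x 5 grid of the gradient field
========== ===================================================== =======

Default total: 1730 dimensions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt
import scipy.fft

from memdsn.errors import ConfigurationError
from memdsn.pssm_io import PSSM

SEGMENT_ORDER = ("pse_pssm", "avblock", "dwt", "dct", "hog")


@dataclass
class FeatureConfig:
    """Tunable parameters of the five extractors.

    Defaults reproduce the 40 + 400 + 640 + 400 + 250 = 1730-dimensional
    layout.  ``dwt_levels=4`` is the four-stage wavelet cascade;
    ``hog_grid_rows * hog_grid_cols = 25`` sub-matrices with
    ``hog_bins=10`` orientation channels each give the 250 HOG features.
    """

    pse_lag: int = 1
    wavelet_name: str = "db4"
    dwt_levels: int = 4
    dct_keep_rows: int = 20
    dct_keep_cols: int = 20
    hog_grid_rows: int = 5
    hog_grid_cols: int = 5
    hog_bins: int = 10
    hog_l2_normalize: bool = True
    hog_signed: bool = False

    def __post_init__(self) -> None:
        if self.pse_lag < 0:
            raise ConfigurationError("pse_lag must be >= 0")
        for name in ("dwt_levels", "dct_keep_rows", "dct_keep_cols",
                     "hog_grid_rows", "hog_grid_cols", "hog_bins"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if self.wavelet_name not in pywt.wavelist(kind="discrete"):
            raise ConfigurationError(f"unknown wavelet {self.wavelet_name!r}")

    def segment_lengths(self) -> dict[str, int]:
        return {
            "pse_pssm": 20 * (1 + self.pse_lag),
            "avblock": 400,
            "dwt": 20 * self.dwt_levels * 2 * 4,
            "dct": self.dct_keep_rows * self.dct_keep_cols,
            "hog": self.hog_grid_rows * self.hog_grid_cols * self.hog_bins,
        }

    @property
    def total_length(self) -> int:
        return sum(self.segment_lengths().values())


@dataclass
class NormalizedPSSM:
    """Row-standardised PSSM: each position's 20 scores have mean 0 and
    population standard deviation 1; rows constant in the source are all-zero."""

    values: np.ndarray
    source_id: str


@dataclass
class FeatureVector:
    """A flat feature vector plus the (name, start, length) layout of its segments."""

    values: np.ndarray
    layout: list[tuple[str, int, int]] = field(default_factory=list)

    def segment(self, name: str) -> np.ndarray:
        for seg, start, length in self.layout:
            if seg == name:
                return self.values[start:start + length]
        raise KeyError(name)


def normalize_pssm(pssm: PSSM) -> NormalizedPSSM:
    """Standardise each profile row over its 20 amino-acid scores.

    f(i,j) = (p(i,j) - mean_i) / sd_i with the population (divide-by-20)
    standard deviation; rows with zero spread map to all zeros.
    """
    p = np.asarray(pssm.scores, dtype=float)
    mean = p.mean(axis=1, keepdims=True)
    sd = p.std(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = (p - mean) / sd
    f[np.repeat(sd == 0, 20, axis=1)] = 0.0
    return NormalizedPSSM(values=f, source_id=pssm.id)


def pse_pssm_features(norm: NormalizedPSSM, lag: int = 1) -> np.ndarray:
    """Pseudo-PSSM descriptor: 20 column means of the standardised profile,
    then for each lag xi = 1..lag the 20 per-column mean squared differences
    (1/(L-xi)) * sum_i (f(i,j) - f(i+xi,j))^2, which retain some of the
    sequence-order information that plain column averaging discards.
    """
    f = norm.values
    L = f.shape[0]
    if L <= lag:
        raise ValueError(f"sequence length {L} must exceed lag {lag}")
    parts = [f.mean(axis=0)]
    for xi in range(1, lag + 1):
        diff = f[:-xi] - f[xi:]
        parts.append((diff ** 2).sum(axis=0) / (L - xi))
    return np.concatenate(parts)


def _block_bounds(n: int, blocks: int) -> np.ndarray:
    # round-half-up boundaries: block sizes differ by at most 1
    return np.floor(np.arange(blocks + 1) * n / blocks + 0.5).astype(int)


def avblock_features(pssm: PSSM) -> np.ndarray:
    """Averaging-block descriptor: the profile rows are cut into 20 consecutive
    blocks (each covering ~5% of the sequence) and each of the 20 columns is
    averaged within each block, giving 400 features in block-major order.
    Blocks left empty by very short sequences (L < 20) contribute zeros.
    """
    p = np.asarray(pssm.scores, dtype=float)
    L = p.shape[0]
    bounds = _block_bounds(L, 20)
    out = np.zeros((20, 20))
    for i in range(20):
        lo, hi = bounds[i], bounds[i + 1]
        if hi > lo:
            out[i] = p[lo:hi].mean(axis=0)
    return out.ravel()


def _symmetric_pad(x: np.ndarray, target: int) -> np.ndarray:
    if len(x) >= target:
        return x
    return np.pad(x, (0, target - len(x)), mode="symmetric")


def dwt_features(pssm: PSSM, cfg: FeatureConfig | None = None) -> np.ndarray:
    """Wavelet-cascade descriptor.

    Each of the 20 profile columns is treated as a 1-D signal and passed
    through a ``dwt_levels``-stage filter cascade (symmetric boundary
    extension; signals shorter than 2**levels are first reflect-padded to that
    length).  At every level the detail (high-pass) and approximation
    (low-pass) coefficient bands are summarised by mean, standard deviation,
    maximum and minimum.  Ordering: column-major, then level, detail before
    approximation, then the four statistics — 20 * levels * 2 * 4 values.
    """
    cfg = cfg or FeatureConfig()
    wavelet = pywt.Wavelet(cfg.wavelet_name)
    p = np.asarray(pssm.scores, dtype=float)
    out = []
    for j in range(20):
        signal = _symmetric_pad(p[:, j], 2 ** cfg.dwt_levels)
        approx = signal
        for _ in range(cfg.dwt_levels):
            approx, detail = pywt.dwt(approx, wavelet, mode="symmetric")
            for band in (detail, approx):
                out.extend((band.mean(), band.std(), band.max(), band.min()))
    return np.array(out)


def dct_features(pssm: PSSM, cfg: FeatureConfig | None = None) -> np.ndarray:
    """Low-frequency block of the orthonormal 2-D DCT-II of the profile.

    Signal energy concentrates in the top-left (low-frequency) corner of the
    coefficient matrix; the top-left ``dct_keep_rows x dct_keep_cols`` block
    is returned row-major, zero-padded when L < dct_keep_rows.
    """
    cfg = cfg or FeatureConfig()
    p = np.asarray(pssm.scores, dtype=float)
    coeffs = scipy.fft.dctn(p, type=2, norm="ortho")
    block = np.zeros((cfg.dct_keep_rows, cfg.dct_keep_cols))
    r = min(cfg.dct_keep_rows, coeffs.shape[0])
    c = min(cfg.dct_keep_cols, coeffs.shape[1])
    block[:r, :c] = coeffs[:r, :c]
    return block.ravel()


def hog_features(pssm: PSSM, cfg: FeatureConfig | None = None) -> np.ndarray:
    """Histogram-of-oriented-gradients descriptor of the profile "image".

    Gradients are central differences (one-sided at the edges) along the
    position axis and the amino-acid axis.  Orientations are folded into
    [0, pi) (profile gradients carry no meaningful sign symmetry) and binned
    into ``hog_bins`` equal bins weighted by gradient magnitude, over a
    ``hog_grid_rows x hog_grid_cols`` partition of the L x 20 field.
    Each sub-histogram is L2-normalised unless ``hog_l2_normalize`` is off.
    """
    cfg = cfg or FeatureConfig()
    p = np.asarray(pssm.scores, dtype=float)
    L = p.shape[0]
    if L < 2:
        raise ValueError("HOG needs at least 2 profile rows")
    g_vert, g_horiz = np.gradient(p)
    magnitude = np.hypot(g_vert, g_horiz)
    theta = np.arctan2(g_vert, g_horiz)
    period = 2 * np.pi if cfg.hog_signed else np.pi
    theta = np.mod(theta, period)
    bin_idx = np.minimum((theta / period * cfg.hog_bins).astype(int), cfg.hog_bins - 1)

    row_bounds = _block_bounds(L, cfg.hog_grid_rows)
    col_bounds = _block_bounds(20, cfg.hog_grid_cols)
    out = np.zeros((cfg.hog_grid_rows, cfg.hog_grid_cols, cfg.hog_bins))
    for i in range(cfg.hog_grid_rows):
        for j in range(cfg.hog_grid_cols):
            rs, re = row_bounds[i], row_bounds[i + 1]
            cs, ce = col_bounds[j], col_bounds[j + 1]
            if re <= rs or ce <= cs:
                continue
            hist = np.bincount(
                bin_idx[rs:re, cs:ce].ravel(),
                weights=magnitude[rs:re, cs:ce].ravel(),
                minlength=cfg.hog_bins,
            )
            if cfg.hog_l2_normalize:
                hist = hist / (np.linalg.norm(hist) + 1e-12)
            out[i, j] = hist
    return out.ravel()


def extract_all(pssm: PSSM, cfg: FeatureConfig | None = None) -> FeatureVector:
    """Concatenate the five descriptors in the fixed order
    pse_pssm | avblock | dwt | dct | hog, with segment layout metadata."""
    cfg = cfg or FeatureConfig()
    norm = normalize_pssm(pssm)
    segments = {
        "pse_pssm": pse_pssm_features(norm, cfg.pse_lag),
        "avblock": avblock_features(pssm),
        "dwt": dwt_features(pssm, cfg),
        "dct": dct_features(pssm, cfg),
        "hog": hog_features(pssm, cfg),
    }
    layout = []
    start = 0
    for name in SEGMENT_ORDER:
        layout.append((name, start, len(segments[name])))
        start += len(segments[name])
    return FeatureVector(values=np.concatenate([segments[n] for n in SEGMENT_ORDER]), layout=layout)


def feature_names(cfg: FeatureConfig | None = None) -> list[str]:
    """Column names ``segment.index`` for the concatenated vector."""
    cfg = cfg or FeatureConfig()
    names = []
    for seg in SEGMENT_ORDER:
        for i in range(cfg.segment_lengths()[seg]):
            names.append(f"{seg}.{i}")
    return names
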