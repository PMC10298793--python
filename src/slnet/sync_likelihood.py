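"""Synchronization Likelihood (SL) between channel pairs.

SL measures generalized synchronization between two signals: each signal is
delay-embedded into state space, a per-signal critical distance is chosen so
that a fixed fraction ``pref`` of time points inside a comparison window
count as recurrences, and SL is the conditional probability that a
recurrence of one signal coincides with a recurrence of the other. By
construction the chance level for independent signals equals ``pref`` and
identical signals score 1, so the index lives on a calibrated [0, 1] scale
regardless of signal amplitude.

The pairwise (bivariate) form is computed here, yielding the symmetric
channels x channels matrix that the graph stage thresholds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .recordings import BandDefinition, MultichannelRecording

__all__ = [
    "SLParameters",
    "SLMatrix",
    "SLDegenerateError",
    "delay_embed",
    "sl_pair",
    "sl_matrix",
    "default_sl_params",
]


class SLDegenerateError(ValueError):
    """Raised when window distances are degenerate (e.g. a constant channel)
    and no meaningful critical distance exists."""


@dataclass(frozen=True)
class SLParameters:
    """Embedding and window parameters of the SL estimator.

    Attributes
    ----------
    m : int
        Embedding dimension (>= 2 for state-space reconstruction; 1 reduces
        to raw samples and is allowed only in :func:`delay_embed`).
    lag : int
        Embedding delay in samples.
    w1 : int
        Inner window half-width (samples): excludes autocorrelation-dominated
        neighbours, |i - j| <= w1 never enters the comparison set.
    w2 : int
        Outer window half-width: only w1 < |i - j| < w2 is compared, keeping
        the estimate quasi-stationary.
    pref : float
        Reference recurrence probability; the fraction of window points
        counted as recurrences, and the chance level of the index.
    """

    m: int
    lag: int
    w1: int
    w2: int
    pref: float = 0.05

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ValueError("embedding dimension m must be >= 2")
        if self.lag < 1:
            raise ValueError("lag must be >= 1")
        if not 0 < self.w1 < self.w2:
            raise ValueError("need 0 < w1 < w2")
        if not 0 < self.pref < 1:
            raise ValueError("pref must lie in (0, 1)")
        if self.w2 - self.w1 < 2:
            raise ValueError("window w1 < |i-j| < w2 is empty")

    def n_embedded(self, n_samples: int) -> int:
        return n_samples - (self.m - 1) * self.lag

    def validate_for_length(self, n_samples: int) -> None:
        if self.n_embedded(n_samples) <= self.w2:
            raise ValueError(
                f"series of {n_samples} samples leaves "
                f"{self.n_embedded(n_samples)} embedded vectors, fewer than "
                f"outer window w2={self.w2}"
            )


@dataclass
class SLMatrix:
    """Symmetric channel x channel SL matrix for one epoch and band."""

    values: np.ndarray
    params: SLParameters
    band: str | None = None
    epoch_id: str | None = None
    channel_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("SL matrix must be square")
        if not np.allclose(v, v.T):
            raise ValueError("SL matrix must be symmetric")
        self.values = v

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]


def delay_embed(series: np.ndarray, m: int, lag: int) -> np.ndarray:
    """Time-delay embedding: vector i is (x_i, x_{i+lag}, ..., x_{i+(m-1)lag}).

    Returns an (N - (m-1)*lag) x m array. ``m=1`` returns the samples as
    column vectors.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be 1-D")
    if m < 1 or lag < 1:
        raise ValueError("m and lag must be positive")
    n_vec = x.size - (m - 1) * lag
    if n_vec < 1:
        raise ValueError(
            f"series of length {x.size} too short for m={m}, lag={lag}"
        )
    # stride trick: no copy
    return np.lib.stride_tricks.sliding_window_view(x, (m - 1) * lag + 1)[:, ::lag]


def _window_offsets(params: SLParameters) -> np.ndarray:
    """Signed offsets j - i admitted by the window w1 < |i-j| < w2."""
    pos = np.arange(params.w1 + 1, params.w2)
    return np.concatenate([-pos[::-1], pos])


def _hit_masks(embedded: np.ndarray, params: SLParameters) -> np.ndarray:
    """Recurrence ('hit') masks for a stack of embedded channels.

    Parameters
    ----------
    embedded : (n_channels, n_vec, m) array

    Returns
    -------
    hits : (n_channels, n_vec, n_offsets) boolean array; entry (c, i, o) is
        True when the distance from vector i of channel c to the vector at
        signed offset o falls within that channel's critical distance at i.
        Offsets falling outside the series are False.
    """
    emb = np.asarray(embedded, dtype=np.float64)
    n_ch, n_vec, _ = emb.shape
    offsets = _window_offsets(params)
    dist = np.full((n_ch, n_vec, offsets.size), np.nan, dtype=np.float32)
    for k, off in enumerate(offsets):
        o = int(off)
        if o > 0:
            d = np.linalg.norm(emb[:, o:, :] - emb[:, :-o, :], axis=2)
            dist[:, : n_vec - o, k] = d
        else:
            d = np.linalg.norm(emb[:, :o, :] - emb[:, -o:, :], axis=2)
            dist[:, -o:, k] = d

    valid = ~np.isnan(dist)
    n_valid = valid.sum(axis=2)
    if np.any(n_valid == 0):
        raise ValueError("empty comparison window")
    # per-reference critical distance: the k-th smallest window distance with
    # k chosen so the recurrence fraction equals pref (up to 1/|window|)
    order = np.sort(dist, axis=2)  # NaNs sort to the end
    k = np.clip(np.round(params.pref * n_valid).astype(int), 1, n_valid)
    eps = np.take_along_axis(order, (k - 1)[:, :, None], axis=2)[:, :, 0]

    span = np.nanmax(dist, axis=(1, 2)) - np.nanmin(dist, axis=(1, 2))
    degenerate = span <= 0
    if np.any(degenerate):
        raise SLDegenerateError(
            "constant window distances on channel(s) "
            f"{np.nonzero(degenerate)[0].tolist()}: no critical distance exists"
        )
    hits = dist <= eps[:, :, None]
    hits &= valid
    return hits


def _sl_from_hits(hits: np.ndarray) -> np.ndarray:
    """Symmetrized SL matrix from per-channel hit masks."""
    n_ch = hits.shape[0]
    flat = hits.reshape(n_ch, -1)
    co = flat.astype(np.float64) @ flat.T.astype(np.float64)
    own = flat.sum(axis=1).astype(np.float64)
    directed = co / own[:, None]  # row c: SL(c -> other)
    sl = 0.5 * (directed + directed.T)
    np.fill_diagonal(sl, 1.0)
    return sl


def sl_pair(x: np.ndarray, y: np.ndarray, params: SLParameters) -> float:
    """SL between two equal-length series (mean of the two directions)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D series of equal length")
    params.validate_for_length(x.size)
    emb = np.stack([delay_embed(x, params.m, params.lag),
                    delay_embed(y, params.m, params.lag)])
    hits = _hit_masks(emb, params)
    return float(_sl_from_hits(hits)[0, 1])


def sl_matrix(
    epoch: MultichannelRecording,
    params: SLParameters,
    band: str | None = None,
    epoch_id: str | None = None,
) -> SLMatrix:
    """Pairwise SL over all channel pairs of one (band-filtered) epoch.

    All channels are embedded once and hit masks reused across pairs, so the
    cost is linear in channels for the distance stage and quadratic only in
    the final co-recurrence counts.
    """
    if epoch.n_channels < 2:
        raise ValueError("need at least 2 channels")
    params.validate_for_length(epoch.n_samples)
    emb = np.stack(
        [delay_embed(epoch.data[c], params.m, params.lag)
         for c in range(epoch.n_channels)]
    )
    hits = _hit_masks(emb, params)
    values = _sl_from_hits(hits)
    return SLMatrix(values, params, band=band, epoch_id=epoch_id,
                    channel_labels=epoch.channel_labels)


def default_sl_params(
    band: BandDefinition,
    fs: float,
    n_samples: int,
    pref: float = 0.05,
    m_cap: int = 10,
) -> SLParameters:
    """Band-adapted SL parameters.

    The recipe ties the embedding to the band content: the delay samples a
    third of the highest period (``lag = round(fs / (3 high))``), the
    dimension spans the lowest period (``m = ceil(3 high / low) + 1``,
    capped at ``m_cap`` — the delta band's 0.01 Hz low edge would otherwise
    demand enormous embeddings), the inner window skips two embedding spans
    (``w1 = 2 lag (m-1)``) and the outer window admits ``round(10 / pref)``
    comparison points so roughly ten recurrences fall inside it. Values are
    relaxed (smaller m, then a shorter outer window) until the series length
    supports them; if nothing fits an error is raised.
    """
    if band.high >= fs / 2:
        raise ValueError("band exceeds Nyquist")
    lag = max(1, int(round(fs / (3.0 * band.high))))
    if band.low > 0:
        m = min(math.ceil(3.0 * band.high / band.low) + 1, m_cap)
    else:
        m = m_cap
    m = max(m, 2)
    win = int(round(10.0 / pref))

    while True:
        w1 = 2 * lag * (m - 1)
        w2 = w1 + win
        n_emb = n_samples - (m - 1) * lag
        if n_emb > w2:
            return SLParameters(m=m, lag=lag, w1=w1, w2=w2, pref=pref)
        if m > 2:
            m -= 1
            continue
        # last resort: shrink the outer window
        w1 = 2 * lag
        max_w2 = n_samples - lag - 1
        if max_w2 - w1 >= 2:
            return SLParameters(m=2, lag=lag, w1=w1, w2=max_w2, pref=pref)
        raise ValueError(
            f"series of {n_samples} samples too short for any SL "
            f"configuration in band {band.name}"
        )


def mean_sl(matrices: list[SLMatrix]) -> SLMatrix:
    """Element-wise mean of SL matrices (e.g. over a task's epochs)."""
    if not matrices:
        raise ValueError("no matrices to average")
    first = matrices[0]
    stack = np.stack([m.values for m in matrices])
    return SLMatrix(stack.mean(axis=0), first.params, band=first.band,
                    epoch_id=None, channel_labels=first.channel_labels)
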