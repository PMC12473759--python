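"""Spatiotemporal warping feature fusion: STW cell state and A-STW attention.

Per-window spatial features (pairwise-channel DTW distances, see
:mod:`astw.dtw_core`) are fused over time through a recursive cell state

    f_t = x_t + beta * c,      c <- f_t

where ``x_t`` is either the raw DTW feature vector of window t (STW) or the
cross-attended combination of the current and previous windows' feature
vectors (A-STW).  The scalar ``beta`` in [0, 1) controls the memory of the
cell; the default 0.75 gives a geometric memory with an asymptotic gain of
1 / (1 - beta) = 4 on constant input.

The attention step is learning-free scaled dot-product attention.  The
feature vector of length 3*P is reshaped to a 3 x P matrix whose rows are
the derivative-order blocks (raw, first difference, second difference) —
the attention "tokens".  With Q = current window, K = previous window,
V = Q:

    out = softmax(Q K^T / d_k) V

flattened back to length 3*P.  Each output row is a convex combination of
the rows of the *current* window, which bounds every output entry by the
column-wise extremes of the current features and damps isolated outlier
windows.  ``d_k`` defaults to P (a plain 1/d_k scaling; a 1/sqrt(d_k)
variant is available as a switch).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dtw_core import DtwConfig, pairwise_dtw_features
from .errors import ConfigError, ContractError
from .io_preprocess import WindowStream, expand_derivatives

N_DERIVATIVE_ORDERS = 3

CONDITIONS = ("emg", "emg+acc", "merged")
MODES = ("stw", "astw")


@dataclass(frozen=True)
class AttentionConfig:
    """Cross-attention settings: scaling denominator and its rule.

    ``d_k=None`` resolves to P, the number of channel pairs per derivative
    order.  ``sqrt_scale=True`` uses 1/sqrt(d_k) instead of 1/d_k.
    """

    d_k: float | None = None
    sqrt_scale: bool = False

    def resolve_dk(self, p: int) -> float:
        dk = float(self.d_k) if self.d_k is not None else float(p)
        if dk <= 0:
            raise ConfigError("d_k must be positive")
        return np.sqrt(dk) if self.sqrt_scale else dk


def attention_fuse(
    curr: np.ndarray, prev: np.ndarray, cfg: AttentionConfig | None = None
) -> np.ndarray:
    """Attend the current window's features with masks from the previous window."""
    cfg = cfg or AttentionConfig()
    curr = np.asarray(curr, dtype=float)
    prev = np.asarray(prev, dtype=float)
    if curr.shape != prev.shape or curr.ndim != 1:
        raise ContractError("curr and prev must be 1-D vectors of equal length")
    if curr.size % N_DERIVATIVE_ORDERS != 0:
        raise ContractError("feature length must be divisible by 3 (derivative orders)")
    p = curr.size // N_DERIVATIVE_ORDERS
    Q = curr.reshape(N_DERIVATIVE_ORDERS, p)
    K = prev.reshape(N_DERIVATIVE_ORDERS, p)
    S = Q @ K.T / cfg.resolve_dk(p)
    S = S - S.max(axis=1, keepdims=True)  # stabilized softmax
    W = np.exp(S)
    W /= W.sum(axis=1, keepdims=True)
    return (W @ Q).ravel()


def softmax_weights(
    curr: np.ndarray, prev: np.ndarray, cfg: AttentionConfig | None = None
) -> np.ndarray:
    """The 3x3 row-stochastic attention matrix (exposed for inspection)."""
    cfg = cfg or AttentionConfig()
    curr = np.asarray(curr, dtype=float)
    prev = np.asarray(prev, dtype=float)
    p = curr.size // N_DERIVATIVE_ORDERS
    Q = curr.reshape(N_DERIVATIVE_ORDERS, p)
    K = prev.reshape(N_DERIVATIVE_ORDERS, p)
    S = Q @ K.T / cfg.resolve_dk(p)
    S = S - S.max(axis=1, keepdims=True)
    W = np.exp(S)
    return W / W.sum(axis=1, keepdims=True)


@dataclass
class FusionState:
    """Recursive cell state ``c`` with memory factor ``beta`` and step index."""

    c: np.ndarray
    beta: float = 0.75
    t: int = 0

    def __post_init__(self):
        self.c = np.asarray(self.c, dtype=float)
        if not (0.0 <= self.beta < 1.0):
            raise ConfigError("beta must lie in [0, 1)")


def init_state(n_features: int, beta: float = 0.75) -> FusionState:
    """Fresh state with a zero cell vector (the t = 0 convention)."""
    return FusionState(c=np.zeros(n_features), beta=beta, t=0)


def stw_step(dtw_t: np.ndarray, state: FusionState):
    """One STW update: ``f_t = dtw_t + beta * c``; the cell becomes ``f_t``."""
    dtw_t = np.asarray(dtw_t, dtype=float)
    if dtw_t.shape != state.c.shape:
        raise ContractError("feature length must match the cell state")
    f_t = dtw_t + state.beta * state.c
    return f_t, FusionState(c=f_t, beta=state.beta, t=state.t + 1)


def astw_step(
    dtw_t: np.ndarray,
    dtw_prev: np.ndarray | None,
    state: FusionState,
    cfg: AttentionConfig | None = None,
):
    """One A-STW update: attended features plus the scaled cell state.

    For the first window (``dtw_prev is None``) the previous-window mask is
    the current vector itself (self-attention), which keeps the operator
    defined at t = 1.
    """
    dtw_t = np.asarray(dtw_t, dtype=float)
    if dtw_t.shape != state.c.shape:
        raise ContractError("feature length must match the cell state")
    prev = dtw_t if dtw_prev is None else np.asarray(dtw_prev, dtype=float)
    attended = attention_fuse(dtw_t, prev, cfg)
    f_t = attended + state.beta * state.c
    return f_t, FusionState(c=f_t, beta=state.beta, t=state.t + 1)


def fuse_stream(
    dtw_rows: np.ndarray,
    mode: str = "astw",
    beta: float = 0.75,
    cfg: AttentionConfig | None = None,
) -> np.ndarray:
    """Fuse a whole trial's (T x n) raw DTW feature rows into output rows.

    The cell state starts at zero and is never carried across trials.
    """
    dtw_rows = np.atleast_2d(np.asarray(dtw_rows, dtype=float))
    if mode not in MODES:
        raise ConfigError(f"mode must be one of {MODES}")
    T, n = dtw_rows.shape
    state = init_state(n, beta=beta)
    out = np.empty_like(dtw_rows)
    prev = None
    for t in range(T):
        if mode == "stw":
            out[t], state = stw_step(dtw_rows[t], state)
        else:
            out[t], state = astw_step(dtw_rows[t], prev, state, cfg)
            prev = dtw_rows[t]
    return out


def spatial_feature_rows(
    windows: np.ndarray, dtw_cfg: DtwConfig | None = None
) -> np.ndarray:
    """Raw (unfused) pairwise-DTW feature rows for a (T x l x C) window array."""
    rows = [
        pairwise_dtw_features(expand_derivatives(w), dtw_cfg) for w in windows
    ]
    return np.vstack(rows)


def extract_features(
    stream: WindowStream,
    condition: str = "emg+acc",
    mode: str = "astw",
    dtw_cfg: DtwConfig | None = None,
    beta: float = 0.75,
    attn_cfg: AttentionConfig | None = None,
):
    """Full per-trial feature extraction for one sensor condition.

    Conditions
    ----------
    ``emg``
        Only the EMG channels enter the spatial DTW stage (5 channels give
        rows of length 30).
    ``emg+acc``
        EMG and ACC channels enter together, so cross-modal channel pairs
        contribute DTW similarities (8 channels give rows of length 84).
    ``merged``
        The ablation baseline: the full pipeline is run separately on the
        EMG channels (30) and on the ACC axes (9) and the fused rows are
        concatenated (length 39).  No cross-modal DTW pair is ever formed.

    Returns ``(features, labels)`` with one row per window.
    """
    if condition not in CONDITIONS:
        raise ConfigError(f"condition must be one of {CONDITIONS}")
    if mode not in MODES:
        raise ConfigError(f"mode must be one of {MODES}")
    if len(stream) == 0:
        raise ContractError("window stream is empty")

    emg_idx = stream.emg_indices
    acc_idx = stream.acc_indices
    if condition in ("emg+acc", "merged") and acc_idx.size == 0:
        raise ConfigError(f"condition {condition!r} requires ACC channels")

    def _run(col_idx):
        rows = spatial_feature_rows(stream.windows[:, :, col_idx], dtw_cfg)
        return fuse_stream(rows, mode=mode, beta=beta, cfg=attn_cfg)

    if condition == "emg":
        feats = _run(emg_idx)
    elif condition == "emg+acc":
        feats = _run(np.arange(stream.windows.shape[2]))
    else:  # merged: per-modality pipelines, concatenated afterwards
        feats = np.hstack([_run(emg_idx), _run(acc_idx)])
    return feats, stream.labels.copy()
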