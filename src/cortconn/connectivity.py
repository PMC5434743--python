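"""Spectro-temporal causal connectivity from windowed MVAR models.

Given a sliding-window VAR model of M ROI signals, each window yields an
MVAR transfer matrix H(f) = [I - sum_k A_k e^{-i 2 pi f k / fs}]^{-1}, a
cross-spectral matrix S(f) = H Sigma H^H / fs, and the partial coherence
P(f) derived from the inverse spectrum.  The short-time direct directed
transfer function (SdDTF) combines the transfer matrix with the partial
coherence so that only direct causal paths survive, normalized jointly
over all node pairs and frequencies within the window:

    eta2[i <- j](f, t) = |H_ij|^2 |P_ij|^2 / sum_{f', k, l} |H_kl|^2 |P_kl|^2

This squared-magnitude convention makes the tensor sum to exactly 1 over
(sink, source, frequency) per window.  A ``literal`` convention with an
unsquared numerator is also available and recorded in the output metadata;
it differs only by a monotone per-window rescaling of each entry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mvar import WindowedMVAR, stability_index

__all__ = [
    "SpectralSet",
    "ConnectivityTensor",
    "transfer_matrix",
    "spectral_and_partial_coherence",
    "sddtf",
    "sddtf_from_model",
    "dtf_no_partial",
    "integrate_flow",
    "default_freq_grid",
]


@dataclass
class SpectralSet:
    """Per-window spectral quantities on a fixed frequency grid."""

    freqs: np.ndarray        # (F,)
    H_tf: np.ndarray         # (M, M, F) complex transfer matrices
    S: np.ndarray            # (M, M, F) complex cross-spectra
    P: np.ndarray            # (M, M, F) complex partial coherences


@dataclass
class ConnectivityTensor:
    """SdDTF values eta2[sink, source, frequency, window].

    Sinks (TO) index rows, causal sources (FROM) index columns.  Diagonal
    entries carry no physical meaning and are masked at reporting time.
    """

    values: np.ndarray               # (M, M, F, W) >= 0
    nodes: list[str]
    freqs: np.ndarray
    window_starts_s: np.ndarray
    pvals: np.ndarray | None = None
    mask: np.ndarray | None = None
    convention: str = "squared"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.window_starts_s = np.asarray(self.window_starts_s, dtype=float)
        M, M2, F, W = self.values.shape
        if M != M2 or len(self.nodes) != M:
            raise ValueError("node axis mismatch")
        if len(self.freqs) != F or len(self.window_starts_s) != W:
            raise ValueError("frequency/window axis mismatch")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    def offdiagonal_mask(self) -> np.ndarray:
        M = self.n_nodes
        return ~np.eye(M, dtype=bool)[:, :, None, None] | np.zeros_like(self.values, bool)


def default_freq_grid(low: float = 2.0, high: float = 50.0, step: float = 1.0) -> np.ndarray:
    return np.arange(low, high + 0.5 * step, step)


# ---------------------------------------------------------------------------
# spectral quantities
# ---------------------------------------------------------------------------


def transfer_matrix(A: np.ndarray, freqs: np.ndarray, fs: float, warn_unstable: bool = True) -> np.ndarray:
    """MVAR transfer matrices H(f) = [I - sum_k A_k e^{-i2pifk/fs}]^{-1}.

    Returns complex (M, M, F).
    """
    A = np.asarray(A, dtype=float)
    if A.ndim == 2:
        A = A[None]
    p, M, _ = A.shape
    freqs = np.asarray(freqs, dtype=float)
    if warn_unstable and stability_index(A) >= 0:
        import warnings

        warnings.warn("transfer matrix of an unstable VAR model", stacklevel=2)
    ks = np.arange(1, p + 1)
    # Abar(f) = I - sum_k A_k z^-k
    phase = np.exp(-2j * np.pi * np.outer(freqs, ks) / fs)  # (F, p)
    Abar = np.eye(M)[None] - np.einsum("fk,kij->fij", phase, A)
    H = np.empty((len(freqs), M, M), dtype=complex)
    for fi in range(len(freqs)):
        try:
            H[fi] = np.linalg.inv(Abar[fi])
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                f"transfer matrix singular at {freqs[fi]:.3f} Hz (unit root)"
            ) from exc
    return H.transpose(1, 2, 0)


def spectral_and_partial_coherence(H_tf: np.ndarray, Sigma: np.ndarray, fs: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Cross-spectral matrices and partial coherences per frequency.

    S(f) = H(f) Sigma H(f)^H / fs.  The partial coherence uses the standard
    inverse-spectrum form: with G = S^{-1},
    P_ij = G_ij / sqrt(G_ii G_jj), so |P_ij| <= 1 and P_ii = 1.  A singular
    spectrum is ridge-stabilized with a jitter proportional to its trace.
    """
    M, _, F = H_tf.shape
    Sigma = np.asarray(Sigma, dtype=float)
    S = np.einsum("ikf,kl,jlf->ijf", H_tf, Sigma, H_tf.conj()) / fs
    P = np.empty_like(S)
    for fi in range(F):
        Sf = S[:, :, fi]
        try:
            G = np.linalg.inv(Sf)
        except np.linalg.LinAlgError:
            jitter = 1e-10 * np.abs(np.trace(Sf)) / M
            G = np.linalg.inv(Sf + jitter * np.eye(M))
        d = np.sqrt(np.abs(np.diag(G)))
        P[:, :, fi] = G / np.outer(d, d)
    return S, P


# ---------------------------------------------------------------------------
# SdDTF
# ---------------------------------------------------------------------------


def _sddtf_window(H: np.ndarray, P: np.ndarray, convention: str) -> np.ndarray:
    """eta2 (M, M, F) for one window from its transfer matrix and partial
    coherence; joint normalization over all pairs (incl. diagonal) and
    frequencies."""
    hp2 = (np.abs(H) ** 2) * (np.abs(P) ** 2)
    denom = hp2.sum()
    if denom <= 0 or not np.isfinite(denom):
        raise ValueError("degenerate model: SdDTF normalization sum is zero or non-finite")
    if convention == "squared":
        return hp2 / denom
    if convention == "literal":
        return np.abs(H) * np.abs(P) / denom
    raise ValueError(f"unknown SdDTF convention: {convention!r}")


def sddtf(
    H_windows: list[np.ndarray],
    P_windows: list[np.ndarray],
    freqs: np.ndarray,
    window_starts_s: np.ndarray,
    nodes: list[str] | None = None,
    convention: str = "squared",
) -> ConnectivityTensor:
    """Assemble the SdDTF tensor from per-window transfer matrices and
    partial coherences (fixed frequency grid across windows)."""
    W = len(H_windows)
    if len(P_windows) != W:
        raise ValueError("H and P window lists must align")
    M = H_windows[0].shape[0]
    F = len(freqs)
    values = np.empty((M, M, F, W))
    for wi in range(W):
        values[:, :, :, wi] = _sddtf_window(H_windows[wi], P_windows[wi], convention)
    if nodes is None:
        nodes = [f"node{i}" for i in range(M)]
    return ConnectivityTensor(
        values=values,
        nodes=nodes,
        freqs=np.asarray(freqs, float),
        window_starts_s=np.asarray(window_starts_s, float),
        convention=convention,
    )


def sddtf_from_model(
    model: WindowedMVAR,
    freqs: np.ndarray | None = None,
    nodes: list[str] | None = None,
    convention: str = "squared",
) -> ConnectivityTensor:
    """SdDTF tensor of a fitted sliding-window MVAR model."""
    if freqs is None:
        freqs = default_freq_grid(high=min(50.0, model.fs / 2 - 1))
    H_list, P_list = [], []
    for A, Sigma in zip(model.A, model.Sigma):
        H = transfer_matrix(A, freqs, model.fs, warn_unstable=False)
        _, P = spectral_and_partial_coherence(H, Sigma, model.fs)
        H_list.append(H)
        P_list.append(P)
    return sddtf(H_list, P_list, freqs, model.window_starts_s, nodes=nodes, convention=convention)


def dtf_no_partial(model: WindowedMVAR, freqs: np.ndarray, nodes: list[str] | None = None) -> ConnectivityTensor:
    """Same normalization as SdDTF but without the partial-coherence weight.

    Used as a comparison baseline: indirect (cascade) paths survive here
    but are suppressed by the partial coherence in the SdDTF proper.
    """
    W = model.n_windows
    M = model.n_nodes
    F = len(freqs)
    values = np.empty((M, M, F, W))
    for wi, (A, Sigma) in enumerate(zip(model.A, model.Sigma)):
        H = transfer_matrix(A, freqs, model.fs, warn_unstable=False)
        h2 = np.abs(H) ** 2
        values[:, :, :, wi] = h2 / h2.sum()
    if nodes is None:
        nodes = [f"node{i}" for i in range(M)]
    return ConnectivityTensor(
        values=values, nodes=nodes, freqs=np.asarray(freqs, float),
        window_starts_s=model.window_starts_s, convention="dtf",
    )


def integrate_flow(
    tensor: ConnectivityTensor,
    band: tuple[float, float] | None = None,
    interval: tuple[float, float] | None = None,
) -> np.ndarray:
    """Mean flow matrix (M, M) over a frequency band and time interval.

    Band and interval are inclusive; the diagonal is set to zero (node
    in-flow = row sums, out-flow = column sums of the result).
    """
    f_sel = np.ones(len(tensor.freqs), bool)
    if band is not None:
        f_sel = (tensor.freqs >= band[0]) & (tensor.freqs <= band[1])
        if not f_sel.any():
            raise ValueError(f"no grid frequencies inside band {band}")
    w_sel = np.ones(len(tensor.window_starts_s), bool)
    if interval is not None:
        w_sel = (tensor.window_starts_s >= interval[0]) & (tensor.window_starts_s <= interval[1])
        if not w_sel.any():
            raise ValueError(f"no windows start inside interval {interval}")
    flow = tensor.values[:, :, f_sel][:, :, :, w_sel].mean(axis=(2, 3))
    np.fill_diagonal(flow, 0.0)
    return flow
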