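import numpy as np


def amari_index(P: np.ndarray) -> float:
    """Permutation/scale-invariant distance of P = W_est @ A_true from a
    scaled permutation matrix; 0 means perfect unmixing."""
    P = np.abs(P)
    n = P.shape[0]
    rows = (P / P.max(axis=1, keepdims=True)).sum(axis=1) - 1
    cols = (P / P.max(axis=0, keepdims=True)).sum(axis=0) - 1
    return float((rows.sum() + cols.sum()) / (2 * n * (n - 1)))
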