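"""Nonparametric significance for spectro-temporal connectivity.

The null hypothesis at every (sink, source, frequency, window) position is
that the evaluated condition's connectivity does not differ from that of an
ensemble in which control and test epochs are randomly mixed with equal
representation.  Per subject, R condition-mixed ensembles are drawn and the
full connectivity analysis is rerun on each, yielding R surrogate values
per position; surrogate replicates are averaged across subjects
(position-wise, by replicate index) and sorted, and the observed
cross-subject mean connectivity is ranked against them for an empirical
p-value.  Benjamini-Hochberg FDR control handles the mass of simultaneous
positions, and condition differences are reported on jointly masked
tensors (non-significant entries contribute zero).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SurrogateDistribution",
    "SignificanceResult",
    "permute_conditions",
    "build_surrogate",
    "empirical_pvalues",
    "fdr_bh",
    "condition_difference",
]


@dataclass
class SurrogateDistribution:
    """Cross-subject averaged, replicate-sorted surrogate values.

    ``values`` has the tensor axes plus a trailing replicate axis of length
    R, non-decreasing along that axis at every position.
    """

    values: np.ndarray
    R: int
    subject_count: int
    seed: int | None = None


@dataclass
class SignificanceResult:
    pvals: np.ndarray
    mask: np.ndarray
    alpha: float
    observed: np.ndarray | None = None


def permute_conditions(
    n_control: int,
    n_test: int,
    size: int,
    R: int,
    seed: int | np.random.Generator,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Index sets for R condition-mixed ensembles of ``size`` epochs.

    Each replicate draws, without replacement, half of its epochs from each
    condition (an odd ``size`` alternates which condition contributes the
    extra epoch across replicates).  Returns per replicate a pair
    ``(control_indices, test_indices)`` into the respective condition's
    epoch axis; the draw is deterministic given the seed.
    """
    if n_control < 1 or n_test < 1:
        raise ValueError("both conditions must be non-empty")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    half, odd = divmod(size, 2)
    out = []
    for r in range(R):
        from_control = half + (odd and r % 2 == 0)
        from_test = size - from_control
        if from_control > n_control or from_test > n_test:
            raise ValueError(
                f"replicate needs {from_control} control / {from_test} test epochs but "
                f"only {n_control} / {n_test} are available"
            )
        ic = rng.choice(n_control, size=from_control, replace=False)
        it = rng.choice(n_test, size=from_test, replace=False)
        out.append((np.sort(ic), np.sort(it)))
    return out


def build_surrogate(per_subject: list[np.ndarray], seed: int | None = None) -> SurrogateDistribution:
    """Average replicate tensors across subjects, then sort per position.

    ``per_subject`` holds one array per subject with a trailing replicate
    axis; replicate r of the average pairs each subject's r-th replicate
    (any fixed pairing is exchangeable under the null).
    """
    shapes = {a.shape for a in per_subject}
    if len(shapes) != 1:
        raise ValueError(f"subjects disagree on tensor axes: {sorted(shapes)}")
    stack = np.stack(per_subject, axis=0)
    avg = stack.mean(axis=0)
    avg.sort(axis=-1)
    return SurrogateDistribution(
        values=avg,
        R=avg.shape[-1],
        subject_count=len(per_subject),
        seed=seed,
    )


def empirical_pvalues(
    observed: np.ndarray,
    surrogate: SurrogateDistribution,
    tail: str = "two",
) -> np.ndarray:
    """Rank-based p-values of the observed group tensor against the
    surrogate.

    With r_hi = 1 + #(surrogate >= observed) and r_lo = 1 + #(surrogate <=
    observed), the one-sided (upper) p is r_hi/(R+1) and the two-sided p is
    2 min(r_hi, r_lo)/(R+1), capped at 1.
    """
    R = surrogate.R
    if R == 0:
        raise ValueError("empty surrogate distribution")
    obs = np.asarray(observed, dtype=float)
    if obs.shape != surrogate.values.shape[:-1]:
        raise ValueError(
            f"observed shape {obs.shape} does not match surrogate {surrogate.values.shape[:-1]}"
        )
    sur = surrogate.values
    # sorted along the last axis: use searchsorted per position
    flat = sur.reshape(-1, R)
    o = obs.ravel()
    n_le = np.empty(o.shape, dtype=int)
    n_ge = np.empty(o.shape, dtype=int)
    for i in range(flat.shape[0]):
        n_le[i] = np.searchsorted(flat[i], o[i], side="right")
        n_ge[i] = R - np.searchsorted(flat[i], o[i], side="left")
    r_hi = 1 + n_ge
    r_lo = 1 + n_le
    if tail == "two":
        p = 2.0 * np.minimum(r_hi, r_lo) / (R + 1)
    elif tail == "upper":
        p = r_hi / (R + 1)
    elif tail == "lower":
        p = r_lo / (R + 1)
    else:
        raise ValueError("tail must be 'two', 'upper' or 'lower'")
    return np.minimum(p, 1.0).reshape(obs.shape)


def fdr_bh(pvals: np.ndarray, alpha: float = 0.05, exclude: np.ndarray | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection mask at level ``alpha``.

    ``exclude`` marks positions (e.g. the tensor diagonal) that are neither
    tested nor counted in the comparison family.
    """
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1) & np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    mask = np.zeros(p.shape, dtype=bool)
    if exclude is None:
        valid = np.isfinite(p)
    else:
        valid = np.isfinite(p) & ~exclude
    pv = p[valid]
    m = pv.size
    if m == 0:
        return mask
    order = np.argsort(pv, kind="stable")
    thresh = alpha * (np.arange(1, m + 1)) / m
    below = pv[order] <= thresh
    if not below.any():
        return mask
    k = np.max(np.flatnonzero(below))
    rejected = np.zeros(m, dtype=bool)
    rejected[order[: k + 1]] = True
    mask[valid] = rejected
    return mask


def condition_difference(sig_test: SignificanceResult, sig_control: SignificanceResult) -> np.ndarray:
    """Masked difference map, test minus control.

    Non-significant entries contribute zero on their side, so an edge
    significant only in the test condition appears with its full (positive)
    test value.
    """
    if sig_test.pvals.shape != sig_control.pvals.shape:
        raise ValueError("test and control results have mismatched axes")
    if sig_test.observed is None or sig_control.observed is None:
        raise ValueError("SignificanceResult.observed required for a difference map")
    t = np.where(sig_test.mask, sig_test.observed, 0.0)
    c = np.where(sig_control.mask, sig_control.observed, 0.0)
    return t - c
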