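"""Cross-subject IC clustering for data-driven ROI definition.

Independent components pooled across subjects are described by a composite
feature vector -- scalp map, ERP, power spectrum, event-related spectral
perturbation (ERSP), inter-trial coherence (ITC), a downsampled ERP-image
and the equivalent-dipole location.  Each feature block is PCA-reduced and
z-scored to unit total variance (the blocks have no natural common scale),
the concatenation is PCA-reduced again to ``pca_dims`` dimensions, and
K-means groups the components across subjects.  Cluster centroids inherit a
mean dipole location, which is mapped to named cortical regions by
nearest-seed lookup; a cluster whose dipoles span both hemispheres may
legitimately receive two region labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.signal

from .forward import HeadModel
from .preprocess import DipoleFit

__all__ = [
    "ICFeatureVector",
    "ClusterResult",
    "compute_erp",
    "compute_spectrum",
    "compute_ersp",
    "compute_itc",
    "compute_erp_image",
    "build_feature_vectors",
    "kmeans_cluster",
    "assign_rois",
]


@dataclass
class ICFeatureVector:
    ic_id: tuple  # (subject, component)
    blocks: dict[str, np.ndarray]
    reduced: np.ndarray | None = None
    dipole_xyz: np.ndarray | None = None


@dataclass
class ClusterResult:
    assignments: dict          # ic_id -> cluster index
    centroids: np.ndarray      # (K, pca_dims)
    centroid_xyz: np.ndarray   # (K, 3)
    roi_labels: dict = field(default_factory=dict)  # cluster -> list of names
    inertia: float = np.nan
    sizes: np.ndarray | None = None


# ---------------------------------------------------------------------------
# per-IC features
# ---------------------------------------------------------------------------


def compute_erp(activations: np.ndarray) -> np.ndarray:
    """Trial-average time course of one component, (T,) from (T, N)."""
    acts = np.asarray(activations, dtype=float)
    if acts.ndim != 2:
        raise ValueError("activations must be (T, N)")
    return acts.mean(axis=1)


def compute_spectrum(activations: np.ndarray, fs: float, nperseg: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Welch power spectrum pooled over trials: (freqs, power in dB)."""
    acts = np.asarray(activations, dtype=float)
    T, N = acts.shape
    if nperseg is None:
        nperseg = min(T, 128)
    f, p = scipy.signal.welch(acts, fs=fs, nperseg=nperseg, axis=0)
    return f, 10.0 * np.log10(p.mean(axis=1) + 1e-300)


def _stft_windows(T: int, window_len: int, step: int) -> list[tuple[int, int]]:
    n = (T - window_len) // step + 1
    if n < 1:
        raise ValueError("window longer than the epoch")
    return [(i * step, i * step + window_len) for i in range(n)]


def _rolling_fft(acts: np.ndarray, window_len: int, step: int) -> np.ndarray:
    """Complex rolling-window FFT, (F, W, N) from (T, N)."""
    T, N = acts.shape
    wins = _stft_windows(T, window_len, step)
    taper = np.hanning(window_len)[:, None]
    out = []
    for lo, hi in wins:
        seg = acts[lo:hi] * taper
        out.append(np.fft.rfft(seg, axis=0))
    return np.stack(out, axis=1)  # (F, W, N)


def compute_ersp(
    activations: np.ndarray,
    fs: float,
    window_len: float = 0.25,
    step: float = 0.05,
    baseline: tuple[float, float] | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Event-related spectral perturbation, dB relative to baseline.

    Short-time Fourier power averaged over trials; each frequency row is
    expressed in dB relative to that frequency's mean power over the
    baseline windows (default: the first quarter of the epoch).

    Returns (freqs, window_start_times, ersp[F, W]).
    """
    acts = np.asarray(activations, dtype=float)
    T, N = acts.shape
    w = int(round(window_len * fs))
    s = max(int(round(step * fs)), 1)
    spec = _rolling_fft(acts, w, s)
    power = (np.abs(spec) ** 2).mean(axis=2)  # (F, W)
    freqs = np.fft.rfftfreq(w, 1.0 / fs)
    starts = np.array([lo for lo, _ in _stft_windows(T, w, s)]) / fs
    if baseline is None:
        baseline = (starts[0], starts[0] + max((starts[-1] - starts[0]) / 4.0, 1e-9))
    sel = (starts >= baseline[0]) & (starts <= baseline[1])
    if not sel.any():
        raise ValueError(f"baseline window {baseline} contains no STFT windows")
    base = power[:, sel].mean(axis=1, keepdims=True)
    ersp = 10.0 * np.log10((power + 1e-300) / (base + 1e-300))
    return freqs, starts, ersp


def compute_itc(
    activations: np.ndarray,
    fs: float,
    window_len: float = 0.25,
    step: float = 0.05,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Inter-trial coherence: magnitude of the trial-mean unit phasor.

    Values lie in [0, 1]; identical trials give exactly 1, and independent
    uniform phases give ~1/sqrt(N) in expectation magnitude.
    """
    acts = np.asarray(activations, dtype=float)
    T, N = acts.shape
    if N < 2:
        raise ValueError("ITC needs at least 2 trials")
    w = int(round(window_len * fs))
    s = max(int(round(step * fs)), 1)
    spec = _rolling_fft(acts, w, s)  # (F, W, N)
    mag = np.abs(spec)
    mag[mag == 0] = 1.0
    phasors = spec / mag
    itc = np.abs(phasors.mean(axis=2))
    freqs = np.fft.rfftfreq(w, 1.0 / fs)
    starts = np.array([lo for lo, _ in _stft_windows(T, w, s)]) / fs
    return freqs, starts, itc


def compute_erp_image(activations: np.ndarray, grid: tuple[int, int] = (16, 16)) -> np.ndarray:
    """Trials-by-time image downsampled to a fixed grid (for the feature
    block; resolution-independent across subjects)."""
    acts = np.asarray(activations, dtype=float).T  # (N, T)
    N, T = acts.shape
    rows = np.linspace(0, N, grid[0] + 1).astype(int)
    cols = np.linspace(0, T, grid[1] + 1).astype(int)
    img = np.empty(grid)
    for i in range(grid[0]):
        r0, r1 = rows[i], max(rows[i + 1], rows[i] + 1)
        for j in range(grid[1]):
            c0, c1 = cols[j], max(cols[j + 1], cols[j] + 1)
            img[i, j] = acts[r0:r1, c0:c1].mean()
    return img


# ---------------------------------------------------------------------------
# feature assembly
# ---------------------------------------------------------------------------


def _pca_reduce(X: np.ndarray, dims: int) -> np.ndarray:
    """PCA projection of rows of X onto the top ``dims`` components."""
    n, d = X.shape
    if n < dims:
        raise ValueError(
            f"{n} pooled ICs cannot support {dims} PCA dimensions; reduce pca_dims"
        )
    mu = X.mean(axis=0, keepdims=True)
    Xc = X - mu
    # SVD of the centered matrix: scores = U * S
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    k = min(dims, len(S))
    scores = U[:, :k] * S[:k]
    if k < dims:
        scores = np.pad(scores, ((0, 0), (0, dims - k)))
    return scores


def _zscore_block(X: np.ndarray) -> np.ndarray:
    """Scale a block to unit total variance (blocks carry no common units)."""
    sd = np.sqrt(np.mean(np.var(X, axis=0)))
    return X / sd if sd > 0 else X


def build_feature_vectors(
    ic_records: list[dict],
    model: HeadModel,
    fs: float,
    pca_dims: int = 10,
) -> list[ICFeatureVector]:
    """Composite reduced feature vectors for ICs pooled across subjects.

    Each record needs ``ic_id`` (subject, component), ``scalp_map`` (C,)
    and ``activations`` (T, N).  The dipole location is fitted here from
    the scalp map.  Per-block PCA to ``pca_dims``, unit-variance scaling,
    concatenation, then a final PCA back to ``pca_dims``; all transforms
    are fitted on the pooled set, so the pipeline is deterministic and
    permutation-equivariant in its inputs.
    """
    from .preprocess import fit_equivalent_dipole

    feats: list[ICFeatureVector] = []
    blocks_raw: dict[str, list[np.ndarray]] = {
        "scalp_map": [], "erp": [], "spectrum": [], "ersp": [], "itc": [],
        "erp_image": [], "dipole_xyz": [],
    }
    for rec in ic_records:
        acts = np.asarray(rec["activations"], dtype=float)
        scalp = np.asarray(rec["scalp_map"], dtype=float)
        fit = fit_equivalent_dipole(scalp, model)
        _, spec_db = compute_spectrum(acts, fs)
        _, _, ersp = compute_ersp(acts, fs)
        _, _, itc = compute_itc(acts, fs)
        blocks = {
            "scalp_map": scalp / (np.linalg.norm(scalp) or 1.0),
            "erp": compute_erp(acts),
            "spectrum": spec_db,
            "ersp": ersp.ravel(),
            "itc": itc.ravel(),
            "erp_image": compute_erp_image(acts).ravel(),
            "dipole_xyz": fit.location,
        }
        for name, v in blocks.items():
            blocks_raw[name].append(v)
        feats.append(ICFeatureVector(ic_id=rec["ic_id"], blocks=blocks, dipole_xyz=fit.location))
    n = len(feats)
    reduced_blocks = []
    for name, rows in blocks_raw.items():
        X = np.vstack([r.ravel() for r in rows])
        if name == "dipole_xyz":
            reduced_blocks.append(_zscore_block(X))  # already 3-dim, keep as-is
            continue
        dims = min(pca_dims, X.shape[1], n)
        if n < pca_dims:
            raise ValueError(
                f"{n} pooled ICs cannot support {pca_dims} PCA dimensions; reduce pca_dims"
            )
        reduced_blocks.append(_zscore_block(_pca_reduce(X, dims)))
    concat = np.hstack(reduced_blocks)
    final = _pca_reduce(concat, pca_dims)
    for i, fv in enumerate(feats):
        fv.reduced = final[i]
    return feats


# ---------------------------------------------------------------------------
# clustering and ROI labeling
# ---------------------------------------------------------------------------


def kmeans_cluster(
    features: list[ICFeatureVector],
    K: int = 14,
    seed: int = 0,
    n_restarts: int = 20,
) -> ClusterResult:
    """K-means over the reduced feature vectors (best of ``n_restarts``).

    Uses k-means++ seeding; the winning run minimizes within-cluster sum of
    squares.  Centroid dipole locations are the mean fitted-dipole
    coordinates of each cluster's members.
    """
    if K <= 0:
        raise ValueError("K must be positive")
    X = np.vstack([f.reduced for f in features])
    if X.shape[0] < K:
        raise ValueError(f"cannot form {K} clusters from {X.shape[0]} ICs")
    from sklearn.cluster import KMeans

    km = KMeans(n_clusters=K, n_init=n_restarts, random_state=seed)
    labels = km.fit_predict(X)
    xyz = np.vstack([f.dipole_xyz for f in features])
    centroid_xyz = np.vstack(
        [xyz[labels == k].mean(axis=0) if np.any(labels == k) else np.full(3, np.nan) for k in range(K)]
    )
    sizes = np.bincount(labels, minlength=K)
    return ClusterResult(
        assignments={f.ic_id: int(l) for f, l in zip(features, labels)},
        centroids=km.cluster_centers_,
        centroid_xyz=centroid_xyz,
        inertia=float(km.inertia_),
        sizes=sizes,
    )


def assign_rois(
    cluster: ClusterResult,
    model: HeadModel,
    features: list[ICFeatureVector] | None = None,
    bilateral_fraction: float = 0.25,
) -> dict[int, list[str]]:
    """Label each cluster with the nearest named region(s).

    The centroid's nearest ROI (by Euclidean distance to the region's mean
    gridpoint position) gives the primary label.  If the cluster's member
    dipoles split across hemispheres (at least ``bilateral_fraction`` on
    each side of the y = 0 plane) and the primary label belongs to a
    lateralized pair, the mirror region is added, so one cluster can
    support the inclusion of two ROIs.  Midline (pre-merged) regions keep a
    single label by construction.  A centroid outside the mesh bounding
    sphere still gets its nearest region, with a warning recorded.
    """
    roi_centers = {
        name: model.mesh.vertices[idx].mean(axis=0) for name, idx in model.roi_map.items()
    }
    names = list(roi_centers)
    centers = np.vstack([roi_centers[n] for n in names])
    labels: dict[int, list[str]] = {}
    xyz_by_cluster: dict[int, np.ndarray] = {}
    if features is not None:
        for f in features:
            k = cluster.assignments[f.ic_id]
            xyz_by_cluster.setdefault(k, [])
            xyz_by_cluster[k].append(f.dipole_xyz)
    r_max = np.linalg.norm(model.mesh.vertices, axis=1).max()
    for k, cxyz in enumerate(cluster.centroid_xyz):
        if np.any(np.isnan(cxyz)):
            labels[k] = []
            continue
        if np.linalg.norm(cxyz) > 1.5 * r_max:
            import warnings

            warnings.warn(f"cluster {k} centroid lies outside the source space; using nearest region")
        d = np.linalg.norm(centers - cxyz[None, :], axis=1)
        primary = names[int(np.argmin(d))]
        out = [primary]
        member_xyz = np.vstack(xyz_by_cluster[k]) if k in xyz_by_cluster else None
        if member_xyz is not None and len(member_xyz) >= 2 and primary.startswith(("L ", "R ")):
            frac_left = np.mean(member_xyz[:, 1] > 0)
            if min(frac_left, 1 - frac_left) >= bilateral_fraction:
                mirror = ("R " + primary[2:]) if primary.startswith("L ") else ("L " + primary[2:])
                if mirror in roi_centers:
                    out.append(mirror)
        labels[k] = out
    cluster.roi_labels = labels
    return labels
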