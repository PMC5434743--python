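"""cLORETA source localization with per-epoch data-driven regularization.

The inverse problem is Tikhonov-regularized least squares on the cortical
mesh: current density J minimizes ||Phi - K J||^2 + lambda^2 ||H J||^2 with
K the lead field and H the discrete surface Laplacian, giving the
closed-form transform

    T(lambda) = (K^T K + lambda^2 H^T H)^{-1} K^T,      J = T Phi.

:func:`cloreta_transform` evaluates this literally by a dense symmetric
solve.  :class:`CLoretaSolver` precomputes a substitution y = R J with
R^T R = H^T H (+ a tiny ridge handling the Laplacian's constant null
space) and an SVD of K R^{-1}, after which T(lambda), the influence matrix
K T(lambda), GCV scores and evidence-based (EM) refinement of lambda are
all cheap per epoch.  lambda is selected per epoch: a log-spaced GCV grid
search initializes it and an optional EM fixed point on the two variance
components (sensor noise vs. source prior) refines it, so spatial
regularization tracks per-epoch signal-to-noise.

Each ROI is collapsed to a representative signal by the max-power
heuristic: the gridpoint with the greatest mean squared current (pooled
over epochs by default) represents the region.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla

from .forward import HeadModel
from .io import EpochedEEG

__all__ = [
    "InverseOperator",
    "SourceActivation",
    "SourceActivationSet",
    "ROISignals",
    "cloreta_transform",
    "CLoretaSolver",
    "gcv_select_lambda",
    "em_refine_lambda",
    "localize_epoch",
    "localize_epochs",
    "maxpower_roi_signals",
]


@dataclass
class InverseOperator:
    T: np.ndarray                 # (G, C)
    lam: float
    gcv_curve: tuple[np.ndarray, np.ndarray] | None = None
    em_iterations: int = 0


@dataclass
class SourceActivation:
    """Current density of one epoch: J (G, T) plus the lambda used."""

    J: np.ndarray
    lam: float


@dataclass
class SourceActivationSet:
    """Localized currents of all epochs, restricted to a gridpoint subset."""

    J: np.ndarray            # (G_sel, T, N)
    gridpoints: np.ndarray   # (G_sel,) global vertex indices
    lambdas: np.ndarray      # (N,)
    fs: float
    condition: np.ndarray | None = None


@dataclass
class ROISignals:
    """Representative current time series per ROI."""

    data: np.ndarray                  # (M, T, N)
    roi_names: list[str]
    chosen_gridpoint: dict
    fs: float
    condition: np.ndarray | None = None


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------


def cloreta_transform(K: np.ndarray, H_lap: np.ndarray, lam: float) -> np.ndarray:
    """Literal evaluation of T = (K^T K + lambda^2 H^T H)^{-1} K^T.

    Dense symmetric solve; raises on a singular system (lambda = 0 with an
    underdetermined lead field needs lambda > 0).
    """
    K = np.asarray(K, dtype=float)
    H = np.asarray(H_lap, dtype=float)
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    M = K.T @ K + lam**2 * (H.T @ H)
    try:
        c, low = sla.cho_factor(M)
        return sla.cho_solve((c, low), K.T)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "normal-equation matrix is singular; with more gridpoints than "
            "channels a regularization lambda > 0 is required"
        ) from exc


class CLoretaSolver:
    """Precomputed machinery for fast per-epoch cLORETA solves.

    Parameters
    ----------
    K : (C, G) lead field.
    H_lap : (G, G) surface Laplacian.
    ridge : float
        Relative weight of an identity (minimum-norm) term added to the
        Laplacian penalty: the prior precision is H^T H + eps I with
        ``eps = ridge * trace(H^T H)/G``.  The pure Laplacian penalty is a
        semi-norm -- its constant null space is unpenalized, so on a closed
        source surface strong regularization collapses the solution onto a
        spatially uniform field that fits the data freely.  The weak
        minimum-norm term makes the source prior proper and removes that
        pathology; set ``ridge`` near zero to reproduce the literal
        semi-norm transform.
    """

    def __init__(self, K: np.ndarray, H_lap: np.ndarray, ridge: float = 1e-2):
        K = np.asarray(K, dtype=float)
        H = np.asarray(H_lap, dtype=float)
        C, G = K.shape
        L = H.T @ H
        eps = ridge * np.trace(L) / G
        R = np.linalg.cholesky(L + eps * np.eye(G)).T  # upper: L + epsI = R^T R
        Kt = sla.solve_triangular(R, K.T, lower=False, trans="T").T  # K R^{-1}
        U, s, Vt = np.linalg.svd(Kt, full_matrices=False)
        self.C, self.G = C, G
        self.R = R
        self.U = U          # (C, r)
        self.s = s          # (r,)
        self.Vt = Vt        # (r, G)
        self.rank = len(s)

    # -- operators ---------------------------------------------------------

    def transform(self, lam: float) -> np.ndarray:
        """T(lambda), shape (G, C)."""
        filt = self.s / (self.s**2 + lam**2)
        W = self.Vt.T * filt[None, :]
        T = sla.solve_triangular(self.R, W, lower=False) @ self.U.T
        return T

    def apply(self, lam: float, phi: np.ndarray) -> np.ndarray:
        """J = T(lambda) Phi without forming T."""
        z = self.U.T @ phi
        z = z * (self.s / (self.s**2 + lam**2))[:, None]
        return sla.solve_triangular(self.R, self.Vt.T @ z, lower=False)

    def influence_diag(self, lam: float) -> np.ndarray:
        return self.s**2 / (self.s**2 + lam**2)

    def lambda_grid(self, n_points: int = 30, span: tuple[float, float] = (1e-4, 1e2)) -> np.ndarray:
        """Log-spaced lambda grid spanning the singular spectrum of the
        transformed lead field."""
        scale = float(np.median(self.s))
        return scale * np.logspace(np.log10(span[0]), np.log10(span[1]), n_points)

    # -- GCV ---------------------------------------------------------------

    def gcv(self, phi: np.ndarray, grid: np.ndarray) -> tuple[float, np.ndarray]:
        """Generalized cross-validation over a lambda grid.

        GCV(lambda) = ||(I - K T) Phi||_F^2 / trace(I - K T)^2.
        Returns (grid minimizer, GCV values).
        """
        phi = np.atleast_2d(np.asarray(phi, dtype=float))
        if not np.any(phi):
            raise ValueError("all-zero epoch: GCV undefined")
        z = self.U.T @ phi                       # (r, T)
        z2 = np.sum(z**2, axis=1)
        total = np.sum(phi**2)
        outside = total - np.sum(z2)             # energy outside the U-span
        n_t = phi.shape[1]
        scores = np.empty(len(grid))
        for i, lam in enumerate(grid):
            w = self.influence_diag(lam)
            rss = outside + np.sum((1.0 - w) ** 2 * z2)
            tr = self.C - np.sum(w)
            scores[i] = rss / n_t / max(tr, 1e-300) ** 2 * self.C**2
        best = int(np.argmin(scores))
        return float(grid[best]), scores

    # -- EM refinement -----------------------------------------------------

    def evidence(self, phi: np.ndarray, sigma2: float, tau2: float) -> float:
        """Gaussian model evidence log p(Phi | sigma2, tau2).

        Columns of Phi are i.i.d. N(0, sigma2 I + tau2 Kt Kt^T) under the
        hierarchical model (source prior confined to the identified
        subspace)."""
        phi = np.atleast_2d(phi)
        C, n_t = phi.shape
        z = self.U.T @ phi
        z2 = np.sum(z**2, axis=1)
        total = np.sum(phi**2)
        outside = total - np.sum(z2)
        var = sigma2 + tau2 * self.s**2
        ll = -0.5 * n_t * (C * np.log(2 * np.pi) + np.sum(np.log(var)) + (C - self.rank) * np.log(sigma2))
        ll -= 0.5 * (np.sum(z2 / var) + outside / sigma2)
        return float(ll)

    def em_refine(
        self,
        phi: np.ndarray,
        lam0: float,
        tol: float = 1e-4,
        max_iter: int = 50,
    ) -> tuple[float, int, bool, list[float]]:
        """Fixed-point iteration on the two variance components.

        lambda^2 is the sensor-noise to source-prior variance ratio; each
        step updates (sigma2, tau2) from the posterior moments of the
        current solution.  Returns (lambda, iterations, converged,
        evidence trace); the evidence is non-decreasing by EM construction.
        """
        phi = np.atleast_2d(np.asarray(phi, dtype=float))
        if lam0 <= 0:
            raise ValueError("lam0 must be > 0")
        n_t = phi.shape[1]
        z = self.U.T @ phi
        z2 = np.sum(z**2, axis=1)
        total = np.sum(phi**2)
        outside = total - np.sum(z2)
        s2 = self.s**2
        r = self.rank
        C = self.C
        # initialize variance components consistent with lam0
        lam = lam0
        sigma2 = max(np.mean((1.0 - self.influence_diag(lam)) * z2 / n_t), 1e-12)
        tau2 = sigma2 / lam**2
        ev = [self.evidence(phi, sigma2, tau2)]
        it = 0
        converged = False
        for it in range(1, max_iter + 1):
            lam2 = sigma2 / tau2
            gain = self.s / (s2 + lam2)             # posterior mean filter for y
            yhat2 = gain**2 * z2                    # sum over time of yhat_i^2
            post_var_y = sigma2 / (s2 + lam2)       # per time sample
            # E||Phi - Kt y||^2
            resid = np.sum((1.0 - self.s * gain) ** 2 * z2) + outside
            e_resid = resid + n_t * np.sum(s2 * post_var_y)
            sigma2_new = e_resid / (C * n_t)
            # E||y||^2 on the identified subspace
            e_y = np.sum(yhat2) + n_t * np.sum(post_var_y)
            tau2_new = e_y / (r * n_t)
            rel = abs(np.sqrt(sigma2_new / tau2_new) - np.sqrt(sigma2 / tau2)) / np.sqrt(sigma2 / tau2)
            sigma2, tau2 = max(sigma2_new, 1e-300), max(tau2_new, 1e-300)
            ev.append(self.evidence(phi, sigma2, tau2))
            if rel < tol:
                converged = True
                break
        if not converged and max_iter > 1:
            import warnings

            warnings.warn(f"EM lambda refinement did not converge in {max_iter} iterations", stacklevel=2)
        return float(np.sqrt(sigma2 / tau2)), it, converged, ev


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------


def make_inverse_operator(
    K: np.ndarray,
    H_lap: np.ndarray,
    phi_epoch: np.ndarray,
    mode: str = "gcv+em",
    solver: CLoretaSolver | None = None,
) -> InverseOperator:
    """Data-driven inverse operator for one epoch: GCV-initialized lambda,
    optional EM refinement, and the resulting transform matrix."""
    if solver is None:
        solver = CLoretaSolver(K, H_lap)
    grid = solver.lambda_grid()
    lam, scores = solver.gcv(phi_epoch, grid)
    iters = 0
    if mode == "gcv+em":
        lam, iters, _, _ = solver.em_refine(phi_epoch, lam)
    elif mode != "gcv":
        raise ValueError("mode must be 'gcv' or 'gcv+em'")
    return InverseOperator(
        T=solver.transform(lam), lam=lam, gcv_curve=(grid, scores), em_iterations=iters
    )


def gcv_select_lambda(
    K: np.ndarray,
    H_lap: np.ndarray,
    phi_epoch: np.ndarray,
    grid: np.ndarray | None = None,
    solver: CLoretaSolver | None = None,
) -> tuple[float, tuple[np.ndarray, np.ndarray]]:
    """Grid minimizer of GCV(lambda) for one epoch; returns (lambda0,
    (grid, scores))."""
    if solver is None:
        solver = CLoretaSolver(K, H_lap)
    if grid is None:
        grid = solver.lambda_grid()
    grid = np.asarray(grid, dtype=float)
    lam, scores = solver.gcv(phi_epoch, grid)
    return lam, (grid, scores)


def em_refine_lambda(
    K: np.ndarray,
    H_lap: np.ndarray,
    phi_epoch: np.ndarray,
    lambda0: float,
    tol: float = 1e-4,
    max_iter: int = 50,
    solver: CLoretaSolver | None = None,
) -> float:
    if solver is None:
        solver = CLoretaSolver(K, H_lap)
    lam, _, _, _ = solver.em_refine(phi_epoch, lambda0, tol=tol, max_iter=max_iter)
    return lam


def localize_epoch(T: np.ndarray, phi_epoch: np.ndarray, lam: float = np.nan) -> SourceActivation:
    """J = T Phi for one epoch (linear in Phi)."""
    T = np.asarray(T, dtype=float)
    phi = np.asarray(phi_epoch, dtype=float)
    if T.shape[1] != phi.shape[0]:
        raise ValueError(f"shape mismatch: T is {T.shape}, Phi is {phi.shape}")
    return SourceActivation(J=T @ phi, lam=lam)


def localize_epochs(
    eeg: EpochedEEG,
    model: HeadModel,
    lam_mode: str = "gcv+em",
    gridpoints: np.ndarray | None = None,
    solver: CLoretaSolver | None = None,
    grid_points: int = 30,
) -> SourceActivationSet:
    """Per-epoch cLORETA localization of an epoched recording.

    ``lam_mode``: ``gcv`` (grid search only), ``gcv+em`` (EM refinement,
    default), or a float-valued string for a fixed lambda.  ``gridpoints``
    restricts the stored currents to a vertex subset (e.g. the union of all
    ROI vertices) to bound memory; localization itself always uses the full
    operator.
    """
    if solver is None:
        solver = CLoretaSolver(model.K, model.H_lap)
    if gridpoints is None:
        gridpoints = np.arange(model.n_gridpoints)
    gridpoints = np.asarray(gridpoints, dtype=int)
    C, T, N = eeg.data.shape
    grid = solver.lambda_grid(grid_points)
    J = np.empty((len(gridpoints), T, N))
    lambdas = np.empty(N)
    fixed = None
    if lam_mode not in ("gcv", "gcv+em"):
        fixed = float(lam_mode)
    Rsub = None
    for n in range(N):
        phi = eeg.data[:, :, n]
        if fixed is not None:
            lam = fixed
        else:
            lam, _ = solver.gcv(phi, grid)
            if lam_mode == "gcv+em":
                lam, _, _, _ = solver.em_refine(phi, lam)
        lambdas[n] = lam
        J[:, :, n] = solver.apply(lam, phi)[gridpoints]
    return SourceActivationSet(
        J=J, gridpoints=gridpoints, lambdas=lambdas, fs=eeg.fs, condition=eeg.condition
    )


def maxpower_roi_signals(
    activations: SourceActivationSet,
    roi_map: dict[str, np.ndarray],
    scope: str = "per_subject",
) -> ROISignals:
    """Collapse each ROI to the time series of its maximum-power gridpoint.

    Power is the mean squared current per gridpoint.  With
    ``scope="per_subject"`` (default) power is pooled over all epochs and a
    single gridpoint represents the ROI in every epoch, keeping the network
    node fixed across the trial ensemble; ``scope="per_epoch"`` re-selects
    the gridpoint independently per epoch.  Ties break to the lowest vertex
    index.
    """
    if scope not in ("per_subject", "per_epoch"):
        raise ValueError("scope must be 'per_subject' or 'per_epoch'")
    pos = {g: i for i, g in enumerate(activations.gridpoints)}
    names = list(roi_map)
    Gsel, T, N = activations.J.shape
    data = np.empty((len(names), T, N))
    chosen: dict = {}
    for ri, name in enumerate(names):
        verts = np.asarray(sorted(roi_map[name]))
        if verts.size == 0:
            raise ValueError(f"ROI {name} is empty")
        missing = [v for v in verts if v not in pos]
        if missing:
            raise ValueError(f"ROI {name} vertices {missing[:3]}... not in the stored gridpoint subset")
        rows = np.asarray([pos[v] for v in verts])
        if scope == "per_subject":
            power = np.mean(activations.J[rows] ** 2, axis=(1, 2))
            best = int(np.argmax(power))  # argmax takes the first (lowest index) on ties
            chosen[name] = int(verts[best])
            data[ri] = activations.J[rows[best]]
        else:
            power = np.mean(activations.J[rows] ** 2, axis=1)  # (n_verts, N)
            best = np.argmax(power, axis=0)
            chosen[name] = verts[best].astype(int)
            for n in range(N):
                data[ri, :, n] = activations.J[rows[best[n]], :, n]
    return ROISignals(
        data=data,
        roi_names=names,
        chosen_gridpoint=chosen,
        fs=activations.fs,
        condition=activations.condition,
    )
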