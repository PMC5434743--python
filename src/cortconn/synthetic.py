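"""Synthetic multi-subject, two-condition EEG with known directed coupling.

Every downstream stage of the pipeline is validated against cohorts built
here: stable time-varying VAR source dynamics with known directed,
frequency-band-specific coupling among ROI nodes, projected to scalp
channels through the spherical lead field, plus white sensor noise and
optional stereotyped artifact components (blinks, spiking channels).

Coupling schedules are piecewise-constant in time, aligned by default to a
planning/execution split at 0.5 s after the event, so condition contrasts
take the form of edges that appear, vanish or change strength between task
phases.  Both conditions share the same node set (the same ROIs); the
contrast lives entirely in the coefficient schedules.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .forward import HeadModel
from .io import CONTROL, TEST, EpochedEEG

__all__ = [
    "Coupling",
    "GroundTruthNetwork",
    "SyntheticSubject",
    "oscillator_coeffs",
    "simulate_var_sources",
    "project_to_channels",
    "add_artifact_components",
    "generate_cohort",
    "default_networks",
    "default_roi_assignment",
]

#: source dipole moment scale: 10 nA*m, a typical effective ECD magnitude
SOURCE_MOMENT_AM = 1e-8
BURNIN_FACTOR = 10


class StabilityError(ValueError):
    """The requested VAR process is not stable (spectral radius >= 1)."""


@dataclass
class Coupling:
    """One directed edge: ``source -> sink`` at a given lag.

    ``schedule`` lists ``(start_s, coefficient)`` breakpoints; the
    coefficient in force at epoch time t is that of the last breakpoint at
    or before t.  A single-element schedule gives a static edge.
    """

    source: int
    sink: int
    lag: int
    schedule: list[tuple[float, float]]

    def coeff_at(self, t: float) -> float:
        c = 0.0
        for start, val in self.schedule:
            if t >= start - 1e-12:
                c = val
        return c


@dataclass
class GroundTruthNetwork:
    n_nodes: int
    couplings: list[Coupling]
    noise_cov: np.ndarray
    order: int

    def __post_init__(self) -> None:
        self.noise_cov = np.asarray(self.noise_cov, dtype=float)
        if self.noise_cov.shape != (self.n_nodes, self.n_nodes):
            raise ValueError("noise_cov must be (M, M)")
        if np.max(np.abs(self.noise_cov - self.noise_cov.T)) > 1e-12:
            raise ValueError("noise_cov must be symmetric")
        if np.min(np.linalg.eigvalsh(self.noise_cov)) <= 0:
            raise ValueError("noise_cov must be positive definite")
        for c in self.couplings:
            if not (1 <= c.lag <= self.order):
                raise ValueError(f"coupling lag {c.lag} outside model order {self.order}")
            if not (0 <= c.source < self.n_nodes and 0 <= c.sink < self.n_nodes):
                raise ValueError("coupling node index out of range")

    def coefficients_at(self, t: float) -> np.ndarray:
        """Stacked coefficient matrices A (order, M, M) in force at time t."""
        A = np.zeros((self.order, self.n_nodes, self.n_nodes))
        for c in self.couplings:
            A[c.lag - 1, c.sink, c.source] += c.coeff_at(t)
        return A

    def breakpoints(self) -> np.ndarray:
        times = sorted({s for c in self.couplings for s, _ in c.schedule})
        return np.asarray(times if times else [0.0])

    def check_stability(self) -> None:
        from .mvar import stability_index

        for t in self.breakpoints():
            idx = stability_index(self.coefficients_at(t))
            if idx >= 0:
                raise StabilityError(
                    f"coefficient set at t={t:.3f}s has stability index {idx:.4f} >= 0"
                )

    def jittered(self, jitter: float, rng: np.random.Generator, max_tries: int = 50) -> "GroundTruthNetwork":
        """Multiplicatively perturb all coupling coefficients by N(1, jitter).

        Draws are rejected and resampled if the perturbed network is
        unstable in any schedule segment.
        """
        if jitter == 0:
            return self
        for _ in range(max_tries):
            new = [
                replace(c, schedule=[(s, v * (1.0 + jitter * rng.standard_normal())) for s, v in c.schedule])
                for c in self.couplings
            ]
            cand = GroundTruthNetwork(self.n_nodes, new, self.noise_cov, self.order)
            try:
                cand.check_stability()
                return cand
            except StabilityError:
                continue
        raise StabilityError(f"could not draw a stable jittered network in {max_tries} tries")


@dataclass
class SyntheticSubject:
    eeg: EpochedEEG
    true_sources: np.ndarray  # (M, T, N)
    roi_assignment: dict[int, str]
    head_model: HeadModel
    seed: int
    net_control: GroundTruthNetwork = None
    net_test: GroundTruthNetwork = None


def oscillator_coeffs(f0: float, fs: float, rho: float = 0.8) -> tuple[float, float]:
    """AR(2) self-coupling (lag-1, lag-2) with spectral peak near f0 Hz."""
    a1 = 2.0 * rho * np.cos(2.0 * np.pi * f0 / fs)
    a2 = -(rho**2)
    return a1, a2


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------


def simulate_var_sources(
    net: GroundTruthNetwork,
    T: int,
    N: int,
    fs: float,
    seed: int | np.random.Generator,
    t0: float = 0.0,
) -> np.ndarray:
    """Simulate N independent trials of the (time-varying) VAR process.

    Returns (M, T, N).  Each trial starts from a burn-in of ``10 * order``
    samples generated with the first schedule segment's coefficients, which
    is discarded.  ``t0`` is the epoch time of the first retained sample.
    """
    if T <= BURNIN_FACTOR * net.order:
        raise ValueError(f"T must exceed {BURNIN_FACTOR} * order = {BURNIN_FACTOR * net.order}")
    net.check_stability()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    M, p = net.n_nodes, net.order
    burn = BURNIN_FACTOR * p
    L = np.linalg.cholesky(net.noise_cov)
    # precompute coefficient stacks per retained sample (piecewise constant)
    times = t0 + np.arange(T) / fs
    A_t = np.empty((T, p, M, M))
    bps = net.breakpoints()
    A_cache = {t: net.coefficients_at(t) for t in bps}
    seg = np.searchsorted(bps, times + 1e-12) - 1
    seg = np.clip(seg, 0, len(bps) - 1)
    for i in range(T):
        A_t[i] = A_cache[bps[seg[i]]]
    A_first = A_cache[bps[0]]

    out = np.empty((M, T, N))
    for n in range(N):
        innov = rng.standard_normal((burn + T, M)) @ L.T
        x = np.zeros((burn + T, M))
        for t in range(burn + T):
            A_now = A_first if t < burn else A_t[t - burn]
            acc = innov[t].copy()
            for k in range(1, p + 1):
                if t - k >= 0:
                    acc += A_now[k - 1] @ x[t - k]
            x[t] = acc
        out[:, :, n] = x[burn:].T
    return out


def _roi_representative_vertex(model: HeadModel, roi: str) -> int:
    """Deterministic gridpoint for a node: the ROI vertex nearest the ROI's
    own centroid (lowest index on ties)."""
    idx = model.roi_map[roi]
    verts = model.mesh.vertices[idx]
    centroid = verts.mean(axis=0)
    d = np.linalg.norm(verts - centroid, axis=1)
    return int(idx[int(np.argmin(d))])


def project_to_channels(
    sources: np.ndarray,
    model: HeadModel,
    roi_assignment: dict[int, str],
    snr_db: float,
    seed: int | np.random.Generator,
    fs: float = 128.0,
    condition: np.ndarray | None = None,
    epoch_window: tuple[float, float] = (0.0, 1.0),
) -> EpochedEEG:
    """Project VAR sources through the lead field and add sensor noise.

    ``channel data = K[:, chosen gridpoints] @ sources + noise`` with white
    Gaussian noise scaled so that the channel-space signal-to-noise ratio
    (total signal power over total noise power, in dB) equals ``snr_db``.
    ``snr_db = inf`` gives noise-free data.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    M, T, N = sources.shape
    gridpoints = np.empty(M, dtype=int)
    for node in range(M):
        roi = roi_assignment[node]
        if roi not in model.roi_map:
            raise IndexError(f"node {node} mapped to unknown ROI {roi!r}")
        gridpoints[node] = _roi_representative_vertex(model, roi)
    Ksub = model.K[:, gridpoints] * SOURCE_MOMENT_AM * 1e6  # volts -> uV
    clean = np.einsum("cm,mtn->ctn", Ksub, sources)
    if np.isinf(snr_db):
        data = clean
    else:
        sig_power = np.mean(clean**2)
        noise_power = sig_power / (10.0 ** (snr_db / 10.0))
        data = clean + rng.standard_normal(clean.shape) * np.sqrt(noise_power)
    if condition is None:
        condition = np.asarray([TEST] * N, dtype=object)
    return EpochedEEG(
        data=data,
        fs=fs,
        channel_names=model.electrode_names,
        channel_pos=model.electrode_pos,
        condition=condition,
        epoch_window=epoch_window,
    )


def add_artifact_components(
    eeg: EpochedEEG,
    kind: str,
    rate: float,
    seed: int | np.random.Generator,
    amplitude_uv: float | None = None,
) -> EpochedEEG:
    """Superimpose stereotyped artifacts on a copy of the data.

    ``blink``: a rank-1 frontal-weighted raised-cosine transient (300 ms)
    shared across channels, occurring as a Poisson process with ``rate``
    events per second.  ``impulse-channel``: sparse heavy-tailed spikes on
    one channel with per-sample probability ``rate``.  ``rate = 0`` is the
    identity.  The clean data remain recoverable in expectation (artifacts
    are zero-mean additions over the ensemble only for the spike sign; the
    blink adds a fixed-shape transient suited to ICA removal).
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = eeg.copy()
    if rate == 0:
        return out
    C, T, N = out.data.shape
    if kind == "blink":
        amp = 60.0 if amplitude_uv is None else amplitude_uv
        # frontal topography: weight by anteriority (+x), strictly rank-1
        x = out.channel_pos[:, 0]
        topo = np.clip(x - x.mean(), 0, None)
        if topo.max() <= 0:
            topo = np.abs(x)
        topo = topo / topo.max()
        width = max(int(round(0.3 * eeg.fs)), 4)
        pulse = 0.5 * (1.0 - np.cos(2.0 * np.pi * np.arange(width) / width))
        p_event = rate * T / eeg.fs
        for n in range(N):
            n_events = rng.poisson(p_event)
            for _ in range(n_events):
                start = rng.integers(0, max(T - width, 1))
                seg = min(width, T - start)
                out.data[:, start : start + seg, n] += amp * topo[:, None] * pulse[None, :seg]
        return out
    if kind == "impulse-channel":
        amp = None if amplitude_uv is None else amplitude_uv
        ch = int(rng.integers(0, C))
        scale = np.std(out.data[ch]) if amp is None else amp
        scale = max(scale, 1.0) * 8.0 if amp is None else amp
        hits = rng.random((T, N)) < rate
        signs = rng.choice([-1.0, 1.0], size=hits.sum())
        spikes = np.zeros((T, N))
        spikes[hits] = signs * scale * (1.0 + rng.exponential(1.0, size=hits.sum()))
        out.data[ch] += spikes
        return out
    raise ValueError(f"unknown artifact kind: {kind!r}")


# ---------------------------------------------------------------------------
# default cohort
# ---------------------------------------------------------------------------

ROI_NODE_ORDER = ["L Occ", "R Occ", "L Par", "R Par", "L Mot", "R Mot", "ACC", "SMA", "Prec"]


def default_roi_assignment() -> dict[int, str]:
    return dict(enumerate(ROI_NODE_ORDER))


def default_networks(
    fs: float = 128.0,
    planted_edge: tuple[int, int] = (6, 4),  # ACC -> L Mot
    planted_coeff: float = 0.4,
    split_s: float = 0.5,
) -> tuple[GroundTruthNetwork, GroundTruthNetwork]:
    """Control and test ground-truth networks over the 9 standard ROI nodes.

    Both conditions share oscillatory self-dynamics (alpha-band AR(2) poles)
    and a backbone of static directed edges.  The test network additionally
    carries one condition-specific edge (default ACC -> L Mot, coefficient
    0.4, whole epoch), plus a planning-only occipital-to-parietal edge that
    switches off at the planning/execution split in both conditions --
    exercising the time-resolved machinery without contributing to the
    condition contrast.
    """
    M = 9
    couplings: list[Coupling] = []
    peaks = [10.0, 10.0, 11.0, 11.0, 12.0, 12.0, 9.0, 10.5, 9.5]
    for node, f0 in enumerate(peaks):
        a1, a2 = oscillator_coeffs(f0, fs, rho=0.75)
        couplings.append(Coupling(node, node, 1, [(0.0, a1)]))
        couplings.append(Coupling(node, node, 2, [(0.0, a2)]))
    backbone = [
        (0, 2, 0.25),  # L Occ -> L Par
        (1, 3, 0.25),  # R Occ -> R Par
        (2, 8, 0.2),   # L Par -> Prec
        (8, 7, 0.2),   # Prec -> SMA
        (7, 6, 0.2),   # SMA -> ACC
    ]
    for src, snk, c in backbone:
        couplings.append(Coupling(src, snk, 1, [(0.0, c)]))
    # planning-only edge in both conditions: R Par -> SMA until the split
    couplings.append(Coupling(3, 7, 1, [(0.0, 0.25), (split_s, 0.0)]))

    noise_cov = np.eye(M)
    control = GroundTruthNetwork(M, list(couplings), noise_cov, order=2)
    test_couplings = list(couplings) + [
        Coupling(planted_edge[0], planted_edge[1], 1, [(0.0, planted_coeff)])
    ]
    test = GroundTruthNetwork(M, test_couplings, noise_cov, order=2)
    control.check_stability()
    test.check_stability()
    return control, test


def generate_cohort(
    n_subjects: int,
    net_control: GroundTruthNetwork,
    net_test: GroundTruthNetwork,
    model: HeadModel,
    jitter: float = 0.05,
    seed: int = 0,
    n_control: int = 96,
    n_test: int = 192,
    T: int = 128,
    fs: float = 128.0,
    snr_db: float = 10.0,
    roi_assignment: dict[int, str] | None = None,
    epoch_window: tuple[float, float] = (0.0, 1.0),
) -> list[SyntheticSubject]:
    """Generate a deterministic multi-subject two-condition cohort.

    Per-subject random streams are spawned from the master seed, and each
    subject's coupling coefficients are jittered by the stated fraction
    (rejecting unstable draws), emulating between-subject variability around
    a shared cortical network.  Default trial counts are 96 control and 192
    test trials per subject.
    """
    if roi_assignment is None:
        roi_assignment = default_roi_assignment()
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_subjects)
    subjects = []
    for si in range(n_subjects):
        rng = np.random.default_rng(children[si])
        sub_net_c = net_control.jittered(jitter, rng)
        sub_net_t = net_test.jittered(jitter, rng)
        src_c = simulate_var_sources(sub_net_c, T, n_control, fs, rng, t0=epoch_window[0])
        src_t = simulate_var_sources(sub_net_t, T, n_test, fs, rng, t0=epoch_window[0])
        sources = np.concatenate([src_c, src_t], axis=2)
        condition = np.asarray([CONTROL] * n_control + [TEST] * n_test, dtype=object)
        eeg = project_to_channels(
            sources, model, roi_assignment, snr_db, rng, fs=fs,
            condition=condition, epoch_window=epoch_window,
        )
        subjects.append(
            SyntheticSubject(
                eeg=eeg,
                true_sources=sources,
                roi_assignment=dict(roi_assignment),
                head_model=model,
                seed=int(children[si].generate_state(1)[0] % (2**31)),
                net_control=sub_net_c,
                net_test=sub_net_t,
            )
        )
    return subjects
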