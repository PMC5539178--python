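"""Synthetic multi-subject, multi-session ROI time series with known truth.

The generator emulates a test-retest resting-state study design: a modular
group covariance (higher correlation within network blocks than between),
subject-level deviations of the connectivity pattern (between-subject
variance), session-level deviations (within-subject variance), and optional
latent modulators that switch the covariance of selected region pairs
through time, inducing correlated dynamic-connectivity fluctuations that
the dHOFC hyper-network can recover.

Perturbations are applied on the Fisher-z scale and back-transformed, which
keeps correlations in range without truncation artifacts; any resulting
non-positive-definite matrix is repaired by eigenvalue flooring (logged
with the Frobenius norm of the change). A single seed expands into
per-subject/per-session substreams via numpy's SeedSequence spawning, so
any subset of the design is reproducible on its own.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .io import NetworkAtlas, ROITimeSeries, ROITimeSeriesSet

__all__ = [
    "Modulator",
    "SimulationConfig",
    "GroundTruth",
    "build_group_covariance",
    "simulate_dataset",
    "theoretical_icc",
    "variances_for_icc",
    "two_network_atlas",
    "with_options",
]

log = logging.getLogger(__name__)

EIG_FLOOR = 1e-6


@dataclass(frozen=True)
class Modulator:
    """A latent signal that scales the covariance of selected region pairs.

    ``pairs`` lists unordered region-id pairs driven together. The signal is
    either a two-state Markov switching process (states +/-1, geometric
    dwell with the given mean, the default — matching state-switching
    descriptions of dynamic FC) or a sinusoid with the given period (in
    timepoints, for analytic checks). ``amplitude`` is the half-swing on the
    Fisher-z scale of the affected correlations.
    """

    pairs: tuple[tuple[str, str], ...]
    amplitude: float = 0.3
    kind: str = "switching"  # or "sinusoid"
    dwell_mean: float = 20.0
    period: float = 60.0

    def __post_init__(self) -> None:
        if self.kind not in ("switching", "sinusoid"):
            raise ValueError("modulator kind must be 'switching' or 'sinusoid'")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        object.__setattr__(self, "pairs", tuple(tuple(p) for p in self.pairs))

    def signal(self, T: int, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "sinusoid":
            phase = rng.uniform(0, 2 * np.pi)
            return np.sin(2 * np.pi * np.arange(T) / self.period + phase)
        stay = 1.0 - 1.0 / self.dwell_mean
        states = np.empty(T)
        s = 1.0 if rng.random() < 0.5 else -1.0
        flips = rng.random(T)
        for t in range(T):
            if flips[t] > stay:
                s = -s
            states[t] = s
        return states


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters for the generator.

    Defaults mirror the emulated test-retest design: 25 subjects, 7
    sessions, 295 retained volumes at TR = 2 s. Correlation targets and
    perturbation scales are on the Fisher-z scale where noted.
    """

    atlas: NetworkAtlas
    n_subjects: int = 25
    n_sessions: int = 7
    T: int = 295
    tr_seconds: float = 2.0
    within_network_r: float = 0.5
    between_network_r: float = 0.1
    subject_sd: float = 0.15      # between-subject sd of z-connectivity
    session_sd: float = 0.10      # within-subject (session) sd of z-connectivity
    modulators: tuple[Modulator, ...] = ()
    subject_amplitude_sd: float = 0.1  # per-subject jitter of modulator amplitude
    seed: int = 0

    def __post_init__(self) -> None:
        if not (abs(self.within_network_r) < 1 and abs(self.between_network_r) < 1):
            raise ValueError("correlation targets must have magnitude < 1")
        if self.subject_sd < 0 or self.session_sd < 0:
            raise ValueError("sd values must be >= 0")
        if self.n_subjects < 1 or self.n_sessions < 1 or self.T < 2:
            raise ValueError("invalid design sizes")
        object.__setattr__(self, "modulators", tuple(self.modulators))


@dataclass(frozen=True)
class GroundTruth:
    """What the generator knows: per-subject targets and implied reliability."""

    subject_z: np.ndarray                 # (S, N, N) subject-level z-connectivity
    theoretical_icc: float                # implied per-connection expected ICC
    modulator_assignments: tuple[tuple[tuple[str, str], ...], ...]
    subject_amplitudes: np.ndarray = field(default=None)  # (S, n_modulators)


def two_network_atlas(n_per_network: Sequence[int], names: Sequence[str] | None = None) -> NetworkAtlas:
    """Convenience builder for small simulation atlases (coordinates zeroed)."""
    import pandas as pd

    names = list(names or [f"Net{i + 1}" for i in range(len(n_per_network))])
    rows = []
    idx = 1
    for name, cnt in zip(names, n_per_network):
        for _ in range(cnt):
            rows.append((idx, idx, 0, 0, 0, name))
            idx += 1
    return NetworkAtlas(
        pd.DataFrame(rows, columns=["roi_index", "orig_index", "x", "y", "z", "network"])
    )


def build_group_covariance(cfg: SimulationConfig) -> np.ndarray:
    """Unit-diagonal block correlation matrix from the atlas' network labels.

    Entries are ``within_network_r`` inside a network block and
    ``between_network_r`` across blocks; repaired to positive-definite by
    eigenvalue flooring if the block construction is indefinite.
    """
    nets = [cfg.atlas.network_of(r) for r in cfg.atlas.roi_ids]
    n = len(nets)
    same = np.equal.outer(nets, nets)
    cov = np.where(same, cfg.within_network_r, cfg.between_network_r)
    np.fill_diagonal(cov, 1.0)
    return _repair_pd(cov, "group covariance")


def _repair_pd(cov: np.ndarray, what: str) -> np.ndarray:
    """Floor eigenvalues at EIG_FLOOR and restore the unit diagonal."""
    vals = np.linalg.eigvalsh(cov)
    if vals.min() >= EIG_FLOOR:
        return cov
    w, v = np.linalg.eigh(cov)
    w = np.maximum(w, EIG_FLOOR)
    fixed = (v * w) @ v.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    delta = np.linalg.norm(fixed - cov)
    log.info("PD repair of %s: Frobenius change %.3e", what, delta)
    fixed_vals = np.linalg.eigvalsh(fixed)
    if fixed_vals.min() <= 0:
        raise ValueError(f"irreparably non-PD {what}")
    return fixed


def _z_offdiag(r: np.ndarray) -> np.ndarray:
    z = np.arctanh(np.clip(r, -1 + 1e-7, 1 - 1e-7))
    np.fill_diagonal(z, 0.0)
    return z


def _corr_from_z(z: np.ndarray) -> np.ndarray:
    r = np.tanh(z)
    np.fill_diagonal(r, 1.0)
    return r


def _sym_noise(n: int, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Symmetric zero-diagonal Gaussian perturbation (upper triangle drawn)."""
    m = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    m[iu] = rng.normal(0.0, sd, size=len(iu[0]))
    return m + m.T


def simulate_dataset(cfg: SimulationConfig) -> tuple[ROITimeSeriesSet, GroundTruth]:
    """Draw the full subjects x sessions collection plus its ground truth.

    For each subject the z-transformed off-diagonal group connectivity is
    perturbed by subject noise; each session adds session noise; the result
    is back-transformed, PD-repaired, and T multivariate-Gaussian samples
    are drawn. Modulated pairs get a time-varying z-offset amplitude *
    signal(t); sampling is segment-wise over runs of constant modulator
    state. Fully reproducible from ``cfg.seed``.
    """
    atlas = cfg.atlas
    roi_ids = atlas.roi_ids
    n = len(roi_ids)
    pos = {r: j for j, r in enumerate(roi_ids)}
    for mod in cfg.modulators:
        for a, b in mod.pairs:
            if a not in pos or b not in pos:
                raise ValueError(f"modulator pair ({a}, {b}) not in atlas")

    group = build_group_covariance(cfg)
    z0 = _z_offdiag(group)

    root = np.random.SeedSequence(cfg.seed)
    subject_streams = root.spawn(cfg.n_subjects)

    subjects = tuple(f"sub-{i + 1:02d}" for i in range(cfg.n_subjects))
    sessions = tuple(f"ses-{j + 1}" for j in range(cfg.n_sessions))
    entries: dict[tuple[str, str], ROITimeSeries] = {}
    subject_z = np.empty((cfg.n_subjects, n, n))
    subject_amp = np.empty((cfg.n_subjects, len(cfg.modulators)))

    for si, (sub, ss) in enumerate(zip(subjects, subject_streams)):
        children = ss.spawn(cfg.n_sessions + 1)
        srng = np.random.default_rng(children[0])
        zs = z0 + _sym_noise(n, cfg.subject_sd, srng)
        subject_z[si] = zs
        for mi, mod in enumerate(cfg.modulators):
            subject_amp[si, mi] = max(
                0.0, mod.amplitude + srng.normal(0.0, cfg.subject_amplitude_sd)
            )
        for ei, ses in enumerate(sessions):
            rng = np.random.default_rng(children[ei + 1])
            zss = zs + _sym_noise(n, cfg.session_sd, rng)
            data = _draw_session(cfg, zss, subject_amp[si], pos, rng)
            entries[(sub, ses)] = ROITimeSeries(data, cfg.tr_seconds, roi_ids)

    truth = GroundTruth(
        subject_z=subject_z,
        theoretical_icc=theoretical_icc(cfg, cfg.T),
        modulator_assignments=tuple(m.pairs for m in cfg.modulators),
        subject_amplitudes=subject_amp,
    )
    return ROITimeSeriesSet(entries, subjects, sessions), truth


def _draw_session(
    cfg: SimulationConfig,
    zss: np.ndarray,
    amplitudes: np.ndarray,
    pos: dict[str, int],
    rng: np.random.Generator,
) -> np.ndarray:
    n = zss.shape[0]
    T = cfg.T
    if not cfg.modulators:
        cov = _repair_pd(_corr_from_z(zss), "session covariance")
        chol = np.linalg.cholesky(cov)
        return rng.standard_normal((T, n)) @ chol.T

    signals = np.stack([m.signal(T, rng) for m in cfg.modulators])  # (M, T)
    # segment boundaries where any modulator state changes
    change = np.any(np.diff(signals, axis=1) != 0.0, axis=0)
    bounds = np.concatenate([[0], np.flatnonzero(change) + 1, [T]])
    data = np.empty((T, n))
    chol_cache: dict[tuple, np.ndarray] = {}
    for a, b in zip(bounds[:-1], bounds[1:]):
        key = tuple(np.round(signals[:, a], 12))
        if key not in chol_cache:
            z = zss.copy()
            for mi, mod in enumerate(cfg.modulators):
                off = amplitudes[mi] * signals[mi, a]
                for p, q in mod.pairs:
                    z[pos[p], pos[q]] += off
                    z[pos[q], pos[p]] += off
            cov = _repair_pd(_corr_from_z(z), "modulated covariance")
            chol_cache[key] = np.linalg.cholesky(cov)
        data[a:b] = rng.standard_normal((b - a, n)) @ chol_cache[key].T
    return data


def theoretical_icc(cfg: SimulationConfig, T: int | None = None) -> float:
    """Expected per-connection ICC implied by the configured variances.

    On the Fisher-z scale the measured connectivity decomposes into the
    subject effect (variance subject_sd^2), the session effect
    (session_sd^2), and correlation-estimation noise, approximately
    1 / (T - 3) for the z of a Pearson correlation at T samples:

        ICC_expected = sb^2 / (sb^2 + sw^2 + 1 / (T - 3))

    This is an approximation: it ignores the slight bias of the correlation
    estimator and any PD-repair shrinkage.
    """
    T = cfg.T if T is None else T
    if T <= 3:
        raise ValueError("T must exceed 3 for the sampling-variance approximation")
    sb2 = cfg.subject_sd**2
    sw2 = cfg.session_sd**2 + 1.0 / (T - 3)
    if sb2 == 0.0:
        return 0.0
    return float(sb2 / (sb2 + sw2))


def variances_for_icc(
    target_icc: float, T: int, session_sd: float = 0.10
) -> tuple[float, float]:
    """Subject sd achieving ``target_icc`` given session sd and T (inverse of
    ``theoretical_icc``); returns (subject_sd, session_sd)."""
    if not 0.0 < target_icc < 1.0:
        raise ValueError("target_icc must be in (0, 1)")
    sw2 = session_sd**2 + 1.0 / (T - 3)
    sb2 = target_icc / (1.0 - target_icc) * sw2
    return float(np.sqrt(sb2)), session_sd


# re-exported convenience: tweak one field of a frozen config
def with_options(cfg: SimulationConfig, **kwargs) -> SimulationConfig:
    return replace(cfg, **kwargs)
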