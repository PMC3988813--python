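"""Einstein/MSD self-diffusion estimation for particle trajectories.

The mean square displacement of normally diffusing particles grows as
MSD(tau) = 2 d D tau (d = dimensionality); a least-squares slope over an
intermediate lag window yields D.  A Brownian-motion generator with
known ground truth serves as the calibration fixture.

Internal trajectory units: nm and ps; diffusivities are exposed in SI
(m^2/s; 1 nm^2/ps = 1e-6 m^2/s).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "Trajectory",
    "DiffusionEstimate",
    "generate_brownian",
    "wrap",
    "unwrap",
    "msd",
    "msd_naive",
    "estimate_D",
    "estimate_D_trajectory",
    "read_xyz_trajectory",
    "write_xyz_trajectory",
]

NM2_PER_PS_TO_M2_PER_S = 1e-6
M2_PER_S_TO_NM2_PER_PS = 1e6


@dataclass
class Trajectory:
    """Particle positions over time: array (frames, particles, 3) in nm."""

    positions: np.ndarray
    dt: float  # ps per frame
    box: tuple[float, float, float] | None = None
    wrapped: bool = False

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise ValueError("positions must have shape (frames, particles, 3)")
        if self.positions.shape[0] < 2:
            raise ValueError("need at least 2 frames")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_particles(self) -> int:
        return self.positions.shape[1]


@dataclass
class DiffusionEstimate:
    """Fitted diffusion coefficient with its MSD curve and diagnostics."""

    D: float  # m^2/s
    stderr: float  # m^2/s
    fit_window: tuple[float, float]  # ps
    msd_curve: np.ndarray  # (lags, 2): lag [ps], msd [nm^2]
    block_D: np.ndarray = field(default_factory=lambda: np.empty(0))
    converged: bool = True


def generate_brownian(
    n_particles: int,
    D_true: float,
    dt: float,
    n_frames: int,
    seed: int,
    box: tuple[float, float, float] | None = None,
) -> Trajectory:
    """Free Brownian motion with ground-truth diffusivity *D_true* (m^2/s).

    Gaussian steps with per-axis variance 2 D dt; if *box* is given the
    positions are wrapped (periodic images), otherwise left free.
    """
    if min(n_particles, n_frames) < 1 or dt <= 0 or D_true < 0:
        raise ValueError("invalid Brownian generator arguments")
    rng = np.random.default_rng(seed)
    d_internal = D_true * M2_PER_S_TO_NM2_PER_PS  # nm^2/ps
    sigma = np.sqrt(2.0 * d_internal * dt)
    steps = rng.normal(0.0, sigma, size=(n_frames - 1, n_particles, 3))
    start = (
        rng.uniform(0.0, box, size=(1, n_particles, 3)) * np.ones(3)
        if box is not None
        else np.zeros((1, n_particles, 3))
    )
    pos = np.concatenate([start, start + np.cumsum(steps, axis=0)])
    t = Trajectory(positions=pos, dt=dt, box=box, wrapped=False)
    return wrap(t) if box is not None else t


def wrap(t: Trajectory) -> Trajectory:
    """Fold all positions into the periodic box."""
    if t.box is None:
        raise ValueError("trajectory has no box")
    box = np.asarray(t.box, dtype=float)
    return Trajectory(np.mod(t.positions, box), t.dt, t.box, wrapped=True)


def unwrap(t: Trajectory) -> Trajectory:
    """Undo periodic wrapping by minimum-image displacement accumulation.

    Assumes no true frame-to-frame displacement exceeds half the box on
    any axis; faster motion is aliased and cannot be recovered.
    """
    if t.box is None:
        raise ValueError("trajectory has no box")
    if not t.wrapped:
        return t
    box = np.asarray(t.box, dtype=float)
    disp = np.diff(t.positions, axis=0)
    disp -= box * np.round(disp / box)
    pos = np.concatenate(
        [t.positions[:1], t.positions[:1] + np.cumsum(disp, axis=0)]
    )
    return Trajectory(pos, t.dt, t.box, wrapped=False)


def _msd_fft_single(x: np.ndarray) -> np.ndarray:
    """MSD over all lags for one particle, (frames, 3) -> (frames,).

    Standard FFT decomposition: MSD(m) = S1(m) - 2 S2(m), with S2 the
    position autocorrelation computed by FFT in O(N log N).
    """
    n = x.shape[0]
    nfft = 1 << (2 * n - 1).bit_length()
    sq = np.einsum("ij,ij->i", x, x)
    s2 = np.zeros(n)
    for d in range(3):
        f = np.fft.rfft(x[:, d], nfft)
        acf = np.fft.irfft(f * f.conj(), nfft)[:n]
        s2 += acf
    sumsq = 2.0 * sq.sum() - np.concatenate([[0.0], np.cumsum(sq[:-1] + sq[:0:-1])])
    counts = n - np.arange(n)
    return (sumsq - 2.0 * s2) / counts


def msd(t: Trajectory, max_lag_fraction: float = 0.5) -> np.ndarray:
    """Time- and particle-averaged MSD, returned as (lag [ps], msd [nm^2]).

    Lags run from 1 frame up to *max_lag_fraction* of the trajectory.
    Wrapped trajectories must be unwrapped first.
    """
    if t.wrapped:
        raise ValueError("unwrap the trajectory before computing the MSD")
    if not (0 < max_lag_fraction <= 1):
        raise ValueError("max_lag_fraction must be in (0, 1]")
    n = t.n_frames
    max_lag = max(1, int((n - 1) * max_lag_fraction))
    acc = np.zeros(n)
    for p in range(t.n_particles):
        acc += _msd_fft_single(t.positions[:, p, :])
    acc /= t.n_particles
    lags = np.arange(1, max_lag + 1)
    return np.column_stack([lags * t.dt, acc[1 : max_lag + 1]])


def msd_naive(t: Trajectory, max_lag_fraction: float = 0.5) -> np.ndarray:
    """Direct double-loop MSD; reference implementation for small cases."""
    if t.wrapped:
        raise ValueError("unwrap the trajectory before computing the MSD")
    n = t.n_frames
    max_lag = max(1, int((n - 1) * max_lag_fraction))
    out = np.zeros(max_lag)
    for lag in range(1, max_lag + 1):
        d = t.positions[lag:] - t.positions[:-lag]
        out[lag - 1] = np.mean(np.sum(d * d, axis=2))
    lags = np.arange(1, max_lag + 1)
    return np.column_stack([lags * t.dt, out])


def estimate_D(
    msd_curve: np.ndarray,
    fit_window: tuple[float, float] | None = None,
    dimensionality: int = 3,
    block_length: float = 200.0,
) -> DiffusionEstimate:
    """Einstein-relation fit: D = slope(MSD vs lag) / (2 d).

    Parameters
    ----------
    msd_curve
        (lag [ps], msd [nm^2]) pairs from :func:`msd`.
    fit_window
        (lag_min, lag_max) in ps; defaults to [10%, 50%] of the largest
        lag, excluding the short-lag ballistic/caging regime.
    block_length
        ps per convergence block: D is re-estimated on successive blocks
        of the curve and the run is flagged non-converged when the last
        two blocks disagree by more than 20%.
    """
    curve = np.asarray(msd_curve, dtype=float)
    lag, m = curve[:, 0], curve[:, 1]
    if fit_window is None:
        fit_window = (0.1 * lag[-1], 0.5 * lag[-1])
    lo, hi = fit_window
    if not lo < hi:
        raise ValueError("fit window must satisfy lag_min < lag_max")
    mask = (lag >= lo) & (lag <= hi)
    if mask.sum() < 5:
        raise ValueError("fewer than 5 MSD points in the fit window")
    x, y = lag[mask], m[mask]
    A = np.column_stack([x, np.ones_like(x)])
    coef, res, *_ = np.linalg.lstsq(A, y, rcond=None)
    slope = coef[0]
    ndof = len(x) - 2
    if ndof > 0 and len(res):
        s2 = res[0] / ndof
        var_slope = s2 / np.sum((x - x.mean()) ** 2)
        stderr = float(np.sqrt(var_slope))
    else:
        stderr = 0.0
    denom = 2.0 * dimensionality
    D = max(0.0, slope / denom) * NM2_PER_PS_TO_M2_PER_S
    stderr_si = stderr / denom * NM2_PER_PS_TO_M2_PER_S

    # block convergence diagnostic
    block_D = []
    n_blocks = int(lag[-1] // block_length)
    for b in range(n_blocks):
        bm = (lag >= b * block_length) & (lag < (b + 1) * block_length)
        if bm.sum() >= 5:
            bc = np.polyfit(lag[bm], m[bm], 1)[0]
            block_D.append(max(0.0, bc / denom) * NM2_PER_PS_TO_M2_PER_S)
    block_D = np.asarray(block_D)
    converged = True
    if len(block_D) >= 2 and block_D[-1] > 0:
        converged = abs(block_D[-1] - block_D[-2]) <= 0.2 * block_D[-1]
    return DiffusionEstimate(
        D=float(D),
        stderr=float(stderr_si),
        fit_window=(float(lo), float(hi)),
        msd_curve=curve,
        block_D=block_D,
        converged=converged,
    )


def estimate_D_trajectory(
    t: Trajectory,
    fit_window: tuple[float, float] | None = None,
    dimensionality: int = 3,
    max_lag_fraction: float = 0.5,
) -> DiffusionEstimate:
    """Ensemble Einstein estimate with a particle-spread standard error.

    Each particle's MSD is fitted separately; D is the mean of the
    per-particle estimates and stderr their standard error of the mean.
    For independent particles (e.g. the Brownian fixture) this stderr is
    statistically valid, unlike the OLS stderr of :func:`estimate_D`
    whose MSD residuals are serially correlated.
    """
    if t.wrapped:
        raise ValueError("unwrap the trajectory before estimating D")
    n = t.n_frames
    max_lag = max(1, int((n - 1) * max_lag_fraction))
    lags = np.arange(1, max_lag + 1) * t.dt
    if fit_window is None:
        fit_window = (0.1 * lags[-1], 0.5 * lags[-1])
    lo, hi = fit_window
    mask = (lags >= lo) & (lags <= hi)
    if mask.sum() < 5:
        raise ValueError("fewer than 5 MSD points in the fit window")
    x = lags[mask]
    A = np.column_stack([x, np.ones_like(x)])
    denom = 2.0 * dimensionality
    per_particle = np.empty(t.n_particles)
    acc = np.zeros(max_lag)
    for p in range(t.n_particles):
        m = _msd_fft_single(t.positions[:, p, :])[1 : max_lag + 1]
        acc += m
        coef, *_ = np.linalg.lstsq(A, m[mask], rcond=None)
        per_particle[p] = coef[0] / denom * NM2_PER_PS_TO_M2_PER_S
    acc /= t.n_particles
    D = float(per_particle.mean())
    stderr = float(per_particle.std(ddof=1) / np.sqrt(t.n_particles)) \
        if t.n_particles > 1 else 0.0
    return DiffusionEstimate(
        D=max(0.0, D),
        stderr=stderr,
        fit_window=(float(lo), float(hi)),
        msd_curve=np.column_stack([lags, acc]),
    )


def write_xyz_trajectory(t: Trajectory, path: str | Path) -> None:
    """Plain multi-frame XYZ-like text dump (nm coordinates)."""
    lines = []
    for f in range(t.n_frames):
        lines.append(str(t.n_particles))
        lines.append(f"frame {f} dt {t.dt}")
        for p in range(t.n_particles):
            x, y, z = t.positions[f, p]
            lines.append(f"W {x:.6f} {y:.6f} {z:.6f}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_xyz_trajectory(path: str | Path, dt: float | None = None) -> Trajectory:
    """Read the multi-frame XYZ-like text format of
    :func:`write_xyz_trajectory`."""
    lines = Path(path).read_text().splitlines()
    frames = []
    i = 0
    file_dt = None
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n = int(lines[i].strip())
        comment = lines[i + 1].split()
        if "dt" in comment:
            file_dt = float(comment[comment.index("dt") + 1])
        frame = [
            [float(v) for v in lines[i + 2 + p].split()[1:4]] for p in range(n)
        ]
        frames.append(frame)
        i += 2 + n
    dt = dt if dt is not None else (file_dt or 1.0)
    return Trajectory(np.asarray(frames), dt=dt)
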