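"""Dipolar evolution traces and their inversion to distance distributions.

The dipolar coupling between two unpaired electrons scales with the inverse
cube of their separation; the powder-averaged kernel is

    K(t, r) = integral_0^1 cos((1 - 3 x^2) * 2 pi * D / r^3 * t) dx

with D = 52.041 MHz nm^3 (mu0 g^2 beta^2 / (4 pi h), free-electron g). The
kernel is evaluated in closed form via Fresnel integrals. Distance
distributions are recovered by non-negative Tikhonov regularization with a
second-difference penalty and L-curve corner selection of alpha.

Units at this boundary: time in microseconds, distance in nanometres.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
from scipy import optimize, special

__all__ = [
    "DIPOLAR_CONSTANT_MHZ_NM3",
    "DipolarTrace",
    "DistanceDistribution",
    "BackgroundModel",
    "build_kernel",
    "correct_background",
    "invert_tikhonov",
    "modal_distance",
    "simulate_trace",
    "default_r_grid",
    "read_trace",
    "write_trace",
    "read_distribution",
    "write_distribution",
]

# mu0/(4 pi) * g^2 * betaE^2 / hbar, expressed as a frequency nu = D / r^3.
# With g = 2.0023193, betaE = 9.2740100657e-24 J/T, h = 6.62607015e-34 J s:
# D = mu0 * g^2 * betaE^2 / (4 pi h) = 52.041 MHz nm^3.
DIPOLAR_CONSTANT_MHZ_NM3 = 52.041


@dataclasses.dataclass
class DipolarTrace:
    """Time-domain dipolar signal, normalized so V(0) = 1."""

    times: np.ndarray  # microseconds, strictly increasing, first >= 0
    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValueError("times and values must be matching 1-D arrays")
        if self.times[0] < 0 or np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing and start >= 0")

    def normalized(self) -> "DipolarTrace":
        v0 = self.values[0]
        if v0 == 0:
            raise ValueError("cannot normalize: V(0) = 0")
        return DipolarTrace(self.times, self.values / v0, self.label)


@dataclasses.dataclass
class DistanceDistribution:
    """P(r) on a uniform r grid in nanometres; integrates to 1."""

    r_grid: np.ndarray
    p: np.ndarray

    def __post_init__(self) -> None:
        self.r_grid = np.asarray(self.r_grid, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        if self.r_grid.shape != self.p.shape or self.r_grid.ndim != 1:
            raise ValueError("r_grid and p must be matching 1-D arrays")
        dr = np.diff(self.r_grid)
        if np.any(dr <= 0) or not np.allclose(dr, dr[0], rtol=1e-6):
            raise ValueError("r grid must be uniform and strictly increasing")
        if np.any(self.p < -1e-12):
            raise ValueError("p must be non-negative")
        self.p = np.clip(self.p, 0.0, None)

    @property
    def dr(self) -> float:
        return float(self.r_grid[1] - self.r_grid[0])

    def normalized(self) -> "DistanceDistribution":
        total = self.p.sum() * self.dr
        if total <= 0:
            raise ValueError("cannot normalize an all-zero distribution")
        return DistanceDistribution(self.r_grid, self.p / total)

    @property
    def mean(self) -> float:
        return float((self.r_grid * self.p).sum() / self.p.sum())


@dataclasses.dataclass(frozen=True)
class BackgroundModel:
    """Homogeneous 3-D background: V_bg(t) = (1 - lambda) exp(-k t)."""

    decay_rate: float  # k, per microsecond
    modulation_depth: float  # lambda, in (0, 1)

    def __post_init__(self) -> None:
        if self.decay_rate < 0:
            raise ValueError("decay rate must be >= 0")
        if not (0 < self.modulation_depth < 1):
            raise ValueError("modulation depth must lie in (0, 1)")

    def evaluate(self, times: np.ndarray) -> np.ndarray:
        return (1.0 - self.modulation_depth) * np.exp(-self.decay_rate * np.asarray(times))


def default_r_grid(r_min: float = 1.5, r_max: float = 10.0, n: int = 256) -> np.ndarray:
    return np.linspace(r_min, r_max, n)


def build_kernel(times: np.ndarray, r_grid: np.ndarray) -> np.ndarray:
    """Powder-averaged dipolar kernel K[i, j] = K(times[i], r_grid[j]).

    Closed form via Fresnel integrals:
        K(t, r) = sqrt(pi / (6 w t)) [ cos(wt) C(z) + sin(wt) S(z) ],
        w = 2 pi D / r^3,  z = sqrt(6 w t / pi).
    K(0, r) = 1 exactly.
    """
    times = np.asarray(times, dtype=float)
    r_grid = np.asarray(r_grid, dtype=float)
    if np.any(r_grid <= 0):
        raise ValueError("r grid must be strictly positive")
    omega = 2.0 * np.pi * DIPOLAR_CONSTANT_MHZ_NM3 / r_grid**3  # rad/us
    phase = np.outer(np.abs(times), omega)  # w * t, >= 0
    kernel = np.ones_like(phase)
    nz = phase > 1e-12
    z = np.sqrt(6.0 * phase[nz] / np.pi)
    s, c = special.fresnel(z)
    kernel[nz] = (
        np.sqrt(np.pi / (6.0 * phase[nz]))
        * (np.cos(phase[nz]) * c + np.sin(phase[nz]) * s)
    )
    return kernel


def correct_background(
    raw: DipolarTrace, fit_start_fraction: float = 0.25
) -> tuple[DipolarTrace, BackgroundModel]:
    """Fit a 3-D homogeneous background to the trace tail and divide it out.

    The window [fit_start_fraction * t_max, t_max] is fitted with
    (1 - lambda) exp(-k t); the returned form factor is raw / background,
    renormalized to 1 at t = 0.
    """
    trace = raw.normalized()
    t, v = trace.times, trace.values
    mask = t >= fit_start_fraction * t[-1]
    if mask.sum() < 10:
        raise ValueError("fit window contains fewer than 10 points")

    def model(tt, k, lam):
        return (1.0 - lam) * np.exp(-k * tt)

    lam0 = float(np.clip(1.0 - v[mask][-1], 0.05, 0.8))
    try:
        popt, _ = optimize.curve_fit(
            model,
            t[mask],
            v[mask],
            p0=[0.05, lam0],
            bounds=([0.0, 1e-6], [np.inf, 1 - 1e-6]),
            maxfev=10000,
        )
    except RuntimeError as exc:
        raise ValueError(f"background fit did not converge: {exc}") from exc
    k, lam = float(popt[0]), float(popt[1])
    bg = BackgroundModel(decay_rate=k, modulation_depth=lam)
    corrected = v / np.exp(-k * t)
    corrected = corrected / corrected[0]
    return DipolarTrace(t, corrected, trace.label), bg


def _second_difference(n: int) -> np.ndarray:
    l2 = np.zeros((n - 2, n))
    for i in range(n - 2):
        l2[i, i : i + 3] = (1.0, -2.0, 1.0)
    return l2


def _nnls_tikhonov(
    kernel: np.ndarray, signal: np.ndarray, l2: np.ndarray, alpha: float
) -> np.ndarray:
    a = np.vstack([kernel, alpha * l2])
    b = np.concatenate([signal, np.zeros(l2.shape[0])])
    sol = optimize.nnls(a, b)[0]
    return sol


def _lcurve_corner(rho: np.ndarray, eta: np.ndarray) -> int:
    """Index of maximum curvature of the parametric log-log L-curve."""
    x = np.log(np.maximum(rho, 1e-30))
    y = np.log(np.maximum(eta, 1e-30))
    dx = np.gradient(x)
    dy = np.gradient(y)
    ddx = np.gradient(dx)
    ddy = np.gradient(dy)
    curvature = (dx * ddy - dy * ddx) / np.power(dx * dx + dy * dy, 1.5)
    interior = curvature[1:-1]
    if len(interior) == 0:
        raise ValueError("alpha grid too small for corner detection")
    return int(np.argmax(interior)) + 1


def invert_tikhonov(
    form_factor: DipolarTrace,
    r_grid: np.ndarray | None = None,
    alpha: float | None = None,
    modulation_depth: float | None = None,
    alpha_grid: np.ndarray | None = None,
) -> tuple[DistanceDistribution, float]:
    """Non-negative Tikhonov inversion of a background-corrected trace.

    Solves min ||K p - s||^2 + alpha^2 ||L2 p||^2 with p >= 0 on the dipolar
    part s = (F(t) - (1 - lambda)) / lambda. If the modulation depth is not
    given it is estimated as 1 - min(F). If alpha is not given it is chosen at
    the L-curve corner over a log-spaced grid.
    """
    if r_grid is None:
        r_grid = default_r_grid()
    trace = form_factor.normalized()
    lam = modulation_depth
    if lam is None:
        lam = float(np.clip(1.0 - trace.values.min(), 1e-3, 0.999))
    signal = (trace.values - (1.0 - lam)) / lam

    kernel = build_kernel(trace.times, r_grid)
    l2 = _second_difference(len(r_grid))

    if alpha is None:
        if alpha_grid is None:
            alpha_grid = np.logspace(-3, 3, 40)
        rho = np.empty(len(alpha_grid))
        eta = np.empty(len(alpha_grid))
        sols = []
        for i, a in enumerate(alpha_grid):
            p = _nnls_tikhonov(kernel, signal, l2, a)
            sols.append(p)
            rho[i] = np.linalg.norm(kernel @ p - signal)
            eta[i] = np.linalg.norm(l2 @ p)
        idx = _lcurve_corner(rho, eta)
        alpha = float(alpha_grid[idx])
        p = sols[idx]
    else:
        p = _nnls_tikhonov(kernel, signal, l2, float(alpha))

    if p.sum() <= 0:
        raise ValueError("Tikhonov inversion produced an all-zero distribution")
    dist = DistanceDistribution(np.asarray(r_grid, dtype=float), p).normalized()
    return dist, float(alpha)


def modal_distance(d: DistanceDistribution) -> float:
    """The r at the global maximum of P(r); ties break toward smaller r."""
    pmax = d.p.max()
    if pmax <= 0:
        raise ValueError("distribution is all-zero")
    if np.allclose(d.p, d.p[0]):
        raise ValueError("flat distribution has no unique mode")
    return float(d.r_grid[int(np.argmax(d.p))])  # argmax takes the first maximum


def simulate_trace(
    d: DistanceDistribution,
    times: np.ndarray,
    background: BackgroundModel,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    label: str = "",
) -> DipolarTrace:
    """Forward model: V(t) = [(1 - lambda) + lambda K p_hat] exp(-k t) + noise."""
    times = np.asarray(times, dtype=float)
    dist = d.normalized()
    kernel = build_kernel(times, dist.r_grid)
    p_hat = dist.p * dist.dr  # sums to 1, so K @ p_hat is 1 at t = 0
    lam = background.modulation_depth
    form = (1.0 - lam) + lam * (kernel @ p_hat)
    values = form * np.exp(-background.decay_rate * times)
    values = values / values[0]
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        values = values + rng.normal(scale=noise_sd, size=len(values))
    return DipolarTrace(times, values, label)


# --------------------------------------------------------------------------
# Text I/O: two-column whitespace/CSV files
# --------------------------------------------------------------------------

def _load_two_columns(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    raw = Path(path).read_text()
    delimiter = "," if "," in raw.splitlines()[0] else None
    data = np.loadtxt(path, delimiter=delimiter, comments="#")
    if data.ndim != 2 or data.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns")
    return data[:, 0], data[:, 1]


def read_trace(path: str | Path, label: str = "") -> DipolarTrace:
    t, v = _load_two_columns(path)
    return DipolarTrace(t, v, label or Path(path).stem)


def write_trace(path: str | Path, trace: DipolarTrace) -> None:
    header = f"time_us intensity ({trace.label})" if trace.label else "time_us intensity"
    np.savetxt(path, np.column_stack([trace.times, trace.values]), header=header)


def read_distribution(path: str | Path) -> DistanceDistribution:
    r, p = _load_two_columns(path)
    return DistanceDistribution(r, p)


def write_distribution(path: str | Path, d: DistanceDistribution) -> None:
    np.savetxt(path, np.column_stack([d.r_grid, d.p]), header="r_nm p")
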