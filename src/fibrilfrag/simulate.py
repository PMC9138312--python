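"""Stochastic and deterministic models of length-dependent fibril fragmentation.

A population of amyloid fibrils subjected to mechanical perturbation
(e.g. probe sonication) is modelled as a pure fragmentation process:
each fibril of length ``x`` (nm) breaks with hazard

    B(x) = (alpha * x) ** gamma   [1/s]

into two fragments ``p*x`` and ``(1-p)*x`` with the break fraction ``p``
drawn from a symmetric breakage kernel. Nucleation, elongation and
depolymerisation are assumed negligible on the sonication time scale, so
total fibril mass (summed length) is conserved and particle number is
non-decreasing. Fibril height is treated as a polymorph label carried
unchanged from parent to fragments.

Two solvers are provided for the same dynamics: an exact event-driven
Monte-Carlo simulation of finite populations (:func:`simulate_fragmentation`)
and a deterministic method-of-lines solution of the binary-breakage
population balance equation (:func:`solve_moments`), which serves as a
cross-validation oracle for the stochastic runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.integrate import solve_ivp

__all__ = [
    "FragmentationParams",
    "BreakageKernel",
    "FibrilPopulation",
    "MomentSolution",
    "DEFAULT_SCHEDULE",
    "MIN_FRAGMENT_NM",
    "division_rate",
    "simulate_fragmentation",
    "solve_moments",
    "apply_detection_limit",
    "population_to_grid",
    "population_to_frame",
    "populations_to_csv",
    "populations_from_csv",
]

#: Sonication schedule (seconds) used throughout: cumulative durations of
#: 5 s pulses. 0 s is the unperturbed sample.
DEFAULT_SCHEDULE: tuple[float, ...] = (0.0, 5.0, 10.0, 20.0, 40.0, 80.0, 320.0, 640.0)

#: Smallest representable fragment length (nm); guards against
#: floating-point zero-length fragments. Far below any detection limit.
MIN_FRAGMENT_NM: float = 1e-3


@dataclass(frozen=True)
class FragmentationParams:
    """Parameters of the fragmentation rate law ``B(x) = (alpha*x)**gamma``.

    Parameters
    ----------
    gamma : float
        Dimensionless exponent (> 0) controlling how strongly the
        fragmentation rate grows with fibril length.
    alpha : float
        Inverse-length rate scale in 1/nm (> 0) setting the overall
        magnitude of division rates.
    C : float, optional
        Amplitude of the mean-length decay law ``mu(t) = C * t**(-1/gamma)``
        (nm * s**(1/gamma)); produced by fitting, unused by the simulator.
    t_s : float, optional
        Plateau time (s) before which the power-law decay is not yet
        reliable; produced by fitting, unused by the simulator.
    """

    gamma: float
    alpha: float
    C: float | None = None
    t_s: float | None = None

    def __post_init__(self) -> None:
        if not (self.gamma > 0):
            raise ValueError(f"gamma must be > 0, got {self.gamma}")
        if not (self.alpha > 0):
            raise ValueError(f"alpha must be > 0, got {self.alpha}")
        if self.C is not None and not (self.C > 0):
            raise ValueError(f"C must be > 0, got {self.C}")
        if self.t_s is not None and self.t_s < 0:
            raise ValueError(f"t_s must be >= 0, got {self.t_s}")

    def rate(self, x):
        """Fragmentation rate B(x) = (alpha*x)**gamma in 1/s."""
        return division_rate(x, self)

    def to_dict(self) -> dict:
        return {"gamma": self.gamma, "alpha": self.alpha, "C": self.C, "t_s": self.t_s}


@dataclass(frozen=True)
class BreakageKernel:
    """Distribution of the break fraction ``p`` on (0, 1).

    ``uniform`` draws p ~ U(0,1); ``symmetric-beta`` draws
    p ~ Beta(concentration, concentration). Both are symmetric about 0.5,
    so binary breakage conserves length by construction. The observable
    decay law constrains only B(x), not the kernel shape, so uniform is
    the default and the beta option exists for sensitivity checks.
    """

    kind: str = "uniform"
    concentration: float = 2.0

    def __post_init__(self) -> None:
        if self.kind not in ("uniform", "symmetric-beta"):
            raise ValueError(f"unknown kernel kind {self.kind!r}")
        if self.kind == "symmetric-beta" and not (self.concentration > 0):
            raise ValueError("concentration must be > 0")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.kind == "uniform":
            return rng.uniform(0.0, 1.0, size=n)
        return rng.beta(self.concentration, self.concentration, size=n)

    def density(self, p: np.ndarray) -> np.ndarray:
        """Kernel density b(p) on (0,1); integrates to 1."""
        p = np.asarray(p, dtype=float)
        if self.kind == "uniform":
            return np.where((p > 0) & (p < 1), 1.0, 0.0)
        return stats.beta.pdf(p, self.concentration, self.concentration)

    def cdf(self, p: np.ndarray) -> np.ndarray:
        """Kernel CDF F(p) = P(break fraction <= p)."""
        p = np.clip(np.asarray(p, dtype=float), 0.0, 1.0)
        if self.kind == "uniform":
            return p
        return stats.beta.cdf(p, self.concentration, self.concentration)

    def partial_moment(self, p: np.ndarray) -> np.ndarray:
        """Partial first moment ``int_0^p u b(u) du`` (reaches 1/2 at p=1)."""
        p = np.clip(np.asarray(p, dtype=float), 0.0, 1.0)
        if self.kind == "uniform":
            return 0.5 * p**2
        # For Beta(a,a): int_0^p u f(u) du = mean * I_p(a+1, a) = I_p(a+1, a)/2.
        a = self.concentration
        return 0.5 * stats.beta.cdf(p, a + 1, a)


@dataclass
class FibrilPopulation:
    """Snapshot of a fibril population at one time point.

    ``lengths`` (nm) and ``heights`` (nm) are parallel arrays;
    ``lineages`` traces each fibril back to its founding particle at t=0.
    """

    time: float
    lengths: np.ndarray
    heights: np.ndarray
    lineages: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.lengths = np.asarray(self.lengths, dtype=float)
        self.heights = np.asarray(self.heights, dtype=float)
        if self.lineages is None:
            self.lineages = np.arange(self.lengths.size, dtype=np.int64)
        self.lineages = np.asarray(self.lineages, dtype=np.int64)
        if not (self.lengths.size == self.heights.size == self.lineages.size):
            raise ValueError("lengths, heights, lineages must have equal size")
        if self.lengths.size and not np.all(self.lengths > 0):
            raise ValueError("all fibril lengths must be > 0")
        if self.lengths.size and not np.all(self.heights > 0):
            raise ValueError("all fibril heights must be > 0")

    def __len__(self) -> int:
        return int(self.lengths.size)

    @property
    def total_length(self) -> float:
        """Total fibril mass as summed length (nm); conserved by fragmentation."""
        return float(self.lengths.sum())

    @property
    def mean_length(self) -> float:
        return float(self.lengths.mean())


def division_rate(x, params: FragmentationParams):
    """Fragmentation rate ``B(x) = (alpha*x)**gamma`` in 1/s.

    Strictly increasing in x for all x > 0. Accepts scalars or arrays.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("fibril length x must be > 0")
    out = (params.alpha * x) ** params.gamma
    return float(out) if out.ndim == 0 else out


def simulate_fragmentation(
    pop0: FibrilPopulation,
    params: FragmentationParams,
    sample_times,
    kernel: BreakageKernel | None = None,
    seed: int = 0,
    max_particles: int = 5_000_000,
) -> list[FibrilPopulation]:
    """Exact event-driven simulation of pure fragmentation.

    Each fibril fragments independently with hazard ``B(x)``; on an event
    it is replaced by fragments ``p*x`` and ``(1-p)*x``. Because fragments
    evolve independently, the full event tree is generated
    generation-by-generation (a next-reaction scheme on independent
    lineages) and snapshots are reconstructed from segment lifetimes, so
    observation times never perturb the event sequence.

    Parameters
    ----------
    pop0 : FibrilPopulation
        Initial population; its ``time`` is taken as 0.
    sample_times : sequence of float
        Strictly increasing snapshot times in seconds (>= 0).
    kernel : BreakageKernel, optional
        Break-fraction distribution; uniform by default.
    seed : int
        Seed for the single random stream of the run.
    max_particles : int
        Abort threshold on the total number of segments ever created;
        guards against runaway fragmentation at large alpha/gamma.

    Returns
    -------
    list of FibrilPopulation, one per requested sample time. Total length
    is conserved to floating-point accuracy at every snapshot.
    """
    sample_times = np.asarray(sample_times, dtype=float)
    if sample_times.size == 0:
        raise ValueError("sample_times must be non-empty")
    if np.any(sample_times < 0) or np.any(np.diff(sample_times) <= 0):
        raise ValueError("sample_times must be strictly increasing and >= 0")
    if len(pop0) == 0:
        raise ValueError("initial population must be non-empty")
    kernel = kernel or BreakageKernel()
    rng = np.random.default_rng(seed)
    horizon = float(sample_times[-1])

    # Active segments: arrays of (length, height, lineage, birth time).
    cur_len = pop0.lengths.copy()
    cur_h = pop0.heights.copy()
    cur_lin = pop0.lineages.copy()
    cur_birth = np.zeros(len(pop0))

    seg_len: list[np.ndarray] = []
    seg_h: list[np.ndarray] = []
    seg_lin: list[np.ndarray] = []
    seg_birth: list[np.ndarray] = []
    seg_death: list[np.ndarray] = []
    n_created = len(pop0)

    while cur_len.size:
        breakable = cur_len > 2 * MIN_FRAGMENT_NM
        rate = np.zeros_like(cur_len)
        rate[breakable] = division_rate(cur_len[breakable], params)
        with np.errstate(divide="ignore"):
            wait = rng.exponential(1.0, size=cur_len.size) / rate
        t_break = cur_birth + wait
        breaks = t_break < horizon

        seg_len.append(cur_len)
        seg_h.append(cur_h)
        seg_lin.append(cur_lin)
        seg_birth.append(cur_birth)
        death = np.where(breaks, t_break, np.inf)
        seg_death.append(death)

        if not np.any(breaks):
            break
        bx = cur_len[breaks]
        p = kernel.sample(rng, bx.size)
        # Clamp so no fragment drops below the representable minimum.
        lo = MIN_FRAGMENT_NM / bx
        p = np.clip(p, lo, 1.0 - lo)
        frag_a = p * bx
        frag_b = bx - frag_a
        cur_len = np.concatenate([frag_a, frag_b])
        cur_h = np.tile(cur_h[breaks], 2)
        cur_lin = np.tile(cur_lin[breaks], 2)
        cur_birth = np.tile(t_break[breaks], 2)
        n_created += cur_len.size
        if n_created > max_particles:
            raise RuntimeError(
                f"fragmentation produced more than {max_particles} segments "
                f"(gamma={params.gamma}, alpha={params.alpha}); the rate law is "
                "in a runaway regime for this population -- reduce alpha/gamma, "
                "shorten the schedule, or raise max_particles"
            )

    lengths = np.concatenate(seg_len)
    heights = np.concatenate(seg_h)
    lineages = np.concatenate(seg_lin)
    births = np.concatenate(seg_birth)
    deaths = np.concatenate(seg_death)

    out = []
    for t in sample_times:
        # Leaves carry death = inf, so this also covers t == horizon.
        alive = (births <= t) & (deaths > t)
        out.append(
            FibrilPopulation(
                time=float(t),
                lengths=lengths[alive],
                heights=heights[alive],
                lineages=lineages[alive],
            )
        )
    return out


@dataclass
class MomentSolution:
    """Deterministic solution of the fragmentation population balance.

    ``density[i, j]`` is the number density n(t_i, x_j) on the length
    grid; moments are computed with trapezoidal weights.
    """

    times: np.ndarray
    grid: np.ndarray
    density: np.ndarray
    N: np.ndarray
    M1: np.ndarray
    M_gamma: np.ndarray
    mu: np.ndarray


def solve_moments(
    params: FragmentationParams,
    grid: np.ndarray,
    init_density: np.ndarray,
    times,
    kernel: BreakageKernel | None = None,
    mass_rtol: float = 5e-3,
) -> MomentSolution:
    """Integrate the binary-breakage population balance equation.

    Solves, by method of lines on the fixed length grid,

        dn(x,t)/dt = -B(x) n(x,t) + 2 * int_x^inf B(y) b(x/y)/y n(y,t) dy

    with ``B(x) = (alpha*x)**gamma`` and the kernel density ``b``. The
    discretised gain term is rescaled column-wise so that first-moment
    (mass) transfer is exact per breakage source node; the smallest node
    is treated as unbreakable, so total mass is conserved up to solver
    tolerance. Serves as the deterministic oracle for
    :func:`simulate_fragmentation`.

    Parameters
    ----------
    grid : array
        Strictly increasing length grid (nm) with >= 200 nodes covering
        the support of the initial condition.
    init_density : array
        Initial number density on the grid (1/nm); total mass must be > 0.
    times : sequence of float
        Output times (s), starting at >= 0.

    Raises
    ------
    ValueError
        If the grid is too coarse to conserve mass within ``mass_rtol``.
    """
    kernel = kernel or BreakageKernel()
    grid = np.asarray(grid, dtype=float)
    n0 = np.asarray(init_density, dtype=float)
    times = np.asarray(times, dtype=float)
    if grid.size < 200:
        raise ValueError("length grid must have at least 200 nodes")
    if np.any(np.diff(grid) <= 0) or grid[0] <= 0:
        raise ValueError("grid must be positive and strictly increasing")
    if n0.shape != grid.shape or np.any(n0 < 0):
        raise ValueError("init_density must be non-negative and match the grid")

    # Trapezoidal quadrature weights.
    w = np.zeros_like(grid)
    w[1:-1] = 0.5 * (grid[2:] - grid[:-2])
    w[0] = 0.5 * (grid[1] - grid[0])
    w[-1] = 0.5 * (grid[-1] - grid[-2])

    # Work with point masses at the grid pivots: N_i = w_i * n_i.
    Npt0 = w * n0
    mass0 = float(np.sum(grid * Npt0))
    if mass0 <= 0:
        raise ValueError("initial mass must be positive")

    B = np.asarray(division_rate(grid, params), dtype=float)
    B[0] = 0.0  # smallest pivot unbreakable: closes the mass budget on the grid

    K = grid.size
    # Fixed-pivot breakage matrix eta[i, j]: expected number of fragments
    # assigned to pivot i per breakage event at pivot j. Each fragment of
    # size v between pivots x_l < v < x_r is split linearly between the two
    # pivots so that fragment number AND mass are preserved exactly
    # (Kumar & Ramkrishna fixed-pivot technique).
    xl = grid[:-1][:, None]            # (K-1, 1) cell left edges
    xr = grid[1:][:, None]             # cell right edges
    xj = grid[None, :]                 # (1, K) source pivots
    ua = np.clip(xl / xj, 0.0, 1.0)
    ub = np.clip(xr / xj, 0.0, 1.0)
    I0 = 2.0 * (kernel.cdf(ub) - kernel.cdf(ua))                 # number in cell
    I1 = 2.0 * xj * (kernel.partial_moment(ub) - kernel.partial_moment(ua))  # mass
    dx = xr - xl
    left_w = (xr * I0 - I1) / dx       # to pivot i
    right_w = (I1 - xl * I0) / dx      # to pivot i+1
    eta = np.zeros((K, K))
    np.add.at(eta, np.arange(K - 1), left_w)
    eta[1:, :] += right_w
    # Fragments below the smallest pivot are counted at pivot 0.
    eta[0, :] += 2.0 * kernel.cdf(np.clip(grid[0] / grid, 0.0, 1.0))
    A = eta * B[None, :] - np.diag(B)

    sol = solve_ivp(
        lambda t, n: A @ n,
        (times[0], times[-1]),
        Npt0,
        t_eval=times,
        method="LSODA",
        rtol=1e-8,
        atol=1e-12 * max(1.0, float(Npt0.max())),
    )
    if not sol.success:
        raise RuntimeError(f"moment solver failed: {sol.message}")
    Npt = sol.y.T  # (T, K) point masses
    dens = Npt / w[None, :]

    N = Npt.sum(axis=1)
    M1 = Npt @ grid
    Mg = Npt @ grid**params.gamma
    mu = M1 / N
    mass_err = np.max(np.abs(M1 - mass0)) / mass0
    if mass_err > mass_rtol:
        raise ValueError(
            f"mass conservation error {mass_err:.2e} exceeds {mass_rtol:.0e}; "
            "refine the length grid (more nodes or wider coverage at small x)"
        )
    return MomentSolution(times=times, grid=grid, density=dens, N=N, M1=M1, M_gamma=Mg, mu=mu)


def apply_detection_limit(pop: FibrilPopulation, x_min: float) -> FibrilPopulation:
    """Drop fibrils shorter than ``x_min`` nm (imaging detection limit).

    Order of the surviving fibrils is preserved; x_min = 0 is the identity.
    """
    if x_min < 0:
        raise ValueError("x_min must be >= 0")
    keep = pop.lengths >= x_min
    return FibrilPopulation(
        time=pop.time,
        lengths=pop.lengths[keep],
        heights=pop.heights[keep],
        lineages=pop.lineages[keep],
    )


def population_to_grid(pop: FibrilPopulation, grid: np.ndarray) -> np.ndarray:
    """Represent a finite population as a number density on a length grid.

    Each fibril is split linearly between the two neighbouring grid pivots
    so that particle number and total length are both preserved exactly —
    the same apportioning rule the fixed-pivot solver uses internally.
    Returns a density suitable as ``init_density`` for :func:`solve_moments`.
    """
    grid = np.asarray(grid, dtype=float)
    L = pop.lengths
    if np.any(L < grid[0]) or np.any(L > grid[-1]):
        raise ValueError("population lengths fall outside the grid")
    Npt = np.zeros(grid.size)
    hi = np.clip(np.searchsorted(grid, L), 1, grid.size - 1)
    lo = hi - 1
    frac_hi = (L - grid[lo]) / (grid[hi] - grid[lo])
    np.add.at(Npt, lo, 1.0 - frac_hi)
    np.add.at(Npt, hi, frac_hi)
    w = np.zeros_like(grid)
    w[1:-1] = 0.5 * (grid[2:] - grid[:-2])
    w[0] = 0.5 * (grid[1] - grid[0])
    w[-1] = 0.5 * (grid[-1] - grid[-2])
    return Npt / w


# ---------------------------------------------------------------------------
# Serialization: populations to/from tidy CSV with a JSON metadata sidecar.

def population_to_frame(pop: FibrilPopulation) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "time_s": pop.time,
            "fibril_id": np.arange(len(pop)),
            "lineage_id": pop.lineages,
            "length_nm": pop.lengths,
            "height_nm": pop.heights,
        }
    )


def populations_to_csv(pops, path, meta: dict | None = None) -> None:
    """Write a list of snapshots to one tidy CSV (+ JSON sidecar of metadata)."""
    df = pd.concat([population_to_frame(p) for p in pops], ignore_index=True)
    df.to_csv(path, index=False)
    if meta is not None:
        with open(str(path) + ".json", "w") as fh:
            json.dump(meta, fh, indent=2, default=str)


def populations_from_csv(path) -> list[FibrilPopulation]:
    df = pd.read_csv(path)
    pops = []
    for t, g in df.groupby("time_s", sort=True):
        pops.append(
            FibrilPopulation(
                time=float(t),
                lengths=g["length_nm"].to_numpy(),
                heights=g["height_nm"].to_numpy(),
                lineages=g["lineage_id"].to_numpy(),
            )
        )
    return pops
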