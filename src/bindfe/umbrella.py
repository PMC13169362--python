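"""Umbrella-sampling leg: harmonic biases, per-window unbiasing, WHAM, and
PMF-depth to standard-state binding free energy.

The reaction coordinate is the ligand-pocket centre-of-mass distance in the
intended application, but every routine here is coordinate-agnostic and works
on 1D sample series in Å.  Per-window unbiasing follows
A(s) = A'(s) - w(s) - kT ln<exp(-w(s)/kT)>; multiple windows are stitched by
the standard WHAM self-consistent equations.  Uncertainty bands come from the
block bootstrap with five contiguous sub-blocks per window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .alchemical import FreeEnergyEstimate
from .core import ConvergenceError, CoverageError, EstimationError, ThermoContext


@dataclass
class UmbrellaWindow:
    """Harmonically biased window: centre z_i (Å), force constant k_i
    (kcal/mol/Å^2) and the retained time-ordered coordinate samples (Å)."""

    center: float
    k: float
    samples: np.ndarray
    equilibration_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise EstimationError("window force constant must be positive")
        if not (0.0 <= self.equilibration_fraction < 1.0):
            raise EstimationError("equilibration fraction must lie in [0, 1)")
        s = np.asarray(self.samples, dtype=float)
        n_skip = int(np.floor(self.equilibration_fraction * len(s)))
        s = s[n_skip:]
        if len(s) < 1:
            raise EstimationError("window retains no samples after equilibration discard")
        if not np.all(np.isfinite(s)):
            raise EstimationError("window samples must be finite")
        self.samples = s


@dataclass
class PMFProfile:
    """Reconstructed free-energy profile W(z), normalised to min = 0."""

    grid: np.ndarray              # bin centres, Å, strictly increasing
    values: np.ndarray            # kcal/mol; NaN where coverage is absent
    band: np.ndarray | None = None   # pointwise 1-SD, kcal/mol
    converged: bool = True
    iterations: int = 0
    window_constants: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(np.diff(self.grid) <= 0):
            raise EstimationError("PMF grid must be strictly increasing")
        finite = np.isfinite(self.values)
        if finite.any():
            self.values = self.values - np.nanmin(self.values[finite])


def bias_energy(z: float | np.ndarray, window: UmbrellaWindow) -> float | np.ndarray:
    """Harmonic bias 0.5 k_i (z - z_i)^2, kcal/mol."""
    z = np.asarray(z, dtype=float)
    out = 0.5 * window.k * (z - window.center) ** 2
    return float(out) if out.ndim == 0 else out


def make_grid(windows: list[UmbrellaWindow], n_bins: int = 200) -> np.ndarray:
    """Default histogram grid: uniform bins over the pooled sample range,
    padded by one bin on each side.  Returns bin *edges* (n_bins + 1)."""
    lo = min(float(w.samples.min()) for w in windows)
    hi = max(float(w.samples.max()) for w in windows)
    width = (hi - lo) / n_bins
    if width <= 0:
        width = 1e-6
    return np.linspace(lo - width, hi + width, n_bins + 1)


def _histogram(window: UmbrellaWindow, edges: np.ndarray) -> np.ndarray:
    counts, _ = np.histogram(window.samples, bins=edges)
    return counts.astype(float)


def unbias_window(
    window: UmbrellaWindow,
    edges: np.ndarray,
    ctx: ThermoContext,
    min_samples: int = 50,
) -> np.ndarray:
    """Single-window unbiased free-energy fragment on the grid.

    Histograms the biased samples into A'(s) = -kT ln p_biased(s), subtracts
    the bias w(s) and the window free-energy constant
    -kT ln<exp(-w/kT)> (the log-average over the biased ensemble).  Bins with
    no samples are returned as NaN (masked), never zero-filled.
    """
    if len(window.samples) < min_samples:
        raise EstimationError(
            f"window at z={window.center} has {len(window.samples)} samples; "
            f"need >= {min_samples}"
        )
    counts = _histogram(window, edges)
    if counts.sum() == 0:
        raise CoverageError(f"window at z={window.center}: all histogram bins empty")
    kT = ctx.kT
    centers = 0.5 * (edges[:-1] + edges[1:])
    with np.errstate(divide="ignore"):
        a_biased = -kT * np.log(counts / counts.sum())
    w = bias_energy(centers, window)
    # window constant from the sampled (biased) ensemble: -kT ln <exp(-w(z)/kT)>
    w_samp = bias_energy(window.samples, window)
    const = -kT * (logsumexp(-w_samp / kT) - np.log(len(window.samples)))
    frag = a_biased - w - const
    frag[counts == 0] = np.nan
    return frag


def wham_pmf(
    windows: list[UmbrellaWindow],
    edges: np.ndarray | None = None,
    n_bins: int = 200,
    tol: float = 1e-7,
    max_iter: int = 100000,
    ctx: ThermoContext | None = None,
) -> PMFProfile:
    """WHAM reconstruction of the unbiased PMF from all umbrella windows.

    Iterates the self-consistent WHAM equations (in log space) until the
    largest change in any window free-energy constant is below ``tol`` (in
    kT).  The profile is normalised so its minimum is zero; bins visited by
    no window are NaN.  Window order does not affect the result.

    Raises
    ------
    CoverageError
        If the pooled histograms leave an internal gap (disjoint windows).
    ConvergenceError
        If ``max_iter`` is exceeded.
    """
    if len(windows) < 1:
        raise EstimationError("need at least one window")
    ctx = ctx or ThermoContext()
    kT = ctx.kT
    # sort by centre so the output is independent of input order
    windows = sorted(windows, key=lambda w: (w.center, w.k, len(w.samples)))
    if edges is None:
        edges = make_grid(windows, n_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])

    counts = np.stack([_histogram(w, edges) for w in windows])   # (W, B)
    n_w = counts.sum(axis=1)                                     # samples per window
    if np.any(n_w == 0):
        bad = [w.center for w, n in zip(windows, n_w) if n == 0]
        raise CoverageError(f"windows at {bad} have no samples on the grid")
    pooled = counts.sum(axis=0)
    occupied = pooled > 0
    if len(windows) >= 2:
        bin_width = float(edges[1] - edges[0])
        for a, b, ca, cb in zip(windows[:-1], windows[1:], counts[:-1], counts[1:]):
            if a.samples.max() < b.samples.min() - bin_width:
                raise CoverageError(
                    f"disjoint windows: no samples on "
                    f"[{a.samples.max():.3f}, {b.samples.min():.3f}] Å between "
                    f"windows at {a.center} and {b.center}")
            if not np.any((ca > 0) & (cb > 0)):
                import warnings

                warnings.warn(
                    f"adjacent windows at {a.center} and {b.center} share no "
                    "occupied bin; WHAM stitching may be unreliable",
                    stacklevel=2,
                )

    # log c_ib = -beta * w_i(z_b)
    log_bias = np.stack([-bias_energy(centers, w) / kT for w in windows])  # (W, B)
    log_n_w = np.log(n_w)
    g = np.zeros(len(windows))         # dimensionless window constants f_i
    converged = False
    it = 0
    with np.errstate(divide="ignore"):
        log_pooled = np.where(occupied, np.log(pooled), -np.inf)
    for it in range(1, max_iter + 1):
        # log p_b = log sum_i n_ib - log sum_i N_i exp(g_i - beta w_ib)
        log_denom = logsumexp(log_bias + (g + log_n_w)[:, None], axis=0)
        log_p = log_pooled - log_denom
        # renormalise p and update window constants g_i = -ln sum_b c_ib p_b
        log_p -= logsumexp(log_p[occupied])
        g_new = -logsumexp(log_bias[:, occupied] + log_p[None, occupied], axis=1)
        g_new -= g_new[0]
        residual = float(np.max(np.abs(g_new - g)))
        g = g_new
        if residual < tol:
            converged = True
            break
    if not converged:
        raise ConvergenceError(
            f"WHAM did not converge in {max_iter} iterations (residual {residual:.3e} kT)",
            residual=residual,
        )
    values = np.full(len(centers), np.nan)
    values[occupied] = -kT * log_p[occupied]
    return PMFProfile(grid=centers, values=values, converged=True, iterations=it,
                      window_constants=kT * g)


def pmf_binding_dG(
    profile: PMFProfile,
    bound_region: tuple[float, float] | None = None,
    cross_section: float = 1.0,
    ctx: ThermoContext | None = None,
    plateau_fraction: float = 0.15,
    rise_kT: float = 2.0,
) -> FreeEnergyEstimate:
    """Standard-state binding free energy from the depth of a PMF.

    dG_bind = -kT ln[ (A / V0) * integral_bound exp(-beta (W(z) - W_unbound)) dz ]
    where A is the effective lateral cross-section (Å^2) of the sampled
    channel, V0 the 1 M standard-state volume and W_unbound the mean of the
    flat unbound plateau (the last ``plateau_fraction`` of the covered grid).

    When ``bound_region`` is None the basin extends from the grid start to the
    first point past the global minimum where W rises ``rise_kT`` kT above it.
    """
    ctx = ctx or ThermoContext()
    kT = ctx.kT
    finite = np.isfinite(profile.values)
    grid = profile.grid[finite]
    w = profile.values[finite]
    if len(grid) < 3:
        raise EstimationError("PMF has too few covered grid points")
    i_min = int(np.argmin(w))
    if bound_region is None:
        j = i_min
        while j < len(grid) - 1 and w[j] < w[i_min] + rise_kT * kT:
            j += 1
        bound_region = (float(grid[0]), float(grid[j]))
    lo, hi = bound_region
    if lo > grid[i_min] or hi < grid[i_min]:
        raise EstimationError("bound region must contain the global PMF minimum")
    n_tail = max(3, int(np.ceil(plateau_fraction * len(grid))))
    tail = w[-n_tail:]
    w_unbound = float(tail.mean())
    tail_slope = np.polyfit(grid[-n_tail:], tail, 1)[0]
    flags = []
    if abs(tail_slope) > 0.5:  # kcal/mol/Å
        import warnings

        warnings.warn("PMF is not flat at the unbound end; plateau reference "
                      "may be biased", stacklevel=2)
        flags.append("non-flat plateau")
    in_bound = (grid >= lo) & (grid <= hi)
    integrand = np.exp(-(w[in_bound] - w_unbound) / kT)
    integral = float(np.trapezoid(integrand, grid[in_bound]))
    value = -kT * np.log(cross_section * integral / ctx.standard_volume)
    return FreeEnergyEstimate(value=float(value), uncertainty=0.0, method="WHAM",
                              temperature=ctx.temperature, flags=flags)


def lateral_cross_section(k_lat: float, ctx: ThermoContext) -> float:
    """Effective lateral area 2 pi kT / k_lat (Å^2) of a planar harmonic
    restraint with force constant ``k_lat`` (kcal/mol/Å^2)."""
    if k_lat <= 0:
        raise EstimationError("lateral force constant must be positive")
    return float(2.0 * np.pi * ctx.kT / k_lat)


@dataclass
class PMFBootstrapResult:
    pointwise_sd: np.ndarray
    dG_sd: float
    n_failures: int = 0
    dG_samples: np.ndarray = field(default_factory=lambda: np.empty(0))


def pmf_bootstrap_band(
    windows: list[UmbrellaWindow],
    edges: np.ndarray | None = None,
    n_bins: int = 200,
    n_blocks: int = 5,
    n_boot: int = 100,
    seed: int = 0,
    ctx: ThermoContext | None = None,
    cross_section: float = 1.0,
    bound_region: tuple[float, float] | None = None,
) -> PMFBootstrapResult:
    """Block-bootstrap error band for the WHAM PMF and its binding dG.

    Each window's time series is split into ``n_blocks`` contiguous blocks
    which are resampled with replacement; WHAM is re-run per resample on the
    *fixed* reference grid.  Deterministic given the seed.  Individual WHAM
    failures are counted; more than 10% aborts.
    """
    ctx = ctx or ThermoContext()
    base_windows = sorted(windows, key=lambda w: (w.center, w.k))
    if edges is None:
        edges = make_grid(base_windows, n_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    if n_boot <= 0:
        return PMFBootstrapResult(pointwise_sd=np.zeros(len(centers)), dG_sd=0.0)
    for w in base_windows:
        if len(w.samples) < n_blocks:
            raise EstimationError(
                f"window at z={w.center} too short to split into {n_blocks} blocks")
    rng = np.random.default_rng(seed)
    profiles = []
    dgs = []
    failures = 0
    for _ in range(n_boot):
        resampled = []
        for w in base_windows:
            blocks = np.array_split(w.samples, n_blocks)
            idx = rng.integers(0, n_blocks, size=n_blocks)
            series = np.concatenate([blocks[i] for i in idx])
            resampled.append(UmbrellaWindow(center=w.center, k=w.k, samples=series))
        try:
            prof = wham_pmf(resampled, edges=edges, ctx=ctx)
            dg = pmf_binding_dG(prof, bound_region=bound_region,
                                cross_section=cross_section, ctx=ctx)
        except (ConvergenceError, CoverageError, EstimationError):
            failures += 1
            continue
        profiles.append(prof.values)
        dgs.append(dg.value)
    if failures > 0.1 * n_boot:
        raise EstimationError(
            f"{failures}/{n_boot} bootstrap WHAM resamples failed")
    stack = np.vstack(profiles)
    pointwise = np.full(len(centers), np.nan)
    cover = np.isfinite(stack).all(axis=0)
    pointwise[cover] = np.std(stack[:, cover], axis=0, ddof=1)
    return PMFBootstrapResult(
        pointwise_sd=pointwise,
        dG_sd=float(np.std(dgs, ddof=1)) if len(dgs) > 1 else 0.0,
        n_failures=failures,
        dG_samples=np.asarray(dgs),
    )
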