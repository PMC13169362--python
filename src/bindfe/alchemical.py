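"""Alchemical absolute-binding-free-energy leg.

Free-energy differences across a λ ladder are estimated from sampled reduced
potentials with the one-sided exponential-averaging (Zwanzig) estimator and
with MBAR, the multistate generalisation of the Bennett acceptance ratio.
Electrostatics are decoupled before van der Waals along the ladder; the two
legs (complex and aqueous solution) are combined through a thermodynamic
cycle with an analytic restraint/standard-state correction.

All reduced potentials are dimensionless (units of k_B T); estimates are
reported in kcal/mol via the shared :class:`~bindfe.core.ThermoContext`.
Uncertainties follow the block-bootstrap scheme with five contiguous
sub-blocks acting as quasi-independent replicas of a correlated series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .core import (
    ConvergenceError,
    EstimationError,
    InvalidContextError,
    ThermoContext,
)


@dataclass(frozen=True)
class LambdaState:
    lam_coul: float
    lam_vdw: float
    stage: str = "electrostatics"  # electrostatics | vdw


@dataclass
class LambdaSchedule:
    """Two-stage decoupling schedule: charges off first, then van der Waals."""

    states: list[LambdaState]

    def __post_init__(self) -> None:
        for s in self.states:
            if not (0.0 <= s.lam_coul <= 1.0 and 0.0 <= s.lam_vdw <= 1.0):
                raise ValueError("lambda values must lie in [0, 1]")
        elec = [s for s in self.states if s.stage == "electrostatics"]
        vdw = [s for s in self.states if s.stage == "vdw"]
        if any(s.lam_vdw != 1.0 for s in elec):
            raise ValueError("electrostatics stage must keep lam_vdw = 1 (fully coupled)")
        if any(s.lam_coul != 0.0 for s in vdw):
            raise ValueError("vdw stage must run at lam_coul = 0")
        for seq in (elec, vdw):
            lams = [s.lam_coul if s.stage == "electrostatics" else s.lam_vdw for s in seq]
            diffs = np.diff(lams)
            if len(diffs) and not (np.all(diffs >= 0) or np.all(diffs <= 0)):
                raise ValueError("lambda values must be monotone within a stage")


@dataclass
class ReducedPotentialMatrix:
    """K-state x N-sample matrix of dimensionless potential-energy evaluations.

    ``u[k, n]`` is the reduced potential of pooled sample n evaluated under the
    Hamiltonian of state k; ``counts[j]`` is the number of samples drawn from
    state j.  States with ``counts == 0`` are legal perturbation targets.
    """

    u: np.ndarray            # (K, N) float
    counts: np.ndarray       # (K,) int
    states: list[LambdaState] | None = None

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        if self.u.ndim != 2 or self.u.shape[0] < 2:
            raise EstimationError("need a (K>=2, N) reduced potential matrix")
        if self.counts.shape != (self.u.shape[0],):
            raise EstimationError("counts must have one entry per state")
        if self.counts.sum() != self.u.shape[1]:
            raise EstimationError(
                f"sum of counts ({self.counts.sum()}) must equal the number of "
                f"sample columns ({self.u.shape[1]})"
            )
        if not np.all(np.isfinite(self.u)):
            raise EstimationError("reduced potentials must be finite")

    @property
    def n_states(self) -> int:
        return self.u.shape[0]

    @property
    def n_samples(self) -> int:
        return self.u.shape[1]


@dataclass
class FreeEnergyEstimate:
    """A free-energy value with 1-SD uncertainty and method provenance."""

    value: float                      # kcal/mol
    uncertainty: float                # kcal/mol, 1 SD
    method: str                       # EXP | MBAR | WHAM | MMPBSA
    temperature: float = 300.0
    per_interval: np.ndarray | None = None   # kcal/mol per adjacent interval
    converged: bool = True
    iterations: int = 0
    gauge_note: str = "state 0 fixed at 0"
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.uncertainty < 0:
            raise EstimationError("uncertainty must be >= 0")


@dataclass
class OverlapMatrix:
    """Row-stochastic K x K phase-space overlap matrix."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if np.any(self.matrix < -1e-12):
            raise EstimationError("overlap entries must be non-negative")
        rows = self.matrix.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=1e-10):
            raise EstimationError("overlap rows must sum to 1")

    @property
    def bottleneck(self) -> float:
        """Smallest nearest-neighbour off-diagonal entry (schedule diagnostic)."""
        k = self.matrix.shape[0]
        neigh = [min(self.matrix[i, i + 1], self.matrix[i + 1, i]) for i in range(k - 1)]
        return float(min(neigh)) if neigh else 1.0


def bootstrap_uncertainty(
    samples: np.ndarray,
    statistic,
    n_blocks: int = 5,
    n_boot: int = 200,
    seed: int = 0,
) -> float:
    """Block-bootstrap SD of ``statistic`` over a (possibly correlated) series.

    The series is cut into ``n_blocks`` contiguous blocks treated as
    quasi-independent replicas; blocks are resampled with replacement
    ``n_boot`` times.  Deterministic for a fixed seed.
    """
    samples = np.asarray(samples)
    if n_blocks < 2:
        raise EstimationError("need n_blocks >= 2")
    if len(samples) < n_blocks:
        raise EstimationError("series shorter than the number of blocks")
    if n_boot <= 0:
        return 0.0
    blocks = np.array_split(samples, n_blocks)
    rng = np.random.default_rng(seed)
    vals = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n_blocks, size=n_blocks)
        resample = np.concatenate([blocks[i] for i in idx])
        try:
            vals[b] = statistic(resample)
        except Exception as exc:  # noqa: BLE001 - annotate resample index
            raise EstimationError(f"statistic failed on bootstrap resample {b}: {exc}") from exc
    return float(np.std(vals, ddof=1))


def _exp_reduced(delta_u: np.ndarray) -> float:
    """beta*dG of the Zwanzig estimator, computed in log space."""
    n = len(delta_u)
    return float(-(logsumexp(-delta_u) - np.log(n)))


def exp_estimate(
    delta_u: np.ndarray,
    ctx: ThermoContext,
    n_blocks: int = 5,
    n_boot: int = 200,
    seed: int = 0,
) -> FreeEnergyEstimate:
    """Zwanzig (one-sided exponential averaging) free-energy estimate.

    ``delta_u`` holds dimensionless work samples u_B - u_A collected in state
    A; the estimate is dG = -kT ln <exp(-du)>_A, evaluated with log-sum-exp so
    samples up to |du| ~ 700 do not overflow.
    """
    delta_u = np.asarray(delta_u, dtype=float)
    if delta_u.size == 0:
        raise EstimationError("EXP needs at least one work sample")
    if delta_u.size < 2:
        raise EstimationError("EXP needs >= 2 samples for an uncertainty estimate")
    if np.all(np.isinf(delta_u)):
        raise EstimationError("degenerate overlap: all work samples infinite")
    kT = ctx.kT
    value = kT * _exp_reduced(delta_u)
    sd = kT * bootstrap_uncertainty(delta_u, _exp_reduced, n_blocks, n_boot, seed)
    return FreeEnergyEstimate(value=value, uncertainty=sd, method="EXP",
                              temperature=ctx.temperature)


def _mbar_denominator(u: np.ndarray, f: np.ndarray, log_counts: np.ndarray) -> np.ndarray:
    """log D_n = log sum_j N_j exp(f_j - u_j(x_n)) for every pooled sample."""
    return logsumexp(f[:, None] - u + log_counts[:, None], axis=0)


def mbar_solve(
    matrix: ReducedPotentialMatrix,
    tol: float = 1e-8,
    max_iter: int = 10000,
    ctx: ThermoContext | None = None,
) -> FreeEnergyEstimate:
    """Self-consistent MBAR solve for the dimensionless state free energies.

    Iterates f_k <- -ln sum_n exp(-u_k(x_n)) / sum_j N_j exp(f_j - u_j(x_n))
    with log-sum-exp accumulation until the largest change in any f_k (after
    regauging f_0 = 0) falls below ``tol``.  States with zero samples are
    valid perturbation targets and are flagged in the output.

    Returns a :class:`FreeEnergyEstimate` whose ``per_interval`` array holds
    the dimensionless f_k ladder (gauge f_0 = 0); ``value`` is the end-to-end
    difference f_{K-1} - f_0 in kcal/mol when a context is given, else in kT.
    """
    if tol <= 0:
        raise EstimationError("tol must be positive")
    u = matrix.u
    counts = matrix.counts
    sampled = counts > 0
    # zero-count states contribute nothing to the denominator: log N_j -> -inf
    with np.errstate(divide="ignore"):
        log_counts = np.where(sampled, np.log(np.maximum(counts, 1)), -np.inf)
    f = np.zeros(matrix.n_states)
    converged = False
    it = 0
    residual = np.inf
    for it in range(1, max_iter + 1):
        log_denom = _mbar_denominator(u, f, log_counts)
        f_new = -logsumexp(-u - log_denom[None, :], axis=1)
        f_new -= f_new[0]
        residual = float(np.max(np.abs(f_new - f)))
        f = f_new
        if residual < tol:
            converged = True
            break
    if not converged:
        raise ConvergenceError(
            f"MBAR did not converge in {max_iter} iterations (residual {residual:.3e})",
            residual=residual,
        )
    kT = ctx.kT if ctx is not None else 1.0
    flags = [f"state {k} has no samples (perturbation target)"
             for k in range(matrix.n_states) if not sampled[k]]
    return FreeEnergyEstimate(
        value=kT * float(f[-1] - f[0]),
        uncertainty=0.0,
        method="MBAR",
        temperature=ctx.temperature if ctx is not None else 0.0,
        per_interval=f.copy(),
        converged=True,
        iterations=it,
        flags=flags,
    )


def mbar_overlap(matrix: ReducedPotentialMatrix, estimate: FreeEnergyEstimate) -> OverlapMatrix:
    """Overlap matrix O_ij = sum_n N_j W_ni W_nj from a converged MBAR solve.

    Rows sum to one at self-consistency; the smallest nearest-neighbour
    off-diagonal entry is the ladder's bottleneck diagnostic
    (:attr:`OverlapMatrix.bottleneck`).
    """
    if estimate.per_interval is None or estimate.method != "MBAR":
        raise EstimationError("mbar_overlap requires a converged MBAR estimate")
    f = np.asarray(estimate.per_interval, dtype=float)
    counts = matrix.counts
    sampled = counts > 0
    with np.errstate(divide="ignore"):
        log_counts = np.where(sampled, np.log(np.maximum(counts, 1)), -np.inf)
    log_denom = _mbar_denominator(matrix.u, f, log_counts)
    log_w = f[:, None] - matrix.u - log_denom[None, :]       # (K, N)
    w = np.exp(log_w)
    overlap = w @ (w.T * counts[None, :])                    # O_ij = sum_n W_ni N_j W_nj
    # regularise tiny negative round-off and renormalise rows
    overlap = np.clip(overlap, 0.0, None)
    overlap /= overlap.sum(axis=1, keepdims=True)
    return OverlapMatrix(matrix=overlap)


def harmonic_restraint_correction(k_restraint: float, ctx: ThermoContext) -> float:
    """Free-energy cost of releasing an isotropic 3D harmonic restraint to 1 M.

    dG_release = -kT ln[ V0 / (2 pi kT / k)^{3/2} ], added to the
    decoupled-leg sum.  ``k_restraint`` in kcal/mol/Å^2.
    """
    if k_restraint <= 0:
        raise EstimationError("restraint force constant must be positive")
    kT = ctx.kT
    v_restraint = (2.0 * np.pi * kT / k_restraint) ** 1.5
    return float(-kT * np.log(ctx.standard_volume / v_restraint))


def cycle_binding_dG(
    complex_leg: FreeEnergyEstimate,
    solvent_leg: FreeEnergyEstimate,
    restraint_corr: float = 0.0,
) -> FreeEnergyEstimate:
    """Assemble dG_bind from the two decoupling legs of the thermodynamic cycle.

    dG_bind = -(dG_complex - dG_solvent) + dG_restraint, uncertainties in
    quadrature; negative values are favourable binding.
    """
    if complex_leg.temperature != solvent_leg.temperature:
        raise InvalidContextError("legs were estimated at different temperatures")
    value = -(complex_leg.value - solvent_leg.value) + restraint_corr
    sd = float(np.hypot(complex_leg.uncertainty, solvent_leg.uncertainty))
    return FreeEnergyEstimate(value=value, uncertainty=sd, method="MBAR",
                              temperature=complex_leg.temperature,
                              gauge_note="thermodynamic cycle")


def statistical_inefficiency(series: np.ndarray) -> float:
    """Integrated-autocorrelation statistical inefficiency g = 1 + 2 tau.

    Optional subsampler support; inputs to the estimators are normally
    assumed pre-subsampled (the block bootstrap handles residual correlation).
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    if n < 3:
        return 1.0
    x = x - x.mean()
    var = np.dot(x, x) / n
    if var == 0:
        return 1.0
    g = 1.0
    for t in range(1, n - 1):
        c = np.dot(x[:-t], x[t:]) / ((n - t) * var)
        if c <= 0:
            break
        g += 2.0 * c * (1.0 - t / n)
    return max(1.0, g)


def subsample_series(series: np.ndarray) -> np.ndarray:
    """Thin a correlated series to ~independent samples via its inefficiency."""
    g = statistical_inefficiency(series)
    stride = max(1, int(np.ceil(g)))
    return np.asarray(series)[::stride]
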