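"""Paralogue selectivity statistics.

Experimental IC50 values are converted to binding free energies through
dG = RT ln(IC50 in molar) with first-order error propagation
sigma_dG = RT sigma_IC50 / IC50.  Selectivity for one ligand across two
targets is ddG = dG(target1) - dG(target2) (negative = selective for
target1).  Method-vs-method and method-vs-experiment agreement is summarised
by an ordinary least-squares fit, its R^2, and the deviation metric
D = sqrt((1/n) sum_i (y_fit,i - y_data,i)^2) in kcal/mol.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .core import EstimationError, PairingError, ThermoContext


@dataclass(frozen=True)
class IC50Record:
    """One experimental potency measurement.  IC50 and sigma in molar."""

    ligand: str
    target: str
    ic50: float
    sigma: float | None = None
    provenance: str = ""

    def __post_init__(self) -> None:
        if not np.isfinite(self.ic50) or self.ic50 <= 0:
            raise EstimationError(f"IC50 must be positive, got {self.ic50}")
        if self.sigma is not None and self.sigma < 0:
            raise EstimationError("sigma_IC50 must be >= 0")


@dataclass(frozen=True)
class AffinityRecord:
    """A binding free energy (kcal/mol) with 1-SD uncertainty and method tag."""

    ligand: str
    target: str
    dG: float
    sigma: float = 0.0
    method: str = "EXPERIMENT"   # MMPBSA | ABFE | US | EXPERIMENT

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise EstimationError("sigma must be >= 0")


@dataclass(frozen=True)
class DDGRecord:
    ligand: str
    target_pair: tuple[str, str]
    ddG: float
    sigma: float
    method: str


@dataclass
class CorrelationReport:
    """OLS fit of paired ddG values with R^2 and the deviation metric D."""

    slope: float
    intercept: float
    r_squared: float
    deviation: float                 # D, kcal/mol
    n: int
    points: pd.DataFrame = field(default_factory=pd.DataFrame)
    excluded: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (-1e-12 <= self.r_squared <= 1.0 + 1e-12):
            raise EstimationError(f"R^2 out of range: {self.r_squared}")
        if self.deviation < 0:
            raise EstimationError("D must be >= 0")


def ic50_to_dG(rec: IC50Record, ctx: ThermoContext | None = None) -> AffinityRecord:
    """dG_binding = RT ln(IC50[M]), kcal/mol; tagged EXPERIMENT."""
    ctx = ctx or ThermoContext()
    dg = ctx.kT * float(np.log(rec.ic50))
    sigma = ic50_sigma_to_dG_sigma(rec, ctx)
    return AffinityRecord(ligand=rec.ligand, target=rec.target, dG=dg,
                          sigma=sigma if sigma is not None else 0.0,
                          method="EXPERIMENT")


def ic50_sigma_to_dG_sigma(rec: IC50Record, ctx: ThermoContext | None = None) -> float | None:
    """First-order propagated uncertainty RT * sigma_IC50 / IC50, kcal/mol.

    Returns None (absent, not zero) when no sigma is recorded.
    """
    if rec.sigma is None:
        return None
    ctx = ctx or ThermoContext()
    return ctx.kT * rec.sigma / rec.ic50


def dG_to_ic50(dG: float, ctx: ThermoContext | None = None) -> float:
    """Inverse of :func:`ic50_to_dG`: IC50[M] = exp(dG / RT)."""
    ctx = ctx or ThermoContext()
    return float(np.exp(dG / ctx.kT))


def ddG_selectivity(a: AffinityRecord, b: AffinityRecord) -> DDGRecord:
    """Selectivity ddG = dG(a.target) - dG(b.target) for one ligand and method.

    Uncertainties combine in quadrature; negative ddG means the ligand is
    selective for ``a``'s target.
    """
    if a.ligand != b.ligand:
        raise PairingError(f"ligand mismatch: {a.ligand} vs {b.ligand}")
    if a.method != b.method:
        raise PairingError(f"method mismatch: {a.method} vs {b.method}")
    if a.target == b.target:
        raise PairingError("ddG needs two distinct targets")
    return DDGRecord(
        ligand=a.ligand,
        target_pair=(a.target, b.target),
        ddG=a.dG - b.dG,
        sigma=float(np.hypot(a.sigma, b.sigma)),
        method=a.method,
    )


def regression_with_deviation(
    x: np.ndarray,
    y: np.ndarray,
    labels: list[str] | None = None,
    exclude: list[str] | None = None,
) -> CorrelationReport:
    """OLS of y on x with R^2 and the deviation metric D (root mean squared
    residual about the fitted line, kcal/mol).  Exclusions are applied by
    label before fitting and logged in the report."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    labels = list(labels) if labels is not None else [str(i) for i in range(len(x))]
    exclude = list(exclude or [])
    keep = np.asarray([lab not in exclude for lab in labels])
    xs, ys = x[keep], y[keep]
    kept_labels = [lab for lab in labels if lab not in exclude]
    if len(xs) < 3:
        raise EstimationError(f"need >= 3 points after exclusions, have {len(xs)}")
    if np.allclose(xs, xs[0]):
        raise EstimationError("degenerate fit: zero variance in x")
    fit = stats.linregress(xs, ys)
    y_fit = fit.slope * xs + fit.intercept
    resid = y_fit - ys
    d = float(np.sqrt(np.mean(resid ** 2)))
    points = pd.DataFrame({
        "ligand": kept_labels, "x": xs, "y": ys, "y_fit": y_fit, "residual": resid,
    })
    return CorrelationReport(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue ** 2),
        deviation=d,
        n=len(xs),
        points=points,
        excluded=exclude,
    )


def ddG_table(affinities: list[AffinityRecord],
              target_pair: tuple[str, str]) -> pd.DataFrame:
    """Per-ligand, per-method ddG between the two targets.

    Ligand/method combinations missing one of the two targets are listed in
    the frame with NaN ddG rather than silently dropped.
    """
    t1, t2 = target_pair
    by_key: dict[tuple[str, str, str], AffinityRecord] = {}
    for rec in affinities:
        by_key[(rec.ligand, rec.method, rec.target)] = rec
    ligands = sorted({r.ligand for r in affinities})
    methods = sorted({r.method for r in affinities})
    rows = []
    for lig in ligands:
        for m in methods:
            a = by_key.get((lig, m, t1))
            b = by_key.get((lig, m, t2))
            if a is None and b is None:
                continue
            if a is None or b is None:
                rows.append({"ligand": lig, "method": m, "ddG": np.nan,
                             "sigma": np.nan, "missing": t1 if a is None else t2})
            else:
                rec = ddG_selectivity(a, b)
                rows.append({"ligand": lig, "method": m, "ddG": rec.ddG,
                             "sigma": rec.sigma, "missing": ""})
    return pd.DataFrame(rows)


def method_comparison_table(
    affinities: list[AffinityRecord],
    target_pair: tuple[str, str],
    exclude: list[str] | None = None,
) -> tuple[pd.DataFrame, dict[tuple[str, str], CorrelationReport]]:
    """ddG matrix (ligand x method) plus pairwise correlation reports.

    Every ordered method pair (x=method A, y=method B over the same ligands)
    gets a :class:`CorrelationReport`; pairs lacking enough common ligands
    are skipped with the missing ligands recorded in the table.
    """
    table = ddG_table(affinities, target_pair)
    if table.empty:
        raise EstimationError("no ddG records could be formed")
    wide = table.pivot(index="ligand", columns="method", values="ddG")
    reports: dict[tuple[str, str], CorrelationReport] = {}
    for ma, mb in combinations(sorted(wide.columns), 2):
        sub = wide[[ma, mb]].dropna()
        if len(sub) < 3:
            continue
        reports[(ma, mb)] = regression_with_deviation(
            sub[ma].to_numpy(), sub[mb].to_numpy(),
            labels=list(sub.index), exclude=exclude,
        )
    return table, reports
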