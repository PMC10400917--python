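"""REST2 corresponding-states analysis and two-state melting fits.

A replica-exchange-with-solute-tempering run scales the solute Hamiltonian
of each replica by a factor lambda <= 1 at one bath temperature. Under the
law of corresponding states a replica at scaling lambda behaves like the
solute at an effective temperature ``T_eff = T_ref / lambda``, so the per-
replica time series of an order parameter (helical fraction or a folded
flag) assemble directly into a thermal unfolding curve. The curve is then
fit with a two-state van 't Hoff model

    f(T) = b_u + (b_f - b_u) / (1 + exp[(dH/R) (1/Tm - 1/T)])

with constant folded/unfolded baselines, giving the melting temperature Tm
and the van 't Hoff enthalpy dH; condition differences are reported as
delta-Tm. Absolute effective temperatures from solute tempering can be
overestimated; differences between conditions are the robust quantity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "R_GAS",
    "LambdaLadder",
    "UnfoldingCurve",
    "TwoStateFit",
    "NonIdentifiableError",
    "make_ladder",
    "effective_temperature",
    "build_curve",
    "two_state_model",
    "fit_two_state",
    "delta_tm",
]

R_GAS = 8.314  # J / (mol K)


class NonIdentifiableError(ValueError):
    """The curve does not constrain a melting transition."""


@dataclass(frozen=True)
class LambdaLadder:
    """Strictly decreasing lambda schedule starting at 1.0."""

    lambdas: np.ndarray
    t_ref: float = 293.15

    def __post_init__(self):
        lam = np.asarray(self.lambdas, dtype=float)
        object.__setattr__(self, "lambdas", lam)
        if lam.size < 2:
            raise ValueError("ladder needs at least 2 replicas")
        if abs(lam[0] - 1.0) > 1e-12:
            raise ValueError("ladder must start at lambda = 1.0")
        if np.any(np.diff(lam) >= 0) or lam[-1] <= 0:
            raise ValueError("lambdas must be strictly decreasing and positive")

    @property
    def n(self) -> int:
        return self.lambdas.size

    def effective_temperatures(self) -> np.ndarray:
        return self.t_ref / self.lambdas


def make_ladder(
    n: int = 30, lambda_min: float = 0.6, t_ref: float = 293.15
) -> LambdaLadder:
    """Geometric lambda ladder: ``lambda_k = lambda_min**(k/(n-1))``.

    Endpoints are exactly 1.0 and ``lambda_min``; geometric spacing keeps
    neighbouring effective-temperature ratios constant, the conventional
    choice for roughly uniform exchange acceptance.
    """
    if n < 2:
        raise ValueError("ladder needs at least 2 replicas")
    if not 0.0 < lambda_min < 1.0:
        raise ValueError("lambda_min must be in (0, 1)")
    k = np.arange(n, dtype=float)
    lam = lambda_min ** (k / (n - 1))
    lam[0], lam[-1] = 1.0, lambda_min
    return LambdaLadder(lambdas=lam, t_ref=t_ref)


def effective_temperature(lam: float, t_ref: float) -> float:
    """Corresponding-states conversion of a scaling factor: T_eff = T_ref/lambda."""
    if lam <= 0:
        raise ValueError("lambda must be positive")
    return t_ref / lam


@dataclass
class UnfoldingCurve:
    """One observable mean per replica against its effective temperature."""

    temperatures: np.ndarray   # K, strictly increasing
    means: np.ndarray
    sems: np.ndarray
    counts: np.ndarray
    condition: str = ""
    subdomain: str = ""

    def __post_init__(self):
        if np.any(np.diff(self.temperatures) <= 0):
            raise ValueError("effective temperatures must be strictly increasing")


def build_curve(
    table: pd.DataFrame,
    ladder: LambdaLadder,
    equilibration_ns: float | None = None,
    keep_last_ns: float = 80.0,
    condition: str = "",
    subdomain: str = "",
) -> UnfoldingCurve:
    """Assemble per-replica means into an unfolding curve.

    ``table`` has columns (replica, lam, time_ns, observable). Frames with
    ``time_ns`` at or below the equilibration cutoff are discarded; by
    default the cutoff retains the last ``keep_last_ns`` of each replica's
    schedule (cutoff = max time - keep_last_ns). A replica left with no
    frames raises an error naming it.
    """
    required = {"replica", "lam", "time_ns", "observable"}
    if not required.issubset(table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    temps, means, sems, counts = [], [], [], []
    for rep, lam in enumerate(ladder.lambdas):
        sub = table[table["replica"] == rep]
        if sub.empty:
            raise ValueError(f"replica {rep} missing from table")
        cutoff = (
            equilibration_ns
            if equilibration_ns is not None
            else float(sub["time_ns"].max()) - keep_last_ns
        )
        kept = sub[sub["time_ns"] > cutoff]["observable"].to_numpy()
        if kept.size == 0:
            raise ValueError(
                f"replica {rep}: no frames retained beyond t = {cutoff} ns"
            )
        temps.append(effective_temperature(float(lam), ladder.t_ref))
        means.append(float(kept.mean()))
        sems.append(float(kept.std(ddof=1) / np.sqrt(kept.size)) if kept.size > 1 else 0.0)
        counts.append(kept.size)
    return UnfoldingCurve(
        temperatures=np.array(temps),
        means=np.array(means),
        sems=np.array(sems),
        counts=np.array(counts),
        condition=condition,
        subdomain=subdomain,
    )


@dataclass
class TwoStateFit:
    """Two-state van 't Hoff fit of an unfolding curve."""

    tm: float                  # K
    dh_kj: float               # kJ/mol (van 't Hoff)
    baseline_folded: float
    baseline_unfolded: float
    tm_stderr: float
    dh_stderr_kj: float
    residual_norm: float
    condition: str = ""
    subdomain: str = ""


def two_state_model(
    T: np.ndarray, tm: float, dh_kj: float, b_f: float, b_u: float
) -> np.ndarray:
    """f(T) = b_u + (b_f - b_u) / (1 + exp[(dH/R)(1/Tm - 1/T)])."""
    T = np.asarray(T, dtype=float)
    x = (dh_kj * 1000.0 / R_GAS) * (1.0 / tm - 1.0 / T)
    return b_u + (b_f - b_u) / (1.0 + np.exp(np.clip(x, -500, 500)))


def fit_two_state(curve: UnfoldingCurve) -> TwoStateFit:
    """Nonlinear least squares of the two-state model to a curve.

    Initialisation: Tm at the point nearest the half-transition, dH = 150
    kJ/mol; bounded optimisation (Tm within the data range +/- 20 K, dH in
    [10, 2000] kJ/mol). Requires >= 5 points straddling the midpoint of the
    observed range; a curve that is entirely folded or unfolded raises
    :class:`NonIdentifiableError`.
    """
    T = curve.temperatures
    y = curve.means
    if T.size < 5:
        raise NonIdentifiableError("need at least 5 curve points")
    span = y.max() - y.min()
    if span < 0.2:
        raise NonIdentifiableError(
            "curve is flat (entirely folded or unfolded); Tm is not identifiable"
        )
    mid = 0.5 * (y.max() + y.min())
    tm0 = float(T[np.argmin(np.abs(y - mid))])
    p0 = [tm0, 150.0, float(y[np.argmin(T)]), float(y[np.argmax(T)])]
    lo = [float(T.min()) - 20.0, 10.0, -0.5, -0.5]
    hi = [float(T.max()) + 20.0, 2000.0, 1.5, 1.5]
    p0 = [min(max(p, a), b) for p, a, b in zip(p0, lo, hi)]
    popt, pcov = curve_fit(
        two_state_model, T, y, p0=p0, bounds=(lo, hi), maxfev=20000
    )
    perr = np.sqrt(np.clip(np.diag(pcov), 0.0, None))
    resid = y - two_state_model(T, *popt)
    return TwoStateFit(
        tm=float(popt[0]),
        dh_kj=float(popt[1]),
        baseline_folded=float(popt[2]),
        baseline_unfolded=float(popt[3]),
        tm_stderr=float(perr[0]),
        dh_stderr_kj=float(perr[1]),
        residual_norm=float(np.linalg.norm(resid)),
        condition=curve.condition,
        subdomain=curve.subdomain,
    )


def delta_tm(fit_a: TwoStateFit, fit_b: TwoStateFit) -> float:
    """Melting-temperature difference Tm_a - Tm_b (K)."""
    return fit_a.tm - fit_b.tm
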