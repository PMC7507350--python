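"""Multiplex cytokine analysis: 5PL standard curves, censoring, log2FC, and
the cooperativity index D.

A bead-array immunoassay reports a response (median fluorescence) that maps
to concentration through a five-parameter logistic (5PL) standard curve

    y = d + (a − d) / (1 + (x/c)^b)^g

with lower asymptote a, slope b, inflection c, upper asymptote d and
asymmetry g.  Concentrations outside the quantifiable range are censored and
imputed at the LLOQ/ULOQ bound (LLOQ/2 available as an option).

For the three-condition co-culture design, the degree of modulation of each
analyte is

    D = (c_co-culture − c_MVN) / c_Spheroids

on absolute concentrations (pg/mL): D = 1 means the co-culture simply adds
the two monoculture secretions, D > 1 supra-additive amplification, D < 1
antagonism.  D is scale-invariant and affine in the co-culture value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .synth.cytokine import CONDITIONS

__all__ = [
    "StandardCurve",
    "CooperativityResult",
    "FivePLFitError",
    "five_pl",
    "fit_five_pl",
    "invert_five_pl",
    "impute_censoring",
    "compute_log2fc",
    "compute_cooperativity_D",
    "log2fc_matrix",
]

CensorMethod = Literal["bound", "half_lloq"]


class FivePLFitError(RuntimeError):
    """Standard-curve fit failed (non-monotone calibrators or no convergence)."""


@dataclass(frozen=True)
class StandardCurve:
    """5PL calibration curve with its quantifiable range."""

    a: float
    b: float
    c: float
    d: float
    g: float
    lloq_pg_ml: float
    uloq_pg_ml: float

    def __post_init__(self) -> None:
        if self.c <= 0:
            raise ValueError("inflection c must be positive")
        if self.g <= 0:
            raise ValueError("asymmetry g must be positive")
        if self.a == self.d:
            raise ValueError("asymptotes a and d must differ")
        if not self.lloq_pg_ml < self.uloq_pg_ml:
            raise ValueError("LLOQ must be below ULOQ")

    @property
    def increasing(self) -> bool:
        """True when response rises with concentration (d > a, b > 0)."""
        return (self.d > self.a) == (self.b > 0)

    @property
    def ec50_pg_ml(self) -> float:
        """Concentration at the half-maximal response, c·(2^(1/g) − 1)^(1/b).

        Unlike the inflection c, which trades off against b and g and is
        poorly identified from noisy calibrators, the midpoint is a stable
        functional of the fitted curve.
        """
        return self.c * (2.0 ** (1.0 / self.g) - 1.0) ** (1.0 / self.b)


def five_pl(x, curve: StandardCurve):
    """Evaluate the 5PL response at concentration ``x`` (scalar or array)."""
    x = np.asarray(x, dtype=float)
    if (x < 0).any():
        raise ValueError("concentrations must be nonnegative")
    y = curve.d + (curve.a - curve.d) / (1.0 + (x / curve.c) ** curve.b) ** curve.g
    return float(y) if y.ndim == 0 else y


def invert_five_pl(y: float, curve: StandardCurve) -> tuple[float, str]:
    """Closed-form inverse of the 5PL with LLOQ/ULOQ censoring.

    Returns ``(concentration_pg_ml, censor_flag)``.  Responses at or beyond
    the response at LLOQ/ULOQ (including the asymptotes) are imputed at the
    bound with the appropriate flag rather than raising.
    """
    y_at_lloq = five_pl(curve.lloq_pg_ml, curve)
    y_at_uloq = five_pl(curve.uloq_pg_ml, curve)
    sign = 1.0 if curve.increasing else -1.0
    if sign * (y - y_at_lloq) <= 0:
        return curve.lloq_pg_ml, "below_lloq"
    if sign * (y - y_at_uloq) >= 0:
        return curve.uloq_pg_ml, "above_uloq"
    ratio = (curve.a - curve.d) / (y - curve.d)
    x = curve.c * (ratio ** (1.0 / curve.g) - 1.0) ** (1.0 / curve.b)
    return float(x), "none"


def fit_five_pl(
    concentrations: Iterable[float],
    responses: Iterable[float],
    lloq_pg_ml: float | None = None,
    uloq_pg_ml: float | None = None,
) -> StandardCurve:
    """Least-squares 5PL fit to calibrator (concentration, response) points.

    Requires >= 6 distinct calibrator levels whose mean responses are
    strictly monotone in concentration.  Replicates at a level are allowed
    (the least-squares objective handles them; noiseless replicates change
    nothing).  Initialisation is multi-start over slope/asymmetry guesses
    with asymptotes from the data range; the best residual wins.  LLOQ/ULOQ
    default to the calibrator range endpoints.
    """
    x = np.asarray(list(concentrations), dtype=float)
    y = np.asarray(list(responses), dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("concentrations and responses must be equal-length 1-D")
    if (x < 0).any():
        raise ValueError("calibrator concentrations must be nonnegative")
    levels = np.unique(x)
    if len(levels) < 6:
        raise FivePLFitError(f"need >= 6 calibrator levels, got {len(levels)}")
    level_means = np.array([y[x == lv].mean() for lv in levels])
    diffs = np.diff(level_means)
    if (diffs > 0).all():
        increasing = True
    elif (diffs < 0).all():
        increasing = False
    else:
        raise FivePLFitError(
            "calibrator responses are not strictly monotone in concentration; "
            f"level means: {level_means.tolist()}"
        )

    pos = levels[levels > 0]
    c0 = float(np.exp(np.mean(np.log(pos)))) if len(pos) else 1.0
    y_min, y_max = float(level_means.min()), float(level_means.max())
    span = y_max - y_min
    a0 = y_min if increasing else y_max
    d0 = y_max if increasing else y_min

    def resid(p):
        a, logb, logc, d, logg = p
        with np.errstate(over="ignore"):
            curve_y = d + (a - d) / (1.0 + (x / np.exp(logc)) ** np.exp(logb)) ** np.exp(logg)
        return curve_y - y

    best = None
    for b0 in (0.5, 1.0, 2.0):
        for g0 in (0.5, 1.0, 2.0):
            p0 = np.array([a0, np.log(b0), np.log(c0), d0, np.log(g0)])
            try:
                sol = least_squares(
                    resid, p0, method="lm", xtol=1e-15, ftol=1e-15, max_nfev=20000
                )
            except Exception:
                continue
            if best is None or sol.cost < best.cost:
                best = sol
    if best is None or not np.isfinite(best.cost):
        raise FivePLFitError("5PL fit did not converge from any start")
    a, logb, logc, d, logg = best.x
    b, c, g = np.exp(logb), np.exp(logc), np.exp(logg)
    # orientation is carried by the sign of d - a; b, g stay positive
    lo = lloq_pg_ml if lloq_pg_ml is not None else float(levels[levels > 0].min())
    hi = uloq_pg_ml if uloq_pg_ml is not None else float(levels.max())
    return StandardCurve(
        a=float(a), b=float(b), c=float(c), d=float(d), g=float(g),
        lloq_pg_ml=lo, uloq_pg_ml=hi,
    )


# ---------------------------------------------------------------------------
# table-level analysis


def _validate_table(table: pd.DataFrame) -> pd.DataFrame:
    required = {"analyte", "condition", "concentration_pg_ml"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"cytokine table missing columns: {sorted(missing)}")
    t = table.copy()
    if "censor" not in t.columns:
        t["censor"] = "none"
    if "replicate" not in t.columns:
        t["replicate"] = 1
    if (t["concentration_pg_ml"] < 0).any():
        raise ValueError("concentrations must be nonnegative")
    return t


def impute_censoring(
    table: pd.DataFrame,
    lloq_pg_ml: dict[str, float] | float | None = None,
    uloq_pg_ml: dict[str, float] | float | None = None,
    method: CensorMethod = "bound",
) -> pd.DataFrame:
    """Replace censored concentrations by their quantitation bound.

    ``below_lloq`` rows become LLOQ (or LLOQ/2 with ``method='half_lloq'``),
    ``above_uloq`` rows become ULOQ.  Bounds may be per-analyte dicts or
    scalars; when None, the censored rows' own values are kept (already
    imputed upstream).
    """
    t = _validate_table(table)

    def bound(limits, analyte):
        if limits is None:
            return None
        return limits[analyte] if isinstance(limits, dict) else float(limits)

    conc = t["concentration_pg_ml"].to_numpy(dtype=float, copy=True)
    for i, row in enumerate(t.itertuples(index=False)):
        if row.censor == "below_lloq":
            lo = bound(lloq_pg_ml, row.analyte)
            if lo is not None:
                conc[i] = lo / 2 if method == "half_lloq" else lo
        elif row.censor == "above_uloq":
            hi = bound(uloq_pg_ml, row.analyte)
            if hi is not None:
                conc[i] = hi
    t["concentration_pg_ml"] = conc
    return t


def _condition_stats(t: pd.DataFrame, analyte: str, condition: str):
    sub = t[(t["analyte"] == analyte) & (t["condition"] == condition)]
    if sub.empty:
        return None, False, True
    mean = float(sub["concentration_pg_ml"].mean())
    any_censored = bool((sub["censor"] != "none").any())
    fully_censored = bool((sub["censor"] != "none").all())
    return mean, any_censored, fully_censored


def compute_log2fc(
    table: pd.DataFrame, treatment: str, control: str
) -> pd.DataFrame:
    """Per-analyte log2 fold change of condition means, treatment vs control.

    Censored values enter as their (already imputed) concentrations; the
    result row is flagged when either side contains censored measurements.
    A zero control mean is an error — no pseudo-counts are applied.
    """
    t = _validate_table(table)
    rows = []
    for analyte in sorted(t["analyte"].unique()):
        m_t, cens_t, _ = _condition_stats(t, analyte, treatment)
        m_c, cens_c, _ = _condition_stats(t, analyte, control)
        if m_t is None or m_c is None:
            raise ValueError(
                f"analyte {analyte!r}: condition {treatment if m_t is None else control!r} absent"
            )
        if m_c == 0:
            raise ValueError(
                f"analyte {analyte!r}: control mean is 0; log2FC undefined (no pseudo-count)"
            )
        rows.append(
            {
                "analyte": analyte,
                "treatment": treatment,
                "control": control,
                "log2fc": float(np.log2(m_t / m_c)),
                "censored": cens_t or cens_c,
            }
        )
    return pd.DataFrame(rows)


def log2fc_matrix(table: pd.DataFrame, contrasts: list[tuple[str, str]]) -> pd.DataFrame:
    """Analytes × contrasts matrix of log2FC, heatmap-ready."""
    cols = {}
    for treatment, control in contrasts:
        fc = compute_log2fc(table, treatment, control)
        cols[f"{treatment}_vs_{control}"] = fc.set_index("analyte")["log2fc"]
    return pd.DataFrame(cols)


@dataclass(frozen=True)
class CooperativityResult:
    """Cooperativity index of one analyte with its three-way classification."""

    analyte: str
    D: float | None
    classification: Literal["supra_additive", "additive", "antagonistic", "undefined"]
    inputs_pg_ml: dict[str, float]
    reason: str | None = None

    def to_dict(self) -> dict:
        return {
            "analyte": self.analyte,
            "D": self.D,
            "classification": self.classification,
            "inputs_pg_ml": dict(self.inputs_pg_ml),
            "reason": self.reason,
        }


def _classify(D: float, tolerance: float) -> str:
    if abs(D - 1.0) <= tolerance:
        return "additive"
    return "supra_additive" if D > 1.0 else "antagonistic"


def compute_cooperativity_D(
    table: pd.DataFrame,
    tolerance: float = 0.05,
    mode: Literal["condition_means", "per_replicate"] = "condition_means",
) -> list[CooperativityResult]:
    """Compute D = (co-culture − MVN)/Spheroids per analyte and classify it.

    ``condition_means`` (default) computes D from the mean concentration of
    each condition; ``per_replicate`` computes D per replicate index and
    reports the mean of the per-replicate values.  An analyte with a missing
    condition, a nonpositive spheroid-only mean, or a fully censored
    spheroid-only condition is reported as ``undefined`` with a reason and
    the pipeline continues.

    Classification: additive iff |D − 1| <= tolerance, else supra-additive
    (D > 1) or antagonistic (D < 1).
    """
    if tolerance < 0:
        raise ValueError("tolerance must be nonnegative")
    t = _validate_table(table)
    results = []
    for analyte in sorted(t["analyte"].unique()):
        means, reasons = {}, []
        fully_censored_sph = False
        for cond in CONDITIONS:
            mean, _, fully = _condition_stats(t, analyte, cond)
            if mean is None:
                reasons.append(f"condition {cond!r} missing")
            else:
                means[cond] = mean
                if cond == "Spheroids" and fully:
                    fully_censored_sph = True
        if reasons:
            results.append(
                CooperativityResult(analyte, None, "undefined", means, "; ".join(reasons))
            )
            continue
        if means["Spheroids"] <= 0:
            results.append(
                CooperativityResult(
                    analyte, None, "undefined", means, "spheroid-only mean <= 0"
                )
            )
            continue
        if fully_censored_sph:
            results.append(
                CooperativityResult(
                    analyte, None, "undefined", means, "spheroid-only condition fully censored"
                )
            )
            continue
        if mode == "condition_means":
            D = (means["MVN_plus_Spheroids"] - means["MVN"]) / means["Spheroids"]
        elif mode == "per_replicate":
            sub = t[t["analyte"] == analyte].pivot_table(
                index="replicate", columns="condition", values="concentration_pg_ml"
            )
            sub = sub.dropna(subset=list(CONDITIONS))
            if sub.empty or (sub["Spheroids"] <= 0).any():
                results.append(
                    CooperativityResult(
                        analyte, None, "undefined", means,
                        "per-replicate D unavailable (incomplete replicates or zero spheroid value)",
                    )
                )
                continue
            D = float(
                ((sub["MVN_plus_Spheroids"] - sub["MVN"]) / sub["Spheroids"]).mean()
            )
        else:
            raise ValueError(f"unknown mode {mode!r}")
        results.append(
            CooperativityResult(analyte, float(D), _classify(float(D), tolerance), means)
        )
    return results
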