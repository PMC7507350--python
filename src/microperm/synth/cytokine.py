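"""Synthetic multiplex cytokine tables with known cooperativity.

Emulates conditioned-media immunoassay panels for the three culture
conditions — vasculature alone (``MVN``), tumour spheroids alone
(``Spheroids``) and the co-culture (``MVN_plus_Spheroids``) — with
mean-preserving multiplicative lognormal measurement noise and LLOQ/ULOQ
censoring flags.  The cooperativity index of each analyte,
D = (co-culture − MVN)/Spheroids, is fixed by construction so downstream
estimates can be scored against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CONDITIONS = ("MVN", "Spheroids", "MVN_plus_Spheroids")

__all__ = ["CONDITIONS", "CytokineGroundTruth", "simulate_cytokine_table"]


@dataclass
class CytokineGroundTruth:
    """True concentrations (pg/mL) per analyte per condition, plus assay limits.

    ``true_concentrations_pg_ml`` maps analyte -> {condition -> pg/mL} for
    the three conditions.  ``lloq_pg_ml``/``uloq_pg_ml`` map analyte -> limit.
    ``noise_cv`` is the coefficient of variation of the multiplicative
    lognormal measurement noise.  D per analyte follows from the three true
    concentrations.
    """

    analytes: list[str]
    true_concentrations_pg_ml: dict[str, dict[str, float]]
    noise_cv: float = 0.1
    lloq_pg_ml: dict[str, float] = field(default_factory=dict)
    uloq_pg_ml: dict[str, float] = field(default_factory=dict)
    seed: int = 0
    n_replicates: int = 4

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be nonnegative")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        for a in self.analytes:
            conc = self.true_concentrations_pg_ml.get(a)
            if conc is None or set(CONDITIONS) - set(conc):
                raise ValueError(f"analyte {a!r} missing one of conditions {CONDITIONS}")
            if any(v < 0 for v in conc.values()):
                raise ValueError(f"analyte {a!r} has a negative true concentration")
            lo = self.lloq_pg_ml.setdefault(a, 0.0)
            hi = self.uloq_pg_ml.setdefault(a, np.inf)
            if not lo < hi:
                raise ValueError(f"analyte {a!r}: LLOQ must be below ULOQ")

    @classmethod
    def from_design(
        cls,
        D_true: float | dict[str, float],
        analytes: list[str] | None = None,
        mvn_pg_ml: float | dict[str, float] = 100.0,
        spheroids_pg_ml: float | dict[str, float] = 50.0,
        **kwargs,
    ) -> "CytokineGroundTruth":
        """Build a truth table from target cooperativity values.

        The co-culture concentration is set to MVN + D·Spheroids so that
        every analyte has exactly the requested D.
        """
        if analytes is None:
            analytes = sorted(D_true) if isinstance(D_true, dict) else ["analyte1"]

        def per(a: str, v) -> float:
            return float(v[a]) if isinstance(v, dict) else float(v)

        conc = {}
        for a in analytes:
            m, s, d = per(a, mvn_pg_ml), per(a, spheroids_pg_ml), per(a, D_true)
            conc[a] = {
                "MVN": m,
                "Spheroids": s,
                "MVN_plus_Spheroids": m + d * s,
            }
        return cls(analytes=analytes, true_concentrations_pg_ml=conc, **kwargs)

    def D_true(self, analyte: str) -> float:
        c = self.true_concentrations_pg_ml[analyte]
        return (c["MVN_plus_Spheroids"] - c["MVN"]) / c["Spheroids"]


def _censor_flag(value: float, lloq: float, uloq: float) -> str:
    if value < lloq:
        return "below_lloq"
    if value > uloq:
        return "above_uloq"
    return "none"


def simulate_cytokine_table(truth: CytokineGroundTruth) -> pd.DataFrame:
    """Draw an observed cytokine table from the ground truth.

    Noise is multiplicative lognormal with the requested CV, mean-preserving
    (E[multiplier] = 1), so ``noise_cv = 0`` reproduces the true table
    exactly.  Columns: ``analyte, condition, replicate, concentration_pg_ml,
    censor, true_concentration_pg_ml``; the raw (uncensored) observed value
    is kept in ``concentration_pg_ml`` with the flag in ``censor`` —
    imputation at the bound is a downstream analysis step.
    Deterministic per seed.
    """
    rng = np.random.default_rng(truth.seed)
    cv = truth.noise_cv
    if cv > 0:
        sigma = np.sqrt(np.log1p(cv * cv))
        mu = -0.5 * sigma * sigma
    rows = []
    for a in truth.analytes:
        lo, hi = truth.lloq_pg_ml[a], truth.uloq_pg_ml[a]
        for cond in CONDITIONS:
            c_true = truth.true_concentrations_pg_ml[a][cond]
            for rep in range(1, truth.n_replicates + 1):
                if cv > 0:
                    obs = c_true * rng.lognormal(mu, sigma)
                else:
                    obs = c_true
                rows.append(
                    {
                        "analyte": a,
                        "condition": cond,
                        "replicate": rep,
                        "concentration_pg_ml": obs,
                        "censor": _censor_flag(obs, lo, hi),
                        "true_concentration_pg_ml": c_true,
                    }
                )
    return pd.DataFrame(rows)
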