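"""Agreement statistics between estimated and reference anthropometrics.

RMSE, MAE, squared Pearson correlation, and the intraclass correlation
coefficient.  The ICC variant is ICC(2,1) — two-way random effects, absolute
agreement, single measurement — the appropriate choice for comparing two
measurement methods on the same subjects, since it penalizes systematic
bias that a consistency ICC would forgive.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np


class UndefinedStatisticError(ValueError):
    """The statistic is undefined for this input (e.g. zero variance)."""


def _paired(est, ref) -> tuple[np.ndarray, np.ndarray]:
    est = np.asarray(est, dtype=float).ravel()
    ref = np.asarray(ref, dtype=float).ravel()
    if est.size == 0:
        raise ValueError("empty input")
    if est.shape != ref.shape:
        raise ValueError(f"length mismatch: {est.size} vs {ref.size}")
    return est, ref


def rmse(est, ref) -> float:
    """Root-mean-square error, sqrt(mean((est - ref)^2))."""
    est, ref = _paired(est, ref)
    return float(np.sqrt(np.mean((est - ref) ** 2)))


def mae(est, ref) -> float:
    """Mean absolute error."""
    est, ref = _paired(est, ref)
    return float(np.mean(np.abs(est - ref)))


def pearson_r2(est, ref) -> float:
    """Squared Pearson correlation coefficient."""
    est, ref = _paired(est, ref)
    if est.size < 2:
        raise ValueError("need at least 2 pairs")
    if np.std(est) == 0 or np.std(ref) == 0:
        raise UndefinedStatisticError("zero variance: correlation undefined")
    r = np.corrcoef(est, ref)[0, 1]
    return float(r * r)


def icc(est, ref) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    From the two-way ANOVA mean squares of the n x 2 table (rows = subjects,
    columns = raters):

        ICC(2,1) = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    with MSR the between-rows, MSC the between-columns and MSE the residual
    mean square, k = 2 raters.
    """
    est, ref = _paired(est, ref)
    if est.size < 2:
        raise ValueError("need at least 2 pairs")
    data = np.column_stack([est, ref])  # (n, k)
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    if ss_total == 0:
        raise UndefinedStatisticError("all values identical: ICC undefined")
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        raise UndefinedStatisticError("degenerate ANOVA table: ICC undefined")
    return float((msr - mse) / denom)


@dataclass
class AgreementReport:
    """RMSE/MAE/ICC/r^2 between estimates and references for one parameter."""

    parameter: str
    units: str
    rmse: float
    mae: float
    icc: float
    r2: float
    n: int

    def as_dict(self) -> dict:
        return asdict(self)

    def as_row(self) -> str:
        return (f"{self.parameter},{self.units},{self.rmse:.4f},{self.mae:.4f},"
                f"{self.icc:.4f},{self.r2:.4f},{self.n}")


def agreement_report(est, ref, parameter: str = "", units: str = "") -> AgreementReport:
    """Bundle all four agreement statistics plus the pair count."""
    est, ref = _paired(est, ref)
    if est.size < 2:
        raise ValueError("need at least 2 pairs")
    if np.array_equal(est, ref):
        # perfect agreement: correlation statistics are 1 by convention even
        # though the ANOVA/corr denominators may vanish for constant vectors
        r2_val = 1.0
        icc_val = 1.0
    else:
        r2_val = pearson_r2(est, ref)
        icc_val = icc(est, ref)
    return AgreementReport(parameter=parameter, units=units,
                           rmse=rmse(est, ref), mae=mae(est, ref),
                           icc=icc_val, r2=r2_val, n=int(est.size))
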