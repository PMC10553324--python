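"""Agreement statistics between device output and patient diaries.

Per 24-h acquisition the pooled confusion counts yield sensitivity
TP/(TP+FN), specificity TN/(TN+FP), accuracy (TP+TN)/total and a
two-class Cohen's kappa in the form

    k = 2 (TP·TN − FN·FP) / ((TP+FP)(FP+TN) + (TP+FN)(FN+TN)).

Study-level summaries are unweighted means across acquisitions with
the sample (n−1) standard deviation of kappa.  Display rounding is
half-up to two decimals evaluated on the exact rational value (39/40
prints as 0.98, not 0.97); full precision is kept internally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .diary_compare import ConfusionCounts

__all__ = [
    "UndefinedRateError",
    "sensitivity",
    "specificity",
    "accuracy",
    "cohen_kappa",
    "round_half_up",
    "AcquisitionStats",
    "acquisition_summary",
]


class UndefinedRateError(ZeroDivisionError):
    """A rate or kappa whose denominator is zero."""


def _ratio(num: int, den: int, what: str) -> Fraction:
    if den == 0:
        raise UndefinedRateError(f"{what} undefined: denominator is zero")
    return Fraction(num, den)


def sensitivity(c: ConfusionCounts) -> float:
    """TP / (TP + FN)."""
    return float(_ratio(c.tp, c.tp + c.fn, "sensitivity"))


def specificity(c: ConfusionCounts) -> float:
    """TN / (TN + FP)."""
    return float(_ratio(c.tn, c.tn + c.fp, "specificity"))


def accuracy(c: ConfusionCounts) -> float:
    """(TP + TN) / (TP + TN + FP + FN)."""
    return float(_ratio(c.tp + c.tn, c.total, "accuracy"))


def _kappa_fraction(c: ConfusionCounts) -> Fraction:
    den = (c.tp + c.fp) * (c.fp + c.tn) + (c.tp + c.fn) * (c.fn + c.tn)
    if den == 0:
        raise UndefinedRateError("kappa undefined: denominator is zero")
    return Fraction(2 * (c.tp * c.tn - c.fn * c.fp), den)


def cohen_kappa(c: ConfusionCounts) -> float:
    """Two-class chance-corrected agreement, evaluated exactly."""
    return float(_kappa_fraction(c))


def round_half_up(x: float | Fraction, ndigits: int = 2) -> float:
    """Half-up decimal rounding on the exact rational value."""
    if isinstance(x, Fraction):
        d = Decimal(x.numerator) / Decimal(x.denominator)
    else:
        d = Decimal(repr(float(x)))
    q = Decimal(1).scaleb(-ndigits)
    return float(d.quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class AcquisitionStats:
    counts: ConfusionCounts
    sensitivity: float
    specificity: float
    accuracy: float
    kappa: float


def _exact_rates(c: ConfusionCounts) -> tuple[Fraction, Fraction, Fraction, Fraction]:
    return (
        _ratio(c.tp, c.tp + c.fn, "sensitivity"),
        _ratio(c.tn, c.tn + c.fp, "specificity"),
        _ratio(c.tp + c.tn, c.total, "accuracy"),
        _kappa_fraction(c),
    )


def acquisition_summary(
    rows: Sequence[ConfusionCounts],
    round_display: bool = True,
    decimal_comma: bool = False,
) -> pd.DataFrame:
    """Per-acquisition rates and kappa plus MEAN VALUE / SD rows.

    Means are unweighted across acquisitions on the full-precision
    per-row values; the trailing rows report the mean of each rate and
    the standard deviation of kappa (sample, n−1).  When
    ``round_display`` is set, rate columns are rounded half-up to two
    decimals (exactly, from the rational values); ``decimal_comma``
    additionally renders them as comma-decimal strings.
    """
    if len(rows) == 0:
        raise ValueError("need at least one acquisition")
    records, sens, spec, acc, kap = [], [], [], [], []
    for i, c in enumerate(rows, start=1):
        try:
            se, sp, ac, ka = _exact_rates(c)
        except UndefinedRateError as err:
            warnings.warn(
                f"acquisition {i}: {err}; excluded from the study means",
                stacklevel=2,
            )
            records.append(
                {
                    "acquisition": str(i),
                    "tn": c.tn,
                    "tp": c.tp,
                    "fn": c.fn,
                    "fp": c.fp,
                    "sensitivity": np.nan,
                    "specificity": np.nan,
                    "accuracy": np.nan,
                    "kappa": np.nan,
                }
            )
            continue
        sens.append(se), spec.append(sp), acc.append(ac), kap.append(ka)
        records.append(
            {
                "acquisition": str(i),
                "tn": c.tn,
                "tp": c.tp,
                "fn": c.fn,
                "fp": c.fp,
                "sensitivity": round_half_up(se) if round_display else float(se),
                "specificity": round_half_up(sp) if round_display else float(sp),
                "accuracy": round_half_up(ac) if round_display else float(ac),
                "kappa": round_half_up(ka) if round_display else float(ka),
            }
        )
    if not sens:
        raise ValueError("no acquisition with defined rates")

    def frac_mean(vals: list[Fraction]) -> Fraction:
        return sum(vals, Fraction(0)) / len(vals)

    mean_row = {
        "acquisition": "MEAN VALUE",
        "sensitivity": round_half_up(frac_mean(sens)),
        "specificity": round_half_up(frac_mean(spec)),
        "accuracy": round_half_up(frac_mean(acc)),
        "kappa": round_half_up(frac_mean(kap)),
    }
    kf = np.array([float(k) for k in kap])
    sd_row = {
        "acquisition": "SD",
        "kappa": round_half_up(float(np.std(kf, ddof=1))) if kf.size > 1 else 0.0,
    }
    out = pd.DataFrame(records + [mean_row, sd_row])
    if decimal_comma:
        for col in ("sensitivity", "specificity", "accuracy", "kappa"):
            out[col] = out[col].map(
                lambda v: "" if pd.isna(v) else f"{v:.2f}".replace(".", ",")
            )
    return out
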