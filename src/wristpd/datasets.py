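"""Reference data from a published clinical validation of wrist-worn
motor-state monitoring in Parkinson's disease.

Twelve patients wore a tri-axial wrist accelerometer for 24–72 h while
keeping a standard four-state motor diary on a 30-minute grid; the 528
recorded hours were split into twenty-two 24-h acquisition periods and
device output was compared with the diary interval by interval, pooling
the OFF-vs-rest and ON-vs-rest dichotomies (two counts per compared
interval).  These tables are inputs for re-deriving the published
agreement statistics; they are not used by any detector.
"""

from __future__ import annotations

from .diary_compare import ConfusionCounts

__all__ = [
    "VALIDATION_CONFUSION_COUNTS",
    "VALIDATION_PRINTED_RATES",
    "VALIDATION_DIARY_HOURS",
    "validation_counts",
]

#: per-acquisition pooled confusion counts as (TN, TP, FN, FP)
VALIDATION_CONFUSION_COUNTS: list[tuple[int, int, int, int]] = [
    (49, 29, 2, 4),
    (54, 24, 3, 3),
    (32, 26, 4, 4),
    (51, 19, 2, 2),
    (56, 17, 7, 6),
    (50, 16, 8, 8),
    (39, 11, 1, 1),
    (46, 20, 6, 2),
    (48, 27, 5, 2),
    (46, 16, 1, 1),
    (55, 21, 7, 7),
    (48, 20, 2, 2),
    (64, 22, 4, 2),
    (61, 26, 3, 2),
    (55, 23, 4, 2),
    (53, 33, 2, 2),
    (58, 27, 4, 1),
    (59, 20, 3, 4),
    (56, 19, 3, 6),
    (57, 28, 3, 2),
    (48, 27, 6, 5),
    (52, 25, 3, 4),
]

#: the rates printed alongside the counts, as (sensitivity,
#: specificity, accuracy) at two decimals.  Note: the published row 16
#: sensitivity/accuracy are inconsistent with that row's own counts
#: (they duplicate row 15); recomputation from the counts gives
#: 0.94/0.96 there.
VALIDATION_PRINTED_RATES: list[tuple[float, float, float]] = [
    (0.94, 0.92, 0.93),
    (0.89, 0.95, 0.93),
    (0.87, 0.89, 0.88),
    (0.90, 0.96, 0.95),
    (0.71, 0.90, 0.85),
    (0.67, 0.86, 0.80),
    (0.92, 0.98, 0.96),
    (0.77, 0.96, 0.89),
    (0.84, 0.96, 0.91),
    (0.94, 0.98, 0.97),
    (0.75, 0.89, 0.84),
    (0.91, 0.96, 0.94),
    (0.85, 0.97, 0.93),
    (0.90, 0.97, 0.95),
    (0.85, 0.96, 0.93),
    (0.85, 0.96, 0.93),
    (0.87, 0.98, 0.94),
    (0.87, 0.94, 0.92),
    (0.86, 0.90, 0.89),
    (0.90, 0.97, 0.94),
    (0.82, 0.91, 0.87),
    (0.89, 0.93, 0.92),
]

#: diary-side hours per acquisition as (OFF, ON/ON-with-NTD, ON-with-TD,
#: sleeping/motor-inactivity); the sum is the diary-covered span, and
#: twice the number of covered 30-min intervals equals the pooled
#: confusion-count total for that acquisition.
VALIDATION_DIARY_HOURS: list[tuple[float, float, float, float]] = [
    (4.0, 11.5, 0.0, 5.5),
    (2.5, 11.5, 0.0, 7.5),
    (2.0, 13.0, 0.0, 1.5),
    (2.0, 8.5, 0.0, 8.0),
    (1.5, 10.0, 0.0, 10.0),
    (2.5, 10.5, 0.0, 7.5),
    (1.5, 4.5, 0.0, 7.0),
    (3.0, 9.0, 1.0, 6.5),
    (1.0, 15.0, 0.0, 4.5),
    (1.0, 7.5, 0.0, 6.5),
    (3.5, 10.5, 0.5, 8.5),
    (2.5, 8.5, 0.0, 7.0),
    (8.0, 4.0, 1.0, 10.0),
    (3.5, 11.0, 0.0, 8.5),
    (7.5, 6.0, 0.0, 7.5),
    (1.5, 16.0, 0.0, 5.0),
    (2.5, 12.0, 0.0, 9.5),
    (4.5, 9.5, 0.0, 10.0),
    (2.5, 11.5, 0.0, 10.0),
    (2.0, 14.0, 0.0, 8.0),
    (3.5, 13.5, 0.0, 7.0),
    (4.5, 11.0, 0.0, 8.5),
]


def validation_counts() -> list[ConfusionCounts]:
    """The 22 acquisitions as :class:`ConfusionCounts` objects."""
    return [
        ConfusionCounts(tn=tn, tp=tp, fn=fn, fp=fp)
        for tn, tp, fn, fp in VALIDATION_CONFUSION_COUNTS
    ]
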