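"""Expected calibration error (ECE) and reliability-curve statistics.

Confidence scores are binned into M equal-width bins over [0,1]; within each
bin, the empirical precision (mean correctness) is compared with the mean
stated confidence. ECE is the bin-count-weighted mean absolute gap:

    ECE = sum_m (|B_m| / N) * |Prec(m) - conf_mean(m)|

Only the confidence is binned; box features affect the calibrator, not the
error measure, so one scalar summarizes a detector's reliability.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .detection_io import CalibrationRecord


@dataclass(frozen=True)
class BinStats:
    """Per-bin aggregate; ``precision``/``mean_confidence`` are NaN when empty."""

    index: int
    lower: float
    upper: float
    count: int
    precision: float
    mean_confidence: float


@dataclass(frozen=True)
class ECEResult:
    ece: float
    M: int
    N: int
    bins: list[BinStats]


def _confidences(records: Sequence[CalibrationRecord], use_calibrated: bool) -> np.ndarray:
    if use_calibrated:
        vals = [getattr(r, "calibrated_confidence", None) for r in records]
        if any(v is None for v in vals):
            raise ValueError("use_calibrated=True but some records lack calibrated_confidence")
        return np.asarray(vals, dtype=float)
    return np.asarray([r.confidence for r in records], dtype=float)


def bin_statistics(
    records: Sequence[CalibrationRecord], M: int = 10, use_calibrated: bool = False
) -> list[BinStats]:
    """Equal-width bin statistics over [0,1].

    Bins are ``[0, 1/M), ..., [(M-1)/M, 1]`` — the last bin is right-closed so
    confidence exactly 1.0 is always counted. Empty bins are reported with
    count 0 and NaN statistics.
    """
    if M < 1:
        raise ValueError(f"M must be >= 1, got {M}")
    if len(records) == 0:
        raise ValueError("ECE/bin statistics are undefined for empty record sets")
    conf = _confidences(records, use_calibrated)
    z = np.asarray([r.z for r in records], dtype=float)
    idx = np.minimum((conf * M).astype(int), M - 1)  # conf == 1.0 -> last bin
    bins: list[BinStats] = []
    for m in range(M):
        mask = idx == m
        n = int(mask.sum())
        bins.append(
            BinStats(
                index=m,
                lower=m / M,
                upper=(m + 1) / M,
                count=n,
                precision=float(z[mask].mean()) if n else float("nan"),
                mean_confidence=float(conf[mask].mean()) if n else float("nan"),
            )
        )
    return bins


def ece(
    records: Sequence[CalibrationRecord], M: int = 10, use_calibrated: bool = False
) -> ECEResult:
    """Expected calibration error over equal-width confidence bins."""
    bins = bin_statistics(records, M, use_calibrated)
    N = sum(b.count for b in bins)
    total = sum(
        b.count / N * abs(b.precision - b.mean_confidence) for b in bins if b.count > 0
    )
    return ECEResult(ece=float(total), M=M, N=N, bins=bins)


def reliability_curve(
    records: Sequence[CalibrationRecord], M: int = 10, use_calibrated: bool = False
) -> pd.DataFrame:
    """Table of (bin midpoint, precision, mean confidence, count) for plotting."""
    bins = bin_statistics(records, M, use_calibrated)
    return pd.DataFrame(
        {
            "bin_midpoint": [(b.lower + b.upper) / 2 for b in bins],
            "precision": [b.precision for b in bins],
            "mean_confidence": [b.mean_confidence for b in bins],
            "count": [b.count for b in bins],
        }
    )
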