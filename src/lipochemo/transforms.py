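"""Deterministic lipophilicity transforms.

Two linear calibrations convert gradient-HPLC chromatographic
hydrophobicity indices (CHI) to logk/logD-scale lipophilicity values at
pH 7.4:

* IAM column:   ``logk_IAM = 0.045 * CHI_IAM + 0.42``
* C18 column:   ``CHI_logD = 0.0525 * CHI_C18 - 1.467``

The consensus logP is the arithmetic mean of the five SwissADME
predictions (iLogP, XLogP3, WLogP, MLogP, Silicos-IT LogP).  Column
standardization (autoscaling) is the shared preprocessing step for the
downstream chemometrics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TransformConstants",
    "CONSTANTS",
    "chi_to_logk_iam",
    "chi_to_chi_logd",
    "consensus_logp",
    "standardize_columns",
    "range_scale_columns",
    "round_half_away",
]


@dataclass(frozen=True)
class TransformConstants:
    """Calibration constants of the CHI-to-logk/logD linear maps."""

    iam_slope: float = 0.045
    iam_intercept: float = 0.42
    chi_slope: float = 0.0525
    chi_intercept: float = -1.467


CONSTANTS = TransformConstants()


def _as_finite_array(x, name):
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite")
    return arr


def chi_to_logk_iam(chi_iam):
    """Convert CHI_IAM retention indices to logk_IAM (elementwise)."""
    chi = _as_finite_array(chi_iam, "chi_iam")
    out = CONSTANTS.iam_slope * chi + CONSTANTS.iam_intercept
    return float(out) if out.ndim == 0 else out


def chi_to_chi_logd(chi_c18):
    """Convert CHI_C18 retention indices to CHI logD (elementwise)."""
    chi = _as_finite_array(chi_c18, "chi_c18")
    out = CONSTANTS.chi_slope * chi + CONSTANTS.chi_intercept
    return float(out) if out.ndim == 0 else out


def consensus_logp(ilogp, xlogp3, wlogp, mlogp, silicos):
    """Arithmetic mean of the five computational logP predictions."""
    parts = [
        _as_finite_array(v, n)
        for v, n in zip(
            (ilogp, xlogp3, wlogp, mlogp, silicos),
            ("ilogp", "xlogp3", "wlogp", "mlogp", "silicos"),
        )
    ]
    out = sum(parts) / 5.0
    return float(out) if np.ndim(out) == 0 else out


def standardize_columns(table: pd.DataFrame) -> pd.DataFrame:
    """Autoscale each column to mean 0 and unit sample SD (ddof=1).

    Raises ``ValueError`` naming the first zero-variance column.
    """
    values = table.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("table contains non-finite values")
    sd = values.std(axis=0, ddof=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        raise ValueError(f"zero-variance column: {table.columns[zero[0]]!r}")
    scaled = (values - values.mean(axis=0)) / sd
    return pd.DataFrame(scaled, index=table.index, columns=table.columns)


def range_scale_columns(table: pd.DataFrame) -> pd.DataFrame:
    """Interval-scale each column onto [0, 1] (min 0, max 1).

    Raises ``ValueError`` naming the first constant column.
    """
    values = table.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("table contains non-finite values")
    lo = values.min(axis=0)
    span = values.max(axis=0) - lo
    zero = np.flatnonzero(span == 0)
    if zero.size:
        raise ValueError(f"zero-range column: {table.columns[zero[0]]!r}")
    return pd.DataFrame((values - lo) / span, index=table.index,
                        columns=table.columns)


def round_half_away(x, decimals: int = 2):
    """Round half away from zero, matching how printed tables are rounded.

    numpy rounds half to even, which disagrees with printed values ending
    in 5 at the rounding digit.
    """
    arr = np.asarray(x, dtype=float)
    factor = 10.0 ** decimals
    # pre-round at high precision so decimal halves stored as
    # 2.4449999... in binary still round up
    scaled = np.round(np.abs(arr) * factor, 8)
    out = np.sign(arr) * np.floor(scaled + 0.5) / factor
    return float(out) if out.ndim == 0 else out
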