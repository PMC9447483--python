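"""Coverage-based discovery of W-linked sequence from female/male read depth.

In a ZW system the female carries one Z and one W while the male carries two
Z.  After normalizing each sex's window depths by its autosomal median, the
log2 ratio of female to male normalized depth (log2FM) has clean analytic
expectations: 0 for autosomes and the pseudoautosomal region, -1 for
Z-linked windows (females are hemizygous) and >= ~2 for W-linked windows
(female depth ~0.5, male depth only spurious background).  Two classifiers
are provided:

* ``classify_log2fm`` — fixed threshold, W iff log2FM >= 1 (plus
  configurable Z and autosomal bands);
* ``classify_iqr`` — adaptive upper-outlier rule on the female share of
  normalized depth f = F/(F+M): W iff f > Q3 + 1.5*IQR of the f
  distribution.

``calibrate`` scores either call set against truth labels (power and
false-positive rate), mirroring the chicken mapping experiment used to pick
the more conservative log2FM rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CalibrationResult",
    "autosomal_median",
    "normalize_depths",
    "log2fm",
    "classify_log2fm",
    "classify_iqr",
    "iqr_upper_fence",
    "calibrate",
    "scaffold_rollup",
]

AUTOSOME_LABELS = ("autosome",)


@dataclass
class CalibrationResult:
    """Power/false-positive summary of W calls against truth labels."""

    power: float | None
    false_positive_rate: float | None
    n_true: int
    n_false: int

    def as_dict(self) -> dict:
        return {
            "power": self.power,
            "false_positive_rate": self.false_positive_rate,
            "n_true": self.n_true,
            "n_false": self.n_false,
        }


def autosomal_median(
    windows: pd.DataFrame,
    label_col: str = "truth_class",
    autosome_labels: Sequence[str] = AUTOSOME_LABELS,
) -> dict[str, float]:
    """Median autosomal depth per sex.

    Uses the sample median (even n: mean of the central pair) of per-window
    mean depths restricted to autosome-labelled windows.
    """
    mask = windows[label_col].isin(autosome_labels)
    if not mask.any():
        raise ValueError(
            "no autosome-labelled windows: supply labels (column "
            f"{label_col!r} with one of {tuple(autosome_labels)})"
        )
    sub = windows.loc[mask]
    return {
        "female": float(sub["female_depth"].median()),
        "male": float(sub["male_depth"].median()),
    }


def log2fm(female_norm, male_norm, pseudocount: float = 0.0):
    """log2((female_norm + pseudocount) / (male_norm + pseudocount)).

    Exact when pseudocount = 0 and both norms > 0; NaN where both inputs and
    the pseudocount are zero.  Accepts scalars or arrays.
    """
    f = np.asarray(female_norm, float)
    m = np.asarray(male_norm, float)
    if (f < 0).any() or (m < 0).any():
        raise ValueError("normalized depths must be >= 0")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.log2(f + pseudocount) - np.log2(m + pseudocount)
    out = np.where((f + pseudocount == 0) & (m + pseudocount == 0), np.nan, out)
    if np.ndim(female_norm) == 0 and np.ndim(male_norm) == 0:
        return float(out)
    return out


def normalize_depths(
    windows: pd.DataFrame,
    medians: Mapping[str, float] | None = None,
    pseudocount: float = 0.05,
    label_col: str = "truth_class",
) -> pd.DataFrame:
    """Add female_norm, male_norm, female_share and log2fm columns.

    Depths are divided by the per-sex autosomal median (computed from
    ``label_col`` when ``medians`` is not given).  The pseudocount (in
    median-normalized units, default 0.05) keeps log2FM finite on W windows
    where the male depth can be zero.
    """
    if medians is None:
        medians = autosomal_median(windows, label_col=label_col)
    if medians["female"] <= 0 or medians["male"] <= 0:
        raise ValueError("autosomal median depth must be positive for both sexes")
    out = windows.copy()
    out["female_norm"] = out["female_depth"] / medians["female"]
    out["male_norm"] = out["male_depth"] / medians["male"]
    tot = out["female_norm"] + out["male_norm"]
    with np.errstate(invalid="ignore"):
        out["female_share"] = np.where(tot > 0, out["female_norm"] / tot, np.nan)
    out["log2fm"] = log2fm(out["female_norm"], out["male_norm"], pseudocount)
    return out


def classify_log2fm(
    normalized: pd.DataFrame,
    w_threshold: float = 1.0,
    z_band: tuple[float, float] = (-1.5, -0.5),
    autosome_band: tuple[float, float] = (-0.25, 0.25),
) -> pd.Series:
    """Threshold classification on log2FM.

    W iff log2fm >= w_threshold (strict ">=": 0.99 is not W at the default
    threshold); otherwise Z or autosomal if log2fm falls in the respective
    band; else ambiguous.
    """
    v = normalized["log2fm"].to_numpy(float)
    call = np.full(v.shape, "ambiguous", dtype=object)
    call[(v >= autosome_band[0]) & (v <= autosome_band[1])] = "autosomal"
    call[(v >= z_band[0]) & (v <= z_band[1])] = "Z"
    call[v >= w_threshold] = "W"
    call[~np.isfinite(v)] = "ambiguous"
    return pd.Series(call, index=normalized.index, name="call_log2fm")


def iqr_upper_fence(values) -> float:
    """Q3 + 1.5*IQR upper outlier fence (type-7 linear-interpolation quartiles)."""
    v = np.asarray(values, float)
    v = v[np.isfinite(v)]
    if v.size < 4:
        raise ValueError("need >= 4 finite values for quartiles")
    q1, q3 = np.percentile(v, [25, 75])  # numpy default = linear (type 7)
    return float(q3 + 1.5 * (q3 - q1))


def classify_iqr(normalized: pd.DataFrame) -> pd.Series:
    """Upper-outlier classification on the female share of normalized depth.

    A window is called W iff its female share f = F_norm/(F_norm+M_norm)
    strictly exceeds Q3 + 1.5*IQR of the f distribution (autosomal windows
    sit at f = 0.5, Z at 1/3, W near 1).  The rule only detects W; all other
    windows are labelled ambiguous.  A degenerate all-equal distribution
    yields no W calls.
    """
    f = normalized["female_share"].to_numpy(float)
    fence = iqr_upper_fence(f)
    call = np.where(f > fence, "W", "ambiguous").astype(object)
    call[~np.isfinite(f)] = "ambiguous"
    return pd.Series(call, index=normalized.index, name="call_iqr")


def calibrate(calls: pd.Series, truth: pd.Series) -> CalibrationResult:
    """Power and false-positive rate of W calls against truth labels.

    power = TP/(TP+FN) over truth-W units; FPR = FP/(FP+TN) over all other
    units.  Power is None (undefined) when there are no truth-W units.
    """
    if len(calls) != len(truth):
        raise ValueError("calls and truth must align")
    is_w_call = (calls == "W").to_numpy()
    is_w_true = (truth == "W").to_numpy()
    n_true = int(is_w_true.sum())
    n_false = int((~is_w_true).sum())
    power = float(is_w_call[is_w_true].mean()) if n_true else None
    fpr = float(is_w_call[~is_w_true].mean()) if n_false else None
    return CalibrationResult(power=power, false_positive_rate=fpr, n_true=n_true, n_false=n_false)


def scaffold_rollup(
    units: pd.DataFrame,
    call_col: str = "call",
    scaffold_col: str = "chrom",
) -> pd.Series:
    """Per-scaffold call from window calls: majority vote, ties -> ambiguous.

    For per-scaffold depth tables, run the classifiers directly on the
    scaffold rows instead (the single-window case reduces to the window
    call, which this function also honours).
    """
    def _vote(s: pd.Series) -> str:
        counts = s.value_counts()
        top = counts[counts == counts.max()]
        return str(top.index[0]) if len(top) == 1 else "ambiguous"

    return units.groupby(scaffold_col)[call_col].agg(_vote).rename("call")
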