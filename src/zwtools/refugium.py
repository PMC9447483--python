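"""Refugium and toxicity statistics for repeat elements across chromosome classes.

Under a uniform genome-wide distribution, the repeat content of each
chromosome class (autosomes, Z, W) is expected to be proportional to the
class's ungapped length.  The Refugium Index quantifies departure from that
expectation per class:

    RI_c = (obs_c - exp_c) / exp_c,   exp_c = total_obs * len_c / total_len

so RI > 0 is an excess (the class acts as a refugium for the element
category) and RI < 0 a depletion.  Departure from uniformity is tested with
a Pearson chi-square on (observed, expected) with df = #classes - 1.  The
Toxicity Index compares the diploid complement of full-length LTR elements
between the heterogametic (ZW female: 2A + Z + W) and homogametic (ZZ male:
2A + 2Z) genotypes:

    TI = (2n_het - 2n_hom) / 2n_hom

with TI = 0 meaning no sex bias, TI > 0 female-biased load.
Both bp totals (repeat families) and element counts (fl-LTRs) are supported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ChromClassTotals",
    "RefugiumResult",
    "ToxicityResult",
    "refugium_index",
    "toxicity_index",
    "fl_ltr_summary",
    "uniformity_test",
]

CLASSES = ("autosome", "Z", "W")


@dataclass
class ChromClassTotals:
    """Ungapped bp per class plus observed element totals per category.

    ``observed`` maps category name -> {class -> bp or count}.  PAR bp, if
    tracked separately upstream, should be assigned to a class (Z by
    default in the pipeline) before construction.
    """

    ungapped_bp: Mapping[str, float]
    observed: Mapping[str, Mapping[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cls in CLASSES:
            if cls not in self.ungapped_bp:
                raise ValueError(f"missing ungapped_bp for class {cls!r}")
            if self.ungapped_bp[cls] <= 0:
                raise ValueError(f"ungapped_bp[{cls!r}] must be positive")
        for cat, per_class in self.observed.items():
            for cls in CLASSES:
                if per_class.get(cls, 0) < 0:
                    raise ValueError(f"{cat}: observed totals must be >= 0")


@dataclass
class RefugiumResult:
    category: str
    observed: dict[str, float]
    expected: dict[str, float]
    ri: dict[str, float]
    chi2: float
    df: int
    p: float


@dataclass
class ToxicityResult:
    n_het_diploid: float  # 2*A + Z + W
    n_hom_diploid: float  # 2*A + 2*Z
    index: float


def _expected(totals: ChromClassTotals, observed: Mapping[str, float]) -> dict[str, float]:
    total_len = sum(totals.ungapped_bp[c] for c in CLASSES)
    total_obs = sum(observed.get(c, 0.0) for c in CLASSES)
    return {c: total_obs * totals.ungapped_bp[c] / total_len for c in CLASSES}


def refugium_index(totals: ChromClassTotals, category: str) -> RefugiumResult:
    """RI and chi-square uniformity test for one element category.

    Works identically for bp totals and element counts.  Raises if an
    expected value is zero (class too small for the test).
    """
    if category not in totals.observed:
        raise ValueError(f"no observed totals for category {category!r}")
    obs = {c: float(totals.observed[category].get(c, 0.0)) for c in CLASSES}
    exp = _expected(totals, obs)
    if any(e == 0 for e in exp.values()):
        raise ValueError("zero expected value: class too small for the test")
    ri = {c: (obs[c] - exp[c]) / exp[c] for c in CLASSES}
    chi2 = sum((obs[c] - exp[c]) ** 2 / exp[c] for c in CLASSES)
    df = len(CLASSES) - 1
    p = float(stats.chi2.sf(chi2, df))
    return RefugiumResult(category, obs, exp, ri, float(chi2), df, p)


def uniformity_test(totals: ChromClassTotals, category: str) -> dict:
    """Pearson chi-square against the length-proportional expectation.

    Emits a warning entry when any expected cell is below 5 (the usual
    chi-square validity guideline).
    """
    res = refugium_index(totals, category)
    warn = any(e < 5 for e in res.expected.values())
    return {"chi2": res.chi2, "df": res.df, "p": res.p, "low_expected_warning": warn}


def toxicity_index(counts: Mapping[str, float]) -> ToxicityResult:
    """Toxicity Index from per-class fl-LTR counts {autosome, Z, W}.

    2n_het = 2A + Z + W (female genotype), 2n_hom = 2A + 2Z (male genotype);
    TI = (2n_het - 2n_hom)/2n_hom.  Z = W gives exactly 0 (no sex bias).
    """
    a = float(counts.get("autosome", 0))
    z = float(counts.get("Z", 0))
    w = float(counts.get("W", 0))
    if min(a, z, w) < 0:
        raise ValueError("counts must be >= 0")
    n_het = 2 * a + z + w
    n_hom = 2 * a + 2 * z
    if n_hom == 0:
        raise ValueError("2n_hom = 0: toxicity index undefined")
    return ToxicityResult(n_het, n_hom, (n_het - n_hom) / n_hom)


def fl_ltr_summary(
    counts: Mapping[str, float], totals: ChromClassTotals | None = None
) -> pd.DataFrame:
    """Per-class fl-LTR counts, genome shares (%) and, with totals, RI.

    An empty record set yields an all-zero table (with a ``warning``
    attribute set on the frame).
    """
    per_class = {c: float(counts.get(c, 0)) for c in CLASSES}
    total = sum(per_class.values())
    rows = []
    ri = None
    if totals is not None and total > 0:
        t = ChromClassTotals(totals.ungapped_bp, {"fl_ltr": per_class})
        ri = refugium_index(t, "fl_ltr").ri
    for c in CLASSES:
        rows.append(
            {
                "class": c,
                "count": per_class[c],
                "share_pct": round(100 * per_class[c] / total, 1) if total else 0.0,
                "ri": ri[c] if ri else np.nan,
            }
        )
    df = pd.DataFrame(rows).set_index("class")
    df.attrs["warning"] = "empty record set" if total == 0 else ""
    return df
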