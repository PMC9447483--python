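"""Nucleotide and repeat composition: GC, CpG, repeat fractions, element ages.

GC content is the proportion of G and C among unambiguous bases; CpG content
is the proportion of CG dinucleotides among unambiguous dinucleotide
positions (single strand, overlapping positions counted).  Repeat fractions
come from an interval annotation: intervals of one family are merged before
computing coverage, different families may legitimately double-count bases.
Element ages use the Kimura 2-parameter distance to the family consensus,
optionally excluding consensus CpG sites (hypermutable via deamination).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "K2PResult",
    "gc_content",
    "cpg_content",
    "merge_intervals",
    "window_composition",
    "k2p_distance",
    "composition_tests",
    "mdg4_gc_association",
    "partial_spearman",
]

_NTS = frozenset("ACGT")


def gc_content(seq: str) -> float | None:
    """G+C proportion among unambiguous bases; None if none are scorable."""
    if not seq:
        raise ValueError("empty sequence")
    s = seq.upper()
    n_valid = sum(b in _NTS for b in s)
    if n_valid == 0:
        return None
    return sum(b in "GC" for b in s) / n_valid


def cpg_content(seq: str) -> float | None:
    """CG-dinucleotide proportion among unambiguous dinucleotide positions.

    Positions touching an ambiguous base are excluded from the denominator;
    overlapping dinucleotide positions are counted; single strand only.
    """
    if not seq:
        raise ValueError("empty sequence")
    s = seq.upper()
    if len(s) < 2:
        return None
    valid = np.fromiter((b in _NTS for b in s), bool, len(s))
    pair_valid = valid[:-1] & valid[1:]
    denom = int(pair_valid.sum())
    if denom == 0:
        return None
    arr = np.frombuffer(s.encode(), np.uint8)
    is_cg = (arr[:-1] == ord("C")) & (arr[1:] == ord("G"))
    return int((is_cg & pair_valid).sum()) / denom


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping/adjacent half-open intervals."""
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def _overlap_per_window(
    merged: Sequence[tuple[int, int]], starts: np.ndarray, ends: np.ndarray
) -> np.ndarray:
    """Covered bp per window from a merged (disjoint, sorted) interval set."""
    out = np.zeros(len(starts), float)
    if not merged:
        return out
    ms = np.array([s for s, _ in merged])
    me = np.array([e for _, e in merged])
    # cumulative covered bp over intervals 0..i-1
    cum = np.concatenate([[0], np.cumsum(me - ms)])

    def covered_until(x: np.ndarray) -> np.ndarray:
        j = np.searchsorted(me, x, side="right")  # intervals ending at or before x
        jj = np.minimum(j, len(ms) - 1)
        partial = np.where((j < len(ms)) & (x > ms[jj]), x - ms[jj], 0)
        return cum[j] + partial

    return covered_until(ends) - covered_until(starts)


def window_composition(
    sequences: Mapping[str, str],
    window_size: int,
    annotation: pd.DataFrame | None = None,
    classes: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-window GC, CpG and repeat fractions.

    ``annotation`` is BED-like (chrom, start, end, family; 0-based
    half-open); same-family intervals are merged before fractions are
    computed and overlaps are clipped to window bounds.  Terminal windows
    shorter than window_size are retained (``short_window`` flag) with
    fractions over the actual length.  ``classes`` optionally maps
    chromosome name to class label (added as a ``class`` column).
    """
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    families = []
    merged_by_chrom_family: dict[tuple[str, str], list[tuple[int, int]]] = {}
    if annotation is not None and len(annotation):
        for (chrom, family), sub in annotation.groupby(["chrom", "family"]):
            if ((sub["start"] < 0) | (sub["end"] > len(sequences.get(chrom, "")))).any():
                raise ValueError(f"annotation out of bounds on {chrom}")
            merged_by_chrom_family[(chrom, family)] = merge_intervals(
                zip(sub["start"], sub["end"])
            )
        families = sorted(annotation["family"].unique())
    rows = []
    for chrom in sorted(sequences):
        seq = sequences[chrom].upper()
        starts = np.arange(0, len(seq), window_size)
        ends = np.minimum(starts + window_size, len(seq))
        fam_cov = {
            fam: _overlap_per_window(
                merged_by_chrom_family.get((chrom, fam), []), starts, ends
            )
            for fam in families
        }
        all_fam = (
            merge_intervals(
                itertools.chain.from_iterable(
                    merged_by_chrom_family.get((chrom, fam), []) for fam in families
                )
            )
            if families
            else []
        )
        tot_cov = _overlap_per_window(all_fam, starts, ends)
        for i, (s, e) in enumerate(zip(starts, ends)):
            sub = seq[s:e]
            length = e - s
            row = {
                "chrom": chrom,
                "start": int(s),
                "end": int(e),
                "length": int(length),
                "gc": gc_content(sub),
                "cpg": cpg_content(sub),
                "repeat_fraction": tot_cov[i] / length,
                "short_window": bool(length < window_size),
            }
            for fam in families:
                row[f"frac_{fam}"] = fam_cov[fam][i] / length
            if classes is not None:
                row["class"] = classes.get(chrom)
            rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class K2PResult:
    """Kimura 2-parameter distance of an element copy to its consensus."""

    element_id: str
    transitions: float  # proportion P
    transversions: float  # proportion Q
    distance: float
    n_sites: int
    cpg_corrected: bool
    saturated: bool = False


_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def k2p_distance(
    element_seq: str,
    consensus_seq: str,
    cpg_correct: bool = False,
    element_id: str = "",
) -> K2PResult:
    """d = -1/2 ln((1-2P-Q) * sqrt(1-2Q)) over scorable aligned sites.

    Scorable sites have unambiguous bases in both sequences; with
    ``cpg_correct`` both positions of every CpG dinucleotide in the
    consensus are additionally excluded (the RepeatMasker calcDivergence
    convention).  Saturated pairs (log argument <= 0) are flagged with NaN
    distance; zero scorable sites also yield NaN.
    """
    if len(element_seq) != len(consensus_seq):
        raise ValueError("aligned sequences must be equal length")
    e = element_seq.upper()
    c = consensus_seq.upper()
    excluded = set()
    if cpg_correct:
        for i in range(len(c) - 1):
            if c[i] == "C" and c[i + 1] == "G":
                excluded.update((i, i + 1))
    n = p = q = 0
    for i, (a, b) in enumerate(zip(e, c)):
        if i in excluded or a not in _NTS or b not in _NTS:
            continue
        n += 1
        if a != b:
            if (a, b) in _TRANSITIONS:
                p += 1
            else:
                q += 1
    if n == 0:
        return K2PResult(element_id, math.nan, math.nan, math.nan, 0, cpg_correct, False)
    P, Q = p / n, q / n
    arg1 = 1 - 2 * P - Q
    arg2 = 1 - 2 * Q
    if arg1 <= 0 or arg2 <= 0:
        return K2PResult(element_id, P, Q, math.nan, n, cpg_correct, True)
    d = -0.5 * math.log(arg1 * math.sqrt(arg2))
    return K2PResult(element_id, P, Q, d, n, cpg_correct, False)


def composition_tests(
    records: pd.DataFrame,
    metrics: Sequence[str] = ("gc", "cpg", "repeat_fraction"),
    class_col: str = "class",
) -> dict:
    """Pairwise Mann-Whitney comparisons of composition metrics across classes.

    Returns per-class means/SDs and two-sided U tests for every class pair
    and metric.  Classes with no finite values for a metric are excluded
    from that metric's comparisons.
    """
    classes = [c for c in records[class_col].dropna().unique()]
    if len(classes) < 2:
        raise ValueError("need >= 2 classes")
    summary = records.groupby(class_col)[list(metrics)].agg(["mean", "std", "count"])
    tests = {}
    for metric in metrics:
        for a, b in itertools.combinations(sorted(classes), 2):
            xa = records.loc[records[class_col] == a, metric].dropna()
            xb = records.loc[records[class_col] == b, metric].dropna()
            if xa.empty or xb.empty:
                continue
            res = stats.mannwhitneyu(xa, xb, alternative="two-sided")
            tests[(metric, a, b)] = {"U": float(res.statistic), "p": float(res.pvalue)}
    return {"summary": summary, "tests": tests}


def partial_spearman(x, y, covariates: np.ndarray) -> tuple[float, float]:
    """Rank-based partial correlation of x and y given covariate columns.

    Computed from the inverse of the Spearman (rank) correlation matrix;
    the p-value uses the t approximation with df = n - 2 - k.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    cov = np.atleast_2d(np.asarray(covariates, float))
    if cov.shape[0] == x.size and cov.ndim == 2:
        cov = cov.T
    data = np.vstack([x, y, *cov])
    ranks = np.apply_along_axis(stats.rankdata, 1, data)
    corr = np.corrcoef(ranks)
    if not np.all(np.isfinite(corr)):
        raise ValueError("constant column: correlation undefined")
    prec = np.linalg.pinv(corr)
    r = -prec[0, 1] / math.sqrt(prec[0, 0] * prec[1, 1])
    n = x.size
    k = cov.shape[0]
    df = n - 2 - k
    if df <= 0:
        return float(r), math.nan
    r_clip = min(max(r, -0.999999), 0.999999)
    t = r_clip * math.sqrt(df / (1 - r_clip**2))
    p = 2 * stats.t.sf(abs(t), df)
    return float(r), float(p)


def mdg4_gc_association(
    records: pd.DataFrame,
    focal_col: str = "frac_mdg4",
    gc_col: str = "gc",
    cpg_col: str = "cpg",
    total_col: str = "repeat_fraction",
) -> dict:
    """Association between focal-family repeat density and GC content.

    Returns the Spearman correlation of (focal fraction, GC), the rank-based
    partial correlation controlling for CpG content and non-focal repeat
    fraction, and the control correlation between GC and the non-focal
    repeat fraction (the focal family removed) — a null check that the GC
    signal is family-specific.
    """
    df = records[[focal_col, gc_col, cpg_col, total_col]].dropna()
    if len(df) < 10:
        raise ValueError("need >= 10 records")
    other = (df[total_col] - df[focal_col]).clip(lower=0)
    for name, col in (("focal", df[focal_col]), ("gc", df[gc_col])):
        if col.nunique() == 1:
            raise ValueError(f"constant {name} column: correlation undefined")
    rho, p = stats.spearmanr(df[focal_col], df[gc_col])
    r_part, p_part = partial_spearman(
        df[focal_col], df[gc_col], np.vstack([df[cpg_col], other])
    )
    rho_ctrl, p_ctrl = stats.spearmanr(other, df[gc_col])
    return {
        "spearman_r": float(rho),
        "spearman_p": float(p),
        "partial_r": r_part,
        "partial_p": p_part,
        "control_r": float(rho_ctrl),
        "control_p": float(p_ctrl),
        "n": int(len(df)),
    }
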