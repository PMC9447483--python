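"""Gametolog divergence, evolutionary strata, and divergence-time estimation.

Synonymous/nonsynonymous divergence between Z and W gametologs is estimated
with the Nei-Gojobori (1986) counting method: synonymous and nonsynonymous
sites are counted per codon, codons differing at more than one position are
resolved by averaging difference counts over all mutational pathways that
avoid stop codons (equal pathway weights), and the resulting proportions are
corrected for multiple hits with the Jukes-Cantor formula
``d = -3/4 ln(1 - 4p/3)``.

Divergence times are obtained from dS under a sex-specific rate model.  The
autosomal per-lineage rate mu_A is scaled to a combined ZW divergence rate as
``mu_A * z_ratio + mu_A * female_fraction`` where ``z_ratio`` is the Z:A
mutation-rate ratio (male-biased mutation makes it > 1) and
``female_fraction`` is the W rate as a fraction of mu_A (the W is confined to
the female germline).  Divergence time is then ``dS / rate``.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable
from scipy import stats

__all__ = [
    "CodonAlignment",
    "DivergencePair",
    "RateModel",
    "StratumAssignment",
    "ng86_pair",
    "filter_pairs",
    "assign_strata",
    "autosomal_rate",
    "sex_linked_rate",
    "ds_to_time",
    "stratum_summary",
    "gc3",
    "gc3_compare",
    "round_sig",
    "pairs_to_frame",
]

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
CODON_TO_AA = dict(_STANDARD.forward_table)
STOP_CODONS = frozenset(_STANDARD.stop_codons)
SENSE_CODONS = tuple(sorted(CODON_TO_AA))
_NTS = "ACGT"


class SaturationError(ValueError):
    """Raised when a divergence target or estimate is beyond correctability."""


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------

@dataclass
class CodonAlignment:
    """A pairwise codon alignment of a Z/W gametolog pair.

    Sequences must be equal length; gaps and ambiguous bases are removed
    codon-wise (a codon is dropped from both sequences if either copy has a
    non-ACGT character in it).
    """

    gene: str
    seq_z: str
    seq_w: str
    z_position: float | None = None

    def __post_init__(self) -> None:
        if len(self.seq_z) != len(self.seq_w):
            raise ValueError(f"{self.gene}: aligned sequences differ in length")
        if len(self.seq_z) % 3 != 0:
            raise ValueError(f"{self.gene}: alignment length not a multiple of 3")

    def clean_codons(self) -> list[tuple[str, str]]:
        """Codon pairs with gaps/ambiguity removed; trailing stops dropped."""
        s1, s2 = self.seq_z.upper(), self.seq_w.upper()
        out = []
        n = len(s1) // 3
        for i in range(n):
            c1, c2 = s1[3 * i : 3 * i + 3], s2[3 * i : 3 * i + 3]
            if any(b not in _NTS for b in c1 + c2):
                continue
            if c1 in STOP_CODONS or c2 in STOP_CODONS:
                if i == n - 1:  # terminal stop codon, not informative
                    continue
                raise ValueError(f"{self.gene}: internal stop codon at codon {i}")
            out.append((c1, c2))
        return out


@dataclass
class DivergencePair:
    """NG86 divergence estimates for one gametolog pair."""

    gene: str
    dn: float
    ds: float
    omega: float | None
    s_sites: float
    n_sites: float
    sd: float  # synonymous differences (pathway-averaged)
    nd: float  # nonsynonymous differences
    n_codons: int
    z_position: float | None = None
    stratum: str | None = None
    saturated: bool = False


@dataclass
class RateModel:
    """Sex-specific mutation-rate model for ZW divergence dating.

    mu_a is the per-lineage autosomal rate (substitutions/site/year), z_ratio
    the Z:A mutation-rate ratio, and female_fraction the W-chromosome rate
    expressed as a fraction of mu_a.  ``rounding`` gives the number of
    significant figures applied to each component of the combined rate before
    summation (None = exact sum).
    """

    mu_a: float = 2.8e-9
    z_ratio: float = 1.1
    female_fraction: float = 0.25
    rounding: int | None = 2

    def __post_init__(self) -> None:
        if self.mu_a <= 0 or self.z_ratio <= 0 or self.female_fraction <= 0:
            raise ValueError("rate model components must be positive")


@dataclass
class StratumAssignment:
    """Stratum membership for anchored gametolog pairs.

    ``breakpoints`` are the Z-coordinate cut points between consecutive
    clusters (strictly increasing); ``labels`` maps positional cluster index
    to a stratum name (ordered by mean dS, higher = older); ``membership``
    is a per-gene Series of stratum labels.
    """

    breakpoints: list[float]
    labels: dict[int, str]
    membership: pd.Series


# ---------------------------------------------------------------------------
# NG86 machinery
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def _syn_site_fraction(codon: str) -> float:
    """Fraction of the 9 single-nucleotide changes that are synonymous.

    Changes creating a stop codon count as nonsynonymous (denominator stays
    3 per position).
    """
    aa = CODON_TO_AA[codon]
    syn = 0
    for j in range(3):
        for nt in _NTS:
            if nt == codon[j]:
                continue
            alt = codon[:j] + nt + codon[j + 1 :]
            if alt not in STOP_CODONS and CODON_TO_AA[alt] == aa:
                syn += 1
    return syn / 3.0


@lru_cache(maxsize=None)
def _pathway_counts(c1: str, c2: str) -> tuple[float, float]:
    """Pathway-averaged (synonymous, nonsynonymous) differences for a codon pair.

    All orderings of the differing positions are enumerated; pathways whose
    intermediate codons are stops are discarded and the remaining pathways
    weighted equally.  If every pathway passes through a stop (possible only
    for a handful of 3-difference pairs), all pathways are used.
    """
    diffs = [j for j in range(3) if c1[j] != c2[j]]
    if not diffs:
        return 0.0, 0.0
    for require_stop_free in (True, False):
        tot_s = tot_n = 0.0
        n_paths = 0
        for order in itertools.permutations(diffs):
            cur = c1
            s = n = 0
            valid = True
            for j in order:
                nxt = cur[:j] + c2[j] + cur[j + 1 :]
                if nxt in STOP_CODONS:
                    if require_stop_free:
                        valid = False
                        break
                    n += 1  # through-stop fallback: steps touching a stop are nonsynonymous
                elif cur in STOP_CODONS:
                    n += 1
                elif CODON_TO_AA[cur] == CODON_TO_AA[nxt]:
                    s += 1
                else:
                    n += 1
                cur = nxt
            if valid:
                n_paths += 1
                tot_s += s
                tot_n += n
        if n_paths:
            return tot_s / n_paths, tot_n / n_paths
    raise AssertionError("unreachable")


def jukes_cantor(p: float) -> float:
    """Jukes-Cantor multiple-hit correction d = -3/4 ln(1 - 4p/3)."""
    if p < 0:
        raise ValueError("proportion must be >= 0")
    if p >= 0.75:
        raise SaturationError(f"proportion {p:.4f} >= 0.75: correction undefined")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def ng86_pair(alignment: CodonAlignment) -> DivergencePair:
    """NG86 dN/dS for one codon alignment.

    Sites are averaged over the two sequences; multi-difference codons are
    resolved by equal-weight averaging over stop-free substitution pathways;
    Jukes-Cantor correction is applied to the synonymous and nonsynonymous
    proportions separately.  Pairs with pS or pN >= 0.75 are returned with
    NaN distances and ``saturated=True``.
    """
    codons = alignment.clean_codons()
    if not codons:
        raise ValueError(f"{alignment.gene}: no scorable codons")
    s_sites = 0.0
    sd = nd = 0.0
    for c1, c2 in codons:
        s_sites += 0.5 * (_syn_site_fraction(c1) + _syn_site_fraction(c2))
        ds_, dn_ = _pathway_counts(c1, c2)
        sd += ds_
        nd += dn_
    n_sites = 3.0 * len(codons) - s_sites
    ps = sd / s_sites if s_sites > 0 else 0.0
    pn = nd / n_sites if n_sites > 0 else 0.0
    try:
        ds = jukes_cantor(ps)
        dn = jukes_cantor(pn)
        saturated = False
    except SaturationError:
        ds = dn = float("nan")
        saturated = True
    omega = (dn / ds) if (not saturated and ds > 0) else None
    return DivergencePair(
        gene=alignment.gene,
        dn=dn,
        ds=ds,
        omega=omega,
        s_sites=s_sites,
        n_sites=n_sites,
        sd=sd,
        nd=nd,
        n_codons=len(codons),
        z_position=alignment.z_position,
        saturated=saturated,
    )


def pairs_to_frame(pairs: Iterable[DivergencePair]) -> pd.DataFrame:
    """Tabulate DivergencePair records (one row per gene)."""
    rows = [
        {
            "gene": p.gene,
            "dN": p.dn,
            "dS": p.ds,
            "omega": np.nan if p.omega is None else p.omega,
            "S_sites": p.s_sites,
            "N_sites": p.n_sites,
            "z_position": np.nan if p.z_position is None else p.z_position,
            "stratum": p.stratum,
            "saturated": p.saturated,
        }
        for p in pairs
    ]
    return pd.DataFrame(rows)


def filter_pairs(
    pairs: pd.DataFrame,
    ds_min: float = 0.001,
    ds_max: float = 2.0,
) -> pd.DataFrame:
    """Retain pairs with ds_min <= dS <= ds_max (bounds inclusive).

    Saturated pairs (NaN dS) are dropped.  Mirrors the filtering used before
    strata assignment: dS below the floor gives no dating signal and dS above
    the ceiling is effectively saturated.
    """
    keep = pairs["dS"].between(ds_min, ds_max, inclusive="both")
    return pairs.loc[keep.fillna(False)].copy()


# ---------------------------------------------------------------------------
# strata
# ---------------------------------------------------------------------------

def assign_strata(
    pairs: pd.DataFrame,
    breakpoints: Sequence[float] | None = None,
    k_clusters: int | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, StratumAssignment]:
    """Assign anchored gametolog pairs to evolutionary strata along the Z.

    Either explicit Z-coordinate ``breakpoints`` (recommended, reproducible)
    or ``k_clusters`` for 1-D k-means on z_position (fixed seed, 100
    restarts).  Clusters are numbered along the chromosome and labelled
    "S1", "S2", ... in order of decreasing mean dS (S1 = oldest stratum).
    Returns the annotated table and the StratumAssignment.
    """
    if (breakpoints is None) == (k_clusters is None):
        raise ValueError("give exactly one of breakpoints or k_clusters")
    if pairs["z_position"].isna().any():
        raise ValueError("all pairs must carry a z_position anchor")
    out = pairs.copy()
    pos = out["z_position"].to_numpy(float)
    if breakpoints is not None:
        bps = sorted(float(b) for b in breakpoints)
        if len(set(bps)) != len(bps):
            raise ValueError("breakpoints must be strictly increasing")
        cluster = np.searchsorted(bps, pos, side="right")
    else:
        if k_clusters > len(out):
            raise ValueError("more clusters than genes")
        from sklearn.cluster import KMeans

        km = KMeans(n_clusters=k_clusters, n_init=100, random_state=seed)
        raw = km.fit_predict(pos.reshape(-1, 1))
        # renumber clusters by position along the chromosome
        order = np.argsort(km.cluster_centers_.ravel())
        remap = {int(old): new for new, old in enumerate(order)}
        cluster = np.array([remap[int(c)] for c in raw])
        centers = np.sort(km.cluster_centers_.ravel())
        bps = [float((centers[i] + centers[i + 1]) / 2) for i in range(len(centers) - 1)]
    out["cluster"] = cluster
    mean_ds = out.groupby("cluster")["dS"].mean().sort_values(ascending=False)
    labels = {int(c): f"S{rank + 1}" for rank, c in enumerate(mean_ds.index)}
    out["stratum"] = out["cluster"].map(labels)
    membership = pd.Series(out["stratum"].to_numpy(), index=out["gene"], name="stratum")
    return out, StratumAssignment(breakpoints=list(bps), labels=labels, membership=membership)


def merge_strata(pairs: pd.DataFrame, groups: dict[str, Sequence[str]]) -> pd.DataFrame:
    """Merge stratum labels into superstrata, e.g. {"older": ["S1","S2"], "recent": ["S3"]}."""
    mapping = {s: name for name, members in groups.items() for s in members}
    out = pairs.copy()
    out["stratum"] = out["stratum"].map(mapping).fillna(out["stratum"])
    return out


def stratum_summary(pairs: pd.DataFrame, stratum_col: str = "stratum") -> dict:
    """Per-stratum dS / dN/dS summaries with pairwise Mann-Whitney tests.

    Returns a dict with a per-stratum table (n, mean/sd of dS and omega),
    two-sided Mann-Whitney U and p for every stratum pair (U reported for
    the first-named group), and Levene's test across strata on dS.
    """
    grouped = pairs.groupby(stratum_col)
    table = grouped.agg(
        n=("dS", "size"),
        mean_dS=("dS", "mean"),
        sd_dS=("dS", "std"),
        mean_omega=("omega", "mean"),
        sd_omega=("omega", "std"),
    )
    strata = list(table.index)
    if len(strata) < 2:
        raise ValueError("need >= 2 strata for comparisons")
    comparisons = {}
    for a, b in itertools.combinations(strata, 2):
        xa = pairs.loc[pairs[stratum_col] == a, "dS"].dropna()
        xb = pairs.loc[pairs[stratum_col] == b, "dS"].dropna()
        res = stats.mannwhitneyu(xa, xb, alternative="two-sided")
        comparisons[(a, b)] = {"U": float(res.statistic), "p": float(res.pvalue)}
    samples = [pairs.loc[pairs[stratum_col] == s, "dS"].dropna() for s in strata]
    lev = stats.levene(*samples)
    return {
        "per_stratum": table,
        "mannwhitney": comparisons,
        "levene": {"W": float(lev.statistic), "p": float(lev.pvalue)},
    }


# ---------------------------------------------------------------------------
# rate model and dating
# ---------------------------------------------------------------------------

def round_sig(x: float, sig: int) -> float:
    """Round to ``sig`` significant figures."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, sig - 1 - math.floor(math.log10(abs(x))))


def autosomal_rate(median_ds: float, split_time_years: float) -> float:
    """Per-lineage autosomal rate from median ortholog dS and a split time.

    Divergence accrues on both lineages, so mu_A = median_dS / (2 * T).
    Report at 2 significant figures in summaries (``round_sig``).
    """
    if median_ds <= 0 or split_time_years <= 0:
        raise ValueError("inputs must be positive")
    return median_ds / (2.0 * split_time_years)


def sex_linked_rate(model: RateModel) -> float:
    """Combined ZW divergence rate: mu_A*z_ratio (Z) + mu_A*female_fraction (W).

    Each component is rounded to ``model.rounding`` significant figures
    before summation (the printed arithmetic 3.1e-9 + 0.7e-9 = 3.8e-9 only
    holds under component rounding); rounding=None gives the exact sum.
    """
    z = model.mu_a * model.z_ratio
    w = model.mu_a * model.female_fraction
    if model.rounding is not None:
        z = round_sig(z, model.rounding)
        w = round_sig(w, model.rounding)
    return z + w


def ds_to_time(ds: float, combined_rate: float) -> float:
    """Divergence time in years: dS / rate."""
    if combined_rate <= 0:
        raise ValueError("rate must be positive")
    if ds < 0:
        raise ValueError("dS must be >= 0")
    return ds / combined_rate


# ---------------------------------------------------------------------------
# GC3 / gene-conversion test
# ---------------------------------------------------------------------------

def gc3(cds: str) -> float:
    """Proportion of G+C at third codon positions (ambiguous bases excluded)."""
    cds = cds.upper()
    if not cds or len(cds) % 3 != 0:
        raise ValueError("CDS length must be a positive multiple of 3")
    thirds = cds[2::3]
    valid = [b for b in thirds if b in _NTS]
    if not valid:
        raise ValueError("no unambiguous third-position bases")
    return sum(b in "GC" for b in valid) / len(valid)


def gc3_compare(z_gc3: Sequence[float], w_gc3: Sequence[float]) -> dict:
    """Welch's t-test of W vs Z GC3 plus the fraction of pairs with W > Z.

    Under GC-biased gene conversion restricted to recombining sequence, W
    gametologs should have *lower* GC3 than their Z partners; W GC3 that is
    not lower (and frequent strict W > Z) points to intrachromosomal gene
    conversion on the W.
    """
    z = np.asarray(z_gc3, float)
    w = np.asarray(w_gc3, float)
    if z.shape != w.shape or z.size == 0:
        raise ValueError("paired GC3 lists must be equal-length and non-empty")
    if np.allclose(w, z):
        t, p = 0.0, 1.0
    else:
        res = stats.ttest_ind(w, z, equal_var=False)
        t, p = float(res.statistic), float(res.pvalue)
    return {
        "t": t,
        "p": p,
        "frac_w_gt_z": float(np.mean(w > z)),
        "mean_z": float(z.mean()),
        "mean_w": float(w.mean()),
    }
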