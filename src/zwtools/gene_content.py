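"""Gene-level evolution on the W: copy number, decay, translocation, expression.

Copy number of a W-linked gene is inferred from female read depth: a
single-copy W gene is hemizygous, so its depth is half the diploid
autosomal median.  The per-female relative value 2 * depth / median is
therefore ~1 for single-copy genes and the mean across females estimates
the copy number directly.  Gene decay per stratum is (Z genes - W genes) /
stratum age; stratum gene enrichment uses Fisher's exact test; candidate
autosome-to-W translocations are W genes with no Z gametolog whose Anolis
ortholog maps off chromosome 6 (the chromosome ancestrally homologous to
the caenophidian ZW pair); expression detection uses the raw-count rule
(count > 0 in any sample of a sex).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CopyNumberEstimate",
    "DecayRate",
    "copy_number",
    "decay_rate",
    "stratum_enrichment",
    "classify_translocation",
    "expression_flags",
    "tpm",
]


@dataclass
class CopyNumberEstimate:
    gene: str
    per_female: dict[str, float]
    copy_number: float
    duplicated: bool


@dataclass
class DecayRate:
    stratum: str
    n_z_genes: int
    n_w_genes: int
    time_years: float
    rate: float  # genes lost per year
    gene_gain: bool  # flagged when n_w > n_z


def copy_number(
    gene_depths: Mapping[str, float],
    autosomal_medians: Mapping[str, float],
    gene: str = "",
    duplication_threshold: float = 1.5,
) -> CopyNumberEstimate:
    """Depth-based copy number of a W-linked gene across females.

    ``gene_depths`` and ``autosomal_medians`` map female sample -> mean exon
    depth / autosomal median depth.  The haploidy correction (x2) scales a
    single-copy gene to 1; copy_number is the mean across females and
    ``duplicated`` flags copy_number >= duplication_threshold.
    """
    if not gene_depths:
        raise ValueError("need >= 1 female sample")
    per_female = {}
    for sample, depth in gene_depths.items():
        med = autosomal_medians.get(sample)
        if med is None or med <= 0:
            raise ValueError(f"autosomal median missing or non-positive for {sample!r}")
        if depth < 0:
            raise ValueError("depths must be >= 0")
        per_female[sample] = 2.0 * depth / med
    cn = float(np.mean(list(per_female.values())))
    return CopyNumberEstimate(gene, per_female, cn, cn >= duplication_threshold)


def copy_number_table(
    depths: pd.DataFrame,
    autosomal_medians: Mapping[str, float],
    duplication_threshold: float = 1.5,
) -> pd.DataFrame:
    """Vectorized copy_number over a (gene, sample, depth) long table."""
    rows = []
    for gene, sub in depths.groupby("gene"):
        est = copy_number(
            dict(zip(sub["sample"], sub["depth"])),
            autosomal_medians,
            gene=str(gene),
            duplication_threshold=duplication_threshold,
        )
        rows.append(
            {"gene": gene, "copy_number": est.copy_number, "duplicated": est.duplicated}
        )
    return pd.DataFrame(rows)


def decay_rate(n_z: int, n_w: int, time_years: float, stratum: str = "") -> DecayRate:
    """Genes lost per year on the W: (n_Z - n_W) / stratum age."""
    if time_years <= 0:
        raise ValueError("time_years must be positive")
    if n_z < 0 or n_w < 0:
        raise ValueError("gene counts must be >= 0")
    return DecayRate(
        stratum=stratum,
        n_z_genes=n_z,
        n_w_genes=n_w,
        time_years=time_years,
        rate=(n_z - n_w) / time_years,
        gene_gain=n_w > n_z,
    )


def stratum_enrichment(
    w_in: int, w_out: int, z_in: int, z_out: int
) -> dict:
    """Fisher's exact test of W vs Z gene proportions inside a stratum.

    Two-sided test on the 2x2 table [[w_in, w_out], [z_in, z_out]].
    """
    if min(w_in, w_out, z_in, z_out) < 0:
        raise ValueError("counts must be >= 0")
    odds, p = stats.fisher_exact([[w_in, w_out], [z_in, z_out]], alternative="two-sided")
    return {"odds_ratio": float(odds), "p": float(p)}


def classify_translocation(
    has_z_gametolog: bool,
    anolis_chrom: str | None,
    ancestral_chrom: str = "6",
) -> str:
    """Candidate autosome-to-W translocation call for one gene.

    'translocated' requires no Z gametolog AND an Anolis ortholog on a
    chromosome other than the ancestrally sex-linked one (chromosome 6);
    genes with no Anolis hit are 'unknown'; everything else 'not_translocated'.
    """
    if has_z_gametolog:
        return "not_translocated"
    if anolis_chrom is None:
        return "unknown"
    return "not_translocated" if str(anolis_chrom) == str(ancestral_chrom) else "translocated"


def expression_flags(
    counts: pd.DataFrame,
    sex_map: Mapping[str, str],
    gene_lengths: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Detection and female-specific flags from raw counts.

    ``counts`` is genes x samples; ``sex_map`` maps sample -> 'female'|'male'.
    detected_<sex> = any raw count > 0 in that sex's samples;
    female_specific = detected in females and not in males.  With
    ``gene_lengths`` the table also carries per-sex mean TPM (counts scaled
    to length-normalized rates summing to 1e6 per sample).
    """
    females = [s for s in counts.columns if sex_map.get(s) == "female"]
    males = [s for s in counts.columns if sex_map.get(s) == "male"]
    if not females or not males:
        raise ValueError("need >= 1 sample per sex")
    out = pd.DataFrame(index=counts.index)
    out["detected_female"] = (counts[females] > 0).any(axis=1)
    out["detected_male"] = (counts[males] > 0).any(axis=1)
    out["female_specific"] = out["detected_female"] & ~out["detected_male"]
    if gene_lengths is not None:
        t = tpm(counts, gene_lengths)
        out["tpm_female"] = t[females].mean(axis=1)
        out["tpm_male"] = t[males].mean(axis=1)
    return out


def tpm(counts: pd.DataFrame, gene_lengths: Mapping[str, float]) -> pd.DataFrame:
    """Transcripts-per-million normalization of a genes x samples count table."""
    missing = [g for g in counts.index if g not in gene_lengths]
    if missing:
        raise ValueError(f"missing gene length for {missing[:3]}...")
    lengths = pd.Series({g: float(gene_lengths[g]) for g in counts.index})
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    rate = counts.div(lengths, axis=0)
    return rate.div(rate.sum(axis=0), axis=1) * 1e6
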