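"""Synthetic data with the statistical structure the ZW analyses assume.

The generators here produce toy genomes, female/male depth profiles,
gametolog codon alignments, repeat landscapes and gene tables so that the
whole pipeline can be exercised end to end without any sequencing data.
Copy structure follows the female-heterogametic expectation: autosomes and
the pseudoautosomal region are diploid in both sexes, the Z is hemizygous in
females (half depth) and diploid in males, and the W is hemizygous in
females and absent in males apart from a small spurious-mapping background.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .divergence import (
    CODON_TO_AA,
    SENSE_CODONS,
    STOP_CODONS,
    CodonAlignment,
    SaturationError,
    _syn_site_fraction,
)

__all__ = [
    "GenomeLayout",
    "CoverageSimParams",
    "GametologSimParams",
    "RepeatFamily",
    "RepeatSimParams",
    "simulate_depth_profiles",
    "simulate_gametolog_pairs",
    "simulate_repeat_annotation",
    "simulate_genome",
    "simulate_gene_depths",
    "simulate_expression_counts",
]

CHROM_CLASSES = ("autosome", "Z", "W", "PAR")

# depth-model constants: reads are read_length bp and counts are drawn per
# 1-kb tile, so a window aggregates window_size/1000 overdispersed tiles
READ_LENGTH = 150
TILE_BP = 1000


@dataclass
class GenomeLayout:
    """Chromosome names, classes and lengths plus the analysis window size."""

    chromosomes: list[tuple[str, str, int]]
    window_size: int = 10_000

    def __post_init__(self) -> None:
        if self.window_size <= 0:
            raise ValueError("window_size must be positive")
        for name, cls, length in self.chromosomes:
            if cls not in CHROM_CLASSES:
                raise ValueError(f"{name}: unknown class {cls!r}")
            if length <= 0:
                raise ValueError(f"{name}: length must be positive")

    def windows(self) -> pd.DataFrame:
        """Half-open 0-based window tiling covering every chromosome."""
        rows = []
        for name, cls, length in self.chromosomes:
            starts = np.arange(0, length, self.window_size)
            ends = np.minimum(starts + self.window_size, length)
            for s, e in zip(starts, ends):
                rows.append((name, int(s), int(e), cls))
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "truth_class"])

    def class_lengths(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for _, cls, length in self.chromosomes:
            out[cls] = out.get(cls, 0) + length
        return out


@dataclass
class CoverageSimParams:
    """Read-depth noise model.

    mean_depth is the diploid autosomal mean (reads/bp); dispersion is the
    negative-binomial size parameter per 1-kb tile (np.inf = noise-free);
    male_w_background is the fraction of mean_depth spuriously mapped to W
    windows in males.  The default 0.125 makes a noise-free W window sit at
    log2FM = log2(0.5/0.125) = 2, the canonical W expectation.
    """

    mean_depth: float = 30.0
    dispersion: float = 10.0
    male_w_background: float = 0.125
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if not 0 <= self.male_w_background < 0.5:
            raise ValueError("male_w_background must be in [0, 0.5)")


# per-class multipliers of the diploid autosomal mean
_FEMALE_FACTOR = {"autosome": 1.0, "PAR": 1.0, "Z": 0.5, "W": 0.5}


def _male_factor(background: float) -> dict[str, float]:
    return {"autosome": 1.0, "PAR": 1.0, "Z": 1.0, "W": background}


def _nb_depth(
    rng: np.random.Generator,
    expected_depth: np.ndarray,
    lengths: np.ndarray,
    dispersion: float,
) -> np.ndarray:
    """Mean depth per window from a tile-aggregated negative-binomial count.

    The window read count is NB with mean = depth * L / READ_LENGTH and size
    = dispersion * L / TILE_BP (the distribution of a sum of independent
    per-tile NB counts), converted back to mean reads/bp.
    """
    if math.isinf(dispersion):
        return expected_depth.astype(float)
    mean_reads = expected_depth * lengths / READ_LENGTH
    size = dispersion * lengths / TILE_BP
    p = size / (size + mean_reads)
    counts = rng.negative_binomial(size, p)
    return counts * READ_LENGTH / lengths


def simulate_depth_profiles(layout: GenomeLayout, params: CoverageSimParams) -> pd.DataFrame:
    """Per-window female and male mean read depths with truth labels.

    Female expected depth is mean_depth * {1 autosome/PAR, 1/2 Z, 1/2 W};
    male expected depth is mean_depth * {1 autosome/PAR/Z, male_w_background
    W}.  Reproducible for a fixed params.seed.
    """
    win = layout.windows()
    rng = np.random.default_rng(params.seed)
    lengths = (win["end"] - win["start"]).to_numpy(float)
    f_exp = win["truth_class"].map(_FEMALE_FACTOR).to_numpy(float) * params.mean_depth
    m_exp = (
        win["truth_class"].map(_male_factor(params.male_w_background)).to_numpy(float)
        * params.mean_depth
    )
    win["female_depth"] = _nb_depth(rng, f_exp, lengths, params.dispersion)
    win["male_depth"] = _nb_depth(rng, m_exp, lengths, params.dispersion)
    return win


# ---------------------------------------------------------------------------
# gametolog codon-pair simulator
# ---------------------------------------------------------------------------

@dataclass
class GametologSimParams:
    """Targets for the codon-pair simulator.

    The W copy is evolved away from the shared ancestral (Z) copy by an
    acceptance-rejection process: single-nucleotide changes are proposed
    uniformly, stop-creating proposals are rejected, synonymous changes are
    accepted with probability 1 and nonsynonymous changes with probability
    omega.  Proposals continue until the accepted synonymous count reaches
    S_sites * target_dS, so the NG86+JC estimate recovers target_dS.
    """

    n_pairs: int = 50
    codons_per_gene: int = 500
    target_ds: float = 0.33
    omega: float = 0.4
    stratum_label: str = "S1"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.target_ds <= 3:
            raise SaturationError("target_ds must be in [0, 3]; larger targets saturate")
        if self.omega <= 0:
            raise ValueError("omega must be positive")
        if self.codons_per_gene < 50:
            raise ValueError("codons_per_gene must be >= 50")
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")


_NTS = "ACGT"
_NON_STOP = SENSE_CODONS


def _random_cds(rng: np.random.Generator, n_codons: int) -> list[str]:
    idx = rng.integers(0, len(_NON_STOP), size=n_codons)
    return [_NON_STOP[i] for i in idx]


def _evolve(
    rng: np.random.Generator,
    codons: list[str],
    n_syn_target: int,
    omega: float,
) -> tuple[list[str], int, int]:
    """Accept-reject evolution until n_syn_target synonymous changes accepted."""
    seq = list(codons)
    n_codons = len(seq)
    n_syn = n_nonsyn = 0
    max_proposals = max(10_000, 600 * n_syn_target + 1000)
    proposals = 0
    while n_syn < n_syn_target:
        proposals += 1
        if proposals > max_proposals:
            raise SaturationError("synonymous target unreachable: proposal budget exhausted")
        ci = int(rng.integers(n_codons))
        pos = int(rng.integers(3))
        codon = seq[ci]
        old = codon[pos]
        nt = _NTS[int(rng.integers(4))]
        while nt == old:  # uniform over the 3 non-identical bases
            nt = _NTS[int(rng.integers(4))]
        alt = codon[:pos] + nt + codon[pos + 1 :]
        if alt in STOP_CODONS:
            continue
        if CODON_TO_AA[alt] == CODON_TO_AA[codon]:
            seq[ci] = alt
            n_syn += 1
        elif rng.random() < omega:
            seq[ci] = alt
            n_nonsyn += 1
    return seq, n_syn, n_nonsyn


def simulate_gametolog_pairs(
    params: GametologSimParams,
) -> tuple[list[CodonAlignment], pd.DataFrame]:
    """Simulate gametolog codon alignments with controlled dS and omega.

    Returns the alignments plus a truth table of accepted synonymous and
    nonsynonymous change counts per pair.  z_position anchors are spread
    uniformly over [0, 1) and are meant to be rescaled by the caller when a
    specific stratum interval is wanted.
    """
    rng = np.random.default_rng(params.seed)
    alignments: list[CodonAlignment] = []
    truth_rows = []
    for i in range(params.n_pairs):
        ancestral = _random_cds(rng, params.codons_per_gene)
        s_sites = sum(_syn_site_fraction(c) for c in ancestral)
        n_syn_target = int(round(s_sites * params.target_ds))
        if params.target_ds == 0:
            derived, n_syn, n_nonsyn = list(ancestral), 0, 0
        else:
            derived, n_syn, n_nonsyn = _evolve(rng, ancestral, n_syn_target, params.omega)
        gene = f"{params.stratum_label}_g{i:04d}"
        alignments.append(
            CodonAlignment(
                gene=gene,
                seq_z="".join(ancestral),
                seq_w="".join(derived),
                z_position=float(rng.uniform()),
            )
        )
        truth_rows.append(
            {
                "gene": gene,
                "stratum": params.stratum_label,
                "n_syn_accepted": n_syn,
                "n_nonsyn_accepted": n_nonsyn,
                "S_sites_ancestral": s_sites,
                "target_dS": params.target_ds,
                "omega": params.omega,
            }
        )
    return alignments, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# repeat landscapes
# ---------------------------------------------------------------------------

@dataclass
class RepeatFamily:
    """One repeat family: genome-wide density plus per-class enrichment."""

    name: str
    density: float  # genome-wide fraction of bp covered
    enrichment: Mapping[str, float]  # per chromosome class, multiplies density
    gc: float = 0.40
    mean_length: int = 400

    def __post_init__(self) -> None:
        if not 0 <= self.density < 1:
            raise ValueError("density must be in [0, 1)")
        if not 0 < self.gc < 1:
            raise ValueError("gc must be in (0, 1)")
        if any(f <= 0 for f in self.enrichment.values()):
            raise ValueError("enrichment factors must be positive")
        if self.mean_length <= 0:
            raise ValueError("mean_length must be positive")


@dataclass
class RepeatSimParams:
    families: list[RepeatFamily]
    seed: int = 0


def _place_nonoverlapping(
    rng: np.random.Generator, chrom_len: int, n: int, elem_len: int
) -> np.ndarray:
    """Uniformly placed non-overlapping interval starts (order-statistics trick)."""
    free = chrom_len - n * elem_len
    if free < 0:
        raise ValueError("requested density > 1 after enrichment")
    gaps = np.sort(rng.uniform(0, free, size=n))
    return (gaps + np.arange(n) * elem_len).astype(int)


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=probs)])


def simulate_repeat_annotation(
    layout: GenomeLayout, params: RepeatSimParams, with_sequences: bool = True
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Repeat intervals with per-class enrichment and family GC composition.

    Per-class target density = genome density * enrichment factor; intervals
    of one family never overlap within a chromosome.  Returns a BED-like
    annotation (chrom, start, end, family[, sequence]) and a truth table of
    realized per-class densities per family.
    """
    rng = np.random.default_rng(params.seed)
    class_len = layout.class_lengths()
    for fam in params.families:
        for cls in class_len:
            if cls not in fam.enrichment:
                raise ValueError(f"family {fam.name}: missing enrichment for class {cls}")
    # density check per class over all families
    for cls in class_len:
        total = sum(f.density * f.enrichment[cls] for f in params.families)
        if total >= 1:
            raise ValueError(f"class {cls}: total requested density {total:.3f} >= 1")
    rows = []
    truth = []
    for fam in params.families:
        realized: dict[str, list[int]] = {cls: [0, 0] for cls in class_len}
        for name, cls, length in layout.chromosomes:
            dens = fam.density * fam.enrichment[cls]
            n = int(round(dens * length / fam.mean_length))
            if n == 0:
                realized[cls][1] += length
                continue
            starts = _place_nonoverlapping(rng, length, n, fam.mean_length)
            for s in starts:
                row = {
                    "chrom": name,
                    "start": int(s),
                    "end": int(s + fam.mean_length),
                    "family": fam.name,
                }
                if with_sequences:
                    row["sequence"] = _random_seq(rng, fam.mean_length, fam.gc)
                rows.append(row)
            realized[cls][0] += n * fam.mean_length
            realized[cls][1] += length
        for cls, (bp, tot) in realized.items():
            truth.append(
                {
                    "family": fam.name,
                    "class": cls,
                    "repeat_bp": bp,
                    "class_bp": tot,
                    "density": bp / tot if tot else np.nan,
                    "target_density": fam.density * fam.enrichment[cls],
                }
            )
    ann = pd.DataFrame(rows).sort_values(["chrom", "start"]).reset_index(drop=True)
    return ann, pd.DataFrame(truth)


def simulate_genome(
    layout: GenomeLayout,
    annotation: pd.DataFrame | None = None,
    background_gc: float = 0.36,
    seed: int = 0,
) -> dict[str, str]:
    """Random genome sequences; annotated repeat intervals get their element
    sequences (so family GC composition is visible to window profiling)."""
    rng = np.random.default_rng(seed)
    seqs = {
        name: list(_random_seq(rng, length, background_gc))
        for name, _, length in layout.chromosomes
    }
    if annotation is not None:
        for rec in annotation.itertuples():
            if rec.chrom not in seqs:
                continue
            seq = rec.sequence if "sequence" in annotation.columns else None
            if seq is None or (isinstance(seq, float) and math.isnan(seq)):
                continue
            seqs[rec.chrom][rec.start : rec.end] = list(seq)
    return {name: "".join(chars) for name, chars in seqs.items()}


# ---------------------------------------------------------------------------
# gene-level depth and expression tables
# ---------------------------------------------------------------------------

def simulate_gene_depths(
    copy_numbers: Sequence[int],
    params: CoverageSimParams,
    n_females: int = 4,
    gene_length: int = 2000,
) -> pd.DataFrame:
    """Per-gene, per-female mean exon depth for W-linked genes.

    A single-copy W gene sits at half the diploid autosomal mean; expected
    depth scales linearly with copy number: (copy_number / 2) * mean_depth.
    """
    if len(copy_numbers) == 0:
        raise ValueError("copy_numbers must be non-empty")
    if any((int(c) != c or c < 1) for c in copy_numbers):
        raise ValueError("copy numbers must be integers >= 1")
    rng = np.random.default_rng(params.seed)
    rows = []
    lengths = np.full(1, float(gene_length))
    for gi, cn in enumerate(copy_numbers):
        expected = params.mean_depth * cn / 2.0
        for f in range(n_females):
            depth = _nb_depth(rng, np.array([expected]), lengths, params.dispersion)[0]
            rows.append(
                {
                    "gene": f"wgene_{gi:04d}",
                    "sample": f"female_{f + 1}",
                    "depth": float(depth),
                    "true_copy_number": int(cn),
                }
            )
    return pd.DataFrame(rows)


def simulate_expression_counts(
    n_genes: int,
    female_mean: float = 5.0,
    male_mean: float = 0.0,
    n_per_sex: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Simple per-sex Poisson raw-count table for the detection-rule tests."""
    rng = np.random.default_rng(seed)
    cols = {}
    for s in range(n_per_sex):
        cols[f"female_{s + 1}"] = rng.poisson(female_mean, size=n_genes)
    for s in range(n_per_sex):
        cols[f"male_{s + 1}"] = rng.poisson(male_mean, size=n_genes)
    df = pd.DataFrame(cols, index=[f"g{i:04d}" for i in range(n_genes)])
    df.index.name = "gene"
    return df
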