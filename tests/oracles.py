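"""Independent brute-force oracles used to pin expected values.

Written deliberately naively (string-based, no caching, no shared code with
the package implementations) so they stay an independent check.
"""

from __future__ import annotations

import itertools
import math
from math import comb

GENETIC_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def syn_sites_codon(codon: str) -> float:
    """Synonymous site count of one codon (stop changes = nonsynonymous)."""
    aa = GENETIC_CODE[codon]
    syn = 0
    for pos in range(3):
        for base in "ACGT":
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if GENETIC_CODE[mutant] != "*" and GENETIC_CODE[mutant] == aa:
                syn += 1
    return syn / 3.0


def pathway_differences(c1: str, c2: str) -> tuple[float, float]:
    """(syn, nonsyn) differences averaged over stop-free pathways."""
    positions = [i for i in range(3) if c1[i] != c2[i]]
    if not positions:
        return 0.0, 0.0
    results = []
    for order in itertools.permutations(positions):
        current = c1
        steps = []
        blocked = False
        for pos in order:
            nxt = current[:pos] + c2[pos] + current[pos + 1 :]
            if GENETIC_CODE[nxt] == "*":
                blocked = True
                break
            steps.append(GENETIC_CODE[current] == GENETIC_CODE[nxt])
            current = nxt
        if not blocked:
            results.append((sum(steps), len(steps) - sum(steps)))
    if not results:
        raise ValueError(f"all pathways blocked for {c1}->{c2}")
    s = sum(r[0] for r in results) / len(results)
    n = sum(r[1] for r in results) / len(results)
    return s, n


def ng86_bruteforce(seq1: str, seq2: str) -> dict:
    """Full NG86 + Jukes-Cantor on two aligned gap-free coding sequences."""
    assert len(seq1) == len(seq2) and len(seq1) % 3 == 0
    s_sites = sd = nd = 0.0
    n_codons = len(seq1) // 3
    for i in range(n_codons):
        a = seq1[3 * i : 3 * i + 3].upper()
        b = seq2[3 * i : 3 * i + 3].upper()
        s_sites += (syn_sites_codon(a) + syn_sites_codon(b)) / 2.0
        s, n = pathway_differences(a, b)
        sd += s
        nd += n
    n_sites = 3.0 * n_codons - s_sites
    ps = sd / s_sites
    pn = nd / n_sites
    return {
        "S": s_sites,
        "N": n_sites,
        "Sd": sd,
        "Nd": nd,
        "dS": -0.75 * math.log(1 - 4 * ps / 3),
        "dN": -0.75 * math.log(1 - 4 * pn / 3),
    }


def fisher_exact_enumeration(table) -> float:
    """Two-sided Fisher exact p by exhaustive hypergeometric enumeration."""
    (a, b), (c, d) = table
    row1, row2 = a + b, c + d
    col1 = a + c
    n = row1 + row2
    denom = comb(n, col1)

    def prob(x: int) -> float:
        return comb(row1, x) * comb(row2, col1 - x) / denom

    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, col1 - row2), min(row1, col1) + 1):
        px = prob(x)
        if px <= p_obs * (1 + 1e-12):
            total += px
    return total
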