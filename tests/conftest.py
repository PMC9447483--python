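import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from zwtools.divergence import SENSE_CODONS


@pytest.fixture
def rng():
    return np.random.default_rng(20220722)


def random_coding_pair(rng, n_codons: int, p_sub: float = 0.06) -> tuple[str, str]:
    """A random stop-free codon sequence and a randomly mutated partner."""
    codons1 = [SENSE_CODONS[i] for i in rng.integers(0, len(SENSE_CODONS), n_codons)]
    codons2 = []
    for c in codons1:
        cc = c
        for pos in range(3):
            if rng.random() < p_sub:
                nt = "ACGT"[rng.integers(4)]
                cand = cc[:pos] + nt + cc[pos + 1 :]
                from zwtools.divergence import STOP_CODONS

                if cand not in STOP_CODONS:
                    cc = cand
        codons2.append(cc)
    return "".join(codons1), "".join(codons2)
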