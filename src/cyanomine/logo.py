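"""Position frequency matrices and information content for leader logos.

The computation behind amino-acid sequence logos: per-column relative
residue frequencies of a gap-free alignment block and the per-column
information content IC_j = log2(20) − H_j, without small-sample
correction by default (matching the WebLogo default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .simsearch import AMINO_ACIDS

_IDX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
MAX_BITS = math.log2(20)


@dataclass
class PositionFrequencyMatrix:
    frequencies: np.ndarray  # shape (length, 20), rows sum to 1
    n_sequences: int

    def __post_init__(self) -> None:
        if self.n_sequences < 1:
            raise ValueError("need at least one sequence")
        if not np.allclose(self.frequencies.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("column frequencies must sum to 1")

    def __len__(self) -> int:
        return self.frequencies.shape[0]

    def column(self, j: int) -> dict[str, float]:
        return {aa: float(self.frequencies[j, i]) for aa, i in _IDX.items()}

    def to_tsv(self) -> str:
        header = "pos\t" + "\t".join(AMINO_ACIDS)
        lines = [header]
        for j in range(len(self)):
            lines.append(f"{j}\t" + "\t".join(f"{v:.6f}" for v in self.frequencies[j]))
        return "\n".join(lines) + "\n"


def build_pfm(aligned_blocks: Sequence[str]) -> PositionFrequencyMatrix:
    """Relative residue frequencies per column of equal-length, gap-free blocks."""
    if not aligned_blocks:
        raise ValueError("no sequences")
    length = len(aligned_blocks[0])
    if any(len(s) != length for s in aligned_blocks):
        raise ValueError("aligned blocks must have equal lengths")
    counts = np.zeros((length, 20))
    for seq in aligned_blocks:
        for j, aa in enumerate(seq):
            if aa not in _IDX:
                raise ValueError(f"invalid residue {aa!r} (gap-free amino acids required)")
            counts[j, _IDX[aa]] += 1
    return PositionFrequencyMatrix(counts / len(aligned_blocks), len(aligned_blocks))


def information_content(pfm: PositionFrequencyMatrix, small_sample_correction: bool = False) -> np.ndarray:
    """Per-position information in bits: log2(20) − H_j, with 0·log 0 := 0.

    The optional small-sample correction subtracts the expected entropy
    excess e_n = 19 / (2·ln 2·n) from each column's information.
    """
    f = pfm.frequencies
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(f > 0, f * np.log2(f), 0.0)
    ic = MAX_BITS + terms.sum(axis=1)
    if small_sample_correction:
        ic = ic - 19.0 / (2.0 * math.log(2) * pfm.n_sequences)
    return np.clip(ic, 0.0, MAX_BITS)
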