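"""Consensus-motif calling from aligned cleavage windows.

The aligned top-k windows are tallied into a 4 x width nucleotide count
matrix (the position weight matrix behind a sequence logo).  Per-column
information content IC_j = 2 - H_j bits, where H_j is the Shannon entropy of
the column's base frequencies; 2 bits marks a perfectly conserved position.
A base is called at a column when it is both frequent (>= min_frequency) and
informative (IC >= min_ic); uncalled columns render as N.  Position labels
run -flank..+flank with the coverage-increase nucleotide at label 0, so a
cleavage motif like UGG appears at labels -1, 0, +1 and the cut sits between
labels -1 and 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import SequenceWindow

__all__ = [
    "FrequencyMatrix",
    "ConsensusCall",
    "build_frequency_matrix",
    "information_content",
    "call_consensus",
    "logo_table",
]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


@dataclass
class FrequencyMatrix:
    """Nucleotide counts per window column.

    ``counts`` is 4 x width over rows A, C, G, T; N's are skipped and
    deducted from ``n_effective``.  ``position_labels`` centre label 0 on the
    coverage-increase nucleotide.
    """

    counts: np.ndarray
    n_effective: np.ndarray
    position_labels: np.ndarray

    @property
    def width(self) -> int:
        return int(self.counts.shape[1])

    def frequencies(self) -> np.ndarray:
        """Column-normalised frequencies; zero-coverage columns stay all-zero."""
        freqs = np.zeros_like(self.counts, dtype=np.float64)
        nz = self.n_effective > 0
        freqs[:, nz] = self.counts[:, nz] / self.n_effective[nz]
        return freqs


@dataclass
class ConsensusCall:
    """Called consensus string with its maximal called span.

    ``consensus`` uses N for uncalled columns and is rendered in the display
    alphabet (U for RNA).  ``called_span`` is the (start, end) position-label
    pair of the longest run of called columns, or None if nothing is called.
    ``cut_offset`` marks the cleavage boundary: it sits 5' of label 0.
    """

    consensus: str
    called_span: tuple[int, int] | None
    cut_offset: int = 0


def build_frequency_matrix(windows: Sequence[SequenceWindow]) -> FrequencyMatrix:
    if not windows:
        raise ValueError("no windows to align")
    width = len(windows[0])
    if any(len(w) != width for w in windows):
        raise ValueError("windows have mismatched widths")
    flank = width // 2

    counts = np.zeros((4, width), dtype=np.int64)
    for w in windows:
        for j, base in enumerate(w.window):
            if base in _BASE_INDEX:
                counts[_BASE_INDEX[base], j] += 1
    return FrequencyMatrix(
        counts=counts,
        n_effective=counts.sum(axis=0),
        position_labels=np.arange(-flank, width - flank),
    )


def information_content(
    matrix: FrequencyMatrix, small_sample_correction: bool = False
) -> np.ndarray:
    """Bits per column: 2 - H_j, optionally minus the small-sample term.

    The correction subtracts e_n = 3 / (2 ln2 n) per column (the standard
    logo adjustment for finite sample size), floored at 0.  Columns with no
    effective observations get IC = 0.
    """
    freqs = matrix.frequencies()
    ic = np.zeros(matrix.width, dtype=np.float64)
    for j in range(matrix.width):
        n = matrix.n_effective[j]
        if n == 0:
            continue
        f = freqs[:, j]
        nz = f > 0
        entropy = -np.sum(f[nz] * np.log2(f[nz]))
        val = 2.0 - entropy
        if small_sample_correction:
            val -= 3.0 / (2.0 * math.log(2) * n)
        ic[j] = max(val, 0.0)
    return ic


def call_consensus(
    matrix: FrequencyMatrix,
    min_frequency: float = 0.5,
    min_ic: float = 1.0,
    rna: bool = False,
    small_sample_correction: bool = False,
) -> ConsensusCall:
    """Call a base per column where frequency and information both pass.

    A column is called as base b iff f_b >= min_frequency and IC >= min_ic;
    otherwise it renders as N.  The returned span is the longest contiguous
    run of called columns in position-label coordinates.
    """
    freqs = matrix.frequencies()
    ic = information_content(matrix, small_sample_correction)
    chars = []
    called = []
    for j in range(matrix.width):
        best = int(np.argmax(freqs[:, j]))
        if freqs[best, j] >= min_frequency and ic[j] >= min_ic:
            chars.append(BASES[best])
            called.append(True)
        else:
            chars.append("N")
            called.append(False)

    span = _longest_run(called, matrix.position_labels)
    consensus = "".join(chars)
    if rna:
        consensus = consensus.replace("T", "U")
    return ConsensusCall(consensus=consensus, called_span=span)


def _longest_run(called: Sequence[bool], labels: np.ndarray) -> tuple[int, int] | None:
    best: tuple[int, int] | None = None
    start = None
    for j, flag in enumerate(list(called) + [False]):
        if flag and start is None:
            start = j
        elif not flag and start is not None:
            if best is None or (j - start) > (best[1] - best[0] + 1):
                best = (int(labels[start]), int(labels[j - 1]))
            start = None
    return best


def logo_table(
    matrix: FrequencyMatrix,
    call: ConsensusCall,
    small_sample_correction: bool = False,
) -> pd.DataFrame:
    """Tabular logo: per-label base counts, effective n, IC and the call."""
    ic = information_content(matrix, small_sample_correction)
    return pd.DataFrame(
        {
            "label": matrix.position_labels,
            "A": matrix.counts[0],
            "C": matrix.counts[1],
            "G": matrix.counts[2],
            "T": matrix.counts[3],
            "n_eff": matrix.n_effective,
            "IC_bits": np.round(ic, 6),
            "call": list(call.consensus),
        }
    )
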