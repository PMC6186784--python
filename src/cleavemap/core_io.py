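"""Shared domain types and the FASTA/TSV dialects exchanged between stages.

The pipeline stores every sequence internally as DNA (``T``); RNA input is
normalised on read (``U`` -> ``T``) and the original alphabet is remembered so
output can be rendered back with ``U`` where appropriate.  Coordinates are
0-based and intervals half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "NucleotideSequence",
    "DepthProfile",
    "DetectionParams",
    "CleavageCandidate",
    "SequenceWindow",
    "read_fasta",
    "write_fasta",
    "read_depth_table",
    "write_depth_table",
    "write_results_table",
    "read_candidate_table",
]

_VALID = set("ACGTN")


def normalise_residues(raw: str) -> str:
    """Uppercase and map U->T.  Idempotent by construction."""
    return raw.upper().replace("U", "T")


@dataclass(frozen=True)
class NucleotideSequence:
    """A named nucleotide sequence stored as DNA.

    ``display_alphabet`` ("DNA" or "RNA") only affects rendering: an RNA
    record is written back with U in place of T.
    """

    id: str
    residues: str
    description: str = ""
    display_alphabet: str = "DNA"

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"sequence {self.id!r}: empty residues")
        bad = set(self.residues) - _VALID
        if bad:
            offset = next(i for i, c in enumerate(self.residues) if c in bad)
            raise ValueError(
                f"sequence {self.id!r}: illegal residue {self.residues[offset]!r} "
                f"at offset {offset}"
            )
        if self.display_alphabet not in ("DNA", "RNA"):
            raise ValueError(f"display_alphabet must be DNA or RNA, got {self.display_alphabet!r}")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def display_residues(self) -> str:
        if self.display_alphabet == "RNA":
            return self.residues.replace("T", "U")
        return self.residues


@dataclass
class DepthProfile:
    """Per-position read coverage for one reference (0-based positions)."""

    reference_id: str
    coverage: np.ndarray

    def __post_init__(self) -> None:
        self.coverage = np.asarray(self.coverage, dtype=np.int64)
        if self.coverage.ndim != 1:
            raise ValueError("coverage must be a 1-D vector")
        if (self.coverage < 0).any():
            raise ValueError(f"profile {self.reference_id!r}: negative coverage")

    def __len__(self) -> int:
        return int(self.coverage.shape[0])


@dataclass(frozen=True)
class DetectionParams:
    """Tunables of the cleavage-site detector.

    Defaults follow the study conditions: positions with coverage below 100
    are excluded, the overall top 50 relative coverage increases are kept,
    and windows extend 5 bases either side of the boundary.  ``filter_side``
    selects which position the minimum-coverage rule applies to: the
    downstream (increase) position, the upstream one, or both.
    """

    min_coverage: int = 100
    top_k: int = 50
    flank: int = 5
    pseudo_count: float = 1.0
    filter_side: str = "down"

    def __post_init__(self) -> None:
        if self.min_coverage < 1:
            raise ValueError("min_coverage must be >= 1")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if self.flank < 0:
            raise ValueError("flank must be >= 0")
        if not self.pseudo_count > 0:
            raise ValueError("pseudo_count must be > 0")
        if self.filter_side not in ("down", "up", "both"):
            raise ValueError("filter_side must be one of down/up/both")

    @property
    def window_width(self) -> int:
        return 2 * self.flank + 1


@dataclass(frozen=True)
class CleavageCandidate:
    """A candidate fragment boundary.

    ``position`` indexes the downstream nucleotide whose coverage jumps (the
    boundary lies between residues ``position - 1`` and ``position``); ``rci``
    is coverage(position) over the pseudo-count-substituted coverage at
    ``position - 1``.
    """

    reference_id: str
    position: int
    cov_up: int
    cov_down: int
    rci: float

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("candidate position must be >= 1")
        if not self.rci > 0:
            raise ValueError("rci must be positive")


@dataclass(frozen=True)
class SequenceWindow:
    """The +/-flank residue window centred on a candidate's boundary position."""

    candidate: CleavageCandidate
    window: str
    padded: bool

    def __len__(self) -> int:
        return len(self.window)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path, alphabet: str = "DNA") -> list[NucleotideSequence]:
    """Read a multi-record FASTA, normalising U->T.

    ``alphabet`` records how the sequences should be rendered on output; it
    does not restrict the input (U is accepted either way).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA not found: {path}")
    records: list[NucleotideSequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        raw = str(rec.seq)
        for i, c in enumerate(raw):
            if c.upper() not in "ACGTUN":
                raise ValueError(
                    f"record {rec.id!r}: illegal residue {c!r} at offset {i}"
                )
        if rec.id in seen:
            raise ValueError(f"duplicate record id {rec.id!r}")
        seen.add(rec.id)
        records.append(
            NucleotideSequence(
                id=rec.id,
                residues=normalise_residues(raw),
                description=rec.description[len(rec.id):].strip(),
                display_alphabet=alphabet,
            )
        )
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[NucleotideSequence], path: str | Path) -> None:
    """Write records in their display alphabet (U restored for RNA)."""
    seq_records = [
        SeqRecord(Seq(r.display_residues), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        SeqIO.write(seq_records, fh, "fasta")


# ---------------------------------------------------------------------------
# Coverage TSV (sparse: unlisted positions are zero)

DEPTH_COLUMNS = ["reference_id", "position", "coverage"]


def read_depth_table(
    path: str | Path, references: Sequence[NucleotideSequence]
) -> list[DepthProfile]:
    """Read a sparse coverage TSV into one dense profile per reference.

    Columns: ``reference_id  position  coverage`` (0-based positions).
    Positions absent from the table default to coverage 0; every reference
    gets a profile even if it has no rows.
    """
    by_id = {r.id: r for r in references}
    df = pd.read_csv(path, sep="\t", dtype={"reference_id": str})
    missing = [c for c in DEPTH_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"coverage table missing columns: {missing}")
    profiles = {rid: np.zeros(len(ref), dtype=np.int64) for rid, ref in by_id.items()}
    for rid, pos, cov in df[DEPTH_COLUMNS].itertuples(index=False):
        if rid not in profiles:
            raise ValueError(f"unknown reference id {rid!r} in coverage table")
        pos = int(pos)
        cov = int(cov)
        if cov < 0:
            raise ValueError(f"negative coverage at {rid}:{pos}")
        if not 0 <= pos < profiles[rid].shape[0]:
            raise ValueError(
                f"position {pos} outside reference {rid!r} "
                f"(length {profiles[rid].shape[0]})"
            )
        profiles[rid][pos] = cov
    return [DepthProfile(r.id, profiles[r.id]) for r in references]


def write_depth_table(profiles: Iterable[DepthProfile], path: str | Path) -> None:
    """Write profiles sparsely: only non-zero positions are listed."""
    rows = []
    for prof in profiles:
        nz = np.nonzero(prof.coverage)[0]
        for pos in nz:
            rows.append((prof.reference_id, int(pos), int(prof.coverage[pos])))
    df = pd.DataFrame(rows, columns=DEPTH_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Generic stage-output tables

_PROBABILITY_COLUMNS = {"P", "p", "rci"}


def _format_cell(column: str, value) -> str:
    if column == "P":
        return f"{value:.3E}"
    if column in ("p",):
        return f"{value:.6E}"
    if isinstance(value, float):
        return f"{value:.6g}"
    return str(value)


def write_results_table(rows: pd.DataFrame | Iterable[dict], path: str | Path) -> None:
    """Write a stage-output TSV with a stable column order.

    Probability columns (``P``, ``p``) are rendered in scientific notation
    with at least 3 significant digits, matching the convention used for
    printed tail probabilities (e.g. ``3.56E-07``).
    """
    if not isinstance(rows, pd.DataFrame):
        rows = pd.DataFrame(list(rows))
    with open(path, "w") as fh:
        fh.write("\t".join(map(str, rows.columns)) + "\n")
        for _, row in rows.iterrows():
            fh.write("\t".join(_format_cell(c, row[c]) for c in rows.columns) + "\n")


CANDIDATE_COLUMNS = ["reference_id", "position", "cov_up", "cov_down", "rci", "window"]


def read_candidate_table(path: str | Path) -> pd.DataFrame:
    """Read a candidate TSV written by the detect stage (windows included)."""
    df = pd.read_csv(path, sep="\t", dtype={"reference_id": str, "window": str})
    missing = [c for c in CANDIDATE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"candidate table missing columns: {missing}")
    return df
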