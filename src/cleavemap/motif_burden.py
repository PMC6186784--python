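"""Per-CDS motif-burden statistic: p, E, K and the binomial tail P.

For each coding sequence of length L, the chance p of the cleavage motif
(default TGG) appearing at any one position is taken as the product of the
CDS's own base frequencies over the motif letters — for TGG that is
f(T) * f(G)^2.  A triplet has L - 2 candidate start positions, so the
expected count is E = p (L - 2).  Given the observed overlapping count K,
the burden statistic is the binomial upper tail

    P = Pr(X >= K),   X ~ Binomial(L - 2, p),

and transcripts are ranked by ascending P: a small P marks a CDS carrying
far more motifs than its own composition predicts, hence a likely preferred
substrate of the endoribonuclease.

Base composition is per-gene, not genome-wide (genes of equal length can
have different E), and the scan is single-strand on the coding sequence.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from scipy.stats import binom

from .core_io import NucleotideSequence, write_results_table

__all__ = [
    "CdsRecord",
    "BurdenRow",
    "composition_probability",
    "count_motif",
    "binomial_tail",
    "burden_from_params",
    "scan_cds_set",
    "fraction_with_motif",
    "cds_records_from_fasta",
    "burden_rows_from_params_table",
    "burden_table",
]

DEFAULT_MOTIF = "TGG"


@dataclass(frozen=True)
class CdsRecord:
    """One coding sequence (coding strand, DNA residues)."""

    id: str
    sequence: str
    symbol: str = ""
    product: str = ""

    def __post_init__(self) -> None:
        if len(self.sequence) < 3:
            raise ValueError(f"CDS {self.id!r}: length must be >= 3")

    @property
    def length_L(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class BurdenRow:
    """Motif-burden summary for one CDS, ranked by ascending P."""

    id: str
    symbol: str
    product: str
    length_L: int
    p: float
    expected_E: float
    actual_K: int
    P: float
    rank: int = 0


def composition_probability(sequence: str, motif: str = DEFAULT_MOTIF) -> float:
    """Per-position motif probability from the sequence's own base frequencies.

    p is the product over the motif's letters of that letter's frequency in
    the sequence, with frequencies computed over A/C/G/T only (N excluded
    from numerator and denominator).
    """
    total = sum(sequence.count(b) for b in "ACGT")
    if total == 0:
        raise ValueError("sequence has no A/C/G/T content")
    p = 1.0
    for letter in motif:
        p *= sequence.count(letter) / total
    return p


def count_motif(sequence: str, motif: str = DEFAULT_MOTIF) -> int:
    """Overlapping exact-match count; windows containing N never match."""
    if len(sequence) < len(motif):
        raise ValueError("sequence shorter than motif")
    m = len(motif)
    return sum(1 for i in range(len(sequence) - m + 1) if sequence[i : i + m] == motif)


def binomial_tail(trials_n: int, p: float, K: int) -> float:
    """Upper-tail binomial probability Pr(X >= K) for X ~ Binomial(n, p).

    Evaluated through the regularized incomplete beta function (scipy's
    binomial survival function), which is stable for tails far below
    floating-point granularity of direct summation.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must be in [0, 1], got {p}")
    if not 0 <= K <= trials_n:
        raise ValueError(f"K must be in [0, {trials_n}], got {K}")
    if K == 0:
        return 1.0
    return float(binom.sf(K - 1, trials_n, p))


def burden_from_params(length_L: int, expected_E: float, actual_K: int) -> float:
    """Tail probability reconstructed from (L, E, K) with p = E / (L - 2).

    This is the replay mode for published per-gene summaries: the expected
    count E determines p without access to the underlying sequence.
    """
    if length_L < 3:
        raise ValueError("length_L must be >= 3")
    n = length_L - 2
    if not 0 <= expected_E <= n:
        raise ValueError(f"expected_E must be in [0, {n}]")
    return binomial_tail(n, expected_E / n, actual_K)


def _burden_row(record: CdsRecord, motif: str) -> BurdenRow:
    n = record.length_L - len(motif) + 1
    p = composition_probability(record.sequence, motif)
    K = count_motif(record.sequence, motif)
    return BurdenRow(
        id=record.id,
        symbol=record.symbol,
        product=record.product,
        length_L=record.length_L,
        p=p,
        expected_E=p * n,
        actual_K=K,
        P=binomial_tail(n, p, K),
    )


def scan_cds_set(
    records: Sequence[CdsRecord], motif: str = DEFAULT_MOTIF
) -> list[BurdenRow]:
    """Burden statistic for every CDS, ranked by ascending P.

    Ties broken by (K descending, id ascending); rank is 1-based.  Ranking
    is by raw P — no multiple-testing correction, as the statistic is used
    for ordering rather than hypothesis rejection.
    """
    rows = [_burden_row(r, motif) for r in records]
    rows.sort(key=lambda r: (r.P, -r.actual_K, r.id))
    return [
        BurdenRow(**{**row.__dict__, "rank": i + 1}) for i, row in enumerate(rows)
    ]


def fraction_with_motif(
    records: Sequence[CdsRecord], motif: str = DEFAULT_MOTIF
) -> float:
    """Fraction of CDS containing the motif at least once."""
    if not records:
        raise ValueError("empty CDS collection")
    return sum(1 for r in records if count_motif(r.sequence, motif) >= 1) / len(records)


# ---------------------------------------------------------------------------
# I/O helpers


def cds_records_from_fasta(sequences: Iterable[NucleotideSequence]) -> list[CdsRecord]:
    """Adapt FASTA records; ``symbol=`` / ``product=`` header key-values parsed."""
    records = []
    for seq in sequences:
        fields = dict(
            kv.split("=", 1) for kv in seq.description.split() if "=" in kv
        )
        records.append(
            CdsRecord(
                id=seq.id,
                sequence=seq.residues,
                symbol=fields.get("symbol", ""),
                product=fields.get("product", ""),
            )
        )
    return records


def burden_rows_from_params_table(path: str | Path) -> list[BurdenRow]:
    """Replay mode: compute P from a TSV of printed per-gene (L, E, K).

    Expected columns: ``id  length  expected_E  actual_K`` with an optional
    ``symbol``.  Rows are ranked by ascending P like a full scan.
    """
    df = pd.read_csv(path, sep="\t")
    for col in ("symbol", "product"):
        if col in df.columns:
            df[col] = df[col].fillna("")
    required = ["id", "length", "expected_E", "actual_K"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"params table missing columns: {missing}")
    rows = []
    for rec in df.itertuples(index=False):
        L = int(rec.length)
        n = L - 2
        rows.append(
            BurdenRow(
                id=str(rec.id),
                symbol=str(getattr(rec, "symbol", "") or ""),
                product=str(getattr(rec, "product", "") or ""),
                length_L=L,
                p=rec.expected_E / n,
                expected_E=float(rec.expected_E),
                actual_K=int(rec.actual_K),
                P=burden_from_params(L, float(rec.expected_E), int(rec.actual_K)),
            )
        )
    rows.sort(key=lambda r: (r.P, -r.actual_K, r.id))
    return [BurdenRow(**{**row.__dict__, "rank": i + 1}) for i, row in enumerate(rows)]


def burden_table(rows: Sequence[BurdenRow]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": [r.id for r in rows],
            "symbol": [r.symbol for r in rows],
            "length": [r.length_L for r in rows],
            "p": [r.p for r in rows],
            "expected_E": [round(r.expected_E, 4) for r in rows],
            "actual_K": [r.actual_K for r in rows],
            "P": [r.P for r in rows],
            "rank": [r.rank for r in rows],
        }
    )


def write_burden_table(rows: Sequence[BurdenRow], path: str | Path) -> None:
    write_results_table(burden_table(rows), path)
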