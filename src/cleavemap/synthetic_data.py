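"""Synthetic references, cleavage coverage profiles and CDS sets.

The generator emulates a motif-specific endoribonuclease digestion read out
by 5'-end sequencing: random references carry the cleavage motif (default
TGG) wherever it arises by composition, the enzyme cuts between the first
and second motif letter, and each cut deposits a burst of fragment 5' ends
at the downstream nucleotide.  Read depth is then the 5'-end count vector
convolved with a read-length box.  Everything is a deterministic function of
the seed, so detector and consensus stages can be tested end to end against
known ground truth with no sequencing data.

The model deliberately skips molecule-level detail (barcodes, sequencing
error, mapping ambiguity): independent Poisson end counts plus the box
convolution preserve exactly the signal the relative-coverage-increase
statistic consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import DepthProfile, NucleotideSequence
from .motif_burden import CdsRecord

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "generate_references",
    "simulate_cleavage_profile",
    "simulate_experiment",
    "generate_cds_set",
    "write_truth_table",
    "read_truth_table",
]

BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the simulated digestion experiment.

    Defaults mirror the scale of the wet experiment being emulated: eight
    references of 500-2000 nt, ~90% of motif sites cleaved, a few hundred
    fragment 5' ends per cleaved site against a low uniform background, and
    150 nt reads.
    """

    n_references: int = 8
    length_range: tuple[int, int] = (500, 2000)
    motif: str = "TGG"
    signal_rate: float = 500.0
    background_rate: float = 2.0
    read_length: int = 150
    cleavage_probability: float = 0.9
    planted_per_reference: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if not (3 <= lo <= hi):
            raise ValueError(f"degenerate length range {self.length_range}")
        if not self.signal_rate >= self.background_rate >= 0:
            raise ValueError("need signal_rate >= background_rate >= 0")
        if not 0 <= self.cleavage_probability <= 1:
            raise ValueError("cleavage_probability must be in [0, 1]")
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")


@dataclass
class GroundTruth:
    """True cleavage boundaries per reference.

    ``sites[ref_id]`` lists boundary positions — the downstream nucleotide
    of each cut, i.e. the index of the motif's second letter (motif start
    + 1), matching the detector's position convention.  ``planted[ref_id]``
    is a parallel flag: True for deliberately inserted motifs, False for
    ones arising by chance in the random sequence.
    """

    sites: dict[str, list[int]] = field(default_factory=dict)
    planted: dict[str, list[bool]] = field(default_factory=dict)


def _motif_sites(residues: str, motif: str) -> list[int]:
    m = len(motif)
    return [
        i + 1
        for i in range(len(residues) - m + 1)
        if residues[i : i + m] == motif
    ]


def generate_references(
    config: SimulationConfig,
) -> tuple[list[NucleotideSequence], GroundTruth]:
    """Random uniform-composition references with recorded motif sites.

    Every motif occurrence — planted or spontaneous — becomes a ground-truth
    cleavage boundary at motif start + 1.  With uniform composition a
    triplet arises spontaneously about once per 64 positions, so the default
    references already carry ample sites; extra motifs can be planted via
    ``planted_per_reference`` (overwriting random non-overlapping triplets).
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.length_range
    references: list[NucleotideSequence] = []
    truth = GroundTruth()
    for i in range(config.n_references):
        length = int(rng.integers(lo, hi + 1))
        residues = "".join(rng.choice(BASES, size=length))
        planted_starts: set[int] = set()
        if config.planted_per_reference > 0:
            chars = list(residues)
            tries = 0
            while len(planted_starts) < config.planted_per_reference and tries < 1000:
                start = int(rng.integers(0, length - len(config.motif) + 1))
                tries += 1
                if any(abs(start - s) < len(config.motif) for s in planted_starts):
                    continue
                chars[start : start + len(config.motif)] = config.motif
                planted_starts.add(start)
            residues = "".join(chars)
        ref_id = f"sim-{i + 1}-{length}"
        references.append(
            NucleotideSequence(id=ref_id, residues=residues, display_alphabet="RNA")
        )
        sites = _motif_sites(residues, config.motif)
        truth.sites[ref_id] = sites
        truth.planted[ref_id] = [(s - 1) in planted_starts for s in sites]
    return references, truth


def simulate_cleavage_profile(
    reference: NucleotideSequence,
    truth: GroundTruth,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> DepthProfile:
    """Poisson 5'-end counts convolved with a read-length box.

    End counts are Poisson(signal_rate * cleavage_probability) at true
    cleavage boundaries and Poisson(background_rate) elsewhere; position 0
    additionally receives Poisson(signal_rate) intact-molecule 5' ends.
    depth(n) sums the end counts at positions s with s <= n < s + read_length.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    L = len(reference)
    sites = truth.sites.get(reference.id, [])
    if any(not 0 <= s < L for s in sites):
        raise ValueError(f"ground-truth site outside reference {reference.id!r}")

    ends = rng.poisson(config.background_rate, size=L)
    site_idx = np.array(sites, dtype=np.int64)
    if site_idx.size:
        ends[site_idx] = rng.poisson(
            config.signal_rate * config.cleavage_probability, size=site_idx.size
        )
    ends[0] += rng.poisson(config.signal_rate)

    # depth = sliding-window (box) sum of the last read_length end counts
    csum = np.concatenate([[0], np.cumsum(ends)])
    idx = np.arange(L)
    lo = np.maximum(idx - config.read_length + 1, 0)
    depth = csum[idx + 1] - csum[lo]
    return DepthProfile(reference.id, depth)


def simulate_experiment(
    config: SimulationConfig,
) -> tuple[list[NucleotideSequence], GroundTruth, list[DepthProfile]]:
    """References, ground truth and one coverage profile per reference.

    Each reference's profile is drawn from an independent stream spawned
    from the master seed, so the whole experiment is reproducible while
    profiles stay statistically independent.
    """
    references, truth = generate_references(config)
    seeds = np.random.SeedSequence(config.seed).spawn(len(references))
    profiles = [
        simulate_cleavage_profile(ref, truth, config, np.random.default_rng(ss))
        for ref, ss in zip(references, seeds)
    ]
    return references, truth, profiles


def generate_cds_set(
    n_records: int,
    length_range: tuple[int, int] = (300, 3000),
    enriched_fraction: float = 0.0,
    enrichment_multiplier: float = 2.0,
    motif: str = "TGG",
    seed: int = 0,
) -> tuple[list[CdsRecord], list[bool]]:
    """Synthetic CDS set with a known motif-enriched subset.

    Background records are uniform-composition random sequence.  Enriched
    records get extra motif insertions (overwriting random non-overlapping
    triplets) targeting an expected count of enrichment_multiplier times the
    uniform-composition expectation (L - 2) / 4^m.  Returns the records and
    a parallel enrichment-label vector for recovery experiments.
    """
    if n_records < 1:
        raise ValueError("n_records must be >= 1")
    lo, hi = length_range
    if not (len(motif) <= lo <= hi):
        raise ValueError(f"degenerate length range {length_range}")
    if not 0 <= enriched_fraction <= 1:
        raise ValueError("enriched_fraction must be in [0, 1]")
    if enrichment_multiplier < 1:
        raise ValueError("enrichment_multiplier must be >= 1")

    rng = np.random.default_rng(seed)
    n_enriched = round(n_records * enriched_fraction)
    labels = [i < n_enriched for i in range(n_records)]
    m = len(motif)
    records: list[CdsRecord] = []
    for i, enriched in enumerate(labels):
        length = int(rng.integers(lo, hi + 1))
        chars = list(rng.choice(BASES, size=length))
        if enriched and enrichment_multiplier > 1:
            base_expect = (length - m + 1) / 4**m
            n_insert = rng.poisson((enrichment_multiplier - 1.0) * base_expect)
            placed: set[int] = set()
            tries = 0
            while len(placed) < n_insert and tries < 100 * max(n_insert, 1):
                start = int(rng.integers(0, length - m + 1))
                tries += 1
                if any(abs(start - s) < m for s in placed):
                    continue
                chars[start : start + m] = motif
                placed.add(start)
        records.append(
            CdsRecord(id=f"cds-{i + 1:04d}", sequence="".join(chars))
        )
    return records, labels


# ---------------------------------------------------------------------------
# Truth TSV

TRUTH_COLUMNS = ["reference_id", "position", "planted"]


def write_truth_table(truth: GroundTruth, path: str | Path) -> None:
    rows = [
        (rid, pos, int(flag))
        for rid in truth.sites
        for pos, flag in zip(truth.sites[rid], truth.planted[rid])
    ]
    pd.DataFrame(rows, columns=TRUTH_COLUMNS).to_csv(path, sep="\t", index=False)


def read_truth_table(path: str | Path) -> GroundTruth:
    df = pd.read_csv(path, sep="\t", dtype={"reference_id": str})
    truth = GroundTruth()
    for rec in df.itertuples(index=False):
        truth.sites.setdefault(rec.reference_id, []).append(int(rec.position))
        truth.planted.setdefault(rec.reference_id, []).append(bool(rec.planted))
    return truth
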