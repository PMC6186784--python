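"""Cleavage-boundary detection from coverage profiles.

An endoribonuclease cut creates a new fragment 5' end, so mapped-read
coverage jumps at the nucleotide just downstream of the cut.  The relative
coverage increase (RCI) at boundary i is coverage(i) / coverage(i-1), with a
pseudo-count substituted for zero coverage so the ratio is always finite and
positive.  Boundaries whose downstream coverage passes the minimum-coverage
filter compete, across all references, for the overall top-k RCI values; the
winners' +/-flank sequence windows feed the motif-consensus stage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core_io import (
    CleavageCandidate,
    DepthProfile,
    DetectionParams,
    NucleotideSequence,
    SequenceWindow,
)

__all__ = ["RciTrack", "compute_rci", "select_candidates", "extract_windows"]


@dataclass
class RciTrack:
    """RCI ratios for the boundary positions 1..len-1 of one reference.

    ``values[i-1]`` is the ratio at boundary position i; ``eligible`` flags
    boundaries that survive the minimum-coverage filter.
    """

    reference_id: str
    values: np.ndarray
    eligible: np.ndarray


def compute_rci(profile: DepthProfile, params: DetectionParams) -> RciTrack:
    """Relative coverage increase along one reference.

    Zero coverage on either side is replaced by ``params.pseudo_count``
    before dividing, so every boundary gets a positive, finite ratio.
    """
    cov = profile.coverage
    if len(cov) < 2:
        raise ValueError(
            f"profile {profile.reference_id!r}: need >= 2 positions, got {len(cov)}"
        )
    eff = cov.astype(np.float64)
    eff[eff == 0] = params.pseudo_count
    values = eff[1:] / eff[:-1]

    down_ok = cov[1:] >= params.min_coverage
    up_ok = cov[:-1] >= params.min_coverage
    if params.filter_side == "down":
        eligible = down_ok
    elif params.filter_side == "up":
        eligible = up_ok
    else:
        eligible = down_ok & up_ok
    return RciTrack(profile.reference_id, values, eligible)


def select_candidates(
    tracks: Sequence[RciTrack],
    profiles: Sequence[DepthProfile],
    params: DetectionParams,
) -> list[CleavageCandidate]:
    """Pool eligible boundaries across references and keep the top-k by RCI.

    Sort order is (rci desc, cov_down desc, reference_id asc, position asc),
    which makes the selection deterministic under ties.  Fewer than top_k
    candidates are returned when fewer boundaries are eligible.
    """
    by_id = {p.reference_id: p for p in profiles}
    missing = [t.reference_id for t in tracks if t.reference_id not in by_id]
    if missing:
        raise ValueError(f"tracks without matching profiles: {missing}")

    pool: list[CleavageCandidate] = []
    for track in tracks:
        cov = by_id[track.reference_id].coverage
        for idx in np.nonzero(track.eligible)[0]:
            pos = int(idx) + 1
            pool.append(
                CleavageCandidate(
                    reference_id=track.reference_id,
                    position=pos,
                    cov_up=int(cov[pos - 1]),
                    cov_down=int(cov[pos]),
                    rci=float(track.values[idx]),
                )
            )
    pool.sort(key=lambda c: (-c.rci, -c.cov_down, c.reference_id, c.position))
    return pool[: params.top_k]


def extract_windows(
    candidates: Sequence[CleavageCandidate],
    references: Sequence[NucleotideSequence],
    params: DetectionParams,
) -> list[SequenceWindow]:
    """Cut the +/-flank window around each candidate's boundary position.

    Positions outside the reference are filled with N (and the window marked
    padded) so every candidate yields a full-width window; the consensus
    stage excludes N from its counts.
    """
    by_id = {r.id: r for r in references}
    windows: list[SequenceWindow] = []
    for cand in candidates:
        if cand.reference_id not in by_id:
            raise ValueError(f"candidate references unknown sequence {cand.reference_id!r}")
        residues = by_id[cand.reference_id].residues
        lo = cand.position - params.flank
        hi = cand.position + params.flank
        chars = []
        padded = False
        for i in range(lo, hi + 1):
            if 0 <= i < len(residues):
                chars.append(residues[i])
            else:
                chars.append("N")
                padded = True
        windows.append(SequenceWindow(cand, "".join(chars), padded))
    return windows
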