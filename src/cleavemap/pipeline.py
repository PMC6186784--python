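"""One-shot pipeline: simulate or ingest -> detect -> logo -> report.

``run_pipeline`` chains the stages with a single configuration object and
writes every artefact plus a run manifest (all parameters and the seed) so a
run can be reproduced byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import core_io
from .cleavage_detect import compute_rci, extract_windows, select_candidates
from .core_io import DetectionParams, write_results_table
from .motif_consensus import build_frequency_matrix, call_consensus, logo_table
from .synthetic_data import SimulationConfig, simulate_experiment, write_truth_table

__all__ = ["PipelineConfig", "run_pipeline", "PipelineError"]

logger = logging.getLogger("cleavemap")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and cause."""


@dataclass
class PipelineConfig:
    """Everything a full run consumes.

    Detection defaults are the study parameters (min_coverage 100, top_k 50,
    flank 5); simulation and consensus defaults are this package's
    documented choices.  When ``simulate`` is False, ``references_fasta``
    and ``coverage_tsv`` must point at existing inputs.
    """

    out_dir: Path = Path("cleavemap-run")
    seed: int = 7
    simulate: bool = True
    references_fasta: Path | None = None
    coverage_tsv: Path | None = None
    detection: DetectionParams = field(default_factory=DetectionParams)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    min_frequency: float = 0.5
    min_ic: float = 1.0
    rna_display: bool = True
    small_sample_correction: bool = False

    def manifest(self) -> dict:
        d = {
            "seed": self.seed,
            "simulate": self.simulate,
            "references_fasta": str(self.references_fasta) if self.references_fasta else None,
            "coverage_tsv": str(self.coverage_tsv) if self.coverage_tsv else None,
            "min_frequency": self.min_frequency,
            "min_ic": self.min_ic,
            "rna_display": self.rna_display,
            "small_sample_correction": self.small_sample_correction,
            "detection": asdict(self.detection),
            "simulation": asdict(self.simulation),
        }
        return d


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns a summary dict (also written to disk).

    Outputs under ``config.out_dir``: references/coverage (simulated runs),
    candidates.tsv, logo.tsv, consensus.json and manifest.json.  Raises
    PipelineError with the failing stage named.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    try:
        if config.simulate:
            sim = SimulationConfig(**{**asdict(config.simulation), "seed": config.seed})
            references, truth, profiles = simulate_experiment(sim)
            core_io.write_fasta(references, out / "refs.fa")
            core_io.write_depth_table(profiles, out / "coverage.tsv")
            write_truth_table(truth, out / "truth.tsv")
            logger.info("simulated %d references", len(references))
        else:
            if config.references_fasta is None or config.coverage_tsv is None:
                raise FileNotFoundError("references_fasta and coverage_tsv required")
            references = core_io.read_fasta(config.references_fasta)
            profiles = core_io.read_depth_table(config.coverage_tsv, references)
            logger.info("loaded %d references", len(references))
    except Exception as exc:
        raise PipelineError(f"input stage: {exc}") from exc

    try:
        tracks = [compute_rci(p, config.detection) for p in profiles]
        candidates = select_candidates(tracks, profiles, config.detection)
        windows = extract_windows(candidates, references, config.detection)
        write_results_table(
            [
                {
                    "reference_id": w.candidate.reference_id,
                    "position": w.candidate.position,
                    "cov_up": w.candidate.cov_up,
                    "cov_down": w.candidate.cov_down,
                    "rci": w.candidate.rci,
                    "window": w.window,
                }
                for w in windows
            ]
            or __empty_candidates(),
            out / "candidates.tsv",
        )
        logger.info("selected %d candidates", len(candidates))
    except Exception as exc:
        raise PipelineError(f"detect stage: {exc}") from exc

    try:
        if not windows:
            raise ValueError("no candidates passed the coverage filter")
        matrix = build_frequency_matrix(windows)
        call = call_consensus(
            matrix,
            min_frequency=config.min_frequency,
            min_ic=config.min_ic,
            rna=config.rna_display,
            small_sample_correction=config.small_sample_correction,
        )
        logo_table(matrix, call, config.small_sample_correction).to_csv(
            out / "logo.tsv", sep="\t", index=False
        )
    except Exception as exc:
        raise PipelineError(f"logo stage: {exc}") from exc

    summary = {
        "consensus": call.consensus,
        "called_span": list(call.called_span) if call.called_span else None,
        "cut_offset": call.cut_offset,
        "n_candidates": len(candidates),
    }
    (out / "consensus.json").write_text(json.dumps(summary, indent=1) + "\n")
    (out / "manifest.json").write_text(json.dumps(config.manifest(), indent=1, sort_keys=True) + "\n")
    logger.info("consensus %s span %s", call.consensus, call.called_span)
    return summary


def __empty_candidates():
    import pandas as pd

    return pd.DataFrame(columns=core_io.CANDIDATE_COLUMNS)
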