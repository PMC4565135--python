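"""End-to-end orchestration: simulate -> diffexp -> combine -> progress -> perturb.

`full_synthetic_run` wires every stage together on generated data with known
ground truth; the CLI's ``full-run`` subcommand wraps it and writes the
stage outputs as TSVs with a run manifest.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .combine import CombinedSignature, combine_scores, score_dataset
from .connectivity import ReferenceDatabase
from .diffexp import DiffExpResults, run_diffexp
from .io import PairedExpressionDataset
from .perturbation import PerturbationConfig, stability_scores
from .progression import ProgressionConfig, ProgressionState, run_progression
from .synthetic import (
    ReferenceSpec,
    ReferenceTruth,
    StudyConfig,
    StudyTruth,
    generate_reference_db,
    generate_study,
)


@dataclass
class PipelineResult:
    """Everything a full synthetic run produced, stage by stage."""

    datasets: list[PairedExpressionDataset]
    study_truth: StudyTruth
    diffexp: list[DiffExpResults]
    combined: CombinedSignature
    database: ReferenceDatabase
    reference_truth: ReferenceTruth
    progression: ProgressionState
    stability: pd.DataFrame | None = None
    seed: int | None = None
    config: dict = field(default_factory=dict)

    @property
    def hits_with_stability(self) -> pd.DataFrame:
        """Final hit table with the PerturbStability column appended."""
        hits = self.progression.final_hits.copy()
        if self.stability is not None:
            hits["PerturbStability"] = self.stability["stability"].reindex(hits.index)
        return hits


def _subseed(seed: int | None, label: str) -> np.random.SeedSequence:
    digest = int.from_bytes(hashlib.sha256(label.encode()).digest()[:4], "big")
    return np.random.SeedSequence(
        entropy=0 if seed is None else seed, spawn_key=(digest,)
    )


def full_synthetic_run(
    seed: int | None = 0,
    study: StudyConfig | None = None,
    reference: ReferenceSpec | None = None,
    progression: ProgressionConfig | None = None,
    perturbation: PerturbationConfig | None = None,
    n_null: int = 2000,
    planting_signature_length: int = 20,
    with_stability: bool = True,
) -> PipelineResult:
    """Run the whole pipeline on synthetic data with planted ground truth.

    The reference database's planted inhibitors are built to reverse the top
    ``planting_signature_length`` genes of the combined ranking actually
    obtained on the simulated study, so the progression has a real signal to
    find.  All randomness derives from ``seed``.
    """
    study = study or StudyConfig()
    reference = reference or ReferenceSpec()
    progression_cfg = progression or ProgressionConfig()
    perturbation_cfg = perturbation or PerturbationConfig()

    datasets, study_truth = generate_study(study, seed=_subseed(seed, "study"))
    diffexp_results = [run_diffexp(ds) for ds in datasets]
    vectors = [score_dataset(res) for res in diffexp_results]
    combined = combine_scores(vectors)

    plant_len = min(planting_signature_length, combined.nonzero_count)
    planted_signature = combined.take_top(plant_len)
    database, reference_truth = generate_reference_db(
        datasets[0].universe,
        spec=reference,
        signature=planted_signature,
        seed=_subseed(seed, "reference"),
    )

    state = run_progression(
        combined, database, progression_cfg, n_null=n_null,
        seed=seed if seed is not None else 0,
    )

    stability = None
    # a signature must keep at least one gene after removal to be perturbable
    if with_stability and state.Ns > 0 and state.final_m > perturbation_cfg.n_remove:
        stability = stability_scores(
            combined.take_top(state.final_m),
            database,
            state.final_hits,
            config=perturbation_cfg,
            efp=progression_cfg.Efp,
            n_null=n_null,
            seed=seed if seed is not None else 0,
        )

    return PipelineResult(
        datasets=datasets,
        study_truth=study_truth,
        diffexp=diffexp_results,
        combined=combined,
        database=database,
        reference_truth=reference_truth,
        progression=state,
        stability=stability,
        seed=seed,
        config={
            "study": asdict(study),
            "reference": asdict(reference),
            "progression": asdict(progression_cfg),
            "perturbation": asdict(perturbation_cfg),
            "n_null": n_null,
            "planting_signature_length": planting_signature_length,
        },
    )


def write_outputs(result: PipelineResult, outdir: str | Path) -> Path:
    """Write every stage's TSV plus a JSON run manifest; returns the directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    row_counts = {}
    for res in result.diffexp:
        path = outdir / f"diffexp_{res.dataset_name}.tsv"
        res.to_tsv(path)
        row_counts[path.name] = len(res.frame)
    result.combined.to_tsv(outdir / "combined_signature.tsv")
    row_counts["combined_signature.tsv"] = len(result.combined.frame)
    result.progression.trace_to_tsv(outdir / "progression_trace.tsv")
    row_counts["progression_trace.tsv"] = len(result.progression.trace)
    hits = result.hits_with_stability
    hits.index.name = "Compound"
    hits.to_csv(outdir / "hits.tsv", sep="\t", float_format="%.4g")
    row_counts["hits.tsv"] = len(hits)

    manifest = {
        "cmapsig_version": __version__,
        "seed": result.seed,
        "config": result.config,
        "config_sha256": hashlib.sha256(
            json.dumps(result.config, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "final_m": result.progression.final_m,
        "Ns": result.progression.Ns,
        "exhausted": result.progression.exhausted,
        "row_counts": row_counts,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return outdir
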