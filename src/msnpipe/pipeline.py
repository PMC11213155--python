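"""End-to-end orchestration: thickness -> MSN -> features -> association
screens -> mediator candidates -> mediation reports.

Every stage writes its artifacts under the configured output directory,
together with a manifest (config, hash, seed, library versions) that
makes a rerun bit-for-bit reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .graph import GraphFeatureExtractor
from .io import (
    PipelineConfig,
    read_cohort_csv,
    read_thickness_table,
    write_msn_csv,
)
from .mediation import MediationResult, run_mediation
from .msn import MSNTransformer
from .stats import (
    cognitive_associations,
    msn_associations,
    select_mediator_candidates,
    thickness_associations,
)

log = logging.getLogger("msnpipe")

__all__ = ["PipelineResults", "run_pipeline"]


@dataclass
class PipelineResults:
    """In-memory handles to everything the pipeline wrote."""

    output_dir: Path
    cohort: pd.DataFrame
    features: pd.DataFrame
    cognitive: pd.DataFrame
    global_results: pd.DataFrame
    local_results: pd.DataFrame
    thickness_results: pd.DataFrame
    candidates: list[tuple[str, str]]
    mediations: list[MediationResult]


def _mean_thickness_table(subjects) -> pd.DataFrame:
    rows = {
        s.subject_id: {roi: float(v.mean()) for roi, v in s.roi_values.items()}
        for s in subjects
    }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "subject_id"
    return df


def run_pipeline(config: PipelineConfig) -> PipelineResults:
    """Run the full analysis described by *config*.

    Stages: read inputs; build per-subject MSNs; extract AUC-integrated
    network features; screen cognitive scores, network features and mean
    thickness against ADI; select mediator candidates (local features at
    the strict tier); run bootstrap mediation of every candidate against
    every ADI-significant cognitive outcome.  Deterministic under the
    config seed.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    _write_manifest(config, out)

    def stage(name):
        log.info("stage: %s", name)

    try:
        stage("read inputs")
        cohort = read_cohort_csv(config.cohort_path)
        subjects, rejections = read_thickness_table(config.thickness_path)
        if rejections:
            (out / "rejected_subjects.json").write_text(
                json.dumps(rejections, indent=2, sort_keys=True)
            )
            log.warning("rejected %d subjects with incomplete profiles", len(rejections))
        kept_ids = {s.subject_id for s in subjects}
        cohort = cohort[cohort["subject_id"].isin(kept_ids)].reset_index(drop=True)

        stage("build MSNs")
        builder = MSNTransformer(
            config.grid_lower, config.grid_upper, config.grid_points
        ).fit(subjects)
        matrices = builder.transform_to_matrices(subjects)
        msn_dir = out / "msn"
        msn_dir.mkdir(exist_ok=True)
        for m in matrices:
            write_msn_csv(m, msn_dir / f"{m.subject_id}.csv")

        stage("extract network features")
        extractor = GraphFeatureExtractor(
            levels=config.sparsity_levels,
            n_random=config.n_random,
            random_state=config.seed,
        ).fit(matrices)
        features = extractor.transform(matrices)
        features.to_csv(out / "network_features.csv")
        qc_lines = [
            f"{sid}\tfragmented at sparsity levels {levels}"
            for sid, levels in sorted(extractor.qc_log_.items())
        ]
        (out / "qc.log").write_text("\n".join(qc_lines) + ("\n" if qc_lines else ""))

        stage("association screens")
        _, cognitive = cognitive_associations(cohort, alpha=config.alpha_cognitive)
        cognitive.to_csv(out / "cognitive_associations.csv", index=False)
        glob, loc = msn_associations(
            features, cohort, config.alpha_report, config.alpha_candidate
        )
        glob.to_csv(out / "global_associations.csv", index=False)
        loc.to_csv(out / "local_associations.csv", index=False)
        mean_thickness = _mean_thickness_table(subjects)
        thick = thickness_associations(mean_thickness, cohort)
        thick.to_csv(out / "thickness_associations.csv", index=False)

        stage("mediation")
        candidates = select_mediator_candidates(loc, config.alpha_candidate)
        (out / "mediator_candidates.json").write_text(
            json.dumps([list(c) for c in candidates], indent=2)
        )
        sig_outcomes = cognitive.loc[cognitive["significant"], "outcome"].tolist()
        mediations: list[MediationResult] = []
        reports = []
        med_seeds = np.random.SeedSequence((config.seed, 7)).generate_state(
            max(len(candidates) * max(len(sig_outcomes), 1), 1)
        )
        k = 0
        for cand in candidates:
            for outcome in sig_outcomes:
                res = run_mediation(
                    cohort, features, cand, outcome,
                    n_boot=config.n_boot, seed=int(med_seeds[k] % (2**31)),
                )
                mediations.append(res)
                reports.append(res.to_dict())
                k += 1
        (out / "mediation_results.json").write_text(
            json.dumps(reports, indent=2)
        )
        (out / "mediation_diagrams.txt").write_text(
            "\n\n".join(m.path_diagram() for m in mediations) + "\n"
        )
    except Exception as err:  # surface the failing stage
        log.error("pipeline failed: %s", err)
        raise

    return PipelineResults(
        output_dir=out, cohort=cohort, features=features, cognitive=cognitive,
        global_results=glob, local_results=loc, thickness_results=thick,
        candidates=candidates, mediations=mediations,
    )


def _write_manifest(config: PipelineConfig, out: Path) -> None:
    import networkx
    import scipy
    import sklearn
    import statsmodels

    from . import __version__

    manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "versions": {
            "msnpipe": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "networkx": networkx.__version__,
            "statsmodels": statsmodels.__version__,
            "scikit-learn": sklearn.__version__,
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
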