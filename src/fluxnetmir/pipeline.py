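"""End-to-end pipeline: extend → initialize → FCA → score, with provenance.

One :func:`run_pipeline` call processes a cohort: the model is extended with
miRNA regulation once, then each sample's expression initializes a fresh
copy that is simulated untreated and treated. Outputs are plain TSV/JSON
for diffability: ``fca_results.tsv`` (per-sample, per-readout fold changes
and convergence diagnostics), ``scores.tsv`` (sensitivity scores and
responder calls) and ``provenance.json`` (package version, seed, config
echo, list of outputs).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .drugs import DrugSpec, builtin_drugs, load_drugs
from .engine import SimulationConfig, run_fca
from .expression import initialize_model, load_profile
from .mirao import DEFAULT_K, extend_model, load_mirt, load_tfmir
from .model import read_model, write_model
from .scoring import classify_responder, sensitivity_score

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "resolve_drug"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; ``stage`` names it."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Everything one pipeline run needs.

    ``samples`` lists (sample_id, gene_profile_path, mirna_profile_path)
    triples. ``drug`` is a catalogue name (case-insensitive) or resolved via
    ``drugs_file``. Simulation settings mirror :class:`SimulationConfig`.
    """

    model_path: str
    mirt_path: str
    tfmir_path: str
    samples: list[tuple[str, str, str]]
    drug: str
    out_dir: str
    inhibitor_conc: float = 1.0
    mirao_k: float = DEFAULT_K
    max_steps: int = 10_000
    steady_tol: float = 0.001
    seed: int = 0
    drugs_file: str | None = None
    readouts: list[str] | None = None
    write_extended: bool = True


def resolve_drug(name: str, drugs_file: str | None = None) -> DrugSpec:
    catalogue = builtin_drugs()
    if drugs_file:
        catalogue.update(load_drugs(drugs_file))
    key = name.lower()
    if key not in catalogue:
        raise KeyError(f"unknown drug {name!r}; known: {sorted(catalogue)}")
    return catalogue[key]


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with the stage name attached."""

    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(name, exc) from exc
            return False

    return _Ctx()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the provenance dict.

    Any stage failure raises :class:`PipelineError` naming the stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    with _stage("read_model"):
        model = read_model(config.model_path)
    with _stage("load_tables"):
        mirt = load_mirt(config.mirt_path)
        tfmir = load_tfmir(config.tfmir_path)
    with _stage("resolve_drug"):
        drug = resolve_drug(config.drug, config.drugs_file)
    with _stage("extend_model"):
        extended = extend_model(model, mirt, tfmir, k=config.mirao_k)
        if config.write_extended:
            write_model(extended, out / "extended.xml")

    sim_config = SimulationConfig(max_steps=config.max_steps, steady_tol=config.steady_tol)
    readouts = config.readouts or list(extended.readouts)
    fca_rows, score_rows = [], []
    for sample_id, gene_path, mirna_path in config.samples:
        with _stage(f"initialize[{sample_id}]"):
            gp = load_profile(gene_path, label=sample_id)
            mp = load_profile(mirna_path, label=sample_id)
            init = initialize_model(extended, gp, mp)
        with _stage(f"fca[{sample_id}]"):
            res = run_fca(
                init, drug, readouts=readouts, config=sim_config,
                inhibitor_conc=config.inhibitor_conc,
            )
        for rid in readouts:
            p = res.P[rid]
            fca_rows.append(
                {
                    "sample_id": sample_id,
                    "treatment": drug.name,
                    "readout": rid,
                    "P": p,
                    "control_value": res.control.final[rid],
                    "treatment_value": res.treatment.final[rid],
                    "control_steps": res.control.steps_taken,
                    "treatment_steps": res.treatment.steps_taken,
                    "reached_steady": res.control.reached_steady and res.treatment.reached_steady,
                }
            )
            if rid == readouts[0] and p is not None:
                score_rows.append(
                    {
                        "sample_id": sample_id,
                        "treatment": drug.name,
                        "P": p,
                        "model_score": sensitivity_score(p),
                        "responder": classify_responder(p),
                    }
                )

    with _stage("score"):
        fca_path = out / "fca_results.tsv"
        scores_path = out / "scores.tsv"
        pd.DataFrame(fca_rows).to_csv(fca_path, sep="\t", index=False)
        pd.DataFrame(score_rows).to_csv(scores_path, sep="\t", index=False)

    provenance = {
        "fluxnetmir_version": __version__,
        "seed": config.seed,
        "config": {
            "model_path": str(config.model_path),
            "mirt_path": str(config.mirt_path),
            "tfmir_path": str(config.tfmir_path),
            "drug": config.drug,
            "inhibitor_conc": config.inhibitor_conc,
            "mirao_k": config.mirao_k,
            "max_steps": config.max_steps,
            "steady_tol": config.steady_tol,
            "n_samples": len(config.samples),
            "readouts": readouts,
        },
        "outputs": sorted(
            {str(p.relative_to(out)) for p in out.iterdir() if p.is_file()}
            | {"provenance.json"}
        ),
    }
    with _stage("provenance"):
        with open(out / "provenance.json", "w") as fh:
            json.dump(provenance, fh, indent=2, sort_keys=True)
    return provenance
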