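"""End-to-end staged pipeline: simulate -> reference -> bulk -> train -> evaluate.

Each stage writes its artifact under the output directory and is skipped
on ``resume`` when the artifact already exists, so deleting an
intermediate regenerates only the downstream stages. A RunManifest with
config, seeds and input checksums is emitted at the end.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np

from . import bulksim, evaluate, harmonize, io as hio
from .config import PipelineConfig, RunManifest
from .deconvnet import DeconvolutionEnsemble, EnsembleSpec
from .synthetic import SyntheticDesign, generate_cells
from .vocabulary import DEFAULT_VOCABULARY

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline"]


def run_pipeline(config: PipelineConfig, outdir, resume: bool = False) -> dict:
    """Execute the full workflow, returning the artifact paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config.to_dict(), seed=config.seed)
    artifacts: dict[str, Path] = {}

    # -- stage 1: synthetic reference cells
    sc_dir = outdir / "sc"
    stage = "simulate-sc"
    if resume and (sc_dir / "matrix.mtx").exists():
        logger.info("resume: reusing %s", sc_dir)
        cells = hio.read_mtx_dir(sc_dir)
    else:
        try:
            design = SyntheticDesign(
                n_batches=config.synthetic.n_batches,
                cells_per_type_per_batch=config.synthetic.cells_per_type_per_batch,
                n_genes=config.synthetic.n_genes,
                program_effect_size=config.synthetic.program_effect_size,
                batch_effect_sd=config.synthetic.batch_effect_sd,
                dropout_rate=config.synthetic.dropout_rate,
                library_size_range=tuple(config.synthetic.library_size_range),
                seed=config.stage_seed(stage),
            )
            cells = generate_cells(design)
            hio.write_mtx_dir(cells, sc_dir)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    artifacts["sc"] = sc_dir

    # -- stage 2: batch-corrected reference
    ref_path = outdir / "reference.h5"
    stage = "build-ref"
    if resume and ref_path.exists():
        ref = harmonize.ReferenceModel.load(ref_path)
    else:
        try:
            rc = config.reference
            ref = harmonize.build_reference(
                cells, n_top=rc.n_top, d=rc.d, K=rc.K, theta=rc.theta,
                sigma=rc.sigma, max_iter=rc.max_iter, tol=rc.tol,
                ridge=rc.ridge, seed=config.stage_seed(stage), correct=rc.correct,
            )
            ref.save(ref_path)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    artifacts["reference"] = ref_path

    # -- stage 3: pseudo-bulk simulation
    bulk_dir = outdir / "bulk"
    stage = "make-bulk"
    if resume and (bulk_dir / "train" / "manifest.json").exists():
        train_set = hio.read_bulk_set(bulk_dir / "train")
        val_set = hio.read_bulk_set(bulk_dir / "val")
    else:
        try:
            pool = ref.corrected_expression if config.reference.correct else ref.normalized_expression
            common = dict(
                type_labels=ref.type_labels,
                gene_ids=ref.scaling.selected_genes,
                cells_per_sample=config.bulk.cells_per_sample,
                mode=config.bulk.mode,
            )
            train_set = bulksim.build_set(
                pool, n_samples=config.bulk.n_train,
                seed=config.stage_seed(stage), source_tag="train", **common,
            )
            val_set = bulksim.build_set(
                pool, n_samples=config.bulk.n_val,
                seed=config.stage_seed(stage + ":val"), source_tag="val", **common,
            )
            hio.write_bulk_set(train_set, bulk_dir / "train")
            hio.write_bulk_set(val_set, bulk_dir / "val")
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    artifacts["bulk"] = bulk_dir

    # -- stage 4: train the ensemble
    model_path = outdir / "model.h5"
    stage = "train"
    if resume and model_path.exists():
        ens = DeconvolutionEnsemble.load(model_path)
    else:
        try:
            tc = config.train
            spec = EnsembleSpec(
                learning_rate=tc.learning_rate, batch_size=tc.batch_size,
                patience=tc.patience, max_epochs=tc.max_epochs,
                dropout_rate=tc.dropout_rate, seed=config.stage_seed(stage),
            )
            ens = DeconvolutionEnsemble.build(spec, train_set.gene_ids)
            ens.train(train_set, val_set)
            ens.save(model_path)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    artifacts["model"] = model_path

    # -- stage 5: evaluate on the validation set
    stage = "evaluate"
    try:
        pred = ens.predict(val_set.expression)
        hio.write_fractions(
            pred, outdir / "fractions.tsv",
            sample_ids=[f"sample{i}" for i in range(pred.shape[0])],
        )
        report = evaluate.make_report(val_set.truth, pred)
        report.to_json(outdir / "report.json")
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    artifacts["fractions"] = outdir / "fractions.tsv"
    artifacts["report"] = outdir / "report.json"

    for name, path in artifacts.items():
        manifest.add_input(name, path)
    manifest.write(outdir / "run_manifest.json")
    artifacts["manifest"] = outdir / "run_manifest.json"
    return artifacts
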