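"""End-to-end orchestration: simulate -> preprocess -> quantify -> PCA ->
classify -> evaluate, from one configuration.

The run emulates the study design: a replicated cohort is generated (or
loaded), preprocessed and screened for outliers; amino-acid ratios are
quantified and compared between outcome groups; samples are split 4:1
into training and test partitions; PCA is fitted on training spectra
only; each requested classifier family is grid-search tuned with
group-aware CV and evaluated on the held-out spectra.  Every stage's
outputs are persisted under the run directory together with a
machine-readable run log.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ramanomics import __version__
from ramanomics.synthetic_data import GeneratorConfig, generate_cohort, write_cohort
from ramanomics.preprocess import PreprocessConfig, preprocess_batch, detect_outlier_spectra
from ramanomics.quantify import quant_table, compare_groups, comparisons_frame
from ramanomics.features import fit_pca, transform
from ramanomics.classify import (ClassifierSpec, make_split, grid_search_cv, predict,
                                 encode_labels)
from ramanomics.evaluate import evaluate_predictions

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    n_components: int = 100
    algorithms: list[str] = field(default_factory=lambda: ["cnn1d", "svm", "rf", "xgboost"])
    grids: dict[str, dict] = field(default_factory=dict)
    cv_folds: int = 5
    split_ratio: float = 0.8
    split_seed: int = 0
    quant_per_sample: bool = False
    quant_test: str = "mannwhitney"
    outdir: str = "run"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        gen = GeneratorConfig(**raw.pop("generator", {}))
        pre = PreprocessConfig(**raw.pop("preprocess", {}))
        return cls(generator=gen, preprocess=pre, **raw)


def run_all(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the summary dict it persists."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    stage = "generate"
    try:
        spectra, manifest, truth = generate_cohort(config.generator)
        write_cohort(spectra, manifest, truth, outdir / "cohort")

        stage = "preprocess"
        processed = preprocess_batch(spectra, config.preprocess)
        screen = detect_outlier_spectra(processed, config.preprocess)
        kept = screen.kept
        kept_ids = {s.spectrum_id for s in kept}
        manifest_kept = manifest[manifest["spectrum_file"].str.replace(".csv", "", regex=False)
                                 .isin(kept_ids)].reset_index(drop=True)

        stage = "quantify"
        ratios = quant_table(kept)
        comparisons = compare_groups(ratios, manifest_kept,
                                     test=config.quant_test,
                                     per_sample=config.quant_per_sample)
        ratios.to_csv(outdir / "ratios.tsv", sep="\t", index=False)
        comparisons_frame(comparisons).to_csv(outdir / "group_stats.tsv", sep="\t", index=False)

        stage = "split"
        plan = make_split(manifest_kept, ratio=config.split_ratio, seed=config.split_seed)
        sample_ids = np.array([s.sample_id for s in kept])
        labels = np.array([s.label for s in kept], dtype=object)
        train_mask = plan.mask(sample_ids)

        stage = "features"
        pca = fit_pca([s for s, m in zip(kept, train_mask) if m], config.n_components)
        X_all = transform(pca, kept)
        X_train, y_train = X_all[train_mask], labels[train_mask]
        X_test, y_test = X_all[~train_mask], labels[~train_mask]
        groups_train = sample_ids[train_mask]
        pca.to_json(outdir / "pca_model.json")

        stage = "classify"
        summary_rows = []
        all_preds = []
        for algo in config.algorithms:
            spec = ClassifierSpec(algorithm=algo,
                                  grid=config.grids.get(algo),
                                  cv_folds=config.cv_folds,
                                  seed=config.generator.seed)
            model = grid_search_cv(spec, X_train, y_train, groups_train)
            preds = predict(model, X_test)
            preds.insert(0, "spectrum_id", [s.spectrum_id for s, m in zip(kept, train_mask) if not m])
            preds.insert(1, "sample_id", sample_ids[~train_mask])
            preds["truth"] = y_test
            preds["algorithm"] = algo
            report = evaluate_predictions(preds["predicted"], y_test,
                                          scores=preds["p_pregnancy"])
            summary_rows.append({
                "algorithm": algo,
                "best_params": json.dumps(model.best_params),
                "cv_accuracy": model.cv_accuracy,
                "test_accuracy": report.overall_accuracy,
                "test_correct": report.correct,
                "test_total": report.total,
                "auc": report.auc,
            })
            all_preds.append(preds)
            (outdir / f"report_{algo}.json").write_text(json.dumps(report.rounded()))
            logger.info("%s: CV acc %.3f, test acc %.3f (%d/%d), AUC %.3f",
                        algo, model.cv_accuracy, report.overall_accuracy,
                        report.correct, report.total, report.auc)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    pd.concat(all_preds, ignore_index=True).to_csv(outdir / "predictions.tsv",
                                                   sep="\t", index=False)
    summary = pd.DataFrame(summary_rows)
    summary.to_csv(outdir / "summary.tsv", sep="\t", index=False)
    run_log = {
        "version": __version__,
        "config": {
            "generator": asdict(config.generator),
            "preprocess": asdict(config.preprocess),
            "n_components": config.n_components,
            "algorithms": config.algorithms,
            "cv_folds": config.cv_folds,
            "split_ratio": config.split_ratio,
            "split_seed": config.split_seed,
        },
        "n_spectra": len(spectra),
        "n_kept": len(kept),
        "n_rejected": len(screen.rejected),
        "train_samples": list(plan.train_samples),
        "test_samples": list(plan.test_samples),
        "group_stats": comparisons_frame(comparisons).to_dict(orient="records"),
        "summary": summary_rows,
    }
    (outdir / "run_log.json").write_text(json.dumps(run_log, indent=1))
    return run_log
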