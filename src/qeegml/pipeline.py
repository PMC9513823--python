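"""End-to-end experiment orchestration.

A :class:`RunConfig` describes one experiment: a synthetic cohort spec (or a
directory of EDF files with a manifest), the signal variants (raw / clean),
demographic variants, selection methods, learner subset, tasks (two- or
three-class) and iteration counts. :func:`run_experiment` executes every
requested configuration cell — synthesize, preprocess, extract features,
standardize, select, train, validate, contrast — and writes a summary CSV
plus per-cell JSON reports under the output directory. Feature tables are
cached on disk keyed by a content hash of the generating configuration, so
reruns and partial runs are cheap and deterministic.

Every stochastic step's seed derives from the master seed through a stable
hash, so any cell can be re-run in isolation with identical results.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .classifiers import enumerate_model_grid, fit_predictor
from .contrasts import coherence_pair_map, median_z_by_category, zscore_to_baseline
from .features import (
    DEMO_FEATURES,
    SCHEMA_VERSION,
    broadband_coherence,
    build_feature_table,
    extract_features,
    schema_hash,
)
from .preprocess import (
    HeuristicLabeler,
    OracleLabeler,
    extract_resting_segment,
    ica_artifact_removal,
    raw_variant,
)
from .recording import EEGRecording
from .selection import (
    LdaSelectionConfig,
    SelectionResult,
    lda_select,
    pca_select,
    sequential_select,
    standardize_features,
    stat_select,
)
from .synthetic import CohortSpec, artifact_signal_from_log, iter_subjects
from .validation import (
    abnormal_detector_bound,
    classification_metrics,
    compare_to_null,
    independent_validate,
    random_label_null,
    repeated_kfold_cv,
    zeror,
)

logger = logging.getLogger("qeegml.pipeline")

SELECTION_METHODS = ("statistics", "lda", "fsfs", "bsfs", "pca")
TASKS = ("2class", "3class")
VARIANTS = ("raw", "clean")

TASK_CLASSES = {"2class": ("normal", "TBI"), "3class": ("normal", "TBI", "stroke")}


def derive_seed(master: int, *keys) -> int:
    """Stable per-cell seed fan-out from the master seed (< 2**31)."""
    h = hashlib.sha256(("/".join(map(str, (master, *keys)))).encode()).hexdigest()
    return int(h[:8], 16) % (2**31 - 1)


@dataclass
class RunConfig:
    """One experiment request; serializable to/from JSON."""

    cohort: CohortSpec
    out_dir: str = "qeegml-run"
    variants: tuple[str, ...] = VARIANTS
    demo_variants: tuple[bool, ...] = (True, False)
    selections: tuple[str, ...] = SELECTION_METHODS
    models: tuple[str, ...] | None = None  # None = full 12-learner grid
    tasks: tuple[str, ...] = TASKS
    cv_folds: int = 10
    cv_iters: int = 200
    null_iters: int = 200
    seed: int = 0
    #: desk-scale knobs for the selection stage
    lda_steps: int = 50
    sfs_mc_reps: int = 50
    sfs_cv_folds: int = 10
    fsfs_max_moves: int | None = 13
    #: oracle labeler uses the injected-artifact event log; heuristic does not
    ic_labeler: str = "oracle"

    def model_specs(self):
        grid = enumerate_model_grid()
        if self.models is None:
            return grid
        by_label = {s.label: s for s in grid}
        return [by_label[m] for m in self.models]

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["cohort"] = json.loads(self.cohort.to_json())
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        cohort = CohortSpec.from_json(json.dumps(d.pop("cohort")))
        for key in ("variants", "demo_variants", "selections", "tasks"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        if d.get("models") is not None:
            d["models"] = tuple(d["models"])
        return cls(cohort=cohort, **d)


def enumerate_cells(config: RunConfig) -> list[dict]:
    """All requested configuration cells (the full default census is
    12 models x 2 variants x 5 selections x 2 demo x 2 tasks = 480)."""
    cells = []
    for task in config.tasks:
        for variant in config.variants:
            for demo in config.demo_variants:
                for selection in config.selections:
                    for spec in config.model_specs():
                        cells.append(
                            {
                                "task": task,
                                "variant": variant,
                                "demo": demo,
                                "selection": selection,
                                "model": spec.label,
                            }
                        )
    return cells


# --- feature-table construction ------------------------------------------------


def preprocess_recording(
    rec: EEGRecording,
    events: list[dict] | None = None,
    variant: str = "raw",
    labeler: str = "oracle",
    seed: int = 0,
):
    """Segment + filter + re-reference; for the clean variant also run ICA
    rejection with the requested component labeler."""
    seg = extract_resting_segment(rec)
    raw = raw_variant(seg)
    if variant == "raw":
        return raw
    if labeler == "oracle" and events:
        i0 = int(round(60 * rec.fs))
        art_full = {
            kind: artifact_signal_from_log(events, rec.n_samples, rec.fs, types=(kind,))
            for kind in {e["type"] for e in events}
        }
        art = {k: v[:, i0 : i0 + raw.n_samples] for k, v in art_full.items()}
        lab = OracleLabeler(art)
    else:
        lab = HeuristicLabeler()
    cleaned, _report = ica_artifact_removal(raw, lab, seed=seed)
    return cleaned


def cohort_feature_tables(
    spec: CohortSpec,
    variant: str = "raw",
    labeler: str = "oracle",
    seed: int = 0,
    with_broadband: bool = True,
) -> dict:
    """Extract full feature tables for both splits of a synthetic cohort.

    Returns ``{"train": (table, labels), "iv": (table, labels)}``; tables
    carry the 1330 EEG features, the 3 demographic columns, and (optionally)
    the 171 broadband-coherence columns used only by the contrast stage.
    """
    out = {}
    for split in ("train", "iv"):
        rows, labels, ids = [], [], []
        for rec, events in iter_subjects(spec, split):
            pre = preprocess_recording(
                rec, events, variant=variant, labeler=labeler,
                seed=derive_seed(seed, "ica", split, rec.subject_id),
            )
            fv = extract_features(pre, include_demo=True)
            if with_broadband:
                bb = pd.Series(broadband_coherence(pre))
                fv = pd.concat([fv, bb])
            rows.append(fv)
            labels.append(rec.class_label)
            ids.append(rec.subject_id)
        table = pd.DataFrame(rows, index=ids)
        out[split] = (table, pd.Series(labels, index=ids, name="class"))
    return out


# --- feature-table / report I/O --------------------------------------------------


def save_feature_table(table: pd.DataFrame, labels: pd.Series, path: str | Path) -> None:
    """CSV feature table + JSON sidecar (schema version and hash)."""
    path = Path(path)
    out = table.copy()
    out.insert(0, "class", labels)
    out.to_csv(path, index_label="subject_id")
    sidecar = {
        "schema_version": SCHEMA_VERSION,
        "schema_hash": schema_hash(table.columns),
        "n_subjects": int(len(table)),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def load_feature_table(path: str | Path) -> tuple[pd.DataFrame, pd.Series]:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    if sidecar.get("schema_version") != SCHEMA_VERSION:
        raise ValueError(
            f"feature-table schema version {sidecar.get('schema_version')!r} "
            f"does not match {SCHEMA_VERSION!r}"
        )
    df = pd.read_csv(path, index_col="subject_id")
    df.index.name = None
    labels = df.pop("class")
    if schema_hash(df.columns) != sidecar["schema_hash"]:
        raise ValueError("feature-table schema hash mismatch")
    return df, labels


# --- selection / cell execution ---------------------------------------------------


def run_selection(
    method: str,
    train_table: pd.DataFrame,
    train_labels: pd.Series,
    config: RunConfig,
    seed: int,
) -> SelectionResult:
    if method == "statistics":
        return stat_select(train_table, train_labels)
    if method == "lda":
        return lda_select(
            train_table, train_labels,
            LdaSelectionConfig(n_steps=config.lda_steps, seed=seed),
        )
    if method == "fsfs":
        return sequential_select(
            train_table, train_labels, direction="forward",
            cv_folds=config.sfs_cv_folds, mc_reps=config.sfs_mc_reps,
            seed=seed, max_moves=config.fsfs_max_moves,
        )
    if method == "bsfs":
        lda_res = lda_select(
            train_table, train_labels,
            LdaSelectionConfig(n_steps=config.lda_steps, seed=seed),
        )
        start = lda_res.selected or list(train_table.columns[:1])
        return sequential_select(
            train_table, train_labels, direction="backward", start_set=start,
            cv_folds=config.sfs_cv_folds, mc_reps=config.sfs_mc_reps, seed=seed,
        )
    if method == "pca":
        return pca_select(train_table)
    raise ValueError(f"unknown selection method {method!r}")


def _cell_id(cell: dict) -> str:
    return "_".join(
        str(cell[k]) for k in ("task", "variant", "demo", "selection", "model")
    )


def run_experiment(config: RunConfig, progress: bool = False) -> pd.DataFrame:
    """Execute every requested cell; returns (and writes) the summary table.

    Results are cached per cell under ``out_dir/cells/<id>.json``; a rerun
    with the same config reuses them, so the summary is reproducible and
    resumable. Failing cells are logged and skipped.
    """
    out = Path(config.out_dir)
    (out / "cells").mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(config.to_json())

    # 1. features per variant (cached on disk)
    tables: dict[str, dict] = {}
    for variant in config.variants:
        key = hashlib.sha256(
            (config.cohort.to_json() + variant + config.ic_labeler).encode()
        ).hexdigest()[:12]
        cache = out / f"features_{variant}_{key}"
        if (cache.with_suffix(".train.csv")).exists():
            tables[variant] = {
                split: load_feature_table(cache.with_suffix(f".{split}.csv"))
                for split in ("train", "iv")
            }
        else:
            t0 = time.time()
            tables[variant] = cohort_feature_tables(
                config.cohort, variant=variant, labeler=config.ic_labeler,
                seed=derive_seed(config.seed, "features", variant),
            )
            for split, (tab, lab) in tables[variant].items():
                save_feature_table(tab, lab, cache.with_suffix(f".{split}.csv"))
            logger.info("features[%s]: %.1f s", variant, time.time() - t0)

    # 2. per-cell training and validation
    rows = []
    selection_cache: dict[tuple, SelectionResult] = {}
    for cell in enumerate_cells(config):
        cid = _cell_id(cell)
        cell_path = out / "cells" / f"{cid}.json"
        if cell_path.exists():
            rows.append(json.loads(cell_path.read_text())["summary"])
            continue
        try:
            row = _run_cell(cell, tables, config, cell_path, selection_cache)
            rows.append(row)
        except Exception as err:  # noqa: BLE001 - cells are isolated on purpose
            logger.exception("cell %s failed: %s", cid, err)
            if progress:
                print(f"FAILED {cid}: {err}")
            continue
        if progress:
            print(f"{cid}: cv={row['cv_mean']:.3f} iv={row['iv_accuracy']:.3f}")

    summary = pd.DataFrame(rows)
    summary.to_csv(out / "summary.csv", index=False)

    # 3. group contrasts per variant (three-class runs only)
    if "3class" in config.tasks:
        for variant in config.variants:
            table, labels = tables[variant]["train"]
            contrast = zscore_to_baseline(table, labels, "normal")
            median_z_by_category(contrast).to_csv(out / f"contrast_median_z_{variant}.csv")
            pairs = coherence_pair_map(contrast, "TBI")
            pairs.to_csv(out / f"contrast_pairs_TBI_{variant}.csv", index=False)
    return summary


def _subset_task(table, labels, task):
    keep = labels.isin(TASK_CLASSES[task])
    return table[keep], labels[keep]


def _run_cell(
    cell: dict,
    tables: dict,
    config: RunConfig,
    cell_path: Path,
    selection_cache: dict[tuple, SelectionResult],
) -> dict:
    variant, task, demo = cell["variant"], cell["task"], cell["demo"]
    sel_seed = derive_seed(config.seed, "select", task, variant, demo, cell["selection"])
    train_table, train_labels = tables[variant]["train"]
    iv_table, iv_labels = tables[variant]["iv"]
    # broadband-coherence columns feed only the contrast stage
    model_cols = [c for c in train_table.columns if not c.startswith("bbCoh:")]
    train_table, iv_table = train_table[model_cols], iv_table[model_cols]
    if not demo:
        keep = [c for c in train_table.columns if c not in DEMO_FEATURES]
        train_table, iv_table = train_table[keep], iv_table[keep]
    train_table, train_labels = _subset_task(train_table, train_labels, task)
    iv_table, iv_labels = _subset_task(iv_table, iv_labels, task)

    train_std, iv_std = standardize_features(train_table, iv_table)
    sel_key = (task, variant, demo, cell["selection"])
    if sel_key not in selection_cache:
        selection_cache[sel_key] = run_selection(
            cell["selection"], train_std, train_labels, config, sel_seed
        )
    selection = selection_cache[sel_key]
    Xtr = selection.apply(train_std)
    Xiv = selection.apply(iv_std)
    if Xtr.shape[1] == 0:
        raise ValueError(f"selection {cell['selection']} kept no features")

    spec = next(s for s in config.model_specs() if s.label == cell["model"])
    cv_seed = derive_seed(config.seed, "cv", *sel_key, cell["model"])
    cv = repeated_kfold_cv(
        spec, Xtr, train_labels, k=min(config.cv_folds, len(train_labels)),
        iters=config.cv_iters, seed=cv_seed,
    )
    null = random_label_null(
        spec, Xtr, train_labels, k=min(config.cv_folds, len(train_labels)),
        iters=config.null_iters, seed=derive_seed(cv_seed, "null"),
    )
    ks = compare_to_null(cv, null)
    model = fit_predictor(spec, Xtr, train_labels)
    iv_report, iv_success = independent_validate(model, Xiv, iv_labels)

    tr_counts = train_labels.value_counts()
    iv_counts = iv_labels.value_counts()
    row = {
        **{k: cell[k] for k in ("task", "variant", "demo", "selection", "model")},
        "n_features": int(Xtr.shape[1]),
        "n_train": int(len(train_labels)),
        "n_iv": int(len(iv_labels)),
        "cv_mean": cv.mean,
        "cv_sd": float(cv.samples.std(ddof=1)) if cv.n_iterations > 1 else 0.0,
        "null_mean": null.mean,
        "ks_p": ks["p_value"],
        "significant_vs_null": ks["significant"],
        "iv_accuracy": iv_report.accuracy,
        "iv_success": iv_success,
        "zeror_cv": zeror(tr_counts.to_numpy()),
        "zeror_iv": zeror(iv_counts.to_numpy()),
    }
    if task == "3class":
        order = ["normal", "TBI", "stroke"]
        row["bound_cv"] = abnormal_detector_bound([tr_counts.get(c, 0) for c in order])
        row["bound_iv"] = abnormal_detector_bound([iv_counts.get(c, 0) for c in order])
    report = {
        "summary": row,
        "selection": selection.to_dict() if selection.loadings is None else
        {"method": "pca", "n_components": len(selection.selected)},
        "cv": cv.summary(),
        "null": null.summary(),
        "ks": ks,
        "iv": iv_report.to_dict(),
        "seeds": {"selection": sel_seed, "cv": cv_seed},
    }
    cell_path.write_text(json.dumps(report, indent=2, default=str))
    return row
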