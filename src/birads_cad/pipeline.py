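"""End-to-end orchestration: segment -> extract -> normalize -> select ->
train -> evaluate, as one reproducible, fully seeded run.

The run consumes either a phantom cohort generated on the fly or a
precomputed feature table, and emits a JSON report embedding the resolved
configuration, the per-size GA results, the selected subset, and the
evaluation metrics with the confusion matrix.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass

import pandas as pd
import yaml

from . import __version__
from .bpn_classifier import BPNConfig, SplitSpec, make_fitness, predict, stratified_split, train
from .feature_table import (
    CATEGORY_IDS,
    apply_scaler,
    assemble,
    feature_column,
    fit_scaler,
    make_table,
    mass_size_mm2,
)
from .ga_select import GAConfig, sweep
from .imaging import (
    ROIImage,
    MassMask,
    equalize_histogram,
    extract_contour,
    fill_holes,
    generate_candidates,
    select_candidate,
)
from .margin_features import margin_features
from .metrics import evaluate
from .shape_features import shape_features
from .synthfix import make_cohort
from .texture_features import texture_features

logger = logging.getLogger(__name__)

FAMILIES = ("shape", "additional", "margin", "density")


@dataclass
class RunConfig:
    """All knobs of one pipeline run; every seed is explicit."""

    seed: int = 0
    n_cases: int = 120
    radius_px: float = 16.0
    n_thresholds: int = 16
    families: tuple[str, ...] = FAMILIES
    ga_lmin: int = 1
    ga_lmax: int = 4
    ga_population_base: int = 2
    ga_max_generations: int = 8
    ga_stagnation: int = 4
    fitness_solver: str = "lbfgs"
    fitness_epochs: int = 200
    bpn_solver: str = "adam"
    bpn_epochs: int = 500
    bpn_learning_rate: float = 0.01
    bpn_patience: int = 25
    train_fraction: float = 0.6
    outdir: str | None = None

    def __post_init__(self) -> None:
        unknown = [f for f in self.families if f not in FAMILIES]
        if unknown:
            raise ValueError(f"unknown feature families: {unknown}")
        # the two additional features (mass size, age) always travel along
        if "additional" not in self.families:
            self.families = tuple(self.families) + ("additional",)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        if "families" in payload:
            payload["families"] = tuple(payload["families"])
        return cls(**payload)


def segment_case(roi: ROIImage, approx_radius: float, n_thresholds: int = 16) -> MassMask:
    """Histogram-equalize and segment one ROI, auto-selecting the candidate."""
    enhanced = equalize_histogram(roi)
    candidates = generate_candidates(enhanced, n_thresholds)
    chosen = select_candidate(candidates, target_radius=approx_radius, strategy="auto")
    return fill_holes(chosen)


def extract_case(roi: ROIImage, mask: MassMask, age_years: float):
    """All 130 features of one segmented case."""
    contour = extract_contour(mask)
    shape = shape_features(mask, contour).as_array()
    margin = margin_features(roi, contour)
    texture = texture_features(roi, mask).as_array()
    size = mass_size_mm2(mask, roi.spacing_mm)
    return assemble(shape, size, age_years, margin, texture)


def build_feature_table(cohort, n_thresholds: int = 16) -> pd.DataFrame:
    """Segment and featurize a cohort of (roi, truth_mask, meta) cases."""
    rows = []
    for i, (roi, _truth, meta) in enumerate(cohort):
        mask = segment_case(roi, meta["approx_radius_px"], n_thresholds)
        fv = extract_case(roi, mask, meta["age_years"])
        rows.append((f"case_{i:04d}", meta["category"], fv))
    return make_table(rows)


def _family_ids(families) -> list[int]:
    ids: list[int] = []
    for fam in FAMILIES:  # keep registry order
        key = "density" if fam == "density" else fam
        if fam in families:
            ids.extend(CATEGORY_IDS[key])
    return sorted(ids)


def run_all(config: RunConfig, table: pd.DataFrame | None = None) -> dict:
    """Execute the full pipeline and return the run report.

    When no feature table is supplied a balanced phantom cohort of
    ``n_cases`` is generated, segmented and featurized first.
    """
    log_handler = None
    if config.outdir:
        os.makedirs(config.outdir, exist_ok=True)
        log_handler = logging.FileHandler(os.path.join(config.outdir, "run.log"))
        log_handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
        logging.getLogger("birads_cad").addHandler(log_handler)

    if table is None:
        logger.info("stage cohort: generating %d phantoms", config.n_cases)
        cohort = make_cohort(config.n_cases, radius_px=config.radius_px, seed=config.seed)
        logger.info("stage segment+extract")
        table = build_feature_table(cohort, config.n_thresholds)

    keep_ids = _family_ids(config.families)
    cols = ["case_id", "label"] + [feature_column(fid) for fid in keep_ids]
    table = table[[c for c in cols if c in table.columns]]

    logger.info("stage split: 60/40 stratified")
    split = SplitSpec(train_fraction=config.train_fraction, seed=config.seed)
    train_tbl, test_tbl = stratified_split(table, split)

    logger.info("stage normalize: min-max fitted on the training split")
    scaler = fit_scaler(train_tbl)
    train_tbl = apply_scaler(scaler, train_tbl)
    test_tbl = apply_scaler(scaler, test_tbl)

    # GA works on positional ids 1..F over the retained columns
    position_to_fid = {pos + 1: fid for pos, fid in enumerate(keep_ids)}
    renamed_train = _positional(train_tbl, keep_ids)
    fitness_cfg = BPNConfig(
        solver=config.fitness_solver, epochs=config.fitness_epochs, seed=config.seed
    )
    fitness = make_fitness(renamed_train, fitness_cfg)

    logger.info("stage select: GA sweep L=%d..%d", config.ga_lmin, config.ga_lmax)
    schedule = lambda L: GAConfig(
        L=L,
        population_base=config.ga_population_base,
        max_generations=config.ga_max_generations,
        stagnation_x=config.ga_stagnation,
        n_features=len(keep_ids),
        seed=config.seed + L,
    )
    result = sweep(
        fitness,
        F=len(keep_ids),
        cfg_schedule=schedule,
        lmin=config.ga_lmin,
        lmax=config.ga_lmax,
        seed=config.seed,
    )
    selected = tuple(sorted(position_to_fid[p] for p in result.global_best.genes))
    logger.info("selected subset (ids): %s", selected)

    logger.info("stage train/evaluate")
    bpn_cfg = BPNConfig(
        solver=config.bpn_solver,
        epochs=config.bpn_epochs,
        learning_rate=config.bpn_learning_rate,
        patience=config.bpn_patience,
        seed=config.seed,
    )
    model = train(train_tbl, selected, bpn_cfg)
    report = evaluate(test_tbl["label"].to_numpy(), predict(model, test_tbl))

    run_report = {
        "package_version": __version__,
        "config": dataclasses.asdict(config),
        "selected_feature_ids": list(selected),
        "selected_fitness": result.global_best.fitness,
        "sweep": json.loads(result.to_json()),
        "metrics": report.to_dict(),
    }
    if config.outdir:
        os.makedirs(config.outdir, exist_ok=True)
        with open(os.path.join(config.outdir, "run_report.json"), "w") as fh:
            json.dump(run_report, fh, indent=2)
        result.to_json(os.path.join(config.outdir, "sweep.json"))
        report.to_json(os.path.join(config.outdir, "metrics.json"))
        report.confusion_matrix.to_csv(os.path.join(config.outdir, "confusion.csv"))
    if log_handler is not None:
        logging.getLogger("birads_cad").removeHandler(log_handler)
        log_handler.close()
    return run_report


def _positional(table: pd.DataFrame, keep_ids: list[int]) -> pd.DataFrame:
    """Relabel feature columns to consecutive positional ids 1..F."""
    mapping = {
        feature_column(fid): feature_column(pos + 1) for pos, fid in enumerate(keep_ids)
    }
    return table.rename(columns=mapping)
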