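"""End-to-end study orchestration.

``run_study`` executes the full protocol for each configured subsite:
obtain a cohort (synthetic, image manifest, or pre-extracted feature
CSV), extract un-normalized and normalized ROI features, make one shared
stratified 75/25 split, fit LDA and QDA on each feature branch, and
collect confusion tables, metric reports, decision grids and
one-vs-rest / macro-average ROC curves into a :class:`ReportBundle`.
``render_report`` writes the bundle as CSV/JSON (and optional PNG)
artifacts plus a human-readable summary.

The normalized and un-normalized branches share split indices so their
comparison is paired rather than confounded by partition noise.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import yaml
from PIL import Image as PILImage

from . import __version__
from .discriminant import DecisionGrid, GaussianDiscriminant, GaussianDiscriminantResults
from .evaluation import (
    ConfusionTable,
    MetricsReport,
    ROCCurve,
    confusion_table,
    macro_average_roc,
    metrics_from_confusion,
    roc_ovr,
    stratified_split,
)
from .exceptions import SchemaError, VelquantError
from .roi import CircleROI, ExtractionConfig, extract_features
from .synthetic import CohortConfig, CohortImage, gen_cohort

logger = logging.getLogger("velquant.pipeline")

FEATURE_COLUMNS = ("id", "subsite", "label", "mu_roi", "sd_roi", "mu_norm", "sd_norm")

_BRANCH_COLS = {
    "unnormalized": ("mu_roi", "sd_roi"),
    "normalized": ("mu_norm", "sd_norm"),
}


@dataclass
class RunConfig:
    """Configuration of one full study run.

    ``mode`` selects the input source: a synthetic cohort, an image
    manifest directory, or a pre-extracted feature CSV.  ``seed`` must be
    set explicitly — there is no wall-clock default.
    """

    seed: int
    mode: str = "synthetic_cohort"  # synthetic_cohort | image_manifest | feature_csv
    cohort: CohortConfig = field(default_factory=CohortConfig)
    manifest_path: Optional[str] = None
    feature_csv_path: Optional[str] = None
    subsites: Tuple[str, ...] = ("tongue", "buccal")
    channel: str = "luma"
    reference: str = "whole"
    on_degenerate: str = "error"
    train_fraction: float = 0.75
    k_folds: int = 2
    classifiers: Tuple[str, ...] = ("lda", "qda")
    regularization: float = 0.0
    grid_resolution: int = 120
    outdir: Optional[str] = None

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if self.mode not in ("synthetic_cohort", "image_manifest", "feature_csv"):
            raise ValueError(f"unknown mode {self.mode!r}")

    @property
    def extraction(self) -> ExtractionConfig:
        return ExtractionConfig(
            channel=self.channel,  # type: ignore[arg-type]
            reference=self.reference,  # type: ignore[arg-type]
            on_degenerate=self.on_degenerate,  # type: ignore[arg-type]
        )

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if "cohort" in data and isinstance(data["cohort"], dict):
            cohort_data = data.pop("cohort")
            cfg = CohortConfig()
            for key, value in cohort_data.items():
                setattr(cfg, key, value)
            data["cohort"] = cfg
        for key in ("subsites", "classifiers"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


# ---------------------------------------------------------------------------
# Feature I/O
# ---------------------------------------------------------------------------


def extract_cohort_features(
    cohort: Sequence[CohortImage],
    config: ExtractionConfig = ExtractionConfig(),
) -> pd.DataFrame:
    """Extract the feature table from in-memory cohort images.

    Returns one row per image with columns
    ``id, subsite, label, mu_roi, sd_roi, mu_norm, sd_norm`` (normalized
    columns are NaN for images skipped under ``on_degenerate="skip"``).
    """
    rows = []
    for item in cohort:
        unnorm, norm = extract_features(
            item.image, item.roi, config, subsite=item.subsite, label=item.label
        )
        rows.append(
            {
                "id": item.image_id,
                "subsite": item.subsite,
                "label": item.label,
                "mu_roi": unnorm.intensity,
                "sd_roi": unnorm.sd,
                "mu_norm": norm.intensity if norm is not None else np.nan,
                "sd_norm": norm.sd if norm is not None else np.nan,
            }
        )
    return pd.DataFrame(rows, columns=list(FEATURE_COLUMNS))


def extract_manifest_features(
    manifest_path: Union[str, Path],
    config: ExtractionConfig = ExtractionConfig(),
) -> pd.DataFrame:
    """Extract features for every image listed in a cohort manifest CSV.

    The manifest needs columns ``path, subsite, class, roi_cx, roi_cy,
    roi_r``; image paths are resolved relative to the manifest location.
    """
    manifest_path = Path(manifest_path)
    manifest = pd.read_csv(manifest_path)
    required = {"path", "subsite", "class", "roi_cx", "roi_cy", "roi_r"}
    missing = required - set(manifest.columns)
    if missing:
        raise SchemaError(f"manifest is missing columns {sorted(missing)}")
    base = manifest_path.parent
    rows = []
    for _, rec in manifest.iterrows():
        image = np.asarray(PILImage.open(base / rec["path"]).convert("RGB"))
        roi = CircleROI(rec["roi_cx"], rec["roi_cy"], rec["roi_r"])
        unnorm, norm = extract_features(
            image, roi, config, subsite=rec["subsite"], label=rec["class"]
        )
        rows.append(
            {
                "id": Path(rec["path"]).stem,
                "subsite": rec["subsite"],
                "label": rec["class"],
                "mu_roi": unnorm.intensity,
                "sd_roi": unnorm.sd,
                "mu_norm": norm.intensity if norm is not None else np.nan,
                "sd_norm": norm.sd if norm is not None else np.nan,
            }
        )
    return pd.DataFrame(rows, columns=list(FEATURE_COLUMNS))


def load_feature_csv(path: Union[str, Path]) -> pd.DataFrame:
    """Load and validate a feature table CSV.

    Requires a ``label`` column and at least one complete feature pair
    (``mu_roi``/``sd_roi`` or ``mu_norm``/``sd_norm``); rows with a
    missing label are rejected with their line numbers.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path} is empty") from exc
    if df.empty:
        raise SchemaError(f"{path} contains no data rows")
    if "label" not in df.columns:
        raise SchemaError(f"{path} has no 'label' column")
    has_unnorm = {"mu_roi", "sd_roi"} <= set(df.columns)
    has_norm = {"mu_norm", "sd_norm"} <= set(df.columns)
    if not (has_unnorm or has_norm):
        raise SchemaError(
            f"{path} needs (mu_roi, sd_roi) and/or (mu_norm, sd_norm) columns"
        )
    bad = df.index[df["label"].isna() | (df["label"].astype(str).str.len() == 0)]
    if len(bad):
        lines = [int(i) + 2 for i in bad]  # +1 header, +1 one-based
        raise SchemaError(f"{path} has rows with missing label at lines {lines}")
    if "subsite" not in df.columns:
        df["subsite"] = "tongue"
    return df


def load_feature_xlsx(
    path: Union[str, Path],
    subsite: str,
    normalized: bool,
    sheet: Union[int, str] = 0,
) -> pd.DataFrame:
    """Load a supplementary-style XLSX feature table into the CSV schema.

    Expects the first three columns to be (intensity, sd, label) or to be
    named so that intensity/sd/label can be identified case-insensitively.
    """
    raw = pd.read_excel(path, sheet_name=sheet)
    cols = {str(c).strip().lower(): c for c in raw.columns}

    def find(*names):
        for name in names:
            if name in cols:
                return cols[name]
        return None

    c_int = find("intensity", "mu", "mean", "mu_roi", "mu_norm")
    c_sd = find("sd", "std", "sigma", "sd_roi", "sd_norm")
    c_lab = find("label", "class", "group")
    if c_int is None or c_sd is None or c_lab is None:
        if raw.shape[1] < 3:
            raise SchemaError(f"{path} does not look like a feature table")
        c_int, c_sd, c_lab = raw.columns[:3]
    mu_col, sd_col = ("mu_norm", "sd_norm") if normalized else ("mu_roi", "sd_roi")
    df = pd.DataFrame(
        {
            "id": [f"{subsite}_{i:03d}" for i in range(len(raw))],
            "subsite": subsite,
            "label": raw[c_lab].astype(str),
            mu_col: pd.to_numeric(raw[c_int]),
            sd_col: pd.to_numeric(raw[c_sd]),
        }
    )
    return df


# ---------------------------------------------------------------------------
# Report bundle
# ---------------------------------------------------------------------------


@dataclass
class ReportBundle:
    """Everything one study run produced.

    ``entries`` is keyed ``subsite/normalization/classifier/partition``
    and holds confusion table + metric report; ``grids`` is keyed
    ``subsite/normalization/classifier``; ``rocs`` is keyed
    ``subsite/normalization/classifier`` and maps class label (plus
    ``macro``) to an ROC curve.
    """

    entries: Dict[str, Dict[str, object]] = field(default_factory=dict)
    grids: Dict[str, DecisionGrid] = field(default_factory=dict)
    rocs: Dict[str, Dict[str, ROCCurve]] = field(default_factory=dict)
    models: Dict[str, GaussianDiscriminantResults] = field(default_factory=dict)
    manifest: Dict[str, object] = field(default_factory=dict)

    def metrics(self, subsite: str, norm: str, clf: str, part: str) -> MetricsReport:
        return self.entries[f"{subsite}/{norm}/{clf}/{part}"]["metrics"]  # type: ignore[return-value]

    def confusion(self, subsite: str, norm: str, clf: str, part: str) -> ConfusionTable:
        return self.entries[f"{subsite}/{norm}/{clf}/{part}"]["confusion"]  # type: ignore[return-value]


def run_study(config: RunConfig) -> ReportBundle:
    """Execute the full study protocol for every configured subsite."""
    rng = np.random.default_rng(config.seed)
    split_seed = int(rng.integers(0, 2**31 - 1))
    cohort_seed = int(rng.integers(0, 2**31 - 1))

    if config.mode == "synthetic_cohort":
        cohort, _ = gen_cohort(config.cohort, cohort_seed)
        features = extract_cohort_features(cohort, config.extraction)
    elif config.mode == "image_manifest":
        if not config.manifest_path:
            raise VelquantError("image_manifest mode needs manifest_path")
        features = extract_manifest_features(config.manifest_path, config.extraction)
    else:
        if not config.feature_csv_path:
            raise VelquantError("feature_csv mode needs feature_csv_path")
        features = load_feature_csv(config.feature_csv_path)

    bundle = ReportBundle(
        manifest={
            "seed": config.seed,
            "mode": config.mode,
            "subsites": list(config.subsites),
            "train_fraction": config.train_fraction,
            "channel": config.channel,
            "reference": config.reference,
            "classifiers": list(config.classifiers),
            "regularization": config.regularization,
            "version": __version__,
        }
    )

    branches = [
        b for b, (mc, sc) in _BRANCH_COLS.items()
        if {mc, sc} <= set(features.columns)
        and not features[[mc, sc]].isna().any().any()
    ]
    for subsite in config.subsites:
        sub = features[features["subsite"] == subsite].reset_index(drop=True)
        if sub.empty:
            logger.warning("subsite %s: no samples, skipped", subsite)
            continue
        logger.info(
            "subsite %s: %d samples (%s)", subsite, len(sub),
            sub["label"].value_counts().to_dict(),
        )
        train_df, test_df = stratified_split(
            sub, config.train_fraction, split_seed, label_col="label"
        )
        logger.info(
            "subsite %s: split %d train / %d test", subsite, len(train_df), len(test_df)
        )
        for norm in branches:
            cols = list(_BRANCH_COLS[norm])
            model = GaussianDiscriminant(
                train_df[cols].to_numpy(), train_df["label"].to_numpy()
            )
            res = model.fit(regularization=config.regularization)
            for clf in config.classifiers:
                bundle.models[f"{subsite}/{norm}/{clf}"] = res
                for part, part_df in (("training", train_df), ("testing", test_df)):
                    pred = res.predict(part_df[cols].to_numpy(), mode=clf)
                    table = confusion_table(
                        part_df["label"].to_numpy(), pred, res.classes
                    )
                    bundle.entries[f"{subsite}/{norm}/{clf}/{part}"] = {
                        "confusion": table,
                        "metrics": metrics_from_confusion(table),
                    }
                bundle.grids[f"{subsite}/{norm}/{clf}"] = res.decision_grid(
                    resolution=config.grid_resolution, mode=clf
                )
                post = res.posterior(test_df[cols].to_numpy(), mode=clf)
                curves: Dict[str, ROCCurve] = {}
                for cls_label in res.classes:
                    curves[cls_label] = roc_ovr(
                        test_df["label"].to_numpy(), post, cls_label,
                        class_order=res.classes, mode=clf,
                    )
                curves["macro"] = macro_average_roc(
                    [curves[c] for c in res.classes]
                )
                bundle.rocs[f"{subsite}/{norm}/{clf}"] = curves
    return bundle


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------


def _summary_block(key: str, metrics: MetricsReport) -> List[str]:
    lines = [key, f"{'':>6} {'Precision':>10} {'Recall':>10} {'f1-score':>10}"]
    for c in metrics.classes:
        m = metrics.per_class[c]
        lines.append(f"{c:>6} {m.precision:>10.2f} {m.recall:>10.2f} {m.f1:>10.2f}")
    lines.append(
        f"{'macro':>6} {metrics.macro_precision:>10.2f} "
        f"{metrics.macro_recall:>10.2f} {metrics.macro_f1:>10.2f}"
    )
    lines.append(
        f"{'wavg':>6} {metrics.weighted_precision:>10.2f} "
        f"{metrics.weighted_recall:>10.2f} {metrics.weighted_f1:>10.2f}"
    )
    lines.append(f"accuracy: {metrics.accuracy:.4f} ({metrics.total} samples)")
    lines.append("")
    return lines


def render_report(
    bundle: ReportBundle, outdir: Union[str, Path], png: bool = False
) -> List[Path]:
    """Write the bundle as files; returns the paths written.

    Output is deterministic (no timestamps): re-rendering an identical
    bundle produces identical bytes.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written: List[Path] = []

    def _emit(path: Path) -> None:
        written.append(path)

    summary_lines: List[str] = []
    for key in sorted(bundle.entries):
        entry = bundle.entries[key]
        stem = key.replace("/", "_")
        cpath = out / f"confusion_{stem}.csv"
        entry["confusion"].to_csv(cpath)  # type: ignore[union-attr]
        _emit(cpath)
        mpath = out / f"metrics_{stem}.json"
        entry["metrics"].to_json(mpath)  # type: ignore[union-attr]
        _emit(mpath)
        summary_lines.extend(_summary_block(key, entry["metrics"]))  # type: ignore[arg-type]

    for key in sorted(bundle.grids):
        grid = bundle.grids[key]
        stem = key.replace("/", "_")
        gpath = out / f"grid_{stem}.csv"
        grid.to_dataframe().to_csv(gpath, index=False)
        _emit(gpath)
        if png:
            import matplotlib

            matplotlib.use("Agg")
            import matplotlib.pyplot as plt

            ax = grid.plot()
            ppath = out / f"grid_{stem}.png"
            ax.figure.savefig(ppath, dpi=100)
            plt.close(ax.figure)
            _emit(ppath)

    auc_summary: Dict[str, Dict[str, float]] = {}
    for key in sorted(bundle.rocs):
        stem = key.replace("/", "_")
        auc_summary[key] = {}
        for label, curve in bundle.rocs[key].items():
            rpath = out / f"roc_{stem}_{label}.csv"
            curve.to_dataframe().to_csv(rpath, index=False)
            _emit(rpath)
            auc_summary[key][label] = curve.auc
    if auc_summary:
        apath = out / "auc_summary.json"
        apath.write_text(json.dumps(auc_summary, indent=2, sort_keys=True))
        _emit(apath)

    mpath = out / "run_manifest.json"
    mpath.write_text(json.dumps(bundle.manifest, indent=2, sort_keys=True))
    _emit(mpath)

    spath = out / "summary.txt"
    spath.write_text("\n".join(summary_lines))
    _emit(spath)
    return written
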