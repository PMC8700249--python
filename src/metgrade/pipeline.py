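"""End-to-end orchestration: phantom -> segment -> extract -> select -> evaluate.

A run produces, under one output directory: the phantom volumes and
manifest (unless an existing manifest is supplied), the segmentation masks,
the 2n x 44 feature table, a selection report and an evaluation report per
(patient group, segmentation kind) pair — three groups (all patients plus
the two scanner subgroups) times two segmentations, mirroring the study's
reporting structure — and a run manifest with the config echo, its hash and
the seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .discretization import BinningConfig
from .evaluation import CvConfig, EvaluationReport, evaluate
from .features.table import build_feature_table, manifest_box
from .phantom import CohortSpec, generate_cohort, make_default_profiles
from .segmentation import SegmentationParams, fixed_roi, threshold_voi
from .selection import sequential_select
from .volume import read_volume, write_mask

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]

MASK_KINDS = ("threshold_voi", "fixed_roi")


@dataclass
class PipelineConfig:
    """Schema-validated configuration of a full run."""

    cohort: CohortSpec = field(default_factory=CohortSpec)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    binning: BinningConfig = field(default_factory=BinningConfig)
    cv: CvConfig = field(default_factory=CvConfig)
    selection_mode: str = "cumulative"
    nested_selection: bool = True
    groups: tuple[str, ...] = ("all", "scanner_a", "scanner_b")
    manifest_path: str | None = None  # reuse an existing cohort instead of generating
    write_masks: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        def build(klass, key):
            section = raw.get(key, {})
            names = {f.name for f in dataclasses.fields(klass)}
            unknown = set(section) - names
            if unknown:
                raise ValueError(f"unknown {key} config keys: {sorted(unknown)}")
            coerced = {
                k: tuple(v) if isinstance(v, list) else v for k, v in section.items()
            }
            return klass(**coerced)

        cfg = cls(
            cohort=build(CohortSpec, "cohort"),
            segmentation=build(SegmentationParams, "segmentation"),
            binning=build(BinningConfig, "binning"),
            cv=build(CvConfig, "cv"),
        )
        for key in ("selection_mode", "nested_selection", "manifest_path", "write_masks"):
            if key in raw:
                setattr(cfg, key, raw[key])
        if "groups" in raw:
            cfg.groups = tuple(raw["groups"])
        return cfg

    def to_dict(self) -> dict:
        return {
            "cohort": dataclasses.asdict(self.cohort),
            "segmentation": dataclasses.asdict(self.segmentation),
            "binning": dataclasses.asdict(self.binning),
            "cv": dataclasses.asdict(self.cv),
            "selection_mode": self.selection_mode,
            "nested_selection": self.nested_selection,
            "groups": list(self.groups),
            "manifest_path": self.manifest_path,
            "write_masks": self.write_masks,
        }

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _write_group_masks(
    manifest: pd.DataFrame, root: Path, params: SegmentationParams, mask_dir: Path
) -> None:
    mask_dir.mkdir(parents=True, exist_ok=True)
    for _, row in manifest.iterrows():
        vol = read_volume(root / row["volume_path"])
        box = manifest_box(row)
        for kind, fn in (("threshold_voi", threshold_voi), ("fixed_roi", fixed_roi)):
            mask = fn(vol, box, params)
            write_mask(mask, vol, mask_dir / f"{row['patient_id']}_{kind}.nii.gz")


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict[str, EvaluationReport]:
    """Execute the full workflow; returns reports keyed by ``group/kind``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    warnings: list[str] = []

    if config.manifest_path:
        manifest = pd.read_csv(config.manifest_path)
        root = Path(config.manifest_path).parent
        logger.info("stage phantom: skipped, using %s", config.manifest_path)
    else:
        logger.info("stage phantom: generating %d patients", config.cohort.n_patients)
        manifest = generate_cohort(config.cohort, out)
        root = out

    if config.write_masks:
        logger.info("stage segment: writing masks")
        _write_group_masks(manifest, root, config.segmentation, out / "masks")

    logger.info("stage extract: building feature table")
    table = build_feature_table(
        manifest, root, seg_params=config.segmentation, binning=config.binning
    )
    table.to_csv(out / "features.csv", index=False)

    from .features.panel import FEATURE_NAMES

    reports: dict[str, EvaluationReport] = {}
    report_dir = out / "reports"
    report_dir.mkdir(exist_ok=True)
    for group in config.groups:
        sub = table if group == "all" else table[table["scanner"] == group]
        if sub.empty:
            raise ValueError(f"group {group!r} selects no rows")
        for kind in MASK_KINDS:
            rows = sub[sub["mask_kind"] == kind].reset_index(drop=True)
            key = f"{group}/{kind}"
            logger.info("stage select+evaluate: %s (%d studies)", key, len(rows))
            sel = sequential_select(
                rows[list(FEATURE_NAMES)], rows["grade"].to_numpy(), mode=config.selection_mode
            )
            report = evaluate(
                rows,
                None if config.nested_selection else sel.selected,
                config.cv,
                selection_mode=config.selection_mode,
                nested_selection=config.nested_selection,
            )
            warnings.extend(f"{key}: {w}" for w in sel.warnings + report.warnings)
            reports[key] = report
            stem = report_dir / f"{group}_{kind}"
            with open(f"{stem}_selection.json", "w") as fh:
                json.dump(sel.to_dict(), fh, indent=2)
            with open(f"{stem}_evaluation.json", "w") as fh:
                json.dump(report.to_dict(), fh, indent=2)
            with open(f"{stem}_evaluation.txt", "w") as fh:
                fh.write(report.summary() + "\n")

    run_info = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.cohort.seed,
        "n_patients": int(manifest.shape[0]),
        "reports": sorted(reports),
        "warnings": warnings,
    }
    with open(out / "run.json", "w") as fh:
        json.dump(run_info, fh, indent=2)
    return reports
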