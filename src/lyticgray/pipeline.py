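"""Study orchestration: manifest -> ROI features -> group statistics.

Mirrors the five-step radiographic workflow: image acquisition, ROI
selection, anisotropic-diffusion noise filtering, gray-level histogram
parameters, and statistical comparison of the pathology groups stratified
by bone class.  A run is driven by a :class:`StudyConfig` (loadable from a
flat key=value file) and produces a :class:`StudyReport` whose tables are
written as CSV: per-ROI features, per-stratum descriptives, MM-vs-OL mean
comparisons, and ROC/AUC diagnostics with exportable curve points.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .diffusion import Conductance, DiffusionParams, anisotropic_diffusion
from .features import compute_gray_features
from .imaging import (BoneClass, Group, MissingImageError, ROIRecord,
                      extract_roi, load_roi_manifest, read_image)
from .stats import descriptive_stats, empirical_auc, roc_curve_points, two_sample_t

__all__ = ["StudyConfig", "StudyReport", "run_study", "write_report", "load_config"]

PARAMETERS = ("mgl", "sdgl", "cvgl")

log = logging.getLogger("lyticgray")


@dataclass(frozen=True)
class StudyConfig:
    """Configuration of one analysis run (single source of truth)."""

    manifest_path: str
    output_dir: str = "study_out"
    diffusion_enabled: bool = True
    diffusion: DiffusionParams = field(default_factory=DiffusionParams)
    sd_denominator: str = "n_minus_1"   # or "n"
    t_test: str = "pooled"              # or "welch"
    positive_class: Group = Group.OL
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sd_denominator not in ("n_minus_1", "n"):
            raise ValueError("sd_denominator must be 'n_minus_1' or 'n'")
        if self.t_test not in ("pooled", "welch"):
            raise ValueError("t_test must be 'pooled' or 'welch'")
        object.__setattr__(self, "positive_class", Group(self.positive_class))

    def to_flat_dict(self) -> dict[str, str]:
        return {
            "manifest": self.manifest_path,
            "output_dir": self.output_dir,
            "diffusion.enabled": str(self.diffusion_enabled).lower(),
            "diffusion.iterations": str(self.diffusion.iterations),
            "diffusion.kappa": repr(self.diffusion.kappa),
            "diffusion.lambda": repr(self.diffusion.lam),
            "diffusion.conductance": self.diffusion.variant.value,
            "sd_denominator": self.sd_denominator,
            "t_test": self.t_test,
            "positive_class": self.positive_class.value,
            "seed": str(self.seed),
        }

    def config_hash(self) -> str:
        blob = "\n".join(f"{k}={v}" for k, v in sorted(self.to_flat_dict().items()))
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_config(path: str | Path) -> StudyConfig:
    """Parse a flat ``key = value`` config file ('#' starts a comment)."""
    kv: dict[str, str] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"config line {lineno}: expected 'key = value', got {raw!r}")
        k, v = (s.strip() for s in line.split("=", 1))
        kv[k] = v
    if "manifest" not in kv:
        raise ValueError("config must set 'manifest'")
    diff = DiffusionParams(
        iterations=int(kv.get("diffusion.iterations", 10)),
        kappa=float(kv.get("diffusion.kappa", 30.0)),
        lam=float(kv.get("diffusion.lambda", 0.25)),
        variant=Conductance(kv.get("diffusion.conductance", "exponential")),
    )
    return StudyConfig(
        manifest_path=kv["manifest"],
        output_dir=kv.get("output_dir", "study_out"),
        diffusion_enabled=kv.get("diffusion.enabled", "true").lower() in ("1", "true", "yes"),
        diffusion=diff,
        sd_denominator=kv.get("sd_denominator", "n_minus_1"),
        t_test=kv.get("t_test", "pooled"),
        positive_class=Group(kv.get("positive_class", "OL")),
        seed=int(kv.get("seed", 0)),
    )


@dataclass
class StudyReport:
    per_roi_features: pd.DataFrame   # case_id, group, bone_class, stratum, mgl, sdgl, cvgl
    descriptives: pd.DataFrame       # parameter, stratum, n, mean, st_dev, min, max
    comparisons: pd.DataFrame        # parameter, bone_class, t_stat, df, p_value
    roc: pd.DataFrame                # parameter, bone_class, auc, se, p_value, n_pos, n_neg
    roc_points: dict[tuple[str, str], np.ndarray]  # (bone_class, parameter) -> (fpr, tpr) rows
    provenance: dict
    warnings: list[str]


def stratum_label(group: Group, bone_class: BoneClass) -> str:
    """Published stratum code: suffix 1 = nonflat bone, 2 = flat bone."""
    return f"{group.value}{1 if bone_class is BoneClass.NONFLAT else 2}"


def _roi_feature_row(record: ROIRecord, config: StudyConfig, manifest_dir: Path) -> dict:
    img_path = Path(record.image_path)
    if not img_path.is_absolute():
        img_path = manifest_dir / img_path
    image = read_image(img_path)
    roi = extract_roi(image, record.roi)
    values = roi.pixels.astype(float)
    if config.diffusion_enabled:
        values = anisotropic_diffusion(values, config.diffusion)
    ddof = 1 if config.sd_denominator == "n_minus_1" else 0
    feats = compute_gray_features(values, ddof=ddof)
    return {
        "case_id": record.case_id,
        "group": record.group.value,
        "bone_class": record.bone_class.value,
        "stratum": stratum_label(record.group, record.bone_class),
        "mgl": feats.mgl,
        "sdgl": feats.sdgl,
        "cvgl": feats.cvgl,
    }


def run_study(config: StudyConfig) -> StudyReport:
    """Execute ROI extraction, filtering, features and statistics.

    Deterministic for fixed inputs and config; output tables are sorted so
    the report is invariant to manifest row order.  All missing images are
    listed before aborting; a bone-class stratum containing a single
    pathology group is skipped from the comparisons with a warning.
    """
    manifest_dir = Path(config.manifest_path).resolve().parent
    records = load_roi_manifest(config.manifest_path)
    missing = [r.image_path for r in records
               if not (Path(r.image_path) if Path(r.image_path).is_absolute()
                       else manifest_dir / r.image_path).exists()]
    if missing:
        raise MissingImageError(
            f"{len(missing)} manifest image(s) not found: " + ", ".join(sorted(missing))
        )

    rows = [_roi_feature_row(r, config, manifest_dir) for r in records]
    features = pd.DataFrame(rows).sort_values("case_id", kind="stable").reset_index(drop=True)

    desc_rows = []
    for param in PARAMETERS:
        for stratum in ("MM1", "OL1", "MM2", "OL2"):
            vals = features.loc[features["stratum"] == stratum, param].to_numpy()
            if vals.size == 0:
                continue
            d = descriptive_stats(vals)
            desc_rows.append({"parameter": param, "stratum": stratum, "n": d.n,
                              "mean": d.mean, "st_dev": d.st_dev, "min": d.min, "max": d.max})
    descriptives = pd.DataFrame(desc_rows)

    warnings: list[str] = []
    comp_rows, roc_rows = [], []
    roc_points: dict[tuple[str, str], np.ndarray] = {}
    pos_group = config.positive_class
    neg_group = Group.MM if pos_group is Group.OL else Group.OL
    for bone in (BoneClass.NONFLAT, BoneClass.FLAT):
        sub = features[features["bone_class"] == bone.value]
        n_pos = int((sub["group"] == pos_group.value).sum())
        n_neg = int((sub["group"] == neg_group.value).sum())
        if n_pos < 2 or n_neg < 2:
            msg = (f"stratum {bone.value}: needs both groups with n >= 2 "
                   f"(got {pos_group.value}={n_pos}, {neg_group.value}={n_neg}); skipped")
            warnings.append(msg)
            log.warning(msg)
            continue
        for param in PARAMETERS:
            pos = sub.loc[sub["group"] == pos_group.value, param].to_numpy()
            neg = sub.loc[sub["group"] == neg_group.value, param].to_numpy()
            t = two_sample_t(neg, pos, pooled=(config.t_test == "pooled"))
            comp_rows.append({"parameter": param, "bone_class": bone.value,
                              "t_stat": t.t_stat, "df": t.df, "p_value": t.p_value})
            r = empirical_auc(pos, neg)
            roc_rows.append({"parameter": param, "bone_class": bone.value,
                             "auc": r.auc, "se": r.se, "p_value": r.p_value,
                             "n_pos": r.n_pos, "n_neg": r.n_neg})
            roc_points[(bone.value, param)] = roc_curve_points(pos, neg)
    comparisons = pd.DataFrame(comp_rows)
    roc = pd.DataFrame(roc_rows)

    provenance = {
        "config": config.to_flat_dict(),
        "config_hash": config.config_hash(),
        "version": __version__,
        "n_records": len(records),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    return StudyReport(per_roi_features=features, descriptives=descriptives,
                       comparisons=comparisons, roc=roc, roc_points=roc_points,
                       provenance=provenance, warnings=warnings)


def write_report(report: StudyReport, output_dir: str | Path) -> Path:
    """Write the report tables as CSV plus run.log; returns the directory.

    Re-running on identical input and config overwrites the CSVs
    byte-identically (run.log carries the config hash and per-ROI record,
    not a wall-clock time, for the same reason).
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.per_roi_features.to_csv(out / "features.csv", index=False)
    report.descriptives.to_csv(out / "descriptives.csv", index=False)
    report.comparisons.to_csv(out / "comparisons.csv", index=False)
    report.roc.to_csv(out / "roc.csv", index=False)
    for (bone, param), pts in report.roc_points.items():
        pd.DataFrame(pts, columns=["fpr", "tpr"]).to_csv(
            out / f"roc_points_{bone}_{param}.csv", index=False)
    lines = [f"lyticgray {report.provenance['version']}",
             f"config_hash {report.provenance['config_hash']}"]
    lines += [f"config {k} = {v}" for k, v in sorted(report.provenance["config"].items())]
    lines += [f"warning {w}" for w in report.warnings]
    lines += [f"roi {r.case_id} {r.stratum} mgl={r.mgl:.6f} sdgl={r.sdgl:.6f} cvgl={r.cvgl:.6f}"
              for r in report.per_roi_features.itertuples()]
    (out / "run.log").write_text("\n".join(lines) + "\n", encoding="utf-8")
    return out
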