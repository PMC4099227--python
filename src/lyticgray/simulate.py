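"""End-to-end synthetic study emitter.

Renders one phantom radiograph per synthetic case (four strata calibrated
to the published group statistics), writes the images as 16-bit TIFF, the
ROI manifest CSV consumed by the pipeline, and a ground-truth parameter
CSV for validation.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .imaging import ROIRecord, write_image, write_roi_manifest
from .synthetic import (GroupDistributionParams, SceneConfig, derive_seed,
                        generate_group_cases, scene_for_case,
                        generate_radiograph_scene, study_presets)

__all__ = ["simulate_study"]


def simulate_study(out_dir: str | Path, seed: int,
                   presets: dict[str, GroupDistributionParams] | None = None,
                   base_scene: SceneConfig | None = None) -> Path:
    """Generate a complete synthetic study under ``out_dir``.

    Produces ``images/<case_id>.tif`` phantom radiographs, ``manifest.csv``
    (one 40x50 lesion-centered ROI per case), and ``ground_truth.csv`` with
    each case's generative (mgl, sdgl, cvgl).  Pure function of
    (presets, seed): identical inputs reproduce identical files.
    """
    presets = presets or study_presets()
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    records: list[ROIRecord] = []
    truth_rows = []
    for label in sorted(presets):
        params = presets[label]
        cases = generate_group_cases(params, seed)
        for i, (mgl, sdgl, cvgl) in enumerate(cases):
            case_id = f"{label}_{i:03d}"
            scene = scene_for_case(mgl, sdgl, derive_seed(seed, label, i), base=base_scene)
            image, roi = generate_radiograph_scene(scene)
            rel = f"images/{case_id}.tif"
            write_image(image, out / rel)
            records.append(ROIRecord(image_path=rel, roi=roi, group=params.group,
                                     bone_class=params.bone_class, case_id=case_id))
            truth_rows.append({"case_id": case_id, "stratum": label,
                               "group": params.group.value,
                               "bone_class": params.bone_class.value,
                               "mgl": mgl, "sdgl": sdgl, "cvgl": cvgl})
    write_roi_manifest(records, out / "manifest.csv")
    pd.DataFrame(truth_rows).to_csv(out / "ground_truth.csv", index=False)
    return out
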