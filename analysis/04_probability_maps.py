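"""Map lesion masks to template space and build the PD maps and region table.

Resamples the ingested infarct masks and the derived WMH/lacune masks
through the estimated transforms, sums them into per-class probability
density maps (lacunes over affected subjects only), samples each atlas
structure with 2-voxel cubic ROIs, and writes the per-region table plus
subtraction-map overlap summaries under results/maps/.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import COHORT_DIR, MAPS_DIR, NORM_DIR, SEG_DIR, subject_ids

from svdmap.io import read_mask, read_transform, read_volume, write_pd_map
from svdmap.normalization import resample_mask
from svdmap.pdmap import default_roiset, pd_map, region_table, rounded_table, subtract_maps


def main() -> None:
    MAPS_DIR.mkdir(parents=True, exist_ok=True)
    template = read_volume(COHORT_DIR / "template_t1.nii.gz", "template")
    atlas = read_volume(COHORT_DIR / "atlas.nii.gz", "atlas")

    standard = {"infarct": [], "wmh": [], "lacune": []}
    for sid in subject_ids():
        transform = read_transform(NORM_DIR / f"{sid}_to_template.txt")
        sources = {
            "infarct": COHORT_DIR / f"{sid}_truth_infarct.nii.gz",
            "wmh": SEG_DIR / f"{sid}_wmh.nii.gz",
            "lacune": SEG_DIR / f"{sid}_lacune.nii.gz",
        }
        for cls, path in sources.items():
            mask = read_mask(path, cls, sid)
            standard[cls].append(resample_mask(mask, transform, template))

    maps = {
        "infarct": pd_map(standard["infarct"], "all"),
        "wmh": pd_map(standard["wmh"], "all"),
        "lacune": pd_map(standard["lacune"], "affected_only"),
    }
    for cls, m in maps.items():
        write_pd_map(m, MAPS_DIR / f"pd_{cls}.nii.gz")
        print(f"{cls}: denominator {m.n}, max PD {m.data.max():.3f}")

    table = region_table(maps, default_roiset(atlas))
    rounded_table(table).to_csv(MAPS_DIR / "region_table.csv", index=False)
    print("\nregional probability densities (3 decimals):")
    print(rounded_table(table).to_string(index=False))

    overlaps = {}
    for a, b in (("wmh", "infarct"), ("lacune", "infarct")):
        _, overlap = subtract_maps(maps[a], maps[b])
        overlaps[f"{a}_minus_{b}_overlap"] = overlap
        print(f"{a} vs {b}: support overlap fraction {overlap:.3f}")
    (MAPS_DIR / "overlap.json").write_text(json.dumps(overlaps, indent=2))


if __name__ == "__main__":
    main()
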