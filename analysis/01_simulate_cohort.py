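"""Generate the demo cohort: template, atlas and 12 misaligned subjects.

Writes per-subject FLAIR/T1 volumes, ground-truth lesion masks, brain
and ventricle masks, the true misalignment transforms and a cohort
manifest (volumetrics in ml) under results/cohort/.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import COHORT_DIR, LESION_SPEC, N_SUBJECTS, SEED, TEMPLATE_SPEC

from svdmap.image import LesionMask, VolumeImage
from svdmap.io import write_mask, write_transform, write_volume
from svdmap.synthetic import make_cohort, make_template


def main() -> None:
    COHORT_DIR.mkdir(parents=True, exist_ok=True)
    template, atlas = make_template(TEMPLATE_SPEC)
    write_volume(template, COHORT_DIR / "template_t1.nii.gz")
    write_volume(atlas, COHORT_DIR / "atlas.nii.gz")

    cohort = make_cohort(
        N_SUBJECTS, template, atlas, LESION_SPEC, seed=SEED, template_spec=TEMPLATE_SPEC
    )
    rows = []
    for s in cohort:
        write_volume(s.seq_flair, COHORT_DIR / f"{s.subject_id}_flair.nii.gz")
        write_volume(s.seq_t1, COHORT_DIR / f"{s.subject_id}_t1.nii.gz")
        for cls, mask in s.truth_masks.items():
            write_mask(mask, COHORT_DIR / f"{s.subject_id}_truth_{cls}.nii.gz")
        for name, arr in (("brain", s.brain_mask), ("ventricles", s.ventricle_mask)):
            write_mask(
                LesionMask(arr.astype(np.uint8), s.seq_flair.affine, lesion_class="wmh"),
                COHORT_DIR / f"{s.subject_id}_{name}.nii.gz",
            )
        write_transform(s.true_affine, COHORT_DIR / f"{s.subject_id}_true_affine.txt")
        icv, brain, vent, wmh = s.volumetrics
        rows.append(
            dict(
                subject_id=s.subject_id,
                icv_ml=icv,
                brain_ml=brain,
                ventricular_ml=vent,
                wmh_ml=wmh,
                has_lacune=not s.truth_masks["lacune"].is_empty(),
            )
        )
    table = pd.DataFrame(rows)
    table.to_csv(COHORT_DIR / "cohort.csv", index=False)

    n_lac = int(table.has_lacune.sum())
    print(f"wrote {N_SUBJECTS} subjects (seed {SEED}) to {COHORT_DIR}")
    print(f"lacunes present in {n_lac}/{N_SUBJECTS} subjects "
          f"(generator prevalence {LESION_SPEC.lacune_prevalence})")
    print("median volumetrics (ml):")
    print(table[["icv_ml", "brain_ml", "ventricular_ml", "wmh_ml"]].median().round(2).to_string())


if __name__ == "__main__":
    main()
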