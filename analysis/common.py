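"""Shared demo-cohort settings and result paths for the analysis scripts.

The scripts run in order (01 -> 05), each reading the previous step's
outputs from ``results/`` and writing its own. The demo cohort is 12
subjects on a 48^3 1-mm grid — small enough to run the whole chain in a
few minutes on one CPU while preserving the full analysis structure.
"""

from pathlib import Path

from svdmap.synthetic import LesionSpec, TemplateSpec

SEED = 7
N_SUBJECTS = 12
GRID = (48, 48, 48)

TEMPLATE_SPEC = TemplateSpec(grid_shape=GRID, seed=SEED)
LESION_SPEC = LesionSpec()

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
COHORT_DIR = RESULTS / "cohort"
SEG_DIR = RESULTS / "segmentation"
NORM_DIR = RESULTS / "normalization"
MAPS_DIR = RESULTS / "maps"
STATS_DIR = RESULTS / "stats"


def subject_ids():
    return [f"sub-{i + 1:03d}" for i in range(N_SUBJECTS)]
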