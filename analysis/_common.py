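"""Shared plumbing for the numbered analysis drivers.

The drivers analyze one reference synthetic resting-state study
(30 ROIs, 8-216 voxels each, 212 time points) whose population
consistency and connectivity are known in closed form, so every number
a driver prints can be compared against its expected value.
"""

from pathlib import Path

from roiconsist import read_4d_image, read_label_volume
from roiconsist.io import filter_low_power_voxels
from roiconsist.signal import detrend_linear
from roiconsist.synthetic import study_spec, write_dataset

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
DATA_DIR = RESULTS / "synthetic"
SEED = 0

# driver-level analysis sizes: between-ROI pairs are subsampled to this
# cap and the permutation null uses this many draws
PAIR_CAP = 200_000
N_PERMUTATIONS = 1000


def get_spec():
    return study_spec(seed=SEED)


def load_study(preprocess: bool = True):
    """Read the study from its NIfTI files, generating them if absent.

    Going through the files (rather than in-memory arrays) exercises the
    same I/O path a real dataset would take. Preprocessing applies the
    2% low-power voxel filter and linear detrending.
    """
    bold = DATA_DIR / "bold.nii.gz"
    if not bold.exists():
        write_dataset(get_spec(), DATA_DIR)
    vts = read_4d_image(bold)
    parc = read_label_volume(DATA_DIR / "labels.nii.gz", vts)
    if preprocess:
        vts, _ = filter_low_power_voxels(vts, fraction=0.02)
        vts = detrend_linear(vts)
    return vts, parc
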