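import numpy as np
import pandas as pd
import pytest

from refstab.core import CpMatrix


def make_cp(values, roles=None, plate=None, mask=None, samples=None, targets=None):
    """Build a small CpMatrix from a 2-D array (targets x samples)."""
    arr = np.asarray(values, dtype=float)
    targets = targets or [f"t{i + 1}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j + 1}" for j in range(arr.shape[1])]
    values = pd.DataFrame(arr, index=targets, columns=samples)
    if mask is None:
        mask = values.isna()
    else:
        mask = pd.DataFrame(np.asarray(mask, dtype=bool), index=targets, columns=samples)
    plate = plate or {s: "p1" for s in samples}
    return CpMatrix(values, mask, roles or {}, plate)


@pytest.fixture
def cp_factory():
    return make_cp


@pytest.fixture(scope="session")
def sim_cohort():
    """One default-scale synthetic cohort with a real prognostic effect."""
    from refstab.simulate import generate_study_cohort

    return generate_study_cohort(20260927, log_hazard_per_cp=np.log(0.5))


@pytest.fixture(scope="session")
def processed_cohort(sim_cohort):
    """The cohort after calibration, spike-in QC and LOD masking."""
    from refstab.missingness import mark_missing
    from refstab.qc import interplate_calibrate, spikein_qc

    m, ann, truth = sim_cohort
    calibrated, offsets = interplate_calibrate(m)
    report, clean = spikein_qc(calibrated, ipc_offsets=offsets)
    return mark_missing(clean), ann, truth


@pytest.fixture(scope="session")
def workflow_grid(processed_cohort):
    """The full 5 x 3 Cox scan on the processed cohort."""
    from refstab.survival import run_workflow_grid

    m, ann, _ = processed_cohort
    return run_workflow_grid(m, ann, seed=1, rf_trees=30)
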