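from __future__ import annotations

import numpy as np
import pytest

from strokeclock.phantom import BRISTOL, PhantomSpec, make_phantom
from strokeclock.qmaps import compute_quant_maps
from strokeclock.lesion_voi import build_voi_pair


@pytest.fixture(scope="session")
def default_spec() -> PhantomSpec:
    return PhantomSpec()


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    """Quarter-size head for fast pipeline tests."""
    return PhantomSpec(
        shape=(32, 32, 16),
        lesion_center_vox=(7.0, 15.5, 7.5),
        lesion_semiaxes_vox=(3.2, 2.8, 2.2),
    )


@pytest.fixture(scope="session")
def noiseless_patient(default_spec):
    return make_phantom(default_spec, onset_minutes=270.0)


def quant_maps_for(patient, sigma=None, acquisition=BRISTOL, seed=None):
    """Simulate signals and compute the full map set for one patient."""
    from strokeclock.phantom import simulate_diffusion, simulate_echo_series

    rng = np.random.default_rng(patient.spec.seed if seed is None else seed)
    echoes = simulate_echo_series(patient, acquisition, sigma=sigma, rng=rng)
    diff = simulate_diffusion(patient, acquisition, sigma=sigma, rng=rng)
    return compute_quant_maps(echoes, diff,
                              voxel_size_mm=patient.spec.voxel_size_mm)


def cohort_table_for(n, seed, spec=None, acquisition=BRISTOL, sampler=None):
    """Full in-memory pipeline: cohort -> maps -> VOIs -> ratio table."""
    from strokeclock.cohort import build_cohort_table
    from strokeclock.phantom import make_cohort

    patients, skeleton = make_cohort(n=n, spec=spec, seed=seed,
                                     onset_sampler=sampler,
                                     acquisition=acquisition)
    ids, onsets, map_sets, vois = [], [], [], []
    for pid, patient in zip(skeleton["patient_id"], patients):
        maps = quant_maps_for(patient, acquisition=acquisition)
        voi = build_voi_pair(maps.adc, maps.t2, patient.brain_mask,
                             voxel_volume_ml=patient.spec.voxel_volume_ml,
                             valid=maps.valid)
        ids.append(pid)
        onsets.append(patient.onset_minutes)
        map_sets.append(maps)
        vois.append(voi)
    return build_cohort_table(ids, onsets, map_sets, vois)
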