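"""Shared fixtures: small synthetic cohorts and hand-built recordings."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from fessmotion.imu_io import Recording, RecordingMeta
from fessmotion.synthetic import CohortSpec, default_cohort_spec


def make_recording(t, acc, *, gyro=None, orient=None, group="senior", hand="DH",
                   procedure="foreign_body_removal", rate=128.0,
                   gravity_free=False, participant_id="P01") -> Recording:
    extras = {"gravity_free": True} if gravity_free else {}
    meta = RecordingMeta(participant_id=participant_id, group=group, hand=hand,
                         procedure=procedure, nominal_rate=rate,
                         acc_units_in="m_s2", extras=extras)
    return Recording(meta=meta, t=np.asarray(t, float),
                     acc=np.asarray(acc, float), gyro=gyro, orient=orient)


@pytest.fixture(scope="session")
def cohort_spec() -> CohortSpec:
    return default_cohort_spec()


@pytest.fixture(scope="session")
def small_spec(cohort_spec) -> CohortSpec:
    """A scaled-down two-procedure cohort for fast pipeline tests."""
    procs = ("foreign_body_removal", "maxillary_antrostomy")
    return dataclasses.replace(
        cohort_spec,
        group_sizes={"resident": 3, "specialist": 3, "senior": 2},
        duration_s={p: cohort_spec.duration_s[p] for p in procs},
        cum_acc={p: cohort_spec.cum_acc[p] for p in procs},
        path_m={p: cohort_spec.path_m[p] for p in procs},
    )
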