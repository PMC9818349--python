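import numpy as np
import pytest

import ssmpca as sp


@pytest.fixture(scope="session")
def default_cohort() -> sp.SynthCohort:
    """One default-sized synthetic cohort shared across the suite."""
    return sp.simulate_cohort(sp.SynthConfig(seed=7))


@pytest.fixture(scope="session")
def derived(default_cohort):
    """Model + composite pattern + score table from the shared cohort."""
    cohort = default_cohort
    model = sp.derive_ssm(cohort.subset(["PD", "C"]), "PD", "C")
    validation = [("PDv", "disease", cohort.subset(["PDv"])),
                  ("AIMN", "control", cohort.subset(["AIMN"]))]
    surviving, _ = sp.cross_validate_components(model, validation)
    groups = np.asarray(model.groups)
    sel = np.flatnonzero((groups == "PD") | (groups == "C"))
    coef, intercept, separated = sp.fit_logistic_combination(
        model.scores[np.ix_(sel, surviving)], (groups[sel] == "PD").astype(int))
    pattern = sp.compose_pattern(model, surviving, coef, intercept, separated)
    scores = sp.score_cohort(cohort.volumes, pattern)
    return {"cohort": cohort, "model": model, "surviving": surviving,
            "pattern": pattern, "scores": scores}


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


def make_volume(data, subject_id="s", group="g", voxel_size=(1.0, 1.0, 1.0)):
    return sp.SubjectVolume(subject_id, group, np.asarray(data, dtype=float), voxel_size)
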