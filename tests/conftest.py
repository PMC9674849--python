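import numpy as np
import pytest

from bodymaps import build_default_template
from bodymaps.simulate import Cohort, CohortConfig, PaintRecord


@pytest.fixture(scope="session")
def template():
    return build_default_template(60, 120)


@pytest.fixture(scope="session")
def small_template():
    return build_default_template(40, 80)


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


def cohort_with_counts(counts: dict[str, int], template, n_stimuli: int = 20) -> Cohort:
    """Hand-built cohort where each subject completes exactly `counts[sid]` maps.

    Completed maps get a single in-mask activation click; the rest are empty.
    """
    r0, c0 = map(int, np.argwhere(template.mask)[0])
    stimuli = tuple(f"stim{i:02d}" for i in range(n_stimuli))
    records = []
    for sid, n_done in counts.items():
        for j, stim in enumerate(stimuli):
            if j < n_done:
                ev = np.array([[r0, c0]])
                records.append(PaintRecord(sid, stim, "activation", ev, True))
            else:
                records.append(
                    PaintRecord(sid, stim, "activation", np.empty((0, 2), int), False)
                )
            records.append(
                PaintRecord(sid, stim, "deactivation", np.empty((0, 2), int), j < n_done)
            )
    return Cohort(
        records=records, truths={}, anomalous_subjects=set(),
        config=CohortConfig(n_subjects=len(counts), stimuli=stimuli),
    )
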