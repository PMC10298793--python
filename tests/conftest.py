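import numpy as np
import pytest

from slnet.synthetic import CouplingSpec, SessionSpec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


#: Base planted structure: a frontal module, an occipito-parietal module,
#: six independent channels (7..12).
BASE_GROUPS = ((1, 2, 3, 4, 5, 6), (13, 14, 15, 16, 17, 18, 19))

#: Programming-type override: channels 7, 8 and 12 join the frontal module.
PLUS_GROUPS = ((1, 2, 3, 4, 5, 6, 7, 8, 12), (13, 14, 15, 16, 17, 18, 19))


@pytest.fixture
def base_coupling():
    return CouplingSpec(groups=BASE_GROUPS, mixing=0.9, noise_sd=0.3,
                        band=(8.0, 12.0), fs=250.0, duration=2.0, seed=7)


def planted_session_spec(seed: int, planted: bool = True,
                         n_subjects: int = 2, stimuli: int = 8) -> SessionSpec:
    """Desk-scale study-shaped session: six tasks, alpha-band modules; the
    programming tasks optionally carry an extra coupled module on channels
    7, 8 and 12."""
    overrides = (
        {t: {"groups": PLUS_GROUPS} for t in ("PS", "PM", "PC")}
        if planted else {}
    )
    return SessionSpec(
        n_subjects=n_subjects,
        tasks=("ES", "EM", "EC", "PS", "PM", "PC"),
        stimuli_per_task=stimuli,
        epoch_duration=2.0,
        coupling=CouplingSpec(groups=BASE_GROUPS, mixing=0.9, noise_sd=0.3,
                              band=(8.0, 12.0), fs=250.0),
        task_overrides=overrides,
        seed=seed,
    )
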