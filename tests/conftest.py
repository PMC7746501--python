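import numpy as np
import pytest

import phonodose as pd


@pytest.fixture(scope="session")
def lecture60():
    """One 60 s synthetic lecture with exact labels, shared across tests."""
    spec = pd.SpeechSynthSpec(duration=60.0, target_speech_fraction=0.6, seed=11)
    audio, labels = pd.make_lecture(spec)
    grid = pd.FrameGrid.for_signal(audio)
    truth = pd.labels_to_frames(labels, grid)
    return {"audio": audio, "labels": labels, "grid": grid, "truth": truth}


@pytest.fixture(scope="session")
def fitted_coef(lecture60):
    """AT coefficients GA-fitted on the shared lecture (moderate budget)."""
    env = pd.compute_envelope(lecture60["audio"], lecture60["grid"])
    train = pd.TrainingSet(utterances=[(env, lecture60["truth"])])
    coef, trace = pd.fit_coefficients(
        train, pd.GAConfig(population_size=40, generations=80, seed=7)
    )
    return coef


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
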