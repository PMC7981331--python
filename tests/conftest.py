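import numpy as np
import pytest

from eegarousal.pipeline import process_recording
from eegarousal.preprocess import PreprocessConfig
from eegarousal.stability import stability_score
from eegarousal.synth import MINIMAL_CHANNELS, make_stage_script, synthesize_recording
from eegarousal.vigilance import ClassifierConfig

N_ROUNDTRIP = 50


@pytest.fixture(scope="session")
def roundtrip_results():
    """Synthesize, preprocess and classify recordings across profiles/seeds.

    Returns one dict per recording with the scripted truth and the
    classifier's output; shared by the calibration and acceptance tests.
    """
    out = []
    for seed in range(N_ROUNDTRIP):
        profile = ("stable_high", "declining", "fluctuating")[seed % 3]
        script = make_stage_script(profile, duration_s=900, seed=seed)
        rec = synthesize_recording(
            script, sfreq=256.0, seed=seed, channels=MINIMAL_CHANNELS
        )
        seq, artifact_fraction = process_recording(
            rec, PreprocessConfig(), ClassifierConfig()
        )
        agreement = float(
            np.mean([a == b for a, b in zip(seq.stages, script.stages)])
        )
        out.append(
            {
                "profile": profile,
                "seed": seed,
                "true_stages": script.stages,
                "true_score": script.true_score,
                "stages": seq.stages,
                "est_score": stability_score(seq).score,
                "agreement": agreement,
                "artifact_fraction": artifact_fraction,
            }
        )
    return out


@pytest.fixture()
def stage_seq():
    """Factory for stage sequences (optionally with an artifact mask)."""
    from eegarousal.io import StageSequenceRecord

    def make(stages, mask=None, subject_id="t"):
        return StageSequenceRecord(
            subject_id=subject_id,
            stages=list(stages),
            artifact_mask=(
                np.zeros(len(stages), bool) if mask is None else np.asarray(mask, bool)
            ),
        )

    return make
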