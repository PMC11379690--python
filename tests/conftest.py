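import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from eldergait import finetune_eval as fe
from eldergait import model_core as mc
from eldergait import preprocess as pp
from eldergait import ssl as S
from eldergait import synthetic_data as sd

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")


def make_labeled_recordings(n_subjects: int, seed0: int,
                            duration_s: float = 600.0,
                            profile: sd.ActivityProfile | None = None):
    """Simulated daily-living recordings with per-sample gait labels."""
    profile = profile or sd.ActivityProfile()
    recs = []
    for s in range(n_subjects):
        rng = np.random.default_rng(seed0 + s)
        sch = sd.BoutSchedule.sample(duration_s, rng)
        recs.append(sd.simulate_recording(profile, sch, fs=30, seed=seed0 + s,
                                          subject_id=f"subj{seed0 + s}"))
    return recs


def windows_of(recs):
    return [w for r in recs for w in pp.segment_windows(r, drop_nonwear=True)]


@pytest.fixture(scope="session")
def labeled_dataset() -> fe.WindowDataset:
    """16 labeled subjects, ~90 windows each."""
    return fe.WindowDataset.from_windows(
        windows_of(make_labeled_recordings(16, 500, duration_s=900.0)))


@pytest.fixture(scope="session")
def ssl_corpus():
    """Unlabeled pretraining windows from 7 additional subjects."""
    return windows_of(make_labeled_recordings(7, 700))


@pytest.fixture(scope="session")
def pretrained_tiny(ssl_corpus) -> S.PretrainResult:
    encoder = mc.Encoder(mc.EncoderConfig.tiny(), seed=0)
    head = mc.build_head(mc.HeadConfig.tiny(), 64, seed=0)
    return S.pretrain(ssl_corpus, encoder, head, "mtl",
                      S.PretrainConfig(epochs=4), seed=0, head_out_dim=32)


def clone_pretrained(pretrained: S.PretrainResult) -> mc.GaitModel:
    """Fresh GaitModel initialized from (copies of) pretrained weights."""
    enc = mc.Encoder(mc.EncoderConfig.tiny(), seed=0)
    enc.load_state_dict(pretrained.encoder.state_dict())
    head = mc.build_head(mc.HeadConfig.tiny(), 64, seed=0)
    head.load_state_dict(pretrained.head.state_dict())
    return mc.GaitModel(enc, head, 32, seed=0)


@pytest.fixture(scope="session")
def fixture_model(labeled_dataset, pretrained_tiny) -> mc.GaitModel:
    """SSL-pretrained tiny model fine-tuned on the 12 labeled subjects."""
    model = clone_pretrained(pretrained_tiny)
    tr, va, te = fe.split_subjectwise(labeled_dataset, fe.SplitPlan(), seed=0)
    train_idx = np.concatenate([tr, te])  # all non-validation subjects
    model, _ = fe.finetune(labeled_dataset.subset(train_idx),
                           labeled_dataset.subset(va), model,
                           fe.TrainState(max_epochs=30, learning_rate=3e-4),
                           seed=0)
    return model
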