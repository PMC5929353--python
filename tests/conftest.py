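import numpy as np
import pytest

from braggscreen import cnn_classifier as cnn
from braggscreen import evaluation as ev
from braggscreen import synth_data
from braggscreen.io_formats import AnnotationTable, Label


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def flat_profile():
    """Monolithic fully-trusted detector: no gaps, no boosts, no noise."""
    return synth_data.DetectorProfile(
        shape=(64, 64),
        psf_sigma=1.5,
        panel_layout=[(0, 0, 64, 64)],
        border_boost=0.0,
        saturation_level=1e9,
        dark_mean=0.0,
        dark_sigma=0.0,
        name="flat",
    )


@pytest.fixture
def quiet_scene():
    """Noise-free, artifact-free scene parameters."""
    return synth_data.SceneParams(
        mode="random",
        mean_spots=5.0,
        spot_intensity=(500.0, 0.3),
        b_factor=0.0,
        poisson_noise=False,
        quantize=False,
    )


def make_table(labels, prefix="f"):
    return AnnotationTable.from_records(
        [(f"{prefix}{i:05d}", Label(l), None, "expert") for i, l in enumerate(labels)]
    )


@pytest.fixture
def three_class_table():
    return make_table([0] * 30 + [1] * 20 + [2] * 50)


def _easy_images(n, edge, rng):
    """Directly constructed 3-class toy images: blank / few / many bright dots."""
    images = np.zeros((n, edge, edge))
    labels = []
    for i in range(n):
        cls = i % 3
        img = rng.normal(0.0, 0.3, (edge, edge))
        n_dots = {0: 18, 1: 6, 2: 0}[cls]
        if n_dots:
            pos = rng.integers(1, edge - 1, size=(n_dots, 2))
            img[pos[:, 0], pos[:, 1]] += 8.0
        images[i] = img
        labels.append(cls)
    return images, labels


@pytest.fixture(scope="session")
def easy_problem():
    """600 trivially separable frames at edge 16 plus a 200-frame holdout."""
    rng = np.random.default_rng(7)
    train_x, train_y = _easy_images(600, 16, rng)
    test_x, test_y = _easy_images(200, 16, rng)
    train_ids = [f"tr{i:05d}" for i in range(600)]
    test_ids = [f"te{i:05d}" for i in range(200)]
    train_t = AnnotationTable.from_records(
        [(fid, Label(l), None, "rule") for fid, l in zip(train_ids, train_y)]
    )
    test_t = AnnotationTable.from_records(
        [(fid, Label(l), None, "rule") for fid, l in zip(test_ids, test_y)]
    )
    arch = cnn.CNNArchitecture(input_size=16, channels_per_stage=(8, 16))
    return {
        "train_x": train_x, "train_ids": train_ids, "train_table": train_t,
        "test_x": test_x, "test_ids": test_ids, "test_table": test_t,
        "arch": arch,
    }


@pytest.fixture(scope="session")
def easy_trained(easy_problem):
    """A model trained for 20 epochs on the easy problem, with history."""
    config = cnn.TrainConfig(
        batch_size=32, batches_per_epoch=19, epochs=20,
        lr_start=0.1, lr_end=0.001, seed=3,
    )
    weights, history = cnn.train(
        easy_problem["train_x"], easy_problem["train_ids"],
        easy_problem["train_table"], easy_problem["arch"], config,
    )
    return {"weights": weights, "history": history, "config": config}


@pytest.fixture(scope="session")
def rayonix_run():
    """One realistic simulated run: data, a trained model and predictions.

    Shared by CNN end-to-end tests, evaluation tests and saliency tests to
    keep the suite within budget.
    """
    config = ev.ExperimentConfig(n_frames=800, seeds=(0,))
    data = ev.prepare_profile_data("rayonix_like", config, seed=0)
    weights, history = cnn.train(
        data["train"]["images"], data["train"]["ids"], data["train"]["table"],
        config.arch(), config.train,
        val_images=data["val"]["images"], val_frame_ids=data["val"]["ids"],
        val_table=data["val"]["table"],
    )
    predictions = cnn.predict(
        weights, config.arch(), data["test"]["images"], data["test"]["ids"]
    )
    return {
        "config": config,
        "data": data,
        "weights": weights,
        "history": history,
        "predictions": predictions,
    }
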