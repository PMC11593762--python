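import numpy as np
import pytest

from entrofuse import GroundTruth, ModelPrediction, VoxelGrid


def mask_grid(arr) -> VoxelGrid:
    return VoxelGrid(np.asarray(arr, dtype=np.uint8), "mask")


def as_pred(arr, model_id="m", role="mask") -> ModelPrediction:
    dtype = np.uint8 if role == "mask" else np.float64
    return ModelPrediction(model_id, VoxelGrid(np.asarray(arr, dtype=dtype), role))


def as_truth(arr) -> GroundTruth:
    return GroundTruth(mask_grid(arr))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def toy_pair():
    """1x2x2 pair with (tp, fp, fn, tn) = (1, 1, 1, 1)."""
    truth = as_truth([[[1, 1], [0, 0]]])
    pred = as_pred([[[1, 0], [1, 0]]])
    return pred, truth
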