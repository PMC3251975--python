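import sys
from pathlib import Path

import numpy as np
import pytest
from skimage import color

sys.path.insert(0, str(Path(__file__).parent))

from gma.aggregation import AggregationParams, run_multiscale
from gma.evaluation import confusion, f_measure
from gma.synthdb import DbConfig, generate_database, render_record


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def bimodal_rgb(height=16, width=16, lo=-40.0, hi=40.0, noise=1.0, seed=0):
    """RGB image whose a* plane is two vertical halves at ``lo``/``hi``
    plus Gaussian noise — ground truth by construction."""
    r = np.random.default_rng(seed)
    lab = np.zeros((height, width, 3))
    lab[..., 0] = 60.0
    half = width // 2
    lab[:, :half, 1] = lo + r.normal(0, noise, (height, half))
    lab[:, half:, 1] = hi + r.normal(0, noise, (height, width - half))
    rgb = np.clip(color.lab2rgb(lab), 0.0, 1.0)
    truth = np.zeros((height, width), dtype=np.uint8)
    truth[:, half:] = 1
    return rgb, truth


@pytest.fixture
def bimodal_image():
    return bimodal_rgb()


#: configuration of the scaled-down headline suite: 5 silhouettes x the
#: first 10 texture families at 150x200
SUITE_CONFIG = dict(
    n_subjects=1,
    hands_per_subject=1,
    acquisitions_per_hand=1,
    images_per_acquisition=5,
    n_textures=10,
    height=150,
    width=200,
    seed=20240901,
)


@pytest.fixture(scope="session")
def suite_results():
    """Segment the 50-composite suite once per session; reused by the
    headline-accuracy, partition/termination and scale-reduction tests."""
    cfg = DbConfig(**SUITE_CONFIG)
    manifest = generate_database(cfg, manifest_only=True)
    results = []
    for record in manifest.records:
        image, truth = render_record(cfg, record)
        image8 = (image * 255).round().astype(np.uint8)
        res = run_multiscale(image8, AggregationParams())
        _, _, f = f_measure(confusion(res.mask, truth))
        results.append(
            {
                "family": record.texture_family,
                "f": f,
                "trace": res.trace,
                "n_segments": res.n_segments,
                "degenerate": res.degenerate,
                "labels": res.labels,
                "shape": truth.shape,
            }
        )
    return results
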