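import numpy as np
import pytest

from petbpnn.bpnn import NetworkConfig
from petbpnn.evaluation import LabeledDataset
from petbpnn.preprocess import PrepConfig, prepare_images
from petbpnn.synthetic import PhantomConfig, generate_images

# Scaled-down phantom geometry used by pipeline-level tests: 128 px slices
# with a half-scale smoothing kernel, prepared on a 100 px grid with 5 px
# segments so the feature count stays at 400.
SMALL_IMAGE = dict(image_size=128, smooth_fwhm_px=4.0)
SMALL_PREP = dict(target_size=100, segment_size=5)


def phantom_dataset(
    n_per_class: int,
    noise_sigma: float,
    seed: int,
    effect_size: dict | None = None,
    classes: tuple[str, ...] | None = None,
    **phantom_kwargs,
) -> LabeledDataset:
    """Generate phantoms in memory and prepare them into a LabeledDataset."""
    kw = dict(SMALL_IMAGE)
    kw.update(phantom_kwargs)
    if effect_size is not None:
        kw["effect_size"] = effect_size
    cfg = PhantomConfig(
        n_per_class=n_per_class, noise_sigma=noise_sigma, seed=seed, **kw
    )
    images = generate_images(cfg)
    if classes is not None:
        images = [item for item in images if item[1] in classes]
    df = prepare_images(images, PrepConfig(**SMALL_PREP))
    return LabeledDataset.from_dataframe(df)


@pytest.fixture(scope="session")
def separable_nc_ad() -> LabeledDataset:
    """30 NC + 30 AD low-noise phantoms; linearly separable by construction."""
    return phantom_dataset(
        n_per_class=30, noise_sigma=0.04, seed=1, classes=("NC", "AD")
    )


def gaussian_dataset(
    n_per_class: int,
    shift: float,
    seed: int,
    n_features: int = 400,
) -> LabeledDataset:
    """Synthetic feature-space dataset: NC ~ N(0.4, .05), AD ~ N(0.4+shift, .05)."""
    rng = np.random.default_rng(seed)
    ids, labels, rows = [], [], []
    for label, mu in (("NC", 0.4), ("AD", 0.4 + shift)):
        for i in range(n_per_class):
            ids.append(f"{label}_{i:03d}")
            labels.append(label)
            rows.append(np.clip(rng.normal(mu, 0.05, n_features), 0, 1))
    return LabeledDataset(ids=ids, labels=labels, X=np.stack(rows))


@pytest.fixture
def fast_net() -> NetworkConfig:
    """Small, quickly-converging configuration for plumbing tests."""
    return NetworkConfig(
        n_input=400,
        n_hidden=10,
        learning_rate=0.01,
        momentum=0.9,
        min_rms=0.05,
        max_epochs=300,
        seed=0,
    )
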