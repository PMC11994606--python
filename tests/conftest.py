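"""Shared fixtures: small synthetic slides and the session-scoped benchmarks.

The two expensive fixtures (the end-to-end pipeline run and the patch
classifier benchmark) are computed once per session and shared between
the module tests and the acceptance tests.
"""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from milt.pipeline import desk_config, run_all
from milt.synthetic import SlideSpec, generate_slide


@pytest.fixture(scope="session")
def small_slide():
    """One deterministic mid-TPS slide with its truth."""
    spec = SlideSpec(slide_id="fix", target_tps=0.5, n_tumor_cells=400, seed=7)
    img, truth = generate_slide(spec)
    return spec, img, truth


@pytest.fixture(scope="session")
def tumor_patch_stack(small_slide):
    """Tumor-labelled patch pixels of the fixture slide, by truth."""
    _, img, truth = small_slide
    px = [
        img[y:y + 256, x:x + 256]
        for key, lab in truth.patch_labels.items()
        if lab
        for x, y in [map(int, key.split("_"))]
    ]
    return np.stack(px)


@pytest.fixture(scope="session")
def e2e_run(tmp_path_factory):
    """Full desk-scale pipeline on 60 synthetic slides (seed 0).

    Returns (held-out truth percents, predictions percents, AgreementReport).
    """
    out = tmp_path_factory.mktemp("e2e")
    cfg = desk_config(out, seed=0)
    result = run_all(
        cfg,
        (
            "simulate",
            "tile",
            "train-classifier",
            "extract-tumor",
            "train-mil",
            "predict",
            "evaluate",
        ),
    )
    manifest = pd.read_csv(out / "cohort" / "manifest.csv")
    preds = pd.read_csv(out / "predictions" / "predictions.csv")
    merged = manifest.merge(preds, on="slide_id")
    held = merged[merged["split"].isin(["val", "test"])]
    return (
        held["tps_truth_percent"].to_numpy(),
        held["tps_ai_percent"].to_numpy(),
        result["report"],
        out,
    )


@pytest.fixture(scope="session")
def classifier_benchmark():
    """Train the patch classifier on balanced synthetic patches and score
    it on an independently generated held-out balanced set of 400."""
    from milt.classifier import ClassifierConfig, train_classifier
    from milt.synthetic import generate_patch_dataset
    from milt.tiling import Patch

    x_train, y_train = generate_patch_dataset(300, seed=1)
    x_test, y_test = generate_patch_dataset(200, seed=2)
    train_patches = [Patch("b", 0, 0, 1.0, px) for px in x_train]
    model = train_classifier(train_patches, y_train, ClassifierConfig(epochs=25, seed=0))
    probs = model.predict_proba(x_test)
    return model, probs, y_test
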