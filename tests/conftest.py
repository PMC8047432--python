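"""Shared fixtures: generated sections and pipeline products reused across tests."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pytest

from fiberquant import preprocess as pp
from fiberquant import scoring as sc
from fiberquant import segmentation as seg
from fiberquant import synthetic as syn


@dataclass
class PipelineResult:
    spec: syn.SectionSpec
    image: syn.SectionImage
    gt: syn.GroundTruth
    pre: syn.SectionImage
    fmap: seg.FiberLabelMap
    lam_mask: np.ndarray
    thresholds: sc.ThresholdSet
    scores: list


def run_pipeline(spec: syn.SectionSpec, preprocess: bool = True) -> PipelineResult:
    """Generate, preprocess, segment, threshold and score one section.

    Noise-free sections skip preprocessing (there is no background or
    shading to remove) and derive the threshold from the raw rendering,
    where the non-sarcolemmal level is the specified background.
    """
    image, gt = syn.generate_section(spec)
    pre = pp.preprocess_section(image) if preprocess else image
    fmap = seg.segment_fibers(pre.laminin)
    lam_mask = sc.laminin_mask(pre.laminin)
    thresholds = sc.derive_threshold([pre], [lam_mask])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        scores = sc.score_fibers(pre, fmap, lam_mask, thresholds)
    return PipelineResult(spec=spec, image=image, gt=gt, pre=pre, fmap=fmap,
                          lam_mask=lam_mask, thresholds=thresholds, scores=scores)


@pytest.fixture(scope="session")
def noisy_section():
    """Default-noise 100-fiber section through the full pipeline."""
    return run_pipeline(syn.SectionSpec(n_fibers=100, seed=0))


@pytest.fixture(scope="session")
def clean_section():
    """Noise-free, shading-free 30-fiber section, scored on the raw rendering."""
    spec = syn.SectionSpec(n_fibers=30, image_shape=(400, 400),
                           shading_amplitude=0.0, noise_sd=0.0, seed=1)
    return run_pipeline(spec, preprocess=False)


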