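"""Image preparation applied uniformly before quantification.

The chain is shading correction -> rolling-ball background subtraction ->
denoising, applied with identical parameters to every image of a batch.
All steps are deterministic and preserve non-negativity.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.morphology import disk
from skimage.transform import resize

from .synthetic import SectionImage


def _check_image(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image, dtype=float)
    if image.size == 0:
        raise ValueError("empty image")
    if image.min() < 0:
        raise ValueError("image must be non-negative")
    return image


def _polynomial_surface(image: np.ndarray, order: int = 2, robust: bool = False,
                        n_iter: int = 3, clip_k: float = 1.0) -> np.ndarray:
    """Least-squares 2-D polynomial fit, the low-order shading model.

    With ``robust`` the fit is re-run excluding pixels far above the
    current surface, so bright structure (fiber walls, arcs) does not
    drag the illumination estimate; dark pixels are kept, as shading is
    a multiplicative loss.
    """
    h, w = image.shape
    yy, xx = np.mgrid[0:h, 0:w]
    y = (yy / h - 0.5).ravel()
    x = (xx / w - 0.5).ravel()
    cols = [np.ones_like(x)]
    for total in range(1, order + 1):
        for i in range(total + 1):
            cols.append(x ** (total - i) * y ** i)
    design = np.column_stack(cols)
    v = image.ravel()
    sel = np.ones(v.size, dtype=bool)
    for _ in range(n_iter if robust else 1):
        coef, *_ = np.linalg.lstsq(design[sel], v[sel], rcond=None)
        fit = design @ coef
        if not robust:
            break
        resid = v - fit
        sd = resid[sel].std()
        if sd <= 1e-9 * max(abs(v).max(), 1e-30):   # exact fit, e.g. constant
            break
        new_sel = resid < clip_k * sd
        if new_sel.sum() < 10 * design.shape[1]:    # keep the fit overdetermined
            break
        sel = new_sel
    return fit.reshape(h, w)


def correct_shading(image: np.ndarray, method: str = "polynomial") -> np.ndarray:
    """Divide out a smooth estimated illumination field (normalized to mean 1).

    ``polynomial`` (default) fits a robust quadratic surface that
    ignores bright structure; ``gaussian`` estimates the field by a
    heavy blur (sigma = 1/4 of the image width).  The output is rescaled
    so its mean equals the input mean exactly, making the step
    equivariant under global intensity scaling.
    """
    image = _check_image(image)
    if image.max() == 0:
        raise ValueError("constant-zero image: illumination not estimable")
    if method == "gaussian":
        sigma = max(image.shape) / 4.0
        field = ndimage.gaussian_filter(image, sigma=sigma, mode="reflect")
    elif method == "polynomial":
        field = _polynomial_surface(image, order=2, robust=True)
    else:
        raise ValueError(f"unknown shading method: {method!r}")
    field = np.clip(field, 1e-6 * field.max(), None)
    field = field / field.mean()
    out = image / field
    out *= image.mean() / out.mean()
    return np.clip(out, 0.0, None)


def subtract_background_rolling_ball(image: np.ndarray, radius: float = 50.0) -> np.ndarray:
    """Morphological rolling-ball background subtraction.

    The background is the grayscale opening of the image with a disk of
    the given radius, computed on a downscaled copy for large radii (the
    standard shrink/roll/enlarge acceleration) and lightly smoothed.
    Structures smaller than the ball survive; the result is floored at 0.
    """
    image = _check_image(image)
    if radius <= 0:
        raise ValueError("radius must be > 0")
    shrink = max(1, int(radius // 10))
    if shrink > 1:
        small_shape = (max(1, image.shape[0] // shrink),
                       max(1, image.shape[1] // shrink))
        # pre-smooth (noise would bias the morphological envelope low),
        # then block-average down; the opening removes structure ridges
        smoothed = ndimage.uniform_filter(image, size=shrink)
        small = ndimage.zoom(smoothed,
                             (small_shape[0] / image.shape[0],
                              small_shape[1] / image.shape[1]), order=1)
        r = max(1, int(round(radius / shrink)))
        bg_small = ndimage.grey_opening(small, footprint=disk(r))
        bg_small = ndimage.gaussian_filter(bg_small, sigma=1.0)
        background = resize(bg_small, image.shape, order=1, mode="edge",
                            anti_aliasing=False)
    else:
        background = ndimage.grey_opening(image, footprint=disk(int(round(radius))))
    return np.clip(image - background, 0.0, None)


def denoise(image: np.ndarray, method: str = "median", size: int = 3) -> np.ndarray:
    """Median or Gaussian denoising; median leaves constant images untouched."""
    image = _check_image(image)
    if size < 1:
        raise ValueError("size must be >= 1")
    if method == "median":
        return ndimage.median_filter(image, size=size)
    if method == "gaussian":
        return ndimage.gaussian_filter(image, sigma=size / 2.0)
    raise ValueError(f"unknown denoise method: {method!r}")


@dataclass
class PreprocessParams:
    shading_method: str = "polynomial"
    rolling_ball_radius: float = 50.0
    denoise_method: str = "median"
    denoise_size: int = 3
    apply_rolling_ball: bool = True


def preprocess_channel(image: np.ndarray, params: PreprocessParams | None = None) -> np.ndarray:
    """Full chain on one channel: shading -> rolling ball -> denoise."""
    params = params or PreprocessParams()
    out = correct_shading(image, method=params.shading_method)
    if params.apply_rolling_ball:
        out = subtract_background_rolling_ball(out, radius=params.rolling_ball_radius)
    return denoise(out, method=params.denoise_method, size=params.denoise_size)


def preprocess_section(image: SectionImage,
                       params: PreprocessParams | None = None) -> SectionImage:
    """Apply the identical chain to both channels of a section image."""
    params = params or PreprocessParams()
    return SectionImage(
        dystrophin=preprocess_channel(image.dystrophin, params),
        laminin=preprocess_channel(image.laminin, params),
        pixel_size=image.pixel_size, sample_id=image.sample_id,
        muscle=image.muscle, dose_group=image.dose_group,
        timepoint=image.timepoint, exposure_batch=image.exposure_batch,
    )


def write_provenance(path: str | Path, params: PreprocessParams) -> None:
    Path(path).write_text(json.dumps(asdict(params), indent=2))
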