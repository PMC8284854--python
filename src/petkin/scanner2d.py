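"""2-D attenuated Radon/Poisson scanning model with FBP reconstruction.

The imaging domain is the unit square discretised to 128 x 128; projections
live on a 183 x 181 sinogram of distances and angles over [0, pi).  Expected
counts are a discretised parallel-beam Radon transform of the source,
attenuated multiplicatively along each line of response (the attenuation
sinogram ``exp(-Radon(mu))`` is computed once from the attenuation map, as
appropriate for coincidence detection), scaled to the study dose, and
Poisson sampled.  Reconstruction is attenuation-corrected filtered
backprojection with a ramp filter (optional Hann apodisation) and Gaussian
post-smoothing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.transform import iradon, radon

__all__ = ["Scanner2DConfig", "Scanner2D"]

IMAGE_SIZE = 128
#: padding the image by one zero row/column makes skimage's projection grid
#: exactly 183 radial bins for a 128-pixel image
_PAD = 1
SINOGRAM_SHAPE = (183, 181)


@dataclass(frozen=True)
class Scanner2DConfig:
    tau: float = 1.0e6
    attenuation_map: Optional[np.ndarray] = None  # linear attenuation, 128x128
    bandwidth: float = 0.0                        # Gaussian sigma, pixels
    hann: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("dose tau must be positive")
        mu = self.attenuation_map
        if mu is None:
            # mild body-like attenuation: broad disc of constant mu
            yy, xx = np.mgrid[0:IMAGE_SIZE, 0:IMAGE_SIZE].astype(float)
            c = (IMAGE_SIZE - 1) / 2.0
            disc = np.hypot(yy - c, xx - c) <= IMAGE_SIZE * 0.45
            mu = np.where(disc, 0.004, 0.0)
        mu = np.asarray(mu, dtype=float)
        if mu.shape != (IMAGE_SIZE, IMAGE_SIZE) or np.any(mu < 0):
            raise ValueError("attenuation map must be non-negative 128x128")
        object.__setattr__(self, "attenuation_map", mu)


class Scanner2D:
    def __init__(self, cfg: Scanner2DConfig):
        self.cfg = cfg
        self.theta = np.linspace(0.0, 180.0, SINOGRAM_SHAPE[1], endpoint=False)
        self._attn_sino = np.exp(-self._radon(cfg.attenuation_map))

    # -- geometry ------------------------------------------------------
    def _radon(self, image: np.ndarray) -> np.ndarray:
        padded = np.pad(image, ((0, _PAD), (0, _PAD)))
        sino = radon(padded, theta=self.theta, circle=False)
        if sino.shape != SINOGRAM_SHAPE:
            raise RuntimeError(f"unexpected sinogram shape {sino.shape}")
        return sino

    def _iradon(self, sino: np.ndarray) -> np.ndarray:
        filter_name = "hann" if self.cfg.hann else "ramp"
        img = iradon(sino, theta=self.theta, circle=False,
                     filter_name=filter_name,
                     output_size=IMAGE_SIZE + _PAD)
        return img[:IMAGE_SIZE, :IMAGE_SIZE]

    # -- forward model ---------------------------------------------------
    def study_scale(self, frame_images: np.ndarray, durations_min) -> float:
        q = self._raw_projection(frame_images, durations_min)
        total = float(q.sum())
        if total <= 0:
            raise ValueError("cannot scale an all-zero study")
        return self.cfg.tau / total

    def _raw_projection(self, frame_images, durations_min) -> np.ndarray:
        frame_images = np.asarray(frame_images, dtype=float)
        if frame_images.ndim == 2:
            frame_images = frame_images[None]
        if frame_images.shape[1:] != (IMAGE_SIZE, IMAGE_SIZE):
            raise ValueError("frame images must be 128x128")
        if np.any(frame_images < 0):
            raise ValueError("source values must be non-negative")
        durations_min = np.atleast_1d(np.asarray(durations_min, dtype=float))
        sinos = np.stack([self._radon(img) for img in frame_images])
        return np.maximum(sinos * self._attn_sino, 0.0) \
            * durations_min[:, None, None]

    def project(self, frame_images: np.ndarray, durations_min,
                scale: Optional[float] = None) -> np.ndarray:
        """Expected counts, shape (N_T, 183, 181)."""
        if scale is None:
            scale = self.study_scale(frame_images, durations_min)
        return scale * self._raw_projection(frame_images, durations_min)

    def sample_counts(self, expected: np.ndarray,
                      rng: np.random.Generator | int | None = None) -> np.ndarray:
        expected = np.asarray(expected, dtype=float)
        if np.any(expected < 0):
            raise ValueError("expected counts must be non-negative")
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(self.cfg.seed if rng is None else rng)
        return rng.poisson(expected)

    # -- reconstruction --------------------------------------------------
    def recon_fbp(self, sinos: np.ndarray, durations_min, scale: float,
                  bandwidth: Optional[float] = None) -> np.ndarray:
        """Attenuation-corrected FBP of count sinograms, per frame."""
        sinos = np.asarray(sinos, dtype=float)
        if sinos.ndim == 2:
            sinos = sinos[None]
        if sinos.shape[1:] != SINOGRAM_SHAPE:
            raise ValueError(f"sinograms must be {SINOGRAM_SHAPE}")
        durations_min = np.atleast_1d(np.asarray(durations_min, dtype=float))
        out = np.empty((sinos.shape[0], IMAGE_SIZE, IMAGE_SIZE))
        for l, s in enumerate(sinos):
            corrected = s / self._attn_sino / (scale * durations_min[l])
            out[l] = self._iradon(corrected)
        h = self.cfg.bandwidth if bandwidth is None else bandwidth
        if h > 0:
            out = np.stack([gaussian_filter(img, sigma=h) for img in out])
        return out
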