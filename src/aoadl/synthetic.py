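"""Seeded generator of two-class histology-like texture images.

Each image is a smooth background texture (Gaussian-filtered noise with a
configurable correlation length) onto which dark elliptical "nuclei" are
stamped: their number is Poisson with a class-specific density, their
radii and intensities Gaussian.  Malignant-class parameters follow the
histological picture — denser, larger, more pleomorphic nuclei — so the
class-conditional nucleus count differs by construction.  The dynamic
range is then compressed (low contrast, to exercise contrast enhancement)
and salt-and-pepper impulse noise is added (to exercise the median
filter).

Class imbalance mirrors a BreakHis-style benchmark: at the 100x
magnification 644 benign / 1437 malignant images, at 200x 623 / 1390
(about 1:2.2).  Everything is reproducible from a (seed, params) manifest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .errors import ParameterError

__all__ = [
    "ClassTextureParams",
    "SyntheticDataset",
    "generate_dataset",
    "make_breakhis_like",
    "EASY_PRESET",
    "HARD_PRESET",
    "BREAKHIS_COUNTS",
]

BREAKHIS_COUNTS = {"100x": (644, 1437), "200x": (623, 1390)}

LABELS = {"benign": 0, "malignant": 1}


@dataclass(frozen=True)
class ClassTextureParams:
    """Texture parameters for one class.

    ``density`` is the mean nucleus count per 64x64 tile (scaled by image
    area); intensities are on the 0-255 scale.
    """

    density: float = 8.0
    radius_mean: float = 3.0
    radius_sd: float = 0.6
    intensity_mean: float = 60.0
    intensity_sd: float = 12.0
    background: float = 170.0
    correlation_length: float = 4.0

    def __post_init__(self):
        if self.density <= 0 or self.radius_mean <= 0:
            raise ParameterError("density and radius must be positive")
        if not (0 <= self.intensity_mean <= 255 and 0 <= self.background <= 255):
            raise ParameterError("intensity means must lie within 0-255")


# Well-separated nucleus densities: end-to-end classification is expected
# to be comfortably learnable, while still exercising every pipeline stage.
EASY_PRESET = {
    "benign": ClassTextureParams(density=6.0, radius_mean=2.8, radius_sd=0.4,
                                 intensity_mean=65.0, intensity_sd=10.0),
    "malignant": ClassTextureParams(density=18.0, radius_mean=4.0, radius_sd=1.0,
                                    intensity_mean=50.0, intensity_sd=14.0),
}

# Overlapping parameters for robustness tests.
HARD_PRESET = {
    "benign": ClassTextureParams(density=9.0, radius_mean=3.0, radius_sd=0.6,
                                 intensity_mean=60.0, intensity_sd=12.0),
    "malignant": ClassTextureParams(density=13.0, radius_mean=3.4, radius_sd=0.9,
                                    intensity_mean=55.0, intensity_sd=14.0),
}


@dataclass
class SyntheticDataset:
    images: list[np.ndarray]
    labels: np.ndarray
    manifest: dict

    @property
    def n_benign(self) -> int:
        return int(np.sum(self.labels == LABELS["benign"]))

    @property
    def n_malignant(self) -> int:
        return int(np.sum(self.labels == LABELS["malignant"]))

    def save(self, out_dir) -> None:
        """Write 8-bit grayscale PNGs, a labels CSV and the manifest JSON."""
        from PIL import Image

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        rows = ["path,label"]
        names = {v: k for k, v in LABELS.items()}
        for i, (img, lab) in enumerate(zip(self.images, self.labels)):
            name = f"img_{i:05d}.png"
            Image.fromarray(img).save(out / name)
            rows.append(f"{name},{names[int(lab)]}")
        (out / "labels.csv").write_text("\n".join(rows) + "\n")
        (out / "manifest.json").write_text(json.dumps(self.manifest, indent=2))


def _render_image(size: int, params: ClassTextureParams, impulse_rate: float,
                  contrast_scale: float, rng: np.random.Generator) -> np.ndarray:
    # correlated background texture around the class background level
    noise = rng.standard_normal((size, size))
    texture = ndimage.gaussian_filter(noise, params.correlation_length)
    sd = texture.std()
    if sd > 0:
        texture = texture / sd * 8.0
    img = params.background + texture

    area_scale = (size / 64.0) ** 2
    n_nuclei = rng.poisson(params.density * area_scale)
    yy, xx = np.mgrid[0:size, 0:size]
    for _ in range(n_nuclei):
        cy, cx = rng.uniform(0, size, size=2)
        r = max(1.0, rng.normal(params.radius_mean, params.radius_sd))
        intensity = np.clip(rng.normal(params.intensity_mean, params.intensity_sd), 0, 255)
        elong = rng.uniform(0.7, 1.3)
        d2 = ((yy - cy) / r) ** 2 + ((xx - cx) / (r * elong)) ** 2
        blob = np.exp(-0.5 * d2 * 4.0)
        img = img * (1 - blob) + intensity * blob

    # compress dynamic range around mid-gray (low contrast)
    img = 127.5 + (img - 127.5) * contrast_scale
    img = np.clip(img, 0, 255)

    # salt-and-pepper impulse noise
    if impulse_rate > 0:
        u = rng.random((size, size))
        img = np.where(u < impulse_rate / 2, 0.0, img)
        img = np.where((u >= impulse_rate / 2) & (u < impulse_rate), 255.0, img)
    return np.floor(img + 0.5).astype(np.uint8)


def generate_dataset(n_benign: int, n_malignant: int, size: int = 64,
                     benign_params: ClassTextureParams | None = None,
                     malignant_params: ClassTextureParams | None = None,
                     impulse_rate: float = 0.02, contrast_scale: float = 0.55,
                     seed: int = 0) -> SyntheticDataset:
    """Generate a labeled two-class image set, deterministic per seed.

    Benign images come first, then malignant; labels are 0/1 accordingly.
    """
    if n_benign < 1 or n_malignant < 1:
        raise ParameterError("class counts must be >= 1")
    if not 0 <= impulse_rate <= 0.2:
        raise ParameterError("impulse_rate must lie in [0, 0.2]")
    if not 0 < contrast_scale <= 1:
        raise ParameterError("contrast_scale must lie in (0, 1]")
    benign_params = benign_params or EASY_PRESET["benign"]
    malignant_params = malignant_params or EASY_PRESET["malignant"]
    rng = np.random.default_rng(seed)
    images: list[np.ndarray] = []
    labels: list[int] = []
    for params, count, label in (
        (benign_params, n_benign, LABELS["benign"]),
        (malignant_params, n_malignant, LABELS["malignant"]),
    ):
        for _ in range(count):
            images.append(_render_image(size, params, impulse_rate,
                                        contrast_scale, rng))
            labels.append(label)
    manifest = {
        "seed": seed,
        "size": size,
        "impulse_rate": impulse_rate,
        "contrast_scale": contrast_scale,
        "benign_params": asdict(benign_params),
        "malignant_params": asdict(malignant_params),
        "n_benign": n_benign,
        "n_malignant": n_malignant,
    }
    return SyntheticDataset(images, np.array(labels, dtype=np.int64), manifest)


def make_breakhis_like(magnification: str = "100x", scale: float = 1.0,
                       seed: int = 0, size: int = 64,
                       preset: str = "easy", **kwargs) -> SyntheticDataset:
    """BreakHis-style class counts, optionally scaled down.

    ``scale=1`` reproduces the benchmark bookkeeping exactly: 644 benign +
    1437 malignant = 2081 images at 100x; 623 + 1390 = 2013 at 200x.
    Scaled counts are ``round(scale * count)``.
    """
    if magnification not in BREAKHIS_COUNTS:
        raise ParameterError(f"magnification must be one of {sorted(BREAKHIS_COUNTS)}")
    if not 0 < scale <= 1:
        raise ParameterError("scale must lie in (0, 1]")
    n_b, n_m = BREAKHIS_COUNTS[magnification]
    n_b = int(np.floor(scale * n_b + 0.5))
    n_m = int(np.floor(scale * n_m + 0.5))
    params = EASY_PRESET if preset == "easy" else HARD_PRESET
    ds = generate_dataset(n_b, n_m, size=size,
                          benign_params=params["benign"],
                          malignant_params=params["malignant"],
                          seed=seed, **kwargs)
    ds.manifest.update({"magnification": magnification, "scale": scale,
                        "preset": preset})
    return ds
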