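"""Synthetic B-mode speckle phantoms with severity-dependent dark regions.

Thermally damaged tissue shows up in B-mode ultrasound as low-intensity
speckle regions (grey levels roughly 0-70) that grow in number and size with
burn severity and appear progressively along the imaging depth, driven by
the acoustic impedance contrast of vapour-filled pores.  The phantoms
emulate that phenomenology without any acoustic field simulation:

* the background is multiplicative Rayleigh-style speckle -- the envelope of
  a spatially smoothed complex Gaussian field -- scaled to a mean grey level
  around 120, giving the spatial correlation of a resolved B-mode texture;
  its amplitude fluctuations are compressed around the mean, emulating the
  dynamic-range (log) compression a scan converter applies for display;
* damage is a Poisson-count collection of dark elliptical blobs with smooth
  (Gaussian-profile) attenuation edges; blob count and mean radius grow
  affinely with the severity parameter ``s`` in [0, 1], and blob centres are
  only placed below a depth-onset row that rises towards the surface as
  severity increases;
* blob interiors mix in a spatially rough (uncorrelated) envelope, so dark
  regions both darken and decorrelate the local texture -- this is what
  drives contrast, difference variance, IMC-II and sum entropy up and
  correlation, homogeneity, inverse difference and maximum probability down
  with severity, the trend pattern expected of real burn images.

At ``s = 0`` the expected blob count is zero and the phantom is pure
background speckle.  Generation is fully deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import json
import numpy as np
from scipy.ndimage import gaussian_filter

from .io import DatasetManifest, GreyImage, save_image, write_manifest

__all__ = [
    "PhantomSpec",
    "DEFAULT_SEVERITIES",
    "generate_phantom",
    "generate_dataset",
    "write_dataset",
]

#: The default four-class severity ladder used by the end-to-end checks.
DEFAULT_SEVERITIES: tuple[float, ...] = (0.0, 1.0 / 3.0, 2.0 / 3.0, 1.0)


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one phantom image.

    Severity maps affinely onto blob density and blob radius; all other
    fields are the static acquisition-like geometry.  Units are pixels and
    grey levels.
    """

    severity: float = 0.0
    height: int = 160
    width: int = 120
    levels: int = 256
    mean_grey: float = 120.0
    #: correlation length (Gaussian sigma, px) of the background speckle
    speckle_sigma: float = 3.0
    #: fractional amplitude of background speckle fluctuations around the
    #: mean (display-style dynamic-range compression of the raw envelope)
    speckle_contrast: float = 0.35
    #: expected dark-blob count per pixel at severity 1 (affine in s)
    blob_density_max: float = 3.5e-3
    #: mean blob radius in px: base + gain * s
    blob_radius_base: float = 2.5
    blob_radius_gain: float = 1.5
    #: lognormal sigma of the per-blob radius draw
    blob_radius_spread: float = 0.25
    #: fraction of the depth kept blob-free at severity -> 0 (shrinks with s)
    depth_onset_max: float = 0.5
    #: per-blob peak attenuation: fraction of intensity removed at the centre
    attenuation_range: tuple[float, float] = (0.5, 0.8)
    #: 0 = blob interiors keep the smooth background texture,
    #: 1 = interiors fully replaced by the finer-grained blob texture
    blob_roughness: float = 1.0
    #: correlation length (px) of the blob-interior texture at severity 0;
    #: much shorter than speckle_sigma, so damaged regions look grainy
    blob_texture_sigma: float = 1.0
    #: affine severity gain on the interior correlation length (negative:
    #: the grain gets finer as the microstructure degrades further)
    blob_texture_sigma_gain: float = -0.2
    #: radial profile exponent: 1 = Gaussian attenuation profile, larger
    #: values flatten the core and sharpen the rim of each blob
    blob_profile_power: float = 2.0
    #: exponent mapping the attenuation profile to the rough-texture mixing
    #: weight (< 1 broadens the grainy rim relative to the dark core)
    blob_rough_exponent: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.severity <= 1.0:
            raise ValueError("severity must lie in [0, 1]")
        if self.height < 1 or self.width < 1:
            raise ValueError("phantom must have a positive area")
        lo, hi = self.attenuation_range
        if not 0.0 <= lo <= hi < 1.0:
            raise ValueError("attenuation_range must satisfy 0 <= lo <= hi < 1")

    @property
    def blob_density(self) -> float:
        return self.blob_density_max * self.severity

    @property
    def blob_radius_mean(self) -> float:
        return self.blob_radius_base + self.blob_radius_gain * self.severity

    @property
    def depth_onset(self) -> float:
        return self.depth_onset_max * (1.0 - self.severity)

    @property
    def interior_sigma(self) -> float:
        return max(self.blob_texture_sigma + self.blob_texture_sigma_gain * self.severity, 0.0)


def _envelope(rng: np.random.Generator, shape: tuple[int, int], sigma: float) -> np.ndarray:
    """Unit-mean Rayleigh-style envelope of a smoothed complex Gaussian field."""
    re = rng.standard_normal(shape)
    im = rng.standard_normal(shape)
    if sigma > 0:
        re = gaussian_filter(re, sigma, mode="reflect")
        im = gaussian_filter(im, sigma, mode="reflect")
    env = np.hypot(re, im)
    return env / env.mean()


def generate_phantom(spec: PhantomSpec) -> GreyImage:
    """Render one phantom image from its spec; deterministic given the seed."""
    M, N = spec.height, spec.width
    rng = np.random.default_rng(spec.seed)
    base = _envelope(rng, (M, N), spec.speckle_sigma)
    # display-style compression: damp background fluctuations around the mean
    base = np.maximum(1.0 + spec.speckle_contrast * (base - 1.0), 0.0)
    # blob interiors keep the full (uncompressed, uncorrelated) envelope so
    # damaged regions are both darker and rougher than the background
    rough = _envelope(rng, (M, N), spec.interior_sigma)

    attenuation = np.ones((M, N))
    blob_weight = np.zeros((M, N))
    n_blobs = rng.poisson(spec.blob_density * M * N)
    onset_row = spec.depth_onset * M
    for _ in range(n_blobs):
        cy = rng.uniform(onset_row, M)
        cx = rng.uniform(0, N)
        r = spec.blob_radius_mean * rng.lognormal(0.0, spec.blob_radius_spread)
        aspect = rng.uniform(0.6, 1.4)
        theta = rng.uniform(0.0, np.pi)
        depth = rng.uniform(*spec.attenuation_range)
        ry, rx = r * aspect, r / aspect
        # bounding window of ~3 sigma around the blob
        ext = 3.0 * max(ry, rx)
        y0, y1 = max(0, int(cy - ext)), min(M, int(cy + ext) + 1)
        x0, x1 = max(0, int(cx - ext)), min(N, int(cx + ext) + 1)
        if y0 >= y1 or x0 >= x1:
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1]
        dy, dx = yy - cy, xx - cx
        u = (np.cos(theta) * dx + np.sin(theta) * dy) / rx
        v = (-np.sin(theta) * dx + np.cos(theta) * dy) / ry
        q = u**2 + v**2
        w = np.exp(-0.5 * q**spec.blob_profile_power)
        attenuation[y0:y1, x0:x1] *= 1.0 - depth * w
        blob_weight[y0:y1, x0:x1] = np.maximum(
            blob_weight[y0:y1, x0:x1], w**spec.blob_rough_exponent
        )

    mix = base * (1.0 - spec.blob_roughness * blob_weight) + rough * (
        spec.blob_roughness * blob_weight
    )
    img = spec.mean_grey * mix * attenuation
    img = np.clip(np.rint(img), 0, spec.levels - 1).astype(np.int64)
    return GreyImage(img, levels=spec.levels, source_id=f"phantom(s={spec.severity:.3f},seed={spec.seed})")


def generate_dataset(
    severities=DEFAULT_SEVERITIES,
    n_per_class: int = 30,
    base_spec: PhantomSpec | None = None,
    seed: int = 0,
    labels=None,
) -> tuple[DatasetManifest, dict[str, GreyImage]]:
    """Generate a labelled multi-class phantom dataset.

    Each severity becomes one class of ``n_per_class`` phantoms with
    per-image seeds derived from ``seed``; the returned manifest pairs the
    in-memory image keys with the class labels (severity names by default).
    """
    severities = tuple(float(s) for s in severities)
    if len(set(severities)) != len(severities):
        raise ValueError("severities must be distinct")
    if n_per_class < 2:
        raise ValueError("n_per_class must be >= 2")
    if base_spec is None:
        base_spec = PhantomSpec()
    if labels is None:
        labels = tuple(f"severity_{s:.2f}" for s in severities)
    if len(labels) != len(severities):
        raise ValueError("labels must match severities in length")
    child_seeds = np.random.SeedSequence(seed).generate_state(
        len(severities) * n_per_class
    ) % (2**31)
    entries = []
    images: dict[str, GreyImage] = {}
    k = 0
    for s, lab in zip(severities, labels):
        for j in range(n_per_class):
            spec = replace(base_spec, severity=s, seed=int(child_seeds[k]))
            key = f"{lab}/img_{j:03d}.png"
            images[key] = generate_phantom(spec)
            entries.append((key, lab))
            k += 1
    return DatasetManifest(tuple(entries)), images


def write_dataset(
    manifest: DatasetManifest,
    images: dict[str, GreyImage],
    out_dir,
    base_spec: PhantomSpec | None = None,
    seed: int | None = None,
) -> Path:
    """Write PNGs, ``manifest.csv`` and a JSON sidecar with the generator spec."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for key, _ in manifest.entries:
        dest = out_dir / key
        dest.parent.mkdir(parents=True, exist_ok=True)
        save_image(images[key], dest)
    write_manifest(manifest, out_dir / "manifest.csv")
    if base_spec is not None:
        sidecar = {
            "base_spec": {
                f: getattr(base_spec, f) for f in base_spec.__dataclass_fields__
            },
            "seed": seed,
            "labels": list(manifest.labels),
        }
        with open(out_dir / "phantom_spec.json", "w") as fh:
            json.dump(sidecar, fh, indent=2)
    return out_dir / "manifest.csv"
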