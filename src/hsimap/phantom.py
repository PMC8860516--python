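"""Synthetic hyperspectral phantoms with known tissue regions and speckle.

The generator emulates a coherent-imaging acquisition of a few spatially
contiguous "tissue" regions: each class carries a smooth reflectance
spectrum (a sum of Gaussian bumps over wavelength), pixels within a class
scatter around that spectrum, and the whole cube is corrupted by
fully-developed multiplicative speckle, ``J = a * n`` with ``n`` drawn from
a unit-mean gamma law of shape ``L`` ("looks"); var(n) = 1/L.

Everything is deterministic given the spec's single integer seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .cube import HyperspectralCube, write_cube, read_cube

__all__ = ["PhantomSpec", "SpecklePhantom", "generate_phantom", "phantom_to_files"]

_GEOMETRIES = ("blobs", "stripes", "nested-ellipses")


@dataclass
class PhantomSpec:
    """Parameters of a synthetic phantom.

    ``signature_means`` may be ``None`` (signatures are drawn from the seed,
    spaced so class mean spectra separate by at least ``3 * intra_class_sd``
    at the most discriminative band) or a list of per-class bump lists
    ``[(center_nm, width_nm, amplitude), ...]``.

    ``speckle_looks=None`` disables noise entirely (the no-noise limit
    ``L -> infinity``).
    """

    height: int = 64
    width: int = 64
    n_bands: int = 128
    wavelength_range: tuple[float, float] = (400.0, 1300.0)
    n_classes: int = 3
    region_geometry: str = "blobs"
    signature_means: list | None = None
    intra_class_sd: float = 0.02
    speckle_looks: float | None = 4.0
    seed: int = 0

    def validate(self) -> None:
        if self.height < 4 or self.width < 4:
            raise ValueError(
                f"height/width must be >= 4; got height={self.height}, "
                f"width={self.width}"
            )
        if self.n_bands < 3:
            raise ValueError(f"n_bands must be >= 3; got n_bands={self.n_bands}")
        lo, hi = self.wavelength_range
        if not lo < hi:
            raise ValueError(
                f"wavelength_range must be increasing; got {self.wavelength_range}"
            )
        if not 2 <= self.n_classes <= 5:
            raise ValueError(f"n_classes must be in [2, 5]; got {self.n_classes}")
        if self.region_geometry not in _GEOMETRIES:
            raise ValueError(
                f"region_geometry must be one of {_GEOMETRIES}; "
                f"got {self.region_geometry!r}"
            )
        if self.intra_class_sd < 0:
            raise ValueError(f"intra_class_sd must be >= 0; got {self.intra_class_sd}")
        if self.speckle_looks is not None and not self.speckle_looks > 0:
            raise ValueError(
                f"speckle_looks must be positive or None; got {self.speckle_looks}"
            )

    @property
    def wavelengths_nm(self) -> np.ndarray:
        return np.linspace(*self.wavelength_range, self.n_bands)


@dataclass
class SpecklePhantom:
    """A generated phantom: clean cube, noise field, noisy cube, truth labels."""

    clean_cube: np.ndarray
    noise_field: np.ndarray
    noisy_cube: np.ndarray
    truth_labels: np.ndarray
    wavelengths_nm: np.ndarray
    spec: PhantomSpec
    signature_spectra: np.ndarray | None = None  # (n_classes, B) model means

    def noisy(self) -> HyperspectralCube:
        return HyperspectralCube(self.noisy_cube, self.wavelengths_nm)

    def clean(self) -> HyperspectralCube:
        return HyperspectralCube(self.clean_cube, self.wavelengths_nm)


# ---------------------------------------------------------------------------
# Region geometry


def _blob_labels(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Contiguous random regions: quantile-sliced low-pass Gaussian field."""
    field = rng.standard_normal((spec.height, spec.width))
    sigma = max(spec.height, spec.width) / 8.0
    smooth = gaussian_filter(field, sigma=sigma, mode="reflect")
    # Quantile thresholds give each class an equal pixel share by construction.
    qs = np.quantile(smooth, np.linspace(0, 1, spec.n_classes + 1)[1:-1])
    return np.searchsorted(qs, smooth, side="right").astype(np.int64)


def _stripe_labels(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    rows = np.arange(spec.height)
    edges = np.linspace(0, spec.height, spec.n_classes + 1)[1:-1]
    lab = np.searchsorted(edges, rows, side="right")
    return np.repeat(lab[:, None], spec.width, axis=1).astype(np.int64)


def _ellipse_labels(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    yy, xx = np.mgrid[0:spec.height, 0:spec.width]
    cy, cx = (spec.height - 1) / 2.0, (spec.width - 1) / 2.0
    r = np.sqrt(((yy - cy) / (spec.height / 2.0)) ** 2
                + ((xx - cx) / (spec.width / 2.0)) ** 2)
    # Equal-area rings in normalized radius.
    edges = np.sqrt(np.linspace(0, 1, spec.n_classes + 1)[1:-1]) * r.max()
    return np.searchsorted(edges, r, side="right").astype(np.int64)


_GEOMETRY_FNS = {
    "blobs": _blob_labels,
    "stripes": _stripe_labels,
    "nested-ellipses": _ellipse_labels,
}


# ---------------------------------------------------------------------------
# Spectral signatures


def _bump_spectrum(wl: np.ndarray, bumps: list[tuple[float, float, float]]
                   ) -> np.ndarray:
    s = np.zeros_like(wl)
    for center, width, amp in bumps:
        s += amp * np.exp(-0.5 * ((wl - center) / width) ** 2)
    return np.clip(s, 0.0, 1.0)


def _default_signatures(spec: PhantomSpec, rng: np.random.Generator) -> list:
    """Draw per-class bump parameters with well-separated primary bumps.

    Primary bump centers are spread evenly across the wavelength range so
    that at each class's home band the other classes contribute little,
    keeping the pairwise separation comfortably above 3 * intra_class_sd.
    """
    lo, hi = spec.wavelength_range
    span = hi - lo
    centers = np.linspace(lo + 0.12 * span, hi - 0.12 * span, spec.n_classes)
    # Bumps must be resolvable on the band grid: never narrower than the
    # band spacing, or a coarse grid can sample straight past them.
    spacing = span / max(spec.n_bands - 1, 1)
    sigs = []
    for c in centers:
        width = max(span / (6.0 * spec.n_classes), 1.5 * spacing)
        amp = float(rng.uniform(0.55, 0.85))
        bumps = [(float(c), width, amp)]
        # Optional broad secondary bump: shared low-amplitude background.
        if rng.random() < 0.7:
            bumps.append((float(rng.uniform(lo, hi)), span / 3.0,
                          float(rng.uniform(0.05, 0.15))))
        sigs.append(bumps)
    return sigs


def _check_separation(means: np.ndarray, sd: float) -> float:
    """Smallest pairwise max-band separation between class mean spectra."""
    worst = math.inf
    k = means.shape[0]
    for i in range(k):
        for j in range(i + 1, k):
            worst = min(worst, float(np.max(np.abs(means[i] - means[j]))))
    return worst


# ---------------------------------------------------------------------------


def generate_phantom(spec: PhantomSpec) -> SpecklePhantom:
    """Generate a seeded speckle phantom satisfying the spec's invariants.

    The noisy cube factorizes exactly as ``clean * noise``; speckle factors
    are Gamma(L, 1/L) (unit mean, variance 1/L). Raises ``ValueError`` when
    the spec is invalid or the requested signatures are not separable by at
    least three intra-class standard deviations at any band.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    wl = spec.wavelengths_nm

    labels = _GEOMETRY_FNS[spec.region_geometry](spec, rng)
    n_pix = labels.size
    counts = np.bincount(labels.ravel(), minlength=spec.n_classes)
    if np.any(counts < 0.01 * n_pix):
        raise ValueError(
            f"region_geometry produced a class below 1% of pixels: {counts}"
        )

    if spec.signature_means is not None:
        bumps = spec.signature_means
        if len(bumps) != spec.n_classes:
            raise ValueError(
                f"signature_means has {len(bumps)} entries for n_classes="
                f"{spec.n_classes}"
            )
        means = np.stack([_bump_spectrum(wl, b) for b in bumps])
        sep = _check_separation(means, spec.intra_class_sd)
        if spec.intra_class_sd > 0 and sep < 3.0 * spec.intra_class_sd:
            raise ValueError(
                f"class mean spectra separate by only {sep:.4f} at the best "
                f"band; need >= 3 * intra_class_sd = "
                f"{3 * spec.intra_class_sd:.4f}"
            )
    else:
        # Seeded redraws until the separation guarantee holds (the random
        # secondary bumps can occasionally close the gap on coarse grids).
        for _ in range(20):
            bumps = _default_signatures(spec, rng)
            means = np.stack([_bump_spectrum(wl, b) for b in bumps])
            if (spec.intra_class_sd == 0
                    or _check_separation(means, spec.intra_class_sd)
                    >= 3.0 * spec.intra_class_sd):
                break
        else:
            raise ValueError(
                "could not draw class signatures separated by 3 * "
                "intra_class_sd; lower intra_class_sd or supply "
                "signature_means"
            )

    clean = means[labels]  # (H, W, B)
    if spec.intra_class_sd > 0:
        clean = clean + rng.normal(
            0.0, spec.intra_class_sd, size=clean.shape
        )
    clean = np.clip(clean, 0.0, 1.0)

    if spec.speckle_looks is None:
        noise = np.ones_like(clean)
    else:
        L = float(spec.speckle_looks)
        noise = rng.gamma(shape=L, scale=1.0 / L, size=clean.shape)
    noisy = clean * noise

    return SpecklePhantom(
        clean_cube=clean,
        noise_field=noise,
        noisy_cube=noisy,
        truth_labels=labels,
        wavelengths_nm=wl,
        spec=spec,
        signature_spectra=means,
    )


def phantom_to_files(phantom: SpecklePhantom, directory: Path | str) -> dict:
    """Write a phantom to ``directory``; returns the JSON-able manifest.

    Writes the noisy cube (+labels) and the clean cube as .npz archives with
    ENVI-style headers, plus ``manifest.json``. Round-trips losslessly
    through :func:`hsimap.cube.read_cube`.
    """
    if str(directory) == "":
        raise ValueError("empty output directory path")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    noisy_path = write_cube(phantom.noisy(), directory / "noisy.npz",
                            labels=phantom.truth_labels)
    clean_path = write_cube(phantom.clean(), directory / "clean.npz",
                            labels=phantom.truth_labels)
    manifest = {
        "height": phantom.spec.height,
        "width": phantom.spec.width,
        "n_bands": phantom.spec.n_bands,
        "wavelength_range": list(phantom.spec.wavelength_range),
        "n_classes": phantom.spec.n_classes,
        "region_geometry": phantom.spec.region_geometry,
        "intra_class_sd": phantom.spec.intra_class_sd,
        "speckle_looks": phantom.spec.speckle_looks,
        "seed": phantom.spec.seed,
        "files": {
            "noisy_cube": noisy_path.name,
            "clean_cube": clean_path.name,
            "noisy_header": noisy_path.name + ".hdr",
            "clean_header": clean_path.name + ".hdr",
        },
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def phantom_from_files(directory: Path | str) -> SpecklePhantom:
    """Re-load a phantom written by :func:`phantom_to_files`."""
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    noisy, labels = read_cube(directory / manifest["files"]["noisy_cube"])
    clean, _ = read_cube(directory / manifest["files"]["clean_cube"])
    spec = PhantomSpec(
        height=manifest["height"], width=manifest["width"],
        n_bands=manifest["n_bands"],
        wavelength_range=tuple(manifest["wavelength_range"]),
        n_classes=manifest["n_classes"],
        region_geometry=manifest["region_geometry"],
        intra_class_sd=manifest["intra_class_sd"],
        speckle_looks=manifest["speckle_looks"], seed=manifest["seed"],
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        noise = np.where(clean.data > 0, noisy.data / np.where(clean.data > 0, clean.data, 1.0), 1.0)
    return SpecklePhantom(
        clean_cube=clean.data, noise_field=noise, noisy_cube=noisy.data,
        truth_labels=labels, wavelengths_nm=noisy.wavelengths_nm, spec=spec,
    )
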