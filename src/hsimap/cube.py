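"""Hyperspectral cube container, readers/writers, and color conversions.

A cube is an ``H x W x B`` array of nonnegative reflectance values with a
strictly increasing wavelength vector (nm) along the last (band) axis.
Pixels are indexed 0-based, row-major, with row 0 the top image line.

On disk a cube is a compressed ``.npz`` archive (keys ``cube``,
``wavelengths`` and optionally ``labels``) accompanied by an ENVI-style
ASCII header (``samples``/``lines``/``bands``/``wavelength``) so that
third-party hyperspectral tooling can at least read the geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "HyperspectralCube",
    "RGBImage",
    "GrayImage",
    "read_cube",
    "write_cube",
    "read_envi_header",
    "write_envi_header",
    "cube_to_rgb",
    "rgb_to_gray",
]

#: BT.601 luminance weights used for RGB -> grayscale.
GRAY_WEIGHTS = (0.299, 0.587, 0.114)

#: Band-window centers (nm) used to render R, G, B channels.
RGB_CENTERS_NM = (650.0, 550.0, 450.0)
#: Half-width (nm) of each rendering window.
RGB_WINDOW_NM = 30.0


@dataclass
class HyperspectralCube:
    """H x W x B reflectance cube with per-band wavelengths in nm."""

    data: np.ndarray
    wavelengths_nm: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(
                f"cube data must be 3-D (H, W, B); got shape {self.data.shape}"
            )
        if self.wavelengths_nm.ndim != 1 or len(self.wavelengths_nm) != self.n_bands:
            raise ValueError(
                f"wavelength vector length {self.wavelengths_nm.size} does not "
                f"match band count {self.n_bands}"
            )
        if np.any(np.diff(self.wavelengths_nm) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if np.any(np.isnan(self.data)):
            raise ValueError("cube contains NaN values")
        if np.any(self.data < 0):
            raise ValueError("cube contains negative reflectance values")

    @property
    def height(self) -> int:
        return self.data.shape[0]

    @property
    def width(self) -> int:
        return self.data.shape[1]

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]

    def sorted_by_wavelength(self) -> "HyperspectralCube":
        """Return a copy with bands sorted by wavelength (no-op if sorted)."""
        order = np.argsort(self.wavelengths_nm, kind="stable")
        return HyperspectralCube(self.data[:, :, order], self.wavelengths_nm[order])

    @classmethod
    def from_unsorted(cls, data: np.ndarray, wavelengths_nm: np.ndarray
                      ) -> "HyperspectralCube":
        """Build a cube from bands in arbitrary wavelength order."""
        wavelengths_nm = np.asarray(wavelengths_nm, dtype=float)
        order = np.argsort(wavelengths_nm, kind="stable")
        return cls(np.asarray(data, dtype=float)[:, :, order],
                   wavelengths_nm[order])


@dataclass
class RGBImage:
    """H x W x 3 image in [0, 1] plus a note on how it was rendered."""

    data: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.shape[2] != 3:
            raise ValueError(f"RGB image must be (H, W, 3); got {self.data.shape}")
        if np.any(self.data < 0) or np.any(self.data > 1):
            raise ValueError("RGB values must lie in [0, 1]")


@dataclass
class GrayImage:
    """H x W image in [0, 1]."""

    data: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError(f"gray image must be 2-D; got {self.data.shape}")
        if np.any(self.data < 0) or np.any(self.data > 1):
            raise ValueError("gray values must lie in [0, 1]")


# ---------------------------------------------------------------------------
# I/O


def write_envi_header(path: Path | str, height: int, width: int,
                      wavelengths_nm: np.ndarray) -> None:
    """Write a minimal ENVI-style ASCII header."""
    wl = ", ".join(f"{w:.4f}" for w in np.asarray(wavelengths_nm, dtype=float))
    text = (
        "ENVI\n"
        f"samples = {width}\n"
        f"lines = {height}\n"
        f"bands = {len(wavelengths_nm)}\n"
        "wavelength units = nm\n"
        f"wavelength = {{{wl}}}\n"
    )
    Path(path).write_text(text)


def read_envi_header(path: Path | str) -> dict:
    """Parse the ENVI-style header dialect written by :func:`write_envi_header`."""
    text = Path(path).read_text()
    out: dict = {}
    # Brace-delimited values may span lines; normalise first.
    text = text.replace("\n", " \n")
    for key in ("samples", "lines", "bands"):
        for line in text.splitlines():
            if line.strip().lower().startswith(key):
                out[key] = int(line.split("=", 1)[1].strip())
    if "wavelength = {" in text or "wavelength= {" in text or "wavelength ={" in text:
        start = text.index("{")
        end = text.index("}", start)
        out["wavelength"] = np.array(
            [float(tok) for tok in text[start + 1:end].split(",") if tok.strip()]
        )
    return out


def _header_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".hdr") if path.suffix != ".hdr" else path


def write_cube(cube: HyperspectralCube, path: Path | str,
               labels: np.ndarray | None = None) -> Path:
    """Write a cube (and optional label map) to ``path`` (.npz) + ENVI header."""
    path = Path(path)
    if str(path) == "":
        raise ValueError("empty output path")
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {"cube": cube.data, "wavelengths": cube.wavelengths_nm}
    if labels is not None:
        labels = np.asarray(labels)
        if labels.shape != (cube.height, cube.width):
            raise ValueError(
                f"label map shape {labels.shape} does not match cube "
                f"({cube.height}, {cube.width})"
            )
        payload["labels"] = labels
    np.savez_compressed(path, **payload)
    if path.suffix != ".npz":  # np.savez appends .npz when missing
        path = path.with_suffix(path.suffix + ".npz")
    write_envi_header(_header_path(path), cube.height, cube.width, cube.wavelengths_nm)
    return path


def read_cube(path: Path | str, check_header: bool = True
              ) -> tuple[HyperspectralCube, np.ndarray | None]:
    """Read a cube archive; returns ``(cube, labels-or-None)``.

    If the sibling ENVI header exists and ``check_header`` is true, its
    geometry must agree with the archive.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with np.load(path) as npz:
        missing = {"cube", "wavelengths"} - set(npz.files)
        if missing:
            raise KeyError(f"cube archive {path} missing keys: {sorted(missing)}")
        data = npz["cube"]
        wavelengths = npz["wavelengths"]
        labels = npz["labels"] if "labels" in npz.files else None
    cube = HyperspectralCube(data, wavelengths)
    hdr = _header_path(path)
    if check_header and hdr.exists():
        meta = read_envi_header(hdr)
        if "bands" in meta and meta["bands"] != cube.n_bands:
            raise ValueError(
                f"header declares bands={meta['bands']} but cube has "
                f"B={cube.n_bands} bands"
            )
        if "samples" in meta and meta["samples"] != cube.width:
            raise ValueError(
                f"header declares samples={meta['samples']} but cube width is "
                f"{cube.width}"
            )
        if "lines" in meta and meta["lines"] != cube.height:
            raise ValueError(
                f"header declares lines={meta['lines']} but cube height is "
                f"{cube.height}"
            )
    return cube, labels


# ---------------------------------------------------------------------------
# Conversions


def _minmax(channel: np.ndarray) -> np.ndarray:
    lo, hi = channel.min(), channel.max()
    if hi > lo:
        return (channel - lo) / (hi - lo)
    # Constant channel: map to its (clipped) value so flat cubes stay flat.
    return np.clip(channel, 0.0, 1.0)


def cube_to_rgb(cube: HyperspectralCube, fallback: bool = True) -> RGBImage:
    """Render a cube to RGB by averaging band windows at 650/550/450 nm.

    Each channel averages the bands within +-30 nm of its center wavelength
    and is min-max normalized to [0, 1]. Cubes with no visible-range bands
    fall back to averaging the first/middle/last thirds of the band axis.
    """
    if cube.n_bands < 3:
        raise ValueError(f"need at least 3 bands to render RGB; got {cube.n_bands}")
    cube = cube.sorted_by_wavelength()
    wl = cube.wavelengths_nm
    channels = []
    windows_hit = []
    for center in RGB_CENTERS_NM:
        mask = np.abs(wl - center) <= RGB_WINDOW_NM
        windows_hit.append(mask.any())
        channels.append(mask)
    visible = np.sum((wl >= 400) & (wl <= 700))
    if all(windows_hit) and visible >= 3:
        rgb = np.stack(
            [_minmax(cube.data[:, :, m].mean(axis=2)) for m in channels], axis=-1
        )
        prov = "band windows 650/550/450 +-30 nm, per-channel min-max"
    else:
        if not fallback:
            raise ValueError(
                "cube lacks bands in the visible range and fallback is disabled"
            )
        thirds = np.array_split(np.arange(cube.n_bands), 3)
        # Long wavelengths render red: last third -> R, middle -> G, first -> B.
        rgb = np.stack(
            [
                _minmax(cube.data[:, :, idx].mean(axis=2))
                for idx in (thirds[2], thirds[1], thirds[0])
            ],
            axis=-1,
        )
        prov = "fallback band thirds (no visible bands), per-channel min-max"
    return RGBImage(np.clip(rgb, 0.0, 1.0), provenance=prov)


def rgb_to_gray(img: RGBImage) -> GrayImage:
    """BT.601 luminance: gray = 0.299 R + 0.587 G + 0.114 B."""
    w = np.asarray(GRAY_WEIGHTS)
    gray = np.tensordot(img.data, w, axes=([2], [0]))
    return GrayImage(np.clip(gray, 0.0, 1.0), provenance="BT.601 luminance")
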