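"""File formats: grayscale TIFF images/stacks and plain-text (TOML)
codebook and simulation configuration files.

Integer images round-trip losslessly; float frames are written as 32-bit
float TIFF.  All frequencies in files are cycles/pixel.
"""

from __future__ import annotations

import tomllib
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import tifffile

from .codec import CarrierCode, CodeBook, Frame, MultiplexedExposure, SensorModel
from .errors import ValidationError

__all__ = [
    "read_image",
    "write_image",
    "read_stack",
    "write_stack",
    "read_codebook",
    "write_codebook",
]


def _check_grayscale(path: Path) -> None:
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        if page.samplesperpixel != 1:
            raise ValidationError(
                f"{path}: only single-channel grayscale TIFF is supported "
                f"(got {page.samplesperpixel} samples/pixel)"
            )


def read_image(path: str | Path, pixel_pitch: float = 7.0 / 1002.0) -> Frame:
    """Read a single-page grayscale TIFF as a frame."""
    path = Path(path)
    _check_grayscale(path)
    arr = tifffile.imread(path)
    if arr.ndim == 3:
        raise ValidationError(
            f"{path} is a multi-page TIFF; use read_stack"
        )
    return Frame(np.asarray(arr, dtype=float), pixel_pitch=pixel_pitch)


def write_image(
    path: str | Path, image: Frame | MultiplexedExposure | np.ndarray
) -> None:
    """Write one image as grayscale TIFF; integer data (e.g. exposures)
    keeps its dtype, float frames are stored as 32-bit float."""
    if isinstance(image, MultiplexedExposure):
        arr = image.pixels
    elif isinstance(image, Frame):
        arr = image.pixels.astype(np.float32)
    else:
        arr = np.asarray(image)
        if arr.dtype.kind == "f":
            arr = arr.astype(np.float32)
    tifffile.imwrite(Path(path), arr, photometric="minisblack")


def read_stack(
    path: str | Path, pixel_pitch: float = 7.0 / 1002.0
) -> list[Frame]:
    """Read a multi-page grayscale TIFF as an ordered frame list."""
    path = Path(path)
    _check_grayscale(path)
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValidationError(f"{path}: expected a 2D or 3D grayscale stack")
    return [Frame(np.asarray(a, dtype=float), pixel_pitch=pixel_pitch) for a in arr]


def write_stack(path: str | Path, frames: Sequence[Frame]) -> None:
    """Write frames as a multi-page 32-bit float TIFF, order preserved."""
    if len(frames) == 0:
        raise ValidationError("cannot write an empty stack")
    data = np.stack([f.pixels for f in frames]).astype(np.float32)
    tifffile.imwrite(Path(path), data, photometric="minisblack")


# --------------------------------------------------------------------------
# codebook files

_CODEBOOK_KEYS = {"filter_radius", "baseband_radius", "carriers"}
_CARRIER_KEYS = {"nu_x", "nu_y", "m", "phi"}


def write_codebook(path: str | Path, codebook: CodeBook) -> None:
    """Write a codebook as a plain-text TOML file (one carrier per
    ``[[carriers]]`` entry, frequencies in cycles/pixel)."""
    lines = [
        f"filter_radius = {codebook.filter_radius!r}",
        f"baseband_radius = {codebook.baseband_radius!r}",
    ]
    for code in codebook.codes:
        lines += [
            "",
            "[[carriers]]",
            f"nu_x = {code.nu[0]!r}",
            f"nu_y = {code.nu[1]!r}",
            f"m = {code.m!r}",
            f"phi = {code.phi!r}",
        ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_codebook(path: str | Path) -> CodeBook:
    """Read and validate a codebook file.

    Unknown keys are rejected; CodeBook validation runs on the result, so
    e.g. duplicate or overlapping carriers raise with the offending pair
    named.
    """
    raw = Path(path).read_text()
    try:
        doc = tomllib.loads(raw)
    except tomllib.TOMLDecodeError as exc:
        raise ValidationError(f"{path}: malformed codebook file: {exc}") from exc
    unknown = set(doc) - _CODEBOOK_KEYS
    if unknown:
        raise ValidationError(f"{path}: unknown keys {sorted(unknown)}")
    if "carriers" not in doc or not doc["carriers"]:
        raise ValidationError(f"{path}: no carriers defined")
    codes = []
    for i, entry in enumerate(doc["carriers"]):
        bad = set(entry) - _CARRIER_KEYS
        if bad:
            raise ValidationError(
                f"{path}: carrier {i} has unknown keys {sorted(bad)}"
            )
        missing = {"nu_x", "nu_y"} - set(entry)
        if missing:
            raise ValidationError(
                f"{path}: carrier {i} is missing {sorted(missing)}"
            )
        codes.append(
            CarrierCode(
                nu=(entry["nu_x"], entry["nu_y"]),
                m=entry.get("m", 1.0),
                phi=entry.get("phi", 0.0),
            )
        )
    return CodeBook(
        codes=codes,
        filter_radius=float(doc.get("filter_radius", 0.0)),
        baseband_radius=float(doc.get("baseband_radius", 0.0)),
    )


# --------------------------------------------------------------------------
# simulation / run configuration

_SIM_SECTIONS = {"pump", "read", "medium", "grid", "delays", "seed", "sensor"}


def read_sim_config(path: str | Path) -> dict[str, Any]:
    """Parse a simulation config (TOML); unknown top-level keys rejected.

    Sections: ``[pump]``, ``[read]`` (PulseSpec fields), ``[medium]``
    (KerrMediumSpec), ``[grid]`` (GridSpec), plus ``delays`` (fs list) and
    optional ``seed`` and ``[sensor]``.
    """
    raw = Path(path).read_text()
    try:
        doc = tomllib.loads(raw)
    except tomllib.TOMLDecodeError as exc:
        raise ValidationError(f"{path}: malformed config: {exc}") from exc
    unknown = set(doc) - _SIM_SECTIONS
    if unknown:
        raise ValidationError(f"{path}: unknown keys {sorted(unknown)}")
    if "delays" not in doc:
        raise ValidationError(f"{path}: missing 'delays'")
    return doc


def sensor_from_config(doc: dict[str, Any]) -> SensorModel:
    cfg = dict(doc.get("sensor", {}))
    unknown = set(cfg) - {
        "bit_depth", "full_well", "read_noise_sigma", "shot_noise", "seed",
    }
    if unknown:
        raise ValidationError(f"sensor config has unknown keys {sorted(unknown)}")
    return SensorModel(**cfg)
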