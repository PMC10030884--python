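"""File I/O, bit-depth conversion and solution arithmetic.

TIFF stacks are read and written through :mod:`tifffile`; CSV artifacts use
comma separation, a header row, UTF-8 and 0-based coordinates.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .simulate import MarkerImage, MovieStack

__all__ = [
    "SolutionSpec",
    "read_movie",
    "write_movie",
    "read_marker",
    "write_marker",
    "convert_16_to_8bit",
    "dilute",
    "save_yaml",
    "load_yaml",
    "save_json",
]


@dataclass
class SolutionSpec:
    """A stock dilution into a bath volume."""

    stock_concentration: float  # in the unit of choice
    stock_volume: float  # mL
    bath_volume: float  # mL

    def final_concentration(self) -> float:
        return dilute(self.stock_concentration, self.stock_volume,
                      self.bath_volume)


def dilute(stock_conc: float, stock_vol: float, bath_vol: float) -> float:
    """Final concentration after adding a stock volume to a bath volume.

    final = stock_conc * stock_vol / (stock_vol + bath_vol).  The same
    formula dilutes a bath component by an added solvent volume when called
    with the component concentration as ``stock_conc`` and the two volumes
    swapped accordingly.
    """
    if stock_vol <= 0 or bath_vol <= 0:
        raise ValueError("volumes must be > 0")
    return stock_conc * stock_vol / (stock_vol + bath_vol)


def read_movie(path, pixel_size: float = 0.10833,
               frame_interval: float = 0.05) -> MovieStack:
    """Read a multipage grayscale TIFF movie."""
    data = tifffile.imread(str(path))
    if data.ndim == 2:
        data = data[None]
    bit_depth = 8 if data.dtype == np.uint8 else 16
    return MovieStack(data, pixel_size=pixel_size,
                      frame_interval=frame_interval, bit_depth=bit_depth)


def write_movie(path, movie: MovieStack) -> None:
    tifffile.imwrite(str(path), movie.data)


def read_marker(path, pixel_size: float = 0.100) -> MarkerImage:
    data = tifffile.imread(str(path))
    return MarkerImage(data, pixel_size=pixel_size)


def write_marker(path, marker: MarkerImage) -> None:
    tifffile.imwrite(str(path), marker.data)


def convert_16_to_8bit(movie: MovieStack) -> MovieStack:
    """Linear global min-max rescale of a 16-bit stack to 8-bit.

    Values map the stack minimum to 0 and maximum to 255, rounding half up.
    A constant stack converts to all zeros with a warning.
    """
    if movie.bit_depth != 16:
        raise ValueError("input movie must be 16-bit")
    data = movie.data.astype(float)
    lo, hi = data.min(), data.max()
    if hi == lo:
        warnings.warn("constant stack: 8-bit conversion yields all zeros",
                      stacklevel=2)
        out = np.zeros_like(data, dtype=np.uint8)
    else:
        scaled = (data - lo) / (hi - lo) * 255.0
        out = np.floor(scaled + 0.5).astype(np.uint8)  # round half up
    return MovieStack(out, pixel_size=movie.pixel_size,
                      frame_interval=movie.frame_interval, bit_depth=8)


def save_yaml(path, obj) -> None:
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=False))


def load_yaml(path):
    return yaml.safe_load(Path(path).read_text())


def save_json(path, obj) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.bool_,)):
            return bool(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default,
                                     sort_keys=True))
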