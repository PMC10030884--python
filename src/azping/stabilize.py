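"""Rigid x-y video stabilization and confocal-to-live registration.

Stabilization translates every frame by the integer (dx, dy) shift that
maximizes the normalized cross-correlation between a reference rectangle in
frame 0 and the current frame, both Gaussian-smoothed (sigma 5 px) for the
shift estimate only.  Registration fits a planar (affine or bilinear)
transform from user-supplied control-point pairs and resamples images with
bilinear interpolation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from skimage.feature import match_template
from skimage.filters import gaussian
from skimage.transform import warp
from sklearn.base import BaseEstimator

from .simulate import MovieStack

__all__ = [
    "ShiftSeries",
    "PlanarTransform",
    "MovieStabilizer",
    "ControlPointWarp",
    "stabilize",
    "fit_transform",
    "apply_transform",
    "shift_frame",
]


@dataclass
class ShiftSeries:
    """Per-frame integer (dx, dy) shifts applied relative to frame 0."""

    shifts: np.ndarray  # (n_frames, 2) int

    def __post_init__(self) -> None:
        self.shifts = np.asarray(self.shifts, dtype=int)
        if self.shifts.ndim != 2 or self.shifts.shape[1] != 2:
            raise ValueError("shifts must be (n_frames, 2)")
        if np.any(self.shifts[0] != 0):
            raise ValueError("shift of frame 0 must be (0, 0)")

    def __len__(self) -> int:
        return len(self.shifts)

    def __getitem__(self, i):
        return tuple(self.shifts[i])


@dataclass
class PlanarTransform:
    """Planar transform mapping confocal (x, y) to live-movie (x, y).

    ``kind='affine'``: homogeneous 3x3 matrix (translation, rotation,
    shear/scale composite).  ``kind='bilinear'``: 8 parameters, per output
    coordinate ``x' = a0 + a1*x + a2*y + a3*x*y``.  For bilinear, the image
    inverse map has no closed form; ``inverse_params`` holds the bilinear
    fit of the swapped control points (exact at 4 points).
    """

    kind: str
    matrix: np.ndarray | None = None  # affine, 3x3
    params: np.ndarray | None = None  # bilinear, (2, 4)
    inverse_params: np.ndarray | None = None  # bilinear live->confocal

    def __post_init__(self) -> None:
        if self.kind not in ("affine", "bilinear"):
            raise ValueError("kind must be 'affine' or 'bilinear'")
        if self.kind == "affine":
            self.matrix = np.asarray(self.matrix, dtype=float)
            if self.matrix.shape != (3, 3):
                raise ValueError("affine matrix must be 3x3")
            if abs(np.linalg.det(self.matrix)) < 1e-12:
                raise ValueError("affine matrix is singular")

    def apply_points(self, points: np.ndarray) -> np.ndarray:
        """Map (n, 2) confocal coordinates into live coordinates."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        if self.kind == "affine":
            homo = np.column_stack([pts, np.ones(len(pts))])
            out = (self.matrix @ homo.T).T
            return out[:, :2] / out[:, 2:3]
        x, y = pts[:, 0], pts[:, 1]
        design = np.column_stack([np.ones_like(x), x, y, x * y])
        return design @ self.params.T

    def inverse_points(self, points: np.ndarray) -> np.ndarray:
        """Map (n, 2) live coordinates back into confocal coordinates."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        if self.kind == "affine":
            inv = np.linalg.inv(self.matrix)
            homo = np.column_stack([pts, np.ones(len(pts))])
            out = (inv @ homo.T).T
            return out[:, :2] / out[:, 2:3]
        if self.inverse_params is None:
            raise ValueError("bilinear transform has no fitted inverse")
        x, y = pts[:, 0], pts[:, 1]
        design = np.column_stack([np.ones_like(x), x, y, x * y])
        return design @ self.inverse_params.T


def shift_frame(frame: np.ndarray, dx: int, dy: int) -> np.ndarray:
    """Integer-translate a frame, zero-filling pixels shifted into view."""
    out = np.zeros_like(frame)
    h, w = frame.shape
    ys0, ys1 = max(-dy, 0), min(h - dy, h)
    xs0, xs1 = max(-dx, 0), min(w - dx, w)
    if ys0 < ys1 and xs0 < xs1:
        out[ys0 + dy : ys1 + dy, xs0 + dx : xs1 + dx] = frame[ys0:ys1, xs0:xs1]
    return out


class MovieStabilizer(BaseEstimator):
    """Estimate and apply per-frame integer x-y shifts against frame 0.

    Parameters
    ----------
    reference_rect : tuple (x, y, w, h) or None
        Rectangle in frame 0 used as the correlation template.  ``None``
        uses the central half of the frame.
    smooth_sigma : float
        Gaussian sigma (pixels) applied to both template and frames for
        shift estimation only; the output frames are translated unsmoothed.
    max_shift : int or None
        Largest allowed |dx|, |dy|.  ``None`` means a quarter of the frame
        edge.  Larger estimates are clamped with a warning.

    Attributes
    ----------
    shifts_ : ShiftSeries
        Estimated shift to apply per frame (the negated drift).
    """

    def __init__(self, reference_rect=None, smooth_sigma: float = 5.0,
                 max_shift: int | None = None):
        self.reference_rect = reference_rect
        self.smooth_sigma = smooth_sigma
        self.max_shift = max_shift

    def _smooth(self, frame: np.ndarray) -> np.ndarray:
        if self.smooth_sigma <= 0:
            return frame.astype(float)
        return gaussian(frame.astype(float), sigma=self.smooth_sigma,
                        preserve_range=True)

    def fit(self, movie: MovieStack, y=None):
        data = movie.data
        n, h, w = data.shape
        if self.reference_rect is None:
            rect = (w // 4, h // 4, w // 2, h // 2)
        else:
            rect = tuple(int(v) for v in self.reference_rect)
        rx, ry, rw, rh = rect
        if rx < 0 or ry < 0 or rx + rw > w or ry + rh > h:
            raise ValueError("reference_rect must lie inside frame 0")
        max_shift = self.max_shift if self.max_shift is not None else min(h, w) // 4

        template = self._smooth(data[0])[ry : ry + rh, rx : rx + rw]
        if np.ptp(template) == 0:
            raise ValueError("reference region has zero variance")

        shifts = np.zeros((n, 2), dtype=int)
        for t in range(1, n):
            frame_sm = self._smooth(data[t])
            corr = match_template(frame_sm, template, pad_input=False)
            peak = np.unravel_index(np.argmax(corr), corr.shape)
            found_y, found_x = int(peak[0]), int(peak[1])
            dx, dy = rx - found_x, ry - found_y
            if abs(dx) > max_shift or abs(dy) > max_shift:
                warnings.warn(
                    f"frame {t}: estimated shift ({dx}, {dy}) exceeds "
                    f"max_shift={max_shift}; clamped",
                    stacklevel=2,
                )
                dx = int(np.clip(dx, -max_shift, max_shift))
                dy = int(np.clip(dy, -max_shift, max_shift))
            shifts[t] = (dx, dy)
        self.shifts_ = ShiftSeries(shifts)
        return self

    def transform(self, movie: MovieStack) -> MovieStack:
        if not hasattr(self, "shifts_"):
            raise RuntimeError("stabilizer is not fitted")
        data = movie.data
        out = np.empty_like(data)
        out[0] = data[0]
        for t in range(1, len(data)):
            dx, dy = self.shifts_[t]
            out[t] = shift_frame(data[t], dx, dy)
        return replace(movie, data=out)

    def fit_transform(self, movie: MovieStack, y=None) -> MovieStack:
        return self.fit(movie).transform(movie)


def stabilize(movie: MovieStack, reference_rect=None, smooth_sigma: float = 5.0,
              max_shift: int | None = None) -> tuple[MovieStack, ShiftSeries]:
    """Stabilize a movie; returns (stabilized movie, applied shifts)."""
    stab = MovieStabilizer(reference_rect=reference_rect,
                           smooth_sigma=smooth_sigma, max_shift=max_shift)
    out = stab.fit_transform(movie)
    return out, stab.shifts_


def _check_not_collinear(points: np.ndarray, label: str) -> None:
    design = np.column_stack([points, np.ones(len(points))])
    if np.linalg.matrix_rank(design, tol=1e-9 * max(1.0, np.abs(points).max())) < 3:
        raise ValueError(f"{label} control points are collinear or coincident")


def fit_transform(points_live: np.ndarray, points_confocal: np.ndarray,
                  kind: str = "affine") -> PlanarTransform:
    """Fit the planar transform mapping confocal points onto live points.

    Exact solve at the minimal point count (3 affine / 4 bilinear), least
    squares with more points.  Degenerate geometries raise with the name of
    the degeneracy.
    """
    live = np.atleast_2d(np.asarray(points_live, dtype=float))
    conf = np.atleast_2d(np.asarray(points_confocal, dtype=float))
    if live.shape != conf.shape:
        raise ValueError("point sets must have matching shapes")
    n = len(live)
    if kind == "affine":
        if n < 3:
            raise ValueError("affine fit needs at least 3 point pairs")
        _check_not_collinear(conf, "confocal")
        design = np.column_stack([conf, np.ones(n)])
        coefs, *_ = np.linalg.lstsq(design, live, rcond=None)  # (3, 2)
        matrix = np.eye(3)
        matrix[0] = [coefs[0, 0], coefs[1, 0], coefs[2, 0]]
        matrix[1] = [coefs[0, 1], coefs[1, 1], coefs[2, 1]]
        return PlanarTransform(kind="affine", matrix=matrix)
    if kind == "bilinear":
        if n < 4:
            raise ValueError("bilinear fit needs at least 4 point pairs")
        _check_bilinear_degeneracy(conf)
        params = _solve_bilinear(conf, live)
        inverse_params = _solve_bilinear(live, conf)
        return PlanarTransform(kind="bilinear", params=params,
                               inverse_params=inverse_params)
    raise ValueError("kind must be 'affine' or 'bilinear'")


def _check_bilinear_degeneracy(points: np.ndarray) -> None:
    import itertools

    for idx in itertools.combinations(range(len(points)), 3):
        sub = points[list(idx)]
        area = 0.5 * abs(
            (sub[1, 0] - sub[0, 0]) * (sub[2, 1] - sub[0, 1])
            - (sub[2, 0] - sub[0, 0]) * (sub[1, 1] - sub[0, 1])
        )
        if area < 1e-9 * max(1.0, np.abs(points).max()) ** 2:
            raise ValueError(
                f"bilinear control points {idx} are collinear"
            )


def _solve_bilinear(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    x, y = src[:, 0], src[:, 1]
    design = np.column_stack([np.ones_like(x), x, y, x * y])
    coefs, *_ = np.linalg.lstsq(design, dst, rcond=None)  # (4, 2)
    return coefs.T  # (2, 4)


def apply_transform(image: np.ndarray, transform: PlanarTransform,
                    output_shape: tuple | None = None) -> np.ndarray:
    """Resample an image under a confocal-to-live planar transform.

    Inverse-mapped with bilinear interpolation; out-of-domain pixels are 0.
    The output lives in live-movie coordinates.
    """
    image = np.asarray(image)
    shape = output_shape if output_shape is not None else image.shape

    def inverse_map(coords: np.ndarray) -> np.ndarray:
        # skimage passes (col, row) = (x, y) pairs of output coordinates
        return transform.inverse_points(coords)

    out = warp(image.astype(float), inverse_map=inverse_map, output_shape=shape,
               order=1, cval=0.0, preserve_range=True)
    if np.issubdtype(image.dtype, np.integer):
        info = np.iinfo(image.dtype)
        out = np.clip(np.rint(out), info.min, info.max).astype(image.dtype)
    return out


class ControlPointWarp(BaseEstimator):
    """sklearn-style wrapper around control-point registration.

    ``fit`` takes matched control points (confocal as X, live as y) and
    ``transform`` resamples confocal-space images into live coordinates.
    """

    def __init__(self, kind: str = "affine"):
        self.kind = kind

    def fit(self, points_confocal: np.ndarray, points_live: np.ndarray):
        self.transform_ = fit_transform(points_live, points_confocal,
                                        kind=self.kind)
        return self

    def transform(self, image: np.ndarray,
                  output_shape: tuple | None = None) -> np.ndarray:
        if not hasattr(self, "transform_"):
            raise RuntimeError("registration is not fitted")
        return apply_transform(image, self.transform_, output_shape=output_shape)
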