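"""Single-molecule localization: precision, Gaussian spot fitting, frame filtering, drift.

The central quantity is the lateral localization precision of a fitted
single-molecule position,

    sigma_xy^2 = (s^2 + q^2/12) / N + 8*pi*s^4*b^2 / (q^2 * N^2)

where ``s`` is the standard deviation of the (Gaussian) point-spread
function, ``q`` the pixel size in image space, ``N`` the number of photons
collected from the molecule and ``b`` the background noise per pixel.  The
first term combines photon shot noise with pixelation; the second is the
background contribution.  All lengths are in nanometres.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, optimize
from skimage.feature import peak_local_max
from skimage.registration import phase_cross_correlation

logger = logging.getLogger(__name__)

#: canonical column order of the localization-table CSV dialect
TABLE_COLUMNS = ["frame", "x_nm", "y_nm", "photons", "sigma_nm", "background", "precision_nm"]


def thompson_precision(s, q, N, b):
    """Lateral localization precision (nm) of a Gaussian-PSF fit.

    Parameters
    ----------
    s : float or array
        PSF standard deviation (nm).
    q : float or array
        Pixel size in image space (nm).
    N : float or array
        Total photons collected from the molecule.
    b : float or array
        Background noise per pixel (photons, standard deviation).

    Returns
    -------
    float or ndarray
        Positive square root of the two-term precision expression.
    """
    s = np.asarray(s, dtype=float)
    q = np.asarray(q, dtype=float)
    N = np.asarray(N, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.any(s <= 0) or np.any(q <= 0) or np.any(N <= 0):
        raise ValueError("s, q and N must all be positive")
    if np.any(b < 0):
        raise ValueError("background noise b must be non-negative")
    var = (s**2 + q**2 / 12.0) / N + (8.0 * np.pi * s**4 * b**2) / (q**2 * N**2)
    out = np.sqrt(var)
    return float(out) if out.ndim == 0 else out


@dataclass
class FrameStack:
    """A stack of camera frames in photon units.

    ``frames`` has shape ``(n_frames, height, width)``; ``pixel_nm`` is the
    pixel size q.  Pixel ``(i, j)`` covers ``[j*q, (j+1)*q) x [i*q, (i+1)*q)``
    in (x, y) nm, origin at the top-left corner, y increasing downwards.
    """

    frames: np.ndarray
    pixel_nm: float

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n_frames, height, width) array")
        if self.pixel_nm <= 0:
            raise ValueError("pixel size must be positive")
        if np.any(self.frames < 0):
            raise ValueError("photon counts must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self):
        return self.frames.shape[1:]

    def to_tiff(self, path) -> None:
        import tifffile

        data = np.clip(np.rint(self.frames), 0, 65535).astype(np.uint16)
        tifffile.imwrite(
            path, data, photometric="minisblack", metadata={"pixel_nm": self.pixel_nm}
        )

    @classmethod
    def from_tiff(cls, path, pixel_nm: float) -> "FrameStack":
        import tifffile

        data = np.asarray(tifffile.imread(path))
        if data.ndim == 2:
            data = data[None]
        return cls(frames=data.astype(float), pixel_nm=pixel_nm)


class LocalizationTable:
    """Per-molecule localization records.

    Wraps a :class:`pandas.DataFrame` with columns
    ``frame, x_nm, y_nm, photons, sigma_nm, background, precision_nm``
    (the on-disk CSV dialect uses exactly this header).
    """

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in TABLE_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"localization table is missing columns {missing}")
        self.df = df[TABLE_COLUMNS].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:
        return isinstance(other, LocalizationTable) and self.df.equals(other.df)

    @property
    def xy(self) -> np.ndarray:
        """(n, 2) array of x/y positions in nm."""
        return self.df[["x_nm", "y_nm"]].to_numpy(dtype=float)

    @classmethod
    def empty(cls) -> "LocalizationTable":
        return cls(pd.DataFrame({c: pd.Series(dtype=float) for c in TABLE_COLUMNS}))

    @classmethod
    def from_records(cls, **cols) -> "LocalizationTable":
        n = max((len(np.atleast_1d(v)) for v in cols.values()), default=0)
        data = {}
        for c in TABLE_COLUMNS:
            v = cols.get(c, 0.0)
            v = np.atleast_1d(v)
            data[c] = np.broadcast_to(v, (n,)).astype(float)
        return cls(pd.DataFrame(data))

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path) -> "LocalizationTable":
        return cls(
            pd.read_csv(
                path, dtype={c: float for c in TABLE_COLUMNS}, float_precision="round_trip"
            )
        )


def exclude_early_frames(table: LocalizationTable, n_exclude: int) -> LocalizationTable:
    """Drop records from the first ``n_exclude`` frames (default workflow: 5000).

    Early frames are acquired before the photo-switching of the probes has
    stabilized; records with ``frame < n_exclude`` are removed, order preserved.
    """
    if n_exclude < 0:
        raise ValueError("n_exclude must be non-negative")
    return LocalizationTable(table.df[table.df["frame"] >= n_exclude].reset_index(drop=True))


def _gauss2d(coords, x0, y0, s_px, amp, offset):
    xx, yy = coords
    return amp * np.exp(-((xx - x0) ** 2 + (yy - y0) ** 2) / (2.0 * s_px**2)) + offset


def _fit_single_spot(window: np.ndarray, s0_px: float):
    """Maximum-likelihood 2D Gaussian fit of one spot window (pixel-index coords).

    Photon counts are Poisson-distributed, so the fit minimizes the Poisson
    negative log-likelihood of a free Gaussian (x, y, s, amplitude) on a flat
    offset.  This weights pixels by their shot noise, which a plain
    least-squares fit does not, and is what the two-term precision formula
    describes.
    """
    h, w = window.shape
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    offset0 = max(float(np.percentile(window, 20)), 1e-3)
    amp0 = max(float(window.max() - offset0), 1e-3)

    def nll(p):
        x0, y0, s_px, amp, offset = p
        model = _gauss2d((xx, yy), x0, y0, s_px, amp, offset)
        model = np.maximum(model, 1e-9)
        return float(np.sum(model - window * np.log(model)))

    p0 = [w / 2.0 - 0.5, h / 2.0 - 0.5, s0_px, amp0, offset0]
    bounds = [(-1.0, w), (-1.0, h), (0.2 * s0_px, 5.0 * s0_px), (1e-6, None), (0.0, None)]
    res = optimize.minimize(nll, p0, method="L-BFGS-B", bounds=bounds)
    if not res.success or not np.all(np.isfinite(res.x)):
        raise RuntimeError(f"spot fit did not converge: {res.message}")
    return res.x


def fit_localizations(
    stack: FrameStack,
    detect_threshold: float,
    init_sigma_nm: float = 130.0,
    fit_radius_px: int | None = None,
    min_separation_px: int = 3,
) -> LocalizationTable:
    """Detect and fit single-molecule spots frame by frame.

    Candidate spots are local maxima of a Gaussian-smoothed frame whose
    smoothed amplitude (above the frame median) exceeds ``detect_threshold``
    photons.  Each candidate is fitted with a free 2D Gaussian
    (x, y, s, amplitude, offset) on a square window; the photon count N is the
    integral of the fitted Gaussian, the background noise b is the standard
    deviation of fit residuals in the window annulus, and the precision is
    filled in from :func:`thompson_precision`.  Diverging fits are dropped and
    logged, never fabricated.
    """
    q = stack.pixel_nm
    s0_px = init_sigma_nm / q
    if fit_radius_px is None:
        fit_radius_px = max(3, int(np.ceil(3.0 * s0_px)))
    r = fit_radius_px
    records = {c: [] for c in TABLE_COLUMNS}
    for f_idx in range(stack.n_frames):
        frame = stack.frames[f_idx].astype(float)
        med = float(np.median(frame))
        smooth = ndimage.gaussian_filter(frame, sigma=max(1.0, s0_px / 2.0))
        peaks = peak_local_max(
            smooth,
            min_distance=min_separation_px,
            threshold_abs=med + detect_threshold,
            exclude_border=False,
        )
        for pr, pc in peaks:
            top = pr - r
            left = pc - r
            if top < 0 or left < 0 or pr + r >= frame.shape[0] or pc + r >= frame.shape[1]:
                continue
            window = frame[top : pr + r + 1, left : pc + r + 1]
            try:
                x0, y0, s_px, amp, offset = _fit_single_spot(window, s0_px)
            except (RuntimeError, ValueError):
                logger.info("spot fit diverged at frame %d (%d, %d); dropped", f_idx, pr, pc)
                continue
            n_photons = 2.0 * np.pi * amp * s_px**2
            if n_photons <= 0 or not np.isfinite(n_photons):
                continue
            yy, xx = np.mgrid[0 : window.shape[0], 0 : window.shape[1]].astype(float)
            model = _gauss2d((xx, yy), x0, y0, s_px, amp, offset)
            annulus = ((xx - x0) ** 2 + (yy - y0) ** 2) > (2.5 * s_px) ** 2
            resid = (window - model)[annulus]
            b = float(np.std(resid)) if resid.size >= 4 else float(np.std(window - model))
            records["frame"].append(f_idx)
            records["x_nm"].append((left + x0 + 0.5) * q)
            records["y_nm"].append((top + y0 + 0.5) * q)
            records["photons"].append(n_photons)
            records["sigma_nm"].append(s_px * q)
            records["background"].append(b)
            records["precision_nm"].append(thompson_precision(s_px * q, q, n_photons, b))
    if not records["frame"]:
        return LocalizationTable.empty()
    return LocalizationTable(pd.DataFrame(records))


@dataclass
class DriftTrajectory:
    """Estimated per-bin drift (nm) and its per-frame interpolation."""

    bin_centers: np.ndarray  # frame index of each bin center
    dx_nm: np.ndarray
    dy_nm: np.ndarray

    def at_frames(self, frames: np.ndarray):
        dx = np.interp(frames, self.bin_centers, self.dx_nm)
        dy = np.interp(frames, self.bin_centers, self.dy_nm)
        return dx, dy


def drift_correct(
    table: LocalizationTable,
    time_bin: int,
    render_pixel_nm: float = 50.0,
    blur_px: float = 1.0,
    upsample: int = 200,
    smooth_bins: int = 1,
):
    """Model-based cross-correlation drift correction.

    Localizations are grouped into time bins of ``time_bin`` frames, each bin
    is rendered as a 2D histogram and lightly Gaussian-blurred (``blur_px``
    render pixels — the binned point images are sparse and raw cross-
    correlation peaks are unreliable without it), and per-bin rigid shifts are
    estimated by (sub-pixel) cross-correlating every bin against the first.  Shifts are
    optionally smoothed with a moving average over ``smooth_bins`` bins,
    interpolated linearly between bin centers, and subtracted.

    Returns the corrected table and the :class:`DriftTrajectory`.
    """
    if time_bin <= 0:
        raise ValueError("time_bin must be positive")
    df = table.df
    if len(df) == 0:
        raise ValueError("cannot drift-correct an empty table")
    frames = df["frame"].to_numpy()
    bin_idx = (frames // time_bin).astype(int)
    n_bins = int(bin_idx.max()) + 1
    if n_bins < 2:
        raise ValueError("drift correction needs at least two time bins with localizations")

    x = df["x_nm"].to_numpy()
    y = df["y_nm"].to_numpy()
    pad = 2 * render_pixel_nm
    x_edges = np.arange(x.min() - pad, x.max() + pad + render_pixel_nm, render_pixel_nm)
    y_edges = np.arange(y.min() - pad, y.max() + pad + render_pixel_nm, render_pixel_nm)

    def _render(mask):
        img, _, _ = np.histogram2d(y[mask], x[mask], bins=(y_edges, x_edges))
        return ndimage.gaussian_filter(img, blur_px) if blur_px > 0 else img

    ref = _render(bin_idx == 0)
    dx = np.zeros(n_bins)
    dy = np.zeros(n_bins)
    for b in range(1, n_bins):
        mask = bin_idx == b
        if not np.any(mask):
            warnings.warn(f"drift bin {b} is empty; interpolating through", stacklevel=2)
            dx[b] = np.nan
            dy[b] = np.nan
            continue
        shift, _, _ = phase_cross_correlation(ref, _render(mask), upsample_factor=upsample)
        dy[b] = shift[0] * render_pixel_nm * -1.0  # shift maps moving->ref; drift is the inverse
        dx[b] = shift[1] * render_pixel_nm * -1.0
    # fill empty bins by linear interpolation over bin index
    for arr in (dx, dy):
        bad = np.isnan(arr)
        if np.any(bad):
            arr[bad] = np.interp(np.flatnonzero(bad), np.flatnonzero(~bad), arr[~bad])
    if smooth_bins > 1:
        kernel = np.ones(smooth_bins) / smooth_bins
        dx = np.convolve(dx, kernel, mode="same")
        dy = np.convolve(dy, kernel, mode="same")
    centers = (np.arange(n_bins) + 0.5) * time_bin
    traj = DriftTrajectory(bin_centers=centers, dx_nm=dx, dy_nm=dy)
    fx, fy = traj.at_frames(frames)
    out = df.copy()
    out["x_nm"] = x - fx
    out["y_nm"] = y - fy
    return LocalizationTable(out), traj
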