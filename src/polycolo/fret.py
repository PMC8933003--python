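"""Pixel-wise normalized FRET (N-FRET) from three-channel sensitized-emission imaging.

A donor/acceptor pair (e.g. Alexa 488 / Alexa 546 on secondary antibodies) is
imaged in three channels: donor excitation/donor emission (I_DD), acceptor
excitation/acceptor emission (I_AA), and donor excitation/acceptor emission
(I_DA, the FRET channel).  I_DA contains true sensitized emission plus linear
bleed-through from both fluorophores.  After background subtraction, the
normalized FRET index per pixel is

    N-FRET = (I_DA - d * I_DD - a * I_AA) / sqrt(I_DD * I_AA)

where ``d`` is the donor bleed-through slope into the FRET channel and ``a``
the acceptor cross-excitation slope.  The square-root normalization makes the
index independent of overall fluorophore abundance and laser power; it is
reported as a percentage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats


@dataclass
class FretImageSet:
    """Donor (I_DD), acceptor (I_AA) and FRET (I_DA) channel images.

    ``a`` and ``d`` are the acceptor->DA and donor->DA bleed-through
    coefficients; ``offsets`` holds additive per-channel backgrounds
    (keys ``dd``, ``aa``, ``da``).
    """

    i_dd: np.ndarray
    i_aa: np.ndarray
    i_da: np.ndarray
    a: float = 0.0
    d: float = 0.0
    offsets: dict = field(default_factory=lambda: {"dd": 0.0, "aa": 0.0, "da": 0.0})
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.i_dd = np.asarray(self.i_dd, dtype=float)
        self.i_aa = np.asarray(self.i_aa, dtype=float)
        self.i_da = np.asarray(self.i_da, dtype=float)
        if not (self.i_dd.shape == self.i_aa.shape == self.i_da.shape):
            raise ValueError("channel images must share a common shape")
        if self.a < 0 or self.d < 0:
            raise ValueError("bleed-through coefficients must be non-negative")


@dataclass
class NFretResult:
    """Per-pixel N-FRET map (in %), the ROI mean, and the valid-pixel mask."""

    nfret_pct: np.ndarray
    mean_pct: float
    mask: np.ndarray
    n_valid: int
    meta: dict = field(default_factory=dict)


def subtract_background(img_set: FretImageSet) -> FretImageSet:
    """Subtract each channel's additive offset, clipping at zero.

    Returns a new set with offsets zeroed; the number of clipped pixels per
    channel is recorded in ``meta['clipped']``.
    """
    clipped = {}
    out = {}
    for key, img in (("dd", img_set.i_dd), ("aa", img_set.i_aa), ("da", img_set.i_da)):
        off = float(img_set.offsets.get(key, 0.0))
        if off < 0:
            raise ValueError("background offsets must be non-negative")
        sub = img - off
        clipped[key] = int(np.sum(sub < 0))
        out[key] = np.clip(sub, 0.0, None)
    meta = dict(img_set.meta)
    meta["clipped"] = clipped
    return FretImageSet(
        i_dd=out["dd"],
        i_aa=out["aa"],
        i_da=out["da"],
        a=img_set.a,
        d=img_set.d,
        offsets={"dd": 0.0, "aa": 0.0, "da": 0.0},
        meta=meta,
    )


def _robust_slope(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if np.ptp(x) == 0:
        raise ValueError("degenerate (constant) control image; cannot estimate a slope")
    res = stats.theilslopes(y, x)
    return float(res.slope)


def estimate_bleedthrough(donor_only: FretImageSet, acceptor_only: FretImageSet):
    """Estimate (a, d) from single-labelled calibration sets.

    ``d`` is the robust (Theil–Sen) slope of I_DA versus I_DD on a
    donor-only specimen; ``a`` the slope of I_DA versus I_AA on an
    acceptor-only specimen.  Both sets should be background-subtracted.
    """
    d = _robust_slope(donor_only.i_dd, donor_only.i_da)
    a = _robust_slope(acceptor_only.i_aa, acceptor_only.i_da)
    return a, d


def nfret_map(
    img_set: FretImageSet,
    mask: np.ndarray | None = None,
    eps_rel: float = 1e-12,
) -> NFretResult:
    """Compute the per-pixel N-FRET map and its ROI mean.

    Pixels where the donor-acceptor intensity product ``I_DD * I_AA`` is at or
    below ``eps_rel`` times its maximum are excluded (the normalization would
    blow up); the ROI mean is the plain average of per-pixel values over the
    valid masked pixels.
    """
    dd, aa, da = img_set.i_dd, img_set.i_aa, img_set.i_da
    prod = dd * aa
    eps = eps_rel * float(prod.max()) if prod.size and prod.max() > 0 else 0.0
    valid = prod > eps
    if mask is not None:
        valid = valid & np.asarray(mask, dtype=bool)
    if not np.any(valid):
        raise ValueError("no valid pixels: donor*acceptor product is zero everywhere in the ROI")
    nfret = np.full(dd.shape, np.nan)
    corrected = da[valid] - img_set.d * dd[valid] - img_set.a * aa[valid]
    nfret[valid] = 100.0 * corrected / np.sqrt(prod[valid])
    return NFretResult(
        nfret_pct=nfret,
        mean_pct=float(np.mean(nfret[valid])),
        mask=valid,
        n_valid=int(valid.sum()),
        meta={"a": img_set.a, "d": img_set.d, "normalization": "sqrt(I_DD*I_AA)"},
    )
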