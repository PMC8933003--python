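"""Nearest-neighbor, overlap and randomization-null colocalization statistics.

Cluster-level statistics operate on two :class:`~polycolo.clustering.ClusterMap`
objects (channel A and channel B):

* nearest-neighbor intercentroid distances A -> B (these are exponentially
  distributed for random fields and shrink under true colocalization);
* the overlap fraction — the share of A clusters that touch a B cluster and
  vice versa.  Two overlap criteria are provided.  The default, ``"disk"``,
  treats each cluster as the disk of its measured area centred on its
  centroid and declares overlap when the disks intersect; this matches the
  area operationalization of the cluster maps and is insensitive to the
  rendering blur.  ``"pixel"`` declares overlap when thresholded footprints
  share at least ``min_shared_px`` render pixels (both maps must share a
  grid).  The criterion is recorded in the result metadata.
* a chance-overlap null in the spirit of Costes' randomization: channel-B
  clusters are rigidly relocated to uniform random in-ROI positions (shape
  and area preserved, out-of-bounds proposals resampled; channel A fixed)
  and the overlap recomputed per iteration, giving a null distribution and a
  one-sided empirical p-value with the (k+1)/(n+1) estimator.

Pixel-level coefficients for reconstructed (e.g. lattice-SIM) image pairs:
Pearson's product-moment r and Mander's M1/M2 overlap coefficients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .clustering import ClusterMap, ExponentialFit, fit_exponential


@dataclass
class NearestNeighborResult:
    """Per-A-cluster distance to the nearest B centroid, with summary."""

    distances_nm: np.ndarray
    mean_nm: float
    hist_edges: np.ndarray
    hist_counts: np.ndarray
    exponential_fit: ExponentialFit | None


@dataclass
class OverlapResult:
    """Overlap fractions in both directions plus the overlapping pair list."""

    fraction_ab: float
    fraction_ba: float
    pairs: list
    meta: dict = field(default_factory=dict)


@dataclass
class RandomizationResult:
    """Chance-overlap null distribution versus the observed overlap."""

    n_iter: int
    null_fractions: np.ndarray
    null_mean: float
    null_sd: float
    observed: float
    p_value: float
    seed: int


@dataclass
class PixelColocResult:
    pearson_r: float
    m1: float
    m2: float
    thresholds: tuple
    mask: np.ndarray | None = None


def nearest_neighbor_distances(
    map_a: ClusterMap, map_b: ClusterMap, bins: int = 20
) -> NearestNeighborResult:
    """Distance from each A-cluster centroid to its nearest B-cluster centroid."""
    if len(map_b) == 0:
        raise ValueError("channel-B map is empty; nearest-neighbor distance undefined")
    if len(map_a) == 0:
        return NearestNeighborResult(
            distances_nm=np.empty(0),
            mean_nm=float("nan"),
            hist_edges=np.empty(0),
            hist_counts=np.empty(0),
            exponential_fit=None,
        )
    tree = cKDTree(map_b.centroids)
    d, _ = tree.query(map_a.centroids)
    counts, edges = np.histogram(d, bins=bins)
    fit = fit_exponential(d) if len(d) >= 2 else None
    return NearestNeighborResult(
        distances_nm=d,
        mean_nm=float(d.mean()),
        hist_edges=edges,
        hist_counts=counts,
        exponential_fit=fit,
    )


def _disk_overlap_pairs(cent_a, rad_a, cent_b, rad_b):
    """Index pairs (i, j) with intersecting disks; brute-force-free via KD-tree."""
    pairs = []
    if len(cent_a) == 0 or len(cent_b) == 0:
        return pairs
    tree = cKDTree(cent_b)
    r_max = float(np.max(rad_b))
    for i, (c, r) in enumerate(zip(cent_a, rad_a)):
        for j in tree.query_ball_point(c, r + r_max):
            if np.hypot(*(c - cent_b[j])) <= r + rad_b[j]:
                pairs.append((i, j))
    return pairs


def _pixel_overlap_pairs(map_a: ClusterMap, map_b: ClusterMap, min_shared_px: int):
    if map_a.pixel_nm != map_b.pixel_nm or tuple(map_a.roi) != tuple(map_b.roi):
        raise ValueError("pixel-overlap criterion requires maps on an identical render grid")
    shape = map_a.grid_shape()
    owner = -np.ones(shape, dtype=int)
    for j, fp in enumerate(map_b.footprints):
        if len(fp):
            owner[fp[:, 0], fp[:, 1]] = j
    pairs = set()
    counts: dict = {}
    for i, fp in enumerate(map_a.footprints):
        if not len(fp):
            continue
        hits = owner[fp[:, 0], fp[:, 1]]
        for j in hits[hits >= 0]:
            key = (i, int(j))
            counts[key] = counts.get(key, 0) + 1
            if counts[key] >= min_shared_px:
                pairs.add(key)
    return sorted(pairs)


def overlap_fraction(
    map_a: ClusterMap,
    map_b: ClusterMap,
    criterion: str = "disk",
    min_shared_px: int = 1,
) -> OverlapResult:
    """Fraction of A clusters overlapping any B cluster, and vice versa."""
    if criterion == "disk":
        pairs = _disk_overlap_pairs(map_a.centroids, map_a.radii, map_b.centroids, map_b.radii)
    elif criterion == "pixel":
        pairs = _pixel_overlap_pairs(map_a, map_b, min_shared_px)
    else:
        raise ValueError(f"unknown overlap criterion {criterion!r}")
    a_hit = {i for i, _ in pairs}
    b_hit = {j for _, j in pairs}
    frac_ab = len(a_hit) / len(map_a) if len(map_a) else 0.0
    frac_ba = len(b_hit) / len(map_b) if len(map_b) else 0.0
    return OverlapResult(
        fraction_ab=frac_ab,
        fraction_ba=frac_ba,
        pairs=list(pairs),
        meta={"criterion": criterion, "min_shared_px": min_shared_px,
              "pixel_nm": map_a.pixel_nm},
    )


def _randomize_map(map_b: ClusterMap, rng, criterion: str) -> ClusterMap:
    """Rigidly relocate every B cluster to a uniform random in-bounds position."""
    x0, y0, x1, y1 = map_b.roi
    df = map_b.clusters.copy()
    new_fps = []
    if criterion == "disk":
        r = map_b.radii
        if np.any(2 * r > min(x1 - x0, y1 - y0)):
            raise ValueError("a cluster is larger than the ROI; cannot randomize")
        df["x_nm"] = rng.uniform(x0 + r, x1 - r)
        df["y_nm"] = rng.uniform(y0 + r, y1 - r)
        new_fps = map_b.footprints
    else:
        ny, nx = map_b.grid_shape()
        for fp in map_b.footprints:
            h = fp[:, 0].max() - fp[:, 0].min() + 1
            w = fp[:, 1].max() - fp[:, 1].min() + 1
            if h > ny or w > nx:
                raise ValueError("a cluster footprint is larger than the ROI")
            base = fp - fp.min(axis=0)
            rr = rng.integers(0, ny - h + 1)
            cc = rng.integers(0, nx - w + 1)
            new_fps.append(base + np.array([rr, cc]))
        df = df.copy()
    return ClusterMap(
        pixel_nm=map_b.pixel_nm,
        roi=map_b.roi,
        channel=map_b.channel,
        clusters=df,
        footprints=new_fps,
        meta=map_b.meta,
    )


def costes_randomize(
    map_a: ClusterMap,
    map_b: ClusterMap,
    n_iter: int = 1000,
    seed: int = 0,
    criterion: str = "disk",
    min_shared_px: int = 1,
) -> RandomizationResult:
    """Cluster-level randomization null for the A->B overlap fraction.

    Per iteration every B cluster is translated to an independent uniform
    in-ROI position (shape and area preserved; A fixed) and the A->B overlap
    fraction recomputed.  The empirical one-sided p-value for the observed
    overlap uses (k+1)/(n+1) where k counts null iterations >= observed.
    """
    if n_iter < 100:
        raise ValueError("need at least 100 randomization iterations")
    rng = np.random.default_rng(seed)
    observed = overlap_fraction(map_a, map_b, criterion, min_shared_px).fraction_ab
    null = np.empty(n_iter)
    for it in range(n_iter):
        shuffled = _randomize_map(map_b, rng, criterion)
        null[it] = overlap_fraction(map_a, shuffled, criterion, min_shared_px).fraction_ab
    k = int(np.sum(null >= observed))
    return RandomizationResult(
        n_iter=n_iter,
        null_fractions=null,
        null_mean=float(null.mean()),
        null_sd=float(null.std(ddof=1)),
        observed=float(observed),
        p_value=(k + 1) / (n_iter + 1),
        seed=seed,
    )


def pearson_coefficient(img1, img2, mask=None) -> float:
    """Pearson product-moment correlation over (masked) pixel pairs."""
    img1 = np.asarray(img1, dtype=float)
    img2 = np.asarray(img2, dtype=float)
    if img1.shape != img2.shape:
        raise ValueError("images must share a shape")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        x, y = img1[mask], img2[mask]
    else:
        x, y = img1.ravel(), img2.ravel()
    if x.size < 2:
        raise ValueError("need at least two masked pixels")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("zero variance in a channel; Pearson r undefined", stacklevel=2)
        return float("nan")
    x = x - x.mean()
    y = y - y.mean()
    return float(np.dot(x, y) / np.sqrt(np.dot(x, x) * np.dot(y, y)))


def manders_coefficients(img1, img2, t1: float = 0.0, t2: float = 0.0):
    """Mander's overlap coefficients (M1, M2).

    M1 is the fraction of channel-1 intensity (over pixels above t1) residing
    in pixels where channel 2 exceeds t2; M2 symmetrically.
    """
    if t1 < 0 or t2 < 0:
        raise ValueError("thresholds must be non-negative")
    img1 = np.asarray(img1, dtype=float)
    img2 = np.asarray(img2, dtype=float)
    if img1.shape != img2.shape:
        raise ValueError("images must share a shape")
    sel1 = img1 > t1
    sel2 = img2 > t2
    denom1 = img1[sel1].sum()
    denom2 = img2[sel2].sum()
    if denom1 == 0 or denom2 == 0:
        warnings.warn("all-zero denominator; Mander's coefficient undefined", stacklevel=2)
        return float("nan"), float("nan")
    m1 = img1[sel1 & sel2].sum() / denom1
    m2 = img2[sel1 & sel2].sum() / denom2
    return float(m1), float(m2)
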