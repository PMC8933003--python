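"""Synthetic ground-truth generators for every input the pipeline consumes.

Emulated data
-------------
* Two-channel localization tables: cluster centers follow a homogeneous
  Poisson process in a rectangular ROI, cluster areas are exponentially
  distributed (default means ~3702.5 and ~2157.1 nm^2, the scale of
  polycystin-1/-2 surface clusters), a configurable fraction of channel-2
  clusters is co-centered with a channel-1 cluster (default 27%), and each
  localization is jittered by Gaussian localization noise (default sd 27 nm,
  inside the 25-30 nm precision range of the Alexa 488/647 labels).
  Nonspecific background labeling is a uniform Poisson point scatter.
* Blinking-emitter camera frames on a pixel-integrated Gaussian PSF, photon
  shot noise per pixel, Bernoulli on-states.
* Three-channel FRET image sets with linear bleed-through and known true
  efficiency maps.
* Biphasic flow-response current traces: baseline, an exponentially decaying
  transient at flow onset (default amplitude -1.3 pA/pF) relaxing to a
  sustained shift (default +4.53 pA/pF, i.e. steady state -0.97 from a
  -5.5 pA/pF baseline), then back to baseline at flow-off.

All generators are deterministic for a fixed seed and record their ground
truth so every downstream estimator can be scored against it.
"""

from __future__ import annotations

import io
import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy import special

from .fret import FretImageSet
from .localization import FrameStack, LocalizationTable
from .physiology import CurrentTrace

# ---------------------------------------------------------------------------
# configs


@dataclass
class SimulationConfig:
    """Generative settings for two-channel cluster localization data.

    Lengths in nm, densities in clusters (or localizations) per um^2.
    ``coloc_fraction`` is the fraction of channel-2 clusters sharing a
    channel-1 centroid (displaced by a Gaussian offset of sd
    ``coloc_offset_sd_nm``, 0 by default).
    """

    roi_width_nm: float = 10000.0
    roi_height_nm: float = 10000.0
    density_ch1: float = 2.0
    density_ch2: float = 2.0
    mean_area_ch1_nm2: float = 3702.5
    mean_area_ch2_nm2: float = 2157.1
    coloc_fraction: float = 0.27
    coloc_offset_sd_nm: float = 0.0
    locs_per_cluster: int = 25
    precision_sd_nm: float = 27.0
    background_density: float = 0.5
    n_frames: int = 20000
    seed: int = 0

    def __post_init__(self):
        if self.roi_width_nm <= 0 or self.roi_height_nm <= 0:
            raise ValueError("ROI dimensions must be positive")
        for name in (
            "density_ch1",
            "density_ch2",
            "mean_area_ch1_nm2",
            "mean_area_ch2_nm2",
            "precision_sd_nm",
            "background_density",
            "coloc_offset_sd_nm",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.coloc_fraction <= 1.0:
            raise ValueError("coloc_fraction must lie in [0, 1]")
        if self.locs_per_cluster < 1:
            raise ValueError("locs_per_cluster must be at least 1")

    @property
    def roi_area_um2(self) -> float:
        return self.roi_width_nm * self.roi_height_nm / 1e6


@dataclass
class FrameSimConfig:
    """Blinking-emitter frame-stack settings (PSF sd s, pixel size q, photons N,
    background noise b — the inputs of the precision formula)."""

    s_nm: float = 130.0
    q_nm: float = 100.0
    n_photons: float = 500.0
    b_noise: float = 1.0
    n_frames: int = 100
    duty_cycle: float = 1.0
    positions_nm: tuple = ((1000.0, 1000.0),)
    fov_width_nm: float = 2000.0
    fov_height_nm: float = 2000.0
    seed: int = 0

    def __post_init__(self):
        if min(self.s_nm, self.q_nm, self.n_photons) < 0 or self.n_frames <= 0:
            raise ValueError("s, q, N must be non-negative and n_frames positive")
        if self.b_noise < 0:
            raise ValueError("background noise b must be non-negative")
        if not 0.0 < self.duty_cycle <= 1.0:
            raise ValueError("duty_cycle must lie in (0, 1]")
        pos = np.asarray(self.positions_nm, dtype=float).reshape(-1, 2)
        if np.any(pos[:, 0] < 0) or np.any(pos[:, 0] > self.fov_width_nm) or np.any(
            pos[:, 1] < 0
        ) or np.any(pos[:, 1] > self.fov_height_nm):
            raise ValueError("emitter positions must lie inside the field of view")


@dataclass
class FretSimConfig:
    """Three-channel FRET image generator settings.

    ``efficiency`` (scalar or map, in [0, 1]) is the true per-pixel FRET
    efficiency; donor/acceptor abundances set channel intensities; ``a`` and
    ``d`` are linear bleed-through coefficients into the FRET channel.
    """

    shape: tuple = (64, 64)
    efficiency: float | np.ndarray = 0.25
    donor_abundance: float | np.ndarray = 1000.0
    acceptor_abundance: float | np.ndarray = 1000.0
    a: float = 0.25
    d: float = 0.60
    noise_sd: float = 0.0
    offsets: dict = field(default_factory=lambda: {"dd": 0.0, "aa": 0.0, "da": 0.0})
    seed: int = 0

    def __post_init__(self):
        eff = np.asarray(self.efficiency, dtype=float)
        if np.any(eff < 0) or np.any(eff > 1):
            raise ValueError("efficiency must lie in [0, 1]")
        if self.a < 0 or self.d < 0:
            raise ValueError("bleed-through coefficients must be non-negative")
        for m in ("efficiency", "donor_abundance", "acceptor_abundance"):
            arr = np.asarray(getattr(self, m))
            if arr.ndim and arr.shape != tuple(self.shape):
                raise ValueError(f"{m} map shape {arr.shape} does not match {self.shape}")


@dataclass
class TraceSimConfig:
    """Biphasic flow-response current-trace settings (densities in pA/pF)."""

    sampling_rate_hz: float = 100.0
    duration_s: float = 240.0
    baseline_pa_pf: float = -5.5
    transient_amplitude_pa_pf: float = -1.3
    transient_tau_s: float = 2.0
    sustained_shift_pa_pf: float = 4.53
    flow_on_s: float = 60.0
    flow_off_s: float = 200.0
    noise_sd_pa_pf: float = 0.05
    capacitance_pf: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling rate must be positive")
        if not (0 <= self.flow_on_s < self.flow_off_s <= self.duration_s):
            raise ValueError("flow-on/off must satisfy 0 <= on < off <= duration")
        if self.capacitance_pf <= 0:
            raise ValueError("capacitance must be positive")
        if self.noise_sd_pa_pf < 0 or self.transient_tau_s <= 0:
            raise ValueError("noise sd must be >= 0 and decay constant > 0")


# ---------------------------------------------------------------------------
# ground truth


@dataclass
class GroundTruth:
    """True per-cluster records for a simulated two-channel field.

    ``clusters`` columns: channel ('ch1'/'ch2'), id, x_nm, y_nm, area_nm2,
    partner_id (cross-channel colocalization partner, -1 for none).
    ``n_background`` counts the uniform nonspecific localizations per channel.
    """

    clusters: pd.DataFrame
    n_background: dict

    COLUMNS = ["channel", "id", "x_nm", "y_nm", "area_nm2", "partner_id"]

    def __post_init__(self):
        self.clusters = self.clusters[self.COLUMNS].reset_index(drop=True)

    def channel(self, name: str) -> pd.DataFrame:
        return self.clusters[self.clusters["channel"] == name].reset_index(drop=True)

    @property
    def realized_coloc_fraction(self) -> float:
        """Fraction of channel-2 clusters with a channel-1 partner."""
        ch2 = self.channel("ch2")
        if len(ch2) == 0:
            return 0.0
        return float((ch2["partner_id"] >= 0).mean())

    def to_json(self) -> str:
        return json.dumps(
            {
                "clusters": self.clusters.to_csv(index=False),
                "n_background": self.n_background,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        raw = json.loads(text)
        df = pd.read_csv(io.StringIO(raw["clusters"])) if raw["clusters"].strip() else (
            pd.DataFrame(columns=cls.COLUMNS)
        )
        if len(df) == 0:
            df = pd.DataFrame(columns=cls.COLUMNS)
        return cls(clusters=df, n_background=raw["n_background"])


# ---------------------------------------------------------------------------
# localization-table generator


def _scatter_cluster(rng, cx, cy, area_nm2, n_locs, precision_sd):
    """Uniform points in a disk of the given area, then Gaussian precision jitter."""
    radius = np.sqrt(area_nm2 / np.pi)
    u = rng.random(n_locs)
    theta = rng.random(n_locs) * 2.0 * np.pi
    r = radius * np.sqrt(u)
    x = cx + r * np.cos(theta) + rng.normal(0.0, precision_sd, n_locs)
    y = cy + r * np.sin(theta) + rng.normal(0.0, precision_sd, n_locs)
    return x, y


def simulate_localizations(config: SimulationConfig):
    """Generate two-channel localization tables with recorded ground truth.

    Returns ``(table_ch1, table_ch2, truth)``.  Channel-2 clusters selected
    for colocalization are re-centered on a distinct channel-1 partner
    centroid (plus the configured offset); the pairing is recorded
    symmetrically in the ground truth.
    """
    rng = np.random.default_rng(config.seed)
    area = config.roi_area_um2
    w, h = config.roi_width_nm, config.roi_height_nm

    n1 = rng.poisson(config.density_ch1 * area)
    cx1 = rng.uniform(0.0, w, n1)
    cy1 = rng.uniform(0.0, h, n1)
    a1 = rng.exponential(config.mean_area_ch1_nm2, n1) if n1 else np.empty(0)

    n2 = rng.poisson(config.density_ch2 * area)
    cx2 = rng.uniform(0.0, w, n2)
    cy2 = rng.uniform(0.0, h, n2)
    a2 = rng.exponential(config.mean_area_ch2_nm2, n2) if n2 else np.empty(0)

    partner1 = np.full(n1, -1, dtype=int)
    partner2 = np.full(n2, -1, dtype=int)
    if n1 > 0 and n2 > 0 and config.coloc_fraction > 0:
        n_pair = min(int(rng.binomial(n2, config.coloc_fraction)), n1)
        ch2_sel = rng.choice(n2, size=n_pair, replace=False)
        ch1_sel = rng.choice(n1, size=n_pair, replace=False)
        cx2[ch2_sel] = cx1[ch1_sel]
        cy2[ch2_sel] = cy1[ch1_sel]
        if config.coloc_offset_sd_nm > 0:
            cx2[ch2_sel] += rng.normal(0.0, config.coloc_offset_sd_nm, n_pair)
            cy2[ch2_sel] += rng.normal(0.0, config.coloc_offset_sd_nm, n_pair)
        partner2[ch2_sel] = ch1_sel
        partner1[ch1_sel] = ch2_sel

    def _make_table(cx, cy, areas):
        xs, ys = [], []
        for x0, y0, a0 in zip(cx, cy, areas):
            x, y = _scatter_cluster(
                rng, x0, y0, a0, config.locs_per_cluster, config.precision_sd_nm
            )
            xs.append(x)
            ys.append(y)
        n_bg = rng.poisson(config.background_density * area)
        if n_bg:
            xs.append(rng.uniform(0.0, w, n_bg))
            ys.append(rng.uniform(0.0, h, n_bg))
        if not xs:
            return LocalizationTable.empty(), 0
        x = np.concatenate(xs)
        y = np.concatenate(ys)
        table = LocalizationTable.from_records(
            frame=rng.integers(0, config.n_frames, len(x)).astype(float),
            x_nm=x,
            y_nm=y,
            photons=np.full(len(x), 500.0),
            sigma_nm=np.full(len(x), 130.0),
            background=np.full(len(x), 1.0),
            precision_nm=np.full(len(x), config.precision_sd_nm),
        )
        return table, int(n_bg)

    table1, bg1 = _make_table(cx1, cy1, a1)
    table2, bg2 = _make_table(cx2, cy2, a2)

    rows = []
    for ch, cx, cy, areas, partner in (
        ("ch1", cx1, cy1, a1, partner1),
        ("ch2", cx2, cy2, a2, partner2),
    ):
        for i in range(len(cx)):
            rows.append(
                {
                    "channel": ch,
                    "id": i,
                    "x_nm": cx[i],
                    "y_nm": cy[i],
                    "area_nm2": areas[i],
                    "partner_id": int(partner[i]),
                }
            )
    truth_df = pd.DataFrame(rows, columns=GroundTruth.COLUMNS)
    truth = GroundTruth(clusters=truth_df, n_background={"ch1": bg1, "ch2": bg2})
    return table1, table2, truth


# ---------------------------------------------------------------------------
# frame-stack generator


def _pixel_weights(center_nm: float, s_nm: float, q_nm: float, n_px: int) -> np.ndarray:
    """Gaussian integrated over half-open pixels [i*q, (i+1)*q)."""
    edges = np.arange(n_px + 1) * q_nm
    cdf = special.ndtr((edges - center_nm) / s_nm)
    return np.diff(cdf)


def expected_frame(config: FrameSimConfig, on_mask=None) -> np.ndarray:
    """Noise-free expected photon image for the given emitter on-states."""
    n_x = int(np.ceil(config.fov_width_nm / config.q_nm))
    n_y = int(np.ceil(config.fov_height_nm / config.q_nm))
    img = np.zeros((n_y, n_x))
    pos = np.asarray(config.positions_nm, dtype=float).reshape(-1, 2)
    if on_mask is None:
        on_mask = np.ones(len(pos), dtype=bool)
    for (x, y), on in zip(pos, on_mask):
        if not on:
            continue
        wx = _pixel_weights(x, config.s_nm, config.q_nm, n_x)
        wy = _pixel_weights(y, config.s_nm, config.q_nm, n_y)
        img += config.n_photons * np.outer(wy, wx)
    return img


def simulate_frames(config: FrameSimConfig) -> FrameStack:
    """Poisson-sampled blinking-emitter frames.

    Per frame, each emitter is on with probability ``duty_cycle``; photons are
    Poisson-drawn per pixel from the pixel-integrated Gaussian PSF expectation
    (mean total N per on-emitter).  Background counts are Poisson with mean
    ``b^2`` per pixel, so their standard deviation equals the background noise
    b of the precision formula.
    """
    rng = np.random.default_rng(config.seed)
    pos = np.asarray(config.positions_nm, dtype=float).reshape(-1, 2)
    n_emit = len(pos)
    frames = []
    for _ in range(config.n_frames):
        on = rng.random(n_emit) < config.duty_cycle
        expect = expected_frame(config, on_mask=on)
        counts = rng.poisson(expect + config.b_noise**2).astype(float)
        frames.append(counts)
    return FrameStack(frames=np.asarray(frames), pixel_nm=config.q_nm)


# ---------------------------------------------------------------------------
# FRET-image generator


def simulate_fret_images(config: FretSimConfig) -> FretImageSet:
    """Three-channel sensitized-emission image set with known truth.

    Donor channel loses the transferred fraction (I_DD0 = D*(1-E)); the FRET
    channel gains it as sensitized emission plus linear bleed-through
    (I_DA = D*E + a*I_AA0 + d*I_DD0).  Offsets and Gaussian noise are added
    per channel; the true efficiency map is stored in ``meta``.
    """
    rng = np.random.default_rng(config.seed)
    shape = tuple(config.shape)
    eff = np.broadcast_to(np.asarray(config.efficiency, dtype=float), shape)
    donor = np.broadcast_to(np.asarray(config.donor_abundance, dtype=float), shape)
    acceptor = np.broadcast_to(np.asarray(config.acceptor_abundance, dtype=float), shape)

    i_dd0 = donor * (1.0 - eff)
    i_aa0 = acceptor.copy()
    sensitized = donor * eff
    i_da0 = sensitized + config.a * i_aa0 + config.d * i_dd0

    def _noisy(img, key):
        out = img + config.offsets.get(key, 0.0)
        if config.noise_sd > 0:
            out = out + rng.normal(0.0, config.noise_sd, shape)
        return out

    return FretImageSet(
        i_dd=_noisy(i_dd0, "dd"),
        i_aa=_noisy(i_aa0, "aa"),
        i_da=_noisy(i_da0, "da"),
        a=config.a,
        d=config.d,
        offsets=dict(config.offsets),
        meta={"true_efficiency": np.array(eff)},
    )


# ---------------------------------------------------------------------------
# current-trace generator


def simulate_current_trace(config: TraceSimConfig) -> CurrentTrace:
    """Biphasic flow-response current trace.

    Density = baseline before flow-on; from flow-on,
    ``baseline + shift + (amplitude - shift) * exp(-dt/tau)`` — i.e. the
    transient peaks at exactly ``baseline + amplitude`` at onset and relaxes
    to ``baseline + shift``; back to baseline at flow-off.  Gaussian noise is
    added pointwise and flow markers are recorded.
    """
    rng = np.random.default_rng(config.seed)
    dt = 1.0 / config.sampling_rate_hz
    t = np.arange(0.0, config.duration_s, dt)
    dens = np.full_like(t, config.baseline_pa_pf)
    flow = (t >= config.flow_on_s) & (t < config.flow_off_s)
    dt_on = t[flow] - config.flow_on_s
    a, s = config.transient_amplitude_pa_pf, config.sustained_shift_pa_pf
    dens[flow] = (
        config.baseline_pa_pf + s + (a - s) * np.exp(-dt_on / config.transient_tau_s)
    )
    if config.noise_sd_pa_pf > 0:
        dens = dens + rng.normal(0.0, config.noise_sd_pa_pf, t.shape)
    return CurrentTrace(
        time_s=t,
        current_pA=dens * config.capacitance_pf,
        capacitance_pF=config.capacitance_pf,
        markers={"flow_on": config.flow_on_s, "flow_off": config.flow_off_s},
    )


def config_to_dict(config) -> dict:
    """Plain-dict view of any generator config (for YAML/JSON serialization)."""
    d = asdict(config)
    for k, v in d.items():
        if isinstance(v, np.ndarray):
            d[k] = v.tolist()
    return d
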