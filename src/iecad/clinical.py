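"""Deterministic clinical computation.

Gensini scoring of coronary lesions, the significance / severity labelling
rules, biplane Simpson ventricular volumes, ejection-fraction and strain
curves, global work efficiency from the pressure-strain loop, and recovery
of EF/strain from segmentation masks.

The Gensini system scores each stenosed segment as (severity points from the
stenosis bin) x (a location multiplier reflecting the myocardium served by
the segment) and sums over lesions.  Severity bins are right-closed:
<=25% -> 1, <=50% -> 2, <=75% -> 4, <=90% -> 8, <=99% -> 16, 100% -> 32.
A total (or near-total, >=99%) occlusion that is collateralised is demoted
to the 90% bin.  Both tables are config-overridable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

__all__ = [
    "Segment", "CoronaryLesion", "GensiniConfig", "GensiniResult", "CadLabel",
    "gensini_score", "classify_significant", "is_severe", "make_cad_label",
    "simpson_biplane_volume", "single_plane_disk_volume", "ef_curve",
    "strain_curve", "gwe_from_loop", "metrics_from_masks", "MaskMetrics",
    "SEVERE_CUTOFF", "LM_SIGNIFICANT_PCT", "NON_LM_SIGNIFICANT_PCT",
]

SEVERE_CUTOFF = 15.0          # Gensini points at or above which CAD is severe
LM_SIGNIFICANT_PCT = 50.0     # left-main stenosis % for significant CAD
NON_LM_SIGNIFICANT_PCT = 70.0  # non-left-main stenosis % for significant CAD


class Segment(str, Enum):
    """Coronary segments of the Gensini system (LAD/LCx/RCA trees)."""

    LM = "LM"
    LAD_PROX = "LAD_prox"
    LAD_MID = "LAD_mid"
    LAD_DIST = "LAD_dist"
    D1 = "D1"
    D2 = "D2"
    LCX_PROX = "LCx_prox"
    OM = "OM"
    LCX_DIST = "LCx_dist"
    PLB = "PLB"
    RCA_PROX = "RCA_prox"
    RCA_MID = "RCA_mid"
    RCA_DIST = "RCA_dist"
    PDA = "PDA"


#: perfusion territory of each segment (used by the synthetic cohort to
#: couple lesions to regional wall motion)
SEGMENT_TERRITORY: dict[Segment, str] = {
    Segment.LM: "LAD",  # dominant effect; LM also supplies the LCx territory
    Segment.LAD_PROX: "LAD", Segment.LAD_MID: "LAD", Segment.LAD_DIST: "LAD",
    Segment.D1: "LAD", Segment.D2: "LAD",
    Segment.LCX_PROX: "LCx", Segment.OM: "LCx", Segment.LCX_DIST: "LCx",
    Segment.PLB: "RCA", Segment.RCA_PROX: "RCA", Segment.RCA_MID: "RCA",
    Segment.RCA_DIST: "RCA", Segment.PDA: "RCA",
}

_DEFAULT_MULTIPLIERS: dict[Segment, float] = {
    Segment.LM: 5.0,
    Segment.LAD_PROX: 2.5, Segment.LCX_PROX: 2.5,
    Segment.LAD_MID: 1.5,
    Segment.LAD_DIST: 1.0, Segment.D1: 1.0, Segment.OM: 1.0,
    Segment.LCX_DIST: 1.0, Segment.RCA_PROX: 1.0, Segment.RCA_MID: 1.0,
    Segment.RCA_DIST: 1.0, Segment.PDA: 1.0,
    Segment.D2: 0.5, Segment.PLB: 0.5,
}

#: (upper stenosis bound, points); right-closed bins scanned in order
_DEFAULT_BINS: tuple[tuple[float, int], ...] = (
    (25.0, 1), (50.0, 2), (75.0, 4), (90.0, 8), (99.0, 16), (100.0, 32),
)


@dataclass(frozen=True)
class CoronaryLesion:
    """One stenosed coronary segment."""

    segment: Segment
    stenosis_pct: float
    collaterals: bool = False

    def __post_init__(self):
        seg = self.segment if isinstance(self.segment, Segment) \
            else Segment(self.segment)
        object.__setattr__(self, "segment", seg)
        if not 0.0 <= self.stenosis_pct <= 100.0:
            raise ValueError(
                f"stenosis_pct must be in [0, 100], got {self.stenosis_pct}")


@dataclass(frozen=True)
class GensiniConfig:
    bins: tuple[tuple[float, int], ...] = _DEFAULT_BINS
    multipliers: dict[Segment, float] = field(
        default_factory=lambda: dict(_DEFAULT_MULTIPLIERS))
    severe_cutoff: float = SEVERE_CUTOFF
    #: demote a collateralised (sub)total occlusion (>=99%) to the 90% bin
    collateral_demotion: bool = True


DEFAULT_GENSINI = GensiniConfig()


@dataclass(frozen=True)
class GensiniResult:
    total: float
    contributions: tuple[float, ...]
    severe: bool


@dataclass(frozen=True)
class CadLabel:
    """Study labels plus the four composite detection assignments."""

    significant: bool
    severe: bool

    @property
    def assignment1(self) -> bool:  # significant CAD
        return self.significant

    @property
    def assignment2(self) -> bool:  # severe CAD
        return self.severe

    @property
    def assignment3(self) -> bool:  # significant or severe, but not both
        return self.significant != self.severe

    @property
    def assignment4(self) -> bool:  # both significant and severe
        return self.significant and self.severe


def _bin_points(stenosis: float, cfg: GensiniConfig) -> int:
    for upper, pts in cfg.bins:
        if stenosis <= upper:
            return pts
    return cfg.bins[-1][1]


def gensini_score(lesions: list[CoronaryLesion],
                  config: GensiniConfig = DEFAULT_GENSINI) -> GensiniResult:
    """Modified Gensini score: bin points x segment multiplier, summed."""
    contributions = []
    for les in lesions:
        if les.segment not in config.multipliers:
            raise ValueError(f"unknown segment: {les.segment}")
        stenosis = les.stenosis_pct
        if config.collateral_demotion and les.collaterals and stenosis >= 99.0:
            stenosis = 90.0
        contributions.append(
            _bin_points(stenosis, config) * config.multipliers[les.segment])
    total = float(sum(contributions))
    return GensiniResult(total=total, contributions=tuple(contributions),
                         severe=total >= config.severe_cutoff)


def classify_significant(lesions: list[CoronaryLesion],
                         lm_threshold: float = LM_SIGNIFICANT_PCT,
                         other_threshold: float = NON_LM_SIGNIFICANT_PCT) -> bool:
    """Significant CAD: >=50% left-main or >=70% non-left-main stenosis."""
    for les in lesions:
        thr = lm_threshold if les.segment is Segment.LM else other_threshold
        if les.stenosis_pct >= thr:
            return True
    return False


def is_severe(gensini_total: float, cutoff: float = SEVERE_CUTOFF) -> bool:
    """Severe CAD: Gensini score at or above the cutoff (15 points)."""
    return gensini_total >= cutoff


def make_cad_label(lesions: list[CoronaryLesion],
                   config: GensiniConfig = DEFAULT_GENSINI) -> CadLabel:
    return CadLabel(significant=classify_significant(lesions),
                    severe=gensini_score(lesions, config).severe)


# ---------------------------------------------------------------------------
# volumes, curves, myocardial work


def simpson_biplane_volume(a4c_diameters, a2c_diameters, long_axis: float) -> float:
    """Biplane method of disks: V = (pi/4) (L/n) sum_i a_i b_i.

    Diameters are orthogonal per-disk cavity widths from two apical views
    (same units as `long_axis`); returns volume in those units cubed.
    """
    a = np.asarray(a4c_diameters, dtype=float)
    b = np.asarray(a2c_diameters, dtype=float)
    if a.ndim != 1 or a.shape != b.shape or a.size < 1:
        raise ValueError("diameter lists must be equal-length 1-D arrays")
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("diameters must be non-negative")
    n = a.size
    return float(np.pi / 4.0 * (long_axis / n) * np.sum(a * b))


def single_plane_disk_volume(diameters, long_axis: float) -> float:
    """Single-plane disk summation (circular disks): V = (pi/4)(L/n) sum a_i^2."""
    a = np.asarray(diameters, dtype=float)
    if np.any(a < 0):
        raise ValueError("diameters must be non-negative")
    n = a.size
    return float(np.pi / 4.0 * (long_axis / n) * np.sum(a * a))


def ef_curve(volumes) -> np.ndarray:
    """Per-frame ejection fraction EF_t = 100 (V_0 - V_t) / V_0 (%)."""
    v = np.asarray(volumes, dtype=float)
    if v[0] <= 0:
        raise ValueError("end-diastolic volume must be positive")
    return 100.0 * (v[0] - v) / v[0]


def strain_curve(lengths) -> np.ndarray:
    """Per-frame longitudinal strain eps_t = 100 (L_t - L_0) / L_0 (%)."""
    ln = np.asarray(lengths, dtype=float)
    if ln[0] <= 0:
        raise ValueError("end-diastolic contour length must be positive")
    return 100.0 * (ln - ln[0]) / ln[0]


def myocardial_work(strain, pressure, es_index: int = 10) -> tuple[float, float]:
    """(constructive, wasted) work over systolic steps of one strain curve.

    Shortening against pressure is constructive, lengthening is wasted;
    pressure is taken at the step midpoint.  Units: mmHg x strain-%.
    """
    eps = np.asarray(strain, dtype=float)
    p = np.asarray(pressure, dtype=float)
    if eps.shape != p.shape:
        raise ValueError("strain and pressure curves must have equal length")
    if np.any(p < 0):
        raise ValueError("pressures must be non-negative")
    d_eps = np.diff(eps[: es_index + 1])
    p_mid = 0.5 * (p[:es_index] + p[1: es_index + 1])
    cw = float(np.sum(p_mid * np.maximum(-d_eps, 0.0)))
    ww = float(np.sum(p_mid * np.maximum(d_eps, 0.0)))
    return cw, ww


def gwe_from_loop(strain, pressure, es_index: int = 10) -> float:
    """Work efficiency (%) of one pressure-strain loop.

    GWE = 100 CW / (CW + WW); invariant to uniform pressure scaling.  The
    cohort generator aggregates CW/WW over wall segments before forming the
    ratio, mirroring how work efficiency is derived from segmental loops.
    """
    cw, ww = myocardial_work(strain, pressure, es_index)
    if cw + ww == 0.0:
        raise ValueError("zero total myocardial work: GWE undefined")
    return 100.0 * cw / (cw + ww)


# ---------------------------------------------------------------------------
# metric recovery from segmentation masks


@dataclass(frozen=True)
class MaskMetrics:
    ef_curve: np.ndarray
    strain_curve: np.ndarray
    lvef: float
    gls: float


def _cavity_disks(mask: np.ndarray, n_disks: int) -> tuple[np.ndarray, float]:
    """Per-disk cavity widths and long-axis length from one frame's mask.

    The cavity long axis is the principal axis of the class-2 pixel cloud;
    disks are perpendicular slabs along it.
    """
    rr, cc = np.nonzero(mask == 2)
    pts = np.stack([rr, cc], axis=1).astype(float)
    center = pts.mean(axis=0)
    centered = pts - center
    cov = centered.T @ centered / len(pts)
    evals, evecs = np.linalg.eigh(cov)
    axis = evecs[:, np.argmax(evals)]
    u = centered @ axis
    v = centered @ evecs[:, np.argmin(evals)]
    lo, hi = u.min(), u.max()
    length = float(hi - lo) + 1.0  # pixel extent
    edges = np.linspace(lo, hi + 1e-9, n_disks + 1)
    idx = np.clip(np.searchsorted(edges, u, side="right") - 1, 0, n_disks - 1)
    widths = np.zeros(n_disks)
    for i in range(n_disks):
        sel = idx == i
        if np.any(sel):
            widths[i] = v[sel].max() - v[sel].min() + 1.0
    return widths, length


def _midline_length(mask: np.ndarray, n_rays: int = 180) -> float:
    """Perimeter of the myocardial midline (between cavity and epicardium).

    Radial profile about the cavity centroid: per angular bin, the midline
    radius is the mean of the outermost cavity radius and the outermost
    myocardium radius.
    """
    rr_c, cc_c = np.nonzero(mask == 2)
    cy, cx = rr_c.mean(), cc_c.mean()
    rr, cc = np.nonzero(mask > 0)
    ang = np.arctan2(rr - cy, cc - cx)
    rad = np.hypot(rr - cy, cc - cx)
    is_cavity = mask[rr, cc] == 2
    bins = np.clip(((ang + np.pi) / (2 * np.pi) * n_rays).astype(int),
                   0, n_rays - 1)
    r_in = np.zeros(n_rays)
    r_out = np.zeros(n_rays)
    np.maximum.at(r_in, bins[is_cavity], rad[is_cavity])
    np.maximum.at(r_out, bins, rad)
    ok = r_in > 0
    theta = (np.arange(n_rays) + 0.5) / n_rays * 2 * np.pi - np.pi
    r_mid = (r_in + r_out) / 2.0
    theta, r_mid = theta[ok], r_mid[ok]
    x = r_mid * np.cos(theta)
    y = r_mid * np.sin(theta)
    dx = np.diff(np.r_[x, x[0]])
    dy = np.diff(np.r_[y, y[0]])
    return float(np.sum(np.hypot(dx, dy)))


def metrics_from_masks(a4c_masks: np.ndarray, a2c_masks: np.ndarray,
                       n_disks: int = 20) -> MaskMetrics:
    """EF and strain curves recovered from an A4C + A2C mask-block pair.

    Volumes use the biplane method of disks on cavity widths extracted along
    each frame's principal cavity axis; midline lengths come from the
    myocardial annulus.  Raises if any frame lacks cavity or myocardium.
    """
    a4c = np.asarray(a4c_masks)
    a2c = np.asarray(a2c_masks)
    if a4c.shape != a2c.shape or a4c.ndim != 3:
        raise ValueError("mask blocks must be equal-shape (T, H, W) arrays")
    n_frames = a4c.shape[0]
    volumes = np.zeros(n_frames)
    lengths = np.zeros(n_frames)
    for t in range(n_frames):
        for name, m in (("A4C", a4c[t]), ("A2C", a2c[t])):
            if not np.any(m == 2):
                raise ValueError(f"empty cavity (class 2) in {name} frame {t}")
            if not np.any(m == 1):
                raise ValueError(f"empty myocardium (class 1) in {name} frame {t}")
        d4, l4 = _cavity_disks(a4c[t], n_disks)
        d2, l2 = _cavity_disks(a2c[t], n_disks)
        volumes[t] = simpson_biplane_volume(d4, d2, 0.5 * (l4 + l2))
        lengths[t] = 0.5 * (_midline_length(a4c[t]) + _midline_length(a2c[t]))
    ef = ef_curve(volumes)
    eps = strain_curve(lengths)
    return MaskMetrics(ef_curve=ef, strain_curve=eps,
                       lvef=float(ef.max()), gls=float(eps.min()))
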