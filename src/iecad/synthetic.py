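"""Synthetic beating-heart subjects.

Emulates the statistical structure of an apical echo study without any
clinical data: an elliptical left-ventricular cavity wrapped in a myocardial
annulus contracts over a 20-frame cardiac cycle (frame 0 = end-diastole,
frame 10 = end-systole), is viewed in three apical planes (A4C/A3C/A2C)
distinguished by in-plane rotation and by which coronary territories the
plane cuts, and is rasterised to speckle-textured sector images with
pixel-exact masks.

Coronary lesions reduce the contractility of their territory (saturating in
the lesion's Gensini contribution) and delay its contraction, producing the
clinically expected couplings: diseased subjects have smaller |GLS|, lower
LVEF and lower global work efficiency.  All reference labels (strain and EF
curves, GLS, LVEF, GWE, Gensini, significant/severe flags) are computed
analytically from the generating geometry, so the generator doubles as the
oracle for metric-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .clinical import (
    CoronaryLesion, Segment, SEGMENT_TERRITORY, classify_significant,
    ef_curve, gensini_score, is_severe, myocardial_work,
    simpson_biplane_volume, strain_curve,
)
from .preprocess import MaskBlock, N_FRAMES, VideoBlock, VIEWS

__all__ = [
    "HeartPhantom", "SubjectRecord", "make_phantom", "render_subject",
    "make_cohort", "write_cohort", "cycle_phase", "CONTRACTILITY_FLOOR",
]

TERRITORIES = ("LAD", "LCx", "RCA")
CONTRACTILITY_FLOOR = 0.3     # contractility of a fully diseased territory
_ES_FRAME = N_FRAMES // 2     # frame index of end-systole
_DELAY_MAX = 2.0              # frames of contraction delay at full territory deficit
_BULGE = 0.18                 # passive systolic stretch at full territory deficit
_N_WALL_SEGMENTS = 6          # angular segments per view for work aggregation
_REF_SIZE = 256               # geometry is parameterised on this raster

#: in-plane rotation (degrees) of the heart in each apical view
VIEW_ROTATION = {"A4C": 0.0, "A3C": -22.0, "A2C": 22.0}
#: per-view acquisition gain (probe position and depth/gain settings differ
#: between apical windows)
VIEW_GAIN = {"A4C": 1.0, "A3C": 0.86, "A2C": 1.14}
#: per-view sector half-angle (degrees): the imaging window constrains how
#: wide a sector each apical view is acquired with
VIEW_SECTOR_HALF_ANGLE = {"A4C": 38.0, "A3C": 32.0, "A2C": 46.0}
#: territory pair cut by each view plane (first lobe centred septally)
VIEW_LOBES = {"A4C": ("LAD", "LCx"), "A3C": ("LAD", "LCx_RCA"),
              "A2C": ("LAD", "RCA")}


def cycle_phase(t) -> np.ndarray:
    """Triangular contraction phase: 0 at ED (t=0), 1 at ES (t=10), back to 0."""
    tt = np.clip(np.asarray(t, dtype=float), 0.0, None)
    return np.where(tt <= _ES_FRAME, tt / _ES_FRAME,
                    (N_FRAMES - tt) / (N_FRAMES - _ES_FRAME))


@dataclass
class HeartPhantom:
    """Analytic beating-heart geometry.

    Lengths are in pixels on the 256-pixel reference raster; rendering at
    other frame sizes rescales isotropically.
    """

    a0: float                      # cavity long semi-axis at ED
    b0: float                      # cavity short semi-axis at ED
    h0: float                      # wall thickness at ED
    alpha: float                   # fractional axis shortening at ES
    contractility: dict[str, float]  # per-territory, 1 = normal
    center: tuple[float, float] = (0.56, 0.54)  # (row, col) fractions
    view_rotation: dict[str, float] = field(
        default_factory=lambda: dict(VIEW_ROTATION))

    def __post_init__(self):
        if not (self.a0 > self.h0 > 0 and self.b0 > self.h0):
            raise ValueError("need cavity semi-axes a0, b0 > wall h0 > 0")
        if not 0.0 <= self.alpha < 1.0:
            raise ValueError(f"alpha must be in [0, 1), got {self.alpha}")
        for terr in TERRITORIES:
            c = self.contractility.get(terr)
            if c is None or not 0.0 <= c <= 1.0:
                raise ValueError(f"contractility[{terr!r}] must be in [0, 1]")


@dataclass
class SubjectRecord:
    """One synthetic subject: three view clips + masks + reference labels."""

    subject_id: str
    clips: dict[str, VideoBlock]
    masks: dict[str, MaskBlock]
    strain: np.ndarray            # 20 values, %; strain[0] = 0
    ef: np.ndarray                # 20 values, %; ef[0] = 0
    gls: float                    # %, peak negative strain
    lvef: float                   # %
    gwe: float                    # %
    lesions: list[CoronaryLesion]
    gensini: float
    significant: bool
    severe: bool

    def __post_init__(self):
        if len(self.strain) != N_FRAMES or len(self.ef) != N_FRAMES:
            raise ValueError("strain and EF curves must have exactly 20 entries")
        if abs(self.strain[0]) > 1e-9 or abs(self.ef[0]) > 1e-9:
            raise ValueError("curves must start at 0 at end-diastole")
        if not (min(self.strain) - 1e-9 <= self.gls <= 1e-9):
            raise ValueError("GLS must be the (non-positive) peak strain")
        if not 0.0 <= self.lvef < 100.0:
            raise ValueError(f"LVEF out of range: {self.lvef}")
        if not 0.0 <= self.gwe <= 100.0:
            raise ValueError(f"GWE out of range: {self.gwe}")
        if self.severe != is_severe(self.gensini):
            raise ValueError("severe flag inconsistent with Gensini cutoff")


# ---------------------------------------------------------------------------
# phantom construction


def _draw_geometry(rng: np.random.Generator) -> dict:
    return {
        "a0": rng.uniform(70.0, 90.0),
        "b0": rng.uniform(42.0, 55.0),
        "h0": rng.uniform(11.0, 15.0),
        "alpha": rng.uniform(0.18, 0.30),
    }


def make_phantom(rng_seed: int, disease_level: float) -> HeartPhantom:
    """Draw a phantom; ``disease_level`` in [0, 1] scales territory deficits.

    At level 0 all contractilities are 1; at level 1 the most affected
    territory sits exactly at the contractility floor (0.3).
    """
    if rng_seed < 0:
        raise ValueError("rng_seed must be non-negative")
    if not 0.0 <= disease_level <= 1.0:
        raise ValueError(f"disease_level must be in [0, 1], got {disease_level}")
    rng = np.random.default_rng(rng_seed)
    geo = _draw_geometry(rng)
    w = rng.uniform(0.05, 1.0, size=len(TERRITORIES))
    w = w / w.max()  # most affected territory carries weight exactly 1
    contract = {terr: 1.0 - disease_level * (1.0 - CONTRACTILITY_FLOOR) * wi
                for terr, wi in zip(TERRITORIES, w)}
    rot = {v: VIEW_ROTATION[v] + rng.uniform(-4.0, 4.0) for v in VIEWS}
    return HeartPhantom(contractility=contract, view_rotation=rot, **geo)


def lesion_contractility(lesions: list[CoronaryLesion]) -> dict[str, float]:
    """Territory contractilities from a lesion list.

    Each territory's deficit saturates in its summed Gensini contribution:
    c = floor + (1 - floor) * exp(-G_territory / 25).
    """
    g_per = {terr: 0.0 for terr in TERRITORIES}
    for les in lesions:
        res = gensini_score([les])
        g_per[SEGMENT_TERRITORY[les.segment]] += res.total
    return {terr: CONTRACTILITY_FLOOR + (1.0 - CONTRACTILITY_FLOOR)
            * float(np.exp(-g / 25.0)) for terr, g in g_per.items()}


# ---------------------------------------------------------------------------
# geometry evaluation


def _territory_contractility(phantom: HeartPhantom, view: str,
                             theta: np.ndarray) -> np.ndarray:
    """Blend the two territory lobes cut by this view over angle."""
    lobe_a, lobe_b = VIEW_LOBES[view]
    c = phantom.contractility
    ca = c[lobe_a]
    cb = 0.5 * (c["LCx"] + c["RCA"]) if lobe_b == "LCx_RCA" else c[lobe_b]
    w = 0.5 * (1.0 + np.cos(theta - np.pi / 2.0))
    return w * ca + (1.0 - w) * cb


def _radii(phantom: HeartPhantom, view: str, theta: np.ndarray,
           t: float) -> tuple[np.ndarray, np.ndarray]:
    """Cavity and epicardial radius profiles at frame t (reference pixels).

    theta is measured in the heart frame, 0 pointing along the long axis
    toward the base.
    """
    a, b, h0 = phantom.a0, phantom.b0, phantom.h0
    r0 = a * b / np.sqrt((b * np.cos(theta)) ** 2 + (a * np.sin(theta)) ** 2)
    c = _territory_contractility(phantom, view, theta)
    c_ref = max(phantom.contractility.values())
    deficit = c_ref - c
    delay = _DELAY_MAX * deficit              # hypokinetic walls lag
    phase = cycle_phase(t - delay)
    # ischaemic walls stretch passively through systole and recover in
    # diastole (post-systolic shortening pattern)
    bulge = _BULGE * deficit * cycle_phase(t) ** 2
    shortening = phantom.alpha * c * phase - bulge
    r_cav = r0 * (1.0 - shortening)
    h = h0 * (1.0 + 0.35 * shortening)        # systolic wall thickening
    return r_cav, r_cav + h


def _boundary_polygon(phantom: HeartPhantom, view: str, t: float,
                      n: int = 720) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(theta, r_cav, r_out) on a dense angular grid."""
    theta = (np.arange(n) + 0.5) / n * 2.0 * np.pi - np.pi
    r_cav, r_out = _radii(phantom, view, theta, t)
    return theta, r_cav, r_out


def _chord_widths(theta: np.ndarray, r: np.ndarray, n_disks: int = 20
                  ) -> tuple[np.ndarray, float]:
    """Disk-method chords of a star-shaped cavity boundary.

    x runs along the long axis; widths are perpendicular extents per slab.
    """
    x = r * np.cos(theta)
    y = r * np.sin(theta)
    lo, hi = x.min(), x.max()
    length = hi - lo
    edges = np.linspace(lo, hi + 1e-12, n_disks + 1)
    idx = np.clip(np.searchsorted(edges, x, side="right") - 1, 0, n_disks - 1)
    widths = np.zeros(n_disks)
    for i in range(n_disks):
        sel = idx == i
        if np.any(sel):
            widths[i] = y[sel].max() - y[sel].min()
    return widths, float(length)


def _midline_perimeter(phantom: HeartPhantom, view: str, t: float) -> float:
    theta, r_cav, r_out = _boundary_polygon(phantom, view, t)
    r_mid = 0.5 * (r_cav + r_out)
    x = r_mid * np.cos(theta)
    y = r_mid * np.sin(theta)
    dx = np.diff(np.r_[x, x[0]])
    dy = np.diff(np.r_[y, y[0]])
    return float(np.sum(np.hypot(dx, dy)))


def _segment_arclengths(phantom: HeartPhantom, view: str, t: float,
                        n_seg: int = _N_WALL_SEGMENTS) -> np.ndarray:
    """Midline arc length of each angular wall segment at frame t."""
    theta, r_cav, r_out = _boundary_polygon(phantom, view, t)
    r_mid = 0.5 * (r_cav + r_out)
    x = r_mid * np.cos(theta)
    y = r_mid * np.sin(theta)
    step = np.hypot(np.diff(x), np.diff(y))
    per_seg = step.size // n_seg
    return np.array([step[i * per_seg:(i + 1) * per_seg].sum()
                     for i in range(n_seg)])


def pressure_curve() -> np.ndarray:
    """Schematic LV pressure over the 20-frame cycle (mmHg)."""
    t = np.arange(N_FRAMES)
    return 8.0 + 112.0 * np.sin(0.5 * np.pi * cycle_phase(t)) ** 2


# ---------------------------------------------------------------------------
# rasterisation


def _sector_mask(size: int, half_angle_deg: float = 38.0) -> np.ndarray:
    """Ultrasound sector: apex near the top centre."""
    apex = (0.02 * size, 0.5 * size)
    half_angle = np.deg2rad(half_angle_deg)
    radius = 0.97 * size
    rr, cc = np.mgrid[0:size, 0:size]
    dy = rr - apex[0]
    dx = cc - apex[1]
    dist = np.hypot(dy, dx)
    ang = np.arctan2(dx, dy)  # 0 pointing straight down
    return (np.abs(ang) <= half_angle) & (dist <= radius) & (dy >= 0)


def _render_view(phantom: HeartPhantom, view: str, size: int,
                 rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Rasterise one view: (video (20,S,S) in [0,1], mask (20,S,S) in {0,1,2})."""
    scale = size / _REF_SIZE
    cy, cx = phantom.center[0] * size, phantom.center[1] * size
    rot = np.deg2rad(phantom.view_rotation.get(view, VIEW_ROTATION[view]))
    rr, cc = np.mgrid[0:size, 0:size]
    dy = (rr - cy) / scale
    dx = (cc - cx) / scale
    # heart frame: long axis along image rows, rotated per view
    theta = np.arctan2(dx * np.cos(rot) - dy * np.sin(rot),
                       dy * np.cos(rot) + dx * np.sin(rot))
    rad = np.hypot(dy, dx)
    sector = _sector_mask(size, VIEW_SECTOR_HALF_ANGLE[view])

    # heart-frame cartesian coordinates (long axis toward the base at +yh)
    yh = rad * np.cos(theta)
    xh = rad * np.sin(theta)

    video = np.zeros((N_FRAMES, size, size), dtype=np.float32)
    masks = np.zeros((N_FRAMES, size, size), dtype=np.uint8)
    # smooth lateral intensity variation, fixed per subject/view
    tissue_var = 1.0 + 0.12 * np.sin(3.0 * theta)
    for t in range(N_FRAMES):
        r_cav, r_out = _radii(phantom, view, theta, float(t))
        cavity = rad < r_cav
        myo = (rad >= r_cav) & (rad < r_out)
        masks[t][myo] = 1
        masks[t][cavity] = 2
        tpl = np.full((size, size), 0.28, dtype=np.float32)
        neighbour = _view_landmark(phantom, view, yh, xh, float(t))
        if neighbour is not None:
            inner, wall = neighbour
            tpl[wall] = 0.85
            tpl[inner] = 0.03
        tpl[myo] = 0.78 * tissue_var[myo]
        tpl[cavity] = 0.07
        speckle = rng.rayleigh(scale=np.sqrt(2.0 / np.pi), size=(size, size))
        speckle = gaussian_filter(speckle, sigma=0.8)
        video[t] = np.clip(tpl * VIEW_GAIN[view] * speckle, 0.0, 1.0) * sector
    return video, masks


def _view_landmark(phantom: HeartPhantom, view: str, yh: np.ndarray,
                   xh: np.ndarray, t: float):
    """Neighbouring structure that identifies the imaging plane.

    A4C additionally cuts the right ventricle (a contracting crescent on the
    septal side), A3C the aortic outflow to the right of the base, and A2C
    the left atrium on the opposite side below the base.  Rendered into the
    video template as (inner, wall) pixel sets, never into the label masks.
    """
    a, b, h = phantom.a0, phantom.b0, phantom.h0
    if view == "A4C":
        s = 1.0 - 0.3 * phantom.alpha * float(cycle_phase(t))
        cy, cx = -0.15 * a, -(b + h + 0.40 * b * s)
        ry, rx = 0.85 * a * s, 0.50 * b * s
    elif view == "A3C":
        cy, cx = 1.10 * a, 0.50 * b
        ry = rx = 0.38 * b
    else:  # A2C: left atrium
        cy, cx = 1.12 * a, -0.50 * b
        ry, rx = 0.42 * b, 0.45 * b
    d = ((yh - cy) / ry) ** 2 + ((xh - cx) / rx) ** 2
    inner = d < 1.0
    wall = (d >= 1.0) & (d < 1.5)
    return inner, wall


# ---------------------------------------------------------------------------
# subject + cohort assembly


def render_subject(phantom: HeartPhantom, lesions: list[CoronaryLesion],
                   noise_seed: int, subject_id: str = "S0",
                   frame_size: int = 256) -> SubjectRecord:
    """Render the three views and compute all reference labels analytically."""
    rng = np.random.default_rng(noise_seed)
    clips: dict[str, VideoBlock] = {}
    masks: dict[str, MaskBlock] = {}
    strain_by_view = {}
    chords = {}
    for view in VIEWS:
        video, mask = _render_view(phantom, view, frame_size, rng)
        clips[view] = VideoBlock(data=video, view=view)
        masks[view] = MaskBlock(data=mask)
        lengths = [_midline_perimeter(phantom, view, float(t))
                   for t in range(N_FRAMES)]
        strain_by_view[view] = strain_curve(lengths)
        if view in ("A4C", "A2C"):
            chords[view] = [_chord_widths(*_boundary_polygon(
                phantom, view, float(t))[:2], n_disks=20)
                for t in range(N_FRAMES)]
    eps = np.mean([strain_by_view[v] for v in VIEWS], axis=0)

    volumes = []
    for t in range(N_FRAMES):
        w4, l4 = chords["A4C"][t]
        w2, l2 = chords["A2C"][t]
        volumes.append(simpson_biplane_volume(w4, w2, 0.5 * (l4 + l2)))
    ef = ef_curve(volumes)

    # work efficiency aggregates constructive/wasted work over wall segments
    pressure = pressure_curve()
    cw_total = ww_total = 0.0
    for view in VIEWS:
        seg_lengths = np.stack([_segment_arclengths(phantom, view, float(t))
                                for t in range(N_FRAMES)])  # (T, n_seg)
        for s in range(seg_lengths.shape[1]):
            seg_eps = strain_curve(seg_lengths[:, s])
            cw, ww = myocardial_work(seg_eps, pressure, es_index=_ES_FRAME)
            cw_total += cw
            ww_total += ww
    gwe = min(100.0, 100.0 * cw_total / (cw_total + ww_total)) \
        if cw_total + ww_total > 0 else 100.0  # motionless heart: nothing wasted
    gres = gensini_score(lesions)
    return SubjectRecord(
        subject_id=subject_id, clips=clips, masks=masks,
        strain=eps, ef=ef, gls=float(eps.min()), lvef=float(ef.max()),
        gwe=float(gwe), lesions=list(lesions), gensini=gres.total,
        significant=classify_significant(lesions), severe=gres.severe)


_NON_LM_SEGMENTS = [s for s in Segment if s is not Segment.LM]


def _draw_lesions(rng: np.random.Generator, significant: bool
                  ) -> list[CoronaryLesion]:
    """Significant subjects get a culprit-territory lesion cluster."""
    lesions: list[CoronaryLesion] = []
    if significant:
        culprit = TERRITORIES[rng.integers(len(TERRITORIES))]
        culprit_segs = [s.value for s in _NON_LM_SEGMENTS
                        if SEGMENT_TERRITORY[s] == culprit]
        main = Segment(str(rng.choice(culprit_segs)))
        lesions.append(CoronaryLesion(main, float(rng.uniform(70.0, 100.0)),
                                      collaterals=bool(rng.random() < 0.2)))
        for _ in range(rng.integers(1, 4)):
            pool = culprit_segs if rng.random() < 0.7 \
                else [s.value for s in _NON_LM_SEGMENTS]
            seg = Segment(str(rng.choice(pool)))
            lesions.append(CoronaryLesion(seg, float(rng.uniform(40.0, 100.0))))
    else:
        for _ in range(rng.integers(0, 4)):
            seg = Segment(str(rng.choice([s.value for s in Segment])))
            cap = 45.0 if seg is Segment.LM else 65.0
            lesions.append(CoronaryLesion(seg, float(rng.uniform(10.0, cap))))
    return lesions


def make_cohort(n_subjects: int, prevalence: float = 122.0 / 290.0,
                rng_seed: int = 0, frame_size: int = 256
                ) -> list[SubjectRecord]:
    """Generate a cohort with ``round(prevalence * n)`` significant subjects.

    Lesions lower the contractility of their coronary territory, so
    significant subjects carry systematically smaller |GLS|, LVEF and GWE.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    rng = np.random.default_rng(rng_seed)
    n_sig = int(round(prevalence * n_subjects))
    flags = np.zeros(n_subjects, dtype=bool)
    flags[:n_sig] = True
    rng.shuffle(flags)
    records = []
    for i in range(n_subjects):
        sub_rng = np.random.default_rng(rng.integers(2 ** 31))
        # redraw until the lesion set realises the intended significance
        for _ in range(50):
            lesions = _draw_lesions(sub_rng, bool(flags[i]))
            if classify_significant(lesions) == bool(flags[i]):
                break
        geo = _draw_geometry(sub_rng)
        phantom = HeartPhantom(
            contractility=lesion_contractility(lesions),
            view_rotation={v: VIEW_ROTATION[v] + sub_rng.uniform(-4.0, 4.0)
                           for v in VIEWS}, **geo)
        records.append(render_subject(
            phantom, lesions, noise_seed=int(sub_rng.integers(2 ** 31)),
            subject_id=f"S{i:04d}", frame_size=frame_size))
    return records


def write_cohort(records: list[SubjectRecord], outdir) -> "pd.DataFrame":
    """Write clips/masks as NPZ and a labels manifest CSV; returns the manifest."""
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        path = outdir / f"{rec.subject_id}.npz"
        arrays = {}
        for view in VIEWS:
            arrays[f"video_{view}"] = rec.clips[view].data
            arrays[f"mask_{view}"] = rec.masks[view].data
        arrays["strain"] = rec.strain
        arrays["ef"] = rec.ef
        np.savez_compressed(path, **arrays)
        rows.append({
            "subject_id": rec.subject_id, "file": path.name,
            "gls": rec.gls, "lvef": rec.lvef, "gwe": rec.gwe,
            "gensini": rec.gensini, "significant": rec.significant,
            "severe": rec.severe,
            "lesions": ";".join(f"{l.segment.value}:{l.stenosis_pct:.0f}"
                                for l in rec.lesions),
        })
    manifest = pd.DataFrame(rows)
    manifest.to_csv(outdir / "cohort.csv", index=False)
    return manifest
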