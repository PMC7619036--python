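"""Seeded synthetic cohorts of multi-class biventricular point clouds.

Each subject is a pair of labeled 3D point clouds (end-diastole and
end-systole) over three substructures — LV endocardium (label 1), LV
epicardium (label 2), RV endocardium (label 3) — built from truncated
prolate ellipsoids with an open base.  Population variability enters through
interpretable generative factors (global size, apex-base elongation,
basal-plane tilt, LV wall thickness, RV size, LV ejection fraction), and a
myocardial-infarction subpopulation is drawn from shifted factor
distributions (lower ejection fraction, thinner wall, mild dilation) so that
the disease label is recoverable from shape alone.  Survival labels follow
an exponential proportional-hazards model on a latent risk score with
administrative right-censoring.

All coordinates are millimetres.  At scale 1 the LV long axis (apex to base)
is about 90 mm and the end-diastolic LV cavity volume about 115 mL, which
keeps absolute reconstruction errors in mm anatomically meaningful.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import shape_metrics

__all__ = [
    "ShapeParams",
    "MultiClassPointCloud",
    "AnatomySample",
    "sample_population_params",
    "build_anatomy",
    "make_survival_labels",
    "split_dataset",
    "generate_cohort",
    "clinical_metric_table",
]

LV_ENDO, LV_EPI, RV_ENDO = 1, 2, 3
CLASS_NAMES = {LV_ENDO: "lv_endo", LV_EPI: "lv_epi", RV_ENDO: "rv_endo"}
GROUPS = ("control", "prevalent_mi", "incident_mi")

# Canonical geometry at scale 1 (mm). The long axis is z, apex toward -z.
LV_ENDO_LONG_SEMI_AXIS = 62.0
LV_ENDO_SHORT_SEMI_AXIS = 25.0
BASE_CUT_FRACTION = 0.30          # base plane at z = 0.30 * LV endo long semi-axis
ES_LONG_SHORTENING = 0.95         # longitudinal shortening factor at ES
RV_LONG_FRACTION = 0.88           # RV long semi-axis relative to LV endo's
RV_SHORT_SEMI_AXIS = 33.0
RV_CENTER_X_FRACTION = 0.88       # RV ellipsoid center offset, fraction of LV endo b
RV_EPI_CLEARANCE = 1.02           # RV endo kept strictly outside the LV epi quadric


@dataclass(frozen=True)
class ShapeParams:
    """Generative factors of one synthetic subject.

    scale, elongation and rv_size are unitless multipliers around 1;
    basal_tilt is in degrees; wall_thickness in mm; ef_target is the LV
    ejection fraction in (0, 1); risk_score is the unitless latent hazard
    driver used by the survival model.
    """

    scale: float
    elongation: float
    basal_tilt: float
    wall_thickness: float
    rv_size: float
    ef_target: float
    mi_flag: bool
    risk_score: float

    def __post_init__(self):
        vals = [self.scale, self.elongation, self.basal_tilt, self.wall_thickness,
                self.rv_size, self.ef_target, self.risk_score]
        if not all(math.isfinite(v) for v in vals):
            raise ValueError("all shape factors must be finite")
        if self.scale <= 0:
            raise ValueError(f"scale must be > 0, got {self.scale}")
        if self.wall_thickness <= 0:
            raise ValueError(f"wall_thickness must be > 0, got {self.wall_thickness}")
        if not 0.0 < self.ef_target < 1.0:
            raise ValueError(f"ef_target must be in (0, 1), got {self.ef_target}")
        if self.rv_size <= 0 or self.elongation <= 0:
            raise ValueError("rv_size and elongation must be > 0")


@dataclass
class MultiClassPointCloud:
    """Labeled 3D point cloud of one cardiac phase (coordinates in mm)."""

    points: np.ndarray          # (n, 3)
    labels: np.ndarray          # (n,), values in {1, 2, 3}
    phase: str                  # "ED" or "ES"

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError(f"points must be (n, 3), got {self.points.shape}")
        if self.points.shape[0] == 0:
            raise ValueError("point cloud must be non-empty")
        if self.labels.shape != (self.points.shape[0],):
            raise ValueError("labels must be one integer per point")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("coordinates must be finite")
        present = set(np.unique(self.labels).tolist())
        if not present <= {LV_ENDO, LV_EPI, RV_ENDO}:
            raise ValueError(f"labels must be in {{1,2,3}}, got {sorted(present)}")
        if present != {LV_ENDO, LV_EPI, RV_ENDO}:
            raise ValueError(f"all three substructure labels required, got {sorted(present)}")
        if self.phase not in ("ED", "ES"):
            raise ValueError(f"phase must be 'ED' or 'ES', got {self.phase!r}")

    def points_of_class(self, class_id: int) -> np.ndarray:
        return self.points[self.labels == class_id]


@dataclass
class AnatomySample:
    """Paired ED/ES clouds with cohort metadata for one subject."""

    subject_id: str
    ed: MultiClassPointCloud
    es: MultiClassPointCloud
    group: str = "control"
    event_time_days: float | None = None
    event_observed: bool = False
    truth: ShapeParams | None = None

    def __post_init__(self):
        if self.ed.phase != "ED" or self.es.phase != "ES":
            raise ValueError("ed/es clouds must carry matching phase tags")
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.group == "incident_mi":
            if not self.event_observed or self.event_time_days is None:
                raise ValueError("incident_mi requires an observed event time")
        if self.event_time_days is not None and self.event_time_days < 0:
            raise ValueError("event_time_days must be nonnegative")


# ---------------------------------------------------------------------------
# population factor sampling
# ---------------------------------------------------------------------------

# (mean, sd, lo, hi) per factor, for the control and MI subpopulations. The
# MI shifts (lower EF, thinner wall, mild dilation) plant the shape signal
# downstream classifiers are evaluated on.
_FACTOR_DISTS = {
    False: {  # control
        "scale": (1.00, 0.06, 0.78, 1.25),
        "elongation": (1.00, 0.07, 0.78, 1.25),
        "basal_tilt": (0.0, 4.0, -14.0, 14.0),
        "wall_thickness": (9.0, 1.0, 6.0, 13.0),
        "rv_size": (1.00, 0.06, 0.78, 1.25),
        "ef_target": (0.60, 0.05, 0.42, 0.74),
    },
    True: {  # myocardial infarction
        "scale": (1.07, 0.07, 0.82, 1.35),
        "elongation": (1.00, 0.07, 0.78, 1.25),
        "basal_tilt": (0.0, 4.0, -14.0, 14.0),
        "wall_thickness": (7.2, 1.0, 4.5, 11.0),
        "rv_size": (1.03, 0.07, 0.80, 1.30),
        "ef_target": (0.44, 0.06, 0.22, 0.60),
    },
}


def _draw_params(rng: np.random.Generator, mi: bool) -> ShapeParams:
    d = _FACTOR_DISTS[mi]
    vals = {}
    for name, (mu, sd, lo, hi) in d.items():
        vals[name] = float(np.clip(rng.normal(mu, sd), lo, hi))
    # latent hazard driver: correlated with the MI-shifted factors plus noise
    risk = (
        0.7 * (0.60 - vals["ef_target"]) / 0.07
        + 0.4 * (9.0 - vals["wall_thickness"]) / 1.3
        + 0.3 * (vals["scale"] - 1.0) / 0.08
        + rng.normal(0.0, 0.5)
    )
    return ShapeParams(mi_flag=mi, risk_score=float(risk), **vals)


def sample_population_params(
    n_subjects: int, mi_fraction: float, seed: int
) -> list[ShapeParams]:
    """Draw generative factors for a cohort, stratified by disease label.

    Exactly ``round(n_subjects * mi_fraction)`` subjects carry ``mi_flag``;
    the returned list is deterministically shuffled.  MI subjects come from
    shifted factor distributions so the group is recoverable from shape.
    """
    if not isinstance(n_subjects, (int, np.integer)) or n_subjects < 1:
        raise ValueError(f"n_subjects must be a positive integer, got {n_subjects!r}")
    if not (math.isfinite(mi_fraction) and 0.0 <= mi_fraction <= 1.0):
        raise ValueError(f"mi_fraction must be in [0, 1], got {mi_fraction!r}")
    rng = np.random.default_rng(seed)
    n_mi = int(round(n_subjects * mi_fraction))
    params = [_draw_params(rng, True) for _ in range(n_mi)]
    params += [_draw_params(rng, False) for _ in range(n_subjects - n_mi)]
    order = rng.permutation(n_subjects)
    return [params[i] for i in order]


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def _truncated_volume(a: float, b: float, zfrac: float) -> float:
    """Volume of the axisymmetric ellipsoid (semi-axes b, b, a) below z = zfrac*a."""
    z = np.clip(zfrac, -1.0, 1.0)
    return math.pi * a * b * b * (z - z**3 / 3.0 + 2.0 / 3.0)


def _bisect(f, lo: float, hi: float, tol: float = 1e-10, it: int = 200) -> float:
    flo, fhi = f(lo), f(hi)
    if flo * fhi > 0:
        raise ValueError("bisection bracket does not contain a root")
    for _ in range(it):
        mid = 0.5 * (lo + hi)
        fm = f(mid)
        if abs(fm) < tol or hi - lo < tol:
            return mid
        if flo * fm <= 0:
            hi, fhi = mid, fm
        else:
            lo, flo = mid, fm
    return 0.5 * (lo + hi)


def _sample_ellipsoid(
    rng: np.random.Generator,
    n: int,
    semi_xy: float,
    semi_z: float,
    center: np.ndarray,
    keep_fn,
) -> np.ndarray:
    """Area-uniform samples on an axisymmetric ellipsoid surface, filtered.

    Uniform sphere directions are mapped to the ellipsoid and accepted with
    probability proportional to the local area stretch, which yields exact
    area-uniform surface sampling; ``keep_fn`` applies the geometric clips
    (basal cut, septal clearance).
    """
    b, a = semi_xy, semi_z
    out = []
    have = 0
    w_axis = (b / a) ** 2 if a >= b else 1.0  # weight normalisation (a >= b here)
    for _ in range(400):
        m = max(4 * (n - have), 256)
        u = rng.normal(size=(m, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        # area weight for (b*ux, b*uy, a*uz): sqrt((ab ux)^2 + (ab uy)^2 + (b^2 uz)^2)
        w = np.sqrt(u[:, 0] ** 2 + u[:, 1] ** 2 + w_axis * u[:, 2] ** 2)
        acc = rng.random(m) < w  # w <= 1 since a >= b
        p = np.column_stack([b * u[acc, 0], b * u[acc, 1], a * u[acc, 2]]) + center
        p = p[keep_fn(p)]
        out.append(p)
        have += p.shape[0]
        if have >= n:
            break
    pts = np.vstack(out)
    if pts.shape[0] < n:
        raise ValueError(
            "surface sampling failed: clips reject too many candidates "
            f"({pts.shape[0]}/{n} accepted)"
        )
    return pts[:n]


@dataclass(frozen=True)
class _Geometry:
    """Analytic surface parameters of one subject at one phase."""

    a_endo: float
    b_endo: float
    a_epi: float
    b_epi: float
    a_rv: float
    b_rv: float
    rv_center: tuple[float, float, float]
    base_point: tuple[float, float, float]
    base_normal: tuple[float, float, float]

    def inside_epi(self, p: np.ndarray) -> np.ndarray:
        return (p[:, 0] ** 2 + p[:, 1] ** 2) / self.b_epi**2 + p[:, 2] ** 2 / self.a_epi**2

    def below_base(self, p: np.ndarray) -> np.ndarray:
        n = np.asarray(self.base_normal)
        return (p - np.asarray(self.base_point)) @ n < 0


def _phase_geometry(params: ShapeParams, phase: str) -> _Geometry:
    s, e, w = params.scale, params.elongation, params.wall_thickness
    a = LV_ENDO_LONG_SEMI_AXIS * s * e
    b = LV_ENDO_SHORT_SEMI_AXIS * s / math.sqrt(e)
    a_epi, b_epi = a + w, b + w
    zb = BASE_CUT_FRACTION * a
    a_rv = RV_LONG_FRACTION * a
    b_rv = RV_SHORT_SEMI_AXIS * s * params.rv_size
    rv_cx = RV_CENTER_X_FRACTION * b

    if phase == "ES":
        ls = ES_LONG_SHORTENING
        # radial contraction factor solved so the truncated LV endo cavity
        # loses exactly ef_target of its ED volume
        v_ed = _truncated_volume(a, b, BASE_CUT_FRACTION)
        target = (1.0 - params.ef_target) * v_ed
        if target >= _truncated_volume(ls * a, b, BASE_CUT_FRACTION):
            raise ValueError(
                "geometrically impossible params: ef_target so low that the "
                "ES endocardium would expand beyond the ED wall")
        c = _bisect(
            lambda cc: _truncated_volume(ls * a, cc * b, BASE_CUT_FRACTION) - target,
            0.05, 1.0,
        )
        v_myo = _truncated_volume(a_epi, b_epi, zb / a_epi) - v_ed
        a_endo_es, b_endo_es = ls * a, c * b
        a_epi_es = ls * a_epi
        zfrac_epi = zb / a_epi  # preserved under uniform ls scaling
        k_epi = zfrac_epi - zfrac_epi**3 / 3.0 + 2.0 / 3.0
        v_endo_es = target
        b_epi_es = math.sqrt((v_myo + v_endo_es) / (math.pi * a_epi_es * k_epi))
        if b_epi_es <= b_endo_es:
            raise ValueError("geometrically impossible params: ES epicardium "
                             "would intersect the endocardium")
        a, b, a_epi, b_epi = a_endo_es, b_endo_es, a_epi_es, b_epi_es
        zb = ls * zb
        a_rv, b_rv = ls * a_rv, c * b_rv

    tilt = math.radians(params.basal_tilt)
    normal = (math.sin(tilt), 0.0, math.cos(tilt))
    return _Geometry(
        a_endo=a, b_endo=b, a_epi=a_epi, b_epi=b_epi,
        a_rv=a_rv, b_rv=b_rv,
        rv_center=(rv_cx, 0.0, 0.0),
        base_point=(0.0, 0.0, zb), base_normal=normal,
    )


def _build_cloud(
    params: ShapeParams, phase: str, n_per_class: int, rng: np.random.Generator
) -> MultiClassPointCloud:
    g = _phase_geometry(params, phase)
    origin = np.zeros(3)

    lv_endo = _sample_ellipsoid(rng, n_per_class, g.b_endo, g.a_endo, origin, g.below_base)
    lv_epi = _sample_ellipsoid(rng, n_per_class, g.b_epi, g.a_epi, origin, g.below_base)
    rv_center = np.asarray(g.rv_center)

    def rv_keep(p):
        return g.below_base(p) & (g.inside_epi(p) > RV_EPI_CLEARANCE)

    rv_endo = _sample_ellipsoid(rng, n_per_class, g.b_rv, g.a_rv, rv_center, rv_keep)

    points = np.vstack([lv_endo, lv_epi, rv_endo])
    labels = np.repeat([LV_ENDO, LV_EPI, RV_ENDO], n_per_class)
    return MultiClassPointCloud(points=points, labels=labels, phase=phase)


def build_anatomy(
    params: ShapeParams, points_per_class: int, seed: int
) -> AnatomySample:
    """Build the paired ED/ES multi-class clouds for one subject.

    ED surfaces are truncated ellipsoids (LV endo inside LV epi by
    wall_thickness; RV endo a septally clipped crescent); the ES surfaces
    are a radial contraction toward the LV long axis with conserved
    myocardial volume (hence wall thickening), solved to hit ``ef_target``.
    Sampling is area-uniform per surface with exactly ``points_per_class``
    points per class.
    """
    if points_per_class < 64:
        raise ValueError(f"points_per_class must be >= 64, got {points_per_class}")
    rng = np.random.default_rng(seed)
    ed = _build_cloud(params, "ED", points_per_class, rng)
    es = _build_cloud(params, "ES", points_per_class, rng)
    return AnatomySample(
        subject_id=f"synthetic-{seed}",
        ed=ed, es=es,
        group="prevalent_mi" if params.mi_flag else "control",
        truth=params,
    )


# ---------------------------------------------------------------------------
# survival labels
# ---------------------------------------------------------------------------

def make_survival_labels(
    params_list: list[ShapeParams],
    followup_days: float,
    seed: int,
    gamma: float = 1.0,
    baseline_hazard: float = 1e-4,
) -> tuple[list[tuple[float, bool]], dict]:
    """Exponential proportional-hazards event times with administrative censoring.

    Each subject's event time is drawn from an exponential distribution with
    rate ``baseline_hazard * exp(gamma * risk_score)`` (per day); subjects
    whose event falls after ``followup_days`` are right-censored there.
    Returns the per-subject ``(event_time_days, event_observed)`` pairs and a
    dict recording the generating ``gamma`` and ``baseline_hazard`` so
    downstream recovery tests know the truth.
    """
    if not (math.isfinite(followup_days) and followup_days > 0):
        raise ValueError(f"followup_days must be > 0, got {followup_days!r}")
    if not math.isfinite(gamma):
        raise ValueError("gamma must be finite")
    if baseline_hazard <= 0:
        raise ValueError(f"baseline_hazard must be > 0, got {baseline_hazard!r}")
    rng = np.random.default_rng(seed)
    labels = []
    for p in params_list:
        rate = baseline_hazard * math.exp(gamma * p.risk_score)
        t = rng.exponential(1.0 / rate)
        if t < followup_days:
            labels.append((float(t), True))
        else:
            labels.append((float(followup_days), False))
    truth = {"gamma": gamma, "baseline_hazard": baseline_hazard,
             "followup_days": followup_days}
    return labels, truth


# ---------------------------------------------------------------------------
# dataset split
# ---------------------------------------------------------------------------

def _largest_remainder(n: int, fractions) -> list[int]:
    quotas = [n * f for f in fractions]
    sizes = [int(math.floor(q)) for q in quotas]
    short = n - sum(sizes)
    rema = sorted(range(len(fractions)), key=lambda i: (-(quotas[i] - sizes[i]), i))
    for i in rema[:short]:
        sizes[i] += 1
    return sizes


def split_dataset(samples, fractions, seed: int):
    """Stratified, seeded train/val/test partition with largest-remainder sizes.

    Global split sizes follow largest-remainder rounding of ``fractions``
    (ties broken toward the earlier split); within each cohort group, subjects
    are shuffled and allocated so that the group composition of each split is
    as proportional as the global sizes allow.  Returns three disjoint lists
    whose union is the input.
    """
    fractions = tuple(float(f) for f in fractions)
    if len(fractions) != 3 or any(f <= 0 for f in fractions):
        raise ValueError("fractions must be three positive numbers")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {sum(fractions)}")
    samples = list(samples)
    n = len(samples)
    if n < 3:
        raise ValueError(f"need at least 3 samples to split, got {n}")
    target = _largest_remainder(n, fractions)

    rng = np.random.default_rng(seed)
    groups: dict[str, list[int]] = {}
    for i, s in enumerate(samples):
        groups.setdefault(getattr(s, "group", "all"), []).append(i)

    splits: list[list[int]] = [[], [], []]
    remaining = list(target)
    for gname in sorted(groups):
        idx = groups[gname]
        idx = [idx[j] for j in rng.permutation(len(idx))]
        # provisional per-group allocation, then clip to remaining capacity
        alloc = _largest_remainder(len(idx), fractions)
        for k in range(3):
            alloc[k] = min(alloc[k], remaining[k])
        # distribute any leftover of this group into splits with spare room
        spare = len(idx) - sum(alloc)
        k = 0
        while spare > 0:
            if alloc[k] < remaining[k]:
                alloc[k] += 1
                spare -= 1
            else:
                k += 1
        pos = 0
        for k in range(3):
            splits[k].extend(idx[pos:pos + alloc[k]])
            remaining[k] -= alloc[k]
            pos += alloc[k]
    return tuple([samples[i] for i in sorted(sp)] for sp in splits)


# ---------------------------------------------------------------------------
# cohort orchestration & clinical metrics
# ---------------------------------------------------------------------------

def generate_cohort(
    n_subjects: int,
    mi_fraction: float = 0.3,
    points_per_class: int = 1024,
    followup_days: float = 3650.0,
    seed: int = 0,
    gamma: float = 1.0,
    baseline_hazard: float = 1e-4,
) -> list[AnatomySample]:
    """Generate a full seeded cohort with shapes, groups, and survival labels.

    Subjects with ``mi_flag`` are labeled ``prevalent_mi`` (infarction before
    imaging; excluded from the incident-survival task).  Among the remaining
    subjects, those with an observed event within follow-up become
    ``incident_mi``; the rest are right-censored controls.
    """
    ss = np.random.SeedSequence(seed)
    s_params, s_surv, s_shapes = ss.spawn(3)
    params = sample_population_params(
        n_subjects, mi_fraction, int(s_params.generate_state(1)[0] % 2**31)
    )
    labels, _ = make_survival_labels(
        params, followup_days, int(s_surv.generate_state(1)[0] % 2**31),
        gamma=gamma, baseline_hazard=baseline_hazard,
    )
    shape_seeds = s_shapes.generate_state(n_subjects) % 2**31
    cohort = []
    for i, (p, (t, ev)) in enumerate(zip(params, labels)):
        sample = build_anatomy(p, points_per_class, int(shape_seeds[i]))
        if p.mi_flag:
            group, time, observed = "prevalent_mi", None, False
        elif ev:
            group, time, observed = "incident_mi", t, True
        else:
            group, time, observed = "control", t, False
        cohort.append(replace(
            sample, subject_id=f"s{i:05d}", group=group,
            event_time_days=time, event_observed=observed,
        ))
    return cohort


def clinical_metric_table(samples) -> pd.DataFrame:
    """Long-format table of clinical metrics per subject.

    Computes end-diastolic LV volume (mL), RV volume (mL) and LV mass (g)
    from the point clouds via :mod:`cardiovae.shape_metrics`.
    """
    rows = []
    for s in samples:
        lv_endo = s.ed.points_of_class(LV_ENDO)
        lv_epi = s.ed.points_of_class(LV_EPI)
        rv = s.ed.points_of_class(RV_ENDO)
        rows.append((s.subject_id, "lv_volume_ml",
                     shape_metrics.cavity_volume(lv_endo) / 1000.0))
        rows.append((s.subject_id, "rv_volume_ml",
                     shape_metrics.cavity_volume(rv) / 1000.0))
        rows.append((s.subject_id, "lv_mass_g",
                     shape_metrics.lv_mass(lv_endo, lv_epi)))
    return pd.DataFrame(rows, columns=["subject_id", "metric", "value"])


def cohort_metadata(samples) -> pd.DataFrame:
    """Cohort metadata frame (subject_id, group, survival, truth factors)."""
    rows = []
    for s in samples:
        row = {
            "subject_id": s.subject_id,
            "group": s.group,
            "event_time_days": s.event_time_days,
            "event_observed": s.event_observed,
        }
        if s.truth is not None:
            for f in ("scale", "elongation", "basal_tilt", "wall_thickness",
                      "rv_size", "ef_target", "mi_flag", "risk_score"):
                row[f"truth_{f}"] = getattr(s.truth, f)
        rows.append(row)
    return pd.DataFrame(rows)
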