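"""Synthetic fixtures with analytic ground truth.

Every stage of the toolkit is testable without any slide download:

* :func:`generate_mask` draws non-overlapping ellipses — glomeruli with an
  inner tuft, tubules, arteries with an inner lumen — onto a label canvas
  and records the analytic area, maximum diameter, eccentricity and
  elongation of every instance. Shapes are smooth ellipses rather than
  histologically textured blobs: the pipeline consumes label maps, so
  intensity realism is irrelevant by design.
* :func:`corrupt_mask` degrades an instance map in controlled ways
  (per-instance erosion, instance dropping, spurious blobs) to drive the
  segmentation-metric tests with known expected scores.
* :func:`generate_cohort` simulates a biopsy cohort with log-normal
  morphometric features and exponential survival whose log-hazard is a
  step function of each biomarker at a known cut-off — the recovery target
  for the maxstat/Cox pipeline.
* :func:`generate_latent_population` simulates structures whose features
  are monotone functions of a latent progression time plus noise — the
  recovery target for the pseudotime pipeline.

All generators are pure functions of their spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.draw import ellipse as draw_ellipse

from .core_io import (
    ARTERY,
    GLOMERULUS,
    LUMEN,
    TUBULE,
    TUFT,
    ClassSchema,
    PixelCalibration,
    SemanticMap,
)
from .postprocess import InstanceMap, InstanceRecord, _link_children

__all__ = [
    "MaskSpec",
    "CohortSpec",
    "generate_mask",
    "corrupt_mask",
    "generate_cohort",
    "generate_latent_population",
]


# ---------------------------------------------------------------------------
# masks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MaskSpec:
    """Parameters of a synthetic label mask.

    Sizes are full diameters in micrometres; axis ratio is minor/major.
    ``min_separation_um`` is enforced between bounding circles, so
    instances never overlap (0 still permits touching after discretisation
    only when negative values are passed — use >= 1 px worth of microns to
    keep instances cleanly separated).
    """

    shape: tuple[int, int] = (1024, 1024)
    calibration: PixelCalibration = field(default_factory=lambda: PixelCalibration(0.5))
    n_glomeruli: int = 3
    n_tubules: int = 12
    n_arteries: int = 2
    glomerulus_diameter_um: tuple[float, float] = (100.0, 150.0)
    tubule_diameter_um: tuple[float, float] = (30.0, 60.0)
    artery_diameter_um: tuple[float, float] = (60.0, 90.0)
    axis_ratio: tuple[float, float] = (0.6, 1.0)
    tuft_area_fraction: tuple[float, float] = (0.55, 0.8)
    lumen_area_fraction: tuple[float, float] = (0.15, 0.35)
    min_separation_um: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_glomeruli, self.n_tubules, self.n_arteries) < 0:
            raise ValueError("counts must be >= 0")


_MAX_PLACEMENT_FAILURES = 10_000


def _place_ellipses(rng, spec: MaskSpec):
    """Rejection-sample non-overlapping ellipse parameters for all classes."""
    mpp = spec.calibration.microns_per_pixel
    h, w = spec.shape
    sep_px = spec.min_separation_um / mpp
    placed: list[tuple] = []  # (class, cy, cx, a_px, b_px, theta)
    plan = (
        [(GLOMERULUS, spec.glomerulus_diameter_um)] * spec.n_glomeruli
        + [(ARTERY, spec.artery_diameter_um)] * spec.n_arteries
        + [(TUBULE, spec.tubule_diameter_um)] * spec.n_tubules
    )
    failures = 0
    for cls, (dlo, dhi) in plan:
        while True:
            d_um = rng.uniform(dlo, dhi)
            ratio = rng.uniform(*spec.axis_ratio)
            a = d_um / 2.0 / mpp  # semi-major axis, px
            if 2 * a + 2 >= min(h, w):
                raise RuntimeError(
                    f"infeasible packing: a {d_um:g} um shape does not fit the "
                    f"{h}x{w} px canvas (placed {len(placed)} of {len(plan)})"
                )
            b = a * ratio
            theta = rng.uniform(0, np.pi)
            cy = rng.uniform(a + 1, h - a - 1)
            cx = rng.uniform(a + 1, w - a - 1)
            ok = all(
                np.hypot(cy - py, cx - px) >= a + pa + sep_px
                for (_, py, px, pa, _, _) in placed
            )
            if ok:
                placed.append((cls, cy, cx, a, b, theta))
                break
            failures += 1
            if failures > _MAX_PLACEMENT_FAILURES:
                raise RuntimeError(
                    f"infeasible packing: placed {len(placed)} of "
                    f"{len(plan)} shapes before exceeding the failure budget"
                )
    return placed


def generate_mask(
    spec: MaskSpec = MaskSpec(),
) -> tuple[SemanticMap, InstanceMap, pd.DataFrame]:
    """Generate a synthetic label mask with analytic ground truth.

    Returns the semantic map, the ground-truth instance map (with
    containment links) and a table of analytic per-instance features
    (area [um^2], d_max [um], eccentricity, elongation and, for glomeruli,
    tuft_area_fraction and bowman_area). Deterministic per seed.
    """
    rng = np.random.default_rng(spec.seed)
    mpp = spec.calibration.microns_per_pixel
    placed = _place_ellipses(rng, spec)

    schema = ClassSchema()
    sem = np.zeros(spec.shape, dtype=np.int32)
    inst = np.zeros(spec.shape, dtype=np.int32)
    records: dict[int, InstanceRecord] = {}
    analytic_rows = []
    next_id = 1

    def draw(cls, cy, cx, a, b, theta, parent=None):
        nonlocal next_id
        rr, cc = draw_ellipse(cy, cx, a, b, shape=spec.shape, rotation=theta)
        iid = next_id
        next_id += 1
        sem[rr, cc] = schema.code(cls)
        inst[rr, cc] = iid
        records[iid] = InstanceRecord(
            id=iid, class_name=cls, n_pixels=len(rr),
            bbox=(int(rr.min()), int(cc.min()), int(rr.max()) + 1, int(cc.max()) + 1),
            parent=parent,
        )
        # Ramanujan's second approximation to the ellipse perimeter
        h = ((a - b) / (a + b)) ** 2
        perim = np.pi * (a + b) * (1 + 3 * h / (10 + np.sqrt(4 - 3 * h)))
        analytic_rows.append(
            {
                "instance_id": iid,
                "class": cls,
                "area": np.pi * a * b * mpp**2,
                "d_max": 2.0 * a * mpp,
                "perimeter": perim * mpp,
                "circularity": 4.0 * np.pi * (np.pi * a * b) / perim**2,
                "eccentricity": np.sqrt(1.0 - (b / a) ** 2),
                "elongation": 1.0 - b / a,
            }
        )
        return iid

    for cls, cy, cx, a, b, theta in placed:
        pid = draw(cls, cy, cx, a, b, theta)
        if cls == GLOMERULUS:
            f = rng.uniform(*spec.tuft_area_fraction)
            draw(TUFT, cy, cx, a * np.sqrt(f), b * np.sqrt(f), theta, parent=pid)
            analytic_rows[-2]["tuft_area_fraction"] = f
            analytic_rows[-2]["bowman_area"] = (1 - f) * analytic_rows[-2]["area"]
        elif cls == ARTERY:
            f = rng.uniform(*spec.lumen_area_fraction)
            draw(LUMEN, cy, cx, a * np.sqrt(f), b * np.sqrt(f), theta, parent=pid)

    # annulus parents: n_pixels in the raster exclude the child, which is
    # what the InstanceMap convention stores (morphometry re-fills holes)
    for iid, rec in records.items():
        rec.n_pixels = int((inst == iid).sum())

    semantic = SemanticMap(labels=sem, schema=schema, calibration=spec.calibration)
    imap = InstanceMap(
        labels=inst, records=records, schema=schema, calibration=spec.calibration
    )
    return semantic, imap, pd.DataFrame(analytic_rows)


def corrupt_mask(
    imap: InstanceMap,
    erosion_px: int = 0,
    drop_fraction: float = 0.0,
    spurious_count: int = 0,
    seed: int = 0,
) -> tuple[InstanceMap, pd.DataFrame]:
    """Controlled degradation of an instance map for metric testing.

    Erodes every kept instance by ``erosion_px`` (disk), drops a seeded
    fraction of instances entirely, and adds ``spurious_count`` elliptical
    blobs in the background. Returns the corrupted map plus a report with,
    per original instance, whether it was kept and the expected Dice
    against the original computed from the actual pixel counts
    (2 * eroded / (original + eroded)).
    """
    from scipy import ndimage
    from skimage.morphology import disk

    if erosion_px < 0 or drop_fraction < 0 or spurious_count < 0:
        raise ValueError("corruption parameters must be >= 0")
    rng = np.random.default_rng(seed)
    ids = sorted(imap.records)
    n_drop = int(round(drop_fraction * len(ids)))
    dropped = set(rng.choice(ids, size=n_drop, replace=False).tolist())

    labels = np.zeros_like(imap.labels)
    records: dict[int, InstanceRecord] = {}
    rows = []
    next_id = 1
    selem = disk(erosion_px) if erosion_px > 0 else None
    for iid in ids:
        rec = imap.records[iid]
        if iid in dropped:
            rows.append({"orig_id": iid, "kept": False, "expected_dice": 0.0})
            continue
        win = imap.window(iid, pad=erosion_px + 1)
        sub = imap.labels[win] == iid
        n0 = int(sub.sum())
        if selem is not None:
            sub = ndimage.binary_erosion(sub, structure=selem)
        n1 = int(sub.sum())
        if n1 == 0:
            rows.append({"orig_id": iid, "kept": False, "expected_dice": 0.0})
            continue
        view = labels[win]
        view[sub] = next_id
        rr, cc = np.nonzero(sub)
        records[next_id] = InstanceRecord(
            id=next_id, class_name=rec.class_name, n_pixels=n1,
            bbox=(win[0].start + int(rr.min()), win[1].start + int(cc.min()),
                  win[0].start + int(rr.max()) + 1, win[1].start + int(cc.max()) + 1),
        )
        rows.append(
            {"orig_id": iid, "kept": True, "new_id": next_id,
             "expected_dice": 2.0 * n1 / (n0 + n1)}
        )
        next_id += 1

    free = (labels == 0) & (imap.labels == 0)
    h, w = labels.shape
    for _ in range(spurious_count):
        for _attempt in range(200):
            a = rng.uniform(4, 10)
            b = a * rng.uniform(0.6, 1.0)
            cy, cx = rng.uniform(a, h - a), rng.uniform(a, w - a)
            rr, cc = draw_ellipse(cy, cx, a, b, shape=(h, w))
            if free[rr, cc].all():
                labels[rr, cc] = next_id
                records[next_id] = InstanceRecord(
                    id=next_id, class_name=TUBULE, n_pixels=len(rr),
                    bbox=(int(rr.min()), int(cc.min()),
                          int(rr.max()) + 1, int(cc.max()) + 1),
                )
                free[rr, cc] = False
                next_id += 1
                break

    out = InstanceMap(
        labels=labels, records=records, schema=imap.schema,
        calibration=imap.calibration, slide_id=imap.slide_id,
        patient_id=imap.patient_id,
    )
    _link_children(out)
    return out, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a simulated biopsy cohort.

    Each biomarker is log-normal; its contribution to the log hazard is a
    step of height ``log_hr`` for patients above ``cut``. Group effects
    multiply feature values per diagnosis group (e.g. a 1.19 multiplier
    emulates a ~19% tuft-area increase in a disease group).
    """

    n_patients: int = 500
    biomarkers: dict = field(
        default_factory=lambda: {
            "dist_min": {"log_mean": np.log(10.0), "log_sd": 0.45,
                         "cut": 10.0, "log_hr": np.log(2.0)}
        }
    )
    group_effects: dict = field(default_factory=dict)  # group -> {feature: mult}
    group_fractions: dict = field(default_factory=dict)  # group -> fraction
    baseline_hazard: float = 0.08  # events per year in the low-risk stratum
    censoring_rate: float = 0.05  # random loss to follow-up, per year
    horizon: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_hazard <= 0 or self.censoring_rate < 0:
            raise ValueError("hazards must be positive")
        if self.n_patients < 20:
            raise ValueError("need n >= 20 patients")


def generate_cohort(
    spec: CohortSpec = CohortSpec(),
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Simulate patient-level features, clinical records and ground truth.

    Returns (patient feature table, clinical table, truth dict). The truth
    dict records every generating parameter plus each patient's true
    high-risk indicator, sufficient to recompute all expectations.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients
    pid = np.array([f"P{i:04d}" for i in range(n)])

    groups = list(spec.group_fractions) or ["all"]
    fracs = np.array([spec.group_fractions.get(g, 1.0) for g in groups], float)
    fracs = fracs / fracs.sum()
    grp = rng.choice(groups, size=n, p=fracs)

    feats = pd.DataFrame({"patient_id": pid, "group": grp})
    z = {}
    loghaz = np.full(n, np.log(spec.baseline_hazard))
    for name, bm in spec.biomarkers.items():
        x = rng.lognormal(bm["log_mean"], bm["log_sd"], size=n)
        for g, effects in spec.group_effects.items():
            if name in effects:
                x[grp == g] *= effects[name]
        feats[name] = x
        z[name] = (x > bm["cut"]).astype(int)
        loghaz += bm["log_hr"] * z[name]

    lam = np.exp(loghaz)
    t_event = rng.exponential(1.0 / lam)
    t_cens = (
        rng.exponential(1.0 / spec.censoring_rate, size=n)
        if spec.censoring_rate > 0
        else np.full(n, np.inf)
    )
    followup = np.minimum(np.minimum(t_event, t_cens), spec.horizon)
    event = (t_event <= np.minimum(t_cens, spec.horizon)).astype(int)

    # clinical covariates
    age = np.clip(rng.normal(45, 12, n), 18, 85)
    sex = rng.integers(0, 2, n)
    egfr0 = np.clip(rng.normal(90, 18, n), 15, 140)
    mestc = {
        "M": rng.integers(0, 2, n), "E": rng.integers(0, 2, n),
        "S": rng.integers(0, 2, n), "T": rng.integers(0, 3, n),
        "C": rng.integers(0, 3, n),
    }

    # attribute event causes and emit consistent eGFR trajectories
    cause_draw = rng.uniform(size=n)
    eskd_years = np.full(n, np.nan)
    egfr_rows = [
        {"patient_id": p, "years": 0.0, "egfr": e} for p, e in zip(pid, egfr0)
    ]
    for i in range(n):
        if event[i]:
            t = t_event[i]
            if cause_draw[i] < 0.4:  # ESKD only
                eskd_years[i] = t
                egfr_rows.append(
                    {"patient_id": pid[i], "years": t, "egfr": 0.6 * egfr0[i]}
                )
            elif cause_draw[i] < 0.7:  # halving only
                egfr_rows.append(
                    {"patient_id": pid[i], "years": t, "egfr": 0.45 * egfr0[i]}
                )
            else:  # both
                eskd_years[i] = t
                egfr_rows.append(
                    {"patient_id": pid[i], "years": t, "egfr": 0.40 * egfr0[i]}
                )
        else:
            egfr_rows.append(
                {"patient_id": pid[i], "years": followup[i],
                 "egfr": 0.8 * egfr0[i]}
            )

    clinical = pd.DataFrame(
        {
            "patient_id": pid, "group": grp, "age": age, "sex": sex,
            "egfr_initial": egfr0, **mestc,
            "followup_years": followup, "eskd_years": eskd_years,
        }
    )
    egfr_records = pd.DataFrame(egfr_rows)
    truth = {
        "spec": spec,
        "true_high_risk": pd.DataFrame({**{"patient_id": pid}, **z}),
        "true_event_time": t_event,
        "true_censor_time": t_cens,
        "egfr_records": egfr_records,
    }
    return feats, clinical, truth


# ---------------------------------------------------------------------------
# latent-time populations
# ---------------------------------------------------------------------------

def generate_latent_population(
    n_instances: int = 2000,
    n_features: int = 14,
    noise_sd: float = 0.05,
    condition_thresholds: tuple[float, float] = (1.0 / 3.0, 2.0 / 3.0),
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Simulate structures whose features are monotone in a latent time.

    ``t ~ Uniform(0, 1)``; feature j is ``f_j(t) + noise`` with ``f_j`` a
    monotone map of unit amplitude (alternating direction; linear,
    quadratic, square-root and logistic shapes cycle across features, so
    the relative feature composition changes along t). The condition label
    encodes disease stage by thresholding t (healthy / intermediate /
    diseased).

    Returns (feature matrix, latent t, condition labels).
    """
    rng = np.random.default_rng(seed)
    t = rng.uniform(0.0, 1.0, size=n_instances)
    shapes = [
        lambda u: u,
        lambda u: u**2,
        lambda u: np.sqrt(u),
        lambda u: 1.0 / (1.0 + np.exp(-8.0 * (u - 0.5))),
    ]
    X = np.empty((n_instances, n_features))
    for j in range(n_features):
        g = shapes[j % len(shapes)](t)
        if j % 2 == 1:
            g = 1.0 - g
        X[:, j] = g + rng.normal(0.0, noise_sd, size=n_instances)
    lo, hi = condition_thresholds
    condition = np.where(t < lo, "healthy",
                         np.where(t < hi, "intermediate", "diseased"))
    return X, t, condition
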