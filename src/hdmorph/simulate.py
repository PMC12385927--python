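"""Synthetic paired-specimen generator.

Real histology slides from Hirschsprung's disease resections are not
publicly available, so the pipeline is exercised on a tissue phantom: paired
aganglionic/ganglionic "specimens" whose per-layer mean thicknesses and
within-patient differences follow the cohort summary statistics of the study
population (normal paired-difference structure, consistent with the
confirmed normality of the real measurements).

Two levels of synthesis are provided:

* :func:`draw_paired_features` draws the per-patient feature table directly
  (layer thicknesses, muscle-coat ratio, folding ratio) — fast, used for
  statistical and classifier simulations;
* :func:`generate_specimen_geometry` / :func:`generate_cohort_geometry`
  additionally emit full delineation geometry — nested closed contours
  around a mildly irregular lumen, with a pleated submucosal inner boundary
  — so the contour-measurement code can be tested end to end.

The phantom is geometric, not histological: it has no texture, no staining,
no transition-zone gradients, and its layers are concentric by
construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .geometry import (
    LAYERS,
    Contour,
    LayerDelineation,
    _outward_normals,
    _ray_polyline_first_hit,
    resample_contour,
)

__all__ = [
    "LayerEffect",
    "CohortParameters",
    "GroundTruth",
    "SimulatedSpecimen",
    "draw_paired_features",
    "generate_specimen_geometry",
    "generate_cohort_geometry",
    "generate_patient_registry",
]


@dataclass(frozen=True)
class LayerEffect:
    """Generating distribution of one feature across the cohort (mm).

    ``aganglionic_mean``/``sd`` parameterise the aganglionic draw; the
    within-patient difference (aganglionic − ganglionic) is drawn as
    Normal(``diff_mean``, ``diff_sd``), so the ganglionic value is the
    aganglionic draw minus the difference draw.
    """

    aganglionic_mean: float
    aganglionic_sd: float
    diff_mean: float
    diff_sd: float


#: Cohort defaults: per-layer aganglionic mean (SD) and paired-difference
#: mean (SD) in mm, matching the study cohort's printed summary statistics.
LAYER_EFFECTS: dict[str, LayerEffect] = {
    "mucosa": LayerEffect(0.505, 0.191, 0.024, 0.187),
    "submucosa": LayerEffect(0.618, 0.244, 0.094, 0.280),
    "muscularis_interna": LayerEffect(0.461, 0.130, -0.205, 0.138),
    "myenteric": LayerEffect(0.018, 0.018, -0.006, 0.020),
    "muscularis_externa": LayerEffect(0.401, 0.203, 0.066, 0.204),
}

#: Folding-ratio feature draw (dimensionless), same paired structure.
FOLDING_EFFECT = LayerEffect(1.101, 0.203, 0.021, 0.222)

#: Muscularis interna/externa ratio draw (dimensionless), used by the
#: default ``mi_me_model="ratio"``; cohort mean (SD) and paired difference.
RATIO_EFFECT = LayerEffect(1.287, 0.356, -0.760, 0.521)

#: Lower truncation of thickness draws, mm.  The myenteric tissue layer is
#: an order of magnitude thinner than every other layer, so it gets its own
#: floor well below its cohort mean.
THICKNESS_FLOOR_MM = 0.05
MYENTERIC_FLOOR_MM = 0.002
FOLDING_FLOOR = 0.2
RATIO_FLOOR = 0.2


@dataclass(frozen=True)
class CohortParameters:
    """Parameters of the synthetic paired cohort.

    Feature-level defaults reproduce the study cohort's per-layer means/SDs
    and paired differences; geometry-level defaults (lumen radius, contour
    irregularity, fold amplitude/frequency) describe an infant rectosigmoid
    cross-section and are calibrated so the measured submucosal folding
    ratio lands near the cohort values (≈1.10 aganglionic, ≈1.08
    ganglionic).
    """

    n_patients: int = 30
    layer_effects: Mapping[str, LayerEffect] = field(
        default_factory=lambda: dict(LAYER_EFFECTS)
    )
    folding_effect: LayerEffect = FOLDING_EFFECT
    ratio_effect: LayerEffect = RATIO_EFFECT
    #: optional within-patient shared scale SD; 0 draws layers independently
    patient_scale_sd: float = 0.0
    #: how the muscle-coat features relate: "ratio" draws the muscularis
    #: interna and the interna/externa ratio as the primary paired features
    #: and derives the externa; "independent" draws both coats and derives
    #: the ratio (see :func:`draw_paired_features`)
    mi_me_model: str = "ratio"
    # --- geometry ---
    lumen_radius_um: float = 1500.0
    lumen_radius_sd_um: float = 200.0
    irregularity_amplitude: float = 0.03
    fold_frequency: int = 40
    #: fold amplitude relative to the submucosal inner-boundary radius
    fold_amplitude: Mapping[str, float] = field(
        default_factory=lambda: {"aganglionic": 0.0344, "ganglionic": 0.0311}
    )
    n_theta: int = 2048
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        for name, eff in self.layer_effects.items():
            if eff.aganglionic_mean <= 0 or eff.aganglionic_sd < 0 or eff.diff_sd < 0:
                raise ValueError(f"invalid effect parameters for {name!r}")
        if self.lumen_radius_um <= 0 or self.lumen_radius_sd_um < 0:
            raise ValueError("invalid lumen radius parameters")


@dataclass
class GroundTruth:
    """Generating values behind a synthetic cohort.

    ``features`` holds one row per patient-segment with the true (drawn)
    layer thicknesses and derived ratios; ``segment`` is the true label.
    """

    features: pd.DataFrame
    params: CohortParameters


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, floor: float, size: int
) -> np.ndarray:
    if sd == 0.0:
        return np.full(size, max(mean, floor))
    a = (floor - mean) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size, random_state=rng)


def draw_paired_features(p: CohortParameters) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw the paired per-patient feature table.

    For each patient and layer, the aganglionic thickness is a truncated
    normal draw at the cohort mean/SD; the within-patient difference is a
    normal draw at the cohort difference mean/SD; the ganglionic thickness
    is their difference (floored at the same truncation bound).  The
    full-wall thickness is the sum of the five layers; the folding ratio is
    drawn with the same paired structure.  Reproducible under ``p.seed``.

    The two muscle coats need a joint model because the diagnostic ratio
    depends on their within-specimen correlation, which the cohort summary
    statistics do not identify.  Under the default ``mi_me_model="ratio"``
    the muscularis interna thickness and the interna/externa ratio — the two
    diagnostic features — are drawn as independent paired features at their
    cohort means/SDs, and the externa is derived as interna/ratio; this
    reproduces both diagnostic feature distributions exactly and makes the
    two criteria fail independently, matching the disjoint criterion
    failures observed across the study cohort.  ``mi_me_model="independent"``
    instead draws both coats independently at their printed marginals and
    derives the ratio; the derived ratio is then far more dispersed than the
    cohort's, because nothing ties a thick interna to a thick externa.
    """
    rng = np.random.default_rng(p.seed)
    n = p.n_patients
    if p.mi_me_model not in ("ratio", "independent"):
        raise ValueError("mi_me_model must be 'ratio' or 'independent'")
    cols_a: dict[str, np.ndarray] = {}
    cols_g: dict[str, np.ndarray] = {}
    for layer in LAYERS:
        eff = p.layer_effects[layer]
        floor = MYENTERIC_FLOOR_MM if layer == "myenteric" else THICKNESS_FLOOR_MM
        a = _truncated_normal(rng, eff.aganglionic_mean, eff.aganglionic_sd, floor, n)
        d = rng.normal(eff.diff_mean, eff.diff_sd, size=n)
        g = np.maximum(a - d, floor)
        cols_a[layer], cols_g[layer] = a, g

    if p.mi_me_model == "ratio":
        re_ = p.ratio_effect
        ratio_a = _truncated_normal(
            rng, re_.aganglionic_mean, re_.aganglionic_sd, RATIO_FLOOR, n
        )
        ratio_g = np.maximum(
            ratio_a - rng.normal(re_.diff_mean, re_.diff_sd, size=n), RATIO_FLOOR
        )
        cols_a["muscularis_externa"] = cols_a["muscularis_interna"] / ratio_a
        cols_g["muscularis_externa"] = cols_g["muscularis_interna"] / ratio_g

    if p.patient_scale_sd > 0:
        scale = np.maximum(rng.normal(1.0, p.patient_scale_sd, size=n), 0.1)
        for layer in LAYERS:
            cols_a[layer] = cols_a[layer] * scale
            cols_g[layer] = cols_g[layer] * scale

    fe = p.folding_effect
    fold_a = _truncated_normal(rng, fe.aganglionic_mean, fe.aganglionic_sd, FOLDING_FLOOR, n)
    fold_g = np.maximum(fold_a - rng.normal(fe.diff_mean, fe.diff_sd, size=n), FOLDING_FLOOR)

    width = max(3, len(str(n)))
    pids = [f"P{i + 1:0{width}d}" for i in range(n)]
    halves = []
    for seg, cols, fold in (("aganglionic", cols_a, fold_a), ("ganglionic", cols_g, fold_g)):
        half = pd.DataFrame({"patient_id": pids, "segment": seg})
        for layer in LAYERS:
            half[layer] = cols[layer]
        half["full_wall"] = sum(cols[layer] for layer in LAYERS)
        half["mi_me_ratio"] = cols["muscularis_interna"] / cols["muscularis_externa"]
        half["folding_ratio"] = fold
        halves.append(half)
    frame = (
        pd.concat(halves, ignore_index=True)
        .sort_values(["patient_id", "segment"], kind="stable")
        .reset_index(drop=True)
    )
    return frame, GroundTruth(features=frame.copy(), params=p)


# ---------------------------------------------------------------------------
# geometry synthesis
# ---------------------------------------------------------------------------


def _smooth_perturbation(rng: np.random.Generator, theta: np.ndarray) -> np.ndarray:
    """Smooth periodic unit-amplitude shape noise from low-order harmonics."""
    g = np.zeros_like(theta)
    for m in range(2, 6):
        g += rng.uniform(0.3, 1.0) * np.cos(m * theta + rng.uniform(0, 2 * math.pi))
    peak = np.abs(g).max()
    return g / peak if peak > 0 else g


def _normal_offset(points: np.ndarray, distance_um: float) -> np.ndarray:
    """Offset a closed polygon outward along its local vertex normals."""
    d = np.roll(points, -1, axis=0) - np.roll(points, 1, axis=0)
    norms = np.hypot(d[:, 0], d[:, 1])
    tangents = d / norms[:, None]
    # counter-clockwise ring: outward normal is the right-hand side
    normals = np.column_stack([tangents[:, 1], -tangents[:, 0]])
    x, y = points[:, 0], points[:, 1]
    signed = 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
    if signed < 0:
        normals = -normals
    return points + distance_um * normals


def _fold_boundary(points: np.ndarray, amplitude_rel: float, frequency: int) -> np.ndarray:
    """Pleat a closed boundary radially by ``A·sin(kθ)`` about the origin."""
    radii = np.hypot(points[:, 0], points[:, 1])
    ang = np.arctan2(points[:, 1], points[:, 0])
    amp_um = amplitude_rel * float(radii.mean())
    radial = points / radii[:, None]
    return points + (amp_um * np.sin(frequency * ang))[:, None] * radial


def _mean_ray_thickness_um(inner_pts: np.ndarray, outer_pts: np.ndarray,
                           spacing_um: float = 14.0) -> float:
    """Coarse normal-ray mean thickness between two closed boundaries, µm."""
    inner = Contour(inner_pts, closed=True)
    outer = Contour(outer_pts, closed=True)
    rs = resample_contour(inner, spacing_um)
    normals = _outward_normals(rs, inner, outer)
    t = _ray_polyline_first_hit(rs.points, normals, outer.vertices_with_closure)
    t = t[np.isfinite(t)]
    if len(t) == 0:
        raise ValueError("no ray reaches the outer boundary")
    return float(t.mean())


def generate_specimen_geometry(
    thicknesses_mm: Mapping[str, float],
    lumen_radius_um: float = 1500.0,
    fold_amplitude: float = 0.0,
    fold_frequency: int = 40,
    irregularity_amplitude: float = 0.0,
    seed: int | np.random.Generator = 0,
    n_theta: int = 2048,
    thickness_wobble: float = 0.0,
) -> list[LayerDelineation]:
    """Build the nested boundary contours of one synthetic cross-section.

    The lumen is ``r(θ) = R₀(1 + ε·g(θ))`` with ``g`` a smooth periodic
    perturbation of unit peak amplitude; each successive boundary offsets
    the previous one outward along its local normals by the layer thickness
    (optionally modulated by a low-amplitude angular wobble).  The
    submucosal inner boundary is additionally pleated radially by
    ``A·sin(kθ)`` with ``A = fold_amplitude ×`` its mean radius.  Returns
    the five layer delineations plus the full wall, sharing boundaries, all
    as simple, strictly nested closed contours.

    Pleating tilts the local normals of the submucosal inner boundary, so
    boundary-anchored normal rays cross the layer obliquely and measure
    systematically more than the radial extent — exactly as they would on a
    real pleated specimen.  The generating thickness is defined as the
    *measured* mean, so when folds are present the radial extent of the
    submucosa is calibrated downward (a short secant iteration against the
    package's own ray measurement) until the normal-ray mean matches the
    requested thickness.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    missing = [l for l in LAYERS if l not in thicknesses_mm]
    if missing:
        raise ValueError(f"missing layer thicknesses: {missing}")
    if any(thicknesses_mm[l] <= 0 for l in LAYERS):
        raise ValueError("layer thicknesses must be positive")

    theta = np.linspace(0.0, 2.0 * math.pi, n_theta, endpoint=False)
    r0 = lumen_radius_um * (
        1.0 + irregularity_amplitude * _smooth_perturbation(rng, theta)
    )

    def wobble(t_um: float):
        if thickness_wobble <= 0.0:
            return t_um
        m = rng.integers(2, 6)
        phase = rng.uniform(0, 2 * math.pi)
        return t_um * (1.0 + thickness_wobble * np.sin(m * theta + phase))

    b0 = np.column_stack([r0 * np.cos(theta), r0 * np.sin(theta)])
    s1 = _normal_offset(b0, wobble(thicknesses_mm["mucosa"] * 1000.0))
    b1 = _fold_boundary(s1, fold_amplitude, fold_frequency) if fold_amplitude > 0 else s1

    t_sub_um = thicknesses_mm["submucosa"] * 1000.0
    gap_um = t_sub_um
    if fold_amplitude > 0.0:
        # calibrate the radial gap so the measured normal-ray mean hits target
        for _ in range(3):
            measured = _mean_ray_thickness_um(b1, _normal_offset(s1, gap_um))
            gap_um = max(gap_um * t_sub_um / measured, 0.05 * t_sub_um)
    b2 = _normal_offset(s1, wobble(gap_um))

    boundaries = [b0, b1, b2]
    for layer in ("muscularis_interna", "myenteric", "muscularis_externa"):
        boundaries.append(
            _normal_offset(boundaries[-1], wobble(thicknesses_mm[layer] * 1000.0))
        )

    try:
        contours = [Contour(b, closed=True) for b in boundaries]
        delins = [
            LayerDelineation(layer, contours[i], contours[i + 1])
            for i, layer in enumerate(LAYERS)
        ]
        delins.append(LayerDelineation("full_wall", contours[0], contours[-1]))
    except ValueError as exc:
        raise ValueError(
            "generated boundaries self-intersect or are not nested; reduce the "
            "fold/irregularity amplitude relative to the layer thicknesses"
        ) from exc
    return delins


@dataclass
class SimulatedSpecimen:
    """One synthetic specimen: identity plus its layer delineations."""

    patient_id: str
    specimen_id: str
    segment: str
    delineations: list[LayerDelineation]


def generate_cohort_geometry(
    p: CohortParameters,
) -> tuple[list[SimulatedSpecimen], GroundTruth]:
    """Draw a paired feature cohort and emit full geometry per specimen.

    Specimens whose drawn submucosa is too thin to accommodate the default
    pleat amplitude (the boundaries would touch or cross) are retried with
    the amplitude progressively reduced — thin submucosae cannot fold as
    deeply — so every cohort draw yields valid geometry.
    """
    frame, truth = draw_paired_features(p)
    rng = np.random.default_rng(np.random.default_rng(p.seed).integers(2**31 - 1))
    specimens: list[SimulatedSpecimen] = []
    for pid, group in frame.groupby("patient_id", sort=True):
        lumen = max(
            rng.normal(p.lumen_radius_um, p.lumen_radius_sd_um), 0.3 * p.lumen_radius_um
        )
        for _, row in group.iterrows():
            seg = row["segment"]
            thick = {layer: float(row[layer]) for layer in LAYERS}
            amplitude = p.fold_amplitude.get(seg, 0.0)
            state = rng.bit_generator.state
            for attempt in range(6):
                try:
                    rng.bit_generator.state = state  # same shape noise per retry
                    delins = generate_specimen_geometry(
                        thick,
                        lumen_radius_um=lumen,
                        fold_amplitude=amplitude,
                        fold_frequency=p.fold_frequency,
                        irregularity_amplitude=p.irregularity_amplitude,
                        seed=rng,
                        n_theta=p.n_theta,
                    )
                    break
                except ValueError:
                    if attempt == 5:
                        raise
                    amplitude *= 0.6
            specimens.append(
                SimulatedSpecimen(
                    patient_id=pid,
                    specimen_id=f"{pid}-{seg[:1].upper()}",
                    segment=seg,
                    delineations=delins,
                )
            )
    return specimens, truth


# ---------------------------------------------------------------------------
# patient registry
# ---------------------------------------------------------------------------

#: Registry covariate defaults: cohort age at surgery (days) has median
#: ≈34.5 and mean ≈45.2 (log-normal shape), weight ≈4.3 (0.7) kg, and
#: aganglionic length ≈11.6 cm with quartiles near 6 and 16 cm.
_AGE_MEDIAN_D = 34.5
_AGE_SIGMA = 0.73  # log-scale SD chosen so the mean/median ratio matches ≈1.31
_WEIGHT_MEAN_KG = 4.3
_WEIGHT_SD_KG = 0.7
_LENGTH_MEAN_CM = 11.6
_LENGTH_SD_CM = 5.5

EXCLUSION_ORDER = (
    "age_over_1_year",
    "prior_stoma",
    "not_primary_surgery",
    "aganglionosis_over_25cm",
    "poor_image_quality",
)


def _passing_record(rng: np.random.Generator, pid: str) -> dict:
    age = float(np.clip(rng.lognormal(math.log(_AGE_MEDIAN_D), _AGE_SIGMA), 5.0, 360.0))
    weight = float(np.clip(rng.normal(_WEIGHT_MEAN_KG, _WEIGHT_SD_KG), 2.0, 8.0))
    length = float(np.clip(rng.normal(_LENGTH_MEAN_CM, _LENGTH_SD_CM), 2.0, 25.0))
    return {
        "patient_id": pid,
        "age_days": round(age, 1),
        "weight_kg": round(weight, 2),
        "prior_stoma": False,
        "primary_surgery": True,
        "aganglionosis_cm": round(length, 1),
        "image_quality_ok": True,
    }


def generate_patient_registry(
    exclusion_counts: Mapping[str, int] | Sequence[int],
    n_included: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Emit a registry whose records fail exactly one named criterion each.

    ``exclusion_counts`` maps criterion names (see :data:`EXCLUSION_ORDER`)
    to counts, or gives the five counts positionally in that order; the
    remaining ``n_included`` records satisfy every criterion, with
    covariates drawn around the cohort descriptives.  Record order is
    shuffled deterministically under ``seed``.
    """
    if not isinstance(exclusion_counts, Mapping):
        if len(exclusion_counts) != len(EXCLUSION_ORDER):
            raise ValueError(f"expected {len(EXCLUSION_ORDER)} positional counts")
        exclusion_counts = dict(zip(EXCLUSION_ORDER, exclusion_counts))
    unknown = set(exclusion_counts) - set(EXCLUSION_ORDER)
    if unknown:
        raise ValueError(f"unknown exclusion categories: {sorted(unknown)}")
    if n_included < 0 or any(c < 0 for c in exclusion_counts.values()):
        raise ValueError("counts must be non-negative")

    rng = np.random.default_rng(seed)
    records: list[dict] = []
    k = 0
    for _ in range(n_included):
        k += 1
        records.append(_passing_record(rng, f"R{k:03d}"))
    for crit in EXCLUSION_ORDER:
        for _ in range(int(exclusion_counts.get(crit, 0))):
            k += 1
            rec = _passing_record(rng, f"R{k:03d}")
            if crit == "age_over_1_year":
                rec["age_days"] = round(float(rng.uniform(400.0, 1000.0)), 1)
            elif crit == "prior_stoma":
                rec["prior_stoma"] = True
            elif crit == "not_primary_surgery":
                rec["primary_surgery"] = False
            elif crit == "aganglionosis_over_25cm":
                rec["aganglionosis_cm"] = round(float(rng.uniform(26.0, 45.0)), 1)
            else:
                rec["image_quality_ok"] = False
            records.append(rec)

    frame = pd.DataFrame(records)
    order = rng.permutation(len(frame))
    return frame.iloc[order].reset_index(drop=True)
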