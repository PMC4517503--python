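"""Synthetic ground-truth LV geometries and simulated reader contour sets.

The truth model is a truncated-ellipsoid stack: per slice, the endocardial
radius follows an ellipsoidal apex-to-base profile with mild low-order
angular irregularity; the epicardium adds a wall whose thickness is solved
from a target myocardial mass; end-systole scales the endocardium in-plane
by sqrt(1 - EF/100) so the phantom's ejection fraction is exact by
construction.  Phenotype ranges (healthy, dilated, hypertrophic) are
calibrated so a default cohort spans roughly 110-360 ml in EDV and
80-195 g in mass, the spread seen across mixed-pathology clinical cohorts.

Simulated readers displace each true contour radially about its centroid
by a per-reader systematic bias (signed, positive = outward, separate for
the two surfaces) plus smooth zero-mean angular noise (a constant term and
Fourier modes 1-3, mimicking the low-frequency character of hand-drawn
contours), and occasionally omit the most apical or most basal slice.
Reader sensitivity and specificity are emergent, never set directly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from numpy.random import SeedSequence, default_rng

from .contour_model import (
    Contour,
    ContourValidationError,
    SliceGeometry,
    StudyContourSet,
    signed_area,
)
from .volumetrics import LVFunction, compute_lv_function

SeedLike = Union[int, SeedSequence]

PHENOTYPES = {
    #                EDV range (ml)   EF range (%)   LVM range (g)
    "healthy":      {"edv_ml": (110.0, 180.0), "ef_pct": (55.0, 68.0), "lvm_g": (80.0, 140.0)},
    "dilated":      {"edv_ml": (240.0, 360.0), "ef_pct": (18.0, 35.0), "lvm_g": (130.0, 190.0)},
    "hypertrophic": {"edv_ml": (110.0, 190.0), "ef_pct": (55.0, 70.0), "lvm_g": (150.0, 195.0)},
}

#: default per-case phenotype pattern for a 15-case cohort
DEFAULT_PHENOTYPE_MIX = (
    "healthy", "dilated", "healthy", "dilated", "hypertrophic",
    "healthy", "dilated", "healthy", "dilated", "hypertrophic",
    "healthy", "dilated", "healthy", "dilated", "healthy",
)


@dataclass
class TruePhantom:
    """Ground-truth case: contours, analytically known function, ES phase."""

    case_id: str
    phenotype: str
    geometry: SliceGeometry
    contours: StudyContourSet
    lv_function: LVFunction
    mid_slice_area_curve: np.ndarray
    true_es_index: int


@dataclass(frozen=True)
class ReaderProfile:
    """Systematic and random contouring behaviour of one simulated reader."""

    reader_id: str
    endo_bias_mm: float = 0.0
    epi_bias_mm: float = 0.0
    noise_sd_mm: float = 0.0
    slice_skip_prob: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_sd_mm < 0:
            raise ValueError("noise_sd_mm must be >= 0")
        if not (0.0 <= self.slice_skip_prob < 1.0):
            raise ValueError("slice_skip_prob must be in [0, 1)")


def default_reader_profiles(n_readers: int = 7,
                            noise_sd_mm: float = 0.8,
                            slice_skip_prob: float = 0.05) -> tuple[ReaderProfile, ...]:
    """Study-shaped reader panel: zero-mean systematic biases.

    Endocardial biases span +/-1.5 mm and epicardial biases +/-1.2 mm with
    mixed signs (some readers contour the cavity small and the epicardium
    large, others the opposite), sized so the induced volume-bias spread is
    tens of ml on a typical ventricle.
    """
    if n_readers == 7:
        endo = (-1.5, -0.9, -0.4, 0.0, 0.4, 0.9, 1.5)
        epi = (1.2, -0.8, 0.8, 0.0, -0.8, 0.8, -1.2)
    else:
        endo = tuple(np.linspace(-1.5, 1.5, n_readers))
        alt = np.array([1.2 * (-1) ** i for i in range(n_readers)])
        epi = tuple(alt - alt.mean())
    return tuple(
        ReaderProfile(
            reader_id=f"reader{i + 1}",
            endo_bias_mm=endo[i],
            epi_bias_mm=epi[i],
            noise_sd_mm=noise_sd_mm,
            slice_skip_prob=slice_skip_prob,
        )
        for i in range(n_readers)
    )


@dataclass
class CohortConfig:
    """Shape and randomness of a simulated multi-reader cohort.

    Defaults reproduce the study layout: 15 cases, 7 readers, 10-15
    contiguous slices of 8 or 10 mm, in-plane pixels 1.1-2.1 mm.
    """

    n_cases: int = 15
    n_readers: int = 7
    seed: int = 0
    phenotype_mix: Optional[Sequence[str]] = None
    n_slices_range: tuple[int, int] = (10, 15)
    slice_thickness_choices: tuple[float, ...] = (8.0, 10.0)
    pixel_size_range: tuple[float, float] = (1.1, 2.1)
    fov_mm: float = 180.0
    n_frames: int = 20
    profiles: Optional[Sequence[ReaderProfile]] = None

    def __post_init__(self) -> None:
        if self.n_readers < 2:
            raise ValueError("n_readers must be >= 2")
        if self.n_cases < 1:
            raise ValueError("n_cases must be >= 1")
        if self.profiles is not None and len(self.profiles) != self.n_readers:
            raise ValueError("profiles length must equal n_readers")

    def resolved_profiles(self) -> tuple[ReaderProfile, ...]:
        if self.profiles is not None:
            return tuple(self.profiles)
        return default_reader_profiles(self.n_readers)

    def resolved_mix(self) -> tuple[str, ...]:
        mix = self.phenotype_mix or DEFAULT_PHENOTYPE_MIX
        return tuple(mix[i % len(mix)] for i in range(self.n_cases))


@dataclass
class CohortResult:
    truths: list
    reader_sets: dict
    manifest: pd.DataFrame


# ---------------------------------------------------------------------------
# phantom construction


def _radius_profile(n_slices: int, rng) -> np.ndarray:
    """Ellipsoidal apex(0)-to-base radius fractions, unimodal by construction."""
    u = (np.arange(n_slices) + 0.5) / n_slices
    g = np.sqrt(1.0 - (1.0 - u) ** 2)
    g = g * (1.0 + rng.normal(0.0, 0.01, n_slices))
    return np.maximum.accumulate(g)  # keep nondecreasing apex -> base


def _angular_shape(rng, n_vertices: int) -> np.ndarray:
    """Mild low-order irregularity factor sampled on the vertex angles."""
    theta = 2.0 * np.pi * np.arange(n_vertices) / n_vertices
    shape = np.ones(n_vertices)
    for m in (2, 3):
        amp = float(np.clip(rng.normal(0.0, 0.015), -0.04, 0.04))
        phase = rng.uniform(0.0, 2.0 * np.pi)
        shape += amp * np.cos(m * theta + phase)
    return shape


def _wall_thickness_mm(lvm_g: float, radii_mm: np.ndarray,
                       spacing_mm: float) -> float:
    """Solve shell volume == mass/1.05 for a constant wall thickness w.

    Shell volume = sum_s pi ((r_s + w)^2 - r_s^2) * spacing, a quadratic
    in w with one positive root.
    """
    shell_mm3 = lvm_g / 1.05 * 1000.0
    a = np.pi * spacing_mm * len(radii_mm)
    b = 2.0 * np.pi * spacing_mm * float(np.sum(radii_mm))
    w = (-b + np.sqrt(b * b + 4.0 * a * shell_mm3)) / (2.0 * a)
    return float(w)


def generate_phantom(phenotype: str, geometry: SliceGeometry, seed: SeedLike,
                     case_id: str = "case", n_frames: int = 20,
                     n_vertices: int = 72) -> TruePhantom:
    """Deterministic ground-truth LV stack for one phenotype and geometry."""
    if phenotype not in PHENOTYPES:
        raise ValueError(f"unknown phenotype {phenotype!r}")
    rng = default_rng(seed)
    ranges = PHENOTYPES[phenotype]
    edv_target = rng.uniform(*ranges["edv_ml"])
    ef_target = rng.uniform(*ranges["ef_pct"])
    lvm_target = rng.uniform(*ranges["lvm_g"])

    n = geometry.n_slices
    spacing = geometry.slice_spacing_mm
    g = _radius_profile(n, rng)
    base_radius = np.sqrt(edv_target * 1000.0 / (np.pi * spacing * float(np.sum(g ** 2))))
    radii = base_radius * g
    wall = _wall_thickness_mm(lvm_target, radii, spacing)
    if wall <= 1.0:
        raise ValueError(
            f"infeasible geometry: wall thickness {wall:.2f} mm for "
            f"{phenotype} phantom"
        )
    margin = 8.0  # head-room for reader bias + noise inside the FOV
    if radii[-1] + wall + margin > min(geometry.width_mm, geometry.height_mm) / 2.0:
        raise ValueError("infeasible geometry: phantom does not fit in the FOV")

    center = np.array([geometry.width_mm / 2.0, geometry.height_mm / 2.0])
    theta = 2.0 * np.pi * np.arange(n_vertices) / n_vertices
    unit = np.column_stack([np.cos(theta), np.sin(theta)])
    shape = _angular_shape(rng, n_vertices)
    lam = np.sqrt(1.0 - ef_target / 100.0)  # in-plane ES scale

    truth = StudyContourSet(case_id=case_id, source_id="truth", geometry=geometry)
    for s in range(n):
        r_endo = radii[s] * shape
        r_epi = (radii[s] + wall) * shape
        truth.add(Contour("endo", "ED", s, center + r_endo[:, None] * unit))
        truth.add(Contour("epi", "ED", s, center + r_epi[:, None] * unit))
        truth.add(Contour("endo", "ES", s, center + lam * r_endo[:, None] * unit))

    lv = compute_lv_function(truth)

    # mid-slice cavity area over the cardiac cycle, contraction peaking at ES
    mid = n // 2
    a_ed = abs(signed_area(truth.get("ED", mid, "endo").points))
    t_es = int(rng.integers(int(0.3 * n_frames), int(0.5 * n_frames) + 1))
    t = np.arange(n_frames, dtype=float)
    h = np.where(
        t <= t_es,
        (1.0 - np.cos(np.pi * t / t_es)) / 2.0,
        (1.0 + np.cos(np.pi * (t - t_es) / (n_frames - t_es))) / 2.0,
    )
    curve = a_ed * (1.0 - (1.0 - lam ** 2) * h)

    return TruePhantom(
        case_id=case_id, phenotype=phenotype, geometry=geometry,
        contours=truth, lv_function=lv,
        mid_slice_area_curve=curve, true_es_index=t_es,
    )


# ---------------------------------------------------------------------------
# reader simulation


def _smooth_radial_noise(theta: np.ndarray, sd: float, rng) -> np.ndarray:
    """Constant + Fourier modes 1-3 with zero angular mean per mode >= 1.

    Pointwise SD is ~0.87 sd (0.25 sd^2 from the constant term, 0.5 sd^2
    from the periodic modes).
    """
    if sd == 0.0:
        return np.zeros_like(theta)
    noise = np.full_like(theta, rng.normal(0.0, 0.5 * sd))
    coef_sd = sd / np.sqrt(6.0)
    for m in (1, 2, 3):
        noise += rng.normal(0.0, coef_sd) * np.cos(m * theta)
        noise += rng.normal(0.0, coef_sd) * np.sin(m * theta)
    return noise


def _displaced(contour: Contour, bias: float, noise_sd: float, rng,
               geometry: SliceGeometry) -> Contour:
    """One radial-displacement draw; raises on invalid output polygon."""
    if bias == 0.0 and noise_sd == 0.0:
        return Contour(contour.surface, contour.frame, contour.slice_index,
                       contour.points.copy())
    pts = contour.points
    c = pts.mean(axis=0)
    vec = pts - c
    r = np.hypot(vec[:, 0], vec[:, 1])
    theta = np.arctan2(vec[:, 1], vec[:, 0])
    r_new = r + bias + _smooth_radial_noise(theta, noise_sd, rng)
    if r_new.min() <= 0.3:
        raise ContourValidationError("radial displacement collapses the polygon")
    new_pts = c + r_new[:, None] * np.column_stack([np.cos(theta), np.sin(theta)])
    tol = 1e-9
    if (new_pts[:, 0].min() < -tol or new_pts[:, 1].min() < -tol
            or new_pts[:, 0].max() > geometry.width_mm + tol
            or new_pts[:, 1].max() > geometry.height_mm + tol):
        raise ContourValidationError("displaced contour leaves the image")
    return Contour(contour.surface, contour.frame, contour.slice_index, new_pts)


def simulate_reader(truth: TruePhantom, profile: ReaderProfile,
                    seed: SeedLike, max_retries: int = 10) -> StudyContourSet:
    """Simulate one reader's contour set for one case, deterministically.

    Each true contour is displaced radially by the profile's surface bias
    plus smooth noise; draws producing self-intersections, collapsed radii
    or un-nested ED surfaces are retried with fresh noise up to
    ``max_retries`` times, then raised.
    """
    rng = default_rng(seed)
    geometry = truth.geometry
    n = geometry.n_slices
    skip_apex = rng.random() < profile.slice_skip_prob
    skip_base = rng.random() < profile.slice_skip_prob
    out = StudyContourSet(case_id=truth.case_id, source_id=profile.reader_id,
                          geometry=geometry)

    def bias_for(surface: str) -> float:
        return profile.endo_bias_mm if surface == "endo" else profile.epi_bias_mm

    for s in range(n):
        if (s == 0 and skip_apex) or (s == n - 1 and skip_base):
            continue
        # ED endo+epi are drawn jointly so nesting can be re-drawn as a pair
        ed_endo = truth.contours.get("ED", s, "endo")
        ed_epi = truth.contours.get("ED", s, "epi")
        if ed_endo is not None and ed_epi is not None:
            for attempt in range(max_retries):
                try:
                    new_endo = _displaced(ed_endo, bias_for("endo"),
                                          profile.noise_sd_mm, rng, geometry)
                    new_epi = _displaced(ed_epi, bias_for("epi"),
                                         profile.noise_sd_mm, rng, geometry)
                    if (abs(signed_area(new_endo.points))
                            >= abs(signed_area(new_epi.points))):
                        raise ContourValidationError("ED surfaces un-nested")
                    break
                except ContourValidationError:
                    if attempt == max_retries - 1:
                        raise ContourValidationError(
                            f"{truth.case_id}/{profile.reader_id}: could not "
                            f"draw valid ED pair on slice {s}"
                        )
            out.add(new_endo)
            out.add(new_epi)
        es_endo = truth.contours.get("ES", s, "endo")
        if es_endo is not None:
            for attempt in range(max_retries):
                try:
                    new_es = _displaced(es_endo, bias_for("endo"),
                                        profile.noise_sd_mm, rng, geometry)
                    break
                except ContourValidationError:
                    if attempt == max_retries - 1:
                        raise ContourValidationError(
                            f"{truth.case_id}/{profile.reader_id}: could not "
                            f"draw valid ES endo on slice {s}"
                        )
            out.add(new_es)
    return out


# ---------------------------------------------------------------------------
# cohort simulation


def _sample_geometry(rng, config: CohortConfig) -> SliceGeometry:
    px = round(float(rng.uniform(*config.pixel_size_range)), 2)
    thickness = float(rng.choice(config.slice_thickness_choices))
    lo, hi = config.n_slices_range
    n_slices = int(rng.integers(lo, hi + 1))
    n_px = int(np.ceil(config.fov_mm / px))
    return SliceGeometry(
        pixel_size_mm=(px, px),
        slice_thickness_mm=thickness,
        slice_spacing_mm=thickness,  # contiguous acquisition
        n_rows=n_px, n_cols=n_px, n_slices=n_slices,
    )


def simulate_cohort(config: CohortConfig) -> CohortResult:
    """Phantoms plus per-reader contour sets for every case.

    All randomness flows from ``config.seed`` through spawned seed
    sequences (one per case, then one per entity within the case); the
    manifest records the derived integer seed of every entity.
    """
    profiles = config.resolved_profiles()
    mix = config.resolved_mix()
    root = SeedSequence(config.seed)
    case_seqs = root.spawn(config.n_cases)
    truths = []
    reader_sets: dict[str, dict[str, StudyContourSet]] = {}
    manifest_rows = []
    for i, case_seq in enumerate(case_seqs):
        case_id = f"case{i + 1:02d}"
        children = case_seq.spawn(2 + config.n_readers)
        geometry = _sample_geometry(default_rng(children[0]), config)
        truth = generate_phantom(mix[i], geometry, children[1],
                                 case_id=case_id, n_frames=config.n_frames)
        truths.append(truth)
        manifest_rows.append({
            "case_id": case_id, "entity": "truth", "phenotype": mix[i],
            "seed": int(children[1].generate_state(1)[0]),
        })
        per_reader = {}
        for j, profile in enumerate(profiles):
            rs = simulate_reader(truth, profile, children[2 + j])
            per_reader[profile.reader_id] = rs
            manifest_rows.append({
                "case_id": case_id, "entity": profile.reader_id,
                "phenotype": mix[i],
                "seed": int(children[2 + j].generate_state(1)[0]),
            })
        reader_sets[case_id] = per_reader
    return CohortResult(
        truths=truths, reader_sets=reader_sets,
        manifest=pd.DataFrame(manifest_rows),
    )
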