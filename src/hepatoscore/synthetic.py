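"""Synthetic inputs: digital liver phantoms and simulated patient cohorts.

Two generators make every downstream stage testable without patient data:

* **Phantoms** — an ellipsoidal liver with an optionally smooth, optionally
  lesioned T1-reduction-rate (rrT1) field, realised as aligned pre- and
  post-contrast T1 volumes plus a binary liver mask, and optionally as
  multi-flip-angle SPGR signal volumes with Rician noise.

* **Cohorts** — per-patient liver-function scores drawn from the group
  marginals of the study population (marginal mode) or from a Gaussian
  copula over scores (copula mode), with a biologically consistent blood
  panel back-solved so that recomputing ALBI and MELD from the panel
  reproduces the drawn values exactly.

All randomness flows from explicit integer seeds; outputs are
bit-reproducible for a fixed seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .geometry import SPACING_INTERPOLATED, VoxelGeometry
from .relaxometry import LiverMask, T1Volume, spgr_signal
from .scoring import BILIRUBIN_UMOL_PER_MG_DL, albi_grade

#: upper clamp for the rr field; keeps post-contrast T1 strictly positive
RR_MAX = 0.95


# -------------------------------------------------------------------- phantom

@dataclass(frozen=True)
class VfaProtocol:
    """Variable-flip-angle SPGR protocol (angles in degrees, times in ms).

    Defaults follow the 3-T liver protocol: flip angles 1/7/14 deg,
    TR 5.79 ms; echo times and the hepatobiliary delay are metadata only.
    """

    flip_angles: tuple[float, ...] = (1.0, 7.0, 14.0)
    tr: float = 5.79
    te: tuple[float, ...] = (2.46, 3.69)
    delay_post_contrast_min: float = 20.0

    def __post_init__(self) -> None:
        angles = tuple(float(a) for a in self.flip_angles)
        if any(not 0 < a <= 90 for a in angles):
            raise ValueError("flip angles must lie in (0, 90] degrees")
        if any(b <= a for a, b in zip(angles, angles[1:])):
            raise ValueError("flip angles must be strictly increasing")
        if self.tr <= 0:
            raise ValueError("TR must be positive")
        object.__setattr__(self, "flip_angles", angles)
        object.__setattr__(self, "te", tuple(float(t) for t in self.te))


@dataclass(frozen=True)
class Lesion:
    """Spherical region whose rr is scaled by ``rr_multiplier`` (<1 = cold)."""

    center_mm: tuple[float, float, float]
    radius_mm: float
    rr_multiplier: float


@dataclass
class PhantomSpec:
    """Recipe for one digital liver phantom.

    ``rr_mean`` sets the average contrast uptake, ``rr_spatial_sd`` and
    ``rr_smoothness`` (mm) shape the smooth Gaussian heterogeneity field,
    and lesions multiply rr locally.  Native liver T1 of 810 ms and
    background 1000 ms are typical 3-T values; both are configurable.
    """

    geometry: VoxelGeometry
    liver_semi_axes_mm: tuple[float, float, float]
    liver_center_mm: tuple[float, float, float] | None = None
    t1_liver_native: float = 810.0
    t1_background: float = 1000.0
    rr_mean: float = 0.5
    rr_spatial_sd: float = 0.0
    rr_smoothness_mm: float = 10.0
    t1_texture_sd: float = 0.0
    lesions: tuple[Lesion, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.rr_mean < 1:
            raise ValueError("rr_mean must lie in [0, 1)")
        if any(a <= 0 for a in self.liver_semi_axes_mm):
            raise ValueError("liver semi-axes must be positive")
        if self.t1_liver_native <= 0 or self.t1_background <= 0:
            raise ValueError("T1 values must be positive")
        if self.rr_spatial_sd < 0:
            raise ValueError("rr_spatial_sd must be non-negative")
        if self.liver_center_mm is None:
            self.liver_center_mm = tuple(
                (n - 1) * s / 2.0 for n, s in zip(self.geometry.shape, self.geometry.spacing)
            )


def _smooth_field(shape, spacing, smoothness_mm, rng, mask) -> np.ndarray:
    """Smooth Gaussian random field, standardised to zero mean and unit
    variance over the mask (so the field perturbs without shifting the
    in-mask average)."""
    noise = rng.standard_normal(shape)
    sigma_vox = [max(smoothness_mm / s, 1e-6) for s in spacing]
    smooth = gaussian_filter(noise, sigma=sigma_vox, mode="nearest")
    inside = smooth[mask]
    sd = inside.std()
    if sd == 0:
        return np.zeros(shape)
    return (smooth - inside.mean()) / sd


def generate_phantom(spec: PhantomSpec):
    """Build aligned pre/post T1 volumes, a liver mask and the true rr field.

    The mask is the voxelised ellipsoid; inside it, ``t1_post = t1_pre *
    (1 - rr)`` with ``rr`` clamped to [0, 0.95].  Outside, both maps equal
    the background T1.  Deterministic for a fixed ``spec.seed``.

    Returns ``(t1_pre, t1_post, mask, rr_truth)``.
    """
    geom = spec.geometry
    rng = np.random.default_rng(spec.seed)

    coords = np.meshgrid(
        *(np.arange(n) * s for n, s in zip(geom.shape, geom.spacing)), indexing="ij"
    )
    mask = sum(
        ((c - c0) / a) ** 2
        for c, c0, a in zip(coords, spec.liver_center_mm, spec.liver_semi_axes_mm)
    ) <= 1.0

    t1_pre = np.full(geom.shape, float(spec.t1_background))
    liver_t1 = np.full(geom.shape, float(spec.t1_liver_native))
    if spec.t1_texture_sd > 0:
        liver_t1 = liver_t1 + spec.t1_texture_sd * _smooth_field(
            geom.shape, geom.spacing, spec.rr_smoothness_mm, rng, mask
        )
        liver_t1 = np.clip(liver_t1, 1.0, None)
    t1_pre[mask] = liver_t1[mask]

    rr = np.full(geom.shape, float(spec.rr_mean))
    if spec.rr_spatial_sd > 0:
        rr = rr + spec.rr_spatial_sd * _smooth_field(
            geom.shape, geom.spacing, spec.rr_smoothness_mm, rng, mask
        )
    for lesion in spec.lesions:
        dist2 = sum((c - c0) ** 2 for c, c0 in zip(coords, lesion.center_mm))
        rr = np.where(dist2 <= lesion.radius_mm ** 2, rr * lesion.rr_multiplier, rr)
    rr = np.clip(rr, 0.0, RR_MAX)
    rr_truth = np.where(mask, rr, 0.0)

    t1_post = np.where(mask, t1_pre * (1.0 - rr_truth), t1_pre)

    return (
        T1Volume(t1_pre, geom, phase="native"),
        T1Volume(t1_post, geom, phase="hepatobiliary"),
        LiverMask(mask, geom),
        rr_truth,
    )


def simulate_spgr_signals(t1: T1Volume, protocol: VfaProtocol,
                          m0=1000.0, b1=1.0, noise_sd: float = 0.0,
                          seed: int = 0,
                          noise_model: Literal["rician", "gaussian"] = "rician"):
    """Forward-simulate one SPGR magnitude volume per flip angle.

    ``noise_sd = 0`` evaluates the steady-state equation exactly; otherwise
    Rician noise (the magnitude of complex Gaussian noise, the physical model
    for magnitude MRI) is added, with plain Gaussian noise as an option.
    """
    if np.any(np.asarray(t1.values) <= 0):
        raise ValueError("T1 must be positive everywhere")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    out = []
    for angle in protocol.flip_angles:
        s = spgr_signal(t1.values, m0, angle, protocol.tr, b1)
        if noise_sd > 0:
            if noise_model == "rician":
                s = np.hypot(s + rng.normal(0, noise_sd, s.shape),
                             rng.normal(0, noise_sd, s.shape))
            elif noise_model == "gaussian":
                s = s + rng.normal(0, noise_sd, s.shape)
            else:
                raise ValueError(f"unknown noise model {noise_model!r}")
        out.append(s)
    return out


# --------------------------------------------------------------------- cohort

@dataclass(frozen=True)
class GroupSpec:
    """Normal marginal of one score within one patient group.

    Several GroupSpecs may share a ``label`` (same patients, different
    scores); their ``n`` must then agree.  ``cirrhosis`` tags the group's
    patients for the cirrhosis dichotomy.
    """

    label: str
    n: int
    score_name: str
    mean: float
    sd: float
    cirrhosis: bool | None = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("group n must be >= 1")
        if self.sd < 0:
            raise ValueError("group sd must be >= 0")


@dataclass
class CohortSpec:
    """Recipe for a simulated cohort.

    ``marginal`` mode draws each group's scores independently from the
    stated Normal marginals; ``copula`` mode draws all scores jointly from a
    Gaussian copula with the given correlation matrix and Normal marginals.
    """

    mode: Literal["marginal", "copula"] = "marginal"
    groups: tuple[GroupSpec, ...] = ()
    score_names: tuple[str, ...] = ()
    correlation_matrix: np.ndarray | None = None
    marginal_means: dict | None = None
    marginal_sds: dict | None = None
    n_total: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode == "marginal":
            if not self.groups:
                raise ValueError("marginal mode needs at least one group")
            per_label: dict[str, int] = {}
            for g in self.groups:
                if per_label.setdefault(g.label, g.n) != g.n:
                    raise ValueError(f"inconsistent n for group label {g.label!r}")
            total = sum(per_label.values())
            if self.n_total is None:
                self.n_total = total
            elif self.n_total != total:
                raise ValueError(f"group n values sum to {total}, not n_total={self.n_total}")
        elif self.mode == "copula":
            if self.correlation_matrix is None or not self.score_names:
                raise ValueError("copula mode needs score_names and a correlation matrix")
            r = np.asarray(self.correlation_matrix, dtype=float)
            k = len(self.score_names)
            if r.shape != (k, k) or not np.allclose(r, r.T) or not np.allclose(np.diag(r), 1):
                raise ValueError("correlation matrix must be symmetric with unit diagonal")
            if np.min(np.linalg.eigvalsh(r)) < -1e-10:
                raise ValueError("correlation matrix must be positive semidefinite")
            if self.n_total is None or self.n_total < 1:
                raise ValueError("copula mode needs n_total >= 1")
            if self.marginal_means is None or self.marginal_sds is None:
                raise ValueError("copula mode needs marginal means and sds per score")
        else:
            raise ValueError(f"unknown cohort mode {self.mode!r}")


#: cohort-level fallbacks for scores a group does not specify (overall study
#: population: MELIF 50 +- 11, ALBI -2.0 +- 0.6)
DEFAULT_SCORE_MARGINALS = {"melif": (50.0, 11.0), "albi": (-2.0, 0.60)}

#: albumin Normal(mean, sd) in g/L per ALBI grade band
ALBUMIN_BY_ALBI_GRADE = {1: (40.0, 2.5), 2: (33.0, 4.2), 3: (23.0, 3.0)}

#: plausible draw ranges when a quantity is not pinned by a drawn score
CREATININE_RANGE_MG_DL = (0.6, 1.4)
INR_RANGE = (0.9, 1.5)
HEIGHT_M = (1.70, 0.08)
WEIGHT_KG = (83.0, 16.0)

_MELD_B, _MELD_I, _MELD_C, _MELD_K = 3.78, 11.2, 9.57, 6.43


def _backsolve_panel(albi: np.ndarray, meld: np.ndarray | None, rng,
                     row_offset: int = 0) -> pd.DataFrame:
    """Blood panel consistent with drawn ALBI (and, if given, MELD) values.

    Albumin is drawn from the grade band of each patient's ALBI; bilirubin is
    the exact algebraic inverse of the ALBI equation; if MELD was drawn,
    creatinine is drawn and INR solved from the MELD equation, otherwise INR
    and creatinine are drawn from plausible ranges.
    """
    n = len(albi)
    bad = ~np.isfinite(albi)
    if np.any(bad):
        rows = row_offset + np.flatnonzero(bad)
        raise ValueError(f"infeasible blood-panel back-solve: non-finite ALBI at rows {rows.tolist()}")
    grades = np.array([albi_grade(a) for a in albi])
    alb_mean = np.array([ALBUMIN_BY_ALBI_GRADE[g][0] for g in grades])
    alb_sd = np.array([ALBUMIN_BY_ALBI_GRADE[g][1] for g in grades])
    albumin = np.clip(rng.normal(alb_mean, alb_sd), 10.0, None)

    bilirubin_umol = 10.0 ** ((albi + 0.085 * albumin) / 0.66)
    bilirubin_mg = bilirubin_umol / BILIRUBIN_UMOL_PER_MG_DL

    creatinine = rng.uniform(*CREATININE_RANGE_MG_DL, size=n)
    if meld is not None:
        ln_inr = (meld - _MELD_K - _MELD_B * np.log(bilirubin_mg)
                  - _MELD_C * np.log(creatinine)) / _MELD_I
        inr = np.exp(ln_inr)
    else:
        inr = rng.uniform(*INR_RANGE, size=n)

    for name, arr in (("albumin", albumin), ("bilirubin", bilirubin_umol), ("inr", inr)):
        bad = ~np.isfinite(arr) | (arr <= 0)
        if np.any(bad):
            rows = row_offset + np.flatnonzero(bad)
            raise ValueError(f"infeasible blood-panel back-solve for {name} at rows {rows.tolist()}")

    return pd.DataFrame({
        "albumin_g_L": albumin,
        "bilirubin_umol_L": bilirubin_umol,
        "creatinine_mg_dL": creatinine,
        "inr": inr,
    })


def _meld_from_panel(panel: pd.DataFrame) -> np.ndarray:
    """Vectorised raw MELD from a back-solved panel (same formula as
    :func:`hepatoscore.scoring.meld_score`)."""
    bili_mg = panel["bilirubin_umol_L"].to_numpy() / BILIRUBIN_UMOL_PER_MG_DL
    return (_MELD_B * np.log(bili_mg) + _MELD_I * np.log(panel["inr"].to_numpy())
            + _MELD_C * np.log(panel["creatinine_mg_dL"].to_numpy()) + _MELD_K)


def simulate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Simulate a patient cohort with scores and a consistent blood panel.

    Returns one row per patient: group label, drawn scores, demographics and
    a back-solved blood panel such that recomputing ALBI (and MELD, when it
    was drawn) from the panel reproduces the drawn values.
    """
    rng = np.random.default_rng(spec.seed)

    if spec.mode == "marginal":
        frames = []
        labels = list(dict.fromkeys(g.label for g in spec.groups))
        offset = 0
        for label in labels:
            specs = [g for g in spec.groups if g.label == label]
            n = specs[0].n
            drawn = {g.score_name: rng.normal(g.mean, g.sd, size=n) for g in specs}
            cirrhosis = next((g.cirrhosis for g in specs if g.cirrhosis is not None), False)
            for name, (mean, sd) in DEFAULT_SCORE_MARGINALS.items():
                if name not in drawn:
                    drawn[name] = rng.normal(mean, sd, size=n)
            meld = drawn.get("meld")
            panel = _backsolve_panel(drawn["albi"], meld, rng, row_offset=offset)
            if meld is None:
                drawn["meld"] = _meld_from_panel(panel)
            df = pd.DataFrame({"group": label, **drawn})
            df = pd.concat([df, panel], axis=1)
            df["cirrhosis"] = bool(cirrhosis)
            frames.append(df)
            offset += n
        out = pd.concat(frames, ignore_index=True)
    else:  # copula
        k = len(spec.score_names)
        z = rng.multivariate_normal(np.zeros(k), np.asarray(spec.correlation_matrix),
                                    size=spec.n_total, method="cholesky")
        drawn = {
            name: spec.marginal_means[name] + spec.marginal_sds[name] * z[:, i]
            for i, name in enumerate(spec.score_names)
        }
        for name, (mean, sd) in DEFAULT_SCORE_MARGINALS.items():
            if name not in drawn:
                drawn[name] = rng.normal(mean, sd, size=spec.n_total)
        panel = _backsolve_panel(drawn["albi"], drawn.get("meld"), rng)
        if "meld" not in drawn:
            drawn["meld"] = _meld_from_panel(panel)
        out = pd.DataFrame({"group": "all", **drawn})
        out = pd.concat([out, panel], axis=1)
        out["cirrhosis"] = False

    n = len(out)
    out.insert(0, "patient_id", [f"P{i:04d}" for i in range(n)])
    out["height_m"] = np.clip(rng.normal(*HEIGHT_M, size=n), 1.2, 2.2)
    out["weight_kg"] = np.clip(rng.normal(*WEIGHT_KG, size=n), 35.0, 200.0)
    out["albi_grade"] = [albi_grade(a) for a in out["albi"]]
    out["ascites_grade"] = "none"
    out["encephalopathy_grade"] = "none"
    return out


def table3_meld_dichotomy_spec(seed: int = 0) -> CohortSpec:
    """Study-population MELD dichotomy: 103 good-function patients
    (MELIF 54 +- 9.8, ALBI -2.2 +- 0.52) vs 47 impaired
    (MELIF 42 +- 10, ALBI -1.7 +- 0.58)."""
    return CohortSpec(mode="marginal", seed=seed, groups=(
        GroupSpec("meld_le_10", 103, "melif", 54.0, 9.8),
        GroupSpec("meld_le_10", 103, "albi", -2.2, 0.52),
        GroupSpec("meld_ge_11", 47, "melif", 42.0, 10.0),
        GroupSpec("meld_ge_11", 47, "albi", -1.7, 0.58),
    ))


def table3_cirrhosis_spec(seed: int = 0) -> CohortSpec:
    """Study-population cirrhosis dichotomy: 64 without cirrhosis
    (MELIF 58 +- 8.9, ALBI -2.4 +- 0.48) vs 86 with
    (MELIF 45 +- 10, ALBI -1.8 +- 0.57)."""
    return CohortSpec(mode="marginal", seed=seed, groups=(
        GroupSpec("no_cirrhosis", 64, "melif", 58.0, 8.9, cirrhosis=False),
        GroupSpec("no_cirrhosis", 64, "albi", -2.4, 0.48, cirrhosis=False),
        GroupSpec("cirrhosis", 86, "melif", 45.0, 10.0, cirrhosis=True),
        GroupSpec("cirrhosis", 86, "albi", -1.8, 0.57, cirrhosis=True),
    ))


def table4_albi_grade_spec(seed: int = 0) -> CohortSpec:
    """Study-population ALBI-grade strata: MELIF 60 +- 6.7 (grade 1, n=33),
    50 +- 10 (grade 2, n=95), 38 +- 9.8 (grade 3, n=22), with matching
    ALBI marginals (-2.8 +- 0.13, -2.0 +- 0.36, -1.0 +- 0.26)."""
    return CohortSpec(mode="marginal", seed=seed, groups=(
        GroupSpec("albi_grade_1", 33, "melif", 60.0, 6.7),
        GroupSpec("albi_grade_1", 33, "albi", -2.8, 0.13),
        GroupSpec("albi_grade_2", 95, "melif", 50.0, 10.0),
        GroupSpec("albi_grade_2", 95, "albi", -2.0, 0.36),
        GroupSpec("albi_grade_3", 22, "melif", 38.0, 9.8),
        GroupSpec("albi_grade_3", 22, "albi", -1.0, 0.26),
    ))
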