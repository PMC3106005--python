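"""Synthetic psoriasis / psoriatic-arthritis cohort generator.

Emulates the statistical structure the analysis pipeline assumes, so
that every stage can be exercised and calibrated without patient data:

* three per-patient latent severities — skin (S), joint (J), nail (N) —
  standard normal with a configurable correlation matrix.  Setting the
  S–J correlation to 0 produces the "independent axes" world; 0.8
  produces a strongly shared-severity world;
* body-region clusters with correlated involvement — hands↔feet
  (acral), face↔scalp (head), buttocks↔chest↔back (trunk) — via
  per-patient cluster effects with configurable loadings;
* ordinal 0–4 item scales produced by fixed normal-quantile thresholds
  (right-skewed, as severity items are in practice), near-continuous
  percent extents with a point mass at zero, per-digit binary nail and
  joint flags, questionnaire answers driven by the joint latent;
* toe-level involvement flags that share an acral effect with foot skin
  extent, so a *qualitative* skin–toe association can coexist with
  quantitatively independent latents;
* an interval-censoring step reproducing the assessor who recorded only
  the total body-surface percentage: the per-region extents of a
  configurable fraction of patients are replaced by the sharpest
  intervals consistent with their total.

Default sizes and rates mirror the study conditions: 180 patients, four
assessors of whom one (a quarter of the cohort) is interval-censored,
and roughly a third of patients with appreciable joint involvement.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, ndtr

from .instruments import (
    AREAS,
    DEFAULT_AREA_WEIGHTS,
    DigitFlags,
    PaseAnswers,
    PatientRecord,
    PsaaItems,
    PwesiArea,
    RegionAssessment,
    region_intervals_from_total,
    validate_area_weights,
)
from .intervals import Interval, as_interval

__all__ = [
    "GeneratorConfig",
    "LatentState",
    "generate_cohort",
    "draw_latents",
    "apply_assessor_censoring",
    "cohort_to_frame",
    "frame_to_records",
    "write_cohort_csv",
    "read_cohort_csv",
]

# Region cluster membership (remaining areas carry no cluster effect).
CLUSTERS: dict[str, tuple[str, ...]] = {
    "acral": ("hands_fingers", "feet_toes"),
    "head": ("scalp_hairline", "face_neck"),
    "trunk": ("buttocks_thighs", "chest_abdomen", "back_shoulders"),
}
_CLUSTER_OF = {a: c for c, areas in CLUSTERS.items() for a in areas}

# Loading of each region's latent on the patient's skin severity S.
_SKIN_LOADING = 0.95
# Measurement noise added to a region latent before each ordinal item.
_ITEM_NOISE = 0.25
# Per-digit flags: log-odds slope on the nail/joint latent and sd of the
# patient-digit noise.
_DIGIT_SLOPE = 3.2
_DIGIT_NOISE = 0.6
# Loading of questionnaire / exam item latents on the joint latent J.
_QUESTION_LOADING = 0.95
# Normal-quantile cut points mapping a unit-variance latent to severities
# 1..4; chosen to give realistic right-skewed item distributions.
SEVERITY_CUTS = (0.25, 0.8, 1.4, 2.0)
_PASE_CUTS = (-0.8, 0.0, 0.8, 1.6)
_ARTHRITIS_CUTS = (0.8, 1.3, 1.8, 2.2)
_PGA_CUTS = (-1.1, -0.55, -0.1, 0.35, 0.8, 1.3, 1.9)


def _default_latent_corr() -> np.ndarray:
    return np.eye(3)


def _default_cluster_loadings() -> dict[str, float]:
    return {"acral": 0.5, "head": 0.5, "trunk": 0.5}


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic cohort.

    ``latent_corr`` is the 3×3 correlation matrix of (skin, joint, nail)
    latents; ``cluster_loadings`` the per-cluster loading of regional
    involvement on the shared cluster effect; ``noise_sd`` the
    region-specific noise; ``involvement_base_rate`` the marginal
    probability that a region is involved at all;
    ``censored_assessor_fraction`` the share of patients whose regional
    extents are interval-censored from a total-BSA entry;
    ``toe_acral_gain`` the log-odds contribution of the acral cluster
    effect to toe nail/joint involvement (the knob that creates a
    qualitative skin–toe association without quantitative correlation).
    """

    n_patients: int = 180
    seed: int = 0
    latent_corr: np.ndarray = field(default_factory=_default_latent_corr)
    cluster_loadings: dict[str, float] = field(default_factory=_default_cluster_loadings)
    noise_sd: float = 0.3
    involvement_base_rate: float = 0.6
    censored_assessor_fraction: float = 0.25
    toe_acral_gain: float = 1.5
    area_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_AREA_WEIGHTS)
    )

    def __post_init__(self) -> None:
        self.latent_corr = np.asarray(self.latent_corr, dtype=float)
        if self.latent_corr.shape != (3, 3):
            raise ValueError("latent_corr must be 3x3")
        if not np.allclose(self.latent_corr, self.latent_corr.T):
            raise ValueError("latent_corr must be symmetric")
        if not np.allclose(np.diag(self.latent_corr), 1.0):
            raise ValueError("latent_corr must have unit diagonal")
        eig = np.linalg.eigvalsh(self.latent_corr)
        if eig.min() < -1e-10:
            raise ValueError("latent_corr must be positive semi-definite")
        if self.n_patients < 1:
            raise ValueError("n_patients must be positive")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        for name in ("involvement_base_rate", "censored_assessor_fraction"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        for c in CLUSTERS:
            lam = self.cluster_loadings.get(c, 0.0)
            if not 0.0 <= lam <= 1.0:
                raise ValueError(f"cluster loading {c} must lie in [0, 1]")
        validate_area_weights(self.area_weights)


@dataclass
class LatentState:
    """Per-patient latent severities and cluster effects, kept for
    calibration and oracle tests."""

    S: np.ndarray
    J: np.ndarray
    N: np.ndarray
    cluster_effects: dict[str, np.ndarray]


def draw_latents(config: GeneratorConfig, rng: np.random.Generator | None = None) -> LatentState:
    """Draw (S, J, N) with the configured correlation plus cluster effects."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_patients
    chol = np.linalg.cholesky(config.latent_corr + 1e-12 * np.eye(3))
    z = rng.standard_normal((n, 3)) @ chol.T
    cluster = {c: rng.standard_normal(n) for c in CLUSTERS}
    return LatentState(S=z[:, 0], J=z[:, 1], N=z[:, 2], cluster_effects=cluster)


def _ordinal(latent: np.ndarray, cuts: Sequence[float]) -> np.ndarray:
    return np.digitize(latent, cuts).astype(int)


def _region_latents(config: GeneratorConfig, state: LatentState, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Unit-variance involvement latents per region: loading on S, plus a
    cluster effect where the region belongs to one, plus region noise."""
    n = config.n_patients
    out = {}
    for area in AREAS:
        lam = 0.0
        contrib = np.zeros(n)
        c = _CLUSTER_OF.get(area)
        if c is not None:
            lam = config.cluster_loadings.get(c, 0.0)
            contrib = lam * state.cluster_effects[c]
        eps = rng.standard_normal(n)
        z = _SKIN_LOADING * state.S + contrib + config.noise_sd * eps
        z /= np.sqrt(_SKIN_LOADING**2 + lam**2 + config.noise_sd**2)
        out[area] = z
    return out


def _noisy(latent: np.ndarray, noise: float, rng: np.random.Generator) -> np.ndarray:
    return (latent + noise * rng.standard_normal(latent.size)) / np.sqrt(1 + noise**2)


def generate_cohort(
    config: GeneratorConfig, return_latents: bool = False
) -> "list[PatientRecord] | tuple[list[PatientRecord], LatentState]":
    """Generate ``config.n_patients`` fully valid patient records.

    Deterministic given the config seed.  All extents are scalar
    (uncensored); apply :func:`apply_assessor_censoring` afterwards for
    the interval-censored assessor.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    state = draw_latents(config, rng)
    zreg = _region_latents(config, state, rng)

    thr = 1.0 - config.involvement_base_rate

    extents: dict[str, np.ndarray] = {}
    sev_items: dict[str, dict[str, np.ndarray]] = {}
    pw_extent: dict[str, np.ndarray] = {}
    pw_severity: dict[str, np.ndarray] = {}
    arthritis: dict[str, np.ndarray] = {}

    for area in AREAS:
        z = zreg[area]
        p = ndtr(z)
        involved = p > thr
        ext = np.where(
            involved,
            np.round(100.0 * (p - thr) / max(config.involvement_base_rate, 1e-12), 1),
            0.0,
        )
        ext = np.clip(ext, 0.0, 100.0)
        extents[area] = ext
        involved = ext > 0  # rounding can push a borderline extent to 0

        items = {}
        for item in ("erythema", "thickness", "scaling"):
            y = _noisy(z, _ITEM_NOISE, rng)
            sev = _ordinal(y, SEVERITY_CUTS)
            sev = np.where(involved, np.maximum(sev, 1), 0)
            items[item] = sev
        sev_items[area] = items

        ya = _noisy(0.85 * state.J, np.sqrt(1 - 0.85**2) / 1.0, rng)
        arthritis[area] = _ordinal(ya, _ARTHRITIS_CUTS)

        # PWESI reads the same underlying region truth with its own
        # measurement noise and coarser 0-4 scales.
        pw_extent[area] = np.digitize(ext, (0.0, 25.0, 50.0, 75.0)).astype(int)
        ys = _noisy(z, 0.35, rng)
        sev_pw = _ordinal(ys, SEVERITY_CUTS)
        pw_severity[area] = np.where(involved, np.maximum(sev_pw, 1), 0)

    # Per-digit binary flags: latent logit linear in N (nails) / J
    # (joints) plus patient-digit noise.
    def digit_flags(latent: np.ndarray, intercept: float) -> np.ndarray:
        zeta = rng.standard_normal((n, 10))
        logit = intercept + _DIGIT_SLOPE * latent[:, None] + _DIGIT_NOISE * zeta
        return (rng.random((n, 10)) < expit(logit)).astype(int)

    nails = digit_flags(state.N, -1.2)
    joints = digit_flags(state.J, -2.2)

    # Questionnaires driven by the joint latent.
    q = _QUESTION_LOADING
    pase_latents = _noisy(
        np.repeat(q * state.J[:, None], 15, axis=1).ravel(), np.sqrt(1 - q**2), rng
    ).reshape(n, 15)
    pase = 1 + _ordinal(pase_latents, _PASE_CUTS)

    hx_pt = (rng.random(n) < expit(-0.3 + 1.5 * state.J)).astype(int)
    hx_fam = (rng.random(n) < expit(-0.8 + 1.0 * state.J)).astype(int)
    exam_latents = _noisy(
        np.repeat(q * state.J[:, None], 6, axis=1).ravel(), np.sqrt(1 - q**2), rng
    ).reshape(n, 6)
    exam = _ordinal(exam_latents, (0.25, 0.9, 1.5, 2.1))

    # Global physician assessment: monotone map of mean regional severity.
    zbar = np.mean([zreg[a] for a in AREAS], axis=0)
    zbar = zbar / zbar.std() if zbar.std() > 0 else zbar
    pga = _ordinal(zbar, _PGA_CUTS)

    qol = _ordinal(_noisy(0.75 * state.S, np.sqrt(1 - 0.75**2), rng), SEVERITY_CUTS)
    pain = _ordinal(_noisy(0.75 * state.S, np.sqrt(1 - 0.75**2), rng), SEVERITY_CUTS)
    itch = _ordinal(_noisy(0.75 * state.S, np.sqrt(1 - 0.75**2), rng), SEVERITY_CUTS)

    # Toe flags share the acral cluster effect with foot skin extent.
    g = config.toe_acral_gain
    acral = state.cluster_effects["acral"]
    toe_nail = (rng.random(n) < expit(-0.5 + 1.4 * state.N + g * acral)).astype(int)
    toe_joint = (rng.random(n) < expit(-0.9 + 1.4 * state.J + g * acral)).astype(int)

    # A quarter of patients per assessor, round-robin over four centers.
    assessors = np.array([f"A{1 + i % 4}" for i in range(n)])

    records = []
    for i in range(n):
        regions = [
            RegionAssessment(
                area=a,
                extent=float(extents[a][i]),
                erythema=int(sev_items[a]["erythema"][i]),
                thickness=int(sev_items[a]["thickness"][i]),
                scaling=int(sev_items[a]["scaling"][i]),
                arthritis=int(arthritis[a][i]),
            )
            for a in AREAS
        ]
        pwesi = [
            PwesiArea(area=a, extent=int(pw_extent[a][i]), severity=int(pw_severity[a][i]))
            for a in AREAS
        ]
        records.append(
            PatientRecord(
                patient_id=f"P{i + 1:04d}",
                assessor_id=str(assessors[i]),
                regions=regions,
                pwesi=pwesi,
                pase=PaseAnswers(
                    symptom=[int(v) for v in pase[i, :7]],
                    function=[int(v) for v in pase[i, 7:]],
                ),
                psaa=PsaaItems(
                    history=[int(hx_pt[i]), int(hx_fam[i])],
                    exam=[int(v) for v in exam[i]],
                ),
                nails=DigitFlags(flags=[int(v) for v in nails[i]], domain="nail"),
                joints=DigitFlags(flags=[int(v) for v in joints[i]], domain="joint"),
                global_pga=int(pga[i]),
                quality_of_life=int(qol[i]),
                pain=int(pain[i]),
                itch=int(itch[i]),
                toe_nail_any=int(toe_nail[i]),
                toe_joint_any=int(toe_joint[i]),
            )
        )
    if return_latents:
        return records, state
    return records


def apply_assessor_censoring(
    records: Sequence[PatientRecord], config: GeneratorConfig
) -> tuple[list[PatientRecord], dict[str, dict[str, float]]]:
    """Interval-censor the regional extents of one assessor's patients.

    A deterministic (seed-derived) subset of ``censored_assessor_fraction``
    of the cohort has every regional extent replaced by the sharpest
    interval consistent with the patient's total body involvement
    ``T = Σ_r w_r·extent_r``.  Returns the new records plus the
    uncensored truth (patient_id → area → extent) for oracle checks.
    """
    n = len(records)
    k = int(round(config.censored_assessor_fraction * n))
    rng = np.random.default_rng(config.seed + 1)
    chosen = set(rng.permutation(n)[:k].tolist())
    weights = config.area_weights

    out: list[PatientRecord] = []
    truth: dict[str, dict[str, float]] = {}
    for i, rec in enumerate(records):
        if i not in chosen:
            out.append(rec)
            continue
        true_ext = {r.area: float(as_interval(r.extent).midpoint) for r in rec.regions}
        truth[rec.patient_id] = true_ext
        total = sum(weights[a] * e for a, e in true_ext.items())
        intervals = region_intervals_from_total(total, weights)
        new_regions = [
            RegionAssessment(
                area=r.area,
                extent=intervals[r.area],
                erythema=r.erythema,
                thickness=r.thickness,
                scaling=r.scaling,
                arthritis=r.arthritis,
            )
            for r in rec.regions
        ]
        out.append(
            PatientRecord(
                patient_id=rec.patient_id,
                assessor_id="A_total_only",
                regions=new_regions,
                pwesi=rec.pwesi,
                pase=rec.pase,
                psaa=rec.psaa,
                nails=rec.nails,
                joints=rec.joints,
                global_pga=rec.global_pga,
                quality_of_life=rec.quality_of_life,
                pain=rec.pain,
                itch=rec.itch,
                toe_nail_any=rec.toe_nail_any,
                toe_joint_any=rec.toe_joint_any,
            )
        )
    return out, truth


# ---------------------------------------------------------------------------
# Cohort CSV schema
# ---------------------------------------------------------------------------


def cohort_columns() -> list[str]:
    cols = ["patient_id", "assessor_id"]
    for a in AREAS:
        cols += [
            f"A_{a}_extent_lo",
            f"A_{a}_extent_hi",
            f"A_{a}_erythema",
            f"A_{a}_thickness",
            f"A_{a}_scaling",
            f"A_{a}_arthritis",
        ]
    for a in AREAS:
        cols += [f"P_{a}_extent", f"P_{a}_severity"]
    cols += [f"pase_s{i}" for i in range(1, 8)]
    cols += [f"pase_f{i}" for i in range(1, 9)]
    cols += ["psaa_hx_pt", "psaa_hx_fam"] + [f"psaa_ex{i}" for i in range(1, 7)]
    cols += [f"na_d{i}" for i in range(1, 11)]
    cols += [f"ja_d{i}" for i in range(1, 11)]
    cols += ["pga", "qol", "pain", "itch", "toe_nail_any", "toe_joint_any"]
    return cols


def cohort_to_frame(records: Sequence[PatientRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        row: dict = {"patient_id": rec.patient_id, "assessor_id": rec.assessor_id}
        for r in rec.regions:
            iv = as_interval(r.extent)
            row[f"A_{r.area}_extent_lo"] = iv.lo
            row[f"A_{r.area}_extent_hi"] = iv.hi
            row[f"A_{r.area}_erythema"] = r.erythema
            row[f"A_{r.area}_thickness"] = r.thickness
            row[f"A_{r.area}_scaling"] = r.scaling
            row[f"A_{r.area}_arthritis"] = r.arthritis
        for p in rec.pwesi:
            row[f"P_{p.area}_extent"] = p.extent
            row[f"P_{p.area}_severity"] = p.severity
        for i, v in enumerate(rec.pase.symptom, 1):
            row[f"pase_s{i}"] = v
        for i, v in enumerate(rec.pase.function, 1):
            row[f"pase_f{i}"] = v
        row["psaa_hx_pt"], row["psaa_hx_fam"] = rec.psaa.history
        for i, v in enumerate(rec.psaa.exam, 1):
            row[f"psaa_ex{i}"] = v
        for i, v in enumerate(rec.nails.flags, 1):
            row[f"na_d{i}"] = v
        for i, v in enumerate(rec.joints.flags, 1):
            row[f"ja_d{i}"] = v
        row["pga"] = rec.global_pga
        row["qol"] = rec.quality_of_life
        row["pain"] = rec.pain
        row["itch"] = rec.itch
        row["toe_nail_any"] = rec.toe_nail_any
        row["toe_joint_any"] = rec.toe_joint_any
        rows.append(row)
    return pd.DataFrame(rows, columns=cohort_columns())


def frame_to_records(df: pd.DataFrame) -> list[PatientRecord]:
    records = []
    for _, row in df.iterrows():
        regions = []
        for a in AREAS:
            lo = float(row[f"A_{a}_extent_lo"])
            hi = float(row[f"A_{a}_extent_hi"])
            extent: "float | Interval" = lo if lo == hi else Interval(lo, hi)
            regions.append(
                RegionAssessment(
                    area=a,
                    extent=extent,
                    erythema=int(row[f"A_{a}_erythema"]),
                    thickness=int(row[f"A_{a}_thickness"]),
                    scaling=int(row[f"A_{a}_scaling"]),
                    arthritis=int(row[f"A_{a}_arthritis"]),
                )
            )
        pwesi = [
            PwesiArea(area=a, extent=int(row[f"P_{a}_extent"]), severity=int(row[f"P_{a}_severity"]))
            for a in AREAS
        ]

        def _opt(col: str):
            if col not in row or pd.isna(row[col]):
                return None
            return int(row[col])

        records.append(
            PatientRecord(
                patient_id=str(row["patient_id"]),
                assessor_id=str(row["assessor_id"]),
                regions=regions,
                pwesi=pwesi,
                pase=PaseAnswers(
                    symptom=[int(row[f"pase_s{i}"]) for i in range(1, 8)],
                    function=[int(row[f"pase_f{i}"]) for i in range(1, 9)],
                ),
                psaa=PsaaItems(
                    history=[int(row["psaa_hx_pt"]), int(row["psaa_hx_fam"])],
                    exam=[int(row[f"psaa_ex{i}"]) for i in range(1, 7)],
                ),
                nails=DigitFlags(flags=[int(row[f"na_d{i}"]) for i in range(1, 11)], domain="nail"),
                joints=DigitFlags(flags=[int(row[f"ja_d{i}"]) for i in range(1, 11)], domain="joint"),
                global_pga=int(row["pga"]),
                quality_of_life=int(row["qol"]),
                pain=int(row["pain"]),
                itch=int(row["itch"]),
                toe_nail_any=_opt("toe_nail_any"),
                toe_joint_any=_opt("toe_joint_any"),
            )
        )
    return records


def write_cohort_csv(records: Sequence[PatientRecord], path, seed: int | None = None) -> None:
    """Write the cohort CSV; the generating seed is recorded in a leading
    ``#`` comment line."""
    df = cohort_to_frame(records)
    buf = io.StringIO()
    if seed is not None:
        buf.write(f"# seed={seed}\n")
    df.to_csv(buf, index=False)
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_cohort_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
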