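"""Cohort-level analysis: score → correlate → associate.

Reproduces the analysis surfaces of the study design on any cohort CSV:
per-patient tool scores for the seven instruments, the 7×7 tool-level
u-score correlation matrix, the item-level correlation matrix with
block summaries (skin / joint / nail and region-cluster blocks), and
the finger / toe odds-ratio analysis.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import instruments as ins
from .association import build_table, odds_ratio
from .cohort import frame_to_records
from .instruments import AREAS, PatientRecord, validate_record
from .intervals import Interval, as_interval
from .ustat import CorrelationMatrix, ObservationVector, correlation_matrix

log = logging.getLogger("psoriastat")

TOOLS = ("xl_pasi", "pwesi", "pga", "pase", "psaa", "na", "ja")
#: Tools that measure the skin axis vs the joint axis.
SKIN_TOOLS = ("xl_pasi", "pwesi", "pga")
JOINT_TOOLS = ("pase", "psaa", "ja")


class CohortValidationError(ValueError):
    def __init__(self, violations: list[str]):
        self.violations = violations
        super().__init__(
            f"{len(violations)} validation failure(s); first: {violations[0]}"
        )


def compute_tool_scores(records: Sequence[PatientRecord], rescale: bool = True) -> pd.DataFrame:
    """Score every instrument for every patient.

    Returns one row per patient with columns ``xl_pasi_lo`` /
    ``xl_pasi_hi`` (equal unless the patient's extents are
    interval-censored), ``pwesi``, ``pga``, ``pase`` (plus subscores),
    ``psaa``, ``na`` and ``ja``.  Aborts with the full violation list if
    any record is invalid.
    """
    violations: list[str] = []
    for rec in records:
        violations += [f"{rec.patient_id}: {v}" for v in validate_record(rec)]
    if violations:
        raise CohortValidationError(violations)

    rows = []
    for rec in records:
        # Tool-level XL-PASI is the skin-only composite: the extension
        # items (arthritis, QoL, pain, itch) are carried in the record
        # but kept out of the skin-severity score, which would otherwise
        # correlate with the joint instruments by construction.
        xl = ins.score_xl_pasi(rec.regions, rescale=rescale, include_globals=False)
        xl_iv = as_interval(xl)
        sym, fun, tot = ins.score_pase(rec.pase)
        rows.append(
            {
                "patient_id": rec.patient_id,
                "xl_pasi_lo": xl_iv.lo,
                "xl_pasi_hi": xl_iv.hi,
                "pwesi": ins.score_pwesi(rec.pwesi, rescale=rescale),
                "pga": rec.global_pga,
                "pase_symptom": sym,
                "pase_function": fun,
                "pase": tot,
                "psaa": ins.score_psaa(rec.psaa),
                "na": ins.score_digit_count(rec.nails),
                "ja": ins.score_digit_count(rec.joints),
            }
        )
    return pd.DataFrame(rows).set_index("patient_id")


def _tool_items(scores: pd.DataFrame) -> list[ObservationVector]:
    items = [
        ObservationVector(
            list(zip(scores["xl_pasi_lo"], scores["xl_pasi_hi"])),
            item_id="xl_pasi",
            scale_kind="interval",
        )
    ]
    for t in TOOLS[1:]:
        items.append(ObservationVector(scores[t], item_id=t, scale_kind="ordinal"))
    return items


def run_tool_correlations(scores: pd.DataFrame) -> CorrelationMatrix:
    """7×7 u-score correlation matrix over the tool scores.

    Interval-valued XL-PASI scores enter through the u-score partial
    order directly, not through midpoints.
    """
    if len(scores) < 3:
        raise ValueError("tool correlations need at least 3 patients")
    return correlation_matrix(_tool_items(scores))


# ---------------------------------------------------------------------------
# Item-level analysis
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class InventoryItem:
    item_id: str
    instrument: str
    scale_kind: str


def default_item_inventory() -> list[InventoryItem]:
    """The default 81-item inventory.

    10 JA digits + 10 NA digits + 15 PASE + 6 PsAA exam + 10 XL-PASI
    extents + 10 XL-PASI activities (mean of erythema/thickness/scaling
    per area) + 10 PWESI extents + 10 PWESI severities.
    """
    inv: list[InventoryItem] = []
    inv += [InventoryItem(f"ja_d{i}", "JA", "binary") for i in range(1, 11)]
    inv += [InventoryItem(f"na_d{i}", "NA", "binary") for i in range(1, 11)]
    inv += [InventoryItem(f"pase_s{i}", "PASE", "ordinal") for i in range(1, 8)]
    inv += [InventoryItem(f"pase_f{i}", "PASE", "ordinal") for i in range(1, 9)]
    inv += [InventoryItem(f"psaa_ex{i}", "PsAA", "ordinal") for i in range(1, 7)]
    inv += [InventoryItem(f"xl_extent_{a}", "XL-PASI", "interval") for a in AREAS]
    inv += [InventoryItem(f"xl_activity_{a}", "XL-PASI", "ordinal") for a in AREAS]
    inv += [InventoryItem(f"pwesi_extent_{a}", "PWESI", "ordinal") for a in AREAS]
    inv += [InventoryItem(f"pwesi_severity_{a}", "PWESI", "ordinal") for a in AREAS]
    return inv


def _resolve_item(df: pd.DataFrame, item: InventoryItem) -> ObservationVector:
    iid = item.item_id
    if iid in df.columns:
        return ObservationVector(df[iid], item_id=iid, scale_kind=item.scale_kind)
    if iid.startswith("xl_extent_"):
        a = iid[len("xl_extent_"):]
        return ObservationVector(
            list(zip(df[f"A_{a}_extent_lo"], df[f"A_{a}_extent_hi"])),
            item_id=iid,
            scale_kind="interval",
        )
    if iid.startswith("xl_activity_"):
        a = iid[len("xl_activity_"):]
        vals = (
            df[f"A_{a}_erythema"] + df[f"A_{a}_thickness"] + df[f"A_{a}_scaling"]
        ) / 3.0
        return ObservationVector(vals, item_id=iid, scale_kind="ordinal")
    if iid.startswith("pwesi_extent_"):
        a = iid[len("pwesi_extent_"):]
        return ObservationVector(df[f"P_{a}_extent"], item_id=iid, scale_kind="ordinal")
    if iid.startswith("pwesi_severity_"):
        a = iid[len("pwesi_severity_"):]
        return ObservationVector(df[f"P_{a}_severity"], item_id=iid, scale_kind="ordinal")
    raise KeyError(f"item id {iid!r} cannot be resolved against the cohort schema")


#: Item blocks for the skin / joint / nail axis summaries.
def axis_blocks(inventory: Sequence[InventoryItem]) -> dict[str, list[str]]:
    blocks: dict[str, list[str]] = {"skin": [], "joint": [], "nail": []}
    for it in inventory:
        if it.instrument in ("XL-PASI", "PWESI"):
            blocks["skin"].append(it.item_id)
        elif it.instrument in ("JA", "PASE", "PsAA"):
            blocks["joint"].append(it.item_id)
        elif it.instrument == "NA":
            blocks["nail"].append(it.item_id)
    return blocks


def region_item_ids(area: str, inventory: Sequence[InventoryItem]) -> list[str]:
    """Skin items belonging to one body area (XL extent/activity + PWESI)."""
    suffix = f"_{area}"
    return [
        it.item_id
        for it in inventory
        if it.instrument in ("XL-PASI", "PWESI") and it.item_id.endswith(suffix)
    ]


_CLUSTER_PAIRS = {
    "hands_feet": ("hands_fingers", "feet_toes"),
    "face_scalp": ("face_neck", "scalp_hairline"),
    "buttocks_chest": ("buttocks_thighs", "chest_abdomen"),
    "buttocks_back": ("buttocks_thighs", "back_shoulders"),
    "chest_back": ("chest_abdomen", "back_shoulders"),
    # non-cluster contrasts
    "hands_chest": ("hands_fingers", "chest_abdomen"),
    "hands_back": ("hands_fingers", "back_shoulders"),
    "hands_buttocks": ("hands_fingers", "buttocks_thighs"),
}


def block_summary(matrix: CorrelationMatrix, inventory: Sequence[InventoryItem]) -> dict:
    """Mean within- and between-block correlations for the three symptom
    axes, plus region-pair means over skin items."""
    blocks = axis_blocks(inventory)
    out: dict = {"within": {}, "between": {}, "region_pairs": {}}
    names = list(blocks)
    for b in names:
        out["within"][b] = {
            "mean_r": matrix.submatrix_mean(blocks[b], blocks[b]),
            "mean_abs_r": matrix.submatrix_mean(blocks[b], blocks[b], absolute=True),
        }
    for i, b1 in enumerate(names):
        for b2 in names[i + 1:]:
            out["between"][f"{b1}_{b2}"] = {
                "mean_r": matrix.submatrix_mean(blocks[b1], blocks[b2]),
                "mean_abs_r": matrix.submatrix_mean(blocks[b1], blocks[b2], absolute=True),
            }
    for name, (a1, a2) in _CLUSTER_PAIRS.items():
        ids1 = region_item_ids(a1, inventory)
        ids2 = region_item_ids(a2, inventory)
        if ids1 and ids2:
            out["region_pairs"][name] = matrix.submatrix_mean(ids1, ids2)
    return out


def run_item_correlations(
    df: pd.DataFrame, inventory: Sequence[InventoryItem] | None = None
) -> tuple[CorrelationMatrix, dict]:
    """Item-level u-score correlation matrix plus block summaries."""
    if inventory is None:
        inventory = default_item_inventory()
    items = [_resolve_item(df, it) for it in inventory]
    matrix = correlation_matrix(items)
    return matrix, block_summary(matrix, inventory)


# ---------------------------------------------------------------------------
# Odds-ratio analysis
# ---------------------------------------------------------------------------


def _skin_involved(df: pd.DataFrame, area: str) -> np.ndarray:
    """Any nonzero skin extent in a region (interval midpoint > 0)."""
    mid = 0.5 * (df[f"A_{area}_extent_lo"] + df[f"A_{area}_extent_hi"])
    return (mid > 0).astype(int).to_numpy()


def run_odds_ratios(df: pd.DataFrame) -> list[dict]:
    """Finger- and toe-level skin × joint/nail association.

    For fingers: skin involvement of the hands region vs any finger nail
    (NA), any finger joint (JA), and either ("pooled").  For toes: skin
    involvement of the feet region vs the toe-level any-nail / any-joint
    flags, when those columns are present.
    """
    results: list[dict] = []

    def emit(comparison: str, skin: np.ndarray, other: np.ndarray) -> None:
        tab = build_table(skin, other)
        res = odds_ratio(tab)
        results.append(
            {
                "comparison": comparison,
                "a": tab.a,
                "b": tab.b,
                "c": tab.c,
                "d": tab.d,
                "or": res.or_estimate,
                "ci": [res.ci_low, res.ci_high],
                "p": res.p_value,
                "zero_cell_corrected": res.corrected,
            }
        )

    hands_skin = _skin_involved(df, "hands_fingers")
    na_any = (df[[f"na_d{i}" for i in range(1, 11)]].sum(axis=1) > 0).astype(int).to_numpy()
    ja_any = (df[[f"ja_d{i}" for i in range(1, 11)]].sum(axis=1) > 0).astype(int).to_numpy()
    emit("fingers_skin_vs_any_nail", hands_skin, na_any)
    emit("fingers_skin_vs_any_joint", hands_skin, ja_any)
    emit("fingers_skin_vs_nail_or_joint", hands_skin, ((na_any | ja_any)).astype(int))

    toe_cols = ("toe_nail_any", "toe_joint_any")
    if all(c in df.columns and df[c].notna().all() for c in toe_cols):
        feet_skin = _skin_involved(df, "feet_toes")
        tn = df["toe_nail_any"].astype(int).to_numpy()
        tj = df["toe_joint_any"].astype(int).to_numpy()
        emit("toes_skin_vs_any_nail", feet_skin, tn)
        emit("toes_skin_vs_any_joint", feet_skin, tj)
        emit("toes_skin_vs_nail_or_joint", feet_skin, ((tn | tj)).astype(int))
    else:
        log.warning("toe involvement flags missing; skipping toe-level odds ratios")
    return results


# ---------------------------------------------------------------------------
# Output writers
# ---------------------------------------------------------------------------


def write_matrix(matrix: CorrelationMatrix, csv_path, json_path=None) -> None:
    matrix.to_frame().to_csv(csv_path)
    if json_path is not None:
        with open(json_path, "w") as fh:
            json.dump(matrix.to_json_dict(), fh, indent=1)


def write_odds_ratios(results: list[dict], json_path, csv_path=None) -> None:
    with open(json_path, "w") as fh:
        json.dump(results, fh, indent=1)
    if csv_path is not None:
        flat = [
            {
                "comparison": r["comparison"],
                "a": r["a"],
                "b": r["b"],
                "c": r["c"],
                "d": r["d"],
                "or": r["or"],
                "ci_low": r["ci"][0],
                "ci_high": r["ci"][1],
                "p": r["p"],
            }
            for r in results
        ]
        pd.DataFrame(flat).to_csv(csv_path, index=False)


def plot_heatmap(matrix: CorrelationMatrix, path) -> None:
    """Render the correlation matrix as a red/green heatmap (undefined
    cells left blank)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = len(matrix.labels)
    fig, ax = plt.subplots(figsize=(max(6, n * 0.15), max(5, n * 0.15)))
    masked = np.ma.masked_invalid(matrix.r)
    im = ax.imshow(masked, cmap="RdYlGn_r", vmin=-1, vmax=1)
    fig.colorbar(im, ax=ax, label="u-score correlation")
    step = max(1, n // 40)
    ax.set_xticks(range(0, n, step))
    ax.set_xticklabels(matrix.labels[::step], rotation=90, fontsize=5)
    ax.set_yticks(range(0, n, step))
    ax.set_yticklabels(matrix.labels[::step], fontsize=5)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def records_from_frame(df: pd.DataFrame) -> list[PatientRecord]:
    return frame_to_records(df)
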