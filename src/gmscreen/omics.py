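"""Rule-based multi-omic labels for breast-tumor cohorts.

Three independent per-patient labellings, all deterministic functions of the
input table:

* **BRCA1/2 deficiency** — a gene is called deficient when a pathogenic
  (germline or somatic) variant co-occurs with loss of heterozygosity
  (GISTIC −1), or the gene is homozygously deleted (GISTIC −2); BRCA1 can
  additionally be silenced epigenetically (promoter methylation β ≥ 0.25
  together with expression z ≤ −2).  BRCA1 and BRCA2 are evaluated
  independently and may co-occur; neither label means "intact".
* **Expression group** — z ≤ −2 low, −2 < z < 2 normal, z ≥ 2 high.
* **Hormone-receptor subtype flags** — ER-positive, HER2-negative and
  triple-negative are non-exclusive IHC-based flags; a missing IHC field
  blocks only the flags that need it.

Pathogenicity booleans, GISTIC calls, methylation β and expression z-scores
are inputs produced by upstream annotation; missing methylation/expression
values never trigger a deficiency call.
"""

from __future__ import annotations

import math

import pandas as pd

from .errors import ValidationError

METHYLATION_BETA_MIN = 0.25
EXPRESSION_Z_LOW = -2.0
EXPRESSION_Z_HIGH = 2.0

OMICS_COLUMNS = (
    "patient_id",
    "brca1_pathogenic_germline", "brca1_pathogenic_somatic", "brca1_gistic",
    "brca1_methylation_beta", "brca1_expression_z",
    "brca2_pathogenic_germline", "brca2_pathogenic_somatic", "brca2_gistic",
    "ihc_er", "ihc_pr", "ihc_her2",
    "g6pc3_expression_z",
)

_GISTIC_VALUES = {-2, -1, 0, 1, 2}


def _is_missing(x) -> bool:
    if x is None:
        return True
    if isinstance(x, float) and math.isnan(x):
        return True
    if isinstance(x, str) and x.strip().lower() in ("", "na", "nan", "missing"):
        return True
    return bool(pd.isna(x))


def _gene_deficient(
    pathogenic_germline: bool,
    pathogenic_somatic: bool,
    gistic: int,
    methylation_beta: float | None = None,
    expression_z: float | None = None,
    allow_methylation: bool = False,
) -> bool:
    if gistic not in _GISTIC_VALUES:
        raise ValidationError(f"GISTIC call must be in {sorted(_GISTIC_VALUES)}, got {gistic}")
    pathogenic = bool(pathogenic_germline) or bool(pathogenic_somatic)
    if pathogenic and gistic == -1:  # pathogenic variant + LOH
        return True
    if gistic == -2:  # homozygous deletion
        return True
    if allow_methylation and not _is_missing(methylation_beta) and not _is_missing(expression_z):
        beta = float(methylation_beta)
        if not 0 <= beta <= 1:
            raise ValidationError(f"methylation beta must be in [0, 1], got {beta}")
        if beta >= METHYLATION_BETA_MIN and float(expression_z) <= EXPRESSION_Z_LOW:
            return True
    return False


def classify_deficiency(patient: dict | pd.Series) -> list[str]:
    """BRCA deficiency labels for one patient.

    Returns a subset of ``["BRCA1-deficient", "BRCA2-deficient"]``; an empty
    list means BRCA1/2-intact.
    """
    labels = []
    if _gene_deficient(
        patient["brca1_pathogenic_germline"],
        patient["brca1_pathogenic_somatic"],
        int(patient["brca1_gistic"]),
        patient.get("brca1_methylation_beta"),
        patient.get("brca1_expression_z"),
        allow_methylation=True,
    ):
        labels.append("BRCA1-deficient")
    if _gene_deficient(
        patient["brca2_pathogenic_germline"],
        patient["brca2_pathogenic_somatic"],
        int(patient["brca2_gistic"]),
    ):
        labels.append("BRCA2-deficient")
    return labels


def expression_group(z: float | None) -> str:
    """Expression category from a tumor-vs-normal z-score.

    low (z <= -2), normal (-2 < z < 2), high (z >= 2); a missing z yields
    "unclassified".
    """
    if _is_missing(z):
        return "unclassified"
    z = float(z)
    if z <= EXPRESSION_Z_LOW:
        return "low"
    if z >= EXPRESSION_Z_HIGH:
        return "high"
    return "normal"


def hormone_subtype(patient: dict | pd.Series) -> dict[str, bool | None]:
    """Non-exclusive IHC receptor-status flags.

    ``er_positive`` iff ER IHC is Positive; ``her2_negative`` iff HER2 IHC is
    Negative; ``triple_negative`` iff ER, PR and HER2 are all Negative.  A
    flag whose required field is missing is None (unclassified).
    """
    er, pr, her2 = patient["ihc_er"], patient["ihc_pr"], patient["ihc_her2"]
    er_m, pr_m, her2_m = _is_missing(er), _is_missing(pr), _is_missing(her2)
    return {
        "er_positive": None if er_m else er == "Positive",
        "her2_negative": None if her2_m else her2 == "Negative",
        "triple_negative": (
            None if (er_m or pr_m or her2_m)
            else er == "Negative" and pr == "Negative" and her2 == "Negative"
        ),
    }


def classify_omics(table: pd.DataFrame) -> pd.DataFrame:
    """Apply all three labellings to a patient table, appending label columns.

    Adds ``brca1_deficient``, ``brca2_deficient``, ``deficiency_label``
    (comma-joined labels or ``intact``), ``g6pc3_group`` and the three
    receptor flags.  Rows are classified independently, so row order never
    affects the labels.
    """
    missing = [c for c in OMICS_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"omics table missing columns: {missing}")
    out = table.copy()
    records = table.to_dict("records")
    deficiency = [classify_deficiency(r) for r in records]
    out["brca1_deficient"] = ["BRCA1-deficient" in d for d in deficiency]
    out["brca2_deficient"] = ["BRCA2-deficient" in d for d in deficiency]
    out["deficiency_label"] = [",".join(d) if d else "intact" for d in deficiency]
    out["g6pc3_group"] = [expression_group(r["g6pc3_expression_z"]) for r in records]
    flags = [hormone_subtype(r) for r in records]
    for key in ("er_positive", "her2_negative", "triple_negative"):
        out[key] = [f[key] for f in flags]
    return out


def deficiency_summary(labelled: pd.DataFrame) -> dict[str, int]:
    """Cohort-level counts of the deficiency labels."""
    return {
        "BRCA1-deficient": int(labelled["brca1_deficient"].sum()),
        "BRCA2-deficient": int(labelled["brca2_deficient"].sum()),
        "intact": int((labelled["deficiency_label"] == "intact").sum()),
        "n": int(len(labelled)),
    }
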