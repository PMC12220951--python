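"""Rare-variant gene-burden shortlisting.

A cohort variant table (one row per observed variant) is reduced to a
shortlist of candidate genes in two steps:

1. remove variants whose population allele frequency exceeds a cutoff
   (default 1%; the comparison is strictly greater, so AF == 0.01 is kept);
2. keep genes that carry, cohort-wide, at least one truncating variant
   (nonsense or frameshift) AND at least one missense variant.

Tables are plain :class:`pandas.DataFrame` objects with columns
``patient_id, gene, consequence, population_af`` and optionally
``chrom, pos, ref, alt`` (1-based coordinates as in VCF).  When positional
columns are present, recurrent observations of the same physical variant
collapse to a single contribution to the burden count.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

from .errors import ValidationError

CONSEQUENCES = ("nonsense", "frameshift", "missense", "synonymous", "other")
TRUNCATING = ("nonsense", "frameshift")

#: columns every variant table must carry
VARIANT_COLUMNS = ("patient_id", "gene", "consequence", "population_af")
#: optional positional columns used to deduplicate recurrent variants
POSITION_COLUMNS = ("chrom", "pos", "ref", "alt")


def _validate(variants: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in VARIANT_COLUMNS if c not in variants.columns]
    if missing:
        raise ValidationError(f"variant table missing columns: {missing}")
    bad = ~variants["consequence"].isin(CONSEQUENCES)
    if bad.any():
        values = sorted(variants.loc[bad, "consequence"].unique().tolist())
        raise ValidationError(f"unknown consequence values: {values}")
    af = variants["population_af"].to_numpy(dtype=float)
    out_of_range = (af < 0) | (af > 1)
    # NaN compares False on both sides, so missing AF passes here on purpose
    if out_of_range.any():
        raise ValidationError("population_af outside [0, 1]")
    return variants


def filter_rare_variants(
    variants: pd.DataFrame,
    af_max: float = 0.01,
    missing_af: str = "zero",
) -> pd.DataFrame:
    """Drop variants with population allele frequency strictly above ``af_max``.

    Parameters
    ----------
    variants
        Cohort variant table (see module docstring for columns).
    af_max
        Inclusive frequency ceiling.  A variant at exactly ``af_max`` is kept:
        only strictly-greater frequencies are removed.
    missing_af
        ``"zero"`` treats a missing AF as 0 (absent from population databases,
        i.e. rare) and keeps the record; ``"drop"`` removes such records.

    Returns
    -------
    pandas.DataFrame
        The retained rows, original order and index preserved.
    """
    if not 0 <= af_max <= 1:
        raise ValidationError(f"af_max must be in [0, 1], got {af_max}")
    if missing_af not in ("zero", "drop"):
        raise ValidationError(f"missing_af must be 'zero' or 'drop', got {missing_af!r}")
    _validate(variants)
    af = variants["population_af"].to_numpy(dtype=float)
    isnan = np.isnan(af)
    if missing_af == "zero":
        keep = isnan | (af <= af_max)
    else:
        keep = (~isnan) & (af <= af_max)
    return variants.loc[keep]


def shortlist_genes(variants: pd.DataFrame, per_patient: bool = False) -> list[str]:
    """Genes with >=1 truncating (nonsense/frameshift) and >=1 missense variant.

    Counting is cohort-wide by default: all (AF-filtered) variants of a gene are
    pooled across patients.  With ``per_patient=True`` both variant classes must
    co-occur within at least one single patient.  When positional columns
    (``chrom, pos, ref, alt``) are present, identical physical variants seen in
    several patients count once (cohort-wide mode only).

    Returns the qualifying gene symbols sorted lexicographically, deduplicated.
    """
    _validate(variants)
    relevant = variants[variants["consequence"].isin(TRUNCATING + ("missense",))]
    if relevant.empty:
        return []

    if per_patient:
        genes: set[str] = set()
        grouped = relevant.groupby(["patient_id", "gene"], sort=False)["consequence"]
        for (_, gene), cons in grouped:
            if cons.isin(TRUNCATING).any() and (cons == "missense").any():
                genes.add(gene)
        return sorted(genes)

    if all(c in relevant.columns for c in POSITION_COLUMNS):
        relevant = relevant.drop_duplicates(subset=["gene", *POSITION_COLUMNS[1:], POSITION_COLUMNS[0]])

    truncating = set(relevant.loc[relevant["consequence"].isin(TRUNCATING), "gene"])
    missense = set(relevant.loc[relevant["consequence"] == "missense", "gene"])
    return sorted(truncating & missense)


def shortlist_pipeline(
    variants: pd.DataFrame,
    af_max: float = 0.01,
    missing_af: str = "zero",
    per_patient: bool = False,
) -> list[str]:
    """AF filter followed by burden shortlisting (the composed operation)."""
    return shortlist_genes(
        filter_rare_variants(variants, af_max=af_max, missing_af=missing_af),
        per_patient=per_patient,
    )


def read_variants_vcf(
    path: str,
    gene_key: str = "GENE",
    consequence_key: str = "CSQ_CLASS",
    af_key: str = "AF",
) -> pd.DataFrame:
    """Minimal VCF reader: one variant record per VCF row.

    Gene symbol, consequence class and population AF are taken from the three
    declared INFO keys; the sample column (if any) is ignored and
    ``patient_id`` is taken from an optional ``PATIENT`` INFO key, else set to
    ``"cohort"``.  Coordinates are 1-based as in VCF.
    """
    from cyvcf2 import VCF

    rows: list[dict] = []
    for rec in VCF(path):
        cons = rec.INFO.get(consequence_key)
        if cons not in CONSEQUENCES:
            raise ValidationError(
                f"{path}: record {rec.CHROM}:{rec.POS} has consequence {cons!r}"
            )
        af = rec.INFO.get(af_key)
        rows.append(
            {
                "patient_id": rec.INFO.get("PATIENT", "cohort"),
                "gene": rec.INFO.get(gene_key),
                "consequence": cons,
                "population_af": float(af) if af is not None else np.nan,
                "chrom": rec.CHROM,
                "pos": rec.POS,
                "ref": rec.REF,
                "alt": rec.ALT[0] if rec.ALT else ".",
            }
        )
    return pd.DataFrame(rows)


def library_manifest(genes: Iterable[str], sirnas_per_gene: int = 3) -> pd.DataFrame:
    """siRNA library manifest for a gene shortlist: one row per (gene, siRNA).

    The screened library used 3 independent siRNAs per shortlisted gene, so a
    150-gene shortlist yields a 450-entry manifest.
    """
    if sirnas_per_gene < 1:
        raise ValidationError("sirnas_per_gene must be >= 1")
    genes = list(genes)
    return pd.DataFrame(
        {
            "gene": np.repeat(genes, sirnas_per_gene),
            "sirna_id": [
                f"{g}_si{i + 1}" for g in genes for i in range(sirnas_per_gene)
            ],
        }
    )
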