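"""Synthetic inputs with planted ground truth for every pipeline stage.

Four generators emulate the four input classes the analysis consumes:

* :func:`gen_screen_cells` — per-cell QIBC feature tables for an arrayed
  siRNA screen (two markers x two cell lines, 3 siRNAs/gene, negative
  controls on every plate, ~2,000 cells/well by default),
* :func:`gen_variant_cohort` — a cohort variant table whose gene-level
  burden composition is controlled, so the rare-variant shortlist is known,
* :func:`gen_amplicon_data` — CRISPR-Select allele counts (or FASTQ reads)
  at two timepoints under a known per-day selection coefficient,
* :func:`gen_omics_cohort` — patient multi-omic tables with planted BRCA
  deficiency labels and expression groups.

Every generator returns its table together with a :class:`TruthManifest`
recording what was planted, and draws all randomness from a single
``numpy.random.Generator`` seeded by its parameters, so identical seeds
give identical outputs.

The per-cell intensity model is deliberately simple: marker intensity is a
two-component lognormal mixture (negative/positive) whose mixture weight
carries the biology; micronucleus counts are Poisson with
``P(count >= 1)`` equal to the planted positive fraction; DNA content is a
2n/4n lognormal pair with S-phase cells spread between and flagged by high
EdU.  Plate bias acts multiplicatively on the positive fraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .crispr_select import AlleleCounts, AlleleSignature
from .errors import ParameterError

CONTROL_TAG = "NEG_CTRL"

DEFAULT_READOUTS = (
    ("gH2AX", "U2OS"),
    ("gH2AX", "MCF10A"),
    ("micronuclei", "U2OS"),
    ("micronuclei", "MCF10A"),
)

# lognormal mixture constants for the marker channel (arbitrary intensity
# units); components are separated by ~9 negative-component SDs so that a
# control-derived mean + 2 SD threshold recovers the planted mixture weight
# to well under binomial sampling error
GH2AX_NEG_LOG_MEAN = math.log(100.0)
GH2AX_NEG_LOG_SD = 0.12
GH2AX_POS_LOG_MEAN = math.log(500.0)
GH2AX_POS_LOG_SD = 0.15

EDU_NEG_LOG_MEAN = math.log(50.0)
EDU_POS_LOG_MEAN = math.log(500.0)
EDU_LOG_SD = 0.25

DAPI_2N_LOG_MEAN = math.log(100.0)
DAPI_4N_LOG_MEAN = math.log(200.0)
DAPI_LOG_SD = 0.06

CELL_CYCLE_FRACTIONS = (0.60, 0.25, 0.15)  # G1, S, G2


# ---------------------------------------------------------------------------
# truth manifest
# ---------------------------------------------------------------------------

@dataclass
class TruthManifest:
    """Ground truth planted by a generator, keyed to the seed that made it."""

    seed: int
    planted_hit_genes: list[str] = field(default_factory=list)
    planted_shortlist_genes: list[str] = field(default_factory=list)
    variant_truth: dict[str, float] = field(default_factory=dict)
    patient_truth: dict[str, str] = field(default_factory=dict)

    def write(self, path: str | Path) -> None:
        """Flat key-value text serialization (tab-separated)."""
        lines = [f"seed\t{self.seed}"]
        lines.append("planted_hit_genes\t" + ",".join(self.planted_hit_genes))
        lines.append("planted_shortlist_genes\t" + ",".join(self.planted_shortlist_genes))
        for vid, s in self.variant_truth.items():
            lines.append(f"variant_truth.{vid}\t{float(s)!r}")
        for pid, label in self.patient_truth.items():
            lines.append(f"patient_truth.{pid}\t{label}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def read(cls, path: str | Path) -> "TruthManifest":
        manifest = cls(seed=0)
        for line in Path(path).read_text().splitlines():
            if not line.strip():
                continue
            key, _, value = line.partition("\t")
            if key == "seed":
                manifest.seed = int(value)
            elif key == "planted_hit_genes":
                manifest.planted_hit_genes = [g for g in value.split(",") if g]
            elif key == "planted_shortlist_genes":
                manifest.planted_shortlist_genes = [g for g in value.split(",") if g]
            elif key.startswith("variant_truth."):
                manifest.variant_truth[key.split(".", 1)[1]] = float(value)
            elif key.startswith("patient_truth."):
                manifest.patient_truth[key.split(".", 1)[1]] = value
        return manifest


# ---------------------------------------------------------------------------
# siRNA screen generator
# ---------------------------------------------------------------------------

@dataclass
class ScreenSimParams:
    """Study-design parameters of a simulated arrayed siRNA screen.

    Defaults follow the screened library's design: 3 siRNAs per gene,
    ~2,000 cells per well, four readouts (γH2AX and micronuclei in U2OS and
    MCF10A).  ``hit_effect`` is the additive increase of the positive-cell
    fraction produced by a fully effective knockdown of a hit gene; the
    realized increase scales with the per-siRNA knockdown efficiency drawn
    from ``knockdown_efficiency_range``.
    """

    n_genes: int = 200
    n_hit_genes: int = 20
    sirnas_per_gene: int = 3
    cells_per_well: int = 2000
    baseline_positive_fraction: float = 0.05
    hit_effect: float = 0.25
    knockdown_efficiency_range: tuple[float, float] = (0.6, 0.9)
    plate_effect_sd: float = 0.05
    readouts: tuple = DEFAULT_READOUTS
    affected_readouts: tuple | None = None  # None = hits affect all readouts
    genes_per_plate: int = 40
    control_wells_per_plate: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.cells_per_well < 1:
            raise ParameterError("n_genes and cells_per_well must be >= 1")
        if self.n_hit_genes > self.n_genes or self.n_hit_genes < 0:
            raise ParameterError("need 0 <= n_hit_genes <= n_genes")
        if self.sirnas_per_gene < 1:
            raise ParameterError("sirnas_per_gene must be >= 1")
        for p in (self.baseline_positive_fraction, self.hit_effect):
            if not 0 <= p <= 1:
                raise ParameterError(f"probability {p} outside [0, 1]")
        lo, hi = self.knockdown_efficiency_range
        if not (0 <= lo <= hi <= 1):
            raise ParameterError("knockdown_efficiency_range must be within [0, 1]")
        if self.plate_effect_sd < 0:
            raise ParameterError("plate_effect_sd must be >= 0")


def _simulate_well_cells(
    rng: np.random.Generator,
    n_cells: int,
    w_marker: float,
    w_micronuclei: float,
) -> dict[str, np.ndarray]:
    """Per-cell features of one well given the two planted positive fractions."""
    phase = rng.choice(3, size=n_cells, p=CELL_CYCLE_FRACTIONS)
    dapi = np.empty(n_cells)
    g1, s, g2 = phase == 0, phase == 1, phase == 2
    dapi[g1] = np.exp(rng.normal(DAPI_2N_LOG_MEAN, DAPI_LOG_SD, g1.sum()))
    dapi[g2] = np.exp(rng.normal(DAPI_4N_LOG_MEAN, DAPI_LOG_SD, g2.sum()))
    # S-phase DNA content sits between 2n and 4n
    frac = rng.uniform(0.15, 0.85, s.sum())
    dapi[s] = np.exp(
        DAPI_2N_LOG_MEAN + frac * (DAPI_4N_LOG_MEAN - DAPI_2N_LOG_MEAN)
        + rng.normal(0.0, 0.05, s.sum())
    )
    edu = np.where(
        s,
        np.exp(rng.normal(EDU_POS_LOG_MEAN, EDU_LOG_SD, n_cells)),
        np.exp(rng.normal(EDU_NEG_LOG_MEAN, EDU_LOG_SD, n_cells)),
    )
    positive = rng.random(n_cells) < w_marker
    gh2ax = np.where(
        positive,
        np.exp(rng.normal(GH2AX_POS_LOG_MEAN, GH2AX_POS_LOG_SD, n_cells)),
        np.exp(rng.normal(GH2AX_NEG_LOG_MEAN, GH2AX_NEG_LOG_SD, n_cells)),
    )
    lam = -math.log1p(-min(w_micronuclei, 1 - 1e-12))
    micronuclei = rng.poisson(lam, n_cells)
    return {
        "dapi_total": dapi,
        "gH2AX_mean": gh2ax,
        "edu_mean": edu,
        "micronucleus_count": micronuclei,
    }


def gen_screen_cells(params: ScreenSimParams) -> tuple[pd.DataFrame, TruthManifest]:
    """Simulate the per-cell QIBC table of a multi-plate arrayed siRNA screen.

    Genes are laid out ``genes_per_plate`` per plate with
    ``control_wells_per_plate`` negative-control wells on every plate; each
    cell line gets its own plate series.  The first ``n_hit_genes`` genes
    (``GENE0001``…) are hits: their wells' positive fractions are raised by
    ``hit_effect`` scaled by the siRNA's knockdown efficiency, in the
    affected readouts (all four by default).
    """
    rng = np.random.default_rng(params.seed)
    genes = [f"GENE{i + 1:04d}" for i in range(params.n_genes)]
    hit_genes = genes[: params.n_hit_genes]
    affected = set(params.affected_readouts or params.readouts)
    cell_lines = list(dict.fromkeys(cl for _, cl in params.readouts))
    markers_by_line = {
        cl: [m for m, c in params.readouts if c == cl] for cl in cell_lines
    }

    # per-siRNA knockdown efficiencies, shared across cell lines
    lo, hi = params.knockdown_efficiency_range
    kd = {
        (g, i): rng.uniform(lo, hi)
        for g in genes
        for i in range(params.sirnas_per_gene)
    }

    n_plates = math.ceil(params.n_genes / params.genes_per_plate)
    frames: list[pd.DataFrame] = []
    for cell_line in cell_lines:
        for plate_idx in range(n_plates):
            plate = f"{cell_line}_P{plate_idx + 1:02d}"
            bias = math.exp(rng.normal(0.0, params.plate_effect_sd))
            plate_genes = genes[
                plate_idx * params.genes_per_plate:
                (plate_idx + 1) * params.genes_per_plate
            ]
            wells: list[tuple[str, str, float, float]] = []  # gene, sirna, w_marker, w_mn
            for g in plate_genes:
                for i in range(params.sirnas_per_gene):
                    w = {}
                    for marker in ("gH2AX", "micronuclei"):
                        effect = 0.0
                        if g in hit_genes and (marker, cell_line) in affected:
                            effect = params.hit_effect * kd[(g, i)]
                        w[marker] = min(
                            1.0,
                            bias * (params.baseline_positive_fraction + effect),
                        )
                    wells.append((g, f"{g}_si{i + 1}", w["gH2AX"], w["micronuclei"]))
            for j in range(params.control_wells_per_plate):
                w0 = min(1.0, bias * params.baseline_positive_fraction)
                wells.append((CONTROL_TAG, f"ctrl_{j + 1}", w0, w0))

            for widx, (gene, sirna, w_marker, w_mn) in enumerate(wells):
                feats = _simulate_well_cells(
                    rng, params.cells_per_well, w_marker, w_mn
                )
                n = params.cells_per_well
                frames.append(
                    pd.DataFrame(
                        {
                            "plate": np.repeat(plate, n),
                            "well": np.repeat(f"W{widx + 1:03d}", n),
                            "gene": np.repeat(gene, n),
                            "sirna_id": np.repeat(sirna, n),
                            "cell_line": np.repeat(cell_line, n),
                            **feats,
                        }
                    )
                )
    table = pd.concat(frames, ignore_index=True)
    manifest = TruthManifest(seed=params.seed, planted_hit_genes=list(hit_genes))
    return table, manifest


# ---------------------------------------------------------------------------
# variant cohort generator
# ---------------------------------------------------------------------------

def burden_spec_with_shortlist(
    n_genes: int,
    n_shortlist: int,
    seed: int = 0,
) -> dict[str, dict[str, int]]:
    """A burden composition with exactly ``n_shortlist`` qualifying genes.

    The first ``n_shortlist`` genes receive at least one rare truncating and
    one rare missense variant; the remainder are constructed to fail the
    burden rule (missing one class, or carrying it only at common AF).
    """
    if n_shortlist > n_genes or n_shortlist < 0:
        raise ParameterError("need 0 <= n_shortlist <= n_genes")
    rng = np.random.default_rng(seed)
    spec: dict[str, dict[str, int]] = {}
    for i in range(n_genes):
        gene = f"GENE{i + 1:04d}"
        if i < n_shortlist:
            spec[gene] = {
                "n_truncating": 1 + rng.poisson(0.5),
                "n_missense": 1 + rng.poisson(1.0),
                "n_other": rng.poisson(1.0),
                "n_common_truncating": 0,
                "n_common_missense": 0,
            }
        else:
            mode = rng.integers(0, 3)
            spec[gene] = {
                # 0: missense only; 1: truncating only; 2: the missing class
                # present but common (AF > 1%), so the filter removes it
                "n_truncating": 0 if mode == 0 else rng.poisson(1.0),
                "n_missense": 0 if mode == 1 else rng.poisson(1.5),
                "n_other": rng.poisson(1.0),
                "n_common_truncating": 1 if mode == 2 else 0,
                "n_common_missense": 0,
            }
            if mode == 2 and spec[gene]["n_truncating"] > 0:
                spec[gene]["n_truncating"] = 0
            if mode == 2 and spec[gene]["n_missense"] > 0:
                # keep the gene failing: rare missense alone is not enough
                pass
    return spec


def gen_variant_cohort(
    n_genes: int = 400,
    burden_spec: Mapping[str, Mapping[str, int]] | None = None,
    seed: int = 0,
    n_patients: int = 135,
) -> tuple[pd.DataFrame, TruthManifest]:
    """Simulate a cohort variant table with a known burden shortlist.

    ``burden_spec`` maps each gene to its variant composition: counts of
    rare truncating (``n_truncating``), rare missense (``n_missense``),
    rare synonymous/other (``n_other``) and common (>1% AF) variants
    (``n_common_truncating``/``n_common_missense``).  Without a spec, a
    random composition is drawn per gene.  Rare AFs are log-uniform in
    [1e-4, 1e-2]; common AFs uniform in (0.011, 0.2).  The manifest lists
    exactly the genes whose rare composition satisfies the burden rule
    (>=1 truncating and >=1 missense at AF <= 1%).
    """
    rng = np.random.default_rng(seed)
    if burden_spec is None:
        burden_spec = {}
        for i in range(n_genes):
            burden_spec[f"GENE{i + 1:04d}"] = {
                "n_truncating": int(rng.poisson(0.6)),
                "n_missense": int(rng.poisson(1.2)),
                "n_other": int(rng.poisson(0.8)),
                "n_common_truncating": int(rng.random() < 0.1),
                "n_common_missense": int(rng.random() < 0.15),
            }
    rows: list[dict] = []
    shortlist: list[str] = []
    for gene in burden_spec:
        comp = burden_spec[gene]
        for key in comp:
            if comp[key] < 0:
                raise ParameterError(f"{gene}: negative count for {key}")
        def _add(n: int, consequence_pool: Sequence[str], common: bool) -> None:
            for _ in range(n):
                consequence = str(rng.choice(consequence_pool))
                af = (
                    float(rng.uniform(0.011, 0.2))
                    if common
                    else float(10 ** rng.uniform(-4, -2))
                )
                rows.append(
                    {
                        "patient_id": f"PT{rng.integers(1, n_patients + 1):04d}",
                        "gene": gene,
                        "consequence": consequence,
                        "population_af": af,
                    }
                )
        _add(comp.get("n_truncating", 0), ("nonsense", "frameshift"), common=False)
        _add(comp.get("n_missense", 0), ("missense",), common=False)
        _add(comp.get("n_other", 0), ("synonymous", "other"), common=False)
        _add(comp.get("n_common_truncating", 0), ("nonsense", "frameshift"), common=True)
        _add(comp.get("n_common_missense", 0), ("missense",), common=True)
        if comp.get("n_truncating", 0) >= 1 and comp.get("n_missense", 0) >= 1:
            shortlist.append(gene)
    table = pd.DataFrame(
        rows, columns=["patient_id", "gene", "consequence", "population_af"]
    )
    if len(table):
        table = table.sample(frac=1.0, random_state=np.random.RandomState(seed)).reset_index(
            drop=True
        )
    manifest = TruthManifest(seed=seed, planted_shortlist_genes=sorted(shortlist))
    return table, manifest


# ---------------------------------------------------------------------------
# CRISPR-Select amplicon generator
# ---------------------------------------------------------------------------

@dataclass
class SelectSimParams:
    """Conditions of a simulated CRISPR-Select-TIME experiment.

    Knock-in fractions default to similar frequencies for the variant and
    WT' alleles (the assay designs its repair templates for that); sampling
    days default to the assay's day-2 / day-12 schedule.  The variant
    lineage grows or declines deterministically as ``exp(s * day)`` with
    ``s = selection_per_day``; the WT' and unedited lineages are neutral.
    """

    knockin_fraction_variant: float = 0.10
    knockin_fraction_wt_prime: float = 0.10
    selection_per_day: float = 0.0
    days: tuple[float, float] = (2.0, 12.0)
    depth_per_timepoint: int = 5000
    error_rate: float = 0.0
    read_length: int = 150
    motif_offset: int = 60
    variant_motif: str = "TGTTGACT"
    wt_prime_motif: str = "TGTCGACT"
    wt_motif: str = "TGTAGACT"
    seed: int = 0

    def __post_init__(self) -> None:
        fv, fw = self.knockin_fraction_variant, self.knockin_fraction_wt_prime
        if not (0 < fv < 1 and 0 < fw < 1 and fv + fw < 1):
            raise ParameterError(
                "knock-in fractions must be in (0, 1) and sum with the "
                "unedited fraction to 1"
            )
        if len(self.days) < 2 or any(
            b <= a for a, b in zip(self.days, self.days[1:])
        ):
            raise ParameterError("days must be strictly increasing")
        if self.depth_per_timepoint <= 0:
            raise ParameterError("depth_per_timepoint must be > 0")
        if not 0 <= self.error_rate < 1:
            raise ParameterError("error_rate must be in [0, 1)")
        motifs = (self.variant_motif, self.wt_prime_motif, self.wt_motif)
        if len({len(m) for m in motifs}) != 1 or len(set(motifs)) != 3:
            raise ParameterError("the three motifs must be equal-length and distinct")
        if self.motif_offset + len(self.variant_motif) > self.read_length:
            raise ParameterError("motif does not fit in the read")

    @property
    def signature(self) -> AlleleSignature:
        return AlleleSignature(
            variant_motif=self.variant_motif,
            wt_prime_motif=self.wt_prime_motif,
            offset=self.motif_offset,
        )


def expected_allele_fractions(params: SelectSimParams, day: float) -> np.ndarray:
    """(variant, WT', unedited) population fractions at ``day``."""
    fv, fw = params.knockin_fraction_variant, params.knockin_fraction_wt_prime
    weights = np.array(
        [fv * math.exp(params.selection_per_day * day), fw, 1.0 - fv - fw]
    )
    return weights / weights.sum()


def gen_amplicon_counts(
    params: SelectSimParams,
    rng: np.random.Generator | None = None,
) -> tuple[list[AlleleCounts], TruthManifest]:
    """Multinomial allele counts at each timepoint under the planted selection."""
    rng = rng or np.random.default_rng(params.seed)
    counts = []
    for day in params.days:
        draw = rng.multinomial(
            params.depth_per_timepoint, expected_allele_fractions(params, day)
        )
        counts.append(
            AlleleCounts(
                variant=int(draw[0]),
                wt_prime=int(draw[1]),
                other=int(draw[2]),
                timepoint_day=float(day),
            )
        )
    manifest = TruthManifest(
        seed=params.seed, variant_truth={"variant": params.selection_per_day}
    )
    return counts, manifest


_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _mutate(reads: np.ndarray, error_rate: float, rng: np.random.Generator) -> np.ndarray:
    """Apply uniform substitution errors to a (n_reads, read_len) byte array."""
    if error_rate == 0:
        return reads
    mask = rng.random(reads.shape) < error_rate
    n_err = int(mask.sum())
    if n_err:
        # substitute with a uniformly random base (may silently restore)
        reads[mask] = _BASES[rng.integers(0, 4, n_err)]
    return reads


def gen_amplicon_fastq(
    params: SelectSimParams,
    out_dir: str | Path,
) -> tuple[dict[float, Path], AlleleSignature, TruthManifest]:
    """FASTQ-mode amplicon simulation: one file per timepoint.

    Reads share a fixed random amplicon template; each read carries the
    variant, WT' or unedited (wild-type) diagnostic motif at the declared
    offset, in multinomial proportions identical to counts mode, then
    suffers uniform substitution errors at ``error_rate``.  Qualities are
    constant Phred+33 'I'.  With ``error_rate=0`` allele counting on the
    emitted reads reproduces the multinomial draw exactly.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    # read synthesis uses its own stream so the allele draw is identical to
    # counts mode at the same seed (count-lossless round trip)
    rng = np.random.default_rng((params.seed, 1))
    template = _BASES[rng.integers(0, 4, params.read_length)].copy()
    counts, manifest = gen_amplicon_counts(params)

    files: dict[float, Path] = {}
    L = len(params.variant_motif)
    motif_arrays = {
        name: np.frombuffer(motif.encode(), dtype="S1")
        for name, motif in (
            ("variant", params.variant_motif),
            ("wt_prime", params.wt_prime_motif),
            ("other", params.wt_motif),
        )
    }
    for ac in counts:
        n_total = ac.total
        reads = np.tile(template, (n_total, 1))
        labels = np.repeat(
            ["variant", "wt_prime", "other"], [ac.variant, ac.wt_prime, ac.other]
        )
        order = rng.permutation(n_total)
        labels = labels[order]
        for name, arr in motif_arrays.items():
            reads[labels == name, params.motif_offset: params.motif_offset + L] = arr
        reads = _mutate(reads, params.error_rate, rng)
        path = out_dir / f"timepoint_day{ac.timepoint_day:g}.fastq"
        qual = "I" * params.read_length
        with open(path, "w") as fh:
            for i in range(n_total):
                seq = reads[i].tobytes().decode()
                fh.write(f"@read{i + 1} day={ac.timepoint_day:g}\n{seq}\n+\n{qual}\n")
        files[float(ac.timepoint_day)] = path
    return files, params.signature, manifest


def gen_amplicon_data(
    params: SelectSimParams,
    mode: str = "counts",
    out_dir: str | Path | None = None,
):
    """Dispatch to counts-mode or FASTQ-mode amplicon simulation."""
    if mode == "counts":
        return gen_amplicon_counts(params)
    if mode == "fastq":
        if out_dir is None:
            raise ParameterError("fastq mode needs out_dir")
        return gen_amplicon_fastq(params, out_dir)
    raise ParameterError(f"mode must be 'counts' or 'fastq', got {mode!r}")


# ---------------------------------------------------------------------------
# multi-omic cohort generator
# ---------------------------------------------------------------------------

DEFAULT_LABEL_MIX = {
    "brca1_variant_loh": 0.015,
    "brca1_homdel": 0.005,
    "brca1_methylation": 0.012,
    "brca2_variant_loh": 0.022,
    "brca2_homdel": 0.008,
}

_IHC_CHOICES = ("Positive", "Negative", "")
_IHC_PROBS = {"ihc_er": (0.70, 0.25, 0.05), "ihc_pr": (0.60, 0.35, 0.05),
              "ihc_her2": (0.20, 0.75, 0.05)}


def gen_omics_cohort(
    n_patients: int = 1000,
    label_mix: Mapping[str, float] | None = None,
    seed: int = 0,
    boundary_cases: bool = True,
) -> tuple[pd.DataFrame, TruthManifest]:
    """Simulate a patient multi-omic table with planted deficiency labels.

    ``label_mix`` gives the fraction of patients deficient through each
    mechanism (pathogenic variant + LOH, homozygous deletion, or — BRCA1
    only — promoter methylation with suppressed expression); the remainder
    are intact.  Mechanism fractions reflect the BRCA-deficiency prevalence
    seen in large sporadic breast-cancer cohorts (a few percent per gene).
    With ``boundary_cases=True`` the first planted-methylation patient sits
    exactly on the β = 0.25 / z = −2 rule boundary and three patients pin
    the G6PC3 expression-group boundaries (z = −2, 2) and a missing z.

    The manifest maps each patient to ``<deficiency>|<g6pc3 group>``.
    """
    label_mix = dict(DEFAULT_LABEL_MIX if label_mix is None else label_mix)
    unknown = set(label_mix) - set(DEFAULT_LABEL_MIX)
    if unknown:
        raise ParameterError(f"unknown label_mix mechanisms: {sorted(unknown)}")
    if any(v < 0 for v in label_mix.values()) or sum(label_mix.values()) > 1:
        raise ParameterError("label_mix fractions must be >= 0 and sum to <= 1")
    rng = np.random.default_rng(seed)

    mechanisms = list(label_mix)
    probs = [label_mix[m] for m in mechanisms] + [1.0 - sum(label_mix.values())]
    assignment = rng.choice(len(mechanisms) + 1, size=n_patients, p=probs)

    rows: list[dict] = []
    truth: dict[str, str] = {}
    first_methylation = True
    for i in range(n_patients):
        pid = f"PT{i + 1:05d}"
        mech = "intact" if assignment[i] == len(mechanisms) else mechanisms[assignment[i]]
        row = {
            "patient_id": pid,
            "brca1_pathogenic_germline": False,
            "brca1_pathogenic_somatic": False,
            "brca1_gistic": 0,
            "brca1_methylation_beta": float(rng.uniform(0.0, 0.24)),
            "brca1_expression_z": float(rng.normal(0.0, 1.0)),
            "brca2_pathogenic_germline": False,
            "brca2_pathogenic_somatic": False,
            "brca2_gistic": 0,
            "g6pc3_expression_z": float(rng.normal(0.0, 1.3)),
        }
        for col, p in _IHC_PROBS.items():
            row[col] = str(rng.choice(_IHC_CHOICES, p=p))

        if mech == "intact":
            # may carry non-qualifying lesions: a lone pathogenic variant
            # without LOH, or a lone hemizygous deletion
            gene = "brca1" if rng.random() < 0.5 else "brca2"
            lesion = rng.integers(0, 4)
            if lesion == 1:
                row[f"{gene}_pathogenic_germline"] = True
                row[f"{gene}_gistic"] = int(rng.choice([0, 1, 2]))
            elif lesion == 2:
                row[f"{gene}_gistic"] = -1
            label = "intact"
        elif mech.endswith("variant_loh"):
            gene = mech.split("_")[0]
            which = "germline" if rng.random() < 0.7 else "somatic"
            row[f"{gene}_pathogenic_{which}"] = True
            row[f"{gene}_gistic"] = -1
            label = f"{gene.upper()}-deficient"
        elif mech.endswith("homdel"):
            gene = mech.split("_")[0]
            row[f"{gene}_gistic"] = -2
            label = f"{gene.upper()}-deficient"
        else:  # brca1_methylation
            if boundary_cases and first_methylation:
                row["brca1_methylation_beta"] = 0.25
                row["brca1_expression_z"] = -2.0
                first_methylation = False
            else:
                row["brca1_methylation_beta"] = float(rng.uniform(0.25, 0.8))
                row["brca1_expression_z"] = float(rng.uniform(-4.0, -2.0))
            label = "BRCA1-deficient"

        rows.append(row)
        g6_group = (
            "low" if row["g6pc3_expression_z"] <= -2
            else "high" if row["g6pc3_expression_z"] >= 2
            else "normal"
        )
        truth[pid] = f"{label}|{g6_group}"

    table = pd.DataFrame(rows)
    if boundary_cases and n_patients >= 4:
        intact_idx = [i for i in range(n_patients) if truth[f"PT{i + 1:05d}"].startswith("intact")]
        pins = [(-2.0, "low"), (2.0, "high"), (float("nan"), "unclassified")]
        for idx, (zval, group) in zip(intact_idx[:3], pins):
            pid = f"PT{idx + 1:05d}"
            table.loc[idx, "g6pc3_expression_z"] = zval
            truth[pid] = truth[pid].split("|")[0] + f"|{group}"
    # truth uses the same partition for g6pc3 groups as the classifier rule;
    # "unclassified" marks a missing z
    for i in range(n_patients):
        pid = f"PT{i + 1:05d}"
        if math.isnan(table.loc[i, "g6pc3_expression_z"]):
            truth[pid] = truth[pid].split("|")[0] + "|unclassified"
    manifest = TruthManifest(seed=seed, patient_truth=truth)
    return table, manifest
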