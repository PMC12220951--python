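"""CRISPR-Select-TIME variant fitness analysis.

The assay knocks a variant of interest and a nearby synonymous control
allele (WT') into the same cell pool; both are read out by amplicon
sequencing at an early (day 2) and a late (day 12) timepoint.  Because the
WT' lineage is neutral by design, the change in the variant/WT' allele
ratio between timepoints isolates the fitness effect of the variant:

    FC   = (variant_late / WT'_late) / (variant_early / WT'_early)
    s    = ln(FC) / delta_t          # per-day selection coefficient

A variant that reduces fitness depletes (FC < 1, s < 0).  Significance is
assessed with a two-sided Fisher exact test on the 2x2 table
[variant, WT'] x [early, late].

The two-sided Fisher p-value is computed by an in-package routine that
enumerates the hypergeometric support once per margin class (the pmf comes
from :mod:`scipy.stats`), which makes grid-scale evaluation practical; its
tie handling mirrors ``scipy.stats.fisher_exact``.
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError, ValidationError

def _tie_rel_tol(total: int) -> float:
    """Relative tolerance treating two pmf values as tied.

    Serves the same purpose as the 1e-14 gate in scipy.stats.fisher_exact,
    but scales with the table total because the betaln-based pmf used here
    loses relative precision roughly linearly in the magnitude of the
    log-factorials being cancelled.  Mathematically distinct pmf ratios in a
    2x2 margin class are never this close to 1, so the gate only ever
    captures true ties.
    """
    return max(10, total) * 1e-14

__all__ = [
    "AlleleSignature",
    "AlleleCounts",
    "FitnessResult",
    "count_alleles",
    "fisher_support_pvalues",
    "fisher_exact_two_sided",
    "fitness_stats",
    "classify_variant",
    "combine_replicates",
    "SelectExperiment",
    "SelectResults",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AlleleSignature:
    """Diagnostic motifs distinguishing the knock-in alleles in a read.

    ``variant_motif`` and ``wt_prime_motif`` are equal-length nucleotide
    strings expected at ``offset`` (0-based) in every read; by assay design
    they differ at one or more positions (the variant and the synonymous WT'
    marker sit within a few nucleotides of each other on the same ssODN).
    """

    variant_motif: str
    wt_prime_motif: str
    offset: int = 0
    read_orientation: str = "forward"  # or "reverse-complement-allowed"

    def __post_init__(self) -> None:
        v, w = self.variant_motif.upper(), self.wt_prime_motif.upper()
        if not v or not w:
            raise ValidationError("motifs must be non-empty")
        if len(v) != len(w):
            raise ValidationError("motifs must have equal length")
        if v == w:
            raise ValidationError("motifs must differ at >=1 position")
        if self.offset < 0:
            raise ValidationError("offset must be >= 0")
        if self.read_orientation not in ("forward", "reverse-complement-allowed"):
            raise ValidationError(f"bad read_orientation {self.read_orientation!r}")
        object.__setattr__(self, "variant_motif", v)
        object.__setattr__(self, "wt_prime_motif", w)

    @property
    def discriminating_positions(self) -> tuple[int, ...]:
        return tuple(
            i for i, (a, b) in enumerate(zip(self.variant_motif, self.wt_prime_motif))
            if a != b
        )


@dataclass
class AlleleCounts:
    """Variant / WT' / other read tallies for one timepoint of one variant."""

    variant: int
    wt_prime: int
    other: int = 0
    timepoint_day: float | None = None
    replicate: str = "rep1"

    def __post_init__(self) -> None:
        if min(self.variant, self.wt_prime, self.other) < 0:
            raise ValidationError("allele counts must be >= 0")

    @property
    def total(self) -> int:
        return self.variant + self.wt_prime + self.other


@dataclass
class FitnessResult:
    """Fitness estimate for one variant between two timepoints."""

    ratio_early: float
    ratio_late: float
    fc: float
    log_fc: float
    se_log_fc: float
    delta_t: float
    s: float
    p: float
    classification: str = "neutral"
    replicate: str = "rep1"
    pseudocount: float = 0.0

    @property
    def s_ci(self) -> tuple[float, float]:
        """95% Wald confidence interval for the per-day selection coefficient."""
        half = 1.959963984540054 * self.se_log_fc / self.delta_t
        return (self.s - half, self.s + half)


# ---------------------------------------------------------------------------
# allele counting
# ---------------------------------------------------------------------------

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _iter_sequences(reads, parse_errors: bool) -> Iterable[str]:
    if isinstance(reads, (str, Path)):
        path = Path(reads)
        opener = gzip.open if path.suffix == ".gz" else open
        from Bio import SeqIO

        with opener(path, "rt") as handle:
            try:
                for rec in SeqIO.parse(handle, "fastq"):
                    yield str(rec.seq)
            except ValueError as exc:  # malformed record
                raise ValidationError(f"{path}: FASTQ parse error: {exc}") from exc
    else:
        for seq in reads:
            yield str(seq)


def _classify_read(seq: str, sig: AlleleSignature, max_mismatches: int) -> str:
    window = seq[sig.offset: sig.offset + len(sig.variant_motif)].upper()
    if len(window) < len(sig.variant_motif):
        return "other"
    if max_mismatches == 0:
        if window == sig.variant_motif:
            return "variant"
        if window == sig.wt_prime_motif:
            return "wt_prime"
        return "other"
    disc = sig.discriminating_positions
    # discriminating bases must match one allele exactly; tolerance applies
    # only outside them so mismatches can never bridge the two alleles
    for name, motif in (("variant", sig.variant_motif), ("wt_prime", sig.wt_prime_motif)):
        if any(window[i] != motif[i] for i in disc):
            continue
        mismatches = sum(
            1 for i, (x, y) in enumerate(zip(window, motif))
            if i not in disc and x != y
        )
        if mismatches <= max_mismatches:
            return name
    return "other"


def count_alleles(
    reads,
    signature: AlleleSignature,
    max_mismatches: int = 0,
    timepoint_day: float | None = None,
    replicate: str = "rep1",
) -> AlleleCounts:
    """Assign each read to exactly one of {variant, WT', other}.

    ``reads`` may be a FASTQ path (gzip-transparent) or any iterable of
    sequence strings.  A read is called for an allele by exact match of the
    diagnostic motif at the declared offset (optionally tolerating
    ``max_mismatches`` substitutions outside the discriminating positions);
    anything else — including reads carrying the unedited allele — counts as
    ``other``.  With ``read_orientation="reverse-complement-allowed"`` a read
    that fails in forward orientation is retried reverse-complemented.
    """
    if max_mismatches < 0:
        raise ParameterError("max_mismatches must be >= 0")
    tallies = {"variant": 0, "wt_prime": 0, "other": 0}
    allow_rc = signature.read_orientation == "reverse-complement-allowed"
    for seq in _iter_sequences(reads, parse_errors=True):
        call = _classify_read(seq, signature, max_mismatches)
        if call == "other" and allow_rc:
            call = _classify_read(_revcomp(seq), signature, max_mismatches)
        tallies[call] += 1
    return AlleleCounts(
        variant=tallies["variant"],
        wt_prime=tallies["wt_prime"],
        other=tallies["other"],
        timepoint_day=timepoint_day,
        replicate=replicate,
    )


# ---------------------------------------------------------------------------
# two-sided Fisher exact test
# ---------------------------------------------------------------------------

def _hypergeom_logpmf(k: np.ndarray, total: int, good: int, draws: int) -> np.ndarray:
    """Hypergeometric log-pmf via the betaln identity (vectorized over k).

    Same formula as scipy's hypergeom, so exact pmf ties (common in
    symmetric tables) are reproduced bit-for-bit without per-call
    distribution overhead.
    """
    from scipy.special import betaln

    bad = total - good
    return (
        betaln(good + 1, 1) + betaln(bad + 1, 1) + betaln(total - draws + 1, draws + 1)
        - betaln(k + 1, good - k + 1) - betaln(draws - k + 1, bad - draws + k + 1)
        - betaln(total + 1, 1)
    )


def fisher_support_pvalues(total: int, row1: int, col1: int):
    """Two-sided Fisher p for every table in one margin class.

    All 2x2 tables sharing margins (``total`` grand total, ``row1`` first-row
    sum, ``col1`` first-column sum) are indexed by their upper-left cell
    ``a``, which ranges over the hypergeometric support.  Returns
    ``(support, pvalues)`` where ``pvalues[i]`` is the two-sided p-value of
    the table with ``a = support[i]``: the total probability of tables whose
    pmf does not exceed that of the observed table (relative tie gate
    ``1 + 1e-14``, and a table whose pmf ties the modal pmf gets p = 1,
    mirroring ``scipy.stats.fisher_exact``).  Computing a whole margin class
    at once makes exhaustive evaluation over count grids practical.
    """
    if not (0 <= row1 <= total and 0 <= col1 <= total):
        raise ParameterError("margins out of range")
    lo = max(0, row1 + col1 - total)
    hi = min(row1, col1)
    support = np.arange(lo, hi + 1)
    if row1 == 0 or col1 == 0 or row1 == total or col1 == total:
        # a zero row or column margin: the table is degenerate, p = 1
        return support, np.ones_like(support, dtype=float)
    rel = _tie_rel_tol(total)
    pmf = np.exp(_hypergeom_logpmf(support, total, row1, col1))
    order = np.argsort(pmf, kind="stable")
    sorted_pmf = pmf[order]
    cum = np.cumsum(sorted_pmf)
    idx = np.searchsorted(sorted_pmf, pmf * (1.0 + rel), side="right")
    pvals = np.minimum(cum[idx - 1], 1.0)
    # modal-tie rule: a pmf tied with the modal pmf -> p = 1
    mode = int((col1 + 1) * (row1 + 1) / (total + 2))
    pmode = pmf[min(max(mode - lo, 0), len(pmf) - 1)]
    tie = np.abs(pmf - pmode) <= rel * np.maximum(pmf, pmode)
    pvals[tie] = 1.0
    return support, pvals


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the table [[a, b], [c, d]]."""
    if min(a, b, c, d) < 0:
        raise ValidationError("table cells must be >= 0")
    total = a + b + c + d
    if total == 0:
        return 1.0
    support, pvals = fisher_support_pvalues(total, a + b, a + c)
    return float(pvals[a - support[0]])


# ---------------------------------------------------------------------------
# fitness statistics
# ---------------------------------------------------------------------------

def fitness_stats(
    early: AlleleCounts,
    late: AlleleCounts,
    alpha: float = 0.05,
    delta_t: float | None = None,
) -> FitnessResult:
    """Fitness of a variant from its variant/WT' ratios at two timepoints.

    The fold change ``FC = ratio_late / ratio_early`` and its log-scale
    standard error ``sqrt(1/a + 1/b + 1/c + 1/d)`` are computed on the four
    variant/WT' cells, with a Haldane–Anscombe pseudocount of 0.5 added to
    all four cells when any of them is zero.  The p-value is a two-sided
    Fisher exact test on the raw (integer) 2x2 table, and
    ``s = ln(FC) / delta_t`` is the per-day selection coefficient.
    """
    if early.variant + early.wt_prime == 0 or late.variant + late.wt_prime == 0:
        raise ValidationError("each timepoint needs at least one variant or WT' read")
    if delta_t is None:
        if early.timepoint_day is None or late.timepoint_day is None:
            raise ParameterError("delta_t or timepoint_day on both counts required")
        delta_t = late.timepoint_day - early.timepoint_day
    if delta_t <= 0:
        raise ParameterError(f"delta_t must be > 0, got {delta_t}")

    cells = np.array([early.variant, late.variant, early.wt_prime, late.wt_prime], float)
    pseudo = 0.5 if (cells == 0).any() else 0.0
    a, b, c, d = cells + pseudo
    ratio_early = a / c
    ratio_late = b / d
    fc = ratio_late / ratio_early
    log_fc = math.log(fc)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    p = fisher_exact_two_sided(
        early.variant, late.variant, early.wt_prime, late.wt_prime
    )
    result = FitnessResult(
        ratio_early=ratio_early,
        ratio_late=ratio_late,
        fc=fc,
        log_fc=log_fc,
        se_log_fc=se,
        delta_t=delta_t,
        s=log_fc / delta_t,
        p=p,
        replicate=early.replicate,
        pseudocount=pseudo,
    )
    result.classification = classify_variant(result, alpha=alpha)
    return result


def classify_variant(result: FitnessResult, alpha: float = 0.05) -> str:
    """Call a variant depleted / neutral / enriched.

    Depleted if FC < 1 with p < alpha (loss of fitness), enriched if FC > 1
    with p < alpha, neutral otherwise.
    """
    if not 0 < alpha < 1:
        raise ParameterError("alpha must be in (0, 1)")
    if result.p < alpha and result.fc < 1:
        return "depleted"
    if result.p < alpha and result.fc > 1:
        return "enriched"
    return "neutral"


def normal_log_ratio_test(early: AlleleCounts, late: AlleleCounts) -> float:
    """Two-sided normal-approximation p on the log fold change (alternative test)."""
    cells = np.array([early.variant, late.variant, early.wt_prime, late.wt_prime], float)
    if (cells == 0).any():
        cells = cells + 0.5
    a, b, c, d = cells
    z = math.log((b / d) / (a / c)) / math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return 2 * stats.norm.sf(abs(z))


def combine_replicates(results: Sequence[FitnessResult], alpha: float = 0.05) -> FitnessResult:
    """Fixed-effect (inverse-variance) combination of per-replicate estimates."""
    if not results:
        raise ParameterError("no replicate results to combine")
    delta_ts = {r.delta_t for r in results}
    if len(delta_ts) > 1:
        raise ParameterError("replicates must share delta_t for a combined estimate")
    delta_t = delta_ts.pop()
    w = np.array([1 / r.se_log_fc**2 for r in results])
    lfc = np.array([r.log_fc for r in results])
    log_fc = float((w * lfc).sum() / w.sum())
    se = float(1 / math.sqrt(w.sum()))
    z = log_fc / se
    p = float(2 * stats.norm.sf(abs(z)))
    combined = FitnessResult(
        ratio_early=float("nan"),
        ratio_late=float("nan"),
        fc=math.exp(log_fc),
        log_fc=log_fc,
        se_log_fc=se,
        delta_t=delta_t,
        s=log_fc / delta_t,
        p=p,
        replicate="combined",
    )
    combined.classification = classify_variant(combined, alpha=alpha)
    return combined


# ---------------------------------------------------------------------------
# model / results wrappers
# ---------------------------------------------------------------------------

class SelectExperiment:
    """A CRISPR-Select time-course over one or more variants and replicates.

    Parameters
    ----------
    counts
        Long-format table with columns ``variant, wt_prime, other,
        timepoint_day, replicate`` and optionally ``variant_id`` (defaults to
        a single variant).  Exactly two timepoints per (variant_id,
        replicate) are analyzed: the earliest and the latest day.
    """

    REQUIRED = ("variant", "wt_prime", "other", "timepoint_day", "replicate")

    def __init__(self, counts: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in counts.columns]
        if missing:
            raise ValidationError(f"counts table missing columns: {missing}")
        counts = counts.copy()
        if "variant_id" not in counts.columns:
            counts["variant_id"] = "variant"
        self.counts = counts

    @classmethod
    def from_fastq(
        cls,
        files: dict[float, str] | dict[float, Path],
        signature: AlleleSignature,
        replicate: str = "rep1",
        variant_id: str = "variant",
        max_mismatches: int = 0,
    ) -> "SelectExperiment":
        """Build the counts table by counting alleles in per-timepoint FASTQs."""
        rows = []
        for day, path in sorted(files.items()):
            ac = count_alleles(
                path, signature, max_mismatches=max_mismatches,
                timepoint_day=day, replicate=replicate,
            )
            rows.append(
                {
                    "variant_id": variant_id,
                    "variant": ac.variant,
                    "wt_prime": ac.wt_prime,
                    "other": ac.other,
                    "timepoint_day": day,
                    "replicate": replicate,
                }
            )
        return cls(pd.DataFrame(rows))

    def fit(self, alpha: float = 0.05) -> "SelectResults":
        per_rep: list[dict] = []
        combined: list[dict] = []
        for vid, vgroup in self.counts.groupby("variant_id", sort=True):
            rep_results = []
            for rep, rgroup in vgroup.groupby("replicate", sort=True):
                rgroup = rgroup.sort_values("timepoint_day")
                if rgroup["timepoint_day"].nunique() < 2:
                    raise ValidationError(
                        f"variant {vid!r} replicate {rep!r}: need >=2 timepoints"
                    )
                first, last = rgroup.iloc[0], rgroup.iloc[-1]
                res = fitness_stats(
                    AlleleCounts(int(first["variant"]), int(first["wt_prime"]),
                                 int(first["other"]), float(first["timepoint_day"]),
                                 str(rep)),
                    AlleleCounts(int(last["variant"]), int(last["wt_prime"]),
                                 int(last["other"]), float(last["timepoint_day"]),
                                 str(rep)),
                    alpha=alpha,
                )
                rep_results.append(res)
                per_rep.append({"variant_id": vid, **_result_row(res)})
            comb = rep_results[0] if len(rep_results) == 1 else combine_replicates(
                rep_results, alpha=alpha
            )
            combined.append({"variant_id": vid, **_result_row(comb)})
        return SelectResults(
            pd.DataFrame(per_rep), pd.DataFrame(combined), alpha=alpha
        )


def _result_row(r: FitnessResult) -> dict:
    lo, hi = r.s_ci
    return {
        "replicate": r.replicate,
        "ratio_early": r.ratio_early,
        "ratio_late": r.ratio_late,
        "fc": r.fc,
        "log_fc": r.log_fc,
        "se_log_fc": r.se_log_fc,
        "delta_t": r.delta_t,
        "s": r.s,
        "s_ci_low": lo,
        "s_ci_high": hi,
        "p": r.p,
        "classification": r.classification,
    }


@dataclass
class SelectResults:
    """Per-replicate and combined fitness estimates for a SelectExperiment."""

    per_replicate: pd.DataFrame
    combined: pd.DataFrame
    alpha: float = 0.05

    def summary(self) -> str:
        lines = [
            "CRISPR-Select fitness results",
            f"alpha = {self.alpha}",
            "",
            "variant        FC      s/day   95% CI              p         call",
        ]
        for _, row in self.combined.iterrows():
            lines.append(
                f"{row['variant_id']:<12} {row['fc']:>7.3f} {row['s']:>8.4f} "
                f"[{row['s_ci_low']:+.4f}, {row['s_ci_high']:+.4f}] "
                f"{row['p']:>9.3g}  {row['classification']}"
            )
        return "\n".join(lines)
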