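"""Per-gene siRNA screen statistics and consensus hit calling.

The screen measures, per well, the percentage of marker-positive cells
(γH2AX or micronuclei) in two cell lines, giving four phenotypic readouts
per gene.  Scoring proceeds per readout:

* wells are normalized to the median of same-plate negative-control wells
  (removing plate-to-plate multiplicative bias),
* the gene-level raw score X is the mean normalized value over the gene's
  siRNA wells (3 per gene in the screened library),
* ``z = (X - mu) / sigma`` where mu and sigma are the mean and population
  standard deviation of X over all genes in the readout,
* SSMD (strictly standardized mean difference) per gene,
  ``(mean_gene - mean_control) / sqrt(var_gene + var_control)`` with sample
  variances (method of moments),
* a one-sided Welch t-test of the gene's wells against the readout's
  negative-control wells yields p; a gene scores in a readout when
  ``p < alpha`` and ``z >= z_min``.

A gene is a consensus hit when it scores in at least ``min_readouts``
(default 3) of the configured readouts.

:class:`ScreenScoring` wraps the whole chain as a model object whose
``fit()`` returns a :class:`ScreenResults` with the per-gene score table,
hit calls and a text summary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError, ValidationError

CONTROL_TAG = "NEG_CTRL"

DEFAULT_READOUTS = (
    ("gH2AX", "U2OS"),
    ("gH2AX", "MCF10A"),
    ("micronuclei", "U2OS"),
    ("micronuclei", "MCF10A"),
)


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def normalize_wells(
    wells: pd.DataFrame,
    value_col: str,
    control_tag: str = CONTROL_TAG,
    min_controls: int = 4,
) -> pd.DataFrame:
    """Divide each well's value by the median of same-plate control wells.

    Adds ``<value_col>_norm`` (raw values stay untouched).  A plate whose
    control median is 0 cannot be scaled; it falls back to additive
    centering (value minus control median) with a warning and is flagged in
    the ``norm_method`` column.
    """
    for col in ("plate", "gene", value_col):
        if col not in wells.columns:
            raise ValidationError(f"well table missing column {col!r}")
    out = wells.copy()
    out[f"{value_col}_norm"] = np.nan
    out["norm_method"] = ""
    for plate, group in out.groupby("plate", sort=False):
        controls = group.loc[group["gene"] == control_tag, value_col]
        if len(controls) < min_controls:
            raise ParameterError(
                f"plate {plate!r}: {len(controls)} control wells, need >= {min_controls}"
            )
        median = float(controls.median())
        idx = group.index
        if median == 0:
            warnings.warn(
                f"plate {plate!r}: control median is 0; falling back to "
                "additive centering",
                stacklevel=2,
            )
            out.loc[idx, f"{value_col}_norm"] = group[value_col] - median
            out.loc[idx, "norm_method"] = "additive"
        else:
            out.loc[idx, f"{value_col}_norm"] = group[value_col] / median
            out.loc[idx, "norm_method"] = "ratio"
    return out


def zscore_genes(gene_x: pd.Series, ddof: int = 0) -> pd.Series:
    """z = (X - mu)/sigma over the gene-level raw scores of one readout.

    mu and sigma are computed over all genes in the readout; sigma is the
    population SD by default (``ddof=0``).
    """
    x = gene_x.to_numpy(dtype=float)
    if len(x) < 2:
        raise ParameterError("need >= 2 genes to compute z-scores")
    sigma = x.std(ddof=ddof)
    if sigma == 0:
        raise ParameterError("zero variance across genes; z undefined")
    return pd.Series((x - x.mean()) / sigma, index=gene_x.index, name="z")


def ssmd(gene_values: np.ndarray, control_values: np.ndarray) -> float:
    """Method-of-moments SSMD of one gene's wells against control wells.

    ``(mean_g - mean_c) / sqrt(var_g + var_c)`` with sample variances
    (ddof=1).  When both variances are 0: 0 if the means agree, otherwise a
    signed infinity.
    """
    g = np.asarray(gene_values, dtype=float)
    c = np.asarray(control_values, dtype=float)
    if len(g) < 2 or len(c) < 2:
        raise ParameterError("need >= 2 gene values and >= 2 control values")
    diff = g.mean() - c.mean()
    denom = g.var(ddof=1) + c.var(ddof=1)
    if denom == 0:
        return 0.0 if diff == 0 else float(np.sign(diff) * np.inf)
    return float(diff / np.sqrt(denom))


def ssmd_genes(
    gene_values: dict[str, np.ndarray] | pd.core.groupby.SeriesGroupBy,
    control_values: np.ndarray,
) -> pd.Series:
    """SSMD per gene against a common set of control wells."""
    if not isinstance(gene_values, dict):
        gene_values = {k: v.to_numpy() for k, v in gene_values}
    return pd.Series(
        {gene: ssmd(vals, control_values) for gene, vals in gene_values.items()},
        name="ssmd",
    )


def readout_significance(
    gene_values: np.ndarray,
    control_values: np.ndarray,
    alpha: float = 0.05,
    z: float | None = None,
    z_min: float = 2.0,
    alternative: str = "greater",
    method: str = "welch",
    permutation_resamples: int = 9999,
    rng: np.random.Generator | None = None,
) -> tuple[float, bool]:
    """(p, significant) for one gene in one readout.

    p compares the gene's siRNA well values to the readout's negative-control
    wells: Welch's unequal-variance t-test by default, one-sided for
    increases (the screen looks for elevated marker levels), or a
    permutation test on the difference of means (``method="permutation"``).
    The gene scores when ``p < alpha`` and, if a z-score is supplied,
    ``z >= z_min``.  Degenerate inputs yield ``(nan, False)``.
    """
    g = np.asarray(gene_values, dtype=float)
    c = np.asarray(control_values, dtype=float)
    if len(g) < 2 or len(c) < 2:
        raise ParameterError("need >= 2 gene values and >= 2 control values")
    if g.std(ddof=1) == 0 and c.std(ddof=1) == 0:
        return float("nan"), False
    if method == "welch":
        with warnings.catch_warnings():
            # near-identical samples trigger scipy's catastrophic-cancellation
            # warning; the resulting large p is the correct answer here
            warnings.simplefilter("ignore", RuntimeWarning)
            p = float(stats.ttest_ind(g, c, equal_var=False, alternative=alternative).pvalue)
    elif method == "permutation":
        res = stats.permutation_test(
            (g, c),
            lambda a, b, axis=-1: a.mean(axis=axis) - b.mean(axis=axis),
            alternative=alternative,
            n_resamples=permutation_resamples,
            vectorized=True,
            rng=rng,
        )
        p = float(res.pvalue)
    else:
        raise ParameterError(f"unknown method {method!r}")
    if np.isnan(p):
        return float("nan"), False
    significant = p < alpha and (z is None or z >= z_min)
    return p, bool(significant)


def consensus_hits(flags: pd.DataFrame, min_readouts: int = 3) -> pd.DataFrame:
    """Consensus hit calls from a gene x readout significance flag table.

    ``flags`` is indexed by gene with one boolean column per readout.  A
    gene with a missing flag (NaN) is incomplete: it is excluded and listed
    in the ``incomplete`` attribute of the result.  Hits are genes
    significant in >= ``min_readouts`` readouts, ordered by the number of
    significant readouts (descending) then gene name (ascending).
    """
    if min_readouts < 1 or min_readouts > flags.shape[1]:
        raise ParameterError(
            f"min_readouts must be in [1, {flags.shape[1]}], got {min_readouts}"
        )
    complete = flags.dropna()
    incomplete = sorted(set(flags.index) - set(complete.index))
    n_significant = complete.astype(bool).sum(axis=1)
    out = pd.DataFrame(
        {
            "gene": complete.index,
            "n_significant": n_significant.to_numpy(dtype=int),
            "is_hit": (n_significant >= min_readouts).to_numpy(),
        }
    )
    out = out.sort_values(
        ["n_significant", "gene"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    out.attrs["incomplete"] = incomplete
    return out


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

class ScreenScoring:
    """Scoring model for a multi-readout arrayed siRNA screen.

    Parameters
    ----------
    wells
        Per-well table with columns ``plate, well, gene, sirna_id,
        cell_line`` and the two percent-positive columns
        ``pct_marker_pos`` / ``pct_micronuclei_pos`` (as produced by
        :func:`gmscreen.qibc.well_positive_fractions`); a ``marker`` column
        may already be present instead, in which case ``value_col`` names
        the single percent column.
    readouts
        The (marker, cell_line) pairs to score; defaults to the screen's
        four readouts (γH2AX and micronuclei in U2OS and MCF10A).
    """

    def __init__(
        self,
        wells: pd.DataFrame,
        readouts: tuple = DEFAULT_READOUTS,
        control_tag: str = CONTROL_TAG,
        alpha: float = 0.05,
        z_min: float = 2.0,
        min_readouts: int = 3,
        sd_ddof: int = 0,
        test_method: str = "welch",
        multiple_testing: str | None = None,
    ):
        if not 0 < alpha < 1:
            raise ParameterError("alpha must be in (0, 1)")
        if min_readouts < 1 or min_readouts > len(readouts):
            raise ParameterError(
                f"min_readouts must be in [1, {len(readouts)}], got {min_readouts}"
            )
        if multiple_testing not in (None, "bh"):
            raise ParameterError("multiple_testing must be None or 'bh'")
        self.wells = _to_long_readout_table(wells)
        self.readouts = tuple(readouts)
        self.control_tag = control_tag
        self.alpha = alpha
        self.z_min = z_min
        self.min_readouts = min_readouts
        self.sd_ddof = sd_ddof
        self.test_method = test_method
        self.multiple_testing = multiple_testing

    def fit(self) -> "ScreenResults":
        rows = []
        for marker, cell_line in self.readouts:
            sub = self.wells[
                (self.wells["marker"] == marker)
                & (self.wells["cell_line"] == cell_line)
            ]
            if sub.empty:
                raise ValidationError(f"no wells for readout {(marker, cell_line)}")
            sub = normalize_wells(sub, "pct_pos", control_tag=self.control_tag)
            controls = sub.loc[sub["gene"] == self.control_tag, "pct_pos_norm"].to_numpy()
            genes = sub[sub["gene"] != self.control_tag]
            gene_x = genes.groupby("gene", sort=True)["pct_pos_norm"].mean()
            z = zscore_genes(gene_x, ddof=self.sd_ddof)
            for gene, group in genes.groupby("gene", sort=True):
                values = group["pct_pos_norm"].to_numpy()
                gene_ssmd = ssmd(values, controls)
                p, significant = readout_significance(
                    values, controls,
                    alpha=self.alpha, z=float(z[gene]), z_min=self.z_min,
                    method=self.test_method,
                )
                rows.append(
                    {
                        "gene": gene,
                        "marker": marker,
                        "cell_line": cell_line,
                        "X": float(gene_x[gene]),
                        "mu": float(gene_x.mean()),
                        "sigma": float(gene_x.to_numpy().std(ddof=self.sd_ddof)),
                        "z": float(z[gene]),
                        "ssmd": gene_ssmd,
                        "p": p,
                        "significant": significant,
                    }
                )
        scores = pd.DataFrame(rows)
        if self.multiple_testing == "bh":
            for key, sub in scores.groupby(["marker", "cell_line"]):
                mask = sub["p"].notna()
                adj = stats.false_discovery_control(sub.loc[mask, "p"], method="bh")
                scores.loc[sub.index[mask], "p_adj"] = adj
            scores["significant"] = (scores["p_adj"] < self.alpha) & (
                scores["z"] >= self.z_min
            )
        flags = scores.pivot_table(
            index="gene",
            columns=["marker", "cell_line"],
            values="significant",
            aggfunc="first",
        )
        hits = consensus_hits(flags, min_readouts=self.min_readouts)
        return ScreenResults(
            scores=scores, hit_calls=hits, model=self,
        )


def _to_long_readout_table(wells: pd.DataFrame) -> pd.DataFrame:
    """Accept wide (pct_marker_pos / pct_micronuclei_pos) or long (marker, pct_pos)."""
    if "marker" in wells.columns and "pct_pos" in wells.columns:
        return wells.copy()
    needed = ("pct_marker_pos", "pct_micronuclei_pos", "cell_line")
    missing = [c for c in needed if c not in wells.columns]
    if missing:
        raise ValidationError(f"well table missing columns: {missing}")
    ident = [c for c in wells.columns if c not in ("pct_marker_pos", "pct_micronuclei_pos")]
    long = wells.melt(
        id_vars=ident,
        value_vars=["pct_marker_pos", "pct_micronuclei_pos"],
        var_name="marker",
        value_name="pct_pos",
    )
    long["marker"] = long["marker"].map(
        {"pct_marker_pos": "gH2AX", "pct_micronuclei_pos": "micronuclei"}
    )
    if "qc_pass" in long.columns:
        long = long[long["qc_pass"]]
    return long


@dataclass
class ScreenResults:
    """Fitted screen scores: per-gene per-readout statistics and hit calls."""

    scores: pd.DataFrame
    hit_calls: pd.DataFrame
    model: ScreenScoring | None = None

    @property
    def hits(self) -> list[str]:
        return self.hit_calls.loc[self.hit_calls["is_hit"], "gene"].tolist()

    def volcano_table(self) -> pd.DataFrame:
        """Volcano-plot-ready table: gene, readout, z and -log10 p."""
        out = self.scores[["gene", "marker", "cell_line", "z", "p"]].copy()
        with np.errstate(divide="ignore"):
            out["neg_log10_p"] = -np.log10(out["p"])
        return out

    def summary(self) -> str:
        n_genes = self.scores["gene"].nunique()
        n_readouts = self.scores.groupby(["marker", "cell_line"]).ngroups
        lines = [
            "Arrayed siRNA screen scoring",
            f"genes scored: {n_genes}   readouts: {n_readouts}",
            f"consensus hits (>= {self.model.min_readouts if self.model else '?'} readouts): "
            f"{len(self.hits)}",
            "",
            "gene            n_significant",
        ]
        for _, row in self.hit_calls[self.hit_calls["is_hit"]].iterrows():
            lines.append(f"{row['gene']:<16} {row['n_significant']}")
        return "\n".join(lines)
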