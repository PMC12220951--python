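"""Allele counting, Fisher exact inference and fitness classification."""

import math
import re
from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gmscreen import crispr_select as cs
from gmscreen import simulate
from gmscreen.errors import ParameterError, ValidationError

SIG = cs.AlleleSignature(variant_motif="TGTTGACT", wt_prime_motif="TGTCGACT", offset=4)


def exact_fisher_oracle(a, b, c, d):
    """Full hypergeometric enumeration in exact integer arithmetic."""
    n, r1, c1 = a + b + c + d, a + b, a + c
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    N = {x: comb(r1, x) * comb(n - r1, c1 - x) for x in range(lo, hi + 1)}
    denom = comb(n, c1)
    D = 10**14
    K = max(10, n)  # the implementation's total-scaled tie gate, exactly
    total = sum(v for x, v in N.items() if v * D <= N[a] * (D + K))
    mode = int((c1 + 1) * (r1 + 1) / (n + 2))
    mode = min(max(mode, lo), hi)
    if abs(N[a] - N[mode]) * D <= max(N[a], N[mode]) * K:
        return 1.0
    return min(float(Fraction(total, denom)), 1.0)


class TestSignature:
    def test_validation(self):
        with pytest.raises(ValidationError):
            cs.AlleleSignature("", "A")
        with pytest.raises(ValidationError):
            cs.AlleleSignature("AAA", "AA")
        with pytest.raises(ValidationError):
            cs.AlleleSignature("AAA", "AAA")
        with pytest.raises(ValidationError):
            cs.AlleleSignature("AAA", "AAT", offset=-1)

    def test_discriminating_positions(self):
        assert SIG.discriminating_positions == (3,)


class TestCountAlleles:
    def test_exact_match_assignment(self):
        reads = [
            "AAAA" + "TGTTGACT" + "CC",  # variant
            "AAAA" + "TGTCGACT" + "CC",  # wt'
            "AAAA" + "TGTAGACT" + "CC",  # unedited -> other
            "AAAA" + "TGTTGACA" + "CC",  # one substitution inside motif -> other
            "short",
        ]
        ac = cs.count_alleles(reads, SIG)
        assert (ac.variant, ac.wt_prime, ac.other) == (1, 1, 3)

    def test_mismatch_tolerance_never_bridges_alleles(self):
        # mismatch outside the discriminating base is forgiven at
        # max_mismatches=1; the discriminating base itself is not
        reads = ["AAAA" + "AGTTGACT" + "CC"]
        assert cs.count_alleles(reads, SIG).variant == 0
        assert cs.count_alleles(reads, SIG, max_mismatches=1).variant == 1
        bridge = ["AAAA" + "AGTCGACT" + "CC"]  # wt' base + 1 mismatch
        ac = cs.count_alleles(bridge, SIG, max_mismatches=1)
        assert ac.variant == 0 and ac.wt_prime == 1

    def test_reverse_complement_mode(self):
        fwd = "AAAA" + "TGTTGACT" + "CC"
        rc = fwd.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        sig_rc = cs.AlleleSignature(
            "TGTTGACT", "TGTCGACT", offset=4,
            read_orientation="reverse-complement-allowed",
        )
        assert cs.count_alleles([rc], SIG).variant == 0
        assert cs.count_alleles([rc], sig_rc).variant == 1

    def test_regex_oracle_equivalence(self, rng):
        """10,000 random reads: counting equals a regex-scan brute force."""
        bases = np.array(list("ACGT"))
        reads = []
        for _ in range(10000):
            read = "".join(rng.choice(bases, size=20))
            reads.append(read)
        ac = cs.count_alleles(reads, SIG)
        pat_v = re.compile("^.{4}" + SIG.variant_motif)
        pat_w = re.compile("^.{4}" + SIG.wt_prime_motif)
        n_v = sum(bool(pat_v.match(r)) for r in reads)
        n_w = sum(bool(pat_w.match(r)) for r in reads)
        assert ac.variant == n_v
        assert ac.wt_prime == n_w
        assert ac.other == 10000 - n_v - n_w

    def test_fastq_round_trip_lossless(self, tmp_path):
        """error_rate=0 FASTQ mode reproduces the multinomial draw exactly."""
        params = simulate.SelectSimParams(
            depth_per_timepoint=400, selection_per_day=-0.2, seed=5
        )
        files, signature, _ = simulate.gen_amplicon_data(
            params, mode="fastq", out_dir=tmp_path
        )
        counts, _ = simulate.gen_amplicon_data(params, mode="counts")
        for expected in counts:
            got = cs.count_alleles(files[expected.timepoint_day], signature)
            assert (got.variant, got.wt_prime, got.other) == (
                expected.variant, expected.wt_prime, expected.other
            )


class TestFisher:
    def test_matches_scipy_on_random_tables(self, rng):
        for _ in range(300):
            t = rng.integers(0, 80, 4)
            p = cs.fisher_exact_two_sided(*t)
            p_ref = stats.fisher_exact(t.reshape(2, 2))[1]
            assert p == pytest.approx(p_ref, rel=1e-10, abs=1e-300)

    def test_matches_exact_enumeration_small_grid(self):
        for a in range(0, 8):
            for b in range(0, 8):
                for c in range(0, 8):
                    for d in range(0, 8):
                        p = cs.fisher_exact_two_sided(a, b, c, d)
                        assert p == pytest.approx(
                            exact_fisher_oracle(a, b, c, d), rel=1e-11, abs=1e-300
                        )

    def test_degenerate_margins(self):
        assert cs.fisher_exact_two_sided(0, 0, 3, 4) == 1.0
        assert cs.fisher_exact_two_sided(0, 3, 0, 4) == 1.0
        assert cs.fisher_exact_two_sided(0, 0, 0, 0) == 1.0


class TestFitnessStats:
    def test_symmetric_table_is_neutral(self):
        r = cs.fitness_stats(
            cs.AlleleCounts(100, 100, 0, 2.0), cs.AlleleCounts(100, 100, 0, 12.0)
        )
        assert r.fc == 1.0
        assert r.p == 1.0
        assert r.classification == "neutral"
        assert r.pseudocount == 0.0

    def test_depletion_example(self):
        early = cs.AlleleCounts(20, 20, 0, 2.0)
        late = cs.AlleleCounts(5, 20, 0, 12.0)
        r = cs.fitness_stats(early, late)
        assert r.fc == pytest.approx(0.25)
        assert r.p == pytest.approx(exact_fisher_oracle(20, 5, 20, 20), rel=1e-11)
        assert r.s == pytest.approx(math.log(0.25) / 10)
        assert r.classification == "depleted"

    def test_pseudocount_applied_only_on_zero_cells(self):
        r = cs.fitness_stats(
            cs.AlleleCounts(10, 10, 0, 2.0), cs.AlleleCounts(0, 10, 0, 12.0)
        )
        assert r.pseudocount == 0.5
        assert r.ratio_late == pytest.approx(0.5 / 10.5)
        assert math.isfinite(r.log_fc)

    def test_antisymmetry_under_timepoint_swap(self, rng):
        for _ in range(50):
            v1, w1, v2, w2 = rng.integers(1, 200, 4)
            fwd = cs.fitness_stats(
                cs.AlleleCounts(v1, w1, 0, 2.0), cs.AlleleCounts(v2, w2, 0, 12.0)
            )
            rev = cs.fitness_stats(
                cs.AlleleCounts(v2, w2, 0, 2.0), cs.AlleleCounts(v1, w1, 0, 12.0)
            )
            assert rev.log_fc == pytest.approx(-fwd.log_fc)
            assert rev.p == pytest.approx(fwd.p, rel=1e-12)

    def test_depth_invariance(self, rng):
        for _ in range(30):
            v1, w1, v2, w2 = rng.integers(1, 50, 4)
            base = cs.fitness_stats(
                cs.AlleleCounts(v1, w1, 0, 2.0), cs.AlleleCounts(v2, w2, 0, 12.0)
            )
            scaled = cs.fitness_stats(
                cs.AlleleCounts(5 * v1, 5 * w1, 0, 2.0),
                cs.AlleleCounts(5 * v2, 5 * w2, 0, 12.0),
            )
            assert scaled.fc == pytest.approx(base.fc)
            assert scaled.p <= base.p + 1e-12

    def test_bad_delta_t(self):
        with pytest.raises(ParameterError):
            cs.fitness_stats(
                cs.AlleleCounts(5, 5, 0, 12.0), cs.AlleleCounts(5, 5, 0, 2.0)
            )

    def test_empty_timepoint_rejected(self):
        with pytest.raises(ValidationError):
            cs.fitness_stats(
                cs.AlleleCounts(0, 0, 10, 2.0), cs.AlleleCounts(5, 5, 0, 12.0)
            )


class TestClassification:
    @pytest.mark.parametrize(
        "fc,p,expected",
        [
            (0.3, 0.001, "depleted"),
            (0.3, 0.2, "neutral"),
            (3.0, 0.001, "enriched"),
            (1.0, 0.0001, "neutral"),
        ],
    )
    def test_rule(self, fc, p, expected):
        r = cs.FitnessResult(
            ratio_early=1, ratio_late=fc, fc=fc, log_fc=math.log(fc),
            se_log_fc=0.1, delta_t=10, s=math.log(fc) / 10, p=p,
        )
        assert cs.classify_variant(r) == expected

    def test_wt_prime_neutrality(self, rng):
        """When both alleles share the same fitness, FC centers on 1."""
        fcs = []
        for _ in range(300):
            # both lineages decline identically; ratio drift is sampling only
            n = 800
            e = rng.multinomial(n, [0.25, 0.25, 0.5])
            l = rng.multinomial(n, [0.1, 0.1, 0.8])
            r = cs.fitness_stats(
                cs.AlleleCounts(int(e[0]), int(e[1]), int(e[2]), 2.0),
                cs.AlleleCounts(int(l[0]), int(l[1]), int(l[2]), 12.0),
            )
            fcs.append(r.log_fc)
        assert abs(np.mean(fcs)) < 0.02


class TestModelWrapper:
    def make_counts(self):
        return pd.DataFrame(
            {
                "variant_id": ["v1"] * 4 + ["v2"] * 4,
                "replicate": ["r1", "r1", "r2", "r2"] * 2,
                "timepoint_day": [2, 12, 2, 12] * 2,
                "variant": [100, 30, 120, 40, 100, 100, 90, 95],
                "wt_prime": [100, 100, 110, 110, 100, 100, 90, 92],
                "other": [800] * 8,
            }
        )

    def test_fit_combines_replicates(self):
        results = cs.SelectExperiment(self.make_counts()).fit()
        assert set(results.combined["variant_id"]) == {"v1", "v2"}
        assert len(results.per_replicate) == 4
        v1 = results.combined.set_index("variant_id").loc["v1"]
        v2 = results.combined.set_index("variant_id").loc["v2"]
        assert v1["classification"] == "depleted"
        assert v2["classification"] == "neutral"
        assert v1["s"] < 0

    def test_inverse_variance_combination(self):
        results = cs.SelectExperiment(self.make_counts()).fit()
        reps = results.per_replicate
        v1 = reps[reps["variant_id"] == "v1"]
        w = 1 / v1["se_log_fc"] ** 2
        expected = float((w * v1["log_fc"]).sum() / w.sum())
        got = float(results.combined.set_index("variant_id").loc["v1", "log_fc"])
        assert got == pytest.approx(expected)

    def test_summary_mentions_each_variant(self):
        text = cs.SelectExperiment(self.make_counts()).fit().summary()
        assert "v1" in text and "v2" in text and "depleted" in text
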