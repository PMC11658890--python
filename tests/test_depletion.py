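"""Depletion statistics: extraction, normalization, thresholding, logo,
consensus, and the end-to-end planted-signal properties."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from casassay import (
    PamCountTable,
    RecognitionModel,
    all_pams,
    call_significant,
    consensus_call,
    depletion_threshold,
    expand_iupac,
    extract_pams,
    log2_fold_change,
    logo_matrix,
    normalize_frequencies,
)
from casassay.library import PamLibrarySpec

from conftest import run_depletion_experiment


def brute_force_extract(reads, library):
    """Position-by-position scanner, independent of the regex machinery."""
    up, down, L = (library.upstream_anchor, library.downstream_anchor,
                   library.randomized_length)
    rc = lambda s: s[::-1].translate(str.maketrans("ACGTN", "TGCAN"))
    counts = {}
    total = matched = 0
    for read in reads:
        total += 1
        read = read.upper()
        hits = []
        for seq in (read, rc(read)):
            for i in range(len(seq) - len(up) - L - len(down) + 1):
                if (seq[i : i + len(up)] == up
                        and seq[i + len(up) + L : i + len(up) + L + len(down)] == down):
                    hits.append(seq[i + len(up) : i + len(up) + L])
        if len(hits) == 1 and set(hits[0]) <= set("ACGT"):
            matched += 1
            counts[hits[0]] = counts.get(hits[0], 0) + 1
    return counts, total, matched


def make_table(counts: dict, role="targeting", sample_id="s", extra_unmatched=0):
    series = pd.Series(0, index=pd.Index(all_pams(), name="pam"), dtype=int)
    for k, v in counts.items():
        series[k] = v
    matched = int(series.sum())
    return PamCountTable(sample_id=sample_id, sample_role=role, counts=series,
                        total_reads=matched + extra_unmatched, matched_reads=matched)


class TestExtractPams:
    def test_planted_tetramer_counted_in_library_orientation(self, design, library):
        read = design.fragment("CAAA")
        table = extract_pams([read, read[::-1].translate(str.maketrans("ACGT", "TGCA"))],
                             library)
        assert table.counts["CAAA"] == 2  # forward and reverse-complement reads
        assert table.matched_reads == table.total_reads == 2

    def test_read_without_anchors_counts_toward_total_only(self, library):
        table = extract_pams(["A" * 206], library)
        assert table.total_reads == 1
        assert table.matched_reads == 0
        assert table.counts.sum() == 0

    def test_ambiguous_base_in_tetramer_discarded(self, library):
        read = library.upstream_anchor + "CANA" + library.downstream_anchor
        table = extract_pams([read], library)
        assert table.matched_reads == 0 and table.total_reads == 1

    def test_double_site_read_discarded(self, library):
        site = library.upstream_anchor + "CAAA" + library.downstream_anchor
        table = extract_pams([site + site], library)
        assert table.matched_reads == 0 and table.total_reads == 1

    def test_counts_equal_generator_ground_truth(self, library):
        from casassay import SimulationPlan, simulate_pam_library_reads

        plan = SimulationPlan(model=RecognitionModel(), reads_per_sample=1000,
                              samples=(("s", "targeting"),), seed=21)
        sample = simulate_pam_library_reads(plan)["s"]
        table = extract_pams(sample.reads, library)
        truth = pd.Series(sample.true_pams).value_counts()
        assert table.matched_reads == 1000
        for pam, n in truth.items():
            assert table.counts[pam] == n

    def test_empty_stream_gives_empty_table(self, library):
        table = extract_pams([], library)
        assert table.total_reads == 0 and table.matched_reads == 0

    def test_fastq_and_gzip_round_trip(self, tmp_path, design, library):
        from casassay import SimulationPlan, simulate_pam_library_reads, write_fastq

        plan = SimulationPlan(model=RecognitionModel(), reads_per_sample=100,
                              samples=(("s", "targeting"),), seed=8)
        sample = simulate_pam_library_reads(plan)["s"]
        for name in ("r.fastq", "r.fastq.gz"):
            path = write_fastq(sample, tmp_path / name)
            table = extract_pams(path, library)
            assert table.matched_reads == 100

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(data=st.data())
    def test_matches_brute_force_scanner_on_random_reads(self, design, library, data):
        """Oracle equivalence on arbitrary <=50-read inputs, including junk
        reads, planted sites, N bases and double sites."""
        alphabet = "ACGTN"
        kinds = st.sampled_from(["junk", "planted", "planted_rc", "double", "n_pam"])
        reads = []
        for _ in range(data.draw(st.integers(0, 50))):
            kind = data.draw(kinds)
            pam = "".join(data.draw(st.sampled_from("ACGT")) for _ in range(4))
            if kind == "junk":
                n = data.draw(st.integers(0, 80))
                reads.append("".join(data.draw(st.sampled_from(alphabet))
                                     for _ in range(n)))
            else:
                site = library.upstream_anchor + pam + library.downstream_anchor
                if kind == "n_pam":
                    site = library.upstream_anchor + "CANA" + library.downstream_anchor
                if kind == "double":
                    site = site + site
                if kind == "planted_rc":
                    site = site[::-1].translate(str.maketrans("ACGT", "TGCA"))
                reads.append(site)
        table = extract_pams(reads, library)
        counts, total, matched = brute_force_extract(reads, library)
        assert table.total_reads == total
        assert table.matched_reads == matched
        for pam, n in counts.items():
            assert table.counts[pam] == n
        assert table.counts.sum() == matched


class TestNormalization:
    def test_uniform_counts_give_uniform_frequencies(self):
        table = make_table({p: 4 for p in all_pams()})
        freq = normalize_frequencies(table, pseudocount=0)
        assert (freq == 1 / 256).all()

    def test_pseudocount_arithmetic(self):
        counts = {p: 4 for p in all_pams()}
        counts["CAAA"] = 0
        freq = normalize_frequencies(make_table(counts), pseudocount=1)
        assert freq["CAAA"] == pytest.approx(1 / (4 * 255 + 256))

    def test_scale_invariance(self):
        a = normalize_frequencies(make_table({p: 3 for p in all_pams()}), 0)
        b = normalize_frequencies(make_table({p: 6 for p in all_pams()}), 0)
        assert np.allclose(a, b)

    def test_frequencies_sum_to_one(self):
        rng = np.random.default_rng(0)
        counts = dict(zip(all_pams(), rng.integers(0, 1000, 256)))
        for pseudocount in (0, 0.5, 1, 10):
            freq = normalize_frequencies(make_table(counts), pseudocount)
            assert abs(freq.sum() - 1.0) < 1e-9

    def test_zero_matched_reads_is_an_error(self):
        with pytest.raises(ValueError, match="no PAMs extracted"):
            normalize_frequencies(make_table({}, extra_unmatched=10))


class TestLog2FoldChange:
    def test_identity_and_halving(self):
        f = pd.Series({"CAAA": 0.5, "GAAA": 0.5})
        assert (log2_fold_change(f, f) == 0).all()
        half = pd.Series({"CAAA": 0.25, "GAAA": 0.75})
        assert log2_fold_change(half, f)["CAAA"] == pytest.approx(-1.0)

    def test_depleted_pam_arithmetic_with_pseudocount(self):
        # equal depth 25,600 in both samples; CAAA fully depleted
        untreated = {p: 100 for p in all_pams()}
        sample = dict(untreated)
        sample["CAAA"] = 0
        sample["GGGG"] = 200
        fc = log2_fold_change(
            normalize_frequencies(make_table(sample), 1),
            normalize_frequencies(make_table(untreated), 1),
        )
        assert fc["CAAA"] == pytest.approx(math.log2(1 / 101), abs=1e-9)
        assert fc["CAAA"] == pytest.approx(-6.658, abs=1e-3)

    def test_zero_untreated_frequency_directs_to_pseudocount(self):
        sample = pd.Series({"CAAA": 1.0})
        untreated = pd.Series({"CAAA": 0.0})
        with pytest.raises(ValueError, match="pseudocount"):
            log2_fold_change(sample, untreated)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        p_low=st.floats(0.0, 1.0, allow_nan=False),
        delta=st.floats(0.001, 1.0, allow_nan=False),
    )
    def test_monotone_in_cleavage_probability(self, p_low, delta):
        """Raising a PAM's cleavage probability never raises its log2FC
        (expectation-level: frequencies from renormalized survival weights)."""
        p_high = min(1.0, p_low + delta)
        pams = all_pams()
        uniform = pd.Series(1 / 256, index=pd.Index(pams, name="pam"))

        def expected_fc(p):
            w = pd.Series(1.0, index=uniform.index)
            w["CAAA"] = 1.0 - p
            freq = (w / w.sum()).clip(lower=1e-300)
            return log2_fold_change(freq, uniform)["CAAA"]

        assert expected_fc(p_high) <= expected_fc(p_low) + 1e-12


class TestThreshold:
    def test_frozen_gaussian_quantile(self):
        # sample mean 0, sample SD exactly 0.1 -> m - z*s at 99.9999%
        a = 0.1 / math.sqrt(2)
        thr = depletion_threshold(pd.Series([-a, a]), confidence=0.999999)
        assert thr == pytest.approx(-0.47534, abs=1e-4)

    def test_matches_normal_quantile_oracle(self):
        rng = np.random.default_rng(1)
        vals = pd.Series(rng.normal(0.02, 0.1, 500))
        for conf in (0.99, 0.999999):
            thr = depletion_threshold(vals, confidence=conf)
            expect = vals.mean() - stats.norm.ppf(conf) * vals.std(ddof=1)
            assert thr == pytest.approx(expect, rel=1e-12)

    def test_degenerate_spread_returns_mean(self):
        assert depletion_threshold(pd.Series([0.0] * 10)) == 0.0

    def test_pooling_across_samples(self):
        s1, s2 = pd.Series([-0.1, 0.1]), pd.Series([-0.2, 0.2])
        pooled = depletion_threshold([s1, s2])
        direct = depletion_threshold(pd.Series([-0.1, 0.1, -0.2, 0.2]))
        assert pooled == direct

    def test_empirical_min_rule(self):
        vals = pd.Series([-0.3, -0.1, 0.2])
        assert depletion_threshold(vals, method="empirical_min") == -0.3

    def test_too_few_values_is_an_error(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            depletion_threshold(pd.Series([0.1]))

    def test_threshold_nonpositive_for_centered_null(self):
        rng = np.random.default_rng(2)
        vals = pd.Series(rng.normal(-0.01, 0.05, 300))
        assert depletion_threshold(vals) <= 0


class TestSignificance:
    def test_strict_inequality_at_boundary(self):
        fc = pd.Series({"CAAA": -0.5, "CTAA": -0.6})
        assert call_significant(fc, -0.5) == ["CTAA"]

    def test_emitted_sorted(self):
        fc = pd.Series({"TTTT": -9.0, "AAAA": -9.0, "CAAA": 0.0})
        assert call_significant(fc, -1.0) == ["AAAA", "TTTT"]

    def test_nonfinite_threshold_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            call_significant(pd.Series({"CAAA": 0.0}), float("nan"))


class TestLogoAndConsensus:
    def test_single_pam_is_one_hot_with_two_bits(self):
        logo = logo_matrix(["CAAA"], (-5, -6, -7, -8))
        assert (logo.bits == 2.0).all()
        assert logo.frequencies.loc[-5, "C"] == 1.0
        assert logo.frequencies.loc[-6, "A"] == 1.0
        assert consensus_call(logo) == "CAAA"

    def test_cwaa_pair_splits_position_minus6(self):
        logo = logo_matrix(["CAAA", "CTAA"], (-5, -6, -7, -8))
        assert logo.frequencies.loc[-6, "A"] == 0.5
        assert logo.frequencies.loc[-6, "T"] == 0.5
        assert logo.bits[-6] == pytest.approx(1.0)
        assert logo.bits[-5] == pytest.approx(2.0)
        assert consensus_call(logo) == "CWAA"

    def test_positions_run_minus5_to_minus8_left_to_right(self):
        logo = logo_matrix(["CAAA"], (-5, -6, -7, -8))
        assert list(logo.frequencies.index) == [-5, -6, -7, -8]

    def test_c_initial_set_calls_cnnn(self):
        logo = logo_matrix(expand_iupac("CNNN"), (-5, -6, -7, -8))
        assert consensus_call(logo) == "CNNN"
        # every base at exactly background 0.25 on the free positions
        assert logo.frequencies.loc[-6].tolist() == [0.25] * 4
        assert logo.bits[-6] == pytest.approx(0.0, abs=1e-12)

    def test_frequencies_sum_to_one_and_bits_in_range(self):
        logo = logo_matrix(expand_iupac("RYSW"), (-5, -6, -7, -8))
        np.testing.assert_allclose(logo.frequencies.sum(axis=1), 1.0)
        assert ((logo.bits >= 0) & (logo.bits <= 2)).all()

    def test_empty_set_is_flagged_not_raised(self):
        logo = logo_matrix([], (-5, -6, -7, -8))
        assert logo.is_empty
        with pytest.raises(ValueError, match="empty"):
            consensus_call(logo)

    def test_depletion_weighting_shifts_composition(self):
        logo = logo_matrix(["CAAA", "CTAA"], (-5, -6, -7, -8),
                           weights={"CAAA": 3.0, "CTAA": 1.0})
        assert logo.frequencies.loc[-6, "A"] == 0.75

    def test_inclusion_fraction_bounds(self):
        logo = logo_matrix(["CAAA"], (-5, -6, -7, -8))
        with pytest.raises(ValueError, match="inclusion_fraction"):
            consensus_call(logo, inclusion_fraction=0.0)


class TestEndToEnd:
    def test_planted_cwaa_signal_recovered_across_seeds(self, design, library):
        """Full depletion of CWAA-matching PAMs: the called set equals the
        planted match set and the consensus equals the planted pattern."""
        model = RecognitionModel(rules=(("CWAA", 1.0),))
        hits = 0
        for seed in range(10):
            res = run_depletion_experiment(model, seed, 100_000, library)
            hits += (res.significant == ["CAAA", "CTAA"] and res.consensus == "CWAA")
        assert hits >= 9

    def test_targeting_identical_to_untreated_yields_no_calls(self, library):
        res = run_depletion_experiment(RecognitionModel(), 17, 20_000, library)
        assert res.significant == []
        assert res.consensus is None
        assert "no significant PAMs" in res.summary()

    def test_missing_role_is_an_error(self, library):
        from casassay import PamDepletionModel

        table = make_table({p: 1 for p in all_pams()}, role="untreated")
        with pytest.raises(ValueError, match="non_targeting"):
            PamDepletionModel([table], library)
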