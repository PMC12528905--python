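"""CDR3 extraction, repertoire statistics, template detection, sizing."""

import collections
import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import beta

from scfvlib.cassette_design import theoretical_position_frequencies
from scfvlib.codon_algebra import aa_distribution
from scfvlib.repertoire_qc import (
    FLAG_INTERNAL_STOP,
    FLAG_TEMPLATE,
    FLAG_UNANCHORED,
    CloneRecord,
    analyze_clone,
    analyze_reads,
    compare_to_reference,
    detect_template,
    estimate_library_size,
    export_logo_matrix,
    extract_cdr3,
    summarize_repertoire,
)
from scfvlib.synthetic_data import GeneratorConfig, generate_repertoire


def _clopper_pearson(k, n, alpha=0.05):
    lo = beta.ppf(alpha / 2, k, n - k + 1) if k > 0 else 0.0
    hi = beta.ppf(1 - alpha / 2, k + 1, n - k) if k < n else 1.0
    return lo, hi


class TestExtraction:
    def test_round_trip_recovers_cassette_realization(self, design):
        reads, truth = generate_repertoire(design, GeneratorConfig(seed=3, n_clones=20))
        for (cid, seq), row in zip(reads, truth.itertuples()):
            clone = analyze_clone(cid, seq, design)
            assert clone.vl_cdr3.nucleotides == row.vl_nt
            assert clone.vh_cdr3.nucleotides == row.vh_nt

    def test_single_anchor_mismatch_tolerated(self, design):
        reads, truth = generate_repertoire(design, GeneratorConfig(seed=4, n_clones=1))
        cid, seq = reads[0]
        up, _ = design.flanks("VL")
        pos = seq.find(up)
        mutated = seq[:pos] + ("A" if seq[pos] != "A" else "G") + seq[pos + 1 :]
        clone = analyze_clone(cid, mutated, design)
        assert clone.vl_cdr3 is not None
        assert clone.vl_cdr3.nucleotides == truth.iloc[0]["vl_nt"]

    def test_scrambled_framework_is_unanchored(self, design):
        rng = np.random.default_rng(0)
        scrambled = "".join(rng.permutation(list(design.template)))
        clone = analyze_clone("x", scrambled, design)
        assert FLAG_UNANCHORED in clone.flags

    def test_short_anchor_is_configuration_error(self):
        with pytest.raises(ValueError):
            extract_cdr3("ACGT" * 30, ("ACGTA", "ACGTACGTACGT"))

    def test_frameshift_flag_follows_length(self, design):
        reads, _ = generate_repertoire(design, GeneratorConfig(seed=5, n_clones=1))
        cid, seq = reads[0]
        vl_up, _ = design.flanks("VL")
        cut = seq.find(vl_up) + len(vl_up) + 2
        shifted = seq[:cut] + seq[cut + 1 :]  # delete one base inside VL CDR3
        clone = analyze_clone(cid, shifted, design)
        assert clone.vl_cdr3 is not None and not clone.vl_cdr3.in_frame
        assert "frameshift" in clone.flags


class TestTemplateDetection:
    def test_template_clone_exact_evidence(self, design):
        clone = analyze_clone("t", design.template, design)
        assert FLAG_TEMPLATE in clone.flags
        assert "VL:exact" in clone.template_evidence
        assert "VH:exact" in clone.template_evidence

    def test_planted_site_triggers_site_evidence(self, design):
        # splice a SacI site into an otherwise mutant VL CDR3
        reads, _ = generate_repertoire(design, GeneratorConfig(seed=6, n_clones=1))
        cid, seq = reads[0]
        clone = analyze_clone(cid, seq, design)
        s = clone.vl_cdr3.start
        planted = seq[:s] + "GAGCTC" + seq[s + 6 :]
        clone = analyze_clone(cid, planted, design)
        is_template, evidence = detect_template(clone, design)
        assert is_template
        assert any(e.startswith("VL:site") for e in evidence)

    def test_site_free_mutant_is_not_template(self, design):
        reads, truth = generate_repertoire(design, GeneratorConfig(seed=7, n_clones=30))
        clones = analyze_reads(reads, design)
        assert all(FLAG_TEMPLATE not in c.flags for c in clones)

    def test_spiked_fraction_recovered_within_binomial_ci(self, design):
        f = 0.2
        n = 2000
        reads, _ = generate_repertoire(
            design, GeneratorConfig(seed=11, n_clones=n, template_fraction=f)
        )
        clones = analyze_reads(reads, design)
        detected = sum(1 for c in clones if FLAG_TEMPLATE in c.flags)
        lo, hi = _clopper_pearson(detected, n)
        assert lo <= f <= hi


@pytest.fixture(scope="module")
def small_run(design):
    reads, truth = generate_repertoire(design, GeneratorConfig(seed=8, n_clones=190))
    clones = analyze_reads(reads, design)
    return clones, truth


class TestSummary:
    def test_lengths_match_truth_exactly(self, design, small_run):
        clones, truth = small_run
        summary = summarize_repertoire(clones, design)
        stop_free = truth[~truth.has_stop.astype(bool)]
        expected = collections.Counter(int(k) for k in stop_free.vh_loop_length)
        assert summary.length_histogram["VH"] == expected
        assert summary.n_usable == len(stop_free)

    def test_histogram_counts_sum_to_usable(self, design, small_run):
        clones, _ = small_run
        summary = summarize_repertoire(clones, design)
        assert sum(summary.length_histogram["VH"].values()) == summary.n_usable
        assert sum(summary.length_histogram["VL"].values()) == summary.n_usable

    def test_matrix_columns_sum_to_coverage(self, design, small_run):
        clones, _ = small_run
        summary = summarize_repertoire(clones, design)
        counts = summary.aa_counts["VH"]
        coverage = collections.Counter()
        for length, n in summary.length_histogram["VH"].items():
            from scfvlib.cassette_design import kabat_vh_labels

            for label in kabat_vh_labels(length):
                coverage[label] += n
        for label in counts.index:
            assert counts.loc[label].sum() == coverage[label]

    def test_entropy_zero_at_fixed_position_bounded_elsewhere(self, design, small_run):
        clones, _ = small_run
        summary = summarize_repertoire(clones, design)
        assert summary.entropy["VL"]["95"] == 0.0  # fixed Pro
        for region in ("VL", "VH"):
            assert (summary.entropy[region] <= math.log2(21) + 1e-9).all()

    def test_empty_input_yields_empty_summary(self, design):
        summary = summarize_repertoire([], design)
        assert summary.n_total == 0 and summary.n_usable == 0

    def test_stop_clones_counted_but_excluded(self, design, small_run):
        clones, truth = small_run
        summary = summarize_repertoire(clones, design)
        n_stop = int(truth.has_stop.astype(bool).sum())
        assert summary.flag_counts[FLAG_INTERNAL_STOP] == n_stop
        assert summary.n_total == 190


class TestReferenceComparison:
    def test_identical_distributions_give_zero(self, design):
        reads, _ = generate_repertoire(design, GeneratorConfig(seed=9, n_clones=100))
        clones = analyze_reads(reads, design)
        summary = summarize_repertoire(clones, design)
        reference = summary.frequencies("VL")
        table = compare_to_reference(summary, reference, "VL")
        positions = [p for p in table.index if p != "mean"]
        assert table.loc[positions, "jsd_bits"].abs().max() == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_support_gives_one_bit(self, design):
        summary_freqs = pd.DataFrame(
            {"A": [1.0], "C": [0.0]}, index=["91"]
        )
        reference = pd.DataFrame({"A": [0.0], "C": [1.0]}, index=["91"])

        class _Stub:
            def frequencies(self, region):
                return summary_freqs

        table = compare_to_reference(_Stub(), reference, "VL")
        assert table.loc["91", "jsd_bits"] == pytest.approx(1.0)

    def test_nnk_against_reference_matches_hand_jsd(self, design):
        """JSD between NNK theory and a uniform 20-residue reference."""
        nnk = aa_distribution("NNK")
        p = {res: nnk[res] / (1 - nnk.stop_probability) for res in nnk.residue_support}
        q = {res: 1 / 20 for res in p}
        m = {res: 0.5 * (p[res] + q[res]) for res in p}
        kl = lambda a, b: sum(a[r] * math.log2(a[r] / b[r]) for r in a if a[r] > 0)
        expected = 0.5 * kl(p, m) + 0.5 * kl(q, m)

        freqs = pd.DataFrame([p], index=["94"])
        reference = pd.DataFrame([q], index=["94"])

        class _Stub:
            def frequencies(self, region):
                return freqs

        table = compare_to_reference(_Stub(), reference, "VL")
        assert table.loc["94", "jsd_bits"] == pytest.approx(expected, abs=1e-12)


class TestLogoMatrix:
    def test_rows_sum_to_one_and_fixed_position_pure(self, design, tmp_path):
        reads, _ = generate_repertoire(design, GeneratorConfig(seed=10, n_clones=150))
        clones = analyze_reads(reads, design)
        summary = summarize_repertoire(clones, design)
        path = tmp_path / "vl_logo.tsv"
        freqs = export_logo_matrix(summary, "VL", path)
        assert freqs.sum(axis=1).to_numpy() == pytest.approx(
            np.ones(len(freqs)), abs=1e-9
        )
        assert freqs.loc["95", "P"] == pytest.approx(1.0)
        reloaded = pd.read_csv(path, sep="\t", index_col="position")
        assert reloaded.shape == freqs.shape

    def test_sampled_nnk_close_to_theory(self, design):
        """At n=10,000 draws an NNK position's empirical frequencies sit
        within total-variation 0.05 of the theoretical distribution."""
        reads, truth = generate_repertoire(
            design, GeneratorConfig(seed=12, n_clones=10_000, sublibrary_mix={"S": 1.0})
        )
        clones = analyze_reads(reads, design)
        summary = summarize_repertoire(clones, design)
        observed = export_logo_matrix(summary, "VL").loc["96"]
        theory = theoretical_position_frequencies(design.vl_cassettes[0]).loc["96"]
        residues = set(observed.index) | set(theory.index)
        tv = 0.5 * sum(
            abs(observed.get(r, 0.0) - theory.get(r, 0.0)) for r in residues
        )
        assert tv < 0.05


class TestLibrarySize:
    def test_single_replicate_scaling(self):
        mean, sd, est = estimate_library_size([173], [1e8])
        assert mean == pytest.approx(1.73e10)
        assert sd == 0.0

    def test_triplicate_mean_and_sd(self):
        mean, sd, est = estimate_library_size([100, 100, 100], [1e6])
        assert mean == pytest.approx(1e8)
        assert sd == 0.0

    def test_plated_fraction_scales_inverse(self):
        full, _, _ = estimate_library_size([50], [1e6], plated_fraction=1.0)
        tenth, _, _ = estimate_library_size([50], [1e6], plated_fraction=0.1)
        assert tenth == pytest.approx(10 * full)

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            estimate_library_size([1, 2], [1e6, 1e6, 1e6])
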