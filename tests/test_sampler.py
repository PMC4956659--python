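"""Mutation operators and the design loop."""

import math

import numpy as np
import pytest

from conftest import random_rna
from pkdesign.fixtures import (
    HAMMERHEAD_DOTBRACKET,
    HAMMERHEAD_TEMPLATE,
    random_sequence_for,
)
from pkdesign.sampler import (
    DesignConfig,
    OperatorInapplicable,
    compute_m,
    design,
    initialize_seed,
    m_mutation,
    mutate_basepair,
    mutate_single_nucleotide,
    run_trials,
)
from pkdesign.structures import (
    ALLOWED_PAIRS,
    DesignTemplate,
    is_compatible,
    parse_dot_bracket,
    validate_template,
)
from pkdesign.thermo import evaluate_ensemble


@pytest.fixture(scope="module")
def frozen():
    """A frozen evaluation for operator tests (matrices never change)."""
    target = parse_dot_bracket("((..[[..))..]].....")
    seq = "GCAAGCAAGCAAGCAAGAC"
    ev = evaluate_ensemble(seq)
    return seq, target, ev.matrices


class TestInitializeSeed:
    def test_pairs_always_allowed(self, hairpin, rng):
        for _ in range(50):
            seq = initialize_seed(hairpin, rng=rng)
            for i, j in hairpin.pairs:
                assert (seq[i - 1], seq[j - 1]) in ALLOWED_PAIRS

    def test_template_copied(self, rng):
        target = parse_dot_bracket(HAMMERHEAD_DOTBRACKET)
        for _ in range(20):
            seq = initialize_seed(target, DesignTemplate(HAMMERHEAD_TEMPLATE), rng=rng)
            assert seq[16:25] == "CCUGAUGAG"
            assert seq[40:46] == "GCGAAA"
            assert seq[68:71] == "UCG"
            assert is_compatible(seq, target)

    def test_gc_one_all_unpaired(self, rng):
        target = parse_dot_bracket("." * 10)
        assert set(initialize_seed(target, gc_content=1.0, rng=rng)) <= {"G", "C"}

    def test_half_locked_pair_compatible(self, rng):
        target = parse_dot_bracket("(((...)))")
        template = validate_template("Goooooooo", target)
        for _ in range(20):
            seq = initialize_seed(target, template, rng=rng)
            assert seq[0] == "G" and seq[8] in ("C", "U")


class TestSingleNucleotideOperator:
    def test_changes_one_unpaired_position(self, frozen, rng):
        seq, target, P = frozen
        tmpl = DesignTemplate.all_open(target.n)
        unpaired = set(target.unpaired_positions)
        for _ in range(200):
            s2 = mutate_single_nucleotide(seq, target, P, tmpl, rng)
            diff = [i + 1 for i in range(len(seq)) if s2[i] != seq[i]]
            assert len(diff) == 1 and diff[0] in unpaired

    def test_locked_positions_never_change(self, rng):
        target = parse_dot_bracket("((..[[..))..]].....")
        tmpl = validate_template("oo" + "AC" + "o" * 15, target)
        seq = "GCACGCAAGCAAGCAAGAC"
        P = evaluate_ensemble(seq).matrices
        for _ in range(2000):
            s2 = mutate_single_nucleotide(seq, target, P, tmpl, rng)
            assert s2[2] == "A" and s2[3] == "C"

    def test_selection_frequency_tracks_defect_weight(self, rng):
        """Empirical pick frequencies follow (1 - P_unpaired) within 3 sigma."""
        target = parse_dot_bracket("((....))....")
        seq = "GCAAGCGCAAAA"  # mixed: some unpaired positions can pair elsewhere
        P = evaluate_ensemble(seq).matrices
        tmpl = DesignTemplate.all_open(target.n)
        unpaired = target.unpaired_positions
        weights = np.array([1 - P.unpaired_probability(i) for i in unpaired])
        assert weights.sum() > 0.1  # fixture must be informative
        expected = weights / weights.sum()
        trials = 10_000
        counts = dict.fromkeys(unpaired, 0)
        for _ in range(trials):
            s2 = mutate_single_nucleotide(seq, target, P, tmpl, rng)
            pos = next(i + 1 for i in range(len(seq)) if s2[i] != seq[i])
            counts[pos] += 1
        emp = np.array([counts[i] for i in unpaired], dtype=float)
        sigma = np.sqrt(trials * expected * (1 - expected))
        assert (np.abs(emp - trials * expected) <= 3 * sigma + 1).all()

    def test_inapplicable_without_unpaired(self, rng):
        target = parse_dot_bracket("((((....))))")
        tmpl = validate_template("ooooAAAAoooo", target)
        seq = "GCGCAAAAGCGC"
        P = evaluate_ensemble(seq).matrices
        with pytest.raises(OperatorInapplicable):
            mutate_single_nucleotide(seq, target, P, tmpl, rng)


class TestBasepairOperator:
    def test_changes_subset_of_one_pair(self, frozen, rng):
        seq, target, M = frozen
        tmpl = DesignTemplate.all_open(target.n)
        pair_sets = [set(p) for p in target.pairs]
        for _ in range(200):
            s2 = mutate_basepair(seq, target, M, template=tmpl, rng=rng)
            diff = {i + 1 for i in range(len(seq)) if s2[i] != seq[i]}
            assert 1 <= len(diff) <= 2
            assert any(diff <= ps for ps in pair_sets)

    def test_nested_pairs_use_printed_alphabet(self, rng):
        target = parse_dot_bracket("((..[[..))..]]")
        seq = "GCAAGCAAGCAAGC"
        M = evaluate_ensemble(seq).matrices
        tmpl = DesignTemplate.all_open(target.n)
        nested = {p for p, pg in target.page.items() if pg == 1}
        nonnested_seen = set()
        for _ in range(3000):
            s2 = mutate_basepair(seq, target, M, template=tmpl, rng=rng)
            diff = {i + 1 for i in range(len(seq)) if s2[i] != seq[i]}
            for i, j in target.pairs:
                if diff <= {i, j}:
                    new = (s2[i - 1], s2[j - 1])
                    if (i, j) in nested:
                        assert new in {("A", "U"), ("G", "C"), ("G", "U")}
                    else:
                        assert new in ALLOWED_PAIRS
                        nonnested_seen.add(new)
                    break
        # non-nested pairs do explore reversed orientations
        assert nonnested_seen & {("U", "A"), ("C", "G"), ("U", "G")}

    def test_acceptance_frequency_nonnested(self, rng):
        """Acceptance of a frozen non-nested pair matches 1 - P'' within 3 sigma."""
        target = parse_dot_bracket("((..[[..))..]]")
        seq = "GCAAGCAAGCAAGC"
        M = evaluate_ensemble(seq).matrices
        tmpl = DesignTemplate.all_open(target.n)
        pairs = target.sorted_pairs()
        weights = np.array(
            [
                1 - M.P_nested[i - 1, j - 1]
                if target.page[(i, j)] == 1
                else 1 - M.P_nonnested[i - 1, j - 1]
                for i, j in pairs
            ]
        )
        expected = weights / weights.sum()
        trials = 10_000
        counts = dict.fromkeys(pairs, 0)
        for _ in range(trials):
            s2 = mutate_basepair(seq, target, M, template=tmpl, rng=rng)
            diff = {i + 1 for i in range(len(seq)) if s2[i] != seq[i]}
            for pr in pairs:
                if diff <= set(pr):
                    counts[pr] += 1
                    break
        emp = np.array([counts[p] for p in pairs], dtype=float)
        sigma = np.sqrt(trials * expected * (1 - expected))
        assert (np.abs(emp - trials * expected) <= 3 * sigma + 1).all()

    def test_both_ends_locked_skipped(self, rng):
        target = parse_dot_bracket("((((....))))")
        tmpl = validate_template("GooooooooooC", target)
        seq = "GGGGAAAACCCC"
        M = evaluate_ensemble(seq).matrices
        for _ in range(500):
            s2 = mutate_basepair(seq, target, M, template=tmpl, rng=rng)
            assert s2[0] == "G" and s2[11] == "C"

    def test_half_locked_mutates_free_end_only(self, rng):
        target = parse_dot_bracket("(((....)))")
        tmpl = validate_template("Uooooooooo", target)
        seq = "UGGAAAACCA"
        M = evaluate_ensemble(seq).matrices
        seen = set()
        for _ in range(500):
            s2 = mutate_basepair(seq, target, M, template=tmpl, rng=rng)
            assert s2[0] == "U"
            if s2[9] != seq[9]:
                seen.add(s2[9])
        assert seen <= {"A", "G"}  # partners of U other than current


class TestComputeM:
    def test_m_prime_formula(self):
        rng = np.random.default_rng(0)
        # N=0.5, n=100, C=5 -> m' = 10; draws concentrate near 10
        draws = [compute_m(0.5, 100, 5.0, rng) for _ in range(2000)]
        assert 8.5 < np.mean(draws) < 10.5

    def test_zero_defect_gives_one(self):
        rng = np.random.default_rng(0)
        assert all(compute_m(0.0, 100, 5.0, rng) == 1 for _ in range(100))

    def test_monte_carlo_mean(self):
        """Mean of floor(|Normal(10, 2)|) with clamp, against its own MC oracle."""
        rng = np.random.default_rng(42)
        draws = np.array([compute_m(0.5, 100, 5.0, rng) for _ in range(100_000)])
        oracle = np.maximum(
            np.floor(np.abs(np.random.default_rng(7).normal(10, 2, 100_000))), 1
        )
        assert abs(draws.mean() - oracle.mean()) < 0.05
        assert 9.2 <= draws.mean() <= 9.8


class TestMMutation:
    def test_m_one_is_single_mutation(self, frozen, rng):
        seq, target, M = frozen
        tmpl = DesignTemplate.all_open(target.n)
        unpaired = set(target.unpaired_positions)
        for _ in range(100):
            s2 = m_mutation(1, seq, target, M, tmpl, rng)
            diff = [i + 1 for i in range(len(seq)) if s2[i] != seq[i]]
            assert len(diff) == 1 and diff[0] in unpaired

    def test_counted_total_equals_m(self, frozen, rng):
        """Counted mutations land exactly on m over randomized calls."""
        seq, target, M = frozen
        tmpl = DesignTemplate.all_open(target.n)
        unpaired = set(target.unpaired_positions)
        for _ in range(2000):
            m = int(rng.integers(1, 7))
            s2 = m_mutation(m, seq, target, M, tmpl, rng)
            diff = {i + 1 for i in range(len(seq)) if s2[i] != seq[i]}
            # counted positions == m; the realized Hamming distance can be
            # smaller (a pair step counts 2 even when one base changes,
            # and later steps may revert earlier ones) but never larger
            assert 0 <= len(diff) <= m
            changed_unpaired = diff & unpaired
            changed_paired = diff - unpaired
            assert len(changed_unpaired) + len(changed_paired) <= m

    def test_counting_instrumented(self, frozen, monkeypatch):
        """Replay the loop accounting: +1 per single step, +2 per pair step."""
        import pkdesign.sampler as sampler_mod

        seq, target, M = frozen
        tmpl = DesignTemplate.all_open(target.n)
        calls = []
        orig_single = sampler_mod.mutate_single_nucleotide
        orig_pair = sampler_mod.mutate_basepair
        monkeypatch.setattr(
            sampler_mod, "mutate_single_nucleotide",
            lambda *a, **k: calls.append(1) or orig_single(*a, **k),
        )
        monkeypatch.setattr(
            sampler_mod, "mutate_basepair",
            lambda *a, **k: calls.append(2) or orig_pair(*a, **k),
        )
        rng = np.random.default_rng(3)
        for _ in range(300):
            calls.clear()
            m = int(rng.integers(1, 8))
            m_mutation(m, seq, target, M, tmpl, rng)
            counted = 0
            for c in calls:
                counted += c
            assert counted == m or (counted == m + 1 and calls[-1] == 2)
            # the +1 overshoot can only occur when no single-step site exists,
            # which this fixture always has:
            assert counted == m


class TestDesignLoop:
    def test_hairpin_converges(self):
        target = parse_dot_bracket("(((...)))")
        config = DesignConfig(f_stop=0.05, max_it=400, rng_seed=5, track_trace=True)
        res = design(target, config=config)
        assert res.reached_fstop
        assert res.mfe_defect == 0
        assert res.N <= 0.05

    def test_trace_contract(self):
        target = parse_dot_bracket("(((...)))")
        config = DesignConfig(f_stop=0.0001, max_it=30, rng_seed=1)
        res = design(target, config=config)
        assert len(res.trace) <= config.max_it
        assert res.iterations_used == len(res.trace)
        observed = [res.seed_N] + [rec.N for rec in res.trace]
        assert res.N == pytest.approx(min(observed))

    def test_intermediates_pair_compatible(self):
        target = parse_dot_bracket("((..[[..))..]]")
        config = DesignConfig(f_stop=0.0001, max_it=25, rng_seed=2)
        res = design(target, config=config)
        assert is_compatible(res.sequence, target)

    def test_trials_reproducible(self):
        target = parse_dot_bracket("(((...)))")
        config = DesignConfig(f_stop=0.05, max_it=50, rng_seed=9, track_trace=False)
        a = run_trials(target, config=config, trials=3)
        b = run_trials(target, config=config, trials=3)
        assert [r.sequence for r in a] == [r.sequence for r in b]
        assert len({r.seed_sequence for r in a}) > 1  # trials are independent

    def test_fully_locked_template_rejected(self):
        target = parse_dot_bracket("(((...)))")
        with pytest.raises(OperatorInapplicable):
            design(target, template="GCGAAACGC", config=DesignConfig(max_it=5))

    def test_template_safety_through_design(self):
        target = parse_dot_bracket("((..[[..))..]].....")
        template = "oo" + "AC" + "o" * 15
        config = DesignConfig(f_stop=0.0001, max_it=20, rng_seed=4)
        res = design(target, template=template, config=config)
        assert res.sequence[2] == "A" and res.sequence[3] == "C"
        assert res.seed_sequence[2] == "A" and res.seed_sequence[3] == "C"

    def test_adaptive_flag_controls_operator_three(self):
        target = parse_dot_bracket("((..[[..))..]].....")
        config = DesignConfig(
            f_stop=0.0001, max_it=40, rng_seed=8, adaptive_enabled=False
        )
        res = design(target, config=config)
        assert all(rec.operator in (1, 2) for rec in res.trace)
        config_on = DesignConfig(f_stop=0.0001, max_it=40, rng_seed=8)
        res_on = design(target, config=config_on)
        assert any(rec.operator == 3 for rec in res_on.trace)
        assert all(rec.m is not None and rec.m >= 1
                   for rec in res_on.trace if rec.operator == 3)
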