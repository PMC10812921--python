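"""Binding model and selection-round simulator."""

import numpy as np
import pytest
from scipy import stats

import bandselex as bx
from bandselex.pattern_census import DegeneratePattern, census
from bandselex.selex_sim import (
    BindingModel,
    ClampRule,
    Condition,
    Psam,
    SimulationCollapseError,
    SimulationConfig,
    amplify,
    best_site_composition,
    channel_weights,
    default_psam,
    emit_raw_reads,
    flat_psam,
    random_library,
    read_affinity,
    run_selex,
    select_round,
    site_affinity,
)
from bandselex.seqio import ReadSet, TrimPolicy, read_sequences, trim_reads


def embed(core, length=35, fill="C"):
    return core + fill * (length - len(core))


class TestPsam:
    def test_consensus_scores_one(self):
        assert site_affinity("ATGCAAAT", default_psam()) == pytest.approx(1.0)

    def test_single_substitution_multiplies_by_its_entry(self):
        psam = default_psam()
        # T at position 5 carries entry 0.5 in the default matrix
        assert site_affinity("ATGCTAAT", psam) == pytest.approx(
            psam.matrix[4, 3]
        )

    def test_zero_weight_base_zeroes_the_site(self):
        mat = default_psam().matrix.copy()
        mat[4] = [1.0, 0.0, 0.0, 0.0]  # only A allowed at position 5
        psam = Psam(matrix=mat)
        assert site_affinity("ATGCTAAT", psam) == 0.0

    def test_matrix_validation(self):
        with pytest.raises(ValueError, match="max entry"):
            Psam(matrix=np.full((8, 4), 0.5))
        with pytest.raises(ValueError, match="shape"):
            Psam(matrix=np.ones((4, 4)))

    def test_clamp_validation(self):
        with pytest.raises(ValueError):
            ClampRule(clamp_gain=0.5)


class TestReadAffinity:
    def test_clamp_boosts_consensus_into_ternary_band(self):
        model = BindingModel()
        insert = embed("ATGCAAAT")
        aff, cls, site = read_affinity(insert, model, Condition("POU1", bob1=True))
        assert cls == "ternary"
        assert aff == pytest.approx(model.clamp.clamp_gain)
        assert site == "ATGCAAAT"

    def test_t5_site_cannot_form_ternary_complex(self):
        model = BindingModel()
        assert model.clamp.word_multiplier("ATGCTAAT") == 0.0
        insert = embed("ATGCTAAT")
        ch = channel_weights([insert], model, bob1=True, insert_length=35)[0]
        mono, dimer, ternary = ch
        assert mono == pytest.approx(site_affinity("ATGCTAAT", model.psam))
        # residual ternary weight comes only from background windows
        assert ternary < 0.05 * model.clamp.clamp_gain * mono
        _, cls, _ = read_affinity(insert, model, Condition("POU1", bob1=True))
        assert cls == "monomer"

    def test_more_element_is_ternary_refractory(self):
        model = BindingModel()
        insert = embed("ATGCATATGCAT")
        ch = channel_weights([insert], model, bob1=True, insert_length=35)[0]
        mono, dimer, ternary = ch
        assert dimer == pytest.approx(model.more_affinity)
        assert dimer > ternary  # MORE contributes nothing to the clamp channel
        _, cls, _ = read_affinity(insert, model, Condition("POU1", bob1=True))
        assert cls == "dimer"

    def test_pore_element_admits_the_clamp(self):
        model = BindingModel()
        insert = embed("ATTTGAAATGCAAAT")
        ch = channel_weights([insert], model, bob1=True, insert_length=35)[0]
        assert ch[2] >= model.clamp.clamp_gain * model.pore_affinity


class TestSelectRound:
    def test_zero_affinity_library_collapses(self):
        mat = np.zeros((8, 4))
        mat[:, 0] = 1.0  # poly-A is the only bindable word
        model = BindingModel(psam=Psam(matrix=mat, reference="A" * 8),
                             more_affinity=0.0, pore_affinity=0.0)
        library = ["C" * 35] * 100
        rng = np.random.default_rng(0)
        with pytest.raises(SimulationCollapseError):
            select_round(library, model, Condition("POU1"), "monomer", 1.0, rng)

    def test_uniform_consensus_library_retains_a_over_a_plus_s(self):
        model = BindingModel()
        library = [embed("ATGCAAAT")] * 4000
        rng = np.random.default_rng(3)
        selected = select_round(library, model, Condition("POU1"), "monomer", 1.0, rng)
        # p = 1/(1+1) = 0.5; binomial(4000, 0.5) three-sigma band
        assert abs(len(selected) - 2000) < 3 * np.sqrt(4000 * 0.25)

    def test_fixed_rng_state_is_deterministic(self):
        model = BindingModel()
        library = random_library(500, 35, np.random.default_rng(5))
        a = select_round(library, model, Condition("POU1"), "monomer", 1.0,
                         np.random.default_rng(9))
        b = select_round(library, model, Condition("POU1"), "monomer", 1.0,
                         np.random.default_rng(9))
        assert a == b


class TestAmplify:
    def test_single_sequence_fills_pool(self):
        out = amplify(["A" * 35], 50, np.random.default_rng(0))
        assert out == ["A" * 35] * 50

    def test_resampling_preserves_proportions(self):
        pool = ["A" * 35] * 5000 + ["C" * 35] * 5000
        out = amplify(pool, 10_000, np.random.default_rng(12))
        n_a = sum(s[0] == "A" for s in out)
        assert stats.chisquare([n_a, 10_000 - n_a]).pvalue > 0.01

    def test_target_equal_to_input_size(self):
        pool = ["A" * 35, "C" * 35]
        assert len(amplify(pool, 2, np.random.default_rng(1))) == 2


class TestRunSelex:
    def test_zero_rounds_returns_initial_library(self):
        cfg = SimulationConfig(library_size=200, rounds=0,
                               conditions=(Condition("POU1"),), seed=2)
        res = run_selex(cfg)
        cres = res.per_condition["POU1"]
        assert len(cres.rounds) == 1
        assert len(cres.final) == 200

    def test_identical_configs_give_byte_identical_outputs(self):
        cfg = SimulationConfig(library_size=2000, rounds=2,
                               conditions=(Condition("POU1"), Condition("POU1", True)),
                               seed=11)
        r1, r2 = run_selex(cfg), run_selex(cfg)
        for label in r1.per_condition:
            for s1, s2 in zip(r1.per_condition[label].rounds,
                              r2.per_condition[label].rounds):
                assert s1.inserts == s2.inserts

    def test_flat_model_selection_is_neutral(self):
        # with a flat PSAM and no dimer elements every molecule binds
        # identically, so the selected pool is an unbiased subsample
        model = BindingModel(psam=flat_psam(), more_affinity=0.0, pore_affinity=0.0)
        rng = np.random.default_rng(21)
        library = random_library(20_000, 35, rng)
        selected = select_round(library, model, Condition("POU1"), "monomer",
                                1.0, np.random.default_rng(22))
        pat = DegeneratePattern()
        before = census(ReadSet("before", library), pat)
        after = census(ReadSet("after", selected), pat)
        words = sorted(set(before.counts) | set(after.counts))
        obs = np.array([[before.counts.get(w, 0) for w in words],
                        [after.counts.get(w, 0) for w in words]])
        keep = obs.sum(axis=0) >= 10  # chi-square validity
        p = stats.chi2_contingency(obs[:, keep]).pvalue
        assert p > 0.01

    def test_ground_truth_logs_every_round(self, small_sim):
        logs = small_sim.ground_truth.round_logs
        assert [l.round for l in logs] == [1, 2]
        assert all(0 < l.n_selected <= l.n_input for l in logs)
        label = next(iter(small_sim.per_condition))
        classes = small_sim.ground_truth.final_classes[label]
        assert len(classes) == len(small_sim.per_condition[label].final)
        assert set(classes) <= {"monomer", "dimer", "ternary"}

    def test_duplex_word_affinity(self, small_sim):
        truth = small_sim.ground_truth
        # ATTTGAAT is the reverse-complement readout of ATTCAAAT
        assert truth.word_affinity("ATTTGAAT") == pytest.approx(
            site_affinity("ATTCAAAT", truth.model.psam)
        )
        assert truth.word_affinity("ATTTGAAT", duplex=False) < 0.1


class TestEmitRawReads:
    def test_default_flanks_give_72_nt_records(self, tmp_path, small_sim):
        label = next(iter(small_sim.per_condition))
        rs = small_sim.per_condition[label].final
        path = tmp_path / "raw.fastq"
        emit_raw_reads(rs, path)
        reads = read_sequences(path, "fastq")
        assert len(reads) == len(rs)
        assert {len(r.sequence) for r in reads} == {72}

    def test_round_trip_through_trimming(self, tmp_path, small_sim):
        label = next(iter(small_sim.per_condition))
        rs = small_sim.per_condition[label].final
        path = tmp_path / "raw.fastq"
        emit_raw_reads(rs, path)
        back, rejected = trim_reads(read_sequences(path, "fastq"), TrimPolicy())
        assert rejected == 0
        assert back.inserts == rs.inserts

    def test_empty_readset(self, tmp_path):
        path = tmp_path / "empty.fastq"
        emit_raw_reads(ReadSet("x", []), path)
        assert read_sequences(path, "fastq") == []


class TestEnrichmentBehavior:
    def test_consensus_word_rank_one_in_monomer_band(self, directional_sim):
        table = bx.census(directional_sim.per_condition["POU1"].final)
        ranking = bx.top_n(table, 1)
        assert ranking.entries[0][0] == "ATGCAAAT"

    def test_ternary_band_sites_are_a5_pure(self, directional_sim):
        comp = best_site_composition(
            directional_sim.per_condition["POU1+BOB1"].final,
            directional_sim.model,
            Condition("POU1", bob1=True),
        )
        assert comp.percent(5, "A") > 95.0
        assert comp.percent(5, "T") < 1.0
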