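"""Enrichment simulator, patient profiling and FASTQ emission."""

import numpy as np
import pandas as pd
import pytest

from adaptseq.design import default_design
from adaptseq.reads import parse_fastq
from adaptseq.simulate import (
    AffinityModel,
    EnrichmentConfig,
    PlasmaModel,
    equimolar_state,
    make_naive_library,
    make_patient,
    pcr_amplify,
    run_enrichment,
    select_l2000,
    selection_round,
    simulate_cohort_matrix,
    simulate_patient_counts,
    default_profiling_system,
    write_fastq,
)


def _toy_system(n_seqs, affinities, abundance=1.0, background=1.0):
    """One target; per-sequence affinities as given."""
    plasma = PlasmaModel("toy", np.array([abundance]), np.array([True]))
    aff = AffinityModel(
        target_of=np.zeros(n_seqs, dtype=np.int64),
        affinity=np.asarray(affinities, dtype=float),
        background=background,
    )
    return plasma, aff


class TestNaiveLibrary:
    def test_zero_dispersion_equal_copies(self):
        st = make_naive_library(10, abundance_sd_log=0.0, seed=1)
        assert st.unique_count == 10
        assert np.allclose(st.copies, st.copies[0])

    def test_same_seed_reproduces(self):
        a = make_naive_library(50, 0.3, seed=9)
        b = make_naive_library(50, 0.3, seed=9)
        assert list(a.sequences) == list(b.sequences)
        assert np.array_equal(a.copies, b.copies)

    def test_mean_copies_low_single_digits(self):
        st = make_naive_library(20000, 0.3, seed=2)
        assert st.unique_count == 20000
        assert 2.0 < st.mean_copies < 4.5

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ValueError):
            make_naive_library(0)


class TestSelectionRound:
    def test_neutral_selection_preserves_composition(self):
        st = make_naive_library(200, 0.0, seed=3, mean_copies=500.0)
        plasma, aff = _toy_system(200, np.zeros(200))
        out = selection_round(st, plasma, aff, "positive", capture_depth=50000, seed=4)
        shares = np.zeros(200)
        shares[np.searchsorted(st.ids, out.ids)] = out.shares()
        assert np.allclose(shares, 1 / 200, atol=3e-3)

    def test_planted_binder_share_increases(self):
        st = make_naive_library(100, 0.0, seed=5, mean_copies=100.0)
        affinities = np.zeros(100)
        affinities[0] = 50.0
        plasma, aff = _toy_system(100, affinities)
        out = selection_round(st, plasma, aff, "positive", capture_depth=2000, seed=6)
        assert out.shares()[out.ids == st.ids[0]][0] > 1 / 100

    def test_counter_selection_depletes_binders(self):
        st = make_naive_library(100, 0.0, seed=7, mean_copies=100.0)
        affinities = np.zeros(100)
        affinities[0] = 50.0
        plasma, aff = _toy_system(100, affinities)
        out = selection_round(st, plasma, aff, "counter", capture_depth=2000, seed=8)
        binder_share = out.shares()[np.isin(out.ids, st.ids[0])]
        assert binder_share.size == 0 or binder_share[0] < 1 / 100

    def test_unique_count_never_increases(self):
        st = make_naive_library(500, 0.3, seed=9)
        plasma, aff = _toy_system(500, np.zeros(500))
        out = selection_round(st, plasma, aff, "positive", capture_depth=200, seed=10)
        assert out.unique_count <= st.unique_count

    def test_empty_population_rejected(self):
        st = make_naive_library(5, 0.0, seed=1)
        st = st.__class__(universe=st.universe, ids=st.ids[:0], copies=st.copies[:0])
        plasma, aff = _toy_system(5, np.zeros(5))
        with pytest.raises(ValueError):
            selection_round(st, plasma, aff, "positive", 10, seed=1)


class TestPCR:
    def test_zero_cycles_identity(self):
        st = make_naive_library(10, 0.3, seed=1)
        out = pcr_amplify(st, cycles=0, efficiency=0.9)
        assert np.array_equal(out.copies, st.copies)

    def test_perfect_efficiency_doubles_per_cycle(self):
        st = make_naive_library(10, 0.0, seed=1, mean_copies=2.0)
        out = pcr_amplify(st, cycles=3, efficiency=1.0, noise_sdlog=0.0)
        assert np.allclose(out.copies, st.copies * 8)

    def test_amplification_adds_no_sequences(self):
        st = make_naive_library(10, 0.3, seed=1)
        out = pcr_amplify(st, cycles=5, efficiency=0.5, seed=3, noise_sdlog=0.2)
        assert out.unique_count == st.unique_count


class TestEnrichment:
    def test_diversity_collapse_and_arm_specificity(self):
        cfg = EnrichmentConfig(n_unique=20000, seed=21)
        run = run_enrichment(cfg)
        uniq = run.per_iteration["unique"].tolist()
        assert uniq[0] < cfg.n_unique
        assert all(b < a for a, b in zip(uniq, uniq[1:]))
        mc = run.per_iteration["mean_copies"].tolist()
        assert all(b > a for a, b in zip(mc, mc[1:]))
        # planted disease binders enrich in the disease arm only
        cb = run.ground_truth["cancer_binders"]
        share_l1 = run.l1.copies[np.isin(run.l1.ids, cb)].sum() / run.l1.total_copies
        share_l2 = run.l2.copies[np.isin(run.l2.ids, cb)].sum() / run.l2.total_copies
        assert share_l1 > 10 * max(share_l2, 1e-12)

    def test_neutral_affinities_no_arm_divergence(self):
        cfg = EnrichmentConfig(n_unique=5000, affinity_mean=1e-9, seed=22)
        run = run_enrichment(cfg)
        cb = run.ground_truth["cancer_binders"]
        share_l1 = run.l1.copies[np.isin(run.l1.ids, cb)].sum() / run.l1.total_copies
        share_l2 = run.l2.copies[np.isin(run.l2.ids, cb)].sum() / run.l2.total_copies
        # planted ids are ordinary sequences here: shares small and similar
        assert abs(share_l1 - share_l2) < 0.02

    def test_identical_config_reproduces(self):
        a = run_enrichment(EnrichmentConfig(n_unique=3000, seed=5))
        b = run_enrichment(EnrichmentConfig(n_unique=3000, seed=5))
        assert np.array_equal(a.l3.ids, b.l3.ids)
        assert np.array_equal(a.l3.copies, b.l3.copies)


class TestSelectL2000:
    def _stats(self, n, n_planted, seed=0):
        r = np.random.default_rng(seed)
        p = pd.DataFrame(
            {
                "p_t": r.uniform(size=n),
                "p_wilcoxon": r.uniform(size=n),
                "p_ks": r.uniform(size=n),
                "fold_change": r.lognormal(0, 0.1, size=n),
            },
            index=[f"seq{i}" for i in range(n)],
        )
        p.iloc[:n_planted, 0] = r.uniform(0, 1e-4, size=n_planted)
        return p

    def test_planted_features_recalled_above_chance(self):
        stats = self._stats(10000, 50, seed=1)
        chosen = select_l2000(stats, n=500)
        planted = {f"seq{i}" for i in range(50)}
        recall = len(planted & set(chosen)) / 50
        assert recall > 0.9  # hypergeometric chance level would be 0.05

    def test_saturation_returns_all_with_warning(self):
        stats = self._stats(100, 5)
        with pytest.warns(UserWarning, match="candidates"):
            chosen = select_l2000(stats, n=2000)
        assert len(chosen) == 100

    def test_equimolar_library(self):
        st = equimolar_state(["A" * 35, "C" * 35])
        assert np.allclose(st.copies, 1.0)
        assert st.branch == "L2000"


class TestPatientProfiling:
    def test_counts_sum_exactly_to_depth(self):
        lib, plasma, aff = default_profiling_system(n_sequences=300, seed=1)
        pat = make_patient(plasma, "p", seed=2)
        counts = simulate_patient_counts(lib, pat, aff, depth=12345, seed=3, n_replicates=3)
        assert counts.shape == (300, 3)
        assert (counts.sum(axis=0) == 12345).all()

    def test_technical_replicates_highly_concordant(self):
        lib, plasma, aff = default_profiling_system(seed=4)
        pat = make_patient(plasma, "p", seed=5)
        c = simulate_patient_counts(lib, pat, aff, depth=1_000_000, seed=6, n_replicates=2)
        r = np.corrcoef(c[:, 0], c[:, 1])[0, 1]
        assert r >= 0.99

    def test_patients_distinct_but_correlated(self):
        lib, plasma, aff = default_profiling_system(seed=7)
        a = simulate_patient_counts(lib, make_patient(plasma, "a", seed=8), aff, 1_000_000, seed=9)
        b = simulate_patient_counts(lib, make_patient(plasma, "b", seed=10), aff, 1_000_000, seed=11)
        r = np.corrcoef(a[:, 0], b[:, 0])[0, 1]
        assert 0.5 < r < 0.99


class TestCohortMatrix:
    def test_shapes_and_labels(self):
        data, labels, info = simulate_cohort_matrix(
            n_features=100, group_sizes={"cancer": 10, "control": 12}, n_informative=5, seed=1
        )
        assert data.shape == (100, 22)
        assert (labels.value_counts() == pd.Series({"control": 12, "cancer": 10})).all()
        assert len(info) == 5

    def test_informative_features_shifted_up_in_target_group(self):
        data, labels, info = simulate_cohort_matrix(
            n_features=200, group_sizes={"cancer": 200, "control": 200},
            n_informative=20, effect_size=1.0, seed=2,
        )
        logx = np.log(data.to_numpy())
        cancer = labels.to_numpy() == "cancer"
        deltas = logx[:, cancer].mean(axis=1) - logx[:, ~cancer].mean(axis=1)
        assert deltas[:20].mean() == pytest.approx(1.0, abs=0.15)
        assert abs(deltas[20:].mean()) < 0.05


class TestWriteFastq:
    def test_exact_record_count_and_layout(self, design3, tmp_path):
        seq = "ACGT" * 8 + "AGC"
        path = tmp_path / "t.fastq"
        n = write_fastq({"s1": {seq: 3}}, design3, path, error_rate=0.0, seed=1)
        lines = path.read_text().splitlines()
        assert n == 3 and len(lines) == 12
        for i in (1, 5, 9):
            assert seq + design3.reverse_primer + design3.i7_indices["s1"] in lines[i]

    def test_same_seed_byte_identical(self, design3, tmp_path):
        counts = {"s1": {"A" * 35: 5, "C" * 35: 2}}
        p1, p2 = tmp_path / "a.fastq", tmp_path / "b.fastq"
        write_fastq(counts, design3, p1, error_rate=0.01, seed=42)
        write_fastq(counts, design3, p2, error_rate=0.01, seed=42)
        assert p1.read_bytes() == p2.read_bytes()

    def test_error_rate_degrades_strict_parsing_only(self, design3, tmp_path):
        counts = {"s1": {"ACGTA" * 7: 2000}}
        path = tmp_path / "e.fastq"
        write_fastq(counts, design3, path, error_rate=0.01, seed=3)
        v0 = parse_fastq(path, design3, anchor_mismatch_tol=0, index_mismatch_tol=0).run_qc.valid_reads
        v1 = parse_fastq(path, design3, anchor_mismatch_tol=1, index_mismatch_tol=1).run_qc.valid_reads
        assert v0 < v1 < 2000

    def test_unknown_sample_rejected(self, design3, tmp_path):
        with pytest.raises(KeyError, match="no i7 index"):
            write_fastq({"nope": {"A" * 35: 1}}, design3, tmp_path / "x.fastq")
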