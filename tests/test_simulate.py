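"""The K80 library simulator: model correctness, truth accounting, determinism."""

import numpy as np
import pytest
from scipy import stats

import barcodekit as bk
from barcodekit.simulate import (
    MergeMode,
    SplitMode,
    _k80_transition_probs,
    random_coding_sequence,
)


class TestRandomCodingSequence:
    def test_length_and_frame(self):
        rng = np.random.default_rng(1)
        seq = random_coding_sequence(658, rng=rng)
        assert len(seq) == 658
        frame, stops = bk.find_reading_frame_and_stops(seq)
        assert stops == 0

    def test_never_flagged_by_qc_over_many_draws(self):
        rng = np.random.default_rng(2)
        recs = [
            bk.SequenceRecord(record_id=f"s{i}", sequence=random_coding_sequence(600, rng=rng))
            for i in range(200)
        ]
        _, report = bk.qc_filter(bk.ReferenceLibrary(records=recs))
        assert report.counts["stop_codon"] == 0
        assert report.counts["pass"] == 200

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            random_coding_sequence(2)


class TestEvolveK80:
    def test_transition_probabilities_are_stochastic_matrix(self):
        for t in (0.0, 0.01, 0.1, 1.0):
            P = _k80_transition_probs(t, kappa=4.0)
            assert np.allclose(P.sum(axis=1), 1.0)
            assert (P >= 0).all()

    def test_expected_substitution_rate_normalized(self):
        # derivative of off-diagonal mass at t=0 equals 1 substitution/site
        eps = 1e-6
        P = _k80_transition_probs(eps, kappa=4.0)
        assert (1 - np.trace(P) / 4) / eps == pytest.approx(1.0, rel=1e-3)

    def test_zero_branch_identity(self):
        rng = np.random.default_rng(3)
        seq = random_coding_sequence(300, rng=rng)
        assert bk.evolve_k80(seq, 0.0, rng=rng) == seq

    def test_k2p_estimator_recovers_branch_length(self):
        rng = np.random.default_rng(4)
        seq = random_coding_sequence(658, rng=rng)
        n_rep = 300
        ests = []
        for _ in range(n_rep):
            mut = bk.evolve_k80(seq, 0.05, kappa=4.0, rng=rng)
            c = bk.count_site_patterns(seq, mut)
            d = bk.k2p_from_counts(c)
            assert d is not None
            ests.append(d)
        se = np.std(ests, ddof=1) / np.sqrt(n_rep)
        assert abs(np.mean(ests) - 0.05) < 3 * se

    def test_transition_fraction_increases_with_kappa(self):
        rng = np.random.default_rng(5)
        seq = random_coding_sequence(658, rng=rng)
        ratios = []
        for kappa in (1.0, 4.0, 16.0):
            ts = tv = 0
            for _ in range(50):
                mut = bk.evolve_k80(seq, 0.08, kappa=kappa, rng=rng)
                c = bk.count_site_patterns(seq, mut)
                ts += c.n_transitions
                tv += c.n_transversions
            ratios.append(ts / max(tv, 1))
        assert ratios[0] < ratios[1] < ratios[2]


class TestSimulateLibrary:
    def test_uncorrupted_config_structure(self):
        cfg = bk.SimulationConfig(n_species=5, records_per_species=3, seed=6)
        lib, truth = bk.simulate_library(cfg)
        assert len(lib) == 15
        assert len(set(lib.species_labels())) == 5
        assert (truth.table["corruption"] == "").all()

    def test_determinism_byte_identical_output(self, tmp_path):
        cfg = bk.SimulationConfig(n_species=6, seed=7, misid_rate=0.1)
        for sub in ("one", "two"):
            lib, truth = bk.simulate_library(cfg)
            bk.write_library(lib, truth, tmp_path / sub)
        for name in ("library.fasta", "library_specimens.tsv", "library_truth.tsv",
                     "library_config.yaml"):
            assert (tmp_path / "one" / name).read_bytes() == (
                tmp_path / "two" / name
            ).read_bytes()

    def test_different_seeds_differ(self):
        lib1, _ = bk.simulate_library(bk.SimulationConfig(n_species=4, seed=1))
        lib2, _ = bk.simulate_library(bk.SimulationConfig(n_species=4, seed=2))
        assert [r.sequence for r in lib1] != [r.sequence for r in lib2]

    def test_misid_count_within_binomial_interval(self):
        n = 600
        rate = 0.05
        cfg = bk.SimulationConfig(
            n_species=n // 3, records_per_species=3, misid_rate=rate, seed=8
        )
        lib, truth = bk.simulate_library(cfg)
        k = (truth.table["corruption"] == "misid").sum()
        lo, hi = stats.binom.interval(0.999, len(lib), rate)
        assert lo <= k <= hi

    def test_split_mode_yields_grade_c(self):
        cfg = bk.SimulationConfig(
            n_species=4,
            records_per_species=6,
            bin_mode=SplitMode(k=2, divergence=0.03, n_species=1),
            seed=9,
        )
        lib, truth = bk.simulate_library(cfg)
        grades = bk.assign_grades(bk.eligible_records(lib))
        assert (grades["grade"] == "C").sum() == 1
        split_species = grades[grades["grade"] == "C"]["species"].item()
        n_bins = truth.table[truth.table["true_species"] == split_species][
            "true_bin"
        ].nunique()
        assert n_bins == 2

    def test_merge_mode_yields_grade_e_pair(self):
        cfg = bk.SimulationConfig(
            n_species=4,
            records_per_species=4,
            bin_mode=MergeMode(pairs=[(0, 1)]),
            seed=10,
        )
        lib, _ = bk.simulate_library(cfg)
        grades = bk.assign_grades(bk.eligible_records(lib))
        assert (grades["grade"] == "E").sum() == 2

    def test_merge_pair_out_of_range_rejected(self):
        cfg = bk.SimulationConfig(
            n_species=3, records_per_species=2, bin_mode=MergeMode(pairs=[(0, 7)])
        )
        with pytest.raises(ValueError):
            bk.simulate_library(cfg)

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            bk.SimulationConfig(misid_rate=0.7, missing_name_rate=0.4)
        with pytest.raises(ValueError):
            bk.SimulationConfig(misid_rate=-0.1)


class TestInjectLabelErrors:
    def _lib(self, seed=11):
        cfg = bk.SimulationConfig(n_species=10, records_per_species=4, seed=seed)
        return bk.simulate_library(cfg)

    def test_zero_rates_noop(self):
        lib, truth = self._lib()
        out, truth2 = bk.inject_label_errors(lib, truth, rng=np.random.default_rng(0))
        assert [r.species_name for r in out] == [r.species_name for r in lib]
        assert (truth2.table["corruption"] == "").all()

    def test_misid_logged_with_old_and_new(self):
        lib, truth = self._lib()
        out, truth2 = bk.inject_label_errors(
            lib, truth, misid_rate=0.5, rng=np.random.default_rng(1)
        )
        log = truth2.corrupted("misid")
        assert len(log) > 0
        for _, row in log.iterrows():
            assert row["replaced_with"] == row["observed_species"]
            assert row["observed_species"] != row["true_species"]
            assert out[row["record_id"]].species_name == row["observed_species"]

    def test_blanking_reduces_strict_species_fraction(self):
        cfg = bk.SimulationConfig(
            n_species=100, records_per_species=3, missing_name_rate=0.3, seed=12
        )
        lib, truth = bk.simulate_library(cfg)
        strict = sum(
            bk.identification_rank(r, "strict_public") == bk.Rank.SPECIES for r in lib
        )
        lo, hi = stats.binom.interval(0.999, len(lib), 0.7)
        assert lo <= strict <= hi
        blanked = truth.table["corruption"] == "blanked"
        assert strict == len(lib) - blanked.sum()

    def test_coded_names_are_genus_rank_strict(self):
        lib, truth = self._lib()
        out, truth2 = bk.inject_label_errors(
            lib, truth, coded_name_rate=0.4, rng=np.random.default_rng(2)
        )
        for rid in truth2.corrupted("coded")["record_id"]:
            rec = out[rid]
            assert " sp. " in rec.species_name
            assert bk.identification_rank(rec, "strict_public") == bk.Rank.GENUS
            assert bk.identification_rank(rec, "permissive_local") == bk.Rank.SPECIES
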