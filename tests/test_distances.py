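"""K2P distance estimation against independent oracles."""

import math
import subprocess
import textwrap

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import barcodekit as bk
from barcodekit import PairwiseSiteCounts

from conftest import make_record


def k2p_textbook(n, ts, tv):
    """Independent closed-form evaluation of the K2P estimator."""
    p, q = ts / n, tv / n
    w1, w2 = 1 - 2 * p - q, 1 - 2 * q
    if w1 <= 0 or w2 <= 0:
        return None
    return -0.5 * math.log(w1 * math.sqrt(w2))


class TestSitePatterns:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ("ACGT", "ACGT", (4, 0, 0)),
            ("AAAAAAAAAA", "GGAAAAAACA", (10, 2, 1)),
            ("ACGT", "ACNT", (3, 0, 0)),
            ("AC-T", "ACGT", (3, 0, 0)),
            ("AG", "GA", (2, 2, 0)),
            ("AC", "CA", (2, 0, 2)),
        ],
    )
    def test_counts(self, a, b, expected):
        c = bk.count_site_patterns(a, b)
        assert (c.n_sites, c.n_transitions, c.n_transversions) == expected

    def test_length_mismatch_instructs_alignment(self):
        with pytest.raises(ValueError, match="align"):
            bk.count_site_patterns("ACGT", "ACG")


class TestK2PFromCounts:
    def test_zero_distance(self):
        assert bk.k2p_from_counts(PairwiseSiteCounts(100, 0, 0)) == 0.0

    def test_worked_value(self):
        # P=0.2, Q=0.1: d = -0.5*ln(0.5) - 0.25*ln(0.8) = 0.402359...
        d = bk.k2p_from_counts(PairwiseSiteCounts(10, 2, 1), min_overlap=1)
        assert d == pytest.approx(0.402359, abs=5e-7)

    def test_saturation_boundary_undefined(self):
        assert bk.k2p_from_counts(PairwiseSiteCounts(100, 40, 20)) is None

    def test_below_min_overlap_undefined(self):
        assert bk.k2p_from_counts(PairwiseSiteCounts(99, 0, 0), min_overlap=100) is None

    def test_matches_textbook_evaluation_on_random_triples(self):
        rng = np.random.default_rng(123)
        checked = 0
        for _ in range(1000):
            n = int(rng.integers(100, 700))
            ts = int(rng.integers(0, n // 2))
            tv = int(rng.integers(0, n - ts))
            ours = bk.k2p_from_counts(PairwiseSiteCounts(n, ts, tv))
            ref = k2p_textbook(n, ts, tv)
            if ref is None:
                assert ours is None
            else:
                assert ours == pytest.approx(ref, abs=1e-12)
                checked += 1
        assert checked > 100  # the sweep must exercise the defined branch

    @given(
        n=st.integers(400, 700),
        ts=st.integers(0, 200),
        tv=st.integers(0, 200),
    )
    @settings(max_examples=200, deadline=None)
    def test_k2p_at_least_p_distance(self, n, ts, tv):
        d = bk.k2p_from_counts(PairwiseSiteCounts(n, ts, tv))
        if d is not None:
            assert d >= (ts + tv) / n - 1e-12


class TestDistanceMatrix:
    def test_identical_records_zero(self):
        seq = "ACGT" * 50
        lib = bk.ReferenceLibrary(records=[make_record("a", seq), make_record("b", seq)])
        m = bk.distance_matrix(lib)
        assert m.values[0, 1] == 0.0
        assert m.defined.all()

    def test_single_record_rejected(self):
        lib = bk.ReferenceLibrary(records=[make_record("a", "ACGT" * 50)])
        with pytest.raises(ValueError):
            bk.distance_matrix(lib)

    def test_matches_per_pair_oracle(self, small_matrix_library):
        m = bk.distance_matrix(small_matrix_library, min_overlap=50)
        recs = list(small_matrix_library)
        for i, ri in enumerate(recs):
            for j, rj in enumerate(recs):
                if i == j:
                    continue
                c = bk.count_site_patterns(ri.sequence, rj.sequence)
                ref = bk.k2p_from_counts(c, min_overlap=50)
                if ref is None:
                    assert not m.defined[i, j]
                else:
                    assert m.values[i, j] == pytest.approx(ref, abs=1e-14)

    def test_long_format_output_carries_site_counts(self, small_matrix_library, tmp_path):
        import pandas as pd

        m = bk.distance_matrix(small_matrix_library, min_overlap=50)
        out = tmp_path / "long.tsv"
        m.write_long_tsv(out)
        df = pd.read_csv(out, sep="\t")
        assert len(df) == len(m) * (len(m) - 1) // 2
        assert (df["n_sites"] == 300).all()

    def test_permutation_equivariance(self, small_matrix_library):
        m = bk.distance_matrix(small_matrix_library, min_overlap=50)
        perm = m.labels[::-1]
        mp = m.reorder(perm)
        for a in m.labels:
            for b in m.labels:
                i, j = m.labels.index(a), m.labels.index(b)
                pi, pj = perm.index(a), perm.index(b)
                assert m.values[i, j] == mp.values[pi, pj]

    def test_simulated_intraspecific_mean_near_target(self):
        # star phylogeny: two intra branches of 0.005 -> expected pair distance 0.01
        cfg = bk.SimulationConfig(
            n_species=10, records_per_species=6, intra_branch=0.005,
            inter_branch=0.04, seed=21,
        )
        lib, _ = bk.simulate_library(cfg)
        m = bk.distance_matrix(lib)
        labels = np.array(lib.species_labels())
        intra = [
            m.values[i, j]
            for i in range(len(lib))
            for j in range(i + 1, len(lib))
            if labels[i] == labels[j]
        ]
        # intra pairs share branch realizations, so the standard error of
        # the mean follows from the 60 independent branches, not the 150
        # pairs: Var(branch) ~ t/L, pair distance = sum of two branches
        se = 2 * np.sqrt(0.005 / 658 / 60)
        assert abs(np.mean(intra) - 0.01) < 3 * se

    def test_agrees_with_r_ape_dist_dna(self, small_matrix_library, tmp_path):
        """Cross-check the whole matrix path against ape::dist.dna (K80)."""
        fasta = tmp_path / "lib.fasta"
        bk.write_fasta(fasta, [(r.record_id, r.sequence) for r in small_matrix_library])
        script = tmp_path / "k80.R"
        script.write_text(
            textwrap.dedent(
                f"""
                suppressMessages(library(ape))
                seqs <- read.dna("{fasta}", format = "fasta")
                d <- dist.dna(seqs, model = "K80", pairwise.deletion = TRUE)
                write.table(as.matrix(d), "{tmp_path}/d.tsv", sep = "\\t")
                """
            )
        )
        subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
        import pandas as pd

        ref = pd.read_csv(tmp_path / "d.tsv", sep="\t").to_numpy()
        ours = bk.distance_matrix(small_matrix_library, min_overlap=50)
        assert np.allclose(ref, ours.values, atol=1e-8)


class TestSpeciesSummary:
    def _matrix(self, labels, vals):
        vals = np.asarray(vals, dtype=float)
        return bk.DistanceMatrix(
            labels=labels, values=vals, defined=~np.isnan(vals), min_overlap=1
        )

    def test_two_species_constructed(self):
        # within-species 0.01, between 0.08
        v = 0.01
        b = 0.08
        m = self._matrix(
            ["a1", "a2", "b1", "b2"],
            [[0, v, b, b], [v, 0, b, b], [b, b, 0, v], [b, b, v, 0]],
        )
        df = bk.species_distance_summary(m, ["A", "A", "B", "B"])
        assert df.set_index("species").loc["A", "max_intra_pct"] == pytest.approx(1.0)
        assert df.set_index("species").loc["A", "nn_inter_pct"] == pytest.approx(8.0)
        assert (df["nearest_neighbor_species"] == ["B", "A"]).all()

    def test_singleton_has_undefined_intra(self):
        m = self._matrix(["a", "b"], [[0, 0.05], [0.05, 0]])
        df = bk.species_distance_summary(m, ["A", "B"])
        assert df["max_intra_pct"].isna().all()
        assert (df["nn_inter_pct"] == 5.0).all()

    def test_saturated_intra_pair_warns(self):
        nan = np.nan
        m = self._matrix(
            ["a1", "a2", "b"], [[0, nan, 0.05], [nan, 0, 0.05], [0.05, 0.05, 0]]
        )
        with pytest.warns(UserWarning, match="undefined"):
            df = bk.species_distance_summary(m, ["A", "A", "B"])
        assert np.isnan(df.set_index("species").loc["A", "max_intra_pct"])

    def test_max_at_least_mean(self, separated_library):
        lib, _ = separated_library
        m = bk.distance_matrix(lib)
        df = bk.species_distance_summary(m, lib.species_labels())
        both = df.dropna(subset=["max_intra_pct"])
        assert (both["max_intra_pct"] >= both["mean_intra_pct"] - 1e-12).all()


class TestBarcodeGap:
    def test_pair_classification_counts(self):
        seqs = ["ACGT" * 60] * 4
        lib = bk.ReferenceLibrary(
            records=[make_record(f"r{i}", s) for i, s in enumerate(seqs)]
        )
        m = bk.distance_matrix(lib)
        table = bk.barcode_gap_table(m, ["A", "A", "B", "B"])
        assert len(table[""]["intra"]) == 2
        assert len(table[""]["inter"]) == 4
        # total = C(4,2)
        assert len(table[""]["intra"]) + len(table[""]["inter"]) == 6

    def test_single_species_no_inter(self):
        lib = bk.ReferenceLibrary(
            records=[make_record("a", "ACGT" * 60), make_record("b", "ACGT" * 60)]
        )
        m = bk.distance_matrix(lib)
        table = bk.barcode_gap_table(m, ["A", "A"])
        assert len(table[""]["inter"]) == 0

    def test_grouping_conserves_pairs(self, separated_library):
        lib, _ = separated_library
        m = bk.distance_matrix(lib)
        groups = ["G1"] * len(lib)
        table = bk.barcode_gap_table(m, lib.species_labels(), groups)
        for kind in ("intra", "inter"):
            assert len(table["G1"][kind]) == len(table[""][kind])
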