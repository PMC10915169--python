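import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ribodyn import codons as cod
from ribodyn import profiles as pio


# ---------------------------------------------------------------------------
# FASTA ingestion
# ---------------------------------------------------------------------------


class TestReadCdsFasta:
    def test_basic_record(self, tmp_path):
        p = tmp_path / "cds.fasta"
        p.write_text(">g1\nATGGCTTAA\n")
        gs = pio.read_cds_fasta(p)
        assert gs.ids == ["g1"]
        assert gs.codons("g1") == ["ATG", "GCT", "TAA"]
        assert gs.length_codons("g1") == 3

    def test_u_mapped_and_case_folded(self, tmp_path):
        p = tmp_path / "cds.fasta"
        p.write_text(">g1\naugGcuTaA\n")
        assert pio.read_cds_fasta(p).codons("g1") == ["ATG", "GCT", "TAA"]

    def test_length_not_divisible_by_three(self, tmp_path):
        p = tmp_path / "cds.fasta"
        p.write_text(">badgene\nATGGCTTAAG\n")
        with pytest.raises(pio.InvalidCdsError, match="badgene"):
            pio.read_cds_fasta(p)

    def test_duplicate_id(self, tmp_path):
        p = tmp_path / "cds.fasta"
        p.write_text(">g1\nATGGCTTAA\n>g1\nATGGCTTAA\n")
        with pytest.raises(pio.DuplicateGeneIdError, match="g1"):
            pio.read_cds_fasta(p)

    def test_invalid_character(self, tmp_path):
        p = tmp_path / "cds.fasta"
        p.write_text(">g1\nATGGNTTAA\n")
        with pytest.raises(pio.InvalidCdsError, match="g1"):
            pio.read_cds_fasta(p)

    def test_fasta_roundtrip(self, tiny_genes, tmp_path):
        p = tmp_path / "out.fasta"
        pio.write_cds_fasta(tiny_genes, p)
        back = pio.read_cds_fasta(p)
        assert back.ids == tiny_genes.ids
        for g in tiny_genes:
            assert back.codons(g) == tiny_genes.codons(g)


# ---------------------------------------------------------------------------
# Profile tables
# ---------------------------------------------------------------------------


class TestReadProfileTable:
    def _write(self, tmp_path, rows):
        p = tmp_path / "prof.tsv"
        body = "".join(f"{g}\t{i}\t{c}\n" for g, i, c in rows)
        p.write_text("gene_id\tposition\tcount\n" + body)
        return p

    def test_dense_vector_with_zero_fill(self, tmp_path, tiny_genes):
        p = self._write(tmp_path, [("g1", 0, 2), ("g1", 5, 1)])
        t = pio.read_profile_table(p, "c", genes=tiny_genes)
        np.testing.assert_array_equal(t.counts["g1"], [2, 0, 0, 0, 0, 1, 0, 0, 0])

    def test_empty_body(self, tmp_path):
        p = self._write(tmp_path, [])
        t = pio.read_profile_table(p, "c")
        assert t.gene_ids == []

    def test_out_of_range_position(self, tmp_path, tiny_genes):
        p = self._write(tmp_path, [("g1", 9, 1)])
        with pytest.raises(pio.ProfileFormatError, match="g1.*9"):
            pio.read_profile_table(p, "c", genes=tiny_genes)

    def test_negative_count(self, tmp_path):
        p = self._write(tmp_path, [("g1", 0, -3)])
        with pytest.raises(pio.ProfileFormatError, match="negative"):
            pio.read_profile_table(p, "c")

    def test_missing_header(self, tmp_path):
        p = tmp_path / "prof.tsv"
        p.write_text("g1\t0\t2\n")
        with pytest.raises(pio.ProfileFormatError):
            pio.read_profile_table(p, "c")

    def test_write_read_roundtrip(self, tmp_path, tiny_genes, uniform_track):
        p = tmp_path / "prof.tsv"
        pio.write_profile_table(uniform_track, p)
        back = pio.read_profile_table(p, "c", genes=tiny_genes)
        for g in uniform_track.counts:
            np.testing.assert_array_equal(back.counts[g], uniform_track.counts[g])


class TestAverageReplicates:
    def _track(self, v, cond="c"):
        return pio.ProfileTrack(cond, None, {"g": np.array(v, dtype=float)})

    def test_elementwise_mean(self):
        avg = pio.average_replicates([self._track([2, 0, 4]), self._track([0, 0, 2])])
        np.testing.assert_array_equal(avg.counts["g"], [1, 0, 3])

    def test_single_track_identity(self):
        t = self._track([1, 2, 3])
        np.testing.assert_array_equal(
            pio.average_replicates([t]).counts["g"], t.counts["g"]
        )

    def test_three_tracks(self):
        avg = pio.average_replicates(
            [self._track([3, 0]), self._track([0, 0]), self._track([0, 3])]
        )
        np.testing.assert_array_equal(avg.counts["g"], [1, 1])

    def test_mixed_conditions_rejected(self):
        with pytest.raises(ValueError, match="condition"):
            pio.average_replicates([self._track([1]), self._track([1], cond="d")])

    def test_mismatched_genes_lists_difference(self):
        a = pio.ProfileTrack("c", None, {"g1": np.ones(3)})
        b = pio.ProfileTrack("c", None, {"g2": np.ones(3)})
        with pytest.raises(ValueError, match="g1.*g2"):
            pio.average_replicates([a, b])

    def test_permutation_invariance(self):
        tracks = [self._track([1, 2]), self._track([5, 0]), self._track([0, 4])]
        a = pio.average_replicates(tracks)
        b = pio.average_replicates(tracks[::-1])
        np.testing.assert_array_equal(a.counts["g"], b.counts["g"])


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------


def _gene_of_length(n_nt, gid="g", fill=1.0):
    seq = ("ATG" + "GCT" * (n_nt // 3 - 1))[:n_nt]
    gs = pio.GeneSet.from_sequences({gid: seq})
    track = pio.ProfileTrack("c", None, {gid: np.full(n_nt, fill)})
    return gs, track


class TestFilterGenes:
    def test_short_gene_excluded(self):
        gs, track = _gene_of_length(198, fill=100.0)
        with pytest.warns(UserWarning, match="no genes"):
            assert len(pio.filter_genes(gs, track, min_reads_per_nt=0.5)) == 0

    def test_boundary_coverage_inclusive(self):
        gs, _ = _gene_of_length(300)
        track = pio.ProfileTrack("c", None, {"g": np.zeros(300)})
        track.counts["g"][0] = 150  # mean exactly 0.5
        assert pio.filter_genes(gs, track, preset="prok").ids == ["g"]

    def test_below_boundary_excluded(self):
        gs, _ = _gene_of_length(300)
        track = pio.ProfileTrack("c", None, {"g": np.zeros(300)})
        track.counts["g"][0] = 149
        with pytest.warns(UserWarning):
            assert len(pio.filter_genes(gs, track, preset="prok")) == 0

    def test_euk_preset_stricter(self):
        gs, track = _gene_of_length(300, fill=1.0)  # mean 1.0 reads/nt
        assert pio.filter_genes(gs, track, preset="prok").ids == ["g"]
        with pytest.warns(UserWarning):
            assert len(pio.filter_genes(gs, track, preset="euk")) == 0


class TestTopGenes:
    def _setup(self, densities):
        seqs = {g: "ATG" + "GCT" * 2 for g in densities}
        gs = pio.GeneSet.from_sequences(seqs)
        track = pio.ProfileTrack(
            "c", None, {g: np.full(9, d) for g, d in densities.items()}
        )
        return gs, track

    def test_selects_highest(self):
        gs, track = self._setup({"a": 5.0, "b": 1.0, "c": 3.0})
        assert set(pio.top_genes_by_density(gs, track, 2).ids) == {"a", "c"}

    def test_n_equal_count_identity(self):
        gs, track = self._setup({"a": 5.0, "b": 1.0})
        assert set(pio.top_genes_by_density(gs, track, 2).ids) == {"a", "b"}

    def test_tie_broken_lexicographically(self):
        gs, track = self._setup({"zz": 3.0, "aa": 3.0})
        assert pio.top_genes_by_density(gs, track, 1).ids == ["aa"]

    def test_n_too_large(self):
        gs, track = self._setup({"a": 1.0})
        with pytest.raises(ValueError):
            pio.top_genes_by_density(gs, track, 2)


# ---------------------------------------------------------------------------
# Codon density and transforms
# ---------------------------------------------------------------------------


class TestCodonDensity:
    def test_sum_of_three_nt(self):
        gs = pio.GeneSet.from_sequences({"g": "ATGGCT"})
        track = pio.ProfileTrack("c", None, {"g": np.array([1, 2, 3, 4, 5, 6.0])})
        cd = pio.codon_density(track, gs)
        np.testing.assert_array_equal(cd.values["g"], [6, 15])

    def test_all_zero(self):
        gs = pio.GeneSet.from_sequences({"g": "ATGGCT"})
        track = pio.ProfileTrack("c", None, {"g": np.zeros(6)})
        np.testing.assert_array_equal(
            pio.codon_density(track, gs).values["g"], [0, 0]
        )

    def test_single_codon(self):
        gs = pio.GeneSet.from_sequences({"g": "ATG"})
        track = pio.ProfileTrack("c", None, {"g": np.array([0, 0, 7.0])})
        np.testing.assert_array_equal(pio.codon_density(track, gs).values["g"], [7])

    def test_length_mismatch(self):
        gs = pio.GeneSet.from_sequences({"g": "ATGGCT"})
        track = pio.ProfileTrack("c", None, {"g": np.zeros(9)})
        with pytest.raises(ValueError, match="g"):
            pio.codon_density(track, gs)

    def test_conservation_property(self, sim_small):
        _, genes, track, _ = sim_small
        cd = pio.codon_density(track, genes)
        for g in genes:
            assert cd.values[g].sum() == pytest.approx(
                track.counts[g].sum(), rel=1e-12
            )


class TestNormalizeAndLog:
    def test_uniform_gene(self):
        cd = pio.CodonDensity({"g": np.full(30, 4.0)})
        out = pio.normalize_and_log(cd)
        np.testing.assert_allclose(out.values["g"], np.log2(1.5))
        assert out.transform == "log"

    def test_double_mean_value(self):
        v = np.ones(30)
        v[15] = 2.0
        cd = pio.CodonDensity({"g": v})
        out = pio.normalize_and_log(cd)
        mean = v[10:20].mean()
        assert out.values["g"][15] == pytest.approx(np.log2(2.0 / mean + 0.5))

    def test_all_zero_gene_dropped(self):
        cd = pio.CodonDensity({"g": np.zeros(30)})
        with pytest.warns(UserWarning, match="dropped"):
            out = pio.normalize_and_log(cd)
        assert out.values == {}

    def test_normalized_mean_is_one(self, sim_small):
        _, genes, track, _ = sim_small
        norm = pio.normalize(pio.codon_density(track, genes))
        for g in norm.values:
            assert norm.values[g][10:-10].mean() == pytest.approx(1.0, abs=1e-9)

    def test_requires_raw(self):
        cd = pio.CodonDensity({"g": np.ones(30)}, transform="log")
        with pytest.raises(pio.TransformError):
            pio.normalize_and_log(cd)


# ---------------------------------------------------------------------------
# Pause scores
# ---------------------------------------------------------------------------


class TestPauseScores:
    def test_uniform_density_scores_one(self, sim_small):
        _, genes, _, _ = sim_small
        cd = pio.CodonDensity(
            {g: np.full(genes.length_codons(g), 3.0) for g in genes}
        )
        table = pio.pause_scores(cd, genes)
        np.testing.assert_allclose(table.instances["score"], 1.0)

    def test_instance_scores_match_example(self):
        # retained codon values [4, 0, 0, 0] -> scores [4, 0, 0, 0]
        gs = pio.GeneSet(
            {"g": np.zeros(24, dtype=np.int16)}  # 24 codons of AAA
        )
        v = np.zeros(24)
        v[10] = 4.0  # retained region is 10..13
        cd = pio.CodonDensity({"g": v})
        table = pio.pause_scores(cd, gs)
        np.testing.assert_allclose(
            table.instances["score"], [4.0, 0.0, 0.0, 0.0]
        )

    def test_per_gene_mean_is_one(self, sim_small):
        _, genes, track, _ = sim_small
        table = pio.pause_scores(pio.codon_density(track, genes), genes)
        for _, grp in table.instances.groupby("gene"):
            assert grp["score"].mean() == pytest.approx(1.0, abs=1e-9)

    def test_zscore_normalization(self, sim_small):
        _, genes, track, _ = sim_small
        table = pio.pause_scores(pio.codon_density(track, genes), genes)
        z = table.codon_z.dropna()
        assert z.mean() == pytest.approx(0.0, abs=1e-9)
        assert z.std(ddof=0) == pytest.approx(1.0, abs=1e-9)
        assert len(table.codon_scores) == 61  # sense codons only

    def test_degenerate_sd_gives_zeros(self, sim_small):
        _, genes, _, _ = sim_small
        cd = pio.CodonDensity(
            {g: np.full(genes.length_codons(g), 2.0) for g in genes}
        )
        table = pio.pause_scores(cd, genes)
        np.testing.assert_array_equal(table.codon_z.dropna(), 0.0)

    def test_missing_codon_type_reported_nan(self):
        gs = pio.GeneSet({"g": np.zeros(30, dtype=np.int16)})  # only AAA
        cd = pio.CodonDensity({"g": np.ones(30)})
        table = pio.pause_scores(cd, gs)
        assert table.codon_scores.loc["AAA"] == pytest.approx(1.0)
        assert table.codon_scores.drop("AAA").isna().all()


# ---------------------------------------------------------------------------
# Window dataset
# ---------------------------------------------------------------------------


def brute_force_centers(L, W, trim=10):
    """Independent enumeration of valid window centers."""
    return [
        c
        for c in range(L)
        if c - W >= 0 and c + W <= L - 1 and trim <= c <= L - 1 - trim
    ]


def _window_inputs(L, seed=0):
    from conftest import make_geneset

    gs = make_geneset(L, seed=seed)
    rng = np.random.default_rng(seed)
    raw = pio.CodonDensity({"g1": rng.uniform(1, 5, size=L)})
    return gs, pio.normalize_and_log(raw), pio.normalize(raw)


class TestBuildWindows:
    @pytest.mark.parametrize(
        "L,W",
        [(61, 20), (41, 20), (25, 1), (70, 20), (100, 5), (21, 1), (40, 20)],
    )
    def test_instance_count_matches_enumeration(self, L, W):
        gs, ref, tgt = _window_inputs(L)
        ds = pio.build_windows(gs, ref, tgt, W=W)
        assert len(ds) == len(brute_force_centers(L, W))

    def test_sixty_one_codon_gene_gives_21(self):
        gs, ref, tgt = _window_inputs(61)
        ds = pio.build_windows(gs, ref, tgt, W=20)
        assert len(ds) == 21
        assert ds.center_index.min() == 20 and ds.center_index.max() == 40

    def test_seq_window_roundtrip(self):
        gs, ref, tgt = _window_inputs(80, seed=3)
        ds = pio.build_windows(gs, ref, tgt, W=7)
        cod = gs.codon_indices("g1")
        for i in range(len(ds)):
            c = ds.center_index[i]
            np.testing.assert_array_equal(ds.seq[i], cod[c - 7 : c + 8])
            np.testing.assert_array_equal(ds.ref[i], ref.values["g1"][c - 7 : c + 8])
            assert ds.target[i] == tgt.values["g1"][c]

    def test_invalid_w(self):
        gs, ref, tgt = _window_inputs(61)
        with pytest.raises(ValueError):
            pio.build_windows(gs, ref, tgt, W=0)

    def test_requires_log_reference(self):
        gs, _, tgt = _window_inputs(61)
        with pytest.raises(pio.TransformError):
            pio.build_windows(gs, tgt, tgt, W=5)


# ---------------------------------------------------------------------------
# Dataset splitting
# ---------------------------------------------------------------------------


def _dummy_ds(n, W=2):
    return pio.WindowDataset(
        seq=np.zeros((n, 2 * W + 1), dtype=np.int16),
        ref=np.zeros((n, 2 * W + 1)),
        target=np.zeros(n),
        gene=np.array(["g"] * n, dtype=object),
        center_index=np.arange(n),
        W=W,
    )


class TestSplitDataset:
    def test_fraction_sizes_70_15_15(self):
        split = pio.split_dataset(_dummy_ds(100), seed=1)
        assert len(split.indices("train")) == 70
        assert len(split.indices("val")) == 15
        assert len(split.indices("test")) == 15

    def test_kfold_each_fold_size_one(self):
        split = pio.split_dataset(_dummy_ds(10), mode="kfold", k=10, seed=1)
        sizes = [len(split.indices(f)) for f in range(10)]
        assert sizes == [1] * 10

    def test_same_seed_identical(self):
        a = pio.split_dataset(_dummy_ds(53), seed=9)
        b = pio.split_dataset(_dummy_ds(53), seed=9)
        np.testing.assert_array_equal(a.assignment, b.assignment)

    def test_k_exceeds_count(self):
        with pytest.raises(ValueError):
            pio.split_dataset(_dummy_ds(5), mode="kfold", k=10)

    def test_empty_dataset(self):
        with pytest.raises(ValueError):
            pio.split_dataset(_dummy_ds(0))

    @settings(max_examples=40, deadline=None)
    @given(
        n=st.integers(3, 400),
        seed=st.integers(0, 2**31),
        mode=st.sampled_from(["fraction", "kfold"]),
    )
    def test_partitions_disjoint_and_exhaustive(self, n, seed, mode):
        k = min(5, n)
        split = pio.split_dataset(_dummy_ds(n), mode=mode, seed=seed, k=k)
        labels = ["train", "val", "test"] if mode == "fraction" else list(range(k))
        parts = [split.indices(l) for l in labels]
        all_idx = np.concatenate(parts)
        assert len(all_idx) == n
        assert len(np.unique(all_idx)) == n
        if mode == "fraction":
            assert abs(len(parts[0]) - 0.70 * n) <= 1
            assert abs(len(parts[1]) - 0.15 * n) <= 1
            assert abs(len(parts[2]) - 0.15 * n) <= 1


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------


def test_export_codon_density_format(tmp_path):
    cd = pio.CodonDensity({"g": np.array([1.0, 2.5])})
    out = tmp_path / "cd.tsv"
    pio.export_codon_density(cd, out)
    lines = out.read_text().splitlines()
    assert lines[0] == "gene_id\tcodon_index\tvalue"
    assert lines[1] == "g\t0\t1.000000"
    assert lines[2] == "g\t1\t2.500000"
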