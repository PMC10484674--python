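"""ChEC binding analytics: enrichment, motif scanning, spike-in, bound calls."""

import numpy as np
import pandas as pd
import pytest

from nucdyn.binding import (assign_motif_zones, categorize_motifs,
                            category_background, classify_bound_motifs,
                            gene_body_promoter_ratio, motif_occupancy,
                            preference_similarity, promoter_preference,
                            pwm_log_odds, regulator_enrichment, scan_motifs,
                            sensor_level_at_motif_groups,
                            spikein_absolute_binding, tf_change_by_region)
from nucdyn.coverage import CoverageTrack

LAYOUT = {"chr1": 3000}


def track_from(arr):
    return CoverageTrack({"chr1": np.asarray(arr, dtype=float)})


def motif_df(*rows):
    return pd.DataFrame([
        {"chrom": "chr1", "start": s, "end": e, "strand": strand, "category": cat}
        for s, e, strand, cat in rows
    ])


class TestRegulatorEnrichment:
    def test_symmetric_spacing_column(self):
        occ = pd.DataFrame({"T": [1.0, 2.0, 4.0]}, index=["r1", "r2", "r3"])
        np.testing.assert_allclose(regulator_enrichment(occ)["T"], [-1, 0, 1])

    def test_degenerate_column_set_to_zero(self):
        occ = pd.DataFrame({"T": [3.0, 3.0, 3.0], "U": [1.0, 2.0, 4.0]}, index=list("abc"))
        enr = regulator_enrichment(occ)
        np.testing.assert_allclose(enr["T"], 0.0)

    def test_matches_bruteforce_standardization_oracle(self):
        rng = np.random.default_rng(0)
        occ = pd.DataFrame(rng.random((6, 12)) + 0.1,
                           index=[f"r{i}" for i in range(6)],
                           columns=[f"T{j}" for j in range(12)])
        enr = regulator_enrichment(occ)
        logv = np.log2(occ.to_numpy())
        expected = (logv - logv.mean(axis=0)) / logv.std(axis=0, ddof=1)
        np.testing.assert_allclose(enr.to_numpy(), expected, rtol=1e-12)

    def test_columns_standardized(self):
        rng = np.random.default_rng(1)
        occ = pd.DataFrame(rng.random((5, 4)) + 0.1)
        enr = regulator_enrichment(occ)
        np.testing.assert_allclose(enr.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(enr.std(axis=0, ddof=1), 1.0, rtol=1e-12)


class TestPromoterPreference:
    PROMS = pd.DataFrame([
        {"gene": "g1", "chrom": "chr1", "start": 100, "end": 400},
        {"gene": "g2", "chrom": "chr1", "start": 800, "end": 1500},
    ])

    def test_signal_is_interval_sum_and_scale_invariant_similarity(self):
        rng = np.random.default_rng(2)
        track = track_from(rng.random(3000))
        sig = promoter_preference(track, self.PROMS)
        assert sig["g1"] == pytest.approx(track.data["chr1"][100:400].sum())
        assert preference_similarity(sig, sig) == pytest.approx(1.0)
        assert preference_similarity(sig, sig * 3.0) == pytest.approx(1.0)

    def test_orthogonal_spikes_anticorrelated(self):
        proms = pd.DataFrame([
            {"gene": f"g{i}", "chrom": "chr1", "start": 100 * i, "end": 100 * i + 50}
            for i in range(10)
        ])
        a, b = np.zeros(3000), np.zeros(3000)
        a[110] = 100.0   # g1 only
        b[210] = 100.0   # g2 only
        sa = promoter_preference(track_from(a), proms)
        sb = promoter_preference(track_from(b), proms)
        assert preference_similarity(sa, sb) < 0


class TestScanMotifs:
    CONSENSUS = "ACGTGACTCA"

    def _pwm(self):
        pwm = np.full((4, 10), 0.01)
        for j, b in enumerate(self.CONSENSUS):
            pwm["ACGT".index(b), j] = 0.97
        return pwm / pwm.sum(axis=0, keepdims=True)

    def test_planted_consensus_found_once_forward(self):
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list("AC"), 500))  # G/T-free background: no chance hits
        seq = seq[:200] + self.CONSENSUS + seq[210:]
        hits = scan_motifs(self._pwm(), {"chr1": seq})
        fwd = hits[hits["strand"] == "+"]
        assert list(fwd["start"]) == [200]

    def test_reverse_complement_hit_on_minus_strand(self):
        rc = self.CONSENSUS.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        seq = "A" * 100 + rc + "A" * 100
        hits = scan_motifs(self._pwm(), {"chr1": seq})
        assert list(hits["strand"]) == ["-"] and hits.iloc[0]["start"] == 100

    def test_matches_exhaustive_window_oracle(self):
        rng = np.random.default_rng(4)
        seq = "".join(rng.choice(list("ACGT"), 2000))
        pwm = rng.dirichlet(np.ones(4), size=8).T  # soft 8-bp PWM
        lod = pwm_log_odds(pwm)
        threshold = 0.4 * float(np.max(lod, axis=0).sum())
        hits = scan_motifs(pwm, {"chr1": seq}, threshold=threshold)
        # oracle: enumerate every window on both strands
        comp = str.maketrans("ACGT", "TGCA")
        expected = []
        for i in range(len(seq) - 7):
            win = seq[i:i + 8]
            for strand, w in (("+", win), ("-", win.translate(comp)[::-1])):
                score = sum(lod["ACGT".index(b), j] for j, b in enumerate(w))
                if score >= threshold:
                    expected.append((i, strand, score))
        assert len(hits) == len(expected)
        for (_, h), (pos, strand, score) in zip(hits.iterrows(),
                                                sorted(expected, key=lambda x: (x[0], x[1]))):
            assert (h["start"], h["strand"]) == (pos, strand)
            assert h["score"] == pytest.approx(score, rel=1e-9)

    def test_sequence_shorter_than_motif_gives_empty(self):
        assert scan_motifs(self._pwm(), {"chr1": "ACGT"}).empty


class TestCategorizeMotifs:
    GENES = pd.DataFrame([{"gene": "g1", "chrom": "chr1", "start": 1000, "end": 2000, "strand": "+"}])
    SPECIALS = pd.DataFrame([
        {"type": "telomere", "chrom": "chr1", "start": 0, "end": 300},
        {"type": "rRNA37", "chrom": "chr1", "start": 2500, "end": 2800},
    ])

    @pytest.mark.parametrize("start,expected", [
        (1500, "gene_body"),
        (500, "promoter"),       # intergenic
        (100, "telomere"),
        (2600, "rRNA"),
    ])
    def test_priority_assignment(self, start, expected):
        m = motif_df((start, start + 10, "+", None))
        out = categorize_motifs(m.drop(columns="category"), self.GENES, self.SPECIALS)
        assert out.iloc[0]["category"] == expected

    def test_telomere_beats_overlapping_gene(self):
        genes = pd.DataFrame([{"gene": "g", "chrom": "chr1", "start": 100, "end": 900, "strand": "+"}])
        m = motif_df((200, 210, "+", None)).drop(columns="category")
        out = categorize_motifs(m, genes, self.SPECIALS)
        assert out.iloc[0]["category"] == "telomere"


class TestMotifOccupancy:
    def test_uniform_track_constant_rows(self):
        motifs = motif_df((500, 510, "+", "promoter"), (1000, 1010, "-", "gene_body"))
        matrix, means = motif_occupancy(track_from(np.full(3000, 2.0)), motifs, halfwidth=20)
        np.testing.assert_allclose(matrix[list(range(-20, 21))].to_numpy(), 2.0)
        np.testing.assert_allclose(means.to_numpy(), 2.0)

    def test_spike_at_center_lands_in_column_zero(self):
        arr = np.zeros(3000)
        arr[505] = 9.0  # center of the 500..510 motif
        matrix, _ = motif_occupancy(track_from(arr), motif_df((500, 510, "+", "promoter")), halfwidth=10)
        row = matrix.iloc[0]
        assert row[0] == 9.0 and row[list(range(-10, 0))].sum() == 0

    def test_rows_sorted_by_category_then_total_desc(self):
        arr = np.zeros(3000)
        arr[505], arr[1005] = 1.0, 5.0
        motifs = motif_df((500, 510, "+", "promoter"), (1000, 1010, "+", "promoter"))
        matrix, means = motif_occupancy(track_from(arr), motifs, halfwidth=10)
        assert list(matrix["total"]) == [5.0, 1.0]
        # category mean equals mean of rows recomputed independently
        np.testing.assert_allclose(
            means.loc["promoter"].to_numpy(),
            matrix[list(range(-10, 11))].to_numpy().mean(axis=0))

    def test_edge_motif_padded_with_missing(self):
        matrix, _ = motif_occupancy(track_from(np.ones(3000)), motif_df((0, 10, "+", "promoter")),
                                    halfwidth=20)
        row = matrix.iloc[0][list(range(-20, 21))].to_numpy(dtype=float)
        assert np.isnan(row[:15]).all() and (row[16:] == 1.0).all()


class TestSpikeIn:
    WINDOWS = [("chr1", 100, 150), ("chr1", 300, 350), ("chr1", 600, 650)]

    def _track(self):
        arr = np.zeros(3000)
        for c, s, e in self.WINDOWS:
            arr[s:e] = 2.0  # 3 windows x 50 bp x 2 = 300 spike mass
        arr[1000:1100] = 10.0  # around gene-body motif
        arr[2000:2100] = 4.0   # around promoter motif
        return track_from(arr)

    MOTIFS = motif_df((1045, 1055, "+", "gene_body"), (2045, 2055, "+", "promoter"))

    def test_division_arithmetic(self):
        res = spikein_absolute_binding(self._track(), self.WINDOWS, self.MOTIFS)
        assert res.spikein_reads == pytest.approx(300.0)
        assert res.absolute_binding["gene_body"] == pytest.approx(10.0 / 300.0)
        assert res.absolute_binding["promoter"] == pytest.approx(4.0 / 300.0)

    def test_depth_rescaling_invariance(self):
        t = self._track()
        a = spikein_absolute_binding(t, self.WINDOWS, self.MOTIFS)
        b = spikein_absolute_binding(t.scale(2.0), self.WINDOWS, self.MOTIFS)
        for cat in ("gene_body", "promoter"):
            assert a.absolute_binding[cat] == pytest.approx(b.absolute_binding[cat])

    def test_requires_three_windows_and_nonzero_mass(self):
        with pytest.raises(ValueError):
            spikein_absolute_binding(self._track(), self.WINDOWS[:2], self.MOTIFS)
        with pytest.raises(ValueError):
            spikein_absolute_binding(track_from(np.zeros(3000)), self.WINDOWS, self.MOTIFS)


class TestGeneBodyPromoterRatio:
    MOTIFS = motif_df((1045, 1055, "+", "gene_body"), (2045, 2055, "+", "promoter"))

    def _track(self, gb, prom):
        arr = np.zeros(3000)
        arr[1050 - 80: 1050 + 81] = gb
        arr[2050 - 80: 2050 + 81] = prom
        return track_from(arr)

    @pytest.mark.parametrize("gb,prom,expected", [(2.0, 2.0, 0.0), (4.0, 1.0, 2.0)])
    def test_log_ratio(self, gb, prom, expected):
        assert gene_body_promoter_ratio(self._track(gb, prom), self.MOTIFS) == pytest.approx(expected)

    def test_scale_invariance_and_positional_variant(self):
        t = self._track(4.0, 1.0)
        assert gene_body_promoter_ratio(t.scale(11.0), self.MOTIFS) == pytest.approx(2.0)
        positions = {"gene_body": [("chr1", 970, 1131)], "promoter": [("chr1", 1970, 2131)]}
        assert gene_body_promoter_ratio(t, positions=positions) == pytest.approx(2.0)


class TestClassifyBoundMotifs:
    MOTIFS = motif_df((1045, 1055, "+", "gene_body"), (2045, 2055, "+", "promoter"))

    def _call(self, window_level, bg):
        arr = np.zeros(3000)
        arr[1050 - 80: 1050 + 81] = window_level
        out = classify_bound_motifs(track_from(arr), self.MOTIFS.iloc[:1],
                                    {"gene_body": bg})
        return out.iloc[0]

    def test_exactly_twofold_is_bound_inclusive(self):
        assert self._call(2.0, 1.0)["bound"] == True  # noqa: E712

    def test_below_threshold_unbound(self):
        row = self._call(1.9, 1.0)
        assert row["bound"] == False and row["group"] == "gene_body-unbound"  # noqa: E712

    def test_monotone_in_occupancy(self):
        levels = np.linspace(0.5, 4.0, 15)
        calls = [bool(self._call(lv, 1.0)["bound"]) for lv in levels]
        assert calls == sorted(calls)  # once bound, higher occupancy stays bound

    def test_zero_background_unclassified(self):
        row = self._call(2.0, 0.0)
        assert pd.isna(row["bound"])

    def test_partition_into_four_groups(self, default_genome):
        genome, truth = default_genome
        from nucdyn.coverage import SampleMeta
        from nucdyn.synthgen import expected_chec_coverage
        cov = expected_chec_coverage(
            genome, SampleMeta("none", "Msn2", 0, 1, "ChEC"), truth)
        bg = category_background(cov, genome.genes, genome.specials)
        calls = classify_bound_motifs(cov, genome.motifs, bg)
        assert set(calls["group"]) <= {"promoter-bound", "promoter-unbound",
                                       "gene_body-bound", "gene_body-unbound"}
        assert calls["bound"].notna().all()


class TestSensorLevels:
    MOTIFS = motif_df((1045, 1055, "+", "gene_body"), (2045, 2055, "+", "promoter")).assign(
        group=["gene_body-bound", "promoter-unbound"])

    def test_uniform_track_equal_groups(self):
        tracks = {0: track_from(np.full(3000, 3.0))}
        out = sensor_level_at_motif_groups(tracks, self.MOTIFS)
        np.testing.assert_allclose(out["level"], 3.0)

    def test_single_motif_group_is_window_mean(self):
        arr = np.zeros(3000)
        arr[1050 - 75: 1050 + 76] = np.linspace(1, 2, 151)
        out = sensor_level_at_motif_groups({0: track_from(arr)}, self.MOTIFS)
        got = out[out["group"] == "gene_body-bound"]["level"].iloc[0]
        assert got == pytest.approx(np.linspace(1, 2, 151).mean())

    def test_pooled_mean_equals_weighted_mean_of_per_motif_means(self):
        rng = np.random.default_rng(6)
        arr = rng.random(3000)
        motifs = motif_df((500, 510, "+", "gene_body"), (1200, 1210, "-", "gene_body"),
                          (2500, 2510, "+", "gene_body")).assign(group="gene_body-bound")
        out = sensor_level_at_motif_groups({0: track_from(arr)}, motifs, halfwidth=30)
        per_motif = [arr[505 - 30: 505 + 31].mean(), arr[1205 - 30: 1205 + 31].mean(),
                     arr[2505 - 30: 2505 + 31].mean()]
        assert out["level"].iloc[0] == pytest.approx(np.mean(per_motif))


class TestTfChangeByRegion:
    def test_zone_assignment_and_stratified_change(self, toy_genes, toy_nucleosomes):
        from nucdyn.features import add_expression_groups, assign_features
        feats = add_expression_groups(
            assign_features(toy_genes, toy_nucleosomes), toy_genes)
        # motif inside gA's 5' region (gA: 1000-2000, 5p = 1000-1350)
        motifs = motif_df((1195, 1205, "+", "gene_body")).assign(chrom="chrA")
        zoned = assign_motif_zones(motifs, feats)
        assert zoned.iloc[0]["zone"] == "5p"
        layout = {"chrA": 5000, "chrB": 3000}

        def mk(mult):
            arrs = {c: np.full(n, 5.0) for c, n in layout.items()}
            arrs["chrA"][1120:1281] *= mult  # the motif's +/-80 window
            return CoverageTrack(arrs)

        tracks = {(0, 1): mk(1.0), (60, 1): mk(2.0)}
        tab = tf_change_by_region(tracks, zoned, pseudocount=0.0)
        row = tab[(tab["zone"] == "5p")].iloc[0]
        assert row["change"] == pytest.approx(1.0, abs=1e-12)

    def test_no_change_all_strata_zero(self, toy_genes, toy_nucleosomes):
        from nucdyn.features import add_expression_groups, assign_features
        feats = add_expression_groups(
            assign_features(toy_genes, toy_nucleosomes), toy_genes)
        motifs = motif_df((1195, 1205, "+", "gene_body"),
                          (3400, 3410, "+", "gene_body")).assign(chrom="chrA")
        zoned = assign_motif_zones(motifs, feats)
        track = CoverageTrack({"chrA": np.full(5000, 5.0), "chrB": np.full(3000, 5.0)})
        tab = tf_change_by_region({(0, 1): track, (60, 1): track}, zoned)
        np.testing.assert_allclose(tab["change"], 0.0, atol=1e-12)
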