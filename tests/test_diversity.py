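"""Alpha/beta diversity: closed forms, oracles, and ordination properties."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import pdist, squareform

from biogeocycler import (
    CopyNumberTable,
    ValidationError,
    alpha_diversity,
    bray_curtis,
    nmds,
    qpcr_summary,
    relative_abundance,
    similarity_clusters,
)
from biogeocycler.synthetic import CommunityTruth, simulate_otu_table
from conftest import make_otu


class TestAlphaDiversity:
    def test_hand_computed_closed_forms(self, toy_otu_table):
        report = alpha_diversity(toy_otu_table)
        # S1 = [5,1,1,2]: S=4, F1=2, F2=1 -> chao1 = 4 + 2*1/(2*2) = 4.5
        s1 = report.loc["S1"]
        assert s1["otus"] == 4
        assert s1["chao1"] == pytest.approx(4.5)
        assert s1["goods_coverage"] == pytest.approx(1 - 2 / 9)

    def test_uniform_identities(self, toy_otu_table):
        # S2 = [3,3,3,3]: H = ln 4, J = 1, no singletons -> chao1 = S_obs
        s2 = alpha_diversity(toy_otu_table).loc["S2"]
        assert s2["shannon"] == pytest.approx(np.log(4))
        assert s2["pielou"] == pytest.approx(1.0)
        assert s2["chao1"] == pytest.approx(4.0)

    def test_no_singletons_full_coverage(self, toy_otu_table):
        # S3 = [8,2,0,0]: F1 = 0 -> Good's coverage = 1
        assert alpha_diversity(toy_otu_table).loc["S3", "goods_coverage"] == 1.0

    def test_skbio_oracle_agreement(self):
        """Independent cross-check of Chao1/Shannon/Pielou against scikit-bio."""
        from skbio.diversity.alpha import chao1, pielou_e, shannon

        rng = np.random.default_rng(4)
        counts = rng.integers(0, 30, size=(5, 40))
        counts[:, 0] += 1  # no empty sample
        table = make_otu(counts)
        report = alpha_diversity(table)
        for i, sample in enumerate(table.sample_ids):
            assert report.loc[sample, "chao1"] == pytest.approx(chao1(counts[i]))
            assert report.loc[sample, "shannon"] == pytest.approx(
                shannon(counts[i], base=np.e))
            assert report.loc[sample, "pielou"] == pytest.approx(
                pielou_e(counts[i]))

    def test_empty_sample_named(self):
        table = make_otu([[1, 2], [0, 0]])
        with pytest.raises(ValidationError, match="S2"):
            alpha_diversity(table)

    def test_singleton_sample_pielou_zero(self):
        assert alpha_diversity(make_otu([[7, 0]])).loc["S1", "pielou"] == 0.0


class TestRelativeAbundance:
    def test_two_phyla_30_70(self, toy_otu_table):
        comp = relative_abundance(toy_otu_table, rank="phylum")
        # S3 = [8,2,0,0]: Proteobacteria 10/10, Firmicutes 0
        assert comp.loc["S3", "Proteobacteria"] == pytest.approx(1.0)
        # S2 uniform: 50/50
        assert comp.loc["S2", "Firmicutes"] == pytest.approx(0.5)
        assert np.allclose(comp.sum(axis=1), 1.0)

    def test_unclassified_pooling(self):
        table = make_otu([[3, 7]])
        table.lineage.iloc[1] = "Bacteria;" + ";".join(["unclassified"] * 5)
        comp = relative_abundance(table, rank="phylum")
        assert comp.loc["S1", "unclassified"] == pytest.approx(0.7)

    def test_unknown_rank_rejected(self, toy_otu_table):
        with pytest.raises(ValidationError):
            relative_abundance(toy_otu_table, rank="kingdom")

    def test_planted_phylum_mass_recovered(self):
        """A community planted at ~66% Proteobacteria-labelled mass yields a
        ~0.66 phylum fraction back (generator round-trip)."""
        rng = np.random.default_rng(8)
        n_prot, n_other = 20, 30
        counts = np.hstack([
            rng.multinomial(66_000, np.ones(n_prot) / n_prot, size=4),
            rng.multinomial(34_000, np.ones(n_other) / n_other, size=4),
        ])
        otus = [f"O{i}" for i in range(n_prot + n_other)]
        lineage = pd.Series(
            ["Bacteria;Proteobacteria;C;O;F;G"] * n_prot
            + ["Bacteria;Acidobacteria;C;O;F;G"] * n_other, index=otus)
        from biogeocycler import OtuTable

        table = OtuTable(
            counts=pd.DataFrame(counts, index=list("ABCD"), columns=otus),
            lineage=lineage)
        comp = relative_abundance(table, rank="phylum")
        assert comp["Proteobacteria"].mean() == pytest.approx(0.66, abs=0.01)


class TestBrayCurtis:
    def test_identical_and_disjoint(self):
        table = make_otu([[4, 6, 0], [4, 6, 0], [0, 0, 5]])
        bc = bray_curtis(table)
        assert bc.loc["S1", "S2"] == pytest.approx(0.0)
        assert bc.loc["S1", "S3"] == pytest.approx(1.0)

    def test_hand_value_on_counts(self):
        # x=[1,1,0], y=[0,1,1]: 1 - 2*1/4 = 0.5
        bc = bray_curtis(make_otu([[1, 1, 0], [0, 1, 1]]), transform="none")
        assert bc.loc["S1", "S2"] == pytest.approx(0.5)

    def test_depth_invariance_under_relative(self):
        a = make_otu([[10, 30, 60], [50, 30, 20]])
        b = make_otu([[100, 300, 600], [5, 3, 2]])
        pd.testing.assert_frame_equal(bray_curtis(a), bray_curtis(b))

    @given(st.integers(min_value=0, max_value=2 ** 31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_metric_properties(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.integers(0, 50, size=(4, 8))
        counts[:, 0] += 1
        bc = bray_curtis(make_otu(counts)).to_numpy()
        assert np.allclose(bc, bc.T)
        assert np.allclose(np.diag(bc), 0.0)
        assert (bc >= -1e-12).all() and (bc <= 1 + 1e-12).all()


class TestNmds:
    def test_exact_planar_embedding_reaches_tiny_stress(self):
        pts = np.random.default_rng(0).standard_normal((7, 2))
        d = squareform(pdist(pts))
        res = nmds(d, seed=1)
        assert res.stress < 1e-3

    def test_stress_non_increasing_within_run(self):
        rng = np.random.default_rng(3)
        d = squareform(pdist(rng.standard_normal((10, 4))))
        res = nmds(d, n_restarts=3, seed=5)
        hist = res.stress_history
        assert all(b <= a + 1e-12 for a, b in zip(hist, hist[1:]))

    def test_rank_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(6)
        d = squareform(pdist(rng.standard_normal((9, 3))))
        s1 = nmds(d, seed=7).stress
        s2 = nmds(np.sqrt(d), seed=7).stress  # strictly increasing transform
        assert abs(s1 - s2) < 1e-3

    def test_configuration_centered(self):
        d = squareform(pdist(np.random.default_rng(1).standard_normal((6, 2))))
        res = nmds(d, seed=2)
        assert np.allclose(res.coordinates.mean(axis=0), 0.0, atol=1e-10)

    def test_planted_groups_separate(self):
        truth = CommunityTruth.grouped(2, 5, 40, effect=3.0)
        bc = bray_curtis(simulate_otu_table(truth, seed=13))
        res = nmds(bc, seed=14)
        coords = res.coordinates
        groups = truth.group_assignment
        within, between = [], []
        for a in coords.index:
            for b in coords.index:
                if a >= b:
                    continue
                dist = np.linalg.norm(coords.loc[a] - coords.loc[b])
                (within if groups[a] == groups[b] else between).append(dist)
        assert max(within) < min(between)

    def test_asymmetric_input_rejected(self):
        d = np.array([[0.0, 1.0], [0.5, 0.0]])
        with pytest.raises(ValidationError):
            nmds(d)


class TestSimilarityClusters:
    def test_cut_100_every_sample_alone(self):
        rng = np.random.default_rng(0)
        d = squareform(pdist(rng.standard_normal((5, 3))))
        labels = similarity_clusters(d, 100)
        assert labels.nunique() == 5

    def test_tiny_cut_single_cluster(self):
        d = np.array([[0, 0.3, 0.4], [0.3, 0, 0.35], [0.4, 0.35, 0]])
        assert similarity_clusters(d, 1).nunique() == 1

    def test_three_planted_groups_at_40_percent(self):
        """Within-group dissimilarity ~0.3, between ~0.8: a 40% similarity
        cut (height 0.6) recovers exactly 3 clusters."""
        groups = [0, 0, 1, 1, 2, 2]
        n = len(groups)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                if i != j:
                    d[i, j] = 0.3 if groups[i] == groups[j] else 0.8
        labels = similarity_clusters(d, 40)
        assert labels.nunique() == 3
        assert labels[0] == labels[1] and labels[2] == labels[3]

    def test_upgma_heights_match_brute_force(self):
        """Average-linkage merge heights equal an exhaustive recomputation."""
        from scipy.cluster.hierarchy import linkage

        rng = np.random.default_rng(21)
        for _ in range(10):
            d = squareform(pdist(rng.standard_normal((4, 3))))
            z = linkage(squareform(d, checks=False), method="average")
            assert np.allclose(sorted(z[:, 2]), sorted(_brute_upgma_heights(d)))

    def test_invalid_cut_rejected(self):
        d = np.zeros((2, 2))
        with pytest.raises(ValidationError):
            similarity_clusters(d, 0)
        with pytest.raises(ValidationError):
            similarity_clusters(d, 150)


def _brute_upgma_heights(d: np.ndarray) -> list[float]:
    """Naive UPGMA: average of original pairwise distances between clusters."""
    clusters = [[i] for i in range(d.shape[0])]
    heights = []
    while len(clusters) > 1:
        best = (np.inf, None)
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                avg = np.mean([d[i, j] for i in clusters[a] for j in clusters[b]])
                if avg < best[0]:
                    best = (avg, (a, b))
        h, (a, b) = best
        heights.append(h)
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)] + [
            clusters[a] + clusters[b]]
    return heights


class TestQpcrSummary:
    def _table(self, rows):
        return CopyNumberTable(frame=pd.DataFrame(
            rows, columns=["sample_id", "bacteria_copies", "archaea_copies"]))

    def test_published_totals_three_sig_figs(self):
        table = self._table([["EH7", 5.91e6, 2.27e4], ["GU8", 4.31e5, 3.73e4]])
        out = qpcr_summary(table)
        assert out.loc["EH7", "total_copies"] == pytest.approx(5.93e6, rel=5e-3)
        assert out.loc["GU8", "total_copies"] == pytest.approx(4.68e5, rel=5e-3)

    def test_zero_archaea_zero_ratio(self):
        out = qpcr_summary(self._table([["A", 1e6, 0.0]]))
        assert out.loc["A", "archaea_pct_of_bacteria"] == 0.0

    def test_missing_rows_propagate(self):
        out = qpcr_summary(self._table([["A", 1e6, 1e4],
                                        ["B", np.nan, np.nan]]))
        assert np.isnan(out.loc["B", "total_copies"])

    def test_all_missing_rejected(self):
        with pytest.raises(ValidationError):
            qpcr_summary(self._table([["A", np.nan, np.nan]]))
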