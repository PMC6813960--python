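"""Marker config validation, phylogeny routing, and the aggregation engine."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from biogeocycler import (
    GeneTable,
    MarkerConfig,
    MarkerStep,
    ValidationError,
    load_marker_config,
    reconstruct_cycles,
    route_ambiguous,
    stress_profile,
    taxa_heatmap,
)
from biogeocycler.cycles import (
    UNASSIGNED,
    step_potentials_frame,
    unused_genes,
    write_marker_config,
)
from biogeocycler.synthetic import PathwayTruth, simulate_gene_table


def make_genes(rows):
    """rows: (gene_id, ko, lineage, abundance)"""
    return GeneTable(frame=pd.DataFrame(
        rows, columns=["gene_id", "ko", "lineage", "abundance"]))


SRB = "Bacteria;Proteobacteria;Deltaproteobacteria;Desulfobacterales;Desulfobacteraceae;Desulfobacter"
SOB = "Bacteria;Proteobacteria;Gammaproteobacteria;Chromatiales;Chromatiaceae;Allochromatium"
AOB = "Bacteria;Proteobacteria;Betaproteobacteria;Nitrosomonadales;Nitrosomonadaceae;Nitrosomonas"
MOB = "Bacteria;Proteobacteria;Alphaproteobacteria;Rhizobiales;Methylocystaceae;Methylocystis"


class TestMarkerConfig:
    def test_default_config_parses(self, marker_config):
        assert {"carbon", "nitrogen", "sulfur"} <= set(marker_config.cycles)
        assert any(c.startswith("stress:") for c in marker_config.cycles)
        assert marker_config.ambiguous_kos  # bidirectional markers shipped

    def test_duplicate_ko_without_ambiguous_flag_rejected(self):
        steps = [
            MarkerStep("carbon", "a", ("K00001",)),
            MarkerStep("carbon", "b", ("K00001",)),
        ]
        with pytest.raises(ValidationError, match="K00001"):
            MarkerConfig(steps=steps)

    def test_malformed_ko_rejected(self):
        with pytest.raises(ValidationError, match="K1"):
            MarkerStep("carbon", "a", ("K1",))

    def test_ambiguous_without_clades_rejected(self):
        with pytest.raises(ValidationError, match="routing"):
            MarkerStep("sulfur", "x", ("K00001",), ambiguous=True)

    def test_round_trip(self, marker_config, tmp_path):
        path = tmp_path / "markers.yaml"
        write_marker_config(marker_config, path)
        again = load_marker_config(path)
        assert again.steps == marker_config.steps

    def test_unknown_cycle_rejected(self, tmp_path):
        path = tmp_path / "bad.yaml"
        path.write_text("cycles:\n  phlogiston:\n    - {name: x, kos: [K00001]}\n")
        with pytest.raises(ValidationError, match="phlogiston"):
            load_marker_config(path)


class TestRouting:
    @pytest.mark.parametrize(
        "ko, lineage, expected_step",
        [
            ("K11180", SRB, "sulfur/dissimilatory_sulfate_reduction"),  # dsrA, SRB
            ("K00394", SOB, "sulfur/sulfide_oxidation"),                # aprA, PSB
            ("K10944", AOB, "nitrogen/nitrification"),                  # amoA
            ("K10944", MOB, "carbon/methane_oxidation"),                # pmoA
        ],
    )
    def test_clade_routing(self, marker_config, ko, lineage, expected_step):
        genes = make_genes([("g1", ko, lineage, 1.0)])
        routed = route_ambiguous(genes, marker_config)
        assert routed.frame.loc[0, "resolved_step"] == expected_step

    def test_unmatched_lineage_reported_unassigned(self, marker_config):
        genes = make_genes([("g1", "K11180", "Bacteria;P;C;O;F;Mysterium", 1.0)])
        routed = route_ambiguous(genes, marker_config)
        assert routed.frame.loc[0, "resolved_step"] == UNASSIGNED
        assert len(unused_genes(routed, marker_config)) == 1

    def test_unambiguous_ko_untouched(self, marker_config):
        genes = make_genes([("g1", "K00958", SRB, 1.0)])  # sat: one owner
        routed = route_ambiguous(genes, marker_config)
        assert routed.frame.loc[0, "resolved_step"] == ""


class TestReconstruction:
    def test_zero_noise_sulfur_mix_recovered_exactly(self, marker_config):
        """Planted 67.4% mineralization / 32.5% assimilatory reduction / 0.1%
        dissimilatory reduction round-trips exactly at zero noise."""
        gx = "Bacteria;P;C;O;F;GX"
        truth = PathwayTruth(
            step_weights={("sulfur", "sulfur_mineralization"): 0.674,
                          ("sulfur", "assimilatory_sulfate_reduction"): 0.325,
                          ("sulfur", "dissimilatory_sulfate_reduction"): 0.001},
            taxa_weights={("sulfur", "sulfur_mineralization"): {gx: 1.0},
                          ("sulfur", "assimilatory_sulfate_reduction"): {gx: 1.0},
                          ("sulfur", "dissimilatory_sulfate_reduction"): {SRB: 1.0}},
            n_genes={("sulfur", "sulfur_mineralization"): 4,
                     ("sulfur", "assimilatory_sulfate_reduction"): 4,
                     ("sulfur", "dissimilatory_sulfate_reduction"): 4},
        )
        genes = simulate_gene_table(truth, marker_config, noise_sd=0.0, seed=5)
        steps = {s.step: s.percent
                 for s in reconstruct_cycles(genes, marker_config, cycles=("sulfur",))}
        assert steps["sulfur_mineralization"] == pytest.approx(67.4, abs=1e-9)
        assert steps["assimilatory_sulfate_reduction"] == pytest.approx(32.5, abs=1e-9)
        assert steps["dissimilatory_sulfate_reduction"] == pytest.approx(0.1, abs=1e-9)

    def test_unknown_ko_counted_as_unused(self, marker_config):
        genes = make_genes([("g1", "K02274", "Bacteria;P;C;O;F;G", 5.0),
                            ("g2", "K99999", "Bacteria;P;C;O;F;G", 3.0),
                            ("g3", "", "Bacteria;P;C;O;F;G", 2.0)])
        unused = unused_genes(genes, marker_config)
        assert sorted(unused.frame["gene_id"]) == ["g2", "g3"]

    def test_brute_force_tally_small_table(self, marker_config):
        """Step abundances equal an exhaustive per-gene hand tally."""
        rng = np.random.default_rng(12)
        kos = [s.kos[0] for s in marker_config.steps
               if s.cycle in ("carbon", "nitrogen") and not s.ambiguous]
        rows = [(f"g{i}", rng.choice(kos), "Bacteria;P;C;O;F;G",
                 float(rng.uniform(0.1, 5))) for i in range(18)]
        genes = make_genes(rows)
        steps = reconstruct_cycles(genes, marker_config)
        by_key = {ko: "/".join(marker_config.steps_for_ko(ko)[0].key) for ko in kos}
        expected: dict[str, float] = {}
        for _, ko, _, ab in rows:
            expected[by_key[ko]] = expected.get(by_key[ko], 0.0) + ab
        for s in steps:
            key = f"{s.cycle}/{s.step}"
            assert s.abundance == pytest.approx(expected.get(key, 0.0))

    def test_taxa_fractions_sum_to_one(self, marker_config):
        genes = make_genes([("g1", "K02274", "Bacteria;P;C;O;F;GA", 3.0),
                            ("g2", "K02274", "Bacteria;P;C;O;F;GB", 1.0)])
        steps = reconstruct_cycles(genes, marker_config, cycles=("carbon",))
        step = next(s for s in steps if s.step == "aerobic_respiration")
        assert sum(f for _, f in step.taxa.values()) == pytest.approx(1.0)
        assert step.taxa["GA"][1] == pytest.approx(0.75)

    def test_empty_cycle_reports_zero_not_nan(self, marker_config, caplog):
        genes = make_genes([("g1", "K02274", "Bacteria;P;C;O;F;G", 1.0)])
        with caplog.at_level("WARNING"):
            steps = reconstruct_cycles(genes, marker_config, cycles=("sulfur",))
        assert all(s.percent == 0.0 for s in steps)
        assert not any(np.isnan(s.percent) for s in steps)

    @given(st.integers(min_value=0, max_value=2 ** 31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_conservation_and_scale_invariance(self, marker_config, seed):
        """A gene contributes to exactly one step: step sums + unused genes
        partition the marker-matching abundance; scaling all abundances leaves
        percents unchanged."""
        rng = np.random.default_rng(seed)
        pool = [s.kos[0] for s in marker_config.steps] + ["K99999", ""]
        lineages = [SRB, SOB, AOB, MOB, "Bacteria;P;C;O;F;G"]
        rows = [(f"g{i}", pool[rng.integers(len(pool))],
                 lineages[rng.integers(len(lineages))],
                 float(rng.uniform(0.1, 10))) for i in range(30)]
        genes = make_genes(rows)
        routed = route_ambiguous(genes, marker_config)
        steps = reconstruct_cycles(routed, marker_config)
        stress = stress_profile(routed, marker_config)
        assigned = sum(s.abundance for s in steps + stress)
        leftover = unused_genes(routed, marker_config).frame["abundance"].sum()
        assert assigned + leftover == pytest.approx(genes.total_abundance)

        scaled = make_genes([(g, k, l, a * 7.3) for g, k, l, a in rows])
        steps2 = reconstruct_cycles(route_ambiguous(scaled, marker_config),
                                    marker_config)
        for s1, s2 in zip(steps, steps2):
            assert s2.percent == pytest.approx(s1.percent)


class TestHeatmap:
    def _steps(self, marker_config, contributions):
        """Build StepPotentials directly from {taxon: per-step abundances}."""
        from biogeocycler.cycles import StepPotential

        n_steps = len(next(iter(contributions.values())))
        steps = []
        for j in range(n_steps):
            col = {t: vals[j] for t, vals in contributions.items()}
            total = sum(col.values())
            taxa = {t: (a, a / total if total else 0.0) for t, a in col.items()}
            steps.append(StepPotential("carbon", f"step{j}", total,
                                       100.0 / n_steps, taxa, len(col)))
        return steps

    def test_hand_z_score(self, marker_config):
        steps = self._steps(marker_config, {"GA": [2.0, 4.0, 6.0]})
        heat = taxa_heatmap(steps)
        row = heat.values.loc["GA"].to_numpy()
        assert row == pytest.approx([-1.2247, 0.0, 1.2247], abs=1e-4)

    def test_exactly_one_percent_excluded(self, marker_config):
        steps = self._steps(marker_config, {"GA": [99.0, 99.0],
                                            "GB": [1.0, 1.0]})
        heat = taxa_heatmap(steps, min_contribution=1.0)
        assert "GB" not in heat.values.index  # strict >
        assert "GA" in heat.values.index

    def test_constant_row_all_zeros(self, marker_config):
        steps = self._steps(marker_config, {"GA": [3.0, 3.0, 3.0]})
        heat = taxa_heatmap(steps)
        assert (heat.values.loc["GA"] == 0.0).all()

    def test_rows_standardised(self, marker_config):
        rng = np.random.default_rng(3)
        steps = self._steps(marker_config,
                            {f"G{i}": rng.uniform(1, 9, 4) for i in range(5)})
        heat = taxa_heatmap(steps, min_contribution=0.5)
        vals = heat.values.to_numpy()
        assert np.allclose(vals.mean(axis=1), 0.0, atol=1e-9)
        assert np.allclose(vals.std(axis=1), 1.0, atol=1e-9)

    def test_no_taxon_passes_empty_with_warning(self, marker_config, caplog):
        steps = self._steps(marker_config, {f"G{i}": [1.0, 1.0]
                                            for i in range(200)})
        with caplog.at_level("WARNING"):
            heat = taxa_heatmap(steps, min_contribution=1.0)
        assert heat.values.empty


class TestStressProfile:
    def test_percent_relative_to_total_abundance(self, marker_config):
        """DNA-repair genes planted at 1.46% of total gene abundance are
        reported at 1.46% — the percent-of-total convention."""
        genes = make_genes([
            ("g1", "K03701", "Bacteria;P;C;O;F;G", 1.46),  # uvrA
            ("g2", "", "Bacteria;P;C;O;F;G", 98.54),
        ])
        stress = stress_profile(genes, marker_config)
        total = sum(s.percent for s in stress if s.cycle == "stress:dna_repair")
        assert total == pytest.approx(1.46)

    def test_empty_theme_zero(self, marker_config):
        genes = make_genes([("g1", "K03701", "Bacteria;P;C;O;F;G", 1.0)])
        stress = stress_profile(genes, marker_config)
        acid = [s for s in stress if s.cycle == "stress:acid"]
        assert all(s.percent == 0.0 for s in acid)

    def test_theme_percents_need_not_sum_to_100(self, marker_config):
        genes = make_genes([("g1", "K03701", "Bacteria;P;C;O;F;G", 1.0),
                            ("g2", "", "Bacteria;P;C;O;F;G", 99.0)])
        stress = stress_profile(genes, marker_config)
        assert sum(s.percent for s in stress) < 100.0

    def test_frame_flattening(self, marker_config):
        genes = make_genes([("g1", "K03701", "Bacteria;P;C;O;F;G", 1.0)])
        frame = step_potentials_frame(stress_profile(genes, marker_config))
        assert {"cycle", "step", "abundance", "percent", "n_genes"} <= set(frame.columns)
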