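"""Synthetic inputs with known ground truth for every pipeline stage.

Two generative worlds are emulated:

* a 16S amplicon OTU table — per sample, latent absolute abundances are drawn
  log-normally with a chosen basis correlation structure and multinomially
  subsampled to the sequencing depth. This is exactly the compositional model
  SparCC assumes, so the network stage's recovery claims are testable against
  the planted ``basis_correlation``.
* a KO-annotated gene table — each conversion step of a marker config receives
  a planted share of marker-gene abundance, split over planted taxa; with zero
  multiplicative noise the cycle-reconstruction engine must return the planted
  step percentages and taxon fractions exactly.

Each generator takes a single integer seed and owns its RNG; generators never
touch global random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cycles import MarkerConfig, MarkerStep, _lineage_matches
from .io import CopyNumberTable, GeneTable, OtuTable, ValidationError

# Genus pool for synthetic lineages; drawn from taxa typical of cold desert
# soils so that clade-routing rules have realistic strings to match against.
_PHYLA = ("Proteobacteria", "Actinobacteria", "Firmicutes", "Bacteroidetes",
          "Acidobacteria", "Cyanobacteria", "Gemmatimonadetes", "Chloroflexi")
_GENUS_POOL = ("Halomonas", "Lysobacter", "Anoxybacillus", "Flavobacterium",
               "Bradyrhizobium", "Sphingopyxis", "Nitrobacter", "Rhodanobacter",
               "Pseudomonas", "Methylobacterium", "Devosia", "Ralstonia",
               "Coxiella", "Nitrolancea", "Luteitalea", "Geobacter")


def _synthetic_lineage(i: int) -> str:
    genus = _GENUS_POOL[i] if i < len(_GENUS_POOL) else f"Genus{i:03d}"
    phylum = _PHYLA[i % len(_PHYLA)]
    return f"Bacteria;{phylum};SynClass;SynOrder;SynFamily;{genus}"


# ---------------------------------------------------------------------------
# Community truth and OTU simulation
# ---------------------------------------------------------------------------

@dataclass
class CommunityTruth:
    """Ground truth behind a simulated OTU table.

    ``basis_correlation`` is the correlation of latent log-abundances
    (symmetric, unit diagonal, positive semi-definite); ``basis_means`` maps
    each group label to a per-taxon log-mean vector; ``depth`` is the
    multinomial total per sample.
    """

    group_assignment: dict[str, str]          # sample -> group
    basis_correlation: np.ndarray             # taxa x taxa
    basis_means: dict[str, np.ndarray]        # group -> per-taxon log means
    depth: dict[str, int]                     # sample -> total counts
    basis_sd: float = 1.0                     # log-scale sd (shared)
    lineages: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        r = np.asarray(self.basis_correlation, dtype=float)
        if r.ndim != 2 or r.shape[0] != r.shape[1]:
            raise ValidationError("basis_correlation must be square")
        if not np.allclose(r, r.T, atol=1e-12):
            raise ValidationError("basis_correlation must be symmetric")
        if not np.allclose(np.diag(r), 1.0, atol=1e-12):
            raise ValidationError("basis_correlation must have unit diagonal")
        self.basis_correlation = r
        if not self.lineages:
            self.lineages = [_synthetic_lineage(i) for i in range(self.n_taxa)]
        for group, mu in self.basis_means.items():
            mu = np.asarray(mu, dtype=float)
            if mu.shape != (self.n_taxa,):
                raise ValidationError(f"group {group!r}: means have wrong length")
            self.basis_means[group] = mu
        for sample, d in self.depth.items():
            if d <= 0:
                raise ValidationError(f"sample {sample!r}: depth must be > 0")

    @property
    def n_taxa(self) -> int:
        return self.basis_correlation.shape[0]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.group_assignment)

    # -- constructors -------------------------------------------------------

    @classmethod
    def independent(cls, n_taxa: int, n_samples: int, depth: int = 10_000,
                    mean_spread: float = 1.0) -> "CommunityTruth":
        """Identity basis correlation, one group: the SparCC null world.

        ``mean_spread`` spaces taxon log-means evenly over ±spread so the
        community is uneven (as real communities are) but structure-free.
        """
        samples = [f"S{i + 1}" for i in range(n_samples)]
        means = np.linspace(-mean_spread, mean_spread, n_taxa)
        return cls(
            group_assignment={s: "all" for s in samples},
            basis_correlation=np.eye(n_taxa),
            basis_means={"all": means},
            depth={s: depth for s in samples},
        )

    @classmethod
    def grouped(cls, n_groups: int, n_per_group: int, n_taxa: int,
                effect: float = 2.5, depth: int = 10_000) -> "CommunityTruth":
        """Block-structured group means: each group boosts its own taxon block.

        With ``effect`` log-units on a group's block, within-group Bray-Curtis
        is smaller than between-group on average — the planted structure for
        ordination and clustering checks.
        """
        assignment: dict[str, str] = {}
        depths: dict[str, int] = {}
        means: dict[str, np.ndarray] = {}
        block = n_taxa // n_groups
        for g in range(n_groups):
            mu = np.zeros(n_taxa)
            mu[g * block:(g + 1) * block] = effect
            means[f"G{g + 1}"] = mu
            for r in range(n_per_group):
                sample = f"G{g + 1}_S{r + 1}"
                assignment[sample] = f"G{g + 1}"
                depths[sample] = depth
        return cls(
            group_assignment=assignment,
            basis_correlation=np.eye(n_taxa),
            basis_means=means,
            depth=depths,
        )

    @classmethod
    def with_planted_pair(cls, n_taxa: int, n_samples: int, rho: float,
                          pair: tuple[int, int] = (0, 1),
                          depth: int = 10_000) -> "CommunityTruth":
        """Identity correlation except one planted pair at basis rho."""
        truth = cls.independent(n_taxa, n_samples, depth=depth)
        i, j = pair
        truth.basis_correlation[i, j] = truth.basis_correlation[j, i] = rho
        return truth


def study_community_truth(n_taxa: int = 212) -> CommunityTruth:
    """The study's sampling design: 6 samples, 4 site groups, Table-2 depths."""
    depths = {"CP14": 60_608, "GU7": 84_399, "GU8": 75_891,
              "EH2": 79_671, "EH5": 89_383, "EH7": 102_593}
    groups = {"CP14": "CP", "GU7": "GU_D", "GU8": "GU_S",
              "EH2": "EH", "EH5": "EH", "EH7": "EH"}
    block = n_taxa // 4
    means = {}
    for g, name in enumerate(["CP", "EH", "GU_S", "GU_D"]):
        mu = np.zeros(n_taxa)
        mu[g * block:(g + 1) * block] = 2.5
        means[name] = mu
    return CommunityTruth(
        group_assignment=groups,
        basis_correlation=np.eye(n_taxa),
        basis_means=means,
        depth=depths,
    )


def simulate_otu_table(truth: CommunityTruth, seed: int) -> OtuTable:
    """Draw an OTU count table under the log-normal/multinomial model.

    Per sample: latent log-abundances ~ MVN(group means, sd^2 * R), absolute
    abundances = exp(latents), then a multinomial draw of the sample's depth
    on the normalised abundances. Deterministic given the seed.
    """
    r = truth.basis_correlation
    w, v = np.linalg.eigh(r)
    if w.min() < -1e-8:
        raise ValidationError(
            f"basis_correlation is not positive semi-definite "
            f"(min eigenvalue {w.min():.3g})"
        )
    chol = v @ np.diag(np.sqrt(np.clip(w, 0, None)))
    rng = np.random.default_rng(seed)
    otu_ids = [f"OTU_{i + 1:04d}" for i in range(truth.n_taxa)]
    rows = []
    for sample in truth.sample_ids:
        mu = truth.basis_means[truth.group_assignment[sample]]
        z = mu + truth.basis_sd * (chol @ rng.standard_normal(truth.n_taxa))
        abundances = np.exp(z)
        probs = abundances / abundances.sum()
        rows.append(rng.multinomial(truth.depth[sample], probs))
    counts = pd.DataFrame(rows, index=truth.sample_ids, columns=otu_ids)
    lineage = pd.Series(truth.lineages, index=otu_ids)
    return OtuTable(counts=counts, lineage=lineage)


# ---------------------------------------------------------------------------
# Pathway truth and gene-table simulation
# ---------------------------------------------------------------------------

@dataclass
class PathwayTruth:
    """Planted cycle structure behind a simulated gene table.

    ``step_weights[(cycle, step)]`` are target step fractions summing to 1
    within each cycle; ``taxa_weights[(cycle, step)]`` maps lineage -> fraction
    summing to 1 within each step; ``n_genes`` is the gene count emitted per
    (step, taxon) pair. ``cycle_masses`` fixes each cycle's share of total
    gene abundance (stress themes use this to plant percent-of-total truths)
    and ``background_mass`` is the abundance of genes outside all steps.
    """

    step_weights: dict[tuple[str, str], float]
    taxa_weights: dict[tuple[str, str], dict[str, float]]
    n_genes: dict[tuple[str, str], int]
    cycle_masses: dict[str, float] = field(default_factory=dict)
    background_mass: float = 0.0
    total_mass: float = 1_000_000.0

    def __post_init__(self) -> None:
        per_cycle: dict[str, float] = {}
        for (cycle, step), w in self.step_weights.items():
            if not 0.0 <= w <= 1.0:
                raise ValidationError(f"step weight for {cycle}/{step} outside [0,1]")
            per_cycle[cycle] = per_cycle.get(cycle, 0.0) + w
        for cycle, total in per_cycle.items():
            if abs(total - 1.0) > 1e-12:
                raise ValidationError(
                    f"cycle {cycle!r}: step weights sum to {total}, not 1"
                )
        for key, tw in self.taxa_weights.items():
            if key not in self.step_weights:
                raise ValidationError(f"taxa_weights for unknown step {key}")
            total = sum(tw.values())
            if abs(total - 1.0) > 1e-12:
                raise ValidationError(
                    f"step {key}: taxa weights sum to {total}, not 1"
                )
        for cycle in self.cycle_masses:
            if cycle not in per_cycle:
                raise ValidationError(f"cycle_masses names unknown cycle {cycle!r}")

    @property
    def cycles(self) -> list[str]:
        out: list[str] = []
        for cycle, _ in self.step_weights:
            if cycle not in out:
                out.append(cycle)
        return out


# The default planted world. Percentages stated in the study are used where
# printed (CO oxidation 20%; denitrification 9.4%; nitrogen fixation 0.4%;
# ammonia oxidation 0.9%; sulfur mineralization 67.4% / assimilatory sulfate
# reduction 32.5%; DNA repair 1.46% of total gene abundance); the remaining
# steps fill each cycle to 100% with assimilation/respiration-dominated
# splits typical of oligotrophic soils.
_DEFAULT_STEP_WEIGHTS: dict[str, dict[str, float]] = {
    "carbon": {
        "aerobic_respiration": 0.40, "co_oxidation": 0.20, "fermentation": 0.20,
        "anaerobic_carbon_fixation": 0.12, "aerobic_carbon_fixation": 0.075,
        "methane_oxidation": 0.004, "methanogenesis": 0.001,
    },
    "nitrogen": {
        "nitrogen_assimilation": 0.60, "nitrogen_mineralization": 0.293,
        "denitrification": 0.094, "nitrification": 0.009,
        "nitrogen_fixation": 0.004,
    },
    "sulfur": {
        "sulfur_mineralization": 0.674, "assimilatory_sulfate_reduction": 0.325,
        "dissimilatory_sulfate_reduction": 0.0004, "sulfide_oxidation": 0.0003,
        "sulfur_oxidation_sox": 0.0003,
    },
}
# Stress themes are fractions of TOTAL gene abundance (DNA repair as printed;
# others set at realistic sub-percent levels).
_DEFAULT_STRESS_MASS = {"stress:dna_repair": 0.0146, "stress:antioxidation": 0.008,
                        "stress:cold_adaptation": 0.006, "stress:osmotic": 0.005,
                        "stress:acid": 0.002}
# C/N/S marker genes as a share of total gene abundance; markers are a
# minority of any metagenome.
_DEFAULT_CYCLE_MASS = {"carbon": 0.12, "nitrogen": 0.10, "sulfur": 0.08}

# Planted taxa per step; ambiguous steps use lineages their routing rules
# accept, so the routed zero-noise world round-trips exactly.
_STEP_TAXA: dict[str, list[str]] = {
    "dissimilatory_sulfate_reduction": [
        "Bacteria;Proteobacteria;Deltaproteobacteria;Desulfobacterales;Desulfobacteraceae;Desulfobacter",
        "Bacteria;Proteobacteria;Deltaproteobacteria;Syntrophobacterales;Syntrophaceae;Desulfomonile",
        "Bacteria;Nitrospirae;Nitrospira;Nitrospirales;Nitrospiraceae;Leptospirillum",
    ],
    "sulfide_oxidation": [
        "Bacteria;Proteobacteria;Gammaproteobacteria;Chromatiales;Chromatiaceae;Allochromatium",
        "Bacteria;Proteobacteria;Gammaproteobacteria;Chromatiales;Ectothiorhodospiraceae;Thiohalobacter",
        "Bacteria;Chlorobi;Chlorobia;Chlorobiales;Chlorobiaceae;Chlorobium",
    ],
    "nitrification": [
        "Bacteria;Proteobacteria;Betaproteobacteria;Nitrosomonadales;Nitrosomonadaceae;Nitrosomonas",
        "Bacteria;Proteobacteria;Betaproteobacteria;Nitrosomonadales;Nitrosomonadaceae;Nitrosospira",
        "Bacteria;Proteobacteria;Alphaproteobacteria;Rhizobiales;Bradyrhizobiaceae;Nitrobacter",
    ],
    "methane_oxidation": [
        "Bacteria;Proteobacteria;Alphaproteobacteria;Rhizobiales;Methylocystaceae;Methylocystis",
        "Bacteria;Proteobacteria;Gammaproteobacteria;Methylococcales;Methylococcaceae;Methylococcus",
    ],
    "nitrogen_fixation": [
        "Bacteria;Cyanobacteria;Cyanophyceae;Chroococcales;Aphanothecaceae;Halothece",
        "Bacteria;Proteobacteria;Betaproteobacteria;Nitrosomonadales;Sterolibacteriaceae;Methyloversatilis",
        "Bacteria;Proteobacteria;Betaproteobacteria;Burkholderiales;Leptothrix;Leptothrix",
    ],
}
_GENERIC_TAXA = [
    "Bacteria;Proteobacteria;Alphaproteobacteria;Rhizobiales;Bradyrhizobiaceae;Bradyrhizobium",
    "Bacteria;Proteobacteria;Gammaproteobacteria;Pseudomonadales;Pseudomonadaceae;Pseudomonas",
    "Bacteria;Actinobacteria;Actinomycetia;Streptosporangiales;Thermomonosporaceae;Thermomonospora",
    "Bacteria;Acidobacteria;Vicinamibacteria;Vicinamibacterales;Vicinamibacteraceae;Luteitalea",
]


def default_pathway_truth(config: MarkerConfig, n_genes: int = 5) -> PathwayTruth:
    """Planted step/taxa weights for a config, mirroring the study's world."""
    step_weights: dict[tuple[str, str], float] = {}
    taxa_weights: dict[tuple[str, str], dict[str, float]] = {}
    genes: dict[tuple[str, str], int] = {}
    for cycle in config.cycles:
        steps = config.cycle_steps(cycle)
        defaults = _DEFAULT_STEP_WEIGHTS.get(cycle)
        if defaults is not None:
            weights = {s.name: defaults.get(s.name, 0.0) for s in steps}
        else:  # stress themes: even split across sub-pathways
            weights = {s.name: 1.0 for s in steps}
        total = sum(weights.values())
        if total == 0:
            weights = {s.name: 1.0 for s in steps}
            total = float(len(steps))
        for step in steps:
            key = (cycle, step.name)
            step_weights[key] = weights[step.name] / total
            taxa = _STEP_TAXA.get(step.name, _GENERIC_TAXA[:3])
            shares = [0.5, 0.3, 0.2][: len(taxa)]
            norm = sum(shares)
            taxa_weights[key] = {t: s / norm for t, s in zip(taxa, shares)}
            genes[key] = n_genes
    masses = dict(_DEFAULT_CYCLE_MASS)
    masses.update({c: _DEFAULT_STRESS_MASS[c] for c in config.cycles
                   if c in _DEFAULT_STRESS_MASS})
    stress_extra = {c: 0.002 for c in config.cycles
                    if c.startswith("stress:") and c not in masses}
    masses.update(stress_extra)
    background = max(0.0, 1.0 - sum(masses.get(c, 0.0) for c in config.cycles))
    return PathwayTruth(
        step_weights=step_weights,
        taxa_weights=taxa_weights,
        n_genes=genes,
        cycle_masses=masses,
        background_mass=background,
    )


def _pick_ko(step: MarkerStep, lineage: str, config: MarkerConfig,
             rng: np.random.Generator) -> str:
    """Choose a KO that the engine will route back to this step."""
    safe = []
    for ko in step.kos:
        owners = config.steps_for_ko(ko)
        if len(owners) == 1:
            safe.append(ko)
        else:
            routed = next((s for s in owners
                           if _lineage_matches(lineage, s.clades)), None)
            if routed is not None and routed.key == step.key:
                safe.append(ko)
    if not safe:
        raise ValidationError(
            f"step {step.cycle}/{step.name}: no KO routes lineage {lineage!r} "
            "back to the step"
        )
    return safe[rng.integers(len(safe))]


def simulate_gene_table(
    truth: PathwayTruth,
    config: MarkerConfig,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> GeneTable:
    """Emit a KO-annotated gene table realising a planted pathway truth.

    Per (step, taxon) pair, ``n_genes`` genes are emitted with abundance
    ``cycle_mass * step_weight * taxon_weight * total_mass / n_genes *
    exp(noise)``, ``noise ~ N(0, noise_sd^2)``. KOs are drawn from the step's
    combination, restricted so phylogeny routing sends each gene back to its
    step; at ``noise_sd = 0`` cycle reconstruction recovers the planted step
    and taxon fractions exactly.
    """
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    known = {(s.cycle, s.name) for s in config.steps}
    for key in truth.step_weights:
        if key not in known:
            raise ValidationError(f"step {key[0]}/{key[1]} absent from config")
    by_key = {s.key: s for s in config.steps}
    rng = np.random.default_rng(seed)
    records = []
    gid = 0
    for key, weight in truth.step_weights.items():
        cycle, _ = key
        step = by_key[key]
        if not step.kos:
            raise ValidationError(f"step {cycle}/{key[1]} has no KOs")
        mass = truth.cycle_masses.get(cycle, 1.0) * truth.total_mass * weight
        n = truth.n_genes.get(key, 1)
        for lineage, frac in truth.taxa_weights.get(key, {"unassigned": 1.0}).items():
            per_gene = mass * frac / n
            for _ in range(n):
                gid += 1
                noise = np.exp(rng.normal(0.0, noise_sd)) if noise_sd > 0 else 1.0
                records.append(
                    {"gene_id": f"gene_{gid:06d}",
                     "ko": _pick_ko(step, lineage, config, rng),
                     "lineage": lineage,
                     "abundance": per_gene * noise}
                )
    if truth.background_mass > 0:
        n_bg = max(10, gid // 2)
        per_gene = truth.background_mass * truth.total_mass / n_bg
        for _ in range(n_bg):
            gid += 1
            noise = np.exp(rng.normal(0.0, noise_sd)) if noise_sd > 0 else 1.0
            records.append(
                {"gene_id": f"gene_{gid:06d}", "ko": "",
                 "lineage": _GENERIC_TAXA[gid % len(_GENERIC_TAXA)],
                 "abundance": per_gene * noise}
            )
    return GeneTable(frame=pd.DataFrame(records))


# ---------------------------------------------------------------------------
# qPCR copy numbers
# ---------------------------------------------------------------------------

def simulate_copy_numbers(
    n_samples: int,
    archaea_fraction_range: tuple[float, float] = (0.004, 0.086),
    seed: int = 0,
) -> CopyNumberTable:
    """Simulate per-gram 16S copy numbers for a bacteria-dominated community.

    Bacterial copies are log-uniform over [1e5, 1e8] (the biomass span of cold
    desert soils); archaeal copies are the bacterial count times a ratio drawn
    uniformly from ``archaea_fraction_range`` — default 0.4–8.6%, the archaeal
    share observed by qPCR in the emulated study.
    """
    lo, hi = archaea_fraction_range
    if not 0 < lo <= hi < 1:
        raise ValidationError(
            f"archaea_fraction_range must satisfy 0 < lo <= hi < 1, got {lo, hi}"
        )
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_samples):
        bact = 10 ** rng.uniform(5, 8)
        ratio = rng.uniform(lo, hi)
        rows.append({"sample_id": f"S{i + 1}", "bacteria_copies": bact,
                     "archaea_copies": bact * ratio})
    frame = pd.DataFrame(rows, columns=["sample_id", "bacteria_copies",
                                        "archaea_copies"])
    return CopyNumberTable(frame=frame)
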