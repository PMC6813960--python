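"""End-to-end orchestration: diversity -> network -> cycles with a manifest.

``run_all`` executes any subset of the three analysis stages from a single
config (dict or YAML path), writing TSV results plus one ``manifest.json``
recording the package version, SHA-256 of every input, all parameters and the
per-stage seeds. A single top-level seed fans out to stage seeds derived by
hashing the stage name, so each stage is individually reproducible; the
manifest deliberately carries no wall-clock timestamp, making re-runs with
the same config byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from importlib.metadata import version as _pkg_version
from pathlib import Path

import yaml

from . import cycles as cycles_mod
from . import diversity as div_mod
from . import network as net_mod
from .io import (
    ValidationError,
    read_copy_numbers,
    read_gene_table,
    read_otu_table,
    write_network,
)

logger = logging.getLogger(__name__)

STAGES = ("diversity", "network", "cycles")


class StageError(RuntimeError):
    """A pipeline stage failed; ``stage`` names it."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {message}")


def derive_seed(seed: int, stage: str) -> int:
    """Stable per-stage seed: hash of (seed, stage name), below 2^31."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


_DEFAULT_PARAMS = {
    "rank": "genus",
    "composition_rank": "phylum",
    "normalize": "relative",
    "cluster_cut": 40.0,
    "nmds_restarts": 20,
    "r_threshold": 0.65,
    "p_threshold": 0.01,
    "n_permutations": 999,
    "min_prevalence": 3,
    "min_contribution": 1.0,
    "network_format": "graphml",
}


def run_all(config, out_dir=None) -> dict:
    """Run the configured stages and write results + manifest to ``out_dir``.

    ``config`` is a dict or a YAML path with keys ``seed``, ``stages``,
    ``inputs`` (paths: otu_table, gene_annotations, gene_quant, marker_config,
    copy_numbers) and optional ``params`` overriding the stage defaults.
    Returns the manifest dict. Raises :class:`StageError` naming the failing
    stage; missing inputs raise :class:`ValidationError` naming the file.
    """
    if not isinstance(config, dict):
        with open(config, encoding="utf-8") as fh:
            config = yaml.safe_load(fh)
    seed = int(config.get("seed", 0))
    stages = list(config.get("stages", STAGES))
    inputs = {k: v for k, v in config.get("inputs", {}).items() if v is not None}
    params = {**_DEFAULT_PARAMS, **config.get("params", {})}
    out_dir = Path(out_dir or config.get("out_dir", "results"))
    out_dir.mkdir(parents=True, exist_ok=True)

    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValidationError(f"unknown stage(s) {sorted(unknown)}")
    for key, path in inputs.items():
        if not Path(path).exists():
            raise ValidationError(f"input {key!r} does not exist: {path}")

    outputs: list[str] = []

    def _save(frame, name, **kwargs):
        path = out_dir / name
        frame.to_csv(path, sep="\t", encoding="utf-8", **kwargs)
        outputs.append(name)

    otu_table = None
    if "otu_table" in inputs:
        otu_table = read_otu_table(inputs["otu_table"])

    if "diversity" in stages:
        try:
            if otu_table is None:
                raise ValidationError("diversity stage needs inputs.otu_table")
            _save(div_mod.alpha_diversity(otu_table), "alpha_diversity.tsv",
                  index_label="sample_id")
            _save(div_mod.relative_abundance(otu_table,
                                             rank=params["composition_rank"]),
                  "composition.tsv", index_label="sample_id")
            bc = div_mod.bray_curtis(otu_table, transform=params["normalize"]
                                     if params["normalize"] != "none" else "none")
            _save(bc, "bray_curtis.tsv", index_label="sample_id")
            ord_res = div_mod.nmds(bc, n_restarts=params["nmds_restarts"],
                                   seed=derive_seed(seed, "diversity"))
            coords = ord_res.coordinates.copy()
            coords["stress"] = ord_res.stress
            _save(coords, "nmds_coordinates.tsv", index_label="sample_id")
            _save(div_mod.similarity_clusters(bc, params["cluster_cut"]).to_frame(),
                  "clusters.tsv", index_label="sample_id")
            if "copy_numbers" in inputs:
                cn = read_copy_numbers(inputs["copy_numbers"])
                _save(div_mod.qpcr_summary(cn), "qpcr_summary.tsv")
        except ValidationError:
            raise
        except Exception as exc:
            raise StageError("diversity", str(exc)) from exc

    if "network" in stages:
        try:
            if otu_table is None:
                raise ValidationError("network stage needs inputs.otu_table")
            net = net_mod.cooccurrence_network(
                otu_table, rank=params["rank"],
                r_threshold=params["r_threshold"],
                p_threshold=params["p_threshold"],
                n_permutations=params["n_permutations"],
                min_prevalence=params["min_prevalence"],
                seed=derive_seed(seed, "network"))
            fmt = params["network_format"]
            name = f"network.{ 'graphml' if fmt == 'graphml' else 'gexf' }"
            write_network(net, out_dir / name, format=fmt)
            outputs.append(name)
            _save(net.edge_frame(), "network_edges.tsv", index=False)
        except ValidationError:
            raise
        except Exception as exc:
            raise StageError("network", str(exc)) from exc

    if "cycles" in stages:
        try:
            if "gene_annotations" not in inputs:
                raise ValidationError("cycles stage needs inputs.gene_annotations")
            genes = read_gene_table(inputs["gene_annotations"],
                                    inputs.get("gene_quant"))
            marker_config = cycles_mod.load_marker_config(
                inputs.get("marker_config"))
            routed = cycles_mod.route_ambiguous(genes, marker_config)
            steps = cycles_mod.reconstruct_cycles(routed, marker_config,
                                                  rank=params["rank"])
            stress = cycles_mod.stress_profile(routed, marker_config,
                                               rank=params["rank"])
            _save(cycles_mod.step_potentials_frame(steps),
                  "step_potentials.tsv", index=False)
            _save(cycles_mod.step_potentials_frame(stress),
                  "stress_potentials.tsv", index=False)
            _save(cycles_mod.taxa_contributions_frame(steps + stress),
                  "taxa_contributions.tsv", index=False)
            heat = cycles_mod.taxa_heatmap(
                steps, min_contribution=params["min_contribution"])
            _save(heat.values, "heatmap.tsv", index_label="taxon")
            _save(cycles_mod.unused_genes(genes, marker_config).frame,
                  "unused_genes.tsv", index=False)
        except ValidationError:
            raise
        except Exception as exc:
            raise StageError("cycles", str(exc)) from exc

    manifest = {
        "tool": "biogeocycler",
        "version": _pkg_version("biogeocycler"),
        "seed": seed,
        "stage_seeds": {s: derive_seed(seed, s) for s in stages},
        "stages": stages,
        "inputs": {k: {"path": str(v), "sha256": _sha256(Path(v))}
                   for k, v in inputs.items()},
        "params": params,
        "outputs": sorted(outputs),
    }
    with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def simulate_bundle(out_dir, seed: int = 0, n_taxa: int = 212,
                    noise_sd: float = 0.3) -> dict:
    """Write a complete synthetic input set (OTU table, gene tables, qPCR).

    Emulates the study's design: 6 samples in 4 site groups with realistic
    depths, a KO-annotated gene table with planted cycle structure (written
    as a GhostKOALA-style annotation plus a Salmon-style quant file), and a
    qPCR copy-number table. Truth tables are serialized alongside for test
    assertions. Returns a ready-to-use ``run_all`` inputs mapping.
    """
    from . import synthetic as syn
    from .io import write_copy_numbers, write_otu_table

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    truth = syn.study_community_truth(n_taxa=n_taxa)
    otu = syn.simulate_otu_table(truth, seed=derive_seed(seed, "synth:otu"))
    write_otu_table(otu, out_dir / "otu_table.tsv")

    config = cycles_mod.load_marker_config()
    ptruth = syn.default_pathway_truth(config)
    genes = syn.simulate_gene_table(ptruth, config, noise_sd=noise_sd,
                                    seed=derive_seed(seed, "synth:genes"))
    df = genes.frame
    df[["gene_id", "ko", "lineage"]].to_csv(
        out_dir / "gene_annotations.tsv", sep="\t", index=False, header=False)
    tpm = 1e6 * df["abundance"] / df["abundance"].sum()
    quant = df[["gene_id"]].rename(columns={"gene_id": "Name"}).assign(
        Length=1000, EffectiveLength=800.0, TPM=tpm,
        NumReads=(tpm * 10).round(2))
    quant.to_csv(out_dir / "quant.sf", sep="\t", index=False)

    cn = syn.simulate_copy_numbers(6, seed=derive_seed(seed, "synth:qpcr"))
    cn.frame["sample_id"] = otu.sample_ids
    write_copy_numbers(cn, out_dir / "copy_numbers.tsv")

    # ground truths for assertions
    import pandas as pd

    pd.DataFrame(
        [{"cycle": c, "step": s, "weight": w}
         for (c, s), w in ptruth.step_weights.items()]
    ).to_csv(out_dir / "truth_step_weights.tsv", sep="\t", index=False)
    pd.Series(truth.group_assignment, name="group").to_csv(
        out_dir / "truth_groups.tsv", sep="\t", index_label="sample_id")

    return {
        "otu_table": str(out_dir / "otu_table.tsv"),
        "gene_annotations": str(out_dir / "gene_annotations.tsv"),
        "gene_quant": str(out_dir / "quant.sf"),
        "copy_numbers": str(out_dir / "copy_numbers.tsv"),
    }
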