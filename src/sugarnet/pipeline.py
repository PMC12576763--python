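"""End-to-end pipeline driver: configuration, stage orchestration, manifest.

Stage order: simulate (or load) -> filter -> contrasts -> intersections ->
correlation -> threshold -> MCL -> eigengenes -> trait screening ->
null models -> hubs -> enrichment. Every stage writes its table under the
output directory and contributes row counts to a manifest; rerunning with the
same configuration reproduces byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io, network, mcl, eigentrait, nullmodels, hubs, enrich, preprocess
from . import simulate as sim

__version__ = "0.1.0"

STAGES = (
    "simulate",
    "filter",
    "contrasts",
    "intersections",
    "network",
    "cluster",
    "eigengenes",
    "screen",
    "nullfit",
    "hubs",
    "enrich",
)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


def default_module_specs() -> list[sim.PlantedModuleSpec]:
    """Planted-module mix emulating the study's module archetypes: modules
    shifted by genotype, nitrogen availability, leaf segment, their
    interaction, plus a trait-coupled and a null module."""
    return [
        sim.PlantedModuleSpec(1, 40, "nitrogen", effect_size=6.0),
        sim.PlantedModuleSpec(2, 30, "nitrogen", effect_size=6.0),
        sim.PlantedModuleSpec(3, 25, "genotype", effect_size=6.0),
        sim.PlantedModuleSpec(4, 20, "genotype", effect_size=6.0),
        sim.PlantedModuleSpec(5, 20, "segment", effect_size=6.0),
        sim.PlantedModuleSpec(6, 15, "interaction", effect_size=6.0),
        sim.PlantedModuleSpec(7, 15, "trait_only"),
        sim.PlantedModuleSpec(8, 10, "noise", effect_size=0.0),
    ]


@dataclass
class PipelineConfig:
    """All stage parameters; defaults mirror the study's choices
    (|r| > 0.90, MCL inflation 1.8, |rho| > 0.7, alpha 0.05, top 10% hubs)."""

    seed: int = 0
    out_dir: str = "sugarnet_run"
    # synthetic inputs (used when no input paths are given)
    n_replicates: int = 3
    modules: list[dict] = field(default_factory=lambda: [asdict(s) for s in default_module_specs()])
    n_noise_genes: int = 300
    noise_sd: float = 1.0
    missing_rate: float = 0.0
    trait_noise_sd: float = 0.3
    n_terms: int = 30
    background_rate: float = 0.05
    planted_terms: dict = field(default_factory=lambda: {1: "GO:SYN0001", 3: "GO:SYN0002"})
    # optional real-data inputs
    expression_path: str | None = None
    design_path: str | None = None
    traits_path: str | None = None
    annotations_path: str | None = None
    # stage parameters
    max_missing_fraction: float = 0.5
    lfc_threshold: float = 1.0
    deg_alpha: float = 0.05
    threshold_r: float = 0.90
    drop_isolated: bool = True
    network_on: str = "degs"  # or "all": build the network on every filtered gene
    inflation: float = 1.8
    rho_cut: float = 0.7
    screen_alpha: float = 0.05
    screen_interaction: bool = True
    null_replicates: int = 20
    null_grid_size: int = 256
    run_null_models: bool = True
    top_fraction: float = 0.10
    enrich_alpha: float = 0.05

    def validate(self) -> None:
        if not 0.0 <= self.threshold_r < 1.0:
            raise ValueError("threshold_r must lie in [0, 1)")
        if self.inflation <= 1.0:
            raise ValueError("inflation must be > 1")
        if not 0.0 < self.rho_cut < 1.0:
            raise ValueError("rho_cut must lie in (0, 1)")
        for name in ("deg_alpha", "screen_alpha", "enrich_alpha"):
            if not 0.0 < getattr(self, name) < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")
        if not 0.0 < self.top_fraction < 1.0:
            raise ValueError("top_fraction must lie in (0, 1)")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "planted_terms" in data and data["planted_terms"]:
            data["planted_terms"] = {int(k): v for k, v in data["planted_terms"].items()}
        return cls(**data)

    def module_specs(self) -> list[sim.PlantedModuleSpec]:
        return [sim.PlantedModuleSpec(**m) for m in self.modules]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns the manifest (also written to manifest.json)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "sugarnet",
        "version": __version__,
        "config": asdict(config),
        "stages": {},
        "outputs": [],
    }

    def record(stage: str, path: Path | None = None, **counts) -> None:
        manifest["stages"].setdefault(stage, {}).update(counts)
        if path is not None:
            manifest["outputs"].append(path.name)

    # ---- simulate / load -------------------------------------------------
    try:
        if config.expression_path:
            X = io.read_expression(config.expression_path)
            design = io.read_design(config.design_path)
            traits = io.read_traits(config.traits_path) if config.traits_path else None
            ann = io.read_annotations(config.annotations_path) if config.annotations_path else None
            truth = None
        else:
            design = sim.generate_design(config.n_replicates, seed=config.seed)
            specs = config.module_specs()
            X, truth = sim.generate_expression(
                design,
                specs,
                n_noise_genes=config.n_noise_genes,
                noise_sd=config.noise_sd,
                seed=config.seed,
                missing_rate=config.missing_rate,
            )
            traits = sim.generate_traits(
                design, truth, trait_noise_sd=config.trait_noise_sd, seed=config.seed + 1
            )
            ann = sim.generate_annotations(
                truth,
                n_terms=config.n_terms,
                planted=config.planted_terms,
                background_rate=config.background_rate,
                seed=config.seed + 2,
            )
            io.write_truth(truth, out / "truth.json")
            record("simulate", out / "truth.json")
        io.write_expression(X, out / "expression.tsv")
        io.write_design(design, out / "design.tsv")
        record("simulate", out / "expression.tsv", n_genes=X.shape[0], n_samples=X.shape[1])
        record("simulate", out / "design.tsv")
        if traits is not None:
            io.write_traits(traits, out / "traits.tsv")
            record("simulate", out / "traits.tsv", n_traits=traits.shape[1])
        if ann is not None:
            io.write_annotations(ann, out / "annotations.tsv")
            record("simulate", out / "annotations.tsv", n_annotations=len(ann))
    except Exception as e:  # noqa: BLE001
        raise StageError("simulate", e) from e

    # ---- filter ----------------------------------------------------------
    try:
        Xf = preprocess.filter_genes(X, config.max_missing_fraction)
        record("filter", None, n_genes_in=X.shape[0], n_genes_kept=Xf.shape[0])
    except Exception as e:  # noqa: BLE001
        raise StageError("filter", e) from e

    # ---- contrasts -------------------------------------------------------
    try:
        results = preprocess.run_all_contrasts(
            Xf, design, config.lfc_threshold, config.deg_alpha
        )
        for cid, res in results.items():
            fname = f"contrast_{cid.replace(' ', '_')}.tsv"
            res.to_csv(out / fname, sep="\t")
            record("contrasts", out / fname)
        union = preprocess.deg_union(results)
        record("contrasts", None, n_contrasts=len(results), n_deg_union=len(union))
    except Exception as e:  # noqa: BLE001
        raise StageError("contrasts", e) from e

    # ---- intersections ---------------------------------------------------
    try:
        sets = preprocess.deg_sets(results)
        inter = preprocess.intersect_sets(sets)
        inter.sizes().to_csv(out / "deg_intersections.tsv", sep="\t", index=False)
        record(
            "intersections",
            out / "deg_intersections.tsv",
            n_sets=len(sets),
            n_exclusive=len(inter.exclusive),
            union_size=len(inter.union),
        )
    except Exception as e:  # noqa: BLE001
        raise StageError("intersections", e) from e

    # ---- network ---------------------------------------------------------
    try:
        genes = sorted(union) if config.network_on == "degs" else list(Xf.index)
        if not genes:
            raise ValueError("no genes enter the network (no DEGs found)")
        R = network.pearson_matrix(Xf.loc[genes])
        G = network.threshold_graph(R, config.threshold_r, config.drop_isolated)
        topo = network.topology_summary(G)
        io.write_edges(network.edge_table(G), out / "edges.tsv")
        io.write_graphml(G, out / "network.graphml")
        record("network", out / "edges.tsv", **{k: v for k, v in topo.items() if k != "degrees"})
        record("network", out / "network.graphml")
    except Exception as e:  # noqa: BLE001
        raise StageError("network", e) from e

    # ---- cluster ---------------------------------------------------------
    try:
        partition = mcl.mcl_cluster(G, inflation=config.inflation)
        partition.to_frame().to_csv(out / "modules.tsv", sep="\t", index=False)
        stats = mcl.module_size_stats(partition) if len(partition) else {}
        record("cluster", out / "modules.tsv", **stats)
    except Exception as e:  # noqa: BLE001
        raise StageError("cluster", e) from e

    # ---- eigengenes ------------------------------------------------------
    try:
        egs = eigentrait.module_eigengenes(Xf, partition)
        if egs:
            eigentrait.eigengene_matrix(egs).to_csv(out / "eigengenes.tsv", sep="\t")
            record("eigengenes", out / "eigengenes.tsv", n_eigengenes=len(egs))
        else:
            record("eigengenes", None, n_eigengenes=0)
    except Exception as e:  # noqa: BLE001
        raise StageError("eigengenes", e) from e

    # ---- screen ----------------------------------------------------------
    try:
        if egs and traits is not None:
            screen = eigentrait.screen_modules(
                egs, traits, rho_cut=config.rho_cut, alpha=config.screen_alpha
            )
            screen.to_csv(out / "screen.tsv", sep="\t", index=False)
            per_var = eigentrait.modules_per_variable(screen)
            io.write_json({k: sorted(v) for k, v in per_var.items()}, out / "modules_per_variable.json")
            record(
                "screen",
                out / "screen.tsv",
                n_tests=len(screen),
                n_selected=int(screen["selected"].sum()),
                bonferroni_m=len(egs) * traits.shape[1],
            )
            record("screen", out / "modules_per_variable.json")
            if config.screen_interaction:
                inter_var = eigentrait.interaction_variable(design).to_frame()
                iscreen = eigentrait.screen_modules(
                    egs, inter_var, rho_cut=config.rho_cut, alpha=config.screen_alpha
                )
                iscreen.to_csv(out / "screen_interaction.tsv", sep="\t", index=False)
                record(
                    "screen",
                    out / "screen_interaction.tsv",
                    n_interaction_selected=int(iscreen["selected"].sum()),
                )
        else:
            record("screen", None, n_tests=0)
    except Exception as e:  # noqa: BLE001
        raise StageError("screen", e) from e

    # ---- null models -----------------------------------------------------
    try:
        if config.run_null_models and G.number_of_nodes() >= 10:
            fits = nullmodels.fit_all_models(
                G,
                replicates=config.null_replicates,
                seed=config.seed + 3,
                grid_size=config.null_grid_size,
            )
            best = nullmodels.select_model(fits)
            rows = [asdict(f) for f in fits.values()]
            pd.DataFrame(rows).to_csv(out / "null_model_fits.tsv", sep="\t", index=False)
            record(
                "nullfit",
                out / "null_model_fits.tsv",
                best_model=best.model,
                best_kl=round(best.kl, 6),
            )
        else:
            record("nullfit", None, skipped=True)
    except Exception as e:  # noqa: BLE001
        raise StageError("nullfit", e) from e

    # ---- hubs ------------------------------------------------------------
    try:
        table = hubs.call_hubs(G, top_fraction=config.top_fraction, scope="global")
        table.to_csv(out / "centrality_global.tsv", sep="\t", index=False)
        record("hubs", out / "centrality_global.tsv", n_hubs_global=int(table["hub"].sum()))
        if len(partition):
            per_mod = hubs.call_hubs(
                G, top_fraction=config.top_fraction, scope="per_module", partition=partition
            )
            per_mod.to_csv(out / "centrality_per_module.tsv", sep="\t", index=False)
            record(
                "hubs",
                out / "centrality_per_module.tsv",
                n_hubs_per_module=int(per_mod["hub"].sum()),
            )
    except Exception as e:  # noqa: BLE001
        raise StageError("hubs", e) from e

    # ---- enrichment ------------------------------------------------------
    try:
        if ann is not None and len(partition):
            universe = set(G.nodes())
            frames = []
            for label, members in sorted(partition.members.items()):
                res = enrich.fisher_enrichment(
                    set(members), ann, universe=universe,
                    alpha=config.enrich_alpha, term_type="GO",
                )
                if len(res):
                    res.insert(0, "module", label)
                    frames.append(res)
            if frames:
                allres = pd.concat(frames, ignore_index=True)
                allres.to_csv(out / "module_enrichment.tsv", sep="\t", index=False)
                record(
                    "enrich",
                    out / "module_enrichment.tsv",
                    n_tests=len(allres),
                    n_enriched=int(allres["enriched"].sum()),
                )
            else:
                record("enrich", None, n_tests=0)
        else:
            record("enrich", None, skipped=True)
    except Exception as e:  # noqa: BLE001
        raise StageError("enrich", e) from e

    io.write_json(manifest, out / "manifest.json")
    return manifest
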