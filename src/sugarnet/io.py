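"""TSV / GraphML / JSON readers and writers for every pipeline table."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import pandas as pd
import networkx as nx

from .simulate import PlantedModuleSpec, SyntheticTruth


def write_expression(X: pd.DataFrame, path: str | Path) -> None:
    X.rename_axis("gene_id").to_csv(path, sep="\t")


def read_expression(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_design(design: pd.DataFrame, path: str | Path) -> None:
    design.to_csv(path, sep="\t", index=False)


def read_design(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"genotype": str, "segment": str})


def write_traits(traits: pd.DataFrame, path: str | Path) -> None:
    traits.to_csv(path, sep="\t")


def read_traits(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_annotations(ann: pd.DataFrame, path: str | Path) -> None:
    ann.to_csv(path, sep="\t", index=False)


def read_annotations(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_edges(edges: pd.DataFrame, path: str | Path) -> None:
    edges.to_csv(path, sep="\t", index=False)


def read_edges(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_graphml(G: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(G, str(path))


def read_graphml(path: str | Path) -> nx.Graph:
    return nx.read_graphml(str(path))


def write_truth(truth: SyntheticTruth, path: str | Path) -> None:
    payload = {
        "gene_to_module": truth.gene_to_module,
        "latents": {
            "modules": [int(m) for m in truth.latents.index],
            "samples": list(truth.latents.columns),
            "values": truth.latents.to_numpy().tolist(),
        },
        "module_specs": [asdict(s) for s in truth.module_specs],
        "loadings": truth.loadings,
        "differential_genes": {k: sorted(v) for k, v in truth.differential_genes.items()},
        "planted_terms": {str(k): v for k, v in truth.planted_terms.items()},
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_truth(path: str | Path) -> SyntheticTruth:
    payload = json.loads(Path(path).read_text())
    lat = payload["latents"]
    latents = pd.DataFrame(lat["values"], index=lat["modules"], columns=lat["samples"])
    latents.index.name = "module_id"
    return SyntheticTruth(
        gene_to_module=payload["gene_to_module"],
        latents=latents,
        module_specs=[PlantedModuleSpec(**s) for s in payload["module_specs"]],
        loadings=payload["loadings"],
        differential_genes={k: set(v) for k, v in payload["differential_genes"].items()},
        planted_terms={int(k): v for k, v in payload["planted_terms"].items()},
    )


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True, default=_coerce))


def _coerce(o):
    if hasattr(o, "item"):
        return o.item()
    if isinstance(o, (set, frozenset)):
        return sorted(o)
    raise TypeError(f"not JSON-serializable: {type(o)}")
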