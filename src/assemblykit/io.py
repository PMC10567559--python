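"""File formats and run manifests.

Tabular data is TSV throughout (no quoting ambiguity), UTF-8.  Assembly-space
DAGs export to GraphML or a versioned JSON schema; polymer lengths can exceed
any fixed-width integer, so node identities are serialized as decimal
strings.  Every simulation or search output can be accompanied by a manifest
(command, config snapshot, seed, version, input/output digests) sufficient to
reproduce it bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import networkx as nx
import pandas as pd
import yaml

from .ensemble import Ensemble, EnsembleRecord, coerce_copy_number
from .simulate import AssemblySpaceDAG

__all__ = [
    "read_ensemble_tsv",
    "write_ensemble_tsv",
    "read_fasta",
    "read_config",
    "export_dag",
    "load_dag_json",
    "RunManifest",
]

ENSEMBLE_COLUMNS = ["object_id", "assembly_index", "copy_number"]
DAG_SCHEMA = "assembly-dag/1"


def read_ensemble_tsv(path) -> Ensemble:
    """Read an ensemble table (columns object_id, assembly_index,
    copy_number); malformed rows are rejected with their line numbers."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ENSEMBLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    records = []
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        try:
            a = float(row["assembly_index"])
            if a < 0 or a != int(a):
                raise ValueError(f"assembly_index must be a non-negative integer, got {a}")
            n = coerce_copy_number(float(row["copy_number"]), str(row["object_id"]))
            records.append(
                EnsembleRecord(
                    object_id=str(row["object_id"]), assembly_index=int(a), copy_number=n
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}, line {line}: {exc}") from exc
    return Ensemble(records=tuple(records))


def write_ensemble_tsv(ens: Ensemble, path) -> None:
    df = pd.DataFrame(
        [
            {"object_id": r.object_id, "assembly_index": r.assembly_index,
             "copy_number": r.copy_number}
            for r in ens.records
        ]
    )
    df.to_csv(path, sep="\t", index=False)


def read_fasta(path) -> list[tuple[str, str]]:
    """FASTA records as (id, sequence); one record = one string object."""
    from Bio import SeqIO

    records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def read_config(path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        return yaml.safe_load(text)
    if path.suffix == ".json":
        return json.loads(text)
    raise ValueError(f"unsupported config format {path.suffix!r} (use .yaml/.yml/.json)")


# ---------------------------------------------------------------------------
# DAG export
# ---------------------------------------------------------------------------


def _dag_payload(dag: AssemblySpaceDAG) -> dict:
    nodes = []
    for n in sorted(dag.graph.nodes):
        d = dag.graph.nodes[n]
        entry = {"id": str(n), "length": str(n), "flag": d["flag"]}
        if "parents" in d:
            entry["parents"] = [str(p) for p in d["parents"]]
        nodes.append(entry)
    edges = [
        {"source": str(u), "target": str(v)}
        for u, v in sorted(dag.graph.edges, key=lambda e: (str(e[0]), str(e[1])))
    ]
    return {"schema": DAG_SCHEMA, "exact": dag.exact, "nodes": nodes, "edges": edges}


def export_dag(dag: AssemblySpaceDAG, path, format: str = "json") -> None:
    """Write an assembly-space DAG as versioned JSON or GraphML.

    JSON export is byte-stable: export -> load -> re-export is the identity.
    """
    path = Path(path)
    if format == "json":
        path.write_text(json.dumps(_dag_payload(dag), indent=2, sort_keys=True) + "\n")
    elif format == "graphml":
        g = nx.DiGraph()
        g.graph["exact"] = dag.exact
        for n, d in dag.graph.nodes(data=True):
            attrs = {"length": str(n), "flag": d["flag"]}
            if "parents" in d:
                attrs["parents"] = "+".join(str(p) for p in d["parents"])
            g.add_node(str(n), **attrs)
        for u, v in dag.graph.edges:
            g.add_edge(str(u), str(v))
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown DAG export format {format!r} (use 'json' or 'graphml')")


def load_dag_json(path) -> AssemblySpaceDAG:
    payload = json.loads(Path(path).read_text())
    if payload.get("schema") != DAG_SCHEMA:
        raise ValueError(f"{path}: unsupported DAG schema {payload.get('schema')!r}")
    g = nx.DiGraph()
    for node in payload["nodes"]:
        attrs = {"flag": node["flag"]}
        if "parents" in node:
            attrs["parents"] = tuple(int(p) for p in node["parents"])
        g.add_node(int(node["id"]), **attrs)
    for edge in payload["edges"]:
        g.add_edge(int(edge["source"]), int(edge["target"]))
    return AssemblySpaceDAG(graph=g, exact=payload["exact"])


# ---------------------------------------------------------------------------
# manifests
# ---------------------------------------------------------------------------


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    command: str
    config: dict
    seed: int | None = None
    version: str = ""
    created: str = ""
    inputs: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.version:
            from . import __version__

            self.version = __version__
        if not self.created:
            self.created = datetime.now(timezone.utc).isoformat()

    def add_input(self, path) -> None:
        self.inputs[str(path)] = _sha256(path)

    def add_output(self, path) -> None:
        self.outputs[str(path)] = _sha256(path)

    def write(self, path) -> None:
        payload = {
            "command": self.command,
            "config": self.config,
            "seed": self.seed,
            "version": self.version,
            "created": self.created,
            "inputs": self.inputs,
            "outputs": self.outputs,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
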