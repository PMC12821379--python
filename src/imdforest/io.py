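"""Matrix and result I/O.

Blocks travel as delimited text (TSV/CSV): header row of feature IDs, first
column of sample IDs, finite numeric values.  Results are TSV tables with a
JSON sidecar of tuned parameters, and each output directory can carry a
machine-readable provenance record.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .forest import OmicsBlock
from .imd import IMDProfile
from .multiomics import ConnectionEdge, ConnectionGraph
from .selection import SelectionResult

__all__ = [
    "load_block",
    "write_block",
    "write_imd",
    "write_selection",
    "write_graph",
    "load_graph",
    "write_provenance",
]


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def load_block(path, name: str | None = None) -> OmicsBlock:
    """Load a sample x feature matrix from CSV/TSV (Unix or Windows line
    endings).  Missing or non-numeric cells and duplicate IDs are errors."""
    path = Path(path)
    sep = _sep_for(path)
    with open(path, newline="") as fh:
        header = fh.readline().rstrip("\r\n").split(sep)[1:]
    if len(set(header)) != len(header):
        raise ValueError(f"{path}: duplicate feature IDs in header")
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.index.has_duplicates:
        raise ValueError(f"{path}: duplicate sample IDs")
    try:
        values = df.to_numpy(dtype=np.float64)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: non-numeric cell ({exc})") from exc
    bad = np.argwhere(~np.isfinite(values))
    if bad.size:
        r, c = bad[0]
        raise ValueError(
            f"{path}: missing/non-finite value at row {df.index[r]!r}, "
            f"column {df.columns[c]!r} ({len(bad)} offending cells)"
        )
    return OmicsBlock(
        values=values,
        sample_ids=[str(s) for s in df.index],
        feature_ids=[str(f) for f in df.columns],
        name=name or path.stem,
    )


def write_block(block: OmicsBlock, path) -> None:
    path = Path(path)
    block.to_dataframe().to_csv(path, sep=_sep_for(path), index_label="sample_id")


def write_imd(profile: IMDProfile, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    profile.to_dataframe().to_csv(path, sep="\t", index=False)


def write_selection(result: SelectionResult, path) -> None:
    """TSV of (feature_id, score, selected) plus a JSON sidecar with the
    strategy parameters actually used."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {
            "feature_id": result.feature_ids,
            "score": result.scores,
            "selected": result.selected_mask.astype(int),
        }
    ).to_csv(path, sep="\t", index=False)
    params = {
        k: (v.tolist() if isinstance(v, np.ndarray) else v)
        for k, v in result.params.items()
    }
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps({"strategy": result.strategy, "params": params, "flags": result.flags}, indent=2)
    )


def write_graph(graph: ConnectionGraph, path) -> None:
    payload = {
        "nodes": graph.nodes,
        "provenance": graph.provenance,
        "edges": [
            {"response": e.response, "predictor": e.predictor, "score": e.score}
            for e in graph.edges
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def load_graph(path) -> ConnectionGraph:
    payload = json.loads(Path(path).read_text())
    return ConnectionGraph(
        nodes=payload["nodes"],
        edges=[ConnectionEdge(**e) for e in payload["edges"]],
        provenance=payload.get("provenance", "prior"),
    )


def write_provenance(outdir, config: dict, seed: int) -> None:
    from . import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    record = {"version": __version__, "seed": seed, "config": config}
    (outdir / "provenance.json").write_text(json.dumps(record, indent=2, default=str))
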