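"""File I/O, run configuration and the batch engines behind the CLI."""

from __future__ import annotations

import dataclasses
import glob as globmod
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import networkx as nx
import numpy as np
import pandas as pd

from .classical import compute_classical
from .graph import UndirectedGraph, WeightedDigraph, binarize_by_density, symmetrize
from .indices import compute_all
from .nulls import null_ensemble
from .stats import compare_corpus

logger = logging.getLogger(__name__)

REPORT_COLUMNS = (
    "name", "n", "m", "density",
    "S", "V_n", "V_hat_n", "Omega", "R", "R_Omega",
    "C", "v", "L", "r", "Q", "seed",
)


class GraphParseError(ValueError):
    """Malformed graph file, with file/line context in the message."""


def _parse_edge_lines(path: Path):
    weighted = False
    arcs = []
    seen_pairs: set[tuple[str, str]] = set()
    duplicates = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").split()
            if len(parts) == 2:
                arcs.append((parts[0], parts[1], 1.0))
            elif len(parts) == 3:
                try:
                    w = float(parts[2])
                except ValueError as exc:
                    raise GraphParseError(
                        f"{path}:{lineno}: bad weight {parts[2]!r}"
                    ) from exc
                weighted = True
                arcs.append((parts[0], parts[1], w))
            else:
                raise GraphParseError(
                    f"{path}:{lineno}: expected 2 or 3 columns, got {len(parts)}"
                )
            pair = (parts[0], parts[1]) if parts[0] <= parts[1] else (parts[1], parts[0])
            if pair in seen_pairs:
                duplicates += 1
            seen_pairs.add(pair)
    if duplicates:
        logger.warning("%s: collapsed %d duplicate edge line(s)", path, duplicates)
    return arcs, weighted, duplicates


def _read_mtx(path: Path):
    from scipy.io import mmread

    try:
        mat = mmread(path).tocoo()
    except Exception as exc:
        raise GraphParseError(f"{path}: not a readable Matrix Market file: {exc}") from exc
    if mat.shape[0] != mat.shape[1]:
        raise GraphParseError(f"{path}: adjacency must be square, got {mat.shape}")
    arcs = [(str(i), str(j), float(w)) for i, j, w in zip(mat.row, mat.col, mat.data)]
    nodes = [str(i) for i in range(mat.shape[0])]
    weighted = any(w not in (0.0, 1.0) for _, _, w in arcs)
    return WeightedDigraph(arcs=arcs, nodes=nodes), weighted


def _read_adjacency_csv(path: Path):
    try:
        df = pd.read_csv(path, header=None)
        mat = df.to_numpy(dtype=float)
    except ValueError:
        # labelled variant: first row/column are labels
        df = pd.read_csv(path, index_col=0)
        mat = df.to_numpy(dtype=float)
    if mat.shape[0] != mat.shape[1]:
        raise GraphParseError(f"{path}: adjacency must be square, got {mat.shape}")
    if df.index.inferred_type in ("string", "mixed"):
        labels = [str(x) for x in df.index]
    else:
        labels = [str(i) for i in range(mat.shape[0])]
    arcs = [
        (labels[i], labels[j], float(mat[i, j]))
        for i, j in zip(*np.nonzero(mat))
    ]
    weighted = any(w not in (0.0, 1.0) for _, _, w in arcs)
    return WeightedDigraph(arcs=arcs, nodes=labels), weighted


def read_graph(
    path,
    dialect: Optional[str] = None,
    binarize_density: Optional[float] = None,
) -> tuple[UndirectedGraph, dict]:
    """Read a graph file and return (graph, provenance record).

    Dialects: ``edgelist`` (2-3 whitespace/comma columns, ``#`` comments),
    ``mtx`` (Matrix Market adjacency), ``graphml``, ``adjacency`` (dense
    CSV). Auto-detected from the extension when ``dialect`` is None.
    Directed or weighted input is symmetrised; with ``binarize_density`` the
    largest-weight pairs are kept at the requested density instead. The
    provenance dict records every cleaning step applied.
    """
    path = Path(path)
    if dialect is None:
        ext = path.suffix.lower()
        dialect = {
            ".mtx": "mtx",
            ".graphml": "graphml",
            ".csv": "adjacency",
        }.get(ext, "edgelist")

    prov: dict = {"path": str(path), "dialect": dialect, "preprocessing": []}

    if dialect == "edgelist":
        arcs, weighted, duplicates = _parse_edge_lines(path)
        W = WeightedDigraph(arcs=arcs)
        prov["weighted"] = weighted
        prov["duplicate_lines"] = duplicates
    elif dialect == "mtx":
        W, weighted = _read_mtx(path)
        prov["weighted"] = weighted
    elif dialect == "adjacency":
        W, weighted = _read_adjacency_csv(path)
        prov["weighted"] = weighted
    elif dialect == "graphml":
        try:
            g = nx.read_graphml(path)
        except Exception as exc:
            raise GraphParseError(f"{path}: not readable GraphML: {exc}") from exc
        prov["weighted"] = False
        prov["directed"] = g.is_directed()
        if g.is_directed():
            prov["preprocessing"].append("symmetrised")
        G = UndirectedGraph(nodes=g.nodes(), edges=g.to_undirected().edges())
        _finish_provenance(G, prov)
        return G, prov
    else:
        raise ValueError(f"unknown dialect: {dialect!r}")

    if binarize_density is not None:
        G = binarize_by_density(W, binarize_density)
        prov["preprocessing"].append(f"binarised at density {binarize_density}")
    else:
        G = symmetrize(W)
        if prov["weighted"]:
            prov["preprocessing"].append("weights dropped (symmetrised support)")
    _finish_provenance(G, prov)
    return G, prov


def _finish_provenance(G: UndirectedGraph, prov: dict) -> None:
    deg = G.degrees()
    prov["dropped_self_loops"] = G.dropped_self_loops
    # duplicate input lines are already collapsed at parse time
    prov["collapsed_duplicates"] = G.collapsed_duplicates + prov.pop("duplicate_lines", 0)
    prov["isolates"] = sum(1 for k in deg.values() if k == 0)
    prov["n"] = G.n
    prov["m"] = G.m


def write_edgelist(G: UndirectedGraph, path) -> None:
    """Canonical export: one ``u v`` line per edge, sorted."""
    with open(path, "w") as fh:
        for u, v in G.edges:
            fh.write(f"{u} {v}\n")


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Reproducible run description; round-trips losslessly through JSON."""

    inputs: list[str] = field(default_factory=list)
    dialect: Optional[str] = None
    binarize_density: Optional[float] = None
    variance_convention: str = "population"
    per_node_normalised_complexity: bool = False
    null_realisations: int = 10
    swaps_per_edge: int = 10
    seed: int = 0
    outdir: Optional[str] = None

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls(**json.loads(text))

    def resolve_inputs(self) -> list[Path]:
        paths: list[Path] = []
        for pattern in self.inputs:
            hits = sorted(globmod.glob(pattern))
            paths.extend(Path(h) for h in hits) if hits else paths.append(Path(pattern))
        return paths


# ---------------------------------------------------------------------------
# batch engines


def _report_row(name: str, G: UndirectedGraph, cfg: RunConfig) -> dict:
    rep = compute_all(
        G,
        variance_convention=cfg.variance_convention,  # type: ignore[arg-type]
        per_node_normalised_complexity=cfg.per_node_normalised_complexity,
    )
    cls = compute_classical(G, cfg.variance_convention)  # type: ignore[arg-type]
    return {
        "name": name,
        "n": G.n,
        "m": G.m,
        "density": G.density,
        "S": rep.S,
        "V_n": rep.V_n,
        "V_hat_n": rep.V_hat_n,
        "Omega": rep.Omega,
        "R": rep.R,
        "R_Omega": rep.R_Omega,
        "C": cls.C,
        "v": cls.v,
        "L": cls.L,
        "r": cls.r,
        "Q": cls.Q,
        "seed": cfg.seed,
    }


@dataclass
class RunResult:
    table: pd.DataFrame
    provenance: list[dict]
    errors: list[dict]

    @property
    def exit_code(self) -> int:
        """0 all succeeded, 1 partial failure, 2 all failed."""
        if not self.errors:
            return 0
        return 2 if self.table.empty else 1


def run_compute(cfg: RunConfig) -> RunResult:
    """Compute all indices for every input graph; failures are isolated."""
    rows, provenance, errors = [], [], []
    for path in cfg.resolve_inputs():
        try:
            G, prov = read_graph(
                path, dialect=cfg.dialect, binarize_density=cfg.binarize_density
            )
            rows.append(_report_row(path.name, G, cfg))
            provenance.append(prov)
        except Exception as exc:  # noqa: BLE001 - per-file isolation is the contract
            logger.error("failed on %s: %s", path, exc)
            errors.append({"path": str(path), "error": str(exc)})
    table = pd.DataFrame(rows, columns=list(REPORT_COLUMNS))
    return RunResult(table=table, provenance=provenance, errors=errors)


def run_nullcmp(cfg: RunConfig) -> tuple[RunResult, pd.DataFrame, Optional[pd.DataFrame]]:
    """Observed vs configuration-model null means, plus corpus-level tests.

    Returns (observed RunResult, long observed-vs-null table, test table or
    None when the corpus is too small to test).
    """
    if cfg.null_realisations < 1:
        raise ValueError("null_realisations must be >= 1")
    paths = cfg.resolve_inputs()
    children = np.random.SeedSequence(cfg.seed).spawn(max(len(paths), 1))
    rows, provenance, errors, long_rows = [], [], [], []
    for path, child in zip(paths, children):
        try:
            G, prov = read_graph(
                path, dialect=cfg.dialect, binarize_density=cfg.binarize_density
            )
            row = _report_row(path.name, G, cfg)
            ens = null_ensemble(
                G,
                n_realisations=cfg.null_realisations,
                seed=int(child.generate_state(1)[0]),
                swaps_per_edge=cfg.swaps_per_edge,
                variance_convention=cfg.variance_convention,  # type: ignore[arg-type]
                per_node_normalised_complexity=cfg.per_node_normalised_complexity,
            )
        except Exception as exc:  # noqa: BLE001
            logger.error("failed on %s: %s", path, exc)
            errors.append({"path": str(path), "error": str(exc)})
            continue
        rows.append(row)
        provenance.append(prov)
        for index in ("S", "V_n", "V_hat_n", "Omega", "R", "R_Omega", "C", "v", "L", "r", "Q"):
            mean, sd, n_def = ens.summary[index]
            long_rows.append(
                {
                    "network": row["name"],
                    "index": index,
                    "observed": row[index],
                    "null_mean": mean,
                    "null_sd": sd,
                    "null_n": n_def,
                }
            )
    observed = RunResult(
        table=pd.DataFrame(rows, columns=list(REPORT_COLUMNS)),
        provenance=provenance,
        errors=errors,
    )
    long_table = pd.DataFrame(long_rows)
    tests = None
    if len(observed.table) >= 2 and not long_table.empty:
        cmp = compare_corpus(long_table.dropna(subset=["observed", "null_mean"]))
        tests = cmp.table
    return observed, long_table, tests


def run_snapshots(cfg: RunConfig) -> RunResult:
    """Per-snapshot indices for an ordered series of graph files."""
    paths = cfg.resolve_inputs()
    if len(paths) < 2:
        raise ValueError("snapshots needs at least 2 ordered input files")
    result = run_compute(cfg)
    result.table.insert(0, "t", range(len(result.table)))
    return result
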