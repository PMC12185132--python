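"""File formats shared by all pipeline stages.

TSV is the canonical interchange format (counts, metadata, GO maps, edge
lists, HOG networks, clade maps); MatrixMarket is accepted for counts,
GraphML for graphs, and HDF5 for dense per-condition precision matrices.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import networkx as nx
import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite
from scipy.sparse import csr_matrix

from .containers import ExpressionMatrix, GroundTruth, SampleTable
from .ggm import PrecisionSet
from .netops import HogNetwork, Network

# --------------------------------------------------------------------------
# expression + metadata


def write_counts_tsv(expr: ExpressionMatrix, path) -> None:
    expr.values.to_csv(path, sep="\t", index_label="gene")


def read_counts_tsv(path, stage: str = "counts") -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty:
        raise ValueError(f"empty counts file: {path}")
    return ExpressionMatrix(values=df, stage=stage)


def write_counts_mtx(expr: ExpressionMatrix, prefix) -> None:
    """Write .mtx plus <prefix>.genes.tsv / <prefix>.samples.tsv index files."""
    prefix = Path(prefix)
    mmwrite(str(prefix.with_suffix(".mtx")), csr_matrix(expr.values.to_numpy()))
    prefix.with_suffix(".genes.tsv").write_text("\n".join(expr.gene_ids) + "\n")
    prefix.with_suffix(".samples.tsv").write_text("\n".join(expr.sample_ids) + "\n")


def read_counts_mtx(prefix, stage: str = "counts") -> ExpressionMatrix:
    prefix = Path(prefix)
    mat = np.asarray(mmread(str(prefix.with_suffix(".mtx"))).todense())
    genes = prefix.with_suffix(".genes.tsv").read_text().split()
    samples = prefix.with_suffix(".samples.tsv").read_text().split()
    return ExpressionMatrix(
        values=pd.DataFrame(mat, index=genes, columns=samples), stage=stage
    )


def write_metadata_tsv(samples: SampleTable, path) -> None:
    samples.table.to_csv(path, sep="\t", index_label="sample")


def read_metadata_tsv(
    path, retained: list[str] | None = None, unwanted: list[str] | None = None
) -> SampleTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    kwargs = {}
    if retained is not None:
        kwargs["retained"] = retained
    if unwanted is not None:
        kwargs["unwanted"] = unwanted
    return SampleTable(table=df, **kwargs)


# --------------------------------------------------------------------------
# GO annotation


def read_go_tsv(path, namespace: str | None = "BP") -> dict[str, set[str]]:
    """Two-column ``gene<TAB>GO:NNNNNNN`` map, optional third namespace column.

    When a namespace column is present and ``namespace`` is given, rows
    are filtered to it (accepts "BP", "biological_process", or "P").
    """
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValueError("GO TSV needs at least two columns: gene, term")
    bp_aliases = {"BP", "biological_process", "P"}
    go_map: dict[str, set[str]] = {}
    for row in df.itertuples(index=False):
        gene, term = row[0], row[1]
        if df.shape[1] >= 3 and namespace is not None:
            ns = row[2]
            if ns and ns not in bp_aliases:
                continue
        go_map.setdefault(gene, set()).add(term)
    return go_map


def read_gaf(path, aspect: str = "P") -> dict[str, set[str]]:
    """GAF 2.x: column 2 = gene, 5 = GO id, 9 = aspect ("P" selects BP)."""
    go_map: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("!") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                raise ValueError(f"malformed GAF line: {line[:80]!r}")
            gene, term, asp = parts[1], parts[4], parts[8]
            if asp != aspect:
                continue
            go_map.setdefault(gene, set()).add(term)
    return go_map


def read_go_map(path, namespace: str | None = "BP") -> dict[str, set[str]]:
    """Dispatch on extension: .gaf -> GAF, otherwise two-column TSV."""
    if str(path).endswith(".gaf"):
        return read_gaf(path)
    return read_go_tsv(path, namespace=namespace)


def write_go_tsv(go_map: dict[str, set[str]], path) -> None:
    with open(path, "w") as fh:
        for gene in sorted(go_map):
            for term in sorted(go_map[gene]):
                fh.write(f"{gene}\t{term}\n")


# --------------------------------------------------------------------------
# clade map


def read_clade_map(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    return dict(zip(df[0], df[1]))


def write_clade_map(clade_map: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for sp in sorted(clade_map):
            fh.write(f"{sp}\t{clade_map[sp]}\n")


# --------------------------------------------------------------------------
# precision matrices


def write_precision_h5(fit: PrecisionSet, path) -> None:
    with h5py.File(path, "w") as h5:
        h5.attrs["gene_ids"] = np.array(fit.gene_ids, dtype="S")
        h5.attrs["conditions"] = np.array(fit.conditions, dtype="S")
        h5.attrs["lambda1"] = fit.lambda1
        h5.attrs["lambda2"] = fit.lambda2
        h5.attrs["converged"] = fit.converged
        h5.attrs["n_iter"] = fit.n_iter
        for cond in fit.conditions:
            h5.create_dataset(cond, data=fit.thetas[cond])


def read_precision_h5(path) -> PrecisionSet:
    with h5py.File(path, "r") as h5:
        gene_ids = [g.decode() for g in h5.attrs["gene_ids"]]
        conditions = [c.decode() for c in h5.attrs["conditions"]]
        thetas = {c: np.asarray(h5[c]) for c in conditions}
        return PrecisionSet(
            thetas=thetas,
            gene_ids=gene_ids,
            conditions=conditions,
            lambda1=float(h5.attrs["lambda1"]),
            lambda2=float(h5.attrs["lambda2"]),
            n_iter=int(h5.attrs["n_iter"]),
            primal_residual=float("nan"),
            dual_residual=float("nan"),
            converged=bool(h5.attrs["converged"]),
        )


def write_precision_tsv(fit: PrecisionSet, path, tol: float = 1e-10) -> None:
    """Sparse upper-triangle dump: gene_a, gene_b, condition, theta."""
    rows = []
    for cond in fit.conditions:
        theta = fit.thetas[cond]
        iu = np.triu_indices_from(theta, k=1)
        for i, j in zip(*iu):
            if abs(theta[i, j]) > tol:
                rows.append(
                    (fit.gene_ids[i], fit.gene_ids[j], cond, theta[i, j])
                )
    pd.DataFrame(rows, columns=["gene_a", "gene_b", "condition", "theta"]).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


# --------------------------------------------------------------------------
# networks


def write_network_tsv(net: Network, path) -> None:
    rows = [
        (a, b, f"{net.weight(a, b):.10g}", net.species, net.condition)
        for a, b in sorted(net.edges)
    ]
    pd.DataFrame(
        rows, columns=["gene_a", "gene_b", "weight", "species", "condition"]
    ).to_csv(path, sep="\t", index=False)


def read_network_tsv(path, nodes: list[str] | None = None) -> Network:
    df = pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str})
    g = nx.Graph()
    if nodes:
        g.add_nodes_from(nodes)
    species = condition = ""
    for row in df.itertuples(index=False):
        g.add_edge(row.gene_a, row.gene_b, weight=float(row.weight))
        species, condition = row.species, row.condition
    return Network(species=species, condition=condition, graph=g)


def write_network_graphml(net: Network, path) -> None:
    g = net.graph.copy()
    for _, _, data in g.edges(data=True):
        if "conditions" in data:
            data["conditions"] = ";".join(data["conditions"])
    g.graph["species"] = net.species
    g.graph["condition"] = net.condition
    nx.write_graphml(g, path)


def write_hog_network_tsv(hog_net: HogNetwork, path) -> None:
    rows = [
        (
            ha,
            hb,
            ";".join(f"{sp}:{cond}" for sp, cond in sorted(prov)),
        )
        for (ha, hb), prov in sorted(hog_net.edges.items())
    ]
    pd.DataFrame(rows, columns=["hog_a", "hog_b", "provenance"]).to_csv(
        path, sep="\t", index=False
    )


def read_hog_network_tsv(path) -> HogNetwork:
    df = pd.read_csv(path, sep="\t", dtype=str)
    net = HogNetwork()
    for row in df.itertuples(index=False):
        prov = {
            tuple(item.split(":", 1)) for item in row.provenance.split(";") if item
        }
        net.add(row.hog_a, row.hog_b, prov)
    return net


# --------------------------------------------------------------------------
# ground truth


def write_truth_json(truth: GroundTruth, path) -> None:
    payload = {
        "condition_names": truth.condition_names,
        "shared_support": sorted(map(list, truth.shared_support)),
        "specific_support": {
            c: sorted(map(list, s)) for c, s in truth.specific_support.items()
        },
        "precision_set": {
            c: truth.precision_set[c].tolist() for c in truth.condition_names
        },
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_truth_json(path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    return GroundTruth(
        precision_set={
            c: np.asarray(m) for c, m in payload["precision_set"].items()
        },
        shared_support={tuple(p) for p in payload["shared_support"]},
        specific_support={
            c: {tuple(p) for p in s} for c, s in payload["specific_support"].items()
        },
        condition_names=payload["condition_names"],
    )
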