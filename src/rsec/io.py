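"""Readers and writers for the formats the workflow touches.

Expression matrices come in as MatrixMarket coordinate files (with sibling
gene/sample name files) or dense CSV/TSV with genes in rows.  Clusterings
go out as a labels CSV (first column sample_id, one integer column per
clustering, -1 for unassigned); the cluster hierarchy as Newick; the full
result as a directory with a JSON manifest recording the configuration and
seed.  All outputs are keyed by names, never positional indices, so they
stay stable under subsetting.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Any

import dendropy
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .align import newick_export
from .core import ClusterLabels, ClusterMatrix, ExpressionMatrix, RSECResult
from .merge import ClusterHierarchy, HNode


def read_expression(path: str | Path, fmt: str | None = None,
                    genes_path: str | Path | None = None,
                    samples_path: str | Path | None = None) -> ExpressionMatrix:
    """Load a genes x samples expression matrix.

    ``fmt`` is inferred from the suffix when omitted.  For MTX, gene and
    sample names default to sibling files ``<stem>.genes.txt`` and
    ``<stem>.samples.txt`` (one name per line).
    """
    path = Path(path)
    if fmt is None:
        fmt = {".mtx": "mtx", ".csv": "csv", ".tsv": "tsv",
               ".txt": "tsv"}.get(path.suffix.lower())
        if fmt is None:
            raise ValueError(f"cannot infer format from {path.name!r}")
    if fmt == "mtx":
        mat = scipy.io.mmread(path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        genes_path = Path(genes_path) if genes_path else path.with_suffix(".genes.txt")
        samples_path = Path(samples_path) if samples_path \
            else path.with_suffix(".samples.txt")
        gene_ids = genes_path.read_text().split()
        sample_ids = samples_path.read_text().split()
        if len(gene_ids) != mat.shape[0] or len(sample_ids) != mat.shape[1]:
            raise ValueError(
                f"name files ({len(gene_ids)} genes, {len(sample_ids)} samples) "
                f"do not match matrix shape {mat.shape}")
        return ExpressionMatrix(np.asarray(mat, dtype=float), gene_ids, sample_ids)
    if fmt in ("csv", "tsv"):
        sep = "," if fmt == "csv" else "\t"
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split(sep)[1:]
        dup = sorted({h for h in header if header.count(h) > 1})
        if dup:
            raise ValueError(f"duplicate sample column(s): {dup}")
        df = pd.read_csv(path, sep=sep, index_col=0)
        return ExpressionMatrix(df.to_numpy(dtype=float),
                                [str(g) for g in df.index],
                                [str(s) for s in df.columns])
    raise ValueError(f"unknown format {fmt!r}")


def write_expression(X: ExpressionMatrix, path: str | Path) -> None:
    """Write CSV/TSV (by suffix) or MTX plus sibling name files."""
    path = Path(path)
    if path.suffix.lower() == ".mtx":
        scipy.io.mmwrite(str(path), scipy.sparse.coo_matrix(X.values))
        path.with_suffix(".genes.txt").write_text("\n".join(X.gene_ids) + "\n")
        path.with_suffix(".samples.txt").write_text("\n".join(X.sample_ids) + "\n")
        return
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    pd.DataFrame(X.values, index=X.gene_ids, columns=X.sample_ids).to_csv(
        path, sep=sep)


def write_labels_csv(M: ClusterMatrix | ClusterLabels, path: str | Path,
                     sample_ids: list[str] | None = None) -> None:
    """Labels CSV: first column sample_id, one integer column per clustering."""
    if isinstance(M, ClusterLabels):
        if sample_ids is None:
            sample_ids = [f"s{i+1}" for i in range(len(M))]
        M = ClusterMatrix(rows=[M], sample_ids=sample_ids)
    M.to_frame().to_csv(path)


def read_labels_csv(path: str | Path) -> ClusterMatrix:
    df = pd.read_csv(path, index_col=0)
    return ClusterMatrix.from_frame(df.astype(int))


def read_newick(path_or_text: str | Path) -> ClusterHierarchy:
    """Rebuild a cluster hierarchy from a Newick string or file.

    Leaf labels must look like ``c<id>``; internal nodes are renamed
    node1.. in pre-order, matching the naming used when the tree is built.
    """
    text = Path(path_or_text).read_text() if Path(str(path_or_text)).exists() \
        else str(path_or_text)
    tree = dendropy.Tree.get(data=text, schema="newick")

    def convert(node) -> HNode:
        children = node.child_nodes()
        if not children:
            name = node.taxon.label if node.taxon else node.label
            cid = int(str(name).lstrip("c"))
            return HNode(name=f"c{cid}", clusters=(cid,), height=0.0)
        if len(children) != 2:
            raise ValueError("hierarchy must be a binary tree")
        left, right = (convert(c) for c in children)
        h_left = left.height + (children[0].edge.length or 0.0)
        return HNode(name="", clusters=tuple(sorted(left.clusters + right.clusters)),
                     height=float(h_left), left=left, right=right)

    root = convert(tree.seed_node)
    idx = {"n": 0}

    def rename(node: HNode) -> None:
        if node.is_leaf:
            return
        idx["n"] += 1
        node.name = f"node{idx['n']}"
        rename(node.left)
        rename(node.right)

    rename(root)
    return ClusterHierarchy(root=root, cluster_ids=sorted(root.clusters))


def node_estimates_frame(result: RSECResult) -> pd.DataFrame:
    rows = []
    if result.hierarchy is not None:
        for node in result.hierarchy.internal_nodes():
            rows.append({"node": node.name,
                         "clusters": "|".join(map(str, node.clusters)),
                         "estimate": node.estimate,
                         "merged": node.merged})
    return pd.DataFrame(rows, columns=["node", "clusters", "estimate", "merged"])


def write_result(result: RSECResult, outdir: str | Path) -> dict[str, Path]:
    """Write the complete result set to a directory.

    Files: clusterings.csv, consensus.csv, merged.csv, dendrogram.nwk,
    node_estimates.tsv, manifest.json.  A ``.incomplete`` marker guards
    against partially written directories.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    marker = outdir / ".incomplete"
    marker.write_text("write in progress\n")
    files: dict[str, Path] = {}
    sample_ids = result.cluster_matrix.sample_ids
    write_labels_csv(result.cluster_matrix, outdir / "clusterings.csv")
    files["clusterings"] = outdir / "clusterings.csv"
    for name, labels in (("consensus", result.consensus),
                         ("merged", result.merged)):
        if labels is not None:
            lab = ClusterLabels(labels.labels, name=name, params=labels.params)
            write_labels_csv(lab, outdir / f"{name}.csv", sample_ids=sample_ids)
            files[name] = outdir / f"{name}.csv"
    if result.hierarchy is not None:
        (outdir / "dendrogram.nwk").write_text(newick_export(result.hierarchy) + "\n")
        files["dendrogram"] = outdir / "dendrogram.nwk"
    est = node_estimates_frame(result)
    est.to_csv(outdir / "node_estimates.tsv", sep="\t", index=False)
    files["node_estimates"] = outdir / "node_estimates.tsv"
    manifest = {"provenance": _jsonable(result.provenance),
                "n_samples": result.cluster_matrix.n_samples,
                "n_clusterings": result.cluster_matrix.n_clusterings,
                "node_estimates": _jsonable(result.node_estimates)}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    files["manifest"] = outdir / "manifest.json"
    marker.unlink()
    return files


def read_result(outdir: str | Path) -> RSECResult:
    """Reload a result directory written by :func:`write_result`."""
    outdir = Path(outdir)
    if (outdir / ".incomplete").exists():
        warnings.warn(f"{outdir} carries an .incomplete marker", RuntimeWarning)
    cm = read_labels_csv(outdir / "clusterings.csv")
    consensus = merged = None
    if (outdir / "consensus.csv").exists():
        consensus = read_labels_csv(outdir / "consensus.csv").rows[0]
    if (outdir / "merged.csv").exists():
        merged = read_labels_csv(outdir / "merged.csv").rows[0]
    hierarchy = None
    if (outdir / "dendrogram.nwk").exists():
        hierarchy = read_newick(outdir / "dendrogram.nwk")
        est = pd.read_csv(outdir / "node_estimates.tsv", sep="\t")
        by_name = {r["node"]: r for _, r in est.iterrows()}
        for node in hierarchy.internal_nodes():
            if node.name in by_name:
                node.estimate = float(by_name[node.name]["estimate"])
                node.merged = bool(by_name[node.name]["merged"])
    manifest = json.loads((outdir / "manifest.json").read_text())
    return RSECResult(cluster_matrix=cm, consensus=consensus, merged=merged,
                      hierarchy=hierarchy,
                      node_estimates=dict(manifest.get("node_estimates", {})),
                      provenance=dict(manifest.get("provenance", {})))


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
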