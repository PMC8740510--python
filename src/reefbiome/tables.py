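"""Domain containers and file IO for the pipeline.

All tabular formats are plain text: TSV (UTF-8, "." decimal), BIOM 1.0
JSON, SIF, GraphML and newick.  Every reader validates at the boundary and
every writer/reader pair is an identity on valid objects.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "OtuTable",
    "SampleFrame",
    "EnvMatrix",
    "DistanceMatrix",
    "TreeNode",
    "read_otu_table",
    "write_otu_table",
    "read_design",
    "write_design",
    "read_env",
    "write_env",
    "export_network",
    "read_edge_tsv",
    "write_newick",
    "newick_string",
]

HABITATS = ("water", "sediment")
SEASONS = ("spring", "summer", "autumn", "winter")
AREAS = ("RR", "TA", "CR", "AA")


class ValidationError(ValueError):
    """Raised when an input object or file violates a structural invariant."""


def _check_unique(ids, kind):
    seen = set()
    for x in ids:
        if x in seen:
            raise ValidationError(f"duplicate {kind} identifier: {x!r}")
        seen.add(x)


@dataclass
class OtuTable:
    """Samples x OTUs count matrix with optional taxonomy.

    ``counts[i, j]`` is the read count of OTU ``otu_ids[j]`` in sample
    ``sample_ids[i]``.  Taxonomy maps otu_id to a QIIME-style lineage
    string (``k__...;p__...;...``).
    """

    sample_ids: list
    otu_ids: list
    counts: np.ndarray
    taxonomy: dict = field(default_factory=dict)

    def __post_init__(self):
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.otu_ids = [str(o) for o in self.otu_ids]
        self.counts = np.asarray(self.counts)
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.otu_ids, "OTU")
        if self.counts.shape != (len(self.sample_ids), len(self.otu_ids)):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.otu_ids)} OTUs"
            )
        if self.counts.size:
            if not np.issubdtype(self.counts.dtype, np.integer):
                if not np.all(np.equal(np.mod(self.counts, 1), 0)):
                    raise ValidationError("counts must be integral")
                self.counts = self.counts.astype(np.int64)
            if (self.counts < 0).any():
                i, j = np.argwhere(self.counts < 0)[0]
                raise ValidationError(
                    f"negative count at sample {self.sample_ids[i]!r}, "
                    f"OTU {self.otu_ids[j]!r}"
                )
        else:
            self.counts = self.counts.reshape(
                len(self.sample_ids), len(self.otu_ids)
            ).astype(np.int64)
        known = set(self.otu_ids)
        for k in self.taxonomy:
            if k not in known:
                raise ValidationError(f"taxonomy key {k!r} is not a known OTU id")

    @property
    def n_samples(self):
        return len(self.sample_ids)

    @property
    def n_otus(self):
        return len(self.otu_ids)

    def relative_abundance(self) -> np.ndarray:
        """Per-sample relative abundances (rows sum to 1)."""
        totals = self.counts.sum(axis=1, keepdims=True).astype(float)
        if (totals == 0).any():
            bad = self.sample_ids[int(np.argmin(totals))]
            raise ValidationError(f"sample {bad!r} has zero total count")
        return self.counts / totals

    def mean_relative_abundance(self) -> np.ndarray:
        return self.relative_abundance().mean(axis=0)

    def phylum(self, otu_id: str) -> str:
        """Phylum parsed from the lineage string, or 'unknown'."""
        lin = self.taxonomy.get(otu_id, "")
        for part in lin.split(";"):
            part = part.strip()
            if part.startswith("p__") and len(part) > 3:
                return part[3:]
        return "unknown"

    def select_otus(self, otu_ids) -> "OtuTable":
        idx = {o: i for i, o in enumerate(self.otu_ids)}
        cols = [idx[o] for o in otu_ids]
        return OtuTable(
            sample_ids=list(self.sample_ids),
            otu_ids=list(otu_ids),
            counts=self.counts[:, cols],
            taxonomy={o: self.taxonomy[o] for o in otu_ids if o in self.taxonomy},
        )

    def select_samples(self, sample_ids) -> "OtuTable":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [idx[s] for s in sample_ids]
        return OtuTable(
            sample_ids=list(sample_ids),
            otu_ids=list(self.otu_ids),
            counts=self.counts[rows, :],
            taxonomy=dict(self.taxonomy),
        )

    def equals(self, other: "OtuTable") -> bool:
        return (
            self.sample_ids == other.sample_ids
            and self.otu_ids == other.otu_ids
            and np.array_equal(self.counts, other.counts)
            and self.taxonomy == other.taxonomy
        )


@dataclass
class SampleFrame:
    """Per-sample design labels: habitat, season, area, replicate."""

    frame: pd.DataFrame  # index = sample_id

    def __post_init__(self):
        df = self.frame
        required = {"habitat", "season", "area", "replicate"}
        missing = required - set(df.columns)
        if missing:
            raise ValidationError(f"design is missing columns: {sorted(missing)}")
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()][0]
            raise ValidationError(f"duplicate sample identifier: {dup!r}")
        df = df.copy()
        df["habitat"] = df["habitat"].astype(str).str.lower()
        df["season"] = df["season"].astype(str).str.lower()
        df["area"] = df["area"].astype(str).str.upper()
        for col, vocab in (("habitat", HABITATS), ("season", SEASONS), ("area", AREAS)):
            bad = set(df[col]) - set(vocab)
            if bad:
                raise ValidationError(
                    f"out-of-vocabulary {col} value: {sorted(bad)[0]!r} "
                    f"(allowed: {vocab})"
                )
        df["replicate"] = df["replicate"].astype(int)
        if (df["replicate"] < 1).any():
            raise ValidationError("replicate must be a positive integer")
        self.frame = df

    @property
    def sample_ids(self):
        return list(self.frame.index)

    def aligned_to(self, sample_ids) -> pd.DataFrame:
        missing = [s for s in sample_ids if s not in self.frame.index]
        if missing:
            raise ValidationError(
                f"samples absent from design: {missing[:5]}"
            )
        return self.frame.loc[list(sample_ids)]

    def subset(self, **criteria) -> "SampleFrame":
        df = self.frame
        for col, val in criteria.items():
            df = df[df[col] == val]
        return SampleFrame(df.copy())


@dataclass
class EnvMatrix:
    """Samples x environmental factors, with a missing-value mask."""

    sample_ids: list
    factor_names: list
    values: np.ndarray
    mask: np.ndarray = None  # True where missing

    def __post_init__(self):
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.factor_names = [str(f) for f in self.factor_names]
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.factor_names, "factor")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.factor_names)):
            raise ValidationError(
                f"env values shape {self.values.shape} does not match ids"
            )
        if self.mask is None:
            self.mask = np.isnan(self.values)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.values.shape:
            raise ValidationError("env mask shape mismatch")
        self.mask |= np.isnan(self.values)
        if self.values.size and self.mask.all(axis=0).any():
            f = self.factor_names[int(np.argmax(self.mask.all(axis=0)))]
            raise ValidationError(f"factor {f!r} is entirely missing")

    def to_frame(self) -> pd.DataFrame:
        vals = self.values.copy()
        vals[self.mask] = np.nan
        return pd.DataFrame(vals, index=self.sample_ids, columns=self.factor_names)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise dissimilarities with sample labels."""

    sample_ids: list
    d: np.ndarray

    def __post_init__(self):
        self.sample_ids = [str(s) for s in self.sample_ids]
        _check_unique(self.sample_ids, "sample")
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.sample_ids)
        if self.d.shape != (n, n):
            raise ValidationError(f"distance matrix shape {self.d.shape} != ({n},{n})")
        if n and not np.allclose(self.d, self.d.T, atol=1e-12, rtol=0):
            raise ValidationError("distance matrix is not symmetric within 1e-12")
        if n and np.abs(np.diag(self.d)).max() > 1e-12:
            raise ValidationError("distance matrix diagonal is not zero")
        if n and self.d.min() < 0:
            raise ValidationError("distance matrix has a negative entry")
        self.d = (self.d + self.d.T) / 2.0
        np.fill_diagonal(self.d, 0.0)

    @property
    def n(self):
        return len(self.sample_ids)

    def condensed(self) -> np.ndarray:
        iu = np.triu_indices(self.n, k=1)
        return self.d[iu]

    def reorder(self, sample_ids) -> "DistanceMatrix":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        order = [idx[s] for s in sample_ids]
        return DistanceMatrix(list(sample_ids), self.d[np.ix_(order, order)])


# ---------------------------------------------------------------------------
# OTU table IO


def read_otu_table(path, format="tsv") -> OtuTable:
    """Read an OTU table from TSV (OTUs as rows) or BIOM 1.0 JSON."""
    if format == "tsv":
        return _read_otu_tsv(path)
    if format == "biom-json":
        return _read_biom_json(path)
    raise ValueError(f"unknown OTU table format: {format!r}")


def write_otu_table(table: OtuTable, path, format="tsv"):
    if format == "tsv":
        _write_otu_tsv(table, path)
    elif format == "biom-json":
        _write_biom_json(table, path)
    else:
        raise ValueError(f"unknown OTU table format: {format!r}")


def _read_otu_tsv(path) -> OtuTable:
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    lines = [ln for ln in lines if ln and not ln.startswith("# ")]
    if not lines:
        raise ValidationError(f"{path}: empty OTU table file")
    header = lines[0].lstrip("#").split("\t")
    has_tax = header and header[-1].strip().lower() == "taxonomy"
    sample_ids = header[1 : -1 if has_tax else None]
    otu_ids, rows, taxonomy = [], [], {}
    for ln_no, ln in enumerate(lines[1:], start=2):
        parts = ln.split("\t")
        otu = parts[0]
        vals = parts[1 : 1 + len(sample_ids)]
        if len(vals) != len(sample_ids):
            raise ValidationError(
                f"{path}:{ln_no}: expected {len(sample_ids)} counts, got {len(vals)}"
            )
        row = []
        for col, v in zip(sample_ids, vals):
            try:
                x = float(v)
            except ValueError:
                raise ValidationError(
                    f"{path}:{ln_no}: non-numeric count {v!r} "
                    f"(OTU {otu!r}, sample {col!r})"
                ) from None
            if x < 0 or x != int(x):
                raise ValidationError(
                    f"{path}:{ln_no}: invalid count {v!r} "
                    f"(OTU {otu!r}, sample {col!r})"
                )
            row.append(int(x))
        otu_ids.append(otu)
        rows.append(row)
        if has_tax:
            tax = parts[1 + len(sample_ids)] if len(parts) > 1 + len(sample_ids) else ""
            if tax:
                taxonomy[otu] = tax
    counts = np.array(rows, dtype=np.int64).reshape(len(otu_ids), len(sample_ids)).T
    return OtuTable(sample_ids, otu_ids, counts, taxonomy)


def _write_otu_tsv(table: OtuTable, path):
    has_tax = bool(table.taxonomy)
    with open(path, "w", encoding="utf-8") as fh:
        cols = ["#OTU ID"] + table.sample_ids + (["taxonomy"] if has_tax else [])
        fh.write("\t".join(cols) + "\n")
        for j, otu in enumerate(table.otu_ids):
            row = [otu] + [str(int(c)) for c in table.counts[:, j]]
            if has_tax:
                row.append(table.taxonomy.get(otu, ""))
            fh.write("\t".join(row) + "\n")


def _read_biom_json(path) -> OtuTable:
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    n_rows, n_cols = doc["shape"]
    otu_ids = [r["id"] for r in doc["rows"]]
    sample_ids = [c["id"] for c in doc["columns"]]
    if len(otu_ids) != n_rows or len(sample_ids) != n_cols:
        raise ValidationError(f"{path}: BIOM shape does not match row/column lists")
    mat = np.zeros((n_rows, n_cols), dtype=np.int64)
    if doc.get("matrix_type") == "sparse":
        for r, c, v in doc["data"]:
            mat[r, c] = v
    else:
        mat[:, :] = np.asarray(doc["data"])
    taxonomy = {}
    for r in doc["rows"]:
        md = r.get("metadata") or {}
        tax = md.get("taxonomy")
        if tax:
            taxonomy[r["id"]] = tax if isinstance(tax, str) else ";".join(tax)
    return OtuTable(sample_ids, otu_ids, mat.T, taxonomy)


def _write_biom_json(table: OtuTable, path):
    mat = table.counts.T  # BIOM rows are observations (OTUs)
    data = [
        [int(r), int(c), int(mat[r, c])]
        for r, c in zip(*np.nonzero(mat))
    ]
    doc = {
        "id": None,
        "format": "Biological Observation Matrix 1.0.0",
        "format_url": "http://biom-format.org",
        "type": "OTU table",
        "generated_by": "reefbiome",
        "date": "1970-01-01T00:00:00",
        "matrix_type": "sparse",
        "matrix_element_type": "int",
        "shape": [table.n_otus, table.n_samples],
        "rows": [
            {
                "id": o,
                "metadata": (
                    {"taxonomy": table.taxonomy[o]} if o in table.taxonomy else None
                ),
            }
            for o in table.otu_ids
        ],
        "columns": [{"id": s, "metadata": None} for s in table.sample_ids],
        "data": data,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh)


# ---------------------------------------------------------------------------
# Design / environment IO


def read_design(path) -> SampleFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in df.columns:
        raise ValidationError(f"{path}: design file must have a sample_id column")
    df = df.set_index("sample_id")
    return SampleFrame(df)


def write_design(design: SampleFrame, path):
    design.frame.to_csv(path, sep="\t", index_label="sample_id")


def read_env(path) -> EnvMatrix:
    df = pd.read_csv(path, sep="\t")
    if "sample_id" not in df.columns:
        raise ValidationError(f"{path}: env file must have a sample_id column")
    df = df.set_index("sample_id")
    values = df.to_numpy(dtype=float)
    return EnvMatrix(list(df.index.astype(str)), list(df.columns), values)


def write_env(env: EnvMatrix, path):
    env.to_frame().to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# Network export


def export_network(net, path, format="edge-tsv"):
    """Export a co-occurrence network for external tools (e.g. Cytoscape).

    Always also writes a companion node-attribute TSV next to ``path``
    (suffix ``.nodes.tsv``).
    """
    import networkx as nx

    g = net.graph if hasattr(net, "graph") else net
    path = str(path)
    if format == "edge-tsv":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("source\ttarget\trho\tp\tsign\n")
            for u, v, attrs in sorted(g.edges(data=True)):
                fh.write(
                    f"{u}\t{v}\t{attrs['rho']:.10g}\t{attrs['p']:.6g}\t{attrs['sign']}\n"
                )
    elif format == "sif":
        with open(path, "w", encoding="utf-8") as fh:
            for u, v in sorted(g.edges()):
                fh.write(f"{u} pp {v}\n")
            for node in sorted(g.nodes()):
                if g.degree(node) == 0:
                    fh.write(f"{node}\n")
    elif format == "graphml":
        h = nx.Graph()
        for node, attrs in g.nodes(data=True):
            h.add_node(node, **{k: v for k, v in attrs.items() if v is not None})
        for u, v, attrs in g.edges(data=True):
            h.add_edge(u, v, rho=float(attrs["rho"]), p=float(attrs["p"]))
        nx.write_graphml(h, path)
    else:
        raise ValueError(f"unknown network export format: {format!r}")

    node_path = path + ".nodes.tsv"
    keys = ["phylum", "mean_rel_abund", "degree", "betweenness", "closeness",
            "keystoneness"]
    with open(node_path, "w", encoding="utf-8") as fh:
        fh.write("otu_id\t" + "\t".join(keys) + "\n")
        for node in sorted(g.nodes()):
            attrs = g.nodes[node]
            vals = []
            for k in keys:
                v = attrs.get(k)
                if k == "degree" and v is None:
                    v = g.degree(node)
                vals.append("" if v is None else f"{v:.10g}" if isinstance(v, float) else str(v))
            fh.write(f"{node}\t" + "\t".join(vals) + "\n")


def read_edge_tsv(path):
    """Read an edge-tsv export back into a networkx Graph."""
    import networkx as nx

    g = nx.Graph()
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["source", "target"]:
            raise ValidationError(f"{path}: not an edge-tsv file")
        for ln in fh:
            u, v, rho, p, sign = ln.rstrip("\n").split("\t")
            g.add_edge(u, v, rho=float(rho), p=float(p), sign=sign)
    return g


# ---------------------------------------------------------------------------
# Dendrogram / newick


@dataclass
class TreeNode:
    """Node of a binary merge tree; leaves carry labels and height 0."""

    height: float = 0.0
    label: str = None
    children: tuple = ()

    @property
    def is_leaf(self):
        return not self.children

    def leaves(self):
        if self.is_leaf:
            return [self.label]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out


def newick_string(root: TreeNode) -> str:
    """Newick serialisation; branch length = parent height - child height."""
    labels = root.leaves()
    _check_unique(labels, "leaf")

    def fmt(node, parent_height):
        bl = parent_height - node.height
        bls = f":{bl:.10g}" if not math.isnan(bl) else ""
        if node.is_leaf:
            return f"{node.label}{bls}"
        inner = ",".join(fmt(c, node.height) for c in node.children)
        return f"({inner}){bls}"

    if root.is_leaf:
        return f"{root.label};"
    inner = ",".join(fmt(c, root.height) for c in root.children)
    return f"({inner});"


def write_newick(root: TreeNode, path):
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(newick_string(root) + "\n")
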