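"""Readers and writers for the plain-text formats used by the pipeline.

Genotypes arrive as a dosage TSV (samples x variants, 0/1/2) with a variant
table (variant_id, chrom, pos), or as a VCF.  Expression/methylation/
phenotype matrices are TSV with samples in rows.  Regions are BED (0-based,
half-open).  Layer assignments map node -> layer in a two-column TSV or a
YAML/JSON mapping.  Networks round-trip as edge-list TSV or GraphML.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .datasets import OmicsDataset

__all__ = [
    "GenotypeData",
    "read_dosage_tsv",
    "read_vcf",
    "read_regions_bed",
    "read_matrix_tsv",
    "read_layer_file",
    "read_omics_dataset",
    "read_phenotype_tsv",
    "read_group_map",
    "read_edge_tsv",
    "write_edge_tsv",
]


@dataclass
class GenotypeData:
    """Dosage matrix (samples x variants) plus per-variant coordinates."""

    dosages: pd.DataFrame
    variants: pd.DataFrame  # columns: variant_id, chrom, pos

    def __post_init__(self) -> None:
        required = {"variant_id", "chrom", "pos"}
        if not required <= set(self.variants.columns):
            raise ValueError(f"variant table needs columns {sorted(required)}")
        missing = set(self.variants["variant_id"]) - set(self.dosages.columns)
        if missing:
            raise ValueError(f"variants missing from dosage matrix: {sorted(missing)[:5]}")


def read_dosage_tsv(dosage_path, variants_path) -> GenotypeData:
    dosages = pd.read_csv(dosage_path, sep="\t", index_col=0)
    variants = pd.read_csv(variants_path, sep="\t")
    return GenotypeData(dosages=dosages, variants=variants)


def read_vcf(path) -> GenotypeData:
    """Read genotypes from a VCF into dosages of the ALT allele."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    ids, chroms, positions, rows = [], [], [], []
    for var in vcf:
        vid = var.ID or f"{var.CHROM}:{var.POS}"
        ids.append(vid)
        chroms.append(var.CHROM)
        positions.append(var.POS)
        # gt_types: 0=hom ref, 1=het, 2=unknown, 3=hom alt
        gt = np.asarray(var.gt_types, dtype=float)
        dosage = np.where(gt == 3, 2.0, np.where(gt == 2, np.nan, gt))
        rows.append(dosage)
    dosages = pd.DataFrame(np.array(rows).T, index=samples, columns=ids)
    variants = pd.DataFrame({"variant_id": ids, "chrom": chroms, "pos": positions})
    return GenotypeData(dosages=dosages, variants=variants)


def read_regions_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    cols = ["chrom", "start", "end", "name"][: df.shape[1]]
    df.columns = cols + [f"extra{i}" for i in range(df.shape[1] - len(cols))]
    if "name" not in df.columns:
        df["name"] = df["chrom"].astype(str) + ":" + df["start"].astype(str)
    return df[["chrom", "start", "end", "name"]]


def read_matrix_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_layer_file(path) -> dict[str, str]:
    path = Path(path)
    if path.suffix in (".yaml", ".yml", ".json"):
        with open(path) as fh:
            return dict(yaml.safe_load(fh))
    df = pd.read_csv(path, sep="\t", header=None, names=["node", "layer"])
    return dict(zip(df["node"].astype(str), df["layer"].astype(str)))


def read_omics_dataset(matrix_path, layer_path) -> OmicsDataset:
    data = read_matrix_tsv(matrix_path)
    layers = read_layer_file(layer_path)
    return OmicsDataset(data=data, layers=layers)


def read_phenotype_tsv(path) -> pd.Series:
    """Two-column TSV (sample_id, status) -> integer-coded Series."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError("phenotype table needs columns sample_id, status")
    return pd.Series(df.iloc[:, 1].to_numpy(), index=df.iloc[:, 0].astype(str), name="status")


def read_group_map(path) -> pd.DataFrame:
    """Two-column TSV (feature, group) or GMT file -> DataFrame(feature, group)."""
    path = Path(path)
    if path.suffix == ".gmt":
        rows = []
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 3:
                    continue
                group = parts[0]
                for feat in parts[2:]:
                    if feat:
                        rows.append({"feature": feat, "group": group})
        return pd.DataFrame(rows)
    return pd.read_csv(path, sep="\t", header=None, names=["feature", "group"])


def read_edge_tsv(path) -> nx.DiGraph:
    df = pd.read_csv(path, sep="\t")
    g = nx.DiGraph()
    for _, row in df.iterrows():
        g.add_node(row["parent"], layer=row.get("parent_layer", ""))
        g.add_node(row["child"], layer=row.get("child_layer", ""))
        attrs = {
            k: row[k] for k in df.columns if k not in ("parent", "child", "parent_layer", "child_layer")
        }
        g.add_edge(row["parent"], row["child"], **attrs)
    return g


def write_edge_tsv(graph: nx.DiGraph, path) -> None:
    rows = []
    for u, v, attrs in graph.edges(data=True):
        row = {
            "parent": u,
            "child": v,
            "parent_layer": graph.nodes[u].get("layer", ""),
            "child_layer": graph.nodes[v].get("layer", ""),
        }
        row.update(attrs)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
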