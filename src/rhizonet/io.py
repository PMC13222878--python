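"""Readers and writers for tables, images and networks.

Tables are UTF-8 TSV/CSV with the delimiter auto-detected between tab and
comma; samples-as-rows is the canonical abundance orientation, with an
``orientation`` flag accepting taxa-as-rows files. Images are read through
imageio (PNG) / tifffile (TIFF) with no rescaling; RGB input is collapsed
to grey with the Rec. 709 luminance weights (0.2126 R + 0.7152 G +
0.0722 B), documented here because zymograms are acquired as greyscale
photographs and a colour file is almost always an acquisition artefact.

Networks round-trip through an edge-list TSV (with a ``# nodes:`` header
line so isolated nodes survive) or GraphML via networkx.
"""

from __future__ import annotations

import logging
from pathlib import Path

import imageio.v3 as iio
import networkx as nx
import numpy as np
import pandas as pd
import tifffile

from .datatypes import (
    AbundanceTable,
    Condition,
    CooccurrenceNetwork,
    TraitTable,
    ValidationError,
    Zymogram,
)

log = logging.getLogger(__name__)

__all__ = [
    "sniff_delimiter",
    "read_abundance_table",
    "write_abundance_table",
    "read_trait_table",
    "write_trait_table",
    "read_zymogram",
    "write_zymogram",
    "read_mask",
    "write_mask",
    "write_network",
    "read_network",
]

_LUMA = (0.2126, 0.7152, 0.0722)  # Rec. 709


def sniff_delimiter(path: str | Path) -> str:
    """Pick tab or comma by which occurs more often in the header line."""
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


def _read_table(path: str | Path, index_col: int = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep=sniff_delimiter(path), index_col=index_col,
                       encoding="utf-8")


def read_abundance_table(
    path: str | Path,
    metadata_path: str | Path,
    orientation: str = "samples_as_rows",
    taxonomy_path: str | Path | None = None,
) -> AbundanceTable:
    """Load counts + metadata (+ optional taxonomy) into an AbundanceTable.

    ``orientation`` is ``"samples_as_rows"`` (canonical) or
    ``"taxa_as_rows"`` (the file is transposed on read).
    """
    if orientation not in ("samples_as_rows", "taxa_as_rows"):
        raise ValidationError(f"unknown orientation {orientation!r}")
    counts = _read_table(path)
    if orientation == "taxa_as_rows":
        counts = counts.T
    counts.index = counts.index.astype(str)
    counts.index.name = "sample_id"
    metadata = _read_table(metadata_path)
    metadata.index = metadata.index.astype(str)
    metadata.index.name = "sample_id"
    taxonomy = None
    if taxonomy_path is not None:
        taxonomy = _read_table(taxonomy_path)
    return AbundanceTable(counts=counts, metadata=metadata, taxonomy=taxonomy)


def write_abundance_table(
    table: AbundanceTable,
    path: str | Path,
    metadata_path: str | Path,
    taxonomy_path: str | Path | None = None,
) -> None:
    table.counts.to_csv(path, sep="\t", encoding="utf-8")
    table.metadata.to_csv(metadata_path, sep="\t", encoding="utf-8")
    if taxonomy_path is not None and table.taxonomy is not None:
        table.taxonomy.to_csv(taxonomy_path, sep="\t", encoding="utf-8")


def read_trait_table(path: str | Path) -> TraitTable:
    values = _read_table(path)
    values.index = values.index.astype(str)
    return TraitTable(values=values)


def write_trait_table(traits: TraitTable, path: str | Path) -> None:
    traits.values.to_csv(path, sep="\t", encoding="utf-8")


def read_zymogram(path: str | Path, pixel_size: float) -> Zymogram:
    """Load an 8/16-bit greyscale TIFF or PNG as-is (no rescaling).

    RGB input is converted to grey with Rec. 709 luminance weights.
    """
    if not (pixel_size > 0):
        raise ValidationError(f"pixel_size must be > 0, got {pixel_size}")
    img = iio.imread(path)
    if img.ndim == 3:
        if img.shape[2] == 4:  # drop alpha
            img = img[:, :, :3]
        img = np.tensordot(img.astype(float), np.asarray(_LUMA), axes=([2], [0]))
        log.info("RGB zymogram %s converted to grey via Rec. 709 luminance", path)
    return Zymogram(image=img, pixel_size=float(pixel_size),
                    meta={"source": str(path)})


def write_zymogram(z: Zymogram, path: str | Path) -> None:
    path = Path(path)
    img = z.image
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, img)
    else:
        iio.imwrite(path, img)


def read_mask(path: str | Path) -> np.ndarray:
    """Read a boolean mask image (nonzero = True)."""
    return np.asarray(iio.imread(path)) > 0


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    arr = (np.asarray(mask, dtype=bool).astype(np.uint8)) * 255
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    else:
        iio.imwrite(path, arr)


# -- networks -----------------------------------------------------------------

_EDGE_COLUMNS = ("source", "target", "rho", "p", "sign")


def write_network(net: CooccurrenceNetwork, path: str | Path, format: str = "edge_list") -> None:
    """Write a network as edge-list TSV or GraphML.

    The edge-list dialect stores the full node set in a ``# nodes:`` header
    line so that write→read reproduces node set, edge set and weights
    exactly, including isolated nodes and the empty graph.
    """
    path = Path(path)
    if format == "edge_list":
        with open(path, "w", encoding="utf-8") as fh:
            nodes = "\t".join(str(n) for n in net.graph.nodes())
            fh.write(f"# nodes:\t{nodes}\n")
            fh.write(f"# edge_alpha:\t{net.edge_alpha!r}\n")
            if net.condition is not None:
                fh.write(f"# condition:\t{net.condition.label()}\n")
            fh.write("\t".join(_EDGE_COLUMNS) + "\n")
            for u, v, d in net.graph.edges(data=True):
                fh.write(
                    f"{u}\t{v}\t{d.get('rho', float('nan'))!r}\t"
                    f"{d.get('p', float('nan'))!r}\t{d.get('sign', 0)}\n"
                )
    elif format == "graphml":
        g = net.graph.copy()
        g.graph["edge_alpha"] = net.edge_alpha
        g.graph["method"] = net.method
        if net.condition is not None:
            g.graph["condition"] = net.condition.label()
        nx.write_graphml(g, path)
    else:
        raise ValidationError(f"unknown network format {format!r}")


def read_network(path: str | Path, format: str = "edge_list") -> CooccurrenceNetwork:
    path = Path(path)
    if format == "edge_list":
        graph = nx.Graph()
        edge_alpha = 1.0
        condition = None
        with open(path, "r", encoding="utf-8") as fh:
            lines = fh.read().splitlines()
        body_start = 0
        for i, line in enumerate(lines):
            if line.startswith("# nodes:"):
                parts = line.split("\t")[1:]
                graph.add_nodes_from(p for p in parts if p)
            elif line.startswith("# edge_alpha:"):
                edge_alpha = float(line.split("\t")[1])
            elif line.startswith("# condition:"):
                condition = Condition(*line.split("\t")[1].split("."))
            elif not line.startswith("#"):
                body_start = i
                break
        for line in lines[body_start + 1:]:
            if not line.strip():
                continue
            u, v, rho, p, sign = line.split("\t")
            graph.add_edge(u, v, rho=float(rho), p=float(p), sign=int(sign))
        return CooccurrenceNetwork(graph=graph, edge_alpha=edge_alpha, condition=condition)
    if format == "graphml":
        g = nx.read_graphml(path)
        edge_alpha = float(g.graph.pop("edge_alpha", 1.0))
        method = g.graph.pop("method", "spearman")
        condition = None
        if "condition" in g.graph:
            condition = Condition(*g.graph.pop("condition").split("."))
        return CooccurrenceNetwork(graph=g, edge_alpha=edge_alpha,
                                   condition=condition, method=method)
    raise ValidationError(f"unknown network format {format!r}")
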