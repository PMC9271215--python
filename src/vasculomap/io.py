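"""Readers and writers for volumes, graphs, and point tables.

Volumes: NRRD (compact built-in raw/gzip codec), multipage TIFF
(tifffile), NIfTI (nibabel).  Graphs: SWC (one tree per connected
component, radius field in μm) plus a JSON sidecar with node/segment
tables.  Cells: CSV with μm coordinates.
"""

from __future__ import annotations

import gzip
import json
import os
from pathlib import Path

import numpy as np

from .graph import VesselGraph
from .volume import VoxelVolume

# ----------------------------------------------------------------------- NRRD

_NRRD_TYPES = {
    "uint8": np.uint8, "uchar": np.uint8, "unsigned char": np.uint8,
    "int16": np.int16, "short": np.int16,
    "uint16": np.uint16, "unsigned short": np.uint16,
    "int32": np.int32, "int": np.int32,
    "uint32": np.uint32, "unsigned int": np.uint32,
    "int64": np.int64, "uint64": np.uint64,
    "float": np.float32, "double": np.float64,
}
_NRRD_NAMES = {
    np.dtype(np.uint8): "uint8", np.dtype(np.int16): "int16",
    np.dtype(np.uint16): "uint16", np.dtype(np.int32): "int32",
    np.dtype(np.uint32): "uint32", np.dtype(np.int64): "int64",
    np.dtype(np.uint64): "uint64", np.dtype(np.float32): "float",
    np.dtype(np.float64): "double",
}


def write_nrrd(path: str | os.PathLike, vol: VoxelVolume, compress: bool = False) -> None:
    """Write a volume as a single-file NRRD (raw or gzip encoding)."""
    data = np.ascontiguousarray(vol.data)
    if data.dtype not in _NRRD_NAMES:
        data = data.astype(np.float64)
    header = [
        "NRRD0004",
        "# vasculomap volume",
        f"type: {_NRRD_NAMES[data.dtype]}",
        "dimension: 3",
        f"sizes: {data.shape[2]} {data.shape[1]} {data.shape[0]}",
        f"spacings: {vol.spacing[2]} {vol.spacing[1]} {vol.spacing[0]}",
        f"axis mins: {vol.origin[2]} {vol.origin[1]} {vol.origin[0]}",
        f"labels: \"{vol.axes[2]}\" \"{vol.axes[1]}\" \"{vol.axes[0]}\"",
        f"encoding: {'gzip' if compress else 'raw'}",
        "endian: little",
    ]
    payload = data.astype(data.dtype.newbyteorder("<")).tobytes(order="C")
    if compress:
        payload = gzip.compress(payload)
    with open(path, "wb") as fh:
        fh.write(("\n".join(header) + "\n\n").encode())
        fh.write(payload)


def read_nrrd(path: str | os.PathLike) -> VoxelVolume:
    """Read a single-file NRRD written by :func:`write_nrrd` (raw/gzip)."""
    with open(path, "rb") as fh:
        raw = fh.read()
    head, _, payload = raw.partition(b"\n\n")
    fields: dict[str, str] = {}
    for line in head.decode().splitlines()[1:]:
        if line.startswith("#") or ":" not in line:
            continue
        key, _, value = line.partition(":")
        fields[key.strip().lower()] = value.strip()
    dtype = np.dtype(_NRRD_TYPES[fields["type"]]).newbyteorder(
        "<" if fields.get("endian", "little") == "little" else ">"
    )
    sizes = [int(s) for s in fields["sizes"].split()]
    if fields.get("encoding", "raw") == "gzip":
        payload = gzip.decompress(payload)
    data = np.frombuffer(payload, dtype=dtype).reshape(sizes[::-1])
    spacing = [1.0, 1.0, 1.0]
    if "spacings" in fields:
        spacing = [float(s) for s in fields["spacings"].split()][::-1]
    origin = [0.0, 0.0, 0.0]
    if "axis mins" in fields:
        origin = [float(s) for s in fields["axis mins"].split()][::-1]
    axes = ("ML", "DV", "AP")
    if "labels" in fields:
        axes = tuple(s.strip('"') for s in fields["labels"].split())[::-1]
    return VoxelVolume(data.astype(dtype.newbyteorder("=")), spacing, axes, origin)


# ----------------------------------------------------------------- TIFF/NIfTI

def write_tiff(path, vol: VoxelVolume) -> None:
    """Multipage TIFF, one page per leading-axis plane; spacing in metadata."""
    import tifffile

    tifffile.imwrite(
        path,
        np.asarray(vol.data),
        photometric="minisblack",
        metadata={"spacing_um": list(vol.spacing), "axes_semantic": list(vol.axes)},
    )


def read_tiff(path, spacing=None, axes=("ML", "DV", "AP")) -> VoxelVolume:
    """Read a multipage TIFF; ``spacing`` overrides any stored metadata."""
    import tifffile

    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    if spacing is None:
        spacing = meta.get("spacing_um", (1.0, 1.0, 1.0))
    if "axes_semantic" in meta:
        axes = tuple(meta["axes_semantic"])
    return VoxelVolume(data, spacing, axes)


def write_nifti(path, vol: VoxelVolume) -> None:
    import nibabel as nib

    affine = np.diag(list(vol.spacing) + [1.0])
    affine[:3, 3] = vol.origin
    nib.save(nib.Nifti1Image(np.asarray(vol.data), affine), str(path))


def read_nifti(path, axes=("ML", "DV", "AP")) -> VoxelVolume:
    import nibabel as nib

    img = nib.load(str(path))
    spacing = img.header.get_zooms()[:3]
    origin = img.affine[:3, 3]
    return VoxelVolume(np.asarray(img.dataobj), spacing, axes, tuple(origin))


def read_volume(path, spacing=None) -> VoxelVolume:
    """Dispatch on file extension (.nrrd, .tif/.tiff, .nii/.nii.gz)."""
    name = str(path).lower()
    if name.endswith(".nrrd"):
        vol = read_nrrd(path)
    elif name.endswith((".tif", ".tiff")):
        vol = read_tiff(path, spacing=spacing)
    elif name.endswith((".nii", ".nii.gz")):
        vol = read_nifti(path)
    else:
        raise ValueError(f"unrecognized volume format: {path}")
    if spacing is not None:
        vol = VoxelVolume(vol.data, spacing, vol.axes, vol.origin)
    return vol


def write_volume(path, vol: VoxelVolume) -> None:
    name = str(path).lower()
    if name.endswith(".nrrd"):
        write_nrrd(path, vol)
    elif name.endswith((".tif", ".tiff")):
        write_tiff(path, vol)
    elif name.endswith((".nii", ".nii.gz")):
        write_nifti(path, vol)
    else:
        raise ValueError(f"unrecognized volume format: {path}")


# ------------------------------------------------------------------------ SWC

def write_swc(path, graph: VesselGraph) -> None:
    """Write one SWC tree per connected component.

    Each polyline point becomes an SWC sample (type 7, "custom"); the
    parent pointer follows a spanning tree of each component, so loops
    are broken at one segment (SWC cannot represent cycles; the JSON
    sidecar written by :func:`write_graph` keeps full connectivity).
    """
    import networkx as nx

    lines = ["# SWC export (radius in um)", "# id type x y z radius parent"]
    sample_id = 1
    for comp in nx.connected_components(graph.g):
        sub = graph.g.subgraph(comp)
        tree_edges = list(nx.minimum_spanning_edges(sub, keys=True, data=False))
        root = min(comp)
        node_sample: dict[int, int] = {}
        # BFS over spanning-tree edges so parents are emitted first
        adj: dict[int, list[tuple[int, int]]] = {n: [] for n in comp}
        for a, b, k in tree_edges:
            adj[a].append((b, k))
            adj[b].append((a, k))
        first_rad = 1.0
        for _, _, k, d in graph.segments():
            if d["u"] in comp:
                first_rad = float(d["radii"][0])
                break
        x, y, z = graph.node_pos(root)
        lines.append(f"{sample_id} 7 {x:.3f} {y:.3f} {z:.3f} {first_rad:.3f} -1")
        node_sample[root] = sample_id
        sample_id += 1
        stack = [root]
        seen_edges = set()
        while stack:
            cur = stack.pop()
            for nxt, key in adj[cur]:
                ek = (min(cur, nxt), max(cur, nxt), key)
                if ek in seen_edges:
                    continue
                seen_edges.add(ek)
                poly, radii = graph.oriented_polyline(cur, nxt, key)
                parent = node_sample[cur]
                for p, r in zip(poly[1:], radii[1:]):
                    lines.append(
                        f"{sample_id} 7 {p[0]:.3f} {p[1]:.3f} {p[2]:.3f} {r:.3f} {parent}"
                    )
                    parent = sample_id
                    sample_id += 1
                if nxt not in node_sample:
                    node_sample[nxt] = parent
                    stack.append(nxt)
    Path(path).write_text("\n".join(lines) + "\n")


def write_graph(out_dir, graph: VesselGraph, stem: str = "graph") -> dict[str, Path]:
    """Write SWC + CSV tables + JSON polylines for a vessel graph."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "swc": out / f"{stem}.swc",
        "nodes": out / f"{stem}_nodes.csv",
        "segments": out / f"{stem}_segments.csv",
        "polylines": out / f"{stem}_polylines.json",
    }
    write_swc(paths["swc"], graph)
    graph.nodes_table().to_csv(paths["nodes"], index=False)
    graph.segments_table().to_csv(paths["segments"], index=False)
    poly = {
        str(key): {
            "node_a": u,
            "node_b": v,
            "points_um": np.round(d["polyline"], 4).tolist(),
            "radii_um": np.round(d["radii"], 4).tolist(),
        }
        for u, v, key, d in graph.segments()
    }
    paths["polylines"].write_text(json.dumps(poly))
    return paths


def read_graph(out_dir, stem: str = "graph") -> VesselGraph:
    """Rebuild a vessel graph from the JSON/CSV tables of :func:`write_graph`."""
    import pandas as pd

    out = Path(out_dir)
    nodes = pd.read_csv(out / f"{stem}_nodes.csv")
    poly = json.loads((out / f"{stem}_polylines.json").read_text())
    graph = VesselGraph()
    remap: dict[int, int] = {}
    for row in nodes.itertuples():
        remap[row.id] = graph.add_node(
            (row.x_um, row.y_um, row.z_um),
            kind=None if row.kind in ("branch", "endpoint") else row.kind,
        )
    for rec in poly.values():
        graph.add_segment(
            remap[rec["node_a"]], remap[rec["node_b"]],
            np.asarray(rec["points_um"]), np.asarray(rec["radii_um"]),
        )
    return graph


# ---------------------------------------------------------------------- cells

def write_cells_csv(path, points_um: np.ndarray, labels=None) -> None:
    import pandas as pd

    points_um = np.asarray(points_um, dtype=float).reshape(-1, 3)
    df = pd.DataFrame(points_um, columns=["x_um", "y_um", "z_um"])
    df["class"] = labels if labels is not None else "cell"
    df.to_csv(path, index=False)


def read_cells_csv(path):
    import pandas as pd

    df = pd.read_csv(path)
    return df[["x_um", "y_um", "z_um"]].to_numpy(), df["class"].to_numpy()
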