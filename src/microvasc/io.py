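"""Network file I/O: JSON document, nodes/segments CSV pair, VTK export.

The on-disk schema keeps the paper-conventional units (positions and
lengths in um).  ``save_network`` / ``load_network`` round-trip losslessly
(exact integers and labels, float64 text precision for coordinates).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .network import DomainDescriptor, SchemaError, VascularNetwork

_NODE_COLS = ["id", "x_um", "y_um", "z_um", "role"]
_SEG_COLS = ["id", "tail", "head", "diameter_um", "length_um", "compartment", "control_points"]


def _cp_to_str(cp: np.ndarray | None) -> str:
    if cp is None or len(cp) == 0:
        return ""
    return ";".join(",".join(repr(float(v)) for v in row) for row in np.asarray(cp))


def _cp_from_str(s) -> np.ndarray | None:
    if s is None or (isinstance(s, float) and np.isnan(s)) or str(s) == "":
        return None
    rows = [[float(v) for v in part.split(",")] for part in str(s).split(";")]
    return np.asarray(rows, dtype=float)


def _node_records(net: VascularNetwork) -> list[dict]:
    return [
        {
            "id": int(i),
            "x_um": float(p[0]),
            "y_um": float(p[1]),
            "z_um": float(p[2]),
            "role": str(r),
        }
        for i, p, r in zip(net.node_ids, net.positions, net.roles)
    ]


def _segment_records(net: VascularNetwork, json_cp: bool) -> list[dict]:
    recs = []
    for k in range(net.n_segments):
        cp = net.control_points[k]
        rec = {
            "id": int(net.seg_ids[k]),
            "tail": int(net.tails[k]),
            "head": int(net.heads[k]),
            "diameter_um": float(net.diameters[k]),
            "length_um": float(net.lengths[k]),
            "compartment": str(net.compartments[k]),
        }
        if json_cp:
            rec["control_points"] = np.asarray(cp).tolist() if cp is not None else []
        else:
            rec["control_points"] = _cp_to_str(cp)
        recs.append(rec)
    return recs


def save_network(net: VascularNetwork, path: str | Path, format: str = "json") -> None:
    """Write a validated network to ``path``.

    ``format='json'`` writes one document with "nodes", "segments" and
    "domain" members; ``format='csv_pair'`` writes ``<path>.nodes.csv``
    and ``<path>.segments.csv`` (or uses ``path`` as a directory stem).
    """
    net.check()
    path = Path(path)
    if format == "json":
        doc = {
            "nodes": _node_records(net),
            "segments": _segment_records(net, json_cp=True),
            "domain": net.domain.to_dict(),
        }
        path.write_text(json.dumps(doc))
    elif format == "csv_pair":
        nodes = pd.DataFrame(_node_records(net), columns=_NODE_COLS)
        segs = pd.DataFrame(_segment_records(net, json_cp=False), columns=_SEG_COLS)
        nodes.to_csv(_pair_paths(path)[0], index=False)
        segs.to_csv(_pair_paths(path)[1], index=False)
        _pair_paths(path)[2].write_text(json.dumps(net.domain.to_dict()))
    else:
        raise ValueError(f"unknown format {format!r}; use 'json' or 'csv_pair'")


def _pair_paths(path: Path) -> tuple[Path, Path, Path]:
    stem = path.with_suffix("") if path.suffix else path
    return (
        stem.with_suffix(".nodes.csv"),
        stem.with_suffix(".segments.csv"),
        stem.with_suffix(".domain.json"),
    )


def load_network(path: str | Path, format: str = "json") -> VascularNetwork:
    """Read and validate a network written by :func:`save_network`."""
    path = Path(path)
    if format == "json":
        try:
            doc = json.loads(Path(path).read_text())
        except json.JSONDecodeError as e:
            raise SchemaError(f"not a JSON network document: {e}") from e
        for key in ("nodes", "segments"):
            if key not in doc:
                raise SchemaError(f"missing top-level member {key!r}")
        nodes = pd.DataFrame(doc["nodes"])
        segs = pd.DataFrame(doc["segments"])
        cps = [
            np.asarray(cp, dtype=float) if cp else None
            for cp in segs.get("control_points", [[]] * len(segs))
        ]
        domain = DomainDescriptor.from_dict(doc.get("domain", {}))
    elif format == "csv_pair":
        npth, spth, dpth = _pair_paths(path)
        nodes = pd.read_csv(npth)
        segs = pd.read_csv(spth)
        cps = [_cp_from_str(s) for s in segs.get("control_points", [""] * len(segs))]
        domain = DomainDescriptor.from_dict(json.loads(dpth.read_text())) if dpth.exists() else DomainDescriptor()
    else:
        raise ValueError(f"unknown format {format!r}")

    for col in ("id", "x_um", "y_um", "z_um", "role"):
        if col not in nodes.columns:
            raise SchemaError(f"nodes table missing column {col!r}")
    for col in ("id", "tail", "head", "diameter_um", "length_um"):
        if col not in segs.columns:
            raise SchemaError(f"segments table missing column {col!r}")

    net = VascularNetwork(
        node_ids=nodes["id"].to_numpy(),
        positions=nodes[["x_um", "y_um", "z_um"]].to_numpy(dtype=float),
        roles=nodes["role"].astype(str).to_numpy(),
        seg_ids=segs["id"].to_numpy(),
        tails=segs["tail"].to_numpy(),
        heads=segs["head"].to_numpy(),
        diameters=segs["diameter_um"].to_numpy(dtype=float),
        lengths=segs["length_um"].to_numpy(dtype=float),
        compartments=segs.get("compartment", pd.Series(["CAP"] * len(segs))).astype(str).to_numpy(),
        control_points=cps,
        domain=domain,
    )
    net.check()
    return net


# ------------------------------------------------------------------ VTK
def export_vtk(net: VascularNetwork, path: str | Path, field=None) -> None:
    """Write a VTK PolyData (.vtp, XML ASCII) polyline file.

    Each segment becomes one polyline (through its Bezier control points
    when present) with per-segment cell scalars: diameter, compartment
    code, and p/Q/h when a solution ``field`` is given.  Pressure is
    averaged onto segments in mmHg.
    """
    if net.n_segments == 0:
        raise ValueError("refusing to export an empty network")
    if field is not None and (len(field.Q) != net.n_segments or len(field.p) != net.n_nodes):
        raise ValueError("solution field dimensions do not match the network")

    pts: list[np.ndarray] = []
    conn: list[list[int]] = []
    for k in range(net.n_segments):
        cp = net.control_points[k]
        if cp is not None and len(cp) >= 2:
            poly = np.asarray(cp, dtype=float)
        else:
            poly = np.vstack([net.positions[net.tail_idx[k]], net.positions[net.head_idx[k]]])
        start = len(pts)
        pts.extend(poly)
        conn.append(list(range(start, start + len(poly))))

    comp_code = {c: i for i, c in enumerate(("PIA", "PEA", "PEC", "CAP", "POC", "AV", "PV"))}
    cell_arrays: dict[str, np.ndarray] = {
        "diameter_um": net.diameters,
        "compartment": np.array([comp_code.get(str(c), -1) for c in net.compartments], dtype=float),
    }
    if field is not None:
        from .units import PA_PER_MMHG

        p_seg = 0.5 * (field.p[net.tail_idx] + field.p[net.head_idx]) / PA_PER_MMHG
        cell_arrays["pressure_mmHg"] = p_seg
        cell_arrays["flow_nl_s"] = field.Q * 1e12
        cell_arrays["hematocrit"] = field.h

    pts_arr = np.asarray(pts, dtype=float)
    offsets = np.cumsum([len(c) for c in conn])
    connectivity = np.concatenate(conn)

    def ascii_block(arr: np.ndarray) -> str:
        return " ".join(repr(float(v)) if arr.dtype.kind == "f" else str(int(v)) for v in np.ravel(arr))

    arrays_xml = "\n".join(
        f'<DataArray type="Float64" Name="{name}" format="ascii">{ascii_block(a)}</DataArray>'
        for name, a in cell_arrays.items()
    )
    xml = f"""<?xml version="1.0"?>
<VTKFile type="PolyData" version="1.0" byte_order="LittleEndian">
<PolyData>
<Piece NumberOfPoints="{len(pts_arr)}" NumberOfLines="{len(conn)}">
<Points>
<DataArray type="Float64" NumberOfComponents="3" format="ascii">{ascii_block(pts_arr)}</DataArray>
</Points>
<Lines>
<DataArray type="Int64" Name="connectivity" format="ascii">{ascii_block(connectivity)}</DataArray>
<DataArray type="Int64" Name="offsets" format="ascii">{ascii_block(offsets)}</DataArray>
</Lines>
<CellData>
{arrays_xml}
</CellData>
</Piece>
</PolyData>
</VTKFile>
"""
    Path(path).write_text(xml)
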