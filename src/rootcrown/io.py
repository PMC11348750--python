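"""Reading and writing skeleton files.

Two plain-text dialects are supported.

Text dialect (authoritative; whitespace-separated, ``#`` comments)::

    pitch 0.44                 # optional, voxel pitch in mm (default 0.44)
    v <id> <x> <y> <z> <thickness>
    e <id1> <id2>
    stem <id1> <id2> ...       # ordered top -> bottom
    label <id1> <id2> <int>    # optional hierarchy label per edge

ASCII PLY dialect (convenience mirror): vertex properties ``x y z thickness``
(float), an ``edge`` element with ``vertex1 vertex2`` (int), the stem path in
a ``comment stem <ids...>`` line and the pitch in ``comment pitch <mm>``.
PLY vertex ids are the 0-based row order.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Optional, Tuple

from .skeleton import (
    DEFAULT_VOXEL_PITCH_MM,
    Skeleton,
    SkeletonError,
    SkeletonVertex,
    StemPath,
    _edge,
)

__all__ = ["read_skeleton", "write_skeleton", "ParseError"]


class ParseError(SkeletonError):
    """Malformed skeleton file; message carries the offending line number."""


def _infer_format(path: Path, fmt: Optional[str]) -> str:
    if fmt is not None:
        if fmt not in ("text", "ply"):
            raise ValueError(f"unknown skeleton format {fmt!r}")
        return fmt
    return "ply" if path.suffix.lower() == ".ply" else "text"


def read_skeleton(
    path, fmt: Optional[str] = None
) -> Tuple[Skeleton, StemPath, Dict[Tuple[int, int], int]]:
    """Read a skeleton file.

    Returns ``(skeleton, stem_path, edge_labels)``; ``edge_labels`` is empty
    unless the file carries ``label`` records.
    """
    path = Path(path)
    if _infer_format(path, fmt) == "ply":
        return _read_ply(path)
    return _read_text(path)


def write_skeleton(
    skeleton: Skeleton,
    stem: StemPath,
    path,
    fmt: Optional[str] = None,
    edge_labels: Optional[Dict[Tuple[int, int], int]] = None,
) -> None:
    path = Path(path)
    if _infer_format(path, fmt) == "ply":
        _write_ply(skeleton, stem, path)
    else:
        _write_text(skeleton, stem, path, edge_labels)


# -- text dialect ----------------------------------------------------------


def _read_text(path: Path):
    pitch = DEFAULT_VOXEL_PITCH_MM
    vertices = []
    edges = []
    labels: Dict[Tuple[int, int], int] = {}
    stem_ids = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            tok = line.split()
            try:
                if tok[0] == "pitch":
                    pitch = float(tok[1])
                elif tok[0] == "v":
                    vid = int(tok[1])
                    x, y, z, th = map(float, tok[2:6])
                    vertices.append(SkeletonVertex(vid, (x, y, z), th))
                elif tok[0] == "e":
                    edges.append((int(tok[1]), int(tok[2])))
                elif tok[0] == "stem":
                    stem_ids = [int(t) for t in tok[1:]]
                elif tok[0] == "label":
                    labels[_edge(int(tok[1]), int(tok[2]))] = int(tok[3])
                else:
                    raise ParseError(
                        f"{path}:{lineno}: unknown record {tok[0]!r}"
                    )
            except ParseError:
                raise
            except (ValueError, IndexError, SkeletonError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    skeleton = Skeleton(voxel_pitch=pitch)
    for v in vertices:
        skeleton.add_vertex(v)
    for a, b in edges:
        try:
            skeleton.add_edge(a, b)
        except SkeletonError as exc:
            raise ParseError(f"{path}: dangling edge: {exc}") from exc
    if stem_ids is None:
        raise ParseError(f"{path}: missing 'stem' record")
    stem = StemPath.from_skeleton(skeleton, stem_ids)
    return skeleton, stem, labels


def _write_text(skeleton, stem, path, edge_labels=None) -> None:
    with open(path, "w") as fh:
        fh.write("# rootcrown skeleton\n")
        fh.write(f"pitch {skeleton.voxel_pitch:.6g}\n")
        for vid in sorted(skeleton.vertices):
            v = skeleton.vertices[vid]
            x, y, z = v.position
            fh.write(f"v {vid} {x:.9g} {y:.9g} {z:.9g} {v.thickness:.9g}\n")
        for a, b in sorted(skeleton.edges):
            fh.write(f"e {a} {b}\n")
        fh.write("stem " + " ".join(str(i) for i in stem.vertex_ids) + "\n")
        if edge_labels:
            for (a, b), lab in sorted(edge_labels.items()):
                fh.write(f"label {a} {b} {lab}\n")


# -- ASCII PLY dialect -----------------------------------------------------


def _read_ply(path: Path):
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if not lines or lines[0].strip() != "ply":
        raise ParseError(f"{path}:1: not a PLY file")
    pitch = DEFAULT_VOXEL_PITCH_MM
    stem_ids = None
    counts = {}
    order = []
    i = 1
    while i < len(lines):
        tok = lines[i].split()
        if not tok:
            i += 1
            continue
        if tok[0] == "end_header":
            i += 1
            break
        if tok[0] == "comment":
            if len(tok) >= 2 and tok[1] == "stem":
                stem_ids = [int(t) for t in tok[2:]]
            elif len(tok) >= 3 and tok[1] == "pitch":
                pitch = float(tok[2])
        elif tok[0] == "format":
            if tok[1] != "ascii":
                raise ParseError(f"{path}:{i + 1}: only ascii PLY is supported")
        elif tok[0] == "element":
            counts[tok[1]] = int(tok[2])
            order.append(tok[1])
        i += 1
    skeleton = Skeleton(voxel_pitch=pitch)
    try:
        for name in order:
            n = counts[name]
            rows = lines[i : i + n]
            if len(rows) < n:
                raise ParseError(f"{path}: truncated element {name!r}")
            i += n
            if name == "vertex":
                for vid, row in enumerate(rows):
                    x, y, z, th = map(float, row.split()[:4])
                    skeleton.add_vertex(SkeletonVertex(vid, (x, y, z), th))
            elif name == "edge":
                for row in rows:
                    a, b = map(int, row.split()[:2])
                    skeleton.add_edge(a, b)
    except (ValueError, SkeletonError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if stem_ids is None:
        raise ParseError(f"{path}: missing 'comment stem' line")
    stem = StemPath.from_skeleton(skeleton, stem_ids)
    return skeleton, stem, {}


def _write_ply(skeleton, stem, path) -> None:
    ids = sorted(skeleton.vertices)
    index = {vid: i for i, vid in enumerate(ids)}
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"comment pitch {skeleton.voxel_pitch:.6g}\n")
        fh.write(
            "comment stem " + " ".join(str(index[v]) for v in stem.vertex_ids) + "\n"
        )
        fh.write(f"element vertex {skeleton.n_vertices}\n")
        for prop in ("x", "y", "z", "thickness"):
            fh.write(f"property float {prop}\n")
        fh.write(f"element edge {skeleton.n_edges}\n")
        fh.write("property int vertex1\nproperty int vertex2\n")
        fh.write("end_header\n")
        for vid in ids:
            v = skeleton.vertices[vid]
            x, y, z = v.position
            fh.write(f"{x:.9g} {y:.9g} {z:.9g} {v.thickness:.9g}\n")
        for a, b in sorted(skeleton.edges):
            fh.write(f"{index[a]} {index[b]}\n")
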