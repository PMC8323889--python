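"""Fixed-topology triangle meshes and their flattened vector form.

Every subject in a scan cohort shares one mesh topology: identical vertex
count, vertex ordering and face connectivity, so that vertex ``i`` refers to
the same anatomical location on every body.  That property is what lets a
cohort of meshes be stacked into an ``n_subjects x 3*n_vertices`` matrix and
fed to a dimensionality-reduction model.  This module owns the :class:`Mesh`
container, strict OBJ / ascii-PLY readers and writers that preserve vertex
order, the cohort flattening used as network input, and the ring-polygon
circumference measurement that backs waist/hip girths.

Coordinates are millimetres throughout; conversion to cm/kg happens at the
measurement boundary in :mod:`shapeincome.synthetic`.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "Mesh",
    "FlatDataset",
    "MeshFormatError",
    "TopologyMismatchError",
    "topology_hash",
    "read_mesh",
    "write_mesh",
    "flatten_cohort",
    "unflatten",
    "ring_circumference",
    "mesh_volume_mm3",
]


class MeshFormatError(ValueError):
    """Raised when a mesh file cannot be parsed or violates the format."""


class TopologyMismatchError(ValueError):
    """Raised when meshes that must share a topology do not."""


def topology_hash(faces: np.ndarray) -> str:
    """Hash of the face list; stable under any change of vertex coordinates."""
    f = np.ascontiguousarray(np.asarray(faces, dtype=np.int64))
    return hashlib.sha1(f.tobytes() + str(f.shape).encode()).hexdigest()


@dataclass
class Mesh:
    """A triangle mesh with fixed topology.

    Parameters
    ----------
    vertices : (n_v, 3) float array, millimetres.
    faces : (n_f, 3) int array, 0-based vertex indices.
    rings, segments : optional layout metadata for tube-of-rings template
        meshes; ring ``i`` occupies vertex indices ``i*segments`` to
        ``(i+1)*segments - 1``.  ``None`` for meshes of unknown layout.
    """

    vertices: np.ndarray
    faces: np.ndarray
    rings: int | None = None
    segments: int | None = None
    topology_id: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be an (n_v, 3) array")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be an (n_f, 3) array of triangles")
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= len(self.vertices)):
            raise MeshFormatError(
                f"face index out of range: max index {self.faces.max()} "
                f"for {len(self.vertices)} vertices"
            )
        if not self.topology_id:
            self.topology_id = topology_hash(self.faces)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def copy(self) -> "Mesh":
        return Mesh(
            self.vertices.copy(), self.faces.copy(),
            rings=self.rings, segments=self.segments, topology_id=self.topology_id,
        )

    def ring_vertices(self, ring_index: int) -> np.ndarray:
        if self.rings is None or self.segments is None:
            raise ValueError("mesh has no ring/segment layout metadata")
        if not 0 <= ring_index < self.rings:
            raise IndexError(f"ring index {ring_index} out of range [0, {self.rings})")
        s = self.segments
        return self.vertices[ring_index * s:(ring_index + 1) * s]


# ---------------------------------------------------------------------------
# OBJ / ascii-PLY io.  Deliberately strict: cross-subject comparability rests
# on the file preserving vertex order and pure-triangle connectivity, so mixed
# polygon sizes or out-of-range indices are hard errors, not things to repair.
# ---------------------------------------------------------------------------

_COORD_FMT = "%.6f"  # round-trip precision declared by the writers


def _parse_obj(lines: list[str], path: str) -> tuple[np.ndarray, np.ndarray]:
    verts: list[tuple[float, float, float]] = []
    faces: list[tuple[int, int, int]] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        tag, *rest = line.split()
        if tag == "v":
            if len(rest) < 3:
                raise MeshFormatError(f"{path}:{lineno}: vertex with <3 coordinates")
            try:
                verts.append((float(rest[0]), float(rest[1]), float(rest[2])))
            except ValueError as exc:
                raise MeshFormatError(f"{path}:{lineno}: bad vertex coordinate") from exc
        elif tag == "f":
            if len(rest) != 3:
                raise MeshFormatError(
                    f"{path}:{lineno}: face with {len(rest)} vertices; "
                    "only pure-triangle meshes are supported"
                )
            idx = []
            for tok in rest:
                head = tok.split("/")[0]  # discard texture/normal refs
                try:
                    idx.append(int(head))
                except ValueError as exc:
                    raise MeshFormatError(f"{path}:{lineno}: bad face index {tok!r}") from exc
            if any(i < 1 for i in idx):
                raise MeshFormatError(f"{path}:{lineno}: OBJ face indices are 1-based")
            faces.append((idx[0] - 1, idx[1] - 1, idx[2] - 1))
        # other tags (vn, vt, usemtl, o, g, s, mtllib) are ignored
    return np.asarray(verts, dtype=np.float64), np.asarray(faces, dtype=np.int64)


def _parse_ply(lines: list[str], path: str) -> tuple[np.ndarray, np.ndarray]:
    if not lines or lines[0].strip() != "ply":
        raise MeshFormatError(f"{path}:1: not a PLY file (missing 'ply' magic)")
    n_vert = n_face = None
    i = 1
    fmt_seen = False
    while i < len(lines):
        line = lines[i].strip()
        i += 1
        if line.startswith("format"):
            if "ascii" not in line:
                raise MeshFormatError(f"{path}:{i}: only ascii PLY is supported")
            fmt_seen = True
        elif line.startswith("element vertex"):
            n_vert = int(line.split()[2])
        elif line.startswith("element face"):
            n_face = int(line.split()[2])
        elif line == "end_header":
            break
    else:
        raise MeshFormatError(f"{path}: PLY header never terminated by end_header")
    if not fmt_seen or n_vert is None or n_face is None:
        raise MeshFormatError(f"{path}: incomplete PLY header")

    body = lines[i:]
    if len(body) < n_vert + n_face:
        raise MeshFormatError(
            f"{path}: body has {len(body)} rows; header promises {n_vert + n_face}"
        )
    try:
        verts = np.array(
            [[float(t) for t in body[j].split()[:3]] for j in range(n_vert)],
            dtype=np.float64,
        ).reshape(n_vert, 3)
    except ValueError as exc:
        raise MeshFormatError(f"{path}: bad vertex row in PLY body") from exc
    faces = []
    for j in range(n_vert, n_vert + n_face):
        toks = body[j].split()
        lineno = i + j + 1
        if int(toks[0]) != 3:
            raise MeshFormatError(
                f"{path}:{lineno}: face with {toks[0]} vertices; "
                "only pure-triangle meshes are supported"
            )
        faces.append((int(toks[1]), int(toks[2]), int(toks[3])))
    return verts, np.asarray(faces, dtype=np.int64)


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        fmt = fmt.lower()
    else:
        fmt = path.suffix.lstrip(".").lower()
    if fmt not in ("obj", "ply"):
        raise MeshFormatError(f"unsupported mesh format {fmt!r} (obj or ply)")
    return fmt


def read_mesh(path: str | Path, fmt: str | None = None) -> Mesh:
    """Read an OBJ or ascii-PLY triangle mesh, preserving vertex order.

    OBJ face indices are converted from the format's 1-based convention to
    0-based.  Parse failures raise :class:`MeshFormatError` naming the file
    and line; a face index beyond the vertex count is likewise an error.
    """
    path = Path(path)
    fmt = _infer_format(path, fmt)
    lines = path.read_text().splitlines()
    verts, faces = (_parse_obj if fmt == "obj" else _parse_ply)(lines, str(path))
    if faces.size and faces.max() >= len(verts):
        raise MeshFormatError(
            f"{path}: face index {faces.max()} out of range for {len(verts)} vertices"
        )
    return Mesh(verts, faces)


def write_mesh(mesh: Mesh, path: str | Path, fmt: str | None = None) -> Path:
    """Write a mesh as OBJ (v/f, 1-based) or ascii PLY at %.6f precision."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    out: list[str] = []
    if fmt == "obj":
        for v in mesh.vertices:
            out.append("v " + " ".join(_COORD_FMT % c for c in v))
        for f in mesh.faces:
            out.append(f"f {f[0] + 1} {f[1] + 1} {f[2] + 1}")
    else:
        out += [
            "ply",
            "format ascii 1.0",
            f"element vertex {mesh.n_vertices}",
            "property float x",
            "property float y",
            "property float z",
            f"element face {len(mesh.faces)}",
            "property list uchar int vertex_indices",
            "end_header",
        ]
        for v in mesh.vertices:
            out.append(" ".join(_COORD_FMT % c for c in v))
        for f in mesh.faces:
            out.append(f"3 {f[0]} {f[1]} {f[2]}")
    path.write_text("\n".join(out) + "\n")
    return path


# ---------------------------------------------------------------------------
# Flattening: cohort of meshes  <->  design matrix for the autoencoder
# ---------------------------------------------------------------------------

@dataclass
class FlatDataset:
    """A cohort of same-topology meshes as an ``n x 3*n_v`` matrix.

    Row ``i`` is subject ``i``'s vertex array in vertex-major, xyz-minor
    order (the C order of the ``(n_v, 3)`` array).  ``column_means`` and
    ``scale`` record the optional centering/scaling applied so a row can be
    mapped back to mesh coordinates exactly.
    """

    matrix: np.ndarray
    subject_ids: list
    topology_id: str
    faces: np.ndarray
    rings: int | None = None
    segments: int | None = None
    column_means: np.ndarray | None = None
    scale: float | None = None

    @property
    def n_subjects(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_inputs(self) -> int:
        return self.matrix.shape[1]

    def to_csv(self, path: str | Path) -> Path:
        """Persist the matrix as CSV with a JSON sidecar (.meta.json).

        The sidecar records subject ids, topology (faces), layout and the
        centering/scaling parameters so :meth:`from_csv` reconstructs the
        dataset exactly (17-significant-digit float round trip).
        """
        import json

        path = Path(path)
        np.savetxt(path, self.matrix, delimiter=",", fmt="%.17g")
        meta = {
            "subject_ids": list(self.subject_ids),
            "topology_id": self.topology_id,
            "faces": self.faces.tolist(),
            "rings": self.rings,
            "segments": self.segments,
            "column_means": (None if self.column_means is None
                             else self.column_means.tolist()),
            "scale": self.scale,
        }
        path.with_suffix(path.suffix + ".meta.json").write_text(
            json.dumps(meta) + "\n")
        return path

    @classmethod
    def from_csv(cls, path: str | Path) -> "FlatDataset":
        import json

        path = Path(path)
        meta = json.loads(
            path.with_suffix(path.suffix + ".meta.json").read_text())
        matrix = np.loadtxt(path, delimiter=",", ndmin=2)
        return cls(
            matrix=matrix,
            subject_ids=meta["subject_ids"],
            topology_id=meta["topology_id"],
            faces=np.asarray(meta["faces"], dtype=np.int64),
            rings=meta["rings"],
            segments=meta["segments"],
            column_means=(None if meta["column_means"] is None
                          else np.asarray(meta["column_means"])),
            scale=meta["scale"],
        )

    def row_to_coords(self, row: np.ndarray) -> np.ndarray:
        """Undo scaling/centering, returning raw mm coordinates (flat)."""
        row = np.asarray(row, dtype=np.float64)
        if row.shape != (self.n_inputs,):
            raise ValueError(f"row length {row.shape} != ({self.n_inputs},)")
        if self.scale is not None:
            row = row * self.scale
        if self.column_means is not None:
            row = row + self.column_means
        return row


def flatten_cohort(
    meshes: list[Mesh],
    center: bool = False,
    scale: bool = False,
    subject_ids: list | None = None,
) -> FlatDataset:
    """Stack a same-topology cohort into the network's input matrix.

    With ``center`` each column (vertex coordinate) has its cohort mean
    removed; with ``scale`` the centered matrix is divided by its maximum
    absolute entry so inputs lie in [-1, 1].  Both transforms are recorded
    for exact inversion.  A 15,178-vertex topology yields rows of length
    45,534.
    """
    if not meshes:
        raise ValueError("empty cohort")
    tid = meshes[0].topology_id
    bad = [i for i, m in enumerate(meshes) if m.topology_id != tid]
    if bad:
        ids = [subject_ids[i] if subject_ids else i for i in bad]
        raise TopologyMismatchError(f"meshes with mismatching topology: {ids}")
    mat = np.stack([m.vertices.reshape(-1) for m in meshes]).astype(np.float64)
    means = None
    sc = None
    if center:
        means = mat.mean(axis=0)
        mat = mat - means
    if scale:
        sc = float(np.abs(mat).max())
        if sc == 0.0:
            sc = 1.0
        mat = mat / sc
    if subject_ids is None:
        subject_ids = list(range(len(meshes)))
    return FlatDataset(
        matrix=mat,
        subject_ids=list(subject_ids),
        topology_id=tid,
        faces=meshes[0].faces.copy(),
        rings=meshes[0].rings,
        segments=meshes[0].segments,
        column_means=means,
        scale=sc,
    )


def unflatten(dataset: FlatDataset, row: np.ndarray) -> Mesh:
    """Rebuild a mesh from one (possibly centered/scaled) flat row."""
    coords = dataset.row_to_coords(row)
    return Mesh(
        coords.reshape(-1, 3),
        dataset.faces,
        rings=dataset.rings,
        segments=dataset.segments,
        topology_id=dataset.topology_id,
    )


def ring_circumference(mesh: Mesh, ring_index: int) -> float:
    """Perimeter (mm) of a template ring: chord sum of the closed polygon.

    A unit-radius ring of ``S`` segments measures ``2*S*sin(pi/S)``, within
    0.3% of ``2*pi`` at S=24.
    """
    ring = mesh.ring_vertices(ring_index)
    diffs = np.diff(np.vstack([ring, ring[:1]]), axis=0)
    return float(np.linalg.norm(diffs, axis=1).sum())


def mesh_volume_mm3(mesh: Mesh) -> float:
    """Signed enclosed volume of a closed mesh via the divergence theorem."""
    v = mesh.vertices
    t0, t1, t2 = v[mesh.faces[:, 0]], v[mesh.faces[:, 1]], v[mesh.faces[:, 2]]
    return float(np.einsum("ij,ij->i", t0, np.cross(t1, t2)).sum() / 6.0)
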