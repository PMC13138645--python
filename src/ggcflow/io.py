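"""Readers and writers for meshes, scalar maps, matrices, and tables.

TSV is the lingua franca (inspectable, diffable); GIFTI is supported for
interoperability with surface viewers, OFF and a simple two-block
vertex/face text format for lightweight exchange, MatrixMarket for sparse
matrices.  Writers emit a provenance comment header (seed / config hash)
where the format permits comments.
"""
from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io as sio

from .errors import ArgumentError, DataValidationError
from .gradients import ConnectivityMatrix
from .mesh import TriangleMesh

__all__ = [
    "read_mesh",
    "write_mesh",
    "read_matrix",
    "write_matrix",
    "read_scalar_map",
    "write_scalar_map",
]


def _provenance_lines(provenance: dict | None) -> list[str]:
    if not provenance:
        return []
    return [f"# {k}: {v}" for k, v in sorted(provenance.items())]


# ---------------------------------------------------------------- meshes


def _detect_mesh_format(path: Path) -> str:
    name = path.name.lower()
    if name.endswith(".gii"):
        return "gifti"
    if name.endswith(".off"):
        return "off"
    return "vtx"


def read_mesh(path, fmt: str | None = None) -> TriangleMesh:
    """Read a surface mesh (GIFTI, OFF, or two-block vertex/face text).

    Face indices are validated as 0-based; files whose indices reach the
    vertex count (a 1-based convention) are rejected with a clear message.
    """
    path = Path(path)
    if not path.exists():
        raise ArgumentError(f"mesh file not found: {path}")
    fmt = fmt or _detect_mesh_format(path)
    if fmt == "gifti":
        return _read_gifti_mesh(path)
    if fmt == "off":
        return _read_off(path)
    if fmt in ("vtx", "vtx-face-text"):
        return _read_vtx_text(path)
    raise ArgumentError(f"unknown mesh format {fmt!r}")


def write_mesh(mesh: TriangleMesh, path, fmt: str | None = None,
               provenance: dict | None = None) -> None:
    path = Path(path)
    fmt = fmt or _detect_mesh_format(path)
    if fmt == "gifti":
        _write_gifti_mesh(mesh, path)
    elif fmt == "off":
        _write_off(mesh, path, provenance)
    elif fmt in ("vtx", "vtx-face-text"):
        _write_vtx_text(mesh, path, provenance)
    else:
        raise ArgumentError(f"unknown mesh format {fmt!r}")


def _read_gifti_mesh(path: Path) -> TriangleMesh:
    import nibabel as nib

    try:
        img = nib.load(str(path))
        coords = img.get_arrays_from_intent("NIFTI_INTENT_POINTSET")[0].data
        faces = img.get_arrays_from_intent("NIFTI_INTENT_TRIANGLE")[0].data
    except DataValidationError:
        raise
    except Exception as exc:
        raise DataValidationError(f"cannot parse GIFTI surface {path}: {exc}") from exc
    return TriangleMesh(np.asarray(coords, float), np.asarray(faces, int))


def _write_gifti_mesh(mesh: TriangleMesh, path: Path) -> None:
    import nibabel as nib

    coords = nib.gifti.GiftiDataArray(
        mesh.vertices.astype(np.float32), intent="NIFTI_INTENT_POINTSET"
    )
    faces = nib.gifti.GiftiDataArray(
        mesh.faces.astype(np.int32), intent="NIFTI_INTENT_TRIANGLE"
    )
    nib.gifti.GiftiImage(darrays=[coords, faces]).to_filename(str(path))


def _read_off(path: Path) -> TriangleMesh:
    tokens: list[str] = []
    with open(path) as fh:
        first = fh.readline().strip()
        if first.split("#")[0].strip() != "OFF":
            raise DataValidationError(f"{path}: missing OFF header")
        for line in fh:
            line = line.split("#")[0].strip()
            if line:
                tokens.extend(line.split())
    try:
        nv, nf = int(tokens[0]), int(tokens[1])
        pos = 3  # skip edge count
        verts = np.array(tokens[pos : pos + 3 * nv], dtype=float).reshape(nv, 3)
        pos += 3 * nv
        faces = []
        for _ in range(nf):
            arity = int(tokens[pos])
            if arity != 3:
                raise DataValidationError(f"{path}: non-triangular face (arity {arity})")
            faces.append([int(t) for t in tokens[pos + 1 : pos + 4]])
            pos += 1 + arity
    except (IndexError, ValueError) as exc:
        raise DataValidationError(
            f"{path}: truncated or malformed OFF file ({exc})"
        ) from exc
    faces = np.asarray(faces, dtype=int)
    if faces.size and faces.max() >= nv:
        raise DataValidationError(
            f"{path}: face index {faces.max()} >= vertex count {nv}; "
            "OFF faces must be 0-based"
        )
    return TriangleMesh(verts, faces)


def _write_off(mesh: TriangleMesh, path: Path, provenance: dict | None) -> None:
    with open(path, "w") as fh:
        fh.write("OFF\n")
        for line in _provenance_lines(provenance):
            fh.write(line + "\n")
        fh.write(f"{mesh.n_vertices} {mesh.n_faces} 0\n")
        for v in mesh.vertices:
            fh.write(f"{v[0]:.17g} {v[1]:.17g} {v[2]:.17g}\n")
        for f in mesh.faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")


def _read_vtx_text(path: Path) -> TriangleMesh:
    """Two-block text: 'NV NF' header, NV xyz lines, NF ijk lines."""
    with open(path) as fh:
        lines = [
            ln.split("#")[0].strip() for ln in fh if ln.split("#")[0].strip()
        ]
    try:
        nv, nf = (int(t) for t in lines[0].split())
        verts = np.array(
            [ln.split() for ln in lines[1 : 1 + nv]], dtype=float
        ).reshape(nv, 3)
        faces = np.array(
            [ln.split() for ln in lines[1 + nv : 1 + nv + nf]], dtype=int
        ).reshape(nf, 3)
    except (IndexError, ValueError) as exc:
        raise DataValidationError(
            f"{path}: malformed vertex/face text file ({exc})"
        ) from exc
    if len(lines) < 1 + nv + nf:
        raise DataValidationError(f"{path}: truncated vertex/face text file")
    return TriangleMesh(verts, faces)


def _write_vtx_text(mesh: TriangleMesh, path: Path, provenance: dict | None) -> None:
    with open(path, "w") as fh:
        for line in _provenance_lines(provenance):
            fh.write(line + "\n")
        fh.write(f"{mesh.n_vertices} {mesh.n_faces}\n")
        for v in mesh.vertices:
            fh.write(f"{v[0]:.17g} {v[1]:.17g} {v[2]:.17g}\n")
        for f in mesh.faces:
            fh.write(f"{f[0]} {f[1]} {f[2]}\n")


# --------------------------------------------------------------- matrices


def _detect_matrix_format(path: Path) -> str:
    return "matrixmarket" if path.name.lower().endswith(".mtx") else "tsv"


def read_matrix(path, fmt: str | None = None) -> ConnectivityMatrix:
    """Read a square symmetric connectivity matrix (TSV or MatrixMarket).

    Symmetry is validated to 1e-9 and enforced by averaging; non-square or
    non-finite content raises with the offending coordinate.
    """
    path = Path(path)
    if not path.exists():
        raise ArgumentError(f"matrix file not found: {path}")
    fmt = fmt or _detect_matrix_format(path)
    if fmt == "matrixmarket":
        mat = sio.mmread(str(path))
        if hasattr(mat, "todense"):
            mat = mat.todense()
        mat = np.asarray(mat, dtype=float)
    elif fmt == "tsv":
        mat = np.loadtxt(path, delimiter="\t", comments="#", ndmin=2)
    else:
        raise ArgumentError(f"unknown matrix format {fmt!r}")
    return ConnectivityMatrix(mat)


def write_matrix(matrix, path, fmt: str | None = None,
                 provenance: dict | None = None) -> None:
    path = Path(path)
    fmt = fmt or _detect_matrix_format(path)
    arr = matrix.counts if isinstance(matrix, ConnectivityMatrix) else np.asarray(matrix)
    if fmt == "matrixmarket":
        from scipy import sparse

        sio.mmwrite(str(path), sparse.coo_matrix(arr))
    elif fmt == "tsv":
        with open(path, "w") as fh:
            for line in _provenance_lines(provenance):
                fh.write(line + "\n")
            np.savetxt(fh, arr, delimiter="\t", fmt="%.17g")
    else:
        raise ArgumentError(f"unknown matrix format {fmt!r}")


# ------------------------------------------------------------ scalar maps


def read_scalar_map(path) -> pd.DataFrame:
    """Read per-vertex/per-node scalar columns from TSV (or GIFTI func)."""
    path = Path(path)
    if not path.exists():
        raise ArgumentError(f"scalar map file not found: {path}")
    if path.name.lower().endswith(".gii"):
        import nibabel as nib

        img = nib.load(str(path))
        data = {f"col{i + 1}": np.asarray(d.data, float)
                for i, d in enumerate(img.darrays)}
        return pd.DataFrame(data)
    df = pd.read_csv(path, sep="\t", comment="#")
    if not np.isfinite(df.to_numpy(dtype=float)).all():
        raise DataValidationError(f"{path}: non-finite scalar values")
    return df


def write_scalar_map(values, path, names=None,
                     provenance: dict | None = None) -> None:
    """Write one or more scalar columns as TSV with named header."""
    path = Path(path)
    arr = np.asarray(values, dtype=np.float64)
    if arr.ndim == 1:
        arr = arr[:, None]
    if names is None:
        names = [f"col{i + 1}" for i in range(arr.shape[1])]
    if len(names) != arr.shape[1]:
        raise ArgumentError("one name per column required")
    buf = _io.StringIO()
    for line in _provenance_lines(provenance):
        buf.write(line + "\n")
    pd.DataFrame(arr, columns=list(names)).to_csv(buf, sep="\t", index=False)
    path.write_text(buf.getvalue())
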