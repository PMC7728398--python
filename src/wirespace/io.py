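"""Readers and writers for the package's on-disk formats.

Matrices travel as CSV/TSV with a header row of node ids and full symmetry
(no triangular shorthand).  Surface meshes are read from GIFTI or FreeSurfer
binary geometry (via nibabel) or from a plain vertices/faces text dialect;
per-vertex labels and scalars are delimited text.  Recordings come from EDF
(via mne, read lazily) or channel-by-time delimited text with a
``# fs=<Hz>`` header line.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .features import FeatureMatrix, IntensityProfileSet, SurfaceMesh
from .manifold import WiringSpace

__all__ = [
    "read_matrix", "write_matrix",
    "read_mesh", "write_mesh_text",
    "read_vertex_table",
    "read_profiles", "write_profiles",
    "read_space", "write_space",
    "read_recording_text",
    "read_gene_sets",
]


def _sep(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def read_matrix(path, modality: str | None = None):
    """Read a symmetric node-by-node matrix (header row = node ids)."""
    df = pd.read_csv(path, sep=_sep(path), index_col=0)
    values = df.to_numpy(dtype=float)
    node_ids = np.array(df.columns)
    if modality is None:
        return values, node_ids
    return FeatureMatrix(values, modality, node_ids)


def write_matrix(path, values: np.ndarray, node_ids) -> None:
    pd.DataFrame(values, index=node_ids, columns=node_ids).to_csv(
        path, sep=_sep(path))


def read_mesh(path, parcel_labels=None) -> SurfaceMesh:
    """Read a surface mesh from GIFTI, FreeSurfer geometry, or text.

    The text dialect has a ``# vertices N faces M`` header followed by N
    ``x y z [label]`` lines and M ``i j k`` lines.  ``parcel_labels``
    (array or path to a one-column text file) overrides labels; without
    labels all vertices form parcel 1.
    """
    path = Path(path)
    if path.suffix == ".gii":
        import nibabel as nib
        img = nib.load(str(path))
        verts = img.darrays[0].data
        faces = img.darrays[1].data
        labels = None
    elif path.suffix in (".asc", ".txt", ".mesh"):
        verts, faces, labels = _read_mesh_text(path)
    else:
        import nibabel.freesurfer as fsio
        verts, faces = fsio.read_geometry(str(path))
        labels = None
    if parcel_labels is not None:
        if isinstance(parcel_labels, (str, Path)):
            labels = np.loadtxt(parcel_labels, dtype=int)
        else:
            labels = np.asarray(parcel_labels, dtype=int)
    if labels is None:
        labels = np.ones(len(verts), dtype=int)
    return SurfaceMesh(np.asarray(verts, float), np.asarray(faces, int), labels)


def _read_mesh_text(path):
    with open(path) as fh:
        header = fh.readline().split()
        n_vert, n_face = int(header[2]), int(header[4])
        rows = [fh.readline().split() for _ in range(n_vert)]
        verts = np.array([r[:3] for r in rows], dtype=float)
        labels = (np.array([r[3] for r in rows], dtype=int)
                  if len(rows[0]) > 3 else None)
        faces = np.array([fh.readline().split() for _ in range(n_face)], dtype=int)
    return verts, faces, labels


def write_mesh_text(path, mesh: SurfaceMesh) -> None:
    with open(path, "w") as fh:
        fh.write(f"# vertices {len(mesh.vertices)} faces {len(mesh.faces)}\n")
        for v, lab in zip(mesh.vertices, mesh.parcel_labels):
            fh.write(f"{v[0]:.6f} {v[1]:.6f} {v[2]:.6f} {lab}\n")
        for f in mesh.faces:
            fh.write(f"{f[0]} {f[1]} {f[2]}\n")


def read_vertex_table(path) -> np.ndarray:
    """Per-vertex scalars (one row per vertex, any number of columns)."""
    return np.loadtxt(path, ndmin=2)


def read_profiles(path) -> IntensityProfileSet:
    """Node-by-depth profile table; columns named by depth fraction."""
    df = pd.read_csv(path, sep=_sep(path), index_col=0)
    return IntensityProfileSet(df.to_numpy(dtype=float),
                               np.array([float(c) for c in df.columns]),
                               np.array(df.index))


def write_profiles(path, profiles: IntensityProfileSet) -> None:
    pd.DataFrame(profiles.profiles, index=profiles.node_ids,
                 columns=[f"{d:.6f}" for d in profiles.depth_fractions]
                 ).to_csv(path, sep=_sep(path))


def read_space(path) -> WiringSpace:
    with open(path) as fh:
        first = fh.readline()
    if not first.startswith("#"):
        raise ValueError(f"{path} lacks the '# eigenvalues=...' metadata header")
    meta = dict(kv.partition("=")[::2] for kv in first[1:].split())
    df = pd.read_csv(path, sep=_sep(path), index_col=0, skiprows=1)
    coords = df[[c for c in df.columns if c.startswith("E")]].to_numpy(float)
    eigenvalues = np.array([float(x) for x in meta["eigenvalues"].split(",")])
    var = np.array([float(x) for x in meta["variance"].split(",")])
    return WiringSpace(coords, eigenvalues, var, float(meta["alpha"]),
                       np.array(df.index))


def write_space(path, space: WiringSpace) -> None:
    with open(path, "w") as fh:
        fh.write("# eigenvalues={} variance={} alpha={}\n".format(
            ",".join(f"{v:.12g}" for v in space.eigenvalues),
            ",".join(f"{v:.12g}" for v in space.variance_explained),
            space.alpha))
        pd.DataFrame(space.coordinates, index=space.node_ids,
                     columns=[f"E{k+1}" for k in range(space.n_components)]
                     ).to_csv(fh, sep=_sep(path))


def read_recording_text(path) -> tuple[np.ndarray, float]:
    """Channel-by-time delimited text with a ``# fs=<Hz>`` header line."""
    with open(path) as fh:
        first = fh.readline().strip()
    if not first.startswith("#") or "fs=" not in first:
        raise ValueError(f"{path} lacks a '# fs=<Hz>' header line")
    fs = float(first.split("fs=")[1].split()[0])
    return np.loadtxt(path, ndmin=2), fs


def read_recording_edf(path, channels=None):
    """Read an EDF recording (requires mne)."""
    import mne
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    if channels is not None:
        raw = raw.pick(channels)
    return raw.get_data(), float(raw.info["sfreq"])


def read_gene_sets(path) -> dict:
    """Two-column (cell_type, gene) delimited text -> dict of gene lists."""
    df = pd.read_csv(path, sep=None, engine="python",
                     names=["cell_type", "gene"], comment="#")
    return {ct: sorted(set(g["gene"])) for ct, g in df.groupby("cell_type")}
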