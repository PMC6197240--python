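"""Minimal VTK legacy (ASCII) writer for quad meshes plus CSV/PNG helpers."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .geometry import ExplantMesh

__all__ = ["write_vtk", "cell_average", "plot_cell_field"]


def cell_average(field: np.ndarray) -> np.ndarray:
    """Average an (E, 4) Gauss-point field to one value per element."""
    return np.asarray(field).mean(axis=1)


def write_vtk(
    path,
    mesh: ExplantMesh,
    point_data: dict[str, np.ndarray] | None = None,
    cell_data: dict[str, np.ndarray] | None = None,
    title: str = "cartidegen output",
) -> None:
    """Write the mesh and fields as a legacy VTK unstructured grid.

    Point data arrays are (n_nodes,) scalars or (n_nodes, 2/3) vectors;
    cell data arrays are (n_elems,) scalars or (E, 4) Gauss fields (these
    are cell-averaged on output).
    """
    path = Path(path)
    lines = [
        "# vtk DataFile Version 3.0",
        title,
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {mesh.n_nodes} double",
    ]
    for x, y in mesh.nodes:
        lines.append(f"{x:.9g} {y:.9g} 0")
    lines.append(f"CELLS {mesh.n_elems} {5 * mesh.n_elems}")
    for el in mesh.elems:
        lines.append("4 " + " ".join(str(int(n)) for n in el))
    lines.append(f"CELL_TYPES {mesh.n_elems}")
    lines.extend(["9"] * mesh.n_elems)  # VTK_QUAD

    def emit(name, arr, n):
        arr = np.asarray(arr, dtype=float)
        out = []
        if arr.ndim == 1:
            out.append(f"SCALARS {name} double 1")
            out.append("LOOKUP_TABLE default")
            out.extend(f"{v:.9g}" for v in arr)
        else:
            out.append(f"VECTORS {name} double")
            for row in arr:
                v = np.zeros(3)
                v[: row.size] = row
                out.append(f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g}")
        return out

    if point_data:
        lines.append(f"POINT_DATA {mesh.n_nodes}")
        for name, arr in point_data.items():
            lines.extend(emit(name, arr, mesh.n_nodes))
    if cell_data:
        lines.append(f"CELL_DATA {mesh.n_elems}")
        for name, arr in cell_data.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim == 2 and arr.shape == (mesh.n_elems, 4):
                arr = cell_average(arr)
            lines.extend(emit(name, arr, mesh.n_elems))
    path.write_text("\n".join(lines) + "\n")


def plot_cell_field(path, mesh: ExplantMesh, field: np.ndarray, title: str, label: str) -> None:
    """PNG map of an element field on the deformed or reference mesh."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.collections import PolyCollection

    field = np.asarray(field, dtype=float)
    if field.ndim == 2:
        field = cell_average(field)
    verts = mesh.nodes[mesh.elems]
    fig, ax = plt.subplots(figsize=(5, 4))
    pc = PolyCollection(verts, array=field, edgecolor="none", cmap="viridis")
    ax.add_collection(pc)
    ax.autoscale()
    ax.set_aspect("equal")
    ax.set_xlabel("r [mm]")
    ax.set_ylabel("z [mm]")
    ax.set_title(title)
    fig.colorbar(pc, ax=ax, label=label)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
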