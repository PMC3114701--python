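"""Versioned plain-text serialization for thresholds, patches, matrices
and library bundles.  All formats are line-oriented, tab-separated and
deterministic, so identical inputs reproduce byte-identical artifacts."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np

from .patch_clustering import PatchLibrary
from .structure_io import AtomRecord, AtomType
from .surface_patches import Patch, SurfaceThresholdTable, build_patch

__all__ = [
    "save_thresholds",
    "load_thresholds",
    "save_patches",
    "load_patches",
    "save_distance_matrix",
    "load_distance_matrix",
    "save_library",
    "load_library",
]

_THRESHOLDS_MAGIC = "# surfpatch-thresholds v1"
_PATCHES_MAGIC = "# surfpatch-patches v1"
_MATRIX_MAGIC = "# surfpatch-distance-matrix v1"
LIBRARY_FORMAT_VERSION = 1


def save_thresholds(table: SurfaceThresholdTable, path: str | Path) -> None:
    lines = [
        _THRESHOLDS_MAGIC,
        f"# alpha={table.alpha!r}\tpercentile={table.percentile!r}\tcorpus_size={table.corpus_size}",
    ]
    for t in sorted(table.thresholds):
        lines.append(f"{t}\t{table.thresholds[t]!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def load_thresholds(path: str | Path) -> SurfaceThresholdTable:
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0] != _THRESHOLDS_MAGIC:
        raise ValueError(f"{path}: not a surfpatch thresholds file")
    meta = dict(
        kv.split("=", 1) for kv in lines[1].lstrip("# ").split("\t")
    )
    thresholds = {}
    for line in lines[2:]:
        if not line.strip():
            continue
        key, value = line.split("\t")
        thresholds[AtomType.parse(key)] = float(value)
    return SurfaceThresholdTable(
        thresholds=thresholds,
        alpha=float(meta["alpha"]),
        percentile=float(meta["percentile"]),
        corpus_size=int(meta["corpus_size"]),
    )


def _atom_line(a: AtomRecord) -> str:
    x, y, z = a.coords
    return (
        f"ATOM\t{a.chain_id}\t{a.residue_number}\t{a.insertion_code}\t"
        f"{a.residue_name}\t{a.atom_name}\t{a.element}\t{x!r}\t{y!r}\t{z!r}"
    )


def _parse_atom_line(line: str) -> AtomRecord:
    _, chain, num, icode, res, name, elem, x, y, z = line.split("\t")
    return AtomRecord(
        chain_id=chain,
        residue_number=int(num),
        residue_name=res,
        atom_name=name,
        element=elem,
        coords=(float(x), float(y), float(z)),
        insertion_code=icode,
    )


def save_patches(patches: Sequence[Patch], path: str | Path) -> None:
    lines = [_PATCHES_MAGIC]
    for p in patches:
        pivot_index = list(p.atoms).index(p.pivot)
        lines.append(f"PATCH\t{p.source_id}\t{pivot_index}\t{p.radius!r}")
        for a in p.atoms:
            lines.append(_atom_line(a))
        lines.append("ENDPATCH")
    Path(path).write_text("\n".join(lines) + "\n")


def load_patches(path: str | Path) -> list[Patch]:
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0] != _PATCHES_MAGIC:
        raise ValueError(f"{path}: not a surfpatch patches file")
    patches: list[Patch] = []
    i = 1
    while i < len(lines):
        line = lines[i]
        if not line.strip():
            i += 1
            continue
        if not line.startswith("PATCH\t"):
            raise ValueError(f"{path}: malformed at line {i + 1}")
        _, source_id, pivot_index, radius = line.split("\t")
        atoms: list[AtomRecord] = []
        i += 1
        while lines[i] != "ENDPATCH":
            atoms.append(_parse_atom_line(lines[i]))
            i += 1
        i += 1
        patches.append(
            build_patch(source_id, atoms[int(pivot_index)], atoms, float(radius))
        )
    return patches


def save_distance_matrix(
    matrix: np.ndarray, ids: Sequence[str], path: str | Path
) -> None:
    matrix = np.asarray(matrix, dtype=float)
    lines = [_MATRIX_MAGIC, "\t".join(ids)]
    for row in matrix:
        lines.append("\t".join("inf" if not np.isfinite(v) else repr(float(v)) for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


def load_distance_matrix(path: str | Path) -> tuple[np.ndarray, list[str]]:
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0] != _MATRIX_MAGIC:
        raise ValueError(f"{path}: not a surfpatch distance matrix")
    ids = lines[1].split("\t")
    rows = [
        [float(v) for v in line.split("\t")] for line in lines[2:] if line.strip()
    ]
    return np.asarray(rows, dtype=float), ids


def save_library(library: PatchLibrary, directory: str | Path) -> None:
    """Write a library bundle: manifest.json + centroids.patches."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    save_patches(library.centroids, directory / "centroids.patches")
    manifest = {
        "format_version": LIBRARY_FORMAT_VERSION,
        "k": library.k,
        "cluster_sizes": library.cluster_sizes.tolist(),
        "training_fractions": library.training_fractions.tolist(),
        "centroid_indices": library.centroid_indices.tolist(),
        "assignments": library.assignments.tolist(),
        "provenance": library.provenance,
    }
    (directory / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )


def load_library(directory: str | Path) -> PatchLibrary:
    directory = Path(directory)
    manifest_path = directory / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"{directory}: no library manifest")
    manifest = json.loads(manifest_path.read_text())
    if manifest.get("format_version") != LIBRARY_FORMAT_VERSION:
        raise ValueError(f"{directory}: unsupported library format")
    centroids = load_patches(directory / "centroids.patches")
    return PatchLibrary(
        centroids=centroids,
        cluster_sizes=np.asarray(manifest["cluster_sizes"], dtype=int),
        training_fractions=np.asarray(manifest["training_fractions"], dtype=float),
        centroid_indices=np.asarray(manifest["centroid_indices"], dtype=int),
        assignments=np.asarray(manifest["assignments"], dtype=int),
        provenance=manifest["provenance"],
    )
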