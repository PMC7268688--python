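"""Domain types and file I/O for the volume-covariance network pipeline.

The unit of exchange between stages is the :class:`VolumeTable` — a
subjects × regions matrix of regional brain volumes in mm³, tagged with the
preprocessing workflow that produced it.  Regions are always ordered as in
the packaged 64-region gray-matter atlas (:func:`load_region_atlas`), which
pairs 32 structures across the Left/Right hemispheres.

File formats are deliberately plain: CSV for tables and matrices, JSON for
metric reports, NIfTI for label maps and Jacobian fields, and 4-line
plain-text row-major matrices for rigid/affine transforms.  Readers and
writers are mutually inverse at 12 significant digits.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "Region",
    "RegionAtlas",
    "VolumeTable",
    "RegistrationFixture",
    "BrainNetwork",
    "SparsityMetrics",
    "MetricReport",
    "AtlasError",
    "VolumeTableError",
    "load_region_atlas",
    "read_volume_table",
    "write_volume_table",
    "read_network",
    "write_network",
    "read_metrics",
    "write_metrics",
    "read_transform",
    "write_transform",
    "read_registration_fixture",
    "write_registration_fixture",
    "FLOAT_FORMAT",
]

HEMISPHERES = ("Left", "Right")

#: numeric grid written by all text writers — 12 significant digits,
#: the precision at which read(write(x)) == x is guaranteed
FLOAT_FORMAT = "%.12g"


class AtlasError(ValueError):
    """Packaged atlas data is malformed."""


class VolumeTableError(ValueError):
    """A volume table file or object violates its contract."""


@dataclass(frozen=True)
class Region:
    """One atlas node: a named gray-matter structure in one hemisphere."""

    index: int
    name: str
    hemisphere: str
    label_code: int


@dataclass(frozen=True)
class RegionAtlas:
    """Ordered 64-region node list (32 structures × 2 hemispheres).

    ``label_code`` is the integer value identifying the region in template
    label maps; the packaged atlas assigns codes 1..64 in row order, and
    external label maps must be remapped to this convention.
    """

    regions: tuple[Region, ...]

    def __post_init__(self) -> None:
        n = len(self.regions)
        if n != 64:
            raise AtlasError(f"atlas must contain exactly 64 regions, got {n}")
        indices = [r.index for r in self.regions]
        if indices != list(range(1, 65)):
            raise AtlasError("atlas indices must be 1..64 in row order")
        pairs = [(r.name, r.hemisphere) for r in self.regions]
        if len(set(pairs)) != 64:
            raise AtlasError("(name, hemisphere) pairs must be unique")
        for hemi in HEMISPHERES:
            if sum(r.hemisphere == hemi for r in self.regions) != 32:
                raise AtlasError(f"atlas must contain 32 {hemi} regions")
        if len({r.label_code for r in self.regions}) != 64:
            raise AtlasError("label codes must be unique")

    @property
    def column_names(self) -> list[str]:
        """Region column labels, e.g. ``'Thalamus (Left)'``."""
        return [f"{r.name} ({r.hemisphere})" for r in self.regions]

    @property
    def label_codes(self) -> list[int]:
        return [r.label_code for r in self.regions]

    def find(self, name: str, hemisphere: str) -> Region:
        for r in self.regions:
            if r.name == name and r.hemisphere == hemisphere:
                return r
        raise KeyError(f"no atlas region {name!r} ({hemisphere})")

    def indices_of(self, names: Sequence[str]) -> np.ndarray:
        """0-based positions of the given column names, atlas order assumed."""
        lookup = {c: i for i, c in enumerate(self.column_names)}
        return np.array([lookup[n] for n in names])


def load_region_atlas() -> RegionAtlas:
    """Load the packaged 64-region atlas.

    Raises :class:`AtlasError` naming the first malformed row if the
    packaged data is corrupt.
    """
    regions: list[Region] = []
    text = resources.files("volcov.data").joinpath("atlas_64.csv").read_text("utf-8")
    reader = csv.DictReader(text.splitlines())
    for lineno, row in enumerate(reader, start=2):
        try:
            region = Region(
                index=int(row["index"]),
                name=row["name"].strip(),
                hemisphere=row["hemisphere"].strip(),
                label_code=int(row["label_code"]),
            )
            if region.hemisphere not in HEMISPHERES:
                raise ValueError(f"bad hemisphere {region.hemisphere!r}")
            if not region.name:
                raise ValueError("empty region name")
            if region.label_code <= 0:
                raise ValueError("label_code must be positive")
        except (KeyError, TypeError, ValueError) as exc:
            raise AtlasError(f"atlas row {lineno} is malformed: {exc}") from exc
        regions.append(region)
    return RegionAtlas(tuple(regions))


@dataclass
class VolumeTable:
    """Subjects × regions matrix of regional volumes (mm³).

    ``workflow`` tags the skull-stripping/preprocessing variant that produced
    the volumes (conventionally ``BET``, ``iBEAT`` or ``iBEAT_corrected``);
    ``measurement_id`` distinguishes repeated measurements of the same
    subjects for the test–retest analyses.
    """

    subject_ids: list[str]
    region_names: list[str]
    values: np.ndarray
    workflow: str = "unspecified"
    measurement_id: int = 1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n_sub, n_reg = len(self.subject_ids), len(self.region_names)
        if self.values.shape != (n_sub, n_reg):
            raise VolumeTableError(
                f"values shape {self.values.shape} does not match "
                f"{n_sub} subjects × {n_reg} regions"
            )
        if len(set(self.subject_ids)) != n_sub:
            raise VolumeTableError("duplicate subject ids")
        if len(set(self.region_names)) != n_reg:
            raise VolumeTableError("duplicate region names")
        if not np.all(np.isfinite(self.values)):
            raise VolumeTableError("volumes must be finite")
        if np.any(self.values <= 0):
            i, j = np.argwhere(self.values <= 0)[0]
            raise VolumeTableError(
                f"volumes must be strictly positive; subject "
                f"{self.subject_ids[i]!r}, region {self.region_names[j]!r} "
                f"has value {self.values[i, j]}"
            )
        if self.measurement_id < 1:
            raise VolumeTableError("measurement_id must be >= 1")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_regions(self) -> int:
        return len(self.region_names)


@dataclass
class RegistrationFixture:
    """Inputs of the atlas-based regional volume estimate for one subject.

    Holds the template-space label map (with voxel size in mm per axis), the
    rigid and affine 4×4 transform matrices mapping the individual to the
    template, and the Jacobian-determinant field of the nonlinear warp,
    sampled on the label-map grid.
    """

    label_map: np.ndarray
    voxel_size: tuple[float, float, float]
    rigid: np.ndarray
    affine: np.ndarray
    jacobian: np.ndarray

    def __post_init__(self) -> None:
        self.label_map = np.asarray(self.label_map)
        self.rigid = np.asarray(self.rigid, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        self.jacobian = np.asarray(self.jacobian, dtype=float)
        if self.label_map.ndim != 3:
            raise ValueError("label_map must be a 3-D array")
        if not np.issubdtype(self.label_map.dtype, np.integer):
            raise ValueError("label_map must be integer-valued")
        if self.jacobian.shape != self.label_map.shape:
            raise ValueError("jacobian must be congruent to label_map")
        if np.any(self.jacobian <= 0):
            raise ValueError("jacobian must be strictly positive everywhere")
        for name, mat in (("rigid", self.rigid), ("affine", self.affine)):
            if mat.shape != (4, 4):
                raise ValueError(f"{name} transform must be 4×4")
        det = np.linalg.det(self.rigid[:3, :3])
        if abs(abs(det) - 1.0) > 1e-6:
            raise ValueError(
                f"rigid 3×3 sub-matrix must be a rotation (|det|=1), got det={det}"
            )
        if any(v <= 0 for v in self.voxel_size) or len(self.voxel_size) != 3:
            raise ValueError("voxel_size must be three positive lengths (mm)")

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.voxel_size))

    def validate_against(self, atlas: RegionAtlas) -> None:
        """Check label-map codes ⊆ atlas label codes ∪ {0 = background}."""
        codes = set(np.unique(self.label_map).tolist())
        extra = codes - set(atlas.label_codes) - {0}
        if extra:
            raise ValueError(f"label map contains non-atlas codes: {sorted(extra)}")


@dataclass
class BrainNetwork:
    """Group-level structural covariance network over atlas nodes.

    ``weights`` is the symmetric partial-correlation matrix (zero diagonal);
    ``adjacency`` maps each sparsity level to its binarized adjacency.
    """

    node_names: list[str]
    weights: np.ndarray
    adjacency: dict[float, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        n = len(self.node_names)
        if self.weights.shape != (n, n):
            raise ValueError("weights must be square over the node list")
        if not np.allclose(self.weights, self.weights.T, atol=1e-10):
            raise ValueError("weights must be symmetric")
        if np.any(np.abs(np.diag(self.weights)) > 0):
            raise ValueError("weight diagonal must be exactly zero")
        if np.any(np.abs(self.weights) > 1 + 1e-12):
            raise ValueError("|weights| must be <= 1")
        for s, a in self.adjacency.items():
            _check_adjacency(a, n, s)

    @property
    def n_nodes(self) -> int:
        return len(self.node_names)

    @property
    def sparsities(self) -> list[float]:
        return sorted(self.adjacency)


def _check_adjacency(a: np.ndarray, n: int, s: float) -> None:
    if a.shape != (n, n):
        raise ValueError(f"adjacency at sparsity {s} has shape {a.shape}")
    if not np.array_equal(a, a.T):
        raise ValueError(f"adjacency at sparsity {s} is not symmetric")
    if not np.isin(a, (0, 1)).all():
        raise ValueError(f"adjacency at sparsity {s} is not binary")
    if np.any(np.diag(a) != 0):
        raise ValueError(f"adjacency at sparsity {s} has nonzero diagonal")


@dataclass
class SparsityMetrics:
    """Graph metrics of one binarized network plus its random-network nulls."""

    cp: float
    lp: float
    eglob: float
    eloc: float
    disconnected: bool = False
    crand: float | None = None
    lrand: float | None = None
    gamma: float | None = None
    lam: float | None = None
    small_world: bool | None = None


@dataclass
class MetricReport:
    """Per-sparsity metrics, range-integrated AUCs and small-world verdicts."""

    per_sparsity: dict[float, SparsityMetrics]
    auc: dict[str, float] = field(default_factory=dict)
    small_world_overall: bool | None = None

    @property
    def sparsities(self) -> list[float]:
        return sorted(self.per_sparsity)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_volume_table(
    path: str | Path,
    atlas: RegionAtlas,
    workflow: str = "unspecified",
    measurement_id: int = 1,
) -> VolumeTable:
    """Read a volume-table CSV and reorder its columns to atlas order.

    The file must have a ``subject_id`` first column followed by one column
    per atlas region.  Missing or unknown region columns, non-numeric or
    non-positive volumes, and duplicate subject ids are rejected with the
    offending row/column named.
    """
    import pandas as pd

    df = pd.read_csv(path)
    if df.columns[0] != "subject_id":
        raise VolumeTableError(
            f"first column must be 'subject_id', got {df.columns[0]!r}"
        )
    file_cols = list(df.columns[1:])
    expected = atlas.column_names
    unknown = sorted(set(file_cols) - set(expected))
    if unknown:
        raise VolumeTableError(f"columns not in atlas: {unknown}")
    missing = sorted(set(expected) - set(file_cols))
    if missing:
        raise VolumeTableError(f"missing region columns: {missing}")
    df = df.set_index("subject_id")[expected]
    for col in expected:
        if not pd.api.types.is_numeric_dtype(df[col]):
            raise VolumeTableError(f"non-numeric volume in column {col!r}")
    return VolumeTable(
        subject_ids=[str(s) for s in df.index],
        region_names=expected,
        values=df.to_numpy(dtype=float),
        workflow=workflow,
        measurement_id=measurement_id,
    )


def write_volume_table(table: VolumeTable, path: str | Path) -> None:
    """Write a volume table as CSV (12 significant digits)."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["subject_id", *table.region_names])
        for sid, row in zip(table.subject_ids, table.values):
            writer.writerow([sid, *(FLOAT_FORMAT % v for v in row)])


def write_network(net: BrainNetwork, directory: str | Path) -> None:
    """Write weights and per-sparsity adjacency matrices as CSV files."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    _write_matrix(net.weights, net.node_names, directory / "weights.csv")
    for s in net.sparsities:
        _write_matrix(
            net.adjacency[s], net.node_names, directory / f"adjacency_{s:g}.csv"
        )


def read_network(directory: str | Path) -> BrainNetwork:
    directory = Path(directory)
    names, weights = _read_matrix(directory / "weights.csv")
    adjacency = {}
    for p in sorted(directory.glob("adjacency_*.csv")):
        s = float(p.stem.split("_", 1)[1])
        adjacency[s] = _read_matrix(p)[1].astype(int)
    return BrainNetwork(node_names=names, weights=weights, adjacency=adjacency)


def _write_matrix(mat: np.ndarray, names: Sequence[str], path: Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["node", *names])
        for name, row in zip(names, np.asarray(mat)):
            writer.writerow([name, *(FLOAT_FORMAT % v for v in row)])


def _read_matrix(path: Path) -> tuple[list[str], np.ndarray]:
    with open(path, encoding="utf-8", newline="") as fh:
        rows = list(csv.reader(fh))
    names = rows[0][1:]
    mat = np.array([[float(v) for v in r[1:]] for r in rows[1:]])
    return names, mat


def write_metrics(report: MetricReport, path: str | Path) -> None:
    """Write a metric report as JSON, one entry per sparsity level."""
    payload = {
        "per_sparsity": {
            f"{s:g}": vars(report.per_sparsity[s]) for s in report.sparsities
        },
        "auc": report.auc,
        "small_world_overall": report.small_world_overall,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, allow_nan=True)


def read_metrics(path: str | Path) -> MetricReport:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    per = {
        float(s): SparsityMetrics(**vals)
        for s, vals in payload["per_sparsity"].items()
    }
    return MetricReport(
        per_sparsity=per,
        auc=payload.get("auc", {}),
        small_world_overall=payload.get("small_world_overall"),
    )


def write_transform(matrix: np.ndarray, path: str | Path) -> None:
    """Write a 4×4 transform as 4 lines of 4 row-major numbers."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape != (4, 4):
        raise ValueError("transform must be 4×4")
    with open(path, "w", encoding="utf-8") as fh:
        for row in matrix:
            fh.write(" ".join(FLOAT_FORMAT % v for v in row) + "\n")


def read_transform(path: str | Path) -> np.ndarray:
    rows = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                rows.append([float(v) for v in line.split()])
    mat = np.array(rows, dtype=float)
    if mat.shape != (4, 4):
        raise ValueError(f"{path}: expected 4 lines of 4 numbers, got {mat.shape}")
    return mat


def write_registration_fixture(
    fixture: RegistrationFixture, directory: str | Path
) -> None:
    """Write label map + Jacobian as NIfTI and transforms as plain text."""
    import nibabel as nib

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    vox = np.diag([*fixture.voxel_size, 1.0])
    nib.save(
        nib.Nifti1Image(fixture.label_map.astype(np.int32), vox),
        directory / "label_map.nii.gz",
    )
    nib.save(
        nib.Nifti1Image(fixture.jacobian.astype(np.float64), vox),
        directory / "jacobian.nii.gz",
    )
    write_transform(fixture.rigid, directory / "rigid.txt")
    write_transform(fixture.affine, directory / "affine.txt")


def read_registration_fixture(directory: str | Path) -> RegistrationFixture:
    import nibabel as nib

    directory = Path(directory)
    label_img = nib.load(directory / "label_map.nii.gz")
    jac_img = nib.load(directory / "jacobian.nii.gz")
    voxel_size = tuple(float(z) for z in label_img.header.get_zooms()[:3])
    return RegistrationFixture(
        label_map=np.asarray(label_img.dataobj).astype(np.int64),
        voxel_size=voxel_size,  # type: ignore[arg-type]
        rigid=read_transform(directory / "rigid.txt"),
        affine=read_transform(directory / "affine.txt"),
        jacobian=np.asarray(jac_img.dataobj, dtype=float),
    )
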