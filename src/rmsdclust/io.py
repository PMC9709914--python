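"""Trajectory loading, atom selection, matrix caching, and the pipeline.

Frame indexing is 0-based internally and reported 1-based in the
human-readable tables (noted in their headers).  Coordinates are nm
internally; mdtraj already delivers nm for PDB/DCD/XTC input.

The matrix cache has two variants sharing a header (N, n_atoms, mode,
selection):

* text — header comment lines followed by the upper triangle, row-major,
  full double precision;
* binary — an ``.npz`` holding the full float64 matrix plus the header
  fields; round-trips bit-exactly.
"""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .clustering import Threshold, ThresholdClustering, ThresholdKind
from .geometry import (
    ConfigurationEnsemble,
    MatrixMode,
    RmsdMatrix,
    pairwise_rmsd_matrix,
)

__all__ = [
    "AtomSelection",
    "RunConfig",
    "load_ensemble",
    "read_coordinate_table",
    "write_coordinate_table",
    "write_matrix_cache",
    "read_matrix_cache",
    "run_pipeline",
]

ANGSTROM_TO_NM = 0.1


@dataclass(frozen=True)
class AtomSelection:
    """Residue range plus atom names, resolving to an ordered atom list.

    ``first_residue``/``last_residue`` are inclusive residue sequence
    numbers as they appear in the PDB; ``atom_names`` is e.g.
    ``("N", "H", "CA", "C", "O")`` for the peptide backbone.
    """

    first_residue: int
    last_residue: int
    atom_names: tuple[str, ...] = ("N", "H", "CA", "C", "O")

    def __post_init__(self) -> None:
        object.__setattr__(self, "atom_names", tuple(self.atom_names))
        if self.last_residue < self.first_residue:
            raise ValueError("last_residue must be >= first_residue")
        if not self.atom_names:
            raise ValueError("atom_names must be nonempty")

    def resolve(self, topology) -> tuple[list[int], list[tuple[int, str]]]:
        """Indices and (residue id, atom name) labels in topology order."""
        wanted = set(self.atom_names)
        indices: list[int] = []
        labels: list[tuple[int, str]] = []
        for atom in topology.atoms:
            resseq = atom.residue.resSeq
            if self.first_residue <= resseq <= self.last_residue and atom.name in wanted:
                indices.append(atom.index)
                labels.append((resseq, atom.name))
        if not indices:
            raise ValueError(
                f"selection matched no atoms: residues "
                f"{self.first_residue}..{self.last_residue}, names {self.atom_names}"
            )
        return indices, labels

    def describe(self) -> str:
        return (
            f"residues {self.first_residue}-{self.last_residue} "
            f"atoms {','.join(self.atom_names)}"
        )


def load_ensemble(
    topology: str | Path,
    trajectory: str | Path | None = None,
    selection: AtomSelection | None = None,
) -> ConfigurationEnsemble:
    """Load a trajectory (PDB/DCD/XTC) into an ensemble, in nm.

    ``topology`` is a PDB; ``trajectory`` defaults to the topology itself
    (single- or multi-model PDB).  Frame order is preserved.
    """
    import mdtraj

    topology = str(topology)
    if trajectory is None:
        traj = mdtraj.load(topology)
    else:
        traj = mdtraj.load(str(trajectory), top=topology)
    if selection is not None:
        indices, labels = selection.resolve(traj.topology)
    else:
        indices = list(range(traj.n_atoms))
        labels = [(a.residue.resSeq, a.name) for a in traj.topology.atoms]
    coords = np.asarray(traj.xyz[:, indices, :], dtype=np.float64)  # mdtraj: nm
    return ConfigurationEnsemble(coords=coords, atom_labels=labels)


# ---------------------------------------------------------------------------
# plain coordinate table


def write_coordinate_table(path: str | Path, ensemble: ConfigurationEnsemble) -> None:
    """Write an ensemble as a whitespace table: one frame per row, n columns."""
    flat = ensemble.coords.reshape(ensemble.n_frames, -1)
    header = (
        f"rmsdclust coordinate table v1\n"
        f"n_frames={ensemble.n_frames} n_atoms={ensemble.n_atoms} "
        f"ndim={ensemble.ndim} units=nm"
    )
    np.savetxt(path, flat, header=header, fmt="%.17g")


def read_coordinate_table(path: str | Path) -> ConfigurationEnsemble:
    with open(path) as fh:
        meta_line = ""
        for line in fh:
            if line.startswith("#") and "n_atoms=" in line:
                meta_line = line
                break
    fields = dict(
        kv.split("=") for kv in meta_line.strip("# \n").split() if "=" in kv
    )
    n_atoms = int(fields["n_atoms"])
    ndim = int(fields.get("ndim", 3))
    flat = np.loadtxt(path, ndmin=2)
    return ConfigurationEnsemble(coords=flat.reshape(len(flat), n_atoms, ndim))


# ---------------------------------------------------------------------------
# matrix cache


def write_matrix_cache(
    path: str | Path,
    matrix: RmsdMatrix,
    n_atoms: int,
    selection: str = "",
    binary: bool | None = None,
) -> None:
    """Write the matrix cache; ``.npz`` paths get the binary variant."""
    path = Path(path)
    if binary is None:
        binary = path.suffix == ".npz"
    if binary:
        np.savez(
            path,
            values=matrix.values,
            n=np.int64(matrix.n),
            n_atoms=np.int64(n_atoms),
            mode=np.bytes_(matrix.mode.value.encode()),
            selection=np.bytes_(selection.encode()),
        )
        return
    iu = np.triu_indices(matrix.n, k=1)
    header = (
        f"rmsdclust matrix cache v1\n"
        f"N={matrix.n} n_atoms={n_atoms} mode={matrix.mode.value}\n"
        f"selection={selection}\n"
        f"upper triangle, row-major, nm"
    )
    np.savetxt(path, matrix.values[iu][None, :] if matrix.n > 1 else np.empty((1, 0)),
               header=header, fmt="%.17g")


def read_matrix_cache(path: str | Path) -> tuple[RmsdMatrix, int, str]:
    """Read either cache variant; returns (matrix, n_atoms, selection)."""
    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path) as data:
            values = data["values"]
            n_atoms = int(data["n_atoms"])
            mode = MatrixMode(bytes(data["mode"]).decode())
            selection = bytes(data["selection"]).decode()
        return RmsdMatrix(values=values, mode=mode), n_atoms, selection
    meta: dict[str, str] = {}
    selection = ""
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.strip("# \n")
            if body.startswith("selection="):
                selection = body[len("selection="):]
            else:
                meta.update(
                    kv.split("=", 1) for kv in body.split() if "=" in kv
                )
    n = int(meta["N"])
    n_atoms = int(meta["n_atoms"])
    mode = MatrixMode(meta["mode"])
    tri = np.loadtxt(path, ndmin=2).ravel()
    values = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    if tri.size != iu[0].size:
        raise ValueError(
            f"cache claims N={n} but holds {tri.size} upper-triangle entries"
        )
    values[iu] = tri
    values = values + values.T
    return RmsdMatrix(values=values, mode=mode), n_atoms, selection


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class RunConfig:
    """Configuration for one end-to-end clustering run."""

    algorithm: str  # "rtc" | "qtc"
    threshold: float
    min_size: int = 1
    mode: MatrixMode | str = MatrixMode.PAIRWISE_FIT
    topology: str | None = None
    trajectory: str | None = None
    coordinate_table: str | None = None
    selection: AtomSelection | None = None
    output_dir: str = "."
    matrix_cache: str | None = None
    n_profiles: int = 6
    size_cutoffs: tuple[int, ...] = (10, 100)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ("rtc", "qtc"):
            raise ValueError("algorithm must be 'rtc' or 'qtc'")
        self.mode = MatrixMode(self.mode)

    @property
    def threshold_obj(self) -> Threshold:
        kind = (
            ThresholdKind.RADIAL if self.algorithm == "rtc" else ThresholdKind.DIAMETRAL
        )
        return Threshold(self.threshold, kind)


def _input_digest(config: RunConfig) -> str:
    h = hashlib.sha256()
    for p in (config.topology, config.trajectory, config.coordinate_table):
        if p:
            h.update(Path(p).read_bytes())
    sel = config.selection.describe() if config.selection else "all"
    h.update(sel.encode())
    h.update(MatrixMode(config.mode).value.encode())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Load -> matrix (cached by content digest) -> cluster -> diagnostics.

    Writes the assignment, summary, coverage and per-seed-profile TSVs plus
    a JSON log of parameters, input digests and library versions into
    ``config.output_dir``.  Returns the in-memory artifacts.
    """
    from . import __version__, diagnostics

    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.coordinate_table:
        ensemble = read_coordinate_table(config.coordinate_table)
    elif config.topology:
        ensemble = load_ensemble(config.topology, config.trajectory, config.selection)
    else:
        raise ValueError("config needs a coordinate table or a topology")

    digest = _input_digest(config)
    matrix = None
    if config.matrix_cache and Path(config.matrix_cache).exists():
        digest_file = Path(str(config.matrix_cache) + ".digest")
        if digest_file.exists() and digest_file.read_text().strip() == digest:
            matrix, _, _ = read_matrix_cache(config.matrix_cache)
        else:
            print(
                "warning: matrix cache digest mismatch; recomputing", file=sys.stderr
            )
    if matrix is None:
        matrix = pairwise_rmsd_matrix(ensemble, mode=config.mode)
        if config.matrix_cache:
            write_matrix_cache(
                config.matrix_cache,
                matrix,
                ensemble.n_atoms,
                selection=config.selection.describe() if config.selection else "all",
            )
            Path(str(config.matrix_cache) + ".digest").write_text(digest)

    model = ThresholdClustering(
        matrix, config.threshold_obj, min_size=config.min_size, ensemble=ensemble
    )
    res = model.fit()

    param_header = (
        f"# rmsdclust v{__version__}\n"
        f"# algorithm={config.algorithm} threshold={config.threshold} "
        f"min_size={config.min_size} mode={MatrixMode(config.mode).value}\n"
        f"# frame ids and seed frames are 1-based; cluster rank 0 = unassigned\n"
    )

    assign = res.assignment_frame()
    assign["frame_id"] = assign["frame_id"] + 1  # 1-based in reports
    _write_tsv(outdir / "assignments.tsv", assign, param_header)

    summary = res.summary_frame(max_rows=None)
    summary["seed_frame"] = summary["seed_frame"] + 1
    _write_tsv(outdir / "clusters.tsv", summary, param_header)

    coverage = res.coverage(config.size_cutoffs)
    _write_tsv(outdir / "coverage.tsv", coverage, param_header)

    profiles = []
    for c in res.clusters[: config.n_profiles]:
        prof = diagnostics.seed_profile(matrix, c.seed)
        profiles.append(prof)
        table = pd.DataFrame({"rmsd": np.sort(prof.distances)})
        _write_tsv(
            outdir / f"seed_profile_rank{c.rank}.tsv",
            table,
            param_header + f"# seed_frame={c.seed + 1}\n",
        )

    log = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "config": {
            "algorithm": config.algorithm,
            "threshold": config.threshold,
            "min_size": config.min_size,
            "mode": MatrixMode(config.mode).value,
            "selection": config.selection.describe() if config.selection else "all",
            "rng_seed": config.rng_seed,
        },
        "input_digest": digest,
        "n_frames": ensemble.n_frames,
        "n_atoms": ensemble.n_atoms,
        "n_clusters": res.n_clusters,
        "n_unassigned": len(res.unassigned),
    }
    (outdir / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True))
    return {"ensemble": ensemble, "matrix": matrix, "results": res,
            "profiles": profiles}


def _write_tsv(path: Path, frame: pd.DataFrame, header: str) -> None:
    with open(path, "w") as fh:
        fh.write(header)
        frame.to_csv(fh, sep="\t", index=False)
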