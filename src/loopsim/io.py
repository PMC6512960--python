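"""File I/O: barrier tables (BED-like TSV), HDF5 trajectories and ensembles,
TSV/NPZ contact maps, and TSV observable tables.

Barrier tables are 4+ column TSV: chrom, start, end, strand, [strength].
Strand ``+`` maps to a leftward-blocking barrier (an inward-pointing motif at
a left TAD boundary halts legs extruding leftward toward it) and ``-`` to
rightward-blocking; the optional 5th column is the barrier strength (default
1.0).  Genomic intervals are half-open, 0-based; the barrier site is the
lattice site containing the interval midpoint.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

from .errors import ConfigError
from .lef_engine import (
    LEFTWARD,
    RIGHTWARD,
    Barrier,
    LEFTrajectory,
    SimConfig1D,
)
from .observables import ContactMap, PsCurve
from .polymer import CouplingSchedule, Ensemble, ForceField

_STRAND_TO_DIRECTION = {"+": LEFTWARD, "-": RIGHTWARD}
_DIRECTION_TO_STRAND = {LEFTWARD: "+", RIGHTWARD: "-"}


def read_barriers_bed(path, site_size: float) -> list[Barrier]:
    """Read barriers from a BED-like TSV (chrom, start, end, strand[, strength]).

    ``site_size`` is in kb; start/end are in bp.  Malformed lines raise
    :class:`ConfigError` naming the offending line number.
    """
    barriers = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ConfigError(
                    f"{path}: line {lineno}: expected >= 4 tab-separated columns "
                    f"(chrom, start, end, strand), got {len(fields)}"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ConfigError(
                    f"{path}: line {lineno}: start/end are not integers"
                ) from None
            strand = fields[3]
            if strand not in _STRAND_TO_DIRECTION:
                raise ConfigError(
                    f"{path}: line {lineno}: strand must be '+' or '-', "
                    f"got {strand!r}"
                )
            strength = 1.0
            if len(fields) >= 5 and fields[4] not in (".", ""):
                try:
                    strength = float(fields[4])
                except ValueError:
                    raise ConfigError(
                        f"{path}: line {lineno}: strength is not a number"
                    ) from None
            site = int(((start + end) // 2) // (site_size * 1000))
            try:
                barriers.append(
                    Barrier(
                        site=site,
                        blocked_direction=_STRAND_TO_DIRECTION[strand],
                        strength=strength,
                    )
                )
            except ConfigError as e:
                raise ConfigError(f"{path}: line {lineno}: {e}") from None
    return barriers


def write_barriers_bed(
    path, barriers: Sequence[Barrier], site_size: float, chrom: str = "chrSim"
) -> None:
    with open(path, "w") as fh:
        for b in sorted(barriers, key=lambda b: b.site):
            start = int(b.site * site_size * 1000)
            end = int((b.site + 1) * site_size * 1000)
            fh.write(
                f"{chrom}\t{start}\t{end}\t"
                f"{_DIRECTION_TO_STRAND[b.blocked_direction]}\t{b.strength:g}\n"
            )


# ---------------------------------------------------------------------------
# HDF5 containers
# ---------------------------------------------------------------------------


def _config_json(config: SimConfig1D) -> str:
    return json.dumps(dataclasses.asdict(config))


def save_trajectory(path, traj: LEFTrajectory) -> None:
    """Write a 1D trajectory as HDF5 with the config embedded as JSON."""
    with h5py.File(path, "w") as f:
        f.create_dataset("frames", data=traj.frames)
        f.create_dataset("times", data=traj.times)
        f.create_dataset("loop_records", data=traj.loop_records)
        f.attrs["config"] = _config_json(traj.config)
        f.attrs["barriers"] = json.dumps(
            [dataclasses.asdict(b) for b in traj.barriers]
        )


def load_trajectory(path) -> LEFTrajectory:
    with h5py.File(path, "r") as f:
        return LEFTrajectory(
            frames=f["frames"][:],
            times=f["times"][:],
            loop_records=f["loop_records"][:],
            config=SimConfig1D(**json.loads(f.attrs["config"])),
            barriers=tuple(
                Barrier(**b) for b in json.loads(f.attrs["barriers"])
            ),
        )


def save_ensemble(path, ensemble: Ensemble) -> None:
    """Write a conformational ensemble as HDF5 with generating configs."""
    with h5py.File(path, "w") as f:
        f.create_dataset("conformations", data=ensemble.coordinates)
        f.attrs["monomer_size"] = ensemble.monomer_size
        if ensemble.seed is not None:
            f.attrs["seed"] = ensemble.seed
        if ensemble.config1d is not None:
            f.attrs["config1d"] = _config_json(ensemble.config1d)
        if ensemble.forcefield is not None:
            f.attrs["forcefield"] = json.dumps(dataclasses.asdict(ensemble.forcefield))
        if ensemble.schedule is not None:
            f.attrs["schedule"] = json.dumps(dataclasses.asdict(ensemble.schedule))


def load_ensemble(path) -> Ensemble:
    with h5py.File(path, "r") as f:
        return Ensemble(
            coordinates=f["conformations"][:],
            monomer_size=float(f.attrs["monomer_size"]),
            seed=int(f.attrs["seed"]) if "seed" in f.attrs else None,
            config1d=(
                SimConfig1D(**json.loads(f.attrs["config1d"]))
                if "config1d" in f.attrs
                else None
            ),
            forcefield=(
                ForceField(**json.loads(f.attrs["forcefield"]))
                if "forcefield" in f.attrs
                else None
            ),
            schedule=(
                CouplingSchedule(**json.loads(f.attrs["schedule"]))
                if "schedule" in f.attrs
                else None
            ),
        )


def write_xyz(path, ensemble: Ensemble) -> None:
    """Plain-text XYZ export (one model per conformation) for viewers."""
    with open(path, "w") as fh:
        for xyz in ensemble.coordinates:
            fh.write(f"{len(xyz)}\nloopsim conformation\n")
            for p in xyz:
                fh.write(f"C {p[0]:.4f} {p[1]:.4f} {p[2]:.4f}\n")


# ---------------------------------------------------------------------------
# Contact maps and observable tables
# ---------------------------------------------------------------------------


def save_contact_map_tsv(path, cmap: ContactMap) -> None:
    header = (
        f"# bin_size_kb={cmap.bin_size:g} contact_radius={cmap.contact_radius:g} "
        f"n_conformations={cmap.n_conformations} monomer_size_kb={cmap.monomer_size:g}"
    )
    np.savetxt(path, cmap.matrix, fmt="%.6g", delimiter="\t", header=header)


def load_contact_map_tsv(path) -> ContactMap:
    meta = {}
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#"):
        for tok in first[1:].split():
            if "=" in tok:
                k, v = tok.split("=", 1)
                meta[k] = float(v)
    matrix = np.loadtxt(path, delimiter="\t")
    return ContactMap(
        matrix=matrix,
        bin_size=meta.get("bin_size_kb", 10.0),
        contact_radius=meta.get("contact_radius", 2.0),
        n_conformations=int(meta.get("n_conformations", 1)),
        monomer_size=meta.get("monomer_size_kb", 10.0),
    )


def save_contact_map_npz(path, cmap: ContactMap) -> None:
    np.savez(
        path,
        matrix=cmap.matrix,
        bin_size=cmap.bin_size,
        contact_radius=cmap.contact_radius,
        n_conformations=cmap.n_conformations,
        monomer_size=cmap.monomer_size,
    )


def load_contact_map_npz(path) -> ContactMap:
    d = np.load(path)
    return ContactMap(
        matrix=d["matrix"],
        bin_size=float(d["bin_size"]),
        contact_radius=float(d["contact_radius"]),
        n_conformations=int(d["n_conformations"]),
        monomer_size=float(d["monomer_size"]),
    )


def save_ps_tsv(path, curve: PsCurve) -> None:
    df = pd.DataFrame(
        {"separation_kb": curve.bin_centers, "contact_probability": curve.prob}
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.8g")


def load_ps_tsv(path) -> PsCurve:
    df = pd.read_csv(path, sep="\t")
    centers = df["separation_kb"].to_numpy()
    edges = np.concatenate([[centers[0]], np.sqrt(centers[:-1] * centers[1:]), [centers[-1]]])
    return PsCurve(
        bin_centers=centers,
        prob=df["contact_probability"].to_numpy(),
        bin_edges=edges,
    )


def save_feature_table(path, rows: Sequence[dict]) -> None:
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_insulation_minima_bed(
    path, minima_bins: np.ndarray, bin_size: float, chrom: str = "chrSim"
) -> None:
    with open(path, "w") as fh:
        for i in np.asarray(minima_bins, dtype=int):
            start = int(i * bin_size * 1000)
            end = int((i + 1) * bin_size * 1000)
            fh.write(f"{chrom}\t{start}\t{end}\tinsulation_minimum\n")
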