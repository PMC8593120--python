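"""File formats: GRO/PDB coordinates, window timeseries, manifests, PMFs.

Coordinate files are parsed through MDAnalysis (GRO fixed-column, PDB) and
converted to nm at this boundary; bead classes are assigned by ordered
match rules over residue and atom names.  Timeseries and PMF files are
self-describing columnar text with ``# key: value`` headers, lossless at
10 significant digits; a JSON manifest ties a set of window files
together for the WHAM stage.
"""

from __future__ import annotations

import ast
import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .chain_coordinate import (BeadClass, Configuration, bead_class_from_name)
from .pmf import PMFProfile, WindowSample

TIMESERIES_MAGIC = "# memstalk timeseries v1"
PMF_MAGIC = "# memstalk pmf v1"


class FileFormatError(ValueError):
    pass


@dataclass(frozen=True)
class ClassRule:
    """Ordered match rule: first rule whose predicates all hold applies."""

    bead_class: BeadClass
    resname: Optional[str] = None
    name_prefix: Optional[str] = None

    def matches(self, resname: str, atomname: str) -> bool:
        if self.resname is not None and resname != self.resname:
            return False
        if self.name_prefix is not None and \
                not atomname.startswith(self.name_prefix):
            return False
        return True


DEFAULT_CLASS_RULES = (
    ClassRule(BeadClass.SOLVENT, resname="SOL"),
    ClassRule(BeadClass.SOLVENT, resname="W"),
    ClassRule(BeadClass.APOLAR_TAIL, name_prefix="T"),
    ClassRule(BeadClass.APOLAR_TAIL, name_prefix="C"),
    ClassRule(BeadClass.HEADGROUP, name_prefix="H"),
)


def classify_beads(resnames, atomnames,
                   rules: Sequence[ClassRule] = DEFAULT_CLASS_RULES):
    out = np.full(len(resnames), int(BeadClass.OTHER), dtype=np.int64)
    for i, (rn, an) in enumerate(zip(resnames, atomnames)):
        for rule in rules:
            if rule.matches(rn, an):
                out[i] = int(rule.bead_class)
                break
    return out


def read_coordinates(path, fmt: Optional[str] = None,
                     rules: Sequence[ClassRule] = DEFAULT_CLASS_RULES
                     ) -> Configuration:
    """Parse a GRO or PDB file into a Configuration (positions in nm)."""
    import MDAnalysis as mda
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    if fmt not in ("gro", "pdb"):
        raise FileFormatError(f"unsupported coordinate format {fmt!r}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            u = mda.Universe(str(path), format=fmt)
        except Exception as exc:
            raise FileFormatError(
                f"malformed {fmt.upper()} file {path}: {exc}") from exc
    dims = u.dimensions
    if dims is None or not np.all(np.asarray(dims[:3]) > 0):
        raise FileFormatError(f"{path}: missing or invalid box record")
    pos_nm = u.atoms.positions / 10.0
    box_nm = np.asarray(dims[:3], dtype=float) / 10.0
    resnames = [a.resname for a in u.atoms]
    names = [a.name for a in u.atoms]
    classes = classify_beads(resnames, names, rules)
    return Configuration(pos_nm, box_nm, classes, np.array(resnames))


def write_coordinates(config: Configuration, path, names=None):
    """Write a Configuration to GRO or PDB (1-based serials, Å converted)."""
    import MDAnalysis as mda
    path = Path(path)
    n = config.n_beads
    u = mda.Universe.empty(n, n_residues=n, atom_resindex=np.arange(n),
                           trajectory=True)
    u.add_TopologyAttr("names", names if names is not None
                       else [_default_atom_name(c) for c in config.bead_class])
    u.add_TopologyAttr("resnames", list(config.species))
    u.add_TopologyAttr("resids", np.arange(1, n + 1))
    u.atoms.positions = config.positions * 10.0
    u.dimensions = [*(config.box * 10.0), 90.0, 90.0, 90.0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(path))
    return path


def _default_atom_name(class_code: int) -> str:
    return {int(BeadClass.APOLAR_TAIL): "T1",
            int(BeadClass.HEADGROUP): "H1",
            int(BeadClass.SOLVENT): "W1"}.get(int(class_code), "X1")


# ---------------------------------------------------------------------------
# columnar timeseries / PMF files

def _meta_repr(v):
    if v is None or isinstance(v, (bool, str)):
        return repr(v)
    if isinstance(v, (int, np.integer)):
        return repr(int(v))
    return repr(float(v))


def write_timeseries(path, times, xi, meta: dict):
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(TIMESERIES_MAGIC + "\n")
        fh.write("# units: time=ps xi=dimensionless\n")
        for key in sorted(meta):
            fh.write(f"# {key}: {_meta_repr(meta[key])}\n")
        for t, x in zip(times, xi):
            fh.write(f"{t:.10g} {x:.10g}\n")
    return path


def read_timeseries(path):
    """Returns (times, xi, meta).  Headerless two-column files are accepted
    with a warning and empty metadata."""
    path = Path(path)
    meta = {}
    rows = []
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
        has_header = first.strip() == TIMESERIES_MAGIC
        if not has_header:
            warnings.warn(f"{path}: no header; treating as legacy "
                          "two-column timeseries with default metadata")
            if first.strip() and not first.startswith("#"):
                rows.append([float(v) for v in first.split()])
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if ":" in line:
                    key, _, val = line.lstrip("# ").partition(":")
                    key = key.strip()
                    if key != "units":
                        try:
                            meta[key] = ast.literal_eval(val.strip())
                        except Exception:
                            meta[key] = val.strip()
                continue
            rows.append([float(v) for v in line.split()])
    if not rows:
        raise FileFormatError(f"{path}: no data rows")
    arr = np.asarray(rows, dtype=float)
    if arr.shape[1] < 2:
        raise FileFormatError(f"{path}: need at least two columns")
    return arr[:, 0], arr[:, 1], meta


def write_window(path, sample: WindowSample):
    meta = {"xi0": sample.xi0, "kappa": sample.kappa,
            "temperature": sample.temperature, "seed": sample.seed,
            "n_equil": sample.n_equil}
    times = (sample.times if sample.times is not None
             else np.arange(len(sample.series), dtype=float))
    return write_timeseries(path, times, sample.series, meta)


def write_manifest(path, window_files, samples):
    entries = [{"file": str(Path(f).name), "xi0": float(s.xi0),
                "kappa": float(s.kappa),
                "temperature": float(s.temperature)}
               for f, s in zip(window_files, samples)]
    path = Path(path)
    path.write_text(json.dumps({"format": "memstalk-windows-v1",
                                "windows": entries}, indent=1),
                    encoding="utf-8")
    return path


def read_windows(manifest_path):
    """Load all windows listed in a manifest into WindowSample objects."""
    manifest_path = Path(manifest_path)
    doc = json.loads(manifest_path.read_text(encoding="utf-8"))
    samples = []
    for entry in doc["windows"]:
        fpath = manifest_path.parent / entry["file"]
        if not fpath.exists():
            raise FileFormatError(
                f"manifest references missing window file {entry['file']}")
        times, xi, meta = read_timeseries(fpath)
        for key in ("xi0", "kappa"):
            if key in meta and abs(float(meta[key]) - float(entry[key])) > 1e-9:
                raise FileFormatError(
                    f"{fpath}: header {key}={meta[key]} disagrees with "
                    f"manifest value {entry[key]}")
        samples.append(WindowSample(
            xi0=float(entry["xi0"]), kappa=float(entry["kappa"]),
            series=xi, times=times,
            temperature=float(entry.get("temperature",
                                        meta.get("temperature", 310.0))),
            seed=meta.get("seed")))
    return samples


def write_pmf(path, profile: PMFProfile, settings: Optional[dict] = None):
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(PMF_MAGIC + "\n")
        fh.write("# units: xi=dimensionless G=kJ/mol SE=kJ/mol\n")
        fh.write(f"# reference: {profile.reference}\n")
        fh.write(f"# temperature: {profile.temperature!r}\n")
        if settings:
            opts = " ".join(f"{k}={v}" for k, v in sorted(settings.items()))
            fh.write(f"# wham: {opts}\n")
        for b, g, s in zip(profile.bins, profile.free_energy, profile.se):
            fh.write(f"{b:.10g} {g:.10g} {s:.10g}\n")
    return path


def write_density_map(path, dmap):
    """Plain-text density maps: one labelled matrix block per species."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# memstalk densitymap v1\n")
        fh.write("# units: r=nm z=nm density=u/nm^3\n")
        fh.write(f"# n_frames: {dmap.n_frames}\n")
        fh.write("# r_edges: " + " ".join(f"{v:.10g}" for v in dmap.r_edges)
                 + "\n")
        fh.write("# z_edges: " + " ".join(f"{v:.10g}" for v in dmap.z_edges)
                 + "\n")
        for name in sorted(dmap.densities):
            fh.write(f"# species: {name}\n")
            for row in dmap.densities[name]:
                fh.write(" ".join(f"{v:.10g}" for v in row) + "\n")
    return path


def read_density_map(path):
    from .analysis import DensityMap2D
    path = Path(path)
    r_edges = z_edges = None
    n_frames = 0
    densities = {}
    current = None
    rows = []
    for line in path.read_text(encoding="utf-8").splitlines():
        if line.startswith("#"):
            if line.startswith("# r_edges:"):
                r_edges = np.array([float(v) for v in line.split(":")[1].split()])
            elif line.startswith("# z_edges:"):
                z_edges = np.array([float(v) for v in line.split(":")[1].split()])
            elif line.startswith("# n_frames:"):
                n_frames = int(line.split(":")[1])
            elif line.startswith("# species:"):
                if current is not None:
                    densities[current] = np.array(rows)
                current = line.split(":")[1].strip()
                rows = []
        elif line.strip():
            rows.append([float(v) for v in line.split()])
    if current is not None:
        densities[current] = np.array(rows)
    if r_edges is None or z_edges is None or not densities:
        raise FileFormatError(f"{path}: not a density-map file")
    return DensityMap2D(r_edges=r_edges, z_edges=z_edges,
                        densities=densities, n_frames=n_frames)


def read_pmf(path) -> PMFProfile:
    path = Path(path)
    temperature = 310.0
    reference = "flat_min"
    rows = []
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
        if first.strip() != PMF_MAGIC:
            raise FileFormatError(f"{path}: not a PMF file")
        for line in fh:
            line = line.strip()
            if line.startswith("#"):
                if line.startswith("# temperature:"):
                    temperature = float(ast.literal_eval(line.split(":", 1)[1].strip()))
                elif line.startswith("# reference:"):
                    reference = line.split(":", 1)[1].strip()
                continue
            if line:
                rows.append([float(v) for v in line.split()])
    arr = np.asarray(rows, dtype=float)
    return PMFProfile(bins=arr[:, 0], free_energy=arr[:, 1], se=arr[:, 2],
                      temperature=temperature, reference=reference)
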