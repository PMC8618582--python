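"""Plain-text file formats: contact matrices, bedGraph profiles, XYZ frames.

All formats are line-oriented text so that fixtures and results remain
diffable.  Contact matrices are written either dense (TSV with a header of
bin start coordinates) or as sparse upper-triangle triplets
``bin_i  bin_j  value``.  Profiles use the bedGraph convention
(``chrom  start  end  value``, 0-based half-open).  Conformations and
trajectories use multi-frame XYZ with bead order equal to chain order.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .contacts import ContactMap, normalize_relative
from .dynamics import Conformation, ConformationEnsemble, Trajectory


# ---------------------------------------------------------------- matrices

def write_contact_matrix(path, cmap: ContactMap, sparse: bool = False,
                         bin_size: int | None = None) -> None:
    bin_size = bin_size or cmap.resolution
    n = cmap.n_bins
    starts = np.arange(n) * bin_size
    if sparse:
        iu = np.triu_indices(n)
        vals = cmap.values[iu]
        nz = vals != 0
        df = pd.DataFrame({"bin_i": iu[0][nz], "bin_j": iu[1][nz],
                           "value": vals[nz]})
        with open(path, "w") as fh:
            fh.write(f"# format=triplet mode={cmap.mode} n_bins={n} "
                     f"bin_size={bin_size}\n")
            df.to_csv(fh, sep="\t", index=False)
    else:
        df = pd.DataFrame(cmap.values, columns=starts)
        with open(path, "w") as fh:
            fh.write(f"# format=dense mode={cmap.mode} n_bins={n} "
                     f"bin_size={bin_size}\n")
            df.to_csv(fh, sep="\t", index=False)


def read_contact_matrix(path, normalize: bool = False,
                        spec=None) -> ContactMap:
    """Read a dense or triplet matrix; optionally normalise to relative.

    Asymmetric or negative input is rejected.  Triplet input fills the
    missing cells with zeros and mirrors the upper triangle.
    """
    with open(path) as fh:
        header = fh.readline().strip()
    if not header.startswith("#"):
        raise ValueError("missing header line")
    meta = dict(kv.split("=") for kv in header[1:].split())
    n = int(meta["n_bins"])
    mode = meta.get("mode", "counts")
    bin_size = int(meta.get("bin_size", 100_000))
    if meta["format"] == "dense":
        vals = pd.read_csv(path, sep="\t", comment=None, skiprows=1).to_numpy(float)
    elif meta["format"] == "triplet":
        df = pd.read_csv(path, sep="\t", skiprows=1)
        vals = np.zeros((n, n))
        vals[df["bin_i"], df["bin_j"]] = df["value"]
        low = np.tril_indices(n, k=-1)
        vals[low] = vals.T[low]
    else:
        raise ValueError(f"unknown matrix format {meta['format']!r}")
    if vals.shape != (n, n):
        raise ValueError("matrix shape does not match the header")
    if np.any(vals < 0):
        raise ValueError("negative contact values")
    if not np.allclose(vals, vals.T):
        raise ValueError("asymmetric contact matrix")
    if normalize:
        vals = normalize_relative(vals, spec)
        mode = "relative"
    return ContactMap(vals, mode, resolution=bin_size)


def write_mask_file(path, beads) -> None:
    with open(path, "w") as fh:
        for b in sorted(beads):
            fh.write(f"{int(b)}\n")


def read_mask_file(path) -> frozenset:
    with open(path) as fh:
        return frozenset(int(line) for line in fh if line.strip())


# ---------------------------------------------------------------- profiles

def write_bedgraph(path, values, chrom: str, bin_size: int,
                   origin: int = 0) -> None:
    values = np.asarray(values, float)
    with open(path, "w") as fh:
        for b, v in enumerate(values):
            start = origin + b * bin_size
            fh.write(f"{chrom}\t{start}\t{start + bin_size}\t{v:.10g}\n")


def read_bedgraph(path, exempt_region: tuple[int, int] | None = None
                  ) -> tuple[str, int, np.ndarray, int]:
    """Read a single-chromosome bedGraph.

    Returns (chrom, bin_size, values, origin).  Intervals must be sorted,
    non-overlapping and of uniform width, except inside a declared
    ``exempt_region`` (bp interval) where a finer uniform width is
    accepted and aggregated onto the base grid.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            c, s, e, v = line.split()
            rows.append((c, int(s), int(e), float(v)))
    if not rows:
        raise ValueError("empty bedGraph")
    chroms = {r[0] for r in rows}
    if len(chroms) > 1:
        raise ValueError("bedGraph must describe a single chromosome")
    chrom = rows[0][0]
    rows.sort(key=lambda r: r[1])
    for (a, b) in zip(rows, rows[1:]):
        if b[1] < a[2]:
            raise ValueError("overlapping intervals")
    widths = {r[2] - r[1] for r in rows}
    base = max(widths)
    if len(widths) > 1:
        if exempt_region is None:
            raise ValueError("mixed interval widths outside an exempt region")
        lo, hi = exempt_region
        for (c, s, e, v) in rows:
            if e - s != base and not (lo <= s and e <= hi):
                raise ValueError("fine intervals outside the exempt region")
    origin = rows[0][1]
    n = (rows[-1][2] - origin + base - 1) // base
    vals = np.zeros(n)
    for (c, s, e, v) in rows:
        b = (s - origin) // base
        vals[b] += v
    return chrom, base, vals, origin


def write_gamma_profile(path, gamma_values) -> None:
    with open(path, "w") as fh:
        fh.write("bead\tprobability\n")
        for b, v in enumerate(np.asarray(gamma_values, float)):
            fh.write(f"{b}\t{v:.10g}\n")


def read_gamma_profile(path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t")
    return df["probability"].to_numpy(float)


# ---------------------------------------------------------------- XYZ

def write_xyz(path, frames, times_ps=None, element: str = "C") -> None:
    """Multi-frame XYZ; one record per frame, beads in chain order."""
    frames = np.asarray(frames, float)
    if frames.ndim == 2:
        frames = frames[None]
    with open(path, "w") as fh:
        for fi, frame in enumerate(frames):
            fh.write(f"{frame.shape[0]}\n")
            t = times_ps[fi] if times_ps is not None else fi
            fh.write(f"t={t}\n")
            for (x, y, z) in frame:
                fh.write(f"{element}\t{x:.8f}\t{y:.8f}\t{z:.8f}\n")


def read_xyz(path) -> Trajectory:
    frames = []
    times = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n = int(lines[i])
        comment = lines[i + 1]
        t = float(comment.split("=", 1)[1]) if "=" in comment else float(len(frames))
        block = lines[i + 2: i + 2 + n]
        frame = np.array([[float(x) for x in ln.split()[1:4]] for ln in block])
        frames.append(frame)
        times.append(t)
        i += 2 + n
    return Trajectory(np.asarray(frames), np.asarray(times))


def write_ensemble(path_xyz, path_meta, ensemble: ConformationEnsemble) -> None:
    write_xyz(path_xyz, ensemble.positions)
    with open(path_meta, "w") as fh:
        fh.write("key\tvalue\n")
        for k, v in ensemble.provenance.items():
            fh.write(f"{k}\t{v}\n")
        fh.write(f"k_members\t{len(ensemble)}\n")


def read_ensemble(path_xyz, provenance: dict | None = None) -> ConformationEnsemble:
    traj = read_xyz(path_xyz)
    return ConformationEnsemble(traj.positions, provenance or {})
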