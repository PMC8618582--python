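"""Bead-chain chromosome descriptions and unit conversions.

A chromosome is coarse-grained into spherical subunits ("beads") of 100 kb
of DNA each.  The first beads of a chain form the centromeric region, one
bead carries the nuclease (I-SceI) recognition site ("breaksite" or "bait"),
and a set of beads may be flagged non-mappable (bins invisible to Hi-C).

Internal simulation units are: length in bead diameters ``d``, energy in
``kT`` and time in picoseconds.  :class:`ScaleMap` converts these to
physical units (nm, hours) using the calibration adopted for interphase
mouse chromosomes: bead mass 100 amu, ``d`` = 1 nm in the integrator and
225 nm physically, and 5500 ps of simulation per real hour.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

KB_J_PER_K = 1.380649e-23
AMU_KG = 1.66053906892e-27

#: genomic content of one bead
BP_PER_SUBUNIT = 100_000


@dataclass(frozen=True)
class ChromosomeSpec:
    """Static description of one model chromosome.

    Parameters
    ----------
    label:
        Chromosome name, passed through verbatim to output files.
    n_subunits:
        Number of 100-kb beads ``N``.
    breaksite:
        Bead index of the nuclease recognition site (0-based).
    centromere_span:
        Half-open bead range ``[lo, hi)`` of the centromeric region.  The
        full-scale mouse chains use the first 30 beads (3 Mb).
    non_mappable:
        Bead indices with no Hi-C signal; excluded from map comparison.
    diameter:
        Bead diameter in internal length units (always 1 by convention).
    cage_radius:
        Radius (in diameters) of the impenetrable sphere used to confine
        the initial coil during equilibration; 14 diameters by default.
    bin_origin:
        Genomic coordinate (bp) of bead 0; bead ``b`` covers the 0-based
        half-open interval ``[bin_origin + b*100kb, +100kb)``.
    """

    label: str
    n_subunits: int
    breaksite: int
    centromere_span: tuple[int, int] = (0, 0)
    non_mappable: frozenset = frozenset()
    diameter: float = 1.0
    cage_radius: float = 14.0
    bin_origin: int = 0
    bin_size: int = BP_PER_SUBUNIT

    def __post_init__(self):
        n = self.n_subunits
        if n < 3:
            raise ValueError("a chain needs at least 3 subunits")
        if not (0 <= self.breaksite < n):
            raise ValueError("breaksite outside the chain")
        lo, hi = self.centromere_span
        if not (0 <= lo <= hi <= n):
            raise ValueError("centromere_span outside the chain")
        nm = frozenset(int(b) for b in self.non_mappable)
        object.__setattr__(self, "non_mappable", nm)
        if any(b < 0 or b >= n for b in nm):
            raise ValueError("non-mappable bead outside the chain")
        if self.breaksite in nm:
            raise ValueError("the breaksite cannot be non-mappable")

    @property
    def masked_bins(self) -> frozenset:
        """Beads excluded from map comparison: centromere + non-mappable."""
        lo, hi = self.centromere_span
        return frozenset(range(lo, hi)) | self.non_mappable

    def bead_interval(self, b: int) -> tuple[int, int]:
        """Genomic half-open interval (bp) covered by bead ``b``."""
        start = self.bin_origin + b * self.bin_size
        return start, start + self.bin_size

    def bead_at(self, position_bp: int) -> int:
        return (position_bp - self.bin_origin) // self.bin_size


# chain lengths and bait bins of the three mouse chromosomes studied at
# full scale; the bait bead indices correspond to the I-SceI bins
# 180.1-180.2 Mb (chr2), 31.2-31.3 Mb (chr7) and 70.6-70.7 Mb (chr18).
_MOUSE = {
    "chr2": (1818, 1801),
    "chr7": (1526, 312),
    "chr18": (908, 706),
}


def mouse_chromosome(label: str) -> ChromosomeSpec:
    """Spec for mouse chromosome 2, 7 or 18 at 100-kb resolution."""
    if label not in _MOUSE:
        raise KeyError(f"unknown mouse chromosome {label!r}")
    n, bait = _MOUSE[label]
    return ChromosomeSpec(label=label, n_subunits=n, breaksite=bait,
                          centromere_span=(0, 30))


@dataclass(frozen=True)
class ScaleMap:
    """Conversion between internal (d, kT, ps) and physical units."""

    bead_mass_amu: float = 100.0
    d_internal_nm: float = 1.0
    d_real_nm: float = 225.0
    temperature_K: float = 300.0
    ps_per_real_hour: float = 5500.0
    t_max_ps: float = 18_000.0
    dt_contact_ps: float = 5.0

    @property
    def tau_ps(self) -> float:
        """Lennard-Jones time ``tau = d * sqrt(m / U0)`` with U0 = kT."""
        u0 = KB_J_PER_K * self.temperature_K
        m = self.bead_mass_amu * AMU_KG
        d = self.d_internal_nm * 1e-9
        return d * math.sqrt(m / u0) * 1e12

    @property
    def gamma_per_ps(self) -> float:
        """Langevin friction coefficient, 0.5 / tau (~0.1 per ps)."""
        return 0.5 / self.tau_ps

    @property
    def mass_internal(self) -> float:
        """Bead mass in (d=1, kT=1, ps) units; equals ``tau_ps**2``."""
        return self.tau_ps ** 2

    def hours(self, t_ps: float) -> float:
        return t_ps / self.ps_per_real_hour

    def seconds(self, t_ps: float) -> float:
        return self.hours(t_ps) * 3600.0

    def nm(self, length_d: float) -> float:
        return length_d * self.d_real_nm


def real_time_conversion(t_internal_ps: float,
                         scale: ScaleMap | None = None) -> tuple[float, float]:
    """Convert an internal time in ps to real (hours, seconds)."""
    if t_internal_ps < 0:
        raise ValueError("time must be non-negative")
    scale = scale or ScaleMap()
    h = scale.hours(t_internal_ps)
    return h, h * 3600.0
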