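"""Pair potentials of the heteropolymer chromosome model.

Non-adjacent beads interact through the sum of a purely repulsive
Weeks-Chandler-Andersen (WCA) excluded-volume term, identical for all
pairs, and a shifted-and-truncated Lennard-Jones attraction whose depth
``u0_attr[i, j]`` is specific to each bead pair.  The attraction is cut at
``r_cut = 3 d`` where the unshifted tail is ~0.5% of the well depth.
Adjacent beads are connected by harmonic bonds and feel neither term.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np

from .chromosome import ChromosomeSpec

#: WCA cutoff, the Lennard-Jones minimum
WCA_CUTOFF = 2.0 ** (1.0 / 6.0)

#: default attraction cutoff in diameters
DEFAULT_R_CUT = 3.0

#: default excluded-volume strength in kT (order of the thermal energy)
DEFAULT_U0_EV = 1.0

# uniform attraction depths (kT) reproducing the homopolymer-globule
# baselines of the three mouse chromosomes, plus the loose-globule variant
HOMOPOLYMER_U0 = {"chr2": 1.57, "chr7": 2.33, "chr18": 9.34}
LOOSE_GLOBULE_U0 = 1.2
HETEROPOLYMER_INITIAL_U0 = 1.2


def excluded_volume_energy(r, u0_ev: float, d: float = 1.0):
    """WCA excluded-volume energy at centre distance ``r``.

    ``4 u0 [(d/r)^12 - (d/r)^6 + 1/4]`` for ``r <= d*2^(1/6)``, zero
    beyond; the +1/4 shift makes the energy continuous at the cutoff.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("distance must be positive")
    inv6 = (d / r) ** 6
    e = 4.0 * u0_ev * (inv6 * inv6 - inv6 + 0.25)
    out = np.where(r <= d * WCA_CUTOFF, e, 0.0)
    return out if out.ndim else float(out)


def attraction_energy(r, u0_attr_ij: float, r_cut: float = DEFAULT_R_CUT,
                      d: float = 1.0):
    """Shifted-truncated Lennard-Jones attraction between one bead pair.

    Zero inside the WCA core (``r <= d*2^(1/6)``) and beyond ``r_cut``;
    in between ``4 u0 [(d/r)^12 - (d/r)^6 - (d/rc)^12 + (d/rc)^6]``,
    which vanishes exactly at ``r_cut``.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("distance must be positive")
    if r_cut <= d * WCA_CUTOFF:
        raise ValueError("r_cut must exceed the WCA cutoff")
    inv6 = (d / r) ** 6
    shift = (d / r_cut) ** 12 - (d / r_cut) ** 6
    e = 4.0 * u0_attr_ij * (inv6 * inv6 - inv6 - shift)
    out = np.where((r > d * WCA_CUTOFF) & (r <= r_cut), e, 0.0)
    return out if out.ndim else float(out)


def attraction_tail_fraction(r_cut: float = DEFAULT_R_CUT) -> float:
    """|unshifted LJ value at r_cut| / well depth.

    The well depth of ``4u[(d/r)^12-(d/r)^6]`` is ``u``, so the fraction is
    independent of the pair coefficient.  ~0.005 at ``r_cut = 3 d``.
    """
    return abs(4.0 * ((1.0 / r_cut) ** 12 - (1.0 / r_cut) ** 6))


@dataclass
class PairPotentialField:
    """Per-pair interaction coefficients of one chromosome.

    ``u0_attr`` is a symmetric, non-negative N x N matrix of attraction
    depths in kT.  Entries on the diagonal and for adjacent beads are
    ignored by the energy (bonds govern neighbours).  ``u0_ev`` is the
    single excluded-volume strength shared by all pairs.
    """

    u0_ev: float
    u0_attr: np.ndarray
    r_cut: float = DEFAULT_R_CUT

    def __post_init__(self):
        self.u0_attr = np.asarray(self.u0_attr, dtype=float)
        if self.u0_attr.ndim != 2 or self.u0_attr.shape[0] != self.u0_attr.shape[1]:
            raise ValueError("u0_attr must be a square matrix")
        if not np.allclose(self.u0_attr, self.u0_attr.T):
            raise ValueError("u0_attr must be symmetric")
        if np.any(self.u0_attr < 0):
            raise ValueError("attraction depths must be non-negative")
        if self.u0_ev < 0:
            raise ValueError("u0_ev must be non-negative")
        if self.u0_attr.size and self.r_cut <= WCA_CUTOFF:
            raise ValueError("r_cut must exceed the WCA cutoff")

    @property
    def n_subunits(self) -> int:
        return self.u0_attr.shape[0]

    def checksum(self) -> str:
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.u0_attr).tobytes())
        h.update(np.float64(self.u0_ev).tobytes())
        h.update(np.float64(self.r_cut).tobytes())
        return h.hexdigest()[:16]

    def copy(self) -> "PairPotentialField":
        return PairPotentialField(self.u0_ev, self.u0_attr.copy(), self.r_cut)


TRIAL_KINDS = ("heteropolymer-init", "homopolymer", "loose-globule",
               "coil", "random-walk")


def make_trial_potentials(kind: str, spec: ChromosomeSpec,
                          u0: float | None = None,
                          u0_ev: float = DEFAULT_U0_EV) -> PairPotentialField:
    """Uniform baseline potential fields.

    ``homopolymer`` uses the chromosome-specific globule depths (1.57,
    2.33 and 9.34 kT for mouse chr2/7/18) unless ``u0`` is given;
    ``loose-globule`` uses 1.2 kT; ``coil`` has excluded volume only;
    ``random-walk`` has neither attraction nor excluded volume;
    ``heteropolymer-init`` fills every pair with the 1.2 kT starting value
    of the inverse fit.
    """
    n = spec.n_subunits
    if kind == "homopolymer":
        if u0 is None:
            try:
                u0 = HOMOPOLYMER_U0[spec.label]
            except KeyError:
                raise ValueError(
                    f"no homopolymer depth on record for {spec.label!r}; pass u0"
                ) from None
        attr = np.full((n, n), float(u0))
    elif kind == "loose-globule":
        attr = np.full((n, n), LOOSE_GLOBULE_U0 if u0 is None else float(u0))
    elif kind == "heteropolymer-init":
        attr = np.full((n, n), HETEROPOLYMER_INITIAL_U0 if u0 is None else float(u0))
    elif kind == "coil":
        attr = np.zeros((n, n))
    elif kind == "random-walk":
        attr = np.zeros((n, n))
        u0_ev = 0.0
    else:
        raise ValueError(f"unknown trial kind {kind!r}; expected one of {TRIAL_KINDS}")
    np.fill_diagonal(attr, 0.0)
    return PairPotentialField(u0_ev=u0_ev, u0_attr=attr)


def alter_breaksite_potentials(field: PairPotentialField, breaksite: int,
                               factor: float) -> PairPotentialField:
    """Scale the attraction row/column of the breaksite bead.

    Used by the conformational-transition scenarios, where only the
    interactions of the bait locus are assumed to change after damage.
    """
    attr = field.u0_attr.copy()
    attr[breaksite, :] *= factor
    attr[:, breaksite] *= factor
    attr[breaksite, breaksite] = field.u0_attr[breaksite, breaksite]
    attr = (attr + attr.T) / 2.0
    return PairPotentialField(field.u0_ev, attr, field.r_cut)


def total_pair_energy(positions: np.ndarray, field: PairPotentialField) -> float:
    """Total non-bonded pair energy of one conformation (reference path).

    Plain vectorised evaluation over all non-adjacent pairs; used for
    invariant checks, not inside the integrator.
    """
    pos = np.asarray(positions, float)
    n = pos.shape[0]
    diff = pos[:, None, :] - pos[None, :, :]
    r = np.sqrt((diff ** 2).sum(-1))
    iu = np.triu_indices(n, k=2)
    rr = r[iu]
    e_ev = excluded_volume_energy(rr, field.u0_ev) if field.u0_ev > 0 else 0.0
    e_at = attraction_energy(rr, 1.0, field.r_cut) * field.u0_attr[iu]
    return float(np.sum(e_ev) + np.sum(e_at))
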