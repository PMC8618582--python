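"""Contact detection and contact-map statistics.

A contact between beads i and j is scored when their centre distance does
not exceed ``R_cont = 1.2 d``.  Ensemble maps come in four modes:

``counts``
    sum of binary per-conformation maps over the ensemble;
``relative``
    counts divided by the total number of contacts over unmasked pairs at
    genomic separation s >= 2 (sums to 1 over the unmasked upper triangle);
``per-chromosome``
    counts / K, the fraction of conformations with the contact;
``per-cell``
    counts / M with M = K/2 cells (two homologous copies per cell), which
    is exactly twice the per-chromosome map.

Masking follows the conventions used when comparing with Hi-C: the
diagonal and adjacent pairs (s <= 1) are always excluded from statistics,
and centromeric plus non-mappable bins are excluded when a chromosome spec
is supplied.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from . import _kernels
from .chromosome import ChromosomeSpec
from .dynamics import Conformation, ConformationEnsemble

DEFAULT_R_CONT = 1.2

MAP_MODES = ("counts", "relative", "per-chromosome", "per-cell")


@dataclass
class ContactMap:
    values: np.ndarray
    mode: str
    resolution: int = 100_000
    masks_applied: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("contact map must be square")
        if self.mode not in MAP_MODES:
            raise ValueError(f"unknown map mode {self.mode!r}")

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]


@dataclass
class ContactProfile:
    """Per-bin values against one anchor bin (e.g. a pseudo-4C track)."""

    values: np.ndarray
    anchor: int
    resolution: int = 100_000
    smoothing: str | None = None
    exempt_mask: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)


def pair_mask(spec: ChromosomeSpec | None, n: int | None = None,
              min_separation: int = 2) -> np.ndarray:
    """Boolean (N, N) matrix, True for pairs entering map statistics.

    Excludes |i - j| < ``min_separation`` and, when a spec is given, every
    pair touching a centromeric or non-mappable bin.
    """
    if spec is None and n is None:
        raise ValueError("need a spec or an explicit size")
    n = spec.n_subunits if spec is not None else n
    idx = np.arange(n)
    mask = np.abs(idx[:, None] - idx[None, :]) >= min_separation
    if spec is not None:
        bad = sorted(spec.masked_bins)
        if bad:
            mask[bad, :] = False
            mask[:, bad] = False
    return mask


def conformation_contacts(conf: Conformation | np.ndarray,
                          r_cont: float = DEFAULT_R_CONT) -> np.ndarray:
    """Binary contact map of one conformation (inclusive r <= R_cont)."""
    if r_cont <= 0:
        raise ValueError("R_cont must be positive")
    pos = conf.positions if isinstance(conf, Conformation) else np.asarray(conf, float)
    out = np.zeros((pos.shape[0], pos.shape[0]), dtype=np.int64)
    _kernels.count_contacts(pos, float(r_cont), out)
    return out


def ensemble_contact_counts(ensemble: ConformationEnsemble,
                            r_cont: float = DEFAULT_R_CONT) -> np.ndarray:
    out = np.zeros((ensemble.n_subunits, ensemble.n_subunits), dtype=np.int64)
    for k in range(len(ensemble)):
        _kernels.count_contacts(ensemble.positions[k], float(r_cont), out)
    return out


def aggregate_contacts(ensemble: ConformationEnsemble, mode: str = "counts",
                       r_cont: float = DEFAULT_R_CONT,
                       spec: ChromosomeSpec | None = None) -> ContactMap:
    """Ensemble contact map in any of the four modes."""
    if mode not in MAP_MODES:
        raise ValueError(f"unknown map mode {mode!r}")
    counts = ensemble_contact_counts(ensemble, r_cont).astype(float)
    k = len(ensemble)
    if mode == "counts":
        vals = counts
    elif mode == "per-chromosome":
        vals = counts / k
    elif mode == "per-cell":
        if k % 2:
            raise ValueError("per-cell mode needs an even ensemble (K = 2M)")
        vals = counts / (k // 2)
    else:  # relative
        vals = normalize_relative(counts, spec)
    return ContactMap(vals, mode, masks_applied=spec is not None)


def normalize_relative(counts: np.ndarray,
                       spec: ChromosomeSpec | None = None) -> np.ndarray:
    """Counts -> relative frequencies summing to 1 over unmasked pairs.

    The denominator is the total over the unmasked upper triangle at
    s >= 2, matching the Hi-C normalisation convention (adjacent-bin
    contacts excluded, masked bins dropped).
    """
    counts = np.asarray(counts, float)
    mask = pair_mask(spec, counts.shape[0])
    iu = np.triu_indices(counts.shape[0], k=1)
    sel = mask[iu]
    total = counts[iu][sel].sum()
    if total <= 0:
        raise ValueError("no contacts on unmasked pairs; cannot normalize")
    return counts / total


def map_pearson(a: np.ndarray, b: np.ndarray, mask: np.ndarray) -> float:
    """Pearson correlation over the unmasked upper-triangle entries."""
    iu = np.triu_indices(a.shape[0], k=1)
    sel = mask[iu]
    x = np.asarray(a, float)[iu][sel]
    y = np.asarray(b, float)[iu][sel]
    if x.std() == 0 or y.std() == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def contact_vs_separation(cmap: ContactMap,
                          spec: ChromosomeSpec | None = None
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Contact frequency versus genomic separation, f(s) = sum_i C(i, i+s).

    Defined on a relative map for s = 2 ... N-1; pairs touching centromeric
    or non-mappable bins are excluded from the sums.
    """
    if cmap.mode != "relative":
        raise ValueError("f(s) is defined on a relative map")
    n = cmap.n_bins
    mask = pair_mask(spec, n)
    s_vals = np.arange(2, n)
    f = np.empty(s_vals.shape[0])
    for k, s in enumerate(s_vals):
        diag = np.diagonal(cmap.values, offset=s)
        m = np.diagonal(mask, offset=s)
        f[k] = diag[m].sum()
    return s_vals, f


def power_exponent(s_vals: np.ndarray, f_vals: np.ndarray,
                   s_range_bp: tuple[float, float] = (500_000, 5_000_000),
                   bin_size: int = 100_000) -> float:
    """Slope of log f(s) vs log s over a genomic-separation window.

    The default window 0.5-5 Mb is the range in which mouse chromosomes
    show an apparent power law with exponent around -0.9.
    """
    s_vals = np.asarray(s_vals, float)
    f_vals = np.asarray(f_vals, float)
    s_bp = s_vals * bin_size
    sel = (s_bp >= s_range_bp[0]) & (s_bp <= s_range_bp[1]) & (f_vals > 0)
    if sel.sum() < 3:
        raise ValueError("fewer than 3 positive points in the fit range")
    slope, _ = np.polyfit(np.log(s_vals[sel]), np.log(f_vals[sel]), 1)
    return float(slope)


def pseudo4c_profile(cmap: ContactMap, anchor: int,
                     spec: ChromosomeSpec | None = None) -> ContactProfile:
    """One row of the map anchored at the bait bin (virtual 4C)."""
    if spec is not None and anchor in spec.masked_bins:
        raise ValueError("anchor bin is masked/non-mappable")
    if not (0 <= anchor < cmap.n_bins):
        raise IndexError("anchor out of range")
    return ContactProfile(cmap.values[anchor].copy(), anchor=anchor,
                          resolution=cmap.resolution)


def single_cell_map(conf_a: Conformation, conf_b: Conformation,
                    r_cont: float = DEFAULT_R_CONT) -> ContactMap:
    """Sum of the binary maps of the two homologous copies (values 0/1/2)."""
    if conf_a.n_subunits != conf_b.n_subunits:
        raise ValueError("homolog conformations must share N")
    vals = conformation_contacts(conf_a, r_cont) + conformation_contacts(conf_b, r_cont)
    return ContactMap(vals.astype(float), "counts")


def pool_average(items: np.ndarray, m: int, seed: int) -> np.ndarray:
    """Mean over a seeded random pool of m cells (without replacement)."""
    items = np.asarray(items, float)
    if m < 1:
        raise ValueError("pool size must be at least 1")
    if m > items.shape[0]:
        raise ValueError("pool larger than the available cells")
    rng = np.random.default_rng(seed)
    idx = rng.choice(items.shape[0], size=m, replace=False)
    return items[idx].mean(axis=0)


def rebin_smooth(profile: ContactProfile | np.ndarray,
                 exempt_bins: tuple[int, int] | None = None,
                 window_bins: int = 5) -> ContactProfile:
    """Aggregate a 100-kb profile to 200 kb and boxcar-smooth over 1 Mb.

    Pairs of 100-kb bins are summed into 200-kb bins (an odd trailing bin
    keeps its own value), then a centred boxcar mean of ``window_bins``
    200-kb bins (5 bins = 1 Mb) is applied, truncated at the edges.
    200-kb bins overlapping the ``exempt_bins`` 100-kb range keep their
    unsmoothed aggregated values (regions with independent high-resolution
    data are not smoothed).
    """
    if window_bins < 1:
        raise ValueError("window must cover at least one bin")
    vals = profile.values if isinstance(profile, ContactProfile) else np.asarray(profile, float)
    n = vals.shape[0]
    n2 = (n + 1) // 2
    agg = np.zeros(n2)
    agg[: n // 2] = vals[: 2 * (n // 2)].reshape(-1, 2).sum(axis=1)
    if n % 2:
        agg[-1] = vals[-1]
    kernel = np.ones(window_bins)
    norm = np.convolve(np.ones(n2), kernel, mode="same")
    smooth = np.convolve(agg, kernel, mode="same") / norm
    exempt = np.zeros(n2, dtype=bool)
    if exempt_bins is not None:
        lo, hi = exempt_bins
        exempt[lo // 2: (hi + 1) // 2] = True
        smooth[exempt] = agg[exempt]
    anchor = getattr(profile, "anchor", 0)
    return ContactProfile(smooth, anchor=anchor // 2, resolution=200_000,
                          smoothing=f"boxcar-{window_bins}x200kb",
                          exempt_mask=exempt)


def contact_count_pmf(ensemble: ConformationEnsemble, anchor: int,
                      r_cont: float = DEFAULT_R_CONT,
                      damage_sampler=None,
                      seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Empirical distribution of per-cell anchor contacts.

    Cells are formed by pairing consecutive ensemble members (K/2 cells).
    If ``damage_sampler`` is given it must be a callable ``rng -> set of
    damaged beads`` for one chromosome copy; only contacts of the anchor
    with damaged beads are counted then.
    """
    if len(ensemble) < 2:
        raise ValueError("need at least two members to form a cell")
    if not (0 <= anchor < ensemble.n_subunits):
        raise IndexError("anchor out of range")
    rng = np.random.default_rng(seed)
    n_cells = len(ensemble) // 2
    counts = np.zeros(n_cells, dtype=np.int64)
    rc2 = r_cont * r_cont
    for c in range(n_cells):
        tot = 0
        for copy in (2 * c, 2 * c + 1):
            pos = ensemble.positions[copy]
            d2 = ((pos - pos[anchor]) ** 2).sum(axis=1)
            hit = d2 <= rc2
            hit[anchor] = False
            if abs(anchor - 1) >= 0:  # exclude adjacent beads (s <= 1)
                for nb in (anchor - 1, anchor + 1):
                    if 0 <= nb < hit.shape[0]:
                        hit[nb] = False
            if damage_sampler is not None:
                dmg = damage_sampler(rng)
                sel = np.zeros_like(hit)
                for b in dmg:
                    sel[b] = True
                hit &= sel
            tot += int(hit.sum())
        counts[c] = tot
    support = np.arange(counts.max() + 1)
    pmf = np.bincount(counts, minlength=support.shape[0]).astype(float)
    pmf /= pmf.sum()
    return support, pmf
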