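"""DNA double-strand-break (DSB) models.

Three lesion origins are modelled on the 100-kb bead scale:

* **IR** — gamma-radiation DSBs.  The per-subunit probability of one DSB
  at dose D is ``alpha * D * L`` with induction efficiency
  ``alpha = 8.2e-9 / (Gy * bp)`` and ``L = 1e5`` bp per bead; the number of
  DSBs per chromosome is Poisson with mean ``N * alpha * D * L`` and
  uniform positions.
* **spontaneous** — per-bead Bernoulli with a phenomenological profile
  ``Gamma_sp(j)``, reconstructed from observed breakpoint frequencies.
* **nuclease** — present at the breaksite bead with probability 1.

A bead hit by any mechanism is a "damaged subunit"; DSB multiplicity
within one bead is collapsed to a single flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.interpolate import Akima1DInterpolator

from .chromosome import BP_PER_SUBUNIT, ChromosomeSpec
from .contacts import rebin_smooth
from .dynamics import ConformationEnsemble

ALPHA_PER_GY_BP = 8.2e-9

ORIGIN_IR = "IR"
ORIGIN_SPONTANEOUS = "spontaneous"
ORIGIN_NUCLEASE = "nuclease"


@dataclass(frozen=True)
class IRParams:
    """Radiation damage parameters (alpha, bp per subunit, dose in Gy)."""

    dose_gy: float
    alpha: float = ALPHA_PER_GY_BP
    bp_per_subunit: float = float(BP_PER_SUBUNIT)

    def __post_init__(self):
        if self.dose_gy < 0 or self.alpha <= 0 or self.bp_per_subunit <= 0:
            raise ValueError("invalid IR parameters")

    @property
    def p_dsb(self) -> float:
        return self.alpha * self.dose_gy * self.bp_per_subunit


def ir_damage_probability(params: IRParams) -> float:
    """Per-subunit probability of an IR DSB, ``alpha * D * L``.

    Valid in the low-occupancy regime (mean per subunit << 1, true for
    doses up to ~15 Gy).  0.0041 at 5 Gy.
    """
    return params.p_dsb


@dataclass
class SpontaneousProfile:
    """Per-bead probability of a spontaneous DSB per chromosome snapshot."""

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("profile must be one-dimensional")
        if np.any((self.values < 0) | (self.values > 1)):
            raise ValueError("probabilities must lie in [0, 1]")

    @classmethod
    def zeros(cls, n: int) -> "SpontaneousProfile":
        return cls(np.zeros(n))

    @classmethod
    def uniform(cls, n: int, p: float) -> "SpontaneousProfile":
        return cls(np.full(n, float(p)))


@dataclass
class DamageProfile:
    """Lesions of one chromosome copy: bead indices with origin labels."""

    beads: np.ndarray
    origins: list
    n_subunits: int

    def __post_init__(self):
        self.beads = np.asarray(self.beads, dtype=np.int64)
        if self.beads.shape[0] != len(self.origins):
            raise ValueError("beads and origins must align")
        if np.any((self.beads < 0) | (self.beads >= self.n_subunits)):
            raise ValueError("lesion outside the chain")
        if len(set(self.beads.tolist())) != self.beads.shape[0]:
            raise ValueError("duplicate damaged bead")

    def origin_of(self, bead: int) -> str:
        i = int(np.where(self.beads == bead)[0][0])
        return self.origins[i]

    def __len__(self):
        return self.beads.shape[0]


def sample_damage(spec: ChromosomeSpec, params: IRParams,
                  gamma_sp: SpontaneousProfile | None = None,
                  nuclease: bool = True,
                  seed: int | np.random.Generator = 0) -> DamageProfile:
    """Monte-Carlo lesion set for one chromosome copy.

    IR lesion count is Poisson with mean ``N * alpha * D * L`` and uniform
    bead positions; each bead is independently spontaneously broken with
    probability ``Gamma_sp(j)``; the nuclease lesion sits at the breaksite
    with probability 1 when enabled.  A bead hit by several mechanisms is
    labelled once, with precedence nuclease > IR > spontaneous.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = spec.n_subunits
    origin = {}
    if gamma_sp is not None:
        if gamma_sp.values.shape[0] != n:
            raise ValueError("spontaneous profile length mismatch")
        hits = np.nonzero(rng.random(n) < gamma_sp.values)[0]
        for b in hits:
            origin[int(b)] = ORIGIN_SPONTANEOUS
    n_ir = rng.poisson(n * params.p_dsb)
    for b in rng.integers(0, n, size=n_ir):
        origin[int(b)] = ORIGIN_IR
    if nuclease:
        origin[int(spec.breaksite)] = ORIGIN_NUCLEASE
    beads = np.array(sorted(origin), dtype=np.int64)
    return DamageProfile(beads, [origin[int(b)] for b in beads], n)


def interpolate_spontaneous_breakpoints(
        coarse_values: np.ndarray, n_bins_out: int,
        coarse_bin_bp: int = 2_000_000, out_bin_bp: int = BP_PER_SUBUNIT,
        highres: tuple[int, int, np.ndarray] | None = None,
        highres_bin_bp: int = 25_000) -> np.ndarray:
    """Resample a coarse breakpoint profile onto 100-kb bins.

    The coarse (2-Mb) profile is interpolated at 100-kb bin centres with an
    Akima spline, negatives are clipped to zero and the result is rescaled
    so its total equals the coarse total.  When a high-resolution (25-kb)
    sub-profile is known for an interval ``(start_bp, end_bp, values)``, it
    is aggregated to 100 kb and spliced in afterwards.
    """
    coarse = np.asarray(coarse_values, float)
    if np.any(coarse < 0):
        raise ValueError("breakpoint counts must be non-negative")
    centers_in = (np.arange(coarse.shape[0]) + 0.5) * coarse_bin_bp
    centers_out = (np.arange(n_bins_out) + 0.5) * out_bin_bp
    spline = Akima1DInterpolator(centers_in, coarse)
    fine = spline(centers_out, extrapolate=True)
    fine = np.clip(np.nan_to_num(fine), 0.0, None)
    total = coarse.sum()
    if fine.sum() > 0:
        # per-bin scale: the coarse profile counts breakpoints per 2-Mb bin
        fine *= total / fine.sum()
    if highres is not None:
        start_bp, end_bp, hv = highres
        hv = np.asarray(highres[2], float)
        if start_bp % out_bin_bp or end_bp % out_bin_bp:
            raise ValueError("high-res interval must align with 100-kb bins")
        lo, hi = start_bp // out_bin_bp, end_bp // out_bin_bp
        if not (0 <= lo < hi <= n_bins_out):
            raise ValueError("high-res interval outside the profile")
        per_bin = out_bin_bp // highres_bin_bp
        if hv.shape[0] != (hi - lo) * per_bin:
            raise ValueError("high-res values do not tile the interval")
        fine[lo:hi] = hv.reshape(-1, per_bin).sum(axis=1)
    return fine


@dataclass
class ReconstructionHistory:
    pearson: list = dc_field(default_factory=list)
    best_pearson: list = dc_field(default_factory=list)

    def __len__(self):
        return len(self.pearson)


def reconstruct_spontaneous_dsbs(target_bp: np.ndarray,
                                 ensemble: ConformationEnsemble,
                                 spec: ChromosomeSpec, p_ce: float,
                                 max_iters: int = 20, patience: int = 3,
                                 improve_tol: float = 1e-4,
                                 floor: float = 1e-8, seed: int = 0
                                 ) -> tuple[SpontaneousProfile, ReconstructionHistory]:
    """Infer the spontaneous-DSB profile from a breakpoint profile at D = 0.

    Iterates from a uniform profile: simulate the bait-involving breakpoint
    distribution by the contact-first mechanism without irradiation,
    compare with the target (both 1-Mb smoothed at 200 kb), and rescale
    each bead's probability by ``target/simulated`` (clipped to
    ``[floor, 1]``) until the Pearson correlation stops improving.
    """
    from .aberrations import population_breakpoints_cf
    from .chromosome import ChromosomeSpec as _C  # noqa: F401  (doc aid)
    from .damage import IRParams as _IR

    target_bp = np.asarray(target_bp, float)
    n = spec.n_subunits
    if target_bp.shape[0] != n:
        raise ValueError("target profile length mismatch")
    total = target_bp.sum()
    gamma = np.full(n, min(0.5, max(floor, total / max(n, 1))))
    params0 = _IR(dose_gy=0.0)
    smooth_target = rebin_smooth(target_bp).values
    hist = ReconstructionHistory()
    best = None
    no_improve = 0
    for _ in range(max_iters):
        bp = population_breakpoints_cf(spec, ensemble, params0,
                                       SpontaneousProfile(gamma), p_ce,
                                       seed=seed, decoupled=True)
        sim = bp.values
        smooth_sim = rebin_smooth(sim).values
        if smooth_sim.std() > 0 and smooth_target.std() > 0:
            r = float(np.corrcoef(smooth_sim, smooth_target)[0, 1])
        else:
            r = 0.0
        hist.pearson.append(r)
        if best is None or r > best[0] + improve_tol:
            best = (r, gamma.copy())
            no_improve = 0
        else:
            no_improve += 1
            if r > best[0]:
                best = (r, gamma.copy())
        hist.best_pearson.append(best[0])
        if no_improve >= patience:
            break
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(sim > 0, target_bp / np.where(sim > 0, sim, 1.0), 1.0)
        gamma = np.clip(gamma * ratio, floor, 1.0)
        gamma[spec.breaksite] = floor
    return SpontaneousProfile(best[1]), hist
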