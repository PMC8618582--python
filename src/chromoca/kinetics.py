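"""Breakage-first mechanism: lesion dynamics and time-resolved exchanges.

After damage the lesions move with the same mobility as undamaged loci.
Whenever two damaged subunits are in contact at a contact-check step
(every 5 ps of simulation, 3.3 s of real time), the contact converts into
an exchange with probability ``V_c-e * dt`` where ``V_c-e`` is the
contact-to-exchange rate per real hour.  Pre-existing contacts (t = 0)
undergo the same trial, so the contact-first mechanism is included as the
t = 0 part of the process.  Once a pair's contact episode ends without
conversion the pair is retired: re-formed contacts are neglected.
Observation runs from 0 to 18000 ps (3.3 real hours).

Contact-formation kinetics are tallied by the pair's initial distance
class ({<=1.2, 1.2-2, 2-3, 3-6, >6} diameters): the differential number of
first contacts per (class, time bin), and its cumulative integral whose
t = 0 column is the pre-existing contact count.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from . import _kernels
from .chromosome import ChromosomeSpec, ScaleMap, real_time_conversion  # noqa: F401
from .contacts import DEFAULT_R_CONT
from .damage import IRParams, SpontaneousProfile, sample_damage
from .dynamics import DynamicsConfig, ConformationEnsemble, _integrate
from .potentials import PairPotentialField

#: fitted conversion rates per real hour
V_CE_DEFAULTS = {"chr2": 0.28, "chr7": 0.52, "chr18": 1.54}

DEFAULT_CLASS_EDGES = (1.2, 2.0, 3.0, 6.0)


@dataclass
class KineticsConfig:
    """Breakage-first run parameters.

    ``v_ce`` is the conversion rate in 1/hour; ``dt_contact_ps`` the
    contact-check step (the per-step conversion probability is
    ``v_ce * dt_real`` and must not exceed 1); ``frozen`` skips the
    integration entirely (static-conformation limit used for closed-form
    checks).
    """

    v_ce: float
    t_max_ps: float = 18_000.0
    dt_contact_ps: float = 5.0
    r_cont: float = DEFAULT_R_CONT
    class_edges: tuple = DEFAULT_CLASS_EDGES
    frozen: bool = False
    dynamics: DynamicsConfig | None = None  # None: step scaled to the field
    scale: ScaleMap = dc_field(default_factory=ScaleMap)

    def __post_init__(self):
        if self.v_ce < 0:
            raise ValueError("V_c-e must be non-negative")
        if list(self.class_edges) != sorted(self.class_edges):
            raise ValueError("distance class edges must increase")
        if self.p_convert_per_step > 1.0:
            raise ValueError("V_c-e * dt exceeds 1; shrink the step")

    @property
    def dt_real_hours(self) -> float:
        return self.dt_contact_ps / self.scale.ps_per_real_hour

    @property
    def p_convert_per_step(self) -> float:
        return self.v_ce * self.dt_real_hours

    def distance_class(self, r0: float) -> int:
        return int(np.searchsorted(np.asarray(self.class_edges), r0))


@dataclass
class PairEvent:
    """Fate of one damaged pair in one cell/copy."""

    cell: int
    copy: int
    i: int
    j: int
    r0: float
    initial_class: int
    first_contact_ps: float | None
    converted_ps: float | None


@dataclass
class LesionKinetics:
    """First-contact counts by (initial-distance class, time bin)."""

    class_edges: tuple
    time_edges_ps: np.ndarray
    differential: np.ndarray  # (n_classes, n_time_bins)
    n_pairs_per_class: np.ndarray

    @property
    def cumulative(self) -> np.ndarray:
        return np.cumsum(self.differential, axis=1)

    @property
    def n_classes(self) -> int:
        return self.differential.shape[0]


def contact_formation_kinetics(events: list[PairEvent], class_edges: tuple,
                               time_edges_ps: np.ndarray) -> LesionKinetics:
    """Histogram first lesion-contact times per initial-distance class.

    The first time bin must start at 0 so that the t = 0 column of the
    cumulative view equals the pre-existing contact count.
    """
    edges = np.asarray(class_edges, float)
    if list(edges) != sorted(edges):
        raise ValueError("distance class edges must increase")
    te = np.asarray(time_edges_ps, float)
    n_cls = edges.shape[0] + 1
    diff = np.zeros((n_cls, te.shape[0] - 1))
    per_class = np.zeros(n_cls, dtype=np.int64)
    for ev in events:
        per_class[ev.initial_class] += 1
        if ev.first_contact_ps is None:
            continue
        t = ev.first_contact_ps
        b = int(np.searchsorted(te, t, side="right")) - 1
        if 0 <= b < diff.shape[1]:
            diff[ev.initial_class, b] += 1
    return LesionKinetics(tuple(edges), te, diff, per_class)


@dataclass
class BreakageFirstResult:
    values: np.ndarray          # bait-involving breakpoints per cell
    dose_gy: float
    m_cells: int
    bait: int
    kinetics: LesionKinetics
    pair_events: list
    conversions: list           # (cell, copy, i, j, t_ps)

    @property
    def total_per_cell(self) -> float:
        return float(self.values.sum())


def simulate_breakage_first(spec: ChromosomeSpec,
                            ensemble: ConformationEnsemble,
                            field: PairPotentialField,
                            params: IRParams,
                            gamma_sp: SpontaneousProfile | None,
                            kinetics: KineticsConfig,
                            m_cells: int, seed: int = 0
                            ) -> BreakageFirstResult:
    """Per-cell lesion-dynamics simulation of exchange formation.

    For each of the two chromosome copies of each cell: draw a random
    conformation, sample damage, then track the damaged-pair distances
    through Langevin dynamics from 0 to ``t_max``.  At every contact-check
    step each currently contacting, still-eligible pair converts with
    probability ``V_c-e * dt``; a pair whose contact episode ends without
    conversion is retired, as is a converted pair.  Lesion number is
    constant (no repair).  Breakpoints are time-stamped; conversions at
    t = 0 constitute the contact-first part.
    """
    rng = np.random.default_rng(seed)
    cfg = kinetics
    dyn = cfg.dynamics or DynamicsConfig.for_field(field)
    n = spec.n_subunits
    bait = spec.breaksite
    p_step = cfg.p_convert_per_step
    steps_per_check = max(1, int(round(cfg.dt_contact_ps / dyn.dt_ps)))
    n_checks = int(round(cfg.t_max_ps / cfg.dt_contact_ps))
    values = np.zeros(n)
    pair_events: list[PairEvent] = []
    conversions = []
    k = len(ensemble)
    for cell in range(m_cells):
        for copy in (0, 1):
            member = int(rng.integers(0, k))
            pos = ensemble.positions[member].copy()
            vel = np.zeros_like(pos)
            dmg = sample_damage(spec, params, gamma_sp, nuclease=True, seed=rng)
            beads = dmg.beads
            ii, jj = [], []
            for a in range(beads.shape[0]):
                for b in range(a + 1, beads.shape[0]):
                    if abs(int(beads[a]) - int(beads[b])) <= 1:
                        continue
                    ii.append(int(beads[a]))
                    jj.append(int(beads[b]))
            if not ii:
                continue
            ii = np.asarray(ii, np.int64)
            jj = np.asarray(jj, np.int64)
            npair = ii.shape[0]
            dist = np.empty(npair)
            _kernels.pair_distances(pos, ii, jj, dist)
            r0 = dist.copy()
            classes = np.searchsorted(np.asarray(cfg.class_edges), r0)
            first_contact = np.full(npair, np.nan)
            converted_at = np.full(npair, np.nan)
            active = np.ones(npair, bool)       # still eligible
            in_contact = dist <= cfg.r_cont
            first_contact[in_contact] = 0.0
            # t = 0 trial for pre-existing contacts
            trial = in_contact & (rng.random(npair) < p_step)
            converted_at[trial] = 0.0
            active &= ~trial
            for step in range(1, n_checks + 1):
                if not active.any() and cfg.frozen:
                    break
                if not cfg.frozen:
                    _integrate(pos, vel, steps_per_check, rng, dyn,
                               field, 1.0, -1.0)
                _kernels.pair_distances(pos, ii, jj, dist)
                now = dist <= cfg.r_cont
                t_ps = step * cfg.dt_contact_ps
                # episode over -> retire
                ended = active & in_contact & ~now
                active &= ~ended
                # first entries into contact
                fresh = active & now & np.isnan(first_contact)
                first_contact[fresh] = t_ps
                # conversion trials for contacting eligible pairs
                eligible = active & now
                if eligible.any():
                    hit = eligible & (rng.random(npair) < p_step)
                    converted_at[hit] = t_ps
                    active &= ~hit
                in_contact = now
            for q in range(npair):
                fc = None if np.isnan(first_contact[q]) else float(first_contact[q])
                cv = None if np.isnan(converted_at[q]) else float(converted_at[q])
                pair_events.append(PairEvent(cell, copy, int(ii[q]), int(jj[q]),
                                             float(r0[q]), int(classes[q]),
                                             fc, cv))
                if cv is not None:
                    conversions.append((cell, copy, int(ii[q]), int(jj[q]), cv))
                    if ii[q] == bait:
                        values[jj[q]] += 1
                    elif jj[q] == bait:
                        values[ii[q]] += 1
    values /= m_cells
    time_edges = np.arange(n_checks + 1) * cfg.dt_contact_ps
    lk = contact_formation_kinetics(pair_events, cfg.class_edges, time_edges)
    return BreakageFirstResult(values, params.dose_gy, m_cells, bait, lk,
                               pair_events, conversions)


def decompose_mechanisms(result: BreakageFirstResult
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Split the breakpoint profile into contact-first and breakage-first.

    Conversions time-stamped t = 0 (pre-existing contacts) form the
    contact-first part; all later conversions the breakage-first part.
    The two parts sum to the total exactly.
    """
    n = result.values.shape[0]
    cf = np.zeros(n)
    bf = np.zeros(n)
    for (_cell, _copy, i, j, t) in result.conversions:
        if i == result.bait:
            partner = j
        elif j == result.bait:
            partner = i
        else:
            continue
        (cf if t == 0.0 else bf)[partner] += 1
    cf /= result.m_cells
    bf /= result.m_cells
    return cf, bf


@dataclass
class TransitionResult:
    values: np.ndarray
    weights: tuple
    chi2: float | None = None


def conformational_transition_scenario(mode: str,
                                       spec: ChromosomeSpec,
                                       profile_early: np.ndarray,
                                       profile_late: np.ndarray,
                                       exp_profile: np.ndarray | None = None,
                                       weights: tuple | None = None,
                                       excluded: np.ndarray | None = None,
                                       weight_grid: np.ndarray | None = None
                                       ) -> TransitionResult:
    """Combine breakpoint profiles across a conformational transition.

    ``early-late`` mode forms the weighted sum ``w * early + (1-w) * late``
    of two contact-first profiles (the altered ensemble differs only in
    the breaksite-row potentials); the weight is either supplied or fitted
    by chi-square minimisation against an experimental profile.
    ``transition-then-dynamics`` mode simply sums a contact-first early
    part and a breakage-first late part with the supplied weights.
    """
    pe = np.asarray(profile_early, float)
    pl = np.asarray(profile_late, float)
    if pe.shape != pl.shape:
        raise ValueError("profiles of different length")
    if mode == "early-late":
        if weights is not None:
            w = float(weights[0])
            vals = w * pe + (1 - w) * pl
            chi = None
            if exp_profile is not None:
                from .aberrations import chi_square
                chi = chi_square(vals, exp_profile, excluded)
            return TransitionResult(vals, (w, 1 - w), chi)
        if exp_profile is None:
            raise ValueError("fitting weights needs an experimental profile")
        from .aberrations import chi_square
        grid = weight_grid if weight_grid is not None else np.linspace(0, 1, 101)
        best = None
        for w in grid:
            vals = w * pe + (1 - w) * pl
            try:
                chi = chi_square(vals, exp_profile, excluded)
            except ValueError:
                continue
            if best is None or chi < best[0]:
                best = (chi, w, vals)
        if best is None:
            raise ValueError("no admissible weight on the grid")
        chi, w, vals = best
        return TransitionResult(vals, (float(w), float(1 - w)), float(chi))
    if mode == "transition-then-dynamics":
        if weights is None:
            weights = (1.0, 1.0)
        vals = weights[0] * pe + weights[1] * pl
        chi = None
        if exp_profile is not None:
            from .aberrations import chi_square
            chi = chi_square(vals, exp_profile, excluded)
        return TransitionResult(vals, tuple(weights), chi)
    raise ValueError(f"unknown scenario mode {mode!r}")
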