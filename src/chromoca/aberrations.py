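"""Contact-first simulation of intrachromosomal exchange aberrations.

In the contact-first picture an exchange (cis-translocation) can only form
between two damaged subunits that are already in spatial contact at the
moment of damage.  Each contacting lesion pair converts into an exchange
independently with probability ``P_c-e`` (fitted values: 0.0035 for mouse
chr2, 0.0029 for chr7 and chr18); symmetric (inversion) and asymmetric
(ring) exchanges are assigned with equal probability.  A cell carries two
independently drawn chromosome copies whose breakpoints are summed.

Two estimators are provided: a full per-cell Monte Carlo, and the
"decoupled" expectation that averages damage analytically over the
ensemble contact statistics -- the default for population-scale numbers,
where the bait-involving breakpoint frequency per cell is

    f_bp(j; D) = 2 * P_c-e * q_cont(i*, j) * [P_DSB(D) + Gamma_sp(j)]

with ``q_cont`` the per-chromosome contact frequency and ``i*`` the
breaksite.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .chromosome import ChromosomeSpec
from .contacts import DEFAULT_R_CONT, ensemble_contact_counts
from .damage import (DamageProfile, IRParams, SpontaneousProfile,
                     ORIGIN_IR, ORIGIN_NUCLEASE, ORIGIN_SPONTANEOUS,
                     sample_damage)
from .dynamics import Conformation, ConformationEnsemble

#: fitted contact-to-exchange probabilities
P_CE_DEFAULTS = {"chr2": 0.0035, "chr7": 0.0029, "chr18": 0.0029}

EXCHANGE_SYMMETRIC = "symmetric"      # inversion
EXCHANGE_ASYMMETRIC = "asymmetric"    # ring

#: origin-pair channel labels, order-insensitive
def channel_label(origin_a: str, origin_b: str) -> str:
    short = {ORIGIN_NUCLEASE: "nucl", ORIGIN_IR: "IR",
             ORIGIN_SPONTANEOUS: "spont"}
    a, b = sorted((short[origin_a], short[origin_b]))
    return f"{a}-{b}"


CHANNELS = ("IR-nucl", "nucl-spont", "IR-IR", "IR-spont", "spont-spont")


@dataclass
class ExchangeEvent:
    i: int
    j: int
    type: str
    origin_pair: str
    cell: int = -1
    copy: int = -1
    t_ps: float = 0.0

    def __post_init__(self):
        if self.i == self.j:
            raise ValueError("an exchange needs two distinct beads")


@dataclass
class BreakpointDistribution:
    """Per-bead breakpoints-per-cell with mechanism/origin decomposition.

    ``values`` is the HTGTS-comparable profile: exchanges involving the
    bait bead, tallied at the non-bait partner, per cell.  ``channels``
    retains the per-bead decomposition by origin pair, including channels
    that do not involve the bait.
    """

    values: np.ndarray
    dose_gy: float
    mechanism: str
    m_cells: float
    channels: dict = dc_field(default_factory=dict)
    events: list | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("breakpoint frequencies must be non-negative")


def lesion_contact_pairs(conf: Conformation, damage: DamageProfile,
                         r_cont: float = DEFAULT_R_CONT) -> list[tuple[int, int]]:
    """Damaged-bead pairs in spatial contact in one conformation.

    Subset of the conformation's contacts (s >= 2) restricted to beads
    that carry lesions of any origin.
    """
    beads = damage.beads
    if beads.shape[0] < 2:
        return []
    pos = conf.positions[beads]
    diff = pos[:, None, :] - pos[None, :, :]
    d2 = (diff ** 2).sum(-1)
    rc2 = r_cont * r_cont
    out = []
    for a in range(beads.shape[0]):
        for b in range(a + 1, beads.shape[0]):
            if abs(int(beads[a]) - int(beads[b])) <= 1:
                continue
            if d2[a, b] <= rc2:
                out.append((int(beads[a]), int(beads[b])))
    return out


def contacts_to_exchanges(pairs: list[tuple[int, int]], p_ce: float,
                          seed: int | np.random.Generator,
                          damage: DamageProfile | None = None
                          ) -> list[ExchangeEvent]:
    """Bernoulli conversion of contacting lesion pairs into exchanges.

    Each pair converts independently with probability ``p_ce``; surviving
    exchanges are symmetric or asymmetric with probability 1/2 each.
    """
    if not (0.0 <= p_ce <= 1.0):
        raise ValueError("p_ce must be a probability")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    events = []
    for (i, j) in pairs:
        if rng.random() >= p_ce:
            continue
        etype = EXCHANGE_SYMMETRIC if rng.random() < 0.5 else EXCHANGE_ASYMMETRIC
        if damage is not None:
            oc = channel_label(damage.origin_of(i), damage.origin_of(j))
        else:
            oc = "unknown"
        events.append(ExchangeEvent(i=i, j=j, type=etype, origin_pair=oc))
    return events


def _damage_prob_vector(spec: ChromosomeSpec, params: IRParams,
                        gamma_sp: SpontaneousProfile | None) -> np.ndarray:
    """Additive per-bead lesion probability P_DSB + Gamma_sp (low-occupancy)."""
    p = np.full(spec.n_subunits, params.p_dsb)
    if gamma_sp is not None:
        p = p + gamma_sp.values
    return p


def population_breakpoints_cf(spec: ChromosomeSpec,
                              ensemble: ConformationEnsemble,
                              params: IRParams,
                              gamma_sp: SpontaneousProfile | None,
                              p_ce: float, m_cells: int | None = None,
                              seed: int = 0, decoupled: bool = True,
                              r_cont: float = DEFAULT_R_CONT
                              ) -> BreakpointDistribution:
    """Population breakpoint distribution by the contact-first mechanism.

    Decoupled mode evaluates the expectation directly from the ensemble
    contact frequencies (suitable for arbitrarily large populations, e.g.
    the conventionally infinite 1e8-cell average).  The full Monte Carlo
    draws, per cell, two random conformations and explicit lesion sets,
    converts contacting lesion pairs with probability ``p_ce`` and tallies
    bait-involving breakpoints at the non-bait partner.
    """
    if len(ensemble) == 0:
        raise ValueError("empty ensemble")
    n = spec.n_subunits
    bait = spec.breaksite
    if decoupled:
        counts = ensemble_contact_counts(ensemble, r_cont).astype(float)
        q = counts / len(ensemble)  # per-chromosome contact frequency
        pvec = _damage_prob_vector(spec, params, gamma_sp)
        qrow = q[bait].copy()
        qrow[max(0, bait - 1): bait + 2] = 0.0  # s <= 1 never scored
        f_ir = 2.0 * p_ce * qrow * params.p_dsb
        f_sp = 2.0 * p_ce * qrow * (gamma_sp.values if gamma_sp is not None
                                    else 0.0)
        values = f_ir + f_sp
        values[bait] = 0.0
        channels = {"IR-nucl": f_ir, "nucl-spont": f_sp}
        return BreakpointDistribution(values, params.dose_gy, "contact-first",
                                      m_cells if m_cells else np.inf, channels)
    if m_cells is None:
        raise ValueError("full Monte Carlo needs an explicit cell count")
    rng = np.random.default_rng(seed)
    values = np.zeros(n)
    channels = {c: np.zeros(n) for c in CHANNELS}
    events: list[ExchangeEvent] = []
    k = len(ensemble)
    for cell in range(m_cells):
        for copy in (0, 1):
            member = int(rng.integers(0, k))
            conf = Conformation(ensemble.positions[member])
            dmg = sample_damage(spec, params, gamma_sp, nuclease=True, seed=rng)
            pairs = lesion_contact_pairs(conf, dmg, r_cont)
            for ev in contacts_to_exchanges(pairs, p_ce, rng, dmg):
                ev.cell, ev.copy = cell, copy
                events.append(ev)
                channels[ev.origin_pair][ev.i] += 1
                channels[ev.origin_pair][ev.j] += 1
                if ev.i == bait:
                    values[ev.j] += 1
                elif ev.j == bait:
                    values[ev.i] += 1
    values /= m_cells
    for c in channels:
        channels[c] /= m_cells
    return BreakpointDistribution(values, params.dose_gy, "contact-first",
                                  m_cells, channels, events)


def dose_response(spec: ChromosomeSpec, ensemble: ConformationEnsemble,
                  doses, gamma_sp: SpontaneousProfile | None, p_ce: float,
                  seed: int = 0, mode: str = "analytic",
                  m_cells: int = 100_000,
                  r_cont: float = DEFAULT_R_CONT) -> dict:
    """Total breakpoints per cell versus dose, split by origin channel.

    Analytic mode evaluates channel expectations from the ensemble contact
    frequencies: the nuclease-spontaneous channel is dose-independent, the
    nuclease-IR channel is linear in D and the IR-IR channel quadratic.
    Monte-Carlo mode tallies the same totals from explicit per-cell
    simulation.  Returns ``{dose: {channel: total breakpoints per cell}}``.
    """
    counts = ensemble_contact_counts(ensemble, r_cont).astype(float)
    q = counts / len(ensemble)
    n = spec.n_subunits
    bait = spec.breaksite
    g = gamma_sp.values if gamma_sp is not None else np.zeros(n)
    out = {}
    for dose in doses:
        if dose < 0:
            raise ValueError("dose must be non-negative")
        params = IRParams(dose_gy=float(dose))
        if mode == "analytic":
            p = params.p_dsb
            qrow = q[bait].copy()
            qrow[max(0, bait - 1): bait + 2] = 0.0
            others = np.ones(n, bool)
            others[bait] = False
            iu = np.triu_indices(n, k=2)
            nb = others[iu[0]] & others[iu[1]]
            qq = q[iu][nb]
            gi, gj = g[iu[0]][nb], g[iu[1]][nb]
            tot = {
                "IR-nucl": 2.0 * p_ce * float(qrow[others].sum()) * p,
                "nucl-spont": 2.0 * p_ce * float((qrow * g).sum()),
                "IR-IR": 2.0 * p_ce * float(qq.sum()) * p * p,
                "IR-spont": 2.0 * p_ce * p * float((qq * (gi + gj)).sum()),
                "spont-spont": 2.0 * p_ce * float((qq * gi * gj).sum()),
            }
        elif mode == "mc":
            bp = population_breakpoints_cf(spec, ensemble, params, gamma_sp,
                                           p_ce, m_cells=m_cells,
                                           seed=seed + int(dose * 1000) % 100_000,
                                           decoupled=False, r_cont=r_cont)
            tot = {c: float(v.sum()) / 2.0 for c, v in bp.channels.items()}
        else:
            raise ValueError("mode must be 'analytic' or 'mc'")
        out[float(dose)] = tot
    return out


def chi_square(sim: np.ndarray, exp: np.ndarray,
               excluded: np.ndarray | None = None) -> float:
    """Goodness of fit ``sum (sim - exp)^2 / sim`` over compared bins.

    Bins flagged in ``excluded`` (boolean, True = drop) are skipped, e.g.
    the 1-Mb window around the breaksite or regions with uncertain
    experimental values; a zero simulated value inside the comparison set
    is an error.
    """
    sim = np.asarray(sim, float)
    exp = np.asarray(exp, float)
    if sim.shape != exp.shape:
        raise ValueError("profiles must share a grid")
    keep = np.ones(sim.shape[0], bool)
    if excluded is not None:
        keep &= ~np.asarray(excluded, bool)
    if np.any(sim[keep] <= 0):
        raise ValueError("zero simulated frequency inside the comparison set")
    s, e = sim[keep], exp[keep]
    return float(((s - e) ** 2 / s).sum())


def breaksite_exclusion_mask(n_bins: int, breaksite_bin: int,
                             halfwidth_bins: int) -> np.ndarray:
    """Boolean mask dropping +-halfwidth bins around the breaksite."""
    mask = np.zeros(n_bins, bool)
    lo = max(0, breaksite_bin - halfwidth_bins)
    hi = min(n_bins, breaksite_bin + halfwidth_bins + 1)
    mask[lo:hi] = True
    return mask


def fit_pce(spec: ChromosomeSpec, ensemble: ConformationEnsemble,
            params: IRParams, gamma_sp: SpontaneousProfile | None,
            exp_profile: np.ndarray, grid,
            excluded: np.ndarray | None = None,
            r_cont: float = DEFAULT_R_CONT) -> float:
    """Contact-to-exchange probability minimising the chi-square.

    The simulated profile is linear in ``p_ce``, so the grid search scans a
    scale factor; the closed-form optimum of the chi-square statistic for a
    pure scale factor, ``p* = sqrt(sum(e^2/g) / sum(g))`` with ``g`` the
    unit-``p_ce`` profile, is available via :func:`pce_closed_form`.
    """
    grid = np.asarray(list(grid), float)
    if grid.size == 0:
        raise ValueError("empty candidate grid")
    exp_profile = np.asarray(exp_profile, float)
    base = population_breakpoints_cf(spec, ensemble, params, gamma_sp,
                                     p_ce=1.0, decoupled=True,
                                     r_cont=r_cont).values
    if excluded is None:
        excluded = breaksite_exclusion_mask(spec.n_subunits, spec.breaksite, 5)
    keep = ~excluded & (base > 0)
    if not keep.any() or exp_profile[keep].sum() == 0:
        raise ValueError("degenerate experimental profile")
    drop = ~keep
    chis = [chi_square(p * base, exp_profile, excluded=drop) for p in grid]
    return float(grid[int(np.argmin(chis))])


def pce_closed_form(base: np.ndarray, exp_profile: np.ndarray,
                    keep: np.ndarray) -> float:
    """Analytic chi-square minimiser for a profile linear in p_ce."""
    g = np.asarray(base, float)[keep]
    e = np.asarray(exp_profile, float)[keep]
    return float(np.sqrt((e ** 2 / g).sum() / g.sum()))


def fluctuation_stats(samples: np.ndarray) -> float:
    """Relative fluctuation SD/mean of per-cell samples."""
    x = np.asarray(samples, float)
    if x.shape[0] < 2:
        raise ValueError("need at least two samples")
    m = x.mean()
    if m == 0:
        raise ValueError("zero mean")
    return float(x.std(ddof=1) / m)


def single_cell_statistics(spec: ChromosomeSpec,
                           ensemble: ConformationEnsemble,
                           params: IRParams,
                           gamma_sp: SpontaneousProfile | None,
                           p_ce: float, m_cells: int, seed: int = 0,
                           r_cont: float = DEFAULT_R_CONT) -> dict:
    """Per-cell samples of the fluctuating quantities.

    Returns arrays (length ``m_cells``) of: total contacts in the cell,
    contacts of any locus with the breaksite, contacts of damaged loci
    with the breaksite, and breakpoints, each summed over the two
    chromosome copies.
    """
    rng = np.random.default_rng(seed)
    k = len(ensemble)
    n = spec.n_subunits
    bait = spec.breaksite
    # per-member contact summaries, precomputed once
    binmaps = []
    for m in range(k):
        from .contacts import conformation_contacts
        bm = conformation_contacts(Conformation(ensemble.positions[m]), r_cont)
        np.fill_diagonal(bm, 0)
        for off in (-1, 1):
            idx = np.arange(max(0, -off), n - max(0, off))
            bm[idx, idx + off] = 0
        binmaps.append(bm.astype(bool))
    totals = np.array([int(np.triu(bm, 2).sum()) for bm in binmaps])
    bait_rows = np.array([bm[bait] for bm in binmaps])
    out = {"total_contacts": np.zeros(m_cells),
           "bait_contacts": np.zeros(m_cells),
           "lesion_bait_contacts": np.zeros(m_cells),
           "breakpoints": np.zeros(m_cells)}
    for c in range(m_cells):
        for copy in range(2):
            m = int(rng.integers(0, k))
            out["total_contacts"][c] += totals[m]
            row = bait_rows[m]
            out["bait_contacts"][c] += row.sum()
            dmg = sample_damage(spec, params, gamma_sp, nuclease=True, seed=rng)
            sel = np.zeros(n, bool)
            sel[dmg.beads] = True
            sel[bait] = False
            n_lc = int((row & sel).sum())
            out["lesion_bait_contacts"][c] += n_lc
            pairs = lesion_contact_pairs(Conformation(ensemble.positions[m]),
                                         dmg, r_cont)
            out["breakpoints"][c] += sum(
                1 for _ in contacts_to_exchanges(pairs, p_ce, rng))
    return out
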