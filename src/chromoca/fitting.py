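"""Inverse fit of the pair attraction field to a target contact map.

The fit is the sign-update iteration used to reconstruct heteropolymer
globule potentials from Hi-C: start from a uniform 1.2 kT attraction,
simulate an ensemble, compare the simulated relative contact map with the
target, and nudge each unmasked pair coefficient up when the simulated
frequency is too low and down when it is too high, clamping at zero.  The
loop stops when the Pearson correlation between maps ceases to improve.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .chromosome import ChromosomeSpec
from .contacts import (DEFAULT_R_CONT, aggregate_contacts, map_pearson,
                       pair_mask)
from .dynamics import (ConformationEnsemble, DynamicsConfig,
                       build_initial_conformation, equilibrate,
                       sample_ensemble)
from .potentials import (HETEROPOLYMER_INITIAL_U0, DEFAULT_U0_EV,
                         PairPotentialField)


@dataclass
class FitConfig:
    initial_u0: float = HETEROPOLYMER_INITIAL_U0
    step_size: float = 0.05
    ensemble_start: int = 200
    ensemble_max: int = 4000
    patience: int = 3
    improve_tol: float = 1e-3
    max_iters: int = 30
    r_cont: float = DEFAULT_R_CONT
    u0_ev: float = DEFAULT_U0_EV
    burn_in_ps: float = 4000.0
    stride_ps: float = 50.0
    equil_window_steps: int = 5000
    dynamics: DynamicsConfig | None = None  # None: step scaled per iteration


@dataclass
class FitHistory:
    """Per-iteration diagnostics of one fit run."""

    pearson: list = dc_field(default_factory=list)
    best_pearson: list = dc_field(default_factory=list)
    mean_abs_update: list = dc_field(default_factory=list)
    ensemble_checksum: list = dc_field(default_factory=list)
    step_size: list = dc_field(default_factory=list)

    def __len__(self):
        return len(self.pearson)


def update_potentials(u0_attr: np.ndarray, sim_map: np.ndarray,
                      target_map: np.ndarray, step_size: float,
                      mask: np.ndarray | None = None) -> np.ndarray:
    """One sign update of the attraction matrix.

    For each unmasked pair: ``u' = max(0, u + step * sign(target - sim))``;
    masked pairs are untouched.  Symmetry and non-negativity are preserved
    by construction.
    """
    u0_attr = np.asarray(u0_attr, float)
    sim_map = np.asarray(sim_map, float)
    target_map = np.asarray(target_map, float)
    if sim_map.shape != target_map.shape or sim_map.shape != u0_attr.shape:
        raise ValueError("potential and map shapes must match")
    delta = step_size * np.sign(target_map - sim_map)
    if mask is not None:
        delta = np.where(mask, delta, 0.0)
    out = np.clip(u0_attr + delta, 0.0, None)
    return (out + out.T) / 2.0


def assign_nonmappable_potentials(u0_attr: np.ndarray,
                                  spec: ChromosomeSpec) -> np.ndarray:
    """Fill non-mappable rows/columns from the nearest mappable flanks.

    The attraction row of a non-mappable bead is replaced by the mean of
    the rows of its nearest mappable neighbours, one on each side; runs at
    a chain end copy the single nearest mappable row.  The assigned row is
    mirrored into the matching column; for a pair of two non-mappable
    beads the assignment of the higher index wins (processed in order).
    """
    nm = sorted(spec.non_mappable)
    out = np.asarray(u0_attr, float).copy()
    if not nm:
        return out
    n = out.shape[0]
    nm_set = set(nm)
    mappable = [i for i in range(n) if i not in nm_set]
    if not mappable:
        raise ValueError("all beads non-mappable")
    src = np.asarray(u0_attr, float)
    for i in nm:
        left = next((j for j in range(i - 1, -1, -1) if j not in nm_set), None)
        right = next((j for j in range(i + 1, n) if j not in nm_set), None)
        if left is None:
            row = src[right].copy()
        elif right is None:
            row = src[left].copy()
        else:
            row = (src[left] + src[right]) / 2.0
        out[i, :] = row
        out[:, i] = row
        out[i, i] = 0.0
    return np.clip(out, 0.0, None)


def fit_potentials(spec: ChromosomeSpec, target_map: np.ndarray,
                   config: FitConfig | None = None, seed: int = 0
                   ) -> tuple[PairPotentialField, ConformationEnsemble, FitHistory]:
    """Iterative recovery of the attraction field from a relative map.

    ``target_map`` must be a relative contact map (unmasked upper triangle
    at s >= 2 summing to 1).  Returns the best-Pearson field, the ensemble
    simulated with it, and the iteration history.  When the Pearson drops,
    the step size is halved (damped sign update); after ``patience``
    iterations without improvement beyond ``improve_tol`` the loop stops.
    """
    cfg = config or FitConfig()
    n = spec.n_subunits
    target_map = np.asarray(target_map, float)
    if target_map.shape != (n, n):
        raise ValueError("target map shape does not match the chromosome")
    mask = pair_mask(spec)

    u = np.full((n, n), cfg.initial_u0)
    np.fill_diagonal(u, 0.0)
    u = assign_nonmappable_potentials(u, spec)

    # one equilibrated excluded-volume coil shared by all iterations;
    # fresh noise seeds per iteration give independent ensembles
    coil = build_initial_conformation(spec, seed)
    ev_only = PairPotentialField(cfg.u0_ev, np.zeros((n, n)))
    eq = equilibrate(coil, ev_only, cfg.dynamics, seed=seed + 1,
                     cage_radius=spec.cage_radius,
                     window_steps=cfg.equil_window_steps)
    if not eq.converged:
        import warnings
        warnings.warn("coil equilibration did not reach the Rg plateau "
                      "within budget; continuing from the final state")
    start = eq.conformation

    history = FitHistory()
    best = None  # (pearson, field, ensemble)
    step = cfg.step_size
    no_improve = 0
    prev_r = -np.inf
    rng = np.random.default_rng(seed)
    for it in range(cfg.max_iters):
        k_it = int(min(cfg.ensemble_max, cfg.ensemble_start * 2 ** it))
        field = PairPotentialField(cfg.u0_ev, u.copy())
        dyn = cfg.dynamics or DynamicsConfig.for_field(field)
        ens = sample_ensemble(spec, field, k_it,
                              int(rng.integers(0, 2 ** 31 - 1)),
                              config=dyn, burn_in_ps=cfg.burn_in_ps,
                              stride_ps=cfg.stride_ps, start=start)
        sim_rel = aggregate_contacts(ens, "relative", cfg.r_cont, spec).values
        r = map_pearson(sim_rel, target_map, mask)

        if best is None or r > best[0] + cfg.improve_tol:
            best = (r, field, ens)
            no_improve = 0
        else:
            no_improve += 1
            if best is not None and r > best[0]:
                best = (r, field, ens)
        if r < prev_r:
            step = max(step / 2.0, cfg.step_size / 16.0)
        prev_r = r

        new_u = update_potentials(u, sim_rel, target_map, step, mask)
        new_u = assign_nonmappable_potentials(new_u, spec)
        history.pearson.append(r)
        history.best_pearson.append(best[0])
        history.mean_abs_update.append(float(np.abs(new_u - u)[mask].mean())
                                       if mask.any() else 0.0)
        history.ensemble_checksum.append(ens.provenance.get("seed"))
        history.step_size.append(step)
        u = new_u
        if no_improve >= cfg.patience:
            break
    return best[1], best[2], history
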