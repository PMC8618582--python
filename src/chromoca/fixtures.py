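"""Forward-generated synthetic datasets with known ground truth.

The generator stands in for external Hi-C matrices and translocation
profiles: it builds a small chromosome with a centromere, a breaksite and
a few non-mappable bins, draws a heteropolymer attraction field with
block structure plus smooth modulation, simulates the conformational
ensemble and derives from it a target contact map, a spontaneous-DSB
profile and a contact-first breakpoint profile with known ``p_ce``.
Everything needed to regenerate the dataset bit-exactly is recorded in
:class:`FixtureTruth`.

Scales: ``tiny`` (N = 50, K = 120) for smoke tests, ``small`` (N = 140,
K = 300) for parameter-recovery studies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .aberrations import population_breakpoints_cf
from .chromosome import ChromosomeSpec
from .contacts import aggregate_contacts
from .damage import IRParams, SpontaneousProfile
from .dynamics import ConformationEnsemble, sample_ensemble
from .potentials import DEFAULT_U0_EV, PairPotentialField

FIXTURE_KINDS = ("contact-map", "breakpoint-profile", "full-pipeline")
SCALES = {"tiny": dict(n=50, k=120), "small": dict(n=120, k=300)}

#: study conditions of the synthetic datasets
FIXTURE_DOSE_GY = 5.0
FIXTURE_P_CE = 0.003


@dataclass
class FixtureTruth:
    """Generating parameters: sufficient to rebuild the fixture bit-exactly."""

    kind: str
    scale: str
    seed: int
    spec: ChromosomeSpec
    field: PairPotentialField
    gamma_sp: SpontaneousProfile | None
    p_ce: float
    dose_gy: float
    k_members: int


def fixture_spec(scale: str = "tiny") -> ChromosomeSpec:
    p = SCALES[scale]
    n = p["n"]
    # proportions follow the full-scale chr18 layout: centromere at the
    # start (~10% of the chain), bait around 3/4 of the length
    cen = max(2, n // 10)
    bait = int(0.75 * n)
    nm = frozenset({n // 3, n // 3 + 1})
    return ChromosomeSpec(label=f"synth{n}", n_subunits=n, breaksite=bait,
                          centromere_span=(0, cen), non_mappable=nm)


def make_truth_field(spec: ChromosomeSpec, seed: int) -> PairPotentialField:
    """Block-structured heteropolymer attractions plus smooth modulation.

    Two diagonal blocks of enhanced self-attraction on a moderate
    background, with a low-frequency sinusoidal texture; clipped at zero.
    """
    n = spec.n_subunits
    rng = np.random.default_rng(seed)
    base = np.full((n, n), 1.0)
    half = n // 2
    base[:half, :half] = 1.8
    base[half:, half:] = 1.5
    idx = np.arange(n)
    tex = 0.25 * np.sin(2 * np.pi * idx / max(8, n // 4))
    base += tex[:, None] + tex[None, :]
    base += 0.05 * rng.standard_normal((n, n))
    base = (base + base.T) / 2.0
    base = np.clip(base, 0.0, None)
    np.fill_diagonal(base, 0.0)
    return PairPotentialField(DEFAULT_U0_EV, base)


def make_truth_gamma(spec: ChromosomeSpec, seed: int = 0) -> SpontaneousProfile:
    """Smooth spontaneous-DSB profile with a hotspot near the bait."""
    n = spec.n_subunits
    idx = np.arange(n)
    bump = 0.02 * np.exp(-0.5 * ((idx - 0.6 * n) / (0.08 * n)) ** 2)
    slope = 0.002 + 0.003 * idx / n
    return SpontaneousProfile(np.clip(slope + bump, 0.0, 1.0))


def generate_fixture(kind: str, scale: str = "tiny", seed: int = 0,
                     k_members: int | None = None) -> dict:
    """Forward-generate a synthetic dataset and its truth record.

    Returns a dict with the chromosome ``spec``, truth ``field``, the
    simulated ``ensemble``, the ``target_map`` (relative mode) and -- for
    the breakpoint kinds -- ``gamma_sp``, ``p_ce`` and the ``profile`` of
    bait-involving breakpoints per cell.  Deterministic for a given seed.
    """
    if kind not in FIXTURE_KINDS:
        raise ValueError(f"unknown fixture kind {kind!r}")
    if scale not in SCALES:
        raise ValueError(f"unknown fixture scale {scale!r}")
    spec = fixture_spec(scale)
    field = make_truth_field(spec, seed)
    k = k_members or SCALES[scale]["k"]
    ensemble = sample_ensemble(spec, field, k, seed + 1)
    target = aggregate_contacts(ensemble, "relative", spec=spec)
    out = {"kind": kind, "scale": scale, "spec": spec, "field": field,
           "ensemble": ensemble, "target_map": target,
           "truth": FixtureTruth(kind, scale, seed, spec, field, None,
                                 FIXTURE_P_CE, FIXTURE_DOSE_GY, k)}
    if kind in ("breakpoint-profile", "full-pipeline"):
        gamma = make_truth_gamma(spec)
        params = IRParams(dose_gy=FIXTURE_DOSE_GY)
        bp = population_breakpoints_cf(spec, ensemble, params, gamma,
                                       FIXTURE_P_CE, decoupled=True)
        out["gamma_sp"] = gamma
        out["p_ce"] = FIXTURE_P_CE
        out["dose_gy"] = FIXTURE_DOSE_GY
        out["profile"] = bp.values
        out["truth"].gamma_sp = gamma
    return out
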