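"""Synthetic inputs with the statistical structure of the digestion study.

Three generators replace the wet-lab data sources so every pipeline stage is
testable end to end:

* densitometry time courses — first-order band decay with multiplicative
  Gaussian noise (band-intensity errors scale with signal);
* identified-peptide tables — draws from the in silico semi-specific digest
  of the Pru p 3 fixture, with dominance weights favouring the preferred
  proteolysis products, log-normal spectral counts, sprinkled phosphorylation
  and a configurable fraction of sub-threshold scores;
* inhibition-ELISA curves — 4PL responses on a seven-decade concentration
  grid with additive Gaussian noise (OD error is roughly signal-independent).

Each generator draws from its own pseudo-random stream derived from the
master seed, so regenerating one table never perturbs the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import DisulphideTopology, ProteinIsoform, load_prup3_fixtures
from .digest import (
    CHYMOTRYPSIN,
    TRYPSIN,
    CleavageRule,
    digest,
    nonreduced_observable,
)

# Rate constants (min^-1) of parent-band decay per digestion condition; None
# marks conditions where the protein is fully resistant (infinite half-life).
PARENT_K_BY_CONDITION: dict[str, float | None] = {
    "high_pH6.5_bile0mM": 0.0022,
    "high_pH6.5_bile4mM": 0.0451,
    "high_pH8_bile0mM": 0.0055,
    "high_pH8_bile4mM": 0.1292,
    "low_pH6.5_bile0mM": None,
    "low_pH6.5_bile1mM": 0.0016,
    "low_pH8_bile0mM": None,
    "low_pH8_bile1mM": 0.0073,
}

# 7 kDa fragment kinetics: low-enzyme tests show rising accumulation with the
# listed formation rate; high-enzyme bile tests show a transient intermediate
# (formation at the parent's decay rate, slower onward degradation).
FRAGMENT_RISING_K: dict[str, float] = {
    "low_pH6.5_bile1mM": 0.0126,
    "low_pH8_bile1mM": 0.0216,
}
FRAGMENT_TRANSIENT: dict[str, tuple[float, float]] = {
    # condition -> (k_form, k_deg); onward degradation set to k_form/4
    "high_pH6.5_bile4mM": (0.0451, 0.0451 / 4),
    "high_pH8_bile4mM": (0.1292, 0.1292 / 4),
}

DEFAULT_TIME_GRID = (0.0, 10.0, 20.0, 40.0, 60.0, 90.0, 120.0)

# Preferred proteolysis products observed to dominate the digests.
DOMINANT_PEPTIDES = (
    (1, 26),   # I1-A26
    (1, 29),   # I1-N29
    (51, 61),  # L51-V61
    (50, 79),  # C50-Y79
    (66, 91),  # A66-K91
    (86, 91),  # N86-K91
    (53, 72),  # Q53-K72 (dominant in non-reduced digests)
)


@dataclass
class DecaySimConfig:
    time_grid: tuple[float, ...] = DEFAULT_TIME_GRID
    noise_sigma: float = 0.05  # multiplicative
    replicates: int = 3
    i0: float = 1.0
    parent_k: dict = field(default_factory=lambda: dict(PARENT_K_BY_CONDITION))


@dataclass
class IdentificationSimConfig:
    n_reduced_range: tuple[int, int] = (97, 114)
    n_nonreduced_range: tuple[int, int] = (21, 23)
    length_range: tuple[int, int] = (6, 30)
    mass_range_Da: tuple[float, float] = (500.0, 5000.0)
    max_missed: int = 2
    dominance_weight: float = 400.0
    count_lognormal_mu: float = 1.2
    count_lognormal_sigma: float = 1.0
    dominant_count_boost: float = 6.0
    phospho_sites: tuple[int, ...] = (55, 57, 82)
    phospho_probability: float = 0.3
    subthreshold_score_fraction: float = 0.15


@dataclass
class ElisaSimConfig:
    conc_grid: tuple[float, ...] = tuple(float(x) for x in np.logspace(-5, 1, 7))
    noise_sigma_rel: float = 0.03  # additive, as a fraction of the upper asymptote
    a: float = 2.0
    d: float = 0.1
    b: float = 1.0
    # per patient: inflection c (µg/mL) for intact / digest / digest+bile
    patients: dict = field(
        default_factory=lambda: {
            "P1": (0.005, 0.005, 0.40),
            "P4": (0.005, 0.005, 3.89),
            "P5": (0.02, 0.25, 20.0),
            "P6": (0.17, 0.005, 1.57),
            "P7": (0.005, 0.005, 30.0),
            "P8": (0.01, 0.21, 25.0),
        }
    )


@dataclass
class SimulationConfig:
    seed: int = 0
    decay: DecaySimConfig = field(default_factory=DecaySimConfig)
    identifications: IdentificationSimConfig = field(
        default_factory=IdentificationSimConfig
    )
    elisa: ElisaSimConfig = field(default_factory=ElisaSimConfig)

    def rng(self, stream: int) -> np.random.Generator:
        # one independent stream per output table, all derived from the seed
        return np.random.default_rng([int(self.seed), stream])


_STREAM_DECAY, _STREAM_IDENT, _STREAM_ELISA = 1, 2, 3


def gen_timecourse(config: SimulationConfig) -> pd.DataFrame:
    """Densitometry table: condition_id, band, replicate, time_min, rel_intensity.

    Parent bands decay as I0·exp(-K·t)·(1+ε), ε ~ N(0, σ), truncated at 0;
    resistant conditions hold at I0.  Fragment bands follow the rising or
    transient model where the condition defines one.
    """
    rng = config.rng(_STREAM_DECAY)
    cfg = config.decay
    t = np.asarray(cfg.time_grid, dtype=float)
    rows = []

    def emit(condition_id, band, clean):
        for rep in range(1, cfg.replicates + 1):
            noisy = clean * (1.0 + rng.normal(0.0, cfg.noise_sigma, size=len(t)))
            noisy = np.maximum(noisy, 0.0)
            for ti, yi in zip(t, noisy):
                rows.append(
                    {
                        "condition_id": condition_id,
                        "band": band,
                        "replicate": rep,
                        "time_min": ti,
                        "rel_intensity": yi,
                    }
                )

    from .kinetics import rising_model, transient_model

    for cond, k in cfg.parent_k.items():
        clean = (
            np.full_like(t, cfg.i0)
            if k is None
            else cfg.i0 * np.exp(-k * t)
        )
        emit(cond, "parent", clean)
        if cond in FRAGMENT_RISING_K:
            emit(cond, "fragment_7kDa",
                 rising_model(t, cfg.i0, FRAGMENT_RISING_K[cond]))
        elif cond in FRAGMENT_TRANSIENT:
            kf, kd = FRAGMENT_TRANSIENT[cond]
            emit(cond, "fragment_7kDa", transient_model(t, cfg.i0, kf, kd))
    return pd.DataFrame(rows)


def _format_mods(mods: list[tuple[int, str]]) -> str:
    return ";".join(f"{pos}:{name}" for pos, name in mods)


def gen_identifications(
    config: SimulationConfig,
    isoform: ProteinIsoform | None = None,
    rules: tuple[CleavageRule, ...] = (TRYPSIN, CHYMOTRYPSIN),
    topology: DisulphideTopology | None = None,
    samples: tuple[tuple[str, bool], ...] = (
        ("high_pH8_bile4mM_red", True),
        ("high_pH8_bile4mM_nonred", False),
    ),
) -> pd.DataFrame:
    """Identification table emulating the LC-MS/MS output of the digests.

    Peptides are drawn without replacement from the semi-specific in silico
    digest, with dominance weights making the preferred products near-certain
    picks.  Non-reduced samples draw only disulphide-untethered peptides.
    """
    if isoform is None or topology is None:
        fix_iso, _, fix_topo = load_prup3_fixtures()
        isoform = isoform or fix_iso
        topology = topology or fix_topo
    rng = config.rng(_STREAM_IDENT)
    cfg = config.identifications

    pool = digest(
        isoform,
        rules=rules,
        max_missed=cfg.max_missed,
        specificity="semi",
        length_range=cfg.length_range,
        mass_range_Da=cfg.mass_range_Da,
    )
    dominant = set(DOMINANT_PEPTIDES)
    nonred_pool = [p for p in pool if nonreduced_observable(p, topology)]

    rows = []
    for sample_id, reduced in samples:
        cand = pool if reduced else nonred_pool
        lo, hi = cfg.n_reduced_range if reduced else cfg.n_nonreduced_range
        n_draw = int(rng.integers(lo, hi + 1))
        if n_draw > len(cand):
            raise ValueError(
                f"sample {sample_id}: requested {n_draw} peptides but the "
                f"theoretical pool holds only {len(cand)}"
            )
        weights = np.array(
            [cfg.dominance_weight if (p.start, p.end) in dominant else 1.0
             for p in cand]
        )
        idx = rng.choice(
            len(cand), size=n_draw, replace=False, p=weights / weights.sum()
        )
        for i in idx:
            pep = cand[i]
            count = max(
                1,
                int(round(rng.lognormal(cfg.count_lognormal_mu,
                                        cfg.count_lognormal_sigma))),
            )
            if (pep.start, pep.end) in dominant:
                count = int(round(count * cfg.dominant_count_boost))
            mods: list[tuple[int, str]] = []
            for site in cfg.phospho_sites:
                if pep.start <= site <= pep.end and (
                    rng.random() < cfg.phospho_probability
                ):
                    mods.append((site - pep.start + 1, "phospho-S"))
            if reduced:
                mods.extend(
                    (j + 1, "carbamidomethyl-C")
                    for j, aa in enumerate(pep.sequence)
                    if aa == "C"
                )
            if rng.random() < cfg.subthreshold_score_fraction:
                score = rng.uniform(1.0, 5.0)
            else:
                score = 5.0 + rng.exponential(10.0)
            rows.append(
                {
                    "sample_id": sample_id,
                    "reduced": reduced,
                    "sequence": pep.sequence,
                    "mods": _format_mods(mods),
                    "score": round(float(score), 3),
                    "spectral_count": count,
                }
            )
    return pd.DataFrame(rows)


def gen_inhibition_curves(config: SimulationConfig) -> pd.DataFrame:
    """ELISA table: patient_id, sample, conc_ug_per_ml, A450."""
    rng = config.rng(_STREAM_ELISA)
    cfg = config.elisa
    x = np.asarray(cfg.conc_grid, dtype=float)
    rows = []
    for patient, c_values in cfg.patients.items():
        for sample, c in zip(("intact", "digest", "digest+bile"), c_values):
            clean = cfg.d + (cfg.a - cfg.d) / (1.0 + (x / c) ** cfg.b)
            noisy = clean + rng.normal(0.0, cfg.noise_sigma_rel * cfg.a, len(x))
            noisy = np.maximum(noisy, 0.0)
            for xi, yi in zip(x, noisy):
                rows.append(
                    {
                        "patient_id": patient,
                        "sample": sample,
                        "conc_ug_per_ml": xi,
                        "A450": yi,
                    }
                )
    return pd.DataFrame(rows)
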