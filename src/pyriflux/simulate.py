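"""Synthetic inputs: toy pyrimidine network, expression, assays, melt curves.

The toy network is a hand-specified 18-reaction model of the pathways a
DHODH inhibitor interrogates: pyrimidine de novo synthesis (glutamine ->
lumped CAD -> dihydroorotate -> DHODH -> orotate -> UMP), the uridine
salvage branch that can rescue UMP production when DHODH is blocked,
glycolysis to lactate with a lumped TCA/respiratory-chain stub that
regenerates the ubiquinone consumed by DHODH, and glutathione synthesis.
Biomass consumes UMP plus an ATP proxy, glutathione and citrate, so de novo
(or salvage) pyrimidine flux is strictly required for growth.

Being hand-specified, the network has closed-form flux expectations; a
separate random-model generator provides guaranteed-feasible fuzz cases for
oracle tests.  Every generator is a pure function of its configuration and
seed (default seed 20250233).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .expression import ExpressionProfile
from .kinetics import AssayTable, MeltCurve
from .network import MetabolicModel, Metabolite, Reaction, parse_gpr
from .flux import optimize_biomass

__all__ = [
    "DEFAULT_SEED",
    "PAPER_SINK_METABOLITES",
    "ToyModelConfig",
    "EffectSpec",
    "build_toy_pyrimidine_model",
    "simulate_expression_profiles",
    "simulate_inhibition_assay",
    "simulate_melt_curve",
    "random_feasible_model",
]

DEFAULT_SEED = 20250233

#: Metabolites given sink reactions in the curated genome-scale model:
#: dihydroorotate, orotate, glutamine, pyruvate, citrate, NAD, NADH,
#: aspartate, acetyl-CoA, ubiquinol, ubiquinone.
PAPER_SINK_METABOLITES = (
    "dho", "oro", "gln", "pyr", "cit", "nad", "nadh", "asp", "accoa", "qh2", "q",
)


@dataclass(frozen=True)
class ToyModelConfig:
    """Knobs of the toy network.

    salvage_ub is the uridine uptake capacity (0 closes the salvage rescue
    route); uptake_ub caps the glutamine and glucose uptakes.  The built-in
    sinks (orotate drain) use drain-only bounds so that de novo synthesis
    stays the sole pyrimidine source; ``include_sinks=False`` omits them for
    curation experiments.
    """

    salvage_ub: float = 0.0
    uptake_ub: float = 10.0
    include_glycolysis: bool = True
    include_glutathione: bool = True
    include_sinks: bool = True
    biomass_stoichiometry: Mapping[str, float] | None = None

    def __post_init__(self):
        if self.salvage_ub < 0:
            raise ValueError("salvage_ub must be >= 0")
        if self.uptake_ub <= 0:
            raise ValueError("uptake_ub must be > 0")


@dataclass(frozen=True)
class EffectSpec:
    """Condition effect on gene expression: treated value = effect x control.

    effects maps gene id to a multiplicative factor (0.2 = 5-fold down);
    noise_cv is the lognormal coefficient of variation; n_replicates
    profiles are drawn per condition.
    """

    effects: Mapping[str, float] = field(default_factory=dict)
    noise_cv: float = 0.1
    n_replicates: int = 3
    seed: int = DEFAULT_SEED

    def __post_init__(self):
        if any(e <= 0 for e in self.effects.values()):
            raise ValueError("effects must be positive multiplicative factors")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        object.__setattr__(self, "effects", dict(self.effects))


def build_toy_pyrimidine_model(config: ToyModelConfig | None = None) -> MetabolicModel:
    """Hand-specified toy pyrimidine-metabolism network (see module docstring).

    Guaranteed feasible with positive biomass at the default configuration.
    """
    cfg = config or ToyModelConfig()
    M = Metabolite
    mets = [
        M("gln", "glutamine"), M("asp", "aspartate"), M("dho", "dihydroorotate"),
        M("oro", "orotate"), M("ump", "UMP"), M("uri", "uridine"),
        M("q", "ubiquinone"), M("qh2", "ubiquinol"), M("gsh", "glutathione"),
    ]
    big = 1000.0

    def rxn(rid, stoich, lb, ub, gpr=None, name="", is_sink=False):
        return Reaction(rid, stoich, lb=lb, ub=ub,
                        gpr=parse_gpr(gpr) if gpr else None, name=name, is_sink=is_sink)

    rxns = [
        rxn("EX_gln", {"gln": 1}, 0, cfg.uptake_ub, name="glutamine uptake"),
        rxn("EX_asp", {"asp": 1}, 0, big, name="aspartate uptake"),
        rxn("EX_uri", {"uri": 1}, 0, cfg.salvage_ub, name="uridine uptake (salvage)"),
        rxn("CAD", {"gln": -1, "asp": -1, "dho": 1}, 0, big, gpr="CAD",
            name="lumped CAD: carbamoyl-P synthesis to dihydroorotate"),
        rxn("DHODH", {"dho": -1, "q": -1, "oro": 1, "qh2": 1}, 0, 10, gpr="DHODH",
            name="dihydroorotate dehydrogenase"),
        rxn("UMPS", {"oro": -1, "ump": 1}, 0, 5, gpr="UMPS",
            name="UMP synthase (lumped OPRT+ODC)"),
        rxn("UK", {"uri": -1, "ump": 1}, 0, big, gpr="UCK2",
            name="uridine kinase (salvage)"),
        rxn("CIII", {"qh2": -1, "q": 1}, 0, big, gpr="UQCRC1",
            name="lumped complex III/IV: ubiquinol re-oxidation"),
    ]
    biomass_stoich: dict[str, float] = {"ump": -1.0}
    if cfg.include_glycolysis:
        mets += [M("glc", "glucose"), M("pyr", "pyruvate"), M("lac", "lactate"),
                 M("atp", "ATP proxy"), M("nad", "NAD"), M("nadh", "NADH"),
                 M("accoa", "acetyl-CoA"), M("cit", "citrate")]
        rxns += [
            rxn("EX_glc", {"glc": 1}, 0, cfg.uptake_ub, name="glucose uptake"),
            rxn("GLYC", {"glc": -1, "pyr": 2, "atp": 2}, 0, big, gpr="GAPDH",
                name="lumped glycolysis"),
            rxn("LDH", {"pyr": -1, "lac": 1}, 0, big, gpr="LDHA",
                name="lactate dehydrogenase"),
            rxn("EX_lac", {"lac": -1}, 0, big, name="lactate export"),
            rxn("PDH", {"pyr": -1, "nad": -1, "accoa": 1, "nadh": 1}, 0, big,
                gpr="PDHA1", name="pyruvate dehydrogenase"),
            rxn("CS", {"accoa": -1, "cit": 1}, 0, big, gpr="CS", name="citrate synthase"),
            rxn("CI", {"nadh": -1, "q": -1, "nad": 1, "qh2": 1}, 0, big,
                gpr="NDUFS1", name="complex I"),
        ]
        biomass_stoich["atp"] = -1.0
        biomass_stoich["cit"] = -0.05
    if cfg.include_glutathione:
        rxns.append(rxn("GCLC", {"gln": -1, "gsh": 1}, 0, big, gpr="GCLC",
                        name="lumped glutathione synthesis"))
        biomass_stoich["gsh"] = -0.2
    else:
        mets = [m for m in mets if m.id != "gsh"]
    if cfg.biomass_stoichiometry is not None:
        biomass_stoich = dict(cfg.biomass_stoichiometry)
    rxns.append(rxn("BIOMASS", biomass_stoich, 0, big, name="biomass demand"))
    if cfg.include_sinks:
        rxns.append(rxn("sink_oro", {"oro": -1}, 0, big, is_sink=True,
                        name="orotate drain"))
    model = MetabolicModel(mets, rxns, "BIOMASS", id="toy_pyrimidine")
    sol = optimize_biomass(model)
    if not sol.optimal or (cfg.biomass_stoichiometry is None
                           and cfg.salvage_ub == 0 and sol.fmax <= 0):
        # With default biomass and salvage closed, de novo flux must support
        # growth; a config that breaks this is rejected at build time.
        if not sol.optimal or sol.fmax <= 0:
            raise ValueError(f"toy model configuration is infeasible (fmax={sol.fmax!r})")
    return model


def simulate_expression_profiles(
    model: MetabolicModel, effects: EffectSpec
) -> list[ExpressionProfile]:
    """Lognormal expression around 1 (control) or the gene effect (treated).

    The lognormal is parameterized so that the arithmetic mean equals the
    targeted level and the coefficient of variation equals noise_cv; with
    noise_cv = 0 the values are exact.
    """
    unknown = set(effects.effects) - model.genes
    if unknown:
        raise KeyError(f"effect genes absent from model: {sorted(unknown)}")
    rng = np.random.default_rng(effects.seed)
    genes = sorted(model.genes)
    sigma2 = math.log(1.0 + effects.noise_cv ** 2)
    sigma = math.sqrt(sigma2)
    profiles = []
    for condition in ("control", "treated"):
        for rep in range(1, effects.n_replicates + 1):
            values = {}
            for g in genes:
                mean = effects.effects.get(g, 1.0) if condition == "treated" else 1.0
                if sigma == 0:
                    values[g] = mean
                else:
                    values[g] = float(
                        rng.lognormal(math.log(mean) - sigma2 / 2.0, sigma)
                    )
            profiles.append(ExpressionProfile(f"{condition}_{rep}", condition, values))
    return profiles


_RATE_LAWS = {
    "competitive": lambda Vmax, S, Km, Ki, I: Vmax * S / (Km * (1.0 + I / Ki) + S),
    "uncompetitive": lambda Vmax, S, Km, Ki, I: Vmax * S / (Km + S * (1.0 + I / Ki)),
}


def simulate_inhibition_assay(
    mode: str,
    Ki: float,
    Km: float,
    Vmax: float,
    S: float,
    I_grid: Sequence[float],
    noise_cv: float = 0.0,
    seed: int = DEFAULT_SEED,
    replicate: str = "r1",
) -> AssayTable:
    """Activities from the competitive or uncompetitive rate law.

    competitive:   v = Vmax S / (Km (1 + I/Ki) + S)
    uncompetitive: v = Vmax S / (Km + S (1 + I/Ki))

    Multiplicative lognormal noise with coefficient of variation noise_cv;
    the I = 0 point reduces to the Michaelis-Menten rate exactly when
    noiseless.
    """
    if mode not in _RATE_LAWS:
        raise ValueError(f"unknown inhibition mode {mode!r}")
    if min(Ki, Km, Vmax, S) <= 0:
        raise ValueError("Ki, Km, Vmax and S must be positive")
    I = np.asarray(list(I_grid), dtype=float)
    if I.size == 0:
        raise ValueError("inhibitor grid is empty")
    v = _RATE_LAWS[mode](Vmax, S, Km, Ki, I)
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        sigma2 = math.log(1.0 + noise_cv ** 2)
        v = v * rng.lognormal(-sigma2 / 2.0, math.sqrt(sigma2), size=v.shape)
    return AssayTable(S, I, v, replicate=replicate)


def simulate_melt_curve(
    Tm: float,
    slope: float = 1.5,
    baselines: tuple[float, float] = (0.85, 1.10),
    drifts: tuple[float, float] = (0.0, 0.0),
    noise_sd: float = 0.0,
    seed: int = DEFAULT_SEED,
    T_range: tuple[float, float] = (35.0, 80.0),
    step: float = 0.25,
    label: str = "",
) -> MeltCurve:
    """Two-state sigmoid 350/330 melt curve with linear baselines.

    ratio(T) = low(T) + (high(T) - low(T)) / (1 + exp((Tm - T)/slope)),
    with low/high the drifting baselines, plus gaussian noise of ``noise_sd``.
    """
    lo, hi = T_range
    if not lo < Tm < hi:
        raise ValueError(f"Tm={Tm} outside temperature range {T_range}")
    if slope <= 0:
        raise ValueError("slope must be positive")
    T = np.arange(lo, hi + step / 2, step)
    base_lo = baselines[0] + drifts[0] * (T - lo)
    base_hi = baselines[1] + drifts[1] * (T - lo)
    frac = 1.0 / (1.0 + np.exp((Tm - T) / slope))
    R = base_lo + (base_hi - base_lo) * frac
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        R = R + rng.normal(0.0, noise_sd, size=R.shape)
    return MeltCurve(T, R, label=label)


def random_feasible_model(
    n_reactions: int = 8, seed: int = DEFAULT_SEED
) -> MetabolicModel:
    """Small random stoichiometric model, feasible by construction.

    Every reaction admits zero flux (lb <= 0 <= ub), so v = 0 is always
    feasible; random source/drain exchanges make nonzero optima common.
    Intended for oracle fuzz tests, not for simulating biology.
    """
    if not 2 <= n_reactions:
        raise ValueError("need at least 2 reactions")
    rng = np.random.default_rng(seed)
    n_mets = max(1, n_reactions - int(rng.integers(1, 3)))
    mets = [Metabolite(f"m{i}") for i in range(n_mets)]
    rxns: list[Reaction] = []
    # a source and a drain guarantee at least one through-path
    rxns.append(Reaction("src", {"m0": 1.0}, lb=0.0, ub=float(rng.integers(1, 11))))
    drain_met = f"m{n_mets - 1}"
    rxns.append(Reaction("drn", {drain_met: -1.0}, lb=0.0, ub=float(rng.integers(5, 16))))
    for k in range(n_reactions - 2):
        size = int(rng.integers(1, min(4, n_mets) + 1))
        chosen = rng.choice(n_mets, size=size, replace=False)
        stoich = {}
        for j, mi in enumerate(chosen):
            coef = float(rng.choice([-2.0, -1.0, 1.0, 2.0]))
            if j == 0 and size > 1:
                coef = -abs(coef)  # bias toward consuming something
            stoich[f"m{mi}"] = coef
        reversible = bool(rng.random() < 0.4)
        ub = float(rng.integers(1, 11))
        lb = -float(rng.integers(1, 11)) if reversible else 0.0
        rxns.append(Reaction(f"r{k}", stoich, lb=lb, ub=ub))
    objective = str(rng.choice([r.id for r in rxns]))
    return MetabolicModel(mets, rxns, objective, id=f"random_{seed}")
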