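"""Regulation rules, reaction networks, and preset builders.

Three families of presets are provided, mirroring the systems the model is
designed to interrogate:

* two-gene reporter/inducible constructs in the four syntaxes (tandem with
  the reporter upstream or downstream, convergent, divergent), under linear
  or circular boundary conditions;
* the mutual-repression toggle switch, with Hill-function repression acting
  directly on mRNA counts;
* the zebrafish her1-her7 segmentation-clock pair, with binary
  (dimer-occupancy) promoters and an explicit translation/dimerization
  reaction network, in gene-paired or unpaired (1 Mb separation) form.

Presets are plain data (layout + rules + network + protocol) and can be
serialized to the configuration schema, so every experiment is a config.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Dict, List, Optional, Tuple

from supertx.physics import (
    InitiationModelKind,
    PhysicalParams,
    TorqueModelKind,
)
from supertx.state import BoundaryKind, GeneAnnotation, GenomeLayout, Strand

#: Default basal initiation rate, 1/s (one polymerase per 160 s).
R0_DEFAULT = 1.0 / 160.0
#: Default mRNA half-life for the synthetic-circuit presets, s (20 min).
MRNA_HALFLIFE = 1200.0
#: Default time at which the adjacent/second gene is induced, s (2.8 h).
INDUCTION_TIME = 10000.0


class Syntax(str, Enum):
    TANDEM_UPSTREAM = "tandem_upstream"      # reporter upstream of the adjacent gene
    TANDEM_DOWNSTREAM = "tandem_downstream"  # reporter downstream
    CONVERGENT = "convergent"
    DIVERGENT = "divergent"


class RuleKind(str, Enum):
    CONSTANT = "constant"
    HILL_REPRESSION = "hill_repression"
    OCCUPANCY_BINARY = "occupancy_binary"


class ConfigurationError(ValueError):
    pass


class CalibrationError(RuntimeError):
    pass


@dataclass
class PromoterRule:
    """Base (biochemical) initiation-rate rule for one promoter.

    The supercoiling Boltzmann factor multiplies this base rate; induction
    is a further multiplicative factor that the protocol may change at run
    time (it starts at ``induction``).
    """

    kind: RuleKind = RuleKind.CONSTANT
    r0: float = R0_DEFAULT
    K: float = 1.0
    n_hill: float = 2.0
    repressor: Optional[str] = None
    induction: float = 1.0
    occupancy_species: Optional[str] = None  # pseudo-species "<gene>_promoter_free"

    def __post_init__(self):
        if self.r0 < 0:
            raise ConfigurationError("r0 must be >= 0")
        if self.kind == RuleKind.HILL_REPRESSION:
            if self.K <= 0 or self.n_hill <= 0:
                raise ConfigurationError("hill rule needs K > 0 and n_hill > 0")
            if self.repressor is None:
                raise ConfigurationError("hill rule needs a repressor species")


def promoter_base_rate(
    rule: PromoterRule,
    species: Dict[str, int],
    induction: Optional[float] = None,
) -> float:
    """Regulation-dependent base initiation rate r(S), 1/s.

    constant          -> induction * r0
    hill_repression   -> induction * r0 / (1 + (R/K)**n)
    occupancy_binary  -> 0 while the promoter is bound, else induction * r0
    """
    ind = rule.induction if induction is None else induction
    if rule.kind == RuleKind.CONSTANT:
        return ind * rule.r0
    if rule.kind == RuleKind.HILL_REPRESSION:
        if rule.repressor not in species:
            raise ConfigurationError(f"unknown repressor species {rule.repressor!r}")
        r = species[rule.repressor]
        return ind * rule.r0 / (1.0 + (r / rule.K) ** rule.n_hill)
    if rule.kind == RuleKind.OCCUPANCY_BINARY:
        if rule.occupancy_species not in species:
            raise ConfigurationError(
                f"unknown promoter occupancy species {rule.occupancy_species!r}"
            )
        return ind * rule.r0 if species[rule.occupancy_species] > 0 else 0.0
    raise ConfigurationError(f"unknown rule kind {rule.kind!r}")


@dataclass(frozen=True)
class Reaction:
    """Mass-action reaction: reactants are consumed, catalysts only enter
    the propensity, products are produced."""

    name: str
    rate: float
    reactants: Dict[str, int] = field(default_factory=dict)
    products: Dict[str, int] = field(default_factory=dict)
    catalysts: Dict[str, int] = field(default_factory=dict)

    def propensity(self, species: Dict[str, int]) -> float:
        a = self.rate
        for s, nu in list(self.reactants.items()) + list(self.catalysts.items()):
            c = species.get(s, 0)
            for j in range(nu):
                a *= max(c - j, 0)
            a /= math.factorial(nu)
        return a

    def apply(self, species: Dict[str, int]) -> None:
        for s, nu in self.reactants.items():
            if species.get(s, 0) < nu:
                raise RuntimeError(f"reaction {self.name}: negative count for {s}")
            species[s] -= nu
        for s, nu in self.products.items():
            species[s] = species.get(s, 0) + nu


@dataclass
class ReactionNetwork:
    species: List[str] = field(default_factory=list)
    reactions: List[Reaction] = field(default_factory=list)

    def consumed_species(self) -> set:
        out = set()
        for r in self.reactions:
            out |= set(r.reactants)
        return out

    def referenced_species(self) -> set:
        """Species whose count enters any propensity."""
        out = set()
        for r in self.reactions:
            out |= set(r.reactants) | set(r.catalysts)
        return out

    @staticmethod
    def decay(species: str, rate: float) -> Reaction:
        return Reaction(name=f"{species}_decay", rate=rate, reactants={species: 1})


@dataclass
class TopoSettings:
    """Stochastic topoisomerase relaxation: mode and firing rate (1/s)."""

    mode: str = "none"  # none | intergenic | intragenic
    rate: float = 0.0


@dataclass
class Protocol:
    """Timed interventions: (time, gene, new induction factor)."""

    duration: float = 40000.0
    interventions: List[Tuple[float, str, float]] = field(default_factory=list)
    sample_dt: float = 10.0


@dataclass
class CircuitPreset:
    """Everything needed to run one experiment."""

    name: str
    layout: GenomeLayout
    rules: Dict[str, PromoterRule]
    network: ReactionNetwork
    protocol: Protocol
    params: PhysicalParams = field(default_factory=PhysicalParams)
    torque_kind: TorqueModelKind = TorqueModelKind.BASE_MARKO
    initiation_kind: InitiationModelKind = InitiationModelKind.SECOND_ORDER
    topo: TopoSettings = field(default_factory=TopoSettings)
    initial_species: Dict[str, int] = field(default_factory=dict)
    normalization: float = 250.0
    ensemble_n: int = 20
    base_seed: int = 0

    def __post_init__(self):
        gene_names = {g.name for g in self.layout.genes}
        missing = gene_names - set(self.rules)
        if missing:
            raise ConfigurationError(f"genes without promoter rules: {sorted(missing)}")


# ---------------------------------------------------------------------------
# two-gene reporter constructs
# ---------------------------------------------------------------------------

def _two_gene_layout(
    syntax: Syntax,
    spacing: float,
    boundary_kind: BoundaryKind,
    gene_length: float,
    margin: float,
) -> GenomeLayout:
    """Reporter + adjacent gene in the requested orientation.

    Layout rule: every promoter's upstream (behind-TSS) wall distance is
    the same B = margin + L + spacing in all four syntaxes, which makes
    reporter-only dynamics syntax-independent (promoter self-enhancement
    scales with the upstream segment) and makes the convergent and
    divergent pairs exact mirror images of each other -- the two members of
    those pairs compete on equal terms.  The reporter is always the
    forward gene.  ``spacing`` separates the nearest ends of the two gene
    bodies: the end-to-start gap for tandem pairs, the TES-to-TES
    (intergenic) distance for convergent, and the TSS-to-TSS
    (inter-promoter) distance for divergent.
    """
    L, s, m = gene_length, spacing, margin
    B = m + L + s  # upstream wall distance of every promoter
    if syntax == Syntax.TANDEM_UPSTREAM:
        # [wall -B- rep> -s- adj> -m- wall]
        reporter = GeneAnnotation("reporter", B, B + L, Strand.FORWARD)
        adjacent = GeneAnnotation("adjacent", B + L + s, B + 2 * L + s, Strand.FORWARD)
        total = B + 2 * L + s + m
    elif syntax == Syntax.TANDEM_DOWNSTREAM:
        # [wall -m- adj> -s- rep> -m- wall]; reporter TSS sits B from the wall
        adjacent = GeneAnnotation("adjacent", m, m + L, Strand.FORWARD)
        reporter = GeneAnnotation("reporter", B, B + L, Strand.FORWARD)
        total = B + L + m
    elif syntax == Syntax.CONVERGENT:
        # [wall -B- rep> -s- <adj -B- wall]: exact mirror pair
        reporter = GeneAnnotation("reporter", B, B + L, Strand.FORWARD)
        adjacent = GeneAnnotation("adjacent", B + 2 * L + s, B + L + s, Strand.REVERSE)
        total = 2 * B + 2 * L + s
    elif syntax == Syntax.DIVERGENT:
        # [wall -m- <adj -s- rep> -m- wall]: exact mirror pair, both
        # promoters' upstream segments span the partner gene to the far wall
        adjacent = GeneAnnotation("adjacent", m + L, m, Strand.REVERSE)
        reporter = GeneAnnotation("reporter", m + L + s, m + 2 * L + s, Strand.FORWARD)
        total = 2 * m + 2 * L + s
    else:
        raise ConfigurationError(f"unknown syntax {syntax!r}")
    return GenomeLayout(
        genes=[reporter, adjacent],
        boundary_kind=boundary_kind,
        boundary_positions=(0.0, total),
    )


def build_two_gene(
    syntax: Syntax | str,
    spacing: float = 3000.0,
    boundary_kind: BoundaryKind | str = BoundaryKind.LINEAR,
    induction: float = 1.0,
    *,
    gene_length: float = 1000.0,
    margin: float = 6000.0,
    r0: float = R0_DEFAULT,
    mrna_halflife: float = MRNA_HALFLIFE,
    induction_time: float = INDUCTION_TIME,
    duration: float = 40000.0,
    params: Optional[PhysicalParams] = None,
    torque_kind: TorqueModelKind = TorqueModelKind.BASE_MARKO,
    initiation_kind: InitiationModelKind = InitiationModelKind.SECOND_ORDER,
) -> CircuitPreset:
    """Constitutive reporter plus an inducible adjacent gene.

    The reporter is always on at base rate ``r0``.  The adjacent gene is
    silent until ``induction_time``, then runs at ``induction * r0``
    (induction = 1 reproduces the equal-induction protocol).
    """
    syntax = Syntax(syntax)
    boundary_kind = BoundaryKind(boundary_kind)
    if not 500.0 <= spacing <= 10000.0:
        raise ConfigurationError("spacing must lie in [500, 10000] bp")
    if induction < 0:
        raise ConfigurationError("induction must be >= 0")
    layout = _two_gene_layout(syntax, spacing, boundary_kind, gene_length, margin)
    d = math.log(2.0) / mrna_halflife
    network = ReactionNetwork(
        species=["reporter_mRNA", "adjacent_mRNA"],
        reactions=[
            ReactionNetwork.decay("reporter_mRNA", d),
            ReactionNetwork.decay("adjacent_mRNA", d),
        ],
    )
    rules = {
        "reporter": PromoterRule(kind=RuleKind.CONSTANT, r0=r0, induction=1.0),
        "adjacent": PromoterRule(kind=RuleKind.CONSTANT, r0=r0, induction=0.0),
    }
    protocol = Protocol(
        duration=duration,
        interventions=[(induction_time, "adjacent", induction)],
    )
    return CircuitPreset(
        name=f"two_gene_{syntax.value}_{boundary_kind.value}",
        layout=layout,
        rules=rules,
        network=network,
        protocol=protocol,
        params=params or PhysicalParams(),
        torque_kind=torque_kind,
        initiation_kind=initiation_kind,
        normalization=10.0 if boundary_kind == BoundaryKind.CIRCULAR else 250.0,
    )


# ---------------------------------------------------------------------------
# toggle switch
# ---------------------------------------------------------------------------

def build_toggle(
    syntax: Syntax | str,
    n_hill: float = 2.0,
    r0: float = R0_DEFAULT,
    K_mode: str = "manual",
    K: float = 250.0,
    *,
    spacing: float = 3000.0,
    boundary_kind: BoundaryKind | str = BoundaryKind.LINEAR,
    gene_length: float = 1000.0,
    margin: float = 6000.0,
    mrna_halflife: float = MRNA_HALFLIFE,
    degradation_scale: float = 1.0,
    induction_time: float = INDUCTION_TIME,
    duration: float = 40000.0,
    params: Optional[PhysicalParams] = None,
    calibration_kwargs: Optional[dict] = None,
    **preset_kwargs,
) -> CircuitPreset:
    """Mutual-repression toggle switch (genes A and B).

    Each gene's base rate follows r0 / (1 + (R/K)**n) where R is the other
    gene's mRNA count; proteins are not modeled explicitly.  Gene A runs
    alone until ``induction_time`` (settling into its stable basin), then
    gene B is enabled.  ``K_mode='calibrated'`` measures K from
    single-gene-enabled ensembles (see :func:`calibrate_K`); with
    ``K_mode='manual'`` the supplied K is used, divided by
    ``degradation_scale`` as the degradation rate is scaled.
    """
    if n_hill <= 0:
        raise ConfigurationError("n_hill must be positive")
    syntax = Syntax(syntax)
    boundary_kind = BoundaryKind(boundary_kind)
    layout = _two_gene_layout(syntax, spacing, boundary_kind, gene_length, margin)
    # reuse the two-gene geometry with toggle names: reporter->A, adjacent->B
    renamed = [
        GeneAnnotation("A", g.tss, g.tes, g.strand) if g.name == "reporter"
        else GeneAnnotation("B", g.tss, g.tes, g.strand)
        for g in layout.genes
    ]
    layout = replace(layout, genes=renamed)
    d = degradation_scale * math.log(2.0) / mrna_halflife
    if K_mode == "calibrated":
        K_val = calibrate_K(
            syntax,
            params=params,
            boundary_kind=boundary_kind,
            spacing=spacing,
            gene_length=gene_length,
            margin=margin,
            r0=r0,
            mrna_halflife=mrna_halflife,
            **(calibration_kwargs or {}),
        )["A"] / degradation_scale
    elif K_mode == "manual":
        K_val = K / degradation_scale
    else:
        raise ConfigurationError("K_mode must be 'manual' or 'calibrated'")
    network = ReactionNetwork(
        species=["A_mRNA", "B_mRNA"],
        reactions=[
            ReactionNetwork.decay("A_mRNA", d),
            ReactionNetwork.decay("B_mRNA", d),
        ],
    )
    rules = {
        "A": PromoterRule(kind=RuleKind.HILL_REPRESSION, r0=r0, K=K_val,
                          n_hill=n_hill, repressor="B_mRNA", induction=1.0),
        "B": PromoterRule(kind=RuleKind.HILL_REPRESSION, r0=r0, K=K_val,
                          n_hill=n_hill, repressor="A_mRNA", induction=0.0),
    }
    protocol = Protocol(duration=duration, interventions=[(induction_time, "B", 1.0)])
    return CircuitPreset(
        name=f"toggle_{syntax.value}_{boundary_kind.value}",
        layout=layout,
        rules=rules,
        network=network,
        protocol=protocol,
        params=params or PhysicalParams(),
        normalization=10.0 if boundary_kind == BoundaryKind.CIRCULAR else 250.0,
        **preset_kwargs,
    )


def calibrate_K(
    syntax: Syntax | str,
    params: Optional[PhysicalParams] = None,
    *,
    degradation_scale: float = 1.0,
    n_replicates: int = 8,
    duration: float = 30000.0,
    base_seed: int = 1234,
    boundary_kind: BoundaryKind | str = BoundaryKind.LINEAR,
    spacing: float = 3000.0,
    gene_length: float = 1000.0,
    margin: float = 6000.0,
    r0: float = R0_DEFAULT,
    mrna_halflife: float = MRNA_HALFLIFE,
    initiation_kind: InitiationModelKind = InitiationModelKind.SECOND_ORDER,
    stall_enabled: bool = True,
) -> Dict[str, float]:
    """Half-max repression constants from single-gene-enabled ensembles.

    For each toggle gene in turn, the other gene is disabled and an
    ensemble is run to steady state under the full supercoiling model; K is
    the mean steady-state mRNA count, divided by the fold increase in the
    mRNA degradation rate.  Raises :class:`CalibrationError` when the last
    two quarters of the run still show a trend (steady state not reached).
    """
    from supertx.dynamics import run_ensemble  # deferred: dynamics builds on circuits

    syntax = Syntax(syntax)
    phys = params or PhysicalParams()
    if not stall_enabled:
        phys = phys.with_stall_disabled()
    out: Dict[str, float] = {}
    for enabled, label in ((0, "A"), (1, "B")):
        preset = build_two_gene(
            syntax,
            spacing=spacing,
            boundary_kind=boundary_kind,
            induction=0.0,
            gene_length=gene_length,
            margin=margin,
            r0=r0,
            mrna_halflife=mrna_halflife,
            duration=duration,
            params=phys,
            initiation_kind=initiation_kind,
        )
        # enable exactly one gene from t=0, keep the other silent
        gene_names = [g.name for g in preset.layout.genes]
        # reporter occupies the A position (left/upstream slot)
        on = "reporter" if enabled == 0 else "adjacent"
        for name in gene_names:
            preset.rules[name].induction = 1.0 if name == on else 0.0
        preset.protocol.interventions = []
        runs = run_ensemble(preset, n_replicates, base_seed + enabled)
        series = [r.trajectory[f"{on}_mRNA"].to_numpy(dtype=float) for r in runs]
        nt = len(series[0])
        w1 = [s[nt // 2: 3 * nt // 4] for s in series]
        w2 = [s[3 * nt // 4:] for s in series]
        m1 = sum(float(w.mean()) for w in w1) / len(w1)
        m2 = sum(float(w.mean()) for w in w2) / len(w2)
        reps = [float(w.mean()) for w in w2]
        mean = sum(reps) / len(reps)
        var = sum((x - mean) ** 2 for x in reps) / max(len(reps) - 1, 1)
        se = math.sqrt(var / len(reps))
        if se > 0 and abs(m2 - m1) > 4.0 * se + 0.05 * max(m2, 1.0):
            raise CalibrationError(
                f"single-gene ensemble not at steady state: "
                f"window means {m1:.2f} vs {m2:.2f} (SE {se:.2f})"
            )
        out[label] = mean / degradation_scale
    return out


# ---------------------------------------------------------------------------
# her1-her7 segmentation clock
# ---------------------------------------------------------------------------

#: Default kinetic rates for the clock network (synthetic placeholders tuned
#: to give minute-scale mRNA/protein turnover; the comparative paired vs
#: unpaired readout does not depend on their precise values).
HER_RATES = {
    "r0": 0.02,              # basal initiation when unbound, 1/s
    "mrna_decay": math.log(2.0) / 180.0,
    "translation": 0.05,     # per mRNA, 1/s
    "protein_decay": math.log(2.0) / 180.0,
    "dimerization": 0.001,   # per molecule pair, 1/s
    "dimer_decay": math.log(2.0) / 180.0,
    "bind": 0.01,            # per dimer, 1/s
    "unbind": 1.0 / 60.0,
    "hes6_pool": 40,
}


def build_her1her7(
    mode: str = "paired",
    topo: str = "none",
    *,
    rates: Optional[dict] = None,
    duration: float = 20000.0,
    params: Optional[PhysicalParams] = None,
    initiation_kind: InitiationModelKind = InitiationModelKind.SECOND_ORDER,
    torque_kind: TorqueModelKind = TorqueModelKind.BASE_MARKO,
    topo_rate: float = 1.0 / 300.0,
) -> CircuitPreset:
    """Divergent her1/her7 pair with dimer-mediated binary repression.

    ``mode='paired'`` places the divergent promoters 1.5 kb apart inside a
    ~25 kb linear domain (walls standing in for the nearest flanking
    genes); ``mode='unpaired'`` moves her7 1 Mb away so transcription-
    generated supercoiling cannot couple the pair while the dimer feedback
    is unchanged.  Either the Her1-Her1 homodimer or the Hes6-Her7
    heterodimer can bind either promoter and silence it.
    """
    if mode not in ("paired", "unpaired"):
        raise ConfigurationError("mode must be 'paired' or 'unpaired'")
    if topo not in ("none", "intergenic", "intragenic"):
        raise ConfigurationError("topo must be none|intergenic|intragenic")
    k = dict(HER_RATES)
    k.update(rates or {})
    shift = 0.0 if mode == "paired" else 1.0e6
    her1 = GeneAnnotation("her1", 11500.0, 8900.0, Strand.REVERSE)
    her7 = GeneAnnotation("her7", 13000.0 + shift, 14300.0 + shift, Strand.FORWARD)
    layout = GenomeLayout(
        genes=[her1, her7],
        boundary_kind=BoundaryKind.LINEAR,
        boundary_positions=(0.0, 25000.0 + shift),
    )
    rxns: List[Reaction] = []
    for g in ("her1", "her7"):
        rxns.append(ReactionNetwork.decay(f"{g}_mRNA", k["mrna_decay"]))
    rxns.append(Reaction("her1_translation", k["translation"],
                         catalysts={"her1_mRNA": 1}, products={"Her1": 1}))
    rxns.append(Reaction("her7_translation", k["translation"],
                         catalysts={"her7_mRNA": 1}, products={"Her7": 1}))
    rxns.append(ReactionNetwork.decay("Her1", k["protein_decay"]))
    rxns.append(ReactionNetwork.decay("Her7", k["protein_decay"]))
    rxns.append(Reaction("her1_dimerization", k["dimerization"],
                         reactants={"Her1": 2}, products={"Her1Her1": 1}))
    rxns.append(Reaction("her7_dimerization", k["dimerization"],
                         reactants={"Her7": 1}, catalysts={"Hes6": 1},
                         products={"Hes6Her7": 1}))
    rxns.append(ReactionNetwork.decay("Her1Her1", k["dimer_decay"]))
    rxns.append(ReactionNetwork.decay("Hes6Her7", k["dimer_decay"]))
    for promoter in ("her1", "her7"):
        for dimer in ("Her1Her1", "Hes6Her7"):
            bound = f"{promoter}_bound_{dimer}"
            rxns.append(Reaction(
                f"{promoter}_bind_{dimer}", k["bind"],
                reactants={dimer: 1, f"{promoter}_promoter_free": 1},
                products={bound: 1},
            ))
            rxns.append(Reaction(
                f"{promoter}_unbind_{dimer}", k["unbind"],
                reactants={bound: 1},
                products={dimer: 1, f"{promoter}_promoter_free": 1},
            ))
    species = sorted({s for r in rxns for s in
                      list(r.reactants) + list(r.products) + list(r.catalysts)})
    network = ReactionNetwork(species=species, reactions=rxns)
    rules = {
        g: PromoterRule(kind=RuleKind.OCCUPANCY_BINARY, r0=k["r0"],
                        occupancy_species=f"{g}_promoter_free")
        for g in ("her1", "her7")
    }
    initial = {s: 0 for s in species}
    initial["her1_promoter_free"] = 1
    initial["her7_promoter_free"] = 1
    initial["Hes6"] = int(k["hes6_pool"])
    return CircuitPreset(
        name=f"her1her7_{mode}_{topo}",
        layout=layout,
        rules=rules,
        network=network,
        protocol=Protocol(duration=duration),
        params=params or PhysicalParams(),
        torque_kind=torque_kind,
        initiation_kind=initiation_kind,
        topo=TopoSettings(mode=topo, rate=0.0 if topo == "none" else topo_rate),
        initial_species=initial,
        normalization=1.0,
    )
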