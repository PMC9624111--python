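"""Declarative run configuration: schema, validation, preset round-trips.

A run is fully described by one structured text file (YAML; JSON is a
subset).  Unknown keys are rejected so that typos in physics parameters
cannot silently fall back to defaults, and validation reports every
violation at once.
"""

from __future__ import annotations

import hashlib
from typing import Dict, List, Literal, Optional, Tuple

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from supertx import circuits as ci
from supertx import physics as ph
from supertx.state import BoundaryKind, GeneAnnotation, GenomeLayout, Strand


class ConfigError(ValueError):
    """Invalid configuration; ``errors`` lists every violation."""

    def __init__(self, errors: List[str]):
        self.errors = errors
        super().__init__("invalid configuration:\n  " + "\n  ".join(errors))


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GeneConfig(_Strict):
    name: str
    tss: float
    tes: float
    strand: Literal["forward", "reverse"] = "forward"


class LayoutConfig(_Strict):
    genes: List[GeneConfig]
    boundary_kind: Literal["linear", "circular"] = "linear"
    boundary_positions: Tuple[float, float] = (0.0, 10000.0)
    bp_to_nm: float = Field(default=ph.BP_TO_NM, gt=0)
    footprint_bp: float = Field(default=35.0, gt=0)


class MarkoConfig(_Strict):
    twist_stiffness: float = Field(default=95.0, gt=0)
    plectoneme_stiffness: float = Field(default=24.0, gt=0)
    bend_stiffness: float = Field(default=50.0, gt=0)
    force: float = Field(default=0.2, gt=0)


class PhysicsConfig(_Strict):
    omega0: float = Field(default=ph.OMEGA0, gt=0)
    kBT: float = Field(default=4.11, gt=0)
    v0: float = Field(default=17.0, gt=0)
    tau_s: float = Field(default=12.0, gt=0)
    tau_w: float = Field(default=3.0, gt=0)
    chi: float = Field(default=1.0, gt=0)
    eta: float = Field(default=6.0e-4, ge=0)
    n_drag: float = Field(default=1.0, ge=0)
    alpha: float = Field(default=0.025, ge=0)
    sigma_hyper_neg: float = Field(default=-0.06, lt=0)
    sigma_hyper_pos: float = Field(default=0.125, gt=0)
    nuc_plateau: Tuple[float, float] = (0.0, 0.031)
    penalty_energy_kbt: float = Field(default=1000.0, gt=0)
    max_enhancement: float = Field(default=40.0, ge=1.0)
    marko: MarkoConfig = MarkoConfig()
    torque_model: Literal["base_marko", "nucleosome_buffered"] = "base_marko"
    initiation_model: Literal[
        "supercoiling_independent",
        "first_order",
        "second_order",
        "second_order_with_hyper_penalty",
    ] = "second_order"

    @model_validator(mode="after")
    def _ordered(self):
        if not self.nuc_plateau[0] <= self.nuc_plateau[1]:
            raise ValueError("nuc_plateau bounds must be ordered")
        return self


class PromoterConfig(_Strict):
    kind: Literal["constant", "hill_repression", "occupancy_binary"] = "constant"
    r0: float = Field(default=ci.R0_DEFAULT, ge=0)
    K: float = Field(default=1.0, gt=0)
    n_hill: float = Field(default=2.0, gt=0)
    repressor: Optional[str] = None
    induction: float = Field(default=1.0, ge=0)
    occupancy_species: Optional[str] = None


class ReactionConfig(_Strict):
    name: str
    rate: float = Field(ge=0)
    reactants: Dict[str, int] = {}
    products: Dict[str, int] = {}
    catalysts: Dict[str, int] = {}


class RegulationConfig(_Strict):
    promoters: Dict[str, PromoterConfig]
    species: List[str] = []
    reactions: List[ReactionConfig] = []
    initial_species: Dict[str, int] = {}


class TopoConfig(_Strict):
    mode: Literal["none", "intergenic", "intragenic"] = "none"
    rate: float = Field(default=0.0, ge=0)


class InterventionConfig(_Strict):
    time: float = Field(ge=0)
    gene: str
    induction: float = Field(ge=0)


class ProtocolConfig(_Strict):
    duration: float = Field(default=40000.0, gt=0)
    sample_dt: float = Field(default=10.0, gt=0)
    interventions: List[InterventionConfig] = []


class EnsembleConfig(_Strict):
    n: int = Field(default=20, ge=1)
    base_seed: int = 0


class AnalysisConfig(_Strict):
    burst_threshold: float = Field(default=30.0, gt=0)
    normalization: float = Field(default=250.0, gt=0)


class RunConfig(_Strict):
    """Complete declarative description of one experiment."""

    name: str = "run"
    layout: LayoutConfig
    physics: PhysicsConfig = PhysicsConfig()
    regulation: RegulationConfig
    topo: TopoConfig = TopoConfig()
    protocol: ProtocolConfig = ProtocolConfig()
    ensemble: EnsembleConfig = EnsembleConfig()
    analysis: AnalysisConfig = AnalysisConfig()

    @model_validator(mode="after")
    def _cross_references(self):
        problems = []
        gene_names = {g.name for g in self.layout.genes}
        missing = gene_names - set(self.regulation.promoters)
        if missing:
            problems.append(f"genes without promoter rules: {sorted(missing)}")
        extra = set(self.regulation.promoters) - gene_names
        if extra:
            problems.append(f"promoter rules for unknown genes: {sorted(extra)}")
        known = set(self.regulation.species) | {f"{g}_mRNA" for g in gene_names}
        for g, p in self.regulation.promoters.items():
            if p.kind == "hill_repression":
                if p.repressor is None:
                    problems.append(f"promoter {g}: hill rule needs a repressor")
                elif p.repressor not in known:
                    problems.append(f"promoter {g}: unknown repressor {p.repressor!r}")
            if p.kind == "occupancy_binary":
                if p.occupancy_species is None:
                    problems.append(f"promoter {g}: occupancy rule needs occupancy_species")
                elif p.occupancy_species not in known:
                    problems.append(
                        f"promoter {g}: unknown occupancy species {p.occupancy_species!r}"
                    )
        for iv in self.protocol.interventions:
            if iv.gene not in gene_names:
                problems.append(f"intervention targets unknown gene {iv.gene!r}")
        if problems:
            raise ValueError("; ".join(problems))
        return self


def _format_pydantic_errors(exc: ValidationError) -> List[str]:
    out = []
    for e in exc.errors():
        loc = ".".join(str(p) for p in e["loc"]) or "<root>"
        out.append(f"{loc}: {e['msg']}")
    return out


def parse_config(data: dict) -> RunConfig:
    try:
        return RunConfig.model_validate(data)
    except ValidationError as exc:
        raise ConfigError(_format_pydantic_errors(exc)) from None


def load_config(path) -> RunConfig:
    """Load and validate a YAML/JSON run configuration.

    Raises :class:`ConfigError` carrying the complete list of schema
    violations (not just the first).
    """
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ConfigError(["configuration root must be a mapping"])
    return parse_config(data)


def dump_config(config: RunConfig, path=None) -> str:
    """Canonical YAML serialization (stable key order; round-trip safe)."""
    text = yaml.safe_dump(config.model_dump(mode="json"), sort_keys=True)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def config_hash(config: RunConfig) -> str:
    return hashlib.sha256(dump_config(config).encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# config <-> runtime objects
# ---------------------------------------------------------------------------

def to_preset(config: RunConfig) -> ci.CircuitPreset:
    genes = []
    for g in config.layout.genes:
        genes.append(GeneAnnotation(g.name, g.tss, g.tes, Strand(g.strand)))
    layout = GenomeLayout(
        genes=genes,
        boundary_kind=BoundaryKind(config.layout.boundary_kind),
        boundary_positions=tuple(config.layout.boundary_positions),
        bp_to_nm=config.layout.bp_to_nm,
        footprint_bp=config.layout.footprint_bp,
    )
    pc = config.physics
    params = ph.PhysicalParams(
        omega0=pc.omega0, kBT=pc.kBT, v0=pc.v0, tau_s=pc.tau_s, tau_w=pc.tau_w,
        chi=pc.chi, eta=pc.eta, n_drag=pc.n_drag,
        marko=ph.MarkoParams(
            twist_stiffness=pc.marko.twist_stiffness,
            plectoneme_stiffness=pc.marko.plectoneme_stiffness,
            bend_stiffness=pc.marko.bend_stiffness,
            force=pc.marko.force,
        ),
        alpha=pc.alpha,
        sigma_hyper_neg=pc.sigma_hyper_neg,
        sigma_hyper_pos=pc.sigma_hyper_pos,
        nuc_plateau=tuple(pc.nuc_plateau),
        penalty_energy_kbt=pc.penalty_energy_kbt,
        max_enhancement=pc.max_enhancement,
    )
    rules = {}
    for name, p in config.regulation.promoters.items():
        rules[name] = ci.PromoterRule(
            kind=ci.RuleKind(p.kind), r0=p.r0, K=p.K, n_hill=p.n_hill,
            repressor=p.repressor, induction=p.induction,
            occupancy_species=p.occupancy_species,
        )
    network = ci.ReactionNetwork(
        species=list(config.regulation.species),
        reactions=[
            ci.Reaction(r.name, r.rate, dict(r.reactants), dict(r.products),
                        dict(r.catalysts))
            for r in config.regulation.reactions
        ],
    )
    protocol = ci.Protocol(
        duration=config.protocol.duration,
        interventions=[(iv.time, iv.gene, iv.induction)
                       for iv in config.protocol.interventions],
        sample_dt=config.protocol.sample_dt,
    )
    return ci.CircuitPreset(
        name=config.name,
        layout=layout,
        rules=rules,
        network=network,
        protocol=protocol,
        params=params,
        torque_kind=ph.TorqueModelKind(pc.torque_model),
        initiation_kind=ph.InitiationModelKind(pc.initiation_model),
        topo=ci.TopoSettings(mode=config.topo.mode, rate=config.topo.rate),
        initial_species=dict(config.regulation.initial_species),
        normalization=config.analysis.normalization,
        ensemble_n=config.ensemble.n,
        base_seed=config.ensemble.base_seed,
    )


def from_preset(preset: ci.CircuitPreset, name: Optional[str] = None) -> RunConfig:
    """Serialize a preset back into the configuration schema."""
    p = preset.params
    genes = [
        GeneConfig(name=g.name, tss=g.tss, tes=g.tes, strand=g.strand.value)
        for g in preset.layout.genes
    ]
    return RunConfig(
        name=name or preset.name,
        layout=LayoutConfig(
            genes=genes,
            boundary_kind=preset.layout.boundary_kind.value,
            boundary_positions=tuple(preset.layout.boundary_positions),
            bp_to_nm=preset.layout.bp_to_nm,
            footprint_bp=preset.layout.footprint_bp,
        ),
        physics=PhysicsConfig(
            omega0=p.omega0, kBT=p.kBT, v0=p.v0, tau_s=p.tau_s, tau_w=p.tau_w,
            chi=p.chi, eta=p.eta, n_drag=p.n_drag, alpha=p.alpha,
            sigma_hyper_neg=p.sigma_hyper_neg, sigma_hyper_pos=p.sigma_hyper_pos,
            nuc_plateau=tuple(p.nuc_plateau),
            penalty_energy_kbt=p.penalty_energy_kbt,
            max_enhancement=p.max_enhancement,
            marko=MarkoConfig(
                twist_stiffness=p.marko.twist_stiffness,
                plectoneme_stiffness=p.marko.plectoneme_stiffness,
                bend_stiffness=p.marko.bend_stiffness,
                force=p.marko.force,
            ),
            torque_model=preset.torque_kind.value,
            initiation_model=preset.initiation_kind.value,
        ),
        regulation=RegulationConfig(
            promoters={
                name: PromoterConfig(
                    kind=r.kind.value, r0=r.r0, K=r.K, n_hill=r.n_hill,
                    repressor=r.repressor, induction=r.induction,
                    occupancy_species=r.occupancy_species,
                )
                for name, r in preset.rules.items()
            },
            species=list(preset.network.species),
            reactions=[
                ReactionConfig(name=r.name, rate=r.rate, reactants=dict(r.reactants),
                               products=dict(r.products), catalysts=dict(r.catalysts))
                for r in preset.network.reactions
            ],
            initial_species=dict(preset.initial_species),
        ),
        topo=TopoConfig(mode=preset.topo.mode, rate=preset.topo.rate),
        protocol=ProtocolConfig(
            duration=preset.protocol.duration,
            sample_dt=preset.protocol.sample_dt,
            interventions=[
                InterventionConfig(time=t, gene=g, induction=i)
                for t, g, i in preset.protocol.interventions
            ],
        ),
        ensemble=EnsembleConfig(n=preset.ensemble_n, base_seed=preset.base_seed),
        analysis=AnalysisConfig(normalization=preset.normalization),
    )
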