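"""Genome layout, polymerase bookkeeping, and supercoiling-density computation.

Coordinates: gene annotations are given in 0-based base pairs and converted
to nanometers (0.34 nm/bp) for all physics.  The supercoiling density in
each segment between adjacent twist anchors (domain walls and polymerases)
is

    sigma_k = (phi_k - phi_{k+1}) / (omega0 * (z_{k+1} - z_k))

with phi = 0 pinned at both walls under linear boundary conditions.  Under
circular boundary conditions the anchor list wraps around an arbitrary
origin; with zero or one polymerase loaded the density is identically zero
(a lone polymerase on a closed circle cannot partition twist).

The segment-length-weighted sum of sigma telescopes to zero at every
instant under both boundary kinds; every operator in this module preserves
that invariant exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Dict, List, Optional

import numpy as np

from supertx.physics import BP_TO_NM, OMEGA0

#: Default exclusion footprint around an occupied transcription start site, bp.
FOOTPRINT_BP = 35.0
#: Slack on footprint comparisons, nm: event root-finding localizes the
#: clearance crossing only to within interpolation error, so occupancy tests
#: must not re-close a gate that just opened.
FOOTPRINT_TOL_NM = 1.0e-6


class Strand(str, Enum):
    FORWARD = "forward"
    REVERSE = "reverse"


class BoundaryKind(str, Enum):
    LINEAR = "linear"
    CIRCULAR = "circular"


class DegenerateSegmentError(RuntimeError):
    """Two twist anchors coincide (or inverted): the integrator stepped too far."""


@dataclass(frozen=True)
class GeneAnnotation:
    """A transcription unit: TSS/TES positions (bp) and strand."""

    name: str
    tss: float
    tes: float
    strand: Strand = Strand.FORWARD

    def __post_init__(self):
        if self.tss == self.tes:
            raise ValueError(f"gene {self.name}: tss == tes")
        if self.strand == Strand.FORWARD and not self.tss < self.tes:
            raise ValueError(f"gene {self.name}: forward gene needs tss < tes")
        if self.strand == Strand.REVERSE and not self.tss > self.tes:
            raise ValueError(f"gene {self.name}: reverse gene needs tss > tes")

    @property
    def direction(self) -> int:
        return 1 if self.strand == Strand.FORWARD else -1

    @property
    def length_bp(self) -> float:
        return abs(self.tes - self.tss)

    @property
    def mrna_species(self) -> str:
        return f"{self.name}_mRNA"

    def span_bp(self) -> tuple:
        """(low, high) genomic extent in bp."""
        return (min(self.tss, self.tes), max(self.tss, self.tes))


@dataclass(frozen=True)
class GenomeLayout:
    """Gene annotations plus the enclosing supercoiling domain."""

    genes: List[GeneAnnotation]
    boundary_kind: BoundaryKind = BoundaryKind.LINEAR
    boundary_positions: tuple = (0.0, 10000.0)  # bp
    bp_to_nm: float = BP_TO_NM
    footprint_bp: float = FOOTPRINT_BP

    def __post_init__(self):
        lo, hi = self.boundary_positions
        if not lo < hi:
            raise ValueError("boundary positions must be increasing")
        names = [g.name for g in self.genes]
        if len(set(names)) != len(names):
            raise ValueError("gene names must be unique")
        for g in self.genes:
            glo, ghi = g.span_bp()
            if self.boundary_kind == BoundaryKind.LINEAR:
                if not (lo < glo and ghi < hi):
                    raise ValueError(f"gene {g.name} not strictly inside boundaries")
            else:
                if not (lo <= glo and ghi < hi):
                    raise ValueError(f"gene {g.name} outside the circular domain")

    # -- unit helpers -------------------------------------------------------
    def to_nm(self, bp: float) -> float:
        return bp * self.bp_to_nm

    @property
    def wall_nm(self) -> tuple:
        lo, hi = self.boundary_positions
        return (self.to_nm(lo), self.to_nm(hi))

    @property
    def circumference_nm(self) -> float:
        lo, hi = self.boundary_positions
        return self.to_nm(hi - lo)

    @property
    def footprint_nm(self) -> float:
        return self.to_nm(self.footprint_bp)

    def gene(self, name: str) -> GeneAnnotation:
        for g in self.genes:
            if g.name == name:
                return g
        raise KeyError(name)

    def tss_nm(self, gene: GeneAnnotation) -> float:
        return self.to_nm(gene.tss)

    def tes_nm(self, gene: GeneAnnotation) -> float:
        return self.to_nm(gene.tes)

    @classmethod
    def from_bed(
        cls,
        path,
        boundary_kind: BoundaryKind = BoundaryKind.LINEAR,
        boundary_positions: Optional[tuple] = None,
        **kwargs,
    ) -> "GenomeLayout":
        """Read a minimal BED-like table: name, start, end, strand.

        ``start < end`` always (BED convention); strand assigns TSS/TES.
        """
        genes = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split()
                name, start, end, strand = parts[0], float(parts[1]), float(parts[2]), parts[3]
                if strand == "+":
                    genes.append(GeneAnnotation(name, start, end, Strand.FORWARD))
                else:
                    genes.append(GeneAnnotation(name, end, start, Strand.REVERSE))
        if boundary_positions is None:
            lo = min(g.span_bp()[0] for g in genes) - 2000.0
            hi = max(g.span_bp()[1] for g in genes) + 2000.0
            boundary_positions = (lo, hi)
        return cls(genes=genes, boundary_kind=boundary_kind,
                   boundary_positions=boundary_positions, **kwargs)


@dataclass
class PolymeraseState:
    """One elongating polymerase.

    z : genomic position, nm; x : nascent-RNA length, nm; phi : local DNA
    excess twist, rad; theta : polymerase rotation angle, rad.
    """

    z: float
    x: float
    phi: float
    theta: float
    gene: str
    direction: int

    def copy(self) -> "PolymeraseState":
        return replace(self)


@dataclass
class SystemState:
    """Full simulation state: clock, polymerases, species counts, promoters."""

    time: float = 0.0
    polymerases: List[PolymeraseState] = field(default_factory=list)
    species: Dict[str, int] = field(default_factory=dict)
    promoter_state: Dict[str, dict] = field(default_factory=dict)

    def sort_polymerases(self) -> None:
        self.polymerases.sort(key=lambda p: p.z)

    def polymerases_of(self, gene: str) -> List[PolymeraseState]:
        return [p for p in self.polymerases if p.gene == gene]

    def copy(self) -> "SystemState":
        return SystemState(
            time=self.time,
            polymerases=[p.copy() for p in self.polymerases],
            species=dict(self.species),
            promoter_state={k: dict(v) for k, v in self.promoter_state.items()},
        )


@dataclass(frozen=True)
class SupercoilingProfile:
    """Piecewise-constant sigma over segments [breaks[k], breaks[k+1])."""

    breaks: np.ndarray  # segment boundaries, nm, length n+1
    sigma: np.ndarray   # densities, length n
    circular: bool = False
    circumference: float = 0.0

    def sigma_at(self, z: float) -> float:
        """Density of the segment containing position z (nm)."""
        if self.circular and len(self.sigma) > 1:
            lo = self.breaks[0]
            z = lo + (z - lo) % self.circumference
            if z < self.breaks[0] or z >= self.breaks[-1]:
                return float(self.sigma[-1])
        k = int(np.searchsorted(self.breaks, z, side="right")) - 1
        k = min(max(k, 0), len(self.sigma) - 1)
        return float(self.sigma[k])

    def twist_integral(self) -> float:
        """Segment-length-weighted sum of sigma (zero by construction)."""
        return float(np.sum(self.sigma * np.diff(self.breaks)))


def _anchors(state: SystemState, layout: GenomeLayout):
    """(positions, twists) of all anchors, walls included, in ascending z."""
    polys = sorted(state.polymerases, key=lambda p: p.z)
    zs = np.array([p.z for p in polys], dtype=float)
    phis = np.array([p.phi for p in polys], dtype=float)
    return polys, zs, phis


def supercoiling_profile(state: SystemState, layout: GenomeLayout) -> SupercoilingProfile:
    """Piecewise-constant supercoiling density over the whole domain."""
    polys, zs, phis = _anchors(state, layout)
    w0 = OMEGA0
    if layout.boundary_kind == BoundaryKind.LINEAR:
        lo, hi = layout.wall_nm
        breaks = np.concatenate([[lo], zs, [hi]])
        twists = np.concatenate([[0.0], phis, [0.0]])
        lengths = np.diff(breaks)
        if np.any(lengths <= 0.0):
            raise DegenerateSegmentError(
                f"zero-length segment at t={state.time:.6g}s (anchors {breaks})"
            )
        sigma = (twists[:-1] - twists[1:]) / (w0 * lengths)
        return SupercoilingProfile(breaks=breaks, sigma=sigma)
    # circular
    lo, hi = layout.wall_nm
    circ = layout.circumference_nm
    if len(polys) <= 1:
        return SupercoilingProfile(
            breaks=np.array([lo, hi]), sigma=np.zeros(1), circular=True, circumference=circ
        )
    # duplicate the first anchor past the origin to close the loop
    breaks = np.concatenate([zs, [zs[0] + circ]])
    twists = np.concatenate([phis, [phis[0]]])
    lengths = np.diff(breaks)
    if np.any(lengths <= 0.0):
        raise DegenerateSegmentError(
            f"zero-length segment at t={state.time:.6g}s (circular anchors {breaks})"
        )
    sigma = (twists[:-1] - twists[1:]) / (w0 * lengths)
    return SupercoilingProfile(breaks=breaks, sigma=sigma, circular=True, circumference=circ)


def _interp_phi(state: SystemState, layout: GenomeLayout, z: float) -> float:
    """Excess twist phi(z) by linear interpolation of the anchor profile."""
    polys, zs, phis = _anchors(state, layout)
    if layout.boundary_kind == BoundaryKind.LINEAR:
        lo, hi = layout.wall_nm
        xs = np.concatenate([[lo], zs, [hi]])
        ys = np.concatenate([[0.0], phis, [0.0]])
        return float(np.interp(z, xs, ys))
    circ = layout.circumference_nm
    if len(polys) == 0:
        return 0.0
    if len(polys) == 1:
        return float(phis[0])  # sigma == 0 everywhere: phi is uniform
    lo = layout.wall_nm[0]
    z = lo + (z - lo) % circ
    k = int(np.searchsorted(zs, z, side="right"))
    if k == 0 or k == len(zs):
        # wrap segment between last and first anchor
        z1, p1 = zs[-1], phis[-1]
        z2, p2 = zs[0] + circ, phis[0]
        if k == 0:
            z = z + circ
    else:
        z1, p1 = zs[k - 1], phis[k - 1]
        z2, p2 = zs[k], phis[k]
    frac = (z - z1) / (z2 - z1)
    return float(p1 + frac * (p2 - p1))


class InitiationRejected(RuntimeError):
    """Insertion footprint at the TSS is occupied; the attempt is dropped."""


def insert_polymerase(
    state: SystemState, gene: GeneAnnotation, layout: GenomeLayout
) -> PolymeraseState:
    """Load a new polymerase at the gene's TSS (in place).

    The new polymerase's excess twist is set by linear interpolation of the
    current phi(z) profile at the TSS, so the supercoiling density of every
    segment is unchanged at the instant of insertion.  Raises
    ``InitiationRejected`` if another polymerase sits within the exclusion
    footprint of the TSS.
    """
    tss = layout.tss_nm(gene)
    fp = layout.footprint_nm
    for p in state.polymerases:
        d = abs(p.z - tss)
        if layout.boundary_kind == BoundaryKind.CIRCULAR:
            d = min(d, layout.circumference_nm - d)
        if d < fp - FOOTPRINT_TOL_NM:
            raise InitiationRejected(gene.name)
    phi = _interp_phi(state, layout, tss)
    pol = PolymeraseState(z=tss, x=0.0, phi=phi, theta=0.0,
                          gene=gene.name, direction=gene.direction)
    state.polymerases.append(pol)
    state.sort_polymerases()
    return pol


def terminate_polymerase(state: SystemState, index: int) -> PolymeraseState:
    """Remove polymerase ``index`` and increment its gene's mRNA count.

    The flanking segments merge; because sigma is always recomputed from
    the surviving anchors, the merged segment automatically carries
    (phi_left - phi_right) / (omega0 * merged length), conserving the
    end-to-end twist difference.
    """
    pol = state.polymerases.pop(index)
    key = f"{pol.gene}_mRNA"
    state.species[key] = state.species.get(key, 0) + 1
    return pol


def _gene_groups(state: SystemState, layout: GenomeLayout):
    """Polymerase index ranges per gene, in ascending-z order."""
    order = sorted(range(len(state.polymerases)), key=lambda i: state.polymerases[i].z)
    groups: Dict[str, List[int]] = {}
    for i in order:
        groups.setdefault(state.polymerases[i].gene, []).append(i)
    return groups


def topo_relax_intergenic(state: SystemState, layout: GenomeLayout) -> None:
    """Zero the supercoiling density of every non-genic segment (in place).

    Topoisomerase action is modeled as an instantaneous rotation of the
    boundary polymerases of each gene: each gene's polymerases receive a
    common twist offset chaining its upstream plateau to the previous
    anchor, and the final gene additionally receives a linear ramp so the
    plateau downstream of it meets the wall at zero.  Intragenic twist
    differences are preserved except for that uniform ramp.
    """
    if not state.polymerases:
        return
    polys = sorted(state.polymerases, key=lambda p: p.z)
    # group consecutive polymerases by gene along the chromosome
    blocks: List[List[PolymeraseState]] = []
    for p in polys:
        if blocks and blocks[-1][0].gene == p.gene:
            blocks[-1].append(p)
        else:
            blocks.append([p])
    plateau = 0.0  # phi of the relaxed region left of the current block
    for bi, block in enumerate(blocks):
        offset = plateau - block[0].phi
        for p in block:
            p.phi += offset
        last = bi == len(blocks) - 1
        if last and layout.boundary_kind == BoundaryKind.LINEAR:
            # ramp so the downstream plateau meets the phi=0 wall
            residual = block[-1].phi
            z0, z1 = block[0].z, block[-1].z
            if len(block) > 1 and z1 > z0:
                for p in block:
                    p.phi -= residual * (p.z - z0) / (z1 - z0)
            else:
                block[0].phi = 0.0
        plateau = block[-1].phi


def topo_relax_intragenic(
    state: SystemState, layout: GenomeLayout, gene: GeneAnnotation
) -> None:
    """Homogenize sigma across a gene's polymerases (in place).

    All segments between the gene's first and last polymerase take the
    single density implied by the end-to-end twist difference (interior
    twists are linearly interpolated), conserving total twist.  A gene with
    fewer than two polymerases is left unchanged.
    """
    polys = sorted(state.polymerases_of(gene.name), key=lambda p: p.z)
    if len(polys) < 2:
        return
    z0, z1 = polys[0].z, polys[-1].z
    p0, p1 = polys[0].phi, polys[-1].phi
    for p in polys[1:-1]:
        p.phi = p0 + (p1 - p0) * (p.z - z0) / (z1 - z0)
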