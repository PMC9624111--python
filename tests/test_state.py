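"""Supercoiling-profile bookkeeping: insertion, termination, relaxation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from supertx.physics import OMEGA0
from supertx.state import (
    BoundaryKind,
    GeneAnnotation,
    GenomeLayout,
    InitiationRejected,
    PolymeraseState,
    Strand,
    SystemState,
    insert_polymerase,
    supercoiling_profile,
    terminate_polymerase,
    topo_relax_intergenic,
    topo_relax_intragenic,
)

BP = 0.34


def make_layout(boundary=BoundaryKind.LINEAR):
    genes = [
        GeneAnnotation("left", 3000, 4000, Strand.FORWARD),
        GeneAnnotation("right", 9000, 8000, Strand.REVERSE),
    ]
    return GenomeLayout(genes=genes, boundary_kind=boundary,
                        boundary_positions=(0.0, 12000.0))


def put(state, z, phi, gene="left", direction=1, x=10.0):
    state.polymerases.append(
        PolymeraseState(z=z, x=x, phi=phi, theta=0.0, gene=gene, direction=direction)
    )
    state.sort_polymerases()


class TestProfile:
    def test_empty_domain_is_relaxed(self):
        prof = supercoiling_profile(SystemState(), make_layout())
        assert np.all(prof.sigma == 0.0)

    def test_single_polymerase_twin_domain(self):
        # walls at 0 and 1000 nm, polymerase at 500 nm with phi = 2 pi:
        # sigma = -+ 2 pi / (omega0 * 500) on the two sides
        layout = GenomeLayout(
            genes=[GeneAnnotation("g", 1000, 2000)],
            boundary_positions=(0.0, 1000.0 / BP),
        )
        st_ = SystemState()
        put(st_, 500.0, 2 * math.pi, "g")
        prof = supercoiling_profile(st_, layout)
        expect = 2 * math.pi / (OMEGA0 * 500.0)
        assert prof.sigma[0] == pytest.approx(-expect)   # behind: underwound
        assert prof.sigma[1] == pytest.approx(+expect)   # ahead: overwound
        assert expect == pytest.approx(0.00679, abs=5e-5)

    def test_circular_single_polymerase_is_relaxed(self):
        layout = make_layout(BoundaryKind.CIRCULAR)
        st_ = SystemState()
        put(st_, 1200.0, 55.0)
        prof = supercoiling_profile(st_, layout)
        assert np.all(prof.sigma == 0.0)

    def test_circular_wrap_segment(self):
        layout = make_layout(BoundaryKind.CIRCULAR)
        st_ = SystemState()
        put(st_, 500.0, 10.0, "left")
        put(st_, 3000.0, -4.0, "right", direction=-1)
        prof = supercoiling_profile(st_, layout)
        circ = layout.circumference_nm
        assert prof.sigma[0] == pytest.approx((10.0 + 4.0) / (OMEGA0 * 2500.0))
        assert prof.sigma[1] == pytest.approx((-4.0 - 10.0) / (OMEGA0 * (circ - 2500.0)))
        assert prof.twist_integral() == pytest.approx(0.0, abs=1e-12)

    @given(
        zs=st.lists(st.floats(10.0, 4000.0), min_size=0, max_size=6, unique=True),
        phis=st.lists(st.floats(-300.0, 300.0), min_size=6, max_size=6),
        circular=st.booleans(),
    )
    @settings(max_examples=150, deadline=None)
    def test_zero_sum_twist(self, zs, phis, circular):
        """Length-weighted sigma telescopes to zero for any anchor set."""
        layout = make_layout(BoundaryKind.CIRCULAR if circular else BoundaryKind.LINEAR)
        st_ = SystemState()
        for z, p in zip(sorted(zs), phis):
            put(st_, z, p)
        prof = supercoiling_profile(st_, layout)
        scale = max(1.0, float(np.max(np.abs(phis))))
        assert prof.twist_integral() * OMEGA0 == pytest.approx(0.0, abs=1e-9 * scale)


class TestInsertion:
    def test_relaxed_insertion_has_zero_twist(self):
        layout = make_layout()
        st_ = SystemState()
        pol = insert_polymerase(st_, layout.gene("left"), layout)
        assert pol.phi == 0.0 and pol.x == 0.0
        assert pol.z == pytest.approx(layout.tss_nm(layout.gene("left")))
        assert np.all(supercoiling_profile(st_, layout).sigma == 0.0)

    def test_insertion_preserves_profile(self):
        layout = make_layout()
        st_ = SystemState()
        put(st_, 500.0, 40.0)
        put(st_, 2500.0, 90.0)
        before = supercoiling_profile(st_, layout)
        insert_polymerase(st_, layout.gene("left"), layout)
        after = supercoiling_profile(st_, layout)
        tss = layout.tss_nm(layout.gene("left"))
        for z in [100.0, 400.0, 700.0, tss - 1.0, tss + 1.0, 3000.0]:
            assert after.sigma_at(z) == pytest.approx(before.sigma_at(z), rel=1e-9)

    def test_midpoint_interpolation(self):
        # flanks with phi = +4 pi and +2 pi at equal distances -> phi = 3 pi
        layout = GenomeLayout(
            genes=[GeneAnnotation("g", 1500, 2500)],
            boundary_positions=(0.0, 3000.0),
        )
        st_ = SystemState()
        tss = layout.tss_nm(layout.gene("g"))
        put(st_, tss - 200.0, 4 * math.pi, "g")
        put(st_, tss + 200.0, 2 * math.pi, "g")
        pol = insert_polymerase(st_, layout.gene("g"), layout)
        assert pol.phi == pytest.approx(3 * math.pi)

    def test_footprint_collision_rejected(self):
        layout = make_layout()
        st_ = SystemState()
        insert_polymerase(st_, layout.gene("left"), layout)
        with pytest.raises(InitiationRejected):
            insert_polymerase(st_, layout.gene("left"), layout)


class TestTermination:
    def test_sole_polymerase_leaves_relaxed_domain(self):
        layout = make_layout()
        st_ = SystemState()
        put(st_, 1300.0, 77.0)
        terminate_polymerase(st_, 0)
        assert np.all(supercoiling_profile(st_, layout).sigma == 0.0)
        assert st_.species["left_mRNA"] == 1

    def test_merged_segment_conserves_end_to_end_twist(self):
        # neighbors phi = +2 pi, -2 pi at 400 nm apart after removal:
        # sigma = 4 pi / (omega0 * 400) = 0.0170
        layout = GenomeLayout(
            genes=[GeneAnnotation("g", 1500, 2500)],
            boundary_positions=(0.0, 3000.0),
        )
        st_ = SystemState()
        put(st_, 300.0, 2 * math.pi, "g")
        put(st_, 500.0, 0.0, "g")
        put(st_, 700.0, -2 * math.pi, "g")
        terminate_polymerase(st_, 1)
        prof = supercoiling_profile(st_, layout)
        assert prof.sigma_at(600.0) == pytest.approx(4 * math.pi / (OMEGA0 * 400.0))
        assert prof.sigma_at(600.0) == pytest.approx(0.0170, abs=2e-4)

    def test_mrna_count_increments(self):
        layout = make_layout()
        st_ = SystemState(species={"left_mRNA": 4})
        put(st_, 1300.0, 0.0)
        terminate_polymerase(st_, 0)
        assert st_.species["left_mRNA"] == 5


class TestTopoisomerase:
    def test_intergenic_idempotent_on_relaxed_state(self):
        layout = make_layout()
        st_ = SystemState()
        put(st_, layout.to_nm(3200), 0.0, "left")
        topo_relax_intergenic(st_, layout)
        assert np.all(supercoiling_profile(st_, layout).sigma == 0.0)

    def test_intergenic_zeroes_every_nongenic_segment(self):
        layout = make_layout()
        st_ = SystemState()
        put(st_, layout.to_nm(3300), 60.0, "left")
        put(st_, layout.to_nm(3700), 80.0, "left")
        put(st_, layout.to_nm(8700), -50.0, "right", direction=-1)
        put(st_, layout.to_nm(8300), -70.0, "right", direction=-1)
        before = supercoiling_profile(st_, layout)
        assert before.sigma_at(layout.to_nm(6000)) > 0.0  # convergent intergenic
        topo_relax_intergenic(st_, layout)
        prof = supercoiling_profile(st_, layout)
        for z_bp in [1000, 2900, 6000, 11000]:  # wall flanks + intergenic
            assert prof.sigma_at(layout.to_nm(z_bp)) == pytest.approx(0.0, abs=1e-12)
        assert prof.twist_integral() == pytest.approx(0.0, abs=1e-9)

    def test_intragenic_no_op_below_two_polymerases(self):
        layout = make_layout()
        st_ = SystemState()
        put(st_, layout.to_nm(3300), 60.0, "left")
        phi_before = st_.polymerases[0].phi
        topo_relax_intragenic(st_, layout, layout.gene("left"))
        assert st_.polymerases[0].phi == phi_before

    def test_intragenic_homogenizes_density(self):
        # two equal-length segments with sigma (+s, 0) -> both s/2
        layout = make_layout()
        st_ = SystemState()
        z0, z1, z2 = layout.to_nm(3100), layout.to_nm(3400), layout.to_nm(3700)
        put(st_, z0, 50.0, "left")
        put(st_, z1, 20.0, "left")   # sigma1 = 30/(w0 L), sigma2 = 0
        put(st_, z2, 20.0, "left")
        before = supercoiling_profile(st_, layout)
        total_before = before.twist_integral()
        topo_relax_intragenic(st_, layout, layout.gene("left"))
        prof = supercoiling_profile(st_, layout)
        s1 = prof.sigma_at(z0 + 1.0)
        s2 = prof.sigma_at(z1 + 1.0)
        assert s1 == pytest.approx(s2)
        assert s1 == pytest.approx(30.0 / (OMEGA0 * (z2 - z0)))
        assert prof.twist_integral() == pytest.approx(total_before, abs=1e-9)


class TestLayout:
    def test_gene_annotation_invariants(self):
        with pytest.raises(ValueError):
            GeneAnnotation("bad", 100, 100)
        with pytest.raises(ValueError):
            GeneAnnotation("bad", 200, 100, Strand.FORWARD)
        with pytest.raises(ValueError):
            GeneAnnotation("bad", 100, 200, Strand.REVERSE)

    def test_genes_must_fit_inside_boundaries(self):
        with pytest.raises(ValueError):
            GenomeLayout(genes=[GeneAnnotation("g", 100, 20000)],
                         boundary_positions=(0.0, 12000.0))

    def test_bed_round_trip(self, tmp_path):
        bed = tmp_path / "genes.bed"
        bed.write_text("g1\t3000\t4000\t+\ng2\t8000\t9000\t-\n")
        layout = GenomeLayout.from_bed(bed, boundary_positions=(0.0, 12000.0))
        g1, g2 = layout.genes
        assert (g1.tss, g1.tes, g1.strand) == (3000.0, 4000.0, Strand.FORWARD)
        assert (g2.tss, g2.tes, g2.strand) == (9000.0, 8000.0, Strand.REVERSE)
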