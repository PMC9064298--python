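"""Event rules of the protofilament lattice: rates, affinities, invariants."""
import numpy as np
import pytest

from mtgrowth import (GDP, GTP, FrozenSystemError, ModelParams, advance,
                      apply_event, enumerate_events, init_state,
                      site_affinity, terminal_gdp_count)
from mtgrowth.lattice import (ASSOCIATE, DISSOCIATE, HYDROLYZE,
                              lateral_neighbor_count)

GMPCPP = ModelParams(k_on=0.74, K_D_long=87.0, K_D_corner=0.025,
                     tubulin_conc=1.5)


class TestInitState:
    def test_blunt_construction(self):
        st = init_state(GMPCPP, seed_layers=10)
        assert st.total_subunits(include_seed=True) == 130
        assert st.total_subunits() == 0
        assert st.mean_length() == 0.0
        assert terminal_gdp_count(st) == 0

    def test_bare_seed_has_no_dissociation_events(self):
        st = init_state(GMPCPP, seed_layers=1)
        events = enumerate_events(st, GMPCPP)
        assert all(e.kind != DISSOCIATE for e in events)
        assert all(e.kind != HYDROLYZE for e in events)

    def test_construction_is_deterministic(self):
        a = init_state(GMPCPP, seed_layers=5)
        b = init_state(GMPCPP, seed_layers=5)
        assert np.array_equal(a.heights, b.heights)
        assert np.array_equal(a.nuc, b.nuc)

    def test_rejects_nonpositive_seed(self):
        with pytest.raises(ValueError):
            init_state(GMPCPP, seed_layers=0)


class TestSiteAffinity:
    """Energy-additive affinities at the published GMPCPP parameter set."""

    PF = 5   # interior protofilament, away from the seam

    def _single_pf_up(self, params, extra=1):
        # one interior protofilament sticks `extra` dimers above a blunt end
        st = init_state(params, seed_layers=10, capacity=64)
        for _ in range(extra):
            st.nuc[self.PF, st.heights[self.PF]] = GTP
            st.heights[self.PF] += 1
        return st

    def test_longitudinal_site_87_uM(self):
        st = self._single_pf_up(GMPCPP)
        assert site_affinity(st, self.PF, GMPCPP) == pytest.approx(87.0)

    def test_corner_site_25_nM(self):
        st = self._single_pf_up(GMPCPP)
        st.heights[self.PF + 1] += 1    # one neighbour reaches the terminal level
        assert site_affinity(st, self.PF, GMPCPP) == pytest.approx(0.025)

    def test_bucket_site_energy_additivity(self):
        st = self._single_pf_up(GMPCPP)
        st.heights[self.PF - 1] += 2
        st.heights[self.PF + 1] += 2    # both neighbours overtop the terminal
        expected = 87.0 * (0.025 / 87.0) ** 2     # ~7.2 pM
        assert site_affinity(st, self.PF, GMPCPP) == pytest.approx(expected)
        assert expected == pytest.approx(7.2e-6, rel=0.01)

    def test_gdp_interface_weakening(self):
        params = GMPCPP.replace(gdp_factor_X=100.0)
        st = self._single_pf_up(params, extra=2)
        st.nuc[self.PF, st.heights[self.PF] - 2] = GDP  # interface below terminal
        assert site_affinity(st, self.PF, params) == pytest.approx(8700.0)

    def test_empty_protofilament_raises(self):
        st = init_state(GMPCPP, seed_layers=3)
        with pytest.raises(ValueError):
            site_affinity(st, 0, GMPCPP)


class TestEnumerateEvents:
    def test_association_rates(self):
        st = init_state(GMPCPP, seed_layers=5)
        events = enumerate_events(st, GMPCPP)
        assoc = [e for e in events if e.kind == ASSOCIATE]
        assert len(assoc) == 13
        for e in assoc:
            assert e.rate == pytest.approx(0.74 * 1.5)

    def test_zero_concentration_no_association(self):
        p = GMPCPP.replace(tubulin_conc=0.0)
        st = init_state(p, seed_layers=5, extra_layers=2)
        events = enumerate_events(st, p)
        assert all(e.kind != ASSOCIATE for e in events)

    def test_no_gtpase_no_hydrolysis_events(self):
        st = init_state(GMPCPP, seed_layers=5, extra_layers=4)
        events = enumerate_events(st, GMPCPP)
        assert all(e.kind != HYDROLYZE for e in events)

    def test_longitudinal_dissociation_rate(self):
        # blunt end + one dimer on pf 0: terminal has no lateral neighbours
        st = init_state(GMPCPP, seed_layers=5, capacity=32)
        st.nuc[0, st.heights[0]] = GTP
        st.heights[0] += 1
        events = enumerate_events(st, GMPCPP)
        d = [e for e in events if e.kind == DISSOCIATE and e.pf == 0]
        assert len(d) == 1
        assert d[0].rate == pytest.approx(0.74 * 87.0)   # ~64.4 s^-1

    def test_hydrolysis_never_targets_terminal(self):
        p = GMPCPP.replace(k_GTPase=0.1)
        st = init_state(p, seed_layers=5, extra_layers=3)
        for e in enumerate_events(st, p):
            if e.kind == HYDROLYZE:
                assert e.index < st.heights[e.pf] - 1
                assert e.index >= st.seed_len

    def test_site_dependent_kon_classes(self):
        p = GMPCPP.replace(site_dependent_kon=True)
        st = init_state(p, seed_layers=5, capacity=32)
        # landing sites on a blunt end are longitudinal (no lateral contact)
        assoc = {e.pf: e.rate for e in enumerate_events(st, p)
                 if e.kind == ASSOCIATE}
        assert assoc[0] == pytest.approx(1.67 * 0.74 * 1.5)
        # raise both neighbours of pf 5 so its landing site is a bucket
        for q in (4, 6):
            st.nuc[q, st.heights[q]] = GTP
            st.heights[q] += 1
        assoc = {e.pf: e.rate for e in enumerate_events(st, p)
                 if e.kind == ASSOCIATE}
        assert assoc[5] == pytest.approx(0.74 * 1.5 / 4.62)
        # pf 4's terminal has no lateral contact: longitudinal-class off-rate
        d = [e for e in enumerate_events(st, p)
             if e.kind == DISSOCIATE and e.pf == 4][0]
        assert d.rate == pytest.approx(1.67 * 0.74 * site_affinity(st, 4, p))


class TestSeamGeometry:
    def test_stagger_across_seam(self):
        p = GMPCPP.replace(seam_offset=2)
        st = init_state(p, seed_layers=10, capacity=32)
        # (12, i) pairs with (0, i - 2): a dimer at index 10 on pf 12 sees the
        # pf-0 stack (height 10, top index 9) only through the stagger
        assert lateral_neighbor_count(st, 12, 10, 2) == 1   # pf 11 absent, pf 0 present
        assert lateral_neighbor_count(st, 0, 10, 2) == 0    # (0,10) -> (12,12) absent
        st.heights[12] = 13
        assert lateral_neighbor_count(st, 0, 10, 2) == 1    # (0,10) -> (12,12) present

    def test_interior_pairs_unstaggered(self):
        st = init_state(GMPCPP, seed_layers=10, capacity=32)
        assert lateral_neighbor_count(st, 5, 9, 2) == 2
        assert lateral_neighbor_count(st, 5, 10, 2) == 0


class TestAdvanceSemantics:
    def test_every_event_conserves_structure(self, rng):
        p = GMPCPP.replace(k_GTPase=0.5)
        st = init_state(p, seed_layers=4, capacity=256)
        for _ in range(400):
            before = st.total_subunits()
            gdp_before = int((st.nuc == GDP).sum())
            ev, dt = advance(st, p, rng)
            delta = st.total_subunits() - before
            gdp_delta = int((st.nuc == GDP).sum()) - gdp_before
            assert dt > 0
            if ev.kind == HYDROLYZE:
                assert delta == 0 and gdp_delta == 1
            else:
                assert abs(delta) == 1 and gdp_delta >= -1
            # contiguity: seed region immutable
            assert st.heights.min() >= st.seed_len

    def test_gdp_irreversible_and_absent_without_gtpase(self, rng):
        st = init_state(GMPCPP, seed_layers=4, capacity=256)
        for _ in range(300):
            advance(st, GMPCPP, rng)
        assert int((st.nuc == GDP).sum()) == 0

    def test_frozen_system_raises(self, rng):
        p = GMPCPP.replace(tubulin_conc=0.0)
        st = init_state(p, seed_layers=3)
        with pytest.raises(FrozenSystemError):
            advance(st, p, rng)


class TestTerminalGdpCount:
    def test_all_gdp_lattice(self):
        st = init_state(GMPCPP, seed_layers=3, extra_layers=2, all_gdp=True)
        assert terminal_gdp_count(st) == 13

    def test_buried_gdp_not_exposed(self):
        st = init_state(GMPCPP, seed_layers=3, extra_layers=2)
        st.nuc[4, 3] = GDP          # below the terminal dimer of pf 4
        assert terminal_gdp_count(st) == 0


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        ModelParams(k_on=-1.0)
    with pytest.raises(ValueError):
        ModelParams(K_D_corner=200.0, K_D_long=87.0)
    with pytest.raises(ValueError):
        ModelParams(gdp_factor_X=0.5)


def test_params_file_round_trip(tmp_path):
    p = ModelParams(k_on=0.5, K_D_long=10.0, K_D_corner=0.1, tubulin_conc=2.0,
                    k_GTPase=0.05, gdp_factor_X=30.0, seam_offset=1)
    f = tmp_path / "params.yaml"
    p.to_file(f)
    assert ModelParams.from_file(f) == p
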