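"""Per-agent stochastic rules: recruitment, movement, phagocytosis,
mediator release, departure, apoptosis and necrosis."""

import numpy as np
import pytest

from inflamsim import agents as ag
from inflamsim.mediators import SourceAccumulator


def make_mac(y=5, x=5, life=100, activated=False):
    return ag.Macrophage(y=y, x=x, prev_dir=0, lifespan_remaining=life,
                         activated=activated)


class TestLifespans:
    def test_intervals_inclusive(self, params, rng):
        draws = {cls: [ag.draw_lifespan(cls, params, rng)
                       for _ in range(2000)]
                 for cls in ("macrophage", "neutrophil", "apoptotic")}
        assert min(draws["neutrophil"]) >= 60
        assert max(draws["neutrophil"]) <= 1440
        assert min(draws["apoptotic"]) >= 60
        assert max(draws["apoptotic"]) <= 720
        assert min(draws["macrophage"]) >= 1440
        assert max(draws["macrophage"]) <= 86400

    def test_uniform_mean_within_3se(self, params, rng):
        n = 100_000
        vals = np.array([ag.draw_lifespan("macrophage", params, rng)
                         for _ in range(n)])
        lo, hi = params.macrophage_lifespan
        se = (hi - lo) / np.sqrt(12 * n)
        assert abs(vals.mean() - (lo + hi) / 2) < 3 * se

    def test_unknown_class_rejected(self, params, rng):
        with pytest.raises(ValueError):
            ag.draw_lifespan("platelet", params, rng)


class TestRecruitment:
    def test_no_mediator_no_macrophages(self, params, rng):
        c = np.zeros(params.grid_shape)
        assert ag.recruit_macrophages(c, params, 0, rng) == []

    def test_cap_blocks_recruitment(self, params, rng):
        c = np.ones(params.grid_shape)
        assert ag.recruit_macrophages(c, params, params.m_max, rng) == []
        g = np.zeros(params.grid_shape)
        assert ag.recruit_neutrophils(c, g, params, params.n_max, rng) == []

    def test_certain_recruitment_fills_qualifying_sites(self, params, rng):
        c = np.zeros(params.grid_shape)
        c[2, 2] = c[3, 7] = c[10, 4] = 1.0
        p = params.replace(p_mr=1.0)
        recruits = ag.recruit_macrophages(c, p, 0, rng)
        assert len(recruits) == 3
        assert {(m.y, m.x) for m in recruits} == {(2, 2), (3, 7), (10, 4)}

    def test_anti_inflammatory_veto(self, params, rng):
        c = np.ones(params.grid_shape)
        g = np.full(params.grid_shape, params.alpha_ngr)  # not strictly below
        p = params.replace(p_nr=1.0)
        assert ag.recruit_neutrophils(c, g, p, 0, rng) == []

    def test_neutrophil_recruitment_respects_cap_exactly(self, params, rng):
        c = np.ones(params.grid_shape)
        g = np.zeros(params.grid_shape)
        p = params.replace(p_nr=1.0, n_max=17)
        recruits = ag.recruit_neutrophils(c, g, p, 5, rng)
        assert len(recruits) == 12


class TestMacrophageMove:
    def test_single_apoptotic_neighbour_always_chosen(self, params, rng):
        apo = np.zeros(params.grid_shape, dtype=np.int64)
        apo[5, 6] = 1  # east of (5, 5)
        c = np.ones(params.grid_shape)
        m = make_mac()
        ag.macrophage_move(m, apo, c, params, rng)
        assert (m.y, m.x) == (5, 6) and m.prev_dir == 0

    def test_no_cues_uniform_random(self, params, rng):
        apo = np.zeros(params.grid_shape, dtype=np.int64)
        c = np.zeros(params.grid_shape)
        n = 40_000
        counts = np.zeros(8)
        for _ in range(n):
            m = make_mac()
            ag.macrophage_move(m, apo, c, params, rng)
            counts[m.prev_dir] += 1
        se = np.sqrt(0.125 * 0.875 / n)
        assert np.all(np.abs(counts / n - 0.125) < 3 * se)

    def test_multiple_apoptotic_neighbours_equally_likely(self, params, rng):
        apo = np.zeros(params.grid_shape, dtype=np.int64)
        targets = [(5, 6), (6, 5), (4, 4)]
        for y, x in targets:
            apo[y, x] = 1
        c = np.zeros(params.grid_shape)
        n = 30_000
        hits = {t: 0 for t in targets}
        for _ in range(n):
            m = make_mac()
            ag.macrophage_move(m, apo, c, params, rng)
            hits[(m.y, m.x)] += 1
        se = np.sqrt((1 / 3) * (2 / 3) / n)
        for t in targets:
            assert abs(hits[t] / n - 1 / 3) < 3 * se

    def test_chemotaxis_engaged_when_mediator_present(self, params, rng):
        """A steep east-west gradient pulls the macrophage east."""
        apo = np.zeros(params.grid_shape, dtype=np.int64)
        c = np.tile(np.linspace(0, 1, params.grid_shape[1]),
                    (params.grid_shape[0], 1))
        east = 0
        n = 2000
        moved_east = 0
        for _ in range(n):
            m = make_mac()
            ag.macrophage_move(m, apo, c, params, rng)
            moved_east += m.prev_dir in (7, east, 1)
        assert moved_east / n > 0.9  # k_grad = 80 on a strong gradient


class TestPhagocytosis:
    def test_nothing_colocated_noop(self, params, rng):
        m = make_mac()
        assert ag.phagocytose(m, [], params, rng) is None
        assert not m.activated

    def test_certain_removal_activates(self, params, rng):
        m = make_mac()
        victim = ag.ApoptoticNeutrophil(5, 5, 100)
        removed = ag.phagocytose(m, [victim], params, rng)  # p_ma = 1
        assert removed is victim and m.activated

    def test_zero_probability_never_removes(self, params, rng):
        p = params.replace(p_ma=0.0)
        m = make_mac()
        for _ in range(200):
            assert ag.phagocytose(
                m, [ag.ApoptoticNeutrophil(5, 5, 9)], p, rng) is None
        assert not m.activated

    def test_activation_is_sticky(self, params, rng):
        m = make_mac(activated=True)
        p = params.replace(p_ma=0.0)
        ag.phagocytose(m, [ag.ApoptoticNeutrophil(5, 5, 9)], p, rng)
        assert m.activated


class TestAntiInflammatoryRelease:
    def test_unactivated_never_releases(self, params, rng):
        src = SourceAccumulator(params.grid_shape)
        m = make_mac(activated=False)
        for _ in range(300):
            assert not ag.release_anti_inflammatory(m, src, params, rng)
        assert src.pending.sum() == 0.0

    def test_activated_certain_release(self, params, rng):
        src = SourceAccumulator(params.grid_shape)
        p = params.replace(p_mg=1.0)
        m = make_mac(activated=True)
        for _ in range(10):
            ag.release_anti_inflammatory(m, src, p, rng)
        assert src.pending[5, 5] == pytest.approx(10 * params.delta_mg)

    def test_release_frequency_within_3se(self, params, rng):
        src = SourceAccumulator(params.grid_shape)
        m = make_mac(activated=True)
        n = 100_000
        hits = sum(ag.release_anti_inflammatory(m, src, params, rng)
                   for _ in range(n))
        se = np.sqrt(0.8 * 0.2 / n)
        assert abs(hits / n - params.p_mg) < 3 * se


class TestDeparture:
    def test_resolved_tissue_certain_departure(self, params, rng):
        p = params.replace(p_ml=1.0)
        c = np.zeros(params.grid_shape)
        assert ag.macrophage_departure(make_mac(), c, p, rng)

    def test_inflamed_tissue_never_departs(self, params, rng):
        c = np.zeros(params.grid_shape)
        c[5, 5] = params.alpha_ml  # 3x3 sum equals the threshold: stays
        for _ in range(200):
            assert not ag.macrophage_departure(make_mac(), c, params, rng)

    def test_departure_frequency_within_3se(self, params, rng):
        c = np.zeros(params.grid_shape)
        n = 100_000
        hits = sum(ag.macrophage_departure(make_mac(), c, params, rng)
                   for _ in range(n))
        se = np.sqrt(0.8 * 0.2 / n)
        assert abs(hits / n - params.p_ml) < 3 * se


class TestNeutrophilStep:
    def test_no_gradient_no_aggregate_drift(self, params, rng):
        c = np.zeros(params.grid_shape)
        src = SourceAccumulator(params.grid_shape)
        p = params.replace(p_nc=0.0)
        n = 20_000
        disp = np.zeros(2)
        for _ in range(n):
            cell = ag.Neutrophil(10, 10, prev_dir=int(rng.integers(8)),
                                 lifespan_remaining=10)
            ag.neutrophil_step(cell, c, src, p, rng)
            disp += ((cell.y - 10 + 10) % 20 - 10,
                     (cell.x - 10 + 10) % 20 - 10)
        # 2 moves per tick, zero-mean step: SE of the mean ~ sqrt(2)/sqrt(n)
        assert np.all(np.abs(disp / n) < 3 * np.sqrt(2.0 / n))

    def test_apoptotic_replacement_in_place(self, params, rng):
        c = np.zeros(params.grid_shape)
        src = SourceAccumulator(params.grid_shape)
        cell = ag.Neutrophil(3, 3, 0, lifespan_remaining=1)
        replacement = ag.neutrophil_step(cell, c, src, params, rng)
        assert isinstance(replacement, ag.ApoptoticNeutrophil)
        assert (replacement.y, replacement.x) == (cell.y, cell.x)
        assert 60 <= replacement.necrosis_countdown <= 720

    def test_release_frequency_within_3se(self, params, rng):
        c = np.zeros(params.grid_shape)
        src = SourceAccumulator(params.grid_shape)
        n = 100_000
        for _ in range(n):
            ag.neutrophil_step(ag.Neutrophil(5, 5, 0, 10), c, src,
                               params, rng)
        freq = src.n_deposits / n
        se = np.sqrt(0.5 * 0.5 / n)
        assert abs(freq - params.p_nc) < 3 * se  # p_nc = 0.5


class TestApoptoticStep:
    def test_deterministic_countdown_and_single_deposit(self, params):
        src = SourceAccumulator(params.grid_shape)
        cell = ag.ApoptoticNeutrophil(4, 9, necrosis_countdown=3)
        assert not ag.apoptotic_step(cell, src, params)
        assert not ag.apoptotic_step(cell, src, params)
        assert src.pending.sum() == 0.0
        assert ag.apoptotic_step(cell, src, params)  # third tick: necrosis
        assert src.pending[4, 9] == params.delta_ac == 1.0

    def test_immobile_for_life(self, params):
        src = SourceAccumulator(params.grid_shape)
        cell = ag.ApoptoticNeutrophil(7, 2, necrosis_countdown=50)
        for _ in range(49):
            ag.apoptotic_step(cell, src, params)
            assert (cell.y, cell.x) == (7, 2)
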