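import numpy as np
import pandas as pd
import pytest

from netecol.fitness import FitnessSurface
from netecol.niches import (
    RATIO_CAP,
    accounting,
    blockmodel_order,
    cell_states,
    dormant_ties,
    niche_density,
)


def _surface(f_matrix, roster):
    rows = []
    for i, ego in enumerate(roster):
        for j, alter in enumerate(roster):
            if i != j:
                rows.append((ego, alter, f_matrix[i, j], f_matrix[i, j]))
    return FitnessSurface(
        table=pd.DataFrame(rows, columns=["ego", "alter", "p", "f"]),
        n=len(roster),
    )


class TestDormantTies:
    roster = list("abcd")
    F = np.array([
        [0.0, 0.9, 0.2, 0.85],
        [0.95, 0.0, 0.5, 0.1],
        [0.3, 0.88, 0.0, 0.4],
        [0.86, 0.2, 0.7, 0.0],
    ])
    R = np.array([
        [0, 1, 0, 0],
        [1, 0, 0, 0],
        [0, 1, 0, 0],
        [0, 0, 1, 0],
    ])

    def test_matches_hand_enumeration(self):
        surf = _surface(self.F, self.roster)
        out = dormant_ties(surf, self.R, 0.83, self.roster)
        assert out == {("a", "d"), ("d", "a")}

    def test_all_fit_reported_gives_empty_set(self):
        surf = _surface(self.F, self.roster)
        R = (self.F >= 0.83).astype(int)
        assert dormant_ties(surf, R, 0.83, self.roster) == set()

    def test_threshold_zero_gives_unreported_complement(self):
        surf = _surface(self.F, self.roster)
        out = dormant_ties(surf, self.R, 0.0, self.roster)
        n = len(self.roster)
        assert len(out) == n * (n - 1) - self.R.sum()

    def test_partition_identity(self):
        """Dormant ties and reported fit ties partition the fit dyads."""
        surf = _surface(self.F, self.roster)
        thr = 0.5
        dormant = dormant_ties(surf, self.R, thr, self.roster)
        idx = {v: i for i, v in enumerate(self.roster)}
        fit = {(e, a) for e, a, f in
               zip(surf.table.ego, surf.table.alter, surf.table.f) if f >= thr}
        reported_fit = {d for d in fit if self.R[idx[d[0]], idx[d[1]]] == 1}
        assert dormant | reported_fit == fit
        assert dormant & reported_fit == set()


class TestAccounting:
    def test_hundred_student_worked_example(self):
        """100 students, 17% fit share: 1683 fit dyads; 368 fit reported
        relations cover 21.9% of them."""
        acc = accounting(n=100, n_reported=400, fit_share_of_dyads=0.17,
                         n_fit_reported=368)
        assert acc.n_fit_dyads == 1683
        assert acc.reported_share_of_fit == pytest.approx(368 / 1683)
        assert round(100 * acc.reported_share_of_fit, 1) == 21.9
        assert acc.n_dormant == 1683 - 368

    def test_everything_reported_means_no_dormant(self):
        acc = accounting(n=10, n_reported=90, fit_share_of_dyads=0.5,
                         n_fit_reported=45)
        assert acc.n_fit_dyads == 45
        assert acc.reported_share_of_fit == 1.0
        assert acc.n_dormant == 0

    def test_inconsistent_counts_raise(self):
        with pytest.raises(ValueError, match="exceed reported"):
            accounting(10, 5, 0.5, 6)
        with pytest.raises(ValueError, match="exceed fit dyads"):
            accounting(10, 80, 0.1, 50)
        with pytest.raises(ValueError, match="fit_share"):
            accounting(10, 5, 1.5, 2)


def _planted_two_block(n=30, p_in=0.9, p_out=0.0, flip=0.0, seed=0):
    rng = np.random.default_rng(seed)
    half = n // 2
    truth = np.array([0] * half + [1] * (n - half))
    P = np.where(truth[:, None] == truth[None, :], p_in, p_out)
    F = (rng.random((n, n)) < P).astype(int)
    if flip:
        mask = rng.random((n, n)) < flip
        F = np.where(mask, 1 - F, F)
    np.fill_diagonal(F, 0)
    return F, truth


def _agreement(blocks, truth):
    a = np.mean(blocks == truth)
    return max(a, 1 - a)


class TestBlockmodel:
    def test_planted_partition_recovered_exactly(self):
        F, truth = _planted_two_block()
        part = blockmodel_order(F, k_blocks=2)
        assert part.k == 2
        assert _agreement(part.blocks, truth) == 1.0
        assert sorted(part.permutation) == list(range(len(truth)))

    def test_relabeling_invariance(self):
        F, truth = _planted_two_block(seed=3)
        perm = np.random.default_rng(1).permutation(len(truth))
        F2 = F[np.ix_(perm, perm)]
        p1 = blockmodel_order(F, k_blocks=2)
        p2 = blockmodel_order(F2, k_blocks=2)
        # identical partition up to block-label permutation
        relabeled = p1.blocks[perm]
        agree = np.mean(relabeled == p2.blocks)
        assert agree in (0.0, 1.0)

    def test_noisy_recovery_above_ninety_percent(self):
        agreements = []
        for seed in range(10):
            F, truth = _planted_two_block(flip=0.05, seed=seed)
            part = blockmodel_order(F, k_blocks=2)
            agreements.append(_agreement(part.blocks, truth))
        assert np.mean(agreements) >= 0.9

    def test_constant_matrix_single_block(self, caplog):
        with caplog.at_level("WARNING"):
            part = blockmodel_order(np.zeros((6, 6), dtype=int))
        assert part.k == 1
        assert "single block" in caplog.text

    def test_deterministic(self):
        F, _ = _planted_two_block(flip=0.05, seed=5)
        p1 = blockmodel_order(F, k_blocks=4)
        p2 = blockmodel_order(F, k_blocks=4)
        assert np.array_equal(p1.blocks, p2.blocks)
        assert np.array_equal(p1.permutation, p2.permutation)


class TestNicheDensity:
    def test_planted_two_block_ratio_capped(self):
        F, truth = _planted_two_block(p_in=1.0, p_out=0.0)
        part = blockmodel_order(F, k_blocks=2)
        dens = niche_density(part, F)
        assert dens.attrs["between_density"] == 0.0
        assert dens.attrs["clustering_ratio"] == RATIO_CAP

    def test_uniform_random_matrix_ratio_near_one(self):
        rng = np.random.default_rng(0)
        F = (rng.random((60, 60)) < 0.5).astype(int)
        np.fill_diagonal(F, 0)
        part = blockmodel_order(F, k_blocks=2)
        dens = niche_density(part, F)
        assert dens.attrs["clustering_ratio"] == pytest.approx(1.0, abs=0.25)

    def test_densities_match_direct_counting(self):
        F, _ = _planted_two_block(flip=0.1, seed=2)
        part = blockmodel_order(F, k_blocks=2)
        dens = niche_density(part, F)
        for _, row in dens.iterrows():
            ia = np.nonzero(part.blocks == row.block_ego)[0]
            ib = np.nonzero(part.blocks == row.block_alter)[0]
            ties = sum(F[i, j] for i in ia for j in ib if i != j)
            cells = (len(ia) * (len(ia) - 1) if row.block_ego == row.block_alter
                     else len(ia) * len(ib))
            assert row.density == pytest.approx(ties / cells)


def test_cell_states_classification(small_cohort, small_fit):
    panel, res, surface = small_fit
    states = cell_states(panel, "T2", surface, threshold=0.8)
    assert set(states.state) <= {
        "dormant", "stable", "forming", "dissolving", "attrited", "unfit"
    }
    assert len(states) == panel.n * (panel.n - 1)
    # every dormant cell is fit and unreported
    reported = panel.wave("T2").edge_set()
    for _, row in states[states.state == "dormant"].head(50).iterrows():
        assert row.f >= 0.8
        assert (row.ego, row.alter) not in reported
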