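"""Mixture L2-discrepancy, balance invariants, and the SOAT search."""

import numpy as np
import pytest

from udpep.errors import BalanceError, ConfigError
from udpep.uniform_design import (
    DesignSeries,
    LevelDesign,
    SoatConfig,
    build_series,
    design_to_peptides,
    level_to_unit,
    load_design,
    md2,
    md2_of_design,
    occupancy_table,
    peptides_to_design,
    random_balanced_design,
    save_design,
    series_sizes,
    soat_optimize,
)


def md2_oracle(x: np.ndarray) -> float:
    """Independent brute-force double-loop evaluation of the MD2 closed form."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    n, s = x.shape
    t1 = (19.0 / 12.0) ** s
    t2 = 0.0
    for i in range(n):
        p = 1.0
        for j in range(s):
            a = abs(x[i, j] - 0.5)
            p *= 5.0 / 3.0 - a / 4.0 - a * a / 4.0
        t2 += p
    t3 = 0.0
    for i in range(n):
        for k in range(n):
            p = 1.0
            for j in range(s):
                ai = abs(x[i, j] - 0.5)
                ak = abs(x[k, j] - 0.5)
                d = abs(x[i, j] - x[k, j])
                p *= 15.0 / 8.0 - ai / 4.0 - ak / 4.0 - 0.75 * d + 0.5 * d * d
            t3 += p
    return t1 - 2.0 / n * t2 + t3 / n**2


class TestMd2:
    def test_hand_derived_single_point_values(self):
        assert md2(np.array([[0.5]])) == pytest.approx(0.125, abs=1e-12)
        assert md2(np.array([[0.0]])) == pytest.approx(0.25, abs=1e-12)

    def test_matches_bruteforce_oracle_on_random_designs(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 50))
            s = int(rng.integers(1, 6))
            x = rng.random((n, s))
            assert md2(x) == pytest.approx(md2_oracle(x), abs=1e-12)

    def test_nonnegative_on_random_designs(self, rng):
        vals = [md2(rng.random((int(rng.integers(2, 30)), 3))) for _ in range(200)]
        assert min(vals) >= 0.0

    def test_row_and_column_permutation_invariance(self, rng):
        x = rng.random((15, 4))
        base = md2(x)
        assert md2(x[rng.permutation(15)]) == pytest.approx(base, abs=1e-12)
        assert md2(x[:, rng.permutation(4)]) == pytest.approx(base, abs=1e-12)

    def test_reflection_invariance(self, rng):
        # kernel terms depend only on |x - 1/2| and |x_i - x_k|
        x = rng.random((12, 3))
        y = x.copy()
        y[:, 1] = 1.0 - y[:, 1]
        assert md2(y) == pytest.approx(md2(x), abs=1e-12)

    def test_lookup_table_path_agrees_with_general_path(self, rng):
        d = random_balanced_design(60, 4, 20, seed=5)
        assert md2_of_design(d) == pytest.approx(md2(level_to_unit(d)), abs=1e-12)

    def test_out_of_cube_rejected(self):
        with pytest.raises(Exception):
            md2(np.array([[1.5]]))


class TestLevelDesigns:
    def test_level_to_unit_centered_convention(self):
        d = LevelDesign(np.tile(np.arange(1, 21)[:, None], (1, 2)), q=20)
        u = level_to_unit(d)
        assert u[0, 0] == pytest.approx(0.025)
        assert u[-1, 0] == pytest.approx(0.975)
        assert np.all((u > 0) & (u < 1))

    def test_random_balanced_design_counts(self):
        d = random_balanced_design(1000, 4, 20, seed=1)
        for j in range(4):
            counts = np.bincount(d.matrix[:, j], minlength=21)[1:]
            assert np.all(counts == 50)

    def test_same_seed_identical(self):
        a = random_balanced_design(100, 4, 20, seed=9)
        b = random_balanced_design(100, 4, 20, seed=9)
        assert np.array_equal(a.matrix, b.matrix)

    def test_unbalanced_n_rejected(self):
        with pytest.raises(BalanceError, match="1001"):
            random_balanced_design(1001, 4, 20)

    def test_peptide_round_trip(self):
        d = random_balanced_design(40, 4, 20, seed=2)
        peps = design_to_peptides(d)
        assert len(peps) == 40
        back = peptides_to_design(peps)
        assert np.array_equal(back.matrix, d.matrix)

    def test_row_of_ones_is_all_alanine(self):
        d = LevelDesign(np.ones((20, 1), dtype=int) * np.arange(1, 21)[:, None], q=20)
        assert design_to_peptides(d)[0] == "A"


class TestSoat:
    def test_final_md2_not_worse_than_random_start(self):
        for seed in range(3):
            cfg = SoatConfig(outer_loops=5, inner_loops=100, seed=seed)
            opt = soat_optimize(100, 4, 20, cfg)
            start = random_balanced_design(100, 4, 20, seed=seed)
            assert opt.md2_value <= md2_of_design(start) + 1e-12

    def test_balance_preserved_and_occupancy_exact(self):
        opt = soat_optimize(200, 4, 20, SoatConfig(outer_loops=4, inner_loops=100, seed=3))
        occ = occupancy_table(opt)
        assert occ.shape == (4, 20)
        assert np.all(occ == 0.05)
        assert np.allclose(occ.sum(axis=1), 1.0, atol=1e-12)

    def test_incremental_value_matches_full_recompute(self):
        opt = soat_optimize(80, 3, 20, SoatConfig(outer_loops=6, inner_loops=150, seed=11))
        assert opt.md2_value == pytest.approx(md2_of_design(opt), abs=1e-9)

    def test_beats_random_baseline_small_space(self, rng):
        # n=40, s=2, q=4: SOAT should match or beat 1000 random balanced designs
        wins = 0
        seeds = range(8)
        for seed in seeds:
            opt = soat_optimize(40, 2, 4, SoatConfig(outer_loops=10, inner_loops=200, seed=seed))
            best_random = min(
                md2_of_design(random_balanced_design(40, 2, 4, seed=1000 * seed + i))
                for i in range(1000)
            )
            wins += opt.md2_value <= best_random + 1e-12
        assert wins >= int(0.95 * len(seeds))

    def test_seed_reproducibility(self):
        cfg = SoatConfig(outer_loops=3, inner_loops=80, seed=21)
        a = soat_optimize(60, 4, 20, cfg)
        b = soat_optimize(60, 4, 20, cfg)
        assert np.array_equal(a.matrix, b.matrix)

    def test_bad_config_rejected(self):
        with pytest.raises(ConfigError):
            SoatConfig(outer_loops=0)
        with pytest.raises(ConfigError):
            SoatConfig(threshold_decay=1.5)

    def test_trace_records_accepted_improvements(self):
        _, trace = soat_optimize(
            60, 4, 20, SoatConfig(outer_loops=4, inner_loops=100, seed=5), return_trace=True
        )
        assert {"outer", "accepted", "md2", "threshold"} <= set(trace.columns)
        assert trace["md2"].is_monotonic_decreasing


class TestSeries:
    def test_default_grid_is_31_sizes(self):
        sizes = series_sizes()
        assert len(sizes) == 31
        assert sizes[0] == 1000 and sizes[-1] == 16000 and sizes[1] - sizes[0] == 500

    def test_sampling_fraction_at_3500(self):
        # 3500 / 160000 = 2.1875%, printed as 2.19%
        designs = tuple(
            random_balanced_design(n, 4, 20, seed=i) for i, n in enumerate((1000, 3500))
        )
        series = DesignSeries((1000, 3500), designs)
        assert series.sampling_fractions[1] * 100 == pytest.approx(2.1875)
        assert round(series.sampling_fractions[1] * 100, 2) == 2.19

    def test_build_series_small_space(self):
        series = build_series(
            start=8, stop=16, step=4, s=2, q=4,
            cfg=SoatConfig(outer_loops=2, inner_loops=40, seed=0),
        )
        assert series.sizes == (8, 12, 16)
        assert all(d.q == 4 for d in series.designs)
        # independent seeds by documented offset
        assert [d.seed for d in series.designs] == [0, 1, 2]


class TestDesignIO:
    def test_csv_sidecar_round_trip(self, tmp_path):
        cfg = SoatConfig(outer_loops=2, inner_loops=50, seed=4)
        d = soat_optimize(40, 4, 20, cfg)
        path = tmp_path / "design.csv"
        save_design(d, path, cfg)
        assert path.with_suffix(".json").exists()
        loaded = load_design(path)
        assert np.array_equal(loaded.matrix, d.matrix)
        header = path.read_text().splitlines()[0]
        assert header == "pos1,pos2,pos3,pos4"
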