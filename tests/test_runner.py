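"""Experiment runner: per-item tables, paired statistics, sweeps, exports."""
import numpy as np
import pytest
from scipy import stats

import tonalctx as tx
from tonalctx.runner import paired_t


@pytest.fixture(scope="module")
def tiny_set():
    return tx.preset_stimuli("slevc09_chords", n_keys=2)


@pytest.fixture(scope="module")
def tiny_cache():
    return {}


def test_paired_t_contracts():
    a = np.array([1.0, 2.0, 3.0, 4.0])
    assert paired_t(a, a) == (0.0, 1.0)
    t, p = paired_t(a, a - 1.0)  # constant shift, zero-variance differences
    assert t == pytest.approx(1e6) and p == pytest.approx(1e-12)
    t, p = paired_t(a - 1.0, a)
    assert t == pytest.approx(-1e6)
    with pytest.raises(ValueError):
        paired_t(a, a[:2])
    with pytest.raises(ValueError):
        paired_t(a[:1], a[:1])
    # agrees with the reference implementation on ordinary data
    rng = np.random.default_rng(0)
    x, y = rng.random(15), rng.random(15)
    t, p = paired_t(x, y)
    tr, pr = stats.ttest_rel(x, y)
    assert t == pytest.approx(float(tr)) and p == pytest.approx(float(pr))


def test_paired_t_type_one_error_rate():
    """Under the null, rejections at alpha=0.05 stay near 5% (1000 reps)."""
    rng = np.random.default_rng(7)
    rejections = 0
    for _ in range(1000):
        a = rng.standard_normal(20)
        b = rng.standard_normal(20)
        _, p = paired_t(a, b)
        rejections += p < 0.05
    assert 0.03 <= rejections / 1000 <= 0.07


def test_run_items_rows_and_windows(tiny_set, tiny_cache):
    df = tx.run_items(tiny_set, tx.EchoicParams(), _series_cache=tiny_cache)
    target_rows = df[df.window == "target"]
    assert len(target_rows) == len(tiny_set.items)
    assert set(df.columns) >= {"item_id", "condition", "key", "mean_z",
                               "mean_r", "n_frames"}
    assert (df.n_frames > 0).all()
    assert df.mean_r.between(-1, 1).all()


def test_sweep_single_cell_matches_run_items(tiny_set, tiny_cache):
    cfg = tx.RunConfig(grid=(0.1, 0.1, 0.1))
    g = tx.sweep(tiny_set, ("inkey", "out_of_key"), cfg,
                 _series_cache=tiny_cache)
    assert g.mean_diff.shape == (1, 1)
    df = tx.run_items(tiny_set, tx.EchoicParams(0.1, 0.1),
                      _series_cache=tiny_cache)
    tgt = df[df.window == "target"].set_index("item_id")
    diffs = [tgt.loc[p.id_a, "mean_z"] - tgt.loc[p.id_b, "mean_z"]
             for p in tiny_set.pairing]
    assert g.mean_diff[0, 0] == pytest.approx(np.mean(diffs), abs=1e-12)


def test_sweep_symmetry_under_label_swap(tiny_set, tiny_cache):
    cfg = tx.RunConfig(grid=(0.1, 1.5, 1.4))
    g1 = tx.sweep(tiny_set, ("inkey", "out_of_key"), cfg,
                  _series_cache=tiny_cache)
    swapped = tx.StimulusSet(
        tiny_set.preset_id, tiny_set.seed, tiny_set.items,
        [tx.PairedComparison(p.id_b, p.id_a, p.window)
         for p in tiny_set.pairing],
        tiny_set.timbre, tiny_set.window_mode, tiny_set.reset_policy)
    g2 = tx.sweep(swapped, ("out_of_key", "inkey"), cfg,
                  _series_cache=tiny_cache)
    np.testing.assert_allclose(g1.mean_diff, -g2.mean_diff, atol=1e-12)
    np.testing.assert_allclose(g1.t_values, -g2.t_values, atol=1e-9)
    np.testing.assert_allclose(g1.p_values, g2.p_values, atol=1e-12)


def test_caching_equivalence(tiny_set, tiny_cache):
    """Cached pitch-image series give the same sweep as a cold recompute."""
    cfg = tx.RunConfig(grid=(0.7, 1.9, 1.2))
    warm = tx.sweep(tiny_set, ("inkey", "out_of_key"), cfg,
                    _series_cache=tiny_cache)
    cold = tx.sweep(tiny_set, ("inkey", "out_of_key"), cfg,
                    _series_cache=None)
    np.testing.assert_allclose(warm.mean_diff, cold.mean_diff, atol=1e-10)


def test_unknown_conditions_and_presets_raise(tiny_set):
    with pytest.raises(ValueError, match="no pairings"):
        tx.sweep(tiny_set, ("inkey", "nonexistent"),
                 tx.RunConfig(grid=(0.1, 0.1, 0.1)))
    with pytest.raises(KeyError, match="available"):
        tx.reproduce("not_a_study")


def test_continuous_mode_carries_state():
    """With state carried across items, an item's TC depends on its context."""
    s = tx.preset_stimuli("loui09_8020", n_sequences=6)
    params = tx.EchoicParams(0.1, 1.5)
    per_trial = tx.run_items(s, params, tx.RunConfig(reset_policy="per_trial"))
    cont = tx.run_items(s, params,
                        tx.RunConfig(reset_policy="continuous", n_runs=2))
    a = per_trial[per_trial.window == "target"].set_index("item_id").mean_z
    b = cont[cont.window == "target"].set_index("item_id").mean_z
    assert not np.allclose(a.sort_index(), b.sort_index())


def test_export_grid_files(tmp_path, tiny_set, tiny_cache):
    cfg = tx.RunConfig(grid=(0.1, 1.3, 0.6))
    g = tx.sweep(tiny_set, ("inkey", "out_of_key"), cfg,
                 _series_cache=tiny_cache)
    csv_path, png_path = tx.export_grid(g, tmp_path)
    assert csv_path.exists() and png_path.exists()
    import pandas as pd

    df = pd.read_csv(csv_path)
    assert len(df) == 9
    assert {"t_local", "t_global", "mean_diff", "t", "p",
            "significant"} <= set(df.columns)


def test_probe_tone_errors():
    s = tx.preset_stimuli("slevc09_chords", n_keys=1)
    with pytest.raises(ValueError, match="probe"):
        tx.probe_tone_profile(s)
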