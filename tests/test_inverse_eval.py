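"""Dipole fitting, source quantization and the evaluation metrics."""

import numpy as np
import pytest

from earshell.bem_forward import Dipole, SourceGrid
from earshell.inverse_eval import (
    ComponentMap,
    EvalResult,
    MixingModel,
    ModeledMap,
    Recording,
    correlation_by_group,
    fit_dipole,
    pvaf,
    predicted_map,
    quantize_source,
    residual_variance,
    results_table,
    select_components,
)

LABELS15 = [f"e{i}" for i in range(15)]


def cmap(values, groups=None, labels=None):
    labels = labels or LABELS15[: len(values)]
    return ComponentMap(values, labels, groups or {"scalp": labels})


def mmap(values, labels=None):
    labels = labels or LABELS15[: len(values)]
    return ModeledMap(values, labels)


# ----------------------------------------------------------------- metrics


def test_correlation_affine_match_is_one(rng):
    c = rng.normal(size=15)
    maps = cmap(c, groups={"scalp": LABELS15})
    assert correlation_by_group(maps, mmap(2 * c + 3))["scalp"] == pytest.approx(1.0)


def test_correlation_negated_map_is_minus_one(rng):
    c = rng.normal(size=15)
    maps = cmap(c, groups={"scalp": LABELS15})
    assert correlation_by_group(maps, mmap(-c))["scalp"] == pytest.approx(-1.0)


def test_correlation_matches_covariance_formula(rng):
    """Oracle: direct evaluation of cov/sqrt(var*var) on random vectors."""
    c = rng.normal(size=15)
    f = rng.normal(size=15)
    got = correlation_by_group(cmap(c, {"scalp": LABELS15}), mmap(f))["scalp"]
    expect = np.mean((c - c.mean()) * (f - f.mean())) / np.sqrt(
        np.mean((c - c.mean()) ** 2) * np.mean((f - f.mean()) ** 2)
    )
    assert abs(got - expect) < 1e-12


def test_correlation_by_group_is_per_group(rng):
    labels = [f"e{i}" for i in range(12)]
    groups = {"left_ear": labels[:4], "scalp": labels[4:8], "right_ear": labels[8:]}
    c = rng.normal(size=12)
    f = c.copy()
    f[:4] = -c[:4]  # anti-correlated in the left ear only
    out = correlation_by_group(ComponentMap(c, labels, groups), ModeledMap(f, labels))
    assert out["left_ear"] == pytest.approx(-1.0)
    assert out["scalp"] == pytest.approx(1.0)
    assert out["right_ear"] == pytest.approx(1.0)


def test_correlation_zero_variance_reported_not_raised():
    labels = ["a", "b", "c"]
    out = correlation_by_group(
        ComponentMap([1.0, 1.0, 1.0], labels, {"scalp": labels}),
        ModeledMap([1.0, 2.0, 3.0], labels),
    )
    assert out["scalp"] is None
    assert "variance" in out["scalp:reason"]


def test_rv_perfect_match_zero(rng):
    c = rng.normal(size=15)
    assert residual_variance(cmap(c), mmap(c)) == 0.0


def test_rv_zero_model_is_100_percent(rng):
    c = rng.normal(size=15)
    assert residual_variance(cmap(c), mmap(np.zeros(15))) == pytest.approx(100.0)


def test_rv_matches_direct_formula(rng):
    c = rng.normal(size=15)
    f = rng.normal(size=15)
    got = residual_variance(cmap(c), mmap(f))
    expect = 100.0 * np.var(c - f) / np.var(c)
    assert abs(got - expect) < 1e-12


def test_rv_not_scale_invariant_but_correlation_is(rng):
    """C is invariant to positive affine rescaling; RV is not."""
    c = rng.normal(size=15)
    f = rng.normal(size=15)
    maps = cmap(c, {"scalp": LABELS15})
    c1 = correlation_by_group(maps, mmap(f))["scalp"]
    c2 = correlation_by_group(maps, mmap(3 * f + 1))["scalp"]
    assert abs(c1 - c2) < 1e-12
    assert residual_variance(maps, mmap(f)) != pytest.approx(
        residual_variance(maps, mmap(3 * f + 1))
    )


def test_pvaf_brute_force_toy(rng):
    """3-channel 2-component toy against per-channel direct variances."""
    x = rng.normal(size=(3, 200))
    W_inv = rng.normal(size=(3, 2))
    u = rng.normal(size=(2, 200))
    rec = Recording(x, 100.0, ["a", "b", "c"])
    mix = MixingModel(W_inv, u, ["a", "b", "c"])
    for m in range(2):
        y = np.outer(W_inv[:, m], u[m])
        expect = 100 - 100 * np.mean(
            [(x[n] - y[n]).var() / x[n].var() for n in range(3)]
        )
        assert abs(pvaf(rec, mix, m) - expect) < 1e-12


def test_pvaf_exact_backprojection_is_100(rng):
    W_inv = rng.normal(size=(4, 2))
    u = rng.normal(size=(2, 100))
    rec = Recording(np.outer(W_inv[:, 1], u[1]), 100.0, list("abcd"))
    mix = MixingModel(W_inv, u, list("abcd"))
    assert pvaf(rec, mix, 1) == pytest.approx(100.0)


def test_pvaf_zero_timecourse_component(rng):
    W_inv = rng.normal(size=(4, 2))
    u = np.vstack([np.zeros(100), rng.normal(size=100)])
    rec = Recording(rng.normal(size=(4, 100)), 100.0, list("abcd"))
    mix = MixingModel(W_inv, u, list("abcd"))
    assert pvaf(rec, mix, 0) == pytest.approx(0.0)


def test_pvaf_excludes_silent_channels(rng):
    data = rng.normal(size=(3, 50))
    data[1] = 0.0
    rec = Recording(data, 100.0, list("abc"))
    mix = MixingModel(rng.normal(size=(3, 1)), rng.normal(size=(1, 50)), list("abc"))
    with pytest.warns(RuntimeWarning, match="silent"):
        pvaf(rec, mix, 0)


# ------------------------------------------------------------ quantization


def grid_1d():
    ijk = np.array([[i, j, k] for i in range(3) for j in range(3) for k in range(3)])
    return SourceGrid(
        nodes=ijk * 4.0, spacing=4.0, near_boundary=np.zeros(27, bool),
        ijk=ijk, origin=np.zeros(3), shape=(3, 3, 3),
    )


def test_quantize_exact_node():
    grid = grid_1d()
    node, d = quantize_source([4.0, 8.0, 0.0], grid)
    np.testing.assert_allclose(grid.nodes[node], [4, 8, 0])
    assert d == 0.0


def test_quantize_lattice_bound(rng):
    grid = grid_1d()
    for _ in range(50):
        p = rng.uniform(0, 8.0, 3)
        _, d = quantize_source(p, grid)
        assert d <= np.sqrt(3) / 2 * 4.0 + 1e-12


def test_quantize_matches_exhaustive_search(rng):
    grid = grid_1d()
    for _ in range(100):
        p = rng.uniform(-4, 12, 3)
        node, d = quantize_source(p, grid)
        dists = np.linalg.norm(grid.nodes - p, axis=1)
        assert node == int(np.argmin(dists))
        assert d == pytest.approx(dists.min())


# ------------------------------------------------------------- dipole fits


def test_fit_recovers_grid_node_dipoles_noiseless(sphere_lfm, rng):
    interior = np.where(~sphere_lfm.grid.near_boundary)[0]
    for _ in range(5):
        node = int(rng.choice(interior))
        mom = rng.normal(size=3) * 1e-9
        c = sphere_lfm.values[:, node, :] @ mom
        dip, rv, info = fit_dipole(cmap(c, labels=sphere_lfm.labels), sphere_lfm)
        assert np.linalg.norm(dip.position - sphere_lfm.grid.nodes[node]) <= 4.0
        assert rv < 1.0


def test_fit_with_noise_median_error_bounded(sphere_lfm):
    errs = []
    interior = np.where(~sphere_lfm.grid.near_boundary)[0]
    for seed in range(20):
        r = np.random.default_rng(seed)
        node = int(r.choice(interior))
        mom = r.normal(size=3) * 1e-9
        c = sphere_lfm.values[:, node, :] @ mom
        c = c + r.normal(0, 0.05 * np.std(c), len(c))
        dip, rv, _ = fit_dipole(cmap(c, labels=sphere_lfm.labels), sphere_lfm)
        errs.append(np.linalg.norm(dip.position - sphere_lfm.grid.nodes[node]))
    assert np.median(errs) <= 8.0


def test_two_antipodal_dipoles_fit_worse_than_one(sphere_lfm, rng):
    interior = np.where(~sphere_lfm.grid.near_boundary)[0]
    node = int(rng.choice(interior))
    pos = sphere_lfm.grid.nodes[node]
    anti, _ = quantize_source(-pos, sphere_lfm.grid)
    mom = rng.normal(size=3) * 1e-9
    c_single = sphere_lfm.values[:, node, :] @ mom
    c_pair = c_single + sphere_lfm.values[:, anti, :] @ (mom * [-1, -1, 1])
    _, rv_single, _ = fit_dipole(cmap(c_single, labels=sphere_lfm.labels), sphere_lfm)
    _, rv_pair, _ = fit_dipole(cmap(c_pair, labels=sphere_lfm.labels), sphere_lfm)
    assert rv_pair > rv_single


def test_fit_rejects_degenerate_maps(sphere_lfm):
    with pytest.raises(ValueError, match="constant"):
        fit_dipole(cmap(np.zeros(64), labels=sphere_lfm.labels), sphere_lfm)
    with pytest.raises(ValueError, match="8 electrodes"):
        fit_dipole(
            ComponentMap([1.0, 2.0], sphere_lfm.labels[:2], {}), sphere_lfm
        )


def test_end_to_end_recovery_all_groups(sphere_lfm, rng):
    """simulate -> fit (scalp only) -> quantize -> predict: C = 1, RV < 1%."""
    labels = sphere_lfm.labels
    groups = {
        "left_ear": labels[:10],
        "scalp": labels[10:54],
        "right_ear": labels[54:],
    }
    interior = np.where(~sphere_lfm.grid.near_boundary)[0]
    node = int(rng.choice(interior))
    mom = rng.normal(size=3) * 1e-9
    full = ComponentMap(sphere_lfm.values[:, node, :] @ mom, labels, groups)
    dip, rv, _ = fit_dipole(full.subset(groups["scalp"]), sphere_lfm)
    qnode, qdist = quantize_source(dip.position, sphere_lfm.grid)
    model_map = predicted_map(sphere_lfm, qnode, dip.moment)
    cs = correlation_by_group(full, model_map)
    for g in ("left_ear", "scalp", "right_ear"):
        assert cs[g] == pytest.approx(1.0, abs=1e-6)
    assert residual_variance(full, model_map) < 1.0
    assert qnode == node


# --------------------------------------------------------------- selection


def result(m, rv, pos=(0, 0, 10.0), in_brain=True):
    return EvalResult(
        component=m, rv=rv, correlations={}, dipole=Dipole(pos, [0, 0, 1e-9]),
        node=0, quantization_distance=0.0, in_brain=in_brain,
    )


def test_select_lowest_rv_in_brain():
    results = [result(m, rv) for m, rv in enumerate([9, 3, 7, 1, 5, 2, 8, 4, 6, 0,
                                                     11, 10, 13, 12])]
    sel = select_components(results, k=12)
    assert len(sel) == 12
    rvs = [r.rv for r in sel]
    assert rvs == sorted(rvs)
    assert max(rvs) <= min(r.rv for r in results if r not in sel)


def test_select_excludes_out_of_brain():
    results = [result(0, 1.0, in_brain=False), result(1, 5.0)]
    sel = select_components(results, k=12)
    assert [r.component for r in sel] == [1]


def test_select_empty_warns():
    results = [result(0, 1.0, in_brain=False)]
    with pytest.warns(RuntimeWarning, match="no fitted dipoles"):
        sel = select_components(results, k=12)
    assert sel == []


def test_select_with_brain_surface(sphere_model_small):
    results = [result(0, 1.0, pos=(0, 0, 10.0)), result(1, 0.5, pos=(0, 0, 95.0))]
    sel = select_components(results, k=12, brain=sphere_model_small.brain)
    assert [r.component for r in sel] == [0]


def test_results_table_format():
    r = result(3, 6.3)
    r.correlations = {"left_ear": 0.34, "scalp": 0.97, "right_ear": 0.41}
    r.pvaf = 12.0
    table = results_table([r])
    header, row = table.strip().split("\n")
    assert header.startswith("component\tRV%")
    assert row.split("\t")[0] == "3"
    assert "0.970" in row
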