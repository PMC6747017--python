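"""Single-dipole fitting of component maps and model-fit metrics.

An ICA decomposition of a multichannel EEG recording yields, for each
independent component, a *component map*: the column of the inverse
mixing matrix giving the component's projection weight at every
electrode.  When a component corresponds to a focal cortical source,
its map resembles the topography of a single current dipole filtered
through the head's forward model.  This module fits that dipole using
the scalp electrodes only, quantizes the fitted location to the lead
field's source grid, predicts the full map (including the in-ear
electrodes) from the forward model, and scores the agreement with

* group-wise Pearson correlation ``C`` (left ear / scalp / right ear),
* residual variance ``RV = 100 var(c - f)/var(c)`` (%),
* ``PVAF``, the percent of recording variance a component accounts for.

Variances in ``C`` and ``RV`` are taken across electrodes; in ``PVAF``
across time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .bem_forward import Dipole, LeadFieldMatrix, SourceGrid

__all__ = [
    "Recording",
    "MixingModel",
    "ComponentMap",
    "ModeledMap",
    "EvalResult",
    "fit_dipole",
    "quantize_source",
    "correlation_by_group",
    "residual_variance",
    "pvaf",
    "select_components",
    "results_table",
]

GROUPS = ("left_ear", "scalp", "right_ear")


@dataclass
class Recording:
    """Multichannel EEG: ``data`` is (n_channels, n_samples) in volts."""

    data: np.ndarray
    rate: float
    labels: list
    triggers: np.ndarray = field(default_factory=lambda: np.array([], np.int64))

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data, float))
        self.labels = list(self.labels)
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("label count must equal channel count")
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        self.triggers = np.asarray(self.triggers, np.int64)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def channel(self, label: str) -> np.ndarray:
        return self.data[self.labels.index(label)]


@dataclass
class MixingModel:
    """ICA unmixing result: inverse mixing matrix and component signals.

    ``back_projection(m)`` returns y_mn(t), the rank-one projection of
    component m to every electrode.
    """

    inverse_mixing: np.ndarray  # (n_channels, n_components)
    timecourses: np.ndarray  # (n_components, n_samples)
    labels: list

    def __post_init__(self):
        self.inverse_mixing = np.atleast_2d(np.asarray(self.inverse_mixing, float))
        self.timecourses = np.atleast_2d(np.asarray(self.timecourses, float))
        if self.inverse_mixing.shape[1] != self.timecourses.shape[0]:
            raise ValueError("component count mismatch")
        self.labels = list(self.labels)

    @property
    def n_components(self) -> int:
        return self.inverse_mixing.shape[1]

    def back_projection(self, m: int) -> np.ndarray:
        return np.outer(self.inverse_mixing[:, m], self.timecourses[m])

    def component_map(self, m: int, groups=None) -> "ComponentMap":
        return ComponentMap(
            values=self.inverse_mixing[:, m].copy(),
            labels=list(self.labels),
            groups=groups or {},
            component=m,
        )


@dataclass
class ComponentMap:
    """Per-electrode coefficients of one independent component.

    ``groups`` maps a group name (``left_ear``/``scalp``/``right_ear``)
    to the member electrode labels.
    """

    values: np.ndarray
    labels: list
    groups: dict
    component: int = 0

    def __post_init__(self):
        self.values = np.asarray(self.values, float).reshape(-1)
        self.labels = list(self.labels)
        if len(self.values) != len(self.labels):
            raise ValueError("coefficient/label length mismatch")
        if not np.isfinite(self.values).all():
            raise ValueError("component map has missing/non-finite coefficients")

    def subset(self, labels) -> "ComponentMap":
        idx = [self.labels.index(s) for s in labels]
        return ComponentMap(self.values[idx], list(labels), self.groups, self.component)

    def group_values(self, group: str) -> np.ndarray:
        labels = self.groups[group]
        idx = [self.labels.index(s) for s in labels]
        return self.values[idx]


@dataclass
class ModeledMap:
    """Forward-model prediction of a component map."""

    values: np.ndarray
    labels: list
    dipole: Dipole = None
    node: int = -1

    def __post_init__(self):
        self.values = np.asarray(self.values, float).reshape(-1)
        self.labels = list(self.labels)
        if len(self.values) != len(self.labels):
            raise ValueError("coefficient/label length mismatch")

    def group_values(self, groups: dict, group: str) -> np.ndarray:
        idx = [self.labels.index(s) for s in groups[group]]
        return self.values[idx]


@dataclass
class EvalResult:
    """Per-component evaluation record."""

    component: int
    rv: float
    correlations: dict
    dipole: Dipole
    node: int
    quantization_distance: float
    pvaf: float = np.nan
    in_brain: bool = True
    on_hull: bool = False


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


def residual_variance(c, f, subset=None) -> float:
    """``RV = 100 var(c - f) / var(c)`` in %, variance across electrodes."""
    cv = c.values if isinstance(c, ComponentMap) else np.asarray(c, float)
    fv = f.values if isinstance(f, ModeledMap) else np.asarray(f, float)
    if subset is not None:
        labels_c = c.labels if isinstance(c, ComponentMap) else None
        if labels_c is None:
            idx = np.asarray(subset)
            cv, fv = cv[idx], fv[idx]
        else:
            idx = [labels_c.index(s) for s in subset]
            cv, fv = cv[idx], fv[idx]
    vc = np.var(cv)
    if vc == 0:
        raise ValueError("component map has zero variance on the subset")
    return float(100.0 * np.var(cv - fv) / vc)


def correlation_by_group(c: ComponentMap, f: ModeledMap) -> dict:
    """Pearson correlation per electrode group.

    Groups with fewer than 2 electrodes or zero variance in either map
    yield ``None`` with the reason recorded under ``<group>:reason``.
    """
    out = {}
    for group, labels in c.groups.items():
        if len(labels) < 2:
            out[group] = None
            out[group + ":reason"] = "fewer than 2 electrodes"
            continue
        cv = c.subset(labels).values
        idx = [f.labels.index(s) for s in labels]
        fv = f.values[idx]
        if np.var(cv) == 0 or np.var(fv) == 0:
            out[group] = None
            out[group + ":reason"] = "zero variance"
            continue
        cov = np.cov(cv, fv, ddof=0)
        out[group] = float(cov[0, 1] / np.sqrt(cov[0, 0] * cov[1, 1]))
    return out


def pvaf(recording: Recording, mixing: MixingModel, m: int) -> float:
    """Percent of recording variance accounted for by component ``m``.

    ``PVAF = 100 - 100 mean_n var(x_n - y_mn)/var(x_n)`` with variance
    over time; silent channels are excluded with a warning.
    """
    if recording.labels != mixing.labels:
        raise ValueError("recording and mixing have different channel sets")
    x = recording.data
    y = mixing.back_projection(m)
    var_x = x.var(axis=1)
    ok = var_x > 0
    if not ok.all():
        warnings.warn(
            f"{int((~ok).sum())} silent channel(s) excluded from PVAF",
            RuntimeWarning,
            stacklevel=2,
        )
    if not ok.any():
        raise ValueError("all channels silent")
    frac = ((x[ok] - y[ok]).var(axis=1) / var_x[ok]).mean()
    return float(100.0 - 100.0 * frac)


# ---------------------------------------------------------------------------
# Dipole fitting
# ---------------------------------------------------------------------------


def _centered_gain(G: np.ndarray) -> np.ndarray:
    return G - G.mean(axis=0, keepdims=True)


def _scan_grid(c: np.ndarray, G_all: np.ndarray):
    """Best moment and RV per node for a centred map, fully vectorized.

    G_all : (n_nodes, n_elec, 3) gains.  Returns (rv_percent, moments).
    """
    Gc = G_all - G_all.mean(axis=1, keepdims=True)
    cc = c - c.mean()
    GtG = np.einsum("nek,nel->nkl", Gc, Gc)
    Gtc = np.einsum("nek,e->nk", Gc, cc)
    # regularize truly degenerate nodes (zero gain) rather than fail
    tr = np.trace(GtG, axis1=1, axis2=2)
    GtG = GtG + (1e-12 * np.maximum(tr, 1e-300) / 3.0)[:, None, None] * np.eye(3)
    q = np.linalg.solve(GtG, Gtc[:, :, None])[:, :, 0]
    ss_tot = float(cc @ cc)
    ss_res = ss_tot - np.einsum("nk,nk->n", q, Gtc)
    rv = 100.0 * np.maximum(ss_res, 0.0) / ss_tot
    return rv, q


def _trilinear_gain(lfm: LeadFieldMatrix, pos: np.ndarray):
    """Interpolate the (n_elec, 3) gain at an off-node position.

    Uses the 8 enclosing lattice nodes; missing nodes (outside the
    brain) fall back to the cell's available nodes by weight
    renormalization.  Returns None outside the lattice hull.
    """
    g = lfm.grid
    rel = (pos - g.origin) / g.spacing
    base = np.floor(rel).astype(int)
    if (base < 0).any() or (base + 1 >= np.array(g.shape)).any():
        return None
    frac = rel - base
    total_w = 0.0
    gain = np.zeros(lfm.values.shape[0::2])
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                w = (
                    (frac[0] if dx else 1 - frac[0])
                    * (frac[1] if dy else 1 - frac[1])
                    * (frac[2] if dz else 1 - frac[2])
                )
                node = g.node_lookup[base[0] + dx, base[1] + dy, base[2] + dz]
                if node >= 0 and w > 0:
                    gain += w * lfm.values[:, node, :]
                    total_w += w
    if total_w <= 0.25:
        return None
    return gain / total_w


def fit_dipole(cmap: ComponentMap, lfm: LeadFieldMatrix, refine: bool = True):
    """Best single dipole explaining a (scalp-only) component map.

    Coarse scan over all source-grid nodes (the moment is linear and
    solved per node in closed form), then derivative-free refinement of
    the location with trilinear lead-field interpolation.  The objective
    is the residual variance; the moment is the least-squares moment of
    the final location, so a perfect shape match yields RV = 0.

    Returns
    -------
    dipole : Dipole
    rv : float (%)
    info : dict with ``node`` (best grid node), ``on_hull`` flag.
    """
    if np.allclose(cmap.values, cmap.values[0]):
        raise ValueError("component map is constant/all-zero: nothing to fit")
    if len(cmap.labels) < 8:
        raise ValueError("need at least 8 electrodes for a stable dipole fit")
    sub = lfm.subset(cmap.labels)
    c = cmap.values
    G_all = np.moveaxis(sub.values, 1, 0)  # (n_nodes, n_elec, 3)
    rv_nodes, q_nodes = _scan_grid(c, G_all)
    best = int(np.argmin(rv_nodes))
    pos = sub.grid.nodes[best].astype(float)
    cc = c - c.mean()

    def objective(p):
        gain = _trilinear_gain(sub, p)
        if gain is None:
            return 1e6
        Gc = _centered_gain(gain)
        q, *_ = np.linalg.lstsq(Gc, cc, rcond=None)
        resid = cc - Gc @ q
        return 100.0 * float(resid @ resid) / float(cc @ cc)

    rv = float(rv_nodes[best])
    if refine:
        res = optimize.minimize(
            objective,
            pos,
            method="Nelder-Mead",
            options={
                "xatol": 0.05,
                "fatol": 1e-8,
                "initial_simplex": pos + np.vstack([np.zeros(3), np.eye(3) * sub.grid.spacing * 0.5]),
            },
        )
        if res.fun <= rv:
            pos = res.x
            rv = float(res.fun)
    gain = _trilinear_gain(sub, pos)
    on_hull = gain is None
    if on_hull:
        gain = sub.values[:, best, :]
        pos = sub.grid.nodes[best].astype(float)
        rv = float(rv_nodes[best])
    Gc = _centered_gain(gain)
    q, *_ = np.linalg.lstsq(Gc, cc, rcond=None)
    return Dipole(pos, q), rv, {"node": best, "on_hull": on_hull}


def quantize_source(location, grid: SourceGrid):
    """Snap a location to the closest source-grid node (ties: lowest index).

    Returns ``(node_index, distance_mm)``.
    """
    if len(grid) == 0:
        raise ValueError("empty source grid")
    d = np.linalg.norm(grid.nodes - np.asarray(location, float), axis=1)
    node = int(np.argmin(d))
    return node, float(d[node])


def predicted_map(lfm: LeadFieldMatrix, node: int, moment) -> ModeledMap:
    """Forward-model component map of a quantized source."""
    return ModeledMap(
        values=lfm.values[:, node, :] @ np.asarray(moment, float),
        labels=list(lfm.labels),
        dipole=Dipole(lfm.grid.nodes[node], moment),
        node=node,
    )


# ---------------------------------------------------------------------------
# Component selection and reporting
# ---------------------------------------------------------------------------


def select_components(results, k: int = 12, brain=None, grid: SourceGrid | None = None):
    """The ``k`` best-modeled in-brain components (lowest RV first).

    A component is "in brain" when its fitted dipole lies strictly
    inside the ``brain`` surface (winding-number test) if one is given,
    else when its ``in_brain`` flag is set.  Ties in RV break toward the
    lower component index.  Returns a (possibly short) list.
    """
    from .mesh_core import points_inside

    eligible = []
    for r in results:
        if brain is not None:
            inside = bool(points_inside(r.dipole.position[None], brain)[0])
        else:
            inside = bool(r.in_brain)
        if inside:
            eligible.append(r)
    if not eligible:
        warnings.warn("no fitted dipoles inside the brain volume", RuntimeWarning,
                      stacklevel=2)
        return []
    eligible.sort(key=lambda r: (r.rv, r.component))
    del grid
    return eligible[:k]


def results_table(results) -> str:
    """Tab-separated summary mirroring per-component map annotations."""
    lines = [
        "component\tRV%\tPVAF%\tC_left\tC_scalp\tC_right\tx_mm\ty_mm\tz_mm\tquant_mm"
    ]
    for r in results:
        cs = [r.correlations.get(g) for g in GROUPS]
        cs = "\t".join("nan" if v is None else f"{v:.3f}" for v in cs)
        x, y, z = r.dipole.position
        lines.append(
            f"{r.component}\t{r.rv:.2f}\t{r.pvaf:.2f}\t{cs}"
            f"\t{x:.1f}\t{y:.1f}\t{z:.1f}\t{r.quantization_distance:.2f}"
        )
    return "\n".join(lines) + "\n"
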