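"""Lead-field sensitivity distributions for electrode configurations.

By the reciprocity theorem, the dipole orientation at a source location
that maximizes the potential difference between two electrodes is the
direction of the current density that injecting current through those
electrodes would produce there.  With a lead field in hand this is
simply the difference of the two electrodes' gain rows: its norm is the
maximal-orientation sensitivity and its direction the current-density
orientation.  These maps show which brain regions an in-ear or
between-ear montage can see, and how quickly sensitivity falls off with
distance for each configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bem_forward import LeadFieldMatrix, SourceGrid

__all__ = [
    "SensitivityMap",
    "pair_sensitivity",
    "single_sensitivity",
    "to_db",
    "compare_configurations",
    "export_table",
]


@dataclass
class SensitivityMap:
    """Per-source sensitivity of one electrode configuration.

    ``vectors`` (n_sources, 3) is the gain difference in V per A*m;
    ``magnitude`` its norm (the best-orientation sensitivity) and
    ``orientation`` the unit current-density direction (NaN where the
    magnitude vanishes).  ``db`` is filled by :func:`to_db`.
    """

    vectors: np.ndarray
    grid: SourceGrid
    config: str
    db: np.ndarray | None = None
    db_reference: float | None = None
    magnitude: np.ndarray = field(init=False)
    orientation: np.ndarray = field(init=False)

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, float)
        self.magnitude = np.linalg.norm(self.vectors, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            self.orientation = self.vectors / self.magnitude[:, None]

    @property
    def zero_nodes(self) -> np.ndarray:
        return self.magnitude == 0


def pair_sensitivity(lfm: LeadFieldMatrix, elec_a: str, elec_b: str) -> SensitivityMap:
    """Sensitivity of the bipolar configuration ``elec_a - elec_b``.

    Invariant to the lead field's reference: the reference row cancels
    in the difference.
    """
    ia, ib = lfm.index(elec_a), lfm.index(elec_b)
    vec = lfm.values[ia] - lfm.values[ib]
    return SensitivityMap(vec, lfm.grid, config=f"{elec_a}-{elec_b}")


def single_sensitivity(lfm: LeadFieldMatrix, elec: str) -> SensitivityMap:
    """Sensitivity of one electrode against an infinite reference.

    Requires the raw (unreferenced) lead field: once a reference has
    been subtracted the infinite-reference potential is unrecoverable.
    """
    if lfm.reference != "raw":
        raise ValueError(
            "single-electrode sensitivity needs the raw (infinite-reference) "
            f"lead field, got reference={lfm.reference!r}"
        )
    return SensitivityMap(
        lfm.values[lfm.index(elec)].copy(), lfm.grid, config=f"{elec}-infinity"
    )


def to_db(smap: SensitivityMap, reference="max") -> SensitivityMap:
    """Express magnitudes in dB re a reference (``20 log10 |s|/ref``).

    ``reference`` is ``"max"`` (the map's maximum, the convention used
    for contour plots) or a positive number.  Zero-magnitude nodes map
    to ``-inf``.
    """
    ref = float(smap.magnitude.max()) if reference == "max" else float(reference)
    if ref <= 0:
        raise ValueError("dB reference must be positive")
    with np.errstate(divide="ignore"):
        db = 20.0 * np.log10(smap.magnitude / ref)
    out = SensitivityMap(smap.vectors.copy(), smap.grid, smap.config)
    out.db = db
    out.db_reference = ref
    return out


def compare_configurations(
    lfm: LeadFieldMatrix, pair_a, pair_b, grid: SourceGrid | None = None
) -> dict:
    """Node-wise dB comparison of two bipolar configurations.

    Returns the per-node dB difference ``20 log10(|s_A|/|s_B|)``, its
    median and quartiles, the count of excluded zero-magnitude nodes,
    and each configuration's sensitivity decay slope: the least-squares
    slope of dB versus log10 distance from the configuration's electrode
    centroid (dB per distance decade; more negative = faster decay).
    """
    grid = grid or lfm.grid
    sa = pair_sensitivity(lfm, *pair_a)
    sb = pair_sensitivity(lfm, *pair_b)
    ok = (sa.magnitude > 0) & (sb.magnitude > 0)
    diff = 20.0 * np.log10(sa.magnitude[ok] / sb.magnitude[ok])

    def decay_slope(smap, pair):
        pos = np.array([lfm.positions[lfm.index(e)] for e in pair])
        centroid = pos.mean(axis=0)
        dist = np.linalg.norm(grid.nodes - centroid, axis=1)
        good = (smap.magnitude > 0) & (dist > 1.0)
        x = np.log10(dist[good])
        y = 20.0 * np.log10(smap.magnitude[good] / smap.magnitude[good].max())
        slope = np.polyfit(x, y, 1)[0]
        return float(slope)

    q1, med, q3 = np.percentile(diff, [25, 50, 75])
    return {
        "db_difference": diff,
        "median_db": float(med),
        "quartiles_db": (float(q1), float(q3)),
        "excluded_nodes": int((~ok).sum()),
        "decay_slope_a": decay_slope(sa, pair_a),
        "decay_slope_b": decay_slope(sb, pair_b),
    }


def export_table(smap: SensitivityMap) -> str:
    """Tab-separated node table: x, y, z, |s|, orientation, dB."""
    lines = ["x_mm\ty_mm\tz_mm\ts_V_per_Am\tsx\tsy\tsz\tdB"]
    db = smap.db if smap.db is not None else np.full(len(smap.magnitude), np.nan)
    for p, m, o, d in zip(smap.grid.nodes, smap.magnitude, smap.orientation, db):
        lines.append(
            f"{p[0]:.1f}\t{p[1]:.1f}\t{p[2]:.1f}\t{m:.6e}"
            f"\t{o[0]:.4f}\t{o[1]:.4f}\t{o[2]:.4f}\t{d:.2f}"
        )
    return "\n".join(lines) + "\n"
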