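"""Differential multiple-regression screen for group-specific 4-probe relations.

Seed pairs are probe pairs with |rho| > 0.8 in one group whose correlation
changes by more than 0.4 between groups, split into four classes by sign and
direction of the change:

* ``A``: rho_contrast >  0.8 and rho_reference <  0.4
* ``B``: rho_reference >  0.8 and rho_contrast <  0.4
* ``C``: rho_contrast < -0.8 and rho_reference > -0.4
* ``D``: rho_reference < -0.8 and rho_contrast > -0.4

For sampled seed pairs, the first probe is regressed (OLS with intercept) on
the second plus a randomly chosen third probe and, consecutively, every
remaining probe as the fourth.  A quadruplet is *selected* when all four
criteria hold: the coefficient of determination transitions between groups
from [0.8, 1) to [0, 0.4]; at least one involved probe does not change its
mean expression; the four probes do not all sit in one connected component of
the strong group's |rho| > 0.8 network; and the six pairwise correlations do
not all change homogeneously (same sign, magnitude > 0.4).  Counts are
extrapolated to the full pair universe by the sampling fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .dataset import ExpressionDataset
from .networks import CorrelationMatrix

CLASS_ORDER = ("A", "B", "C", "D")


# --------------------------------------------------------------------------
# seed-pair classification
# --------------------------------------------------------------------------


def classify_seed_pairs(
    corr_ref: CorrelationMatrix,
    corr_con: CorrelationMatrix,
    high: float = 0.8,
    low: float = 0.4,
    delta: float = 0.4,
) -> pd.DataFrame:
    """Assign every qualifying probe pair to exactly one class A-D.

    ``corr_ref`` is the reference group (rho_N), ``corr_con`` the contrast
    group (rho_P).  Besides the per-class threshold inequalities, the global
    filter |rho| > ``high`` in one group AND |change| > ``delta`` is applied
    conjunctively.  The rare pair satisfying two class definitions at once
    (an extreme sign flip) is assigned the first match in the order A, B, C,
    D.  Non-qualifying pairs are omitted.
    """
    if not corr_ref.probe_ids.equals(corr_con.probe_ids):
        raise ValueError("correlation matrices must share one probe set")
    p = corr_ref.n_probes
    iu = np.triu_indices(p, k=1)
    rn = corr_ref.matrix[iu]
    rp = corr_con.matrix[iu]
    qualifies = ((np.abs(rp) > high) | (np.abs(rn) > high)) & (np.abs(rp - rn) > delta)
    masks = {
        "A": (rp > high) & (rn < low),
        "B": (rn > high) & (rp < low),
        "C": (rp < -high) & (rn > -low),
        "D": (rn < -high) & (rp > -low),
    }
    label = np.full(rn.shape, "none", dtype=object)
    for cls in reversed(CLASS_ORDER):  # apply in order so A wins overlaps
        label[masks[cls]] = cls
    keep = qualifies & (label != "none")
    ids = np.asarray(corr_ref.probe_ids)
    return pd.DataFrame(
        {
            "probe1": ids[iu[0][keep]],
            "probe2": ids[iu[1][keep]],
            "r_reference": rn[keep],
            "r_contrast": rp[keep],
            "class": label[keep],
        }
    )


# --------------------------------------------------------------------------
# OLS quadruplet fits
# --------------------------------------------------------------------------


@dataclass
class QuadrupletFit:
    group: str
    regressand: str
    regressors: tuple[str, str, str]
    r_squared: float
    coefficients: np.ndarray  # intercept first
    degenerate: bool = False


def fit_quadruplet(
    ds: ExpressionDataset, group: str, regressand: str, regressors
) -> QuadrupletFit:
    """OLS with intercept of one probe on three others within one group.

    A rank-deficient design (duplicated/collinear regressors) is flagged
    degenerate with NaN R^2.
    """
    regressors = tuple(regressors)
    probes = (regressand, *regressors)
    if len(set(probes)) != 4:
        raise ValueError("the four probes must be distinct")
    m = ds.group_matrix(group)
    if m.shape[1] <= 5:
        raise ValueError("group sample size must exceed 5")
    y = m.loc[regressand].to_numpy()
    x = np.column_stack([np.ones(y.size)] + [m.loc[r].to_numpy() for r in regressors])
    if np.linalg.matrix_rank(x) < 4:
        return QuadrupletFit(group, regressand, regressors, np.nan, np.full(4, np.nan), True)
    beta, _, _, _ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    sstot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / sstot if sstot > 0 else np.nan
    return QuadrupletFit(group, regressand, regressors, r2, beta, False)


def _sweep_r2(y: np.ndarray, x2: np.ndarray, x3: np.ndarray, cands: np.ndarray) -> np.ndarray:
    """R^2 of y ~ 1 + x2 + x3 + c for every candidate row c, vectorized.

    Collinear candidates (no residual variation after projecting out the
    base design) get NaN.
    """
    n = y.size
    base = np.column_stack([np.ones(n), x2, x3])
    q, _ = np.linalg.qr(base)
    ry = y - q @ (q.T @ y)
    sstot = float(((y - y.mean()) ** 2).sum())
    if sstot == 0:
        return np.full(cands.shape[0], np.nan)
    rc = cands - (cands @ q) @ q.T
    norms = (rc**2).sum(axis=1)
    rss_base = float((ry**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        gain = (rc @ ry) ** 2 / norms
    rss = rss_base - gain
    r2 = 1.0 - rss / sstot
    r2[norms <= 1e-10 * n] = np.nan
    return np.clip(r2, 0.0, 1.0, out=r2)


# --------------------------------------------------------------------------
# selection criteria
# --------------------------------------------------------------------------


def abs_high_corr_graph(corr: CorrelationMatrix, threshold: float = 0.8) -> nx.Graph:
    """|rho| > threshold network of one group (both signs pooled)."""
    iu = np.triu_indices(corr.n_probes, k=1)
    vals = corr.matrix[iu]
    mask = np.abs(vals) > threshold
    ids = np.asarray(corr.probe_ids)
    g = nx.Graph(group=corr.group, threshold=threshold)
    for i, j, w in zip(iu[0][mask], iu[1][mask], vals[mask]):
        g.add_edge(ids[i], ids[j], weight=float(w))
    return g


def default_homogeneous_change(delta_rhos: np.ndarray, threshold: float = 0.4) -> bool:
    """All six pairwise correlation changes share one sign and exceed the
    threshold in magnitude."""
    d = np.asarray(delta_rhos, float)
    return bool((np.all(d > threshold)) or (np.all(d < -threshold)))


@dataclass
class SelectionThresholds:
    r2_high: float = 0.8
    r2_low: float = 0.4
    delta_rho: float = 0.4


def _pair_deltas(
    probes, corr_ref: CorrelationMatrix, corr_con: CorrelationMatrix
) -> np.ndarray:
    pos = {pid: k for k, pid in enumerate(corr_ref.probe_ids)}
    idx = [pos[p] for p in probes]
    deltas = []
    for a in range(4):
        for b in range(a + 1, 4):
            deltas.append(
                corr_con.matrix[idx[a], idx[b]] - corr_ref.matrix[idx[a], idx[b]]
            )
    return np.array(deltas)


def evaluate_quadruplet(
    ds: ExpressionDataset,
    regressand: str,
    regressors,
    me_table: pd.DataFrame,
    corr_ref: CorrelationMatrix,
    corr_con: CorrelationMatrix,
    high_graphs: dict[str, nx.Graph] | None = None,
    thresholds: SelectionThresholds = SelectionThresholds(),
    homogeneous_change=default_homogeneous_change,
) -> dict:
    """Fit one quadruplet in both groups and evaluate the four selection
    criteria.  Returns a record with per-group R^2, the flags, and the
    final ``selected`` call."""
    regressors = tuple(regressors)
    fit1 = fit_quadruplet(ds, ds.group1, regressand, regressors)
    fit2 = fit_quadruplet(ds, ds.group2, regressand, regressors)
    if high_graphs is None:
        high_graphs = {
            ds.group1: abs_high_corr_graph(corr_ref),
            ds.group2: abs_high_corr_graph(corr_con),
        }
    probes = (regressand, *regressors)
    record = {
        "regressand": regressand,
        "regressor1": regressors[0],
        "regressor2": regressors[1],
        "regressor3": regressors[2],
        "r2_group1": fit1.r_squared,
        "r2_group2": fit2.r_squared,
        "degenerate": fit1.degenerate or fit2.degenerate,
    }
    if record["degenerate"]:
        record.update(
            r2_transition=False, me_stable_count=0, same_network=False,
            homogeneous_change=False, selected=False, strong_group=None,
        )
        return record

    th = thresholds
    hi1 = th.r2_high <= fit1.r_squared < 1.0
    hi2 = th.r2_high <= fit2.r_squared < 1.0
    lo1 = 0.0 <= fit1.r_squared <= th.r2_low
    lo2 = 0.0 <= fit2.r_squared <= th.r2_low
    r2_transition = (hi1 and lo2) or (hi2 and lo1)
    strong_group = ds.group1 if hi1 else ds.group2 if hi2 else None

    stable = (~me_table.loc[list(probes), "me_significant"]).sum()

    same_network = False
    if strong_group is not None:
        g = high_graphs[strong_group]
        if all(p in g for p in probes):
            comp = nx.node_connected_component(g, regressand)
            same_network = all(p in comp for p in probes)

    homog = homogeneous_change(_pair_deltas(probes, corr_ref, corr_con), th.delta_rho)

    record.update(
        r2_transition=r2_transition,
        me_stable_count=int(stable),
        same_network=same_network,
        homogeneous_change=homog,
        strong_group=strong_group,
        selected=bool(
            r2_transition and stable >= 1 and not same_network and not homog
        ),
    )
    return record


# --------------------------------------------------------------------------
# the screen
# --------------------------------------------------------------------------


@dataclass
class ScreenConfig:
    """Sampling plan of the screen: how many seed pairs per class and how
    many random third probes per pair; the fourth regressor always sweeps
    every remaining probe."""

    pairs_per_class: dict[str, int] = field(
        default_factory=lambda: {"A": 3, "B": 4, "C": 4, "D": 4}
    )
    third_probe_samples: int = 20
    seed: int = 0
    thresholds: SelectionThresholds = field(default_factory=SelectionThresholds)

    def __post_init__(self) -> None:
        if self.third_probe_samples < 1:
            raise ValueError("third_probe_samples must be >= 1")
        if any(v < 1 for v in self.pairs_per_class.values()):
            raise ValueError("pairs_per_class entries must be >= 1")


def screen_relations(
    ds: ExpressionDataset,
    seed_pairs: pd.DataFrame,
    me_table: pd.DataFrame,
    corr_ref: CorrelationMatrix,
    corr_con: CorrelationMatrix,
    config: ScreenConfig | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Run the sampled screen over the classified seed pairs.

    For each class, up to ``pairs_per_class`` seed pairs are drawn; for each,
    ``third_probe_samples`` random third probes are drawn and the fourth
    regressor sweeps all remaining probes.  Quadruplets passing the fast R^2
    transition pre-filter are then evaluated against all four selection
    criteria.  Returns the selected-fit table and per-class counts (empty
    classes report zero).
    """
    config = config or ScreenConfig()
    rng = np.random.default_rng(config.seed)
    th = config.thresholds
    all_probes = np.asarray(ds.probe_ids)
    probe_pos = {pid: k for k, pid in enumerate(all_probes)}
    m1v = ds.group_values(ds.group1)
    m2v = ds.group_values(ds.group2)

    # component index of every probe in each group's |rho| > high network
    # (-1 when the probe is absent, i.e. trivially "not in the network")
    def component_ids(graph: nx.Graph) -> np.ndarray:
        comp = np.full(all_probes.size, -1, dtype=int)
        for k, members in enumerate(nx.connected_components(graph)):
            for node in members:
                comp[probe_pos[node]] = k
        return comp

    comp_by_group = {
        ds.group1: component_ids(abs_high_corr_graph(corr_ref, th.r2_high)),
        ds.group2: component_ids(abs_high_corr_graph(corr_con, th.r2_high)),
    }
    delta_m = corr_con.matrix - corr_ref.matrix
    unstable = me_table["me_significant"].reindex(ds.probe_ids).fillna(False).to_numpy()

    selected_records: list[pd.DataFrame] = []
    examined = {c: 0 for c in CLASS_ORDER}
    candidates_checked = {c: 0 for c in CLASS_ORDER}

    for cls in CLASS_ORDER:
        cls_pairs = seed_pairs[seed_pairs["class"] == cls]
        if cls_pairs.empty:
            continue
        take = min(config.pairs_per_class.get(cls, 0), len(cls_pairs))
        rows = cls_pairs.iloc[rng.choice(len(cls_pairs), size=take, replace=False)]
        for _, pair in rows.iterrows():
            p1, p2 = pair["probe1"], pair["probe2"]
            others = all_probes[~np.isin(all_probes, [p1, p2])]
            n_third = min(config.third_probe_samples, len(others) - 1)
            thirds = rng.choice(others, size=n_third, replace=False)
            for p3 in thirds:
                cands_ids = others[others != p3]
                cand_idx = np.array([probe_pos[c] for c in cands_ids])
                i1, i2, i3 = probe_pos[p1], probe_pos[p2], probe_pos[p3]
                r2_1 = _sweep_r2(m1v[i1], m1v[i2], m1v[i3], m1v[cand_idx])
                r2_2 = _sweep_r2(m2v[i1], m2v[i2], m2v[i3], m2v[cand_idx])
                examined[cls] += len(cands_ids)
                hi1 = (r2_1 >= th.r2_high) & (r2_1 < 1.0)
                hi2 = (r2_2 >= th.r2_high) & (r2_2 < 1.0)
                transition = (hi1 & (r2_2 <= th.r2_low)) | (hi2 & (r2_1 <= th.r2_low))
                candidates_checked[cls] += int(transition.sum())

                # remaining criteria, vectorized over the fourth regressor
                stable_count = (
                    (~unstable[[i1, i2, i3]]).sum() + (~unstable[cand_idx]).astype(int)
                )
                base = np.array([i1, i2, i3])
                comp_strong = np.where(
                    hi1, comp_by_group[ds.group1][cand_idx],
                    comp_by_group[ds.group2][cand_idx],
                )
                base_comp_g1 = comp_by_group[ds.group1][base]
                base_comp_g2 = comp_by_group[ds.group2][base]
                base_same_g1 = (base_comp_g1 >= 0).all() and len(set(base_comp_g1)) == 1
                base_same_g2 = (base_comp_g2 >= 0).all() and len(set(base_comp_g2)) == 1
                same_network = np.where(
                    hi1,
                    base_same_g1 & (comp_strong >= 0) & (comp_strong == base_comp_g1[0]),
                    base_same_g2 & (comp_strong >= 0) & (comp_strong == base_comp_g2[0]),
                )
                fixed = np.array([delta_m[i1, i2], delta_m[i1, i3], delta_m[i2, i3]])
                dc = delta_m[np.ix_(base, cand_idx)]  # deltas probe-vs-candidate
                all_six = np.vstack([np.tile(fixed[:, None], len(cand_idx)), dc])
                homogeneous = ((all_six > th.delta_rho).all(axis=0)) | (
                    (all_six < -th.delta_rho).all(axis=0)
                )

                keep = transition & (stable_count >= 1) & ~same_network & ~homogeneous
                if keep.any():
                    selected_records.append(
                        pd.DataFrame(
                            {
                                "class": cls,
                                "regressand": p1,
                                "regressor1": p2,
                                "regressor2": p3,
                                "regressor3": cands_ids[keep],
                                "r2_group1": r2_1[keep],
                                "r2_group2": r2_2[keep],
                                "me_stable_count": stable_count[keep],
                                "strong_group": np.where(
                                    hi1[keep], ds.group1, ds.group2
                                ),
                            }
                        )
                    )

    table = (
        pd.concat(selected_records, ignore_index=True)
        if selected_records
        else pd.DataFrame(
            columns=[
                "class", "regressand", "regressor1", "regressor2", "regressor3",
                "r2_group1", "r2_group2", "me_stable_count", "strong_group",
            ]
        )
    )
    counts = {
        "examined_per_class": examined,
        "examined_total": sum(examined.values()),
        "candidates_per_class": candidates_checked,
        "selected_per_class": {
            c: int((table["class"] == c).sum()) if len(table) else 0
            for c in CLASS_ORDER
        },
        "selected_total": int(len(table)),
    }
    return table, counts


def extrapolate_relation_counts(found: int, examined: int, total: int) -> dict:
    """Scale a sampled count to the full universe: found * total / examined."""
    if examined <= 0:
        raise ValueError("examined must be positive")
    if found > examined:
        raise ValueError("found cannot exceed examined")
    return {
        "found": found,
        "examined": examined,
        "total": total,
        "sampling_fraction": examined / total if total else np.nan,
        "estimate": found * total / examined,
    }
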