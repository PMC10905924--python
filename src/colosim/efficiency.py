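"""Data envelopment analysis of screening strategies (colonoscopies vs LYG).

Each strategy is a decision-making unit with one input (lifetime
colonoscopies per 1000) and one output (life-years gained per 1000).
Input-oriented DEA under variable returns to scale (VRS) scores each unit
by the linear program

    min θ  s.t.  Σ λ_j x_j ≤ θ x_0,  Σ λ_j y_j ≥ y_0,  Σ λ_j = 1,  λ ≥ 0.

A score of 1 marks the efficient frontier; with a single input and a
single output the efficient *set* is the same in either orientation.
Strategies below the frontier whose LYG exceeds 98% of the frontier value
at their colonoscopy count are *near-efficient*, and summaries group both
under "efficient".  Two incremental ratios accompany the classification:
the efficiency ratio ΔCOL/ΔLYG against the category default (the
least-colonoscopy efficient strategy) and additional colonoscopies per
LYG against no screening.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linprog

SCORE_TOL = 1e-9


class EfficiencyError(ValueError):
    pass


@dataclass(frozen=True)
class StrategyPoint:
    label: str
    input: float    # colonoscopies per 1000
    output: float   # LYG per 1000
    category: str = ""


def dea_vrs(points) -> np.ndarray:
    """Input-oriented VRS efficiency score for each point, in (0, 1]."""
    x = np.asarray([p.input for p in points], dtype=float)
    y = np.asarray([p.output for p in points], dtype=float)
    if len(x) == 0:
        raise EfficiencyError("no points")
    if np.any(x < 0) or np.any(~np.isfinite(x)) or np.any(~np.isfinite(y)):
        raise EfficiencyError("inputs must be non-negative and finite")
    n = len(x)
    scores = np.empty(n)
    for i in range(n):
        # variables: [theta, lambda_1..n]
        c = np.zeros(n + 1)
        c[0] = 1.0
        a_ub = np.zeros((2, n + 1))
        a_ub[0, 0] = -x[i]          # sum(l*x) - theta*x0 <= 0
        a_ub[0, 1:] = x
        a_ub[1, 1:] = -y            # -sum(l*y) <= -y0
        b_ub = np.array([0.0, -y[i]])
        a_eq = np.zeros((1, n + 1))
        a_eq[0, 1:] = 1.0
        res = linprog(c, A_ub=a_ub, b_ub=b_ub, A_eq=a_eq, b_eq=[1.0],
                      bounds=[(None, None)] + [(0.0, None)] * n,
                      method="highs")
        if not res.success:
            raise EfficiencyError(f"DEA LP failed for point {points[i].label}: "
                                  f"{res.message}")
        scores[i] = res.fun
    return np.minimum(scores, 1.0)


def _frontier_vertices(points, scores):
    """Efficient-frontier polyline, sorted by input, deduplicated."""
    eff = sorted(((p.input, p.output) for p, s in zip(points, scores)
                  if s >= 1.0 - SCORE_TOL))
    verts = []
    for x, y in eff:
        if not verts or x > verts[-1][0] or y > verts[-1][1]:
            if verts and x == verts[-1][0]:
                verts[-1] = (x, y)
            else:
                verts.append((x, y))
    return verts


def frontier_lyg_at(verts, x: float) -> float:
    """Frontier LYG at colonoscopy count x (linear between vertices, flat
    beyond the largest frontier input under VRS)."""
    xs = np.array([v[0] for v in verts])
    ys = np.array([v[1] for v in verts])
    return float(np.interp(x, xs, ys))


@dataclass
class FrontierResult:
    table: pd.DataFrame            # label, input, output, score, class, ...
    frontier: list                 # polyline vertices [(input, output), ...]

    @property
    def efficient_labels(self):
        """Efficient plus near-efficient (both 'efficient' in summaries)."""
        sel = self.table["class"].isin(["efficient", "near_efficient"])
        return list(self.table.loc[sel, "label"])


def classify(points, scores=None) -> FrontierResult:
    """DEA classification: efficient / near-efficient / inefficient."""
    points = list(points)
    if scores is None:
        scores = dea_vrs(points)
    verts = _frontier_vertices(points, scores)
    rows = []
    for p, s in zip(points, scores):
        if s >= 1.0 - SCORE_TOL:
            cls = "efficient"
        else:
            f = frontier_lyg_at(verts, p.input)
            cls = "near_efficient" if (f > 0 and p.output > 0.98 * f) \
                else "inefficient"
        rows.append({"label": p.label, "category": p.category,
                     "input": p.input, "output": p.output,
                     "score": float(s), "class": cls})
    return FrontierResult(table=pd.DataFrame(rows), frontier=verts)


def efficiency_ratios(frontier_points: pd.DataFrame) -> pd.DataFrame:
    """ΔCOL/ΔLYG against the category default strategy.

    ``frontier_points``: the efficient + near-efficient rows of one
    category with columns label, input, output.  The default is the
    least-input point.  A point with the default's LYG yields an infinite
    (or degenerate 0/0) ratio, flagged with a warning.
    """
    if len(frontier_points) < 1:
        raise EfficiencyError("need at least one classified point")
    pts = frontier_points.sort_values(["input", "output"]).reset_index(drop=True)
    x0, y0 = float(pts.loc[0, "input"]), float(pts.loc[0, "output"])
    ratios, flags = [], []
    for _, row in pts.iterrows():
        dx, dy = row["input"] - x0, row["output"] - y0
        if dx == 0 and dy == 0:
            ratios.append(np.nan)
            flags.append("Default")
        elif dy == 0:
            warnings.warn(f"{row['label']}: zero incremental LYG; "
                          "efficiency ratio is infinite")
            ratios.append(np.inf)
            flags.append("degenerate")
        else:
            ratios.append(dx / dy)
            flags.append("")
    out = pts.copy()
    out["efficiency_ratio"] = ratios
    out["note"] = flags
    return out


def additional_cols_per_lyg(point, no_screen_cols: float) -> float:
    """(COL − COL_no-screening) / LYG for one strategy point."""
    if point.output <= 0:
        warnings.warn(f"{point.label}: non-positive LYG; ratio undefined")
        return np.inf
    return (point.input - no_screen_cols) / point.output


def plot_frontier(classified: pd.DataFrame, path=None):
    """Scatter of strategies with the efficient frontier per category."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cats = sorted(classified["category"].unique())
    fig, axes = plt.subplots(1, len(cats), figsize=(4 * len(cats), 3.4),
                             squeeze=False)
    for ax, cat in zip(axes[0], cats):
        sub = classified[classified["category"] == cat]
        eff = sub[sub["class"] == "efficient"].sort_values("input")
        near = sub[sub["class"] == "near_efficient"]
        other = sub[sub["class"] == "inefficient"]
        ax.plot(eff["input"], eff["output"], "k-o", ms=4, label="frontier")
        ax.plot(near["input"], near["output"], "^", color="tab:orange",
                ms=5, label="near-efficient")
        ax.plot(other["input"], other["output"], ".", color="0.6",
                label="inefficient")
        ax.set_xlabel("colonoscopies per 1000")
        ax.set_ylabel("LYG per 1000")
        ax.set_title(cat or "all")
        ax.legend(fontsize=7)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def points_from_outcomes(df: pd.DataFrame, category_from_label=True):
    """Build StrategyPoints from an outcomes table (run_grid output)."""
    pts = []
    for _, row in df.iterrows():
        cat = row["strategy"].split(":")[0] if category_from_label else ""
        pts.append(StrategyPoint(label=row["strategy"],
                                 input=float(row["colonoscopies"]),
                                 output=float(row["lyg"]), category=cat))
    return pts


def analyze_grid(outcomes: pd.DataFrame, per_category: bool = True) -> pd.DataFrame:
    """Classify a full outcomes grid, per test category by default."""
    pts = points_from_outcomes(outcomes)
    frames = []
    if per_category:
        cats = sorted({p.category for p in pts})
        groups = [[p for p in pts if p.category == c] for c in cats]
    else:
        groups = [pts]
    for group in groups:
        res = classify(group)
        tab = res.table
        eff = tab[tab["class"].isin(["efficient", "near_efficient"])]
        if len(eff):
            rated = efficiency_ratios(eff[["label", "input", "output"]])
            tab = tab.merge(rated[["label", "efficiency_ratio", "note"]],
                            on="label", how="left")
        frames.append(tab)
    return pd.concat(frames, ignore_index=True)
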