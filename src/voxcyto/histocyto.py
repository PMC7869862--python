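"""Flow-style gating, frequency quantification, positional export and
group statistics on wide object tables.

Gates are conjunctions of per-column conditions, organised into a tree;
frequencies are reported relative to the explicit parent gate (flow
convention), not the total object count.  The Mann–Whitney U test uses an
exact null distribution (dynamic programming over rank arrangements) for
small tie-free samples and a tie-corrected normal approximation
otherwise; Welch's t uses the Welch–Satterthwaite degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GateCondition",
    "Gate",
    "apply_gate",
    "population_frequencies",
    "positional_export",
    "plot_positions",
    "compare_volumes_mwu",
    "compare_means_welch",
    "EXACT_MWU_MAX_N",
]

#: largest combined sample size for the exact (tie-free) MWU path
EXACT_MWU_MAX_N = 12

_OPS = {
    "==": lambda col, v: col == v,
    "<": lambda col, v: col < v,
    "<=": lambda col, v: col <= v,
    ">": lambda col, v: col > v,
    ">=": lambda col, v: col >= v,
    "in": lambda col, v: (col >= v[0]) & (col <= v[1]),
}


@dataclass
class GateCondition:
    """One condition: ``column <op> value``; op ``"in"`` takes a closed
    ``(lo, hi)`` interval."""

    column: str
    op: str
    value: object

    def __post_init__(self) -> None:
        if self.op not in _OPS:
            raise ValueError(f"unknown gate operator {self.op!r}; have {sorted(_OPS)}")

    def mask(self, table: pd.DataFrame) -> np.ndarray:
        if self.column not in table.columns:
            raise KeyError(f"unknown column {self.column!r} in gate condition")
        return np.asarray(_OPS[self.op](table[self.column], self.value))

    def to_dict(self) -> dict:
        return {"column": self.column, "op": self.op, "value": self.value}


@dataclass
class Gate:
    """Named conjunction of conditions with an optional parent gate name
    (``None`` = root, i.e. all objects)."""

    name: str
    conditions: list[GateCondition] = field(default_factory=list)
    parent: str | None = None

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "parent": self.parent,
            "conditions": [c.to_dict() for c in self.conditions],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Gate":
        return cls(
            name=d["name"],
            parent=d.get("parent"),
            conditions=[GateCondition(**c) for c in d.get("conditions", [])],
        )


def apply_gate(table: pd.DataFrame, gate: Gate) -> pd.DataFrame:
    """Rows satisfying all of the gate's conditions, in original order."""
    mask = np.ones(len(table), dtype=bool)
    for cond in gate.conditions:
        mask &= cond.mask(table)
    return table.loc[mask]


def _resolve_tree(gates: Sequence[Gate]) -> list[Gate]:
    """Topologically order gates; raise on cycles / unknown parents."""
    by_name = {g.name: g for g in gates}
    if len(by_name) != len(gates):
        raise ValueError("gate names must be unique")
    order: list[Gate] = []
    state: dict[str, int] = {}  # 0 visiting, 1 done

    def visit(g: Gate) -> None:
        if state.get(g.name) == 1:
            return
        if state.get(g.name) == 0:
            raise ValueError(f"cyclic gating tree at {g.name!r}")
        state[g.name] = 0
        if g.parent is not None:
            if g.parent not in by_name:
                raise ValueError(f"gate {g.name!r} references unknown parent {g.parent!r}")
            visit(by_name[g.parent])
        state[g.name] = 1
        order.append(g)

    for g in gates:
        visit(g)
    return order


def population_frequencies(table: pd.DataFrame, gates: Sequence[Gate]) -> pd.DataFrame:
    """Counts and parent-relative frequencies for a gating tree.

    Gate membership is cumulative down the tree (a gate selects within its
    parent's rows).  ``frequency_pct`` is 100 * count / parent count, NaN
    (undefined marker) when the parent is empty.
    """
    order = _resolve_tree(gates)
    members: dict[str | None, pd.DataFrame] = {None: table}
    rows = []
    for g in order:
        parent_rows = members[g.parent]
        sub = apply_gate(parent_rows, g)
        members[g.name] = sub
        parent_count = len(parent_rows)
        rows.append(
            {
                "gate": g.name,
                "parent": g.parent if g.parent is not None else "<all>",
                "count": len(sub),
                "parent_count": parent_count,
                "frequency_pct": (100.0 * len(sub) / parent_count)
                if parent_count else np.nan,
            }
        )
    return pd.DataFrame(rows)


def positional_export(table: pd.DataFrame, gates: Sequence[Gate]) -> pd.DataFrame:
    """Per-object (x_um, y_um, gate) rows for positional scatter plots.

    One row per object per matched gate, so an object matching two sibling
    gates appears twice.  Gates are evaluated against the full table (not
    cumulatively) here; pass leaf gates with explicit distance conditions
    for tree-restricted exports.
    """
    for col in ("x_um", "y_um"):
        if col not in table.columns:
            raise KeyError(f"positional export needs centroid column {col!r}")
    frames = []
    for g in gates:
        sub = apply_gate(table, g)
        out = sub[["x_um", "y_um"]].copy()
        out["gate"] = g.name
        if "object_id" in sub.columns:
            out.insert(0, "object_id", sub["object_id"])
        else:
            out.insert(0, "object_id", sub.index)
        frames.append(out)
    if not frames:
        return pd.DataFrame(columns=["object_id", "x_um", "y_um", "gate"])
    return pd.concat(frames, ignore_index=True)


def plot_positions(positions: pd.DataFrame, path=None, ax=None):
    """Scatter the positional export, one colour per gate (helper; the
    table itself is the contract)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    for gate, sub in positions.groupby("gate"):
        ax.scatter(sub["x_um"], sub["y_um"], s=8, label=str(gate), alpha=0.7)
    ax.set_xlabel("x (µm)")
    ax.set_ylabel("y (µm)")
    ax.set_aspect("equal")
    ax.legend(fontsize=8)
    if path is not None:
        ax.figure.savefig(path, dpi=150)
        plt.close(ax.figure)
    return ax


# ---------------------------------------------------------------------------
# group statistics
# ---------------------------------------------------------------------------


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U of group A: pairs with a > b, ties counted half."""
    diff = a[:, None] - b[None, :]
    return float((diff > 0).sum() + 0.5 * (diff == 0).sum())


def _exact_u_counts(n1: int, n2: int) -> np.ndarray:
    """Number of rank arrangements per U value under the tie-free null.

    DP over the recurrence c(i, j, u) = c(i-1, j, u-j) + c(i, j-1, u):
    the largest remaining observation comes from group A (adding j to U)
    or from group B (adding 0).
    """
    c = np.zeros((n1 + 1, n2 + 1, n1 * n2 + 1), dtype=float)
    c[0, :, 0] = 1.0
    c[:, 0, 0] = 1.0
    for i in range(1, n1 + 1):
        for j in range(1, n2 + 1):
            c[i, j] = c[i, j - 1]
            width = (i - 1) * j + 1  # support of c[i-1, j]
            c[i, j, j : j + width] += c[i - 1, j, :width]
    return c[n1, n2]


def compare_volumes_mwu(group_a: Sequence[float], group_b: Sequence[float]) -> dict:
    """Two-tailed Mann–Whitney U test.

    Exact enumeration-equivalent p for combined n <= 12 without ties
    (two-tailed = doubled smaller tail, capped at 1), otherwise a normal
    approximation with tie correction and continuity correction.
    Returns ``{"U", "p_two_tailed", "method"}`` with U the statistic of
    group A.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = len(a), len(b)
    u_a = _u_statistic(a, b)
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)

    if n1 + n2 <= EXACT_MWU_MAX_N and not has_ties:
        counts = _exact_u_counts(n1, n2)
        total = counts.sum()
        u_small = min(u_a, n1 * n2 - u_a)
        tail = counts[: int(u_small) + 1].sum() / total
        p = min(1.0, 2.0 * tail)
        return {"U": u_a, "p_two_tailed": float(p), "method": "exact"}

    n = n1 + n2
    mean_u = n1 * n2 / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum())) / (n * (n - 1))
    var_u = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var_u <= 0:
        return {"U": u_a, "p_two_tailed": 1.0, "method": "normal"}
    z = (abs(u_a - mean_u) - 0.5) / np.sqrt(var_u)
    z = max(z, 0.0)
    p = 2.0 * sps.norm.sf(z)
    return {"U": u_a, "p_two_tailed": float(min(1.0, p)), "method": "normal"}


def compare_means_welch(group_a: Sequence[float], group_b: Sequence[float]) -> dict:
    """Unpaired two-tailed Welch's t test (Welch–Satterthwaite df)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return {"t": 0.0, "df": float(len(a) + len(b) - 2), "p_two_tailed": 1.0}
        raise ValueError("both groups have zero variance; Welch's t undefined")
    se2 = va / len(a) + vb / len(b)
    t = float((a.mean() - b.mean()) / np.sqrt(se2))
    df = se2**2 / (
        (va / len(a)) ** 2 / (len(a) - 1) + (vb / len(b)) ** 2 / (len(b) - 1)
    )
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return {"t": t, "df": float(df), "p_two_tailed": min(1.0, p)}
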