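"""Statistical evaluation of docking-score tables.

Docking engines emit one scalar per (receptor, ligand, engine) triple —
binding energies in kcal/mol (more negative = stronger predicted binding) or
a unitless CNN pose score.  This module ingests such tables and asks the
standard questions: do score distributions differ across receptors
(Kruskal–Wallis, Dunn's post hoc with multiplicity adjustment), and do the
scores discriminate experimentally responsive from unresponsive ligands
(ROC/AUC via the rank / Mann–Whitney formulation, with half credit for ties)?
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ScoreTable",
    "KWResult",
    "DunnMatrix",
    "ROCResult",
    "load_scores",
    "kruskal_wallis",
    "dunn_posthoc",
    "roc_auc",
    "receptor_summary",
]

ENGINES = ("vina", "gnina_affinity", "gnina_cnnscore")
#: per-engine ROC orientation: energies are better when lower, CNN scores when higher
ENGINE_ORIENTATION = {
    "vina": "lower_is_active",
    "gnina_affinity": "lower_is_active",
    "gnina_cnnscore": "higher_is_active",
}

_TRUTHY = {"1", "true", "yes", "t"}
_FALSY = {"0", "false", "no", "f"}


@dataclass
class ScoreTable:
    """Validated docking-score table; rows unique on (receptor, ligand, engine)."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"receptor", "ligand", "engine", "value"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"missing required columns: {sorted(missing)}")
        dupes = self.frame.duplicated(subset=["receptor", "ligand", "engine"], keep=False)
        if dupes.any():
            offenders = self.frame.loc[dupes, ["receptor", "ligand", "engine"]]
            raise ValueError(
                "duplicate (receptor, ligand, engine) keys:\n"
                + offenders.drop_duplicates().to_string(index=False)
            )
        if not np.all(np.isfinite(self.frame["value"].to_numpy(dtype=float))):
            raise ValueError("score values must be finite")
        bad = set(self.frame["engine"]) - set(ENGINES)
        if bad:
            raise ValueError(f"unknown engines {sorted(bad)}; expected one of {ENGINES}")

    def __len__(self) -> int:
        return len(self.frame)

    def groups_by(self, column: str = "receptor",
                  engine: Optional[str] = None) -> Dict[str, np.ndarray]:
        df = self.frame if engine is None else self.frame[self.frame["engine"] == engine]
        return {key: g["value"].to_numpy(dtype=float) for key, g in df.groupby(column)}


def _normalize_bool(x) -> bool:
    s = str(x).strip().lower()
    if s in _TRUTHY:
        return True
    if s in _FALSY:
        return False
    raise ValueError(f"cannot interpret responsiveness label {x!r} as boolean")


def load_scores(path_or_frame: Union[str, pd.DataFrame]) -> ScoreTable:
    """Load and validate a scores CSV with header
    receptor,ligand,engine,value[,responsive]."""
    df = (path_or_frame.copy() if isinstance(path_or_frame, pd.DataFrame)
          else pd.read_csv(path_or_frame))
    if "responsive" in df.columns:
        df["responsive"] = df["responsive"].map(_normalize_bool)
    df["value"] = pd.to_numeric(df["value"])
    return ScoreTable(df)


# ---------------------------------------------------------------------------
# Kruskal–Wallis


@dataclass
class KWResult:
    h_statistic: float
    df: int
    p_value: float
    tie_correction: float


def _tie_correction(values: np.ndarray) -> float:
    n = values.size
    if n < 2:
        return 1.0
    _, counts = np.unique(values, return_counts=True)
    return 1.0 - (counts ** 3 - counts).sum() / (n ** 3 - n)


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> KWResult:
    """Rank-based H test across ≥ 2 groups with tie correction.

    The degenerate all-values-identical case is reported as H = 0, p = 1
    (convention: no evidence of any difference).
    """
    if len(groups) < 2:
        raise ValueError("at least 2 groups required")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("each group needs at least 1 value")
    pooled = np.concatenate(arrays)
    tie = _tie_correction(pooled)
    if np.ptp(pooled) == 0.0:
        return KWResult(0.0, len(groups) - 1, 1.0, tie)
    h, p = stats.kruskal(*arrays)
    return KWResult(float(h), len(groups) - 1, float(p), tie)


# ---------------------------------------------------------------------------
# Dunn's post hoc


@dataclass
class DunnMatrix:
    labels: List[str]
    p_values: pd.DataFrame
    z_values: pd.DataFrame
    adjustment: str


def dunn_posthoc(groups: Dict[str, Sequence[float]],
                 adjust: str = "bonferroni") -> DunnMatrix:
    """Pairwise Dunn z tests on the pooled ranking, with tie correction.

    z_ij = (R̄_i − R̄_j) / sqrt([N(N+1)/12 − ΣT/(12(N−1))](1/n_i + 1/n_j)),
    two-sided normal p-values, adjusted (default Bonferroni) and capped at 1.
    """
    if len(groups) < 2:
        raise ValueError("at least 2 groups required")
    if adjust not in ("bonferroni", "none"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    labels = list(groups)
    arrays = [np.asarray(groups[lab], dtype=float) for lab in labels]
    sizes = np.array([a.size for a in arrays])
    pooled = np.concatenate(arrays)
    n_total = pooled.size
    ranks = stats.rankdata(pooled)
    mean_ranks = []
    start = 0
    for sz in sizes:
        mean_ranks.append(ranks[start:start + sz].mean())
        start += sz

    _, counts = np.unique(pooled, return_counts=True)
    tie_sum = (counts ** 3 - counts).sum()
    var_term = n_total * (n_total + 1) / 12.0 - tie_sum / (12.0 * (n_total - 1))

    g = len(labels)
    n_comparisons = g * (g - 1) // 2
    P = np.ones((g, g))
    Z = np.zeros((g, g))
    for i, j in combinations(range(g), 2):
        se = np.sqrt(var_term * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p = 2.0 * stats.norm.sf(abs(z))
        if adjust == "bonferroni":
            p = min(1.0, p * n_comparisons)
        P[i, j] = P[j, i] = p
        Z[i, j] = z
        Z[j, i] = -z
    return DunnMatrix(
        labels=labels,
        p_values=pd.DataFrame(P, index=labels, columns=labels),
        z_values=pd.DataFrame(Z, index=labels, columns=labels),
        adjustment=adjust,
    )


# ---------------------------------------------------------------------------
# ROC / AUC


@dataclass
class ROCResult:
    auc: float
    n_pos: int
    n_neg: int
    fpr: np.ndarray
    tpr: np.ndarray
    orientation: str


def roc_auc(scores: Sequence[float], labels: Sequence[bool],
            orientation: str = "lower_is_active") -> ROCResult:
    """AUC by the rank (Mann–Whitney) formulation with ½ credit for ties.

    ``lower_is_active`` (binding energies) negates the scores so that higher
    oriented score = more active.  The stored (FPR, TPR) curve includes (0,0)
    and (1,1), steps through tied scores jointly, and its trapezoidal area
    equals the rank AUC.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D")
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    if orientation == "lower_is_active":
        oriented = -s
    elif orientation == "higher_is_active":
        oriented = s.copy()
    else:
        raise ValueError(f"unknown orientation {orientation!r}")

    ranks = stats.rankdata(oriented)  # midranks give the tie convention
    auc = (ranks[y].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)

    order = np.argsort(-oriented, kind="stable")
    fpr = [0.0]
    tpr = [0.0]
    tp = fp = 0
    i = 0
    n = s.size
    while i < n:
        j = i
        while j < n and oriented[order[j]] == oriented[order[i]]:
            j += 1
        tp += int(y[order[i:j]].sum())
        fp += (j - i) - int(y[order[i:j]].sum())
        fpr.append(fp / n_neg)
        tpr.append(tp / n_pos)
        i = j
    return ROCResult(auc=float(auc), n_pos=n_pos, n_neg=n_neg,
                     fpr=np.array(fpr), tpr=np.array(tpr),
                     orientation=orientation)


# ---------------------------------------------------------------------------
# summaries


def receptor_summary(table: ScoreTable) -> pd.DataFrame:
    """n/mean/median/sd/min/max per (receptor, engine)."""
    if len(table) == 0:
        raise ValueError("empty score table")
    g = table.frame.groupby(["receptor", "engine"])["value"]
    out = g.agg(n="count", mean="mean", median="median", sd="std",
                min="min", max="max")
    out["sd"] = out["sd"].fillna(0.0)
    return out.reset_index()
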