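"""Rigid-body superposition, iterative-pruning RMSD, and ensemble observables.

The pruning procedure mirrors the common structure-comparison convention for
isolating the conserved core of two protein models: fit CA pairs by a
least-squares (Kabsch) superposition, then iteratively discard the
worst-fitting residue pairs beyond a distance cutoff — each round removing
either 10% of the current pairs or 50% of the pairs exceeding the cutoff,
whichever is fewer — and refit, until every retained pair lies within the
cutoff.  Both the all-pair RMSD and the final pruned RMSD are reported.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .structio import Ensemble, ResidueKey, StructureModel, select_atoms

__all__ = [
    "Transform",
    "ResiduePairing",
    "SuperpositionResult",
    "EnsembleSeries",
    "PairingError",
    "pair_residues",
    "kabsch",
    "pruned_rmsd",
    "ensemble_rmsd",
    "rmsf",
    "radius_of_gyration",
    "summarize_rmsd_table",
    "load_benchmark_table",
]

ATOMIC_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999,
    "S": 32.06, "P": 30.974, "SE": 78.971, "FE": 55.845,
}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M",
}


class PairingError(ValueError):
    """Fewer than three residue pairs could be established."""


@dataclass
class Transform:
    """Proper rigid transform: x -> rotation @ x + translation."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation must be orthonormal")
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-8:
            raise ValueError("rotation must have determinant +1")

    @classmethod
    def identity(cls) -> "Transform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation


@dataclass
class ResiduePairing:
    pairs: List[Tuple[ResidueKey, ResidueKey]]
    source: str  # "numbering" | "alignment"
    alignment_score: Optional[float] = None

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class SuperpositionResult:
    transform: Transform
    rmsd_all: float
    n_all: int
    rmsd_pruned: float
    n_pruned: int
    retained: List[Tuple[ResidueKey, ResidueKey]]
    iterations: int
    cutoff: float
    converged: bool = True

    def to_dict(self) -> dict:
        return {
            "rmsd_all": self.rmsd_all,
            "n_all": self.n_all,
            "rmsd_pruned": self.rmsd_pruned,
            "n_pruned": self.n_pruned,
            "iterations": self.iterations,
            "cutoff": self.cutoff,
            "converged": self.converged,
            "rotation": self.transform.rotation.tolist(),
            "translation": self.transform.translation.tolist(),
        }


@dataclass
class EnsembleSeries:
    rmsd: List[float] = field(default_factory=list)
    rmsf: List[float] = field(default_factory=list)
    rg: List[float] = field(default_factory=list)


# ---------------------------------------------------------------------------
# residue pairing


def _ca_residues(model: StructureModel) -> "dict[ResidueKey, np.ndarray]":
    return {a.residue_key: a.xyz for a in select_atoms(model, "CA")}


def pair_residues(
    ref: StructureModel,
    mob: StructureModel,
    mode: str = "numbering",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> ResiduePairing:
    """Pair CA-bearing residues of two models.

    ``numbering`` pairs identical (chain, resseq, icode) keys; ``alignment``
    derives one-letter sequences and pairs the non-gap columns of a global
    Needleman–Wunsch alignment (BLOSUM62, affine gaps with the given positive
    penalties).
    """
    ref_ca = _ca_residues(ref)
    mob_ca = _ca_residues(mob)
    if len(ref_ca) < 3 or len(mob_ca) < 3:
        raise PairingError("both models need at least 3 CA-bearing residues")

    if mode == "numbering":
        pairs = [(k, k) for k in ref_ca if k in mob_ca]
        if len(pairs) < 3:
            raise PairingError(f"numbering mode produced only {len(pairs)} pairs")
        return ResiduePairing(pairs, "numbering")

    if mode != "alignment":
        raise ValueError(f"unknown pairing mode {mode!r}")

    from Bio import Align
    from Bio.Align import substitution_matrices

    ref_keys = list(ref_ca)
    mob_keys = list(mob_ca)
    ref_res = {k: None for k in ref_keys}
    resnames_ref = {a.residue_key: a.resname for a in select_atoms(ref, "CA")}
    resnames_mob = {a.residue_key: a.resname for a in select_atoms(mob, "CA")}
    seq_ref = "".join(THREE_TO_ONE.get(resnames_ref[k], "X") for k in ref_keys)
    seq_mob = "".join(THREE_TO_ONE.get(resnames_mob[k], "X") for k in mob_keys)

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    aln = aligner.align(seq_ref, seq_mob)[0]

    pairs: List[Tuple[ResidueKey, ResidueKey]] = []
    for (r0, r1), (m0, m1) in zip(*aln.aligned):
        for i, j in zip(range(r0, r1), range(m0, m1)):
            pairs.append((ref_keys[i], mob_keys[j]))
    if len(pairs) < 3:
        raise PairingError(f"alignment mode produced only {len(pairs)} pairs")
    return ResiduePairing(pairs, "alignment", alignment_score=float(aln.score))


# ---------------------------------------------------------------------------
# Kabsch superposition


def kabsch(
    ref_coords: np.ndarray,
    mob_coords: np.ndarray,
    weights: Optional[np.ndarray] = None,
) -> Tuple[Transform, float]:
    """Optimal proper rigid superposition of ``mob`` onto ``ref``.

    Returns the transform minimizing the (weighted) RMSD and that RMSD.
    Reflections are excluded by the usual determinant sign correction.
    """
    P = np.asarray(ref_coords, dtype=float)
    Q = np.asarray(mob_coords, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("coordinate arrays must both be (N, 3)")
    n = P.shape[0]
    if n < 3:
        raise ValueError("at least 3 points are required")
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    w = w / w.sum()

    pc = (w[:, None] * P).sum(axis=0)
    qc = (w[:, None] * Q).sum(axis=0)
    P0, Q0 = P - pc, Q - qc
    H = (w[:, None] * Q0).T @ P0
    if np.linalg.matrix_rank(H) < 2:
        warnings.warn("degenerate (collinear) coordinates: fit may be ill-conditioned")
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = pc - R @ qc
    transform = Transform(R, t)
    diff = transform.apply(Q) - P
    rmsd = float(np.sqrt((w * (diff ** 2).sum(axis=1)).sum()))
    return transform, rmsd


# ---------------------------------------------------------------------------
# iterative-pruning RMSD


def pruned_rmsd(
    ref: StructureModel,
    mob: StructureModel,
    pairing: Optional[ResiduePairing] = None,
    cutoff: float = 2.0,
    frac_all: float = 0.10,
    frac_exceed: float = 0.50,
    max_iterations: Optional[int] = None,
) -> SuperpositionResult:
    """All-pair and iteratively pruned CA RMSD between two models.

    Each round fits the retained CA pairs (Kabsch), finds the pairs whose
    fitted distance exceeds ``cutoff``, and removes the ``r`` farthest pairs
    with ``r = max(1, min(floor(frac_all*N), floor(frac_exceed*|exceeding|)))``
    (ties broken by lower residue index), stopping when no pair exceeds the
    cutoff or when a removal would leave fewer than 3 pairs (non-converged).
    """
    if pairing is None:
        pairing = pair_residues(ref, mob, "numbering")
    if len(pairing) < 3:
        raise PairingError("pruned_rmsd requires at least 3 pairs")

    ref_ca = _ca_residues(ref)
    mob_ca = _ca_residues(mob)
    try:
        P = np.array([ref_ca[a] for a, _ in pairing.pairs])
        Q = np.array([mob_ca[b] for _, b in pairing.pairs])
    except KeyError as exc:
        raise PairingError(f"paired residue {exc} has no CA atom") from None

    n_all = len(pairing)
    idx = np.arange(n_all)
    transform, rmsd_all = kabsch(P, Q)
    rmsd_current = rmsd_all
    iterations = 0
    converged = True
    limit = max_iterations if max_iterations is not None else n_all

    while iterations < limit:
        d = np.linalg.norm(transform.apply(Q[idx]) - P[idx], axis=1)
        exceeding = np.nonzero(d > cutoff)[0]
        if exceeding.size == 0:
            break
        n_current = idx.size
        r = max(1, min(math.floor(frac_all * n_current),
                       math.floor(frac_exceed * exceeding.size)))
        if n_current - r < 3:
            converged = False
            break
        # farthest r pairs; ties resolved toward the lower residue index
        order = np.lexsort((idx, -d))
        idx = np.delete(idx, np.sort(order[:r]))
        iterations += 1
        transform, rmsd_current = kabsch(P[idx], Q[idx])
    else:
        converged = False

    retained = [pairing.pairs[i] for i in idx]
    return SuperpositionResult(
        transform=transform,
        rmsd_all=rmsd_all,
        n_all=n_all,
        rmsd_pruned=rmsd_current,
        n_pruned=idx.size,
        retained=retained,
        iterations=iterations,
        cutoff=cutoff,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# ensemble observables


def _selection_coords(ens: Ensemble, selector: str) -> np.ndarray:
    sel = select_atoms(ens[0], selector)
    if not sel:
        raise ValueError(f"selection {selector!r} is empty")
    keys = [a.atom_key for a in sel]
    index = {k: i for i, k in enumerate(ens.topology_fingerprint)}
    cols = [index[k] for k in keys]
    return ens.coords()[:, cols, :]


def ensemble_rmsd(
    ens: Ensemble,
    reference: Union[int, StructureModel] = 0,
    selector: str = "CA",
) -> List[float]:
    """Per-model RMSD to a reference after Kabsch fitting on the selection."""
    X = _selection_coords(ens, selector)
    if isinstance(reference, StructureModel):
        sel = select_atoms(reference, selector)
        ref = np.array([a.xyz for a in sel])
        if ref.shape != X[0].shape:
            raise ValueError("reference selection does not match ensemble topology")
    else:
        ref = X[reference]
    return [kabsch(ref, X[i])[1] for i in range(X.shape[0])]


def rmsf(ens: Ensemble, selector: str = "CA") -> List[float]:
    """Per-atom root-mean-square fluctuation about the mean structure.

    Two-pass mean-structure reference: models are first fitted to model 1,
    the mean structure is computed, each model is refitted to that mean, and
    fluctuations are measured about the refitted mean.
    """
    if len(ens) < 2:
        raise ValueError("RMSF requires at least 2 models")
    X = _selection_coords(ens, selector)
    fitted = np.stack([kabsch(X[0], X[i])[0].apply(X[i]) for i in range(X.shape[0])])
    mean1 = fitted.mean(axis=0)
    fitted = np.stack([kabsch(mean1, X[i])[0].apply(X[i]) for i in range(X.shape[0])])
    mean2 = fitted.mean(axis=0)
    sq = ((fitted - mean2) ** 2).sum(axis=2)  # (models, atoms)
    return list(np.sqrt(sq.mean(axis=0)))


def radius_of_gyration(model: StructureModel, weighting: str = "uniform") -> float:
    """Radius of gyration: sqrt(sum w_i |x_i - xbar|^2 / sum w_i), in Å."""
    coords = model.coords()
    if coords.shape[0] == 0:
        raise ValueError("model has no atoms")
    if weighting == "uniform":
        w = np.ones(coords.shape[0])
    elif weighting == "mass":
        w = np.array([ATOMIC_MASSES.get(a.element.upper(), 12.011) for a in model.atoms])
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    w = w / w.sum()
    center = (w[:, None] * coords).sum(axis=0)
    return float(np.sqrt((w * ((coords - center) ** 2).sum(axis=1)).sum()))


def ensemble_observables(
    ens: Ensemble,
    reference: Union[int, StructureModel] = 0,
    selector: str = "CA",
    rg_weighting: str = "uniform",
) -> EnsembleSeries:
    """RMSD series, per-atom RMSF and per-model Rg for one ensemble."""
    series = EnsembleSeries()
    series.rmsd = ensemble_rmsd(ens, reference, selector)
    if len(ens) >= 2:
        series.rmsf = rmsf(ens, selector)
    series.rg = [radius_of_gyration(m, rg_weighting) for m in ens.models]
    return series


# ---------------------------------------------------------------------------
# benchmark-table summarization


def summarize_rmsd_table(table: Union[pd.DataFrame, str]) -> pd.DataFrame:
    """Per-method mean/sd/min/max over a structures x methods RMSD table.

    Rows are structures, columns are modeling methods; missing cells are
    skipped with a warning.  A column with no values at all is an error.
    """
    if not isinstance(table, pd.DataFrame):
        table = pd.read_csv(table, index_col=0)
    numeric = table.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        n_missing = int(numeric.isna().sum().sum())
        warnings.warn(f"{n_missing} missing/non-numeric cells skipped")
    out = {}
    for col in numeric.columns:
        vals = numeric[col].dropna()
        if vals.empty:
            raise ValueError(f"method column {col!r} has no values")
        out[col] = {
            "n": int(vals.size),
            "mean": float(vals.mean()),
            "sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
            "min": float(vals.min()),
            "max": float(vals.max()),
        }
    return pd.DataFrame(out).T[["n", "mean", "sd", "min", "max"]]


def load_benchmark_table(which: str = "unpruned") -> pd.DataFrame:
    """Packaged benchmark: unpruned/pruned CA RMSD of four modeling approaches
    against 15 experimentally determined human GPCR structures."""
    if which not in ("unpruned", "pruned"):
        raise ValueError("which must be 'unpruned' or 'pruned'")
    with resources.files("odorkit.data").joinpath("gpcr_benchmark_rmsd.csv").open() as fh:
        df = pd.read_csv(fh, index_col=0)
    cols = [c for c in df.columns if c.endswith(which)]
    out = df[cols].copy()
    out.columns = [c.rsplit("_", 1)[0] for c in cols]
    return out
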