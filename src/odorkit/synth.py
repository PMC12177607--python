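"""Seeded synthetic-fixture generators with known ground truth.

Every other module is testable offline through these: an ideal-geometry
backbone builder (internal-to-Cartesian, so the set torsions are exactly
recoverable), a structure perturber producing known "core + outlier" pairs
for the pruning procedure, a Gaussian-mixture descriptor generator emulating
a clustered odorant chemical space, and a two-population docking-score
simulator with attached responsiveness labels.

All generators are pure functions of (spec, seed): identical inputs give
bitwise-identical outputs (NumPy ``default_rng``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .chemspace import DescriptorMatrix
from .dockstats import ScoreTable
from .geomqc import load_ideal_backbone
from .structio import AtomRecord, StructureModel
from .superpose import Transform

__all__ = [
    "HelixSpec",
    "MixtureSpec",
    "ScoreSimSpec",
    "build_helix",
    "perturb_structure",
    "gen_mixture",
    "gen_scores",
]


# ---------------------------------------------------------------------------
# backbone builder


@dataclass
class HelixSpec:
    """Regular backbone: every residue gets the same (phi, psi, omega).

    Defaults are ideal alpha-helical torsions; bond lengths/angles come from
    the packaged ideal-backbone table, so the built model passes the
    bond/angle QC with zero flags by construction.
    """

    n_res: int = 20
    phi: float = -57.0
    psi: float = -47.0
    omega: float = 180.0
    sequence: Optional[List[str]] = None
    chain: str = "A"
    #: optional per-residue torsion overrides (length n_res), e.g. to inject
    #: a single Ramachandran outlier into an otherwise ideal helix
    phi_list: Optional[List[float]] = None
    psi_list: Optional[List[float]] = None

    def __post_init__(self) -> None:
        if self.n_res < 3:
            raise ValueError("n_res must be >= 3")
        for name in ("phi", "psi", "omega"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.sequence is not None and len(self.sequence) != self.n_res:
            raise ValueError("sequence length must equal n_res")
        for name in ("phi_list", "psi_list"):
            lst = getattr(self, name)
            if lst is not None and len(lst) != self.n_res:
                raise ValueError(f"{name} length must equal n_res")

    def phi_at(self, i: int) -> float:
        return self.phi if self.phi_list is None else self.phi_list[i]

    def psi_at(self, i: int) -> float:
        return self.psi if self.psi_list is None else self.psi_list[i]


def _nerf_place(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Natural-extension reference frame: place D so that |C-D| = bond,
    angle(B,C,D) = angle and dihedral(A,B,C,D) = torsion."""
    angle = np.radians(angle_deg)
    torsion = np.radians(torsion_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(angle),
        bond * np.sin(angle) * np.cos(torsion),
        bond * np.sin(angle) * np.sin(torsion),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_helix(spec: HelixSpec) -> StructureModel:
    """Deterministic backbone (N, CA, C, O) from ideal internal coordinates."""
    table = load_ideal_backbone()
    b = {k: v["mean"] for k, v in table["bonds"].items()}
    a = {k: v["mean"] for k, v in table["angles"].items()}

    N: List[np.ndarray] = [np.zeros(3)]
    CA: List[np.ndarray] = [np.array([b["N-CA"], 0.0, 0.0])]
    ang = np.radians(a["N-CA-C"])
    CA0 = CA[0]
    C: List[np.ndarray] = [CA0 + b["CA-C"] * np.array([-np.cos(ang), np.sin(ang), 0.0])]

    for i in range(1, spec.n_res):
        N.append(_nerf_place(N[i - 1], CA[i - 1], C[i - 1],
                             b["C-N"], a["CA-C-N"], spec.psi_at(i - 1)))
        CA.append(_nerf_place(CA[i - 1], C[i - 1], N[i],
                              b["N-CA"], a["C-N-CA"], spec.omega))
        C.append(_nerf_place(C[i - 1], N[i], CA[i],
                             b["CA-C"], a["N-CA-C"], spec.phi_at(i)))
    # carbonyl O opposite the next N in the peptide plane
    O = [_nerf_place(N[i], CA[i], C[i], b["C-O"], a["CA-C-O"], spec.psi_at(i) - 180.0)
         for i in range(spec.n_res)]

    seq = spec.sequence or ["ALA"] * spec.n_res
    atoms: List[AtomRecord] = []
    serial = 1
    for i in range(spec.n_res):
        for name, xyz, element in (("N", N[i], "N"), ("CA", CA[i], "C"),
                                   ("C", C[i], "C"), ("O", O[i], "O")):
            atoms.append(AtomRecord(
                serial=serial, name=name, altloc="", resname=seq[i],
                chain=spec.chain, resseq=i + 1, icode="", xyz=xyz,
                occupancy=1.0, bfactor=0.0, element=element,
            ))
            serial += 1
    return StructureModel(model_id=1, atoms=atoms)


def perturb_structure(model: StructureModel,
                      rigid: Optional[Transform] = None,
                      noise_sd: float = 0.0,
                      displaced: Sequence = (),
                      displacement: Sequence[float] = (0.0, 0.0, 0.0),
                      seed: Optional[int] = None) -> StructureModel:
    """Rigid motion + seeded i.i.d. Gaussian noise + a fixed displacement of a
    chosen residue subset — a known "core + outlier" partner structure.

    ``displaced`` holds residue keys or bare resseq integers; naming a residue
    absent from the model is an error.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    resseqs = {k[1] for k in model.residue_keys}
    keys = set(model.residue_keys)
    target_keys = set()
    for item in displaced:
        if isinstance(item, int):
            if item not in resseqs:
                raise ValueError(f"residue number {item} not in model")
            target_keys |= {k for k in keys if k[1] == item}
        else:
            if tuple(item) not in keys:
                raise ValueError(f"residue key {item} not in model")
            target_keys.add(tuple(item))

    coords = model.coords()
    if rigid is not None:
        coords = rigid.apply(coords)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        coords = coords + rng.normal(0.0, noise_sd, size=coords.shape)
    disp = np.asarray(displacement, dtype=float)
    for i, atom in enumerate(model.atoms):
        if atom.residue_key in target_keys:
            coords[i] = coords[i] + disp
    return model.with_coords(coords)


# ---------------------------------------------------------------------------
# descriptor mixtures


_DEFAULT_CENTERS = np.array([
    [0.0, 0.0], [12.0, 0.0], [0.0, 12.0], [12.0, 12.0], [24.0, 24.0],
])


@dataclass
class MixtureSpec:
    """Gaussian-mixture descriptor space with known component labels.

    Defaults emulate a well-separated clustered odorant space: 5 components
    in 2-D, unit sigma, centers at least 10 sigma apart, 30 points each.
    ``hard()`` shrinks the separation to ~2 sigma for diagnostic behavior.
    """

    k_true: int = 5
    dims: int = 2
    centers: np.ndarray = field(default_factory=lambda: _DEFAULT_CENTERS.copy())
    sigma: float = 1.0
    n_per_cluster: int = 30
    seed: Optional[int] = 0
    n_exact_copies: int = 0     # appended exact linear copies of column 0
    n_near_copies: int = 0      # appended near-copies with |r| ~ 0.96

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float)
        if self.centers.shape != (self.k_true, self.dims):
            raise ValueError("centers must be k_true × dims")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        d = np.linalg.norm(self.centers[:, None] - self.centers[None, :], axis=2)
        if np.any(d[np.triu_indices(self.k_true, 1)] == 0):
            raise ValueError("centers must be pairwise distinct")

    @classmethod
    def hard(cls, seed: Optional[int] = 0) -> "MixtureSpec":
        return cls(centers=_DEFAULT_CENTERS * (2.0 / 12.0), seed=seed)


def gen_mixture(spec: MixtureSpec) -> Tuple[DescriptorMatrix, np.ndarray]:
    """Seeded mixture draws plus ground-truth component labels."""
    rng = np.random.default_rng(spec.seed)
    blocks = [spec.centers[j] + rng.normal(0.0, spec.sigma, size=(spec.n_per_cluster, spec.dims))
              for j in range(spec.k_true)]
    X = np.vstack(blocks)
    labels = np.repeat(np.arange(spec.k_true), spec.n_per_cluster)
    names = [f"d{j + 1}" for j in range(spec.dims)]

    extra_cols = []
    for c in range(spec.n_exact_copies):
        extra_cols.append(2.0 * X[:, 0])
        names.append(f"copy_exact_{c + 1}")
    for c in range(spec.n_near_copies):
        base = X[:, 0]
        target_r = 0.96
        noise_sd = base.std() * np.sqrt(1.0 / target_r ** 2 - 1.0)
        extra_cols.append(base + rng.normal(0.0, noise_sd, size=base.shape))
        names.append(f"copy_near_{c + 1}")
    if extra_cols:
        X = np.column_stack([X] + extra_cols)

    ids = [f"mol_{i + 1:04d}" for i in range(X.shape[0])]
    dm = DescriptorMatrix(ids=ids, descriptor_names=names, values=X,
                          provenance=f"gen_mixture(seed={spec.seed})")
    return dm, labels


# ---------------------------------------------------------------------------
# docking-score simulator


@dataclass
class ScoreSimSpec:
    """Two-population docking scores: energies ~ N(base + shift_r, sd²), with
    an ``active_fraction`` of ligands shifted by −delta (stronger binding)."""

    receptors: Tuple[str, ...] = ("OR51E1", "OR51E2", "OR51D1", "OR51G2")
    shifts: Tuple[float, ...] = (0.0, 1.5, -0.8, -0.8)
    base: float = -6.0
    noise_sd: float = 1.0
    n_ligands: int = 50
    active_fraction: float = 0.5
    delta: float = 1.0
    engine: str = "gnina_affinity"
    seed: Optional[int] = 0

    def __post_init__(self) -> None:
        if len(self.shifts) != len(self.receptors):
            raise ValueError("one shift per receptor required")
        if not 0.0 < self.active_fraction < 1.0:
            raise ValueError("active_fraction must be in (0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")


def gen_scores(spec: ScoreSimSpec) -> ScoreTable:
    """Seeded score table with ground-truth responsiveness labels."""
    rng = np.random.default_rng(spec.seed)
    rows = []
    n_active = int(round(spec.active_fraction * spec.n_ligands))
    for receptor, shift in zip(spec.receptors, spec.shifts):
        active = np.zeros(spec.n_ligands, dtype=bool)
        active[:n_active] = True
        rng.shuffle(active)
        energies = (spec.base + shift
                    + rng.normal(0.0, spec.noise_sd, size=spec.n_ligands)
                    - spec.delta * active)
        for i in range(spec.n_ligands):
            rows.append({
                "receptor": receptor,
                "ligand": f"{receptor}_lig_{i + 1:04d}",
                "engine": spec.engine,
                "value": float(energies[i]),
                "responsive": bool(active[i]),
            })
    return ScoreTable(pd.DataFrame(rows))
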