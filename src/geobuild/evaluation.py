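"""Evaluation of reconstructions against a reference structure.

A distance set determines a structure only up to a rigid motion and
possibly a reflection, so reconstruction error is measured as the RMSD
after optimal superposition, minimized over the two enantiomers.  The
``used_reflection`` flag reports which enantiomer the solver built.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import ReconstructionResult, SparseDistanceSet, Structure
from .errors import MismatchedAtoms
from .graph import build_distance_set
from .solvers import SolverOptions, solve
from .superposition import center, rmsd

__all__ = ["EvaluationReport", "aligned_rmsd", "max_distance_violation", "run_experiment"]


@dataclass
class EvaluationReport:
    algorithm: str
    status: str
    n_total: int
    n_positioned: int
    aligned_rmsd: Optional[float]  # Å; None when no reference available
    used_reflection: Optional[bool]
    max_distance_violation: float  # Å
    restart_count: int
    sweep_count: int


def _kabsch_proper(X1: np.ndarray, Y1: np.ndarray) -> np.ndarray:
    """Best proper rotation (det +1) minimizing ‖X1 − Y1 Q‖_F."""
    C = Y1.T @ X1
    U, _, Vt = np.linalg.svd(C)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, 1.0, d if d != 0 else 1.0])
    return U @ D @ Vt


def aligned_rmsd(
    reconstructed: np.ndarray | Structure,
    reference: np.ndarray | Structure,
    allow_reflection: bool = True,
) -> tuple[float, bool]:
    """RMSD after optimal rigid superposition.

    Superposes the reconstruction onto the reference (centering + best
    proper rotation); with ``allow_reflection`` (the default) the
    z-negated copy is superposed too and the smaller RMSD is returned
    together with a flag saying whether the mirror branch won.
    """
    X = reconstructed.coords if isinstance(reconstructed, Structure) else np.asarray(reconstructed, float)
    Y = reference.coords if isinstance(reference, Structure) else np.asarray(reference, float)
    if X.shape != Y.shape:
        raise MismatchedAtoms(
            f"point sets differ in shape: {X.shape} vs {Y.shape}"
        )
    Yc, _ = center(Y)

    def branch(pts: np.ndarray) -> float:
        Xc, _ = center(pts)
        Q = _kabsch_proper(Yc, Xc)
        return rmsd(Xc @ Q, Yc)

    direct = branch(X)
    if not allow_reflection:
        return direct, False
    mirrored = branch(X * np.array([1.0, 1.0, -1.0]))
    if mirrored < direct:
        return mirrored, True
    return direct, False


def max_distance_violation(
    result: ReconstructionResult, dset: SparseDistanceSet
) -> float:
    """Largest |‖x_i − x_j‖ − d_ij| over positioned pairs with a known
    distance (Å)."""
    coords = result.structure.coords
    mask = result.positioned_mask
    worst = 0.0
    for (i, j), d in dset.entries.items():
        if mask[i] and mask[j]:
            worst = max(worst, abs(float(np.linalg.norm(coords[i] - coords[j])) - d))
    return worst


def evaluate(
    result: ReconstructionResult,
    dset: SparseDistanceSet,
    reference: Optional[Structure] = None,
    allow_reflection: bool = True,
) -> EvaluationReport:
    """Summarize one reconstruction; RMSD is computed over positioned
    atoms only (with ``n_positioned`` reported alongside)."""
    value: Optional[float] = None
    used_ref: Optional[bool] = None
    if reference is not None and result.n_positioned >= 1:
        ids = result.positioned_ids()
        value, used_ref = aligned_rmsd(
            result.structure.coords[ids], reference.coords[ids], allow_reflection
        )
    return EvaluationReport(
        algorithm=result.algorithm,
        status=result.status,
        n_total=result.structure.n_atoms,
        n_positioned=result.n_positioned,
        aligned_rmsd=value,
        used_reflection=used_ref,
        max_distance_violation=max_distance_violation(result, dset),
        restart_count=result.restart_count,
        sweep_count=result.sweep_count,
    )


def run_experiment(
    dset: SparseDistanceSet,
    algorithms: Sequence[str] = ("gb", "ugb", "rugb"),
    reference: Optional[Structure] = None,
    opts: Optional[SolverOptions] = None,
) -> pd.DataFrame:
    """Solve one instance with each algorithm and tabulate the reports.

    Solver failures become status rows, not exceptions.  Deterministic
    under fixed options.
    """
    rows = []
    for algo in algorithms:
        run_opts = SolverOptions(
            algorithm=algo,
            degeneracy_rel_tol=opts.degeneracy_rel_tol if opts else 1e-8,
            distance_consistency_tol=opts.distance_consistency_tol if opts else 1e-6,
            max_restarts=opts.max_restarts if opts else 25,
            max_sweeps=opts.max_sweeps if opts else None,
            max_base_candidates=opts.max_base_candidates if opts else 5000,
        )
        result = solve(dset, run_opts)
        rows.append(evaluate(result, dset, reference).__dict__)
    return pd.DataFrame(rows)
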