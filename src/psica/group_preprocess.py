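"""Multi-subject stacking, two-stage SVD reduction and back-reconstruction.

Group spatial ICA assumes common spatial maps across subjects with
subject-specific mixing: stacking the ``I`` subject matrices ``X_i``
(``T x V``) in the temporal domain gives ``X = A S`` with a ``TI x Q``
group mixing matrix.  To make the system determined the data are reduced in
two SVD stages: within each subject the top ``R`` temporal components are
retained, then a group SVD of the ``RI x V`` stack keeps ``Q`` components.
The retained factors are principal-component scores over voxels
(``Sigma V^T`` rows), standardized to unit row variance before ICA so the
unit-variance source convention holds.  All projection operators are stored
so that subject-level mixing matrices can be back-reconstructed by
partitioning the group mixing matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SubjectStack",
    "GroupICAResult",
    "fit_group_ica",
    "initial_unmixing_candidates",
    "ReductionResult",
    "demean",
    "subject_reduce",
    "group_reduce",
    "reduce_stack",
    "initialize_unmixing",
    "backreconstruct_mixing",
]


@dataclass
class SubjectStack:
    """Per-subject ``T x V`` matrices sharing a common voxel dimension."""

    matrices: list

    def __post_init__(self):
        mats = [np.asarray(m, dtype=float) for m in self.matrices]
        if not mats:
            raise ValueError("need at least one subject")
        V = mats[0].shape[1]
        for i, m in enumerate(mats):
            if m.ndim != 2 or m.shape[1] != V:
                raise ValueError(f"subject {i} matrix must be T x {V}")
            if m.shape[0] < 2:
                raise ValueError(f"subject {i} needs at least 2 rows")
        self.matrices = mats

    @property
    def n_subjects(self) -> int:
        return len(self.matrices)

    @property
    def n_voxels(self) -> int:
        return self.matrices[0].shape[1]

    @property
    def n_timepoints(self) -> list:
        return [m.shape[0] for m in self.matrices]


@dataclass
class ReductionResult:
    """Stored operators of the two-stage reduction.

    ``reduced`` is the ``Q x V`` matrix handed to ICA (unit-variance rows).
    ``subject_bases[i]`` (``T_i x R``) and ``group_basis`` (``RI x Q``) have
    orthonormal columns; ``row_scales`` holds the standard deviations divided
    out of the group scores.
    """

    reduced: np.ndarray
    subject_bases: list
    subject_svals: list
    group_basis: np.ndarray
    group_svals: np.ndarray
    row_scales: np.ndarray
    subject_rank: int
    group_rank: int
    row_means: list = field(default_factory=list)

    @property
    def subject_projections(self) -> list:
        """Row-orthonormal R x T operators mapping subject data to scores."""
        return [U.T for U in self.subject_bases]

    @property
    def group_projection(self) -> np.ndarray:
        """Row-orthonormal Q x RI operator mapping the stack to group scores."""
        return self.group_basis.T


def demean(X):
    """Remove row means; returns ``(X_centered, offsets)``."""
    X = np.asarray(X, dtype=float)
    offsets = X.mean(axis=1, keepdims=True)
    return X - offsets, offsets.ravel()


def _signed_svd(X):
    """Economy SVD with a deterministic sign convention: the largest-|entry|
    element of each left singular vector is made positive."""
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    for k in range(U.shape[1]):
        j = np.argmax(np.abs(U[:, k]))
        if U[j, k] < 0:
            U[:, k] = -U[:, k]
            Vt[k] = -Vt[k]
    return U, s, Vt


def subject_reduce(X_i, R: int):
    """Retain the top-R temporal SVD structure of one subject.

    Returns ``(scores, basis, svals)`` where ``scores = Sigma_R V_R^T``
    (``R x V`` principal-component scores over voxels) and ``basis`` is the
    ``T x R`` orthonormal temporal basis; ``basis @ scores`` is the best
    rank-R approximation of ``X_i``.
    """
    X_i = np.asarray(X_i, dtype=float)
    T, V = X_i.shape
    if not 1 <= R <= min(T, V):
        raise ValueError(f"R={R} out of range for a {T} x {V} matrix")
    U, s, Vt = _signed_svd(X_i)
    return s[:R, None] * Vt[:R], U[:, :R], s


def group_reduce(stacked, Q: int):
    """Retain the top-Q SVD structure of the stacked ``RI x V`` matrix.

    Returns ``(reduced, basis, svals, row_scales)``: ``reduced`` is
    ``Sigma_Q V_Q^T`` with rows standardized to unit variance and
    ``row_scales`` the divided-out standard deviations.
    """
    stacked = np.asarray(stacked, dtype=float)
    RI, V = stacked.shape
    if not 1 <= Q <= min(RI, V):
        raise ValueError(f"Q={Q} out of range for a {RI} x {V} matrix")
    U, s, Vt = _signed_svd(stacked)
    Z = s[:Q, None] * Vt[:Q]
    scales = Z.std(axis=1)
    if np.any(scales < 1e-14):
        raise ValueError("a retained group component has zero variance")
    return Z / scales[:, None], U[:, :Q], s, scales


def default_subject_rank(T: int, Q: int) -> int:
    """Default R = 2Q when the scan length allows, else R = T."""
    return min(T, 2 * Q)


def reduce_stack(stack: SubjectStack, Q: int, R: int | None = None) -> ReductionResult:
    """Demean and two-stage-reduce a subject stack to a ``Q x V`` matrix."""
    if R is None:
        R = default_subject_rank(min(stack.n_timepoints), Q)
    scores, bases, svals, means = [], [], [], []
    for X_i in stack.matrices:
        Xc, mu = demean(X_i)
        sc, U, s = subject_reduce(Xc, R)
        scores.append(sc)
        bases.append(U)
        svals.append(s)
        means.append(mu)
    stacked = np.vstack(scores)
    reduced, Ug, sg, scales = group_reduce(stacked, Q)
    return ReductionResult(
        reduced=reduced, subject_bases=bases, subject_svals=svals,
        group_basis=Ug, group_svals=sg, row_scales=scales,
        subject_rank=R, group_rank=Q, row_means=means,
    )


def initialize_unmixing(reduction, Q: int | None = None, jitter: float = 1e-6) -> np.ndarray:
    """Deterministic starting unmixing matrix in the reduced Q x Q space.

    The reduced matrix already consists of the population-value-decomposition
    scores (the rows of ``U Sigma`` mapped through the stored projections,
    standardized), so those scores themselves serve as the starting sources:
    the identity is the corresponding unmixing matrix.  A diagonal jitter
    fallback guards the (impossible for the identity) singular case.

    Accepts either a :class:`ReductionResult` or a :class:`SubjectStack`
    together with ``Q`` (the stack is then reduced with default ranks).
    """
    if isinstance(reduction, SubjectStack):
        if Q is None:
            raise ValueError("Q is required when passing a SubjectStack")
        reduction = reduce_stack(reduction, Q)
    Q = reduction.group_rank
    B0 = np.eye(Q)
    if abs(np.linalg.det(B0)) == 0:  # pragma: no cover - defensive
        B0 += jitter * np.eye(Q)
    return B0


def initial_unmixing_candidates(reduction: ReductionResult, obliques=(0.2, 0.4)) -> list:
    """Deterministic starting points for a multi-start group ICA run.

    The profile likelihood over the unmixing matrix can be multimodal when
    sources share strong between-region structure: the PVD scores themselves
    (identity start) sit in a basin where one component absorbs all the
    shared structure.  Oblique starts — every row loaded on the leading
    score with a small distinct admixture, ``B0 = 1 e_1^T + eps I`` — mimic
    raw-observation coordinates and reach the complementary basin.  The
    caller runs the full algorithm from each start and keeps the solution
    with the highest final log-likelihood.
    """
    Q = reduction.group_rank
    out = [initialize_unmixing(reduction)]
    for eps in obliques:
        B = np.zeros((Q, Q))
        B[:, 0] = 1.0
        B += eps * np.eye(Q)
        out.append(B)
    return out


@dataclass
class GroupICAResult:
    """A fitted group decomposition: ICA state, reduction operators and
    back-reconstructed per-subject mixing matrices."""

    state: object
    reduction: ReductionResult
    subject_mixing: list


def fit_group_ica(stack: SubjectStack, Q: int, R: int | None = None, config=None,
                  parcellation=None, multistart: bool = True) -> GroupICAResult:
    """Two-stage reduction, (multi-start) ICA and back-reconstruction."""
    from .ica_core import DegenerateComponentError, StepFailureError, run_ica
    from .pspline_density import FitConvergenceError

    reduction = reduce_stack(stack, Q, R)
    candidates = (initial_unmixing_candidates(reduction) if multistart
                  else [initialize_unmixing(reduction)])
    best = None
    failures = []
    for B0 in candidates:
        try:
            state = run_ica(reduction.reduced, config, parcellation=parcellation, B0=B0)
        except (StepFailureError, FitConvergenceError, DegenerateComponentError) as exc:
            failures.append(exc)
            continue
        if best is None or state.loglik_trace[-1] > best.loglik_trace[-1]:
            best = state
    if best is None:
        raise failures[-1]
    return GroupICAResult(state=best, reduction=reduction,
                          subject_mixing=backreconstruct_mixing(
                              np.linalg.inv(best.B), reduction))


def backreconstruct_mixing(A_group, reduction: ReductionResult) -> list:
    """Subject-level mixing matrices from the group-level mixing matrix.

    Chains the stored operators: ``X_i ~= U_i W_i diag(scales) A_group S``
    where ``W_i`` is subject i's block of rows of the group basis, so
    ``A_i = U_i W_i diag(scales) A_group`` maps the common sources to an
    approximation of subject i's data, with error bounded by the two SVD
    truncation residuals.
    """
    A_group = np.asarray(A_group, dtype=float)
    Q = reduction.group_rank
    if A_group.shape != (Q, Q):
        raise ValueError(f"group mixing matrix must be {Q} x {Q}")
    R = reduction.subject_rank
    out = []
    for i, U_i in enumerate(reduction.subject_bases):
        W_i = reduction.group_basis[i * R:(i + 1) * R]  # R x Q block
        out.append(U_i @ W_i @ (reduction.row_scales[:, None] * A_group))
    return out
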