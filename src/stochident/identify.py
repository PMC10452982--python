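"""Sensitivity-based practical identifiability analysis.

Starting from estimates S_ik(t_l) = dE[X_i(t_l)]/dc_k and the mean
trajectory E[X_i(t_l)], the analysis proceeds through

1. the concatenated non-dimensional sensitivity matrix with entries
   s_ik(t_l) = c_k / E[X_i(t_l)] * S_ik(t_l), one row per (time point,
   species), rows with vanishing means masked and the all-zero t = 0 block
   dropped;
2. the parameter-importance measure delta_k^msqr, the root-mean-square of
   column k of that (un-normalized) matrix;
3. unit-normalized columns, whose subset Gram matrices give the collinearity
   index CI_K = 1 / sqrt(lambda_min); a subset is treated as practically
   identifiable when every member is important (delta above threshold) and
   CI_K does not exceed a critical value, conventionally 20;
4. the singular spectrum and numerical rank of the matrix (the number of
   non-collinear parameters), and the determinant measure
   rho_K = det(S_K^T S_K)^(1/2k) for comparing candidate subsets.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .network import ModelConfigError, _as_param_vector

__all__ = [
    "ConcatenatedSensitivity",
    "NormalizedSensitivityMatrix",
    "SubsetResult",
    "IdentifiabilityReport",
    "build_concatenated",
    "delta_msqr",
    "normalize_columns",
    "collinearity_index",
    "svd_spectrum",
    "determinant_measure",
    "select_identifiable_subsets",
    "DELTA_THRESHOLD",
    "CI_THRESHOLD",
]

DELTA_THRESHOLD = 0.2
CI_THRESHOLD = 20.0
MAX_SUBSET_BUDGET = 100_000


class EmptyMatrixError(ModelConfigError):
    """Every row of the concatenated sensitivity matrix was masked."""


@dataclass
class ConcatenatedSensitivity:
    matrix: np.ndarray                  # n_rows x P
    row_index: list                     # (time, species-index) per row
    mask_log: list = field(default_factory=list)

    @property
    def n_rows(self):
        return self.matrix.shape[0]

    @property
    def n_params(self):
        return self.matrix.shape[1]


@dataclass
class NormalizedSensitivityMatrix:
    matrix: np.ndarray                  # n_rows x P, unit columns
    zero_columns: frozenset             # flagged parameter indices
    column_norms: np.ndarray            # raw norms before normalization


@dataclass
class SubsetResult:
    indices: tuple
    ci: float | None                    # None -> undefined (flagged column)
    rho: float | None
    identifiable: bool


@dataclass
class IdentifiabilityReport:
    delta: np.ndarray
    ranked_params: list                 # indices with delta > threshold, desc.
    subsets: list                       # SubsetResult, ordered by (size, CI)
    singular_values: np.ndarray
    rank: int
    delta_threshold: float
    ci_threshold: float
    warnings: list = field(default_factory=list)


def build_concatenated(sens, means, c, mask_tol=None, observed=None):
    """Assemble the non-dimensional concatenated sensitivity matrix.

    ``sens`` is an L x N x P array (or an object with a ``.values`` /
    ``.sens`` attribute of that shape), ``means`` an L x N array (or object
    with ``.means`` / ``.states``) on the same grid. Rows with
    E[X_i(t_l)] <= mask_tol are dropped (and logged), as is the t = 0 block,
    whose sensitivities vanish identically. ``observed`` optionally restricts
    rows to a subset of species indices (what is measured determines what is
    identifiable).
    """
    grid = getattr(sens, "grid", None)
    S = np.asarray(getattr(sens, "values", getattr(sens, "sens", sens)), float)
    Xm = np.asarray(getattr(means, "means", getattr(means, "states", means)), float)
    cv = _as_param_vector(c)
    if S.ndim != 3:
        raise ModelConfigError("sensitivity array must be L x N x P")
    L, N, P = S.shape
    if Xm.shape != (L, N):
        raise ModelConfigError(
            f"means have shape {Xm.shape}, expected {(L, N)}")
    if cv.size != P:
        raise ModelConfigError(
            f"{cv.size} parameters for a sensitivity tensor with P = {P}")
    if mask_tol is None:
        mask_tol = 1e-8 * max(float(np.max(Xm)), 1.0)
    species = range(N) if observed is None else list(observed)
    times = np.asarray(grid, float) if grid is not None else np.arange(L, dtype=float)
    rows, index, mask_log = [], [], []
    for l in range(L):
        if times[l] == 0.0:
            continue  # S(0) = 0 identically: no information
        for i in species:
            if Xm[l, i] <= mask_tol:
                mask_log.append((float(times[l]), int(i),
                                 f"mean {Xm[l, i]:.3g} <= mask_tol {mask_tol:.3g}"))
                continue
            rows.append(cv / Xm[l, i] * S[l, i, :])
            index.append((float(times[l]), int(i)))
    if not rows:
        raise EmptyMatrixError("all rows were masked; nothing to analyse")
    mat = np.asarray(rows)
    if not np.all(np.isfinite(mat)):
        raise ModelConfigError("non-finite entries in the sensitivity matrix")
    return ConcatenatedSensitivity(mat, index, mask_log)


def _matrix(s):
    return s.matrix if isinstance(s, (ConcatenatedSensitivity,
                                      NormalizedSensitivityMatrix)) else np.asarray(s, float)


def delta_msqr(s):
    """Root-mean-square of each column of the un-normalized matrix."""
    m = _matrix(s)
    if m.shape[0] < 1:
        raise ModelConfigError("empty sensitivity matrix")
    return np.sqrt((m ** 2).mean(axis=0))


def normalize_columns(s, zero_tol=None):
    """Scale every column to unit Euclidean norm; flag degenerate columns.

    Columns whose raw norm is <= ``zero_tol`` (default: 1e-12 times the
    largest column norm, floored at 1e-300) are left unnormalized and
    flagged: any collinearity index over a subset containing them is
    undefined rather than numeric.
    """
    m = _matrix(s).copy()
    norms = np.linalg.norm(m, axis=0)
    if zero_tol is None:
        zero_tol = max(1e-12 * (norms.max() if norms.size else 0.0), 1e-300)
    flagged = frozenset(int(k) for k in np.nonzero(norms <= zero_tol)[0])
    for k in range(m.shape[1]):
        if k not in flagged:
            m[:, k] /= norms[k]
    return NormalizedSensitivityMatrix(m, flagged, norms)


def collinearity_index(normalized, subset):
    """CI_K = 1 / sqrt(lambda_min(S~_K^T S~_K)) over unit-norm columns.

    Returns None when the subset touches a flagged (zero) column, and
    ``math.inf`` when the smallest eigenvalue is at machine level (exactly
    collinear columns).
    """
    idx = tuple(int(k) for k in (subset.indices if isinstance(subset, SubsetResult)
                                 else subset))
    if len(set(idx)) != len(idx):
        raise ModelConfigError(f"subset {idx} has repeated indices")
    if len(idx) < 2:
        raise ModelConfigError("collinearity needs a subset of >= 2 parameters")
    if isinstance(normalized, NormalizedSensitivityMatrix):
        if set(idx) & normalized.zero_columns:
            return None
        m = normalized.matrix
    else:
        m = np.asarray(normalized, float)
    sub = m[:, idx]
    lam = float(np.linalg.eigvalsh(sub.T @ sub)[0])
    if lam <= len(idx) * np.finfo(float).eps:
        return math.inf
    return 1.0 / math.sqrt(lam)


def svd_spectrum(s, rank_tol=None):
    """Descending singular values and the numerical rank of the matrix."""
    m = _matrix(s)
    if m.size == 0:
        raise ModelConfigError("empty matrix")
    sv = np.linalg.svd(m, compute_uv=False)
    if rank_tol is None:
        rank_tol = max(m.shape) * np.finfo(float).eps
    rank = int(np.sum(sv > rank_tol * sv[0])) if sv.size and sv[0] > 0 else 0
    return sv, rank


def determinant_measure(s_k):
    """rho_K = det(S_K^T S_K)^(1/(2k)); 0 for a singular Gram matrix."""
    m = np.asarray(_matrix(s_k), float)
    k = m.shape[1]
    if k < 1:
        raise ModelConfigError("determinant measure needs >= 1 column")
    sign, logdet = np.linalg.slogdet(m.T @ m)
    if sign <= 0:
        return 0.0
    return float(np.exp(logdet / (2 * k)))


def select_identifiable_subsets(normalized, delta, delta_threshold=DELTA_THRESHOLD,
                                ci_threshold=CI_THRESHOLD, max_subset_size=None,
                                rank_tol=None, raw=None, candidates="all"):
    """Rank parameters by importance, then score every candidate subset.

    Parameters with delta <= ``delta_threshold`` are considered too weak to
    estimate and are excluded from the ranking. Collinearity indices are
    tabulated for every subset with 2 <= k <= ``max_subset_size`` (with
    ``candidates="ranked"`` only subsets of the ranked list are enumerated);
    a subset is flagged identifiable iff its CI is defined, CI <=
    ``ci_threshold`` and every member clears the importance threshold.
    Subset enumeration is guarded by a combinatorial budget. When ``raw``
    (the un-normalized non-dimensional matrix) is given, the reported
    singular spectrum and rank are taken from it; otherwise from the
    normalized matrix.
    """
    delta = np.asarray(delta, float)
    P = delta.size
    if isinstance(normalized, ConcatenatedSensitivity) or (
            not isinstance(normalized, NormalizedSensitivityMatrix)):
        normalized = normalize_columns(normalized)
    if normalized.matrix.shape[1] != P:
        raise ModelConfigError("delta and matrix disagree on parameter count")
    sv, rank = svd_spectrum(raw if raw is not None else normalized.matrix,
                            rank_tol)
    warnings = []
    ranked = sorted((k for k in range(P) if delta[k] > delta_threshold),
                    key=lambda k: -delta[k])
    pool = ranked if candidates == "ranked" else list(range(P))
    subsets = []
    if not ranked:
        warnings.append("no parameter exceeds the importance threshold; "
                        "nothing is identifiable at this scale")
    if len(pool) >= 2 and ranked:
        kmax = len(pool) if max_subset_size is None else \
            min(max_subset_size, len(pool))
        total = sum(math.comb(len(pool), k) for k in range(2, kmax + 1))
        if total > MAX_SUBSET_BUDGET:
            raise ModelConfigError(
                f"{total} candidate subsets exceed the enumeration budget "
                f"({MAX_SUBSET_BUDGET}); restrict max_subset_size")
        ranked_set = set(ranked)
        for k in range(2, kmax + 1):
            for combo in itertools.combinations(sorted(pool), k):
                ci = collinearity_index(normalized, combo)
                rho = None
                if not (set(combo) & normalized.zero_columns):
                    rho = determinant_measure(normalized.matrix[:, combo])
                ident = (ci is not None and ci <= ci_threshold
                         and set(combo) <= ranked_set)
                subsets.append(SubsetResult(combo, ci, rho, ident))
        subsets.sort(key=lambda s: (len(s.indices),
                                    s.ci if s.ci is not None else math.inf))
    return IdentifiabilityReport(delta, ranked, subsets, sv, rank,
                                 delta_threshold, ci_threshold, warnings)
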