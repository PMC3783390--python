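"""Binary support matrices and their spectral (Perron-Frobenius) analysis.

A society is a set of occupations linked by directed *support*: entry
``c_ij = 1`` of the support matrix ``C`` means occupation ``j`` supports
occupation ``i``.  A standalone ("legal") society must be irreducible, i.e.
its support digraph strongly connected, so that every occupation is supported
-- directly or through intermediaries -- by every other.  The Perron-Frobenius
theorem then guarantees a unique positive eigenvector of ``C``; the
equilibrium productivity profile of the society is that eigenvector, scaled so
that total productivity equals ``(a/b) * lambda_pf`` where ``a`` is the
supporting coefficient, ``b`` the environmental restriction coefficient and
``lambda_pf`` the spectral radius of ``C``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

ORIGINAL = "original"
DERIVED = "derived"
INVADER = "invader"
SOCIETY_LABELS = (ORIGINAL, DERIVED, INVADER)

DEFAULT_MAX_ATTEMPTS = 1000


class ConvergenceError(RuntimeError):
    """Raised when an iterative eigenvalue computation fails to converge."""


class IrreducibilityError(RuntimeError):
    """Raised when rejection sampling cannot produce an irreducible matrix."""


def _as_array(C) -> np.ndarray:
    """Accept a SupportMatrix or array-like and return a 2-D float ndarray."""
    if isinstance(C, SupportMatrix):
        return C.C
    A = np.asarray(C, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {A.shape}")
    return A


@dataclass
class EigenResult:
    """Spectral radius and the associated sum-1 nonnegative eigenvector."""

    lambda_pf: float
    perron_vector: np.ndarray

    def __iter__(self):
        return iter((self.lambda_pf, self.perron_vector))


@dataclass
class InterSocietySpec:
    """Block sizes and block-wise support probabilities for up to three societies.

    ``p_c_xy`` is the probability that an occupation of society *x* supports an
    occupation of society *y* (so it fills the block with rows in *y* and
    columns in *x*).  Probabilities above 1 are capped to 1 with a warning.
    """

    n_o: int
    p_c_oo: float
    n_d: int = 0
    n_i: int = 0
    p_c_od: float = 0.0
    p_c_do: float = 0.0
    p_c_dd: float = 0.0
    p_c_ii: float = 0.0

    def __post_init__(self):
        for name in ("n_o", "n_d", "n_i"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative, got {getattr(self, name)}")
        if self.n_o < 1:
            raise ValueError("n_o must be at least 1")
        for name in ("p_c_oo", "p_c_od", "p_c_do", "p_c_dd", "p_c_ii"):
            p = getattr(self, name)
            if p < 0:
                raise ValueError(f"{name} must be nonnegative, got {p}")
            if p > 1:
                warnings.warn(
                    f"{name}={p} exceeds 1; capping to 1.0", UserWarning, stacklevel=2
                )
                setattr(self, name, 1.0)

    @property
    def n_total(self) -> int:
        return self.n_o + self.n_d + self.n_i


@dataclass
class SupportMatrix:
    """Binary directed support structure with per-occupation society labels."""

    C: np.ndarray
    labels: np.ndarray = None
    gen_params: dict = field(default_factory=dict)

    def __post_init__(self):
        self.C = np.asarray(self.C, dtype=float)
        if self.C.ndim != 2 or self.C.shape[0] != self.C.shape[1]:
            raise ValueError(f"support matrix must be square, got shape {self.C.shape}")
        if not np.all((self.C == 0) | (self.C == 1)):
            raise ValueError("support matrix entries must be 0 or 1")
        if self.labels is None:
            self.labels = np.full(self.n, ORIGINAL, dtype=object)
        else:
            self.labels = np.asarray(self.labels, dtype=object)
            if self.labels.shape != (self.n,):
                raise ValueError("labels must have one entry per occupation")
            bad = set(self.labels) - set(SOCIETY_LABELS)
            if bad:
                raise ValueError(f"unknown society labels: {sorted(bad)}")

    @property
    def n(self) -> int:
        return self.C.shape[0]

    @property
    def societies(self) -> list[str]:
        """Labels present, in canonical original/derived/invader order."""
        present = set(self.labels)
        return [s for s in SOCIETY_LABELS if s in present]

    def indices_of(self, label: str) -> np.ndarray:
        return np.flatnonzero(self.labels == label)

    def submatrix(self, indices) -> np.ndarray:
        idx = np.asarray(indices)
        return self.C[np.ix_(idx, idx)]


def is_irreducible(C) -> bool:
    """True iff the support digraph (edge j -> i for c_ij = 1) is strongly connected.

    A 1x1 matrix is irreducible iff its entry is 1 (a self-supporting
    occupation is a legal singleton society; an unsupported one is not).
    """
    A = _as_array(C)
    n = A.shape[0]
    if n == 0:
        raise ValueError("empty matrix has no irreducibility status")
    if n == 1:
        return bool(A[0, 0] != 0)
    ncomp, _ = connected_components(csr_matrix(A != 0), directed=True, connection="strong")
    return bool(ncomp == 1)


def spectral_radius_and_perron(
    C, tol: float = 1e-13, max_iter: int = 20_000
) -> EigenResult:
    """Spectral radius and sum-1 Perron vector of a nonnegative square matrix.

    Power iteration on ``C + I``: the unit diagonal shift makes any irreducible
    matrix primitive (so periodic structures such as 2-cycles converge) and
    shifts every eigenvalue by exactly +1, which is removed from the result.
    On irreducible input the vector is strictly positive.  Reducible input can
    make the dominant eigenvalue defective and the iteration stall; in that
    case the spectral radius is taken from a dense eigendecomposition and the
    last power iterate is returned as the (nonnegative) direction.
    """
    A = _as_array(C)
    n = A.shape[0]
    if n == 0:
        raise ValueError("cannot compute spectral radius of an empty matrix")
    if np.any(A < 0):
        raise ValueError("matrix must be nonnegative")
    v = np.full(n, 1.0 / n)
    lam_shifted = 1.0
    for _ in range(max_iter):
        w = A @ v + v
        s = w.sum()
        if s == 0:  # can only happen for the zero matrix with v -> 0, not here
            return EigenResult(0.0, np.full(n, 1.0 / n))
        w /= s
        if abs(s - lam_shifted) < tol and np.max(np.abs(w - v)) < tol:
            return EigenResult(max(s - 1.0, 0.0), w)
        v, lam_shifted = w, s
    lam = float(np.max(np.abs(np.linalg.eigvals(A))))
    return EigenResult(lam, v)


def equilibrium_productivity(C_active, a: float, b: float) -> np.ndarray:
    """Closed-form equilibrium productivity of an irreducible support structure.

    ``x* = X* v`` with ``v`` the sum-1 Perron vector and the total constrained
    to ``X* = (a/b) * lambda_pf``.  Only the ratio ``a/b`` matters.
    """
    if a <= 0 or b <= 0:
        raise ValueError("supporting and restriction coefficients must be positive")
    A = _as_array(C_active)
    if not is_irreducible(A):
        raise ValueError(
            "equilibrium_productivity requires an irreducible support matrix; "
            "use dynamics.develop for reducible structures"
        )
    lam, v = spectral_radius_and_perron(A)
    return (a / b) * lam * v


def average_reserve(x, limina: float) -> float:
    """Mean productivity of active occupations minus the functioning threshold.

    The surplus each functioning occupation holds on average above ``limina``;
    negative values flag a society at risk.
    """
    x = np.asarray(x, dtype=float)
    active = x > 0
    if x.size == 0 or not active.any():
        raise ValueError("no active occupations: average reserve undefined")
    return float(x[active].mean() - limina)


def wipeout_threshold(X: float, n0: int, limina: float) -> float:
    """Critical pulse severity wiping out a uniformly distributed society.

    With ``n0`` occupations sharing total productivity ``X`` uniformly, a pulse
    of severity ``r_d`` scales each equilibrium productivity to ``X/(n0 r_d)``;
    the whole society falls below ``limina`` exactly when
    ``r_d > r* = X / (n0 * limina)``.
    """
    if X <= 0 or n0 < 1 or limina <= 0:
        raise ValueError("wipeout_threshold requires X > 0, n0 >= 1, limina > 0")
    return X / (n0 * limina)


# ---------------------------------------------------------------------------
# generation


def _bernoulli(n_rows: int, n_cols: int, p: float, rng: np.random.Generator) -> np.ndarray:
    return (rng.random((n_rows, n_cols)) < p).astype(float)


def generate_support_matrix(
    n: int,
    p_c: float,
    rng: np.random.Generator,
    require_irreducible: bool = True,
    ensure_self_supporter: bool = False,
    max_attempts: int = DEFAULT_MAX_ATTEMPTS,
) -> SupportMatrix:
    """Random binary support matrix with i.i.d. Bernoulli(p_c) entries.

    When ``require_irreducible`` is set the draw is repeated (rejection
    sampling) until the matrix is irreducible; failure after ``max_attempts``
    draws signals that ``p_c`` is too small for ``n``.  When
    ``ensure_self_supporter`` is set and no diagonal entry came up 1, one
    randomly chosen diagonal entry is forced to 1 (so a self-boot seed exists).
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    if not 0 <= p_c <= 1:
        raise ValueError(f"p_c must be in [0, 1], got {p_c}")
    rng = np.random.default_rng(rng)
    for _ in range(max_attempts):
        C = _bernoulli(n, n, p_c, rng)
        if ensure_self_supporter and not np.any(np.diag(C)):
            i = rng.integers(n)
            C[i, i] = 1.0
        if not require_irreducible or is_irreducible(C):
            return SupportMatrix(C, gen_params={"n": n, "p_c": p_c})
    raise IrreducibilityError(
        f"no irreducible matrix found in {max_attempts} attempts "
        f"(n={n}, p_c={p_c}): p_c is likely too small for this n"
    )


def generate_two_society_matrix(
    spec: InterSocietySpec,
    rng: np.random.Generator,
    max_attempts: int = DEFAULT_MAX_ATTEMPTS,
) -> SupportMatrix:
    """Block-structured support matrix for original / derived / invader societies.

    The original block is drawn irreducible (a legal society).  The derived
    block need not be irreducible; it is coupled to the original block by
    ``p_c_od`` (original supports derived) and ``p_c_do`` (derived supports
    original).  The invader block, when present, is drawn irreducible and has
    no cross-support with the others (competition).
    """
    rng = np.random.default_rng(rng)
    n = spec.n_total
    C = np.zeros((n, n))
    o = slice(0, spec.n_o)
    d = slice(spec.n_o, spec.n_o + spec.n_d)
    i = slice(spec.n_o + spec.n_d, n)

    C[o, o] = generate_support_matrix(
        spec.n_o, spec.p_c_oo, rng, require_irreducible=True, max_attempts=max_attempts
    ).C
    if spec.n_d:
        # rows = supported society, cols = supporting society
        C[d, o] = _bernoulli(spec.n_d, spec.n_o, spec.p_c_od, rng)
        C[o, d] = _bernoulli(spec.n_o, spec.n_d, spec.p_c_do, rng)
        C[d, d] = _bernoulli(spec.n_d, spec.n_d, spec.p_c_dd, rng)
    if spec.n_i:
        C[i, i] = generate_support_matrix(
            spec.n_i, spec.p_c_ii, rng, require_irreducible=True, max_attempts=max_attempts
        ).C

    labels = np.array(
        [ORIGINAL] * spec.n_o + [DERIVED] * spec.n_d + [INVADER] * spec.n_i,
        dtype=object,
    )
    return SupportMatrix(C, labels=labels, gen_params=vars(spec).copy())


# ---------------------------------------------------------------------------
# I/O: dense adjacency CSV, edge-list TSV, label companion CSV


def write_adjacency_csv(sm: SupportMatrix, path) -> None:
    ids = [f"occ{i}" for i in range(sm.n)]
    pd.DataFrame(sm.C.astype(int), index=ids, columns=ids).to_csv(path)


def read_adjacency_csv(path, labels_path=None) -> SupportMatrix:
    df = pd.read_csv(path, index_col=0)
    labels = read_labels_csv(labels_path) if labels_path else None
    return SupportMatrix(df.to_numpy(dtype=float), labels=labels)


def write_edge_list(sm: SupportMatrix, path) -> None:
    """Two-column TSV ``supporter<TAB>supported`` (one row per c_ij = 1)."""
    supported, supporter = np.nonzero(sm.C)
    pd.DataFrame({"supporter": supporter, "supported": supported}).to_csv(
        path, sep="\t", index=False
    )


def read_edge_list(path, n: int = None, labels=None) -> SupportMatrix:
    df = pd.read_csv(path, sep="\t")
    if n is None:
        n = int(max(df["supporter"].max(), df["supported"].max())) + 1 if len(df) else 0
    C = np.zeros((n, n))
    C[df["supported"].to_numpy(), df["supporter"].to_numpy()] = 1.0
    return SupportMatrix(C, labels=labels)


def write_labels_csv(sm: SupportMatrix, path) -> None:
    pd.DataFrame({"id": np.arange(sm.n), "label": sm.labels}).to_csv(path, index=False)


def read_labels_csv(path) -> np.ndarray:
    df = pd.read_csv(path).sort_values("id")
    return df["label"].to_numpy(dtype=object)
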