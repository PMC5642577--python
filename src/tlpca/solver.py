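"""Alternating eigen-based least-squares fit of the two-level bilinear model.

The model predicts a sample's bioactivity as

    w_i = sum_l b_l * ( sum_k a_k * x_{i,l,k} )

with one coefficient per physicochemical property (a_k, shared across
fragments) and one per fragment position (b_l, shared across properties).
Fitting alternates two exact linear least-squares half-steps: with B fixed,
the tensor collapses to an N x K property matrix F = X.B and A solves the
normal system (F'F) A = F'W; with A fixed it collapses to an N x L fragment
matrix H = X.A and B solves (H'H) B = H'W. Each normal system is inverted
through a symmetric eigendecomposition with small eigenvalues truncated,
which regularises the frequent near-collinearity of property scales.

The product form b_l * a_k is invariant under (A, B) -> (c*A, B/c); the fit
makes no attempt to pin this scale down (matching the original procedure),
so individual coefficient magnitudes are convention-dependent while
predictions and all derived analyses are not. ``normalize_model`` offers a
reporting convention that fixes ||B||_2 = sqrt(L).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .descriptors import FragmentTensor
from .exceptions import ConvergenceWarning, SingularSystemError, ValidationError

__all__ = [
    "SolverConfig",
    "CoefficientModel",
    "FitTrace",
    "collapse_to_property_matrix",
    "collapse_to_fragment_matrix",
    "solve_normal_system",
    "fit",
    "predict",
    "pearson_r",
    "q_residue",
    "normalize_model",
]

_MODEL_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class SolverConfig:
    """Tunable parameters of the alternating fit.

    epsilon
        Convergence threshold on |Q(n+1) - Q(n)|, where Q is the
        root-mean-square training residual after the fragment half-step
        of each cycle (pIC50 units).
    max_iterations
        Cap on full cycles; hitting it returns ``converged=False``.
    init_b
        Initial fragment coefficients: a scalar broadcast over all L
        positions (default 1.0 — all fragments start equally weighted)
        or an explicit length-L vector.
    inversion_rtol
        Relative eigenvalue cutoff for the pseudo-inverse: eigenvalues
        below ``inversion_rtol * largest`` are dropped.
    principal_energy
        Optional cumulative-eigenvalue fraction; when set, each normal
        solve keeps only the leading eigenpairs reaching that fraction
        of the spectrum (principal-component regularised inversion).
    seed
        Recorded for provenance; the fit itself is deterministic.
    """

    epsilon: float = 1e-6
    max_iterations: int = 500
    init_b: float | tuple[float, ...] = 1.0
    inversion_rtol: float = 1e-10
    principal_energy: float | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValidationError("epsilon must be positive")
        if self.max_iterations < 1:
            raise ValidationError("max_iterations must be >= 1")
        if self.principal_energy is not None and not (0 < self.principal_energy <= 1):
            raise ValidationError("principal_energy must lie in (0, 1]")


@dataclass
class CoefficientModel:
    """Fitted coefficient vectors with their axis labels and fit metadata."""

    A: np.ndarray
    B: np.ndarray
    property_names: tuple[str, ...]
    fragment_labels: tuple[str, ...]
    n_iterations: int | None = None
    converged: bool = True
    config: SolverConfig | None = None

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        self.B = np.asarray(self.B, dtype=float)
        self.property_names = tuple(self.property_names)
        self.fragment_labels = tuple(self.fragment_labels)
        if self.A.shape != (len(self.property_names),):
            raise ValidationError("A length does not match property_names")
        if self.B.shape != (len(self.fragment_labels),):
            raise ValidationError("B length does not match fragment_labels")
        if not (np.all(np.isfinite(self.A)) and np.all(np.isfinite(self.B))):
            raise ValidationError("coefficients contain non-finite values")

    def save(self, path: str | Path) -> None:
        payload = {
            "schema_version": _MODEL_SCHEMA_VERSION,
            "property_names": list(self.property_names),
            "fragment_labels": list(self.fragment_labels),
            "A": [float(f"{v:.17g}") for v in self.A],
            "B": [float(f"{v:.17g}") for v in self.B],
            "n_iterations": self.n_iterations,
            "converged": bool(self.converged),
            "config": asdict(self.config) if self.config is not None else None,
        }
        Path(path).write_text(json.dumps(payload, indent=1) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "CoefficientModel":
        payload = json.loads(Path(path).read_text())
        cfg = payload.get("config")
        if cfg is not None and "init_b" in cfg and isinstance(cfg["init_b"], list):
            cfg["init_b"] = tuple(cfg["init_b"])
        return cls(
            A=np.array(payload["A"], dtype=float),
            B=np.array(payload["B"], dtype=float),
            property_names=tuple(payload["property_names"]),
            fragment_labels=tuple(payload["fragment_labels"]),
            n_iterations=payload.get("n_iterations"),
            converged=bool(payload.get("converged", True)),
            config=SolverConfig(**cfg) if cfg is not None else None,
        )


@dataclass
class FitTrace:
    """Per-iteration convergence diagnostics.

    For each full cycle n: the Pearson correlation R and RMS residual Q of
    the training predictions after the property half-step (``r_a``,
    ``q_a``) and after the fragment half-step (``r_b``, ``q_b``).
    """

    r_a: list[float] = field(default_factory=list)
    q_a: list[float] = field(default_factory=list)
    r_b: list[float] = field(default_factory=list)
    q_b: list[float] = field(default_factory=list)

    def append(self, r_a: float, q_a: float, r_b: float, q_b: float) -> None:
        self.r_a.append(float(r_a))
        self.q_a.append(float(q_a))
        self.r_b.append(float(r_b))
        self.q_b.append(float(q_b))

    def __len__(self) -> int:
        return len(self.r_a)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "iteration": np.arange(1, len(self) + 1),
                "R_a": self.r_a,
                "Q_a": self.q_a,
                "R_b": self.r_b,
                "Q_b": self.q_b,
            }
        )

    def save(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def load(cls, path: str | Path) -> "FitTrace":
        frame = pd.read_csv(path)
        return cls(
            r_a=list(frame["R_a"]), q_a=list(frame["Q_a"]),
            r_b=list(frame["R_b"]), q_b=list(frame["Q_b"]),
        )


def _tensor_array(X: FragmentTensor | np.ndarray) -> np.ndarray:
    arr = X.X if isinstance(X, FragmentTensor) else np.asarray(X, dtype=float)
    if arr.ndim != 3:
        raise ValidationError(f"expected an N x L x K tensor, got ndim={arr.ndim}")
    return arr


def collapse_to_property_matrix(X: FragmentTensor | np.ndarray, B: np.ndarray) -> np.ndarray:
    """Contract the fragment axis: F[i, k] = sum_l B[l] * X[i, l, k]."""
    arr = _tensor_array(X)
    B = np.asarray(B, dtype=float)
    if B.shape != (arr.shape[1],):
        raise ValidationError(f"B has length {B.size}, tensor has {arr.shape[1]} fragments")
    return np.einsum("ilk,l->ik", arr, B)


def collapse_to_fragment_matrix(X: FragmentTensor | np.ndarray, A: np.ndarray) -> np.ndarray:
    """Contract the property axis: H[i, l] = sum_k A[k] * X[i, l, k].

    Row i holds the per-fragment activity contributions Delta-g of sample i
    under property coefficients A.
    """
    arr = _tensor_array(X)
    A = np.asarray(A, dtype=float)
    if A.shape != (arr.shape[2],):
        raise ValidationError(f"A has length {A.size}, tensor has {arr.shape[2]} properties")
    return np.einsum("ilk,k->il", arr, A)


def solve_normal_system(
    M: np.ndarray,
    rhs: np.ndarray,
    config: SolverConfig | None = None,
    symmetry_tol: float = 1e-8,
) -> np.ndarray:
    """Solve M x = rhs for symmetric PSD M via truncated eigendecomposition.

    The solution is Phi diag(1/beta) Phi' rhs over the eigenpairs kept by
    ``config.inversion_rtol`` (relative to the largest eigenvalue) and, when
    set, the ``config.principal_energy`` cumulative-spectrum cutoff.
    """
    config = config or SolverConfig()
    M = np.asarray(M, dtype=float)
    rhs = np.asarray(rhs, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValidationError(f"M must be square, got shape {M.shape}")
    if rhs.shape != (M.shape[0],):
        raise ValidationError("rhs length does not match M")
    scale = np.max(np.abs(M)) or 1.0
    if np.max(np.abs(M - M.T)) > symmetry_tol * scale:
        raise ValidationError("M is not symmetric within tolerance")
    eigvals, eigvecs = np.linalg.eigh(M)
    eigvals, eigvecs = eigvals[::-1], eigvecs[:, ::-1]  # descending
    keep = eigvals > config.inversion_rtol * max(eigvals[0], 0.0)
    if config.principal_energy is not None:
        total = eigvals[keep].sum()
        if total > 0:
            cum = np.cumsum(np.where(keep, eigvals, 0.0)) / total
            keep &= np.arange(len(eigvals)) <= np.searchsorted(cum, config.principal_energy)
    if not np.any(keep):
        raise SingularSystemError(
            "all eigenvalues fall below the inversion cutoff; the normal system is singular"
        )
    vecs = eigvecs[:, keep]
    return vecs @ ((vecs.T @ rhs) / eigvals[keep])


def pearson_r(pred: np.ndarray, expt: np.ndarray) -> float:
    """Pearson product-moment correlation between two activity vectors."""
    pred = np.asarray(pred, dtype=float)
    expt = np.asarray(expt, dtype=float)
    if pred.shape != expt.shape:
        raise ValidationError("vectors have different lengths")
    if pred.size < 3:
        raise ValidationError("need at least 3 points for a correlation")
    if np.ptp(pred) == 0 or np.ptp(expt) == 0:
        raise ValidationError("correlation undefined for a constant vector")
    return float(stats.pearsonr(pred, expt).statistic)


def q_residue(pred: np.ndarray, expt: np.ndarray) -> float:
    """Root-mean-square residual sqrt(mean((expt - pred)^2))."""
    pred = np.asarray(pred, dtype=float)
    expt = np.asarray(expt, dtype=float)
    if pred.shape != expt.shape:
        raise ValidationError("vectors have different lengths")
    return float(np.sqrt(np.mean((expt - pred) ** 2)))


def fit(
    tensor: FragmentTensor,
    config: SolverConfig | None = None,
) -> tuple[CoefficientModel, FitTrace]:
    """Fit (A, B) on a tensor with activities by alternating least squares.

    Starts from the configured B (all-ones by default, treating every
    fragment as equally important), then cycles property and fragment
    half-steps until the RMS residual change drops below ``epsilon`` or
    ``max_iterations`` is reached. Returns the model and the full
    per-iteration trace of R and Q for both half-steps.
    """
    config = config or SolverConfig()
    if tensor.W is None:
        raise ValidationError("fitting requires a tensor with activities")
    N, L, K = tensor.shape
    if N <= max(K, L):
        warnings.warn(
            f"only {N} samples for {K} properties x {L} fragments; "
            "the fit is under-determined or weakly determined",
            UserWarning,
            stacklevel=2,
        )
    if np.isscalar(config.init_b):
        B = np.full(L, float(config.init_b))
    else:
        B = np.asarray(config.init_b, dtype=float)
        if B.shape != (L,):
            raise ValidationError(f"init_b has length {B.size}, tensor has {L} fragments")
    W = tensor.W
    trace = FitTrace()
    q_prev = np.inf
    converged = False
    n = 0
    for n in range(1, config.max_iterations + 1):
        try:
            F = collapse_to_property_matrix(tensor, B)
            A = solve_normal_system(F.T @ F, F.T @ W, config)
        except SingularSystemError as err:
            raise SingularSystemError(f"property half-step at iteration {n}: {err}") from err
        pred_a = F @ A
        r_a, q_a = pearson_r(pred_a, W), q_residue(pred_a, W)
        try:
            H = collapse_to_fragment_matrix(tensor, A)
            B = solve_normal_system(H.T @ H, H.T @ W, config)
        except SingularSystemError as err:
            raise SingularSystemError(f"fragment half-step at iteration {n}: {err}") from err
        pred_b = H @ B
        r_b, q_b = pearson_r(pred_b, W), q_residue(pred_b, W)
        trace.append(r_a, q_a, r_b, q_b)
        if abs(q_b - q_prev) <= config.epsilon:
            converged = True
            break
        q_prev = q_b
    if not converged:
        warnings.warn(
            f"alternating fit did not converge within {config.max_iterations} iterations "
            f"(last |dQ| = {abs(q_b - q_prev):.3g})",
            ConvergenceWarning,
            stacklevel=2,
        )
    model = CoefficientModel(
        A=A,
        B=B,
        property_names=tensor.property_names,
        fragment_labels=tensor.fragment_labels,
        n_iterations=n,
        converged=converged,
        config=config,
    )
    return model, trace


def predict(model: CoefficientModel, tensor: FragmentTensor) -> np.ndarray:
    """Predicted activities w_i = sum_l b_l sum_k a_k x_{i,l,k}.

    The tensor's property and fragment labels must match the model's in
    order; the model has no intercept, so a zero tensor predicts zero.
    """
    if tensor.property_names != model.property_names:
        raise ValidationError(
            "property labels differ from the model's: "
            f"{list(tensor.property_names)} vs {list(model.property_names)}"
        )
    if tensor.fragment_labels != model.fragment_labels:
        raise ValidationError(
            "fragment labels differ from the model's: "
            f"{list(tensor.fragment_labels)} vs {list(model.fragment_labels)}"
        )
    return collapse_to_fragment_matrix(tensor, model.A) @ model.B


def normalize_model(model: CoefficientModel) -> CoefficientModel:
    """Rescale to the reporting convention ||B||_2 = sqrt(L).

    Predictions are unchanged: the bilinear form is invariant under
    (A, B) -> (c*A, B/c).
    """
    L = len(model.fragment_labels)
    norm = float(np.linalg.norm(model.B))
    if norm == 0:
        raise ValidationError("cannot normalize a zero fragment-coefficient vector")
    c = norm / np.sqrt(L)
    return replace(model, A=model.A * c, B=model.B / c)
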