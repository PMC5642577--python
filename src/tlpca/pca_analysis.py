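"""Principal-component decomposition of the converged fit.

At convergence the collapsed matrices F (N x K, properties) and H (N x L,
fragments) summarise how the training samples occupy property space and
fragment space. Eigendecomposing their Gram matrices V = F'F and U = H'H
yields orthonormal eigenbases whose normalized eigenvalue shares say how
concentrated the data are, and eigenvalue-weighted squared loadings say how
much each individual property (gamma) or fragment position (lambda)
explains the modelled activity. Per-sample cosine projections onto the
eigenbases and the derived per-sample contributions localise those
statements to single molecules.

All quantities here are invariant under the bilinear model's coefficient
rescaling (A, B) -> (c*A, B/c): F and H scale uniformly, and normalized
shares and cosines are scale-free.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .descriptors import FragmentTensor
from .exceptions import ValidationError
from .solver import (
    CoefficientModel,
    collapse_to_fragment_matrix,
    collapse_to_property_matrix,
)

__all__ = [
    "EigenReport",
    "ContributionReport",
    "eigen_report",
    "property_contributions",
    "fragment_contributions",
    "sample_projections",
    "sample_contributions",
    "analyze_model",
    "report_table",
]

#: default cumulative-eigenvalue fraction defining the principal components
DEFAULT_ENERGY_THRESHOLD = 0.95


@dataclass
class EigenReport:
    """Sorted eigenstructure of one Gram matrix (property or fragment side).

    ``eigenvectors[:, k]`` is the unit eigenvector of the k-th largest
    eigenvalue; ``eigenvalues_normalized`` sums to 1; ``principal_count``
    is the smallest m whose leading normalized eigenvalues reach
    ``energy_threshold``. Eigenvector signs are fixed so each vector's
    largest-magnitude entry is positive, making reports reproducible.
    """

    side: str  # "property" | "fragment"
    labels: tuple[str, ...]
    eigenvalues_raw: np.ndarray
    eigenvalues_normalized: np.ndarray
    eigenvectors: np.ndarray  # columns, descending eigenvalue order
    principal_count: int
    energy_threshold: float

    @property
    def dim(self) -> int:
        return len(self.labels)


@dataclass
class ContributionReport:
    """Global and per-sample contribution tables for one fitted model."""

    per_property: pd.Series  # gamma, indexed by property name
    per_fragment: pd.Series  # lambda, indexed by fragment label
    property_projections: pd.DataFrame  # J_{i,k}: sample x eigenvector cosines
    fragment_projections: pd.DataFrame  # I_{i,l}
    property_sample_contributions: pd.DataFrame  # xi_{i,r}: sample x property
    fragment_sample_contributions: pd.DataFrame  # sigma_{i,r}: sample x fragment
    property_report: EigenReport
    fragment_report: EigenReport


def eigen_report(
    M: np.ndarray,
    labels: tuple[str, ...] | list[str],
    side: str = "property",
    energy_threshold: float = DEFAULT_ENERGY_THRESHOLD,
    symmetry_tol: float = 1e-8,
) -> EigenReport:
    """Eigendecompose a symmetric PSD Gram matrix into a sorted report."""
    if side not in ("property", "fragment"):
        raise ValidationError(f"side must be 'property' or 'fragment', got {side!r}")
    if not (0 < energy_threshold <= 1):
        raise ValidationError("energy_threshold must lie in (0, 1]")
    M = np.asarray(M, dtype=float)
    p = len(labels)
    if M.shape != (p, p):
        raise ValidationError(f"matrix shape {M.shape} does not match {p} labels")
    scale = np.max(np.abs(M)) or 1.0
    if np.max(np.abs(M - M.T)) > symmetry_tol * scale:
        raise ValidationError("matrix is not symmetric within tolerance")
    eigvals, eigvecs = np.linalg.eigh(M)
    eigvals, eigvecs = eigvals[::-1].copy(), eigvecs[:, ::-1].copy()
    eigvals = np.clip(eigvals, 0.0, None)  # round-off can dip slightly negative
    total = eigvals.sum()
    if total <= 0:
        raise ValidationError("matrix has no positive eigenvalues")
    # deterministic sign: largest-magnitude entry of each eigenvector positive
    for k in range(p):
        j = int(np.argmax(np.abs(eigvecs[:, k])))
        if eigvecs[j, k] < 0:
            eigvecs[:, k] = -eigvecs[:, k]
    normalized = eigvals / total
    principal = int(np.searchsorted(np.cumsum(normalized), energy_threshold) + 1)
    principal = min(principal, p)
    return EigenReport(
        side=side,
        labels=tuple(labels),
        eigenvalues_raw=eigvals,
        eigenvalues_normalized=normalized,
        eigenvectors=eigvecs,
        principal_count=principal,
        energy_threshold=float(energy_threshold),
    )


def _contributions(report: EigenReport) -> np.ndarray:
    """Eigenvalue-weighted squared loadings over the retained components."""
    m = report.principal_count
    return (report.eigenvectors[:, :m] ** 2) @ report.eigenvalues_normalized[:m]


def property_contributions(report: EigenReport) -> pd.Series:
    """Total contribution gamma_j of each property over the principal components.

    gamma_j = sum_{k <= K'} beta~_k * phi_{j,k}^2 with normalized
    eigenvalues beta~; the gammas sum to the retained normalized energy.
    """
    if report.side != "property":
        raise ValidationError("report is not from the property side")
    return pd.Series(_contributions(report), index=list(report.labels), name="gamma")


def fragment_contributions(report: EigenReport) -> pd.Series:
    """Total contribution lambda_j of each fragment position, analogous to gamma."""
    if report.side != "fragment":
        raise ValidationError("report is not from the fragment side")
    return pd.Series(_contributions(report), index=list(report.labels), name="lambda")


def sample_projections(rows: np.ndarray, report: EigenReport) -> np.ndarray:
    """Cosine of each sample row with each eigenvector.

    ``rows`` is the collapsed matrix (F for the property side, H for the
    fragment side); entry [i, k] is (row_i . phi_k) / (|row_i| |phi_k|),
    so each sample's projections satisfy sum_k J_{i,k}^2 = 1.
    """
    rows = np.asarray(rows, dtype=float)
    if rows.ndim != 2 or rows.shape[1] != report.dim:
        raise ValidationError(
            f"rows have shape {rows.shape}, expected (N, {report.dim})"
        )
    norms = np.linalg.norm(rows, axis=1)
    zero = np.nonzero(norms == 0)[0]
    if len(zero):
        raise ValidationError(f"sample row {zero[0]} has zero norm; cosine undefined")
    vec_norms = np.linalg.norm(report.eigenvectors, axis=0)
    return (rows @ report.eigenvectors) / norms[:, None] / vec_norms[None, :]


def sample_contributions(projections: np.ndarray, report: EigenReport) -> np.ndarray:
    """Per-sample, per-label contributions over the principal components.

    Entry [i, r] = sum_{k <= K'} beta~_k * J_{i,k} * phi_{r,k}^2: the part
    of sample i's placement in eigenspace attributable to property (or
    fragment) r.
    """
    projections = np.asarray(projections, dtype=float)
    if projections.ndim != 2 or projections.shape[1] != report.dim:
        raise ValidationError(
            f"projections have shape {projections.shape}, expected (N, {report.dim})"
        )
    m = report.principal_count
    weighted = projections[:, :m] * report.eigenvalues_normalized[:m]
    return weighted @ (report.eigenvectors[:, :m] ** 2).T


def analyze_model(
    model: CoefficientModel,
    tensor: FragmentTensor,
    energy_threshold: float = DEFAULT_ENERGY_THRESHOLD,
) -> ContributionReport:
    """Full eigen/contribution analysis of a fitted model on its training tensor."""
    F = collapse_to_property_matrix(tensor, model.B)
    H = collapse_to_fragment_matrix(tensor, model.A)
    prop_report = eigen_report(
        F.T @ F, model.property_names, "property", energy_threshold
    )
    frag_report = eigen_report(
        H.T @ H, model.fragment_labels, "fragment", energy_threshold
    )
    ids = list(tensor.sample_ids)
    J = sample_projections(F, prop_report)
    I = sample_projections(H, frag_report)
    eig_cols_p = [f"eigenvector-{k + 1}" for k in range(prop_report.dim)]
    eig_cols_f = [f"eigenvector-{k + 1}" for k in range(frag_report.dim)]
    return ContributionReport(
        per_property=property_contributions(prop_report),
        per_fragment=fragment_contributions(frag_report),
        property_projections=pd.DataFrame(J, index=ids, columns=eig_cols_p),
        fragment_projections=pd.DataFrame(I, index=ids, columns=eig_cols_f),
        property_sample_contributions=pd.DataFrame(
            sample_contributions(J, prop_report), index=ids, columns=list(model.property_names)
        ),
        fragment_sample_contributions=pd.DataFrame(
            sample_contributions(I, frag_report), index=ids, columns=list(model.fragment_labels)
        ),
        property_report=prop_report,
        fragment_report=frag_report,
    )


def report_table(report: EigenReport, contributions: pd.Series) -> pd.DataFrame:
    """Flat export table: ``index,eigenvalue_normalized,label,contribution``.

    Eigenvalues are listed in descending order; the contribution column is
    keyed by label (its own order), mirroring the side-by-side layout used
    for published eigenvalue/contribution summaries.
    """
    return pd.DataFrame(
        {
            "index": np.arange(1, report.dim + 1),
            "eigenvalue_normalized": report.eigenvalues_normalized,
            "label": list(contributions.index),
            "contribution": contributions.to_numpy(),
        }
    )
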