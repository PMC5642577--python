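"""Bundled HLA-A*0201 peptide benchmark and synthetic tensor generation.

The packaged benchmark is the published study of nonamer epitope peptides
binding the class I MHC allele HLA-A*0201: an 8-property x 20-residue
amino-acid scale table, 90 training peptides and 40 independent test
peptides with experimental pIC50 values (the printed model predictions are
kept alongside for cross-checking), and the published converged coefficient
vectors as a reference model. Values are stored verbatim as printed,
including their original irregular decimal precision.

The synthetic generator plants known coefficient vectors (a*, b*) in a
random descriptor tensor and adds Gaussian noise to the bilinear
activities, so recovery of the planted structure can be tested end to
end. Per-property scale multipliers can mimic the magnitude heterogeneity
of real amino-acid scales (surface areas and volumes two orders of
magnitude above potency indices); note that strong heterogeneity lowers
the effective signal-to-noise of the weak-scale coefficients and hence
the fidelity of their recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from .descriptors import FragmentTensor, PeptideRecord, PropertyTable, load_property_table
from .exceptions import ValidationError
from .solver import CoefficientModel

__all__ = [
    "Benchmark",
    "SyntheticSpec",
    "builtin_benchmark",
    "benchmark_property_table",
    "training_frame",
    "testing_frame",
    "reference_model",
    "simulate_tensor",
    "export_fixtures",
]

_DATA_FILES = (
    "property_table.csv",
    "training_peptides.csv",
    "testing_peptides.csv",
    "reference_model.json",
)


def _data_path(name: str) -> Path:
    return Path(resources.files("tlpca").joinpath("data", name))  # type: ignore[arg-type]


class Benchmark(NamedTuple):
    property_table: PropertyTable
    training: list[PeptideRecord]
    testing: list[PeptideRecord]
    reference_model: CoefficientModel


def benchmark_property_table() -> PropertyTable:
    """The 8 physicochemical scales over the 20 natural amino acids.

    Four heuristic molecular lipophilicity potential (HMLP) descriptors
    (lipophilicity index Lip, hydrophilicity index Hyd, lipophilic and
    hydrophilic surface areas S_L/S_H in A^2), three secondary-structure
    potencies (P_alpha, P_beta, P_c) and the side-chain volume (A^3).
    """
    return load_property_table(_data_path("property_table.csv"))


def training_frame() -> pd.DataFrame:
    """The 90 training peptides with experimental and published predicted pIC50."""
    return pd.read_csv(_data_path("training_peptides.csv"), dtype={"sequence": str})


def testing_frame() -> pd.DataFrame:
    """The 40 independent test peptides, same columns as :func:`training_frame`."""
    return pd.read_csv(_data_path("testing_peptides.csv"), dtype={"sequence": str})


def reference_model() -> CoefficientModel:
    """The published converged property/position coefficient vectors."""
    return CoefficientModel.load(_data_path("reference_model.json"))


def _records(frame: pd.DataFrame) -> list[PeptideRecord]:
    return [
        PeptideRecord(id=str(r.id), sequence=r.sequence, activity=float(r.activity))
        for r in frame.itertuples()
    ]


def builtin_benchmark() -> Benchmark:
    """Property table, 90 training and 40 testing records, reference model."""
    return Benchmark(
        property_table=benchmark_property_table(),
        training=_records(training_frame()),
        testing=_records(testing_frame()),
        reference_model=reference_model(),
    )


def export_fixtures(directory: str | Path) -> list[Path]:
    """Copy the bundled benchmark files into ``directory``; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for name in _DATA_FILES:
        target = directory / name
        target.write_bytes(_data_path(name).read_bytes())
        written.append(target)
    return written


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for a synthetic fragment tensor with planted coefficients.

    Defaults mirror the benchmark geometry (L=9 fragments, K=8 properties)
    at N=200 samples — enough for a well-conditioned fit — with unit
    descriptor scales so every coefficient is identified at comparable
    signal-to-noise. ``property_scales`` optionally reproduces the
    magnitude heterogeneity of real amino-acid scales; coefficient ranges
    span the sign-mixed values seen in fitted models. ``noise_sd`` is the
    standard deviation of additive Gaussian noise on the activities, in
    the same (pIC50-like) units.
    """

    n_samples: int = 200
    n_fragments: int = 9
    n_properties: int = 8
    a_range: tuple[float, float] = (-0.25, 0.25)
    b_range: tuple[float, float] = (-5.0, 9.0)
    property_scales: tuple[float, ...] | None = None
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_samples, self.n_fragments, self.n_properties) < 1:
            raise ValidationError("tensor dimensions must be >= 1")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.property_scales is not None and len(self.property_scales) != self.n_properties:
            raise ValidationError("property_scales length must equal n_properties")

    def scales(self) -> np.ndarray:
        if self.property_scales is not None:
            return np.asarray(self.property_scales, dtype=float)
        return np.ones(self.n_properties)


def simulate_tensor(spec: SyntheticSpec) -> tuple[FragmentTensor, np.ndarray, np.ndarray]:
    """Draw a tensor and bilinear activities from planted coefficients.

    X[i, l, k] ~ Normal(0, scale_k); W_i = sum_l b*_l sum_k a*_k X[i,l,k]
    + Normal(0, noise_sd). Identical specs (including seed) give identical
    output. Returns (tensor-with-activities, a*, b*).
    """
    rng = np.random.default_rng(spec.seed)
    a_star = rng.uniform(*spec.a_range, size=spec.n_properties)
    b_star = rng.uniform(*spec.b_range, size=spec.n_fragments)
    X = rng.normal(
        0.0, 1.0, size=(spec.n_samples, spec.n_fragments, spec.n_properties)
    ) * spec.scales()
    W = np.einsum("ilk,k,l->i", X, a_star, b_star)
    if spec.noise_sd > 0:
        W = W + rng.normal(0.0, spec.noise_sd, size=spec.n_samples)
    tensor = FragmentTensor(
        sample_ids=tuple(f"S{i + 1}" for i in range(spec.n_samples)),
        fragment_labels=tuple(f"Residue-{l + 1}" for l in range(spec.n_fragments)),
        property_names=tuple(f"P{k + 1}" for k in range(spec.n_properties)),
        X=X,
        W=W,
    )
    return tensor, a_star, b_star
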