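"""Property tables, peptide encoding, and fragment-descriptor tensors.

The modelling unit is a *fragment* carrying K physicochemical properties.
For fixed-length peptides each residue side chain is one fragment, so a
peptide dataset encodes into a dense N x L x K tensor: N samples, L sequence
positions, K amino-acid property scales. Non-peptide molecules enter through
the same tensor type via a tidy long-format file, with descriptors computed
by whatever external tool fragmented the molecule.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError

__all__ = [
    "PropertyTable",
    "PeptideRecord",
    "FragmentTensor",
    "load_property_table",
    "save_property_table",
    "read_peptides",
    "encode_peptides",
    "load_fragment_tensor",
    "save_fragment_tensor",
]

#: number of decimal significant digits used when writing tensors/tables,
#: chosen so that float64 values round-trip bit-exactly through text.
_SIG_DIGITS = 17


def _fmt(x: float) -> str:
    return f"{float(x):.{_SIG_DIGITS}g}"


@dataclass(frozen=True)
class PropertyTable:
    """K named physicochemical scales over a residue alphabet.

    ``values[i, k]`` is property ``property_names[k]`` of residue
    ``residues[i]``. Units are whatever the source scales use (surface
    areas in A^2, volumes in A^3, potency and lipophilicity indices
    dimensionless); the model is unit-agnostic.
    """

    residues: tuple[str, ...]
    property_names: tuple[str, ...]
    values: np.ndarray  # shape (len(residues), K)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "residues", tuple(self.residues))
        object.__setattr__(self, "property_names", tuple(self.property_names))
        object.__setattr__(self, "values", values)
        if len(set(self.residues)) != len(self.residues):
            dupes = sorted({r for r in self.residues if self.residues.count(r) > 1})
            raise ValidationError(f"duplicate residue rows: {', '.join(dupes)}")
        if len(set(self.property_names)) != len(self.property_names):
            raise ValidationError("property names are not unique")
        if len(self.property_names) < 1:
            raise ValidationError("a property table needs at least one property")
        if values.shape != (len(self.residues), len(self.property_names)):
            raise ValidationError(
                f"values shape {values.shape} does not match "
                f"{len(self.residues)} residues x {len(self.property_names)} properties"
            )
        if not np.all(np.isfinite(values)):
            raise ValidationError("property table contains non-finite entries")

    @property
    def n_properties(self) -> int:
        return len(self.property_names)

    def row(self, residue: str) -> np.ndarray:
        """The K property values of one residue."""
        try:
            i = self.residues.index(residue)
        except ValueError:
            raise KeyError(f"residue {residue!r} not in table") from None
        return self.values[i]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=pd.Index(self.residues, name="residue"),
            columns=list(self.property_names),
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "PropertyTable":
        return cls(
            residues=tuple(str(r) for r in frame.index),
            property_names=tuple(str(c) for c in frame.columns),
            values=frame.to_numpy(dtype=float),
        )


@dataclass(frozen=True)
class PeptideRecord:
    """One fixed-length peptide with an optional measured activity (pIC50)."""

    id: str
    sequence: str
    activity: float | None = None


@dataclass
class FragmentTensor:
    """Dense N x L x K fragment-descriptor tensor with optional activities.

    ``X[i, l, k]`` is property ``property_names[k]`` of fragment
    ``fragment_labels[l]`` in sample ``sample_ids[i]``; ``W[i]`` is the
    sample's bioactivity (pIC50) when measured.
    """

    sample_ids: tuple[str, ...]
    fragment_labels: tuple[str, ...]
    property_names: tuple[str, ...]
    X: np.ndarray
    W: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.sample_ids = tuple(str(s) for s in self.sample_ids)
        self.fragment_labels = tuple(str(s) for s in self.fragment_labels)
        self.property_names = tuple(str(s) for s in self.property_names)
        self.X = np.asarray(self.X, dtype=float)
        for name, labels in (
            ("sample_ids", self.sample_ids),
            ("fragment_labels", self.fragment_labels),
            ("property_names", self.property_names),
        ):
            if len(labels) < 1:
                raise ValidationError(f"{name} is empty")
            if len(set(labels)) != len(labels):
                raise ValidationError(f"{name} contains duplicates")
        expected = (len(self.sample_ids), len(self.fragment_labels), len(self.property_names))
        if self.X.shape != expected:
            raise ValidationError(f"X has shape {self.X.shape}, expected {expected}")
        if not np.all(np.isfinite(self.X)):
            raise ValidationError("tensor contains non-finite entries")
        if self.W is not None:
            self.W = np.asarray(self.W, dtype=float)
            if self.W.shape != (len(self.sample_ids),):
                raise ValidationError(
                    f"activity vector length {self.W.shape} does not match "
                    f"{len(self.sample_ids)} samples"
                )
            if not np.all(np.isfinite(self.W)):
                raise ValidationError("activity vector contains non-finite entries")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.X.shape  # type: ignore[return-value]

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    def without_activities(self) -> "FragmentTensor":
        return replace(self, W=None)


def load_property_table(path: str | Path | io.TextIOBase, sep: str = ",") -> PropertyTable:
    """Read a delimited table with header ``residue,<prop1>,...,<propK>``.

    Column order is preserved. Duplicate residues and non-numeric cells are
    reported with the offending row/column.
    """
    frame = pd.read_csv(path, sep=sep, dtype=str)
    if frame.shape[1] < 2:
        raise ValidationError("property table needs a residue column plus >=1 property column")
    residue_col = frame.columns[0]
    residues = [str(r).strip() for r in frame[residue_col]]
    dupes = sorted({r for r in residues if residues.count(r) > 1})
    if dupes:
        raise ValidationError(f"duplicate residue rows: {', '.join(dupes)}")
    values = np.empty((len(residues), frame.shape[1] - 1), dtype=float)
    for j, col in enumerate(frame.columns[1:]):
        for i, cell in enumerate(frame[col]):
            try:
                values[i, j] = float(cell)
            except (TypeError, ValueError):
                raise ValidationError(
                    f"non-numeric value {cell!r} at residue {residues[i]!r}, column {col!r}"
                ) from None
    return PropertyTable(tuple(residues), tuple(str(c) for c in frame.columns[1:]), values)


def save_property_table(table: PropertyTable, path: str | Path, sep: str = ",") -> None:
    with open(path, "w") as fh:
        fh.write("residue" + sep + sep.join(table.property_names) + "\n")
        for residue, row in zip(table.residues, table.values):
            fh.write(residue + sep + sep.join(_fmt(v) for v in row) + "\n")


def _records_from_fasta(path: str | Path) -> list[PeptideRecord]:
    from Bio import SeqIO

    return [
        PeptideRecord(id=rec.id, sequence=str(rec.seq), activity=None)
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def read_peptides(path: str | Path, fmt: str | None = None) -> list[PeptideRecord]:
    """Read peptides from ``id,sequence[,activity]`` delimited text or FASTA.

    Format is inferred from the extension (``.fasta``/``.fa``/``.faa`` ->
    FASTA) unless ``fmt`` is given explicitly. FASTA carries no activities.
    """
    path = Path(path)
    if fmt is None:
        fmt = "fasta" if path.suffix.lower() in {".fasta", ".fa", ".faa"} else "csv"
    if fmt == "fasta":
        records = _records_from_fasta(path)
        if not records:
            raise ValidationError(f"no FASTA records found in {path}")
        return records
    frame = pd.read_csv(path, dtype={"id": str, "sequence": str})
    required = {"id", "sequence"}
    if not required.issubset(frame.columns):
        raise ValidationError(
            f"peptide file must have columns id,sequence[,activity]; got {list(frame.columns)}"
        )
    has_activity = "activity" in frame.columns
    records = []
    for _, row in frame.iterrows():
        act = row["activity"] if has_activity else None
        act = None if act is None or pd.isna(act) else float(act)
        records.append(PeptideRecord(str(row["id"]), str(row["sequence"]).strip(), act))
    return records


def encode_peptides(
    records: Sequence[PeptideRecord],
    table: PropertyTable,
    case_fold: bool = False,
) -> FragmentTensor:
    """Encode fixed-length peptides into an N x L x K tensor.

    ``X[i, l, k]`` is the table value of property k for the residue at
    position l (N-terminus first) of sequence i; fragment labels are
    ``Residue-1`` .. ``Residue-L``. The activity vector is attached only
    when every record carries one. Residue letters are matched
    case-sensitively unless ``case_fold`` upper-cases them first.
    """
    if not records:
        raise ValidationError("no peptide records to encode")
    seqs = [r.sequence.upper() if case_fold else r.sequence for r in records]
    L = len(seqs[0])
    bad = [r.id for r, s in zip(records, seqs) if len(s) != L]
    if bad:
        raise ValidationError(
            f"mixed sequence lengths (expected {L}): offending ids {', '.join(bad)}"
        )
    if L < 1:
        raise ValidationError("sequences are empty")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate sample ids in peptide records")
    index = {res: i for i, res in enumerate(table.residues)}
    X = np.empty((len(records), L, table.n_properties), dtype=float)
    for i, (rec, seq) in enumerate(zip(records, seqs)):
        for l, letter in enumerate(seq):
            if letter not in index:
                raise ValidationError(
                    f"unknown residue {letter!r} at position {l + 1} of record {rec.id!r}"
                )
            X[i, l] = table.values[index[letter]]
    activities = [r.activity for r in records]
    W = np.array(activities, dtype=float) if all(a is not None for a in activities) else None
    return FragmentTensor(
        sample_ids=tuple(ids),
        fragment_labels=tuple(f"Residue-{l + 1}" for l in range(L)),
        property_names=table.property_names,
        X=X,
        W=W,
    )


def load_fragment_tensor(path: str | Path, sep: str = ",") -> FragmentTensor:
    """Read a long-format tensor: ``sample_id,fragment,property,value[,activity]``.

    Every (sample, fragment, property) combination must appear exactly once.
    Axis orders follow first appearance in the file. An ``activity`` column,
    when present, must be constant within each sample.
    """
    frame = pd.read_csv(
        path, sep=sep,
        dtype={"sample_id": str, "fragment": str, "property": str},
        float_precision="round_trip",
    )
    required = ["sample_id", "fragment", "property", "value"]
    if not set(required).issubset(frame.columns):
        raise ValidationError(
            f"tensor file must have columns {required}[,activity]; got {list(frame.columns)}"
        )
    samples = list(dict.fromkeys(frame["sample_id"]))
    fragments = list(dict.fromkeys(frame["fragment"]))
    properties = list(dict.fromkeys(frame["property"]))
    si = {s: i for i, s in enumerate(samples)}
    fi = {f: i for i, f in enumerate(fragments)}
    pi = {p: i for i, p in enumerate(properties)}
    X = np.full((len(samples), len(fragments), len(properties)), np.nan)
    for sample, fragment, prop, value in zip(
        frame["sample_id"], frame["fragment"], frame["property"], frame["value"]
    ):
        i, l, k = si[sample], fi[fragment], pi[prop]
        if not np.isnan(X[i, l, k]):
            raise ValidationError(f"duplicate combination ({sample}, {fragment}, {prop})")
        X[i, l, k] = float(value)
    missing = np.argwhere(np.isnan(X))
    if len(missing):
        i, l, k = missing[0]
        raise ValidationError(
            f"missing combination ({samples[i]}, {fragments[l]}, {properties[k]})"
            + (f" and {len(missing) - 1} more" if len(missing) > 1 else "")
        )
    W = None
    if "activity" in frame.columns:
        per_sample = frame.groupby("sample_id", sort=False)["activity"].nunique(dropna=False)
        if (per_sample > 1).any():
            bad = per_sample[per_sample > 1].index[0]
            raise ValidationError(f"sample {bad!r} has inconsistent activity values")
        acts = frame.drop_duplicates("sample_id").set_index("sample_id")["activity"]
        if not acts.isna().any():
            W = acts.loc[samples].to_numpy(dtype=float)
    return FragmentTensor(tuple(samples), tuple(fragments), tuple(properties), X, W)


def save_fragment_tensor(tensor: FragmentTensor, path: str | Path, sep: str = ",") -> None:
    """Write the long-format representation read back by :func:`load_fragment_tensor`."""
    has_w = tensor.W is not None
    with open(path, "w") as fh:
        header = ["sample_id", "fragment", "property", "value"] + (["activity"] if has_w else [])
        fh.write(sep.join(header) + "\n")
        for i, sample in enumerate(tensor.sample_ids):
            for l, fragment in enumerate(tensor.fragment_labels):
                for k, prop in enumerate(tensor.property_names):
                    row = [sample, fragment, prop, _fmt(tensor.X[i, l, k])]
                    if has_w:
                        row.append(_fmt(tensor.W[i]))
                    fh.write(sep.join(row) + "\n")
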