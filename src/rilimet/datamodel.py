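"""Core containers and delimited-table I/O for the metabolomics pipeline.

The universal currency of the pipeline is the :class:`SampleTable`: a
samples x metabolites matrix of LC-MS peak areas (or normalized
intensities) together with per-sample and per-metabolite metadata.
Orientation is fixed — samples are rows everywhere.

Missing measurements are represented as NaN, never as zero: zero is a
legal measured intensity, and the missingness filter downstream must be
able to tell the two apart.

On-disk layout is three delimited files sharing sample/metabolite ids:
an abundance matrix (sample ids as the first column, metabolite ids as
the header) plus one metadata table per axis. Comma is the default
delimiter; tab is accepted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

TISSUES = ("lung", "plasma")
ROLES = ("study", "qc")
CHEM_CLASSES = ("amino_acid", "bile_acid", "acylcarnitine", "lipid",
                "organic_acid", "other")
NORMALIZED_STATES = ("raw", "is_normalized", "is_weight_normalized")

SAMPLE_META_COLUMNS = ("animal_id", "tissue", "dose_gy", "day", "role",
                       "tissue_weight_mg")
METABOLITE_META_COLUMNS = ("name", "chem_class", "acyl_chain", "is_channel")

#: Metabolite names that carry an acyl_chain token despite not being
#: acylcarnitine esters themselves (free carnitine, and acetylcarnitine
#: when annotated under another class).
CARNITINE_NAMES = ("carnitine", "acetylcarnitine")


class TableError(ValueError):
    """Structural problem in a sample table or its on-disk layout."""


@dataclass
class ValidationReport:
    """Outcome of :func:`validate_table`: a list of (severity, message,
    location) issues. ``ok`` is true iff no issue has severity ``error``."""

    issues: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not any(sev == "error" for sev, _, _ in self.issues)

    def add(self, severity: str, message: str, location: str = "") -> None:
        self.issues.append((severity, message, location))

    def errors(self) -> list:
        return [i for i in self.issues if i[0] == "error"]

    def to_dict(self) -> dict:
        return {"ok": self.ok,
                "issues": [{"severity": s, "message": m, "location": l}
                           for s, m, l in self.issues]}


@dataclass
class SampleTable:
    """Samples x metabolites abundance matrix with aligned metadata.

    Parameters
    ----------
    abundance : DataFrame, index sample_id, columns metabolite_id, float;
        NaN encodes a missing measurement.
    samples : DataFrame indexed by sample_id with columns
        ``animal_id, tissue, dose_gy, day, role, tissue_weight_mg``.
    metabolites : DataFrame indexed by metabolite_id with columns
        ``name, chem_class, acyl_chain, is_channel``.
    normalized : one of ``raw | is_normalized | is_weight_normalized``.

    Construction enforces the structural contract (unique ids, metadata
    covering exactly the matrix axes); semantic invariants are reported,
    not raised, by :func:`validate_table`.
    """

    abundance: pd.DataFrame
    samples: pd.DataFrame
    metabolites: pd.DataFrame
    normalized: str = "raw"

    def __post_init__(self):
        ab, sm, mm = self.abundance, self.samples, self.metabolites
        for name, idx in (("sample", ab.index), ("metabolite", ab.columns),
                          ("sample metadata", sm.index),
                          ("metabolite metadata", mm.index)):
            dup = idx[idx.duplicated()].unique().tolist()
            if dup:
                raise TableError(f"duplicate {name} ids: {dup}")
        orphan_rows = ab.index.difference(sm.index).tolist()
        orphan_cols = ab.columns.difference(mm.index).tolist()
        extra_sm = sm.index.difference(ab.index).tolist()
        extra_mm = mm.index.difference(ab.columns).tolist()
        if orphan_rows or orphan_cols or extra_sm or extra_mm:
            raise TableError(
                "id mismatch between matrix and metadata: "
                f"matrix rows without sample metadata {orphan_rows}; "
                f"matrix columns without metabolite metadata {orphan_cols}; "
                f"unused sample metadata {extra_sm}; "
                f"unused metabolite metadata {extra_mm}")
        if self.normalized not in NORMALIZED_STATES:
            raise TableError(f"unknown normalized state {self.normalized!r}")
        # align metadata to the matrix order, canonicalize axis names /
        # NA encoding so write->read round-trips compare equal
        sm = sm.reindex(ab.index)
        mm = mm.reindex(ab.columns)
        self.samples = sm.where(sm.notna(), np.nan) \
            .rename_axis("sample_id")
        self.metabolites = mm.where(mm.notna(), np.nan) \
            .rename_axis("metabolite_id")
        self.abundance = ab.astype(float) \
            .rename_axis(index="sample_id", columns=None)
        for col in ("dose_gy", "tissue_weight_mg"):
            if col in self.samples:
                self.samples[col] = pd.to_numeric(self.samples[col],
                                                  errors="coerce")
        if "day" in self.samples:
            self.samples["day"] = pd.to_numeric(self.samples["day"],
                                                errors="coerce")

    # -- basic introspection -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.abundance.shape[0]

    @property
    def n_metabolites(self) -> int:
        return self.abundance.shape[1]

    @property
    def is_channel_ids(self) -> list:
        """Metabolite ids that serve as internal-standard channels."""
        chans = self.metabolites["is_channel"].dropna().unique()
        return [c for c in self.abundance.columns if c in set(chans)]

    @property
    def measured_ids(self) -> list:
        """Metabolite ids that are not internal-standard channels."""
        isc = set(self.is_channel_ids)
        return [c for c in self.abundance.columns if c not in isc]

    def study_mask(self) -> pd.Series:
        return self.samples["role"] == "study"

    def qc_mask(self) -> pd.Series:
        return self.samples["role"] == "qc"

    # -- manipulation --------------------------------------------------------
    def copy(self) -> "SampleTable":
        return SampleTable(self.abundance.copy(), self.samples.copy(),
                           self.metabolites.copy(), self.normalized)

    def subset(self, sample_ids=None, metabolite_ids=None) -> "SampleTable":
        ab = self.abundance
        if sample_ids is not None:
            sample_ids = [s for s in ab.index if s in set(sample_ids)]
            ab = ab.loc[sample_ids]
        if metabolite_ids is not None:
            metabolite_ids = [m for m in ab.columns if m in set(metabolite_ids)]
            ab = ab[metabolite_ids]
        return SampleTable(ab.copy(), self.samples.loc[ab.index].copy(),
                           self.metabolites.loc[ab.columns].copy(),
                           self.normalized)

    def equals(self, other: "SampleTable") -> bool:
        try:
            pd.testing.assert_frame_equal(self.abundance, other.abundance)
            pd.testing.assert_frame_equal(self.samples, other.samples,
                                          check_dtype=False)
            pd.testing.assert_frame_equal(self.metabolites, other.metabolites,
                                          check_dtype=False)
        except AssertionError:
            return False
        return self.normalized == other.normalized


# ---------------------------------------------------------------------------
# readers / writers


def _sniff_sep(path) -> str:
    suffix = Path(path).suffix.lower()
    if suffix in (".tsv", ".tab"):
        return "\t"
    with open(path) as fh:
        header = fh.readline()
    if "\t" in header and "," not in header:
        return "\t"
    return ","


def read_sample_table(abundance_path, sample_meta_path, metabolite_meta_path,
                      normalized: str = "raw") -> SampleTable:
    """Read the three-file layout into a validated :class:`SampleTable`.

    Empty cells and the usual NA spellings become missing values (NaN),
    never zero. Negative abundances and id mismatches raise
    :class:`TableError`.
    """
    ab = pd.read_csv(abundance_path, sep=_sniff_sep(abundance_path),
                     index_col=0, float_precision="round_trip")
    ab.index = ab.index.astype(str)
    ab.columns = ab.columns.astype(str)
    sm = pd.read_csv(sample_meta_path, sep=_sniff_sep(sample_meta_path),
                     index_col=0)
    sm.index = sm.index.astype(str)
    mm = pd.read_csv(metabolite_meta_path,
                     sep=_sniff_sep(metabolite_meta_path), index_col=0)
    mm.index = mm.index.astype(str)
    neg = ab.lt(0)
    if neg.any().any():
        rows, cols = np.nonzero(neg.to_numpy())
        cells = [f"({ab.index[r]}, {ab.columns[c]})"
                 for r, c in zip(rows[:5], cols[:5])]
        raise TableError(f"negative abundance at {', '.join(cells)}")
    return SampleTable(ab, sm, mm, normalized=normalized)


def write_sample_table(table: SampleTable, abundance_path, sample_meta_path,
                       metabolite_meta_path) -> None:
    """Write the three-file layout (CSV). Inverse of
    :func:`read_sample_table` up to float round-trip (exact for float64
    via the shortest-repr convention pandas uses)."""
    table.abundance.rename_axis("sample_id").to_csv(abundance_path)
    table.samples.rename_axis("sample_id").to_csv(sample_meta_path)
    table.metabolites.rename_axis("metabolite_id").to_csv(metabolite_meta_path)


# ---------------------------------------------------------------------------
# validation


def validate_table(table: SampleTable) -> ValidationReport:
    """Check every semantic invariant of the table; never mutates.

    Problems are reported in the returned :class:`ValidationReport`
    rather than raised, so a pipeline can decide how strict to be.
    """
    rep = ValidationReport()
    ab, sm, mm = table.abundance, table.samples, table.metabolites

    neg = ab.lt(0)
    if neg.any().any():
        for r, c in zip(*np.nonzero(neg.to_numpy())):
            rep.add("error", "negative abundance",
                    f"({ab.index[r]}, {ab.columns[c]})")

    for sid, row in sm.iterrows():
        if row.get("tissue") not in TISSUES:
            rep.add("error", f"unknown tissue {row.get('tissue')!r}", sid)
        if row.get("role") not in ROLES:
            rep.add("error", f"unknown role {row.get('role')!r}", sid)
        if (row.get("tissue") == "lung" and row.get("role") == "study"
                and not (pd.notna(row.get("tissue_weight_mg"))
                         and row.get("tissue_weight_mg") > 0)):
            rep.add("error", "lung study sample lacks positive "
                             "tissue_weight_mg", sid)
        if row.get("role") == "study" and pd.isna(row.get("dose_gy")):
            rep.add("error", "study sample lacks dose_gy", sid)

    is_ids = set(table.is_channel_ids)
    for mid, row in mm.iterrows():
        if row.get("chem_class") not in CHEM_CLASSES:
            rep.add("error", f"unknown chem_class {row.get('chem_class')!r}",
                    mid)
        chan = row.get("is_channel")
        if pd.notna(chan) and chan not in ab.columns:
            rep.add("error", f"is_channel {chan!r} not a column in the "
                             "abundance matrix", mid)
        needs_chain = (row.get("chem_class") == "acylcarnitine"
                       or str(row.get("name", "")).lower() in CARNITINE_NAMES)
        has_chain = pd.notna(row.get("acyl_chain"))
        if needs_chain and not has_chain and mid not in is_ids:
            rep.add("error", "acylcarnitine without acyl_chain token", mid)
        if has_chain and not needs_chain:
            rep.add("warning", "acyl_chain token on a non-acylcarnitine", mid)

    n_missing = int(ab.isna().sum().sum())
    if n_missing:
        rep.add("info", f"{n_missing} missing cells", "")
    return rep


# ---------------------------------------------------------------------------
# result export

def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="index")
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def export_results(obj, path, format: str = "csv") -> None:
    """Write a result object (DiffResult, MarkerPanel, TriageResult,
    RatioResult, ...) to disk.

    ``csv`` uses the object's ``to_frame()`` (numerics round-trip at full
    precision); ``json`` uses ``to_dict()`` and is schema-stable.
    """
    path = Path(path)
    if format == "csv":
        frame = obj.to_frame()
        frame.to_csv(path)
    elif format == "json":
        with open(path, "w") as fh:
            json.dump(obj.to_dict(), fh, indent=1, default=_jsonable)
    else:
        raise ValueError(f"unknown export format {format!r}")
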