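"""Domain tables for outflow-transect datasets.

Four tables describe a study: per-sample geochemistry (with explicit units),
an ASV × sample count table, an ASV taxonomy (SILVA-style lineage strings),
and per-sample transect metadata (spring, downstream order, fringe label).
All are plain delimited text; geochemistry headers carry the unit of every
variable as ``name[unit]`` (``[-]`` for unitless quantities such as pH).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")
FRINGE_LABELS = ("above", "at", "below", "unknown")

_UNITLESS = {"", "-", "unitless", "1"}


class FormatError(ValueError):
    """Malformed table: duplicates, negative counts, bad labels."""


class UnitError(ValueError):
    """Missing or unparseable unit tag."""


class MismatchError(ValueError):
    """Sample/ASV identifiers disagree between paired tables."""


def _read_delimited(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep, dtype={0: str})


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


# ---------------------------------------------------------------------------
# geochemistry

@dataclass
class GeochemTable:
    """Samples × geochemical variables, each variable with one unit tag.

    ``values`` is indexed by sample id; missing measurements are NaN and
    exposed through :meth:`mask` rather than imputed.
    """

    values: pd.DataFrame                      # index: sample ids
    units: dict[str, str]                     # variable -> unit tag

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise FormatError(f"duplicate sample id(s): {dups}")
        missing = [v for v in self.values.columns if v not in self.units]
        if missing:
            raise UnitError(f"variables without a unit tag: {missing}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def variables(self) -> list[str]:
        return list(self.values.columns)

    def mask(self) -> pd.DataFrame:
        """Boolean mask, True where a measurement is missing."""
        return self.values.isna()

    def row(self, sample_id: str) -> pd.Series:
        return self.values.loc[sample_id]

    @classmethod
    def read(cls, path: str | Path) -> "GeochemTable":
        raw = _read_delimited(path)
        raw = raw.set_index(raw.columns[0])
        units: dict[str, str] = {}
        names: list[str] = []
        for col in raw.columns:
            m = re.fullmatch(r"(.+?)\s*\[(.*)\]", str(col))
            if m is None:
                raise UnitError(
                    f"geochemistry column {col!r} lacks a [unit] tag "
                    f"(use [-] for unitless variables)"
                )
            name, unit = m.group(1), m.group(2)
            names.append(name)
            units[name] = "" if unit in _UNITLESS else unit
        out = raw.copy()
        out.columns = names
        out.index = out.index.astype(str)
        return cls(out.astype(float), units)

    def write(self, path: str | Path) -> None:
        path = Path(path)
        out = self.values.copy()
        out.columns = [
            f"{v}[{self.units[v] or '-'}]" for v in self.values.columns
        ]
        out.to_csv(path, sep=_sep_for(path), index_label="sample_id",
                   float_format="%.10g")


# ---------------------------------------------------------------------------
# ASV counts

@dataclass
class ASVTable:
    """ASV × sample abundance matrix.

    Raw tables hold nonnegative integers; ``normalized=True`` marks tables
    rescaled to a common library size (values then real-valued).
    """

    counts: pd.DataFrame                      # index: ASV ids, columns: samples
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            raise FormatError("duplicate ASV id(s)")
        if self.counts.columns.duplicated().any():
            raise FormatError("duplicate sample id(s)")
        vals = self.counts.to_numpy()
        if np.isnan(vals).all(axis=1).any():
            raise FormatError("ASV row with all values missing")
        if (vals < 0).any():
            bad = self.counts.index[(vals < 0).any(axis=1)].tolist()
            raise FormatError(f"negative count(s) in ASV(s): {bad}")
        if not self.normalized:
            with np.errstate(invalid="ignore"):
                if not np.allclose(vals, np.round(vals), equal_nan=True):
                    raise FormatError("raw count table must be integer-valued")

    @property
    def asv_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @classmethod
    def read(cls, path: str | Path, normalized: bool = False) -> "ASVTable":
        raw = _read_delimited(path)
        raw = raw.set_index(raw.columns[0])
        raw.index = raw.index.astype(str)
        return cls(raw.astype(float), normalized=normalized)

    def write(self, path: str | Path) -> None:
        path = Path(path)
        out = self.counts
        if not self.normalized:
            out = out.astype(int)
        out.to_csv(path, sep=_sep_for(path), index_label="asv_id",
                   float_format="%.10g")


# ---------------------------------------------------------------------------
# taxonomy

@dataclass
class TaxonomyTable:
    """ASV id → seven-rank lineage, stored one rank per column.

    Lineages are parsed from SILVA-style strings
    (``d__Bacteria;p__Cyanobacteria;c__Cyanobacteriia;...``); absent ranks
    are empty strings.
    """

    lineages: pd.DataFrame                    # index: ASV ids, columns: RANKS

    _PREFIX = re.compile(r"^[dpcofgs]__")

    def __post_init__(self) -> None:
        missing = [r for r in RANKS if r not in self.lineages.columns]
        if missing:
            raise FormatError(f"taxonomy missing rank column(s): {missing}")

    @property
    def asv_ids(self) -> list[str]:
        return list(self.lineages.index)

    def rank(self, asv_id: str, rank: str) -> str:
        return str(self.lineages.at[asv_id, rank])

    @classmethod
    def from_lineage_strings(cls, lineages: dict[str, str]) -> "TaxonomyTable":
        rows = {}
        for asv, s in lineages.items():
            parts = [cls._PREFIX.sub("", p.strip()) for p in s.split(";")]
            parts = (parts + [""] * len(RANKS))[: len(RANKS)]
            rows[asv] = parts
        df = pd.DataFrame.from_dict(rows, orient="index", columns=list(RANKS))
        return cls(df.fillna(""))

    def to_lineage_strings(self) -> pd.Series:
        prefixes = ["d__", "p__", "c__", "o__", "f__", "g__", "s__"]
        return self.lineages.apply(
            lambda row: ";".join(p + str(v) for p, v in zip(prefixes, row)),
            axis=1,
        )

    @classmethod
    def read(cls, path: str | Path) -> "TaxonomyTable":
        raw = _read_delimited(path)
        raw = raw.set_index(raw.columns[0])
        raw.index = raw.index.astype(str)
        col = raw.columns[0]
        return cls.from_lineage_strings(raw[col].astype(str).to_dict())

    def write(self, path: str | Path) -> None:
        path = Path(path)
        pd.DataFrame({"lineage": self.to_lineage_strings()}).to_csv(
            path, sep=_sep_for(path), index_label="asv_id"
        )


# ---------------------------------------------------------------------------
# sample metadata

@dataclass
class SampleMetadata:
    """Per-sample transect context: spring, downstream order, fringe label."""

    table: pd.DataFrame                       # index: sample ids

    REQUIRED = ("spring_id", "outflow_index", "fringe_label")

    def __post_init__(self) -> None:
        if self.table.index.duplicated().any():
            raise FormatError("duplicate sample id(s) in metadata")
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise FormatError(f"metadata missing column(s): {missing}")
        bad = set(self.table["fringe_label"]) - set(FRINGE_LABELS)
        if bad:
            raise FormatError(f"unknown fringe label(s): {sorted(bad)}")
        if "distance" not in self.table.columns:
            self.table["distance"] = np.nan

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def spring(self, sample_id: str) -> str:
        return str(self.table.at[sample_id, "spring_id"])

    def transects(self):
        """Yield (spring_id, sub-table sorted by outflow_index)."""
        for spring, sub in self.table.groupby("spring_id", sort=False):
            yield str(spring), sub.sort_values("outflow_index")

    @classmethod
    def read(cls, path: str | Path) -> "SampleMetadata":
        raw = _read_delimited(path)
        raw = raw.set_index(raw.columns[0])
        raw.index = raw.index.astype(str)
        raw["outflow_index"] = raw["outflow_index"].astype(int)
        return cls(raw)

    def write(self, path: str | Path) -> None:
        path = Path(path)
        self.table.to_csv(path, sep=_sep_for(path), index_label="sample_id",
                          float_format="%.10g")


# ---------------------------------------------------------------------------
# dataset

@dataclass
class Dataset:
    """A complete study: geochemistry, counts, taxonomy, metadata."""

    geochem: GeochemTable
    counts: ASVTable
    taxonomy: TaxonomyTable
    metadata: SampleMetadata

    def __post_init__(self) -> None:
        g = set(self.geochem.sample_ids)
        c = set(self.counts.sample_ids)
        m = set(self.metadata.sample_ids)
        if g != c or g != m:
            detail = []
            for name, ids in (("geochemistry", g), ("counts", c), ("metadata", m)):
                extra = sorted(ids - (g & c & m))
                if extra:
                    detail.append(f"only in {name}: {extra}")
            raise MismatchError("sample ids disagree; " + "; ".join(detail))

    @property
    def sample_ids(self) -> list[str]:
        return self.geochem.sample_ids

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "geochem": outdir / "geochem.tsv",
            "counts": outdir / "counts.tsv",
            "taxonomy": outdir / "taxonomy.tsv",
            "metadata": outdir / "metadata.tsv",
        }
        self.geochem.write(paths["geochem"])
        self.counts.write(paths["counts"])
        self.taxonomy.write(paths["taxonomy"])
        self.metadata.write(paths["metadata"])
        return paths


def load_dataset(
    geochem_path: str | Path,
    counts_path: str | Path,
    taxonomy_path: str | Path,
    metadata_path: str | Path,
    counts_normalized: bool = False,
) -> Dataset:
    """Read and cross-validate the four study tables.

    Raises :class:`UnitError` on a missing unit tag, :class:`FormatError`
    on duplicate ids or negative counts, and :class:`MismatchError` (naming
    the offending ids) when sample sets disagree between tables.
    """
    geochem = GeochemTable.read(geochem_path)
    counts = ASVTable.read(counts_path, normalized=counts_normalized)
    taxonomy = TaxonomyTable.read(taxonomy_path)
    metadata = SampleMetadata.read(metadata_path)
    return Dataset(geochem, counts, taxonomy, metadata)


# ---------------------------------------------------------------------------
# validation

@dataclass
class Violation:
    check: str
    ident: str
    message: str

    def __str__(self) -> str:
        return f"[{self.check}] {self.ident}: {self.message}"


@dataclass
class ValidationReport:
    violations: list[Violation] = field(default_factory=list)

    def ok(self) -> bool:
        return not self.violations

    def __len__(self) -> int:
        return len(self.violations)

    def add(self, check: str, ident: str, message: str) -> None:
        self.violations.append(Violation(check, ident, message))


def validate_dataset(ds: Dataset) -> ValidationReport:
    """Check every domain invariant; returns a report, never raises.

    Checks: pH ∈ [0, 14]; temperature ∈ [0, 120] °C; concentrations ≥ 0;
    counts nonnegative (integer when raw); outflow indices strictly
    increasing downstream within each spring; at most one "at"-fringe sample
    per transect; every ASV present in the taxonomy.
    """
    report = ValidationReport()
    g = ds.geochem.values
    if "pH" in g.columns:
        for sid in g.index[(g["pH"] < 0) | (g["pH"] > 14)]:
            report.add("pH_range", str(sid), f"pH={g.at[sid, 'pH']} outside [0, 14]")
    if "temperature" in g.columns:
        bad = (g["temperature"] < 0) | (g["temperature"] > 120)
        for sid in g.index[bad]:
            report.add("temperature_range", str(sid),
                       f"temperature={g.at[sid, 'temperature']} outside [0, 120]")
    conc = [v for v in g.columns if v not in ("pH", "temperature")]
    for var in conc:
        for sid in g.index[g[var] < 0]:
            report.add("negative_concentration", str(sid), f"{var}={g.at[sid, var]}")

    cv = ds.counts.counts.to_numpy()
    if (cv < 0).any():
        for asv in ds.counts.counts.index[(cv < 0).any(axis=1)]:
            report.add("negative_count", str(asv), "negative abundance")

    known = set(ds.taxonomy.asv_ids)
    for asv in ds.counts.asv_ids:
        if asv not in known:
            report.add("missing_taxonomy", asv, "ASV absent from taxonomy table")

    for spring, sub in ds.metadata.transects():
        idx = sub["outflow_index"].to_numpy()
        if not (np.diff(idx) > 0).all():
            report.add("outflow_order", spring,
                       f"outflow_index not strictly increasing: {idx.tolist()}")
        n_at = int((sub["fringe_label"] == "at").sum())
        if n_at > 1:
            report.add("multiple_fringe", spring,
                       f'{n_at} samples labelled "at" in one transect')
    return report
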