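"""Data model, file readers/writers and configuration shared by all stages.

Two tabular containers travel through the pipeline:

``MeasurementTable``
    tidy per-sample numeric measurements (soil physicochemistry, enzyme
    activities, tea-leaf quality components) keyed by treatment, sampling
    period and replicate;

``OtuTable``
    a samples x OTUs count matrix with a taxonomic lineage string per OTU.

Tables are always matched on ``sample_id``, never on row order, so metadata
and count files cannot be silently misaligned.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

KEY_COLUMNS = ("sample_id", "treatment", "period", "replicate")

#: taxonomic rank prefixes in lineage strings, e.g. "k__Fungi;p__Ascomycota"
RANK_PREFIXES = {
    "kingdom": "k__",
    "phylum": "p__",
    "class": "c__",
    "order": "o__",
    "family": "f__",
    "genus": "g__",
    "species": "s__",
}


class InvariantError(ValueError):
    """A table violates one of its declared invariants."""


def parse_lineage(lineage: str) -> dict[str, str]:
    """Parse a rank-prefixed lineage string into a ``rank -> name`` mapping.

    Unnamed ranks (empty after the prefix) become ``unclassified_<rank>``.
    """
    out: dict[str, str] = {}
    for token in str(lineage).split(";"):
        token = token.strip()
        if not token:
            continue
        for rank, prefix in RANK_PREFIXES.items():
            if token.lower().startswith(prefix):
                name = token[len(prefix):].strip()
                out[rank] = name if name else f"unclassified_{rank}"
                break
    return out


@dataclass(frozen=True)
class SampleKey:
    """Identity of one biological sample: treatment x period x replicate."""

    sample_id: str
    treatment: str
    period: int
    replicate: int


class MeasurementTable:
    """Tidy table of per-sample numeric measurements with declared units.

    Parameters
    ----------
    data:
        DataFrame containing the key columns ``sample_id``, ``treatment``,
        ``period``, ``replicate`` plus one numeric column per variable.
    units:
        Mapping variable name -> unit string. Units are carried as declared
        metadata and never converted.
    """

    def __init__(self, data: pd.DataFrame, units: Mapping[str, str] | None = None):
        data = data.copy()
        for col in KEY_COLUMNS:
            if col not in data.columns:
                raise InvariantError(f"missing key column: {col!r}")
        data["sample_id"] = data["sample_id"].astype(str)
        data["treatment"] = data["treatment"].astype(str)
        data["period"] = data["period"].astype(int)
        data["replicate"] = data["replicate"].astype(int)
        self.variables: list[str] = [c for c in data.columns if c not in KEY_COLUMNS]
        for v in self.variables:
            data[v] = pd.to_numeric(data[v], errors="raise")
        self.data = data.reset_index(drop=True)
        self.units = dict(units or {v: "" for v in self.variables})
        self._validate()

    def _validate(self) -> None:
        if self.data["sample_id"].duplicated().any():
            dup = self.data.loc[self.data["sample_id"].duplicated(), "sample_id"]
            raise InvariantError(f"duplicate sample_id: {sorted(set(dup))}")
        keys = self.data[["treatment", "period", "replicate"]]
        if keys.duplicated().any():
            dup = keys[keys.duplicated()].iloc[0]
            raise InvariantError(
                "duplicate (treatment, period, replicate) key: "
                f"({dup['treatment']}, {dup['period']}, {dup['replicate']})"
            )
        num = self.data[self.variables]
        with np.errstate(invalid="ignore"):
            if np.isinf(num.to_numpy(dtype=float)).any():
                raise InvariantError("non-finite (inf) measurement values")
        if "pH" in self.variables:
            ph = self.data["pH"].dropna()
            if ((ph <= 0) | (ph >= 14)).any():
                raise InvariantError("pH outside (0, 14)")
        conc = [v for v in self.variables if v != "pH"]
        if conc and (self.data[conc] < 0).any().any():
            bad = [v for v in conc if (self.data[v] < 0).any()]
            raise InvariantError(f"negative concentrations in: {bad}")

    # -- convenience -------------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data["sample_id"])

    @property
    def treatments(self) -> list[str]:
        return sorted(self.data["treatment"].unique())

    @property
    def periods(self) -> list[int]:
        return sorted(self.data["period"].unique())

    def matrix(self, variables: Sequence[str] | None = None) -> pd.DataFrame:
        """Numeric matrix indexed by sample_id."""
        variables = list(variables) if variables is not None else self.variables
        return self.data.set_index("sample_id")[variables]

    def group_means(self, variables: Sequence[str] | None = None) -> pd.DataFrame:
        """Mean of every variable per (treatment, period); NaN-aware."""
        variables = list(variables) if variables is not None else self.variables
        return self.data.groupby(["treatment", "period"])[variables].mean()

    def group_sds(self, variables: Sequence[str] | None = None) -> pd.DataFrame:
        variables = list(variables) if variables is not None else self.variables
        return self.data.groupby(["treatment", "period"])[variables].std(ddof=1)

    def subset_period(self, period: int) -> "MeasurementTable":
        sub = self.data[self.data["period"] == period]
        if sub.empty:
            raise KeyError(f"no samples with period={period}")
        return MeasurementTable(sub, self.units)

    def __repr__(self) -> str:  # pragma: no cover
        return (f"MeasurementTable({len(self.data)} samples, "
                f"{len(self.variables)} variables)")


class OtuTable:
    """Sample x OTU count matrix plus taxonomy lineage per OTU.

    ``counts`` is indexed by sample_id with one integer column per OTU;
    ``taxonomy`` maps every OTU id to a rank-prefixed lineage string.
    """

    def __init__(self, counts: pd.DataFrame, taxonomy: Mapping[str, str],
                 marker: str = "16S"):
        counts = counts.copy()
        arr = counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise InvariantError("OTU counts must be numeric")
        if (arr < 0).any():
            raise InvariantError("negative OTU counts")
        if not np.allclose(arr, np.round(arr)):
            raise InvariantError("OTU counts must be integers")
        self.counts = counts.astype(np.int64)
        self.counts.index = self.counts.index.astype(str)
        self.counts.index.name = None
        self.counts.columns.name = None
        missing = [o for o in self.counts.columns if o not in taxonomy]
        if missing:
            raise InvariantError(f"taxonomy missing for OTUs: {missing[:5]}")
        self.taxonomy = {o: str(taxonomy[o]) for o in self.counts.columns}
        self.marker = marker
        zero = self.counts.sum(axis=0) == 0
        self.zero_otus: list[str] = list(self.counts.columns[zero])
        if self.zero_otus:
            warnings.warn(f"{len(self.zero_otus)} OTUs have all-zero counts",
                          stacklevel=2)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.columns)

    def rank_of(self, otu_id: str, rank: str = "phylum") -> str:
        ranks = parse_lineage(self.taxonomy[otu_id])
        return ranks.get(rank, f"unclassified_{rank}")

    def relative(self) -> pd.DataFrame:
        """Per-sample total-sum-scaled relative abundances."""
        totals = self.counts.sum(axis=1)
        if (totals == 0).any():
            bad = list(totals.index[totals == 0])
            raise InvariantError(f"samples with zero total counts: {bad}")
        return self.counts.div(totals, axis=0)

    def align_to(self, sample_ids: Iterable[str]) -> "OtuTable":
        ids = [str(s) for s in sample_ids]
        missing = [s for s in ids if s not in self.counts.index]
        if missing:
            raise InvariantError(f"samples absent from OTU table: {missing}")
        return OtuTable(self.counts.loc[ids], self.taxonomy, self.marker)

    def __repr__(self) -> str:  # pragma: no cover
        return (f"OtuTable({self.counts.shape[0]} samples, "
                f"{self.counts.shape[1]} OTUs, marker={self.marker})")


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","


def read_measurement_table(path: str | Path,
                           schema: Mapping[str, str] | None = None,
                           ) -> MeasurementTable:
    """Read a tidy CSV/TSV of measurements.

    Key columns (sample_id, treatment, period, replicate) must be present.
    Unparseable numeric cells (e.g. "n.d.") become missing values and are
    counted in a single warning.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep=_sep_for(path))
    for col in KEY_COLUMNS:
        if col not in raw.columns:
            raise InvariantError(f"missing key column: {col!r} in {path.name}")
    variables = [c for c in raw.columns if c not in KEY_COLUMNS]
    n_bad = 0
    for v in variables:
        coerced = pd.to_numeric(raw[v], errors="coerce")
        n_bad += int((coerced.isna() & raw[v].notna()).sum())
        raw[v] = coerced
    if n_bad:
        warnings.warn(f"{n_bad} unparseable numeric cells set to missing "
                      f"in {path.name}", stacklevel=2)
    units = dict(schema or {})
    return MeasurementTable(raw, units or None)


def write_measurement_table(table: MeasurementTable, path: str | Path) -> None:
    path = Path(path)
    table.data.to_csv(path, sep=_sep_for(path), index=False)


def read_otu_table(path: str | Path,
                   taxonomy_path: str | Path | None = None,
                   dialect: str = "auto",
                   marker: str = "16S") -> OtuTable:
    """Read an OTU table from wide TSV or BIOM 1.0 (JSON flavor).

    tsv_wide dialect: rows are OTUs (header sentinel ``#OTU ID`` / ``otu_id``
    in the first column), columns are samples; an optional trailing
    ``taxonomy`` column or a separate two-column taxonomy file supplies
    lineages.
    """
    path = Path(path)
    if dialect == "auto":
        dialect = "biom_json" if path.suffix.lower() == ".biom" or \
            path.read_text()[:1] == "{" else "tsv_wide"
    if dialect == "biom_json":
        return _read_biom_json(path, marker)
    if dialect != "tsv_wide":
        raise ValueError(f"unknown dialect: {dialect}")

    raw = pd.read_csv(path, sep="\t")
    first = raw.columns[0]
    if first.lstrip("#").strip().lower().replace(" ", "_") not in {
            "otu_id", "otu", "otuid"}:
        raise InvariantError(
            f"first header cell {first!r} is not an OTU-id sentinel")
    raw = raw.rename(columns={first: "otu_id"}).set_index("otu_id")
    raw.index = raw.index.astype(str)
    taxonomy: dict[str, str] = {}
    if "taxonomy" in raw.columns:
        taxonomy = raw["taxonomy"].astype(str).to_dict()
        raw = raw.drop(columns=["taxonomy"])
    if taxonomy_path is not None:
        tx = pd.read_csv(Path(taxonomy_path), sep=_sep_for(Path(taxonomy_path)),
                         header=None, names=["otu_id", "taxonomy"])
        taxonomy.update(dict(zip(tx["otu_id"].astype(str), tx["taxonomy"])))
    counts = raw.T  # -> samples x OTUs
    if (counts.to_numpy() < 0).any():
        raise InvariantError("negative OTU counts")
    if not taxonomy:
        raise InvariantError("no taxonomy provided (inline column or file)")
    return OtuTable(counts, taxonomy, marker)


def write_otu_table(otu: OtuTable, path: str | Path) -> None:
    """Write the wide-TSV dialect (rows OTUs, inline taxonomy column)."""
    path = Path(path)
    wide = otu.counts.T.copy()  # copy: .T shares axis objects
    wide.insert(len(wide.columns), "taxonomy",
                [otu.taxonomy[o] for o in wide.index])
    wide.index.name = "#OTU ID"
    wide.to_csv(path, sep="\t")


def _read_biom_json(path: Path, marker: str) -> OtuTable:
    doc = json.loads(path.read_text())
    otu_ids = [str(r["id"]) for r in doc["rows"]]
    sample_ids = [str(c["id"]) for c in doc["columns"]]
    shape = tuple(doc["shape"])
    mat = np.zeros(shape, dtype=np.int64)
    if doc.get("matrix_type") == "sparse":
        for i, j, v in doc["data"]:
            mat[int(i), int(j)] = int(v)
    else:
        mat[:] = np.asarray(doc["data"], dtype=np.int64)
    taxonomy = {}
    for r in doc["rows"]:
        tax = (r.get("metadata") or {}).get("taxonomy", "")
        if isinstance(tax, list):
            tax = ";".join(tax)
        taxonomy[str(r["id"])] = tax
    counts = pd.DataFrame(mat.T, index=sample_ids, columns=otu_ids)
    return OtuTable(counts, taxonomy, marker)


# ---------------------------------------------------------------------------
# configuration + result writing
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Thresholds, scoring assignments and run parameters for all stages."""

    scoring: dict[str, str] = field(default_factory=dict)  # variable -> kind
    reference_treatment: str = "CK"
    network_r_min: float = 0.6
    network_p_max: float = 0.001
    prevalence_min: float = 0.2
    vif_cutoff: float = 10.0
    phylum_min_frac: float = 0.01
    n_permutations: int = 999
    alpha: float = 0.05
    seed: int = 0
    output_dir: str = "results"

    def __post_init__(self) -> None:
        if not (0.0 <= self.network_r_min <= 1.0):
            raise InvariantError("network_r_min must lie in [0, 1]")
        if not (0.0 < self.network_p_max < 1.0):
            raise InvariantError("network_p_max must lie in (0, 1)")
        if self.vif_cutoff <= 1.0:
            raise InvariantError("vif_cutoff must exceed 1")
        if not (0.0 < self.alpha < 1.0):
            raise InvariantError("alpha must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**doc)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.__dict__, sort_keys=True))

    def digest(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def write_manifest(out_dir: str | Path, config: PipelineConfig,
                   files: Iterable[str | Path], warnings_log: list[str] | None = None,
                   ) -> Path:
    """Echo seed/config and per-file checksums into ``manifest.json``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    checksums = {}
    for f in files:
        f = Path(f)
        checksums[f.name] = hashlib.sha256(f.read_bytes()).hexdigest()
    manifest = {
        "seed": config.seed,
        "config_digest": config.digest(),
        "config": config.__dict__,
        "checksums": checksums,
        "warnings": list(warnings_log or []),
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path
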