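"""Data model and table I/O for pulldown quantification data.

Reads MaxQuant-style proteinGroups tables (tab-separated, per-sample iBAQ
intensity columns, "+" flag columns), sample-design tables mapping samples to
bait groups, and plain-text annotation lists of expected ubiquitin-binding
proteins (UbBPs).
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

#: Bait groups the analysis knows about.  ``bead_control`` is the streptavidin
#: bead-only negative control; the rest are ubiquitin chain baits named by
#: linkage (K48/K63/branched) and length (mono, Ub2, Ub3, Ub4).
BAIT_LEVELS = (
    "bead_control",
    "mono_Ub",
    "K48_Ub2",
    "K48_Ub3",
    "K48_Ub4",
    "K63_Ub2",
    "K63_Ub3",
    "K63_Ub4",
    "Br_Ub3",
)

DEFAULT_FLAG_COLUMNS = {
    "reverse": "Reverse",
    "contaminant": "Potential contaminant",
    "site_only": "Only identified by site",
}


class FormatError(ValueError):
    """Raised when an input table does not match the expected layout."""


@dataclass
class IntensityMatrix:
    """Protein x sample quantification with an explicit missingness mask.

    ``values`` holds NaN at masked cells so that no statistic can silently
    read a missing measurement.  ``scale`` is ``"linear"`` (raw iBAQ) or
    ``"log2"``.
    """

    protein_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    missing: np.ndarray
    scale: str = "linear"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.missing = np.asarray(self.missing, dtype=bool)
        shape = (len(self.protein_ids), len(self.sample_ids))
        if self.values.shape != shape or self.missing.shape != shape:
            raise ValueError(
                f"values/missing shape {self.values.shape} does not match "
                f"{len(self.protein_ids)} proteins x {len(self.sample_ids)} samples"
            )
        if self.scale not in ("linear", "log2"):
            raise ValueError(f"unknown scale {self.scale!r}")
        # enforce NaN at masked cells
        self.values = np.where(self.missing, np.nan, self.values)
        present = self.values[~self.missing]
        if self.scale == "linear" and present.size and not np.all(present > 0):
            raise ValueError("linear-scale intensities must be positive where present")

    @property
    def n_proteins(self) -> int:
        return len(self.protein_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def present_per_sample(self) -> np.ndarray:
        return (~self.missing).sum(axis=0)

    def present_per_protein(self) -> np.ndarray:
        return (~self.missing).sum(axis=1)

    def sample_index(self, sample_ids) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            return np.array([lookup[s] for s in sample_ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"sample {exc.args[0]!r} not in matrix") from exc

    def subset_proteins(self, protein_ids) -> "IntensityMatrix":
        lookup = {p: i for i, p in enumerate(self.protein_ids)}
        idx = np.array([lookup[p] for p in protein_ids], dtype=int)
        return IntensityMatrix(
            list(protein_ids), list(self.sample_ids),
            self.values[idx], self.missing[idx], self.scale,
        )

    def subset_samples(self, sample_ids) -> "IntensityMatrix":
        idx = self.sample_index(sample_ids)
        return IntensityMatrix(
            list(self.protein_ids), list(sample_ids),
            self.values[:, idx], self.missing[:, idx], self.scale,
        )

    def to_log2(self) -> "IntensityMatrix":
        """Log2-transform present cells; bijective on present values, mask kept."""
        if self.scale == "log2":
            return self.copy()
        with np.errstate(invalid="ignore"):
            vals = np.where(self.missing, np.nan, np.log2(self.values))
        return IntensityMatrix(
            list(self.protein_ids), list(self.sample_ids), vals, self.missing, "log2"
        )

    def to_linear(self) -> "IntensityMatrix":
        if self.scale == "linear":
            return self.copy()
        vals = np.where(self.missing, np.nan, np.exp2(self.values))
        return IntensityMatrix(
            list(self.protein_ids), list(self.sample_ids), vals, self.missing, "linear"
        )

    def copy(self) -> "IntensityMatrix":
        return IntensityMatrix(
            list(self.protein_ids), list(self.sample_ids),
            self.values.copy(), self.missing.copy(), self.scale,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.protein_ids, columns=self.sample_ids)


@dataclass
class ProteinRecord:
    """One protein-isoform row of the quantification table."""

    protein_id: str
    gene: str = ""
    isoform: str = ""
    reverse: bool = False
    contaminant: bool = False
    site_only: bool = False
    is_expected_ubbp: bool = False
    ubd_names: list[str] = field(default_factory=list)

    @property
    def flagged(self) -> bool:
        return self.reverse or self.contaminant or self.site_only


@dataclass
class SampleDesign:
    """Maps samples to bait group, replicate and dataset.

    Each dataset must contain exactly one ``bead_control`` group; groups used
    in variance estimation need at least two replicates.
    """

    frame: pd.DataFrame  # columns: sample_id, bait, replicate, dataset

    def __post_init__(self) -> None:
        required = {"sample_id", "bait", "replicate", "dataset"}
        missing_cols = required - set(self.frame.columns)
        if missing_cols:
            raise FormatError(f"design table lacks columns {sorted(missing_cols)}")
        if self.frame["sample_id"].duplicated().any():
            dup = self.frame.loc[self.frame["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise ValueError(f"duplicate sample id {dup!r} in design")
        for ds in self.datasets():
            baits = self.frame.loc[self.frame["dataset"] == ds, "bait"]
            if (baits == "bead_control").sum() == 0:
                raise ValueError(f"no control group: dataset {ds!r} has no bead_control samples")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame["sample_id"])

    def datasets(self) -> list[str]:
        return list(dict.fromkeys(self.frame["dataset"]))

    def baits(self, dataset: str | None = None) -> list[str]:
        sub = self.frame if dataset is None else self.frame[self.frame["dataset"] == dataset]
        return list(dict.fromkeys(sub["bait"]))

    def samples_for(self, bait: str, dataset: str | None = None) -> list[str]:
        sub = self.frame if dataset is None else self.frame[self.frame["dataset"] == dataset]
        return list(sub.loc[sub["bait"] == bait, "sample_id"])

    def group_sizes(self, dataset: str | None = None) -> dict[str, int]:
        return {b: len(self.samples_for(b, dataset)) for b in self.baits(dataset)}

    def subset(self, dataset: str) -> "SampleDesign":
        return SampleDesign(self.frame[self.frame["dataset"] == dataset].reset_index(drop=True))

    def drop_samples(self, sample_ids) -> "SampleDesign":
        keep = ~self.frame["sample_id"].isin(list(sample_ids))
        return SampleDesign(self.frame[keep].reset_index(drop=True))

    def statistical_baits(self, dataset: str | None = None, min_n: int = 2) -> list[str]:
        """Bait groups with enough replicates to enter variance estimation."""
        out = []
        for bait, n in self.group_sizes(dataset).items():
            if n >= min_n:
                out.append(bait)
            else:
                warnings.warn(
                    f"group {bait!r} has {n} sample(s); excluded from variance estimation"
                )
        return out


@dataclass
class AnnotationSet:
    """Expected-UbBP identifiers with their source tags; lookup is case-insensitive."""

    sources: dict[str, list[str]]  # case-normalized identifier -> source tags

    @classmethod
    def from_pairs(cls, pairs) -> "AnnotationSet":
        sources: dict[str, list[str]] = {}
        n_dup = 0
        for ident, source in pairs:
            key = str(ident).strip().upper()
            if not key:
                continue
            if key in sources:
                n_dup += 1
                if source and source not in sources[key]:
                    sources[key].append(source)
            else:
                sources[key] = [source] if source else []
        if n_dup:
            warnings.warn(f"annotation list: {n_dup} duplicate identifier(s) deduplicated")
        return cls(sources)

    def __contains__(self, ident: str) -> bool:
        return str(ident).strip().upper() in self.sources

    def __len__(self) -> int:
        return len(self.sources)

    def tags(self, ident: str) -> list[str]:
        return self.sources.get(str(ident).strip().upper(), [])


# ---------------------------------------------------------------------------
# readers / writers


def read_protein_table(
    path,
    intensity_prefix: str = "iBAQ ",
    flag_columns: dict[str, str] | None = None,
    id_column: str = "Protein IDs",
    gene_column: str = "Gene names",
) -> tuple[IntensityMatrix, list[ProteinRecord]]:
    """Read a MaxQuant-style proteinGroups table.

    Intensity columns are identified by ``intensity_prefix``; zeros and empty
    cells become missing (iBAQ zero means "not quantified").  Flag columns
    mark a row with ``"+"``.
    """
    flag_columns = {**DEFAULT_FLAG_COLUMNS, **(flag_columns or {})}
    df = pd.read_csv(path, sep="\t", dtype=str)
    icols = [c for c in df.columns if c.startswith(intensity_prefix)]
    if not icols:
        raise FormatError(f"no intensity columns with prefix {intensity_prefix!r} in {path}")
    if id_column not in df.columns:
        raise FormatError(f"missing id column {id_column!r}")
    ids = df[id_column].astype(str).tolist()
    seen: set[str] = set()
    for pid in ids:
        if pid in seen:
            raise ValueError(f"duplicate protein_id {pid!r}")
        seen.add(pid)

    raw = df[icols].apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    missing = ~np.isfinite(raw) | (raw == 0)
    matrix = IntensityMatrix(
        ids,
        [c[len(intensity_prefix):] for c in icols],
        np.where(missing, np.nan, raw),
        missing,
        "linear",
    )

    def _flag(col: str) -> np.ndarray:
        if col in df.columns:
            return df[col].fillna("").str.strip().eq("+").to_numpy()
        return np.zeros(len(df), dtype=bool)

    rev = _flag(flag_columns["reverse"])
    con = _flag(flag_columns["contaminant"])
    sit = _flag(flag_columns["site_only"])
    genes = df[gene_column].fillna("") if gene_column in df.columns else [""] * len(df)
    records = []
    for i, pid in enumerate(ids):
        base, _, iso = pid.partition("_")
        records.append(
            ProteinRecord(
                protein_id=pid,
                gene=str(genes[i]) if len(genes) else "",
                isoform=iso,
                reverse=bool(rev[i]),
                contaminant=bool(con[i]),
                site_only=bool(sit[i]),
            )
        )
    return matrix, records


def write_protein_table(
    matrix: IntensityMatrix,
    records: list[ProteinRecord],
    path,
    intensity_prefix: str = "iBAQ ",
) -> None:
    if len(records) != matrix.n_proteins:
        raise ValueError("records do not align with matrix rows")
    out = pd.DataFrame({"Protein IDs": matrix.protein_ids})
    out["Gene names"] = [r.gene for r in records]
    out["Reverse"] = ["+" if r.reverse else "" for r in records]
    out["Potential contaminant"] = ["+" if r.contaminant else "" for r in records]
    out["Only identified by site"] = ["+" if r.site_only else "" for r in records]
    lin = matrix.to_linear()
    vals = np.where(lin.missing, 0.0, lin.values)
    for j, sid in enumerate(matrix.sample_ids):
        out[intensity_prefix + sid] = vals[:, j]
    out.to_csv(path, sep="\t", index=False)


def read_design(path, extra_baits: tuple[str, ...] = ()) -> SampleDesign:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "bait": str, "dataset": str})
    design = SampleDesign(df)
    known = set(BAIT_LEVELS) | set(extra_baits)
    unknown = sorted(set(design.frame["bait"]) - known)
    if unknown:
        raise ValueError(f"unknown bait labels {unknown}; declare them via extra_baits")
    return design


def write_design(design: SampleDesign, path) -> None:
    design.frame.to_csv(path, sep="\t", index=False)


def check_design_matches_matrix(design: SampleDesign, matrix: IntensityMatrix) -> None:
    absent = [s for s in design.sample_ids if s not in set(matrix.sample_ids)]
    if absent:
        raise ValueError(f"design samples absent from matrix: {absent}")


def read_annotation(path) -> AnnotationSet:
    """Read an annotation list: one identifier per line, or identifier<TAB>source."""
    pairs = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            pairs.append((parts[0], parts[1].strip() if len(parts) > 1 else ""))
    if not pairs:
        raise FormatError(f"annotation file {path} is empty")
    return AnnotationSet.from_pairs(pairs)


def annotate(records: list[ProteinRecord], annotation: AnnotationSet) -> list[ProteinRecord]:
    """Return records with is_expected_ubbp / ubd_names filled from the list.

    Both the gene symbol and the full protein id (isoform suffix stripped) are
    tried, case-normalized.
    """
    out = []
    for rec in records:
        base = rec.protein_id.partition("_")[0]
        hit = rec.gene in annotation or base in annotation or rec.protein_id in annotation
        tags = annotation.tags(rec.gene) or annotation.tags(base) or annotation.tags(rec.protein_id)
        out.append(replace(rec, is_expected_ubbp=hit, ubd_names=list(tags)))
    return out


# ---------------------------------------------------------------------------
# run configuration


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise FormatError(f"config {path} did not parse to a mapping")
    return cfg


def config_hash(cfg: dict) -> str:
    """Stable short hash of a config mapping, for run logs."""
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
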