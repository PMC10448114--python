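"""Readers and writers for the on-disk formats the pipeline touches.

Four kinds of input are supported, all plain tab-separated UTF-8 text with
'.' decimals:

* per-read poly(A) tail tables in the nanopolish-polya TSV dialect
  (mandatory columns ``readname``, ``contig``, ``polya_length``, ``qc_tag``;
  the remaining columns of the full ten-column output are accepted and
  ignored);
* gene × sample integer count matrices with a companion sample-metadata
  table (condition / assay / replicate per sample);
* plain-text gene lists (TOP membership, mitochondrial/pseudogene
  exclusions), one identifier per line;
* a YAML pipeline configuration.

Every reader validates its input strictly and raises :class:`FormatError`
with the offending column, sample or line named, so that malformed tables
fail loudly rather than silently biasing downstream statistics.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "FormatError",
    "QcTag",
    "TailRead",
    "CountMatrix",
    "GeneSets",
    "PipelineConfig",
    "read_polya_table",
    "write_polya_table",
    "tail_reads_to_frame",
    "frame_to_tail_reads",
    "read_count_matrix",
    "write_count_matrix",
    "read_gene_list",
    "read_gene_sets",
]


class FormatError(ValueError):
    """A table violates the expected dialect (missing column, bad value)."""


class QcTag(enum.Enum):
    """Per-read QC verdict of the nanopolish poly(A) segmentation.

    Tags outside the known vocabulary are mapped to ``OTHER`` and treated as
    non-PASS, tolerating tool-version drift in upstream callers.
    """

    PASS = "PASS"
    NOREGION = "NOREGION"
    SUFFCLIP = "SUFFCLIP"
    ADAPTER = "ADAPTER"
    READ_FAILED_LOAD = "READ_FAILED_LOAD"
    OTHER = "OTHER"

    @classmethod
    def parse(cls, value: str) -> "QcTag":
        try:
            return cls(str(value))
        except ValueError:
            return cls.OTHER


@dataclass
class TailRead:
    """One sequenced molecule's estimated poly(A) tail length.

    ``transcript_id`` is the contig the read maps to; ``polya_length`` is the
    estimated tail length in nucleotides (non-negative).
    """

    read_id: str
    transcript_id: str
    sample_id: str
    condition: str
    polya_length: float
    qc_tag: QcTag = QcTag.PASS

    def __post_init__(self) -> None:
        if isinstance(self.qc_tag, str):
            self.qc_tag = QcTag.parse(self.qc_tag)
        if not (self.polya_length >= 0 and math.isfinite(self.polya_length)):
            raise ValueError(
                f"polya_length must be finite and >= 0, got {self.polya_length!r}"
            )


#: mandatory columns of the accepted nanopolish-polya dialect
POLYA_MANDATORY = ("readname", "contig", "polya_length", "qc_tag")


def read_polya_table(
    path,
    require_pass: bool = False,
    sample_id: str | None = None,
    condition: str | None = None,
) -> list[TailRead]:
    """Read a nanopolish-polya style TSV into a list of :class:`TailRead`.

    ``sample_id`` / ``condition`` columns are honoured when present in the
    file; otherwise the keyword values (or ``"sample1"`` / ``"unknown"``)
    label every row.  With ``require_pass`` only PASS rows are returned; the
    filter is idempotent and never reorders rows.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in POLYA_MANDATORY:
        if col not in df.columns:
            raise FormatError(f"missing mandatory column '{col}' in {path}")
    def _parse_float(s: str) -> float:
        try:
            return float(s)  # correctly-rounded parse, exact round-trips
        except ValueError:
            return math.nan

    lengths = df["polya_length"].map(_parse_float).astype(float)
    bad = lengths.isna() | (lengths < 0) | ~np.isfinite(lengths)
    if bad.any():
        # +2: one for the header line, one for 1-based numbering
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
        raise FormatError(
            f"non-numeric or negative polya_length at line {line} of {path}"
        )
    samples = (
        df["sample_id"].astype(str)
        if "sample_id" in df.columns
        else pd.Series([sample_id or "sample1"] * len(df))
    )
    conditions = (
        df["condition"].astype(str)
        if "condition" in df.columns
        else pd.Series([condition or "unknown"] * len(df))
    )
    reads = [
        TailRead(
            read_id=r,
            transcript_id=t,
            sample_id=s,
            condition=c,
            polya_length=float(l),
            qc_tag=QcTag.parse(q),
        )
        for r, t, s, c, l, q in zip(
            df["readname"], df["contig"], samples, conditions, lengths, df["qc_tag"]
        )
    ]
    if require_pass:
        reads = [r for r in reads if r.qc_tag is QcTag.PASS]
    return reads


def tail_reads_to_frame(reads: Iterable[TailRead]) -> pd.DataFrame:
    """Tabular view of a read list (column names follow the TSV dialect)."""
    reads = list(reads)
    return pd.DataFrame(
        {
            "readname": [r.read_id for r in reads],
            "contig": [r.transcript_id for r in reads],
            "sample_id": [r.sample_id for r in reads],
            "condition": [r.condition for r in reads],
            "polya_length": np.array([r.polya_length for r in reads], dtype=float),
            "qc_tag": [r.qc_tag.value for r in reads],
        }
    )


def frame_to_tail_reads(df: pd.DataFrame) -> list[TailRead]:
    return [
        TailRead(
            read_id=row.readname,
            transcript_id=row.contig,
            sample_id=row.sample_id,
            condition=row.condition,
            polya_length=float(row.polya_length),
            qc_tag=QcTag.parse(row.qc_tag),
        )
        for row in df.itertuples(index=False)
    ]


def write_polya_table(reads: Iterable[TailRead] | pd.DataFrame, path) -> Path:
    """Write reads as a nanopolish-polya dialect TSV (round-trip safe).

    Floats are written with pandas' shortest round-tripping representation,
    so ``read_polya_table(write_polya_table(x))`` reproduces every field
    bit-for-bit.
    """
    df = reads if isinstance(reads, pd.DataFrame) else tail_reads_to_frame(reads)
    path = Path(path)
    df.to_csv(path, sep="\t", index=False)
    return path


@dataclass
class CountMatrix:
    """Gene × sample integer counts with per-sample metadata.

    ``sample_meta`` is indexed by sample id and carries ``condition``,
    ``assay`` (``rna`` or ``rfp``) and ``replicate`` columns.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise FormatError(
                f"counts shape {self.counts.shape} inconsistent with "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.mod(self.counts, 1) == 0):
                raise FormatError("counts must be integral")
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            raise FormatError("counts must be non-negative")
        missing = [s for s in self.sample_ids if s not in self.sample_meta.index]
        if missing:
            raise FormatError(f"sample '{missing[0]}' has no metadata row")
        for col in ("condition", "assay"):
            if col not in self.sample_meta.columns:
                raise FormatError(f"sample metadata lacks '{col}' column")
        bad_assay = set(self.sample_meta["assay"]) - {"rna", "rfp"}
        if bad_assay:
            raise FormatError(f"unknown assay value {sorted(bad_assay)[0]!r}")
        self.sample_meta = self.sample_meta.loc[self.sample_ids]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids)

    def condition_labels(self) -> pd.Series:
        return self.sample_meta["condition"]

    def samples_for(self, condition: str) -> list[str]:
        meta = self.sample_meta
        return list(meta.index[meta["condition"] == condition])

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return CountMatrix(
            gene_ids=list(self.gene_ids),
            sample_ids=list(sample_ids),
            counts=self.counts[:, idx],
            sample_meta=self.sample_meta.loc[list(sample_ids)],
        )


def read_count_matrix(path, meta_path) -> CountMatrix:
    """Read a genes × samples counts TSV plus its sample-metadata TSV.

    All-zero genes are retained; filtering policy belongs downstream.
    Raises :class:`FormatError` for samples missing from the metadata and for
    negative or fractional counts.
    """
    table = pd.read_csv(path, sep="\t", index_col=0)
    values = table.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise FormatError(f"non-numeric count value in {path}")
    if (values < 0).any():
        raise FormatError(f"negative count in {path}")
    if not np.all(np.mod(values, 1) == 0):
        raise FormatError(f"fractional count in {path}")
    meta = pd.read_csv(meta_path, sep="\t")
    if "sample_id" not in meta.columns:
        raise FormatError(f"sample metadata {meta_path} lacks 'sample_id' column")
    meta = meta.set_index("sample_id")
    missing = [s for s in table.columns if s not in meta.index]
    if missing:
        raise FormatError(f"sample '{missing[0]}' present in counts but not in metadata")
    return CountMatrix(
        gene_ids=[str(g) for g in table.index],
        sample_ids=[str(s) for s in table.columns],
        counts=values.astype(np.int64),
        sample_meta=meta,
    )


def write_count_matrix(cm: CountMatrix, path, meta_path) -> None:
    cm.to_frame().rename_axis("gene_id").to_csv(path, sep="\t")
    cm.sample_meta.rename_axis("sample_id").to_csv(meta_path, sep="\t")


@dataclass
class GeneSets:
    """TOP membership and exclusion lists over a gene universe."""

    universe: set[str]
    top_genes: set[str]
    exclusions: set[str] = field(default_factory=set)
    n_dropped: int = 0

    def __post_init__(self) -> None:
        if not self.top_genes <= self.universe:
            raise ValueError("top_genes must be a subset of the universe")


def read_gene_list(path) -> list[str]:
    """One gene id per line; blank lines and '#' comments ignored."""
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line)
    return out


def read_gene_sets(top_list_path, universe: Iterable[str], exclusions_path=None) -> GeneSets:
    """Load TOP/exclusion lists, restricting TOP genes to the universe.

    The universe is the set of genes actually captured in the current
    dataset; TOP list entries outside it are counted in ``n_dropped``.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("gene universe is empty")
    top = read_gene_list(top_list_path)
    top_in = set(top) & universe
    exclusions = set(read_gene_list(exclusions_path)) if exclusions_path else set()
    return GeneSets(
        universe=universe,
        top_genes=top_in,
        exclusions=exclusions,
        n_dropped=len(set(top)) - len(top_in),
    )


@dataclass
class PipelineConfig:
    """Plumbing-level settings shared by the CLI commands.

    ``bin_edges`` are the tail-length band edges in nt (default 30 / 90,
    giving the <30, ~60 and >90 bands); ``alpha`` is the raw tail-shift
    threshold, ``q_threshold`` the FDR cut for differential accumulation and
    ``te_threshold`` the |Δlog2TE| call threshold.
    """

    bin_edges: tuple[float, float] = (30.0, 90.0)
    min_reads_per_contig: int = 30
    alpha: float = 0.05
    q_threshold: float = 0.05
    te_threshold: float = 0.5
    timepoints_h: tuple[float, ...] = (0.0, 3.0, 6.0, 9.0)
    n_replicates: int = 3
    seed: int = 0
    paths: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        edges = tuple(float(e) for e in self.bin_edges)
        if not all(a < b for a, b in zip(edges, edges[1:])):
            raise ValueError("bin_edges must be strictly increasing")
        if self.min_reads_per_contig < 1:
            raise ValueError("min_reads_per_contig must be >= 1")
        self.bin_edges = edges
        self.timepoints_h = tuple(float(t) for t in self.timepoints_h)
        self.seed = int(self.seed)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["bin_edges"] = list(self.bin_edges)
        data["timepoints_h"] = list(self.timepoints_h)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)
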