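"""Tabular IO: RSEM-style expression tables, sample metadata, GMT gene sets,
centroid tables.

Two dialects are read for isoform expression:

* per-sample RSEM ``isoforms.results`` files (one row per transcript,
  columns including ``transcript_id``, ``TPM`` and optionally
  ``expected_count`` / ``effective_length`` / ``gene_id``);
* a "wide" matrix TSV (first column transcript id, one column per sample),
  which is also the dialect this package writes.

Gene symbols are the join key throughout; an optional two-column id map
translates foreign identifier spaces (Entrez, Ensembl) to symbols.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, IntegrityError

logger = logging.getLogger(__name__)

__all__ = [
    "IsoformMatrix",
    "GeneMatrix",
    "read_rsem_isoforms",
    "read_isoform_table",
    "write_isoform_table",
    "collapse_to_gene",
    "read_gmt",
    "write_gmt",
    "read_centroid_table",
    "write_centroid_table",
    "read_metadata",
    "write_metadata",
    "read_id_map",
]

METADATA_ENUMS = {
    "tissue": {"tumor", "normal", "unknown"},
    "subtype": {"TRU", "PP", "PI", "unknown"},
    "cimp": {"low", "intermediate", "high", "unknown"},
    "stage": {"I", "II", "III", "IV", "unknown"},
}


@dataclass
class IsoformMatrix:
    """Transcript-level expression with a transcript→gene grouping.

    ``tpm`` (and optional ``counts``) are transcripts × samples DataFrames;
    ``gene_of_transcript`` maps each transcript id to a gene symbol.
    Transcripts with no known gene are retained under their own id and
    listed in ``unmapped``.
    """

    tpm: pd.DataFrame
    gene_of_transcript: pd.Series
    counts: pd.DataFrame | None = None
    effective_length: pd.Series | None = None
    unmapped: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.tpm.index.duplicated().any():
            raise IntegrityError("duplicate transcript ids")
        if self.tpm.columns.duplicated().any():
            raise IntegrityError("duplicate sample ids")
        vals = self.tpm.to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            raise IntegrityError("non-finite TPM values")
        if (vals < 0).any():
            raise IntegrityError("negative TPM values")
        if self.counts is not None:
            if self.counts.shape != self.tpm.shape:
                raise IntegrityError("counts and tpm must have the same shape")
            if (self.counts.to_numpy(dtype=float) < 0).any():
                raise IntegrityError("negative counts")
        if self.effective_length is not None and (self.effective_length <= 0).any():
            raise IntegrityError("effective lengths must be positive")
        missing = self.tpm.index.difference(self.gene_of_transcript.index)
        if len(missing):
            raise IntegrityError(f"transcripts without gene mapping entry: {list(missing)[:5]}")

    @property
    def transcripts(self) -> list[str]:
        return list(self.tpm.index)

    @property
    def samples(self) -> list[str]:
        return list(self.tpm.columns)

    @property
    def genes(self) -> list[str]:
        return sorted(set(self.gene_of_transcript.loc[self.tpm.index]))


@dataclass
class GeneMatrix:
    """Gene-level values (genes × samples) with a tag for what they are."""

    values: pd.DataFrame
    value_kind: str = "TPM"

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise IntegrityError("duplicate gene ids")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise IntegrityError("non-finite values")


def read_id_map(path: str | Path) -> pd.Series:
    """Two-column TSV (foreign id, gene symbol) → Series foreign→symbol."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise FormatError(f"{path}: id map needs two columns")
    return pd.Series(df[1].values, index=df[0].values)


def _rsem_frame(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    cols = {c.lower(): c for c in df.columns}
    if "transcript_id" not in cols:
        # tolerate a bare first column of transcript ids
        df = df.rename(columns={df.columns[0]: "transcript_id"})
        cols = {c.lower(): c for c in df.columns}
    if "tpm" not in cols:
        raise FormatError(f"{path}: no TPM column")
    return df.rename(columns={cols["tpm"]: "TPM", cols["transcript_id"]: "transcript_id"})


def read_rsem_isoforms(
    paths: str | Path | Sequence[str | Path],
    sample_names: Sequence[str] | None = None,
    id_map: Mapping[str, str] | pd.Series | None = None,
) -> IsoformMatrix:
    """Read one or more RSEM ``isoforms.results``-style files into a matrix.

    Each file contributes one sample (named from ``sample_names`` or the
    file stem).  Transcripts are grouped to genes via the file's
    ``gene_id`` column and/or ``id_map``; unmapped transcripts keep their
    own id and are flagged.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    names = list(sample_names) if sample_names else [Path(p).stem for p in paths]
    if len(names) != len(paths):
        raise ValueError("sample_names length must match paths")

    tpm_cols, count_cols = {}, {}
    gene_map: dict[str, str] = {}
    eff_len: dict[str, float] = {}
    for name, path in zip(names, paths):
        df = _rsem_frame(path)
        if df["transcript_id"].duplicated().any():
            dup = df.loc[df["transcript_id"].duplicated(), "transcript_id"].iloc[0]
            raise IntegrityError(f"{path}: duplicate transcript id {dup!r}")
        df = df.set_index("transcript_id")
        tpm_cols[name] = df["TPM"].astype(float)
        lower = {c.lower(): c for c in df.columns}
        if "expected_count" in lower:
            count_cols[name] = df[lower["expected_count"]].astype(float)
        if "effective_length" in lower:
            eff_len.update(df[lower["effective_length"]].astype(float).to_dict())
        if "gene_id" in lower:
            gene_map.update(df[lower["gene_id"]].astype(str).to_dict())

    tpm = pd.DataFrame(tpm_cols)
    counts = pd.DataFrame(count_cols) if len(count_cols) == len(names) else None
    if id_map is not None:
        id_map = pd.Series(id_map)
        for tx in tpm.index:
            key = gene_map.get(tx, tx)
            if key in id_map.index:
                gene_map[tx] = str(id_map[key])
            elif tx in id_map.index:
                gene_map[tx] = str(id_map[tx])
    unmapped = [tx for tx in tpm.index if tx not in gene_map]
    if unmapped:
        logger.warning("%d transcripts without gene mapping; kept under own id", len(unmapped))
    genes = pd.Series({tx: gene_map.get(tx, tx) for tx in tpm.index})
    lengths = pd.Series(eff_len).reindex(tpm.index) if eff_len else None
    if lengths is not None and lengths.isna().any():
        lengths = None
    return IsoformMatrix(tpm, genes, counts=counts, effective_length=lengths, unmapped=unmapped)


def read_isoform_table(
    path: str | Path,
    gene_map_path: str | Path | None = None,
    counts_path: str | Path | None = None,
) -> IsoformMatrix:
    """Read a wide transcripts × samples TPM table (this package's dialect).

    The first column is the transcript id; an optional second column
    ``gene_id`` carries the grouping (otherwise supply ``gene_map_path``).
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    first = df.columns[0]
    df = df.set_index(first)
    if df.index.duplicated().any():
        raise IntegrityError(f"{path}: duplicate transcript ids")
    if "gene_id" in df.columns:
        genes = df["gene_id"].astype(str)
        df = df.drop(columns=["gene_id"])
    elif gene_map_path is not None:
        genes = read_id_map(gene_map_path).reindex(df.index)
        genes = genes.fillna(pd.Series(df.index, index=df.index))
    else:
        genes = pd.Series(df.index, index=df.index)
    counts = None
    if counts_path is not None:
        cdf = pd.read_csv(counts_path, sep="\t", comment="#").set_index(first)
        if "gene_id" in cdf.columns:
            cdf = cdf.drop(columns=["gene_id"])
        counts = cdf.astype(float).reindex(index=df.index, columns=df.columns)
    return IsoformMatrix(df.astype(float), genes, counts=counts)


def write_isoform_table(iso: IsoformMatrix, path: str | Path, what: str = "tpm",
                        header_lines: Sequence[str] = ()) -> None:
    """Write the TPM (or counts) matrix as wide TSV with a gene_id column."""
    mat = iso.tpm if what == "tpm" else iso.counts
    if mat is None:
        raise ValueError(f"matrix has no {what}")
    out = mat.copy()
    out.insert(0, "gene_id", iso.gene_of_transcript.loc[out.index])
    out.index.name = "transcript_id"
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        out.to_csv(fh, sep="\t", float_format="%.10g")


def collapse_to_gene(iso: IsoformMatrix, genes: Sequence[str] | None = None) -> GeneMatrix:
    """Sum member-transcript TPMs to gene-level TPM.

    Empty gene groups (requested genes with no transcript) are absent
    from the output and logged.
    """
    grouping = iso.gene_of_transcript.loc[iso.tpm.index]
    summed = iso.tpm.groupby(grouping).sum()
    if genes is not None:
        missing = [g for g in genes if g not in summed.index]
        if missing:
            logger.warning("collapse_to_gene: %d requested genes have no transcripts", len(missing))
        summed = summed.loc[[g for g in genes if g in summed.index]]
    return GeneMatrix(summed, value_kind="TPM")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT file into {set name: member gene list}."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3 or not any(p.strip() for p in parts[2:]):
                raise FormatError(f"{path}:{lineno}: GMT line needs a name, description and ≥1 member")
            name = parts[0]
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = [p for p in parts[2:] if p.strip()]
    return sets


def write_gmt(sets: Mapping[str, Sequence[str]], path: str | Path,
              descriptions: Mapping[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc, *members]) + "\n")


def read_centroid_table(path: str | Path) -> pd.DataFrame:
    """Gene × class centroid profile table (TSV, first column = gene)."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if df.index.duplicated().any():
        raise IntegrityError(f"{path}: duplicate genes in centroid table")
    if not np.isfinite(df.to_numpy(dtype=float)).all():
        raise FormatError(f"{path}: non-finite centroid values")
    return df.astype(float)


def write_centroid_table(profile: pd.DataFrame, path: str | Path) -> None:
    out = profile.copy()
    out.index.name = out.index.name or "gene"
    out.to_csv(path, sep="\t", float_format="%.10g")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Sample metadata TSV, indexed by sample_id.

    Missing categorical fields parse to ``"unknown"`` rather than
    erroring; survival fields stay NaN when absent.  Categories outside
    the known enumerations are a format error.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        df = df.rename(columns={df.columns[0]: "sample_id"})
    df = df.set_index("sample_id")
    if df.index.duplicated().any():
        raise IntegrityError(f"{path}: duplicate sample ids")
    for col, allowed in METADATA_ENUMS.items():
        if col not in df.columns:
            df[col] = "unknown"
        df[col] = df[col].fillna("unknown").astype(str)
        bad = set(df[col]) - allowed
        if bad:
            raise FormatError(f"{path}: invalid {col} values {sorted(bad)}")
    if "gender" not in df.columns:
        df["gender"] = "unknown"
    df["gender"] = df["gender"].fillna("unknown").astype(str)
    for col in ("pfi_time", "pfi_event"):
        if col not in df.columns:
            df[col] = np.nan
        df[col] = pd.to_numeric(df[col], errors="coerce")
    has_event = df["pfi_event"].notna()
    if (df.loc[has_event, "pfi_time"].isna()).any():
        raise IntegrityError(f"{path}: pfi_event present without pfi_time")
    if (df.loc[df["pfi_time"].notna(), "pfi_time"] < 0).any():
        raise IntegrityError(f"{path}: negative pfi_time")
    bad_ev = df.loc[has_event, "pfi_event"]
    if (~bad_ev.isin([0, 1])).any():
        raise IntegrityError(f"{path}: pfi_event must be 0/1")
    return df


def write_metadata(meta: pd.DataFrame, path: str | Path,
                   header_lines: Sequence[str] = ()) -> None:
    out = meta.copy()
    out.index.name = "sample_id"
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        out.to_csv(fh, sep="\t", float_format="%.10g")
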