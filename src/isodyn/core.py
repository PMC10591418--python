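"""Core containers and I/O for two-breed, seven-stage transcript expression data.

The study design this package targets is a pair of time-series transcriptome
profiles: two chicken breeds (a fast-growing broiler, ``AA``, and a
slow-growing indigenous breed, ``LS``) sampled at three embryonic and four
post-hatching stages with three biological replicates each.  Expression is
carried at transcript resolution so that isoform-level questions (dominant
isoforms, switch events) remain answerable downstream.

All tabular data live in pandas objects; annotation is read from Ensembl-style
GTF via :mod:`pyranges`.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pyranges

logger = logging.getLogger(__name__)

#: The seven sampled developmental stages, in developmental order.
STAGES: tuple[str, ...] = ("E10", "E14", "E18", "D1", "W1", "W3", "W5")

#: Default numeric encoding of stages as days since onset of incubation
#: (hatch at day 21, so post-hatch day 1 is day 22).
STAGE_DAYS: dict[str, float] = {
    "E10": 10.0,
    "E14": 14.0,
    "E18": 18.0,
    "D1": 22.0,
    "W1": 28.0,
    "W3": 42.0,
    "W5": 56.0,
}

#: Post-hatching stages (used when restricting DET sets to adult time points).
POSTHATCH_STAGES: tuple[str, ...] = ("D1", "W1", "W3", "W5")


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


class GTFParseError(ValueError):
    """Raised when a GTF record cannot be interpreted."""


# ---------------------------------------------------------------------------
# Sample metadata
# ---------------------------------------------------------------------------

@dataclass
class SampleMetadata:
    """Per-sample design information.

    ``frame`` is indexed by ``sample_id`` and carries ``breed``, ``stage``,
    ``replicate`` and ``library_size`` (total mapped fragments).  Stage is an
    ordered categorical over the seven stages; breed is categorical with two
    levels.
    """

    frame: pd.DataFrame
    stages: tuple[str, ...] = STAGES

    def __post_init__(self) -> None:
        required = {"breed", "stage", "replicate", "library_size"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValidationError(f"metadata missing columns: {sorted(missing)}")
        if self.frame.index.has_duplicates:
            dupes = self.frame.index[self.frame.index.duplicated()].tolist()
            raise ValidationError(f"duplicate sample ids: {dupes}")
        unknown = set(self.frame["stage"]) - set(self.stages)
        if unknown:
            raise ValidationError(f"unknown stages: {sorted(unknown)}")
        if (self.frame["library_size"] <= 0).any():
            raise ValidationError("library_size must be positive")
        self.frame = self.frame.copy()
        self.frame["stage"] = pd.Categorical(
            self.frame["stage"], categories=list(self.stages), ordered=True
        )

    @property
    def sample_ids(self) -> pd.Index:
        return self.frame.index

    @property
    def breeds(self) -> list[str]:
        return sorted(self.frame["breed"].unique())

    def samples_for(self, breed: str | None = None, stage: str | None = None) -> pd.Index:
        mask = pd.Series(True, index=self.frame.index)
        if breed is not None:
            mask &= self.frame["breed"] == breed
        if stage is not None:
            mask &= self.frame["stage"] == stage
        return self.frame.index[mask]

    @property
    def library_sizes(self) -> pd.Series:
        return self.frame["library_size"]

    @classmethod
    def read_tsv(cls, path, stages: tuple[str, ...] = STAGES) -> "SampleMetadata":
        frame = pd.read_csv(path, sep="\t", index_col="sample_id")
        return cls(frame, stages=stages)

    def write_tsv(self, path) -> None:
        out = self.frame.copy()
        out.index.name = "sample_id"
        out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Transcript annotation
# ---------------------------------------------------------------------------

def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping 1-based closed intervals; keeps adjacent ones apart."""
    merged: list[tuple[int, int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1]:
            prev = merged.pop()
            merged.append((prev[0], max(prev[1], end)))
        else:
            merged.append((start, end))
    return merged


@dataclass
class TranscriptAnnotation:
    """Gene/transcript mapping with exonic lengths.

    ``frame`` is indexed by ``transcript_id`` with columns ``gene_id`` and
    ``length_bp`` (sum of merged exon widths).  ``exons`` maps transcript id to
    its 1-based closed exon intervals as given in the source GTF.
    """

    frame: pd.DataFrame
    exons: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.frame.index.has_duplicates:
            raise ValidationError("duplicate transcript ids in annotation")
        if (self.frame["length_bp"] <= 0).any():
            raise ValidationError("transcript lengths must be positive")

    @property
    def transcript_ids(self) -> pd.Index:
        return self.frame.index

    @property
    def gene_of(self) -> pd.Series:
        return self.frame["gene_id"]

    @property
    def lengths(self) -> pd.Series:
        return self.frame["length_bp"]

    def transcripts_of_gene(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for tid, gid in self.frame["gene_id"].items():
            out.setdefault(gid, []).append(tid)
        return {g: sorted(ts) for g, ts in out.items()}

    def multi_isoform_genes(self) -> list[str]:
        counts = self.frame.groupby("gene_id").size()
        return sorted(counts.index[counts >= 2])

    def genes_for(self, transcripts) -> set[str]:
        tids = pd.Index(list(transcripts))
        missing = tids.difference(self.frame.index)
        if len(missing):
            raise ValidationError(f"unknown transcripts: {sorted(missing)[:5]}")
        return set(self.frame.loc[tids, "gene_id"])


_ATTR_RE = re.compile(r'(\w+) "([^"]*)"')


def read_gtf(path) -> TranscriptAnnotation:
    """Read an Ensembl-dialect GTF and build the transcript annotation.

    Only ``exon`` records are used; a transcript's length is the summed width
    of its merged exon intervals.  Exon records lacking a ``transcript_id`` or
    ``gene_id`` attribute raise :class:`GTFParseError` naming the line.
    """
    # Pre-scan exon records so attribute errors carry a line number
    # (pyranges would silently yield NaN).
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise GTFParseError(f"line {lineno}: expected 9 tab-separated fields")
            if fields[2] != "exon":
                continue
            attrs = dict(_ATTR_RE.findall(fields[8]))
            for key in ("transcript_id", "gene_id"):
                if key not in attrs:
                    raise GTFParseError(f'line {lineno}: exon record lacks "{key}"')

    gr = pyranges.read_gtf(path)
    df = gr.df
    exon_df = df[df["Feature"] == "exon"]
    if exon_df.empty:
        raise GTFParseError("GTF contains no exon records")

    exons: dict[str, list[tuple[int, int]]] = {}
    genes: dict[str, str] = {}
    for row in exon_df.itertuples():
        tid = row.transcript_id
        # pyranges stores 0-based half-open; restore the GTF's 1-based closed.
        exons.setdefault(tid, []).append((int(row.Start) + 1, int(row.End)))
        genes[tid] = row.gene_id

    records = []
    for tid in sorted(exons):
        raw = exons[tid]
        merged = _merge_intervals(raw)
        if len(merged) != len(raw):
            logger.warning("transcript %s: overlapping exon rows merged", tid)
        length = sum(end - start + 1 for start, end in merged)
        records.append((tid, genes[tid], length))
        exons[tid] = merged
    frame = pd.DataFrame(records, columns=["transcript_id", "gene_id", "length_bp"])
    frame = frame.set_index("transcript_id")
    return TranscriptAnnotation(frame, exons)


def write_gtf(ann: TranscriptAnnotation, path, chrom: str = "1", source: str = "isodyn") -> None:
    """Write the annotation back out as a minimal exon-only GTF."""
    with open(path, "w") as fh:
        for tid in ann.transcript_ids:
            gid = ann.gene_of[tid]
            for start, end in ann.exons.get(tid, [(1, int(ann.lengths[tid]))]):
                attrs = f'gene_id "{gid}"; transcript_id "{tid}";'
                fh.write(
                    f"{chrom}\t{source}\texon\t{start}\t{end}\t.\t+\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """A transcripts x samples quantification table.

    ``layer`` is ``"counts"`` (non-negative integers) or ``"fpkm"``
    (non-negative reals).
    """

    values: pd.DataFrame
    layer: str

    def __post_init__(self) -> None:
        if self.layer not in ("counts", "fpkm"):
            raise ValidationError(f"unknown layer {self.layer!r}")
        arr = self.values.to_numpy()
        if (arr < 0).any():
            raise ValidationError(f"{self.layer} layer contains negative values")
        if self.layer == "counts" and not np.allclose(arr, np.round(arr)):
            raise ValidationError("counts layer must be integer-valued")

    @property
    def transcript_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def require_layer(self, layer: str) -> None:
        if self.layer != layer:
            raise ValidationError(f"expected {layer} layer, got {self.layer}")

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values[list(sample_ids)], self.layer)

    def validate_against(self, ann: TranscriptAnnotation | None = None,
                         meta: SampleMetadata | None = None) -> None:
        if ann is not None:
            unknown = self.values.index.difference(ann.transcript_ids)
            if len(unknown):
                raise ValidationError(
                    f"transcripts absent from annotation: {sorted(unknown)[:5]}")
        if meta is not None:
            unknown = self.values.columns.difference(meta.sample_ids)
            if len(unknown):
                raise ValidationError(
                    f"samples absent from metadata: {sorted(unknown)[:5]}")

    def write_tsv(self, path) -> None:
        out = self.values.copy()
        out.index.name = "transcript_id"
        if self.layer == "counts":
            out = out.astype(int)
        out.to_csv(path, sep="\t")


def read_matrix(path, layer: str, ann: TranscriptAnnotation | None = None,
                meta: SampleMetadata | None = None) -> ExpressionMatrix:
    """Read a headered TSV (``transcript_id`` first column) into a matrix.

    Raises :class:`ValidationError` for negative entries, non-integer counts,
    or row/column ids not present in the supplied annotation/metadata.
    """
    frame = pd.read_csv(path, sep="\t", index_col=0)
    frame.index.name = "transcript_id"
    mat = ExpressionMatrix(frame.astype(float), layer)
    mat.validate_against(ann, meta)
    if ann is not None:
        mat = ExpressionMatrix(
            mat.values.reindex(ann.transcript_ids.intersection(mat.values.index)), layer)
    return mat


def compute_fpkm(counts: ExpressionMatrix, ann: TranscriptAnnotation,
                 meta: SampleMetadata) -> ExpressionMatrix:
    """Fragments per kilobase of transcript per million mapped fragments.

    ``fpkm[t, s] = counts[t, s] / ((length_bp[t] / 1e3) * (library_size[s] / 1e6))``

    The effective length is the annotated exonic length; library size is the
    per-sample total mapped fragments from the metadata.
    """
    counts.require_layer("counts")
    counts.validate_against(ann, meta)
    lengths = ann.lengths.reindex(counts.transcript_ids)
    if lengths.isna().any():
        raise ValidationError("transcript missing from annotation")
    libs = meta.library_sizes.reindex(counts.sample_ids)
    if libs.isna().any() or (libs <= 0).any():
        raise ValidationError("library sizes must be positive for all samples")
    denom = np.outer(lengths.to_numpy() / 1e3, libs.to_numpy() / 1e6)
    fpkm = counts.values.to_numpy() / denom
    return ExpressionMatrix(
        pd.DataFrame(fpkm, index=counts.transcript_ids, columns=counts.sample_ids),
        "fpkm",
    )


def filter_expressed(fpkm: ExpressionMatrix, ann: TranscriptAnnotation | None = None,
                     threshold: float = 1.0) -> tuple[set[str], set[str]]:
    """Transcripts (and their genes) with FPKM strictly above ``threshold``
    in at least one sample.

    Returns ``(transcript_ids, gene_ids)``; genes are empty when no
    annotation is given.
    """
    fpkm.require_layer("fpkm")
    mask = (fpkm.values > threshold).any(axis=1)
    transcripts = set(fpkm.transcript_ids[mask])
    genes: set[str] = set()
    if ann is not None and transcripts:
        genes = ann.genes_for(transcripts)
    return transcripts, genes


def average_replicates(fpkm: ExpressionMatrix, meta: SampleMetadata) -> pd.DataFrame:
    """Mean FPKM per (breed, stage) cell over biological replicates.

    Returns a transcripts x (breed, stage) DataFrame whose columns are a
    MultiIndex over the observed breeds and the ordered stages.
    """
    fpkm.require_layer("fpkm")
    fpkm.validate_against(meta=meta)
    cols = {}
    for breed in meta.breeds:
        for stage in meta.stages:
            samples = meta.samples_for(breed, stage)
            if len(samples) == 0:
                raise ValidationError(f"no replicates for ({breed}, {stage})")
            cols[(breed, stage)] = fpkm.values[list(samples)].mean(axis=1)
    out = pd.DataFrame(cols)
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["breed", "stage"])
    return out


def log2p1(fpkm: ExpressionMatrix) -> pd.DataFrame:
    """The package-wide expression transform, log2(FPKM + 1)."""
    fpkm.require_layer("fpkm")
    return np.log2(fpkm.values + 1.0)
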