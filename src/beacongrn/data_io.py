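"""Readers, writers and core containers for expression data and regulons.

Expression values are replicate-averaged FPKM profiles over an ordered
series of developmental timepoints; raw counts (with replicate structure)
live in :class:`CountMatrix` and are consumed only by the differential
expression module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


class ExpressionMatrix:
    """Gene x timepoint matrix of nonnegative expression values (FPKM-like).

    Parameters
    ----------
    gene_ids : sequence of str
        Row identifiers; must be unique.
    timepoints : sequence
        Ordered timepoint labels (at least two).
    values : array-like, shape (n_genes, n_timepoints)
        Nonnegative, finite expression values.
    """

    def __init__(self, gene_ids: Sequence[str], timepoints: Sequence, values) -> None:
        gene_ids = [str(g) for g in gene_ids]
        timepoints = [str(t) for t in timepoints]
        values = np.asarray(values, dtype=float)
        if values.ndim != 2 or values.shape != (len(gene_ids), len(timepoints)):
            raise ValueError(
                f"values shape {values.shape} does not match "
                f"{len(gene_ids)} genes x {len(timepoints)} timepoints"
            )
        if len(timepoints) < 2:
            raise ValueError("an expression matrix needs at least two timepoints")
        dupes = pd.Index(gene_ids)[pd.Index(gene_ids).duplicated()].unique()
        if len(dupes):
            raise ValueError(f"duplicate gene ids: {', '.join(dupes[:5])}")
        if not np.all(np.isfinite(values)):
            g, t = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(f"non-finite value at gene {gene_ids[g]!r}, timepoint {timepoints[t]!r}")
        if np.any(values < 0):
            g, t = np.argwhere(values < 0)[0]
            raise ValueError(
                f"negative value {values[g, t]} at gene {gene_ids[g]!r}, "
                f"timepoint {timepoints[t]!r}"
            )
        self.gene_ids = list(gene_ids)
        self.timepoints = list(timepoints)
        self.values = values
        self._index = {g: i for i, g in enumerate(gene_ids)}

    # -- accessors ---------------------------------------------------------
    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_timepoints(self) -> int:
        return len(self.timepoints)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._index

    def profile(self, gene_id: str) -> np.ndarray:
        """Return the expression profile of one gene (a length-k vector)."""
        try:
            return self.values[self._index[gene_id]]
        except KeyError:
            raise KeyError(f"gene {gene_id!r} not in expression matrix") from None

    def subset(self, gene_ids: Iterable[str]) -> "ExpressionMatrix":
        gene_ids = list(gene_ids)
        rows = [self._index[g] for g in gene_ids]
        return ExpressionMatrix(gene_ids, self.timepoints, self.values[rows])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.timepoints)

    # -- I/O ---------------------------------------------------------------
    @classmethod
    def from_tsv(cls, path) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str}, float_precision="round_trip")
        return cls(df.index, df.columns, df.to_numpy(dtype=float))

    def to_tsv(self, path) -> None:
        # repr() round-trips doubles exactly, unlike to_csv's float formatting
        with open(path, "w") as fh:
            fh.write("gene_id\t" + "\t".join(self.timepoints) + "\n")
            for g, row in zip(self.gene_ids, self.values):
                fh.write(g + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


class CountMatrix:
    """Gene x sample matrix of raw nonnegative integer counts.

    Each sample carries a ``(timepoint, replicate)`` label; timepoint order
    is taken from first appearance in ``samples``.
    """

    def __init__(self, gene_ids: Sequence[str], samples: Sequence[tuple], counts) -> None:
        counts = np.asarray(counts)
        if not np.issubdtype(counts.dtype, np.integer):
            rounded = np.rint(counts)
            if not np.allclose(counts, rounded):
                raise ValueError("counts must be integers")
            counts = rounded.astype(np.int64)
        if np.any(counts < 0):
            raise ValueError("counts must be nonnegative")
        if counts.shape != (len(gene_ids), len(samples)):
            raise ValueError("counts shape does not match gene_ids x samples")
        self.gene_ids = [str(g) for g in gene_ids]
        self.samples = [(str(t), str(r)) for t, r in samples]
        self.counts = counts
        seen: list[str] = []
        for t, _ in self.samples:
            if t not in seen:
                seen.append(t)
        self.timepoint_order = seen

    @property
    def sample_names(self) -> list[str]:
        return [f"{t}_{r}" for t, r in self.samples]

    def replicate_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for t, _ in self.samples:
            out[t] = out.get(t, 0) + 1
        return out

    @classmethod
    def from_tsv(cls, counts_path, design_path) -> "CountMatrix":
        """Load counts from a TSV plus a design TSV (sample, timepoint, replicate)."""
        df = pd.read_csv(counts_path, sep="\t", index_col=0)
        design = read_design(design_path)
        missing = [s for s in df.columns if s not in design]
        if missing:
            raise ValueError(f"samples missing from design: {', '.join(missing)}")
        samples = [design[s] for s in df.columns]
        return cls(df.index, samples, df.to_numpy())

    def to_tsv(self, counts_path, design_path) -> None:
        df = pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_names)
        df.index.name = "gene_id"
        df.to_csv(counts_path, sep="\t")
        with open(design_path, "w") as fh:
            fh.write("sample\ttimepoint\treplicate\n")
            for name, (t, r) in zip(self.sample_names, self.samples):
                fh.write(f"{name}\t{t}\t{r}\n")


def read_design(path) -> dict[str, tuple[str, str]]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample", "timepoint", "replicate"}
    if not required.issubset(df.columns):
        raise ValueError(f"design file needs columns {sorted(required)}")
    return {row["sample"]: (row.timepoint, row.replicate) for _, row in df.iterrows()}


class RegulonSet:
    """Map from regulator id to its set of known target genes."""

    def __init__(self, regulons: Mapping[str, Iterable[str]] | None = None) -> None:
        self._regulons: dict[str, set[str]] = {}
        if regulons:
            for reg, targets in regulons.items():
                for t in targets:
                    self.add(reg, t)

    def add(self, regulator: str, target: str) -> None:
        if regulator == target:
            raise ValueError(f"self-loop {regulator} -> {target} is not allowed")
        self._regulons.setdefault(regulator, set()).add(target)

    @property
    def regulators(self) -> list[str]:
        return sorted(self._regulons)

    def targets(self, regulator: str) -> set[str]:
        return set(self._regulons.get(regulator, set()))

    def __len__(self) -> int:
        return len(self._regulons)

    def __iter__(self):
        return iter(self.regulators)

    def items(self):
        return ((r, set(t)) for r, t in sorted(self._regulons.items()))

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("regulator_id\ttarget_id\n")
            for reg, targets in self.items():
                for t in sorted(targets):
                    fh.write(f"{reg}\t{t}\n")


@dataclass(frozen=True)
class GeneAnnotation:
    """One gene locus: 1-based inclusive coordinates as in GFF3."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start {self.start} > end {self.end}")
        if self.start < 1:
            raise ValueError(f"{self.gene_id}: coordinates are 1-based, got start {self.start}")


# ---------------------------------------------------------------------------
# operations


def read_expression_table(path) -> ExpressionMatrix:
    """Read a TSV expression table (header = timepoints, first column = gene ids)."""
    return ExpressionMatrix.from_tsv(path)


def write_expression_table(matrix: ExpressionMatrix, path) -> None:
    matrix.to_tsv(path)


def aggregate_transcripts(
    transcript_matrix: ExpressionMatrix, transcript_to_gene: Mapping[str, str]
) -> ExpressionMatrix:
    """Sum transcript-level FPKM over splice variants to gene-level values.

    Every transcript id must be present in ``transcript_to_gene``; genes are
    emitted in order of first appearance of one of their transcripts.
    """
    unmapped = [t for t in transcript_matrix.gene_ids if t not in transcript_to_gene]
    if unmapped:
        shown = ", ".join(unmapped[:10])
        raise ValueError(f"{len(unmapped)} unmapped transcript id(s): {shown}")
    order: list[str] = []
    rows: dict[str, np.ndarray] = {}
    for tid, profile in zip(transcript_matrix.gene_ids, transcript_matrix.values):
        gene = transcript_to_gene[tid]
        if gene not in rows:
            order.append(gene)
            rows[gene] = profile.astype(float).copy()
        else:
            rows[gene] += profile
    return ExpressionMatrix(order, transcript_matrix.timepoints, np.array([rows[g] for g in order]))


def split_transcript_suffix(transcript_ids: Iterable[str], sep: str = ".") -> dict[str, str]:
    """Opt-in convenience: map 'AT1G01010.1'-style ids to the prefix before ``sep``."""
    return {t: t.rsplit(sep, 1)[0] for t in transcript_ids}


def read_regulons(path) -> RegulonSet:
    """Read a 2(+)-column TSV of (regulator_id, target_id[, evidence]) rows.

    Duplicate rows collapse; self-loop rows are dropped with a single warning
    stating how many were skipped.  An empty file yields an empty set with a
    warning.
    """
    regulons = RegulonSet()
    n_self = 0
    n_rows = 0
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] in ("regulator_id", "regulator"):
                continue
            if len(parts) < 2:
                raise ValueError(f"malformed regulon row: {line!r}")
            reg, target = parts[0], parts[1]
            n_rows += 1
            if reg == target:
                n_self += 1
                continue
            regulons.add(reg, target)
    if n_self:
        warnings.warn(f"dropped {n_self} self-loop row(s) from {path}", stacklevel=2)
    if n_rows == 0:
        warnings.warn(f"regulon file {path} contains no rows", stacklevel=2)
    return regulons


def split_regulon_by_de(regulon: set[str], de_genes: set[str]) -> tuple[set[str], set[str]]:
    """Partition a regulon into (differentially expressed, stably expressed) targets."""
    regulon = set(regulon)
    de_positives = regulon & set(de_genes)
    return de_positives, regulon - de_positives


def read_gff3_genes(path, featuretype: str = "gene") -> list[GeneAnnotation]:
    """Read gene features from a GFF3 file into :class:`GeneAnnotation` records."""
    import gffutils

    db = gffutils.create_db(
        str(Path(path)), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    out = []
    for feat in db.features_of_type(featuretype, order_by=("seqid", "start")):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        out.append(GeneAnnotation(gene_id, feat.seqid, feat.strand, feat.start, feat.end))
    return out
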