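"""Promoter extraction and PWM motif scanning with exact p-values.

Promoters are the strand-oriented upstream regions of genes (3000 bp or up
to the nearest annotated neighbouring gene).  Motifs come in as MEME-minimal
position probability matrices, are converted to log2 odds against a
background model, and every promoter window is scored on both strands.
Window-score p-values are exact under the background model: scores are
discretised to a 1/1000 grid and the full null distribution is obtained by
dynamic programming over positions, so ``p = P(score >= s)`` carries no
sampling error.  A target with at least one hit below the p threshold is a
direct target; targets without a promoter sequence are reported unscanned.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .data_io import GeneAnnotation

__all__ = [
    "PWM",
    "Promoter",
    "MotifHit",
    "TargetClassification",
    "read_meme_motifs",
    "write_meme_motifs",
    "extract_promoters",
    "LogOddsMatrix",
    "log_odds",
    "scan_sequence",
    "score_pvalue",
    "scan_promoters",
    "classify_targets",
    "secondary_cascade",
]

ALPHABET = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
SCORE_SCALE = 1000  # integer discretisation grid for exact p-values
MAX_PROMOTER = 3000
DEFAULT_PSEUDOCOUNT = 0.01
DEFAULT_P_THRESHOLD = 1e-4


@dataclass
class PWM:
    """Position probability matrix over ACGT with a background model."""

    motif_id: str
    probs: np.ndarray                       # L x 4, rows sum to 1
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4 or self.probs.shape[0] < 1:
            raise ValueError(f"motif {self.motif_id}: matrix must be L x 4 with L >= 1")
        bad = np.where(np.abs(self.probs.sum(axis=1) - 1.0) > 1e-6)[0]
        if bad.size:
            raise ValueError(
                f"motif {self.motif_id}: probability row(s) {bad.tolist()} do not sum to 1"
            )
        if abs(self.background.sum() - 1.0) > 1e-6:
            raise ValueError(f"motif {self.motif_id}: background does not sum to 1")

    @property
    def length(self) -> int:
        return self.probs.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.probs.argmax(axis=1))


@dataclass(frozen=True)
class Promoter:
    gene_id: str
    sequence: str
    chrom: str
    start: int   # 1-based inclusive, forward-strand coordinates
    end: int
    strand: str


@dataclass(frozen=True)
class MotifHit:
    gene_id: str
    motif_id: str
    start: int          # 1-based offset within the promoter sequence
    strand: str         # strand of the match relative to the promoter
    score: float
    p_value: float


# ---------------------------------------------------------------------------
# MEME minimal format

_BG_LINE = re.compile(r"([ACGT])\s+([0-9.eE+-]+)")


def read_meme_motifs(path) -> list[PWM]:
    """Parse a MEME-minimal motif file into PWMs.

    Honors a "Background letter frequencies" block when present (uniform
    otherwise) and rejects probability rows that do not sum to 1 within
    1e-6, naming the offending motif.
    """
    with open(path) as fh:
        lines = [l.rstrip("\n") for l in fh]
    if not any(l.startswith("MEME version") for l in lines):
        raise ValueError(f"{path} is not a MEME minimal file (missing version line)")
    background = np.full(4, 0.25)
    motifs: list[PWM] = []
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("Background letter frequencies"):
            pairs = dict(_BG_LINE.findall(lines[i + 1]))
            if set(pairs) == set(ALPHABET):
                background = np.array([float(pairs[b]) for b in ALPHABET])
            i += 2
            continue
        if line.startswith("MOTIF"):
            motif_id = line.split()[1]
            j = i + 1
            while j < len(lines) and not lines[j].strip().startswith("letter-probability matrix"):
                j += 1
            if j == len(lines):
                raise ValueError(f"motif {motif_id}: no letter-probability matrix")
            header = lines[j].strip()
            m = re.search(r"w=\s*(\d+)", header)
            rows = []
            j += 1
            while j < len(lines):
                fields = lines[j].split()
                if len(fields) != 4:
                    break
                try:
                    rows.append([float(v) for v in fields])
                except ValueError:
                    break
                j += 1
            if m and int(m.group(1)) != len(rows):
                raise ValueError(
                    f"motif {motif_id}: header says w={m.group(1)} but {len(rows)} rows found"
                )
            motifs.append(PWM(motif_id, np.array(rows), background.copy()))
            i = j
            continue
        i += 1
    return motifs


def write_meme_motifs(motifs: Sequence[PWM], path) -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        bg = motifs[0].background if motifs else np.full(4, 0.25)
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{b} {f:.5f}" for b, f in zip(ALPHABET, bg)) + "\n\n")
        for m in motifs:
            fh.write(f"MOTIF {m.motif_id}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {m.length} nsites= 20 E= 0\n"
            )
            for row in m.probs:
                fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# promoters


def extract_promoters(
    genome: Mapping[str, str],
    annotations: Sequence[GeneAnnotation],
    genes: Iterable[str],
    max_length: int = MAX_PROMOTER,
) -> tuple[dict[str, Promoter], list[str]]:
    """Upstream regions (up to ``max_length`` bp or the nearest gene) per gene.

    ``genome`` maps chromosome name to sequence (a ``pyfaidx.Fasta`` works:
    entries are sliced and stringified).  Returns the promoter map and the
    list of genes skipped because their upstream region is empty.  The
    neighbour rule is strand-agnostic: any annotated gene boundary truncates
    the region.
    """
    by_id = {a.gene_id: a for a in annotations}
    genes = list(genes)
    missing = [g for g in genes if g not in by_id]
    if missing:
        raise KeyError(f"gene(s) absent from annotation: {', '.join(missing[:10])}")
    by_chrom: dict[str, list[GeneAnnotation]] = {}
    for a in annotations:
        by_chrom.setdefault(a.chrom, []).append(a)

    def chrom_seq(chrom: str) -> str:
        if chrom not in genome:
            raise KeyError(f"chromosome {chrom!r} absent from genome")
        return str(genome[chrom][:]).upper()

    promoters: dict[str, Promoter] = {}
    skipped: list[str] = []
    seq_cache: dict[str, str] = {}
    for g in genes:
        a = by_id[g]
        if a.chrom not in seq_cache:
            seq_cache[a.chrom] = chrom_seq(a.chrom)
        seq = seq_cache[a.chrom]
        neighbours = [n for n in by_chrom[a.chrom] if n.gene_id != g]
        if a.strand == "+":
            upstream_ends = [n.end for n in neighbours if n.end < a.start]
            lo = max(1, a.start - max_length, max(upstream_ends) + 1 if upstream_ends else 1)
            hi = a.start - 1
            oriented = seq[lo - 1 : hi]
        else:
            downstream_starts = [n.start for n in neighbours if n.start > a.end]
            lo = a.end + 1
            hi = min(
                len(seq), a.end + max_length,
                min(downstream_starts) - 1 if downstream_starts else len(seq),
            )
            oriented = seq[lo - 1 : hi].translate(_COMPLEMENT)[::-1]
        if hi < lo or not oriented:
            skipped.append(g)
            continue
        promoters[g] = Promoter(g, oriented, a.chrom, lo, hi, a.strand)
    return promoters, skipped


# ---------------------------------------------------------------------------
# scoring


class LogOddsMatrix:
    """log2-odds score matrix of a PWM, with its exact null score distribution.

    Entries are ``log2((p + pc*bg) / ((1+pc)*bg))`` per position/letter.
    Scores are carried on an integer grid (1/SCORE_SCALE resolution); the
    null distribution of the integer window score under the background model
    is computed once by dynamic programming, giving exact survival
    probabilities for any score the scanner can produce.
    """

    def __init__(self, pwm: PWM, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> None:
        self.motif_id = pwm.motif_id
        self.background = pwm.background
        bg = pwm.background
        self.matrix = np.log2((pwm.probs + pseudocount * bg) / ((1.0 + pseudocount) * bg))
        self.int_matrix = np.rint(self.matrix * SCORE_SCALE).astype(np.int64)
        self._build_null()

    @property
    def length(self) -> int:
        return self.matrix.shape[0]

    def _build_null(self) -> None:
        lo = int(self.int_matrix.min(axis=1).sum())
        hi = int(self.int_matrix.max(axis=1).sum())
        dist = np.zeros(hi - lo + 1)
        # DP over positions: dist[s - lo] = P(partial score == s)
        offs = np.zeros(1)
        offs[0] = 1.0
        cur_lo = 0
        for pos in range(self.length):
            col = self.int_matrix[pos]
            new_lo = cur_lo + int(col.min())
            new_hi = cur_lo + len(offs) - 1 + int(col.max())
            new = np.zeros(new_hi - new_lo + 1)
            for letter in range(4):
                shift = cur_lo + int(col[letter]) - new_lo
                new[shift : shift + len(offs)] += offs * self.background[letter]
            offs = new
            cur_lo = new_lo
        assert cur_lo == lo and len(offs) == hi - lo + 1
        dist = offs
        # survival function: P(score >= s)
        self._score_lo = lo
        self._sf = np.concatenate([np.cumsum(dist[::-1])[::-1], [0.0]])

    def int_score(self, window: str) -> int | None:
        """Integer-grid score of one exact-length window; None if it contains N."""
        total = 0
        for pos, base in enumerate(window):
            idx = _BASE_INDEX.get(base)
            if idx is None:
                return None
            total += int(self.int_matrix[pos, idx])
        return total

    def pvalue_int(self, int_score: int) -> float:
        idx = int_score - self._score_lo
        if idx < 0:
            return 1.0
        if idx >= len(self._sf) - 1:
            return float(self._sf[-2]) if len(self._sf) > 1 else 1.0
        return float(min(self._sf[idx], 1.0))

    def max_score(self) -> float:
        return float(self.matrix.max(axis=1).sum())


def log_odds(pwm: PWM, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> LogOddsMatrix:
    return LogOddsMatrix(pwm, pseudocount)


def score_pvalue(score_matrix: LogOddsMatrix, score: float) -> float:
    """Exact p-value P(window score >= score) under the background model."""
    return score_matrix.pvalue_int(int(np.rint(score * SCORE_SCALE)))


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def scan_sequence(
    sequence: str, score_matrix: LogOddsMatrix
) -> list[tuple[int, str, float]]:
    """Best-strand score at every window: (1-based start, strand, score).

    Both strands are scored with the same matrix (the reverse strand via the
    window's reverse complement); windows containing N are skipped.
    """
    seq = sequence.upper()
    L = score_matrix.length
    out = []
    for off in range(len(seq) - L + 1):
        window = seq[off : off + L]
        fwd = score_matrix.int_score(window)
        if fwd is None:
            continue
        rev = score_matrix.int_score(_revcomp(window))
        if rev > fwd:
            out.append((off + 1, "-", rev / SCORE_SCALE))
        else:
            out.append((off + 1, "+", fwd / SCORE_SCALE))
    return out


def scan_promoters(
    promoters: Mapping[str, Promoter],
    motifs: Sequence[PWM] | Sequence[LogOddsMatrix],
    p_threshold: float = DEFAULT_P_THRESHOLD,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> list[MotifHit]:
    """All motif occurrences with p < threshold across a promoter set."""
    mats = [m if isinstance(m, LogOddsMatrix) else LogOddsMatrix(m, pseudocount) for m in motifs]
    hits = []
    for gene in sorted(promoters):
        seq = promoters[gene].sequence
        for mat in mats:
            for start, strand, score in scan_sequence(seq, mat):
                p = score_pvalue(mat, score)
                if p < p_threshold:
                    hits.append(MotifHit(gene, mat.motif_id, start, strand, score, p))
    return hits


@dataclass
class TargetClassification:
    regulator: str
    direct: set[str]
    indirect: set[str]
    unscanned: set[str]
    secondary: dict[str, "TargetClassification"] = field(default_factory=dict)
    secondary_without_motif: set[str] = field(default_factory=set)


def classify_targets(
    regulator: str,
    targets: Iterable[str],
    hits: Sequence[MotifHit],
    promoters: Mapping[str, Promoter],
    motif_ids: Iterable[str] | None = None,
    alpha: float = DEFAULT_P_THRESHOLD,
) -> TargetClassification:
    """Split targets into direct (>=1 hit with p < alpha), indirect, unscanned."""
    targets = set(targets)
    motif_ids = set(motif_ids) if motif_ids is not None else None
    hit_genes = {
        h.gene_id
        for h in hits
        if h.p_value < alpha and (motif_ids is None or h.motif_id in motif_ids)
    }
    unscanned = {t for t in targets if t not in promoters}
    scanned = targets - unscanned
    direct = scanned & hit_genes
    return TargetClassification(regulator, direct, scanned - direct, unscanned)


def secondary_cascade(
    primary: TargetClassification,
    tf_list: Iterable[str],
    motif_db: Mapping[str, PWM],
    promoters: Mapping[str, Promoter],
    alpha: float = DEFAULT_P_THRESHOLD,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> TargetClassification:
    """One-level cascade: direct targets that are TFs explain indirect targets.

    Secondary TFs are the primary regulator's direct targets that appear in
    ``tf_list``.  Those with a motif in ``motif_db`` are scanned against the
    primary regulator's *indirect* targets; those without a motif are listed
    but not scanned.  Returns the input classification with the ``secondary``
    slot filled in.
    """
    tf_set = set(tf_list)
    secondary_tfs = sorted(primary.direct & tf_set)
    for tf in secondary_tfs:
        if tf not in motif_db:
            primary.secondary_without_motif.add(tf)
            continue
        sub_promoters = {g: promoters[g] for g in primary.indirect if g in promoters}
        hits = scan_promoters(sub_promoters, [motif_db[tf]], alpha, pseudocount)
        primary.secondary[tf] = classify_targets(
            tf, primary.indirect, hits, promoters, motif_ids={motif_db[tf].motif_id}, alpha=alpha
        )
    return primary
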