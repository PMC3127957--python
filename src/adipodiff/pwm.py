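"""Position weight matrix handling and promoter scanning.

Implements information-weighted matrix-similarity scoring of promoter
windows (the MatInspector family of scores): each matrix position
contributes its conservation weight ``ci`` times the frequency of the
observed base, normalised by the best attainable contribution, so the
consensus sequence always scores 1.0.  Matrix-specific score thresholds
are calibrated empirically against a background sequence pool so that a
matrix yields a fixed false-positive rate (by default one hit per 10 kb
of background sequence, both strands scanned).

Matrices are read from TRANSFAC- or JASPAR-formatted text files into a
:class:`PwmModel`; promoter regions spanning -3 kb..+2 kb around
transcription start sites are extracted strand-aware from a genome and
scanned on both strands.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PwmModel",
    "MotifHit",
    "PromoterRegion",
    "parse_pfm",
    "read_pfms",
    "pfm_to_frequencies",
    "information_weights",
    "matrix_similarity",
    "core_similarity",
    "calibrate_threshold",
    "extract_promoter_regions",
    "scan_sequence",
    "scan_region",
    "dr1_annotate",
    "hits_to_frame",
    "write_hits_bed",
    "reverse_complement",
]

BASES = "ACGT"
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: default promoter region relative to the TSS, in gene orientation
UPSTREAM = 3000
DOWNSTREAM = 2000

#: default calibration target: one binding site per 10 kb of background
DEFAULT_RATE = 1.0 / 10_000.0


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode_sequence(seq: str) -> np.ndarray:
    """Encode A/C/G/T/N as 0..4; any other letter is rejected."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, 255, dtype=np.uint8)
    for base, idx in _BASE_INDEX.items():
        out[arr == ord(base)] = idx
    if (out == 255).any():
        bad = chr(int(arr[np.argmax(out == 255)]))
        raise ValueError(f"unsupported character {bad!r} in sequence (only ACGTN allowed)")
    return out


def pfm_to_frequencies(counts: np.ndarray, pseudocount: float = 0.0) -> np.ndarray:
    """Convert a 4 x L count matrix to per-column base frequencies.

    ``f(b, i) = (count(b, i) + pseudocount) / (column_total(i) + 4 * pseudocount)``
    """
    counts = np.asarray(counts, dtype=float)
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    if counts.ndim != 2 or counts.shape[0] != 4:
        raise ValueError("count matrix must be 4 x L")
    totals = counts.sum(axis=0)
    if pseudocount == 0 and (totals == 0).any():
        raise ValueError("all-zero count column requires a positive pseudocount")
    return (counts + pseudocount) / (totals + 4.0 * pseudocount)


def information_weights(freqs: np.ndarray) -> np.ndarray:
    """Per-position conservation weights ci in [0, 100].

    ``ci(i) = (100 / ln 4) * sum_b f(b, i) * ln(4 f(b, i))`` with the
    convention ``0 * ln 0 = 0``; 0 for a uniform column, 100 for a
    single-base column.
    """
    f = np.asarray(freqs, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(f > 0, f * np.log(4.0 * f), 0.0)
    ci = (100.0 / np.log(4.0)) * terms.sum(axis=0)
    # clip tiny negative round-off
    return np.clip(ci, 0.0, 100.0)


def _core_positions(ci: np.ndarray, core_length: int = 4) -> np.ndarray:
    """Indices of the ``core_length`` consecutive positions maximising sum(ci)."""
    L = ci.size
    if L <= core_length:
        return np.arange(L)
    sums = np.convolve(ci, np.ones(core_length), mode="valid")
    start = int(np.argmax(sums))  # ties -> leftmost window
    return np.arange(start, start + core_length)


@dataclass
class PwmModel:
    """A position frequency matrix with its derived scoring quantities.

    Rows of ``counts`` are A, C, G, T in that order.  ``threshold`` is the
    calibrated matrix-similarity cutoff in [0, 1]; ``None`` until
    :func:`calibrate_threshold` has been run or a value supplied.
    """

    matrix_id: str
    counts: np.ndarray
    pseudocount_scale: float = 1e-4
    threshold: float | None = None
    name: str = ""

    freqs: np.ndarray = field(init=False, repr=False)
    ci: np.ndarray = field(init=False, repr=False)
    core: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != 4:
            raise ValueError(f"{self.matrix_id}: count matrix must be 4 x L")
        if (self.counts < 0).any():
            raise ValueError(f"{self.matrix_id}: negative counts")
        totals = self.counts.sum(axis=0)
        # pseudocount proportional to each column total keeps heavily- and
        # lightly-sampled matrices on the same footing; all-zero columns
        # (legal in some TRANSFAC exports) become uniform
        pc = np.where(totals > 0, self.pseudocount_scale * totals, 1.0)
        self.freqs = (self.counts + pc) / (totals + 4.0 * pc)
        self.ci = information_weights(self.freqs)
        self.core = _core_positions(self.ci)
        if self.threshold is not None and not (0.0 <= self.threshold <= 1.0):
            raise ValueError("threshold must lie in [0, 1]")

    # -- derived scoring tables -------------------------------------------------
    @property
    def length(self) -> int:
        return self.counts.shape[1]

    def _weighted(self) -> np.ndarray:
        """5 x L table of ci(i) * f(b, i); the N row contributes 0."""
        w = self.ci[None, :] * self.freqs
        return np.vstack([w, np.zeros((1, self.length))])

    def _max_score(self, positions: np.ndarray | None = None) -> float:
        w = self.ci * self.freqs.max(axis=0)
        if positions is not None:
            w = w[positions]
        return float(w.sum())

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.freqs.argmax(axis=0))


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

def _parse_transfac(lines: list[str]) -> list[tuple[str, str, np.ndarray]]:
    records: list[tuple[str, str, np.ndarray]] = []
    matrix_id, name = "", ""
    columns: list[list[float]] = []
    col_order: list[str] | None = None
    in_matrix = False

    def flush(lineno: int) -> None:
        nonlocal matrix_id, name, columns, col_order, in_matrix
        if columns:
            mat = np.array(columns, dtype=float).T  # -> 4 x L in file column order
            order = col_order or list(BASES)
            idx = [order.index(b) for b in BASES]
            records.append((matrix_id or f"matrix{len(records) + 1}", name, mat[idx]))
        matrix_id, name, columns, col_order, in_matrix = "", "", [], None, False

    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip()
        if not line:
            continue
        tag = line[:2]
        if tag == "ID":
            matrix_id = line[2:].strip()
        elif tag == "NA":
            name = line[2:].strip()
        elif tag in ("P0", "PO"):
            col_order = line.split()[1:5]
            if sorted(col_order) != sorted(BASES):
                raise ValueError(f"line {lineno}: matrix header must name A C G T")
            in_matrix = True
        elif tag == "//":
            flush(lineno)
        elif in_matrix and line[:2].strip().isdigit():
            parts = line.split()
            vals = parts[1:5]
            if len(vals) < 4:
                raise ValueError(f"line {lineno}: expected 4 count columns, got {len(vals)}")
            try:
                columns.append([float(v) for v in vals])
            except ValueError as exc:
                raise ValueError(f"line {lineno}: non-numeric count") from exc
        elif tag == "XX":
            in_matrix = False
    flush(len(lines))
    return records


def _parse_jaspar(lines: list[str]) -> list[tuple[str, str, np.ndarray]]:
    records: list[tuple[str, str, np.ndarray]] = []
    matrix_id, name = "", ""
    rows: dict[str, list[float]] = {}

    def flush() -> None:
        nonlocal matrix_id, name, rows
        if rows:
            if sorted(rows) != sorted(BASES):
                raise ValueError(f"matrix {matrix_id!r}: need one row per base A/C/G/T")
            lengths = {len(v) for v in rows.values()}
            if len(lengths) != 1:
                raise ValueError(f"matrix {matrix_id!r}: ragged rows {sorted(lengths)}")
            mat = np.array([rows[b] for b in BASES], dtype=float)
            records.append((matrix_id or f"matrix{len(records) + 1}", name, mat))
        matrix_id, name, rows = "", "", {}

    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith(">"):
            flush()
            parts = line[1:].split(None, 1)
            matrix_id = parts[0] if parts else ""
            name = parts[1].strip() if len(parts) > 1 else ""
        else:
            base, rest = line[:1].upper(), line[1:]
            if base not in BASES:
                raise ValueError(f"line {lineno}: unknown base row {base!r}")
            rest = rest.replace("[", " ").replace("]", " ")
            try:
                rows[base] = [float(v) for v in rest.split()]
            except ValueError as exc:
                raise ValueError(f"line {lineno}: non-numeric count") from exc
    flush()
    return records


def read_pfms(source, dialect: str, pseudocount_scale: float = 1e-4) -> list[PwmModel]:
    """Read all matrices from a TRANSFAC or JASPAR formatted file.

    ``source`` may be a path or an open text handle.
    """
    if hasattr(source, "read"):
        lines = source.read().splitlines()
    else:
        with open(source) as fh:
            lines = fh.read().splitlines()
    dialect = dialect.upper()
    if dialect == "TRANSFAC":
        raw = _parse_transfac(lines)
    elif dialect == "JASPAR":
        raw = _parse_jaspar(lines)
    else:
        raise ValueError(f"unknown PFM dialect {dialect!r}")
    if not raw:
        raise ValueError("no matrices found in input")
    return [
        PwmModel(matrix_id=mid, counts=mat, name=nm, pseudocount_scale=pseudocount_scale)
        for mid, nm, mat in raw
    ]


def parse_pfm(source, dialect: str, **kwargs) -> PwmModel:
    """Read a single matrix; errors if the file holds more than one."""
    models = read_pfms(source, dialect, **kwargs)
    if len(models) != 1:
        raise ValueError(f"expected exactly one matrix, found {len(models)}")
    return models[0]


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def _score_encoded(model: PwmModel, enc: np.ndarray,
                   positions: np.ndarray | None = None) -> np.ndarray:
    """Matrix-similarity of every window of an encoded sequence (one strand)."""
    L = model.length
    n = enc.size - L + 1
    if n <= 0:
        return np.empty(0)
    windows = np.lib.stride_tricks.sliding_window_view(enc, L)
    w = model._weighted()
    cols = np.arange(L)
    if positions is not None:
        windows = windows[:, positions]
        cols = positions
    denom = model._max_score(positions)
    if denom == 0.0:
        return np.zeros(n)
    return w[windows, cols].sum(axis=1) / denom


def matrix_similarity(model: PwmModel, window: str) -> float:
    """Information-weighted similarity of one window to the matrix, in [0, 1].

    ``score = sum_i ci(i) f(base_i, i) / sum_i ci(i) max_b f(b, i)``;
    an N at position i contributes 0 to the numerator.  An all-uniform
    matrix (zero denominator) scores 0 by convention.
    """
    if len(window) != model.length:
        raise ValueError(f"window length {len(window)} != matrix length {model.length}")
    return float(_score_encoded(model, encode_sequence(window))[0])


def core_similarity(model: PwmModel, window: str) -> float:
    """Matrix similarity restricted to the core (most conserved 4 consecutive
    positions; the whole matrix when L < 4)."""
    if len(window) != model.length:
        raise ValueError(f"window length {len(window)} != matrix length {model.length}")
    return float(_score_encoded(model, encode_sequence(window), positions=model.core)[0])


@dataclass(frozen=True)
class MotifHit:
    """A scored match of a matrix on one strand of a region.

    Coordinates are 0-based half-open in region space (forward orientation
    of the supplied sequence); ``genomic_start``/``genomic_end`` are filled
    in when the region carries genomic coordinates.
    """

    matrix_id: str
    seq_id: str
    start: int
    end: int
    strand: str
    score: float
    core_score: float
    genomic_start: int | None = None
    genomic_end: int | None = None


def scan_sequence(model: PwmModel, seq: str, seq_id: str = "",
                  threshold: float | None = None,
                  strict: bool = False) -> list[MotifHit]:
    """Scan both strands of ``seq``; emit every window whose matrix
    similarity is >= threshold (or > threshold when ``strict``).

    Overlapping hits are all kept.  Minus-strand hits are reported in
    forward coordinates of ``seq`` covering the matched window.
    """
    if threshold is None:
        threshold = model.threshold
    if threshold is None:
        raise ValueError(f"{model.matrix_id}: no threshold calibrated or supplied")
    L = model.length
    n = len(seq)
    hits: list[MotifHit] = []
    enc_fwd = encode_sequence(seq)
    enc_rev = encode_sequence(reverse_complement(seq))
    for strand, enc in (("+", enc_fwd), ("-", enc_rev)):
        scores = _score_encoded(model, enc)
        keep = scores > threshold if strict else scores >= threshold
        if not keep.any():
            continue
        core_scores = _score_encoded(model, enc, positions=model.core)
        for p in np.flatnonzero(keep):
            p = int(p)
            if strand == "+":
                start = p
            else:
                start = n - (p + L)
            hits.append(MotifHit(model.matrix_id, seq_id, start, start + L, strand,
                                 float(scores[p]), float(core_scores[p])))
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


# ---------------------------------------------------------------------------
# threshold calibration
# ---------------------------------------------------------------------------

def background_window_scores(model: PwmModel, backgrounds: Iterable[str]) -> np.ndarray:
    """Matrix-similarity of every window on both strands of the background."""
    chunks = []
    for seq in backgrounds:
        if len(seq) < model.length:
            continue
        enc = encode_sequence(seq)
        chunks.append(_score_encoded(model, enc))
        chunks.append(_score_encoded(model, encode_sequence(reverse_complement(seq))))
    if not chunks:
        raise ValueError(f"{model.matrix_id}: background shorter than the matrix")
    return np.concatenate(chunks)


def calibrate_threshold(model: PwmModel, backgrounds: Sequence[str],
                        rate: float = DEFAULT_RATE,
                        per_strand: bool = False) -> tuple[float, float]:
    """Calibrate the matrix threshold to a background false-positive rate.

    The threshold is the smallest achievable score ``t`` such that the
    number of background windows (both strands) scoring >= t, divided by
    the number of background bases, is <= ``rate`` (default one hit per
    10 kb of sequence).  With ``per_strand`` the denominator counts each
    base once per scanned strand instead.  Sets ``model.threshold`` and
    returns ``(threshold, achieved_rate)``.  If even a perfect score
    occurs too often the threshold is capped at 1.0 with a warning.
    """
    total_bases = sum(len(s) for s in backgrounds)
    if total_bases < 100 * model.length:
        raise ValueError(
            f"{model.matrix_id}: background of {total_bases} bp is too short "
            f"(need >= {100 * model.length})")
    denom = 2 * total_bases if per_strand else total_bases
    scores = np.sort(background_window_scores(model, backgrounds))
    allowed = rate * denom
    candidates = np.unique(scores)
    # hits at or above each candidate, scanning from the smallest score up
    n = scores.size
    counts_ge = n - np.searchsorted(scores, candidates, side="left")
    ok = counts_ge <= allowed
    if ok.any():
        threshold = float(candidates[np.argmax(ok)])
        achieved = float(counts_ge[np.argmax(ok)]) / denom
    else:
        warnings.warn(
            f"{model.matrix_id}: target rate {rate:g}/base unattainable even at "
            "score 1.0; threshold capped at 1.0", stacklevel=2)
        threshold = 1.0
        achieved = float((scores >= 1.0).sum()) / denom
    threshold = min(threshold, 1.0)
    model.threshold = threshold
    return threshold, achieved


# ---------------------------------------------------------------------------
# promoter regions
# ---------------------------------------------------------------------------

@dataclass
class PromoterRegion:
    """Strand-aware promoter region around a TSS.

    ``start``/``end`` are genomic, 0-based half-open; ``sequence`` is in
    gene orientation (reverse-complemented for '-' genes), so region
    coordinate 0 is the most upstream position of the scanned window.
    """

    gene_id: str
    chrom: str
    tss: int
    strand: str
    start: int
    end: int
    sequence: str
    clipped: bool = False

    def __len__(self) -> int:
        return self.end - self.start

    def to_genomic(self, rel_start: int, rel_end: int) -> tuple[int, int]:
        """Map region-space coordinates to genomic coordinates."""
        if self.strand == "+":
            return self.start + rel_start, self.start + rel_end
        return self.end - rel_end, self.end - rel_start


def extract_promoter_regions(tss_table: pd.DataFrame, genome: Mapping[str, str],
                             upstream: int = UPSTREAM,
                             downstream: int = DOWNSTREAM) -> list[PromoterRegion]:
    """Extract -upstream..+downstream regions around each TSS.

    ``tss_table`` needs columns gene, chrom, tss, strand; ``genome`` maps
    chromosome name to sequence.  For '+' genes the genomic interval is
    [tss - upstream, tss + downstream); for '-' genes the mirror interval
    [tss - downstream, tss + upstream), reverse-complemented.  Regions
    running off a chromosome end are clipped and flagged.
    """
    regions = []
    for row in tss_table.itertuples(index=False):
        if row.chrom not in genome:
            raise KeyError(f"unknown chromosome {row.chrom!r} for gene {row.gene!r}")
        chrom_seq = genome[row.chrom]
        chrom_len = len(chrom_seq)
        if not 0 <= row.tss < chrom_len:
            raise ValueError(f"gene {row.gene!r}: TSS {row.tss} outside {row.chrom}")
        if row.strand == "+":
            start, end = row.tss - upstream, row.tss + downstream
        elif row.strand == "-":
            start, end = row.tss - downstream, row.tss + upstream
        else:
            raise ValueError(f"gene {row.gene!r}: strand must be '+' or '-'")
        clipped = start < 0 or end > chrom_len
        start, end = max(start, 0), min(end, chrom_len)
        seq = str(chrom_seq[start:end]).upper()
        if row.strand == "-":
            seq = reverse_complement(seq)
        regions.append(PromoterRegion(row.gene, row.chrom, int(row.tss), row.strand,
                                      int(start), int(end), seq, clipped))
    return regions


def scan_region(model: PwmModel, region: PromoterRegion,
                threshold: float | None = None) -> list[MotifHit]:
    """Scan a promoter region; hits carry both region-space and genomic
    coordinates."""
    raw = scan_sequence(model, region.sequence, seq_id=region.gene_id,
                        threshold=threshold)
    out = []
    for h in raw:
        gs, ge = region.to_genomic(h.start, h.end)
        out.append(MotifHit(h.matrix_id, h.seq_id, h.start, h.end, h.strand,
                            h.score, h.core_score, gs, ge))
    return out


def dr1_annotate(regions: Iterable[PromoterRegion], dr1_model: PwmModel,
                 min_score: float = 0.90) -> list[MotifHit]:
    """Annotate nuclear-receptor DR1 (direct repeat 1) response elements.

    A fixed strictly-greater-than cutoff (default 0.90) replaces the
    calibrated threshold; strand is recorded per hit so browser tracks can
    keep the conventional blue '+' / red '-' colouring.
    """
    hits: list[MotifHit] = []
    for region in regions:
        raw = scan_sequence(dr1_model, region.sequence, seq_id=region.gene_id,
                            threshold=min_score, strict=True)
        for h in raw:
            gs, ge = region.to_genomic(h.start, h.end)
            hits.append(MotifHit(h.matrix_id, h.seq_id, h.start, h.end, h.strand,
                                 h.score, h.core_score, gs, ge))
    return hits


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def hits_to_frame(hits: Iterable[MotifHit]) -> pd.DataFrame:
    cols = ["matrix_id", "seq_id", "start", "end", "strand", "score", "core_score",
            "genomic_start", "genomic_end"]
    return pd.DataFrame([[getattr(h, c) for c in cols] for h in hits], columns=cols)


def write_hits_bed(hits: Iterable[MotifHit], path, chrom_of: Mapping[str, str] | None = None) -> None:
    """Write hits as a BED6 track: name = matrix id, score = 1000 * similarity
    (truncated)."""
    with open(path, "w") as fh:
        for h in hits:
            chrom = chrom_of[h.seq_id] if chrom_of else h.seq_id
            start = h.genomic_start if h.genomic_start is not None else h.start
            end = h.genomic_end if h.genomic_end is not None else h.end
            fh.write(f"{chrom}\t{start}\t{end}\t{h.matrix_id}\t{int(h.score * 1000)}\t{h.strand}\n")
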