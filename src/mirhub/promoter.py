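"""Promoter extraction and PWM scanning with exact score p-values.

Promoters are taken as a window around annotated TSSs (default 1 kb
upstream + 500 bp downstream, on the transcribed strand). TRANSFAC-format
count matrices are converted to log2-odds PWMs; the distribution of the
match score of a random background word is computed exactly by dynamic
programming on a discretized score grid, giving a calibrated mapping from
score to right-tail probability. Windows whose tail probability falls
below the threshold (default 5e-6) are reported as high-confidence hits.

All genome coordinates are 0-based half-open.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import _defaults
from .seq import canonicalize, revcomp

log = logging.getLogger(__name__)

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}


class TransfacParseError(ValueError):
    """Raised on malformed TRANSFAC matrix text; carries the line number."""

    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


@dataclass
class CountMatrix:
    """Per-position base counts of a motif, shape (width, 4) in ACGT order."""

    motif_id: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[1] != 4:
            raise ValueError("count matrix must have shape (width, 4)")
        if (self.counts < 0).any():
            raise ValueError("negative counts in matrix")
        if (self.counts.sum(axis=1) <= 0).any():
            raise ValueError("every position needs a positive count sum")

    @property
    def width(self) -> int:
        return self.counts.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.counts.argmax(axis=1))


def parse_transfac_records(text: str) -> list[CountMatrix]:
    """Parse all matrices in a TRANSFAC-format text.

    Accepts ``P0``/``PO`` column headers, arbitrary run-length whitespace,
    and an optional trailing consensus letter per row. ``//`` separates
    records.
    """
    matrices: list[CountMatrix] = []
    motif_id = None
    columns: list[int] | None = None
    rows: list[list[float]] = []
    expected_index = 1

    def flush(line_no: int) -> None:
        nonlocal motif_id, columns, rows, expected_index
        if rows:
            order = np.argsort(columns)  # reorder to ACGT
            counts = np.asarray(rows, dtype=float)[:, order]
            matrices.append(CountMatrix(motif_id or f"motif_{len(matrices) + 1}", counts))
        motif_id, columns, rows, expected_index = None, None, [], 1

    for line_no, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith(("XX", "CC", "BF", "BA", "DE")):
            continue
        if line.startswith("//"):
            flush(line_no)
            continue
        tokens = re.split(r"\s+", line)
        tag = tokens[0]
        if tag in ("ID", "AC", "NA"):
            if motif_id is None and len(tokens) > 1:
                motif_id = tokens[1]
            continue
        if tag in ("P0", "PO"):
            letters = [t.upper() for t in tokens[1:5]]
            if sorted(letters) != ["A", "C", "G", "T"]:
                raise TransfacParseError(f"bad column header {letters}", line_no)
            columns = [_BASE_INDEX[b] for b in letters]
            continue
        if re.fullmatch(r"\d+", tag):
            if columns is None:
                columns = [0, 1, 2, 3]
            if int(tag) != expected_index:
                raise TransfacParseError(
                    f"row index {tag} out of order (expected {expected_index:02d})", line_no
                )
            values = tokens[1:5]
            if len(values) < 4:
                raise TransfacParseError("fewer than 4 count fields", line_no)
            try:
                row = [float(v) for v in values]
            except ValueError:
                raise TransfacParseError(f"non-numeric count in {values}", line_no) from None
            if any(v < 0 for v in row):
                raise TransfacParseError("negative count", line_no)
            rows.append(row)
            expected_index += 1
            continue
        raise TransfacParseError(f"unrecognized line {raw!r}", line_no)
    flush(-1)
    if not matrices:
        raise ValueError("no matrices found in TRANSFAC text")
    return matrices


def parse_transfac(text: str) -> CountMatrix:
    """Parse a single TRANSFAC matrix block (see :func:`parse_transfac_records`)."""
    records = parse_transfac_records(text)
    if len(records) != 1:
        raise ValueError(f"expected one matrix, found {len(records)}")
    return records[0]


def write_transfac(matrix: CountMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"ID {matrix.motif_id}\nP0      A      C      G      T\n")
        for i, row in enumerate(matrix.counts, start=1):
            fh.write(f"{i:02d}  " + "  ".join(f"{v:g}" for v in row) + "\n")
        fh.write("XX\n//\n")


@dataclass
class ScoreTail:
    """Exact right-tail distribution of a PWM score on a discretized grid.

    ``pmf[k]`` is the probability that a random background word scores in
    bin ``min_bin + k``; a score ``s`` maps to bin ``round(s / bin_width)``.
    The discretization error of a tail query is bounded by
    ``width * bin_width`` in score units.
    """

    bin_width: float
    min_bin: int
    pmf: np.ndarray
    tail_cum: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.tail_cum = np.cumsum(self.pmf[::-1])[::-1]

    def tail(self, score: float) -> float:
        """P(score of a random background word >= ``score``).

        The query score is mapped to its nearest bin, so a word's own
        probability mass is included in its tail; error <= width*bin_width.
        """
        k = int(np.round(score / self.bin_width)) - self.min_bin
        if k <= 0:
            return 1.0
        if k >= self.pmf.size:
            return 0.0
        return float(self.tail_cum[k])

    def tails(self, scores: np.ndarray) -> np.ndarray:
        k = np.round(np.asarray(scores) / self.bin_width).astype(int) - self.min_bin
        k = np.clip(k, 0, self.pmf.size)
        padded = np.append(self.tail_cum, 0.0)
        return padded[k]


@dataclass
class PWMModel:
    """Calibrated log2-odds matrix with a score-to-tail-probability table."""

    motif_id: str
    counts: np.ndarray
    pseudocount: float
    background: np.ndarray
    log_odds: np.ndarray
    score_tail: ScoreTail | None = None

    @property
    def width(self) -> int:
        return self.log_odds.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.log_odds.argmax(axis=1))

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    def score(self, word: str) -> float:
        word = canonicalize(word)
        if len(word) != self.width:
            raise ValueError(f"word length {len(word)} != motif width {self.width}")
        return float(sum(self.log_odds[i, _BASE_INDEX[b]] for i, b in enumerate(word)))


def build_pwm(
    counts: CountMatrix,
    *,
    pseudocount: float = _defaults.PWM_PSEUDOCOUNT,
    background: Sequence[float] | None = None,
) -> PWMModel:
    """Log2-odds PWM from a count matrix.

    Cell (i, b) is ``log2(((count + pseudocount) / (colsum + 4*pseudocount))
    / background_b)``.
    """
    bg = np.full(4, 0.25) if background is None else np.asarray(background, dtype=float)
    if bg.shape != (4,) or (bg <= 0).any():
        raise ValueError("background must be 4 positive frequencies")
    if not np.isclose(bg.sum(), 1.0):
        raise ValueError("background frequencies must sum to 1")
    c = counts.counts
    probs = (c + pseudocount) / (c.sum(axis=1, keepdims=True) + 4 * pseudocount)
    if (probs == 0).any():
        raise ValueError("zero probability cell; use a positive pseudocount")
    log_odds = np.log2(probs / bg)
    return PWMModel(
        motif_id=counts.motif_id,
        counts=c.copy(),
        pseudocount=pseudocount,
        background=bg,
        log_odds=log_odds,
    )


def score_pvalue_table(
    pwm: PWMModel,
    *,
    bin_width: float = _defaults.SCORE_BIN_WIDTH,
    max_bins: int = 2_000_000,
) -> ScoreTail:
    """Exact score distribution under the background, by DP convolution.

    Per-column scores are rounded to a grid of ``bin_width`` bits and the
    distribution of their sum is built position by position. The resulting
    survival function starts at 1 and is non-increasing.
    """
    if not np.isfinite(pwm.log_odds).all():
        raise ValueError("log-odds contain non-finite entries; use pseudocount > 0")
    col_bins = np.round(pwm.log_odds / bin_width).astype(np.int64)
    min_total = int(col_bins.min(axis=1).sum())
    max_total = int(col_bins.max(axis=1).sum())
    n_bins = max_total - min_total + 1
    if n_bins > max_bins:
        raise ValueError(
            f"score grid needs {n_bins} bins (> {max_bins}); increase bin_width"
        )
    # running support tracking keeps the convolution cheap for narrow motifs
    cur = np.ones(1)
    cur_min = 0
    for i in range(pwm.width):
        bins_i = col_bins[i]
        new_min = cur_min + int(bins_i.min())
        new_max = cur_min + cur.size - 1 + int(bins_i.max())
        new = np.zeros(new_max - new_min + 1)
        for b in range(4):
            shift = cur_min + int(bins_i[b]) - new_min
            new[shift: shift + cur.size] += cur * pwm.background[b]
        cur, cur_min = new, new_min
    tail = ScoreTail(bin_width=bin_width, min_bin=cur_min, pmf=cur)
    pwm.score_tail = tail
    return tail


@dataclass
class PromoterRegion:
    """A promoter window, sequence 5'->3' on the transcribed strand."""

    id: str
    chrom: str
    strand: str
    start: int  # 0-based half-open genome interval
    end: int
    sequence: str
    truncated: bool = False

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if self.end - self.start != len(self.sequence):
            raise ValueError("interval length does not match sequence length")


@dataclass(frozen=True)
class MotifHit:
    """A scored PWM match inside one promoter (offset 0-based)."""

    promoter_id: str
    motif_id: str
    offset: int
    strand: str  # orientation relative to the promoter sequence
    score: float
    p_value: float


def extract_promoters(
    tss_table: pd.DataFrame,
    genome: Mapping[str, str],
    *,
    upstream: int = _defaults.UPSTREAM,
    downstream: int = _defaults.DOWNSTREAM,
) -> list[PromoterRegion]:
    """Promoter windows around TSSs, on the transcribed strand.

    ``tss_table`` needs columns ``id``, ``chrom``, ``strand`` and ``tss``
    (0-based TSS coordinate). For a plus-strand TSS t the genome interval
    is [t - upstream, t + downstream); for minus strand it is
    [t - downstream + 1, t + upstream + 1) reverse-complemented, so the
    returned sequence always reads 5'->3' with the TSS at offset
    ``upstream``. Windows beyond chromosome ends are truncated with a
    warning.
    """
    required = {"id", "chrom", "strand", "tss"}
    missing = required - set(tss_table.columns)
    if missing:
        raise ValueError(f"TSS table missing columns: {sorted(missing)}")
    promoters: list[PromoterRegion] = []
    for row in tss_table.itertuples():
        chrom_seq = genome.get(str(row.chrom))
        if chrom_seq is None:
            raise KeyError(f"chromosome {row.chrom!r} not in genome")
        t = int(row.tss)
        strand = str(row.strand)
        if strand == "+":
            start, end = t - upstream, t + downstream
        elif strand == "-":
            start, end = t - downstream + 1, t + upstream + 1
        else:
            raise ValueError(f"bad strand {strand!r} for TSS {row.id}")
        clipped_start, clipped_end = max(start, 0), min(end, len(chrom_seq))
        if clipped_end <= clipped_start:
            raise ValueError(f"TSS {row.id} window lies outside chromosome {row.chrom}")
        truncated = (clipped_start, clipped_end) != (start, end)
        if truncated:
            log.warning(
                "promoter %s truncated to [%d, %d) (requested [%d, %d))",
                row.id, clipped_start, clipped_end, start, end,
            )
        seq = canonicalize(chrom_seq[clipped_start:clipped_end])
        if strand == "-":
            seq = revcomp(seq)
        promoters.append(
            PromoterRegion(
                id=str(row.id), chrom=str(row.chrom), strand=strand,
                start=clipped_start, end=clipped_end, sequence=seq,
                truncated=truncated,
            )
        )
    return promoters


def _encode(sequence: str) -> np.ndarray:
    codes = np.full(len(sequence), -1, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        codes[np.frombuffer(sequence.encode(), dtype=np.uint8) == ord(base)] = idx
    return codes


def scan_promoter(
    pwm: PWMModel,
    promoter: PromoterRegion,
    *,
    p_max: float = _defaults.PWM_P_MAX,
    both_strands: bool = True,
) -> list[MotifHit]:
    """High-confidence PWM matches in one promoter.

    Every window is scored on the promoter sequence and, when
    ``both_strands`` is set, on its reverse complement (reported at the
    same offset with strand '-'). Windows containing N are skipped. Hits
    with tail probability < ``p_max`` are returned sorted by offset.
    """
    if pwm.score_tail is None:
        raise ValueError("PWM is not calibrated; call score_pvalue_table first")
    w = pwm.width
    seq = promoter.sequence
    if len(seq) < w:
        log.warning("promoter %s shorter than motif width %d", promoter.id, w)
        return []
    codes = _encode(seq)
    windows = np.lib.stride_tricks.sliding_window_view(codes, w)
    valid = ~(windows < 0).any(axis=1)
    n_skipped = int((~valid).sum())
    if n_skipped:
        log.info("promoter %s: skipped %d windows containing N", promoter.id, n_skipped)
    positions = np.arange(w)
    hits: list[MotifHit] = []
    lo = pwm.log_odds
    # minus-orientation scoring == scoring the same window with the
    # reverse-complemented PWM
    lo_rc = lo[::-1, ::-1]
    for strand, matrix in (("+", lo), ("-", lo_rc)):
        if strand == "-" and not both_strands:
            continue
        safe = np.where(windows < 0, 0, windows)
        scores = matrix[positions[None, :], safe].sum(axis=1)
        pvals = pwm.score_tail.tails(scores)
        for offset in np.flatnonzero(valid & (pvals < p_max)):
            hits.append(
                MotifHit(
                    promoter_id=promoter.id,
                    motif_id=pwm.motif_id,
                    offset=int(offset),
                    strand=strand,
                    score=float(scores[offset]),
                    p_value=float(pvals[offset]),
                )
            )
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def scan_promoters(
    pwms: Sequence[PWMModel],
    promoters: Sequence[PromoterRegion],
    *,
    p_max: float = _defaults.PWM_P_MAX,
    both_strands: bool = True,
) -> list[MotifHit]:
    hits: list[MotifHit] = []
    for pwm in pwms:
        for promoter in promoters:
            hits.extend(
                scan_promoter(pwm, promoter, p_max=p_max, both_strands=both_strands)
            )
    return hits


def hits_to_bed(
    hits: Sequence[MotifHit],
    promoters: Mapping[str, PromoterRegion],
    pwms: Mapping[str, PWMModel],
    path: str | Path,
) -> None:
    """Write hits as BED6 + score + p columns, in genome coordinates."""
    with open(path, "w") as fh:
        for hit in hits:
            prom = promoters[hit.promoter_id]
            width = pwms[hit.motif_id].width
            if prom.strand == "+":
                g_start = prom.start + hit.offset
            else:
                g_start = prom.end - hit.offset - width
            g_strand = hit.strand if prom.strand == "+" else ("-" if hit.strand == "+" else "+")
            fh.write(
                f"{prom.chrom}\t{g_start}\t{g_start + width}\t"
                f"{hit.motif_id}@{hit.promoter_id}\t{hit.score:.4f}\t{g_strand}\t"
                f"{hit.p_value:.3e}\n"
            )


def hits_table(hits: Sequence[MotifHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "promoter_id": h.promoter_id,
                "motif_id": h.motif_id,
                "offset": h.offset,
                "strand": h.strand,
                "score": h.score,
                "p_value": h.p_value,
            }
            for h in hits
        ]
    )
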