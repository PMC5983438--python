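"""TRANSFAC matrices and MATCH-style promoter scanning.

A position-weight matrix (PWM) is read from the TRANSFAC flat-file layout
(ID line, numbered count rows with four values, ``//`` terminator). MATCH
scoring weights each position by its information content
I(i) = sum_b f(i,b) ln(4 f(i,b)) and reports a matrix similarity score

    MSS = (Current - Min) / (Max - Min),   Current = sum_i I(i) f(i, b_i)

normalized so the consensus scores 1 and the anti-consensus 0, together with
a core similarity score (CSS) computed identically over the 5 consecutive
positions of highest total information. Promoters are scanned on both
strands; hits are windows with MSS and CSS above their cutoffs (defaults
0.85 / 0.95) lying fully inside conserved regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping, Sequence

import numpy as np

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
CORE_LENGTH = 5


@dataclass
class PWM:
    """A TRANSFAC-style count matrix with derived MATCH quantities."""

    id: str
    counts: np.ndarray  # positions x 4 (A, C, G, T)
    frequencies: np.ndarray = field(init=False)
    information: np.ndarray = field(init=False)  # nats, per position
    core_start: int = field(init=False)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        if counts.ndim != 2 or counts.shape[1] != 4 or counts.shape[0] == 0:
            raise ValueError(f"matrix {self.id!r}: counts must be non-empty L x 4")
        if (counts < 0).any():
            raise ValueError(f"matrix {self.id!r}: negative counts")
        row_sums = counts.sum(axis=1)
        if (row_sums <= 0).any():
            raise ValueError(f"matrix {self.id!r}: a position has zero total count")
        self.counts = counts
        self.frequencies = counts / row_sums[:, None]
        self.information = information_vector(self.frequencies)
        self.core_start = define_core(self.information)

    def __len__(self) -> int:
        return self.counts.shape[0]

    @property
    def core_positions(self) -> range:
        return range(self.core_start, self.core_start + min(CORE_LENGTH, len(self)))

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.frequencies.argmax(axis=1))


def information_vector(frequencies: np.ndarray) -> np.ndarray:
    """Per-position information I(i) = sum_b f ln(4 f), with 0 ln 0 := 0.

    Ranges from 0 (uniform position) to ln 4 (fully determined position).
    """
    f = np.asarray(frequencies, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(f > 0, f * np.log(4.0 * f), 0.0)
    return np.maximum(terms.sum(axis=1), 0.0)


def define_core(information: np.ndarray) -> int:
    """Start of the core: the length-5 window maximizing total information.

    Leftmost window on ties; the whole matrix if shorter than 5 positions.
    """
    info = np.asarray(information, dtype=float)
    w = min(CORE_LENGTH, len(info))
    sums = np.convolve(info, np.ones(w), mode="valid")
    return int(np.argmax(np.round(sums, 12)))


def parse_transfac(stream: IO[str] | str) -> list[PWM]:
    """Parse PWMs from a TRANSFAC flat-file text stream or string.

    Accepts ID/NA/AC/P0 header lines, numbered position rows of four counts
    (optionally followed by a consensus letter), and a ``//`` record
    terminator. A record without its terminator, or a count row without
    exactly four numeric fields, is a parse error naming the line.
    """
    text = stream if isinstance(stream, str) else stream.read()
    pwms: list[PWM] = []
    current_id: str | None = None
    rows: list[list[float]] = []
    open_record = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("//"):
            if current_id is None:
                raise ValueError(f"line {lineno}: record terminator without an ID")
            if not rows:
                raise ValueError(f"line {lineno}: matrix {current_id!r} has no count rows")
            pwms.append(PWM(id=current_id, counts=np.array(rows)))
            current_id, rows, open_record = None, [], False
            continue
        fields = line.split()
        tag = fields[0]
        if tag in ("ID", "NA", "AC"):
            if tag == "ID":
                if open_record:
                    raise ValueError(
                        f"line {lineno}: new ID before '//' terminator of {current_id!r}"
                    )
                current_id = fields[1] if len(fields) > 1 else ""
                open_record = True
            continue
        if tag in ("P0", "PO", "XX", "BF", "DE", "CC"):
            continue
        if tag[0].isdigit():
            if not open_record:
                raise ValueError(f"line {lineno}: count row outside a record")
            numeric = fields[1:]
            if numeric and not _is_number(numeric[-1]):
                numeric = numeric[:-1]  # trailing consensus letter
            if len(numeric) != 4 or not all(_is_number(v) for v in numeric):
                raise ValueError(
                    f"line {lineno}: expected 4 numeric count fields, got {fields[1:]!r}"
                )
            rows.append([float(v) for v in numeric])
            continue
        raise ValueError(f"line {lineno}: unrecognized line {raw!r}")
    if open_record:
        raise ValueError(f"matrix {current_id!r} missing '//' terminator")
    return pwms


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def write_transfac(pwms: Iterable[PWM], stream: IO[str]) -> None:
    """Write PWMs in the TRANSFAC flat-file layout (round-trips counts)."""
    for pwm in pwms:
        stream.write(f"ID {pwm.id}\n")
        stream.write("P0      A      C      G      T\n")
        for i, row in enumerate(pwm.counts, start=1):
            vals = "  ".join(f"{v:g}" for v in row)
            cons = BASES[int(np.argmax(row))]
            stream.write(f"{i:02d}  {vals}  {cons}\n")
        stream.write("//\n")


def match_score(pwm: PWM, subsequence: str) -> tuple[float, float]:
    """MATCH matrix and core similarity scores for an oriented window.

    The window must have the matrix's length and contain only A/C/G/T.
    Returns (MSS, CSS), each in [0, 1].
    """
    if len(subsequence) != len(pwm):
        raise ValueError(
            f"window length {len(subsequence)} != matrix length {len(pwm)}"
        )
    try:
        idx = np.array([_BASE_INDEX[b] for b in subsequence.upper()])
    except KeyError as exc:
        raise ValueError(f"window contains non-ACGT base {exc}") from None
    return (
        _similarity(pwm.information, pwm.frequencies, idx, slice(None)),
        _similarity(pwm.information, pwm.frequencies, idx, pwm.core_positions),
    )


def _similarity(info, freq, idx, positions) -> float:
    if isinstance(positions, range):
        positions = slice(positions.start, positions.stop)
    i, f, b = info[positions], freq[positions], idx[positions]
    current = float((i * f[np.arange(len(b)), b]).sum())
    mx = float((i * f.max(axis=1)).sum())
    mn = float((i * f.min(axis=1)).sum())
    if mx - mn <= 0:
        return 0.0  # matrix carries no information over these positions
    return (current - mn) / (mx - mn)


@dataclass(frozen=True)
class PromoterRecord:
    """A promoter sequence window; position 0 is the most upstream base."""

    gene_id: str
    species: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.gene_id}: empty promoter sequence")
        object.__setattr__(self, "sequence", self.sequence.upper())
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ValueError(f"{self.gene_id}: invalid bases {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SiteHit:
    """A strand-aware PWM hit, reported by its reference-strand start."""

    gene_id: str
    matrix_id: str
    start: int  # 0-based on the reference promoter
    strand: str  # '+' or '-'
    mss: float
    css: float


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _encode(seq: str) -> np.ndarray:
    out = np.full(len(seq), -1, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        out[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(b)] = i
    return out


def _window_scores(weights: np.ndarray, code: np.ndarray, length: int) -> np.ndarray:
    """Sliding-window sums of weights[i, code[p+i]]; NaN where a window has N."""
    n_win = len(code) - length + 1
    if n_win <= 0:
        return np.empty(0)
    win = np.lib.stride_tricks.sliding_window_view(code, length)
    valid = (win >= 0).all(axis=1)
    safe = np.where(win >= 0, win, 0)
    scores = np.take_along_axis(
        np.broadcast_to(weights, (n_win, length, 4)), safe[:, :, None], axis=2
    )[:, :, 0].sum(axis=1)
    scores[~valid] = np.nan
    return scores


def scan_promoter(
    pwms: Sequence[PWM],
    record: PromoterRecord,
    regions: Sequence[tuple[int, int]] | None,
    mss_min: float = 0.85,
    css_min: float = 0.95,
) -> list[SiteHit]:
    """All above-cutoff PWM windows on both strands inside conserved regions.

    ``regions`` is a list of half-open [start, end) intervals on the
    reference promoter; ``None`` scans the whole promoter. A window counts
    only if fully inside one region. Windows containing N are skipped.
    Hits are returned in (matrix, start) coordinate order; minus-strand hits
    are reported by their reference-strand start.
    """
    if not (0 <= mss_min <= 1 and 0 <= css_min <= 1):
        raise ValueError("cutoffs must lie in [0, 1]")
    length = len(record)
    if regions is None:
        allowed = np.ones(length, dtype=bool)
    else:
        allowed = np.zeros(length, dtype=bool)
        for start, end in regions:
            allowed[max(0, start) : min(length, end)] = True
    code = _encode(record.sequence)
    csum = np.concatenate([[0], np.cumsum(allowed)])
    hits: list[SiteHit] = []
    for pwm in pwms:
        L = len(pwm)
        if L > length:
            continue
        n_win = length - L + 1
        inside = (csum[L:] - csum[:-L])[:n_win] == L
        w_fwd = pwm.information[:, None] * pwm.frequencies
        # scoring the reverse complement of a window equals scoring the
        # window with the reversed, base-complemented weight matrix
        w_rev = w_fwd[::-1, ::-1]
        core = np.zeros((L, 4))
        core_slice = slice(pwm.core_start, pwm.core_start + min(CORE_LENGTH, L))
        core[core_slice] = w_fwd[core_slice]
        core_rev = core[::-1, ::-1]

        mx = (pwm.information * pwm.frequencies.max(axis=1)).sum()
        mn = (pwm.information * pwm.frequencies.min(axis=1)).sum()
        info_core = pwm.information[core_slice]
        freq_core = pwm.frequencies[core_slice]
        cmx = (info_core * freq_core.max(axis=1)).sum()
        cmn = (info_core * freq_core.min(axis=1)).sum()
        span, cspan = mx - mn, cmx - cmn
        if span <= 0:
            continue

        for strand in "+-":
            wf = w_fwd if strand == "+" else w_rev
            wc = core if strand == "+" else core_rev
            mss = (_window_scores(wf, code, L) - mn) / span
            if cspan > 0:
                css = (_window_scores(wc, code, L) - cmn) / cspan
            else:
                css = np.zeros(n_win)
            ok = inside & ~np.isnan(mss) & (mss >= mss_min) & (css >= css_min)
            for pos in np.flatnonzero(ok):
                hits.append(
                    SiteHit(
                        gene_id=record.gene_id,
                        matrix_id=pwm.id,
                        start=int(pos),
                        strand=strand,
                        mss=float(mss[pos]),
                        css=float(css[pos]),
                    )
                )
    hits.sort(key=lambda h: (h.matrix_id, h.start, h.strand))
    return hits


@dataclass(frozen=True)
class GeneScanStatus:
    """Promoter-stage fate of a cluster gene."""

    gene_id: str
    status: str  # no_ortholog | no_tfbs | analysis_ready


def classify_gene_status(
    cluster_genes: Sequence[str],
    ortholog_table: Mapping[str, str | None],
    hits_by_gene: Mapping[str, Sequence[SiteHit]],
) -> list[GeneScanStatus]:
    """Partition cluster genes into no_ortholog / no_tfbs / analysis_ready.

    A gene with no ortholog (table value None or 'NA') is ``no_ortholog``;
    with an ortholog but zero hits across all matrices, ``no_tfbs``;
    otherwise ``analysis_ready``. Every cluster gene must appear in the
    ortholog table.
    """
    statuses = []
    for gene in cluster_genes:
        if gene not in ortholog_table:
            raise KeyError(f"gene {gene!r} missing from ortholog table")
        orth = ortholog_table[gene]
        if orth is None or (isinstance(orth, str) and orth.upper() == "NA"):
            status = "no_ortholog"
        elif len(hits_by_gene.get(gene, ())) == 0:
            status = "no_tfbs"
        else:
            status = "analysis_ready"
        statuses.append(GeneScanStatus(gene_id=gene, status=status))
    return statuses
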