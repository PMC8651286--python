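"""Interpretation of bisulfite amplicon reads.

Reads are assigned to panel markers by ungapped sliding-offset comparison
against bisulfite-converted references (both orientations, CpG positions
wildcarded to C/T), quality- and conversion-filtered, CpG-called by the
CG/TG rule, and tallied into per-marker fully-unmethylated-molecule
fractions.

Per-read operations (`assign_read`, `call_cpgs`, `conversion_rate`,
`classify_molecule`) define the semantics; `tally_sample` applies the same
semantics through a numpy-vectorized engine for throughput.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .constants import DEFAULT_MIN_IDENTITY
from .panel import ALLOW_ONE, STRICT, AmpliconDef, Panel, bisulfite_reference

# CpG call codes
METHYLATED = "M"
UNMETHYLATED = "U"
AMBIGUOUS = "?"
ABSENT = "-"

# reject reasons
R_NONE = "none"
R_LOW_QUALITY = "low_quality"
R_LOW_IDENTITY = "low_identity"
R_AMBIGUOUS = "ambiguous_assignment"
R_MISSING_CPGS = "missing_cpgs"
R_POOR_CONVERSION = "poor_conversion"

REJECT_REASONS = (R_LOW_QUALITY, R_LOW_IDENTITY, R_AMBIGUOUS,
                  R_MISSING_CPGS, R_POOR_CONVERSION)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

_COMP_TABLE = np.arange(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTN", b"TGCAN"):
    _COMP_TABLE[_a] = _b

_Y = ord("Y")
_C = ord("C")
_T = ord("T")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ReadRecord:
    """A sequenced read: id, bases, per-base Phred scores."""

    id: str
    seq: str
    quals: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.quals):
            raise ValueError(f"{self.id}: len(seq) != len(quals)")
        if set(self.seq) - set("ACGTN"):
            raise ValueError(f"{self.id}: bases outside ACGTN")

    @property
    def mean_quality(self) -> float:
        return sum(self.quals) / len(self.quals)


@dataclass(frozen=True)
class Assignment:
    marker: str | None
    identity: float
    offset: int = 0
    orientation: str = "+"
    reason: str = R_NONE


@dataclass
class ReadAssessment:
    read_id: str
    assigned_marker: str | None
    identity: float
    mean_quality: float
    cpg_calls: str
    conversion_rate: float | None
    retained: bool
    reject_reason: str
    fully_unmethylated: bool = False


@dataclass
class MarkerCount:
    marker: str
    cell_type: str
    n_total_assigned: int = 0
    n_retained: int = 0
    n_fully_unmethylated: int = 0
    _conv_sum: float = 0.0
    _conv_n: int = 0

    @property
    def fraction(self) -> float | None:
        if self.n_retained == 0:
            return None
        return self.n_fully_unmethylated / self.n_retained

    @property
    def mean_conversion_rate(self) -> float | None:
        return self._conv_sum / self._conv_n if self._conv_n else None


@dataclass(frozen=True)
class ReadFilterConfig:
    """Retention thresholds. Identity is a percentage; quality a Phred."""

    min_identity: float = DEFAULT_MIN_IDENTITY
    min_mean_quality: float = 30.0
    min_conversion: float = 0.95
    require_all_cpgs: bool = True


# ---------------------------------------------------------------------------
# alignment core

def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _match_counts(reads: np.ndarray, ref: np.ndarray,
                  offset: int) -> tuple[np.ndarray, int]:
    """Ungapped match counts of a (n, L_read) batch against a converted
    reference at one offset. Offset is the reference position aligned to
    read base 0 (negative when the read overhangs the reference start).
    Full overlap of the shorter sequence is required by the caller."""
    lr, lm = reads.shape[1], ref.shape[0]
    if offset >= 0:
        ref_sub = ref[offset:offset + lr]
        read_sub = reads[:, :ref_sub.shape[0]]
    else:
        ref_sub = ref[:min(lm, lr + offset)]
        read_sub = reads[:, -offset:-offset + ref_sub.shape[0]]
    wc = ref_sub == _Y
    eq = read_sub == ref_sub
    ct = (read_sub == _C) | (read_sub == _T)
    return (eq | (wc & ct)).sum(axis=1), ref_sub.shape[0]


def _offsets(len_read: int, len_ref: int) -> range:
    """Offsets giving full overlap of the shorter sequence."""
    if len_read <= len_ref:
        return range(0, len_ref - len_read + 1)
    return range(len_ref - len_read, 1)


def _best_alignment(read_seq: str, conv_ref: str) -> tuple[int, int, int]:
    """(matches, overlap, offset) of the best ungapped placement."""
    reads = _encode(read_seq)[None, :]
    ref = _encode(conv_ref)
    best = (-1, 1, 0)
    for off in _offsets(len(read_seq), len(conv_ref)):
        m, ov = _match_counts(reads, ref, off)
        if int(m[0]) > best[0]:
            best = (int(m[0]), ov, off)
    return best


def assign_read(read: ReadRecord, panel: Panel,
                min_identity: float = DEFAULT_MIN_IDENTITY) -> Assignment:
    """Assign a read to its best-matching marker, or to none.

    Both orientations are tried; the marker with the highest percent
    identity (matches over aligned length, CpG wildcards matching C or T)
    wins if it reaches ``min_identity`` and is unique; ties at the top are
    ambiguous.
    """
    scored: list[tuple[float, str, int, str]] = []
    rc = revcomp(read.seq)
    for amp in panel:
        ref = bisulfite_reference(amp)
        for orient, seq in (("+", read.seq), ("-", rc)):
            matches, overlap, off = _best_alignment(seq, ref)
            scored.append((100.0 * matches / overlap, amp.name, off, orient))
    scored.sort(key=lambda t: -t[0])
    best = scored[0]
    if best[0] < min_identity:
        return Assignment(None, best[0], reason=R_LOW_IDENTITY)
    runners = [s for s in scored[1:]
               if s[1] != best[1] and abs(s[0] - best[0]) < 1e-9]
    if runners:
        return Assignment(None, best[0], reason=R_AMBIGUOUS)
    return Assignment(best[1], best[0], offset=best[2], orientation=best[3])


# ---------------------------------------------------------------------------
# per-read calling

def call_cpgs(seq: str, amplicon: AmpliconDef, offset: int = 0) -> str:
    """Call each amplicon CpG from an oriented, aligned read.

    CG -> methylated, TG -> unmethylated, other dinucleotide -> ambiguous,
    CpG outside the read span -> absent. ``offset`` is the reference
    position aligned to read base 0.
    """
    calls = []
    for o in amplicon.cpg_offsets:
        i = o - offset
        if i < 0 or i + 1 >= len(seq):
            calls.append(ABSENT)
            continue
        dinuc = seq[i:i + 2]
        if dinuc == "CG":
            calls.append(METHYLATED)
        elif dinuc == "TG":
            calls.append(UNMETHYLATED)
        else:
            calls.append(AMBIGUOUS)
    return "".join(calls)


def conversion_rate(seq: str, amplicon: AmpliconDef,
                    offset: int = 0) -> float | None:
    """Fraction of covered non-CpG reference cytosines read as T.

    Returns None when the read covers no such position (e.g. an amplicon
    without non-CpG cytosines); the conversion filter then passes by
    default.
    """
    covered = 0
    converted = 0
    for o in amplicon.non_cpg_c_offsets:
        i = o - offset
        if 0 <= i < len(seq):
            covered += 1
            if seq[i] == "T":
                converted += 1
    if covered == 0:
        return None
    return converted / covered


def classify_molecule(cpg_calls: str, rule: str = STRICT,
                      exempt_cpgs: Sequence[int] = ()) -> bool:
    """Is this molecule fully unmethylated under the marker's rule?

    Ambiguous or absent calls never count as fully unmethylated. Under
    ``allow_one_exception`` at most one CpG may read methylated, and when
    exempt indices are listed the deviation must be at a listed index.
    """
    if AMBIGUOUS in cpg_calls or ABSENT in cpg_calls:
        return False
    deviations = [i for i, c in enumerate(cpg_calls) if c != UNMETHYLATED]
    if rule == STRICT:
        return not deviations
    if rule == ALLOW_ONE:
        if len(deviations) > 1:
            return False
        if deviations and exempt_cpgs:
            return deviations[0] in exempt_cpgs
        return True
    raise ValueError(f"unknown unmeth_rule {rule!r}")


# ---------------------------------------------------------------------------
# sample-level tally (vectorized)

def read_fastq(path: str | Path) -> list[ReadRecord]:
    """Load a FASTQ (optionally gzipped) into ReadRecords."""
    from Bio import SeqIO

    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        return [
            ReadRecord(rec.id, str(rec.seq).upper(),
                       tuple(rec.letter_annotations["phred_quality"]))
            for rec in SeqIO.parse(fh, "fastq")
        ]


def write_fastq(reads: Iterable[ReadRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            qual = "".join(chr(q + 33) for q in r.quals)
            fh.write(f"@{r.id}\n{r.seq}\n+\n{qual}\n")


@dataclass
class TallyResult:
    counts: dict[str, MarkerCount]
    assessments: list[ReadAssessment]
    filter_tally: dict[str, int] = field(default_factory=dict)

    @property
    def sample_mean_conversion(self) -> float | None:
        rates = [a.conversion_rate for a in self.assessments
                 if a.retained and a.conversion_rate is not None]
        return float(np.mean(rates)) if rates else None


def _batch_assign(seqs: list[str], panel: Panel,
                  min_identity: float) -> list[Assignment]:
    """Vectorized equivalent of assign_read over many reads."""
    n = len(seqs)
    refs = {a.name: _encode(bisulfite_reference(a)) for a in panel}
    out: list[Assignment | None] = [None] * n

    by_len: dict[int, list[int]] = {}
    for i, s in enumerate(seqs):
        by_len.setdefault(len(s), []).append(i)

    for lr, idxs in by_len.items():
        blob = "".join(seqs[i] for i in idxs).encode("ascii")
        fwd = np.frombuffer(blob, dtype=np.uint8).reshape(len(idxs), lr)
        rev = _COMP_TABLE[fwd[:, ::-1]]
        m = len(idxs)
        best_ident = np.full(m, -1.0)
        second_ident = np.full(m, -1.0)
        best_marker = np.full(m, -1, dtype=int)
        best_off = np.zeros(m, dtype=int)
        best_orient = np.zeros(m, dtype=int)  # 0 = '+', 1 = '-'
        names = [a.name for a in panel]
        for mi, amp in enumerate(panel):
            ref = refs[amp.name]
            ident_marker = np.full(m, -1.0)
            off_marker = np.zeros(m, dtype=int)
            orient_marker = np.zeros(m, dtype=int)
            for oi, mat in ((0, fwd), (1, rev)):
                for off in _offsets(lr, ref.shape[0]):
                    counts, ov = _match_counts(mat, ref, off)
                    ident = 100.0 * counts / ov
                    upd = ident > ident_marker
                    ident_marker[upd] = ident[upd]
                    off_marker[upd] = off
                    orient_marker[upd] = oi
            upd = ident_marker > best_ident
            second_ident[upd] = best_ident[upd]
            tie = ~upd & (ident_marker > second_ident)
            second_ident[tie] = ident_marker[tie]
            best_ident[upd] = ident_marker[upd]
            best_marker[upd] = mi
            best_off[upd] = off_marker[upd]
            best_orient[upd] = orient_marker[upd]
        for j, i in enumerate(idxs):
            if best_ident[j] < min_identity:
                out[i] = Assignment(None, float(best_ident[j]),
                                    reason=R_LOW_IDENTITY)
            elif abs(best_ident[j] - second_ident[j]) < 1e-9:
                out[i] = Assignment(None, float(best_ident[j]),
                                    reason=R_AMBIGUOUS)
            else:
                out[i] = Assignment(names[best_marker[j]],
                                    float(best_ident[j]),
                                    offset=int(best_off[j]),
                                    orientation="+-"[best_orient[j]])
    return out  # type: ignore[return-value]


def tally_sample(reads: Iterable[ReadRecord] | str | Path, panel: Panel,
                 config: ReadFilterConfig = ReadFilterConfig(),
                 ) -> TallyResult:
    """Filter, assign and call every read; tally per-marker fractions.

    Every input read lands in exactly one category (retained or a single
    reject reason). Fractions are computed over retained reads only.
    """
    if isinstance(reads, (str, Path)):
        reads = read_fastq(reads)
    reads = list(reads)

    counts = {a.name: MarkerCount(a.name, a.cell_type) for a in panel}
    tally = {r: 0 for r in (R_NONE,) + REJECT_REASONS}
    assessments: list[ReadAssessment] = []

    mean_quals = [r.mean_quality for r in reads]
    pass_q = [q >= config.min_mean_quality for q in mean_quals]
    to_assign = [i for i, ok in enumerate(pass_q) if ok]
    assigns = _batch_assign([reads[i].seq for i in to_assign], panel,
                            config.min_identity)
    assign_of = dict(zip(to_assign, assigns))

    for i, read in enumerate(reads):
        if not pass_q[i]:
            tally[R_LOW_QUALITY] += 1
            assessments.append(ReadAssessment(
                read.id, None, 0.0, mean_quals[i], "", None, False,
                R_LOW_QUALITY))
            continue
        asg = assign_of[i]
        if asg.marker is None:
            tally[asg.reason] += 1
            assessments.append(ReadAssessment(
                read.id, None, asg.identity, mean_quals[i], "", None,
                False, asg.reason))
            continue
        amp = panel.get(asg.marker)
        mc = counts[asg.marker]
        mc.n_total_assigned += 1
        seq = read.seq if asg.orientation == "+" else revcomp(read.seq)
        calls = call_cpgs(seq, amp, asg.offset)
        conv = conversion_rate(seq, amp, asg.offset)
        reason = R_NONE
        if config.require_all_cpgs and ABSENT in calls:
            reason = R_MISSING_CPGS
        elif calls.count(AMBIGUOUS) > 1:
            reason = R_MISSING_CPGS
        elif conv is not None and conv < config.min_conversion:
            reason = R_POOR_CONVERSION
        retained = reason == R_NONE
        fully = False
        if retained:
            mc.n_retained += 1
            if conv is not None:
                mc._conv_sum += conv
                mc._conv_n += 1
            fully = classify_molecule(calls, amp.unmeth_rule, amp.exempt_cpgs)
            if fully:
                mc.n_fully_unmethylated += 1
        tally[reason] += 1
        assessments.append(ReadAssessment(
            read.id, asg.marker, asg.identity, mean_quals[i], calls, conv,
            retained, reason, fully))

    return TallyResult(counts=counts, assessments=assessments,
                       filter_tally=tally)


def counts_to_frame(counts: dict[str, MarkerCount]):
    import pandas as pd

    return pd.DataFrame([
        {"marker": c.marker, "cell_type": c.cell_type,
         "n_total": c.n_total_assigned, "n_retained": c.n_retained,
         "n_fully_unmeth": c.n_fully_unmethylated,
         "fraction": c.fraction, "mean_conversion": c.mean_conversion_rate}
        for c in counts.values()
    ])
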