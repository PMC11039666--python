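"""Readers and writers for the genomic text formats the pipeline consumes.

All coordinates held in memory are 0-based, half-open (the BED convention).
Inputs that are 1-based by convention (GWAS SNP tables) are converted exactly
once, at read time, under an explicit flag.

Formats covered: BED3/BED6, ENCODE narrowPeak (10 columns), bedGraph, a
gene/TSS annotation TSV, a SNP TSV, JASPAR-format position frequency
matrices, FASTA and plain TSV matrices (expression, totals).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pyfaidx

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}


class FormatError(ValueError):
    """A malformed record in one of the supported text formats."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based, half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass(frozen=True)
class Peak:
    """One called peak from one sample, with its signal density."""

    interval: GenomicInterval
    sample_id: str = ""
    signal: float = 0.0
    name: str = ""

    def __post_init__(self) -> None:
        if self.signal < 0:
            raise ValueError(f"peak signal must be >= 0, got {self.signal}")


@dataclass(frozen=True)
class GeneRecord:
    """A gene anchored at its TSS (a width-1 interval), with a TF flag."""

    gene_id: str
    symbol: str
    tss: GenomicInterval
    is_tf: bool = False

    def __post_init__(self) -> None:
        if self.tss.length != 1:
            raise ValueError(f"TSS of {self.gene_id} must have width 1")


@dataclass(frozen=True)
class SnpRecord:
    """A GWAS SNP: a width-1 position plus its association statistics.

    p-value and odds ratio are input metadata carried through verbatim;
    they are never recomputed.
    """

    rsid: str
    position: GenomicInterval
    p_value: float
    odds_ratio: float
    alleles: str = ""

    def __post_init__(self) -> None:
        if self.position.length != 1:
            raise ValueError(f"SNP {self.rsid} position must have width 1")
        if not (0 < self.p_value <= 1):
            raise ValueError(f"SNP {self.rsid} p-value must lie in (0, 1]")
        if self.odds_ratio <= 0:
            raise ValueError(f"SNP {self.rsid} odds ratio must be positive")


@dataclass(frozen=True)
class PWM:
    """A position weight matrix stored as per-position base probabilities.

    ``matrix`` is L x 4 over the base order A, C, G, T; rows sum to 1.
    ``background`` is the 4-vector of background base frequencies.
    """

    name: str
    matrix: np.ndarray
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        bg = np.asarray(self.background, dtype=float)
        if m.ndim != 2 or m.shape[1] != 4 or m.shape[0] < 4:
            raise ValueError(f"PWM {self.name}: matrix must be Lx4 with L >= 4")
        if not np.allclose(m.sum(axis=1), 1.0):
            raise ValueError(f"PWM {self.name}: probability rows must sum to 1")
        if not np.isclose(bg.sum(), 1.0):
            raise ValueError(f"PWM {self.name}: background must sum to 1")
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "background", bg)

    @classmethod
    def from_counts(
        cls,
        name: str,
        counts: np.ndarray,
        pseudocount: float = 0.01,
        background: Sequence[float] | None = None,
    ) -> "PWM":
        """Normalize an L x 4 count matrix to probabilities."""
        c = np.asarray(counts, dtype=float) + pseudocount
        probs = c / c.sum(axis=1, keepdims=True)
        bg = np.full(4, 0.25) if background is None else np.asarray(background)
        return cls(name=name, matrix=probs, background=bg)

    def __len__(self) -> int:
        return self.matrix.shape[0]

    def log_odds(self) -> np.ndarray:
        """L x 4 log2(p/background); zero probabilities map to -inf."""
        with np.errstate(divide="ignore"):
            return np.log2(self.matrix) - np.log2(self.background)

    @property
    def max_score(self) -> float:
        return float(self.log_odds().max(axis=1).sum())

    @property
    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.matrix.argmax(axis=1))


# ---------------------------------------------------------------------------
# Interval formats: BED / narrowPeak
# ---------------------------------------------------------------------------


def _parse_interval_fields(fields: list[str], path: str, lineno: int) -> tuple:
    try:
        chrom, start, end = fields[0], int(fields[1]), int(fields[2])
    except (ValueError, IndexError) as exc:
        raise FormatError(f"{path}, line {lineno}: malformed record ({exc})") from None
    if start >= end:
        raise FormatError(f"{path}, line {lineno}: start >= end ({start} >= {end})")
    return chrom, start, end


def read_intervals(path: str | Path, format: str = "bed", sample_id: str = "") -> list[Peak]:
    """Read a BED (>= 3 columns) or 10-column narrowPeak file into peaks.

    For narrowPeak, column 7 (signalValue) populates ``Peak.signal``; for
    BED, column 5 (score) is used when present, otherwise the signal is 0.
    """
    fmt = format.lower()
    if fmt not in ("bed", "narrowpeak"):
        raise ValueError(f"unknown interval format {format!r}")
    peaks: list[Peak] = []
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            chrom, start, end = _parse_interval_fields(fields, str(path), lineno)
            name, strand, signal = "", ".", 0.0
            if fmt == "narrowpeak":
                if len(fields) != 10:
                    raise FormatError(
                        f"{path}, line {lineno}: narrowPeak requires 10 columns, "
                        f"got {len(fields)}"
                    )
                name = fields[3]
                strand = fields[5] if fields[5] in ("+", "-", ".") else "."
                try:
                    signal = float(fields[6])
                except ValueError:
                    raise FormatError(
                        f"{path}, line {lineno}: bad signalValue {fields[6]!r}"
                    ) from None
            else:
                if len(fields) >= 4:
                    name = fields[3]
                if len(fields) >= 5 and fields[4] not in (".", ""):
                    try:
                        signal = float(fields[4])
                    except ValueError:
                        raise FormatError(
                            f"{path}, line {lineno}: bad score {fields[4]!r}"
                        ) from None
                if len(fields) >= 6 and fields[5] in ("+", "-", "."):
                    strand = fields[5]
            peaks.append(
                Peak(
                    interval=GenomicInterval(chrom, start, end, strand),
                    sample_id=sample_id,
                    signal=signal,
                    name=name,
                )
            )
    return peaks


def write_intervals(peaks: Iterable[Peak], path: str | Path, format: str = "bed") -> None:
    """Write peaks as BED6 or 10-column narrowPeak (signal -> signalValue)."""
    fmt = format.lower()
    if fmt not in ("bed", "narrowpeak"):
        raise ValueError(f"unknown interval format {format!r}")
    with open(path, "w") as fh:
        for p in peaks:
            iv = p.interval
            if fmt == "narrowpeak":
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{p.name or '.'}\t0\t"
                    f"{iv.strand}\t{p.signal:.10g}\t-1\t-1\t-1\n"
                )
            else:
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{p.name or '.'}\t"
                    f"{p.signal:.10g}\t{iv.strand}\n"
                )


# ---------------------------------------------------------------------------
# bedGraph coverage
# ---------------------------------------------------------------------------


class CoverageMap:
    """Per-chromosome step-function coverage from a bedGraph.

    ``query`` returns the sum of value x overlap-length over covered bases;
    bases outside any record contribute 0.
    """

    def __init__(self, records: Mapping[str, tuple[np.ndarray, np.ndarray, np.ndarray]]):
        # records: chrom -> (starts, ends, values), sorted by start, non-overlapping
        self._records = dict(records)

    @classmethod
    def from_records(
        cls, rows: Iterable[tuple[str, int, int, float]], source: str = "<records>"
    ) -> "CoverageMap":
        by_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, value in rows:
            by_chrom.setdefault(chrom, []).append((start, end, value))
        out: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, recs in by_chrom.items():
            recs.sort()
            starts = np.array([r[0] for r in recs], dtype=np.int64)
            ends = np.array([r[1] for r in recs], dtype=np.int64)
            values = np.array([r[2] for r in recs], dtype=float)
            if np.any(starts[1:] < ends[:-1]):
                bad = int(np.argmax(starts[1:] < ends[:-1]))
                raise FormatError(
                    f"{source}: overlapping bedGraph records on {chrom} near "
                    f"{int(starts[bad + 1])}"
                )
            out[chrom] = (starts, ends, values)
        return cls(out)

    def query(self, interval: GenomicInterval) -> float:
        """Sum of value x overlap-length over the interval."""
        rec = self._records.get(interval.chrom)
        if rec is None:
            return 0.0
        starts, ends, values = rec
        i0 = int(np.searchsorted(ends, interval.start, side="right"))
        i1 = int(np.searchsorted(starts, interval.end, side="left"))
        if i0 >= i1:
            return 0.0
        ov = np.minimum(ends[i0:i1], interval.end) - np.maximum(
            starts[i0:i1], interval.start
        )
        return float(np.dot(np.clip(ov, 0, None), values[i0:i1]))

    @property
    def chroms(self) -> list[str]:
        return sorted(self._records)

    def records(self) -> Iterable[tuple[str, int, int, float]]:
        for chrom in sorted(self._records):
            starts, ends, values = self._records[chrom]
            for s, e, v in zip(starts, ends, values):
                yield chrom, int(s), int(e), float(v)


def read_coverage(path: str | Path) -> CoverageMap:
    """Read a bedGraph into a queryable coverage map."""
    rows: list[tuple[str, int, int, float]] = []
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(f"{path}, line {lineno}: bedGraph requires 4 columns")
            chrom, start, end = _parse_interval_fields(fields, str(path), lineno)
            try:
                value = float(fields[3])
            except ValueError:
                raise FormatError(
                    f"{path}, line {lineno}: bad coverage value {fields[3]!r}"
                ) from None
            rows.append((chrom, start, end, value))
    return CoverageMap.from_records(rows, source=str(path))


def write_coverage(rows: Iterable[tuple[str, int, int, float]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, value in rows:
            fh.write(f"{chrom}\t{start}\t{end}\t{value:.10g}\n")


# ---------------------------------------------------------------------------
# Gene, SNP, expression and totals tables
# ---------------------------------------------------------------------------

GENE_COLUMNS = ["gene_id", "symbol", "chrom", "tss_pos", "strand", "is_tf"]


def read_gene_table(path: str | Path) -> list[GeneRecord]:
    """Read the gene/TSS annotation TSV (tss_pos is 0-based)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(GENE_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: gene table missing columns {sorted(missing)}")
    genes = []
    seen: set[str] = set()
    for row in df.itertuples(index=False):
        if row.gene_id in seen:
            raise FormatError(f"{path}: duplicate gene_id {row.gene_id}")
        seen.add(row.gene_id)
        tss = GenomicInterval(row.chrom, int(row.tss_pos), int(row.tss_pos) + 1,
                              row.strand if row.strand in ("+", "-") else ".")
        genes.append(
            GeneRecord(gene_id=row.gene_id, symbol=row.symbol, tss=tss,
                       is_tf=bool(row.is_tf))
        )
    return genes


def write_gene_table(genes: Iterable[GeneRecord], path: str | Path) -> None:
    rows = [
        {
            "gene_id": g.gene_id,
            "symbol": g.symbol,
            "chrom": g.tss.chrom,
            "tss_pos": g.tss.start,
            "strand": g.tss.strand,
            "is_tf": int(g.is_tf),
        }
        for g in genes
    ]
    pd.DataFrame(rows, columns=GENE_COLUMNS).to_csv(path, sep="\t", index=False)


SNP_COLUMNS = ["rsid", "chrom", "pos", "p", "OR", "alleles"]


def read_snp_table(path: str | Path, one_based: bool = True) -> list[SnpRecord]:
    """Read the SNP TSV; positions declared 1-based (GWAS convention) are
    converted to 0-based exactly once here."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(SNP_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: SNP table missing columns {sorted(missing)}")
    offset = 1 if one_based else 0
    snps = []
    for row in df.itertuples(index=False):
        pos0 = int(row.pos) - offset
        snps.append(
            SnpRecord(
                rsid=row.rsid,
                position=GenomicInterval(row.chrom, pos0, pos0 + 1),
                p_value=float(row.p),
                odds_ratio=float(getattr(row, "OR")),
                alleles=str(row.alleles),
            )
        )
    return snps


def write_snp_table(snps: Iterable[SnpRecord], path: str | Path, one_based: bool = True) -> None:
    offset = 1 if one_based else 0
    rows = [
        {
            "rsid": s.rsid,
            "chrom": s.position.chrom,
            "pos": s.position.start + offset,
            "p": s.p_value,
            "OR": s.odds_ratio,
            "alleles": s.alleles,
        }
        for s in snps
    ]
    pd.DataFrame(rows, columns=SNP_COLUMNS).to_csv(path, sep="\t", index=False)


def read_expression(path: str | Path) -> pd.DataFrame:
    """Gene x sample matrix of normalized counts (TSV, first column gene_id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        raise FormatError(f"{path}: duplicate gene ids in expression matrix")
    return df


def write_expression(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="gene_id", float_format="%.10g")


def read_totals(path: str | Path) -> dict[str, float]:
    """Per-sample mapped-read totals (TSV: sample_id, total)."""
    df = pd.read_csv(path, sep="\t")
    if not {"sample_id", "total"} <= set(df.columns):
        raise FormatError(f"{path}: totals table requires sample_id and total columns")
    return {str(r.sample_id): float(r.total) for r in df.itertuples(index=False)}


def write_totals(totals: Mapping[str, float], path: str | Path) -> None:
    pd.DataFrame(
        {"sample_id": list(totals), "total": [totals[s] for s in totals]}
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# JASPAR PFMs
# ---------------------------------------------------------------------------


def read_pwm_jaspar(path: str | Path, pseudocount: float = 0.01) -> list[PWM]:
    """Read JASPAR 2016+ text PFMs (">ID NAME" header, rows "A [ 1 2 3 ]").

    Counts are normalized to per-position probabilities with a pseudocount
    added to every cell before normalization.
    """
    pwms: list[PWM] = []
    name = None
    rows: dict[str, list[float]] = {}
    path = Path(path)

    def _flush(lineno: int) -> None:
        nonlocal name, rows
        if name is None:
            return
        if set(rows) != set(_BASES):
            raise FormatError(f"{path}: PWM {name} missing base rows")
        lengths = {len(v) for v in rows.values()}
        if len(lengths) != 1:
            raise FormatError(
                f"{path}, near line {lineno}: PWM {name} has unequal row lengths"
            )
        counts = np.array([rows[b] for b in _BASES]).T  # L x 4
        pwms.append(PWM.from_counts(name, counts, pseudocount=pseudocount))
        name, rows = None, {}

    lineno = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                _flush(lineno)
                header = line[1:].split()
                name = header[1] if len(header) > 1 else header[0]
            else:
                parts = line.replace("[", " ").replace("]", " ").split()
                if not parts or parts[0].upper() not in _BASE_INDEX:
                    raise FormatError(f"{path}, line {lineno}: malformed PFM row")
                base = parts[0].upper()
                try:
                    rows[base] = [float(x) for x in parts[1:]]
                except ValueError:
                    raise FormatError(
                        f"{path}, line {lineno}: non-numeric count in PFM row"
                    ) from None
        _flush(lineno)
    return pwms


def write_pwm_jaspar(pwms_counts: Mapping[str, np.ndarray], path: str | Path) -> None:
    """Write count matrices (name -> L x 4) in JASPAR text format."""
    with open(path, "w") as fh:
        for name, counts in pwms_counts.items():
            c = np.asarray(counts)
            fh.write(f">{name} {name}\n")
            for bi, base in enumerate(_BASES):
                vals = " ".join(f"{v:g}" for v in c[:, bi])
                fh.write(f"{base} [ {vals} ]\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def open_genome(path: str | Path) -> pyfaidx.Fasta:
    """Open a genome FASTA for random access (builds a .fai on first use)."""
    return pyfaidx.Fasta(str(path), as_raw=True, sequence_always_upper=True)


def fetch_sequence(genome, interval: GenomicInterval) -> str:
    """Fetch the sequence of a half-open interval from an open genome."""
    return str(genome[interval.chrom][interval.start : interval.end])


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def reverse_complement(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTNacgtn", "TGCANtgcan"))[::-1]
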